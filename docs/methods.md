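# Methods

This note documents the models, the numerical choices, and what the
synthetic data does and does not emulate. Parameter defaults live in
`atacatlas.params.PipelineParams` and `atacatlas.synthetic.SimConfig`.

## Fragment model and processing

The pipeline's atomic input is a paired-end *fragment*: 0-based half-open
coordinates, mapping quality, SAM-style flag bits and insert length. The
read-level filter removes records with any of the flag bits
4/8/256/512/1024 (unmapped, mate-unmapped, secondary, QC-fail, duplicate —
the `-F 1804` set without the proper-pair bit) plus mitochondrial records;
no mapping-quality cutoff is applied by default because the filter is
flag-based (a `min_mapq` knob exists). Positional deduplication keys on
(chrom, start, end) without strand — fragments are unstranded after
pairing. The Tn5 correction moves the fragment to (start+4, end−5),
equivalent to shifting each read's 5′ cut site, so a surviving fragment is
exactly 9 bp shorter (the transposase-dimer gap); fragments of ≤ 9 bp
collapse to empty intervals and are dropped. A marker on the frame makes
the shift idempotent, so re-running filter→dedup→shift on its own output
is a no-op.

Insert-size QC reports the exact integer histogram plus modes detected on
a 21-bp moving average with 2% relative prominence — enough smoothing to
merge counting noise without displacing a nucleosomal mode by more than a
few bp.

## Peak calling

A simplified, fully specified equivalent of MACS-style calling, not a
re-implementation of any published caller. Coverage at base resolution is
tested against λ_local = max(λ_BG, mean coverage in centered 1-kb, 5-kb
and 10-kb windows), with λ_BG = total coverage / effective (non-blacklist)
genome length and edge-truncated windows. Candidate regions are maximal
runs of bases with Poisson upper-tail p < 1e−5, bridged across gaps ≤ 75 bp
and kept at ≥ 100 bp; the peak p-value is the run's best per-base p,
computed with `poisson.logsf` so extreme peaks retain distinct, finite
−log10 p scores rather than underflowing to zero. BH correction is applied
across candidate peaks (not bases) and peaks with q below the threshold
(0.01 accessibility, 0.05 ChIP) are kept; any ≥ 1 bp overlap with a
blacklist interval removes a peak entirely. A conservative screen
(coverage < λ + 2√λ + 1 implies p ≳ 1e−2) skips the exact tail computation
on the vast non-candidate majority of positions.

Because the local lambda is computed from the treatment itself, a peak
inflates its own background: a 500-bp region at enrichment e over rate λ
faces λ_local ≈ (0.5e + 0.5)λ in the 1-kb window, so detection needs
roughly e ≥ 8 at λ ≥ 8/bp. The default synthetic depth is chosen so
planted regions sit comfortably above this boundary (below).

The ChIP comparison track is the signed Poisson log-likelihood ratio
`sign(t−c)·|t·ln(t/c) − (t−c)|/ln 10` on RPM-scaled bins plus a
pseudocount. This is a KL-type divergence of the observed (treatment) rate
from the control rate: swapping the tracks flips every bin's sign but not,
in general, its magnitude.

## Reproducibility (IDR)

Peaks of a replicate pair are matched greedily by largest overlap
(leftmost on ties, each peak used once). Matched scores — the caller's
−log10 p; only their ranks matter — are mapped through average ranks to
uniform quantiles with an (n+1) denominator and modelled as a
two-component bivariate Gaussian copula mixture: reproducible
N((μ,μ), σ², ρ) with weight π1 against independent standard-normal noise.
Estimation alternates one EM step with a pseudo-data update in which the
normal scores are recomputed through the inverse CDF of the current
marginal mixture; convergence at max parameter change < 1e−6 or 500
updates (non-convergence is flagged and the best estimate returned — the
usual outcome on null-like input, where the mixture is unidentified but
every local idr is large, so nothing passes the threshold).

Two numerical constraints matter in practice. The reproducible component's
variance is **fixed at the noise scale (σ² = 1)**: with σ² free, the rank
transform lets EM manufacture likelihood by compressing pseudo-data into a
shrinking component, and small peak sets (≲ 100 pairs) reliably find this
degenerate optimum. ρ is constrained to [0, 0.999] — the reproducible
component is positively correlated by construction. Three deterministic
starting points are run and the best pseudo-likelihood wins. On data drawn
from the model itself (π1 = 0.7, μ = 2.5, σ² = 1, ρ = 0.95, n = 10,000)
the fit recovers π1 within ±0.01 and ρ within ±0.01.

Per pair, the local idr is the posterior noise probability; the global IDR
is the running mean of sorted local idr values. A peak passes within its
sample group if any replicate pair containing it reaches IDR < 0.005 (a
per-peak OR over pairs — the literal reading of "at least one pair");
passing footprints (union of the two matched peaks) are merged within the
group. The atlas is the union over groups, merging overlapping *and
bookended* intervals, with ids assigned in genomic order and per-interval
group provenance.

IDR scores use −log10 p rather than −log10 q: BH q-values are running
minima, so the strongest peaks tie exactly and the tied rank mass
destabilises the copula fit; the p-ranking strictly refines the q-ranking.

## Gene assignment

Priority rule 1: genes whose transcribed region extended by 2 kb on both
sides (half-open interval arithmetic) intersects the peak; among several,
smallest |center − TSS| wins, then smallest |center − 3′ end|, then
lexicographic gene id. Rule 2 (no rule-1 candidate): minimize
min(|center − TSS|, |center − 3′|) over all genes on the chromosome, same
tie-breaks. Peak center = floor((start+end)/2); the reported distance is
signed in gene orientation (negative = upstream of the TSS). Features:
promoter if the center is within 5 kb of the TSS (two-sided — the
one-sidedness is not determined by the rule set, and two-sided matches the
center-based distance metric), else exon / intron by center containment,
else upstream/downstream within the 2-kb flank by gene orientation, else
distal. A peak on a chromosome without genes yields an explicit unassigned
record.

## Differential accessibility

Counts are ≥ 1 bp fragment–interval overlaps (a fragment spanning the gap
between two atlas intervals increments both). Size factors are plain
median-of-ratios: geometric means over rows with all-positive counts,
factor_j = median_i(count_ij / g_i), not rescaled afterwards.

Dispersion: per-peak method of moments on normalized counts with the
variance pooled within groups, α̂ = (s² − ȳ)/ȳ²; a trend α(μ) = a₀ + a₁/μ
fitted across peaks by a Huber M-estimator (rows at the floor excluded);
the final dispersion is the equal-weight log-scale average of the
per-peak estimate and the trend. The per-peak moment estimate is **floored
at the trend value** before averaging: with a handful of replicates a peak
cannot carry usable evidence of sub-trend dispersion, and letting a
negative moment estimate collapse to a near-zero dispersion turns the Wald
test into a near-Poisson one (measured type-I error ≈ 0.09 at nominal
0.05); with the floor the measured type-I error is 0.035–0.046 on 5,000
null NB peaks at 3 vs 3, μ = 100, α = 0.05, and the power on planted
8-fold peaks through the FDR < 0.05, FC > 4 gate is ≈ 100%. This scheme is
a simplified, testable stand-in for the full Cox–Reid/MAP machinery of
count-model packages; it is deliberately mildly conservative.

The GLM is a per-peak two-group NB regression with log link and log size
factors as offsets, fitted by vectorized IRLS (closed-form 2×2 solves
across all peaks simultaneously); Wald z = β̂/SE with a two-sided normal
p; BH across peaks with positive base mean; all-zero peaks are reported
with null statistics and excluded from the BH denominator. The
fold-change gate applies to the unshrunk GLM estimate: q < FDR and
|log2FC| > log2(FC).

PCA: log2(normalized + 1), top 500 peaks by variance, per-peak centering,
SVD; sample scores and variance fractions are reported, with component
signs fixed deterministically (largest-magnitude loading positive) so
outputs are byte-stable.

## Coverage tracks and signatures

Tracks count fragment overlaps in 10-bp bins anchored at coordinate 0,
scaled to RPM (1e6 / library fragments); blacklist-intersecting bins are
zeroed and flagged. Group tracks are the bin-wise arithmetic *mean* of the
replicates' RPM tracks — the combine function is not dictated by the
union-then-merge description, and the mean keeps groups with different
replicate counts comparable. The signal matrix takes, per atlas peak, the
200 bins covering [center − 1 kb, center + 1 kb); no strand flipping
(peaks are unstranded); rows running past a chromosome edge are
zero-padded and flagged. K-means (Euclidean, k-means++ init, 10 restarts,
fixed seed) clusters rows of the concatenated per-group blocks, with
labels renumbered by decreasing cluster mean so output is deterministic.
Display capping uses T = Q75 + 1.5×IQR of all entries under type-7
(linear-interpolation) quantiles — on {1,2,3,4,100}, T = 7; capping never
feeds back into clustering or statistics.

## Synthetic experiment

The generator emulates the statistical structure the pipeline assumes, on
a toy genome of two 5-Mb autosomes plus a 16-kb mitochondrial chromosome —
large enough for 10-kb local-lambda windows, small enough for
seconds-scale runs. It plants:

- 200 non-overlapping genes (2–8 kb, ≥ 4-kb gaps, 1–3 exons, random
  strand) and 5 intergenic blacklist intervals kept ≥ 2.5 kb from genes;
- 120 open 500-bp regions, each within ±2 kb of its linked gene (so
  assignment truth is known): 40% shared across all groups, the rest split
  between lineage A ("T_FH-like") and lineage B ("T_H1-like"), with
  lineage-specific openness scaled by a per-timepoint gradient (1, 2, 4 —
  a doubling per sampled timepoint, a graded chromatin-remodelling
  program) and a per-region strength multiplier, log-uniform on [0.5, 3].
  The strength term matters: real peak intensities span orders of
  magnitude, and the rank-based IDR step is uninformative if all planted
  regions have identical rates (matched ranks would be pure Poisson
  noise);
- per replicate, 600,000 fragments: midpoints from a background-uniform
  plus open-region-enriched mixture (enrichment 10× by default; the
  background rate this depth implies, ≈ 7/bp, keeps a 10× region safely
  above the caller's self-inflated local lambda), insert lengths from the
  mixture 0.55·N(60,15) + 0.35·N(200,35) + 0.10·N(400,45) truncated at
  10 bp (sub-nucleosomal/mono/di-nucleosomal periodicity), 5% exact
  positional duplicates, 5% mitochondrial records, 3% flag-failing
  records, and a replicate-discordant fraction (10%) of open regions
  present in only one replicate, to exercise the reproducibility filter.

All randomness derives from one seed through fixed stream keys
((seed, 0) annotation, (seed, 1) truth, (seed, 3, group) discordance,
(seed, 2, group, replicate) fragments), so any replicate can be
regenerated independently and runs are byte-reproducible.

Not emulated: read sequences (no FASTQ), alignment or GC bias, Tn5
sequence preference, footprint structure, chromatin-state autocorrelation
beyond the planted intervals, and realistic genome scale. Passing tests
therefore demonstrate the correctness and calibration of each algorithm
under its own model assumptions — not performance on real libraries,
where peak shapes, covariate structure and score distributions are less
clean.

## Problem sizes in the checks

The validation suite and `scripts/acceptance.py` run at desk scale chosen
for signal, not realism: caller fidelity on one 5-Mb chromosome with 100
regions at exactly 8× (strength pinned to 1, the stated condition);
IDR recovery on 10,000 model draws and a 5,000-pair permuted null;
differential calibration on 5,000 null NB peaks at 3 vs 3; PCA structure
on ten seeded two-lineage × three-timepoint experiments at 150,000
fragments per replicate (two replicates per group); the end-to-end run on
the day-8 contrast at default depth. The CLI determinism check uses a
2-Mb genome at 200,000 fragments so two full pipeline runs complete in
seconds.

## Known limitations

- The peak caller is treatment-only; there is no paired-control mode, no
  fragment-length model and no broad-peak mode.
- The IDR fit pins σ² = 1; data whose reproducible component has a very
  different marginal spread is absorbed into μ and ρ through the rank
  transform, which preserves the pass/fail ordering but not the literal
  component variance.
- IDR < 0.005 is stringent by design: when replicate score ranks are only
  weakly correlated (e.g. many peaks of near-identical strength), few
  pairs pass — the correct reading of irreproducibility, but it shrinks
  the atlas on low-heterogeneity data.
- The dispersion estimator never goes below the fitted trend, which
  slightly under-rejects when true dispersions genuinely scatter below
  it.
- One transcript model per gene; no isoform, UTR or CpG categories.
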