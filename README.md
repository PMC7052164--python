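# atacatlas

A desk-scale, fully tested re-implementation of the ATAC-seq differential
chromatin-accessibility analysis used to contrast virus-specific T
follicular helper (T_FH) and type-1 helper (T_H1) CD4+ T cells: from
aligned paired-end fragment records through Tn5 cut-site shifting, peak
calling, IDR reproducibility filtering, atlas construction, priority-rule
gene assignment, negative-binomial differential testing, PCA of sample
chromatin states, and K-means signature heatmaps. A synthetic-experiment
generator with planted lineage-specific accessibility programs stands in
for deposited sequencing data, so every stage is testable end to end with
known ground truth.

It is aimed at readers who want to understand, check or adapt each step of
such a pipeline with transparent, fully specified code — not at production
processing of full-scale sequencing runs.

## The analysis

Given per-replicate fragment records for several sample groups (e.g. naive,
T_FH day 2/5/8, T_H1 day 2/5/8):

1. **Fragment processing.** Drop records with any of the SAM flags
   {unmapped, mate-unmapped, secondary, QC-fail, duplicate} (the `-F 1804`
   screen) and mitochondrial fragments; remove positional PCR duplicates by
   the (chrom, start, end) key; shift each fragment to
   (start+4, end−5) so coordinates mark Tn5 insertion centers (the dimer
   inserts two adaptors 9 bp apart); QC the insert-size histogram for
   sub-nucleosomal / mono- / di-nucleosomal periodicity.
2. **Peak calling.** Test base-resolution coverage against a local Poisson
   background λ_local = max(λ_genome, mean coverage in centered 1/5/10-kb
   windows); merge significant runs (per-base p < 1e−5, gaps ≤ 75 bp,
   length ≥ 100 bp); Benjamini–Hochberg over candidate peaks, keep q < 0.01
   (0.05 for ChIP); remove peaks touching blacklist intervals. A signed
   Poisson log-likelihood-ratio track compares ChIP samples.
3. **Reproducibility (IDR).** Match peaks across replicate pairs by largest
   overlap, rank the peak scores, and fit a two-component Gaussian copula
   mixture — reproducible N((μ,μ), σ², ρ) versus independent noise
   N(0, I) — by an EM whose normal-score pseudo-data are refreshed from the
   current marginal mixture CDF. A peak is kept if its pair reaches global
   IDR < 0.005 in at least one replicate pair of its group.
4. **Atlas & annotation.** Merge reproducible peaks of all groups
   (bookended intervals included) into an atlas with stable ids; assign
   each atlas peak to exactly one gene — first to any gene whose ±2-kb
   extended transcribed region it touches (nearest TSS wins), otherwise to
   the gene minimizing center-to-TSS/3′ distance — and classify features
   with promoter (center within 5 kb of the TSS) > exon > intron > flank >
   distal.
5. **Differential accessibility.** Count fragments per atlas peak and
   sample; normalize by median-of-ratios size factors; per-peak NB
   dispersion by method of moments shrunk toward an a₀+a₁/μ trend; two-group
   NB GLM (log link, IRLS) Wald test; gates FDR < 0.05 with fold change > 4
   (lineage contrasts) or > 1.5 (perturbation contrasts). PCA runs on
   log2(normalized+1) over the 500 most variable peaks.
6. **Signatures.** 10-bp RPM coverage tracks with blacklist masking, pooled
   per group; ±1-kb peak-centered signal matrices (200 bins per row);
   K-means signature clusters; display capping at Q75 + 1.5×IQR (analysis
   always uses uncapped values).

## Worked example

```python
import atacatlas as aa

cfg = aa.SimConfig(seed=11,
                   groups=[aa.GroupSpec("TFH_d8", 2, "A", 2),
                           aa.GroupSpec("TH1_d8", 2, "B", 2)])
sizes, (genes, exons), blacklist, truth, frags = aa.simulate_experiment(cfg)

shifted, group_peaks = {}, {}
effective = sum(sizes.values()) - int((blacklist.end - blacklist.start).sum())
for group in cfg.groups:
    peak_sets = []
    for rep in range(group.n_replicates):
        kept, _ = aa.filter_fragments(frags[(group.label, rep)])
        kept, _ = aa.deduplicate(kept)
        sh, _ = aa.tn5_shift(kept)
        shifted[f"{group.label}_rep{rep}"] = sh
        peaks = aa.call_peaks(aa.build_pileup(sh, sizes),
                              q_threshold=0.01, effective_length=effective)
        peak_sets.append(aa.subtract_blacklist(peaks, blacklist))
    group_peaks[group.label] = aa.reproducible_peaks(peak_sets)
    print(f"{group.label}: {len(peak_sets[0])} peaks in rep0, "
          f"{len(group_peaks[group.label])} reproducible (IDR<0.005)")

atlas = aa.build_atlas(group_peaks)
print(f"atlas: {len(atlas.intervals)} accessible regions")
assignments = aa.assign_peaks(atlas.intervals, genes, exons)
print("features:", assignments["feature"].value_counts().to_dict())

am = aa.count_matrix(atlas.intervals, shifted)
am.size_factors = aa.estimate_size_factors(am.counts)
labels = [c.rsplit("_rep", 1)[0] for c in am.counts.columns]
res = aa.nb_wald_test(am, labels, "TFH_d8", "TH1_d8")
sel = aa.select_differential(res, fdr=0.05, fc=4.0)
print(f"differential peaks (FDR<0.05, FC>4): {len(sel)} of {len(res)}; "
      f"up in TH1_d8: {(sel['direction'] == 'up_in_group2').sum()}")
```

prints:

```
TFH_d8: 62 peaks in rep0, 57 reproducible (IDR<0.005)
TH1_d8: 65 peaks in rep0, 62 reproducible (IDR<0.005)
atlas: 98 accessible regions
features: {'promoter': 76, 'downstream': 11, 'exon': 9, 'intron': 2}
differential peaks (FDR<0.05, FC>4): 64 of 98; up in TH1_d8: 34
```

Reading: each day-8 replicate yields ~60 blacklist-filtered peaks at
q < 0.01, of which ~92% survive the IDR < 0.005 filter; merging both
lineages gives a 98-region atlas, dominated by promoter-proximal peaks
(the generator plants regions near genes); 64 regions pass the strict
FDR < 0.05, FC > 4 differential gate between the lineages, split roughly
evenly between T_FH-up and T_H1-up — the planted lineage-specific programs.

The same flow is available as a CLI:

```bash
atacatlas pipeline --config config.yaml --outdir out/
```

which writes fragment BEDs, narrowPeak files, the atlas BED, assignment and
count TSVs, differential results, PCA coordinates, the capped-heatmap
signal matrix and a JSON report; individual stages are exposed as
`simulate`, `filter`, `shift`, `qc-insert`, `callpeaks`, `idr`, `atlas`,
`annotate`, `counts`, `diff`, `pca`, `track`, `heatmap-matrix` and
`chip-compare` subcommands.

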