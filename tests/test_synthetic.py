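"""Generator contracts: determinism, planted structure, marginal rates."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import atacatlas as aa


@pytest.fixture(scope="module")
def config():
    return aa.SimConfig(seed=7, groups=[aa.GroupSpec("TFH_d5", 2, "A", 1),
                                        aa.GroupSpec("TH1_d5", 2, "B", 1)],
                        depth=60_000)


@pytest.fixture(scope="module")
def annotation(config):
    return aa.make_genome_annotation(config)


@pytest.fixture(scope="module")
def truth(config, annotation):
    _, (genes, _), _ = annotation
    return aa.make_truth_program(genes, config)


class TestGenomeAnnotation:
    def test_deterministic_for_fixed_seed(self, config, annotation):
        sizes, (genes, exons), blacklist = annotation
        sizes2, (genes2, exons2), blacklist2 = aa.make_genome_annotation(
            config)
        pd.testing.assert_frame_equal(genes, genes2)
        pd.testing.assert_frame_equal(exons, exons2)
        pd.testing.assert_frame_equal(blacklist, blacklist2)
        assert sizes == sizes2

    def test_zero_genes_rejected(self, config):
        bad = aa.SimConfig(**{**config.to_dict(), "n_genes": 0})
        with pytest.raises(ValueError):
            aa.make_genome_annotation(bad)

    def test_chromosome_too_small(self):
        with pytest.raises(aa.SizingError):
            aa.make_genome_annotation(aa.SimConfig(
                chrom_sizes={"chr1": 50_000, "chrM": 16_000}, n_genes=50))

    def test_gene_geometry(self, annotation):
        """TSS at txStart on +, at txEnd-1 on -; genes non-overlapping;
        every gene has >= 1 exon inside its body."""
        sizes, (genes, exons), _ = annotation
        for gene in genes.itertuples():
            assert gene.start < gene.end <= sizes[gene.chrom]
            if gene.strand == "+":
                assert gene.tss == gene.start and gene.tes == gene.end - 1
            else:
                assert gene.tss == gene.end - 1 and gene.tes == gene.start
        for chrom, sub in genes.groupby("chrom"):
            s = sub.sort_values("start")
            assert (s["start"].to_numpy()[1:]
                    >= s["end"].to_numpy()[:-1]).all()
        counts = exons.groupby("gene_id").size()
        assert set(counts.index) == set(genes["gene_id"])
        merged = exons.merge(genes, on="gene_id", suffixes=("", "_g"))
        assert (merged["start"] >= merged["start_g"]).all()
        assert (merged["end"] <= merged["end_g"]).all()

    def test_blacklist_clear_of_gene_bodies(self, annotation):
        _, (genes, _), blacklist = annotation
        for b in blacklist.itertuples():
            sub = genes[genes["chrom"] == b.chrom]
            assert not ((sub["start"] < b.end) & (sub["end"] > b.start)
                        ).any()


class TestTruthProgram:
    def test_lineage_sets_disjoint_and_gene_linked(self, truth, annotation):
        regions = truth.regions
        assert (regions["label"].isin(["shared", "A", "B"])).all()
        _, (genes, _), _ = annotation
        merged = regions.merge(genes, on="gene_id", suffixes=("", "_g"))
        assert len(merged) == len(regions)
        center = (merged["start"] + merged["end"]) // 2
        near = ((center >= merged["start_g"] - 2_000)
                & (center <= merged["end_g"] + 2_000))
        assert near.all()
        assert regions["gene_id"].is_unique

    def test_shared_fraction_matches_config(self, truth, config):
        n_shared = (truth.regions["label"] == "shared").sum()
        expected = config.shared_fraction * len(truth.regions)
        assert abs(n_shared - expected) <= 1

    def test_flat_gradient_gives_equal_openness(self, annotation):
        cfg = aa.SimConfig(seed=7, timepoint_gradient=(1.0, 1.0, 1.0),
                           groups=[aa.GroupSpec(f"A_d{d}", 2, "A", t)
                                   for t, d in enumerate((2, 5, 8))])
        _, (genes, _), _ = aa.make_genome_annotation(cfg)
        tr = aa.make_truth_program(genes, cfg)
        op = [tr.openness(g) for g in cfg.groups]
        assert np.array_equal(op[0], op[1]) and np.array_equal(op[1], op[2])

    def test_gradient_scales_lineage_regions_only(self, truth, config):
        g_d5 = config.group("TFH_d5")
        op = truth.openness(g_d5)
        lab = truth.regions["label"].to_numpy()
        assert (op[lab == "shared"] == 1.0).all()
        assert (op[lab == "A"] == config.timepoint_gradient[1]).all()
        assert (op[lab == "B"] == 0.0).all()

    def test_empty_genes_rejected(self, config):
        with pytest.raises(ValueError):
            aa.make_truth_program(pd.DataFrame(columns=["gene_id"]), config)


class TestSimulateReplicate:
    def test_exact_depth_and_determinism(self, truth, config):
        f1 = aa.simulate_replicate(truth, "TFH_d5", 0, config)
        f2 = aa.simulate_replicate(truth, "TFH_d5", 0, config)
        assert len(f1) == config.depth
        pd.testing.assert_frame_equal(f1, f2)
        f_other = aa.simulate_replicate(truth, "TFH_d5", 1, config)
        assert not f1[["start", "end"]].equals(f_other[["start", "end"]])

    def test_unknown_group_rejected(self, truth, config):
        with pytest.raises(KeyError):
            aa.simulate_replicate(truth, "nonexistent", 0, config)

    def test_open_fraction_matches_closed_form(self, truth, config):
        frags = aa.simulate_replicate(truth, "TFH_d5", 0, config)
        clean = frags[(frags["flags"] == 0)
                      & (frags["chrom"] != config.mito_name)]
        clean, _ = aa.deduplicate(clean)  # drop coordinate-copy duplicates
        eff = aa.replicate_openness(truth, "TFH_d5", 0, config)
        open_iv = truth.regions[eff > 0]
        mid = ((clean["start"] + clean["end"]) // 2).to_numpy()
        hit = np.zeros(len(clean), dtype=bool)
        for r in open_iv.itertuples():
            hit |= ((clean["chrom"] == r.chrom).to_numpy()
                    & (mid >= r.start) & (mid < r.end))
        p_exp = aa.expected_open_fraction(truth, "TFH_d5", 0, config)
        n = len(clean)
        se = np.sqrt(p_exp * (1 - p_exp) / n)
        assert abs(hit.mean() - p_exp) < 3 * se

    def test_category_rates_within_binomial_ci(self, truth, config):
        frags = aa.simulate_replicate(truth, "TH1_d5", 1, config)
        n = len(frags)
        checks = {
            "mito": ((frags["chrom"] == config.mito_name).sum(),
                     config.mito_rate),
            "unmapped": ((frags["flags"] & 4 != 0).sum(),
                         config.flag_fail_rates["unmapped"]),
            "qcfail": ((frags["flags"] & 512 != 0).sum(),
                       config.flag_fail_rates["qcfail"]),
        }
        for name, (count, rate) in checks.items():
            lo, hi = stats.binom.interval(0.99, n, rate)
            assert lo <= count <= hi, name

    def test_duplicate_records_are_exact_copies(self, truth, config):
        frags = aa.simulate_replicate(truth, "TFH_d5", 0, config)
        _, n_dup = aa.deduplicate(frags)
        n = len(frags)
        lo, hi = stats.binom.interval(0.999, n, config.dup_rate)
        assert lo <= n_dup <= hi

    def test_fragments_within_chromosome_bounds(self, truth, config):
        frags = aa.simulate_replicate(truth, "TFH_d5", 0, config)
        sizes = pd.Series(config.chrom_sizes)
        assert (frags["start"] >= 0).all()
        assert (frags["end"] <= sizes[frags["chrom"]].to_numpy()).all()

    def test_insert_modes_near_mixture_means(self, truth, config):
        cfg = aa.SimConfig(**{**config.to_dict(), "depth": 120_000})
        frags = aa.simulate_replicate(truth, "TFH_d5", 0, cfg)
        prof = aa.insert_size_profile(frags)
        for mean in (60, 200, 400):
            assert min(abs(m - mean) for m in prof.modes) <= 15


class TestConfigValidation:
    @pytest.mark.parametrize("field,value", [
        ("depth", 0), ("dup_rate", 1.0), ("mito_rate", -0.1),
        ("open_enrichment", 0.5),
    ])
    def test_bad_values_rejected(self, field, value):
        with pytest.raises(ValueError):
            aa.SimConfig(**{field: value})

    def test_insert_weights_must_sum_to_one(self):
        with pytest.raises(ValueError):
            aa.SimConfig(insert_mixture=((0.5, 60, 15), (0.4, 200, 35)))

    def test_yaml_roundtrip(self, tmp_path, config):
        path = tmp_path / "sim.yaml"
        config.to_yaml(path)
        again = aa.SimConfig.from_yaml(path)
        assert again.to_dict() == config.to_dict()
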