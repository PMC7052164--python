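"""Counting, size factors, NB Wald testing, gates and PCA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

import atacatlas as aa
from atacatlas.differential import AccessibilityMatrix
from conftest import make_fragments


def nb_counts(rng, mu, alpha, size):
    """Gamma-Poisson draw with mean mu, variance mu + alpha mu^2."""
    lam = rng.gamma(1.0 / alpha, alpha * mu, size=size)
    return rng.poisson(lam)


@pytest.fixture
def toy_atlas():
    return pd.DataFrame({
        "chrom": ["chr1"] * 4 + ["chr2"],
        "start": [100, 500, 900, 1500, 50],
        "end": [200, 700, 1200, 1600, 450],
        "atlas_id": [f"atlas_{i:04d}" for i in range(1, 6)]})


class TestCountMatrix:
    def test_exact_interval_counts_once(self, toy_atlas):
        frags = make_fragments([("chr1", 100, 200)])
        am = aa.count_matrix(toy_atlas, {"s1": frags})
        assert am.counts["s1"].tolist() == [1, 0, 0, 0, 0]

    def test_matches_quadratic_oracle(self, toy_atlas):
        rng = np.random.default_rng(3)
        spans = [(rng.choice(["chr1", "chr2"]), int(s), int(s + w))
                 for s, w in zip(rng.integers(0, 1_800, 20),
                                 rng.integers(20, 900, 20))]
        frags = make_fragments(spans)
        am = aa.count_matrix(toy_atlas, {"s1": frags})
        for i, iv in enumerate(toy_atlas.itertuples()):
            expected = sum(1 for c, s, e in spans
                           if c == iv.chrom and s < iv.end and e > iv.start)
            assert am.counts["s1"].iloc[i] == expected

    def test_column_linearity_under_duplication(self, toy_atlas):
        rng = np.random.default_rng(4)
        spans = [("chr1", int(s), int(s + 150))
                 for s in rng.integers(0, 1_500, 30)]
        single = aa.count_matrix(toy_atlas,
                                 {"s": make_fragments(spans)})
        double = aa.count_matrix(toy_atlas,
                                 {"s": make_fragments(spans + spans)})
        assert (double.counts["s"] == 2 * single.counts["s"]).all()

    def test_zero_fragment_sample_warns(self, toy_atlas):
        with pytest.warns(UserWarning):
            am = aa.count_matrix(toy_atlas, {"s": make_fragments([])})
        assert (am.counts["s"] == 0).all()


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        counts = pd.DataFrame({"a": [5, 9, 14], "b": [5, 9, 14]})
        assert np.allclose(aa.estimate_size_factors(counts), [1.0, 1.0])

    def test_doubled_column_closed_form(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [20, 40, 60]})
        sf = aa.estimate_size_factors(counts)
        assert np.allclose(sf, [2 ** -0.5, 2 ** 0.5], atol=5e-5)

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(5)
        counts = pd.DataFrame(rng.integers(1, 200, (40, 4)),
                              columns=list("abcd"))
        sf = aa.estimate_size_factors(counts)
        perm = counts.sample(frac=1.0, random_state=1)
        assert np.allclose(sf, aa.estimate_size_factors(perm))

    def test_no_positive_row_rejected(self):
        counts = pd.DataFrame({"a": [0, 5], "b": [3, 0]})
        with pytest.raises(ValueError):
            aa.estimate_size_factors(counts)

    def test_normalization_removes_planted_depth_factor(self):
        rng = np.random.default_rng(6)
        base = nb_counts(rng, 80.0, 0.05, (500, 1))
        counts = pd.DataFrame({"a": base[:, 0],
                               "b": rng.poisson(3.0 * base[:, 0])})
        am = AccessibilityMatrix(counts)
        am.size_factors = aa.estimate_size_factors(counts)
        norm = am.normalized
        assert abs(norm["a"].mean() / norm["b"].mean() - 1) < 0.01


class TestNBWald:
    def _matrix(self, counts):
        df = pd.DataFrame(counts,
                          columns=[f"g1_rep{i}" for i in range(3)]
                          + [f"g2_rep{i}" for i in range(3)])
        df.index = [f"atlas_{i:04d}" for i in range(len(df))]
        am = AccessibilityMatrix(df)
        am.size_factors = pd.Series(1.0, index=df.columns)
        return am

    def test_label_swap_negates_log2fc(self):
        rng = np.random.default_rng(7)
        am = self._matrix(nb_counts(rng, 100.0, 0.05, (300, 6)))
        labels = ["g1"] * 3 + ["g2"] * 3
        fwd = aa.nb_wald_test(am, labels, "g1", "g2")
        rev = aa.nb_wald_test(am, labels, "g2", "g1")
        assert np.allclose(fwd["log2FC"], -rev["log2FC"], atol=1e-6)
        assert np.allclose(fwd["pvalue"], rev["pvalue"], atol=1e-9)

    def test_planted_fold_change_recovered(self):
        rng = np.random.default_rng(8)
        low = nb_counts(rng, 50.0, 0.05, (400, 3))
        high = nb_counts(rng, 400.0, 0.05, (400, 3))
        am = self._matrix(np.hstack([low, high]))
        res = aa.nb_wald_test(am, ["g1"] * 3 + ["g2"] * 3, "g1", "g2")
        assert abs(np.median(res["log2FC"]) - 3.0) < 0.2

    def test_all_zero_row_gets_null_statistics(self):
        rng = np.random.default_rng(9)
        counts = nb_counts(rng, 60.0, 0.05, (50, 6))
        counts[7] = 0
        am = self._matrix(counts)
        res = aa.nb_wald_test(am, ["g1"] * 3 + ["g2"] * 3, "g1", "g2")
        assert np.isnan(res["pvalue"].iloc[7])
        assert np.isnan(res["qvalue"].iloc[7])
        assert res["qvalue"].drop(index=7).notna().all()

    def test_single_replicate_group_rejected(self):
        rng = np.random.default_rng(10)
        am = self._matrix(nb_counts(rng, 60.0, 0.05, (30, 6)))
        with pytest.raises(ValueError):
            aa.nb_wald_test(am, ["g1"] * 5 + ["g2"], "g1", "g2")


class TestBenjaminiHochberg:
    @given(st.lists(st.floats(1e-8, 1.0), min_size=1, max_size=200))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_bruteforce_stepup(self, pvals):
        p = np.array(pvals)
        q = multipletests(p, method="fdr_bh")[1]
        # brute-force step-up: q_(i) = min_{j >= i} p_(j) * n / j
        order = np.argsort(p, kind="stable")
        n = len(p)
        expected = np.empty(n)
        running = 1.0
        for rank in range(n, 0, -1):
            running = min(running, p[order[rank - 1]] * n / rank)
            expected[order[rank - 1]] = running
        assert np.allclose(q, expected)


class TestSelectDifferential:
    @pytest.fixture
    def results(self):
        return pd.DataFrame({
            "atlas_id": [f"a{i}" for i in range(4)],
            "log2FC": [1.9, 2.5, -3.0, 0.5],
            "qvalue": [0.04, 0.04, 0.01, 0.001]})

    def test_fc_gate_excludes_sub_threshold_fold(self, results):
        out = aa.select_differential(results, fdr=0.05, fc=4.0)
        assert set(out["atlas_id"]) == {"a1", "a2"}
        assert list(out["direction"]) == ["up_in_group2", "up_in_group1"]

    def test_unit_fc_keeps_all_significant(self, results):
        out = aa.select_differential(results, fdr=0.05, fc=1.0)
        assert set(out["atlas_id"]) == {"a0", "a1", "a2", "a3"}

    def test_strict_gate_nested_in_loose(self, results):
        strict = set(aa.select_differential(results, 0.05, 4.0)["atlas_id"])
        loose = set(aa.select_differential(results, 0.05, 1.5)["atlas_id"])
        assert strict <= loose


class TestPCA:
    def test_duplicated_sample_colocates(self):
        rng = np.random.default_rng(11)
        counts = pd.DataFrame(rng.integers(1, 300, (200, 3)),
                              columns=["a", "b", "c"])
        counts["a2"] = counts["a"]
        am = AccessibilityMatrix(counts)
        coords, var_frac = aa.pca_samples(am, n_top=100)
        assert np.allclose(coords.loc["a"], coords.loc["a2"], atol=1e-8)
        assert var_frac.sum() <= 1.0 + 1e-9

    def test_too_few_samples_rejected(self):
        am = AccessibilityMatrix(pd.DataFrame({"a": [1, 2], "b": [3, 4]}))
        with pytest.raises(ValueError):
            aa.pca_samples(am)

    def test_fewer_peaks_than_requested_warns(self):
        rng = np.random.default_rng(12)
        am = AccessibilityMatrix(pd.DataFrame(
            rng.integers(1, 50, (20, 4)), columns=list("abcd")))
        with pytest.warns(UserWarning):
            coords, _ = aa.pca_samples(am, n_top=500)
        assert coords.shape[0] == 4
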