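import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gliomix.diffexp import (
    CutlineThresholds,
    bh_adjust,
    de_contrast,
    filter_low_counts,
    nb_de_test,
    rank_metric,
    relevance_cutline,
    tmm_factors,
)


def _counts(arr, prefix="s"):
    arr = np.asarray(arr)
    return pd.DataFrame(arr, index=[f"g{i}" for i in range(arr.shape[0])],
                        columns=[f"{prefix}{j}" for j in range(arr.shape[1])])


class TestFilterLowCounts:
    def test_all_zero_gene_removed(self):
        c = _counts([[0, 0, 0, 0], [100, 90, 110, 95]])
        assert filter_low_counts(c) == ["g1"]

    def test_high_cpm_gene_kept(self):
        c = _counts(np.full((5, 4), 1000))
        assert "g0" in filter_low_counts(c)

    def test_boundary_strictly_greater(self):
        # one gene at exactly min_cpm in every sample: excluded by strict >
        lib = 1_000_000
        c = _counts([[1, 1], [lib - 1, lib - 1]])
        kept = filter_low_counts(c, min_cpm=1.0, min_samples=1)
        assert kept == ["g1"]

    def test_min_samples_defaults_to_smallest_group(self):
        c = _counts([[0, 0, 0, 50, 50], [50, 50, 50, 50, 50]])
        groups = ["a", "a", "a", "b", "b"]
        # g0 has cpm > 1 in only 2 samples = smallest group size -> kept
        assert filter_low_counts(c, groups) == ["g0", "g1"]


class TestTmm:
    def test_identical_libraries_unit_factors(self):
        rng = np.random.default_rng(0)
        y = rng.negative_binomial(10, 0.1, 300).astype(float)
        c = _counts(np.column_stack([y, y, y]))
        np.testing.assert_allclose(tmm_factors(c), 1.0, atol=1e-12)

    def test_proportional_libraries_unit_factors(self):
        rng = np.random.default_rng(1)
        y = rng.negative_binomial(10, 0.1, 400).astype(float) + 1
        c = _counts(np.column_stack([y, 2 * y, 3 * y]))
        np.testing.assert_allclose(tmm_factors(c), 1.0, atol=1e-9)

    def test_geometric_mean_one(self):
        rng = np.random.default_rng(2)
        c = _counts(rng.negative_binomial(5, 0.05, (500, 6)))
        f = tmm_factors(c)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-12)

    def test_invariant_to_global_library_rescaling(self):
        rng = np.random.default_rng(3)
        c = _counts(rng.negative_binomial(5, 0.05, (500, 4)))
        f1 = tmm_factors(c)
        f2 = tmm_factors(c * 10)
        np.testing.assert_allclose(f1, f2, rtol=1e-10)

    def test_composition_bias_detected(self):
        # one sample where a handful of genes take over half the library:
        # its factor must drop below 1 to compensate
        rng = np.random.default_rng(4)
        base = rng.negative_binomial(20, 0.1, 1000).astype(float) + 1
        boosted = base.copy()
        boosted[:5] *= 400
        c = _counts(np.column_stack([base, base, boosted]))
        f = tmm_factors(c)
        assert f.iloc[2] < 0.9

    def test_all_zero_sample_rejected(self):
        with pytest.raises(ValueError):
            tmm_factors(_counts([[0, 5], [0, 5]]))


class TestNbTest:
    def test_identical_groups_logfc_near_zero(self):
        c = _counts([[100, 100, 100, 100]] * 3)
        res = nb_de_test(c, ["a", "a", "b", "b"])
        np.testing.assert_allclose(res["logFC"], 0.0, atol=1e-8)

    def test_shifted_genes_detected_with_power(self):
        rng = np.random.default_rng(5)
        G, shift_n = 2000, 200
        mu = rng.lognormal(np.log(100), 1.0, G)
        r = 1 / 0.1
        half = np.tile(mu[:, None], (1, 10))
        mu2 = half.copy()
        mu2[:shift_n] *= 4.0  # 4-fold shift in group 2
        y = np.column_stack([
            rng.negative_binomial(r, r / (r + half)),
            rng.negative_binomial(r, r / (r + mu2)),
        ])
        res = nb_de_test(_counts(y), ["a"] * 10 + ["b"] * 10)
        fdr = bh_adjust(res["p"].to_numpy())
        power = np.mean(fdr[:shift_n] < 0.05)
        assert power > 0.8
        assert np.median(res["logFC"].to_numpy()[:shift_n]) == pytest.approx(2.0, abs=0.3)

    def test_non_integer_counts_rejected(self):
        c = _counts([[1.5, 2.0, 1.0, 2.0]])
        with pytest.raises(ValueError):
            nb_de_test(c, ["a", "a", "b", "b"])

    def test_small_groups_rejected(self):
        c = _counts([[1, 2, 3]])
        with pytest.raises(ValueError):
            nb_de_test(c, ["a", "a", "b"])


def _bh_oracle(p):
    """Literal step-up: sort, p_(i)*n/i, cumulative min from the top, cap at 1."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="mergesort")
    adj = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


class TestBhAdjust:
    def test_hand_computed_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.05]), [0.03, 0.03, 0.05])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_matches_step_up_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            p = rng.uniform(size=int(rng.integers(1, 400)))
            np.testing.assert_allclose(bh_adjust(p), _bh_oracle(p), atol=1e-15)

    def test_output_at_least_input(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(size=100)
        assert np.all(bh_adjust(p) >= p - 1e-15)

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, np.nan])


class TestCutline:
    def test_positive_relevant_plugin(self):
        # M=10, logFC=1: threshold collapses to c = 1.3010; FDR=0.04 passes
        status = relevance_cutline([1.0], [0.04], CutlineThresholds(M=10.0))
        assert status[0] == "pos_relevant"

    def test_small_logfc_significant_not_relevant(self):
        # M=10, logFC=0.2: threshold 10 + 0.2*(1.3010-10) = 8.260 > 6
        status = relevance_cutline([0.2], [1e-6], CutlineThresholds(M=10.0))
        assert status[0] == "significant_not_relevant"

    def test_negative_relevant_plugin(self):
        # M=10, logFC=-1: threshold 10 + (-1)*(10-1.3010) = 1.3010
        status = relevance_cutline([-1.0], [0.04], CutlineThresholds(M=10.0))
        assert status[0] == "neg_relevant"

    def test_threshold_identities(self):
        # at logFC = +-1 the line passes exactly through -log10(0.05)
        M, c = 7.0, -np.log10(0.05)
        assert M + 1.0 * (c - M) == pytest.approx(c)
        assert M + (-1.0) * (M - c) == pytest.approx(c)
        # at logFC = 0 both lines sit at M: only the minimum-FDR gene reaches it
        fdr = np.array([10**-M, 0.01])
        status = relevance_cutline([0.0, 0.0], fdr)
        assert list(status) == ["significant_not_relevant"] * 2

    def test_not_significant_never_relevant(self):
        status = relevance_cutline([5.0], [0.2], CutlineThresholds(M=10.0))
        assert status[0] == "ns"

    def test_degenerate_m_falls_back_with_warning(self):
        with pytest.warns(UserWarning, match="degenerate"):
            status = relevance_cutline([2.0, 0.5], [0.04, 0.04],
                                       CutlineThresholds(M=1.0))
        assert status[0] == "pos_relevant"
        assert status[1] == "significant_not_relevant"

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(lfc=st.floats(-6, 6), fdr=st.floats(1e-12, 1.0), M=st.floats(2.0, 300.0))
    def test_statuses_mutually_exclusive_and_gated(self, lfc, fdr, M):
        M = max(M, -np.log10(fdr))  # M is the max -log10(FDR) over the contrast
        status = relevance_cutline([lfc], [fdr], CutlineThresholds(M=M))[0]
        if fdr >= 0.05:
            assert status == "ns"
        else:
            assert status in ("pos_relevant", "neg_relevant", "significant_not_relevant")
            if status == "pos_relevant":
                assert lfc > 0
            if status == "neg_relevant":
                assert lfc < 0


class TestRankMetric:
    def test_signed_log_p(self):
        np.testing.assert_allclose(rank_metric([0.01], [-2.0]), [-2.0])

    def test_p_one_gives_zero(self):
        assert rank_metric([1.0], [3.0])[0] == 0.0

    def test_zero_logfc_gives_zero(self):
        assert rank_metric([0.001], [0.0])[0] == 0.0

    def test_p_zero_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            out = rank_metric([0.0], [1.0])
        assert np.isfinite(out[0]) and out[0] > 300


class TestDeContrast:
    def test_end_to_end_orientation_and_columns(self):
        rng = np.random.default_rng(8)
        G = 400
        mu = rng.lognormal(np.log(200), 0.7, G)
        r = 1 / 0.1
        base = rng.negative_binomial(r, r / (r + np.tile(mu[:, None], (1, 12))))
        base[:30, 6:] = rng.negative_binomial(
            r, r / (r + 6 * np.tile(mu[:30, None], (1, 6))))
        counts = _counts(base)
        labels = ["lggA"] * 6 + ["lggB"] * 6
        res = de_contrast(counts, labels, ("lggA", "lggB"))
        assert {"logFC", "p", "FDR", "status", "rank_metric"} <= set(res.columns)
        up = res.iloc[:30]
        assert (up["logFC"] > 0).mean() > 0.9  # higher in lggB = pair[1]
        assert (up["FDR"] < 0.05).mean() > 0.8
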