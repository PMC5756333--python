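import numpy as np
import pandas as pd
import pytest

from exprmap import (
    ExpressionMatrix,
    GeneLengths,
    SizeFactors,
    apply_size_factors,
    detect_spike_ins,
    normalize_per_value,
    quantile_normalize,
    size_factors_median_ratio,
    size_factors_spike_in,
    size_factors_tmm,
    size_factors_upper_quartile,
)
from exprmap.simulate import SimulationSpec, simulate_counts
from conftest import random_counts


def classic_median_ratio(counts: np.ndarray) -> np.ndarray:
    """Independent oracle: the textbook median-of-ratios on a zero-free matrix."""
    log_ref = np.log(counts).mean(axis=1)
    raw = np.array(
        [np.median(counts[:, j] / np.exp(log_ref)) for j in range(counts.shape[1])]
    )
    return raw / np.exp(np.mean(np.log(raw)))


def brute_force_tmm(counts: np.ndarray, ref: int, g: int, trim_m: float, trim_a: float) -> float:
    """Independent oracle for the TMM component: explicit sort-based trimming."""
    lib = counts.sum(axis=0)
    kg, kr = counts[:, g], counts[:, ref]
    both = (kg > 0) & (kr > 0)
    pg, pr = kg[both] / lib[g], kr[both] / lib[ref]
    m_vals = np.log2(pg / pr)
    a_vals = 0.5 * np.log2(pg * pr)
    w = 1.0 / (
        (lib[g] - kg[both]) / (lib[g] * kg[both])
        + (lib[ref] - kr[both]) / (lib[ref] * kr[both])
    )
    n = m_vals.size

    def average_rank(x):
        order = np.argsort(x, kind="stable")
        ranks = np.empty(n)
        ranks[order] = np.arange(1, n + 1)
        for v in np.unique(x):
            ranks[x == v] = ranks[x == v].mean()
        return ranks

    rm, ra = average_rank(m_vals), average_rank(a_vals)
    keep = (rm >= n * trim_m + 1) & (rm <= n * (1 - trim_m))
    keep &= (ra >= n * trim_a + 1) & (ra <= n * (1 - trim_a))
    return 2.0 ** (np.sum(w[keep] * m_vals[keep]) / np.sum(w[keep]))


class TestMedianRatio:
    def test_worked_three_gene_example_strict_inclusion(self, worked_counts):
        sf = size_factors_median_ratio(worked_counts, min_detect_frac=1.0)
        np.testing.assert_allclose(sf.factors.to_numpy(), [0.5, 2.0], atol=1e-12)

    def test_worked_example_relaxed_inclusion(self, worked_counts):
        # g3 enters with reference 5; its ratio only contributes to sample B,
        # whose median over {2, 2, 1} is still 2
        sf = size_factors_median_ratio(worked_counts, min_detect_frac=0.5)
        np.testing.assert_allclose(sf.factors.to_numpy(), [0.5, 2.0], atol=1e-12)

    def test_pure_scaling_gives_sqrt2_convention(self):
        rng = np.random.default_rng(0)
        a = rng.integers(1, 100, size=20).astype(float)
        m = ExpressionMatrix(
            pd.DataFrame({"A": a, "B": 2 * a}, index=[f"g{i}" for i in range(20)])
        )
        sf = size_factors_median_ratio(m, 1.0)
        np.testing.assert_allclose(
            sf.factors.to_numpy(), [1 / np.sqrt(2), np.sqrt(2)], rtol=1e-12
        )

    @pytest.mark.parametrize("seed", range(8))
    def test_equals_classic_estimator_on_zero_free_matrices(self, seed):
        m = random_counts(np.random.default_rng(seed), 50, 4, zero_free=True)
        sf = size_factors_median_ratio(m, min_detect_frac=1.0)
        expected = classic_median_ratio(m.values.to_numpy())
        np.testing.assert_allclose(sf.factors.to_numpy(), expected, atol=1e-12)

    def test_no_eligible_feature_suggests_lower_threshold(self):
        m = ExpressionMatrix(
            pd.DataFrame({"A": [1.0, 0.0], "B": [0.0, 1.0]}, index=["g1", "g2"])
        )
        with pytest.raises(ValueError, match="min_detect_frac"):
            size_factors_median_ratio(m, 1.0)

    def test_sample_without_eligible_ratio_is_named(self):
        m = ExpressionMatrix(
            pd.DataFrame({"A": [1.0, 2.0], "B": [3.0, 4.0], "C": [0.0, 0.0]}, index=["g1", "g2"])
        )
        with pytest.raises(ValueError, match="'C'"):
            size_factors_median_ratio(m, min_detect_frac=0.5)

    def test_scaling_equivariance_of_factor_ratios(self):
        # scaling one column by c moves the geometric-mean reference by
        # c^(1/m), so the exact invariant is on factor ratios: the scaled
        # sample gains a factor c relative to every other sample
        rng = np.random.default_rng(3)
        m = random_counts(rng, 30, 4, zero_free=True)
        scaled = m.values.copy()
        scaled["s1"] *= 3.0
        m2 = ExpressionMatrix(scaled)
        f1 = size_factors_median_ratio(m, 1.0).factors
        f2 = size_factors_median_ratio(m2, 1.0).factors
        others = [s for s in m.sample_ids if s != "s1"]
        for s in others:
            np.testing.assert_allclose(
                (f2["s1"] / f2[s]) / (f1["s1"] / f1[s]), 3.0, rtol=1e-12
            )


class TestTMM:
    def test_pure_library_scaling_gives_unit_tmm_component(self):
        rng = np.random.default_rng(1)
        a = rng.integers(10, 500, size=50).astype(float)
        m = ExpressionMatrix(
            pd.DataFrame({"A": a, "B": 3 * a}, index=[f"g{i}" for i in range(50)])
        )
        sf = size_factors_tmm(m)
        comp = sf.params["tmm_component"]
        np.testing.assert_allclose(list(comp.values()), [1.0, 1.0], atol=1e-12)
        np.testing.assert_allclose(
            sf.factors.to_numpy(), [1 / np.sqrt(3), np.sqrt(3)], rtol=1e-12
        )

    def test_reference_sample_component_is_one(self):
        m = random_counts(np.random.default_rng(2), 40, 3, zero_free=True)
        sf = size_factors_tmm(m)
        assert sf.params["tmm_component"][sf.params["reference_sample"]] == 1.0

    def test_matches_brute_force_trimming_oracle(self):
        rng = np.random.default_rng(4)
        base = rng.integers(20, 400, size=20).astype(float)
        other = base.copy()
        other[0] *= 40.0  # planted composition bias
        other[1] *= 25.0
        m = ExpressionMatrix(
            pd.DataFrame({"A": base, "B": other}, index=[f"g{i}" for i in range(20)])
        )
        sf = size_factors_tmm(m)
        ref = m.sample_ids.index(sf.params["reference_sample"])
        g = 1 - ref
        expected = brute_force_tmm(m.values.to_numpy(), ref, g, 0.30, 0.05)
        got = sf.params["tmm_component"][m.sample_ids[g]]
        assert abs(got - expected) < 1e-9

    def test_falls_back_with_warning_when_overtrimmed(self):
        m = random_counts(np.random.default_rng(5), 8, 2, zero_free=True)
        with pytest.warns(UserWarning, match="untrimmed"):
            size_factors_tmm(m)


class TestUpperQuartile:
    def test_identical_columns_unit_factors(self):
        col = np.arange(1.0, 11.0)
        m = ExpressionMatrix(pd.DataFrame({"A": col, "B": col}, index=[f"g{i}" for i in range(10)]))
        np.testing.assert_allclose(size_factors_upper_quartile(m).factors, [1, 1])

    def test_q75_linear_interpolation_by_hand(self):
        m = ExpressionMatrix(
            pd.DataFrame({"A": [1, 2, 3, 4], "B": [1, 2, 3, 4]}, index=list("wxyz"))
        )
        np.testing.assert_allclose(size_factors_upper_quartile(m).raw, [3.25, 3.25])

    def test_doubling_column_scales_raw_factor(self):
        m = ExpressionMatrix(
            pd.DataFrame({"A": [1, 2, 3, 4], "B": [2, 4, 6, 8]}, index=list("wxyz"))
        )
        sf = size_factors_upper_quartile(m)
        np.testing.assert_allclose(sf.factors, [1 / np.sqrt(2), np.sqrt(2)])

    def test_all_zero_sample_rejected(self):
        m = ExpressionMatrix(pd.DataFrame({"A": [1.0, 2.0], "B": [0.0, 0.0]}, index=["g1", "g2"]))
        with pytest.raises(ValueError, match="'B'"):
            size_factors_upper_quartile(m)


class TestSpikeIn:
    def build(self, bio, spikes):
        idx = [f"g{i}" for i in range(len(bio))] + [f"ERCC-{i:04d}" for i in range(len(spikes))]
        vals = np.vstack([np.asarray(bio, float), np.asarray(spikes, float)])
        return ExpressionMatrix(pd.DataFrame(vals, index=idx, columns=["A", "B"]))

    def test_identical_spike_rows_give_unit_factors(self):
        m = self.build([[5, 50], [7, 70]], [[10, 10], [20, 20], [40, 40]])
        sf = size_factors_spike_in(m, detect_spike_ins(m))
        np.testing.assert_allclose(sf.factors, [1, 1])

    def test_doubled_spikes_give_sqrt2_factors(self):
        m = self.build([[5, 5]], [[10, 20], [30, 60]])
        sf = size_factors_spike_in(m, detect_spike_ins(m))
        np.testing.assert_allclose(sf.factors, [1 / np.sqrt(2), np.sqrt(2)])

    def test_matches_median_ratio_on_spike_submatrix(self):
        m = self.build([[1, 9], [2, 8]], [[10, 21], [30, 66], [50, 95]])
        sf = size_factors_spike_in(m, detect_spike_ins(m))
        sub = m.subset(feature_ids=[f for f in m.feature_ids if f.startswith("ERCC-")])
        oracle = classic_median_ratio(sub.values.to_numpy())
        np.testing.assert_allclose(sf.factors.to_numpy(), oracle, atol=1e-12)

    def test_too_few_spikes_rejected(self):
        m = self.build([[1, 2]], [[10, 20]])
        with pytest.raises(ValueError, match="2 spike"):
            size_factors_spike_in(m, detect_spike_ins(m))


class TestPerValue:
    def test_cpm_and_tpm_columns_sum_to_a_million(self):
        m = random_counts(np.random.default_rng(6), 30, 4, zero_free=True)
        lengths = GeneLengths(pd.Series(500.0 + np.arange(30) * 100, index=m.feature_ids))
        cpm = normalize_per_value(m, "cpm").matrix.values.sum(axis=0)
        tpm = normalize_per_value(m, "tpm", lengths).matrix.values.sum(axis=0)
        np.testing.assert_allclose(cpm, 1e6, rtol=1e-9)
        np.testing.assert_allclose(tpm, 1e6, rtol=1e-9)

    def test_rpkm_single_gene_by_hand(self):
        m = ExpressionMatrix(pd.DataFrame({"A": [10.0]}, index=["g"]))
        lengths = GeneLengths(pd.Series({"g": 1000.0}))
        out = normalize_per_value(m, "rpkm", lengths).matrix.values.iloc[0, 0]
        assert out == pytest.approx(1e9 * 10 / (10 * 1000))

    def test_missing_length_names_feature(self):
        m = random_counts(np.random.default_rng(7), 3, 2, zero_free=True)
        lengths = GeneLengths(pd.Series({"g0": 100.0, "g1": 100.0}))
        with pytest.raises(ValueError, match="g2"):
            normalize_per_value(m, "tpm", lengths)


class TestQuantile:
    def test_identical_columns_are_a_fixed_point(self):
        col = np.array([3.0, 1.0, 7.0])
        m = ExpressionMatrix(pd.DataFrame({"A": col, "B": col}, index=list("xyz")))
        out = quantile_normalize(m).matrix
        np.testing.assert_allclose(out.values.to_numpy(), m.values.to_numpy())

    def test_worked_two_column_example(self):
        m = ExpressionMatrix(pd.DataFrame({"A": [2, 4, 6], "B": [1, 5, 12]}, index=list("xyz")))
        out = quantile_normalize(m).matrix.values
        np.testing.assert_allclose(out["A"], [1.5, 4.5, 9.0])
        np.testing.assert_allclose(out["B"], [1.5, 4.5, 9.0])

    @pytest.mark.parametrize("seed", range(5))
    def test_sorted_columns_identical_and_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.random((20, 5)) * 100  # continuous → tie-free
        m = ExpressionMatrix(
            pd.DataFrame(vals, index=[f"g{i}" for i in range(20)],
                         columns=[f"s{j}" for j in range(5)]),
            kind="normalized",
        )
        once = quantile_normalize(m).matrix
        arr = once.values.to_numpy()
        sorted_cols = np.sort(arr, axis=0)
        for j in range(1, arr.shape[1]):
            np.testing.assert_allclose(sorted_cols[:, j], sorted_cols[:, 0])
        twice = quantile_normalize(once).matrix
        np.testing.assert_allclose(twice.values.to_numpy(), arr)

    def test_ties_receive_mean_of_rank_means(self):
        m = ExpressionMatrix(
            pd.DataFrame({"A": [1.0, 1.0, 5.0], "B": [2.0, 4.0, 6.0]}, index=list("xyz"))
        )
        out = quantile_normalize(m).matrix.values
        # rank means: (1.5, 2.5, 5.5); A's tie at value 1 spans ranks 1-2
        np.testing.assert_allclose(out["A"], [2.0, 2.0, 5.5])


class TestApplyFactors:
    def unit_factors(self, sample_ids):
        return SizeFactors(pd.Series(1.0, index=sample_ids), "manual", {})

    def test_unit_factors_no_log_is_identity(self):
        m = random_counts(np.random.default_rng(8), 5, 3)
        out = apply_size_factors(m, self.unit_factors(m.sample_ids))
        np.testing.assert_array_equal(out.matrix.values.to_numpy(), m.values.to_numpy())
        assert out.matrix.kind == "normalized"

    def test_log_transform_values_by_hand(self):
        m = ExpressionMatrix(pd.DataFrame({"A": [0.0], "B": [7.0]}, index=["g"]))
        sf = SizeFactors(pd.Series({"A": 0.5, "B": 2.0}), "manual", {})
        out = apply_size_factors(m, sf, log=True, pseudocount=1.0).matrix
        assert out.values.loc["g", "A"] == 0.0
        assert out.values.loc["g", "B"] == pytest.approx(np.log2(4.5))
        assert out.kind == "log_normalized"

    def test_missing_sample_factor_rejected(self):
        m = random_counts(np.random.default_rng(9), 4, 3)
        sf = SizeFactors(pd.Series({"s0": 1.0, "s1": 1.0}), "manual", {})
        with pytest.raises(ValueError, match="s2"):
            apply_size_factors(m, sf)


class TestFactorInvariants:
    def test_geometric_mean_one_enforced(self):
        with pytest.raises(ValueError, match="geometric mean"):
            SizeFactors(pd.Series({"a": 2.0, "b": 3.0}), "manual", {})

    def test_nonpositive_factors_rejected(self):
        with pytest.raises(ValueError):
            SizeFactors(pd.Series({"a": -1.0, "b": 1.0}), "manual", {})

    @pytest.mark.parametrize("estimator", ["median_ratio", "tmm"])
    def test_parameter_recovery_on_simulated_truth(self, estimator):
        spec = SimulationSpec(de_frac=0.0, dropout=False, seed=11)
        m, _design, truth = simulate_counts(spec)
        sf = (
            size_factors_median_ratio(m, 0.5)
            if estimator == "median_ratio"
            else size_factors_tmm(m)
        )
        r = np.corrcoef(np.log(sf.factors), np.log(truth.size_factors))[0, 1]
        assert r >= 0.95
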