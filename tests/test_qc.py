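import numpy as np
import pandas as pd
import pytest

from exprmap import (
    ExpressionMatrix,
    FilterCriteria,
    feature_query,
    filter_features,
    filter_samples,
    mean_variability,
    rank_frequency,
    sample_qc_stats,
    size_factors_upper_quartile,
)
from conftest import random_counts


class TestSampleQC:
    def test_counting_by_hand(self):
        m = ExpressionMatrix(
            pd.DataFrame({"A": [0, 0, 5, 5], "B": [1, 1, 1, 1]}, index=list("wxyz"))
        )
        stats = sample_qc_stats(m)
        assert stats.loc["A", "total_counts"] == 10
        assert stats.loc["A", "detected_features"] == 2
        assert stats.loc["A", "dropout_rate"] == 0.5

    def test_all_zero_sample_boundary(self):
        m = ExpressionMatrix(pd.DataFrame({"A": [0.0, 0.0], "B": [1.0, 2.0]}, index=["g1", "g2"]))
        stats = sample_qc_stats(m)
        assert stats.loc["A", "total_counts"] == 0
        assert stats.loc["A", "detected_features"] == 0
        assert stats.loc["A", "dropout_rate"] == 1.0

    @pytest.mark.parametrize("seed", range(4))
    def test_dropout_detected_identity(self, seed):
        m = random_counts(np.random.default_rng(seed), 15, 5)
        stats = sample_qc_stats(m)
        recon = stats["dropout_rate"] * m.n_features + stats["detected_features"]
        np.testing.assert_allclose(recon, m.n_features)

    def test_size_factor_column_attached(self):
        m = random_counts(np.random.default_rng(9), 10, 3, zero_free=True)
        sf = size_factors_upper_quartile(m)
        stats = sample_qc_stats(m, sf)
        np.testing.assert_allclose(stats["size_factor"], sf.factors)


class TestFilterFeatures:
    def grid(self):
        return ExpressionMatrix(
            pd.DataFrame([[6, 6], [6, 0], [0, 0]], index=["g1", "g2", "g3"], columns=["A", "B"])
        )

    def test_min_count_in_min_samples_by_hand(self):
        kept, removed = filter_features(self.grid(), FilterCriteria(min_count=5, min_samples=2))
        assert kept.feature_ids == ["g1"] and removed == ["g2", "g3"]

    def test_empty_criteria_is_identity(self):
        m = self.grid()
        kept, removed = filter_features(m, FilterCriteria())
        assert kept.equals(m) and removed == []

    def test_keep_list_overrides_expression_criteria(self):
        kept, _ = filter_features(
            self.grid(),
            FilterCriteria(min_count=5, min_samples=2, feature_keep_list=["g3"]),
        )
        assert kept.feature_ids == ["g1", "g3"]

    def test_all_removed_is_an_error(self):
        with pytest.raises(ValueError, match="all features"):
            filter_features(self.grid(), FilterCriteria(min_mean_expr=1e9))

    def test_unknown_list_ids_warn_and_are_ignored(self, caplog):
        with caplog.at_level("WARNING", logger="exprmap.qc"):
            kept, _ = filter_features(self.grid(), FilterCriteria(feature_drop_list=["ghost", "g3"]))
        assert "unknown" in caplog.text
        assert kept.feature_ids == ["g1", "g2"]

    @pytest.mark.parametrize("seed", range(4))
    def test_idempotent_and_partitioning(self, seed):
        m = random_counts(np.random.default_rng(seed), 25, 4)
        criteria = FilterCriteria(min_count=10, min_samples=2)
        once, removed = filter_features(m, criteria)
        twice, removed2 = filter_features(once, criteria)
        assert twice.equals(once) and removed2 == []
        assert sorted(once.feature_ids + removed) == sorted(m.feature_ids)


class TestFilterSamples:
    def test_dropout_cutoff_by_hand(self):
        m = ExpressionMatrix(
            pd.DataFrame(
                {"A": [1, 1, 0, 0, 3, 1, 0, 2, 1, 1], "B": [0, 0, 0, 0, 0, 0, 0, 0, 0, 5]},
                index=[f"g{i}" for i in range(10)],
            )
        )
        qc = sample_qc_stats(m)
        kept, removed = filter_samples(m, FilterCriteria(dropout_max=0.6), qc)
        assert kept.sample_ids == ["A"] and removed == ["B"]
        assert kept.feature_ids == m.feature_ids

    def test_inactive_size_factor_range_is_identity(self):
        m = random_counts(np.random.default_rng(1), 10, 4, zero_free=True)
        qc = sample_qc_stats(m, size_factors_upper_quartile(m))
        kept, removed = filter_samples(m, FilterCriteria(size_factor_range=(0.2, 5)), qc)
        assert kept.equals(m) and removed == []

    def test_explicit_drop_list(self):
        m = random_counts(np.random.default_rng(2), 10, 4)
        qc = sample_qc_stats(m)
        kept, removed = filter_samples(m, FilterCriteria(sample_drop_list=["s2"]), qc)
        assert removed == ["s2"] and "s2" not in kept.sample_ids

    def test_stale_qc_table_rejected(self):
        m = random_counts(np.random.default_rng(3), 10, 4)
        qc = sample_qc_stats(m.subset(sample_ids=m.sample_ids[:2]))
        with pytest.raises(ValueError, match="not computed on this matrix"):
            filter_samples(m, FilterCriteria(dropout_max=0.5), qc)


class TestRankFrequency:
    def test_worked_example(self):
        m = ExpressionMatrix(pd.DataFrame({"A": [10, 30, 60]}, index=list("xyz")))
        table = rank_frequency(m, "A")
        assert table["rank"].tolist() == [1, 2, 3]
        np.testing.assert_allclose(table["frequency"], [0.6, 0.3, 0.1])

    def test_single_positive_gene(self):
        m = ExpressionMatrix(pd.DataFrame({"A": [0, 7, 0]}, index=list("xyz")))
        table = rank_frequency(m, "A")
        assert table["rank"].tolist() == [1] and table["frequency"].tolist() == [1.0]

    @pytest.mark.parametrize("seed", range(4))
    def test_frequencies_sum_to_one(self, seed):
        m = random_counts(np.random.default_rng(seed), 30, 2, zero_free=True)
        table = rank_frequency(m, "s0")
        assert abs(table["frequency"].sum() - 1.0) < 1e-12

    def test_all_zero_sample_rejected(self):
        m = ExpressionMatrix(pd.DataFrame({"A": [0.0, 0.0]}, index=["g1", "g2"]))
        with pytest.raises(ValueError, match="'A'"):
            rank_frequency(m, "A")


class TestMeanVariability:
    def test_arithmetic_by_hand(self):
        m = ExpressionMatrix(
            pd.DataFrame({"A": [1.0, 4.0], "B": [3.0, 4.0]}, index=["g1", "g2"]),
            kind="normalized",
        )
        table = mean_variability(m)
        row = table.set_index("feature_id").loc["g1"]
        assert row["mean"] == 2.0 and row["sd"] == pytest.approx(np.sqrt(2))
        assert row["cv"] == pytest.approx(np.sqrt(2) / 2)

    def test_constant_feature_zero_sd(self):
        m = ExpressionMatrix(
            pd.DataFrame({"A": [4.0, 0.0], "B": [4.0, 0.0]}, index=["g1", "g2"]),
            kind="normalized",
        )
        table = mean_variability(m).set_index("feature_id")
        assert table.loc["g1", "sd"] == 0.0
        assert np.isnan(table.loc["g2", "cv"])  # zero mean → CV omitted

    def test_row_order_preserved(self):
        m = random_counts(np.random.default_rng(4), 12, 3)
        assert mean_variability(m)["feature_id"].tolist() == m.feature_ids


class TestFeatureQuery:
    def build(self):
        base = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        return ExpressionMatrix(
            pd.DataFrame(
                {
                    "target": base,
                    "double": 2 * base,
                    "anti": -(base - base.mean()),
                    "square": base**2,
                    "flat": np.ones(5),
                    "noise": [2.0, 1.0, 4.0, 3.0, 5.0],
                },
                index=[f"s{j}" for j in range(5)],
            ).T,
            kind="normalized",
        )

    def test_linear_copy_ranks_first_with_r_one(self):
        table = feature_query(self.build(), "target", "pearson", top_n=10)
        assert table.iloc[0]["feature_id"] == "double"
        assert table.iloc[0]["correlation"] == pytest.approx(1.0)

    def test_anticorrelated_feature_ranks_last(self):
        table = feature_query(self.build(), "target", "pearson", top_n=10)
        assert table.iloc[-1]["feature_id"] == "anti"
        assert table.iloc[-1]["correlation"] == pytest.approx(-1.0)

    def test_spearman_is_rank_invariant_on_monotone_copy(self):
        table = feature_query(self.build(), "target", "spearman", top_n=10)
        sq = table.set_index("feature_id").loc["square", "correlation"]
        assert sq == pytest.approx(1.0)

    def test_constant_features_skipped_and_target_excluded(self, caplog):
        with caplog.at_level("WARNING", logger="exprmap.qc"):
            table = feature_query(self.build(), "target", top_n=10)
        assert "constant" in caplog.text
        assert "flat" not in set(table["feature_id"])
        assert "target" not in set(table["feature_id"])

    def test_unknown_or_constant_target_rejected(self):
        m = self.build()
        with pytest.raises(KeyError):
            feature_query(m, "ghost")
        with pytest.raises(ValueError, match="constant"):
            feature_query(m, "flat")
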