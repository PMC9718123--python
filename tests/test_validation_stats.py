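import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synovolume.validation_stats import (
    CASE_DEFINITIONS,
    CaseDefinition,
    CohortTable,
    auc_case_control,
    bootstrap_ci,
    icc,
    rank_auc,
    run_validation_battery,
    sensitivity_without_outliers,
    spearman_r,
)
from _oracles import icc_oracle, pair_count_auc, spearman_oracle

ICC_MODELS = ("two_way_random_absolute_single", "two_way_mixed_consistency_single")


class TestSpearman:
    def test_monotone_is_one(self):
        x = np.array([1.0, 2.0, 5.0, 9.0, 20.0])
        assert spearman_r(x, np.exp(x)) == pytest.approx(1.0)

    def test_antitone_is_minus_one(self):
        x = np.array([1.0, 2.0, 5.0, 9.0, 20.0])
        assert spearman_r(x, -x) == pytest.approx(-1.0)

    def test_ties_match_midrank_oracle(self):
        x = [1, 2, 3, 4, 5]
        y = [1, 1, 2, 2, 3]
        assert spearman_r(x, y) == pytest.approx(spearman_oracle(x, y), abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_random_tied_data_match_midrank_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 6, size=20).astype(float)
        y = rng.integers(0, 4, size=20).astype(float)
        if np.all(x == x[0]) or np.all(y == y[0]):
            return
        assert spearman_r(x, y) == pytest.approx(spearman_oracle(x, y), abs=1e-12)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_invariant_under_strictly_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        base = spearman_r(x, y)
        assert spearman_r(np.exp(x), y) == pytest.approx(base, abs=1e-12)
        assert spearman_r(x, 3 * y + 7) == pytest.approx(base, abs=1e-12)
        assert spearman_r(x, -y) == pytest.approx(-base, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_r([1, 1, 1, 1], [1, 2, 3, 4])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="n >= 3"):
            spearman_r([1, 2], [3, 4])


class TestAUC:
    def test_perfect_separation_is_one_with_warning(self):
        values = np.array([10.0, 11.0, 12.0, 1.0, 2.0, 3.0])
        labels = np.array([True, True, True, False, False, False])
        res = auc_case_control(values, labels)
        assert res.auc == 1.0
        assert res.warning is not None

    def test_constant_measure_is_half(self):
        values = np.zeros(10)
        labels = np.arange(10) < 4
        assert auc_case_control(values, labels).auc == pytest.approx(0.5)
        assert auc_case_control(values, labels).p_value == pytest.approx(1.0)

    def test_overlapping_values_match_pair_oracle(self):
        rng = np.random.default_rng(0)
        cases = rng.integers(0, 6, 5).astype(float)
        controls = rng.integers(0, 6, 5).astype(float)
        values = np.concatenate([cases, controls])
        labels = np.arange(10) < 5
        assert auc_case_control(values, labels).auc == pytest.approx(
            pair_count_auc(cases, controls), abs=1e-12
        )

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 100_000))
    def test_rank_auc_equals_exhaustive_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 31))
        n_case = int(rng.integers(1, n))
        values = rng.integers(0, 8, size=n).astype(float)
        labels = np.zeros(n, dtype=bool)
        labels[rng.choice(n, size=n_case, replace=False)] = True
        expected = pair_count_auc(values[labels], values[~labels])
        assert rank_auc(values, labels) == pytest.approx(expected, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="case"):
            rank_auc([1.0, 2.0], [True, True])

    def test_discriminative_measure_has_small_p(self):
        rng = np.random.default_rng(4)
        values = np.concatenate([rng.normal(2, 1, 40), rng.normal(0, 1, 40)])
        labels = np.arange(80) < 40
        res = auc_case_control(values, labels)
        assert res.auc > 0.8
        assert res.p_value < 1e-6


class TestICC:
    @pytest.mark.parametrize("model", ICC_MODELS)
    def test_duplicate_columns_are_perfect_agreement(self, model):
        col = np.array([1.0, 4.0, 2.0, 8.0, 5.0, 3.0])
        table = np.column_stack([col, col])
        assert icc(table, model=model).icc == pytest.approx(1.0)

    @pytest.mark.parametrize("model", ICC_MODELS)
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_hand_expanded_anova_oracle(self, model, seed):
        rng = np.random.default_rng(seed)
        table = rng.integers(0, 10, size=(6, 2)).astype(float)
        if np.allclose(table.mean(axis=1), table.mean()):
            return
        assert icc(table, model=model).icc == pytest.approx(
            icc_oracle(table, model), abs=1e-12
        )

    def test_matches_pingouin_cross_check(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(12)
        table = rng.normal(10, 3, size=(12, 2))
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(12), 2),
                "rater": np.tile([0, 1], 12),
                "score": table.ravel(),
            }
        )
        ref = pingouin.intraclass_corr(long, targets="subject", raters="rater", ratings="score")
        ref = ref.set_index("Type")["ICC"]
        assert icc(table, model="two_way_random_absolute_single").icc == pytest.approx(
            ref["ICC(A,1)"], abs=1e-9
        )
        assert icc(table, model="two_way_mixed_consistency_single").icc == pytest.approx(
            ref["ICC(C,1)"], abs=1e-9
        )

    def test_constant_shift_separates_models(self):
        col = np.array([1.0, 4.0, 2.0, 8.0, 5.0, 3.0])
        table = np.column_stack([col, col + 2.0])
        assert icc(table, model="two_way_mixed_consistency_single").icc == pytest.approx(1.0)
        assert icc(table, model="two_way_random_absolute_single").icc < 1.0

    def test_zero_between_subject_variance_is_nan_with_warning(self):
        table = np.array([[1.0, 3.0]] * 6)
        res = icc(table)
        assert math.isnan(res.icc)
        assert "between-subject variance" in res.warning

    def test_unbalanced_table_rejected(self):
        table = np.array([[1.0, 2.0], [3.0, np.nan], [4.0, 5.0], [6.0, 7.0], [8.0, 9.0]])
        with pytest.raises(ValueError, match="unbalanced"):
            icc(table)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match=">= 5"):
            icc(np.ones((4, 2)))

    def test_noise_strictly_decreases_expected_icc(self):
        """Averaged over 200 seeded replicates, noising one column lowers the ICC."""
        rng = np.random.default_rng(2024)
        clean_vals, noisy_vals = [], []
        for _ in range(200):
            col = rng.normal(0, 5, size=10)
            clean = np.column_stack([col, col + rng.normal(0, 0.5, 10)])
            noisy = np.column_stack([clean[:, 0], clean[:, 1] + rng.normal(0, 5, 10)])
            clean_vals.append(icc(clean).icc)
            noisy_vals.append(icc(noisy).icc)
        assert np.mean(noisy_vals) < np.mean(clean_vals)


class TestSensitivityWithoutOutliers:
    def _concordant(self, n=8):
        col = np.linspace(1, 20, n)
        return np.column_stack([col, col])

    def test_discordant_subject_removal_raises_icc(self):
        table = self._concordant()
        table[3, 1] = 200.0  # grossly discordant second rating
        with_all, without = sensitivity_without_outliers(table)
        assert without.icc > with_all.icc
        assert without.outlier_ids_excluded == (3,)

    def test_perfectly_concordant_table_unchanged(self):
        with_all, without = sensitivity_without_outliers(self._concordant())
        assert with_all.icc == pytest.approx(1.0)
        assert without.icc == pytest.approx(1.0)

    def test_removal_changes_n_by_exactly_one(self):
        with_all, without = sensitivity_without_outliers(self._concordant())
        assert with_all.n_subjects - without.n_subjects == 1

    def test_dataframe_index_labels_reported(self):
        table = pd.DataFrame(self._concordant(), index=[f"k{i}" for i in range(8)])
        table.iloc[5, 1] = 999.0
        _, without = sensitivity_without_outliers(table)
        assert without.outlier_ids_excluded == ("k5",)


class TestBootstrap:
    def _cohort(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "value": np.concatenate([rng.normal(1, 1, n // 2), rng.normal(0, 1, n // 2)]),
                "case": np.arange(n) < n // 2,
            }
        )

    @staticmethod
    def _auc_stat(df):
        return rank_auc(df["value"].to_numpy(), df["case"].to_numpy())

    @staticmethod
    def _valid(df):
        return 0 < df["case"].sum() < len(df)

    def test_constant_statistic_gives_degenerate_interval(self):
        ci = bootstrap_ci(lambda df: 3.25, self._cohort(), replicates=200, seed=1)
        assert (ci.lower, ci.upper) == (3.25, 3.25)

    def test_same_seed_reproduces_interval_exactly(self):
        cohort = self._cohort()
        a = bootstrap_ci(self._auc_stat, cohort, replicates=200, seed=42, valid=self._valid)
        b = bootstrap_ci(self._auc_stat, cohort, replicates=200, seed=42, valid=self._valid)
        assert a == b

    def test_interval_width_shrinks_with_sample_size(self):
        small = self._cohort(n=50, seed=3)
        large = self._cohort(n=500, seed=3)
        ci_small = bootstrap_ci(self._auc_stat, small, replicates=300, seed=7, valid=self._valid)
        ci_large = bootstrap_ci(self._auc_stat, large, replicates=300, seed=7, valid=self._valid)
        assert (ci_large.upper - ci_large.lower) < (ci_small.upper - ci_small.lower)

    def test_mostly_undefined_statistic_fails_naming_it(self):
        def broken_stat(df):
            raise RuntimeError("boom")

        with pytest.raises(RuntimeError, match="broken_stat"):
            bootstrap_ci(broken_stat, self._cohort(), replicates=100, seed=0)

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError, match="100"):
            bootstrap_ci(lambda df: 0.0, self._cohort(), replicates=50, seed=0)


class TestCaseDefinitions:
    def test_standard_definitions_partition_groups(self):
        assert CASE_DEFINITIONS["primary"].case_groups == {1}
        assert CASE_DEFINITIONS["radiographic"].case_groups == {1, 2}
        assert CASE_DEFINITIONS["pain"].case_groups == {1, 3}
        for cd in CASE_DEFINITIONS.values():
            assert cd.case_groups | cd.control_groups == {1, 2, 3, 4}
            assert not cd.case_groups & cd.control_groups

    def test_overlapping_definition_rejected(self):
        with pytest.raises(ValueError):
            CaseDefinition("bad", frozenset({1, 2}), frozenset({2, 3, 4}))

    def test_is_case_vectorizes(self):
        cd = CASE_DEFINITIONS["radiographic"]
        np.testing.assert_array_equal(
            cd.is_case([1, 2, 3, 4]), np.array([True, True, False, False])
        )


class TestCohortTable:
    def _frame(self):
        return pd.DataFrame(
            {
                "knee_id": [0, 1, 2],
                "reader_id": 1,
                "session_id": 1,
                "v_eff_mm3": [1.0, 2.0, 3.0],
                "v_norm_mm3_per_slice": [0.1, 0.2, 0.3],
                "x_hoff_mm3": [5.0, 6.0, 7.0],
                "grade": [0, 1, 2],
                "group": [1, 2, 4],
            }
        )

    def test_valid_table_accepted_and_round_trips(self, tmp_path):
        table = CohortTable(self._frame())
        path = tmp_path / "cohort.csv"
        table.to_csv(path)
        back = CohortTable.from_csv(path)
        pd.testing.assert_frame_equal(back.df, table.df)

    def test_duplicate_knee_in_same_read_rejected(self):
        df = pd.concat([self._frame(), self._frame().iloc[[0]]], ignore_index=True)
        with pytest.raises(ValueError, match="unique"):
            CohortTable(df)

    @pytest.mark.parametrize("col,bad", [("grade", 5), ("group", 0)])
    def test_out_of_range_codes_rejected(self, col, bad):
        df = self._frame()
        df.loc[0, col] = bad
        with pytest.raises(ValueError):
            CohortTable(df)


class TestBattery:
    def test_battery_reports_all_analyses(self):
        from synovolume import simulate_cohort

        _, cohort, _ = simulate_cohort(n=80, seed=5)
        out = run_validation_battery(cohort, bootstrap_replicates=100, seed=5)
        analyses = set(out["analysis"])
        assert {"spearman_vs_grade", "icc_intra_reader", "icc_inter_reader"} <= analyses
        assert {"auc_primary", "auc_radiographic", "auc_pain"} <= analyses
        aucs = out[out["analysis"].str.startswith("auc_")]
        assert ((aucs["ci_lower"] <= aucs["value"]) & (aucs["value"] <= aucs["ci_upper"])).all()

    def test_phantom_cohort_spearman_beats_permuted_labels(self):
        """Measure-grade correlation exceeds its label-permuted counterpart
        in >= 99 of 100 seeded runs when the grade effect is positive."""
        from synovolume import simulate_cohort

        wins = 0
        for seed in range(100):
            _, cohort, _ = simulate_cohort(n=60, seed=seed)
            primary = cohort.primary_reads()
            rng = np.random.default_rng(seed + 10_000)
            permuted = rng.permutation(primary["grade"].to_numpy())
            if np.all(permuted == permuted[0]):
                continue
            r_true = spearman_r(primary["v_eff_mm3"], primary["grade"])
            r_perm = spearman_r(primary["v_eff_mm3"], permuted)
            wins += r_true > r_perm
        assert wins >= 99
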