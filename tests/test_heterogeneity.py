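"""CV statistics and nonparametric tests against hand values and enumeration oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from rppahet import (EffectModel, StudyDesign, VarianceModel, boxplot_stats, cv,
                     friedman_cv_test, generate_study, group_summary,
                     heterogeneity_table, interpatient_cv, intratumoral_cvs,
                     mann_whitney, rms_average)
from rppahet.errors import ValidationError
from rppahet.heterogeneity import friedman_statistic
from conftest import make_meta


def exact_mw_pvalue(x, y):
    """Brute-force two-sided Mann-Whitney p: enumerate every group labelling."""
    x, y = list(x), list(y)
    combined = x + y
    nx = len(x)

    def u_stat(xs, ys):
        return sum(1 for a in xs for b in ys if a > b) \
            + 0.5 * sum(1 for a in xs for b in ys if a == b)

    u_obs = u_stat(x, y)
    us = []
    for idx in itertools.combinations(range(len(combined)), nx):
        xs = [combined[i] for i in idx]
        ys = [combined[i] for i in range(len(combined)) if i not in idx]
        us.append(u_stat(xs, ys))
    us = np.array(us)
    p = 2 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return min(p, 1.0)


class TestCv:
    def test_constant_is_zero(self):
        assert cv([5.0, 5.0, 5.0]) == 0.0

    def test_hand_value(self):
        # sd of {1,2,3} with n-1 denominator is 1, mean is 2
        assert cv([1.0, 2.0, 3.0]) == pytest.approx(50.0)

    @given(st.floats(min_value=0.01, max_value=1e4))
    @settings(deadline=None, derandomize=True)
    def test_scale_invariance(self, c):
        base = [1.0, 2.0, 4.0, 8.0]
        assert cv([c * v for v in base]) == pytest.approx(cv(base), rel=1e-9)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValidationError):
            cv([1.0])

    def test_non_positive_mean_rejected(self):
        with pytest.raises(ValidationError):
            cv([-1.0, 1.0])


class TestRmsAverage:
    def test_constant(self):
        assert rms_average([25.0, 25.0, 25.0]) == 25.0

    def test_hand_value(self):
        assert rms_average([3.0, 4.0]) == pytest.approx(math.sqrt(12.5))

    @given(st.lists(st.floats(min_value=0.0, max_value=100.0), min_size=1,
                    max_size=20))
    @settings(deadline=None, derandomize=True)
    def test_bounded_by_mean_and_extremes(self, values):
        rms = rms_average(values)
        assert rms >= np.mean(values) - 1e-9
        assert min(values) - 1e-9 <= rms <= max(values) + 1e-9

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            rms_average([])


class TestIntratumoralCvs:
    def test_single_patient_hand_value(self, toy_matrix_meta):
        matrix, meta = toy_matrix_meta
        records = intratumoral_cvs(matrix, meta)
        assert len(records) == 1
        assert records.iloc[0]["cv_percent"] == pytest.approx(50.0)
        assert records.iloc[0]["n_values"] == 3

    def test_normal_samples_ignored(self, toy_matrix_meta):
        matrix, meta = toy_matrix_meta
        with_extra = matrix.copy()
        with_extra["n2"] = 100.0  # wild normal value must not affect tumor CVs
        meta2 = pd.concat([meta, make_meta([("n2", "n2", "healthy_tube")])],
                          ignore_index=True)
        pd.testing.assert_frame_equal(intratumoral_cvs(with_extra, meta2),
                                      intratumoral_cvs(matrix, meta))

    def test_single_sample_patient_skipped(self):
        matrix = pd.DataFrame({"t1": [1.0], "t2": [2.0], "t3": [3.0]},
                              index=pd.Index(["A"], name="protein"))
        meta = make_meta([("t1", "p1", "tumor"), ("t2", "p1", "tumor"),
                          ("t3", "p2", "tumor")])
        records = intratumoral_cvs(matrix, meta)
        assert list(records["patient_id"]) == ["p1"]

    def test_no_tumor_samples_rejected(self):
        matrix = pd.DataFrame({"n1": [1.0]}, index=pd.Index(["A"], name="protein"))
        meta = make_meta([("n1", "n1", "healthy_tube")])
        with pytest.raises(ValidationError, match="tumor"):
            intratumoral_cvs(matrix, meta)


class TestInterpatientCv:
    def test_reduces_to_cv_of_patient_means(self):
        matrix = pd.DataFrame({"a1": [1.0], "a2": [1.0], "b1": [3.0]},
                              index=pd.Index(["A"], name="protein"))
        meta = make_meta([("a1", "pa", "tumor"), ("a2", "pa", "tumor"),
                          ("b1", "pb", "tumor")])
        records = interpatient_cv(matrix, meta)
        assert records.iloc[0]["cv_percent"] == pytest.approx(cv([1.0, 3.0]))

    def test_identical_patients_give_zero(self):
        matrix = pd.DataFrame({"a1": [2.0], "b1": [2.0], "c1": [2.0]},
                              index=pd.Index(["A"], name="protein"))
        meta = make_meta([("a1", "pa", "tumor"), ("b1", "pb", "tumor"),
                          ("c1", "pc", "tumor")])
        assert interpatient_cv(matrix, meta).iloc[0]["cv_percent"] == 0.0

    def test_recovers_between_patient_cv_without_within_noise(self):
        # 200 patients, no within-tumor noise: the CV of patient means
        # estimates the between-patient CV directly
        design = StudyDesign(200, (2,) * 200, 0, 0, 1, (False,))
        variance = VarianceModel(1000.0, 0.25, 0.0, 0.0, n_proteins=1)
        matrix, meta, _ = generate_study(design, variance, EffectModel.null(), seed=3)
        records = interpatient_cv(matrix, meta)
        assert records.iloc[0]["cv_percent"] == pytest.approx(25.0, abs=3.0)

    def test_single_group_rejected(self, toy_matrix_meta):
        matrix, meta = toy_matrix_meta
        with pytest.raises(ValidationError, match=">= 2"):
            interpatient_cv(matrix, meta, "tumor")


class TestGroupSummary:
    @staticmethod
    def table_from(rms_values, inter_values, proteins):
        return pd.DataFrame({"rms_cv_percent": rms_values,
                             "interpatient_cv_percent": inter_values},
                            index=pd.Index(proteins, name="protein"))

    def test_two_protein_hand_values(self):
        table = self.table_from([17.0, 53.0], [10.0, 20.0], ["A", "B"])
        out = group_summary(table, [True, False])
        overall = out[(out.statistic == "rms") & (out.group == "overall")].iloc[0]
        assert overall["mean_cv_percent"] == 35.0
        assert (overall["min_cv_percent"], overall["max_cv_percent"]) == (17.0, 53.0)

    def test_degenerate_range(self):
        table = self.table_from([20.0, 20.0], [20.0, 20.0], ["A", "B"])
        out = group_summary(table, [False, False])
        row = out[(out.statistic == "rms") & (out.group == "overall")].iloc[0]
        assert row["min_cv_percent"] == row["max_cv_percent"] == 20.0

    def test_empty_group_absent_not_zero(self):
        table = self.table_from([20.0], [20.0], ["A"])
        out = group_summary(table, [False])
        assert "phospho" not in set(out["group"])

    def test_monte_carlo_recovery_of_within_cv(self):
        design = StudyDesign(13, (7,) * 13, 0, 0, 36, (False,) * 36)
        variance = VarianceModel.default(36)
        matrix, meta, _ = generate_study(design, variance, EffectModel.null(), seed=17)
        table = heterogeneity_table(matrix, meta)
        out = group_summary(table, [False] * 36)
        row = out[(out.statistic == "rms") & (out.group == "overall")].iloc[0]
        assert 22.0 <= row["mean_cv_percent"] <= 28.0


class TestFriedman:
    @staticmethod
    def records_from(matrix):
        """patient x protein CV matrix -> long records."""
        rows = []
        for i, patient in enumerate(matrix.index):
            for j, protein in enumerate(matrix.columns):
                rows.append({"protein": protein, "patient_id": patient,
                             "cv_percent": matrix.iloc[i, j], "n_values": 5})
        return pd.DataFrame(rows)

    def test_hand_example_consistent_ranking(self):
        # ranks (1,2,3) in every one of 3 blocks: chi2 = 6, p = exp(-3)
        wide = pd.DataFrame([[1.0, 2.0, 3.0]] * 3, index=["p1", "p2", "p3"],
                            columns=["A", "B", "C"])
        res = friedman_cv_test(self.records_from(wide))
        assert res.statistic == pytest.approx(6.0)
        assert res.p_value == pytest.approx(math.exp(-3), rel=1e-6)

    def test_all_tied_blocks_give_zero_statistic(self):
        wide = pd.DataFrame([[2.0, 2.0, 2.0]] * 3, index=["p1", "p2", "p3"],
                            columns=["A", "B", "C"])
        res = friedman_cv_test(self.records_from(wide))
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_statistic_matches_rank_formula_on_random_instances(self):
        # enumeration-backed oracle: recompute from raw rank sums for every
        # 3x3 rank assignment reachable from random data
        rng = np.random.default_rng(4)
        for _ in range(25):
            data = rng.integers(1, 5, size=(3, 3)).astype(float)  # ties likely
            wide = pd.DataFrame(data, index=["p1", "p2", "p3"],
                                columns=["A", "B", "C"])
            res = friedman_cv_test(self.records_from(wide))
            ranks = np.apply_along_axis(stats.rankdata, 1, data)
            assert res.statistic == pytest.approx(friedman_statistic(ranks))

    def test_agrees_with_scipy_on_tie_free_data(self):
        rng = np.random.default_rng(5)
        data = rng.permuted(np.tile(np.arange(1.0, 6.0), (8, 1)), axis=1)
        wide = pd.DataFrame(data, index=[f"p{i}" for i in range(8)],
                            columns=list("ABCDE"))
        res = friedman_cv_test(self.records_from(wide))
        ref = stats.friedmanchisquare(*[data[:, j] for j in range(5)])
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_permutation_null_calibration_3x3(self):
        # the chi-square p is an approximation; on the full 3x3 permutation
        # null (216 equally likely rank tables) the statistic 6.0 is the
        # most extreme value, reached only when all blocks rank identically
        # (6 tables), so the exact tail probability is 6/216
        stats_all = []
        for perm in itertools.product(itertools.permutations([1.0, 2.0, 3.0]),
                                      repeat=3):
            stats_all.append(friedman_statistic(np.array(perm)))
        stats_all = np.array(stats_all)
        assert stats_all.max() == pytest.approx(6.0)
        assert (stats_all >= 6.0 - 1e-9).mean() == pytest.approx(6 / 216)

    def test_incomplete_blocks_dropped(self):
        wide = pd.DataFrame([[1.0, 2.0, 3.0]] * 3 + [[1.0, np.nan, 3.0]],
                            index=["p1", "p2", "p3", "p4"], columns=["A", "B", "C"])
        records = self.records_from(wide).dropna(subset=["cv_percent"])
        res = friedman_cv_test(records)
        assert "3 blocks" in res.method

    def test_too_few_blocks_rejected(self):
        wide = pd.DataFrame([[1.0, 2.0]], index=["p1"], columns=["A", "B"])
        with pytest.raises(ValidationError, match="blocks"):
            friedman_cv_test(self.records_from(wide))


class TestMannWhitney:
    def test_hand_example(self):
        res = mann_whitney([1.0, 2.0], [3.0, 4.0])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1 / 3)
        assert res.method == "exact enumeration"

    def test_identical_multisets_give_p_one(self):
        res = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == 1.0

    def test_all_equal_values_give_p_one(self):
        res = mann_whitney([2.0] * 10, [2.0] * 12)
        assert res.p_value == 1.0

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_p_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.permutation(np.arange(1.0, 9.0))  # tie-free, nx = ny = 4
        x, y = vals[:4], vals[4:]
        res = mann_whitney(x, y)
        assert res.method == "exact enumeration"
        assert res.p_value == pytest.approx(exact_mw_pvalue(x, y), rel=1e-9)

    def test_large_samples_use_normal_approximation(self):
        rng = np.random.default_rng(9)
        res = mann_whitney(rng.normal(size=20), rng.normal(size=20))
        assert "normal approximation" in res.method

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney([], [1.0])


class TestBoxplotStats:
    def test_hand_example_with_outlier(self):
        out = boxplot_stats([1.0, 2.0, 3.0, 4.0, 100.0])
        assert (out.median, out.q25, out.q75) == (3.0, 2.0, 4.0)
        assert out.whisker_high == 4.0  # fence at 4 + 1.5*2 = 7
        assert out.whisker_low == 1.0
        assert list(out.outliers) == [100.0]

    def test_constant_input_degenerate_box(self):
        out = boxplot_stats([7.0, 7.0, 7.0])
        assert out.median == out.q25 == out.q75 == 7.0
        assert out.whisker_low == out.whisker_high == 7.0
        assert out.outliers.size == 0

    def test_symmetric_input_has_zero_median(self):
        out = boxplot_stats([-3.0, -1.0, 0.0, 1.0, 3.0])
        assert out.median == 0.0

    def test_single_value(self):
        out = boxplot_stats([5.0])
        assert out.median == out.whisker_low == out.whisker_high == 5.0
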