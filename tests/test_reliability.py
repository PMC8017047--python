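import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import petquant as pq
from petquant.reliability import PairedMeasurements, RmAnovaResult

# fixed 6-subject test/retest fixture used across the oracle checks
TEST6 = np.array([13.2, 11.5, 15.0, 12.1, 14.3, 10.8])
RETEST6 = np.array([14.1, 11.9, 15.8, 12.0, 15.2, 11.5])


def _pairs(test=TEST6, retest=RETEST6):
    return PairedMeasurements(tuple(f"s{i}" for i in range(len(test))), test, retest)


class TestTrv:
    def test_identical_sessions_give_zero(self):
        assert pq.trv(13.2, 13.2) == 0.0

    def test_worked_pair(self):
        # (14.7 − 13.2)/13.95 × 100
        assert pq.trv(13.2, 14.7) == pytest.approx(10.7527, abs=1e-3)
        assert pq.atrv(13.2, 14.7) == pytest.approx(10.7527, abs=1e-3)

    def test_zero_mean_rejected(self):
        with pytest.raises(ZeroDivisionError):
            pq.trv(-1.0, 1.0)

    @settings(derandomize=True, max_examples=60)
    @given(
        a=st.floats(min_value=0.5, max_value=50.0),
        b=st.floats(min_value=0.5, max_value=50.0),
    )
    def test_antisymmetry_and_swap_invariance(self, a, b):
        assert pq.trv(a, b) == pytest.approx(-pq.trv(b, a), rel=1e-12)
        assert pq.atrv(a, b) == pytest.approx(pq.atrv(b, a), rel=1e-12)
        assert pq.atrv(a, b) >= 0

    def test_cohort_atrv_bounds_mean_trv(self):
        t = np.mean(pq.atrv(TEST6, RETEST6))
        assert t >= abs(np.mean(pq.trv(TEST6, RETEST6)))


class TestIcc:
    def test_perfect_retest_gives_one(self):
        assert pq.icc(_pairs(TEST6, TEST6)) == pytest.approx(1.0)

    def test_session_shift_with_equal_subjects_is_negative(self):
        test = np.full(4, 10.0)
        retest = np.full(4, 12.0)
        assert pq.icc(_pairs(test, retest)) < 0

    def test_matches_hand_computed_mean_squares(self):
        """Independent one-way ANOVA decomposition computed with explicit loops."""
        data = np.column_stack([TEST6, RETEST6])
        n, k = data.shape
        grand = sum(data[i, j] for i in range(n) for j in range(k)) / (n * k)
        subj_means = [sum(data[i, j] for j in range(k)) / k for i in range(n)]
        bs = k * sum((m - grand) ** 2 for m in subj_means) / (n - 1)
        ws = sum(
            (data[i, j] - subj_means[i]) ** 2 for i in range(n) for j in range(k)
        ) / (n * (k - 1))
        expected = (bs - ws) / (bs + ws)
        assert pq.icc(_pairs()) == pytest.approx(expected, abs=1e-10)

    def test_matches_pingouin_one_way_icc(self):
        pg = pytest.importorskip("pingouin")
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(6), 2),
                "rater": np.tile(["test", "retest"], 6),
                "score": np.column_stack([TEST6, RETEST6]).ravel(),
            }
        )
        ref = pg.intraclass_corr(long, targets="subject", raters="rater", ratings="score")
        icc1 = float(ref.loc[ref["Type"].str.startswith("ICC1") |
                             (ref["Type"] == "ICC(1,1)"), "ICC"].iloc[0])
        assert pq.icc(_pairs()) == pytest.approx(icc1, abs=1e-10)

    @settings(derandomize=True, max_examples=30)
    @given(scale=st.floats(min_value=0.1, max_value=10.0),
           offset=st.floats(min_value=-50.0, max_value=50.0))
    def test_affine_invariance(self, scale, offset):
        base = pq.icc(_pairs())
        shifted = pq.icc(_pairs(scale * TEST6 + offset, scale * RETEST6 + offset))
        assert shifted == pytest.approx(base, abs=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pq.icc(_pairs(np.full(4, 5.0), np.full(4, 5.0)))

    def test_classification_bands(self):
        assert pq.icc_classification(0.95) == "excellent"
        assert pq.icc_classification(0.8) == "good"
        assert pq.icc_classification(0.6) == "moderate"
        assert pq.icc_classification(0.3) == "poor"


class TestPercentBias:
    def test_identical_vectors_zero(self):
        assert pq.percent_bias(TEST6, TEST6) == 0.0

    def test_worked_pair_vs_average(self):
        # (12.7 − 13.2)/12.95 × 100
        assert pq.percent_bias([13.2], [12.7], "vs_average") == pytest.approx(-3.861, abs=1e-3)

    def test_worked_pair_vs_reference(self):
        assert pq.percent_bias([13.2], [12.7], "vs_reference") == pytest.approx(-3.788, abs=1e-3)

    def test_vs_average_antisymmetric(self):
        fwd = pq.percent_bias(TEST6, RETEST6, "vs_average")
        rev = pq.percent_bias(RETEST6, TEST6, "vs_average")
        assert fwd == pytest.approx(-rev, rel=1e-12)

    def test_unknown_definition_rejected(self):
        with pytest.raises(ValueError):
            pq.percent_bias(TEST6, RETEST6, "vs_median")


class TestPearson:
    def test_perfect_linear_relation(self):
        r, p = pq.pearson_r(TEST6, 2.0 * TEST6 + 1.0)
        assert r == pytest.approx(1.0)
        assert p < 1e-6

    def test_orthogonalized_sample_gives_zero(self):
        x = TEST6 - TEST6.mean()
        y = RETEST6 - RETEST6.mean()
        y_orth = y - (x @ y) / (x @ x) * x
        r, _ = pq.pearson_r(x, y_orth)
        assert abs(r) < 1e-12

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(12)
        x, y = rng.normal(size=20), rng.normal(size=20)
        r, _ = pq.pearson_r(x, y)
        expected = (np.mean(x * y) - x.mean() * y.mean()) / (np.std(x) * np.std(y))
        assert r == pytest.approx(expected, abs=1e-12)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            pq.pearson_r([1.0, 2.0], [1.0, 2.0])


class TestRmAnovaLsd:
    def test_identical_methods_give_zero_f(self):
        subj = np.array([10.0, 12.0, 14.0, 9.0])
        table = pd.DataFrame({m: subj for m in ("a", "b", "c")})
        res = pq.rm_anova_lsd(table)
        assert res.f_statistic == pytest.approx(0.0)
        assert not res.omnibus_significant
        assert res.lsd.empty

    def test_large_shift_flagged_in_all_its_pairs(self):
        rng = np.random.default_rng(3)
        base = rng.normal(12, 1, 8)
        table = pd.DataFrame(
            {
                "a": base + rng.normal(0, 0.05, 8),
                "b": base + rng.normal(0, 0.05, 8),
                "c": base + 5.0 + rng.normal(0, 0.05, 8),
            }
        )
        res = pq.rm_anova_lsd(table)
        assert res.omnibus_significant
        involving_c = res.lsd[(res.lsd.method_a == "c") | (res.lsd.method_b == "c")]
        assert involving_c["significant"].all()
        other = res.lsd[(res.lsd.method_a != "c") & (res.lsd.method_b != "c")]
        assert not other["significant"].any()

    def test_matches_hand_computed_block_anova(self):
        table = pd.DataFrame(
            {
                "m1": [10.0, 12.0, 11.0, 13.0],
                "m2": [11.0, 12.5, 11.5, 14.0],
                "m3": [9.5, 11.0, 10.0, 12.0],
            }
        )
        data = table.to_numpy()
        n, k = data.shape
        grand = data.mean()
        ss_m = n * sum((data[:, j].mean() - grand) ** 2 for j in range(k))
        ss_s = k * sum((data[i].mean() - grand) ** 2 for i in range(n))
        ss_t = sum((data[i, j] - grand) ** 2 for i in range(n) for j in range(k))
        ss_e = ss_t - ss_m - ss_s
        f_expected = (ss_m / (k - 1)) / (ss_e / ((n - 1) * (k - 1)))
        res = pq.rm_anova_lsd(table)
        assert res.f_statistic == pytest.approx(f_expected, abs=1e-10)
        assert res.df == (2, 6)

    def test_matches_pingouin_rm_anova(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(17)
        table = pd.DataFrame(
            {m: rng.normal(12 + s, 1.0, 10) for s, m in enumerate(("a", "b", "c", "d"))}
        )
        long = table.reset_index().melt(id_vars="index", var_name="method", value_name="vt")
        ref = pg.rm_anova(data=long, dv="vt", within="method", subject="index")
        res = pq.rm_anova_lsd(table)
        assert res.f_statistic == pytest.approx(float(ref["F"].iloc[0]), rel=1e-9)
        pcol = "p_unc" if "p_unc" in ref.columns else "p-unc"
        assert res.p_value == pytest.approx(float(ref[pcol].iloc[0]), rel=1e-9)

    def test_missing_cells_rejected(self):
        table = pd.DataFrame({"a": [1.0, np.nan], "b": [2.0, 3.0]})
        with pytest.raises(ValueError, match="missing"):
            pq.rm_anova_lsd(table)

    def test_result_type(self):
        table = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [1.1, 2.1, 3.1]})
        assert isinstance(pq.rm_anova_lsd(table), RmAnovaResult)


class TestAvDifference:
    def _tables(self, art_parent, ven_parent, times=(30.0, 60.0, 120.0, 180.0)):
        t = np.asarray(times)
        pf = np.full(t.size, 0.5)
        art = pq.BloodSampleTable(t, np.asarray(art_parent) * 2, np.asarray(art_parent) / pf,
                                  pf, "arterial")
        ven = pq.BloodSampleTable(t, np.asarray(ven_parent) * 2, np.asarray(ven_parent) / pf,
                                  pf, "venous")
        return art, ven

    def test_identical_tables_zero_everywhere(self):
        art, ven = self._tables([2.0, 1.5, 1.0, 0.5], [2.0, 1.5, 1.0, 0.5])
        np.testing.assert_allclose(pq.av_difference(art, ven).to_numpy(), 0.0)

    def test_worked_value_at_30min(self):
        art, ven = self._tables([2.0, 1.5, 1.0, 0.5], [1.5, 1.5, 1.0, 0.5])
        assert pq.av_difference(art, ven)[30.0] == pytest.approx(25.0)

    def test_missing_timepoint_named_in_error(self):
        art, ven = self._tables([2.0, 1.5, 1.0], [2.0, 1.5, 1.0], times=(30.0, 60.0, 120.0))
        with pytest.raises(ValueError, match="180"):
            pq.av_difference(art, ven)

    def test_profile_summary_shape(self):
        pairs = [self._tables([2.0, 1.5, 1.0, 0.5], [1.8, 1.5, 1.1, 0.7]) for _ in range(3)]
        df = pq.av_profile_summary(pairs)
        assert list(df["time_min"]) == [30.0, 60.0, 120.0, 180.0]
        assert (df["n"] == 3).all()
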