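import numpy as np
import pandas as pd
import pytest

from proteostrat.survival import (
    build_endpoint,
    classify_nuclei,
    cox_fit,
    cox_score_test,
    group_rank_tests,
    km_curve,
    logrank,
    lymphocyte_growth,
    viability_normalize,
)


def km_closed_form(times, events):
    """Independent oracle: textbook product-limit over event times."""
    order = np.argsort(times)
    t_sorted = np.asarray(times, float)[order]
    e_sorted = np.asarray(events, int)[order]
    s = 1.0
    out = {}
    for t in np.unique(t_sorted):
        at_risk = (t_sorted >= t).sum()
        deaths = ((t_sorted == t) & (e_sorted == 1)).sum()
        s *= 1.0 - deaths / at_risk
        out[float(t)] = s
    return out


class TestBuildEndpoint:
    def _records(self):
        return pd.DataFrame({
            "collection_day": [0.0, 0.0, 0.0, 0.0],
            "diagnosis_day": [-500.0, -300.0, -100.0, -900.0],
            "treatment_day": [100.0, np.nan, np.nan, np.nan],
            "death_day": [np.nan, 350.0, np.nan, np.nan],
            "last_contact_day": [150.0, 400.0, 600.0, np.nan],
        }, index=["p1", "p2", "p3", "p4"])

    def test_treated_patient_event(self):
        out = build_endpoint(self._records(), "TTNT")
        assert out.loc["p1", "time_days"] == 100
        assert out.loc["p1", "event"] == 1

    def test_death_before_treatment_censored(self):
        out = build_endpoint(self._records(), "TTNT")
        assert out.loc["p2", "time_days"] == 400
        assert out.loc["p2", "event"] == 0

    def test_no_followup_excluded_with_count(self):
        with pytest.warns(UserWarning, match="1 sample"):
            out = build_endpoint(self._records(), "TTNT")
        assert "p4" not in out.index
        assert out.attrs["n_excluded"] == 1

    def test_os_uses_death(self):
        with pytest.warns(UserWarning):
            out = build_endpoint(self._records(), "OS")
        assert out.loc["p2", "time_days"] == 350
        assert out.loc["p2", "event"] == 1
        assert out.loc["p3", "event"] == 0

    def test_ttft_runs_from_diagnosis(self):
        out = build_endpoint(self._records(), "TTFT")
        assert out.loc["p1", "time_days"] == 600  # 100 - (-500)

    def test_treatment_before_origin_rejected(self):
        rec = self._records()
        rec.loc["p1", "treatment_day"] = -10.0
        with pytest.raises(ValueError, match="p1"):
            build_endpoint(rec, "TTNT")


class TestKmCurve:
    def test_no_events_flat_undefined_median(self):
        curve, median = km_curve([5, 8, 2], [0, 0, 0])
        assert (curve["survival"] == 1.0).all()
        assert median is None

    def test_two_events_product_limit(self):
        curve, median = km_curve([1, 2], [1, 1])
        lookup = dict(zip(curve["time"], curve["survival"]))
        assert lookup[1.0] == 0.5 and lookup[2.0] == 0.0
        assert median == 1.0

    def test_censor_then_event_risk_set(self):
        curve, _ = km_curve([1, 2], [0, 1])
        lookup = dict(zip(curve["time"], curve["survival"]))
        assert lookup[1.0] == 1.0 and lookup[2.0] == 0.0

    def test_matches_closed_form_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(3, 40))
            times = rng.integers(1, 15, n).astype(float)
            events = rng.integers(0, 2, n)
            if events.sum() == 0:
                continue
            curve, _ = km_curve(times, events)
            oracle = km_closed_form(times, events)
            lookup = dict(zip(curve["time"], curve["survival"]))
            for t, s in oracle.items():
                assert lookup[t] == pytest.approx(s, abs=1e-12)

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            km_curve([-1, 2], [1, 1])


class TestLogrank:
    def test_identical_groups_null(self):
        g = pd.DataFrame({"time_days": [1, 2, 3], "event": [1, 1, 0]})
        chi2, df, p = logrank([g, g.copy()])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_toy(self):
        gA = pd.DataFrame({"time_days": [1, 2], "event": [1, 1]})
        gB = pd.DataFrame({"time_days": [3, 4], "event": [1, 1]})
        chi2, df, p = logrank([gA, gB])
        assert chi2 == pytest.approx(2.8824, abs=1e-3)
        assert df == 1

    def test_power_with_planted_hazard(self):
        rejections = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            tA = rng.exponential(1000, 100)
            tB = rng.exponential(1000 / 3, 100)
            gA = pd.DataFrame({"time_days": tA, "event": np.ones(100, int)})
            gB = pd.DataFrame({"time_days": tB, "event": np.ones(100, int)})
            if logrank([gA, gB])[2] < 0.01:
                rejections += 1
        assert rejections >= 38  # >= 95% power

    def test_empty_group_rejected(self):
        g = pd.DataFrame({"time_days": [1], "event": [1]})
        with pytest.raises(ValueError):
            logrank([g, g.iloc[:0]])


class TestCox:
    def test_null_covariate_ci_covers_one(self):
        rng = np.random.default_rng(0)
        n = 800
        x = rng.normal(size=n)
        t = rng.exponential(100, n)
        ep = pd.DataFrame({"time_days": t, "event": np.ones(n, int)},
                          index=range(n))
        res = cox_fit(pd.DataFrame({"x": x}, index=range(n)), ep)
        row = res.table.iloc[0]
        assert abs(row["coef"]) < 0.1
        assert row["ci_lower"] < 1.0 < row["ci_upper"]

    def test_hr_recovery_and_ci_coverage(self):
        """True HR 2, n = 1000: estimate near 2, ~95% CI coverage."""
        covered, estimates = 0, []
        n_rep = 60
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            x = rng.integers(0, 2, 1000).astype(float)
            t = rng.exponential(1.0 / (0.001 * np.exp(np.log(2.0) * x)))
            c = rng.uniform(0, 3000, 1000)
            ep = pd.DataFrame({"time_days": np.minimum(t, c),
                               "event": (t <= c).astype(int)},
                              index=range(1000))
            res = cox_fit(pd.DataFrame({"x": x}, index=range(1000)), ep)
            row = res.table.iloc[0]
            estimates.append(row["hr"])
            if row["ci_lower"] <= 2.0 <= row["ci_upper"]:
                covered += 1
        assert 1.8 <= np.mean(estimates) <= 2.2
        assert covered / n_rep >= 0.9

    def test_matches_lifelines_oracle(self):
        from lifelines import CoxPHFitter
        rng = np.random.default_rng(4)
        n = 300
        df = pd.DataFrame({
            "x1": rng.normal(size=n),
            "x2": rng.integers(0, 2, n).astype(float),
        })
        t = rng.exponential(1.0 / (0.01 * np.exp(0.5 * df["x1"]
                                                 - 0.7 * df["x2"])))
        c = rng.uniform(0, 200, n)
        ep = pd.DataFrame({"time_days": np.minimum(t, c),
                           "event": (t <= c).astype(int)}, index=df.index)
        res = cox_fit(df, ep, ties="efron")
        ll_df = df.copy()
        ll_df["T"] = ep["time_days"]
        ll_df["E"] = ep["event"]
        cph = CoxPHFitter()
        cph.fit(ll_df, duration_col="T", event_col="E")
        assert np.allclose(res.table["coef"],
                           cph.params_[["x1", "x2"]], atol=1e-5)
        assert np.allclose(res.table["se"],
                           cph.standard_errors_[["x1", "x2"]], atol=1e-5)

    def test_interaction_recovery(self):
        rng = np.random.default_rng(9)
        n = 1500
        a = rng.integers(0, 2, n).astype(float)
        b = rng.integers(0, 2, n).astype(float)
        lin = 0.3 * a + 0.2 * b + 0.8 * a * b
        t = rng.exponential(1.0 / (0.001 * np.exp(lin)))
        ep = pd.DataFrame({"time_days": t, "event": np.ones(n, int)},
                          index=range(n))
        cov = pd.DataFrame({"a": a, "b": b, "ab": a * b}, index=range(n))
        res = cox_fit(cov, ep)
        row = res.table.loc["ab"]
        assert row["ci_lower"] <= np.exp(0.8) <= row["ci_upper"]

    def test_score_test_equals_logrank_tie_free(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = 80
            x = rng.integers(0, 2, n).astype(float)
            t = rng.exponential(1.0 / (0.01 * np.exp(0.6 * x)))
            ep = pd.DataFrame({"time_days": t, "event": np.ones(n, int)},
                              index=range(n))
            chi2, _, _ = logrank([ep[x == 0], ep[x == 1]])
            stat, _ = cox_score_test(pd.DataFrame({"x": x}, index=range(n)),
                                     ep, ties="breslow")
            assert abs(chi2 - stat) < 1e-6

    def test_constant_covariate_rejected(self):
        ep = pd.DataFrame({"time_days": [1.0, 2.0, 3.0], "event": [1, 1, 1]},
                          index=range(3))
        with pytest.raises(ValueError, match="constant"):
            cox_fit(pd.DataFrame({"x": [1.0, 1.0, 1.0]}, index=range(3)), ep)

    def test_perfect_separation_flagged(self):
        # events only while x = 1 at early times: monotone likelihood
        ep = pd.DataFrame({
            "time_days": [1.0, 2.0, 3.0, 10.0, 11.0, 12.0],
            "event": [1, 1, 1, 0, 0, 0]}, index=range(6))
        x = pd.DataFrame({"x": [1.0, 1, 1, 0, 0, 0]}, index=range(6))
        with pytest.warns(UserWarning):
            res = cox_fit(x, ep)
        assert res.warnings


class TestLymphocyteGrowth:
    def test_exact_doubling_slope(self):
        series = pd.DataFrame({
            "sample_id": ["s1"] * 4,
            "day": [0, 1, 2, 3],
            "count": [100, 200, 400, 800],
        })
        out = lymphocyte_growth(series)
        assert out.loc["s1", "growth_rate"] == pytest.approx(np.log10(2),
                                                             abs=1e-12)

    def test_constant_counts_zero_slope(self):
        series = pd.DataFrame({
            "sample_id": ["s1"] * 5, "day": range(5), "count": [300] * 5})
        assert lymphocyte_growth(series).loc["s1", "growth_rate"] == \
            pytest.approx(0.0, abs=1e-12)

    def test_three_points_excluded(self):
        series = pd.DataFrame({
            "sample_id": ["s1"] * 3, "day": [0, 1, 2],
            "count": [100, 200, 400]})
        out = lymphocyte_growth(series)
        assert "s1" not in out.index
        assert out.attrs["excluded"] == ["s1"]

    def test_nonpositive_counts_rejected(self):
        series = pd.DataFrame({
            "sample_id": ["s1"] * 4, "day": range(4),
            "count": [100, 0, 400, 800]})
        with pytest.raises(ValueError):
            lymphocyte_growth(series)

    def test_asb_grows_faster_in_default_cohort(self, default_bundle):
        out = lymphocyte_growth(default_bundle.lymph_series)
        truth = default_bundle.truth.loc[out.index]
        asb_rate = out.loc[truth == "ASB", "growth_rate"].median()
        other_rate = out.loc[truth != "ASB", "growth_rate"].median()
        assert asb_rate > other_rate


class TestViability:
    def _plate(self):
        return pd.DataFrame({
            "sample_id": ["s1"] * 4,
            "drug": ["DMSO", "DMSO", "drugA", "drugA"],
            "conc_index": [0, 0, 0, 1],
            "well_id": ["w0", "w1", "w2", "w3"],
            "n_cells": [100, 100, 100, 200],
            "n_alive": [80, 80, 40, 80],
            "is_solvent_control": [1, 1, 0, 0],
        })

    def test_solvent_mean_is_reference(self):
        out = viability_normalize(self._plate())
        w2 = out[out["well_id"] == "w2"]["viability_pct"].iloc[0]
        assert w2 == pytest.approx(50.0)
        w0 = out[out["well_id"] == "w0"]["viability_pct"].iloc[0]
        assert w0 == pytest.approx(100.0)

    def test_scale_invariance(self):
        plate = self._plate()
        scaled = plate.copy()
        scaled["n_cells"] *= 7
        scaled["n_alive"] *= 7
        a = viability_normalize(plate)["viability_pct"]
        b = viability_normalize(scaled)["viability_pct"]
        assert np.allclose(a, b)

    def test_zero_cell_well_missing(self):
        plate = self._plate()
        plate.loc[3, "n_cells"] = 0
        plate.loc[3, "n_alive"] = 0
        with pytest.warns(UserWarning, match="zero cells"):
            out = viability_normalize(plate)
        assert np.isnan(out[out["well_id"] == "w3"]["viability_pct"]).all()

    def test_no_solvent_wells_rejected(self):
        plate = self._plate()
        plate["is_solvent_control"] = 0
        with pytest.raises(ValueError):
            viability_normalize(plate)

    def test_tp53_group_resistant_to_dna_damage(self, default_bundle):
        out = viability_normalize(default_bundle.drug_plate)
        flu = out[(out["drug"] == "fludarabine") & (out["conc_index"] == 2)]
        by_sample = flu.groupby("sample_id")["viability_pct"].mean()
        truth = default_bundle.truth.loc[by_sample.index]
        assert (by_sample[truth == "TP53"].median()
                > by_sample[truth != "TP53"].median())


class TestClassifyNuclei:
    def test_all_large_alive(self):
        assert classify_nuclei([30.0, 30.0, 30.0]) == 1.0

    def test_half_split(self):
        assert classify_nuclei([10.0, 30.0]) == 0.5

    def test_boundary_is_dead(self):
        assert classify_nuclei([23.8]) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            classify_nuclei([])


class TestGroupRankTests:
    def test_identical_groups_p_one(self):
        p = group_rank_tests([1, 2, 3, 1, 2, 3],
                             ["a", "a", "a", "b", "b", "b"])
        assert p == pytest.approx(1.0)

    def test_exact_enumeration_example(self):
        p = group_rank_tests([1, 2, 3, 4, 5, 6],
                             ["a", "a", "a", "b", "b", "b"])
        assert p == pytest.approx(0.1)  # 2 / C(6,3)

    def test_three_identical_groups_kruskal_zero(self):
        from scipy.stats import kruskal
        vals = [1, 2, 3] * 3
        groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        p = group_rank_tests(vals, groups)
        assert p == pytest.approx(kruskal([1, 2, 3], [1, 2, 3],
                                          [1, 2, 3]).pvalue)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            group_rank_tests([1, 2], ["a", "a"])
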