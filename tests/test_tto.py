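"""Time-to-onset: exclusions, KM, parametric MLE, selection, rank tests."""

import datetime as dt
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pvsignal import (
    ParametricFit,
    TimeToOnsetModel,
    classify_hazard,
    compute_tto,
    fit_parametric,
    km_estimate,
    kruskal_wallis,
    mean_tto_by_pt,
    model_selection,
    per_pt_tto,
    tto_summary,
)
from pvsignal.faers_io import CaseReport
from pvsignal.tto import HAZARD_CONSTANT, HAZARD_DECREASING, HAZARD_INCREASING


def _case(caseid, event, start, pts=("X",)):
    return CaseReport(
        primaryid=caseid, caseid=caseid, fda_dt=None, event_dt=event, sex="female",
        age_years=None, reporter="consumer", country="US", pts=frozenset(pts),
        therapy_starts={"elmiron": start} if start else {},
        drugs=[("ELMIRON", "PS")],
    )


class TestComputeTto:
    def test_whole_day_interval(self):
        recs, tally = compute_tto([_case("1", dt.date(2020, 1, 31), dt.date(2020, 1, 1))])
        assert recs[0].included and recs[0].tto_days == 30
        assert tally["included"] == 1

    def test_event_before_start_excluded(self):
        recs, _ = compute_tto([_case("1", dt.date(2019, 12, 31), dt.date(2020, 1, 1))])
        assert not recs[0].included and recs[0].exclusion_reason == "negative_interval"

    def test_missing_dates_excluded_with_reason(self):
        recs, _ = compute_tto(
            [_case("1", None, dt.date(2020, 1, 1)), _case("2", dt.date(2020, 1, 1), None)]
        )
        assert [r.exclusion_reason for r in recs] == [
            "missing_event_date", "missing_start_date",
        ]

    def test_same_day_onset_becomes_half_day(self):
        d = dt.date(2020, 1, 1)
        recs, _ = compute_tto([_case("1", d, d)])
        assert recs[0].tto_days == 0.5
        recs, _ = compute_tto([_case("1", d, d)], zero_day="exclude")
        assert not recs[0].included

    def test_earliest_start_across_target_names(self):
        case = _case("1", dt.date(2020, 1, 10), dt.date(2020, 1, 5))
        case.therapy_starts["pentosan polysulfate sodium"] = dt.date(2020, 1, 1)
        recs, _ = compute_tto([case])
        assert recs[0].tto_days == 9


class TestSummary:
    def test_odd_n_median(self):
        s = tto_summary([100, 212, 1715, 4018, 5000])
        assert s["median"] == 1715

    def test_bins_closed_on_right(self):
        s = tto_summary([30, 31, 365, 366])
        assert s["bins"] == {"<=30d": 1, "31-365d": 2, ">365d": 1}

    def test_degenerate_iqr(self):
        s = tto_summary([7.0] * 5)
        assert s["q3"] - s["q1"] == 0

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            tto_summary([])


class TestKaplanMeier:
    def test_textbook_three_events(self):
        km = km_estimate([1, 2, 3])
        assert km.survival == pytest.approx([2 / 3, 1 / 3, 0.0])

    def test_tied_events(self):
        km = km_estimate([2, 2, 4])
        assert km.survival[km.times == 2] == pytest.approx(1 / 3)

    def test_equals_one_minus_ecdf_without_censoring(self):
        rng = np.random.default_rng(8)
        t = rng.exponential(100, size=500).round(1)
        km = km_estimate(t)
        ecdf = np.array([(t <= u).mean() for u in km.times])
        assert np.max(np.abs(km.survival - (1 - ecdf))) < 1e-12

    def test_risk_table_counts_at_grid(self):
        km = km_estimate([1, 5, 10], grid=[0, 5, 11])
        assert km.n_at_risk.tolist() == [3, 2, 0]

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            km_estimate([])


class TestParametricFits:
    def test_exponential_scale_is_mean_when_shape_fixed(self):
        fit = fit_parametric([1, 2, 3, 4], "weibull", fixed_shape=1.0)
        assert fit.params["scale"] == pytest.approx(2.5)
        assert fit.k == 1

    def test_weibull_matches_lifelines(self):
        from lifelines import WeibullFitter

        rng = np.random.default_rng(3)
        t = 300 * rng.weibull(0.8, size=400)
        fit = fit_parametric(t, "weibull")
        wf = WeibullFitter().fit(t, event_observed=np.ones_like(t))
        assert fit.params["scale"] == pytest.approx(wf.lambda_, rel=1e-3)
        assert fit.params["shape"] == pytest.approx(wf.rho_, rel=1e-3)
        assert fit.loglik == pytest.approx(wf.log_likelihood_, rel=1e-6)

    def test_lognormal_matches_scipy_mle(self):
        rng = np.random.default_rng(4)
        t = rng.lognormal(5.0, 1.5, size=300)
        fit = fit_parametric(t, "lognormal")
        shape, _, scale = stats.lognorm.fit(t, floc=0)
        assert fit.params["sigma"] == pytest.approx(shape, rel=1e-6)
        assert fit.params["mu"] == pytest.approx(math.log(scale), rel=1e-6)

    def test_loglogistic_matches_scipy_mle(self):
        rng = np.random.default_rng(5)
        u = rng.uniform(size=400)
        t = 200 * (u / (1 - u)) ** (1 / 1.3)
        fit = fit_parametric(t, "loglogistic")
        c, _, scale = stats.fisk.fit(t, floc=0)
        assert fit.params["shape"] == pytest.approx(c, rel=1e-3)
        assert fit.params["scale"] == pytest.approx(scale, rel=1e-3)

    def test_mle_is_local_optimum(self):
        rng = np.random.default_rng(6)
        t = 100 * rng.weibull(0.7, size=200)
        fit = fit_parametric(t, "weibull")
        from pvsignal.tto import _weibull_loglik

        best = _weibull_loglik(t, math.log(fit.params["scale"]), math.log(fit.params["shape"]))
        for _ in range(100):
            da, db = rng.normal(0, 0.05, size=2)
            perturbed = _weibull_loglik(
                t, math.log(fit.params["scale"]) + da, math.log(fit.params["shape"]) + db
            )
            assert perturbed <= best + 1e-9

    def test_shape_recovery_at_large_n(self):
        rng = np.random.default_rng(7)
        t = np.maximum(3097 * rng.weibull(0.62, size=10_000), 0.5)
        fit = fit_parametric(t, "weibull")
        assert fit.params["shape"] == pytest.approx(0.62, abs=0.02)

    def test_aic_bic_identities(self):
        fit = fit_parametric([3, 9, 27, 81, 243.0], "lognormal")
        assert fit.aic == pytest.approx(2 * fit.k - 2 * fit.loglik)
        assert fit.bic - fit.aic == pytest.approx(fit.k * (math.log(fit.n) - 2))

    def test_nonpositive_values_rejected(self):
        with pytest.raises(ValueError):
            fit_parametric([0.0, 1.0], "weibull")


class TestModelSelection:
    def test_lower_aic_wins(self):
        fits = [
            ParametricFit.from_loglik("weibull", -2567.35, 297),
            ParametricFit.from_loglik("loglogistic", -2617.7, 297),
            ParametricFit.from_loglik("lognormal", -2622.45, 297),
        ]
        assert model_selection(fits).best.family == "weibull"

    def test_tie_broken_by_family_name(self):
        fits = [
            ParametricFit.from_loglik("lognormal", -100.0, 50),
            ParametricFit.from_loglik("loglogistic", -100.0, 50),
        ]
        assert [f.family for f in model_selection(fits).fits] == ["loglogistic", "lognormal"]

    def test_mismatched_n_rejected(self):
        fits = [
            ParametricFit.from_loglik("weibull", -10.0, 50),
            ParametricFit.from_loglik("lognormal", -10.0, 60),
        ]
        with pytest.raises(ValueError):
            model_selection(fits)

    def test_recovers_lognormal_generator(self):
        rng = np.random.default_rng(11)
        wins = 0
        for _ in range(10):
            t = rng.lognormal(6.0, 1.2, size=3000)
            res = model_selection([fit_parametric(t, f) for f in
                                   ("weibull", "lognormal", "loglogistic")])
            wins += res.best.family == "lognormal"
        assert wins >= 9


class TestHazardClassification:
    def _fit(self, shape, ci):
        return ParametricFit(
            family="weibull", params={"scale": 3097.0, "shape": shape},
            loglik=-1.0, n=297, shape_ci95=ci,
        )

    def test_decreasing_early_failure(self):
        assert classify_hazard(self._fit(0.62, (0.56, 0.69))) == HAZARD_DECREASING

    def test_constant_random(self):
        assert classify_hazard(self._fit(1.00, (0.9, 1.1))) == HAZARD_CONSTANT

    def test_increasing_wear_out(self):
        assert classify_hazard(self._fit(1.5, (1.2, 1.8))) == HAZARD_INCREASING

    def test_requires_weibull(self):
        fit = ParametricFit.from_loglik("lognormal", -1.0, 10)
        with pytest.raises(ValueError):
            classify_hazard(fit)


class TestKruskalWallis:
    def test_hand_ranked_example(self):
        h, df, p = kruskal_wallis({"A": [1, 2, 3], "B": [4, 5, 6]})
        assert h == pytest.approx(3.857, abs=0.001)
        assert df == 1

    def test_identical_groups_give_zero(self):
        h, _, p = kruskal_wallis({"A": [1, 2, 3], "B": [1, 2, 3]})
        assert h == pytest.approx(0.0)

    def test_all_constant_degenerate(self):
        h, _, p = kruskal_wallis({"A": [5, 5], "B": [5, 5]})
        assert (h, p) == (0.0, 1.0)

    def test_single_group_is_error(self):
        with pytest.raises(ValueError):
            kruskal_wallis({"A": [1, 2]})

    def test_chi_square_p_close_to_permutation_p(self):
        rng = np.random.default_rng(12)
        groups = {k: rng.gamma(2, 50, size=12).tolist() for k in "ABC"}
        h, df, p = kruskal_wallis(groups)
        pooled = np.concatenate(list(groups.values()))
        sizes = [len(v) for v in groups.values()]
        count = 0
        reps = 2000
        for _ in range(reps):
            rng.shuffle(pooled)
            parts = np.split(pooled, np.cumsum(sizes)[:-1])
            hp = stats.kruskal(*parts)[0]
            count += hp >= h - 1e-12
        p_perm = count / reps
        mc_se = math.sqrt(p_perm * (1 - p_perm) / reps)
        assert abs(p - p_perm) < 4 * mc_se + 0.02


class TestPerPt:
    def test_mean_by_pt(self):
        df = pd.DataFrame({"pt": ["A", "A"], "tto_days": [100, 300], "caseid": ["1", "2"]})
        out = mean_tto_by_pt(df)
        assert out.loc[0, "mean_days"] == 200 and out.loc[0, "n"] == 2
        assert out.loc[0, "flagged"]  # n < 3

    def test_multi_pt_case_contributes_to_each_group(self):
        cases = [_case("1", dt.date(2020, 2, 1), dt.date(2020, 1, 1), pts=("A", "B"))]
        recs, _ = compute_tto(cases)
        df = per_pt_tto(cases, recs)
        assert sorted(df["pt"]) == ["A", "B"]
        assert (df["tto_days"] == 31).all()


class TestModelObject:
    def test_end_to_end_from_cases(self, target_cases):
        model = TimeToOnsetModel.from_cases(target_cases)
        res = model.fit()
        assert set(res.fits) == {"weibull", "lognormal", "loglogistic"}
        assert res.best.family in res.fits
        assert "Weibull shape" in res.summary()
        km = res.km(grid=[0, 1000])
        assert km.n_at_risk[0] == model.days.size

    def test_exclusion_tally_matches_records(self, target_cases):
        model = TimeToOnsetModel.from_cases(target_cases)
        assert model.exclusion_tally["included"] == sum(
            r.included for r in model.records
        )
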