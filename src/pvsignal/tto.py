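"""Time-to-onset (TTO) analysis: exclusions, Kaplan-Meier, parametric fits.

TTO is the interval in days from the suspect drug's therapy start
(THER.START_DT, earliest record) to the adverse-event occurrence
(DEMO.EVENT_DT).  Cases with missing or partial dates, or with the event
preceding therapy start, are excluded; same-day onsets are remapped to
half a day so log-time models remain defined.

The included onsets (all treated as observed events, no censoring) are
summarized by the Kaplan-Meier estimator and by maximum-likelihood fits
of three parametric families:

* Weibull:       f(t) = (b/a) (t/a)^(b-1) exp(-(t/a)^b)
* log-normal:    ln t ~ Normal(mu, sigma^2)
* log-logistic:  S(t) = 1 / (1 + (t/a)^b)

Families are compared by AIC/BIC (k = 2 parameters each) and the
Anderson-Darling statistic at the fitted parameters.  The Weibull shape b
classifies the hazard regime: b < 1 with CI upper bound < 1 means a
decreasing hazard (early-failure pattern), b > 1 with CI lower bound > 1
an increasing hazard (wear-out), otherwise effectively constant.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import optimize, stats

from .faers_io import CaseReport, PPS_SYNONYMS, normalize_drugname

FAMILIES = ("weibull", "lognormal", "loglogistic")

_EULER_GAMMA = 0.5772156649015329


@dataclass
class TTORecord:
    """Per-case time to onset with inclusion status."""

    caseid: str
    tto_days: float | None
    included: bool
    exclusion_reason: str  # missing_event_date | missing_start_date |
    #                        negative_interval | zero_interval | none


@dataclass
class KMCurve:
    """Kaplan-Meier survival curve with a number-at-risk table."""

    times: np.ndarray  # distinct event times, ascending
    survival: np.ndarray  # S(t) at each event time
    grid: np.ndarray  # requested grid for the risk table
    n_at_risk: np.ndarray  # count with tto_days >= grid point

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "survival": self.survival})


@dataclass
class ParametricFit:
    """A maximum-likelihood parametric fit of the TTO distribution."""

    family: str
    params: dict[str, float]
    loglik: float
    n: int
    k: int = 2
    aic: float = field(init=False)
    bic: float = field(init=False)
    ad_stat: float | None = None
    shape_ci95: tuple[float, float] | None = None
    converged: bool = True
    message: str = ""

    def __post_init__(self):
        self.aic = 2 * self.k - 2 * self.loglik
        self.bic = self.k * math.log(self.n) - 2 * self.loglik

    @classmethod
    def from_loglik(cls, family: str, loglik: float, n: int, k: int = 2, **kw):
        return cls(family=family, params=kw.pop("params", {}), loglik=loglik, n=n, k=k, **kw)

    @property
    def shape(self) -> float | None:
        return self.params.get("shape", self.params.get("sigma"))


def compute_tto(
    cases: Sequence[CaseReport],
    target_names: Sequence[str] = PPS_SYNONYMS,
    zero_day: str = "half",
) -> tuple[list[TTORecord], dict[str, int]]:
    """Compute per-case TTO records and an exclusion tally.

    The therapy start is the earliest parseable START_DT among the case's
    target-drug records.  ``zero_day`` is 'half' (same-day onset counts
    as 0.5 days) or 'exclude'.
    """
    if zero_day not in ("half", "exclude"):
        raise ValueError("zero_day must be 'half' or 'exclude'")
    targets = {normalize_drugname(s) for s in target_names}
    records: list[TTORecord] = []
    for case in cases:
        starts = [
            d for name, d in case.therapy_starts.items() if name in targets and d is not None
        ]
        if case.event_dt is None:
            records.append(TTORecord(case.caseid, None, False, "missing_event_date"))
        elif not starts:
            records.append(TTORecord(case.caseid, None, False, "missing_start_date"))
        else:
            days = float((case.event_dt - min(starts)).days)
            if days < 0:
                records.append(TTORecord(case.caseid, None, False, "negative_interval"))
            elif days == 0 and zero_day == "exclude":
                records.append(TTORecord(case.caseid, None, False, "zero_interval"))
            else:
                records.append(TTORecord(case.caseid, max(days, 0.5), True, "none"))
    tally = Counter(r.exclusion_reason for r in records)
    tally["included"] = sum(r.included for r in records)
    return records, dict(tally)


def per_pt_tto(
    cases: Sequence[CaseReport], records: Sequence[TTORecord]
) -> pd.DataFrame:
    """Expand included per-case TTO records to one row per (case, PT)."""
    tto = {r.caseid: r.tto_days for r in records if r.included}
    rows = [
        {"caseid": c.caseid, "pt": pt, "tto_days": tto[c.caseid]}
        for c in cases
        if c.caseid in tto
        for pt in sorted(c.pts)
    ]
    return pd.DataFrame(rows, columns=["caseid", "pt", "tto_days"])


def tto_summary(days: Iterable[float]) -> dict:
    """Median, IQR and latency-bin counts of the included onsets.

    Quartiles use linear interpolation; bins are closed on the right at
    30 and 365 days.
    """
    t = np.asarray(list(days), dtype=float)
    if t.size == 0:
        raise ValueError("no included TTO records")
    q1, med, q3 = np.percentile(t, [25, 50, 75])
    bins = {
        "<=30d": int((t <= 30).sum()),
        "31-365d": int(((t > 30) & (t <= 365)).sum()),
        ">365d": int((t > 365).sum()),
    }
    return {
        "n": int(t.size),
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "bins": bins,
        "bin_pct": {k: round(100.0 * v / t.size, 1) for k, v in bins.items()},
    }


def km_estimate(days: Iterable[float], grid: Iterable[float] | None = None) -> KMCurve:
    """Kaplan-Meier estimate treating every record as an observed event.

    S(t) is the product over event times t_i <= t of (1 - d_i / n_i);
    without censoring this equals 1 minus the empirical CDF.  The risk
    table reports, per grid point g, the count of records with
    tto_days >= g.
    """
    t = np.asarray(list(days), dtype=float)
    if t.size == 0:
        raise ValueError("no TTO records to estimate from")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=np.ones_like(t))
    times = np.unique(t)
    survival = (
        kmf.survival_function_at_times(times).to_numpy().astype(float)
    )
    if grid is None:
        grid = np.linspace(0.0, float(t.max()), 9)
    grid = np.asarray(list(grid), dtype=float)
    n_at_risk = np.array([(t >= g).sum() for g in grid])
    return KMCurve(times=times, survival=survival, grid=grid, n_at_risk=n_at_risk)


# ---------------------------------------------------------------------------
# parametric likelihoods (parameterized on log scale for optimization)


def _weibull_loglik(t, lna, lnb):
    a, b = math.exp(lna), math.exp(lnb)
    z = t / a
    return float(t.size * (lnb - lna) + (b - 1) * np.sum(np.log(z)) - np.sum(z**b))


def _lognormal_loglik(t, mu, sigma):
    lt = np.log(t)
    n = t.size
    return float(
        -0.5 * n * math.log(2 * math.pi)
        - n * math.log(sigma)
        - np.sum(lt)
        - np.sum((lt - mu) ** 2) / (2 * sigma**2)
    )


def _loglogistic_loglik(t, lna, lnb):
    a, b = math.exp(lna), math.exp(lnb)
    z = np.log(t) - lna
    return float(
        t.size * (lnb - lna) + (b - 1) * np.sum(z) - 2 * np.sum(np.logaddexp(0.0, b * z))
    )


def _cdf(family: str, t: np.ndarray, params: Mapping[str, float]) -> np.ndarray:
    if family == "weibull":
        return 1.0 - np.exp(-((t / params["scale"]) ** params["shape"]))
    if family == "lognormal":
        return stats.norm.cdf((np.log(t) - params["mu"]) / params["sigma"])
    if family == "loglogistic":
        return 1.0 / (1.0 + (t / params["scale"]) ** (-params["shape"]))
    raise ValueError(f"unknown family {family!r}")


def anderson_darling(family: str, t: np.ndarray, params: Mapping[str, float]) -> float:
    """A^2 = -n - (1/n) sum (2i-1) [ln F(t_(i)) + ln(1 - F(t_(n+1-i)))]."""
    x = np.sort(np.asarray(t, dtype=float))
    n = x.size
    f = np.clip(_cdf(family, x, params), 1e-15, 1 - 1e-15)
    i = np.arange(1, n + 1)
    return float(-n - np.mean((2 * i - 1) * (np.log(f) + np.log(1 - f[::-1]))))


def _hessian(fun, x, h=1e-5):
    """Central-difference Hessian of a scalar function of a vector."""
    x = np.asarray(x, dtype=float)
    k = x.size
    H = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = h
            ej[j] = h
            H[i, j] = H[j, i] = (
                fun(x + ei + ej) - fun(x + ei - ej) - fun(x - ei + ej) + fun(x - ei - ej)
            ) / (4 * h * h)
    return H


def fit_parametric(
    days: Iterable[float], family: str, fixed_shape: float | None = None
) -> ParametricFit:
    """Maximum-likelihood fit of one parametric family to positive onsets.

    Weibull and log-logistic are optimized over (ln scale, ln shape) with
    moment-based initialization (Nelder-Mead, tolerance 1e-8, at most 500
    iterations); the log-normal MLE is closed-form.  The shape CI is Wald
    on the log of the shape parameter using the observed information.
    ``fixed_shape`` pins the Weibull shape (k drops to 1); with shape 1
    the scale MLE is the sample mean (exponential).
    """
    t = np.asarray(list(days), dtype=float)
    if t.size == 0 or (t <= 0).any():
        raise ValueError("parametric fits require positive TTO values")
    n = int(t.size)
    lt = np.log(t)

    if family == "lognormal":
        mu = float(lt.mean())
        sigma = float(lt.std(ddof=0))
        if sigma == 0:
            raise ValueError("degenerate sample: all onsets identical")
        ll = _lognormal_loglik(t, mu, sigma)
        se_lnsigma = 1.0 / math.sqrt(2 * n)
        ci = (sigma * math.exp(-1.96 * se_lnsigma), sigma * math.exp(1.96 * se_lnsigma))
        fit = ParametricFit(
            family, {"mu": mu, "sigma": sigma}, ll, n, k=2, shape_ci95=ci
        )
        fit.ad_stat = anderson_darling(family, t, fit.params)
        return fit

    if family == "weibull" and fixed_shape is not None:
        b = float(fixed_shape)
        a = float(np.mean(t**b) ** (1.0 / b))
        ll = _weibull_loglik(t, math.log(a), math.log(b))
        fit = ParametricFit(family, {"scale": a, "shape": b}, ll, n, k=1)
        fit.ad_stat = anderson_darling(family, t, fit.params)
        return fit

    if family == "weibull":
        loglik = _weibull_loglik
        sd = max(float(lt.std(ddof=0)), 1e-6)
        b0 = (math.pi / math.sqrt(6)) / sd
        x0 = np.array([float(lt.mean()) + _EULER_GAMMA / b0, math.log(b0)])
        # first slot of x0 is ln(scale) since ln alpha = E[ln t] + gamma/beta
    elif family == "loglogistic":
        loglik = _loglogistic_loglik
        sd = max(float(lt.std(ddof=0)), 1e-6)
        b0 = math.pi / (math.sqrt(3) * sd)
        x0 = np.array([float(np.median(lt)), math.log(b0)])
    else:
        raise ValueError(f"unknown family {family!r}")

    nll = lambda x: -loglik(t, x[0], x[1])
    res = optimize.minimize(
        nll,
        x0,
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-8, "maxiter": 500},
    )
    lna, lnb = res.x
    params = {"scale": math.exp(lna), "shape": math.exp(lnb)}
    H = _hessian(nll, res.x)
    try:
        var_lnb = float(np.linalg.inv(H)[1, 1])
    except np.linalg.LinAlgError:
        var_lnb = float("nan")
    if var_lnb > 0:
        se = math.sqrt(var_lnb)
        ci = (params["shape"] * math.exp(-1.96 * se), params["shape"] * math.exp(1.96 * se))
    else:
        ci = None
    fit = ParametricFit(
        family,
        params,
        -float(res.fun),
        n,
        k=2,
        shape_ci95=ci,
        converged=bool(res.success),
        message=str(res.message),
    )
    fit.ad_stat = anderson_darling(family, t, params)
    return fit


@dataclass
class ModelComparison:
    """Candidate fits ranked by AIC (ties broken by family name)."""

    fits: list[ParametricFit]

    def __post_init__(self):
        ns = {f.n for f in self.fits}
        if len(self.fits) < 2:
            raise ValueError("model selection needs at least two fits")
        if len(ns) != 1:
            raise ValueError("fits compare different record counts")
        self.fits = sorted(self.fits, key=lambda f: (f.aic, f.family))

    @property
    def best(self) -> ParametricFit:
        return self.fits[0]

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "family": f.family,
                    **{k: round(v, 4) for k, v in f.params.items()},
                    "loglik": f.loglik,
                    "aic": f.aic,
                    "bic": f.bic,
                    "ad_stat": f.ad_stat,
                }
                for f in self.fits
            ]
        )


def model_selection(fits: Sequence[ParametricFit]) -> ModelComparison:
    """Rank candidate parametric fits; lower AIC wins."""
    return ModelComparison(list(fits))


HAZARD_DECREASING = "decreasing/early-failure"
HAZARD_CONSTANT = "constant/random"
HAZARD_INCREASING = "increasing/wear-out"


def classify_hazard(fit: ParametricFit) -> str:
    """Hazard regime from the Weibull shape and its 95% CI.

    Decreasing (early failure) when shape < 1 and CI upper bound < 1;
    increasing (wear-out) when shape > 1 and CI lower bound > 1;
    otherwise effectively constant (random failure).
    """
    if fit.family != "weibull":
        raise ValueError("hazard classification requires a Weibull fit")
    b = fit.params["shape"]
    if fit.shape_ci95 is None:
        return HAZARD_CONSTANT
    lo, hi = fit.shape_ci95
    if b < 1 and hi < 1:
        return HAZARD_DECREASING
    if b > 1 and lo > 1:
        return HAZARD_INCREASING
    return HAZARD_CONSTANT


def kruskal_wallis(groups: Mapping[str, Sequence[float]]):
    """Kruskal-Wallis rank test across PT groups (tie-corrected).

    Returns (H, df, p).  All observations identical across groups gives
    H = 0, p = 1 (the tie correction is degenerate there).
    """
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis needs at least two groups")
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    if any(a.size == 0 for a in arrays):
        raise ValueError("every group needs at least one observation")
    df = len(arrays) - 1
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, df, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), df, float(p)


def mean_tto_by_pt(per_pt: pd.DataFrame, min_n: int = 3) -> pd.DataFrame:
    """Arithmetic mean onset per PT; PTs with n < min_n are flagged."""
    if per_pt.empty:
        return pd.DataFrame(columns=["pt", "n", "mean_days", "flagged"])
    g = per_pt.groupby("pt")["tto_days"]
    out = pd.DataFrame({"n": g.size(), "mean_days": g.mean()}).reset_index()
    out["flagged"] = out["n"] < min_n
    return out.sort_values("mean_days", ascending=False).reset_index(drop=True)


class TimeToOnsetModel:
    """Survival model of adverse-event onset times.

    Built either from assembled cases (``from_cases``, which applies the
    date exclusions) or directly from positive onset values.  ``fit``
    estimates all requested parametric families and returns a results
    object carrying the fits, their comparison, the hazard
    classification, the Kaplan-Meier curve and distribution summaries.
    """

    def __init__(self, days: Iterable[float], per_pt: pd.DataFrame | None = None):
        self.days = np.asarray(list(days), dtype=float)
        if self.days.size == 0:
            raise ValueError("no included TTO records")
        self.per_pt = per_pt

    @classmethod
    def from_cases(
        cls,
        cases: Sequence[CaseReport],
        target_names: Sequence[str] = PPS_SYNONYMS,
        zero_day: str = "half",
    ) -> "TimeToOnsetModel":
        records, tally = compute_tto(cases, target_names, zero_day=zero_day)
        model = cls(
            [r.tto_days for r in records if r.included],
            per_pt=per_pt_tto(cases, records),
        )
        model.records = records
        model.exclusion_tally = tally
        return model

    def fit(self, families: Sequence[str] = FAMILIES) -> "TimeToOnsetResults":
        fits = {fam: fit_parametric(self.days, fam) for fam in families}
        comparison = model_selection(list(fits.values())) if len(fits) > 1 else None
        return TimeToOnsetResults(self, fits, comparison)


class TimeToOnsetResults:
    """Fitted TTO distributions, their ranking and derived diagnostics."""

    def __init__(self, model, fits, comparison):
        self.model = model
        self.fits = fits
        self.comparison = comparison

    @property
    def best(self) -> ParametricFit:
        return self.comparison.best if self.comparison else next(iter(self.fits.values()))

    @property
    def hazard_class(self) -> str | None:
        fit = self.fits.get("weibull")
        return classify_hazard(fit) if fit else None

    def km(self, grid: Iterable[float] | None = None) -> KMCurve:
        return km_estimate(self.model.days, grid=grid)

    def distribution(self) -> dict:
        return tto_summary(self.model.days)

    def kruskal_by_pt(self, pts: Sequence[str] | None = None, min_n: int = 1):
        """Kruskal-Wallis across PT-level onset groups (a multi-PT case
        contributes to each of its PTs)."""
        if self.model.per_pt is None or self.model.per_pt.empty:
            raise ValueError("model carries no per-PT records")
        df = self.model.per_pt
        if pts is not None:
            df = df[df["pt"].isin(set(pts))]
        groups = {
            pt: g["tto_days"].tolist()
            for pt, g in df.groupby("pt")
            if len(g) >= min_n
        }
        return kruskal_wallis(groups)

    def mean_by_pt(self, min_n: int = 3) -> pd.DataFrame:
        if self.model.per_pt is None:
            raise ValueError("model carries no per-PT records")
        return mean_tto_by_pt(self.model.per_pt, min_n=min_n)

    def summary(self) -> str:
        d = self.distribution()
        lines = [
            f"Time-to-onset analysis: n = {d['n']} included events",
            f"  median {d['median']:.0f} d, IQR {d['q1']:.0f}-{d['q3']:.0f} d",
            "  latency bins: "
            + ", ".join(
                f"{k} {v} ({d['bin_pct'][k]}%)" for k, v in d["bins"].items()
            ),
        ]
        if self.comparison:
            lines.append(self.comparison.table().to_string(index=False))
            lines.append(f"  best by AIC: {self.best.family}")
        wb = self.fits.get("weibull")
        if wb is not None:
            ci = wb.shape_ci95
            ci_txt = f" (95% CI {ci[0]:.2f}-{ci[1]:.2f})" if ci else ""
            lines.append(
                f"  Weibull shape = {wb.params['shape']:.2f}{ci_txt}"
                f" -> hazard {classify_hazard(wb)}"
            )
        return "\n".join(lines)
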