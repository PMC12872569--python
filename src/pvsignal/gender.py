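"""Sex-differential adverse-event signals among target-drug reports.

Within the target drug's own reports, each preferred term gets a
female-vs-male 2x2 table

    =======  ==========  ============
    sex      target AE   all other AE
    =======  ==========  ============
    female   a           b
    male     c           d
    =======  ==========  ============

with ROR = (a/c)/(b/d).  An ROR above 1 with CI lower bound > 1 means the
event is reported relatively more often in females; below 1 with CI upper
bound < 1, in males.  Raw two-sided p-values come from the Wald z-test on
ln ROR and are adjusted across PTs by the Benjamini-Hochberg false
discovery rate procedure; volcano-plot coordinates are (log2 ROR,
-log10 adjusted p).  Reports of unknown sex are excluded here only.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .disproportionality import ContingencyTable
from .faers_io import CaseReport


class EmptyStratumError(ValueError):
    """The analysis needs at least one female and one male report."""


def build_gender_table(cases: Sequence[CaseReport], pt: str) -> ContingencyTable:
    """Female-vs-male 2x2 table for one PT over target-drug cases.

    Unknown-sex cases contribute to no cell.  Raises
    :class:`EmptyStratumError` when either sex stratum is entirely empty.
    """
    a = b = c = d = 0
    for case in cases:
        if case.sex == "female":
            a += pt in case.pts
            b += pt not in case.pts
        elif case.sex == "male":
            c += pt in case.pts
            d += pt not in case.pts
    if a + b == 0 or c + d == 0:
        raise EmptyStratumError("need at least one female and one male report")
    return ContingencyTable(a, b, c, d)


def gender_ror(t: ContingencyTable, z: float = 1.96):
    """ROR, Wald CI and raw two-sided p for a female-vs-male table.

    Zero cells are Haldane-corrected (+0.5 everywhere) as in the main
    disproportionality analysis.  p is the normal two-sided tail of
    z = ln ROR / SE(ln ROR).
    """
    tc = t.haldane()
    ror = (tc.a * tc.d) / (tc.b * tc.c)
    se = math.sqrt(1 / tc.a + 1 / tc.b + 1 / tc.c + 1 / tc.d)
    lo = ror * math.exp(-z * se)
    hi = ror * math.exp(z * se)
    zstat = math.log(ror) / se
    p_raw = 2.0 * stats.norm.sf(abs(zstat))
    return ror, (lo, hi), min(p_raw, 1.0)


def fdr_adjust(p_values: Iterable[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment, input order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


def volcano_coordinates(frame: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Volcano-plot coordinates (x = log2 ROR, y = -log10 adjusted p).

    ``labeled`` marks PTs significant after FDR; p is floored at 1e-300
    so coordinates stay finite.
    """
    out = frame[["pt"]].copy()
    out["x"] = np.log2(frame["ror"].astype(float))
    out["y"] = -np.log10(np.maximum(frame["p_adj"].astype(float), 1e-300))
    out["labeled"] = frame["p_adj"].astype(float) < alpha
    return out


class SexDifferenceModel:
    """Female-vs-male disproportionality screen within target-drug cases.

    Parameters
    ----------
    cases : sequence of CaseReport
        Target-drug cases only (the comparator here is the other sex, not
        other drugs).
    min_count : int
        A PT enters the FDR family only when it has at least this many
        sexed reports (a + c), mirroring the a >= 3 reporting floor.
    alpha : float
        Significance level applied to the FDR-adjusted p-values.
    """

    def __init__(self, cases: Sequence[CaseReport], min_count: int = 3, alpha: float = 0.05):
        self.cases = [c for c in cases if c.sex in ("female", "male")]
        self.min_count = min_count
        self.alpha = alpha
        if not any(c.sex == "female" for c in self.cases) or not any(
            c.sex == "male" for c in self.cases
        ):
            raise EmptyStratumError("need at least one female and one male report")

    def fit(self, pts: Iterable[str] | None = None) -> "SexDifferenceResults":
        n_f = sum(c.sex == "female" for c in self.cases)
        n_m = len(self.cases) - n_f
        count_f: dict[str, int] = {}
        count_m: dict[str, int] = {}
        for case in self.cases:
            bucket = count_f if case.sex == "female" else count_m
            for pt in case.pts:
                bucket[pt] = bucket.get(pt, 0) + 1
        if pts is None:
            pts = sorted(set(count_f) | set(count_m))
        rows = []
        for pt in pts:
            a = count_f.get(pt, 0)
            c = count_m.get(pt, 0)
            if a + c < self.min_count:
                continue
            t = ContingencyTable(a, n_f - a, c, n_m - c)
            ror, (lo, hi), p_raw = gender_ror(t)
            rows.append(
                {
                    "pt": pt,
                    "a_f": a,
                    "b_f": n_f - a,
                    "c_m": c,
                    "d_m": n_m - c,
                    "ror": ror,
                    "low": lo,
                    "high": hi,
                    "p_raw": p_raw,
                }
            )
        frame = pd.DataFrame(
            rows,
            columns=["pt", "a_f", "b_f", "c_m", "d_m", "ror", "low", "high", "p_raw"],
        )
        if len(frame):
            frame["p_adj"] = fdr_adjust(frame["p_raw"])
            sig = frame["p_adj"] < self.alpha
            frame["direction"] = np.select(
                [sig & (frame["low"] > 1.0), sig & (frame["high"] < 1.0)],
                ["female", "male"],
                default="none",
            )
            frame["log2_ror"] = np.log2(frame["ror"])
            frame["neglog10_padj"] = -np.log10(np.maximum(frame["p_adj"], 1e-300))
        else:
            for col in ("p_adj", "direction", "log2_ror", "neglog10_padj"):
                frame[col] = []
        return SexDifferenceResults(self, frame)


class SexDifferenceResults:
    """Per-PT sex-difference estimates with FDR-adjusted significance."""

    def __init__(self, model: SexDifferenceModel, frame: pd.DataFrame):
        self.model = model
        self.frame = frame

    @property
    def significant(self) -> pd.DataFrame:
        return self.frame[self.frame["direction"] != "none"].reset_index(drop=True)

    def volcano(self) -> pd.DataFrame:
        return volcano_coordinates(self.frame, alpha=self.model.alpha)

    def summary(self) -> str:
        sig = self.significant.sort_values("p_adj")
        n_f = sum(c.sex == "female" for c in self.model.cases)
        n_m = len(self.model.cases) - n_f
        header = (
            f"Sex-difference screen: {n_f} female / {n_m} male cases, "
            f"{len(self.frame)} PTs tested, {len(sig)} significant at "
            f"FDR {self.model.alpha:g}\n"
        )
        if sig.empty:
            return header + "(no significant sex-differential PTs)"
        cols = ["pt", "a_f", "c_m", "ror", "low", "high", "p_adj", "direction"]
        with pd.option_context("display.float_format", "{:.4g}".format):
            return header + sig[cols].to_string(index=False)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)
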