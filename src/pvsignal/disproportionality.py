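"""Drug-event disproportionality statistics on 2x2 contingency tables.

For a target drug and a target adverse event (MedDRA preferred term), the
case-level 2x2 table is

    =================  ==========  ============
    stratum            target AE   all other AE
    =================  ==========  ============
    target drug        a           b
    all other drugs    c           d
    =================  ==========  ============

with the reporting odds ratio ROR = (a/c)/(b/d) = ad/bc, the proportional
reporting ratio PRR = [a/(a+b)] / [c/(c+d)], and the Pearson chi-square on
the table.  The 95% CI of the ROR is the Wald interval on the log scale,

    exp( ln ROR +/- z * sqrt(1/a + 1/b + 1/c + 1/d) ),  z = 1.96.

A drug-event pair is flagged as a signal when jointly (1) a >= 3, (2) the
ROR CI lower bound exceeds 1, and (3) PRR >= 2 with chi-square >= 4.
When any cell is zero the Haldane-Anscombe correction (+0.5 to every
cell) keeps the ROR finite; corrected tables are flagged as such.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .faers_io import CaseReport


@dataclass(frozen=True)
class ContingencyTable:
    """Cells of a 2x2 disproportionality table (case-level counts)."""

    a: float
    b: float
    c: float
    d: float
    corrected: bool = False

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")
        if self.total < 1:
            raise ValueError("contingency table must contain at least one report")

    @property
    def total(self) -> float:
        return self.a + self.b + self.c + self.d

    @property
    def has_zero_cell(self) -> bool:
        return min(self.a, self.b, self.c, self.d) == 0

    def haldane(self) -> "ContingencyTable":
        """Apply the Haldane-Anscombe +0.5 correction to all cells when
        any cell is zero; identity otherwise."""
        if not self.has_zero_cell:
            return self
        return ContingencyTable(
            self.a + 0.5, self.b + 0.5, self.c + 0.5, self.d + 0.5, corrected=True
        )


@dataclass(frozen=True)
class SignalThresholds:
    """The joint signal criteria for ROR/PRR disproportionality."""

    min_reports: int = 3
    z: float = 1.96
    prr_min: float = 2.0
    chi2_min: float = 4.0
    rule: str = "and"  # 'and': all criteria; 'any': either algorithm + floor
    yates: bool = False


def build_table(
    cases: Sequence[CaseReport], target_pt: str, target_ids: set[str]
) -> ContingencyTable:
    """Count unique deduplicated cases into the 2x2 table.

    ``target_ids`` holds the caseids of target-drug reports; a case
    contributes once to a cell regardless of how many times it lists the
    PT.
    """
    a = b = c = d = 0
    for case in cases:
        has_pt = target_pt in case.pts
        if case.caseid in target_ids:
            a += has_pt
            b += not has_pt
        else:
            c += has_pt
            d += not has_pt
    return ContingencyTable(a, b, c, d)


def ror_with_ci(t: ContingencyTable, z: float = 1.96):
    """Reporting odds ratio with Wald CI on ln ROR.

    Returns (None, None, None) when a zero cell makes the estimate
    undefined (apply :meth:`ContingencyTable.haldane` first to avoid).
    """
    if t.has_zero_cell:
        return None, None, None
    ror = (t.a * t.d) / (t.b * t.c)
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    return ror, ror * math.exp(-z * se), ror * math.exp(z * se)


def prr_chi2(t: ContingencyTable, yates: bool = False):
    """Proportional reporting ratio and Pearson chi-square.

    PRR is None for degenerate margins (no target-drug reports, no
    comparator reports, or no comparator events); chi-square is None when
    a table margin is empty.  No continuity correction unless ``yates``.
    """
    prr = None
    if (t.a + t.b) > 0 and (t.c + t.d) > 0 and t.c > 0:
        prr = (t.a / (t.a + t.b)) / (t.c / (t.c + t.d))
    chi2 = _pearson_chi2(t, yates)
    return prr, chi2


def _pearson_chi2(t: ContingencyTable, yates: bool) -> float | None:
    obs = np.array([[t.a, t.b], [t.c, t.d]], dtype=float)
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        return None
    expected = np.outer(rows, cols) / obs.sum()
    dev = np.abs(obs - expected)
    if yates:
        dev = np.maximum(dev - 0.5, 0.0)
    return float((dev**2 / expected).sum())


def evaluate_signal(
    t: ContingencyTable, thresholds: SignalThresholds = SignalThresholds()
) -> dict:
    """Compute all statistics and the joint signal decision for a table.

    The ROR (and its CI) is computed on the Haldane-corrected table when a
    cell is zero; PRR and chi-square are computed on the raw counts.
    Returns a dict with keys a,b,c,d, corrected, ror, ror_low, ror_high,
    prr, chi2, n_reports, criteria_flags and is_signal.
    """
    tc = t.haldane()
    ror, lo, hi = ror_with_ci(tc, z=thresholds.z)
    prr, chi2 = prr_chi2(t, yates=thresholds.yates)
    flags = {
        "n_min": t.a >= thresholds.min_reports,
        "ror": lo is not None and lo > 1.0,
        "prr": (prr is not None and prr >= thresholds.prr_min)
        and (chi2 is not None and chi2 >= thresholds.chi2_min),
    }
    if thresholds.rule == "any":
        is_signal = flags["n_min"] and (flags["ror"] or flags["prr"])
    else:
        is_signal = all(flags.values())
    return {
        "a": t.a,
        "b": t.b,
        "c": t.c,
        "d": t.d,
        "corrected": tc.corrected,
        "ror": ror,
        "ror_low": lo,
        "ror_high": hi,
        "prr": prr,
        "chi2": chi2,
        "n_reports": int(t.a),
        "criteria_flags": flags,
        "is_signal": bool(is_signal),
    }


def rank_top_pts(results: pd.DataFrame, k: int, by: str = "n_reports") -> pd.DataFrame:
    """Top-k PTs by ``n_reports`` or ``ror``, ties broken alphabetically."""
    if k <= 0:
        return results.iloc[0:0]
    if by not in ("n_reports", "ror"):
        raise ValueError("by must be 'n_reports' or 'ror'")
    df = results.sort_values(
        [by, "pt"], ascending=[False, True], kind="mergesort", na_position="last"
    )
    return df.head(k).reset_index(drop=True)


def top_signals_per_soc(
    results: pd.DataFrame, pt_to_soc: Mapping[str, str], k: int = 3
) -> dict[str, pd.DataFrame]:
    """Within each system organ class, the top-k signal-positive PTs by
    ROR.  PTs absent from the mapping are grouped under 'UNMAPPED'."""
    import logging

    df = results.copy()
    df["soc"] = df["pt"].map(lambda p: pt_to_soc.get(p, "UNMAPPED"))
    if (df["soc"] == "UNMAPPED").any():
        logging.getLogger(__name__).warning(
            "%d PTs missing from the SOC map", int((df["soc"] == "UNMAPPED").sum())
        )
    sig = df[df["is_signal"]]
    out = {}
    for soc, grp in sig.groupby("soc"):
        ranked = grp.sort_values(
            ["ror", "pt"], ascending=[False, True], kind="mergesort", na_position="last"
        )
        out[soc] = ranked.head(k).reset_index(drop=True)
    return out


class DisproportionalityModel:
    """ROR/PRR disproportionality screen of a target drug against the
    full-database comparator.

    Parameters
    ----------
    cases : sequence of CaseReport
        The deduplicated case universe (target and comparator reports).
    target_ids : set of caseid
        Cases whose primary-suspect drug is the target.
    pt_to_soc : mapping, optional
        MedDRA PT -> SOC map for per-SOC summaries.
    thresholds : SignalThresholds

    Examples
    --------
    >>> model = DisproportionalityModel(cases, target_ids, pt_to_soc=soc_map)
    >>> res = model.fit()
    >>> res.top_pts(20)          # ranked by number of reports
    >>> res.top_per_soc(3)       # strongest signals per organ class
    """

    def __init__(
        self,
        cases: Sequence[CaseReport],
        target_ids: set[str],
        pt_to_soc: Mapping[str, str] | None = None,
        thresholds: SignalThresholds = SignalThresholds(),
    ):
        self.cases = list(cases)
        self.target_ids = set(target_ids)
        self.pt_to_soc = dict(pt_to_soc or {})
        self.thresholds = thresholds

    def fit(self, pts: Iterable[str] | None = None) -> "DisproportionalityResults":
        """Screen every PT (default: all PTs reported with the target
        drug) and return the per-PT results."""
        target = [c for c in self.cases if c.caseid in self.target_ids]
        n_target = len(target)
        n_total = len(self.cases)
        target_counts: Counter = Counter()
        other_counts: Counter = Counter()
        for case in self.cases:
            bucket = target_counts if case.caseid in self.target_ids else other_counts
            for pt in case.pts:
                bucket[pt] += 1
        if pts is None:
            pts = sorted(target_counts)
        rows = []
        for pt in pts:
            a = target_counts.get(pt, 0)
            c = other_counts.get(pt, 0)
            t = ContingencyTable(a, n_target - a, c, n_total - n_target - c)
            row = evaluate_signal(t, self.thresholds)
            flags = row.pop("criteria_flags")
            row.update({f"flag_{k}": v for k, v in flags.items()})
            row["pt"] = pt
            row["soc"] = self.pt_to_soc.get(pt)
            row["reporting_pct"] = 100.0 * a / n_target if n_target else np.nan
            rows.append(row)
        cols = [
            "pt", "soc", "a", "b", "c", "d", "corrected", "ror", "ror_low",
            "ror_high", "prr", "chi2", "n_reports", "reporting_pct",
            "flag_n_min", "flag_ror", "flag_prr", "is_signal",
        ]
        frame = pd.DataFrame(rows, columns=cols)
        return DisproportionalityResults(self, frame)


class DisproportionalityResults:
    """Per-PT disproportionality estimates from a fitted screen."""

    def __init__(self, model: DisproportionalityModel, frame: pd.DataFrame):
        self.model = model
        self.frame = frame

    @property
    def signals(self) -> pd.DataFrame:
        return self.frame[self.frame["is_signal"]].reset_index(drop=True)

    def top_pts(self, k: int = 20, by: str = "n_reports") -> pd.DataFrame:
        return rank_top_pts(self.frame, k, by=by)

    def top_per_soc(self, k: int = 3) -> dict[str, pd.DataFrame]:
        return top_signals_per_soc(self.frame, self.model.pt_to_soc, k=k)

    def summary(self, k: int = 20) -> str:
        """Readable top-k table in the style of a results listing."""
        df = self.top_pts(k)
        cols = ["pt", "soc", "a", "reporting_pct", "ror", "ror_low", "ror_high",
                "prr", "chi2", "is_signal"]
        header = (
            f"Disproportionality screen: {len(self.model.target_ids)} target cases, "
            f"{len(self.model.cases)} cases total, {len(self.frame)} PTs "
            f"({int(self.frame['is_signal'].sum())} signals)\n"
        )
        with pd.option_context("display.float_format", "{:.2f}".format):
            return header + df[cols].to_string(index=False)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)
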