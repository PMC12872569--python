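"""Outcome seriousness classification and clinical-characteristics summary.

FAERS OUTC codes mark the FDA seriousness outcomes: DE death, LT
life-threatening, HO hospitalization (initial or prolonged), DS
disability, CA congenital anomaly, RI required intervention, OT other
serious (medically important).  A case may carry several codes; here each
case is assigned the single most severe category by the precedence
DE > LT > DS > HO > CA > OT, and cases with no OUTC record fall into
unknown/non-serious.
"""

from __future__ import annotations

import logging
from collections import Counter
from typing import Iterable, Sequence

import pandas as pd

from .faers_io import CaseReport

logger = logging.getLogger(__name__)

#: Most-severe-first precedence of outcome codes and their display labels.
OUTCOME_PRECEDENCE: tuple[str, ...] = ("DE", "LT", "DS", "HO", "CA", "OT")

OUTCOME_LABELS: dict[str, str] = {
    "DE": "death",
    "LT": "life-threatening",
    "HO": "hospitalization",
    "DS": "disability",
    "CA": "congenital anomaly",
    "OT": "other serious",
}

UNKNOWN_OUTCOME = "unknown/non-serious"

#: RI ("required intervention") appears in FAERS but not in the six-way
#: seriousness tabulation; it is folded into "other serious".
_CODE_ALIASES = {"RI": "OT"}

AGE_BANDS = ("<18", "18-64", ">=65", "unknown")


def classify_outcome(codes: Iterable[str]) -> str:
    """Single seriousness category for a case's set of OUTC codes.

    The highest-precedence code present wins; an empty set is
    unknown/non-serious; unrecognized codes are ignored with a warning.
    """
    present = set()
    for code in codes:
        code = str(code).strip().upper()
        code = _CODE_ALIASES.get(code, code)
        if code in OUTCOME_LABELS:
            present.add(code)
        elif code:
            logger.warning("ignoring unrecognized outcome code %r", code)
    for code in OUTCOME_PRECEDENCE:
        if code in present:
            return OUTCOME_LABELS[code]
    return UNKNOWN_OUTCOME


def _age_band(age_years: float | None) -> str:
    if age_years is None:
        return "unknown"
    if age_years < 18:
        return "<18"
    if age_years < 65:
        return "18-64"
    return ">=65"


def summarize_characteristics(cases: Sequence[CaseReport]) -> pd.DataFrame:
    """Stratified counts and percentages of the case cohort.

    One row per (family, level) for the families gender, age band
    (completed years: <18, 18-64, >=65, unknown), reporter type, country,
    calendar year (of the retained version's FDA_DT) and outcome
    category.  Percentages use the family's own total as denominator and
    are rounded to one decimal.
    """
    if not cases:
        return pd.DataFrame(columns=["family", "level", "n", "pct"])
    families: dict[str, Counter] = {
        "gender": Counter(c.sex for c in cases),
        "age": Counter(_age_band(c.age_years) for c in cases),
        "reporter": Counter(c.reporter for c in cases),
        "country": Counter(c.country or "unknown" for c in cases),
        "year": Counter(
            str(c.fda_dt.year) if c.fda_dt is not None else "unknown" for c in cases
        ),
        "outcome": Counter(classify_outcome(c.outcome_codes) for c in cases),
    }
    rows = []
    for family, counter in families.items():
        total = sum(counter.values())
        for level, n in sorted(counter.items(), key=lambda kv: (-kv[1], kv[0])):
            rows.append(
                {
                    "family": family,
                    "level": level,
                    "n": n,
                    "pct": round(100.0 * n / total, 1),
                }
            )
    return pd.DataFrame(rows, columns=["family", "level", "n", "pct"])


def gender_ratio(cases: Sequence[CaseReport]) -> float | None:
    """Female:male case ratio, rounded to 2 decimals; None without males."""
    n_f = sum(c.sex == "female" for c in cases)
    n_m = sum(c.sex == "male" for c in cases)
    if n_m == 0:
        return None
    return round(n_f / n_m, 2)
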