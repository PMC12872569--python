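"""FAERS quarterly ASCII ingestion: parsing, deduplication, case assembly.

FAERS distributes spontaneous reports as '$'-delimited ASCII tables.  A
single safety case (CASEID) may appear as several report versions
(PRIMARYID) as follow-up information arrives; the FDA-recommended
deduplication keeps, per CASEID, the version with the highest FDA_DT,
breaking ties by the highest PRIMARYID.  Suspect-drug matching is by
normalized whole-field equality against a synonym list, restricted to
primary-suspect (ROLE_COD='PS') drug records.
"""

from __future__ import annotations

import io
import logging
import os
import re
from dataclasses import dataclass, field
from datetime import date, datetime
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class SchemaError(ValueError):
    """A required column is missing from a FAERS table stream."""


#: The trade/generic name variants under which pentosan polysulfate sodium
#: reports appear in FAERS drug records.
PPS_SYNONYMS: tuple[str, ...] = (
    "ELMIRON",
    "ELMIRON BLADDER",
    "ELMIRON CAP",
    "ELMIRON CAPSULE",
    "ELMIRON 100",
    "ELMIRON 100MG ORAL",
    "ELMIRON PENTOSAN POLYSULFATE SODIUM 100 MG",
    "ELMIRON PENTOSAN POLYSULFATE SODIUM",
    "PENTOSAN POLYSULFATE ELMIRON",
    "PENTOSAN POLYSULFATE SODIUM",
    "PENTOSAN POLYSULFATE SODIUM CAPSULE",
    "PENTOSAN POLYSULFATE SODIUM 100 MG",
)

REQUIRED_COLUMNS: dict[str, tuple[str, ...]] = {
    "demo": ("primaryid", "caseid", "fda_dt"),
    "drug": ("primaryid", "caseid", "drugname", "role_cod"),
    "reac": ("primaryid", "caseid", "pt"),
    "outc": ("primaryid", "caseid", "outc_cod"),
    "ther": ("primaryid", "caseid", "start_dt"),
}

_REPORTER_CODES = {
    "MD": "physician",
    "CN": "consumer",
    "HP": "health professional",
    "OT": "other health-professional",
    "PH": "pharmacist",
    "LW": "lawyer",
}

_AGE_TO_YEARS = {
    "YR": 1.0,
    "DEC": 10.0,
    "MON": 1.0 / 12.0,
    "WK": 7.0 / 365.25,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / (24.0 * 365.25),
}

VALID_OUTCOME_CODES = frozenset({"DE", "LT", "HO", "DS", "CA", "RI", "OT"})


@dataclass
class CaseReport:
    """One deduplicated safety report, analysis-ready.

    ``therapy_starts`` maps the normalized drug name to the earliest
    parseable therapy start date found among the case's THER records.
    """

    primaryid: str
    caseid: str
    fda_dt: date | None
    event_dt: date | None
    sex: str  # female / male / unknown
    age_years: float | None
    reporter: str
    country: str
    drugs: list[tuple[str, str]] = field(default_factory=list)  # (drugname, role)
    pts: frozenset[str] = frozenset()
    outcome_codes: frozenset[str] = frozenset()
    therapy_starts: dict[str, date | None] = field(default_factory=dict)


def parse_faers_date(s) -> date | None:
    """Parse an 8-digit YYYYMMDD string to a date; anything else is None.

    Partial dates (YYYY or YYYYMM), empty strings and impossible calendar
    days all map to None — this is a total function, never an error.
    """
    if s is None:
        return None
    s = str(s).strip()
    if len(s) != 8 or not s.isdigit():
        return None
    try:
        return datetime.strptime(s, "%Y%m%d").date()
    except ValueError:
        return None


def normalize_drugname(name: str) -> str:
    """Trim, casefold and collapse internal whitespace."""
    return re.sub(r"\s+", " ", str(name).strip()).casefold()


def parse_faers_table(stream, schema: str, typed: bool = True) -> pd.DataFrame:
    """Parse one '$'-delimited FAERS table.

    Parameters
    ----------
    stream : file-like, str (path or literal text containing a newline)
    schema : one of 'demo', 'drug', 'reac', 'outc', 'ther'
    typed : bool
        When True, map the schema's known fields to typed values (dates to
        ``datetime64`` with NaT for anything malformed, SEX to
        female/male/unknown, AGE+AGE_COD to ``age_years``); unknown columns
        are preserved as opaque strings.  When False, return the raw
        string table (used by round-trip checks).
    """
    if schema not in REQUIRED_COLUMNS:
        raise ValueError(f"unknown schema {schema!r}")
    if isinstance(stream, str):
        looks_like_path = "\n" not in stream and os.path.exists(stream)
        stream = open(stream) if looks_like_path else io.StringIO(stream)
    text = stream.read()
    required = REQUIRED_COLUMNS[schema]
    if not text.strip():
        return pd.DataFrame(columns=list(required))
    df = pd.read_csv(
        io.StringIO(text), sep="$", dtype=str, keep_default_na=False, engine="python"
    )
    df.columns = [c.strip().lower() for c in df.columns]
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{schema.upper()} table is missing required column {col!r}")
    if not typed:
        return df
    return _apply_types(df, schema)


def _apply_types(df: pd.DataFrame, schema: str) -> pd.DataFrame:
    df = df.copy()
    date_cols = {
        "demo": ("fda_dt", "event_dt"),
        "ther": ("start_dt", "end_dt"),
    }.get(schema, ())
    for col in date_cols:
        if col in df.columns:
            df[col] = _parse_date_column(df[col])
    if schema == "demo":
        if "sex" in df.columns:
            df["sex"] = (
                df["sex"].str.strip().str.upper().map({"F": "female", "M": "male"}).fillna("unknown")
            )
        df["age_years"] = _age_years(df)
        if "rept_cod" in df.columns:
            df["reporter"] = (
                df["rept_cod"].str.strip().str.upper().map(_REPORTER_CODES).fillna("unknown")
            )
    return df


def _parse_date_column(col: pd.Series) -> pd.Series:
    s = col.astype(str).str.strip()
    ok = s.str.fullmatch(r"\d{8}")
    out = pd.to_datetime(s.where(ok, None), format="%Y%m%d", errors="coerce")
    return out


def _age_years(df: pd.DataFrame) -> pd.Series:
    if "age" not in df.columns:
        return pd.Series(np.nan, index=df.index)
    age = pd.to_numeric(df["age"].str.strip(), errors="coerce")
    if "age_cod" in df.columns:
        factor = df["age_cod"].str.strip().str.upper().map(_AGE_TO_YEARS)
        factor = factor.where(df["age_cod"].str.strip() != "", 1.0)  # blank code: assume years
    else:
        factor = pd.Series(1.0, index=df.index)
    years = age * factor
    return years.where((years >= 0) & (years <= 130))


def read_faers_directory(directory, typed: bool = True) -> dict[str, pd.DataFrame]:
    """Read DEMO/DRUG/REAC/OUTC/THER .txt files from a directory."""
    out = {}
    for name in REQUIRED_COLUMNS:
        path = os.path.join(directory, f"{name.upper()}.txt")
        with open(path) as fh:
            out[name] = parse_faers_table(fh, name, typed=typed)
    return out


def _primaryid_sort_key(pid: pd.Series) -> tuple[pd.Series, pd.Series]:
    """Total order over PRIMARYID: all-digit ids numerically, before
    non-digit ids compared lexicographically."""
    s = pid.astype(str).str.strip()
    is_num = s.str.fullmatch(r"\d+")
    num = pd.to_numeric(s.where(is_num, None), errors="coerce")
    return (~is_num).astype(int), num


def deduplicate(demo: pd.DataFrame) -> pd.DataFrame:
    """Keep one report version per CASEID: highest FDA_DT, then highest
    PRIMARYID; missing FDA_DT sorts lowest.  Output ascending by CASEID."""
    if demo.empty:
        return demo.copy()
    df = demo.copy()
    nonnum, num = _primaryid_sort_key(df["primaryid"])
    df["_pid_nonnum"] = nonnum
    df["_pid_num"] = num
    df = df.sort_values(
        ["caseid", "fda_dt", "_pid_nonnum", "_pid_num", "primaryid"],
        na_position="first",
        kind="mergesort",
    )
    df = df.groupby("caseid", sort=True).tail(1)
    df = df.sort_values("caseid", kind="mergesort").reset_index(drop=True)
    return df.drop(columns=["_pid_nonnum", "_pid_num"])


def match_primary_suspect(drug: pd.DataFrame, synonyms: Sequence[str]) -> set[str]:
    """Primaryids of reports where a ROLE_COD='PS' drug record's name
    matches a synonym (whole-field, after normalization)."""
    if not synonyms:
        raise ValueError("synonym list must be non-empty")
    targets = {normalize_drugname(s) for s in synonyms}
    role = drug["role_cod"].astype(str).str.strip().str.upper()
    name = drug["drugname"].map(normalize_drugname)
    hit = (role == "PS") & name.isin(targets)
    return set(drug.loc[hit, "primaryid"].astype(str))


def assemble_cases(
    tables, synonyms: Sequence[str] = PPS_SYNONYMS, restrict: bool = True
) -> list[CaseReport]:
    """Deduplicate, match the suspect drug and build analysis-ready cases.

    Deduplication is applied first; with ``restrict`` (the default) only
    reports whose retained version carries a primary-suspect match are
    kept, while ``restrict=False`` assembles the full deduplicated case
    universe (the comparator population of the disproportionality
    analysis).  REAC/DRUG/OUTC/THER rows whose PRIMARYID has no DEMO row
    are dropped with a logged count, as are reports with no reaction rows
    at all.
    """
    if hasattr(tables, "tables"):  # RawTables from the generator
        raw = {name: _apply_types(df, name) for name, df in tables.tables().items()}
    else:
        raw = dict(tables)
    demo, drug, reac = raw["demo"], raw["drug"], raw["reac"]
    outc = raw.get("outc", pd.DataFrame(columns=["primaryid", "caseid", "outc_cod"]))
    ther = raw.get("ther", pd.DataFrame(columns=["primaryid", "caseid", "start_dt"]))

    all_pids = set(demo["primaryid"].astype(str))
    n_orphans = 0
    parts = {}
    for name, df in (("drug", drug), ("reac", reac), ("outc", outc), ("ther", ther)):
        keep = df["primaryid"].astype(str).isin(all_pids)
        n_orphans += int((~keep).sum())
        parts[name] = df[keep]
    if n_orphans:
        logger.warning("dropped %d rows without a DEMO parent", n_orphans)

    kept = deduplicate(demo)
    kept_pids = set(kept["primaryid"].astype(str))
    matched = match_primary_suspect(parts["drug"], synonyms) & kept_pids
    wanted = matched if restrict else kept_pids

    drug_m = parts["drug"][parts["drug"]["primaryid"].isin(wanted)]
    reac_m = parts["reac"][parts["reac"]["primaryid"].isin(wanted)]
    outc_m = parts["outc"][parts["outc"]["primaryid"].isin(wanted)]
    ther_m = parts["ther"][parts["ther"]["primaryid"].isin(wanted)]

    pts_by_pid: dict[str, set] = {}
    for pid, pt in zip(reac_m["primaryid"], reac_m["pt"]):
        pts_by_pid.setdefault(pid, set()).add(str(pt).strip())
    drugs_by_pid: dict[str, list] = {}
    for pid, name, role in zip(drug_m["primaryid"], drug_m["drugname"], drug_m["role_cod"]):
        drugs_by_pid.setdefault(pid, []).append((name, role))
    outc_by_pid: dict[str, set] = {}
    for pid, code in zip(outc_m["primaryid"], outc_m["outc_cod"]):
        outc_by_pid.setdefault(pid, set()).add(str(code).strip().upper())
    starts_by_pid = _therapy_starts(ther_m, drug_m)

    cases: list[CaseReport] = []
    n_no_reac = 0
    for row in kept[kept["primaryid"].isin(wanted)].itertuples(index=False):
        pid = str(row.primaryid)
        pts = frozenset(pts_by_pid.get(pid, ()))
        if not pts:
            n_no_reac += 1
            continue
        age = getattr(row, "age_years", np.nan)
        cases.append(
            CaseReport(
                primaryid=pid,
                caseid=str(row.caseid),
                fda_dt=_to_date(row.fda_dt),
                event_dt=_to_date(getattr(row, "event_dt", None)),
                sex=getattr(row, "sex", "unknown"),
                age_years=None if pd.isna(age) else float(age),
                reporter=getattr(row, "reporter", "unknown"),
                country=str(getattr(row, "occr_country", "")),
                drugs=drugs_by_pid.get(pid, []),
                pts=pts,
                outcome_codes=frozenset(outc_by_pid.get(pid, ())),
                therapy_starts=starts_by_pid.get(pid, {}),
            )
        )
    if n_no_reac:
        logger.warning("dropped %d matched reports without reactions", n_no_reac)
    cases.sort(key=lambda c: c.caseid)
    return cases


def _therapy_starts(ther: pd.DataFrame, drug: pd.DataFrame) -> dict[str, dict[str, date]]:
    """Earliest parseable START_DT per normalized drugname per report.

    THER rows link to drug names through DSG_DRUG_SEQ = DRUG.DRUG_SEQ when
    both columns are present; otherwise each THER row is attributed to the
    report's first primary-suspect drug.
    """
    if ther.empty:
        return {}
    t = ther.copy()
    if "dsg_drug_seq" in t.columns and "drug_seq" in drug.columns:
        link = drug[["primaryid", "drug_seq", "drugname"]].rename(
            columns={"drug_seq": "dsg_drug_seq"}
        )
        t = t.merge(link, on=["primaryid", "dsg_drug_seq"], how="left")
    else:
        ps = drug[drug["role_cod"].astype(str).str.upper() == "PS"]
        first_ps = ps.groupby("primaryid")["drugname"].first()
        t["drugname"] = t["primaryid"].map(first_ps)
    t = t.dropna(subset=["drugname"])
    t["drugname"] = t["drugname"].map(normalize_drugname)
    t = t.dropna(subset=["start_dt"])
    if t.empty:
        return {}
    earliest = t.groupby(["primaryid", "drugname"])["start_dt"].min()
    out: dict[str, dict[str, date]] = {}
    for (pid, name), start in earliest.items():
        out.setdefault(str(pid), {})[name] = _to_date(start)
    return out


def filter_by_age(cases: Iterable[CaseReport], min_age: float) -> list[CaseReport]:
    """Keep cases with a documented age of at least ``min_age`` years;
    cases with missing age are excluded."""
    if min_age < 0:
        raise ValueError("min_age must be >= 0")
    return [c for c in cases if c.age_years is not None and c.age_years >= min_age]


def target_caseids(cases: Iterable[CaseReport], synonyms: Sequence[str]) -> set[str]:
    """Caseids of assembled cases carrying a primary-suspect synonym match."""
    targets = {normalize_drugname(s) for s in synonyms}
    return {
        c.caseid
        for c in cases
        if any(
            str(role).strip().upper() == "PS" and normalize_drugname(name) in targets
            for name, role in c.drugs
        )
    }


def cases_to_frame(cases: Iterable[CaseReport]) -> pd.DataFrame:
    """Flatten cases to a DataFrame (nested fields JSON-encoded) so the
    CLI stages can hand cases between processes as CSV."""
    import json

    rows = []
    for c in cases:
        rows.append(
            {
                "primaryid": c.primaryid,
                "caseid": c.caseid,
                "fda_dt": c.fda_dt.isoformat() if c.fda_dt else "",
                "event_dt": c.event_dt.isoformat() if c.event_dt else "",
                "sex": c.sex,
                "age_years": "" if c.age_years is None else c.age_years,
                "reporter": c.reporter,
                "country": c.country,
                "drugs": json.dumps([list(d) for d in c.drugs]),
                "pts": json.dumps(sorted(c.pts)),
                "outcome_codes": json.dumps(sorted(c.outcome_codes)),
                "therapy_starts": json.dumps(
                    {k: (v.isoformat() if v else None) for k, v in c.therapy_starts.items()}
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "primaryid", "caseid", "fda_dt", "event_dt", "sex", "age_years",
            "reporter", "country", "drugs", "pts", "outcome_codes", "therapy_starts",
        ],
    )


def frame_to_cases(df: pd.DataFrame) -> list[CaseReport]:
    """Inverse of :func:`cases_to_frame`."""
    import json

    def _d(s):
        s = str(s).strip()
        return date.fromisoformat(s) if s and s != "nan" else None

    cases = []
    for row in df.itertuples(index=False):
        age = row.age_years
        cases.append(
            CaseReport(
                primaryid=str(row.primaryid),
                caseid=str(row.caseid),
                fda_dt=_d(row.fda_dt),
                event_dt=_d(row.event_dt),
                sex=str(row.sex),
                age_years=None if pd.isna(age) or str(age).strip() == "" else float(age),
                reporter=str(row.reporter),
                country="" if pd.isna(row.country) else str(row.country),
                drugs=[tuple(d) for d in json.loads(row.drugs)],
                pts=frozenset(json.loads(row.pts)),
                outcome_codes=frozenset(json.loads(row.outcome_codes)),
                therapy_starts={
                    k: (date.fromisoformat(v) if v else None)
                    for k, v in json.loads(row.therapy_starts).items()
                },
            )
        )
    return cases


def load_soc_map(path) -> dict[str, str]:
    """Read a PT->SOC mapping CSV with columns ``pt`` and ``soc``."""
    df = pd.read_csv(path, dtype=str)
    cols = {c.strip().lower(): c for c in df.columns}
    if "pt" not in cols or "soc" not in cols:
        raise SchemaError("SOC map requires columns 'pt' and 'soc'")
    return dict(zip(df[cols["pt"]].str.strip(), df[cols["soc"]].str.strip()))


def load_synonyms(path) -> list[str]:
    """Read a drug-synonym list, one name per line; blank lines ignored."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def _to_date(value) -> date | None:
    if value is None or pd.isna(value):
        return None
    if isinstance(value, date) and not isinstance(value, datetime):
        return value
    return pd.Timestamp(value).date()
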