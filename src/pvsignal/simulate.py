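"""Synthetic FAERS-shaped data with known statistical structure.

:func:`generate` draws a multi-table dataset (DEMO/DRUG/REAC/OUTC/THER)
from the generative model described by :class:`~pvsignal.config.SimulationConfig`:

* each case picks one primary-suspect drug and 0-2 concomitant drugs;
* preferred terms are drawn independently per PT as Bernoulli with rate
  ``baseline * signal_multiplier(drug, pt) * gender_multiplier(sex, pt)``,
  so the realised drug-event cross-tabulation converges in expectation to
  the configured disproportionality structure;
* time-to-onset is drawn from the configured parametric family and turned
  into THER start / DEMO event dates;
* a configurable fraction of cases is emitted twice as versioned reports
  sharing a CASEID (distinct PRIMARYID / FDA_DT), with the older version
  possibly carrying a subset of the reactions — the deduplication ground
  truth is the version with the largest (FDA_DT, PRIMARYID).

All tables are plain string DataFrames exactly as they would appear in the
'$'-delimited quarterly ASCII files; :func:`write_faers_ascii` round-trips
with :func:`pvsignal.faers_io.parse_faers_table`.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SimulationConfig

TABLE_NAMES = ("demo", "drug", "reac", "outc", "ther")

_SEX_CODES = {"female": "F", "male": "M", "unknown": "UNK"}
# age-band mix among reports with a documented age: minors / adults / elderly
_AGE_BAND_PROBS = (0.259, 0.542, 0.199)
_AGE_BANDS = ((1, 17), (18, 64), (65, 90))


@dataclass
class RawTables:
    """The five FAERS-style tables as string DataFrames, plus ground truth.

    ``truth`` has one row per generated case (final retained version) with
    the latent values the tables were drawn from; it is what oracle tests
    compare pipeline output against.
    """

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    outc: pd.DataFrame
    ther: pd.DataFrame
    truth: pd.DataFrame | None = field(default=None, compare=False)

    def tables(self) -> dict[str, pd.DataFrame]:
        return {name: getattr(self, name) for name in TABLE_NAMES}


def generate(config: SimulationConfig) -> RawTables:
    """Draw a complete synthetic dataset; deterministic for a fixed seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_reports

    caseid = np.array([str(10_000_000 + i) for i in range(n)])
    pid_final = np.array([c + "2" for c in caseid])

    drug_names = list(config.drug_names)
    probs = None if config.drug_probs is None else np.asarray(config.drug_probs, float)
    ps_drug = rng.choice(drug_names, size=n, p=probs)

    sex = rng.choice(
        ["female", "male", "unknown"],
        size=n,
        p=[config.female_fraction, config.male_fraction, config.unknown_gender_fraction],
    )

    age = _draw_ages(rng, n, config.missing_age_rate)

    pts = [pt for pt, _ in config.pt_catalog]
    hits = _draw_pt_matrix(rng, config, ps_drug, sex)

    tto_days = _draw_tto(rng, config, n)

    start64, event64, fda64 = _draw_dates(rng, config, tto_days)
    start_str, start_missing, start_partial = _format_dates(
        rng, start64, config.missing_start_date_rate, config.partial_date_rate
    )
    event_str, event_missing, event_partial = _format_dates(
        rng, event64, config.missing_event_date_rate, config.partial_date_rate
    )
    fda_str = _strf(fda64)

    reporter = rng.choice(
        list(config.reporter_probs), size=n, p=list(config.reporter_probs.values())
    )

    # ---- older duplicate versions -------------------------------------
    dup = rng.random(n) < config.duplicate_rate
    dup_idx = np.flatnonzero(dup)
    pid_old = np.array([caseid[i] + "1" for i in dup_idx])
    # mostly an earlier FDA_DT; ~10% exact ties to exercise the PRIMARYID tie-break
    back = rng.integers(1, 100, size=dup_idx.size)
    tie = rng.random(dup_idx.size) < 0.10
    back[tie] = 0
    fda_old64 = fda64[dup_idx] - back.astype("timedelta64[D]")
    fda_old_str = _strf(fda_old64)

    # ---- DEMO ---------------------------------------------------------
    age_str = np.where(np.isnan(age), "", np.char.mod("%d", np.nan_to_num(age).astype(int)))
    sex_code = np.vectorize(_SEX_CODES.get)(sex)
    demo_final = pd.DataFrame(
        {
            "primaryid": pid_final,
            "caseid": caseid,
            "fda_dt": fda_str,
            "event_dt": event_str,
            "sex": sex_code,
            "age": age_str,
            "age_cod": np.where(age_str == "", "", "YR"),
            "rept_cod": reporter,
            "occr_country": "US",
        }
    )
    demo_old = demo_final.iloc[dup_idx].copy()
    demo_old["primaryid"] = pid_old
    demo_old["fda_dt"] = fda_old_str
    demo = pd.concat([demo_final, demo_old], ignore_index=True)

    # ---- DRUG ---------------------------------------------------------
    background = [d for d in drug_names if d != config.target_drug]
    drug_rows = _drug_rows(rng, caseid, pid_final, ps_drug, background)
    drug_old = _reindex_versions(drug_rows, caseid, dup_idx, pid_old)
    drug = pd.concat([drug_rows, drug_old], ignore_index=True)

    # ---- REAC ---------------------------------------------------------
    rep_idx, pt_idx = np.nonzero(hits)
    reac_final = pd.DataFrame(
        {
            "primaryid": pid_final[rep_idx],
            "caseid": caseid[rep_idx],
            "pt": np.asarray(pts, object)[pt_idx],
        }
    )
    reac_old = _old_version_reactions(rng, reac_final, caseid, dup_idx, pid_old)
    reac = pd.concat([reac_final, reac_old], ignore_index=True)

    # ---- OUTC ---------------------------------------------------------
    outc_parts = []
    for code, p in config.outcome_code_probs.items():
        mask = rng.random(n) < p
        outc_parts.append(
            pd.DataFrame(
                {"primaryid": pid_final[mask], "caseid": caseid[mask], "outc_cod": code}
            )
        )
    outc_final = (
        pd.concat(outc_parts, ignore_index=True)
        if outc_parts
        else pd.DataFrame(columns=["primaryid", "caseid", "outc_cod"])
    )
    outc_old = _reindex_versions(outc_final, caseid, dup_idx, pid_old)
    outc = pd.concat([outc_final, outc_old], ignore_index=True)

    # ---- THER (therapy start for the suspect drug, DSG_DRUG_SEQ=1) ----
    ther_final = pd.DataFrame(
        {
            "primaryid": pid_final,
            "caseid": caseid,
            "dsg_drug_seq": "1",
            "start_dt": start_str,
        }
    )
    ther_old = _reindex_versions(ther_final, caseid, dup_idx, pid_old)
    ther = pd.concat([ther_final, ther_old], ignore_index=True)

    truth = pd.DataFrame(
        {
            "caseid": caseid,
            "primaryid": pid_final,
            "drug": ps_drug,
            "sex": sex,
            "age_years": age,
            "pts": [tuple(np.asarray(pts, object)[row]) for row in hits],
            "tto_days": tto_days,
            "start_missing": start_missing,
            "start_partial": start_partial,
            "event_missing": event_missing,
            "event_partial": event_partial,
        }
    )

    return RawTables(
        demo=demo.astype(str),
        drug=drug.astype(str),
        reac=reac.astype(str),
        outc=outc.astype(str),
        ther=ther.astype(str),
        truth=truth,
    )


def write_faers_ascii(tables: RawTables, directory) -> dict[str, str]:
    """Write one '$'-delimited ASCII file per table (header + records).

    The FAERS dialect has no quoting mechanism; any '$' inside a value is
    replaced by '/'.  Returns a map table name -> file path.
    """
    os.makedirs(directory, exist_ok=True)
    paths = {}
    for name, df in tables.tables().items():
        path = os.path.join(directory, f"{name.upper()}.txt")
        clean = df.astype(str).apply(lambda s: s.str.replace("$", "/", regex=False))
        lines = ["$".join(df.columns)]
        lines += ["$".join(row) for row in clean.itertuples(index=False, name=None)]
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
        paths[name] = path
    return paths


# ---------------------------------------------------------------------------


def _draw_ages(rng, n, missing_rate):
    band = rng.choice(3, size=n, p=_AGE_BAND_PROBS)
    age = np.empty(n)
    for b, (lo, hi) in enumerate(_AGE_BANDS):
        m = band == b
        age[m] = rng.integers(lo, hi + 1, size=m.sum())
    age[rng.random(n) < missing_rate] = np.nan
    return age


def _draw_pt_matrix(rng, config, ps_drug, sex):
    pts = [pt for pt, _ in config.pt_catalog]
    pt_index = {pt: j for j, pt in enumerate(pts)}
    base = np.array(
        [config.baseline_pt_rates.get(pt, config.default_pt_rate) for pt in pts]
    )
    rates = np.tile(base, (len(ps_drug), 1))
    for (drug, pt), m in config.signal_multipliers.items():
        if pt in pt_index:
            rates[ps_drug == drug, pt_index[pt]] *= m
    for (sex_label, pt), m in config.gender_pt_multipliers.items():
        if pt in pt_index:
            rates[sex == sex_label, pt_index[pt]] *= m
    rates = np.clip(rates, 0.0, 1.0)
    hits = rng.random(rates.shape) < rates
    # every report carries at least one reaction: Gumbel-max draw
    # proportional to the report's own rates for empty rows
    empty = ~hits.any(axis=1)
    if empty.any():
        logits = np.log(np.maximum(rates[empty], 1e-300))
        pick = np.argmax(logits + rng.gumbel(size=logits.shape), axis=1)
        hits[np.flatnonzero(empty), pick] = True
    return hits


def _draw_tto(rng, config, n):
    p = config.tto_params
    if config.tto_family == "weibull":
        raw = p["scale"] * rng.weibull(p["shape"], size=n)
    elif config.tto_family == "lognormal":
        raw = rng.lognormal(p["mu"], p["sigma"], size=n)
    else:  # loglogistic
        u = rng.uniform(size=n)
        raw = p["scale"] * (u / (1 - u)) ** (1.0 / p["shape"])
    return np.maximum(np.round(raw), 0).astype(int)


def _draw_dates(rng, config, tto_days):
    y0, y1 = config.start_year_range
    lo = np.datetime64(f"{y0}-01-01")
    hi = np.datetime64(f"{y1 + 1}-01-01")
    span = (hi - lo).astype(int)
    start = lo + rng.integers(0, span, size=tto_days.size).astype("timedelta64[D]")
    event = start + tto_days.astype("timedelta64[D]")
    fda = event + rng.integers(0, 180, size=tto_days.size).astype("timedelta64[D]")
    return start, event, fda


def _strf(dates64) -> np.ndarray:
    return pd.Series(dates64).dt.strftime("%Y%m%d").to_numpy()


def _format_dates(rng, dates64, missing_rate, partial_rate):
    s = _strf(dates64).astype(object)
    n = len(s)
    missing = rng.random(n) < missing_rate
    partial = (rng.random(n) < partial_rate) & ~missing
    s[partial] = [v[:6] for v in s[partial]]
    s[missing] = ""
    return s, missing, partial


def _drug_rows(rng, caseid, pid, ps_drug, background):
    n = len(caseid)
    parts = [
        pd.DataFrame(
            {
                "primaryid": pid,
                "caseid": caseid,
                "drug_seq": "1",
                "drugname": ps_drug,
                "role_cod": "PS",
            }
        )
    ]
    if background:
        n_extra = rng.integers(0, 3, size=n)
        for k in (1, 2):
            m = n_extra >= k
            cnt = int(m.sum())
            if cnt == 0:
                continue
            parts.append(
                pd.DataFrame(
                    {
                        "primaryid": pid[m],
                        "caseid": caseid[m],
                        "drug_seq": str(k + 1),
                        "drugname": rng.choice(background, size=cnt),
                        "role_cod": rng.choice(["SS", "C"], size=cnt),
                    }
                )
            )
    return pd.concat(parts, ignore_index=True)


def _reindex_versions(df, caseid, dup_idx, pid_old):
    """Copy a final-version table for the duplicated cases under old ids."""
    pid_map = dict(zip(caseid[dup_idx], pid_old))
    old = df[df["caseid"].isin(pid_map)].copy()
    old["primaryid"] = old["caseid"].map(pid_map)
    return old


def _old_version_reactions(rng, reac_final, caseid, dup_idx, pid_old):
    """Older versions may list only a subset of the final reactions."""
    old = _reindex_versions(reac_final, caseid, dup_idx, pid_old)
    if old.empty:
        return old
    keep = rng.random(len(old)) >= 0.3
    # never drop a version's last reaction
    first_of_case = ~old["caseid"].duplicated()
    kept_any = pd.Series(keep, index=old.index).groupby(old["caseid"].values).transform("any")
    keep = keep | (first_of_case.values & ~kept_any.values)
    return old[keep]
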