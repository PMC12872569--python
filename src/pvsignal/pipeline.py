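"""End-to-end orchestration: simulate/ingest -> signals -> sex differences
-> outcomes -> time-to-onset, with a machine-readable run manifest.

The manifest records the case funnel (raw report versions -> deduplicated
cases -> suspect-matched cases -> TTO-eligible events) together with the
headline results of every stage, so a run is fully reproducible from its
config and seed.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import yaml

from .config import ConfigurationError, SimulationConfig
from .disproportionality import DisproportionalityModel, SignalThresholds
from .faers_io import (
    PPS_SYNONYMS,
    assemble_cases,
    cases_to_frame,
    deduplicate,
    filter_by_age,
    load_soc_map,
    load_synonyms,
    read_faers_directory,
    target_caseids,
)
from .gender import EmptyStratumError, SexDifferenceModel
from .outcomes import gender_ratio, summarize_characteristics
from .simulate import generate, write_faers_ascii
from .tto import TimeToOnsetModel

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Exactly one data source is used: an existing FAERS-style directory
    (``data_dir``) or the synthetic generator (``simulation``, the
    default).  ``seed`` overrides the simulation seed so one integer
    drives the whole run.
    """

    out_dir: str = "pvsignal_run"
    simulation: SimulationConfig | None = None
    data_dir: str | None = None
    synonyms: Sequence[str] = PPS_SYNONYMS
    pt_to_soc: Mapping[str, str] | None = None
    thresholds: SignalThresholds = field(default_factory=SignalThresholds)
    alpha: float = 0.05
    min_age: float | None = None
    seed: int = 0
    write_tables: bool = False  # also dump the simulated ASCII tables

    def __post_init__(self):
        if self.data_dir is None and self.simulation is None:
            self.simulation = SimulationConfig(seed=self.seed)
        for name in ("min_reports", "z", "prr_min", "chi2_min"):
            if getattr(self.thresholds, name) <= 0:
                raise ConfigurationError(f"thresholds.{name} must be positive")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must be in (0, 1)")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw or {})

    @classmethod
    def from_dict(cls, raw: Mapping) -> "RunConfig":
        raw = dict(raw)
        if "simulation" in raw and raw["simulation"] is not None:
            raw["simulation"] = SimulationConfig.from_dict(raw["simulation"])
        if "thresholds" in raw and isinstance(raw["thresholds"], Mapping):
            raw["thresholds"] = SignalThresholds(**raw["thresholds"])
        if isinstance(raw.get("synonyms"), str):
            raw["synonyms"] = load_synonyms(raw["synonyms"])
        if isinstance(raw.get("pt_to_soc"), str):
            raw["pt_to_soc"] = load_soc_map(raw["pt_to_soc"])
        return cls(**raw)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage, write per-stage CSVs plus ``manifest.json`` into
    ``config.out_dir``, and return the manifest."""
    from . import __version__ as _version

    os.makedirs(config.out_dir, exist_ok=True)
    manifest: dict = {
        "pvsignal_version": _version,
        "seed": config.seed,
        "counts": {},
        "stages": {},
    }
    counts = manifest["counts"]

    # -- data source ----------------------------------------------------
    stage = "ingest"
    try:
        if config.data_dir is not None:
            raw = read_faers_directory(config.data_dir)
            tables = raw
            demo = raw["demo"]
            soc_map = dict(config.pt_to_soc or {})
        else:
            sim = config.simulation
            if sim.seed != config.seed:
                sim = SimulationConfig.from_dict({**sim.to_dict(), "seed": config.seed})
            tables = generate(sim)
            demo = tables.demo
            if config.write_tables:
                write_faers_ascii(tables, os.path.join(config.out_dir, "data"))
            soc_map = dict(config.pt_to_soc or dict(sim.pt_catalog))
        counts["raw_report_versions"] = int(len(demo))
        counts["deduplicated_cases"] = int(len(deduplicate(demo)))
        cases = assemble_cases(tables, config.synonyms, restrict=False)
        target_ids = target_caseids(cases, config.synonyms)
        counts["assembled_cases"] = len(cases)
        counts["suspect_matched_cases"] = len(target_ids)
        logger.info(
            "ingest: %d raw versions -> %d cases -> %d suspect-matched",
            counts["raw_report_versions"],
            counts["deduplicated_cases"],
            counts["suspect_matched_cases"],
        )
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise PipelineError(stage, exc) from exc

    if config.min_age is not None:
        cases = filter_by_age(cases, config.min_age)
        target_ids = {c.caseid for c in cases if c.caseid in target_ids}
        counts["age_filtered_cases"] = len(cases)
        counts["age_filtered_suspect_cases"] = len(target_ids)

    target_cases = [c for c in cases if c.caseid in target_ids]

    # -- disproportionality screen --------------------------------------
    stage = "signals"
    try:
        model = DisproportionalityModel(
            cases, target_ids, pt_to_soc=soc_map, thresholds=config.thresholds
        )
        signal_res = model.fit()
        signal_res.to_csv(os.path.join(config.out_dir, "signals.csv"))
        manifest["stages"]["signals"] = {
            "n_pts_screened": int(len(signal_res.frame)),
            "n_signals": int(signal_res.frame["is_signal"].sum()),
        }
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # -- sex differences -------------------------------------------------
    stage = "gender"
    try:
        sex_model = SexDifferenceModel(
            target_cases, min_count=config.thresholds.min_reports, alpha=config.alpha
        )
        sex_res = sex_model.fit()
        sex_res.to_csv(os.path.join(config.out_dir, "gender.csv"))
        directions = sex_res.frame["direction"].value_counts().to_dict()
        manifest["stages"]["gender"] = {
            "n_pts_tested": int(len(sex_res.frame)),
            "n_female_signals": int(directions.get("female", 0)),
            "n_male_signals": int(directions.get("male", 0)),
        }
    except EmptyStratumError as exc:
        logger.warning("gender stage skipped: %s", exc)
        manifest["stages"]["gender"] = {"skipped": str(exc)}
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # -- outcome / characteristics summary -------------------------------
    stage = "summarize"
    try:
        chars = summarize_characteristics(target_cases)
        chars.to_csv(os.path.join(config.out_dir, "characteristics.csv"), index=False)
        ratio = gender_ratio(target_cases)
        manifest["stages"]["summarize"] = {
            "n_cases": len(target_cases),
            "female_male_ratio": ratio,
        }
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # -- time to onset ----------------------------------------------------
    stage = "tto"
    try:
        tto_manifest: dict = {}
        try:
            tto_model = TimeToOnsetModel.from_cases(target_cases, config.synonyms)
        except ValueError as exc:
            logger.warning("tto stage skipped: %s", exc)
            tto_manifest = {"skipped": str(exc)}
            tto_model = None
        if tto_model is not None:
            counts["tto_eligible_cases"] = int(tto_model.days.size)
            tto_res = tto_model.fit()
            dist = tto_res.distribution()
            km = tto_res.km()
            import pandas as pd

            pd.DataFrame(
                {
                    "time": km.times,
                    "survival": km.survival,
                    "n_at_risk": [int((tto_model.days >= t).sum()) for t in km.times],
                }
            ).to_csv(os.path.join(config.out_dir, "km_curve.csv"), index=False)
            tto_res.comparison.table().to_csv(
                os.path.join(config.out_dir, "fits.csv"), index=False
            )
            rec = pd.DataFrame(
                [
                    {
                        "caseid": r.caseid,
                        "tto_days": r.tto_days,
                        "included": r.included,
                        "exclusion_reason": r.exclusion_reason,
                    }
                    for r in tto_model.records
                ]
            )
            rec.to_csv(os.path.join(config.out_dir, "tto_records.csv"), index=False)
            wb = tto_res.fits.get("weibull")
            tto_manifest = {
                "exclusions": tto_model.exclusion_tally,
                "median_days": dist["median"],
                "iqr_days": [dist["q1"], dist["q3"]],
                "bins": dist["bins"],
                "best_family": tto_res.best.family,
                "hazard_class": tto_res.hazard_class,
            }
            if wb is not None:
                tto_manifest["weibull"] = {
                    "scale": wb.params["scale"],
                    "shape": wb.params["shape"],
                    "shape_ci95": list(wb.shape_ci95) if wb.shape_ci95 else None,
                    "aic": wb.aic,
                    "bic": wb.bic,
                }
        manifest["stages"]["tto"] = tto_manifest
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    cases_to_frame(target_cases).to_csv(
        os.path.join(config.out_dir, "cases.csv"), index=False
    )
    with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
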