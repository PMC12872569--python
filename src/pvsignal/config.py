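"""Configuration for the synthetic FAERS generator.

The defaults describe the study conditions this package targets: a single
heavily female-reported suspect drug (pentosan polysulfate sodium, PPS)
with strong injected ocular signals, sex-differential reporting for a few
terms, Weibull-distributed event onset times with a decreasing hazard
(shape < 1), duplicated case versions, and partially or wholly missing
dates — the structural features of real FAERS extracts that the pipeline
must survive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import yaml


class ConfigurationError(ValueError):
    """A simulation or pipeline configuration field is invalid."""


#: Default MedDRA-like preferred-term catalogue: (PT, SOC).  The terms echo
#: the adverse-event profile reported for PPS: retinal/macular toxicity in
#: Eye disorders plus a spread of non-ocular background terms.
DEFAULT_PT_CATALOG: tuple[tuple[str, str], ...] = (
    ("Maculopathy", "Eye disorders"),
    ("Pigmentary maculopathy", "Eye disorders"),
    ("Retinal pigmentation", "Eye disorders"),
    ("Retinal dystrophy", "Eye disorders"),
    ("Macular degeneration", "Eye disorders"),
    ("Visual impairment", "Eye disorders"),
    ("Retinopathy", "Eye disorders"),
    ("Vision blurred", "Eye disorders"),
    ("Blindness", "Eye disorders"),
    ("Vitreous detachment", "Eye disorders"),
    ("Alopecia", "Skin and subcutaneous tissue disorders"),
    ("Rash", "Skin and subcutaneous tissue disorders"),
    ("Pruritus", "Skin and subcutaneous tissue disorders"),
    ("Depression", "Psychiatric disorders"),
    ("Anxiety", "Psychiatric disorders"),
    ("Insomnia", "Psychiatric disorders"),
    ("Nausea", "Gastrointestinal disorders"),
    ("Diarrhoea", "Gastrointestinal disorders"),
    ("Abdominal discomfort", "Gastrointestinal disorders"),
    ("Vomiting", "Gastrointestinal disorders"),
    ("Bladder pain", "Renal and urinary disorders"),
    ("Urinary bladder haemorrhage", "Renal and urinary disorders"),
    ("Bladder irritation", "Renal and urinary disorders"),
    ("Headache", "Nervous system disorders"),
    ("Dizziness", "Nervous system disorders"),
    ("Pain", "General disorders and administration site conditions"),
    ("Fatigue", "General disorders and administration site conditions"),
    ("Arthralgia", "Musculoskeletal and connective tissue disorders"),
    ("Weight decreased", "Metabolism and nutrition disorders"),
    ("Dyspnoea", "Respiratory, thoracic and mediastinal disorders"),
)

DEFAULT_TARGET_DRUG = "PENTOSAN POLYSULFATE SODIUM"

DEFAULT_BACKGROUND_DRUGS: tuple[str, ...] = tuple(
    f"BACKGROUND DRUG {i:02d}" for i in range(1, 20)
)


def _default_baseline_rates() -> dict[str, float]:
    # The retinal-toxicity terms are rare in the background population;
    # their strength as signals comes from near-exclusivity to the target
    # drug, not from high absolute frequency.
    return {
        "Maculopathy": 0.004,
        "Pigmentary maculopathy": 0.004,
        "Retinal pigmentation": 0.004,
        "Retinal dystrophy": 0.004,
        "Macular degeneration": 0.004,
        "Urinary bladder haemorrhage": 0.005,
        "Bladder pain": 0.008,
    }


def _default_signal_multipliers() -> dict[tuple[str, str], float]:
    # Strong ocular signal injection for the target drug, echoing the
    # reported dominance of the Eye disorders SOC, plus a few weaker
    # non-ocular signals.
    t = DEFAULT_TARGET_DRUG
    return {
        (t, "Maculopathy"): 30.0,
        (t, "Pigmentary maculopathy"): 25.0,
        (t, "Retinal pigmentation"): 20.0,
        (t, "Retinal dystrophy"): 12.0,
        (t, "Macular degeneration"): 8.0,
        (t, "Alopecia"): 4.0,
        (t, "Depression"): 3.0,
        (t, "Bladder pain"): 6.0,
    }


def _default_gender_multipliers() -> dict[tuple[str, str], float]:
    # Female-skewed maculopathy terms and male-skewed gastrointestinal /
    # bladder terms, the qualitative sex-difference pattern seen for PPS.
    return {
        ("female", "Maculopathy"): 2.5,
        ("female", "Pigmentary maculopathy"): 2.5,
        ("male", "Diarrhoea"): 3.0,
        ("male", "Abdominal discomfort"): 3.0,
        ("male", "Urinary bladder haemorrhage"): 4.0,
    }


def _default_outcome_probs() -> dict[str, float]:
    # Marginal probability of each FDA outcome code per report; reports
    # drawing no code at all end up in the unknown/non-serious stratum.
    return {"OT": 0.55, "HO": 0.030, "DS": 0.012, "DE": 0.004, "LT": 0.003, "CA": 0.001}


def _default_reporter_probs() -> dict[str, float]:
    # REPT_COD marginals approximating a litigation-driven reporting mix
    # (lawyers and consumers dominate).
    return {"LW": 0.492, "CN": 0.301, "HP": 0.112, "MD": 0.044, "PH": 0.024, "OT": 0.021, "": 0.006}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic FAERS-shaped data generator.

    Parameters
    ----------
    n_reports : int
        Number of distinct cases (CASEIDs) to generate.
    drug_names : sequence of str
        All drug names in play; ``target_drug`` must be among them.
    target_drug : str
        The suspect drug of interest; always emitted with ROLE_COD='PS'
        in its reports.
    drug_probs : sequence of float, optional
        Probability that a report's primary suspect is each drug, aligned
        with ``drug_names``; uniform when omitted.
    pt_catalog : sequence of (str, str)
        (preferred term, system organ class) pairs.
    baseline_pt_rates : mapping PT -> probability
        Per-report Bernoulli rate of each PT before multipliers; PTs
        missing from the map default to ``default_pt_rate``.
    signal_multipliers : mapping (drug, PT) -> float
        Relative reporting-rate multiplier applied when the report's
        suspect drug matches.
    gender_pt_multipliers : mapping (sex, PT) -> float
        Multiplier applied by reporter sex ('female'/'male').
    female_fraction, male_fraction, unknown_gender_fraction : float
        Report sex mix; must sum to 1.
    tto_family : {'weibull', 'lognormal', 'loglogistic'}
        Family of the time-to-onset distribution (days).
    tto_params : mapping
        Family parameters.  Weibull and log-logistic: ``scale`` (alpha,
        days) and ``shape`` (beta); log-normal: ``mu`` and ``sigma`` on
        log-days.
    duplicate_rate : float
        Fraction of cases emitted as two report versions sharing a CASEID
        with distinct PRIMARYID / FDA_DT.
    missing_event_date_rate, missing_start_date_rate : float
        Probability that EVENT_DT / START_DT is emitted empty.
    partial_date_rate : float
        Probability that a present date is truncated to 6-digit YYYYMM.
    missing_age_rate : float
        Probability that AGE is emitted empty.
    outcome_code_probs : mapping OUTC code -> probability
        Independent per-code emission probabilities.
    reporter_probs : mapping REPT_COD -> probability
        Reporter-type mix; the empty string stands for a missing code.
    start_year_range : (int, int)
        Calendar window (inclusive) for therapy start dates.
    seed : int
        Seed of the single random generator driving everything.
    """

    n_reports: int = 5000
    drug_names: Sequence[str] = (DEFAULT_TARGET_DRUG,) + DEFAULT_BACKGROUND_DRUGS
    target_drug: str = DEFAULT_TARGET_DRUG
    drug_probs: Sequence[float] | None = None
    pt_catalog: Sequence[tuple[str, str]] = DEFAULT_PT_CATALOG
    baseline_pt_rates: Mapping[str, float] = field(default_factory=_default_baseline_rates)
    default_pt_rate: float = 0.02
    signal_multipliers: Mapping[tuple[str, str], float] = field(
        default_factory=_default_signal_multipliers
    )
    gender_pt_multipliers: Mapping[tuple[str, str], float] = field(
        default_factory=_default_gender_multipliers
    )
    female_fraction: float = 0.873
    male_fraction: float = 0.071
    unknown_gender_fraction: float = 0.056
    tto_family: str = "weibull"
    tto_params: Mapping[str, float] = field(
        default_factory=lambda: {"scale": 3097.0, "shape": 0.62}
    )
    duplicate_rate: float = 0.10
    missing_event_date_rate: float = 0.60
    missing_start_date_rate: float = 0.30
    partial_date_rate: float = 0.05
    missing_age_rate: float = 0.487
    outcome_code_probs: Mapping[str, float] = field(default_factory=_default_outcome_probs)
    reporter_probs: Mapping[str, float] = field(default_factory=_default_reporter_probs)
    start_year_range: tuple[int, int] = (2004, 2024)
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not isinstance(self.n_reports, (int,)) or self.n_reports < 1:
            raise ConfigurationError("n_reports must be a positive integer")
        if not self.drug_names:
            raise ConfigurationError("drug_names must be non-empty")
        if self.target_drug not in set(self.drug_names):
            raise ConfigurationError("target_drug must appear in drug_names")
        if self.drug_probs is not None:
            if len(self.drug_probs) != len(self.drug_names):
                raise ConfigurationError("drug_probs must align with drug_names")
            if any(p < 0 for p in self.drug_probs) or abs(sum(self.drug_probs) - 1) > 1e-9:
                raise ConfigurationError("drug_probs must be non-negative and sum to 1")
        if not self.pt_catalog:
            raise ConfigurationError("pt_catalog must be non-empty")
        fractions = {
            "female_fraction": self.female_fraction,
            "male_fraction": self.male_fraction,
            "unknown_gender_fraction": self.unknown_gender_fraction,
        }
        for name, v in fractions.items():
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if abs(sum(fractions.values()) - 1.0) > 1e-9:
            raise ConfigurationError("gender fractions must sum to 1")
        for name in (
            "duplicate_rate",
            "missing_event_date_rate",
            "missing_start_date_rate",
            "partial_date_rate",
            "missing_age_rate",
            "default_pt_rate",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        for pt, r in self.baseline_pt_rates.items():
            if not 0 <= r <= 1:
                raise ConfigurationError(f"baseline_pt_rates[{pt!r}] must be in [0, 1]")
        for key, m in self.signal_multipliers.items():
            if m < 0:
                raise ConfigurationError(f"signal_multipliers[{key!r}] must be >= 0")
        for key, m in self.gender_pt_multipliers.items():
            if m < 0:
                raise ConfigurationError(f"gender_pt_multipliers[{key!r}] must be >= 0")
        if self.tto_family not in {"weibull", "lognormal", "loglogistic"}:
            raise ConfigurationError(
                "tto_family must be one of weibull, lognormal, loglogistic"
            )
        if self.tto_family in {"weibull", "loglogistic"}:
            scale = self.tto_params.get("scale")
            shape = self.tto_params.get("shape")
            if scale is None or scale <= 0 or shape is None or shape <= 0:
                raise ConfigurationError("tto_params requires scale > 0 and shape > 0")
        else:
            if self.tto_params.get("sigma", 0) <= 0 or "mu" not in self.tto_params:
                raise ConfigurationError("tto_params requires mu and sigma > 0")
        for code, p in self.outcome_code_probs.items():
            if not 0 <= p <= 1:
                raise ConfigurationError(f"outcome_code_probs[{code!r}] must be in [0, 1]")
        rp = self.reporter_probs
        if any(p < 0 for p in rp.values()) or abs(sum(rp.values()) - 1) > 1e-9:
            raise ConfigurationError("reporter_probs must be non-negative and sum to 1")
        y0, y1 = self.start_year_range
        if y0 > y1:
            raise ConfigurationError("start_year_range must be (low, high)")
        if not isinstance(self.seed, int):
            raise ConfigurationError("seed must be an integer")

    # -- (de)serialization: tuple-keyed maps become nested dicts on disk --

    def to_dict(self) -> dict:
        d = asdict(self)
        d["drug_names"] = list(self.drug_names)
        if self.drug_probs is not None:
            d["drug_probs"] = list(self.drug_probs)
        d["pt_catalog"] = [list(x) for x in self.pt_catalog]
        d["signal_multipliers"] = _nest(self.signal_multipliers)
        d["gender_pt_multipliers"] = _nest(self.gender_pt_multipliers)
        d["start_year_range"] = list(self.start_year_range)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "pt_catalog" in d:
            d["pt_catalog"] = [tuple(x) for x in d["pt_catalog"]]
        for key in ("signal_multipliers", "gender_pt_multipliers"):
            if key in d and d[key] and not isinstance(next(iter(d[key])), tuple):
                d[key] = _unnest(d[key])
        if "start_year_range" in d:
            d["start_year_range"] = tuple(d["start_year_range"])
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "SimulationConfig":
        text = open(path).read()
        data = yaml.safe_load(text) if str(path).endswith((".yaml", ".yml")) else json.loads(text)
        return cls.from_dict(data)

    def to_file(self, path) -> None:
        d = self.to_dict()
        with open(path, "w") as fh:
            if str(path).endswith((".yaml", ".yml")):
                yaml.safe_dump(d, fh, sort_keys=False)
            else:
                json.dump(d, fh, indent=2)


def _nest(flat: Mapping[tuple[str, str], float]) -> dict[str, dict[str, float]]:
    out: dict[str, dict[str, float]] = {}
    for (k1, k2), v in flat.items():
        out.setdefault(k1, {})[k2] = v
    return out


def _unnest(nested: Mapping[str, Mapping[str, float]]) -> dict[tuple[str, str], float]:
    return {(k1, k2): v for k1, inner in nested.items() for k2, v in inner.items()}
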