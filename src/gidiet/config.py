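"""Simulation and analysis configuration.

The synthetic cohort emulates a UK-style prospective dietary cohort:
multi-recall 24-hour dietary data, biallelic SNP dosages, covariates with
planted missingness, and Weibull proportional-hazards event times for three
gastrointestinal cancer sites (esophageal EC, gastric GC, colorectal CRC).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from datetime import date
from typing import Optional

import yaml

CANCERS = ("EC", "GC", "CRC")

#: Illustrative UK age-standardized incidence weights per 100,000 person-years
#: used to combine site-specific polygenic scores into the composite score.
#: These are round illustrative values, not estimates from any single registry
#: year; the composite's quintile grouping is invariant to their overall scale.
DEFAULT_INCIDENCE_WEIGHTS = {"EC": 14.0, "GC": 11.0, "CRC": 70.0}

#: Sex-specific plausibility bounds for mean daily energy intake (kcal/day).
#: Outside these, a participant's dietary record is treated as implausible.
ENERGY_BOUNDS_KCAL = {"male": (800.0, 5000.0), "female": (500.0, 4000.0)}

KCAL_TO_KJ = 4.184

#: End of registry follow-up (administrative censoring date).
DEFAULT_ADMIN_END = date(2022, 5, 31)

# Fractions of the initial sample removed by each exclusion rule in the
# study population this simulator emulates (prevalent cancer, implausible
# energy, consent withdrawal, unusable genetic data).
_DEFAULT_PLANT_FRACTIONS = {
    "prevalent_cancer": 17502 / 201131,
    "implausible_energy": 1795 / 201131,
    "withdrawn": 65 / 201131,
    "missing_genetics": 3621 / 201131,
}

EXCLUSION_ORDER = (
    "prevalent_cancer",
    "implausible_energy",
    "withdrawn",
    "missing_genetics",
)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort generator.

    Defaults reproduce the structure of the emulated study: ~54% female,
    baseline recruitment 2006-2010, administrative censoring after ~13.5
    years, a 205-SNP panel split across the three cancer sites, and planted
    per-SD log hazard ratios of -0.05 for the dietary index and +0.39 for
    the composite genetic score (protective diet, deleterious genetics).
    """

    n_participants: int = 20_000
    n_recalls_max: int = 5
    seed: int = 42
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_snps_per_cancer: tuple[int, int, int] = (50, 30, 125)
    incidence_weights: dict = field(
        default_factory=lambda: dict(DEFAULT_INCIDENCE_WEIGHTS)
    )
    true_loghr_digm_per_sd: float = -0.05
    true_loghr_cprs_per_sd: float = 0.39
    true_interaction_loghr: float = 0.0
    weibull_shape: float = 1.1
    baseline_scale: float = 600.0  # Weibull scale (years); ~1.5% events by 13.5y
    admin_censor_time: float = 16.5  # years; calendar-date censoring binds first
    death_rate: float = 0.004  # per year, all-cause death censoring
    exclusion_plant: Optional[dict] = None  # reason -> exact planted count

    def __post_init__(self) -> None:
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        lo, hi = self.maf_range
        if not (0 < lo < 1 and 0 < hi < 1 and lo <= hi):
            raise ValueError("maf_range frequencies must lie in (0,1)")
        if self.weibull_shape <= 0 or self.baseline_scale <= 0:
            raise ValueError("weibull_shape and baseline_scale must be positive")
        if self.admin_censor_time < 0:
            raise ValueError("admin_censor_time must be nonnegative")
        if any(h <= 0 for h in self.incidence_weights.values()):
            raise ValueError("incidence weights must be positive")
        if self.exclusion_plant is None:
            self.exclusion_plant = {
                k: int(round(f * self.n_participants))
                for k, f in _DEFAULT_PLANT_FRACTIONS.items()
            }
        unknown = set(self.exclusion_plant) - set(EXCLUSION_ORDER)
        if unknown:
            raise ValueError(f"unknown exclusion reasons: {sorted(unknown)}")
        for k in EXCLUSION_ORDER:
            self.exclusion_plant.setdefault(k, 0)
        if any(v < 0 for v in self.exclusion_plant.values()):
            raise ValueError("exclusion plant counts must be nonnegative")
        if sum(self.exclusion_plant.values()) >= self.n_participants:
            raise ValueError(
                "planted exclusion counts must sum to less than n_participants"
            )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "maf_range" in d:
            d["maf_range"] = tuple(d["maf_range"])
        if "n_snps_per_cancer" in d:
            d["n_snps_per_cancer"] = tuple(d["n_snps_per_cancer"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def scenario_config(name: str, n: Optional[int] = None, seed: int = 42) -> SimulationConfig:
    """Named simulation scenarios.

    - ``null``: no diet or genetic effect on hazard.
    - ``main-effects``: planted per-SD log-HRs, no interaction.
    - ``interaction``: main effects plus a planted product-term log-HR.
    - ``paper-scale``: main effects at the emulated study's initial sample
      size with its exact planted exclusion counts.
    """
    if name == "null":
        cfg = SimulationConfig(
            true_loghr_digm_per_sd=0.0,
            true_loghr_cprs_per_sd=0.0,
            true_interaction_loghr=0.0,
            seed=seed,
        )
    elif name == "main-effects":
        cfg = SimulationConfig(seed=seed)
    elif name == "interaction":
        cfg = SimulationConfig(true_interaction_loghr=-0.1, seed=seed)
    elif name == "paper-scale":
        cfg = SimulationConfig(
            n_participants=201_131,
            exclusion_plant={
                "prevalent_cancer": 17_502,
                "implausible_energy": 1_795,
                "withdrawn": 65,
                "missing_genetics": 3_621,
            },
            seed=seed,
        )
    else:
        raise ValueError(
            f"unknown scenario {name!r}; valid: null, main-effects, interaction, paper-scale"
        )
    if n is not None:
        plant = None if name != "paper-scale" else cfg.exclusion_plant
        if plant is not None and sum(plant.values()) >= n:
            plant = None
        cfg = SimulationConfig(
            **{**cfg.to_dict(), "n_participants": n, "exclusion_plant": plant}
        )
    return cfg
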