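"""Synthetic cohort generator.

Every downstream stage of the pipeline (dietary scoring, genetic scoring,
exclusion cascade, survival modelling, interaction analysis) is exercised on
data produced here, so the generator plants the statistical structure the
analysis assumes:

- a participant registry with demographics, covariates with missingness, and
  exclusion flags planted at exact configured counts;
- per-recall dietary intake from zero-inflated gamma distributions with
  sex-specific location shifts, plus internally consistent energy variables;
- biallelic allele dosages under uniform-random minor-allele frequencies and
  a per-cancer effect-size (weights) table;
- Weibull proportional-hazards event times whose log hazard is linear in the
  standardized dietary index and composite genetic score, with an optional
  planted product (interaction) term, multinomial site assignment, all-cause
  death and administrative censoring.

Determinism: one global seed; each stage draws from an independent substream
derived as ``default_rng([seed, stage])`` so stages can be regenerated
independently and reruns are byte-identical.
"""

from __future__ import annotations

from datetime import date, timedelta

import numpy as np
import pandas as pd

from .config import CANCERS, ENERGY_BOUNDS_KCAL, SimulationConfig

_STAGE = {"registry": 1, "intake": 2, "genotypes": 3, "outcomes": 4}


def _rng(cfg: SimulationConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, _STAGE[stage]])


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

_CATEGORICALS = {
    "income": (["<31,000", ">=31,000"], [0.39, 0.61], 0.10),
    "education": (["none", "medium", "high"], [0.085, 0.49, 0.425], 0.004),
    "smoking": (["never", "previous", "current"], [0.566, 0.358, 0.076], 0.002),
    "alcohol": (["never", "previous", "current"], [0.026, 0.029, 0.945], 0.0004),
    "physical_activity": (["low", "medium", "high"], [0.148, 0.614, 0.238], 0.0),
    "family_history": (["no", "yes"], [0.645, 0.355], 0.005),
}

_BASELINE_START = date(2006, 3, 13)
_BASELINE_END = date(2010, 10, 1)


def generate_registry(cfg: SimulationConfig) -> pd.DataFrame:
    """Generate the participant registry with planted exclusion flags.

    The four exclusion flags (``prevalent_cancer``, ``plant_implausible_energy``,
    ``withdrawn``, ``missing_genetics``) are planted on mutually disjoint
    participant sets with exactly the configured counts, so a sequential
    exclusion cascade recovers each count exactly.
    """
    rng = _rng(cfg, "registry")
    n = cfg.n_participants
    pid = np.arange(1, n + 1)

    sex = np.where(rng.random(n) < 0.54, "female", "male")
    male = sex == "male"
    age = np.clip(rng.normal(56.5, 8.0, n), 39.0, 72.0)
    offsets = rng.integers(0, (_BASELINE_END - _BASELINE_START).days, n)
    baseline = np.array(
        [_BASELINE_START + timedelta(days=int(d)) for d in offsets], dtype=object
    )
    townsend = rng.normal(-1.6, 2.8, n)
    height = np.where(male, rng.normal(1.76, 0.07, n), rng.normal(1.63, 0.06, n))
    bmi = np.clip(rng.normal(27.0, 4.6, n), 15.0, 55.0)
    weight = bmi * height**2

    df = pd.DataFrame(
        {
            "participant_id": pid,
            "sex": sex,
            "age": age,
            "baseline_date": baseline,
            "townsend": townsend,
            "height_m": height,
            "weight_kg": weight,
        }
    )
    for col, (levels, probs, miss) in _CATEGORICALS.items():
        vals = rng.choice(levels, size=n, p=probs).astype(object)
        if miss > 0:
            vals[rng.random(n) < miss] = None
        df[col] = vals
    # continuous missingness (Townsend index only, as in postcode-derived data)
    df.loc[rng.random(n) < 0.002, "townsend"] = np.nan

    # plant disjoint exclusion sets with exact counts
    plant = cfg.exclusion_plant
    order = ["prevalent_cancer", "implausible_energy", "withdrawn", "missing_genetics"]
    perm = rng.permutation(n)
    start = 0
    flags = {}
    for reason in order:
        k = plant[reason]
        idx = perm[start : start + k]
        start += k
        flag = np.zeros(n, dtype=bool)
        flag[idx] = True
        flags[reason] = flag
    df["prevalent_cancer"] = flags["prevalent_cancer"]
    df["plant_implausible_energy"] = flags["implausible_energy"]
    df["withdrawn"] = flags["withdrawn"]
    df["missing_genetics"] = flags["missing_genetics"]
    return df


# ---------------------------------------------------------------------------
# dietary intake
# ---------------------------------------------------------------------------

#: component -> (zero-inflation prob, gamma shape, gamma scale, male multiplier)
#: Amounts are g/day except fiber (g/day of the nutrient) and beverages
#: (g/day of prepared beverage). Zero-inflation probabilities reflect the
#: semicontinuous character of single-day food records.
INTAKE_DISTRIBUTIONS = {
    "avocado": (0.45, 1.5, 30.0, 0.9),
    "broccoli": (0.35, 1.5, 40.0, 0.9),
    "coffee": (0.10, 2.0, 200.0, 1.05),
    "cranberries": (0.45, 1.2, 20.0, 0.9),
    "fermented_dairy": (0.25, 1.5, 80.0, 0.95),
    "fiber": (0.0, 8.0, 2.0, 1.1),
    "green_tea": (0.40, 1.3, 150.0, 0.9),
    "soybean": (0.45, 1.3, 40.0, 0.95),
    "whole_grains": (0.15, 1.6, 50.0, 1.1),
    "pulses": (0.35, 1.4, 50.0, 1.0),
    "red_meat": (0.25, 1.8, 40.0, 1.3),
    "processed_meat": (0.30, 1.6, 25.0, 1.35),
    "refined_grains": (0.08, 2.0, 60.0, 1.15),
}

#: probability of completing k recalls (k = 1..5); most complete few
_RECALL_PROBS = np.array([0.35, 0.25, 0.20, 0.12, 0.08])


def generate_intake(
    cfg: SimulationConfig,
    registry: pd.DataFrame,
    zero_inflation_override: dict | None = None,
) -> pd.DataFrame:
    """Generate the per-recall intake table.

    Each participant completes 1..``n_recalls_max`` recalls. Component
    consumption is zero-inflated gamma with a lognormal participant-level
    habit multiplier and sex-specific location shifts. Total energy is
    normal around sex-specific means with per-recall lognormal variation;
    participants flagged ``plant_implausible_energy`` have all their recalls
    rescaled outside the sex-specific plausibility bounds, everyone else is
    rescaled (rarely needed) to stay inside them, so the implausible-energy
    exclusion count is exact. Fat energy is a Beta fraction of total energy,
    hence never exceeds it.
    """
    rng = _rng(cfg, "intake")
    n = len(registry)
    probs = _RECALL_PROBS[: cfg.n_recalls_max]
    probs = probs / probs.sum()
    n_recalls = rng.choice(np.arange(1, cfg.n_recalls_max + 1), size=n, p=probs)

    pid = np.repeat(registry["participant_id"].to_numpy(), n_recalls)
    sex = np.repeat(registry["sex"].to_numpy(), n_recalls)
    recall_index = np.concatenate([np.arange(1, k + 1) for k in n_recalls])
    m = len(pid)
    male = sex == "male"

    out = pd.DataFrame(
        {"participant_id": pid, "recall_index": recall_index, "sex": sex}
    )
    zi_over = zero_inflation_override or {}
    for comp, (p0, shape, scale, male_mult) in INTAKE_DISTRIBUTIONS.items():
        p0 = zi_over.get(comp, p0)
        habit = np.repeat(rng.lognormal(0.0, 0.3, n), n_recalls)
        amount = rng.gamma(shape, scale, m) * habit
        amount = np.where(male, amount * male_mult, amount)
        amount[rng.random(m) < p0] = 0.0
        out[comp] = amount

    # energy: participant habitual mean x per-recall noise
    male_p = registry["sex"].to_numpy() == "male"
    mean_energy = np.where(
        male_p, rng.normal(2330.0, 520.0, n), rng.normal(1870.0, 430.0, n)
    )
    noise = rng.lognormal(0.0, 0.12, m)
    energy = np.repeat(mean_energy, n_recalls) * noise

    # realized per-participant mean, used to enforce plausibility plants
    tmp = pd.Series(energy).groupby(pid).transform("mean").to_numpy()
    lo = np.where(male, *_bounds("lo")), np.where(male, *_bounds("hi"))
    lo_b, hi_b = lo
    planted = np.repeat(
        registry["plant_implausible_energy"].to_numpy(), n_recalls
    )
    # planted: scale whole record outside the bounds (alternating low/high)
    plant_high = np.repeat(rng.random(n) < 0.5, n_recalls)
    factor = np.ones(m)
    factor[planted & plant_high] = (hi_b * 1.5 / tmp)[planted & plant_high]
    factor[planted & ~plant_high] = (lo_b * 0.5 / tmp)[planted & ~plant_high]
    # non-planted: pull stray means back inside the band
    stray_lo = ~planted & (tmp < lo_b)
    stray_hi = ~planted & (tmp > hi_b)
    factor[stray_lo] = (lo_b * 1.05 / tmp)[stray_lo]
    factor[stray_hi] = (hi_b * 0.95 / tmp)[stray_hi]
    energy = energy * factor

    fat_frac = rng.beta(13.2, 26.8, m)  # mean 0.33, sd ~0.07
    out["total_energy_kcal"] = energy
    out["fat_energy_fraction"] = fat_frac
    return out


def _bounds(which: str) -> tuple[np.ndarray, np.ndarray]:
    i = 0 if which == "lo" else 1
    return (
        np.array(ENERGY_BOUNDS_KCAL["male"][i]),
        np.array(ENERGY_BOUNDS_KCAL["female"][i]),
    )


# ---------------------------------------------------------------------------
# genotypes and weights
# ---------------------------------------------------------------------------

def generate_genotypes_and_weights(
    cfg: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate an allele-dosage matrix and a per-cancer weights table.

    Dosages are Binomial(2, MAF) per SNP (independent loci, no linkage
    structure). SNP identifiers are disjoint across the three cancer panels;
    per-allele log-scale effect sizes are small, of either sign, on the scale
    typical of genome-wide-significant cancer loci.
    """
    rng = _rng(cfg, "genotypes")
    n = cfg.n_participants
    rows = []
    dosage_cols = {}
    alleles = np.array(list("ACGT"))
    for cancer, k in zip(CANCERS, cfg.n_snps_per_cancer):
        mafs = rng.uniform(*cfg.maf_range, size=k)
        betas = rng.normal(0.0, 0.05, size=k) + rng.choice([-1, 1], k) * 0.04
        eff = rng.choice(alleles, size=k)
        for j in range(k):
            snp_id = f"rs{cancer}{j + 1:04d}"
            rows.append((snp_id, eff[j], float(betas[j]), cancer))
            dosage_cols[snp_id] = rng.binomial(2, mafs[j], size=n).astype(np.int8)
    weights = pd.DataFrame(rows, columns=["snp_id", "effect_allele", "beta", "cancer"])
    dosages = pd.DataFrame(dosage_cols)
    dosages.insert(0, "participant_id", np.arange(1, n + 1))
    return dosages, weights


# ---------------------------------------------------------------------------
# outcomes
# ---------------------------------------------------------------------------

def simulate_outcomes(
    cfg: SimulationConfig,
    digm_sd: np.ndarray,
    cprs_sd: np.ndarray,
    participant_id: np.ndarray | None = None,
) -> pd.DataFrame:
    """Draw event times from a Weibull proportional-hazards model.

    The log hazard is ``a*digm_sd + b*cprs_sd + c*digm_sd*cprs_sd`` with the
    planted coefficients from the config; baseline cumulative hazard
    ``H0(t) = (t/scale)^shape``. Observations are censored at the earlier of
    an exponential all-cause death time and the administrative horizon.
    Event sites are multinomial with probabilities proportional to the
    configured incidence weights.

    Returns columns: participant_id, time_years, event, event_site,
    death_time_years (NaN when death plays no role before the horizon).
    """
    digm_sd = np.asarray(digm_sd, dtype=float)
    cprs_sd = np.asarray(cprs_sd, dtype=float)
    if digm_sd.shape != cprs_sd.shape:
        raise ValueError("exposure vectors must have equal length")
    n = len(digm_sd)
    rng = _rng(cfg, "outcomes")
    lp = (
        cfg.true_loghr_digm_per_sd * digm_sd
        + cfg.true_loghr_cprs_per_sd * cprs_sd
        + cfg.true_interaction_loghr * digm_sd * cprs_sd
    )
    u = rng.uniform(size=n)
    # inverse of S(t) = exp(-(t/scale)^shape * exp(lp))
    t_event = cfg.baseline_scale * (-np.log(u) / np.exp(lp)) ** (1.0 / cfg.weibull_shape)
    t_death = (
        rng.exponential(1.0 / cfg.death_rate, size=n)
        if cfg.death_rate > 0
        else np.full(n, np.inf)
    )
    t_cens = np.minimum(t_death, cfg.admin_censor_time)
    event = t_event <= t_cens
    time = np.where(event, t_event, t_cens)

    h = np.array([cfg.incidence_weights[c] for c in CANCERS], dtype=float)
    site_idx = rng.choice(len(CANCERS), size=n, p=h / h.sum())
    site = np.where(event, np.array(CANCERS)[site_idx], "none")
    if participant_id is None:
        participant_id = np.arange(1, n + 1)
    return pd.DataFrame(
        {
            "participant_id": participant_id,
            "time_years": time,
            "event": event.astype(int),
            "event_site": site,
            "death_time_years": np.where(np.isfinite(t_death), t_death, np.nan),
        }
    )


def events_to_dates(
    events: pd.DataFrame, registry: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convert simulated event/death times into diagnosis and death tables.

    Produces the (participant_id, icd10_code, date) diagnosis table and the
    (participant_id, date) death table consumed by the follow-up derivation,
    so the calendar-date path is exercised end to end on synthetic data.
    """
    site_to_icd = {"EC": "C15", "GC": "C16", "CRC": "C18"}
    merged = events.merge(
        registry[["participant_id", "baseline_date"]], on="participant_id"
    )
    base = pd.to_datetime(merged["baseline_date"])
    ev = merged[merged["event"] == 1]
    diagnoses = pd.DataFrame(
        {
            "participant_id": ev["participant_id"].to_numpy(),
            "icd10_code": ev["event_site"].map(site_to_icd).to_numpy(),
            "date": (
                pd.to_datetime(ev["baseline_date"])
                + pd.to_timedelta((ev["time_years"] * 365.25).round(), unit="D")
            ).dt.date,
        }
    )
    # deaths many decades out can never precede administrative censoring
    # (and would overflow nanosecond datetimes); drop them from the table
    dead = merged[merged["death_time_years"].notna() & (merged["death_time_years"] < 100.0)]
    deaths = pd.DataFrame(
        {
            "participant_id": dead["participant_id"].to_numpy(),
            "date": (
                pd.to_datetime(dead["baseline_date"])
                + pd.to_timedelta((dead["death_time_years"] * 365.25).round(), unit="D")
            ).dt.date,
        }
    )
    return diagnoses, deaths


def simulate_dataset(cfg: SimulationConfig) -> dict[str, pd.DataFrame]:
    """Generate registry, intake, dosages and weights for a config."""
    registry = generate_registry(cfg)
    intake = generate_intake(cfg, registry)
    dosages, weights = generate_genotypes_and_weights(cfg)
    return {
        "registry": registry,
        "intake": intake,
        "dosages": dosages,
        "weights": weights,
    }
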