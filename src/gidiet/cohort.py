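"""Cohort construction: exclusion cascade, covariate imputation, follow-up.

The analytic cohort is built by sequential exclusion (prevalent cancer at
baseline, implausible mean energy intake, consent withdrawal, unusable
genetic data — each participant removed at the first matching rule), mean /
indicator imputation of covariates, and derivation of follow-up time and
event indicators from diagnosis and death tables under administrative
censoring.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd

from .config import DEFAULT_ADMIN_END, ENERGY_BOUNDS_KCAL

DAYS_PER_YEAR = 365.25

#: ICD-10 three-character prefixes mapped to GI cancer sites:
#: esophagus C15, stomach C16, colorectum C18-C20.
ICD10_SITE_MAP = {"C15": "EC", "C16": "GC", "C18": "CRC", "C19": "CRC", "C20": "CRC"}

#: Default continuous/categorical covariate typing for imputation.
CONTINUOUS_COVARIATES = ("age", "townsend", "bmi", "total_energy_kcal")
CATEGORICAL_COVARIATES = (
    "income",
    "education",
    "smoking",
    "alcohol",
    "family_history",
    "physical_activity",
)
MISSING_LEVEL = "unknown/missing"


@dataclass
class ExclusionReport:
    """Ordered record of the exclusion cascade."""

    n_initial: int
    steps: list[tuple[str, int]] = field(default_factory=list)

    @property
    def n_final(self) -> int:
        return self.n_initial - sum(n for _, n in self.steps)

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_initial": self.n_initial,
                "steps": [{"reason": r, "n_removed": n} for r, n in self.steps],
                "n_final": self.n_final,
            }
        )

    def __str__(self) -> str:  # human flow-diagram style log
        lines = [f"initial sample: {self.n_initial}"]
        remaining = self.n_initial
        for reason, n in self.steps:
            remaining -= n
            lines.append(f"  - {reason}: removed {n} -> {remaining}")
        lines.append(f"final analytic sample: {self.n_final}")
        return "\n".join(lines)


def mean_energy_by_participant(intake: pd.DataFrame) -> pd.Series:
    """Mean daily energy (kcal) over each participant's recalls."""
    return intake.groupby("participant_id")["total_energy_kcal"].mean()


def implausible_energy(mean_energy: pd.Series, sex: pd.Series) -> pd.Series:
    """True where mean energy falls strictly outside the sex-specific band."""
    lo = sex.map({s: b[0] for s, b in ENERGY_BOUNDS_KCAL.items()})
    hi = sex.map({s: b[1] for s, b in ENERGY_BOUNDS_KCAL.items()})
    return (mean_energy < lo) | (mean_energy > hi)


def apply_exclusions(
    registry: pd.DataFrame,
    intake: pd.DataFrame,
    order: tuple[str, ...] = (
        "prevalent_cancer",
        "implausible_energy",
        "withdrawn",
        "missing_genetics",
    ),
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Sequential exclusion cascade; each participant removed once.

    Default order: prevalent cancer at baseline -> implausible mean energy
    intake (< 800 or > 5000 kcal/day for males, < 500 or > 4000 for
    females; the boundary itself is retained) -> withdrawal -> missing
    genetic data. A participant matching several rules is counted only
    under the first; permuting ``order`` can change per-reason counts but
    never the final retained set. Participants with no dietary recalls, or
    unknown sex where the energy rule applies, are routed to their own
    logged reasons.
    """
    report = ExclusionReport(n_initial=len(registry))
    df = registry.set_index("participant_id", drop=False)

    energy_all = mean_energy_by_participant(intake)

    def remove(mask: pd.Series, reason: str) -> None:
        nonlocal df
        n = int(mask.sum())
        report.steps.append((reason, n))
        df = df[~mask]

    for reason in order:
        if reason == "implausible_energy":
            energy = energy_all.reindex(df.index)
            known_sex = df["sex"].isin(list(ENERGY_BOUNDS_KCAL))
            bad = implausible_energy(energy, df["sex"]).fillna(False) & known_sex
            remove(bad & energy.notna(), reason)
        else:
            remove(df[reason].astype(bool), reason)
    no_recalls = ~df.index.isin(energy_all.index)
    if no_recalls.any():
        remove(pd.Series(no_recalls, index=df.index), "no_dietary_recalls")
    unknown = ~df["sex"].isin(list(ENERGY_BOUNDS_KCAL))
    if unknown.any():
        remove(unknown, "unknown_sex")
    return df.reset_index(drop=True), report


def impute_covariates(
    cohort: pd.DataFrame,
    continuous: tuple[str, ...] = CONTINUOUS_COVARIATES,
    categorical: tuple[str, ...] = CATEGORICAL_COVARIATES,
) -> pd.DataFrame:
    """Mean-impute continuous covariates; indicator-impute categorical ones.

    Missing continuous values take the analytic-population mean; missing
    categorical values become the literal level ``unknown/missing``. A
    boolean ``any_covariate_imputed`` column flags affected rows for the
    complete-covariate sensitivity analysis.
    """
    out = cohort.copy()
    imputed = np.zeros(len(out), dtype=bool)
    for col in continuous:
        if col not in out.columns:
            continue
        miss = out[col].isna()
        if miss.all():
            raise ValueError(f"continuous covariate {col!r} is entirely missing")
        if miss.any():
            out.loc[miss, col] = out[col].mean()
            imputed |= miss.to_numpy()
    for col in categorical:
        if col not in out.columns:
            continue
        miss = out[col].isna()
        if miss.any():
            out[col] = out[col].astype(object)
            out.loc[miss, col] = MISSING_LEVEL
            imputed |= miss.to_numpy()
    out["any_covariate_imputed"] = imputed
    return out


def map_icd10_site(code: str) -> str | None:
    """Map an ICD-10 code (e.g. 'C19', 'C18.9') to a GI site, else None."""
    return ICD10_SITE_MAP.get(str(code).strip().upper()[:3])


def derive_followup(
    cohort: pd.DataFrame,
    diagnoses: pd.DataFrame,
    deaths: pd.DataFrame,
    admin_end: date = DEFAULT_ADMIN_END,
) -> pd.DataFrame:
    """Follow-up time and event indicators under administrative censoring.

    Follow-up runs from baseline to the earliest of the first GI cancer
    diagnosis, death from any cause, or the administrative end of follow-up;
    years = days / 365.25. ``event_site`` records which site's code the
    first GI diagnosis carried; per-site indicator columns (``event_EC``,
    ``event_GC``, ``event_CRC``) support cause-specific analyses in which
    other-site GI cancers are censoring events at their diagnosis date.
    """
    df = cohort.copy()
    base = pd.to_datetime(df["baseline_date"])

    dx = diagnoses.copy()
    dx["site"] = dx["icd10_code"].map(map_icd10_site)
    dx = dx.dropna(subset=["site"])
    dx["date"] = pd.to_datetime(dx["date"])
    dx = dx.sort_values("date").drop_duplicates("participant_id", keep="first")
    dx = dx.set_index("participant_id")

    dth = deaths.copy()
    dth["date"] = pd.to_datetime(dth["date"])
    dth = dth.sort_values("date").drop_duplicates("participant_id", keep="first")
    dth = dth.set_index("participant_id")

    pid = df["participant_id"]
    dx_date = pid.map(dx["date"])
    dx_site = pid.map(dx["site"])
    death_date = pid.map(dth["date"])
    admin = pd.Timestamp(admin_end)

    if (dx_date < base).any():
        bad = pid[(dx_date < base).fillna(False)].tolist()
        raise ValueError(
            f"GI diagnosis before baseline for participants {bad[:5]}; "
            "these should have been excluded as prevalent cases"
        )

    end = pd.concat(
        [dx_date, death_date, pd.Series(admin, index=df.index)], axis=1
    ).min(axis=1)
    event = dx_date.notna() & (dx_date <= end)
    df["followup_years"] = (end - base).dt.days / DAYS_PER_YEAR
    df["event_overall"] = event.astype(int)
    df["event_site"] = np.where(event, dx_site.fillna("none"), "none")
    for site in ("EC", "GC", "CRC"):
        df[f"event_{site}"] = (event & (dx_site == site)).astype(int)
    if (df["followup_years"] < 0).any():
        raise ValueError("negative follow-up time; check baseline and admin_end dates")
    return df


SENSITIVITY_VARIANTS = (
    "pulses",
    "no_cranberries",
    "landmark_2y",
    "multi_recall_only",
    "complete_covariates",
)


def sensitivity_filters(
    cohort: pd.DataFrame,
    which: str,
    mean_intake: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Sensitivity-analysis cohort variants.

    - ``pulses`` / ``no_cranberries``: re-score the dietary index under the
      alternative component registry (requires ``mean_intake``).
    - ``landmark_2y``: drop participants with a GI cancer event in the
      first two years of follow-up (reverse-causality guard).
    - ``multi_recall_only``: keep only participants with >= 2 dietary
      recalls, then re-learn thresholds and re-score on the survivors
      when ``mean_intake`` is given.
    - ``complete_covariates``: drop rows with any imputed covariate.

    Returns the filtered/re-scored cohort and a small delta report.
    """
    from .dietary import DietaryIndexScorer  # local import avoids cycle

    delta: dict = {"variant": which, "n_before": len(cohort)}
    if which in ("pulses", "no_cranberries"):
        if mean_intake is None:
            raise ValueError(f"variant {which!r} requires the mean intake table")
        sub = mean_intake[mean_intake["participant_id"].isin(cohort["participant_id"])]
        scored = DietaryIndexScorer(registry=which).fit(sub).transform(sub)
        out = cohort.drop(
            columns=[c for c in cohort.columns if c.startswith(("score_", "digm"))]
        ).merge(scored, on="participant_id")
    elif which == "landmark_2y":
        out = cohort[
            ~((cohort["event_overall"] == 1) & (cohort["followup_years"] < 2.0))
        ].copy()
    elif which == "multi_recall_only":
        out = cohort[cohort["n_recalls"] >= 2].copy()
        if mean_intake is not None:
            sub = mean_intake[
                mean_intake["participant_id"].isin(out["participant_id"])
            ]
            scored = DietaryIndexScorer().fit(sub).transform(sub)
            out = out.drop(
                columns=[c for c in out.columns if c.startswith(("score_", "digm"))]
            ).merge(scored, on="participant_id")
    elif which == "complete_covariates":
        out = cohort[~cohort["any_covariate_imputed"]].copy()
    else:
        raise ValueError(
            f"unknown sensitivity variant {which!r}; valid: {SENSITIVITY_VARIANTS}"
        )
    delta["n_after"] = len(out)
    delta["n_removed"] = delta["n_before"] - delta["n_after"]
    return out, delta
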