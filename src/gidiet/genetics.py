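"""Polygenic risk scoring and the incidence-weighted composite score.

Per-cancer polygenic risk scores (PRS) are weighted allele-dosage sums,
``PRS_i = sum_k beta_k * dosage_ik`` over the cancer's SNP panel. The
composite score (CPRS) aggregates the three site-specific PRSs with
positive weights ``h_k`` — the age-standardized incidence of each cancer —
so common cancers dominate the composite genetic risk for the combined
outcome. Participants are grouped by CPRS quintile: lowest fifth = low
risk, middle three-fifths = moderate, top fifth = high.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .config import CANCERS

RISK_GROUP_LEVELS = ("low", "moderate", "high")


def compute_prs(
    dosages: pd.DataFrame,
    weights: pd.DataFrame,
    cancer: str,
    strict: bool = True,
) -> pd.Series:
    """Weighted dosage sum for one cancer's SNP panel.

    ``dosages`` holds one column per SNP plus ``participant_id``; values in
    [0, 2] count copies of the effect allele. In strict mode every weighted
    SNP must be present; in lenient mode absent SNPs are dropped (their
    count is recorded on the result's ``.attrs['n_dropped']``).
    """
    w = weights.loc[weights["cancer"] == cancer]
    if w.empty:
        raise ValueError(f"no weights for cancer {cancer!r}")
    if w.duplicated("snp_id").any():
        raise ValueError(f"duplicate snp_id entries for cancer {cancer!r}")
    present = w["snp_id"].isin(dosages.columns)
    if not present.all():
        missing = w.loc[~present, "snp_id"].tolist()
        if strict:
            raise KeyError(
                f"{len(missing)} weighted SNPs absent from dosage matrix "
                f"(first few: {missing[:5]})"
            )
        w = w[present]
    mat = dosages[w["snp_id"].to_numpy()].to_numpy(dtype=float)
    if mat.size and (mat.min() < 0 or mat.max() > 2):
        raise ValueError("dosages must lie in [0, 2]")
    prs = pd.Series(
        mat @ w["beta"].to_numpy(),
        index=pd.Index(dosages["participant_id"], name="participant_id"),
        name=f"prs_{cancer}",
    )
    prs.attrs["n_dropped"] = int((~present).sum())
    return prs


def compute_cprs(
    prs_by_cancer: pd.DataFrame,
    h: dict[str, float],
    standardize_first: bool = True,
) -> pd.Series:
    """Incidence-weighted composite of the per-cancer scores.

    ``CPRS_i = sum_k h_k * PRS*_ik`` where ``PRS*`` is the z-standardized
    PRS when ``standardize_first`` is on (the default: raw PRS scales are
    incomparable across panels of different size, and weighting raw sums
    would let scale artifacts dominate the incidence weights). With the
    flag off the literal weighted sum of raw scores is returned.
    """
    cancers = [c for c in CANCERS if f"prs_{c}" in prs_by_cancer.columns]
    if len(cancers) != len(h):
        missing = set(h) - set(cancers)
        if missing:
            raise ValueError(f"PRS columns missing for cancers: {sorted(missing)}")
    if any(h[c] < 0 for c in cancers):
        raise ValueError("incidence weights must be nonnegative")
    total = np.zeros(len(prs_by_cancer))
    for c in cancers:
        if h[c] == 0:
            continue
        x = prs_by_cancer[f"prs_{c}"].to_numpy(dtype=float)
        if standardize_first:
            sd = x.std(ddof=1)
            if sd == 0:
                raise ValueError(f"constant PRS for {c}; cannot standardize")
            x = (x - x.mean()) / sd
        total = total + h[c] * x
    return pd.Series(total, index=prs_by_cancer.index, name="cprs")


def quintile_cutpoints(cprs: pd.Series | np.ndarray) -> tuple[float, float]:
    """Empirical 20th and 80th percentile cutpoints."""
    arr = np.asarray(cprs, dtype=float)
    if arr.size < 5:
        raise ValueError("need at least 5 observations for quintile groups")
    c1, c2 = np.quantile(arr, [0.2, 0.8])
    if c1 == c2:
        raise ValueError("constant or near-constant CPRS: quintiles undefined")
    return float(c1), float(c2)


def assign_risk_groups(
    cprs: pd.Series | np.ndarray, cutpoints: tuple[float, float] | None = None
) -> pd.Categorical:
    """Quintile-based genetic risk groups.

    low = lowest quintile, moderate = quintiles 2-4, high = top quintile.
    Intervals are closed on the right, so values tied with a cutpoint all
    fall in the lower of the two adjacent groups; assignment is invariant
    to participant order.
    """
    arr = np.asarray(cprs, dtype=float)
    c1, c2 = cutpoints if cutpoints is not None else quintile_cutpoints(arr)
    labels = np.where(arr <= c1, "low", np.where(arr <= c2, "moderate", "high"))
    return pd.Categorical(labels, categories=list(RISK_GROUP_LEVELS), ordered=True)


class GeneticRiskScorer(BaseEstimator, TransformerMixin):
    """Per-cancer PRS, composite CPRS and quintile risk groups.

    ``fit`` learns, on the analytic population, the per-cancer PRS
    standardization constants, the CPRS quintile cutpoints and the CPRS
    mean/SD; ``transform`` scores a dosage matrix against them.

    Parameters
    ----------
    weights : DataFrame with columns snp_id, effect_allele, beta, cancer.
    incidence_weights : mapping cancer -> positive h_k.
    standardize_first : z-standardize each PRS before incidence weighting.
    strict : require every weighted SNP in the dosage matrix.
    """

    def __init__(
        self,
        weights: pd.DataFrame | None = None,
        incidence_weights: dict[str, float] | None = None,
        standardize_first: bool = True,
        strict: bool = True,
    ):
        self.weights = weights
        self.incidence_weights = incidence_weights
        self.standardize_first = standardize_first
        self.strict = strict

    def _raw_prs(self, X: pd.DataFrame) -> pd.DataFrame:
        cancers = list(dict.fromkeys(self.weights["cancer"]))
        return pd.DataFrame(
            {f"prs_{c}": compute_prs(X, self.weights, c, self.strict) for c in cancers}
        )

    def fit(self, X: pd.DataFrame, y=None) -> "GeneticRiskScorer":
        if self.weights is None or self.incidence_weights is None:
            raise ValueError("weights and incidence_weights are required")
        prs = self._raw_prs(X)
        self.prs_mean_ = prs.mean()
        self.prs_sd_ = prs.std(ddof=1)
        if self.standardize_first and (self.prs_sd_ == 0).any():
            bad = self.prs_sd_.index[self.prs_sd_ == 0].tolist()
            raise ValueError(f"constant PRS, cannot standardize: {bad}")
        cprs = self._cprs(prs)
        self.cutpoints_ = quintile_cutpoints(cprs)
        self.cprs_mean_ = float(cprs.mean())
        self.cprs_sd_ = float(cprs.std(ddof=1))
        return self

    def _cprs(self, prs: pd.DataFrame) -> pd.Series:
        total = np.zeros(len(prs))
        for col in prs.columns:
            cancer = col.removeprefix("prs_")
            x = prs[col].to_numpy(dtype=float)
            if self.standardize_first:
                x = (x - self.prs_mean_[col]) / self.prs_sd_[col]
            total = total + self.incidence_weights[cancer] * x
        return pd.Series(total, index=prs.index, name="cprs")

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "cutpoints_"):
            raise RuntimeError("GeneticRiskScorer must be fit before transform")
        prs = self._raw_prs(X)
        out = prs.copy()
        out["cprs"] = self._cprs(prs)
        out["cprs_sd"] = (out["cprs"] - self.cprs_mean_) / self.cprs_sd_
        out["risk_group"] = assign_risk_groups(out["cprs"], self.cutpoints_)
        return out.reset_index()


def dosages_from_vcf(path) -> pd.DataFrame:
    """Read a (small, uncompressed) VCF into the dosage-matrix shape.

    GT fields are converted to counts of the ALT allele; the ALT allele is
    taken as the effect allele (harmonization beyond a string match against
    the weights table is out of scope). Missing genotypes become NaN.
    """
    meta_cols = 9
    header = None
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            parts = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                header = parts
                continue
            if header is None:
                raise ValueError("malformed VCF: missing #CHROM header")
            snp_id = parts[2]
            gts = []
            for field in parts[meta_cols:]:
                gt = field.split(":")[0].replace("|", "/")
                if "." in gt:
                    gts.append(np.nan)
                else:
                    gts.append(sum(int(a) > 0 for a in gt.split("/")))
            rows.append((snp_id, gts))
    if header is None:
        raise ValueError("malformed VCF: missing #CHROM header")
    samples = header[meta_cols:]
    out = pd.DataFrame({sid: g for sid, g in rows}, index=samples)
    out.insert(0, "participant_id", samples)
    return out.reset_index(drop=True)
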