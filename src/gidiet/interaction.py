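"""Joint classification and additive/multiplicative interaction.

Participants are cross-classified into nine cells by dietary-index group
(low/moderate/high) and genetic-risk group (low/moderate/high), with the
low-diet / high-genetic-risk cell as the reference, and a Cox model over
the 9-level factor yields per-cell hazard ratios.

Additive interaction for a chosen 2x2 corner of that grid is quantified by
the relative excess risk due to interaction, RERI = HR11 - HR10 - HR01 + 1,
and the attributable proportion AP = RERI / HR11, with delta-method
confidence intervals propagated from the fitted log-HR covariance block.
Multiplicative interaction is a likelihood-ratio test of exposure product
terms in the adjusted Cox model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import stats

from .survival import CoxFitResult, ModelSpec, build_design, fit_cox, _check_design

JOINT_COL = "joint_group"
#: reference cell: low dietary index, high genetic risk
JOINT_REFERENCE = "low:high"

_DIGM_LEVELS = ("low", "moderate", "high")
_RISK_LEVELS = ("low", "moderate", "high")


def joint_levels() -> list[str]:
    """The 9 'digm:genetic' levels, reference first."""
    cells = [f"{d}:{g}" for d in _DIGM_LEVELS for g in _RISK_LEVELS]
    cells.remove(JOINT_REFERENCE)
    return [JOINT_REFERENCE] + cells


def assign_joint_groups(
    digm_group: pd.Series, risk_group: pd.Series
) -> pd.Categorical:
    """9-level 'digm:genetic' factor with low-diet/high-risk as reference."""
    if digm_group.isna().any() or risk_group.isna().any():
        raise ValueError("both groupings must be assigned for every participant")
    labels = digm_group.astype(str) + ":" + risk_group.astype(str)
    cats = joint_levels()
    bad = set(labels) - set(cats)
    if bad:
        raise ValueError(f"unexpected joint labels: {sorted(bad)}")
    return pd.Categorical(labels, categories=cats, ordered=False)


def fit_joint_model(
    cohort: pd.DataFrame, spec: ModelSpec | None = None, penalizer: float = 0.0
) -> CoxFitResult:
    """Adjusted Cox fit over the 9-cell joint factor."""
    if spec is None:
        spec = ModelSpec(exposure=JOINT_COL)
    return fit_cox(cohort, spec, penalizer=penalizer)


def joint_grid_table(cohort: pd.DataFrame, fit: CoxFitResult) -> pd.DataFrame:
    """Per-cell n, events, HR and CI (reference cell HR = 1)."""
    rows = []
    counts = cohort[JOINT_COL].value_counts()
    events = cohort.groupby(JOINT_COL, observed=False)[fit.event_col].sum()
    for cell in joint_levels():
        term = f"{JOINT_COL}[{cell}]"
        if cell == JOINT_REFERENCE:
            hr = lo = hi = 1.0
        elif term in fit.summary.index:
            hr = fit.summary.loc[term, "hr"]
            lo = fit.summary.loc[term, "ci_low"]
            hi = fit.summary.loc[term, "ci_high"]
        else:  # empty cell: no estimate
            hr = lo = hi = float("nan")
        d, g = cell.split(":")
        rows.append(
            {
                "digm_level": d,
                "genetic_level": g,
                "n": int(counts.get(cell, 0)),
                "events": int(events.get(cell, 0)),
                "hr": float(hr),
                "ci_low": float(lo),
                "ci_high": float(hi),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class InteractionResult:
    cells: dict[str, str]  # role ('11','10','01') -> cell label
    hr: dict[str, float]
    reri: float
    reri_ci: tuple[float, float]
    reri_se: float
    ap: float
    ap_ci: tuple[float, float]
    ap_se: float
    p_multiplicative: float | None = None


def compute_reri_ap(
    fit: CoxFitResult,
    cell11: str = "high:low",
    cell10: str = "high:high",
    cell01: str = "low:low",
) -> InteractionResult:
    """Delta-method RERI and AP from a fitted joint-factor Cox model.

    ``cell11`` is the doubly-"exposed" corner relative to the model's
    reference cell, ``cell10``/``cell01`` the single-exposure corners; with
    the low-diet/high-genetic-risk reference the defaults contrast a
    favorable diet and favorable genetics. Only the fit object is consumed
    — the model is never refit here.

    RERI = HR11 - HR10 - HR01 + 1 and AP = RERI / HR11; standard errors
    propagate the fitted covariance of (log HR11, log HR10, log HR01)
    through the gradient of each functional, and 95% CIs are estimate
    +/- 1.96 SE.
    """
    roles = {"11": cell11, "10": cell10, "01": cell01}
    if len(set(roles.values())) != 3:
        raise ValueError("cell11, cell10 and cell01 must be three distinct cells")
    terms = {}
    for role, cell in roles.items():
        if cell == JOINT_REFERENCE:
            raise ValueError(
                f"cell {cell!r} is the reference cell and cannot play role {role}"
            )
        term = f"{JOINT_COL}[{cell}]"
        if term not in fit.summary.index:
            raise KeyError(f"cell {cell!r} not present in the fitted model")
        terms[role] = term

    order = [terms["11"], terms["10"], terms["01"]]
    beta = fit.model.params_[order].to_numpy(dtype=float)
    cov = fit.model.variance_matrix_.loc[order, order].to_numpy(dtype=float)
    eig = np.linalg.eigvalsh(cov)
    if eig.min() < -1e-8 * max(abs(eig.max()), 1.0):
        raise ValueError("coefficient covariance block is not positive semidefinite")

    h11, h10, h01 = np.exp(beta)
    reri = h11 - h10 - h01 + 1.0
    g_reri = np.array([h11, -h10, -h01])
    reri_se = float(np.sqrt(g_reri @ cov @ g_reri))

    ap = reri / h11
    g_ap = np.array(
        [(h10 + h01 - 1.0) / h11, -h10 / h11, -h01 / h11]
    )
    ap_se = float(np.sqrt(g_ap @ cov @ g_ap))

    z = 1.96
    return InteractionResult(
        cells=roles,
        hr={"11": float(h11), "10": float(h10), "01": float(h01)},
        reri=float(reri),
        reri_ci=(float(reri - z * reri_se), float(reri + z * reri_se)),
        reri_se=reri_se,
        ap=float(ap),
        ap_ci=(float(ap - z * ap_se), float(ap + z * ap_se)),
        ap_se=ap_se,
    )


def multiplicative_interaction(
    cohort: pd.DataFrame,
    spec: ModelSpec | None = None,
    exposures: tuple[str, str] = ("digm_group", "risk_group"),
    form: str = "scores",
) -> float:
    """Likelihood-ratio p-value for departure from multiplicativity.

    Compares the adjusted Cox model with and without exposure product
    terms. ``form='scores'`` codes each group variable as integer scores
    and adds their single product (1 df); ``form='factors'`` adds all
    dummy-by-dummy products (4 df for two 3-level factors).
    """
    if spec is None:
        spec = ModelSpec(exposure=exposures[0])
    a, b = exposures

    def scores(col: pd.Series) -> pd.Series:
        if isinstance(col.dtype, pd.CategoricalDtype):
            return col.cat.codes.astype(float)
        return pd.Series(pd.Categorical(col).codes.astype(float), index=col.index)

    if form == "scores":
        Xa = scores(cohort[a]).rename(a).to_frame()
        Xb = scores(cohort[b]).rename(b).to_frame()
    elif form == "factors":
        Xa = build_design(cohort, [a])
        Xb = build_design(cohort, [b])
    else:
        raise ValueError("form must be 'scores' or 'factors'")
    prods = pd.DataFrame(index=cohort.index)
    for ca in Xa.columns:
        for cb in Xb.columns:
            prods[f"{ca}*{cb}"] = Xa[ca] * Xb[cb]

    covs = [c for c in spec.covariates if c not in (a, b)]
    Xcov = build_design(cohort, covs) if covs else None

    def _ll(parts) -> float:
        X = pd.concat(parts, axis=1)
        _check_design(X)
        df = X.copy()
        df[spec.duration_col] = cohort[spec.duration_col].to_numpy(dtype=float)
        df[spec.event_col] = cohort[spec.event_col].to_numpy(dtype=int)
        cph = CoxPHFitter()
        cph.fit(df, duration_col=spec.duration_col, event_col=spec.event_col)
        return float(cph.log_likelihood_)

    base = [x for x in (Xa, Xb, Xcov) if x is not None]
    ll0 = _ll(base)
    ll1 = _ll(base + [prods])
    lr = 2.0 * (ll1 - ll0)
    return float(stats.chi2.sf(max(lr, 0.0), prods.shape[1]))
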