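"""Per-factor direction of effect on incident CKD.

One Cox proportional-hazards model per lifestyle factor, adjusted for age
and sex, gives the hazard ratio whose 95% CI signs the factor as healthy
(CI entirely below 1), unhealthy (entirely above 1) or indeterminate. A
Fine–Gray subdistribution-hazard fit with death as the competing event is
provided as a sensitivity analysis, and Nelson–Aalen curves summarize
group-wise cumulative hazard.

The Cox fits go through lifelines (Newton–Raphson partial likelihood,
Efron ties). The Fine–Gray estimator is implemented here directly as an
IPCW-weighted Breslow partial likelihood, since no installed Python
package provides it: participants who die remain in later risk sets with
weights G(t)/G(T_i) from the Kaplan–Meier estimate of the censoring
distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, NelsonAalenFitter
from lifelines.exceptions import ConvergenceError
from scipy import optimize, stats

from .codebook import FactorCodebook

__all__ = [
    "HazardEstimate",
    "fit_factor_cox",
    "fit_all_factors",
    "fit_finegray",
    "cumulative_hazard",
    "assign_direction",
    "direction_from_ci",
    "estimates_frame",
    "estimates_from_frame",
]


@dataclass
class HazardEstimate:
    factor: str
    exposure_level: str
    hr: float
    ci_low: float
    ci_high: float
    p_value: float
    direction: str = field(init=False)
    flagged: bool = False
    model: str = "cox"

    def __post_init__(self):
        if self.flagged or not np.isfinite(self.hr):
            self.direction = "indeterminate"
        else:
            if not (0 < self.ci_low <= self.hr <= self.ci_high):
                raise ValueError(
                    f"{self.factor}: inconsistent estimate "
                    f"({self.ci_low}, {self.hr}, {self.ci_high})"
                )
            self.direction = direction_from_ci(self.hr, self.ci_low, self.ci_high)


def direction_from_ci(hr: float, ci_low: float, ci_high: float) -> str:
    """healthy iff the 95% CI lies entirely below 1, unhealthy iff above."""
    if ci_high < 1.0:
        return "healthy"
    if ci_low > 1.0:
        return "unhealthy"
    return "indeterminate"


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

def factor_design(
    dataset: pd.DataFrame,
    factor: str,
    codebook: FactorCodebook,
    adjustment=("age", "sex"),
    duration_col: str = "event_time",
    event_col: str = "ckd_event",
) -> tuple[pd.DataFrame, list[str]]:
    """Build the per-factor Cox design.

    Counts enter through their exposure indicator, binaries as 0/1, and
    polytomous factors as level indicators against the first declared
    level. Rows with a missing factor value are dropped (factor-wise
    complete-case analysis).
    """
    spec = codebook[factor]
    keep = dataset[factor].notna()
    df = dataset.loc[keep]
    design = pd.DataFrame(index=df.index)
    if spec.var_type == "polytomous":
        levels = list(spec.levels)
        exposure_cols = []
        for lev in levels[1:]:
            ind = (df[factor] == lev).astype(float)
            if ind.sum() == 0:
                continue  # unobserved level: no indicator
            col = f"{factor}[{lev}]"
            design[col] = ind
            exposure_cols.append(col)
    elif spec.var_type == "binary":
        design[factor] = df[factor].astype(float)
        exposure_cols = [factor]
    else:
        col = f"{factor}_exposed"
        design[col] = spec.is_exposed(df[factor]).astype(float)
        exposure_cols = [col]
    for adj in adjustment:
        if adj == "sex":
            design["male"] = (df["sex"] == "male").astype(float)
        else:
            design[adj] = df[adj].astype(float)
    design[duration_col] = df[duration_col].astype(float)
    if event_col is not None:
        design[event_col] = df[event_col].astype(int)
    return design, exposure_cols


def _level_label(col: str, factor: str) -> str:
    if col.startswith(f"{factor}[") and col.endswith("]"):
        return col[len(factor) + 1 : -1]
    if col == f"{factor}_exposed" or col == factor:
        return "exposed"
    return col


# ---------------------------------------------------------------------------
# Cox per factor
# ---------------------------------------------------------------------------

def fit_factor_cox(
    dataset: pd.DataFrame,
    factor: str,
    codebook: FactorCodebook,
    adjustment=("age", "sex"),
    duration_col: str = "event_time",
    event_col: str = "ckd_event",
) -> list[HazardEstimate]:
    """Age/sex-adjusted Cox HR per non-reference level of one factor.

    Monotone likelihood (complete separation) yields a flagged estimate
    with indeterminate direction rather than an exception.
    """
    design, exposure_cols = factor_design(
        dataset, factor, codebook, adjustment, duration_col, event_col
    )
    if design[exposure_cols].to_numpy().std(axis=0).max() == 0:
        raise ValueError(f"{factor}: fewer than 2 observed exposure levels")

    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(design, duration_col=duration_col, event_col=event_col)
    except ConvergenceError:
        return [
            HazardEstimate(factor, _level_label(c, factor), np.nan, np.nan, np.nan, np.nan, flagged=True)
            for c in exposure_cols
        ]
    summary = cph.summary
    out = []
    for col in exposure_cols:
        row = summary.loc[col]
        hr = float(row["exp(coef)"])
        lo = float(row["exp(coef) lower 95%"])
        hi = float(row["exp(coef) upper 95%"])
        # degenerate CI (monotone likelihood on a sparse level) -> flagged
        degenerate = not (np.isfinite(hr) and np.isfinite(hi) and lo > 0 and hr > 0)
        out.append(
            HazardEstimate(
                factor=factor,
                exposure_level=_level_label(col, factor),
                hr=hr,
                ci_low=lo,
                ci_high=hi,
                p_value=float(row["p"]),
                flagged=degenerate,
            )
        )
    return out


def fit_all_factors(
    dataset: pd.DataFrame,
    codebook: FactorCodebook,
    adjustment=("age", "sex"),
    duration_col: str = "event_time",
    event_col: str = "ckd_event",
) -> list[HazardEstimate]:
    """Run :func:`fit_factor_cox` for every codebook factor present."""
    estimates: list[HazardEstimate] = []
    for spec in codebook:
        if spec.name not in dataset.columns:
            continue
        try:
            estimates.extend(
                fit_factor_cox(dataset, spec.name, codebook, adjustment, duration_col, event_col)
            )
        except ValueError as exc:
            warnings.warn(f"skipping {spec.name}: {exc}", stacklevel=2)
    return estimates


def assign_direction(estimates: list[HazardEstimate]) -> dict[str, str]:
    """Per-factor direction labels.

    For polytomous factors, the direction is taken from the highest
    declared exposure level versus the reference (the last estimate in
    declaration order).
    """
    last: dict[str, HazardEstimate] = {}
    for est in estimates:
        last[est.factor] = est
    return {name: est.direction for name, est in last.items()}


def estimates_from_frame(frame: pd.DataFrame) -> list[HazardEstimate]:
    """Rebuild estimates from an :func:`estimates_frame` CSV/DataFrame."""
    out = []
    for _, row in frame.iterrows():
        flagged = bool(row.get("flagged", False)) or not np.isfinite(row["hr"])
        out.append(
            HazardEstimate(
                factor=row["factor"],
                exposure_level=str(row.get("level", "exposed")),
                hr=float(row["hr"]),
                ci_low=float(row["ci_low"]),
                ci_high=float(row["ci_high"]),
                p_value=float(row.get("p", np.nan)),
                flagged=flagged,
                model=str(row.get("model", "cox")),
            )
        )
    return out


def estimates_frame(estimates: list[HazardEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "factor": e.factor,
                "level": e.exposure_level,
                "hr": e.hr,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "p": e.p_value,
                "direction": e.direction,
                "model": e.model,
                "flagged": e.flagged,
            }
            for e in estimates
        ]
    )


# ---------------------------------------------------------------------------
# Fine–Gray subdistribution hazards
# ---------------------------------------------------------------------------

def _censoring_survival(time: np.ndarray, status: np.ndarray):
    """Kaplan–Meier estimate of the censoring distribution G(t).

    Returns a step-function evaluator for the left limit G(t−).
    """
    order = np.argsort(time, kind="stable")
    t, s = time[order], status[order]
    uniq = np.unique(t[s == 0])
    n = len(t)
    surv = []
    g = 1.0
    # number at risk just before each censoring time
    for u in uniq:
        at_risk = np.sum(t >= u)
        d_cens = np.sum((t == u) & (s == 0))
        if at_risk > 0:
            g *= 1.0 - d_cens / at_risk
        surv.append(g)
    times = uniq
    surv = np.asarray(surv)

    def g_left(x: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(times, x, side="left") - 1  # strictly before x
        out = np.ones_like(np.asarray(x, dtype=float))
        valid = idx >= 0
        out[valid] = surv[idx[valid]]
        return out

    return g_left


def _finegray_weights(time, status, g_left):
    """Per-event-time IPCW risk-set weights (rows: events in time order)."""
    ev_idx = np.flatnonzero(status == 1)
    ev_idx = ev_idx[np.argsort(time[ev_idx], kind="stable")]
    g_subject = g_left(time)  # G(T_j −) per subject
    weights = np.empty((len(ev_idx), len(time)))
    for r, i in enumerate(ev_idx):
        t_i = time[i]
        g_t = g_left(np.array([t_i]))[0]
        w = np.where(
            time >= t_i,
            1.0,
            np.where(status == 2, g_t / g_subject, 0.0),
        )
        weights[r] = w
    return ev_idx, weights


def finegray_loglik(beta, X, eta_idx, weights, want_hessian=False):
    """Negative IPCW-weighted Breslow log partial likelihood.

    ``eta_idx`` are the case row indices aligned with ``weights`` rows.
    Returns (neg_ll, gradient[, hessian]).
    """
    beta = np.asarray(beta, dtype=float)
    eta = X @ beta
    ex = np.exp(eta)
    neg_ll = 0.0
    grad = np.zeros_like(beta)
    hess = np.zeros((len(beta), len(beta))) if want_hessian else None
    for r, i in enumerate(eta_idx):
        wex = weights[r] * ex
        s0 = wex.sum()
        s1 = X.T @ wex
        neg_ll -= eta[i] - np.log(s0)
        grad -= X[i] - s1 / s0
        if want_hessian:
            s2 = (X * wex[:, None]).T @ X
            hess += s2 / s0 - np.outer(s1 / s0, s1 / s0)
    if want_hessian:
        return neg_ll, grad, hess
    return neg_ll, grad


def fit_finegray(
    dataset: pd.DataFrame,
    factor: str,
    codebook: FactorCodebook,
    adjustment=("age", "sex"),
    duration_col: str = "event_time",
    event_type_col: str = "event_type",
    competing: str = "death",
) -> list[HazardEstimate]:
    """Fine–Gray subdistribution HR for one factor with death competing.

    With no competing events present this reduces exactly to the
    cause-specific (Breslow) Cox fit; a warning notes the fallback.
    """
    design, exposure_cols = factor_design(
        dataset, factor, codebook, adjustment, duration_col, event_col=None
    )
    etypes = dataset.loc[design.index, event_type_col].astype(str)
    status = np.select([etypes == "ckd", etypes == competing], [1, 2], default=0)
    if (status == 2).sum() == 0:
        warnings.warn(
            "no competing events present; subdistribution fit reduces to cause-specific",
            stacklevel=2,
        )
    time = design.pop(duration_col).to_numpy(dtype=float)
    X = design.to_numpy(dtype=float)
    cols = list(design.columns)
    if (status == 1).sum() == 0:
        raise ValueError(f"{factor}: no events of interest")

    g_left = _censoring_survival(time, status)
    ev_idx, weights = _finegray_weights(time, status, g_left)
    res = optimize.minimize(
        lambda b: finegray_loglik(b, X, ev_idx, weights),
        x0=np.zeros(X.shape[1]),
        jac=True,
        method="BFGS",
        options={"gtol": 1e-8, "maxiter": 200},
    )
    beta = res.x
    _, _, hess = finegray_loglik(beta, X, ev_idx, weights, want_hessian=True)
    cov = np.linalg.inv(hess)
    se = np.sqrt(np.diag(cov))
    z = stats.norm.ppf(0.975)
    out = []
    for j, col in enumerate(cols):
        if col not in exposure_cols:
            continue
        hr = float(np.exp(beta[j]))
        out.append(
            HazardEstimate(
                factor=factor,
                exposure_level=_level_label(col, factor),
                hr=hr,
                ci_low=float(np.exp(beta[j] - z * se[j])),
                ci_high=float(np.exp(beta[j] + z * se[j])),
                p_value=float(2 * stats.norm.sf(abs(beta[j] / se[j]))),
                model="finegray",
            )
        )
    return out


# ---------------------------------------------------------------------------
# Nelson–Aalen cumulative hazard
# ---------------------------------------------------------------------------

def cumulative_hazard(
    dataset: pd.DataFrame,
    grouping: str,
    duration_col: str = "event_time",
    event_col: str = "ckd_event",
) -> dict[str, pd.DataFrame]:
    """Per-group Nelson–Aalen cumulative-hazard curves with standard errors."""
    curves = {}
    for key, grp in dataset.groupby(grouping, observed=True):
        if len(grp) == 0:
            continue
        naf = NelsonAalenFitter(nelson_aalen_smoothing=False)
        naf.fit(grp[duration_col].astype(float), grp[event_col].astype(int))
        df = naf.cumulative_hazard_.copy()
        df.columns = ["cumulative_hazard"]
        var = naf._cumulative_sq.reindex(df.index).ffill().fillna(0.0)
        df["se"] = np.sqrt(np.asarray(var, dtype=float).reshape(len(df), -1)[:, 0])
        curves[str(key)] = df
    if not curves:
        raise ValueError("empty grouping: no rows in any group")
    return curves
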