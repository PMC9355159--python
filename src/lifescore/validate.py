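"""Scorecard validation: dose–response shape, graded risk, discrimination.

* restricted cubic spline (RCS) Cox regression of outcome hazard on the
  total lifestyle score, with a likelihood-ratio test of linearity;
* Cox hazard ratios per score grade versus grade 0, reported as "% lower
  risk" (1 − HR);
* discrimination of the age-adjusted score: ROC AUC at a fixed
  administrative horizon (censored-before-horizon excluded) and Harrell's
  C-statistic over all usable pairs, mirroring the two conventions in use.

The RCS basis is Harrell's truncated-power parameterization: k knots give
k−2 nonlinear terms, each linear beyond the boundary knots and C² at the
knots.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.utils import concordance_index
from scipy import stats
from sklearn.metrics import roc_auc_score

__all__ = [
    "rcs_basis",
    "default_knots",
    "RcsFit",
    "fit_rcs",
    "grade_hazards",
    "discrimination",
    "validation_report",
    "OUTCOME_COLUMNS",
]

OUTCOME_COLUMNS = {
    "ckd": ("event_time", "ckd_event"),
    "cvd": ("cvd_time", "cvd_event"),
    "death": ("death_time", "death_event"),
}

_KNOT_QUANTILES = {
    3: (0.10, 0.50, 0.90),
    4: (0.05, 0.35, 0.65, 0.95),
    5: (0.05, 0.275, 0.50, 0.725, 0.95),
}


# ---------------------------------------------------------------------------
# restricted cubic spline basis
# ---------------------------------------------------------------------------

def rcs_basis(x, knots) -> np.ndarray:
    """Harrell restricted-cubic-spline nonlinear basis, shape (n, k−2).

    For knots t_1 < … < t_k and j = 1 … k−2::

        B_j(x) = [ (x−t_j)₊³ − (x−t_{k−1})₊³ (t_k−t_j)/(t_k−t_{k−1})
                               + (x−t_k)₊³ (t_{k−1}−t_j)/(t_k−t_{k−1}) ]
                 / (t_k − t_1)²

    Together with the linear term this spans all natural cubic splines on
    the knots (linear beyond the boundary knots, C² everywhere).
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(knots, dtype=float)
    if t.ndim != 1 or len(t) < 3:
        raise ValueError("need at least 3 knots")
    if np.any(np.diff(t) <= 0):
        raise ValueError(f"knots must be strictly increasing, got {t.tolist()}")
    k = len(t)
    norm = (t[-1] - t[0]) ** 2
    cols = []
    for j in range(k - 2):
        p = np.clip(x - t[j], 0, None) ** 3
        p -= np.clip(x - t[k - 2], 0, None) ** 3 * (t[-1] - t[j]) / (t[-1] - t[k - 2])
        p += np.clip(x - t[-1], 0, None) ** 3 * (t[k - 2] - t[j]) / (t[-1] - t[k - 2])
        cols.append(p / norm)
    return np.column_stack(cols)


def default_knots(x, n_knots: int = 4) -> np.ndarray:
    """Knots at the conventional quantiles (e.g. 5/35/65/95% for 4 knots)."""
    if n_knots not in _KNOT_QUANTILES:
        raise ValueError("n_knots must be 3, 4 or 5")
    knots = np.quantile(np.asarray(x, dtype=float), _KNOT_QUANTILES[n_knots])
    if np.any(np.diff(knots) <= 0):
        raise ValueError(f"degenerate score distribution: knot collision at {knots.tolist()}")
    return knots


@dataclass
class RcsFit:
    knots: np.ndarray
    coefficients: np.ndarray  # linear + nonlinear terms
    covariance: np.ndarray
    linearity_p: float
    log_likelihood: float
    linear_log_likelihood: float
    reference: float

    def curve(self, x) -> pd.DataFrame:
        """log-HR (and 95% band) at x, relative to the reference score."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        B = np.column_stack([x, rcs_basis(x, self.knots)])
        B0 = np.column_stack([[self.reference], rcs_basis([self.reference], self.knots)])
        D = B - B0
        log_hr = D @ self.coefficients
        se = np.sqrt(np.einsum("ij,jk,ik->i", D, self.covariance, D))
        z = stats.norm.ppf(0.975)
        return pd.DataFrame(
            {"x": x, "log_hr": log_hr, "lo": log_hr - z * se, "hi": log_hr + z * se}
        )


def fit_rcs(
    scores,
    durations,
    events,
    n_knots: int = 4,
    knots=None,
    adjust: pd.DataFrame | None = None,
) -> RcsFit:
    """Cox regression of the hazard on an RCS expansion of the score.

    ``linearity_p`` is the likelihood-ratio test of the k−2 nonlinear
    terms against the plain linear fit (chi-squared, k−2 df).
    """
    scores = np.asarray(scores, dtype=float)
    if knots is None:
        knots = default_knots(scores, n_knots)
    knots = np.asarray(knots, dtype=float)
    if len(np.unique(scores)) < len(knots):
        raise ValueError("fewer distinct score values than knots")
    basis = rcs_basis(scores, knots)
    nl_cols = [f"score_nl{j + 1}" for j in range(basis.shape[1])]
    df = pd.DataFrame({"score": scores})
    for j, c in enumerate(nl_cols):
        df[c] = basis[:, j]
    if adjust is not None:
        df = pd.concat([df, adjust.reset_index(drop=True)], axis=1)
    df["_t"] = np.asarray(durations, dtype=float)
    df["_e"] = np.asarray(events, dtype=int)
    if df["_e"].sum() == 0:
        raise ValueError("no events")

    full = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full.fit(df, duration_col="_t", event_col="_e")
        reduced = CoxPHFitter()
        reduced.fit(df.drop(columns=nl_cols), duration_col="_t", event_col="_e")
    lr = 2.0 * (full.log_likelihood_ - reduced.log_likelihood_)
    p = float(stats.chi2.sf(max(lr, 0.0), df=len(nl_cols)))
    cols = ["score"] + nl_cols
    return RcsFit(
        knots=knots,
        coefficients=full.params_[cols].to_numpy(),
        covariance=full.variance_matrix_.loc[cols, cols].to_numpy(),
        linearity_p=p,
        log_likelihood=float(full.log_likelihood_),
        linear_log_likelihood=float(reduced.log_likelihood_),
        reference=float(np.median(scores)),
    )


# ---------------------------------------------------------------------------
# graded risk
# ---------------------------------------------------------------------------

def grade_hazards(grades, durations, events, reference: int = 0) -> pd.DataFrame:
    """Cox HR per score grade versus the reference grade.

    Returns one row per non-reference grade with ``hr``, 95% CI and
    ``pct_lower_risk`` = 100·(1 − HR).
    """
    grades = np.asarray(grades, dtype=int)
    events = np.asarray(events, dtype=int)
    observed = np.unique(grades)
    if reference not in observed:
        raise ValueError(f"reference grade {reference} is empty")
    with_events = np.unique(grades[events == 1])
    if len(with_events) < 2:
        raise ValueError("need events in at least 2 grades")
    df = pd.DataFrame({"_t": np.asarray(durations, dtype=float), "_e": events})
    cols = []
    for g in observed:
        if g == reference:
            continue
        col = f"grade_{g}"
        df[col] = (grades == g).astype(float)
        cols.append((g, col))
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="_t", event_col="_e")
    rows = [
        {
            "grade": reference, "hr": 1.0, "ci_low": 1.0, "ci_high": 1.0,
            "p": np.nan, "pct_lower_risk": 0.0, "n": int((grades == reference).sum()),
            "events": int(events[grades == reference].sum()),
        }
    ]
    s = cph.summary
    for g, col in cols:
        hr = float(s.loc[col, "exp(coef)"])
        rows.append(
            {
                "grade": g,
                "hr": hr,
                "ci_low": float(s.loc[col, "exp(coef) lower 95%"]),
                "ci_high": float(s.loc[col, "exp(coef) upper 95%"]),
                "p": float(s.loc[col, "p"]),
                "pct_lower_risk": 100.0 * (1.0 - hr),
                "n": int((grades == g).sum()),
                "events": int(events[grades == g].sum()),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# discrimination
# ---------------------------------------------------------------------------

def harrell_c_exact(durations, predictions, events) -> tuple[float, float]:
    """Exact Harrell's C by pair enumeration, with U-statistic variance.

    A pair is usable when the earlier time is an event; ties in the
    prediction count 1/2. O(n²) — intended for moderate n.
    """
    t = np.asarray(durations, dtype=float)
    p = np.asarray(predictions, dtype=float)
    e = np.asarray(events, dtype=int)
    n = len(t)
    conc = np.zeros(n)
    comp = np.zeros(n)
    for i in range(n):
        if e[i] != 1:
            continue
        usable = (t > t[i]) | ((t == t[i]) & (e == 0))
        usable[i] = False
        u = np.flatnonzero(usable)
        if len(u) == 0:
            continue
        score = np.where(p[u] < p[i], 1.0, np.where(p[u] == p[i], 0.5, 0.0))
        conc[i] += score.sum()
        comp[i] += len(u)
        conc[u] += score
        comp[u] += 1.0
    total_comp = comp.sum()
    if total_comp == 0:
        return 0.5, np.nan
    c = conc.sum() / total_comp
    phi = conc - c * comp
    var = 4.0 * np.sum(phi**2) / total_comp**2
    return float(c), float(np.sqrt(var))


def discrimination(
    dataset: pd.DataFrame,
    score_col: str = "total_score",
    duration_col: str = "event_time",
    event_col: str = "ckd_event",
    age_col: str | None = "age",
    horizon: float | None = None,
    n_bootstrap: int = 200,
    seed: int = 0,
    variance_cap: int = 4000,
) -> dict:
    """AUC and Harrell's C of the (age-adjusted) score.

    The risk score is the linear predictor of a Cox fit on score (+ age).
    AUC compares it with event status at the administrative ``horizon``
    (default: 95th percentile of follow-up), excluding participants
    censored earlier; its CI is a seeded bootstrap. The C-statistic uses
    all usable pairs under censoring; its CI uses the closed-form
    U-statistic variance (computed on a subsample above ``variance_cap``
    rows).
    """
    df = dataset[[score_col, duration_col, event_col] + ([age_col] if age_col else [])].dropna()
    t = df[duration_col].to_numpy(dtype=float)
    e = df[event_col].to_numpy(dtype=int)
    if e.sum() == 0:
        raise ValueError("no events: discrimination undefined")

    if age_col is None:
        # the score itself is the risk prediction (higher = riskier);
        # refitting its sign in-sample would bias null discrimination away
        # from 0.5
        lp = df[score_col].to_numpy(dtype=float)
    else:
        cols = [score_col, age_col]
        fit_df = df[cols].copy()
        fit_df["_t"], fit_df["_e"] = t, e
        cph = CoxPHFitter()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(fit_df, duration_col="_t", event_col="_e")
            lp = df[cols].to_numpy(dtype=float) @ cph.params_[cols].to_numpy()
        except Exception:  # degenerate design (e.g. constant score)
            lp = np.zeros(len(df))

    if not np.all(np.isfinite(lp)) or np.ptp(lp) == 0:
        lp = np.zeros(len(df))
        warnings.warn("all risk scores tied; concordance is 0.5", stacklevel=2)
        c, c_se = 0.5, np.nan
    elif len(df) <= variance_cap:
        c, c_se = harrell_c_exact(t, lp, e)
    else:
        c = concordance_index(t, -lp, e)
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(df), size=variance_cap, replace=False)
        _, c_se = harrell_c_exact(t[idx], lp[idx], e[idx])
    z = stats.norm.ppf(0.975)
    c_ci = (c - z * c_se, c + z * c_se) if np.isfinite(c_se) else (np.nan, np.nan)

    if horizon is None:
        horizon = float(np.quantile(t, 0.95))
    case = (e == 1) & (t <= horizon)
    control = t >= horizon
    keep = case | control
    auc = auc_lo = auc_hi = np.nan
    n_cases = int(case.sum())
    if n_cases > 0 and int((control & ~case).sum()) > 0:
        y, x = case[keep].astype(int), lp[keep]
        auc = float(roc_auc_score(y, x))
        rng = np.random.default_rng(seed)
        boots = []
        idx_all = np.arange(len(y))
        for _ in range(n_bootstrap):
            bidx = rng.choice(idx_all, size=len(y), replace=True)
            if y[bidx].min() == y[bidx].max():
                continue
            boots.append(roc_auc_score(y[bidx], x[bidx]))
        if boots:
            auc_lo, auc_hi = np.quantile(boots, [0.025, 0.975])

    # full-follow-up binary label variant (both conventions are reported)
    auc_full = float(roc_auc_score(e, lp)) if e.min() != e.max() else np.nan

    return {
        "c_statistic": float(c),
        "c_ci": (float(c_ci[0]), float(c_ci[1])),
        "auc": auc,
        "auc_ci": (float(auc_lo), float(auc_hi)),
        "auc_full_followup": auc_full,
        "horizon": float(horizon),
        "n": int(len(df)),
        "n_cases_at_horizon": n_cases,
    }


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def validation_report(
    scores: pd.DataFrame,
    cohort: pd.DataFrame,
    outcomes=("ckd", "cvd", "death"),
    n_knots: int = 4,
    horizon: float | None = None,
    seed: int = 0,
) -> dict:
    """Per-outcome validation of per-participant totals.

    ``scores`` is the output of :func:`lifescore.scorecard.score_cohort`
    (aligned with ``cohort`` by position or participant_id). Outcomes with
    no events are replaced by a notice instead of failing the whole
    report.
    """
    if "participant_id" in scores.columns and "participant_id" in cohort.columns:
        merged = cohort.merge(scores, on="participant_id")
    else:
        merged = pd.concat(
            [cohort.reset_index(drop=True), scores.reset_index(drop=True)], axis=1
        )
    report: dict = {}
    for outcome in outcomes:
        dur_col, ev_col = OUTCOME_COLUMNS[outcome]
        if dur_col not in merged.columns or ev_col not in merged.columns:
            report[outcome] = {"notice": f"outcome columns for {outcome!r} missing"}
            continue
        if merged[ev_col].sum() == 0:
            report[outcome] = {"notice": f"no {outcome} events in cohort"}
            continue
        entry: dict = {}
        try:
            rcs = fit_rcs(
                merged["total_score"], merged[dur_col], merged[ev_col], n_knots=n_knots
            )
            entry["rcs"] = {
                "knots": rcs.knots.tolist(),
                "coefficients": rcs.coefficients.tolist(),
                "linearity_p": rcs.linearity_p,
                "linear_slope": float(rcs.coefficients[0]),
            }
        except ValueError as exc:
            entry["rcs"] = {"notice": str(exc)}
        try:
            gh = grade_hazards(merged["grade"], merged[dur_col], merged[ev_col])
            entry["grade_hazards"] = gh.to_dict(orient="records")
        except ValueError as exc:
            entry["grade_hazards"] = {"notice": str(exc)}
        entry["discrimination"] = discrimination(
            merged,
            duration_col=dur_col,
            event_col=ev_col,
            horizon=horizon,
            seed=seed,
        )
        report[outcome] = entry
    return report
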