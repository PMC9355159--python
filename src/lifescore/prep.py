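"""Cohort preparation: eGFR, eligibility exclusions, MET volumes, derived
lifestyle codings and the composite incident-CKD outcome.

The analysis dataset produced here is what the importance and hazards
stages consume: one row per eligible participant, 37 model-ready lifestyle
columns, and per-outcome (duration, indicator) pairs for CKD, CVD and
all-cause death.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codebook import FactorCodebook, CodebookError

__all__ = [
    "MET_WEIGHTS",
    "OutcomeDefinition",
    "egfr_mdrd",
    "met_minutes",
    "apply_exclusions",
    "derive_factors",
    "define_outcome",
]

#: IPAQ energy-cost weights (MET) for walking / moderate / vigorous activity.
MET_WEIGHTS = {"walking": 3.3, "moderate": 4.0, "vigorous": 8.0}

UMOL_PER_MGDL = 88.4  # creatinine unit conversion


class SchemaError(KeyError):
    """A required column is missing from the cohort table."""


@dataclass
class OutcomeDefinition:
    """Composite CKD event definition.

    CKD = first of: follow-up eGFR at/below threshold, renal-failure
    diagnosis (hospitalization, death record or self-report), or initiation
    of renal replacement therapy.
    """

    egfr_threshold: float = 60.0
    #: ``True`` uses eGFR <= threshold (Methods dialect); ``False`` strict <.
    inclusive_threshold: bool = True
    icd10_codes: frozenset = frozenset({"N18"})
    icd9_codes: frozenset = frozenset({"5859"})
    self_report_codes: frozenset = frozenset({"1192"})
    rrt_codes: frozenset = frozenset({"Z99.2", "Z94.0", "Z49"})

    def __post_init__(self):
        if self.egfr_threshold <= 0:
            raise ValueError("egfr_threshold must be positive")
        for name in ("icd10_codes", "icd9_codes", "self_report_codes", "rrt_codes"):
            codes = frozenset(getattr(self, name))
            if not codes:
                raise ValueError(f"{name} must be non-empty")
            object.__setattr__(self, name, codes)

    def egfr_qualifies(self, egfr) -> np.ndarray:
        egfr = np.asarray(egfr, dtype=float)
        if self.inclusive_threshold:
            return egfr <= self.egfr_threshold
        return egfr < self.egfr_threshold

    def code_qualifies(self, kind: str, code) -> np.ndarray:
        codes = {
            "icd10": self.icd10_codes,
            "icd9": self.icd9_codes,
            "self_report": self.self_report_codes,
            "rrt": self.rrt_codes,
        }[kind]
        return pd.Series(code).astype(str).isin(codes).to_numpy()


# ---------------------------------------------------------------------------
# eGFR
# ---------------------------------------------------------------------------

def egfr_mdrd(creatinine_umol_l, age_years, sex, black_ethnicity=False) -> np.ndarray:
    """Estimated GFR (ml/min/1.73 m²) by the IDMS-traceable 4-variable MDRD
    equation.

    eGFR = 175 · Scr^(−1.154) · age^(−0.203) · 0.742 [female] · 1.212 [Black],
    with serum creatinine converted from µmol/L to mg/dL (÷ 88.4).

    ``sex`` is ``"male"``/``"female"`` (scalar or array). Scalars in, scalar
    out.
    """
    scr = np.asarray(creatinine_umol_l, dtype=float)
    age = np.asarray(age_years, dtype=float)
    if np.any(scr <= 0) or np.any(~np.isfinite(scr)):
        raise ValueError("creatinine must be positive and finite")
    if np.any(age <= 0) or np.any(~np.isfinite(age)):
        raise ValueError("age must be positive and finite")
    scr_mgdl = scr / UMOL_PER_MGDL
    female = np.asarray(pd.Series(np.atleast_1d(sex)).eq("female"))
    black = np.asarray(np.atleast_1d(black_ethnicity), dtype=bool)
    egfr = 175.0 * scr_mgdl ** (-1.154) * age ** (-0.203)
    egfr = egfr * np.where(female, 0.742, 1.0) * np.where(black, 1.212, 1.0)
    if np.ndim(creatinine_umol_l) == 0 and np.ndim(sex) == 0:
        return float(np.squeeze(egfr))
    return egfr


# ---------------------------------------------------------------------------
# MET volume
# ---------------------------------------------------------------------------

def met_minutes(
    walking_min_per_day=0.0,
    moderate_min_per_day=0.0,
    vigorous_min_per_day=0.0,
    walking_days_per_week=0,
    moderate_days_per_week=0,
    vigorous_days_per_week=0,
) -> dict:
    """Weekly MET volume per activity category.

    MET-min/week = MET weight × min/day × days/week with IPAQ weights
    3.3 (walking), 4.0 (moderate), 8.0 (vigorous). Accepts scalars or
    aligned arrays; returns a dict of the three categories.
    """
    args = {
        "walking": (walking_min_per_day, walking_days_per_week),
        "moderate": (moderate_min_per_day, moderate_days_per_week),
        "vigorous": (vigorous_min_per_day, vigorous_days_per_week),
    }
    out = {}
    for cat, (minutes, days) in args.items():
        m = np.asarray(minutes, dtype=float)
        d = np.asarray(days, dtype=float)
        if np.any(m < 0):
            raise ValueError(f"{cat}: minutes must be non-negative")
        if np.any((d < 0) | (d > 7)):
            raise ValueError(f"{cat}: days/week must lie in 0–7")
        out[cat] = MET_WEIGHTS[cat] * m * d
    return out


# ---------------------------------------------------------------------------
# Exclusions
# ---------------------------------------------------------------------------

def apply_exclusions(
    cohort: pd.DataFrame,
    outcome_def: OutcomeDefinition | None = None,
    codebook: FactorCodebook | None = None,
    max_missing_fraction: float = 0.95,
) -> tuple[pd.DataFrame, pd.Series]:
    """Baseline eligibility filter.

    Rules, applied in order with first-matching-rule attribution:

    1. baseline eGFR at/below the outcome threshold (requires ``creatinine``,
       ``age``, ``sex`` and optionally ``ethnicity`` columns);
    2. prevalent chronic renal failure (``baseline_codes`` column holding
       comma-separated diagnosis/self-report codes);
    3. prior renal replacement therapy (``prior_rrt`` boolean column);
    4. fewer than 5 % of lifestyle fields non-missing (equivalently,
       a missing fraction above ``max_missing_fraction``).

    Returns the retained table and a Series of per-rule exclusion counts
    (``retained`` + exclusions partitions the input rows).
    """
    outcome_def = outcome_def or OutcomeDefinition()
    if "creatinine" not in cohort.columns:
        raise SchemaError("cohort lacks a 'creatinine' column")
    n = len(cohort)
    excluded = np.zeros(n, dtype=bool)
    reasons = {}

    black = (
        cohort["ethnicity"].eq("black").to_numpy()
        if "ethnicity" in cohort.columns
        else np.zeros(n, dtype=bool)
    )
    egfr = egfr_mdrd(
        cohort["creatinine"].to_numpy(),
        cohort["age"].to_numpy(),
        cohort["sex"].to_numpy(),
        black,
    )
    hit = outcome_def.egfr_qualifies(egfr) & ~excluded
    reasons["baseline_egfr"] = int(hit.sum())
    excluded |= hit

    if "baseline_codes" in cohort.columns:
        prevalent_codes = outcome_def.icd10_codes | outcome_def.icd9_codes | outcome_def.self_report_codes
        has_code = (
            cohort["baseline_codes"]
            .fillna("")
            .astype(str)
            .apply(lambda s: bool(set(s.split(",")) & prevalent_codes))
            .to_numpy()
        )
    else:
        has_code = np.zeros(n, dtype=bool)
    hit = has_code & ~excluded
    reasons["prevalent_ckd"] = int(hit.sum())
    excluded |= hit

    if "prior_rrt" in cohort.columns:
        rrt = cohort["prior_rrt"].fillna(False).astype(bool).to_numpy()
    else:
        rrt = np.zeros(n, dtype=bool)
    hit = rrt & ~excluded
    reasons["prior_rrt"] = int(hit.sum())
    excluded |= hit

    if codebook is not None:
        lifestyle_cols = [c for c in codebook.names if c in cohort.columns]
        # Derived factors may not exist yet; count over their raw sources too.
        if lifestyle_cols:
            present = cohort[lifestyle_cols].notna().mean(axis=1).to_numpy()
            hit = (1.0 - present > max_missing_fraction) & ~excluded
        else:
            hit = np.zeros(n, dtype=bool)
    else:
        hit = np.zeros(n, dtype=bool)
    reasons["lifestyle_missingness"] = int(hit.sum())
    excluded |= hit

    log = pd.Series(reasons, name="excluded")
    log["retained"] = int(n - excluded.sum())
    return cohort.loc[~excluded].reset_index(drop=True), log


# ---------------------------------------------------------------------------
# Derived lifestyle codings
# ---------------------------------------------------------------------------

_ADVERSITY_FLAGS = ("illness_2y", "injury_2y", "bereavement_2y", "stress_2y")


def derive_factors(cohort: pd.DataFrame, codebook: FactorCodebook) -> pd.DataFrame:
    """Attach the 37 model-ready factor columns.

    Derivations:

    * ``walking_met`` / ``moderate_met`` / ``vigorous_met`` — weekly MET
      volume from minutes/day × days/week raw fields;
    * ``current_smoking`` / ``current_alcohol`` — status collapsed to
      current vs non-current (never and former are non-current);
    * ``adequate_sleep`` — sleep duration in the 7–9 h/day window;
    * ``psychological_health`` — none of illness, injury, bereavement or
      stress reported in the past 2 years.

    Direct (non-derived) factors are validated against their declared
    support; an unknown polytomous label raises :class:`CodebookError`
    naming the variable and value.
    """
    out = cohort.copy()
    for spec in codebook:
        if spec.is_derived:
            gen = spec.marginal["generator"]
            if gen in ("walking", "moderate", "vigorous"):
                mins = out.get(f"{gen}_min_day")
                days = out.get(f"{gen}_days_wk")
                if mins is None or days is None:
                    raise SchemaError(f"missing raw activity fields for {spec.name}")
                met = MET_WEIGHTS[gen] * mins.astype(float) * days.astype(float)
                out[spec.name] = met.round().astype("Int64")
                out.loc[mins.isna() | days.isna(), spec.name] = pd.NA
            elif gen == "smoking":
                out[spec.name] = _current_status(out, "smoking_status", spec.name)
            elif gen == "alcohol":
                out[spec.name] = _current_status(out, "alcohol_status", spec.name)
            elif gen == "sleep":
                if "sleep_duration_h" not in out.columns:
                    raise SchemaError("missing raw field sleep_duration_h")
                h = out["sleep_duration_h"].astype(float)
                val = ((h >= 7.0) & (h <= 9.0)).astype("Int64")
                val[h.isna()] = pd.NA
                out[spec.name] = val
            elif gen == "psych":
                missing_flags = [f for f in _ADVERSITY_FLAGS if f not in out.columns]
                if missing_flags:
                    raise SchemaError(f"missing adversity flags: {missing_flags}")
                flags = out[list(_ADVERSITY_FLAGS)]
                any_adversity = flags.fillna(0).astype(float).sum(axis=1) > 0
                val = (~any_adversity).astype("Int64")
                val[flags.isna().all(axis=1)] = pd.NA
                out[spec.name] = val
            else:  # pragma: no cover - codebook misconfiguration
                raise CodebookError(f"{spec.name}: unknown generator {gen!r}")
        else:
            if spec.name not in out.columns:
                raise SchemaError(f"missing factor column {spec.name!r}")
            if spec.var_type == "polytomous":
                vals = out[spec.name].dropna()
                bad = set(vals.unique()) - set(spec.levels)
                if bad:
                    raise CodebookError(
                        f"{spec.name}: unknown category label(s) {sorted(map(str, bad))}"
                    )
                out[spec.name] = pd.Categorical(
                    out[spec.name], categories=spec.levels, ordered=True
                )
    return out


def _current_status(df: pd.DataFrame, col: str, target: str) -> pd.Series:
    if col not in df.columns:
        raise SchemaError(f"missing raw field {col!r} for {target}")
    status = df[col].astype("string")
    known = {"never", "former", "current"}
    bad = set(status.dropna().unique()) - known
    if bad:
        raise CodebookError(f"{target}: unknown category label(s) {sorted(bad)}")
    val = status.eq("current").astype("Int64")
    val[status.isna()] = pd.NA
    return val


# ---------------------------------------------------------------------------
# Outcome definition from event records
# ---------------------------------------------------------------------------

def define_outcome(
    cohort: pd.DataFrame,
    records: pd.DataFrame,
    outcome_def: OutcomeDefinition | None = None,
    end_of_followup: float | str = "followup_end",
) -> pd.DataFrame:
    """Attach the composite CKD event indicator and follow-up time.

    ``records`` is a long table with columns ``participant_id``, ``kind``
    (``egfr`` / ``icd10`` / ``icd9`` / ``self_report`` / ``rrt`` /
    ``death`` / ``cvd``), ``code`` (diagnosis code, where applicable),
    ``time`` (years from baseline) and ``value`` (the eGFR measurement for
    ``egfr`` records).

    The CKD event is the *first* qualifying record of any composite
    component; follow-up runs to that event or to the end of follow-up
    (a per-participant ``followup_end`` column, or a constant number of
    years). Secondary flags ``cvd_event``/``cvd_time`` and
    ``death_event``/``death_time`` are attached the same way.
    """
    outcome_def = outcome_def or OutcomeDefinition()
    rec = records.copy()
    if (rec["time"] <= 0).any():
        bad = rec.loc[rec["time"] <= 0, "participant_id"].iloc[0]
        raise ValueError(f"event record at or before baseline for participant {bad!r}")

    if isinstance(end_of_followup, str):
        if end_of_followup not in cohort.columns:
            raise SchemaError(f"missing end-of-followup column {end_of_followup!r}")
        fu_end = cohort[end_of_followup].astype(float).to_numpy()
    else:
        fu_end = np.full(len(cohort), float(end_of_followup))

    qualifies = np.zeros(len(rec), dtype=bool)
    kinds = rec["kind"].to_numpy()
    mask = kinds == "egfr"
    if mask.any():
        qualifies[mask] = outcome_def.egfr_qualifies(rec.loc[mask, "value"])
    for kind in ("icd10", "icd9", "self_report", "rrt"):
        mask = kinds == kind
        if mask.any():
            lookup = "rrt" if kind == "rrt" else kind
            qualifies[mask] = outcome_def.code_qualifies(lookup, rec.loc[mask, "code"])
    # deaths attributed to renal failure count as CKD events
    mask = kinds == "death"
    if mask.any():
        qualifies[mask] = outcome_def.code_qualifies("icd10", rec.loc[mask, "code"])

    ckd_first = (
        rec.loc[qualifies].groupby("participant_id")["time"].min()
    )
    death_first = (
        rec.loc[kinds == "death"].groupby("participant_id")["time"].min()
    )
    cvd_first = (
        rec.loc[kinds == "cvd"].groupby("participant_id")["time"].min()
    )

    out = cohort.copy()
    pid = out["participant_id"]
    t_ckd = pid.map(ckd_first).to_numpy(dtype=float)
    t_death = pid.map(death_first).to_numpy(dtype=float)
    t_cvd = pid.map(cvd_first).to_numpy(dtype=float)

    # CKD follow-up ends at the event, death, or administrative end.
    horizon = np.fmin(np.where(np.isnan(t_death), np.inf, t_death), fu_end)
    has_ckd = ~np.isnan(t_ckd) & (t_ckd <= horizon)
    time = np.where(has_ckd, t_ckd, horizon)
    died_first = ~has_ckd & ~np.isnan(t_death) & (t_death <= fu_end)
    out["event_type"] = np.select(
        [has_ckd, died_first], ["ckd", "death"], default="censored"
    )
    out["event_time"] = time
    out["ckd_event"] = has_ckd.astype(int)

    death_horizon = fu_end
    has_death = ~np.isnan(t_death) & (t_death <= death_horizon)
    out["death_event"] = has_death.astype(int)
    out["death_time"] = np.where(has_death, t_death, death_horizon)

    cvd_horizon = np.fmin(np.where(np.isnan(t_death), np.inf, t_death), fu_end)
    has_cvd = ~np.isnan(t_cvd) & (t_cvd <= cvd_horizon)
    out["cvd_event"] = has_cvd.astype(int)
    out["cvd_time"] = np.where(has_cvd, t_cvd, cvd_horizon)

    if (out["event_time"] <= 0).any():
        raise ValueError("non-positive follow-up time produced; check followup_end")
    return out
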