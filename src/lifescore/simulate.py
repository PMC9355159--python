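"""Synthetic UK-Biobank-like cohort generation.

The simulator draws demographics, serum creatinine and the 37 lifestyle
variables of the codebook, then generates a CKD event time from a Weibull
proportional-hazards model whose linear predictor sums the planted
per-factor log hazards plus age and sex terms. Death is a competing
exponential cause (independent of lifestyle by default); cardiovascular
events are a parallel secondary process. Administrative censoring emulates
the ~11-year median follow-up of a 2006–2010 recruitment window.

Raw fields (activity minutes/days, smoking/alcohol status, sleep duration,
adversity flags) are emitted alongside the direct factor columns so that
the prep stage has real work to do; the planted truth is computed from the
same derivation rules it applies.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .codebook import FactorCodebook, FactorSpec, default_codebook
from .prep import MET_WEIGHTS, derive_factors

__all__ = [
    "SimulationConfig",
    "CalibrationError",
    "generate_cohort",
    "event_records",
    "calibrate_incidence",
    "write_cohort",
    "read_cohort",
]


class CalibrationError(RuntimeError):
    """Incidence calibration could not reach the requested target."""


def recovery_config(n_participants: int = 50_000) -> "SimulationConfig":
    """Study conditions for rank/sign recovery experiments.

    Pairs with :func:`lifescore.codebook.recovery_codebook`; the baseline
    scale is pre-calibrated so cumulative CKD incidence is ~2.9% under
    that codebook's planted effects.
    """
    return SimulationConfig(n_participants=n_participants, baseline_scale=102.7)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults emulate the analysed cohort: n held small here (callers pick
    their own), male fraction 53.91 %, age ~ Normal(57, 8) truncated to the
    40–69 recruitment window, ~2.9 % cumulative CKD incidence over a median
    11 years of follow-up, and a competing death process.
    """

    n_participants: int = 10_000
    male_fraction: float = 0.5391
    age_mean: float = 57.0
    age_sd: float = 8.0
    age_range: tuple = (40.0, 69.0)
    #: lognormal creatinine (µmol/L): median by sex, common log-scale sd
    creatinine_median: dict = field(default_factory=lambda: {"male": 80.0, "female": 65.0})
    creatinine_log_sd: float = 0.17
    #: Weibull baseline for the CKD cause: H0(t) = (t / scale)^shape
    baseline_shape: float = 1.5
    #: default pre-calibrated to ~2.9% cumulative CKD incidence at 11 years
    baseline_scale: float = 46.5
    #: exponential competing-death rate per year (lifestyle-independent by default)
    death_rate: float = 0.004
    death_loghr_scale: float = 0.0
    #: secondary cardiovascular process
    cvd_rate: float = 0.007
    cvd_loghr_scale: float = 0.5
    #: age/sex terms of the true hazard (per year, centred; male indicator)
    age_loghr: float = 0.07
    age_center: float = 57.0
    male_loghr: float = -0.12
    admin_censor_years: float = 11.0
    #: half-width of the uniform staggered-entry jitter on follow-up end
    entry_jitter_years: float = 1.0
    target_median_followup: float = 11.0
    #: Gaussian-copula correlation between lifestyle factors (0 = independent)
    copula_rho: float = 0.0
    missing_rate: float = 0.02
    high_missing_fraction: float = 0.001
    prevalent_ckd_rate: float = 0.004
    prior_rrt_rate: float = 0.0005
    seed: int = 20220722

    def __post_init__(self):
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ValueError("male_fraction must lie in [0, 1]")
        for name in ("age_sd", "baseline_shape", "baseline_scale", "admin_censor_years"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("death_rate", "cvd_rate", "missing_rate", "copula_rho"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.copula_rho >= 1.0:
            raise ValueError("copula_rho must be < 1")

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)

    def to_yaml(self, path) -> None:
        doc = dataclasses.asdict(self)
        doc["age_range"] = list(self.age_range)
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown SimulationConfig keys: {sorted(unknown)}")
        if "age_range" in doc:
            doc["age_range"] = tuple(doc["age_range"])
        return cls(**doc)


# ---------------------------------------------------------------------------
# marginal samplers
# ---------------------------------------------------------------------------

def _truncnorm_loc(target_mean: float, sd: float, lo: float, hi: float) -> float:
    """Location parameter whose [lo, hi]-truncated normal has the target mean."""
    if not lo < target_mean < hi:
        raise ValueError("age_mean must lie inside age_range")

    def f(loc):
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return stats.truncnorm.mean(a, b, loc=loc, scale=sd) - target_mean

    from scipy.optimize import brentq

    return float(brentq(f, lo, hi, xtol=1e-10))


_ETHNICITY = ("white", "mixed", "asian", "black", "chinese", "other")
_ETHNICITY_P = (0.9455, 0.0060, 0.0196, 0.0164, 0.0033, 0.0092)

_DAYS_P = {
    "walking": (0.05, 0.05, 0.08, 0.10, 0.12, 0.12, 0.12, 0.36),
    "moderate": (0.15, 0.10, 0.12, 0.14, 0.12, 0.10, 0.08, 0.19),
    "vigorous": (0.35, 0.12, 0.14, 0.12, 0.09, 0.07, 0.04, 0.07),
}
_MIN_LOGNORM = {"walking": (40.0, 0.9, 240), "moderate": (30.0, 1.0, 240), "vigorous": (20.0, 1.1, 180)}
_SMOKING_P = (0.550, 0.343, 0.107)   # never / former / current
_ALCOHOL_P = (0.040, 0.038, 0.922)


def _sample_factor(spec: FactorSpec, u: np.ndarray, rng: np.random.Generator, raw: dict) -> None:
    """Draw one factor (model-ready column or raw fields) into ``raw``."""
    m = spec.marginal
    kind = m["kind"]
    if kind == "probs":
        cum = np.cumsum(m["probs"])
        idx = np.searchsorted(cum, u, side="right").clip(0, len(cum) - 1)
        if spec.var_type == "polytomous":
            raw[spec.name] = pd.Categorical.from_codes(idx, list(spec.levels), ordered=True)
        else:
            support = m.get("support", list(range(len(cum))))
            raw[spec.name] = np.asarray(support)[idx]
    elif kind == "poisson":
        vals = stats.poisson.ppf(u, m["lam"]).astype(int)
        raw[spec.name] = np.clip(vals, 0, m.get("max", np.inf)).astype(int)
    elif kind == "lognormal_int":
        vals = np.round(stats.lognorm.ppf(u, s=m["sigma"], scale=np.exp(m["mu"])))
        raw[spec.name] = np.clip(vals, 0, m.get("max", np.inf)).astype(int)
    elif kind == "bernoulli":
        raw[spec.name] = (u < m["p"]).astype(int)
    elif kind == "derived":
        _sample_derived(spec, u, rng, raw)
    else:
        raise ValueError(f"{spec.name}: unknown marginal kind {kind!r}")


def _sample_derived(spec: FactorSpec, u: np.ndarray, rng: np.random.Generator, raw: dict) -> None:
    gen = spec.marginal["generator"]
    n = len(u)
    if gen in _MIN_LOGNORM:
        med, sig, cap = _MIN_LOGNORM[gen]
        minutes = np.clip(np.round(stats.lognorm.ppf(u, s=sig, scale=med)), 0, cap)
        days = rng.choice(8, size=n, p=_DAYS_P[gen])
        raw[f"{gen}_min_day"] = minutes.astype(int)
        raw[f"{gen}_days_wk"] = days.astype(int)
    elif gen == "smoking":
        cum = np.cumsum(_SMOKING_P)
        idx = np.searchsorted(cum, u, side="right").clip(0, 2)
        raw["smoking_status"] = np.array(["never", "former", "current"])[idx]
    elif gen == "alcohol":
        cum = np.cumsum(_ALCOHOL_P)
        idx = np.searchsorted(cum, u, side="right").clip(0, 2)
        raw["alcohol_status"] = np.array(["never", "former", "current"])[idx]
    elif gen == "sleep":
        dur = stats.norm.ppf(u, loc=7.15, scale=1.05)
        raw["sleep_duration_h"] = np.clip(np.round(dur, 1), 3.0, 12.0)
    elif gen == "psych":
        raw["stress_2y"] = (u < 0.25).astype(int)
        raw["illness_2y"] = (rng.random(n) < 0.12).astype(int)
        raw["injury_2y"] = (rng.random(n) < 0.06).astype(int)
        raw["bereavement_2y"] = (rng.random(n) < 0.10).astype(int)
    else:
        raise ValueError(f"{spec.name}: unknown derived generator {gen!r}")


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(
    config: SimulationConfig,
    codebook: FactorCodebook | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Generate a synthetic cohort table.

    Returns one row per participant with demographics, creatinine, raw and
    direct lifestyle fields, baseline exclusion flags, per-outcome event
    columns and ``followup_end``. Deterministic given config (and the
    optional ``seed`` override).
    """
    codebook = codebook or default_codebook()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_participants

    # demographics -------------------------------------------------------
    male = rng.random(n) < config.male_fraction
    lo, hi = config.age_range
    # location adjusted so the *truncated* mean equals age_mean
    loc = _truncnorm_loc(config.age_mean, config.age_sd, lo, hi)
    a, b = (lo - loc) / config.age_sd, (hi - loc) / config.age_sd
    age = stats.truncnorm.ppf(rng.random(n), a, b, loc=loc, scale=config.age_sd)
    ethnicity = rng.choice(_ETHNICITY, size=n, p=_ETHNICITY_P)
    creat_med = np.where(male, config.creatinine_median["male"], config.creatinine_median["female"])
    creatinine = np.round(
        creat_med * np.exp(rng.normal(0.0, config.creatinine_log_sd, n)), 1
    )

    # lifestyle ----------------------------------------------------------
    raw: dict = {}
    rho = config.copula_rho
    common = rng.standard_normal(n) if rho > 0 else None
    for spec in codebook:
        if rho > 0:
            z = np.sqrt(rho) * common + np.sqrt(1.0 - rho) * rng.standard_normal(n)
            u = stats.norm.cdf(z)
        else:
            u = rng.random(n)
        _sample_factor(spec, u, rng, raw)

    table = pd.DataFrame(raw)
    table.insert(0, "participant_id", np.arange(1, n + 1))
    table.insert(1, "age", np.round(age, 2))
    table.insert(2, "sex", pd.Categorical(np.where(male, "male", "female")))
    table.insert(3, "ethnicity", pd.Categorical(ethnicity, categories=_ETHNICITY))
    table.insert(4, "creatinine", creatinine)

    # planted truth: linear predictor from the *derived* factor columns
    derived = derive_factors(table, codebook)
    lp = (
        codebook.linear_predictor(derived)
        + config.age_loghr * (table["age"].to_numpy() - config.age_center)
        + config.male_loghr * male.astype(float)
    )

    # event processes ----------------------------------------------------
    e_ckd = rng.exponential(1.0, n)
    t_ckd = config.baseline_scale * (e_ckd * np.exp(-lp)) ** (1.0 / config.baseline_shape)
    t_death = rng.exponential(1.0, n) / (
        config.death_rate * np.exp(config.death_loghr_scale * lp)
    )
    t_cvd = rng.exponential(1.0, n) / (
        config.cvd_rate * np.exp(config.cvd_loghr_scale * lp)
    )
    jitter = config.entry_jitter_years
    fu_end = config.admin_censor_years + (
        rng.uniform(-jitter, jitter, n) if jitter > 0 else np.zeros(n)
    )
    fu_end = np.maximum(np.round(fu_end, 3), 0.05)

    horizon = np.minimum(t_death, fu_end)
    has_ckd = t_ckd <= horizon
    event_time = np.where(has_ckd, t_ckd, horizon)
    died_first = ~has_ckd & (t_death <= fu_end)
    table["event_type"] = pd.Categorical(
        np.select([has_ckd, died_first], ["ckd", "death"], default="censored"),
        categories=["ckd", "death", "censored"],
    )
    table["event_time"] = np.round(np.maximum(event_time, 1e-3), 4)
    table["ckd_event"] = has_ckd.astype(int)
    has_death = t_death <= fu_end
    table["death_event"] = has_death.astype(int)
    table["death_time"] = np.round(np.where(has_death, t_death, fu_end), 4)
    cvd_horizon = np.minimum(t_death, fu_end)
    has_cvd = t_cvd <= cvd_horizon
    table["cvd_event"] = has_cvd.astype(int)
    table["cvd_time"] = np.round(np.where(has_cvd, t_cvd, cvd_horizon), 4)
    table["followup_end"] = fu_end

    # baseline exclusion material ---------------------------------------
    prev = rng.random(n) < config.prevalent_ckd_rate
    table["baseline_codes"] = pd.array(np.where(prev, "N18", None), dtype=object)
    table["prior_rrt"] = rng.random(n) < config.prior_rrt_rate

    # missingness (after truth computation; MCAR) ------------------------
    factor_cols = [c for c in codebook.names if c in table.columns]
    raw_cols = [
        c
        for c in table.columns
        if c.endswith(("_min_day", "_days_wk", "_2y"))
        or c in ("smoking_status", "alcohol_status", "sleep_duration_h")
    ]
    lifestyle_cols = factor_cols + raw_cols
    if config.missing_rate > 0 or config.high_missing_fraction > 0:
        for col in lifestyle_cols:
            if pd.api.types.is_integer_dtype(table[col]):
                table[col] = table[col].astype("Int64")
        if config.missing_rate > 0:
            for col in lifestyle_cols:
                miss = rng.random(n) < config.missing_rate
                table.loc[miss, col] = _na_for(table[col])
        if config.high_missing_fraction > 0:
            wipe = rng.random(n) < config.high_missing_fraction
            if wipe.any():
                keep = rng.choice(lifestyle_cols)  # leave a single field present
                for col in lifestyle_cols:
                    if col != keep:
                        table.loc[wipe, col] = _na_for(table[col])
    return table


def _na_for(col: pd.Series):
    if isinstance(col.dtype, pd.CategoricalDtype) or str(col.dtype) == "Int64":
        return pd.NA
    if pd.api.types.is_float_dtype(col):
        return np.nan
    return None


def event_records(cohort: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Emit a long event-record table consistent with the cohort's events.

    CKD events are attributed to a random composite component (follow-up
    eGFR measurement, N18 hospitalization, renal-replacement-therapy code
    or self-report); deaths and CVD events get non-renal codes. Feeding the
    result to :func:`lifescore.prep.define_outcome` reproduces the cohort's
    event columns.
    """
    rng = np.random.default_rng(seed)
    rows = []
    ckd = cohort[cohort["event_type"] == "ckd"]
    comp = rng.choice(4, size=len(ckd), p=[0.60, 0.25, 0.10, 0.05])
    for (pid, t), c in zip(ckd[["participant_id", "event_time"]].to_numpy(), comp):
        if c == 0:
            rows.append((pid, "egfr", "", t, 55.0))
        elif c == 1:
            rows.append((pid, "icd10", "N18", t, np.nan))
        elif c == 2:
            rows.append((pid, "rrt", "Z49", t, np.nan))
        else:
            rows.append((pid, "self_report", "1192", t, np.nan))
    dead = cohort[cohort["death_event"] == 1]
    for pid, t in dead[["participant_id", "death_time"]].to_numpy():
        rows.append((pid, "death", "I25", t, np.nan))
    cvd = cohort[cohort["cvd_event"] == 1]
    for pid, t in cvd[["participant_id", "cvd_time"]].to_numpy():
        rows.append((pid, "cvd", "I21", t, np.nan))
    return pd.DataFrame(rows, columns=["participant_id", "kind", "code", "time", "value"])


# ---------------------------------------------------------------------------
# incidence calibration
# ---------------------------------------------------------------------------

def calibrate_incidence(
    config: SimulationConfig,
    target_events: float,
    codebook: FactorCodebook | None = None,
    n_sim: int = 20_000,
    rel_tol: float = 0.10,
    max_iter: int = 40,
    scale_bounds: tuple = (5.0, 50_000.0),
) -> SimulationConfig:
    """Adjust the Weibull baseline scale so the simulated cumulative CKD
    incidence matches ``target_events`` (bisection; incidence is monotone
    decreasing in the scale).
    """
    if not 0.0 < target_events < 1.0:
        raise ValueError("target_events must lie strictly between 0 and 1")
    codebook = codebook or default_codebook()
    probe = config.replace(n_participants=n_sim)

    def incidence(scale: float) -> float:
        cohort = generate_cohort(probe.replace(baseline_scale=scale), codebook)
        return float((cohort["event_type"] == "ckd").mean())

    lo, hi = scale_bounds
    f_lo, f_hi = incidence(lo), incidence(hi)
    if not (f_hi <= target_events <= f_lo):
        raise CalibrationError(
            f"target {target_events:.4f} outside attainable range "
            f"[{f_hi:.4f}, {f_lo:.4f}] for scale bounds {scale_bounds}"
        )
    for _ in range(max_iter):
        mid = float(np.sqrt(lo * hi))  # bisect on the log scale
        f_mid = incidence(mid)
        if abs(f_mid - target_events) <= rel_tol * target_events:
            return config.replace(baseline_scale=mid)
        if f_mid > target_events:
            lo = mid
        else:
            hi = mid
    achieved = incidence(float(np.sqrt(lo * hi)))
    raise CalibrationError(
        f"calibration did not converge; achieved incidence {achieved:.4f} "
        f"for target {target_events:.4f}"
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_cohort(cohort: pd.DataFrame, path, fmt: str | None = None) -> None:
    """Write a cohort as CSV (with a JSON schema sidecar) or parquet.

    The sidecar records dtypes and categorical level order so that a CSV
    round-trip recovers an identical table.
    """
    path = Path(path)
    fmt = fmt or ("parquet" if path.suffix == ".parquet" else "csv")
    if fmt == "csv":
        cohort.to_csv(path, index=False)
        schema = {}
        for col in cohort.columns:
            dt = cohort[col].dtype
            if isinstance(dt, pd.CategoricalDtype):
                schema[col] = {
                    "dtype": "category",
                    "categories": [str(c) for c in dt.categories],
                    "ordered": bool(dt.ordered),
                }
            else:
                schema[col] = {"dtype": str(dt)}
        Path(str(path) + ".schema.json").write_text(json.dumps(schema, indent=1))
    elif fmt == "parquet":
        cohort.to_parquet(path, index=False)
    else:
        raise ValueError(f"unknown cohort format {fmt!r}")


def read_cohort(path, fmt: str | None = None) -> pd.DataFrame:
    path = Path(path)
    fmt = fmt or ("parquet" if path.suffix == ".parquet" else "csv")
    if fmt == "parquet":
        return pd.read_parquet(path)
    if fmt != "csv":
        raise ValueError(f"unknown cohort format {fmt!r}")
    schema_path = Path(str(path) + ".schema.json")
    table = pd.read_csv(path)
    if schema_path.exists():
        schema = json.loads(schema_path.read_text())
        for col, info in schema.items():
            if col not in table.columns:
                continue
            if info["dtype"] == "category":
                table[col] = pd.Categorical(
                    table[col].astype("string").astype(object),
                    categories=info["categories"],
                    ordered=info["ordered"],
                )
            elif info["dtype"] == "object":
                col_obj = table[col].astype(object)
                table[col] = col_obj.where(pd.notna(col_obj), None)
            else:
                try:
                    table[col] = table[col].astype(info["dtype"])
                except (TypeError, ValueError):
                    pass
    return table
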