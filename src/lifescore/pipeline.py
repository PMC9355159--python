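"""End-to-end orchestration: simulate → prep → rank → cox → score → validate.

Each stage is a plain function over files so it can be run standalone (the
CLI exposes them as subcommands); :func:`run_pipeline` chains them and
writes a manifest with the config hash, seed and library versions so any
artifact can be regenerated from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .codebook import FactorCodebook, default_codebook
from .simulate import SimulationConfig, generate_cohort, write_cohort, read_cohort
from .prep import OutcomeDefinition, apply_exclusions, derive_factors
from .importance import DEFAULT_HYPERPARAMS, fit_importance, rank_report
from .hazards import fit_all_factors, estimates_frame, estimates_from_frame
from .scorecard import Scorecard, build_scorecard, score_cohort, scorecard_report
from .validate import validation_report

__all__ = ["RunConfig", "run_pipeline", "StageError"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {message}")


@dataclass
class RunConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    hyperparams: dict = field(default_factory=lambda: dict(DEFAULT_HYPERPARAMS))
    mdi_divisor: float = 1000.0
    boundary: str = "left"
    keep_indeterminate: bool = False
    n_knots: int = 4
    horizon: float | None = None
    outcomes: tuple = ("ckd", "cvd", "death")
    make_figures: bool = True
    seed: int = 20220722

    def config_hash(self) -> str:
        doc = dataclasses.asdict(self)
        doc["outcomes"] = list(self.outcomes)
        doc["simulation"]["age_range"] = list(self.simulation.age_range)
        return hashlib.sha256(
            json.dumps(doc, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    def to_yaml(self, path) -> None:
        doc = dataclasses.asdict(self)
        doc["outcomes"] = list(self.outcomes)
        doc["simulation"]["age_range"] = list(self.simulation.age_range)
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        doc = dict(doc)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown RunConfig keys: {sorted(unknown)}")
        sim = doc.pop("simulation", {})
        if isinstance(sim, dict):
            sim_known = {f.name for f in dataclasses.fields(SimulationConfig)}
            sim_unknown = set(sim) - sim_known
            if sim_unknown:
                raise ValueError(f"unknown SimulationConfig keys: {sorted(sim_unknown)}")
            if "age_range" in sim:
                sim["age_range"] = tuple(sim["age_range"])
            sim = SimulationConfig(**sim)
        if "outcomes" in doc:
            doc["outcomes"] = tuple(doc["outcomes"])
        return cls(simulation=sim, **doc)


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def run_pipeline(
    config: RunConfig,
    out_dir,
    codebook: FactorCodebook | None = None,
) -> dict:
    """Run every stage and write all artifacts under ``out_dir``.

    Returns a dict of the in-memory results (cohort, analysis table,
    importance table, estimates, scorecard, scores, validation report).
    Deterministic: identical config ⇒ byte-identical CSV artifacts.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    codebook = codebook or default_codebook()
    results: dict = {}

    stage = "simulate"
    try:
        sim_cfg = config.simulation.replace(seed=config.seed)
        cohort = generate_cohort(sim_cfg, codebook)
        write_cohort(cohort, out / "cohort.csv")
        codebook.to_yaml(out / "codebook.yaml")
        results["cohort"] = cohort
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, str(exc)) from exc

    stage = "prep"
    try:
        retained, log = apply_exclusions(cohort, OutcomeDefinition(), codebook)
        analysis = derive_factors(retained, codebook)
        log.to_csv(out / "exclusion_log.csv", header=["count"])
        write_cohort(analysis, out / "analysis.csv")
        results["analysis"], results["exclusions"] = analysis, log
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, str(exc)) from exc

    stage = "rank"
    try:
        importance = fit_importance(
            analysis, codebook, hyperparams=config.hyperparams, seed=config.seed
        )
        rank_report(importance).to_csv(out / "importance.csv", index=False)
        results["importance"] = importance
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, str(exc)) from exc

    stage = "cox"
    try:
        estimates = fit_all_factors(analysis, codebook)
        estimates_frame(estimates).to_csv(out / "hazards.csv", index=False)
        results["estimates"] = estimates
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, str(exc)) from exc

    stage = "score"
    try:
        card = build_scorecard(
            importance,
            estimates,
            codebook,
            mdi_divisor=config.mdi_divisor,
            boundary=config.boundary,
            keep_indeterminate=config.keep_indeterminate,
        )
        card.to_csv(out / "scorecard.csv")
        card.to_yaml(out / "scorecard.yaml")
        (out / "scorecard.txt").write_text(scorecard_report(card) + "\n")
        scores = score_cohort(analysis, card)
        scores.to_csv(out / "scores.csv", index=False)
        results["scorecard"], results["scores"] = card, scores
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, str(exc)) from exc

    stage = "validate"
    try:
        report = validation_report(
            scores,
            analysis,
            outcomes=config.outcomes,
            n_knots=config.n_knots,
            horizon=config.horizon,
            seed=config.seed,
        )
        (out / "validation.json").write_text(json.dumps(_jsonify(report), indent=1))
        results["validation"] = report
        if config.make_figures:
            _export_figure(report, scores, out / "validation_ckd.svg")
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, str(exc)) from exc

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "package_version": __version__,
        "versions": _library_versions(),
        "exclusions": {k: int(v) for k, v in results["exclusions"].items()},
        "n_scored_factors": len(card.entries),
        "artifacts": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    results["manifest"] = manifest
    return results


def _library_versions() -> dict:
    import lifelines
    import lightgbm
    import sklearn

    return {
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "lightgbm": lightgbm.__version__,
        "lifelines": lifelines.__version__,
        "sklearn": sklearn.__version__,
    }


def _export_figure(report: dict, scores: pd.DataFrame, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ckd = report.get("ckd", {})
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    gh = ckd.get("grade_hazards")
    if isinstance(gh, list):
        df = pd.DataFrame(gh)
        axes[0].bar(df["grade"].astype(str), df["hr"], color="#4477aa")
        axes[0].errorbar(
            df["grade"].astype(str), df["hr"],
            yerr=[df["hr"] - df["ci_low"], df["ci_high"] - df["hr"]],
            fmt="none", ecolor="black", capsize=3,
        )
        axes[0].axhline(1.0, ls="--", c="grey", lw=0.8)
        axes[0].set_xlabel("score grade")
        axes[0].set_ylabel("HR vs grade 0")
    axes[1].hist(scores["total_score"], bins=30, color="#66ccee")
    axes[1].set_xlabel("total lifestyle score")
    axes[1].set_ylabel("participants")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
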