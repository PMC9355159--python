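"""The lifestyle scorecard: MDI/1,000 points signed by Cox direction.

Each scored factor carries an integer point value, ``round(MDI / 1,000)``
(half-to-even), and a direction from its age/sex-adjusted hazard ratio.
A participant's total score is the sum of the healthy points they satisfy
minus the sum of the unhealthy points they satisfy; totals map to graded
risk categories (<0, 0–20, 20–40, 40–60, ≥60 → grades 0–4).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .codebook import FactorCodebook, evaluate_exposure, describe_exposure
from .hazards import HazardEstimate, assign_direction

__all__ = [
    "FactorScore",
    "Scorecard",
    "build_scorecard",
    "score_participant",
    "score_cohort",
    "scorecard_report",
    "DEFAULT_CUTPOINTS",
]

DEFAULT_CUTPOINTS = (0.0, 20.0, 40.0, 60.0)


@dataclass
class FactorScore:
    factor: str
    direction: str  # "healthy" | "unhealthy"
    score: int
    exposure: dict
    mdi: float | None = None

    def __post_init__(self):
        if self.direction not in ("healthy", "unhealthy"):
            raise ValueError(f"{self.factor}: direction must be healthy/unhealthy")
        if self.score < 0:
            raise ValueError(f"{self.factor}: score must be non-negative")
        self.score = int(self.score)

    @property
    def signed_score(self) -> int:
        return self.score if self.direction == "healthy" else -self.score

    @property
    def contributes(self) -> bool:
        return self.score > 0

    def describe(self) -> str:
        return describe_exposure(self.exposure, self.factor)


@dataclass
class Scorecard:
    entries: list = field(default_factory=list)
    unscored: list = field(default_factory=list)  # (factor, reason)
    cutpoints: tuple = DEFAULT_CUTPOINTS
    #: "left" = [0,20),[20,40),[40,60),[60,∞); "right" = (0,20]…(60,∞)
    boundary: str = "left"

    def __post_init__(self):
        cuts = tuple(float(c) for c in self.cutpoints)
        if any(b <= a for a, b in zip(cuts, cuts[1:])):
            raise ValueError("cutpoints must be strictly increasing")
        self.cutpoints = cuts
        if self.boundary not in ("left", "right"):
            raise ValueError("boundary must be 'left' or 'right'")
        names = [e.factor for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("duplicate factor in scorecard entries")

    # -- scoring ----------------------------------------------------------

    def grade_of(self, total) -> np.ndarray | int:
        """Grade 0–4 of a total score (scalar or array)."""
        t = np.asarray(total, dtype=float)
        g = np.digitize(t, self.cutpoints, right=(self.boundary == "right"))
        return int(g) if np.ndim(total) == 0 else g

    @property
    def max_total(self) -> int:
        return sum(e.score for e in self.entries if e.direction == "healthy")

    @property
    def min_total(self) -> int:
        return -sum(e.score for e in self.entries if e.direction == "unhealthy")

    # -- serialization ----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.entries:
            rows.append(
                {
                    "factor": e.factor,
                    "direction": e.direction,
                    "score": e.score,
                    "mdi": e.mdi,
                    "exposure_kind": e.exposure["kind"],
                    "exposure_op": e.exposure.get("op", ""),
                    "exposure_value": e.exposure.get("value", ""),
                    "exposure_levels": "|".join(
                        map(str, e.exposure.get("exposed_levels", []))
                    ),
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "factor", "direction", "score", "mdi",
                "exposure_kind", "exposure_op", "exposure_value", "exposure_levels",
            ],
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, cutpoints=DEFAULT_CUTPOINTS, boundary="left") -> "Scorecard":
        entries = []
        for _, row in frame.iterrows():
            kind = row["exposure_kind"]
            if kind == "threshold":
                exposure = {"kind": kind, "op": row["exposure_op"], "value": float(row["exposure_value"])}
            elif kind == "levels":
                exposure = {"kind": kind, "exposed_levels": str(row["exposure_levels"]).split("|")}
            else:
                val = row["exposure_value"]
                try:
                    val = int(val)
                except (TypeError, ValueError):
                    pass
                exposure = {"kind": "equals", "value": val}
            mdi = row.get("mdi")
            entries.append(
                FactorScore(
                    factor=row["factor"],
                    direction=row["direction"],
                    score=int(row["score"]),
                    exposure=exposure,
                    mdi=None if pd.isna(mdi) else float(mdi),
                )
            )
        return cls(entries=entries, cutpoints=cutpoints, boundary=boundary)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, **kw) -> "Scorecard":
        return cls.from_frame(pd.read_csv(path), **kw)

    def to_yaml(self, path) -> None:
        doc = {
            "cutpoints": list(self.cutpoints),
            "boundary": self.boundary,
            "entries": [
                {
                    "factor": e.factor,
                    "direction": e.direction,
                    "score": e.score,
                    "mdi": e.mdi,
                    "exposure": e.exposure,
                }
                for e in self.entries
            ],
            "unscored": [list(u) for u in self.unscored],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "Scorecard":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        entries = [
            FactorScore(
                factor=e["factor"],
                direction=e["direction"],
                score=e["score"],
                exposure=e["exposure"],
                mdi=e.get("mdi"),
            )
            for e in doc["entries"]
        ]
        return cls(
            entries=entries,
            unscored=[tuple(u) for u in doc.get("unscored", [])],
            cutpoints=tuple(doc.get("cutpoints", DEFAULT_CUTPOINTS)),
            boundary=doc.get("boundary", "left"),
        )


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def build_scorecard(
    importance: pd.DataFrame,
    estimates: list[HazardEstimate],
    codebook: FactorCodebook,
    mdi_divisor: float = 1000.0,
    cutpoints=DEFAULT_CUTPOINTS,
    boundary: str = "left",
    keep_indeterminate: bool = False,
) -> Scorecard:
    """Combine the importance table and Cox directions into a scorecard.

    Per-factor points are ``round(mdi / mdi_divisor)`` (half-to-even).
    Factors with indeterminate direction are listed under ``unscored``
    rather than silently dropped (or kept, signed by the point estimate,
    with ``keep_indeterminate``); so are factors missing a direction
    altogether.
    """
    directions = assign_direction(estimates)
    point_hr = {e.factor: e.hr for e in estimates}
    entries, unscored = [], []
    for _, row in importance.iterrows():
        name = row["factor"]
        score = int(np.round(float(row["mdi"]) / mdi_divisor))
        if name not in directions:
            unscored.append((name, "no direction estimate"))
            continue
        direction = directions[name]
        if direction == "indeterminate":
            if keep_indeterminate and np.isfinite(point_hr.get(name, np.nan)):
                direction = "healthy" if point_hr[name] < 1.0 else "unhealthy"
            else:
                unscored.append((name, "indeterminate direction"))
                continue
        spec = codebook[name]
        entries.append(
            FactorScore(
                factor=name,
                direction=direction,
                score=score,
                exposure=dict(spec.exposure),
                mdi=float(row["mdi"]),
            )
        )
    return Scorecard(entries=entries, unscored=unscored, cutpoints=tuple(cutpoints), boundary=boundary)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def score_participant(profile, card: Scorecard) -> dict:
    """Total score and grade for one participant.

    ``profile`` maps factor names to lifestyle values. A missing factor
    (absent key or NA value) contributes 0 points and is reported in the
    ``missing`` list.
    """
    if isinstance(profile, pd.Series):
        profile = profile.to_dict()
    total = 0
    missing = []
    for e in card.entries:
        val = profile.get(e.factor)
        if val is None or (np.isscalar(val) and pd.isna(val)):
            missing.append(e.factor)
            continue
        if bool(evaluate_exposure(e.exposure, [val], e.factor)[0]):
            total += e.signed_score
    return {"total": int(total), "grade": card.grade_of(total), "missing": missing}


def score_cohort(dataset: pd.DataFrame, card: Scorecard) -> pd.DataFrame:
    """Vectorized per-participant totals and grades.

    Factors absent from the table (or NA per row) contribute 0.
    """
    total = np.zeros(len(dataset), dtype=int)
    n_missing = np.zeros(len(dataset), dtype=int)
    for e in card.entries:
        if e.factor not in dataset.columns:
            n_missing += 1
            continue
        col = dataset[e.factor]
        exposed = evaluate_exposure(e.exposure, col, e.factor)
        total += e.signed_score * exposed.astype(int)
        n_missing += col.isna().to_numpy().astype(int)
    out = pd.DataFrame(
        {
            "total_score": total,
            "grade": card.grade_of(total),
            "n_missing_factors": n_missing,
        }
    )
    if "participant_id" in dataset.columns:
        out.insert(0, "participant_id", dataset["participant_id"].to_numpy())
    return out


def scorecard_report(card: Scorecard) -> str:
    """Two-panel human-readable score table (healthy / unhealthy)."""
    lines = ["Lifestyle scorecard", "=" * 55]
    for panel in ("healthy", "unhealthy"):
        lines.append(f"\n{panel.capitalize()} factors")
        lines.append("-" * 55)
        entries = sorted(
            (e for e in card.entries if e.direction == panel),
            key=lambda e: (-e.score, e.factor),
        )
        if not entries:
            lines.append("  (none)")
        for e in entries:
            pts = e.signed_score
            flag = "" if e.contributes else "   [non-contributing]"
            lines.append(f"  {pts:+4d}  {e.describe()}{flag}")
    if card.unscored:
        lines.append("\nUnscored factors")
        lines.append("-" * 55)
        for name, reason in card.unscored:
            lines.append(f"        {name}: {reason}")
    cuts = card.cutpoints
    lines.append(
        f"\nGrades: <{cuts[0]:g} -> 0; "
        + "; ".join(
            f"{a:g}-{b:g} -> {i + 1}" for i, (a, b) in enumerate(zip(cuts, cuts[1:]))
        )
        + f"; >{cuts[-1]:g} -> {len(cuts)}"
    )
    return "\n".join(lines)
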