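"""Cumulative weighted aggregation and five-level risk grading.

Tertiary scores propagate up the hierarchy by weighted sums: each secondary
index is the dot product of its tertiary scores with their weights, each
primary index the weighted sum of unrounded secondaries, and the total risk
value R the weighted sum of unrounded primaries.  Because every sibling
weight group sums to one, each aggregate is a convex combination and R stays
on the same 0-5 scale as the raw scores.

R is then mapped onto five lower-open/upper-closed intervals:
negligible (0, 1], low (1, 2], medium (2, 3], high (3, 4] and
extremely high (4, 5], each carrying a policy recommendation.  R = 0 (an
all-zero sheet) is graded negligible by closure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, ScoreSheetError
from .hierarchy import RiskHierarchy, load_model_config
from .rubric import Rubric, ScoreSheet, validate_score_sheet

#: report values are displayed at four decimal places (round-half-even)
DISPLAY_DECIMALS = 4


@dataclass(frozen=True)
class RiskGrade:
    """One risk level: a lower-open/upper-closed interval of R plus the
    policy recommendation attached to it."""

    name: str
    lower: float
    upper: float
    recommendation: str

    def contains(self, r: float) -> bool:
        return self.lower < r <= self.upper


class GradeScale:
    """An ordered set of grades partitioning (0, upper bound]."""

    def __init__(self, grades: Sequence[RiskGrade]):
        grades = sorted(grades, key=lambda g: g.lower)
        for a, b in zip(grades, grades[1:]):
            if abs(a.upper - b.lower) > 1e-12:
                raise ConfigError(
                    f"grade intervals must be contiguous: {a.name} ends at "
                    f"{a.upper} but {b.name} starts at {b.lower}"
                )
        self.grades = list(grades)
        self.lower = grades[0].lower
        self.upper = grades[-1].upper

    @classmethod
    def from_config(cls, source=None) -> "GradeScale":
        doc = load_model_config(source)
        recs = doc.get("grades")
        if not recs:
            raise ConfigError("model config defines no risk grades")
        return cls([
            RiskGrade(name=str(r["name"]), lower=float(r["lower"]),
                      upper=float(r["upper"]),
                      recommendation=str(r.get("recommendation", "")))
            for r in recs
        ])

    def grade(self, r: float) -> RiskGrade:
        if not self.lower <= r <= self.upper:
            raise ValueError(
                f"total risk value {r} outside [{self.lower}, {self.upper}]"
            )
        if r == self.lower:  # closure of the bottom interval
            return self.grades[0]
        for g in self.grades:
            if g.contains(r):
                return g
        raise AssertionError("contiguous intervals cover the range")


def default_grade_scale() -> GradeScale:
    return GradeScale.from_config(None)


def risk_grade(r: float, scale: GradeScale | None = None) -> RiskGrade:
    """Grade a total risk value on the five-level scale."""
    return (scale or default_grade_scale()).grade(r)


def aggregate_node(child_values: Sequence[float],
                   child_weights: Sequence[float]) -> float:
    """Weighted sum of child values — the cumulative aggregation rule.

    No clamping or rounding: with weights summing to 1 the result already
    lies between the smallest and largest child value.
    """
    if len(child_values) != len(child_weights):
        raise ValueError(
            f"{len(child_values)} values but {len(child_weights)} weights"
        )
    return float(np.dot(np.asarray(child_values, dtype=float),
                        np.asarray(child_weights, dtype=float)))


@dataclass(frozen=True)
class AssessmentResult:
    """Per-subject aggregate values, grades and the cross-subject ranking.

    ``values[subject]`` maps every secondary, primary and total node id to
    its full-precision value; ``grades`` holds grade names; ``ranking`` is
    sorted by descending R with lexicographic subject-id tie-break.
    """

    subjects: tuple[str, ...]
    values: Mapping[str, Mapping[str, float]]
    grades: Mapping[str, str]
    recommendations: Mapping[str, str]
    ranking: tuple[str, ...]
    row_order: tuple[str, ...]
    root_id: str

    def total(self, subject: str) -> float:
        return self.values[subject][self.root_id]

    def to_frame(self, decimals: int | None = DISPLAY_DECIMALS) -> pd.DataFrame:
        """Report table mirroring the published layout: one row per
        secondary/primary index, the total, and the grade; one column per
        subject.  ``decimals=None`` keeps full precision."""
        rows = {}
        for node_id in self.row_order:
            vals = [self.values[s][node_id] for s in self.subjects]
            if decimals is not None:
                vals = [f"{round(v, decimals):.{decimals}f}" for v in vals]
            rows[node_id] = vals
        rows["Risk grade"] = [self.grades[s] for s in self.subjects]
        frame = pd.DataFrame.from_dict(rows, orient="index",
                                       columns=self.subjects)
        frame.index.name = "Index"
        return frame

    def to_dict(self) -> dict:
        """Machine-readable result with full-precision values."""
        return {
            "subjects": list(self.subjects),
            "values": {s: dict(self.values[s]) for s in self.subjects},
            "grades": dict(self.grades),
            "recommendations": dict(self.recommendations),
            "ranking": list(self.ranking),
        }


def assess(sheet: ScoreSheet, hierarchy: RiskHierarchy,
           scale: GradeScale | None = None,
           rubric: Rubric | None = None,
           validate: bool = True,
           strict: bool = False) -> AssessmentResult:
    """Run the full assessment: validate, aggregate bottom-up, grade, rank.

    All intermediate values propagate unrounded; rounding happens only in
    display output.  Raises :class:`ScoreSheetError` (with the validation
    report attached) if the sheet does not fit the hierarchy.
    """
    if not sheet.subjects:
        raise ScoreSheetError("score sheet has no subjects")
    if validate:
        report = validate_score_sheet(sheet, hierarchy, rubric, strict=strict)
        if not report.valid:
            raise ScoreSheetError(
                f"score sheet failed validation with "
                f"{len(report.issues)} issue(s)", report=report)
    scale = scale or default_grade_scale()

    # bottom-up order: secondaries, then primaries, then the total
    order = (hierarchy.ids_at_level("secondary")
             + hierarchy.ids_at_level("primary") + [hierarchy.root_id])
    values: dict[str, dict[str, float]] = {}
    for subject in sheet.subjects:
        tier = {tid: float(sheet.scores[subject][tid])
                for tid in hierarchy.tertiary_ids}
        vals: dict[str, float] = {}
        for node_id in order:
            child_ids = hierarchy.children(node_id)
            child_vals = [tier[c] if c in tier else vals[c] for c in child_ids]
            weights = [hierarchy.nodes[c].weight for c in child_ids]
            vals[node_id] = aggregate_node(child_vals, weights)
        values[subject] = vals

    grades, recs = {}, {}
    for subject in sheet.subjects:
        g = scale.grade(values[subject][hierarchy.root_id])
        grades[subject] = g.name
        recs[subject] = g.recommendation
    ranking = tuple(sorted(
        sheet.subjects,
        key=lambda s: (-values[s][hierarchy.root_id], s)))
    row_order = tuple(hierarchy.ids_at_level("secondary")
                      + hierarchy.ids_at_level("primary")
                      + [hierarchy.root_id])
    return AssessmentResult(
        subjects=tuple(sheet.subjects), values=values, grades=grades,
        recommendations=recs, ranking=ranking, row_order=row_order,
        root_id=hierarchy.root_id)


def rank_subjects(result: AssessmentResult) -> list[str]:
    """Subjects by descending total risk value (ties broken by id)."""
    return list(result.ranking)
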