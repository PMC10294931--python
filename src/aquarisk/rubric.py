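"""Scoring rubric and score-sheet handling.

Every tertiary index is scored on a six-level scale — 0 negligible, 1 low,
2 slight, 3 medium, 4 high, 5 extremely high risk.  The rubric stores the
published criterion text for each index and level.  Two kinds of entry exist:
enumerated indices print one criterion sentence per level (a few of them only
for levels 1-5), while discussion indices print a single scoring instruction
and are graded against the shared discussion rules after expert deliberation.

Score sheets are delimited tables mirroring the published layout: one row per
tertiary index, one column per assessed subject (species).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from .errors import ConfigError
from .hierarchy import RiskHierarchy, load_model_config

#: the global assignment range shared by all tertiary indices
SCORE_LEVELS = tuple(range(6))

#: marker returned when a rubric does not print text for a defined-range level
LEVEL_NOT_DEFINED = "(level not defined for this index)"


@dataclass(frozen=True)
class RubricEntry:
    """Criterion texts for one tertiary index."""

    index_id: str
    levels: Mapping[int, str | None]
    discussion: bool
    source_table: str
    guidance: str | None = None

    @property
    def defined_levels(self) -> tuple[int, ...]:
        """Levels for which the rubric prints a criterion (or, for discussion
        indices, the full instructed range)."""
        if self.discussion:
            return tuple(sorted(self.levels))
        return tuple(sorted(k for k, v in self.levels.items() if v is not None))


class Rubric:
    """Machine-readable criterion texts for every tertiary index of a model."""

    def __init__(self, entries: Mapping[str, RubricEntry],
                 discussion_rules: Mapping[int, str] | None = None):
        self.entries = dict(entries)
        self.discussion_rules = dict(discussion_rules or {})

    @classmethod
    def from_config(cls, source=None) -> "Rubric":
        doc = load_model_config(source)
        raw = doc.get("rubric", {})
        entries = {}
        for index_id, rec in raw.items():
            entries[index_id] = RubricEntry(
                index_id=index_id,
                levels={int(k): v for k, v in rec.get("levels", {}).items()},
                discussion=bool(rec.get("discussion", False)),
                source_table=str(rec.get("source_table", "")),
                guidance=rec.get("guidance"),
            )
        return cls(entries, doc.get("discussion_rules"))

    def lookup(self, index_id: str, score: int) -> str:
        """Verbatim criterion text for (index, level).

        Discussion indices return their scoring instruction for every level;
        enumerated indices return the per-level sentence, or
        :data:`LEVEL_NOT_DEFINED` when the printed scale omits that level.
        """
        if index_id not in self.entries:
            raise KeyError(f"unknown tertiary index {index_id!r}")
        if score not in SCORE_LEVELS:
            raise ValueError(f"score {score!r} outside the 0-5 range")
        entry = self.entries[index_id]
        if entry.discussion:
            return entry.guidance or LEVEL_NOT_DEFINED
        text = entry.levels.get(score)
        return text if text is not None else LEVEL_NOT_DEFINED


def default_rubric() -> Rubric:
    return Rubric.from_config(None)


def rubric_lookup(r: Rubric, index_id: str, score: int) -> str:
    return r.lookup(index_id, score)


# ---------------------------------------------------------------------------
# score sheets


class ScoreSheet:
    """Per-subject integer scores for every tertiary index.

    ``subjects`` keeps column order; ``scores[subject][index_id]`` holds the
    raw value as read (validation, not construction, decides whether it is a
    legal integer in range).
    """

    def __init__(self, subjects, scores: Mapping[str, Mapping[str, object]],
                 index_order=None):
        self.subjects = list(subjects)
        self.scores = {s: dict(scores[s]) for s in self.subjects}
        if index_order is not None:
            self.index_order = list(index_order)
        elif self.subjects:
            self.index_order = list(self.scores[self.subjects[0]])
        else:
            self.index_order = []

    def __eq__(self, other):
        return (isinstance(other, ScoreSheet)
                and self.subjects == other.subjects
                and self.scores == other.scores)

    # -- I/O ----------------------------------------------------------------

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ScoreSheet":
        subjects = [str(c) for c in frame.columns]
        scores = {s: {} for s in subjects}
        for index_id, row in frame.iterrows():
            for s in subjects:
                scores[s][str(index_id)] = row[s]
        return cls(subjects, scores, index_order=[str(i) for i in frame.index])

    def to_frame(self) -> pd.DataFrame:
        data = {s: [self.scores[s].get(i) for i in self.index_order]
                for s in self.subjects}
        frame = pd.DataFrame(data, index=self.index_order)
        frame.index.name = "index"
        return frame

    @classmethod
    def read(cls, path: str | Path, *, delimiter: str | None = None) -> "ScoreSheet":
        """Read a delimited sheet (first column ``index``, one column per
        subject).  The dialect follows the extension (.tsv = tab) unless
        ``delimiter`` is given."""
        path = Path(path)
        if delimiter is None:
            delimiter = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
        frame = pd.read_csv(path, sep=delimiter, index_col=0)
        return cls.from_frame(frame)

    def write(self, path: str | Path, *, delimiter: str | None = None) -> None:
        path = Path(path)
        if delimiter is None:
            delimiter = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
        self.to_frame().to_csv(path, sep=delimiter)


# ---------------------------------------------------------------------------
# validation


@dataclass(frozen=True)
class Issue:
    subject: str
    index_id: str
    kind: str
    message: str


@dataclass(frozen=True)
class ValidationReport:
    issues: tuple[Issue, ...] = ()
    warnings: tuple[Issue, ...] = ()

    @property
    def valid(self) -> bool:
        return not self.issues

    def render(self) -> str:
        lines = []
        for issue in self.issues:
            lines.append(f"ERROR {issue.subject} / {issue.index_id}: {issue.message}")
        for issue in self.warnings:
            lines.append(f"WARNING {issue.subject} / {issue.index_id}: {issue.message}")
        return "\n".join(lines) if lines else "score sheet is valid"


def _as_int_score(value):
    """Return the value as an exact integer, or None if it is not one."""
    import numbers

    if isinstance(value, bool):
        return None
    if isinstance(value, numbers.Integral):
        return int(value)
    if isinstance(value, numbers.Real):
        return int(value) if float(value).is_integer() else None
    if isinstance(value, str):
        try:
            return _as_int_score(float(value))
        except ValueError:
            return None
    return None


def validate_score_sheet(sheet: ScoreSheet, hierarchy: RiskHierarchy,
                         rubric: Rubric | None = None,
                         strict: bool = False) -> ValidationReport:
    """Check a sheet against a model; reports problems, never raises.

    Errors: missing or unknown index ids, non-integer values, values outside
    0-5.  In strict mode, scores falling on levels the rubric does not print
    for that index are reported as warnings (the global assignment range
    always allows 0-5, so these are advisory only).
    """
    expected = set(hierarchy.tertiary_ids)
    issues: list[Issue] = []
    warns: list[Issue] = []
    for subject in sheet.subjects:
        present = sheet.scores[subject]
        for missing in sorted(expected - set(present)):
            issues.append(Issue(subject, missing, "missing",
                                "no score for this tertiary index"))
        for index_id, value in present.items():
            if index_id not in expected:
                issues.append(Issue(subject, index_id, "unknown",
                                    "index id not in the model hierarchy"))
                continue
            score = _as_int_score(value)
            if score is None:
                issues.append(Issue(subject, index_id, "non_integer",
                                    f"score {value!r} is not an integer"))
            elif not 0 <= score <= 5:
                issues.append(Issue(subject, index_id, "out_of_range",
                                    f"score {score} outside [0, 5]"))
            elif strict and rubric is not None and index_id in rubric.entries:
                if score not in rubric.entries[index_id].defined_levels:
                    warns.append(Issue(
                        subject, index_id, "undefined_level",
                        f"score {score} is in the global 0-5 range but the "
                        f"rubric for {index_id} defines levels "
                        f"{list(rubric.entries[index_id].defined_levels)}"))
    return ValidationReport(tuple(issues), tuple(warns))
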