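"""The embedded five-species case study and seeded synthetic score sheets.

The case study covers five aquatic animals commonly introduced into southern
China — *Pterygoplichthys pardalis* (fish), *Macrobrachium rosenbergii*
(crustacean), *Crassostrea gigas* (shellfish), *Trachemys scripta elegans*
(reptile) and *Ambystoma mexicanum* (amphibian) — with their published
tertiary scores and the published aggregate values and grades, which serve
as the package's primary regression fixture.

Known erratum: the published R4 for *Pterygoplichthys pardalis* (3.8843) is
inconsistent with the same table's P11 = 3.7002 and P12 = 4.6164, whose
weighted sum 0.8·P11 + 0.2·P12 = 3.8834; the printed value appears to be a
digit transposition.  Expected values are stored verbatim as printed;
:data:`KNOWN_ERRATA` flags the cell.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import numpy as np
import yaml

from .hierarchy import RiskHierarchy, default_hierarchy
from .rubric import ScoreSheet

_DATA = resources.files("aquarisk") / "data"
SCORES_RESOURCE = _DATA / "case_study_scores.tsv"
EXPECTED_RESOURCE = _DATA / "case_study_expected.yaml"

#: (index id, subject) cells of the published results table whose printed
#: value contradicts the table's own intermediate values (see module docs)
KNOWN_ERRATA: frozenset[tuple[str, str]] = frozenset(
    {("R4", "Pterygoplichthys pardalis")}
)


@dataclass(frozen=True)
class CaseStudy:
    """The published worked example: scores, expected aggregates, grades."""

    score_sheet: ScoreSheet
    #: per node id, per subject: printed value string (verbatim, 4 decimals)
    expected_values: Mapping[str, Mapping[str, str]]
    expected_grades: Mapping[str, str]
    citation: Mapping[str, str]

    @property
    def subjects(self) -> list[str]:
        return list(self.score_sheet.subjects)

    def expected_value(self, node_id: str, subject: str) -> float:
        return float(self.expected_values[node_id][subject])


def builtin_case_study() -> CaseStudy:
    """Load the embedded five-species case study."""
    import io

    sheet_text = SCORES_RESOURCE.read_text()
    import pandas as pd

    frame = pd.read_csv(io.StringIO(sheet_text), sep="\t", index_col=0)
    sheet = ScoreSheet.from_frame(frame)
    doc = yaml.safe_load(EXPECTED_RESOURCE.read_text())
    subjects = doc["subjects"]
    expected = {
        node_id: dict(zip(subjects, printed))
        for node_id, printed in doc["expected_values"].items()
    }
    return CaseStudy(
        score_sheet=sheet,
        expected_values=expected,
        expected_grades=dict(doc["expected_grades"]),
        citation=dict(doc.get("source", {})),
    )


def random_score_sheet(seed: int, n_subjects: int,
                       hierarchy: RiskHierarchy | None = None) -> ScoreSheet:
    """Seeded sheet of uniform integer scores in [0, 5] for property tests.

    The same seed always yields the same sheet, and the result always passes
    validation against the given hierarchy.
    """
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    hierarchy = hierarchy or default_hierarchy()
    rng = np.random.default_rng(seed)
    tertiary = hierarchy.tertiary_ids
    subjects = [f"subject_{i + 1:02d}" for i in range(n_subjects)]
    draws = rng.integers(0, 6, size=(len(tertiary), n_subjects))
    scores = {
        s: {tid: int(draws[i, j]) for i, tid in enumerate(tertiary)}
        for j, s in enumerate(subjects)
    }
    return ScoreSheet(subjects, scores, index_order=tertiary)
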