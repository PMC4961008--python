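"""Literature evidence table for the faster-growth prediction.

Fourteen published comparisons of above-ground growth in small shrubs
versus small trees, graded ``++`` (good support), ``+`` (support), ``+/-``
(inconclusive) or ``-`` (against).  The packaged table ships with the
library; :func:`tally_support` produces the vote-count summary.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Union

__all__ = ["StudyRecord", "VALID_GRADES", "load_studies", "tally_support"]

VALID_GRADES = ("++", "+", "+/-", "-")

CATEGORIES = (
    "disturbed_resprouting",
    "disturbed_seeders",
    "lab_experiment",
    "field_experiment",
    "natural_colonization",
    "other",
)


@dataclass(frozen=True)
class StudyRecord:
    """One reviewed study comparing shrub and tree growth."""

    category: str
    region: str
    habitat: str
    comparison: str
    grade: str
    reference_key: str
    footnotes: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.grade not in VALID_GRADES:
            raise ValueError(
                f"invalid grade {self.grade!r} for {self.reference_key!r}; "
                f"expected one of {VALID_GRADES}"
            )
        if self.category not in CATEGORIES:
            raise ValueError(
                f"invalid category {self.category!r} for {self.reference_key!r}"
            )


def _normalise_grade(raw: str) -> str:
    # accept the typographic minus sign used in print
    return raw.strip().replace("−", "-").replace("–", "-")


def load_studies(path: Optional[Union[str, Path]] = None) -> List[StudyRecord]:
    """Read study records from a TSV file (packaged table when ``path`` is None).

    Raises ``ValueError`` naming the offending row when a grade symbol is
    not one of ``++ + +/- -``.
    """
    if path is None:
        source = resources.files("multistem.data") / "hypothesis1_studies.tsv"
        text = source.read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    lines = text.splitlines()
    if not lines or not lines[0].strip():
        return []
    reader = csv.DictReader(lines, delimiter="\t")
    records: List[StudyRecord] = []
    for i, row in enumerate(reader, start=2):
        try:
            record = StudyRecord(
                category=row["category"].strip(),
                region=row["region"].strip(),
                habitat=row["habitat"].strip(),
                comparison=row["comparison"].strip(),
                grade=_normalise_grade(row["grade"]),
                reference_key=row["reference_key"].strip(),
                footnotes=[
                    f.strip()
                    for f in (row.get("footnotes") or "").split(",")
                    if f.strip()
                ],
            )
        except ValueError as exc:
            raise ValueError(f"row {i}: {exc}") from exc
        records.append(record)
    return records


def tally_support(records: Iterable[StudyRecord]) -> Dict[str, int]:
    """Vote-count summary of the evidence grades.

    ``supportive_total`` counts ``++`` and ``+`` studies together;
    the four grade counts always sum to ``n_studies``.
    """
    counts = {g: 0 for g in VALID_GRADES}
    n = 0
    for record in records:
        counts[record.grade] += 1
        n += 1
    return {
        "good_support": counts["++"],
        "support": counts["+"],
        "inconclusive": counts["+/-"],
        "negative": counts["-"],
        "supportive_total": counts["++"] + counts["+"],
        "n_studies": n,
    }
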