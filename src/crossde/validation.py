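"""Third-species validation scoring.

Scores human (RTT brain) QPCR-style expression outcomes for genes
nominated by the rodent models. The rodent prediction for a
loss-of-function comparison is simply the rodent direction; each panel
record is labelled with exactly one of:

- ``predicted_direction``: detected in both groups, significant, human
  direction equals the rodent prediction;
- ``opposite_direction``: significant but the direction disagrees;
- ``undetectable_in_case``: detected in control brain but not in case;
- ``not_expressed``: detected in neither group;
- ``not_significant``: detected but no significant difference.

Label percentages are reported to the nearest integer; exact fractions are
kept in the machine-readable summary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import math

import pandas as pd

__all__ = [
    "ValidationRecord",
    "VALIDATION_LABELS",
    "RODENT_CATEGORIES",
    "expected_direction",
    "classify_validation_record",
    "summarize_validation",
    "records_to_frame",
    "frame_to_records",
]

VALIDATION_LABELS = (
    "predicted_direction",
    "opposite_direction",
    "undetectable_in_case",
    "not_significant",
    "not_expressed",
)
RODENT_CATEGORIES = ("common_rat_mouse", "unique_rat", "unique_mouse")


@dataclass(frozen=True)
class ValidationRecord:
    """One panel gene: rodent nomination plus the human measurement outcome."""

    gene: str
    rodent_category: str
    rodent_direction: str
    detected_case: bool
    detected_control: bool
    significant: bool
    human_direction: str = "none"  # up / down / none
    relative_expression: float | None = None

    def __post_init__(self) -> None:
        if self.rodent_category not in RODENT_CATEGORIES:
            raise ValueError(f"invalid rodent category {self.rodent_category!r}")
        if self.rodent_direction not in ("up", "down"):
            raise ValueError(f"invalid rodent direction {self.rodent_direction!r}")
        if self.human_direction not in ("up", "down", "none"):
            raise ValueError(f"invalid human direction {self.human_direction!r}")
        if self.significant and not (self.detected_case and self.detected_control):
            raise ValueError(
                f"{self.gene}: significant requires detection in both case and control"
            )
        if self.significant and self.human_direction == "none":
            raise ValueError(
                f"{self.gene}: a significant record must carry a human direction"
            )
        if not self.significant and self.human_direction != "none":
            raise ValueError(
                f"{self.gene}: human direction is only defined for significant records"
            )


def expected_direction(record: ValidationRecord) -> str:
    """Rodent-predicted human direction: the rodent direction itself."""
    return record.rodent_direction


def classify_validation_record(record: ValidationRecord) -> str:
    """Assign the single validation label for one panel record."""
    if not record.detected_case and record.detected_control:
        return "undetectable_in_case"
    if not record.detected_case and not record.detected_control:
        return "not_expressed"
    if record.significant:
        if record.human_direction == expected_direction(record):
            return "predicted_direction"
        return "opposite_direction"
    return "not_significant"


def summarize_validation(records: Iterable[ValidationRecord]) -> dict:
    """Per-label tallies, the altered-or-undetectable aggregate, and percentages.

    Percentages (of panel size) are rounded to the nearest integer for the
    report; exact fractions are included alongside.
    """
    counts = {label: 0 for label in VALIDATION_LABELS}
    n = 0
    for record in records:
        counts[classify_validation_record(record)] += 1
        n += 1
    altered_or_undetectable = (
        counts["predicted_direction"]
        + counts["opposite_direction"]
        + counts["undetectable_in_case"]
    )
    def pct(c: int) -> int:
        return int(round(100.0 * c / n)) if n else 0

    def frac(c: int) -> float:
        return c / n if n else 0.0

    return {
        "panel_size": n,
        "counts": counts,
        "altered_or_undetectable": altered_or_undetectable,
        "percent": {label: pct(c) for label, c in counts.items()},
        "percent_altered_or_undetectable": pct(altered_or_undetectable),
        "fraction": {label: frac(c) for label, c in counts.items()},
        "fraction_altered_or_undetectable": frac(altered_or_undetectable),
    }


_COLUMNS = [
    "gene",
    "rodent_category",
    "rodent_direction",
    "detected_case",
    "detected_control",
    "significant",
    "human_direction",
    "relative_expression",
]


def records_to_frame(records: Sequence[ValidationRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records], columns=_COLUMNS)


def frame_to_records(frame: pd.DataFrame) -> list[ValidationRecord]:
    records = []
    for row in frame.itertuples(index=False):
        rel = getattr(row, "relative_expression", None)
        if rel is not None and isinstance(rel, float) and math.isnan(rel):
            rel = None
        records.append(
            ValidationRecord(
                gene=row.gene,
                rodent_category=row.rodent_category,
                rodent_direction=row.rodent_direction,
                detected_case=bool(row.detected_case),
                detected_control=bool(row.detected_control),
                significant=bool(row.significant),
                human_direction=row.human_direction,
                relative_expression=rel,
            )
        )
    return records
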