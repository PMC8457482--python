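"""Conflict-record tallies: complaint types cross-tabulated by severity.

Wildlife agencies log each reported interaction with a complaint type
(garbage break-in, residential damage, ...) and a severity class from 1 (most
severe) to 4 (least). The summary here reproduces the standard descriptive
table: counts per type, whole-percent shares of the grand total, the
type-by-severity cross-tab, and the shares of the severity groups
(class 1 / classes 2-3 / class 4). Percentages are rounded half away from
zero to whole percent, the convention of agency reporting.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

import numpy as np
import pandas as pd

__all__ = ["ConflictRecord", "ConflictSummary", "summarize_conflicts",
           "DEFAULT_COMPLAINT_TYPES"]

#: open registry of complaint types; extend via the ``registry`` argument
DEFAULT_COMPLAINT_TYPES = (
    "garbage break-in",
    "residential damage",
    "livestock injury",
    "illegal feeding",
    "campground issue",
    "contact with humans",
    "agricultural damage",
    "vehicle collision",
    "sighting",
    "other",
)

SEVERITY_CLASSES = (1, 2, 3, 4)


@dataclass(frozen=True)
class ConflictRecord:
    """One reported human-bear interaction."""

    id: int
    complaint_type: str
    severity: int
    x: float | None = None  # coordinates may be withheld
    y: float | None = None
    date: date | None = None

    def __post_init__(self) -> None:
        if self.severity not in SEVERITY_CLASSES:
            raise ValueError("severity must be a class in 1..4 (1 most severe)")


@dataclass
class ConflictSummary:
    """Tallies of a conflict-record table."""

    n_records: int
    by_type: pd.DataFrame           # count + percent per complaint type
    type_by_severity: pd.DataFrame  # cross-tab counts
    severity_shares: dict[str, int]  # whole-percent shares of severity groups


def _round_half_away(x: np.ndarray | float) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return (np.sign(x) * np.floor(np.abs(x) + 0.5)).astype(int)


def summarize_conflicts(records: pd.DataFrame,
                        registry: tuple[str, ...] = DEFAULT_COMPLAINT_TYPES
                        ) -> ConflictSummary:
    """Tally a conflict-record table (columns ``complaint_type``, ``severity``).

    Raises on an empty table, an unregistered complaint type, or a severity
    outside 1-4. The grand total of the cross-tab always equals the input
    record count.
    """
    if len(records) == 0:
        raise ValueError("no conflict records to summarize")
    bad_type = set(records["complaint_type"]) - set(registry)
    if bad_type:
        raise ValueError(f"unregistered complaint types: {sorted(bad_type)}")
    sev = records["severity"].astype(int)
    if not sev.isin(SEVERITY_CLASSES).all():
        raise ValueError("severity classes must lie in 1..4")

    n = len(records)
    counts = records["complaint_type"].value_counts()
    by_type = pd.DataFrame({
        "count": counts,
        "percent": _round_half_away(100.0 * counts / n),
    }).rename_axis("complaint_type").reset_index()

    cross = pd.crosstab(records["complaint_type"], sev)
    cross = cross.reindex(columns=SEVERITY_CLASSES, fill_value=0)

    shares = {
        "class_1": int(_round_half_away(100.0 * (sev == 1).sum() / n)),
        "class_2_3": int(_round_half_away(100.0 * sev.isin((2, 3)).sum() / n)),
        "class_4": int(_round_half_away(100.0 * (sev == 4).sum() / n)),
    }
    return ConflictSummary(n_records=n, by_type=by_type,
                           type_by_severity=cross, severity_shares=shares)
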