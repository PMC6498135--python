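"""Classification of per-protein secretion dynamics.

Each protein's binary call sequence over the time course falls into exactly
one of four classes:

* ``ALL_ON``  — secreted at every window;
* ``ON_OFF``  — active from the basal window, then permanently off
  (``1..10..0``);
* ``OFF_ON``  — initially silent, then permanently on (``0..01..1``);
* ``OTHER``   — never secreted, or an oscillatory sequence with two or more
  on/off transitions.

The four labels partition all binary sequences of any length T >= 2.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .tracking import complete_courses

__all__ = ["PatternLabel", "PatternError", "classify_pattern",
           "classify_courses", "summarize_patterns", "PatternSummary",
           "true_pattern_label"]


class PatternError(ValueError):
    """Raised for invalid call sequences."""


class PatternLabel(str, Enum):
    ALL_ON = "ALL_ON"
    ON_OFF = "ON_OFF"
    OFF_ON = "OFF_ON"
    OTHER = "OTHER"

    def __str__(self) -> str:  # CSV-friendly
        return self.value


def classify_pattern(calls) -> PatternLabel:
    """Classify one binary secretion sequence (length T >= 2)."""
    seq = np.asarray(calls)
    if seq.ndim != 1 or seq.size < 2:
        raise PatternError("calls must be a 1-D sequence of length >= 2")
    if not np.isin(seq, (0, 1)).all():
        raise PatternError(f"non-binary entry in calls: {list(seq)}")
    seq = seq.astype(int)
    transitions = int(np.count_nonzero(np.diff(seq)))
    if transitions == 0:
        return PatternLabel.ALL_ON if seq[0] == 1 else PatternLabel.OTHER
    if transitions == 1:
        return PatternLabel.ON_OFF if seq[0] == 1 else PatternLabel.OFF_ON
    return PatternLabel.OTHER


def true_pattern_label(mode: str) -> PatternLabel:
    """Map a generator mode name to the classifier label it must produce."""
    if mode in ("OTHER_SILENT", "OTHER_OSC"):
        return PatternLabel.OTHER
    return PatternLabel(mode)


def classify_courses(courses, panel) -> pd.DataFrame:
    """Per-cell, per-protein labels for complete courses.

    Returns a long DataFrame ``cell_id, protein, label``.
    """
    courses = complete_courses(courses)
    records = []
    for c in courses:
        for k, protein in enumerate(panel):
            records.append({
                "cell_id": c.cell_id,
                "protein": protein,
                "label": classify_pattern(c.calls[:, k]).value,
            })
    return pd.DataFrame(records)


@dataclass
class PatternSummary:
    """Counts and fractions of the four labels for one protein."""

    protein: str
    n_cells: int
    counts: dict
    fractions: dict

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "protein": self.protein,
            "label": list(self.counts),
            "count": list(self.counts.values()),
            "fraction": [self.fractions[l] for l in self.counts],
        })


def summarize_patterns(courses, protein: str, panel=None) -> PatternSummary:
    """Label counts/fractions of one protein over complete courses."""
    courses = complete_courses(courses)
    if not courses:
        raise PatternError("no complete courses to summarize")
    if panel is None:
        raise PatternError("panel must be given to locate the protein column")
    k = list(panel).index(protein)
    labels = [classify_pattern(c.calls[:, k]) for c in courses]
    counts = {lab.value: 0 for lab in PatternLabel}
    for lab in labels:
        counts[lab.value] += 1
    n = len(labels)
    fractions = {lab: cnt / n for lab, cnt in counts.items()}
    return PatternSummary(protein=protein, n_cells=n, counts=counts,
                          fractions=fractions)
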