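"""Same-cell time-course assembly.

Adherent cells stay in their microtrough, so identity across antibody-slide
exchanges is given by well coordinates alone.  Gated single-cell records
sharing (chip, row, col) across windows form one candidate course; a course
is *complete* iff the well held exactly one cell at every window.  Wells that
are empty or multi-cell at a window contribute no record there, so a course
missing any window (cell lost, or a detached neighbour drifted in) is kept
but flagged incomplete; downstream population analyses use complete courses
only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CellTimeCourse", "TrackingError", "link_time_courses",
           "complete_courses", "retention_summary", "courses_to_frame",
           "frame_to_courses", "panel_from_gated"]


class TrackingError(ValueError):
    """Raised for inconsistent inputs to course assembly."""


def panel_from_gated(gated: pd.DataFrame) -> list:
    return [c[:-5] for c in gated.columns if c.endswith("_log2")]


@dataclass
class CellTimeCourse:
    """One candidate single cell tracked across all time windows.

    ``log2`` and ``calls`` are (T, K) arrays (window x protein); windows where
    the well was not single-occupied are zero-filled and masked out via
    ``present``.  ``complete`` means present at every window.
    """

    cell_id: str
    chip_id: str
    row: int
    col: int
    log2: np.ndarray
    calls: np.ndarray
    present: np.ndarray
    complete: bool = field(init=False)

    def __post_init__(self):
        self.log2 = np.asarray(self.log2, dtype=float)
        self.calls = np.asarray(self.calls, dtype=int)
        self.present = np.asarray(self.present, dtype=bool)
        if self.log2.shape != self.calls.shape or self.log2.ndim != 2:
            raise TrackingError("log2 and calls must be equal-shape (T, K)")
        if self.present.shape[0] != self.log2.shape[0]:
            raise TrackingError("present mask length must equal T")
        self.complete = bool(self.present.all())

    @property
    def n_timepoints(self) -> int:
        return self.log2.shape[0]

    @property
    def n_proteins(self) -> int:
        return self.log2.shape[1]


def link_time_courses(gated: pd.DataFrame, *, n_timepoints: int | None = None
                      ) -> list:
    """Assemble time courses from gated single-cell records of one chip.

    ``gated`` is the output of :func:`seqsecrete.gating.gate_chip` (or the
    per-window records concatenated).  All windows must share one panel; the
    chip must be unique.
    """
    if gated.empty:
        return []
    chips = gated["chip_id"].unique()
    if len(chips) != 1:
        raise TrackingError(f"expected one chip, found {list(chips)}")
    chip = chips[0]
    panel = panel_from_gated(gated)
    if not panel:
        raise TrackingError("no <protein>_log2 columns found")
    T = int(n_timepoints if n_timepoints is not None
            else gated["time_index"].max() + 1)
    K = len(panel)

    log2_cols = [f"{p}_log2" for p in panel]
    call_cols = [f"{p}_call" for p in panel]
    missing = [c for c in log2_cols + call_cols if c not in gated.columns]
    if missing:
        raise TrackingError(f"inconsistent panel: missing columns {missing}")

    courses = []
    for (row, col), grp in gated.groupby(["row", "col"], sort=True):
        times = grp["time_index"].to_numpy()
        if len(np.unique(times)) != len(times):
            raise TrackingError(
                f"duplicate window records for well ({row}, {col})")
        log2 = np.zeros((T, K))
        calls = np.zeros((T, K), dtype=int)
        present = np.zeros(T, dtype=bool)
        log2[times] = grp[log2_cols].to_numpy()
        calls[times] = grp[call_cols].to_numpy()
        present[times] = True
        courses.append(CellTimeCourse(
            cell_id=f"{chip}_r{row:03d}c{col:03d}", chip_id=chip,
            row=int(row), col=int(col),
            log2=log2, calls=calls, present=present))
    return courses


def complete_courses(courses) -> list:
    return [c for c in courses if c.complete]


def retention_summary(courses) -> pd.DataFrame:
    """Per-exchange retention: of the cells present at window e-1, the
    fraction still present at window e (exchanges e = 1..T-1)."""
    if not courses:
        raise TrackingError("retention_summary needs at least one course")
    present = np.array([c.present for c in courses])
    T = present.shape[1]
    records = []
    for e in range(1, T):
        before = present[:, e - 1]
        after = before & present[:, e]
        n_before = int(before.sum())
        n_after = int(after.sum())
        records.append({
            "exchange": e,
            "n_before": n_before,
            "n_after": n_after,
            "fraction": (n_after / n_before) if n_before else np.nan,
        })
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# Wide-format (CSV) round trip used by the CLI
# ---------------------------------------------------------------------------

def courses_to_frame(courses, panel) -> pd.DataFrame:
    """One row per course: ids, per-window presence, and window-major
    ``<protein>_t<t>_log2`` / ``_call`` columns."""
    rows = []
    for c in courses:
        T = c.n_timepoints
        rec = {"cell_id": c.cell_id, "chip_id": c.chip_id,
               "row": c.row, "col": c.col, "complete": int(c.complete)}
        for t in range(T):
            rec[f"present_t{t}"] = int(c.present[t])
        for t in range(T):
            for k, p in enumerate(panel):
                rec[f"{p}_t{t}_log2"] = c.log2[t, k]
                rec[f"{p}_t{t}_call"] = c.calls[t, k]
        rows.append(rec)
    return pd.DataFrame(rows)


def frame_to_courses(frame: pd.DataFrame, panel) -> list:
    T = len([c for c in frame.columns if c.startswith("present_t")])
    courses = []
    for _, rec in frame.iterrows():
        log2 = np.array([[rec[f"{p}_t{t}_log2"] for p in panel]
                         for t in range(T)])
        calls = np.array([[rec[f"{p}_t{t}_call"] for p in panel]
                          for t in range(T)])
        present = np.array([rec[f"present_t{t}"] for t in range(T)], dtype=bool)
        courses.append(CellTimeCourse(
            cell_id=rec["cell_id"], chip_id=rec["chip_id"],
            row=int(rec["row"]), col=int(rec["col"]),
            log2=log2, calls=calls, present=present))
    return courses
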