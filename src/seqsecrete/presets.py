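"""Study-scale preset configurations and cohort builders.

These presets encode the measurement conditions the analysis is validated
under: one 18,000-well chip loaded at lambda = 0.5 cells/well, 10 proteins
over 4 windows, and — for population-level analyses — a cohort of 1,752
complete single-cell time courses (the study-scale dataset size).  Complete
courses at full retention are subsampled deterministically (row-major well
order) to that size.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import gating, tracking
from .chip_sim import simulate_chip
from .config import DEFAULT_PANEL, MODES, STATES, SimulationConfig

__all__ = ["COHORT_SIZE", "default_config", "pattern_validation_config",
           "coupling_validation_config", "retention_validation_config",
           "build_cohort", "true_states_for_courses",
           "true_modes_for_courses"]

#: Number of complete single-cell time courses in the reference cohort.
COHORT_SIZE = 1752


def default_config(seed: int = 0) -> SimulationConfig:
    """The generator's default chip: all parameters at their study values."""
    return SimulationConfig(seed=seed)


def _set_modes(config: SimulationConfig, protein: str, **probs) -> None:
    """Overwrite one protein's mode table (both states) with the given
    probabilities; unassigned mass goes to OTHER_SILENT."""
    assigned = sum(probs.values())
    if assigned > 1 + 1e-9:
        raise ValueError("mode probabilities exceed 1")
    vec = {m: float(probs.get(m, 0.0)) for m in MODES}
    vec["OTHER_SILENT"] += 1.0 - assigned
    config.mode_probs[protein] = {s: dict(vec) for s in STATES}


def pattern_validation_config(seed: int = 0) -> SimulationConfig:
    """Cohort config with the study's printed stable-pattern fractions.

    CCL2 all-on 71.1% / on-off 7.9%; TNF on-off 13.4% / off-on 4.7%;
    IL-6 off-on 7.1% / on-off 0.6%; remainder silent.  Retention is 1 and
    the basal coupling disabled so realized per-protein modes equal the
    drawn modes — the condition under which classifier recovery of the
    prescribed fractions is meaningful.
    """
    config = SimulationConfig(seed=seed, retention_p=1.0, basal_coupling=0.0)
    _set_modes(config, "CCL2", ALL_ON=0.711, ON_OFF=0.079)
    _set_modes(config, "TNF", ON_OFF=0.134, OFF_ON=0.047)
    _set_modes(config, "IL6", OFF_ON=0.071, ON_OFF=0.006)
    return config


def retention_validation_config(seed: int = 0) -> SimulationConfig:
    """Two-window chip for measuring per-exchange retention.

    Oscillatory realizations need at least three windows, so their default
    probability mass folds into the silent mode here; all other parameters
    keep their defaults (18,000 wells, retention 0.56).
    """
    config = SimulationConfig(seed=seed, n_timepoints=2)
    for protein in config.panel:
        for s in STATES:
            vec = config.mode_probs[protein][s]
            vec["OTHER_SILENT"] += vec["OTHER_OSC"]
            vec["OTHER_OSC"] = 0.0
    return config


def coupling_validation_config(seed: int = 0) -> SimulationConfig:
    """Cohort config for basal-coupling and two-state analyses: generator
    defaults (coupling slope 0.5) at full retention."""
    return SimulationConfig(seed=seed, retention_p=1.0)


def build_cohort(config: SimulationConfig, n_cells: int = COHORT_SIZE):
    """Simulate, gate and track one chip; return a complete-course cohort.

    Returns ``(courses, truth, panel)`` where ``courses`` are the first
    ``n_cells`` complete time courses in row-major well order.  Raises if the
    chip yields fewer complete courses than requested.
    """
    wells, truth = simulate_chip(config)
    gated, _ = gating.gate_chip(wells)
    courses = tracking.complete_courses(tracking.link_time_courses(gated))
    if len(courses) < n_cells:
        raise ValueError(
            f"chip yielded {len(courses)} complete courses, need {n_cells}; "
            "increase n_wells or retention_p")
    courses.sort(key=lambda c: (c.row, c.col))
    return courses[:n_cells], truth, list(config.panel)


def true_states_for_courses(courses, truth) -> pd.Series:
    """Latent basal-state labels ('low'/'high') for tracked courses.

    Matches courses to ground-truth cells by well coordinates; only wells
    that truly held a single cell can be matched unambiguously, so courses
    from multi-cell wells (rare) get NaN.
    """
    cells = truth.cells
    singles = cells[cells["well_cell_count"] == 1].set_index(["row", "col"])
    out = {}
    for c in courses:
        key = (c.row, c.col)
        out[c.cell_id] = (singles.loc[key, "state"]
                          if key in singles.index else np.nan)
    return pd.Series(out, name="state")


def true_modes_for_courses(courses, truth) -> pd.DataFrame:
    """Realized ground-truth modes (long format) for tracked courses."""
    cells = truth.cells
    singles = cells[cells["well_cell_count"] == 1]
    coords = {(c.row, c.col): c.cell_id for c in courses}
    keep = singles[[coords.get((r, co)) is not None
                    for r, co in zip(singles["row"], singles["col"])]]
    merged = keep.merge(truth.modes, on="cell_id")
    merged = merged.assign(
        course_id=[coords[(r, co)] for r, co in
                   zip(merged["row"], merged["col"])])
    return merged[["course_id", "protein", "mode", "calls"]]
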