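"""Synthetic microtrough-chip data generator.

Emulates the measurement process of a sequential, antibody-barcode,
single-cell secretion assay: Poisson loading of ~18,000 microtroughs, two
latent basal activation states, per-protein dynamic secretion modes,
basal-coupled stimulated activation, lognormal secretion signal on top of a
truncated-normal fluorescence background, and stochastic cell loss at every
antibody-slide exchange.  Returns both the observable per-window well table
and the latent ground truth, so downstream stages can be tested by parameter
recovery.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import truncnorm

from .config import MODES, SimulationConfig

__all__ = [
    "GroundTruth",
    "WellTableError",
    "simulate_chip",
    "write_well_table",
    "read_well_table",
    "well_key_columns",
    "oscillation_sequences",
]

#: Fixed leading columns of the well table, followed by one column per protein.
WELL_KEY = ["chip_id", "time_index", "row", "col", "cell_count"]

_ALL_ON = MODES.index("ALL_ON")
_ON_OFF = MODES.index("ON_OFF")
_OFF_ON = MODES.index("OFF_ON")
_SILENT = MODES.index("OTHER_SILENT")
_OSC = MODES.index("OTHER_OSC")


class WellTableError(ValueError):
    """Raised when a well-table file cannot be parsed."""


def well_key_columns():
    return list(WELL_KEY)


@dataclass
class GroundTruth:
    """Latent truth for every simulated cell.

    Attributes
    ----------
    cells
        One row per cell: ``cell_id, row, col, well_cell_count, state,
        basal_count, last_window`` where ``state`` is the latent basal state,
        ``basal_count`` the number of proteins active at window 0 and
        ``last_window`` the last window at which the cell was still present.
    modes
        Long table, one row per (cell, protein): realized dynamic ``mode``
        (after basal-coupled conversion) and the true on/off sequence
        ``calls`` as a string like ``"0011"``.
    """

    cells: pd.DataFrame
    modes: pd.DataFrame

    def write(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.cells.to_csv(directory / "truth_cells.csv", index=False)
        self.modes.to_csv(directory / "truth_modes.csv", index=False)

    @classmethod
    def read(cls, directory) -> "GroundTruth":
        directory = Path(directory)
        cells = pd.read_csv(directory / "truth_cells.csv")
        modes = pd.read_csv(directory / "truth_modes.csv",
                            dtype={"calls": str})
        return cls(cells=cells, modes=modes)


def oscillation_sequences(n_timepoints: int) -> np.ndarray:
    """All binary sequences of the given length with >= 2 transitions.

    These are the oscillatory realizations of the OTHER class; at T=4 there
    are 8 of them.
    """
    if n_timepoints > 16:
        raise ValueError("oscillation enumeration limited to T <= 16")
    seqs = []
    for bits in range(2 ** n_timepoints):
        seq = [(bits >> t) & 1 for t in range(n_timepoints)]
        transitions = sum(a != b for a, b in zip(seq, seq[1:]))
        if transitions >= 2:
            seqs.append(seq)
    return np.array(seqs, dtype=np.int8)


def simulate_chip(config: SimulationConfig, rng=None):
    """Simulate one chip over all time windows.

    Parameters
    ----------
    config
        Generator parameters; validated before use.
    rng
        Optional ``numpy.random.Generator``; defaults to
        ``default_rng(config.seed)``.  Identical config (and default rng)
        gives bit-identical output.

    Returns
    -------
    (wells, truth)
        ``wells`` is a DataFrame with one row per well per window
        (columns ``chip_id,time_index,row,col,cell_count,<panel...>``);
        ``truth`` is the :class:`GroundTruth`.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)

    K = len(config.panel)
    T = config.n_timepoints
    n_wells = config.n_wells

    n_cols = int(np.ceil(np.sqrt(n_wells)))
    well_rows = np.arange(n_wells) // n_cols
    well_cols = np.arange(n_wells) % n_cols

    # --- loading: Poisson occupancy -----------------------------------
    counts0 = rng.poisson(config.loading_rate, n_wells)
    well_of_cell = np.repeat(np.arange(n_wells), counts0)
    n_cells = well_of_cell.size

    # --- latent state and dynamic modes -------------------------------
    is_high = rng.random(n_cells) < config.state_mix
    mode = np.empty((n_cells, K), dtype=np.int8)
    for k, protein in enumerate(config.panel):
        for state_name, mask in (("low", ~is_high), ("high", is_high)):
            probs = np.array([config.mode_probs[protein][state_name].get(m, 0.0)
                              for m in MODES])
            if mask.any():
                mode[mask, k] = rng.choice(len(MODES), size=int(mask.sum()),
                                           p=probs)

    # Auxiliary draws are made for every (cell, protein) regardless of mode
    # so the stream layout depends only on the population size.
    off_time = rng.integers(1, T, size=(n_cells, K))   # ON_OFF: on for t < off_time
    on_time = rng.integers(1, T, size=(n_cells, K))    # OFF_ON: on for t >= on_time
    osc_seqs = oscillation_sequences(T)
    if len(osc_seqs) == 0 and (mode == _OSC).any():
        raise ValueError(
            f"OTHER_OSC mode requires T >= 3 (no sequence of length {T} "
            "has >= 2 transitions)")
    osc_choice = rng.integers(0, max(len(osc_seqs), 1), size=(n_cells, K))

    t_idx = np.arange(T)
    on = np.zeros((n_cells, K, T), dtype=np.int8)
    on[mode == _ALL_ON] = 1
    sel = mode == _ON_OFF
    on[sel] = (t_idx[None, :] < off_time[sel][:, None]).astype(np.int8)
    sel = mode == _OFF_ON
    on[sel] = (t_idx[None, :] >= on_time[sel][:, None]).astype(np.int8)
    sel = mode == _OSC
    if sel.any():
        on[sel] = osc_seqs[osc_choice[sel]]

    # --- basal-coupled stimulated activation ---------------------------
    # A cell already secreting many proteins at the basal window is more
    # likely to switch on additional (silent-mode) proteins after
    # stimulation; implemented as a logistic conversion of OTHER_SILENT
    # proteins to a late-onset off->on realization.
    basal_count = on[:, :, 0].sum(axis=1)
    if config.basal_coupling > 0:
        p_convert = expit(config.coupling_intercept
                          + config.basal_coupling * basal_count)
        conv_u = rng.random((n_cells, K))
        conv_onset = rng.integers(1, T, size=(n_cells, K))
        convert = (mode == _SILENT) & (conv_u < p_convert[:, None])
        mode[convert] = _OFF_ON
        on[convert] = (t_idx[None, :] >= conv_onset[convert][:, None]).astype(np.int8)

    # --- retention across slide exchanges ------------------------------
    present = np.ones((n_cells, T), dtype=bool)
    if T > 1:
        survive = rng.random((n_cells, T - 1)) < config.retention_p
        present[:, 1:] = np.cumprod(survive, axis=1).astype(bool)
    last_window = present.sum(axis=1) - 1

    # --- fluorescence: background + secreted signal ---------------------
    mu_bg = np.array([config.background_mean[p] for p in config.panel])
    sd_bg = np.array([config.background_sd[p] for p in config.panel])
    logmean = np.array([config.signal_logmean[p] for p in config.panel])
    logsd = np.array([config.signal_logsd[p] for p in config.panel])

    # Truncated-normal background (>= 0) per well, protein, window.
    with np.errstate(divide="ignore"):
        a = np.where(sd_bg > 0, -mu_bg / np.where(sd_bg > 0, sd_bg, 1.0), 0.0)
    bg = np.empty((n_wells, K, T))
    for k in range(K):
        if sd_bg[k] > 0:
            bg[:, k, :] = truncnorm.rvs(a[k], np.inf, loc=mu_bg[k],
                                        scale=sd_bg[k], size=(n_wells, T),
                                        random_state=rng)
        else:
            bg[:, k, :] = mu_bg[k]

    signal = rng.lognormal(mean=logmean[None, :, None],
                           sigma=logsd[None, :, None],
                           size=(n_cells, K, T))
    secreting = on.astype(bool) & present[:, None, :]
    intensity = bg.copy()
    np.add.at(intensity, well_of_cell, signal * secreting)

    cell_count = np.zeros((n_wells, T), dtype=np.int64)
    for t in range(T):
        cell_count[:, t] = np.bincount(well_of_cell,
                                       weights=present[:, t],
                                       minlength=n_wells).astype(np.int64)

    frames = []
    for t in range(T):
        frame = pd.DataFrame({
            "chip_id": config.chip_id,
            "time_index": t,
            "row": well_rows,
            "col": well_cols,
            "cell_count": cell_count[:, t],
        })
        for k, protein in enumerate(config.panel):
            frame[protein] = intensity[:, k, t]
        frames.append(frame)
    wells = pd.concat(frames, ignore_index=True)

    cell_ids = np.array([f"cell{idx:06d}" for idx in range(n_cells)])
    cells = pd.DataFrame({
        "cell_id": cell_ids,
        "row": well_rows[well_of_cell],
        "col": well_cols[well_of_cell],
        "well_cell_count": counts0[well_of_cell],
        "state": np.where(is_high, "high", "low"),
        "basal_count": basal_count,
        "last_window": last_window,
    })
    calls = on.astype(str)
    modes_long = pd.DataFrame({
        "cell_id": np.repeat(cell_ids, K),
        "protein": np.tile(np.array(config.panel), n_cells),
        "mode": np.array(MODES, dtype=object)[mode.ravel()],
        "calls": ["".join(calls[i, k]) for i in range(n_cells)
                  for k in range(K)],
    })
    truth = GroundTruth(cells=cells, modes=modes_long)
    return wells, truth


# ---------------------------------------------------------------------------
# Well-table round trip
# ---------------------------------------------------------------------------

def write_well_table(wells: pd.DataFrame, path) -> None:
    """Write the per-window well table as UTF-8 CSV (round-trippable)."""
    missing = [c for c in WELL_KEY if c not in wells.columns]
    if missing:
        raise WellTableError(f"well table missing columns {missing}")
    wells.to_csv(path, index=False)


def read_well_table(path) -> pd.DataFrame:
    """Read a well-table CSV, validating schema and well-key uniqueness.

    Raises :class:`WellTableError` naming the first offending line for
    malformed headers, negative intensities or duplicate
    (chip, time, row, col) keys.
    """
    try:
        wells = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise WellTableError(f"{path}: empty file, expected a header") from exc
    header = list(wells.columns)
    if header[: len(WELL_KEY)] != WELL_KEY:
        raise WellTableError(
            f"{path}: line 1: malformed header {header[:len(WELL_KEY)]}, "
            f"expected leading columns {WELL_KEY}")
    panel = header[len(WELL_KEY):]
    if not panel:
        raise WellTableError(f"{path}: line 1: no protein columns in header")
    if wells.empty:
        return wells
    for column in ("time_index", "row", "col", "cell_count"):
        wells[column] = wells[column].astype(np.int64)
    if (wells["cell_count"] < 0).any():
        line = int(wells.index[wells["cell_count"] < 0][0]) + 2
        raise WellTableError(f"{path}: line {line}: negative cell_count")
    neg = (wells[panel] < 0).any(axis=1)
    if neg.any():
        line = int(wells.index[neg][0]) + 2
        raise WellTableError(f"{path}: line {line}: negative intensity")
    dup = wells.duplicated(subset=["chip_id", "time_index", "row", "col"])
    if dup.any():
        line = int(wells.index[dup][0]) + 2
        raise WellTableError(
            f"{path}: line {line}: duplicate (chip_id, time_index, row, col) key")
    return wells
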