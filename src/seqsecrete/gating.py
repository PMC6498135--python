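"""Background gating of raw well intensities.

Zero-cell wells serve as on-chip background controls: per protein and time
window the secretion threshold is the zero-cell mean plus three standard
deviations.  Intensities at or below threshold are set to 0 ("no secretion");
values above it keep their raw value and receive a positive call.  Signals
are reported on a log2(x+1) scale.  Only single-cell wells yield records.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chip_sim import WELL_KEY

__all__ = ["GatingError", "GatingModel", "fit_background", "gate_cells",
           "gate_chip", "panel_from_wells"]


class GatingError(ValueError):
    """Raised when background cannot be estimated."""


def panel_from_wells(wells: pd.DataFrame) -> list:
    """Protein columns of a well table (everything after the well key)."""
    return [c for c in wells.columns if c not in WELL_KEY]


@dataclass
class GatingModel:
    """Per-protein background statistics and thresholds for one time window.

    ``table`` is indexed by (region_block, protein) with columns
    ``mu0, sd0, threshold, n_zero_wells``; ``row_blocks`` is the number of
    equal row-bands the chip was split into for background pooling
    (1 = one global estimate, the default).
    """

    time_index: int
    table: pd.DataFrame
    row_blocks: int = 1
    n_rows: int = 0

    def block_of(self, rows: np.ndarray) -> np.ndarray:
        if self.row_blocks <= 1:
            return np.zeros(len(rows), dtype=int)
        band = int(np.ceil(self.n_rows / self.row_blocks))
        return np.minimum(rows // band, self.row_blocks - 1)

    def threshold(self, protein: str, block: int = 0) -> float:
        return float(self.table.loc[(block, protein), "threshold"])

    def to_frame(self) -> pd.DataFrame:
        out = self.table.reset_index()
        out.insert(0, "time_index", self.time_index)
        return out


def fit_background(wells: pd.DataFrame, time_index: int, *,
                   row_blocks: int = 1) -> GatingModel:
    """Estimate per-protein background from zero-cell wells at one window.

    mu0 and sd0 are the sample mean and sample SD (ddof=1) of the zero-cell
    intensities; threshold = mu0 + 3*sd0.  Requires at least two zero-cell
    wells per region block.
    """
    panel = panel_from_wells(wells)
    window = wells[wells["time_index"] == time_index]
    zero = window[window["cell_count"] == 0]
    n_rows = int(window["row"].max()) + 1 if len(window) else 0
    band = int(np.ceil(n_rows / row_blocks)) if row_blocks > 1 else max(n_rows, 1)

    records = []
    for block in range(max(row_blocks, 1)):
        if row_blocks > 1:
            in_block = zero[np.minimum(zero["row"] // band, row_blocks - 1) == block]
        else:
            in_block = zero
        if len(in_block) < 2:
            raise GatingError(
                f"window {time_index}: only {len(in_block)} zero-cell wells "
                f"in block {block}; need >= 2 for a background estimate")
        mu0 = in_block[panel].mean()
        sd0 = in_block[panel].std(ddof=1)
        for protein in panel:
            records.append({
                "region_block": block,
                "protein": protein,
                "mu0": float(mu0[protein]),
                "sd0": float(sd0[protein]),
                "threshold": float(mu0[protein] + 3.0 * sd0[protein]),
                "n_zero_wells": int(len(in_block)),
            })
    table = pd.DataFrame(records).set_index(["region_block", "protein"])
    return GatingModel(time_index=int(time_index), table=table,
                       row_blocks=max(row_blocks, 1), n_rows=n_rows)


def gate_cells(wells: pd.DataFrame, model: GatingModel) -> pd.DataFrame:
    """Gate the single-cell wells of the model's time window.

    Returns one row per 1-cell well with, per protein, ``<p>_raw`` (0 if at
    or below threshold), ``<p>_log2`` (= log2(raw_gated + 1)) and ``<p>_call``
    (1 iff above threshold).  Multi-cell and empty wells yield no record.
    """
    panel = panel_from_wells(wells)
    window = wells[wells["time_index"] == model.time_index]
    singles = window[window["cell_count"] == 1]
    out = singles[["chip_id", "time_index", "row", "col"]].reset_index(drop=True)
    blocks = model.block_of(singles["row"].to_numpy())
    for protein in panel:
        raw = singles[protein].to_numpy(dtype=float)
        if model.row_blocks > 1:
            per_block = np.array([model.threshold(protein, b)
                                  for b in range(model.row_blocks)])
            thr = per_block[blocks]
        else:
            thr = model.threshold(protein)
        gated = np.where(raw > thr, raw, 0.0)
        out[f"{protein}_raw"] = gated
        out[f"{protein}_log2"] = np.log2(gated + 1.0)
        out[f"{protein}_call"] = (gated > 0).astype(int)
    return out


def gate_chip(wells: pd.DataFrame, *, row_blocks: int = 1):
    """Fit backgrounds and gate every time window of a chip.

    Returns ``(gated, models)``: the concatenated gated single-cell records
    across windows and the per-window :class:`GatingModel` list.
    """
    windows = sorted(wells["time_index"].unique())
    models = [fit_background(wells, t, row_blocks=row_blocks) for t in windows]
    gated = pd.concat([gate_cells(wells, m) for m in models],
                      ignore_index=True)
    return gated, models
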