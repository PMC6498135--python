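"""Simulation configuration for the microtrough-chip generator.

The generator emulates a sequential single-cell secretion assay: an array of
sub-nanoliter microtroughs is loaded with cells at random (Poisson statistics),
each captured cell secretes a 10-plex protein panel over several 2-hour
windows (one antibody slide per window), and every slide exchange loses a
fraction of cells.  Cells belong to one of two latent activation states
("low" / "high" basal activity); each protein of each cell follows one of
five dynamic modes, and a cell's stimulated activation probability is coupled
to its basal polyfunctionality.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import yaml

__all__ = [
    "ConfigError",
    "SimulationConfig",
    "DEFAULT_PANEL",
    "MODES",
    "STATES",
    "default_mode_probs",
    "uniform_mode_probs",
    "config_from_yaml",
    "config_to_yaml",
]

class ConfigError(ValueError):
    """Raised for invalid simulation parameters."""


#: Secreted-protein panel of the LPS-stimulated macrophage assay.  The first
#: six are the proteins discussed individually in the study; the remaining
#: four complete a representative 10-plex innate-immune secretome panel.
DEFAULT_PANEL = (
    "CXCL8", "IL6", "CCL2", "TNF", "IL10",
    "CCL4", "MIF", "CCL3", "IL1B", "GMCSF",
)

#: Dynamic modes of one protein in one cell.  The classifier's OTHER class
#: lumps the last two (silent and oscillatory secretion).
MODES = ("ALL_ON", "ON_OFF", "OFF_ON", "OTHER_SILENT", "OTHER_OSC")

#: Latent basal activation states.
STATES = ("low", "high")


def _mode_table(all_on, on_off, off_on, silent, osc):
    probs = {"ALL_ON": all_on, "ON_OFF": on_off, "OFF_ON": off_on,
             "OTHER_SILENT": silent, "OTHER_OSC": osc}
    total = sum(probs.values())
    if abs(total - 1.0) > 1e-9:
        raise ConfigError(f"mode probabilities sum to {total}, expected 1")
    return probs


# Per-protein, per-state dynamic-mode probabilities.  The 0.65/0.35 low/high
# state mixture reproduces the study's printed population pattern fractions
# for CCL2 (all-on 71.1%, on-off 7.9%), TNF (on-off 13.4%, off-on 4.7%) and
# IL-6 (off-on 7.1%, on-off 0.6%), and gives a mean basal polyfunctionality
# of ~2.3 proteins per cell.  The "high" state is more active both at the
# basal window and after stimulation.
_DEFAULT_MODE_PROBS = {
    #           (all_on, on_off, off_on, silent, osc)
    "CXCL8": {"low": (0.02, 0.02, 0.40, 0.53, 0.03),
              "high": (0.60, 0.05, 0.35, 0.00, 0.00)},
    "IL6":   {"low": (0.01, 0.005, 0.03, 0.855, 0.10),
              "high": (0.20, 0.01, 0.15, 0.54, 0.10)},
    "CCL2":  {"low": (0.61, 0.10, 0.05, 0.19, 0.05),
              "high": (0.90, 0.04, 0.04, 0.00, 0.02)},
    "TNF":   {"low": (0.02, 0.10, 0.03, 0.75, 0.10),
              "high": (0.10, 0.20, 0.08, 0.52, 0.10)},
    "IL10":  {"low": (0.00, 0.01, 0.05, 0.91, 0.03),
              "high": (0.15, 0.02, 0.55, 0.25, 0.03)},
    "CCL4":  {"low": (0.04, 0.03, 0.15, 0.75, 0.03),
              "high": (0.60, 0.05, 0.33, 0.00, 0.02)},
    "MIF":   {"low": (0.10, 0.05, 0.08, 0.74, 0.03),
              "high": (0.70, 0.08, 0.20, 0.00, 0.02)},
    "CCL3":  {"low": (0.03, 0.03, 0.15, 0.76, 0.03),
              "high": (0.50, 0.05, 0.40, 0.03, 0.02)},
    "IL1B":  {"low": (0.01, 0.02, 0.08, 0.86, 0.03),
              "high": (0.25, 0.03, 0.55, 0.15, 0.02)},
    "GMCSF": {"low": (0.00, 0.01, 0.04, 0.92, 0.03),
              "high": (0.12, 0.02, 0.45, 0.39, 0.02)},
}


def default_mode_probs(panel=DEFAULT_PANEL):
    """Default per-protein, per-state mode-probability tables.

    Proteins outside the default panel get a generic moderately-active table.
    """
    generic = {"low": (0.05, 0.05, 0.20, 0.60, 0.10),
               "high": (0.30, 0.05, 0.40, 0.15, 0.10)}
    out = {}
    for protein in panel:
        raw = _DEFAULT_MODE_PROBS.get(protein, generic)
        out[protein] = {s: _mode_table(*raw[s]) for s in STATES}
    return out


def uniform_mode_probs(panel, probs):
    """Same mode-probability vector for every protein and both states.

    ``probs`` maps mode name -> probability (missing modes get 0).
    """
    vec = {m: float(probs.get(m, 0.0)) for m in MODES}
    total = sum(vec.values())
    if abs(total - 1.0) > 1e-9:
        raise ConfigError(f"mode probabilities sum to {total}, expected 1")
    return {protein: {s: dict(vec) for s in STATES} for protein in panel}


def _as_per_protein(value, panel, name) -> dict:
    """Broadcast a scalar to a per-protein mapping, or validate a mapping."""
    if isinstance(value, Mapping):
        missing = [p for p in panel if p not in value]
        if missing:
            raise ConfigError(f"{name} missing entries for {missing}")
        return {p: float(value[p]) for p in panel}
    return {p: float(value) for p in panel}


@dataclass
class SimulationConfig:
    """All generator parameters for one chip run.

    Parameters
    ----------
    n_wells
        Number of microtroughs on the chip (default 18,000).
    loading_rate
        Poisson mean of cells per well; 0.5 puts ~30.3% of wells at exactly
        one cell.
    n_timepoints
        Number of 2-h measurement windows, window 0 being the unstimulated
        basal state.
    panel
        Ordered protein names (length K).
    retention_p
        Probability that a cell survives each antibody-slide exchange.
    state_mix
        Fraction of cells in the high-basal latent state.
    mode_probs
        ``{protein: {state: {mode: prob}}}`` dynamic-mode probabilities.
    background_mean, background_sd
        Per-protein additive fluorescence background (photon counts), drawn
        truncated-normal at 0.  Scalars broadcast over the panel.
    signal_logmean, signal_logsd
        Per-protein log-normal secretion-signal parameters (natural log).
    basal_coupling
        Logistic slope linking a cell's basal active-protein count to its
        probability of turning on additional (silent-mode) proteins after
        stimulation; 0 disables the coupling entirely.
    coupling_intercept
        Logistic intercept of the same conversion probability.
    chip_id
        Identifier stamped on every well row.
    seed
        Seed for the generator's random stream.
    """

    n_wells: int = 18_000
    loading_rate: float = 0.5
    n_timepoints: int = 4
    panel: tuple = DEFAULT_PANEL
    retention_p: float = 0.56
    state_mix: float = 0.35
    mode_probs: dict = field(default_factory=default_mode_probs)
    background_mean: object = 150.0
    background_sd: object = 15.0
    signal_logmean: object = 7.3
    signal_logsd: object = 0.35
    basal_coupling: float = 0.5
    coupling_intercept: float = -3.5
    chip_id: str = "chip01"
    seed: int = 0

    def __post_init__(self):
        self.panel = tuple(self.panel)
        self.background_mean = _as_per_protein(self.background_mean, self.panel, "background_mean")
        self.background_sd = _as_per_protein(self.background_sd, self.panel, "background_sd")
        self.signal_logmean = _as_per_protein(self.signal_logmean, self.panel, "signal_logmean")
        self.signal_logsd = _as_per_protein(self.signal_logsd, self.panel, "signal_logsd")

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        if self.n_wells < 1:
            raise ConfigError("n_wells must be >= 1")
        if not np.isfinite(self.loading_rate) or self.loading_rate <= 0:
            raise ConfigError("loading_rate must be finite and > 0")
        if self.n_timepoints < 2:
            raise ConfigError("n_timepoints must be >= 2")
        if not 0.0 <= self.retention_p <= 1.0:
            raise ConfigError("retention_p must lie in [0, 1]")
        if not 0.0 <= self.state_mix <= 1.0:
            raise ConfigError("state_mix must lie in [0, 1]")
        if len(self.panel) < 1 or len(set(self.panel)) != len(self.panel):
            raise ConfigError("panel must be non-empty with unique names")
        for name, table in (("background_mean", self.background_mean),
                            ("background_sd", self.background_sd),
                            ("signal_logmean", self.signal_logmean),
                            ("signal_logsd", self.signal_logsd)):
            for p, v in table.items():
                if not np.isfinite(v):
                    raise ConfigError(f"{name}[{p}] is not finite")
        for p in self.panel:
            if any(v < 0 for v in self.background_sd.values()):
                raise ConfigError("background_sd must be >= 0")
            if any(v < 0 for v in self.background_mean.values()):
                raise ConfigError("background_mean must be >= 0")
            if any(v < 0 for v in self.signal_logsd.values()):
                raise ConfigError("signal_logsd must be >= 0")
            if p not in self.mode_probs:
                raise ConfigError(f"mode_probs missing protein {p!r}")
            for s in STATES:
                if s not in self.mode_probs[p]:
                    raise ConfigError(f"mode_probs[{p!r}] missing state {s!r}")
                vec = self.mode_probs[p][s]
                unknown = set(vec) - set(MODES)
                if unknown:
                    raise ConfigError(f"unknown modes {unknown} for {p!r}")
                total = sum(vec.get(m, 0.0) for m in MODES)
                if abs(total - 1.0) > 1e-9:
                    raise ConfigError(
                        f"mode_probs[{p!r}][{s!r}] sums to {total}, expected 1")
                if any(vec.get(m, 0.0) < 0 for m in MODES):
                    raise ConfigError(f"negative mode probability for {p!r}")
        if not np.isfinite(self.basal_coupling) or self.basal_coupling < 0:
            raise ConfigError("basal_coupling must be finite and >= 0")
        if not np.isfinite(self.coupling_intercept):
            raise ConfigError("coupling_intercept must be finite")

    # -- (de)serialisation --------------------------------------------------

    def replace(self, **kwargs) -> "SimulationConfig":
        """Return a deep copy with the given fields overridden."""
        data = self.to_dict()
        data.update(kwargs)
        return SimulationConfig(**data)

    def to_dict(self) -> dict:
        data = asdict(self)
        data["panel"] = list(self.panel)
        return copy.deepcopy(data)


def config_to_yaml(config: SimulationConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def config_from_yaml(path) -> SimulationConfig:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} does not hold a mapping")
    try:
        config = SimulationConfig(**data)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc
    config.validate()
    return config
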