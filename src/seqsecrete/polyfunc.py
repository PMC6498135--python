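"""Polyfunctionality statistics.

A cell's polyfunctionality at one window is the number of proteins with a
positive secretion call, m(t).  The population is summarized by the
polyfunctionality index

    PI = sum_i F_i * (i / n)**q

where the cells are binned by function count into i = 0, 1, ..., n-1 (the top
bin pools counts >= n-1), F_i is the percentage of cells in bin i, n = 6 is
the function-count cutoff and q = 1 the weight exponent.  With the default
six bins (0, 1, 2, 3, 4, >=5), the pooled top bin carries weight i = 5.

The basal-coupling fit quantifies how strongly a cell's polyfunctionality
after stimulation depends on its unstimulated (basal, window 0) activity:
cells are binned by basal count (0..4, >=5) and, for each stimulated window,
the mean stimulated count per bin is regressed on the bin's basal count by
ordinary least squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tracking import complete_courses

__all__ = ["PolyfuncError", "PIResult", "function_counts",
           "polyfunctionality_index", "BasalCouplingFit", "basal_coupling"]


class PolyfuncError(ValueError):
    """Raised for empty or invalid polyfunctionality inputs."""


def function_counts(courses, window: int) -> np.ndarray:
    """Per-cell function counts m at one window, over complete courses."""
    courses = complete_courses(courses)
    if not courses:
        raise PolyfuncError("no complete courses")
    return np.array([int(c.calls[window].sum()) for c in courses])


@dataclass
class PIResult:
    """Polyfunctionality index with its underlying bin frequencies.

    ``frequencies`` are percentages over bins i = 0..n-1 (top bin pooled);
    they sum to 100.
    """

    n: int
    q: float
    bin_counts: np.ndarray
    frequencies: np.ndarray
    pi: float


def polyfunctionality_index(counts, n: int = 6, q: float = 1.0, *,
                            form: str = "ratio_power") -> PIResult:
    """Compute the polyfunctionality index of a population.

    Parameters
    ----------
    counts
        Per-cell function counts (non-negative integers).
    n
        Function-count cutoff; cells with m >= n-1 pool into the top bin.
    q
        Weight exponent.
    form
        ``"ratio_power"`` (default): weight (i/n)**q — the standard index.
        ``"linear_over_nq"``: weight i/(n*q), an alternative reading of the
        same formula kept behind this flag.
    """
    counts = np.asarray(counts)
    if counts.size == 0:
        raise PolyfuncError("empty counts")
    if (counts < 0).any():
        raise PolyfuncError("negative function count")
    if n < 1:
        raise PolyfuncError("n must be >= 1")
    binned = np.minimum(counts, n - 1)
    bin_counts = np.bincount(binned, minlength=n)
    freqs = 100.0 * bin_counts / counts.size
    i = np.arange(n)
    if form == "ratio_power":
        weights = (i / n) ** q
    elif form == "linear_over_nq":
        weights = i / (n * q)
    else:
        raise PolyfuncError(f"unknown PI form {form!r}")
    pi = float(np.sum(freqs * weights))
    return PIResult(n=n, q=q, bin_counts=bin_counts, frequencies=freqs, pi=pi)


@dataclass
class BasalCouplingFit:
    """Binned linear fits of stimulated on basal polyfunctionality.

    ``fits`` has one row per stimulated window (slope, intercept, r2);
    ``bin_means`` one row per (window, basal bin) with the bin's basal-count
    center, mean stimulated count and cell count; ``neighbor_tests`` the
    Welch t-test p-value between adjacent basal bins' stimulated counts.
    """

    fits: pd.DataFrame
    bin_means: pd.DataFrame
    neighbor_tests: pd.DataFrame


def basal_coupling(courses, *, max_bin: int = 5) -> BasalCouplingFit:
    """Fit mean stimulated polyfunctionality against basal bins.

    Cells are grouped by basal (window 0) function count into bins
    0..max_bin-1 and >=max_bin; the top bin's regressor is its within-bin
    mean basal count.  Requires at least 3 non-empty basal bins.
    """
    courses = complete_courses(courses)
    if not courses:
        raise PolyfuncError("no complete courses")
    T = courses[0].n_timepoints
    basal = function_counts(courses, 0)
    bins = np.minimum(basal, max_bin)
    occupied = np.unique(bins)
    if len(occupied) < 3:
        raise PolyfuncError(
            f"only {len(occupied)} non-empty basal bins; need >= 3 for a fit")

    centers = {}
    for b in occupied:
        members = basal[bins == b]
        centers[b] = float(members.mean()) if b == max_bin else float(b)

    fit_rows, mean_rows, test_rows = [], [], []
    for t in range(1, T):
        stim = function_counts(courses, t)
        xs, ys = [], []
        for b in occupied:
            sel = bins == b
            mean_rows.append({
                "window": t, "basal_bin": int(b),
                "bin_center": centers[b],
                "mean_stimulated": float(stim[sel].mean()),
                "n_cells": int(sel.sum()),
            })
            xs.append(centers[b])
            ys.append(float(stim[sel].mean()))
        res = stats.linregress(xs, ys)
        fit_rows.append({"window": t, "slope": res.slope,
                         "intercept": res.intercept,
                         "r2": res.rvalue ** 2})
        for b0, b1 in zip(occupied[:-1], occupied[1:]):
            a = stim[bins == b0]
            b = stim[bins == b1]
            if len(a) >= 2 and len(b) >= 2:
                p = stats.ttest_ind(a, b, equal_var=False).pvalue
            else:
                p = np.nan
            test_rows.append({"window": t, "bin_low": int(b0),
                              "bin_high": int(b1), "p_value": float(p)})
    return BasalCouplingFit(fits=pd.DataFrame(fit_rows),
                            bin_means=pd.DataFrame(mean_rows),
                            neighbor_tests=pd.DataFrame(test_rows))
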