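"""Kernel-density peak detection for divergence distributions.

Paralog-wide distributions of Ks or 4DTv are typically multimodal: each
whole-genome duplication leaves a mode at the divergence accumulated since
the event. Peaks are located as strict local maxima of a Gaussian kernel
density estimate evaluated on an even grid over a configured range
(default bandwidth: Silverman's rule).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde
from sklearn.base import BaseEstimator

from .errors import InputError


@dataclass(frozen=True)
class PeakSet:
    """KDE evaluation and detected peaks, sorted by location."""

    values_used: int
    grid: np.ndarray
    density: np.ndarray
    peaks: tuple[tuple[float, float], ...]  # (location, density)
    bandwidth: float

    @property
    def locations(self) -> tuple[float, ...]:
        return tuple(loc for loc, _ in self.peaks)

    def to_dict(self) -> dict:
        return {
            "values_used": self.values_used,
            "bandwidth": self.bandwidth,
            "peaks": [{"location": loc, "density": den} for loc, den in self.peaks],
        }


class KdePeakDetector(BaseEstimator):
    """Estimate a 1-D Gaussian KDE and locate its local maxima.

    Parameters
    ----------
    bandwidth : "silverman" or float
        Silverman's rule, or an absolute kernel standard deviation.
    value_range : (float, float)
        Only values strictly inside the range are used, and the density is
        evaluated on an even grid across it.
    grid_points : int
        Number of grid points (default 512).
    min_values : int
        Minimum number of usable values (default 10).

    Attributes
    ----------
    grid_, density_ : ndarray
        Evaluation grid and density estimates.
    peaks_ : tuple of (location, density)
        Strict local maxima, peaks closer than 2 grid steps merged (the
        higher one kept), sorted by location.
    """

    def __init__(self, bandwidth="silverman", value_range=(0.0, 1.0),
                 grid_points: int = 512, min_values: int = 10):
        self.bandwidth = bandwidth
        self.value_range = value_range
        self.grid_points = grid_points
        self.min_values = min_values

    def fit(self, X, y=None):
        values = np.asarray(X, dtype=float).ravel()
        lo, hi = self.value_range
        if not hi > lo:
            raise InputError(f"invalid value range {self.value_range}")
        values = values[np.isfinite(values) & (values > lo) & (values < hi)]
        if values.size < self.min_values:
            raise InputError(
                f"need at least {self.min_values} finite values in "
                f"({lo}, {hi}); got {values.size}"
            )
        if self.bandwidth == "silverman":
            kde = gaussian_kde(values, bw_method="silverman")
        else:
            bw = float(self.bandwidth)
            if bw <= 0:
                raise InputError("bandwidth must be positive")
            std = values.std(ddof=1)
            if std == 0:
                raise InputError("cannot scale a fixed bandwidth: zero variance")
            kde = gaussian_kde(values, bw_method=bw / std)
        grid = np.linspace(lo, hi, self.grid_points)
        density = kde(grid)
        self.n_used_ = int(values.size)
        self.bandwidth_ = float(kde.factor * values.std(ddof=1))
        self.grid_ = grid
        self.density_ = density
        self.peaks_ = _local_maxima(grid, density)
        return self

    def to_peak_set(self) -> PeakSet:
        return PeakSet(
            values_used=self.n_used_,
            grid=self.grid_,
            density=self.density_,
            peaks=self.peaks_,
            bandwidth=self.bandwidth_,
        )


def _local_maxima(grid: np.ndarray, density: np.ndarray) -> tuple[tuple[float, float], ...]:
    d = density
    idx = [i for i in range(1, len(d) - 1) if d[i] > d[i - 1] and d[i] > d[i + 1]]
    # merge peaks closer than 2 grid steps, keeping the denser one
    merged: list[int] = []
    for i in idx:
        if merged and i - merged[-1] < 2:
            if d[i] > d[merged[-1]]:
                merged[-1] = i
        else:
            merged.append(i)
    return tuple((float(grid[i]), float(d[i])) for i in merged)


def detect_peaks(values, bandwidth="silverman", value_range=(0.0, 1.0),
                 grid_points: int = 512) -> PeakSet:
    """Functional wrapper around :class:`KdePeakDetector`."""
    det = KdePeakDetector(
        bandwidth=bandwidth, value_range=value_range, grid_points=grid_points
    ).fit(values)
    return det.to_peak_set()
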