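"""Mean/fluctuation decomposition and turbulence intensity.

Instantaneous velocity decomposes as u = u_mean + u', where u_mean is the
mean over a fixed averaging window (600 s by default, matching 10-min ADCP
means) and u' is the residual fluctuation.  Turbulence intensity is the
RMS fluctuation normalised by the window mean, I = RMS(u') / u_mean; it is
dimensionless and scale-invariant.  Depth coordinates are normalised by
the water depth so profiles from different sites can be combined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_WINDOW_S = 600.0


def decompose(
    series: np.ndarray, window: float, dt: float
) -> tuple[np.ndarray, np.ndarray]:
    """Split a speed series into per-window means and per-sample fluctuations.

    Parameters
    ----------
    series : 1-D array of instantaneous speeds (m/s)
    window : averaging duration (s)
    dt : sampling interval (s)

    Returns ``(means, fluctuations)`` where ``means`` has one entry per
    complete window and ``fluctuations`` covers exactly the samples inside
    complete windows (a partial trailing window is dropped).  Within each
    window the fluctuations sum to zero by construction.
    """
    series = np.asarray(series, dtype=float)
    if dt <= 0 or window <= 0:
        raise ValueError("window and dt must be positive")
    spw = int(round(window / dt))
    if spw < 2:
        raise ValueError(
            f"window ({window:g} s) must span at least two sampling intervals ({dt:g} s)"
        )
    n_win = series.size // spw
    if n_win == 0:
        raise ValueError("series shorter than one averaging window")
    used = series[: n_win * spw].reshape(n_win, spw)
    means = used.mean(axis=1)
    fluct = (used - means[:, None]).ravel()
    return means, fluct


def intensity(fluctuations: np.ndarray, u_mean: float) -> float:
    """Turbulence intensity I = RMS(u') / u_mean (dimensionless, >= 0)."""
    if not u_mean > 0:
        raise ValueError("turbulence intensity undefined for non-positive mean velocity")
    f = np.asarray(fluctuations, dtype=float)
    return float(np.sqrt(np.mean(f * f)) / u_mean)


def intensity_series(series: np.ndarray, window: float, dt: float) -> np.ndarray:
    """Per-window turbulence intensity for an instantaneous speed series."""
    means, fluct = decompose(series, window, dt)
    spw = fluct.size // means.size
    per_win = fluct.reshape(means.size, spw)
    out = np.empty(means.size)
    for i, (m, f) in enumerate(zip(means, per_win)):
        out[i] = intensity(f, m)
    return out


def normalize_depth(heights: np.ndarray, water_depth: float) -> np.ndarray:
    """Heights above the seabed scaled to [0, 1] by the water depth."""
    if water_depth <= 0:
        raise ValueError("water depth must be positive")
    h = np.asarray(heights, dtype=float)
    if np.any(h < 0) or np.any(h > water_depth + 1e-9):
        raise ValueError("heights must lie within [0, water_depth]")
    return h / water_depth


@dataclass
class TurbulenceProfile:
    """Depth-normalised turbulence-intensity profile."""

    heights_norm: np.ndarray
    intensity: np.ndarray
    window: float = DEFAULT_WINDOW_S

    def __post_init__(self) -> None:
        self.heights_norm = np.asarray(self.heights_norm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.heights_norm.shape != self.intensity.shape:
            raise ValueError("heights_norm and intensity must have equal length")
        if np.any(self.heights_norm < 0) or np.any(self.heights_norm > 1):
            raise ValueError("normalised heights must lie in [0, 1]")
        if np.any(self.intensity < 0):
            raise ValueError("turbulence intensity must be >= 0")
        if self.window <= 0:
            raise ValueError("window must be positive")
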