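"""Synthetic site conditions with the statistical character of a macrotidal bay.

No public field record backs the case study, so every pipeline stage is
exercised on generated data that emulates the documented statistics:

* a sheared tidal current — per-height long-run means interpolating
  linearly from 0.11 m/s at the seabed to 0.24 m/s at the surface, with
  semidiurnal reversals and a half-monthly spring-neap envelope built as
  the beat of two semidiurnal constituents (M2 at 12.42 h and S2 at
  12.00 h, beating with a 14.77-day period);
* turbulent fluctuations at a configurable intensity (bulk 0.8 — the
  site's maximum depth-averaged value);
* storm sea states (H = 3.99 m, T = 7.4 s by default);
* a seasonal dissolved-oxygen cycle with an annual minimum of 8.98 mg/L.

Speed magnitudes only (no direction).  All randomness flows from the
spec's seed, so a given spec reproduces byte-identical fields.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evp_data import DOSeries, EXTERNAL, VelocityField

M2_PERIOD_S = 12.4206012 * 3600.0
S2_PERIOD_S = 12.0 * 3600.0
#: beat period of M2 against S2: the spring-neap cycle, ~14.77 days
SPRING_NEAP_PERIOD_S = 1.0 / (1.0 / S2_PERIOD_S - 1.0 / M2_PERIOD_S)

_START = "2016-01-01T00:00:00"


@dataclass
class SyntheticSpec:
    """Parameters of the generated site conditions (defaults: Falmouth-like)."""

    duration_days: float = 30.0
    cadence: float = 600.0  # s, 10-min means
    heights: tuple = (1.24, 5.0, 10.0, 15.0, 20.0, 25.0, 29.0)  # m above seabed
    water_depth: float = 30.0  # m
    u_surface_mean: float = 0.24  # m/s, long-run mean at the surface
    u_seabed_mean: float = 0.11  # m/s, long-run mean at the bed
    m2_amplitude: float = 0.75  # relative M2 constituent weight
    s2_amplitude: float = 0.25  # relative S2 constituent weight
    noise_sigma: float = 0.15  # lognormal sigma of multiplicative noise
    intensity: float = 0.8  # bulk turbulence intensity
    wave_height: float = 3.99  # m, storm significant height
    wave_period: float = 7.4  # s, storm mean period
    do_min: float = 8.98  # mg/L, annual minimum
    do_max: float = 10.5  # mg/L, annual maximum
    do_phase_day: float = 245.0  # day-of-run at which the DO minimum falls
    do_noise_sigma: float = 0.05  # mg/L, additive measurement noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_days <= 0 or self.cadence <= 0:
            raise ValueError("duration and cadence must be positive")
        if self.m2_amplitude < 0 or self.s2_amplitude < 0:
            raise ValueError("constituent amplitudes must be >= 0")
        if self.noise_sigma < 0 or self.do_noise_sigma < 0:
            raise ValueError("noise levels must be >= 0")
        if self.intensity < 0:
            raise ValueError("turbulence intensity must be >= 0")
        if not self.do_min <= self.do_max:
            raise ValueError("do_min must not exceed do_max")
        if self.water_depth <= 0:
            raise ValueError("water depth must be positive")


def _shear_profile(spec: SyntheticSpec) -> np.ndarray:
    h = np.asarray(spec.heights, dtype=float)
    frac = h / spec.water_depth
    return spec.u_seabed_mean + (spec.u_surface_mean - spec.u_seabed_mean) * frac


def _tidal_modulation(spec: SyntheticSpec, t_s: np.ndarray) -> np.ndarray:
    """Rectified two-constituent tide, normalised to unit long-run mean.

    The normalising constant is the mean of |a1 cos w1 t + a2 cos w2 t|
    over one full spring-neap beat, evaluated on a dense grid, so the
    long-run mean of the returned modulation is 1 regardless of the run
    duration.
    """
    a1, a2 = spec.m2_amplitude, spec.s2_amplitude
    if a1 + a2 == 0:
        return np.ones_like(t_s, dtype=float)
    w1 = 2.0 * math.pi / M2_PERIOD_S
    w2 = 2.0 * math.pi / S2_PERIOD_S
    raw = np.abs(a1 * np.cos(w1 * t_s) + a2 * np.cos(w2 * t_s))
    grid = np.linspace(0.0, SPRING_NEAP_PERIOD_S, 65536, endpoint=False)
    norm = np.abs(a1 * np.cos(w1 * grid) + a2 * np.cos(w2 * grid)).mean()
    return raw / norm


def gen_current_field(spec: SyntheticSpec, start: str = _START) -> VelocityField:
    """Generate an external current-speed grid speed(t, h) = shear(h) * tide(t) * noise(t).

    The multiplicative lognormal noise has unit mean and is drawn once per
    timestamp, shared across heights (vertically coherent modulation), so
    the instantaneous vertical ordering always follows the shear profile.
    """
    if spec.cadence > S2_PERIOD_S / 4.0:
        raise ValueError(
            f"cadence {spec.cadence:g} s aliases the semidiurnal tide "
            f"(must be <= {S2_PERIOD_S / 4.0:g} s)"
        )
    n = int(spec.duration_days * 86400.0 // spec.cadence)
    if n < 1:
        raise ValueError("duration shorter than one cadence interval")
    t_s = np.arange(n) * spec.cadence
    rng = np.random.default_rng(spec.seed)
    if spec.noise_sigma > 0:
        s = spec.noise_sigma
        noise = np.exp(s * rng.standard_normal(n) - 0.5 * s * s)  # mean-1 lognormal
    else:
        noise = np.ones(n)
    modulation = _tidal_modulation(spec, t_s) * noise
    speed = np.outer(modulation, _shear_profile(spec))
    times = pd.Timestamp(start) + pd.to_timedelta(t_s, unit="s")
    return VelocityField(
        times=times,
        heights=np.asarray(spec.heights, dtype=float),
        speed=speed,
        cadence=spec.cadence,
        provenance=EXTERNAL,
        water_depth_ref=spec.water_depth,
    )


def gen_turbulent_series(
    mean_series: np.ndarray,
    intensity: float,
    samples_per_window: int = 4096,
    seed: int = 0,
) -> np.ndarray:
    """Instantaneous speeds around per-window means with Gaussian fluctuations.

    For each window mean m_i, emits ``samples_per_window`` samples
    m_i * (1 + intensity * Z), so the expected per-window RMS fluctuation
    is ``intensity * m_i``.  At high intensity individual samples may go
    negative; they represent the along-stream component relative to the
    mean and are left unclipped so the RMS is unbiased.
    """
    if intensity < 0:
        raise ValueError("turbulence intensity must be >= 0")
    if samples_per_window < 2:
        raise ValueError("need at least two samples per window")
    m = np.asarray(mean_series, dtype=float)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((m.size, samples_per_window))
    return (m[:, None] * (1.0 + intensity * z)).ravel()


def gen_do_series(
    spec: SyntheticSpec,
    n_days: int = 365,
    cadence_days: float = 1.0,
    start: str = _START,
) -> DOSeries:
    """Seasonal DO cycle: sinusoid between the annual minimum and maximum.

    With zero noise the series attains ``do_min`` exactly at
    ``do_phase_day`` (late summer by default, when warm water holds the
    least oxygen) and ``do_max`` half a year away.
    """
    t_days = np.arange(0.0, n_days, cadence_days)
    phase = 2.0 * math.pi * (t_days - spec.do_phase_day) / 365.0
    amp = spec.do_max - spec.do_min
    conc = spec.do_min + amp * (1.0 - np.cos(phase)) / 2.0
    if spec.do_noise_sigma > 0:
        rng = np.random.default_rng(spec.seed + 1)
        conc = conc + spec.do_noise_sigma * rng.standard_normal(conc.size)
        conc = np.clip(conc, 1e-6, None)  # concentrations stay physical
    times = pd.Timestamp(start) + pd.to_timedelta(t_days, unit="D")
    return DOSeries(times=times, concentration=conc)
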