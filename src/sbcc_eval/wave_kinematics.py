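"""Linear (Airy) wave kinematics for deep-water sea states.

A sea state is summarised by its significant wave height ``H`` (m) and
period ``T`` (s).  The wavelength follows from an implicit dispersion
relation solved by damped fixed-point iteration:

    lambda = (g T^2 / 2 pi) * tanh(2 pi a / lambda)

The default ("printed") form uses ``a = H``, which is the form the
framework was calibrated with and which yields 44.0 m for the Falmouth
maximum-annual storm (H = 3.99 m, T = 7.4 s).  The "standard" textbook
form substitutes the water depth, ``a = d``.  The wave number is
``k = 2 pi / lambda`` throughout.

Deep water holds when the depth exceeds half the wavelength; deep-water
orbital velocities are circular with amplitude (pi H / T) e^{k z}, where
``z <= 0`` is measured downward from the surface, so they decay
exponentially toward the seabed.  Shallow/intermediate (elliptic)
kinematics are out of scope and raise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

GRAVITY = 9.81  # m/s^2

PRINTED = "printed"
STANDARD = "standard"

DEEP = "deep"
NOT_DEEP = "not_deep"


class DispersionError(RuntimeError):
    """Fixed-point iteration failed to converge; carries the last iterate."""

    def __init__(self, message: str, last_iterate: float):
        super().__init__(message)
        self.last_iterate = last_iterate


def _tanh_argument(H: float, d: float | None, formula: str) -> float:
    if formula == PRINTED:
        return H
    if formula == STANDARD:
        if d is None:
            raise ValueError("standard dispersion requires a water depth d")
        return d
    raise ValueError(f"unknown dispersion formula {formula!r}")


def dispersion_residual(
    lam: float, H: float, T: float, g: float = GRAVITY,
    formula: str = PRINTED, d: float | None = None,
) -> float:
    """Residual lambda − (g T^2/2 pi) tanh(2 pi a/lambda); zero at the solution."""
    a = _tanh_argument(H, d, formula)
    return lam - (g * T * T / (2.0 * math.pi)) * math.tanh(2.0 * math.pi * a / lam)


def solve_dispersion(
    H: float,
    T: float,
    g: float = GRAVITY,
    tol: float = 1e-4,
    max_iter: int = 200,
    formula: str = PRINTED,
    d: float | None = None,
    damping: float = 0.5,
) -> float:
    """Solve the dispersion relation for the wavelength (m).

    Damped fixed-point iteration seeded at the deep-water wavelength
    ``g T^2 / 2 pi``; converged when successive iterates move less than
    ``tol`` metres and the residual is below ``tol``.

    Raises
    ------
    DispersionError
        If not converged within ``max_iter`` iterations; the exception
        carries the last iterate.
    """
    if not (H > 0 and T > 0):
        raise ValueError("wave height and period must be positive")
    if not (0 < damping <= 1):
        raise ValueError("damping must lie in (0, 1]")
    a = _tanh_argument(H, d, formula)
    l_deep = g * T * T / (2.0 * math.pi)
    lam = l_deep
    for _ in range(max_iter):
        nxt = (1.0 - damping) * lam + damping * l_deep * math.tanh(2.0 * math.pi * a / lam)
        if abs(nxt - lam) < tol and abs(dispersion_residual(nxt, H, T, g, formula, d)) < tol:
            return nxt
        lam = nxt
    raise DispersionError(
        f"dispersion not converged after {max_iter} iterations (last iterate {lam:.6g} m)",
        last_iterate=lam,
    )


def classify_regime(d: float, wavelength: float) -> str:
    """``deep`` iff the water depth strictly exceeds half the wavelength."""
    if not (d > 0 and wavelength > 0):
        raise ValueError("depth and wavelength must be positive")
    return DEEP if d > wavelength / 2.0 else NOT_DEEP


@dataclass
class WaveState:
    """A solved sea state: wavelength, wave number and depth regime."""

    H: float
    T: float
    d: float
    g: float = GRAVITY
    formula: str = PRINTED
    tol: float = 1e-4
    wavelength: float = field(init=False)
    k: float = field(init=False)
    regime: str = field(init=False)

    def __post_init__(self) -> None:
        if self.d <= 0:
            raise ValueError("water depth must be positive")
        self.wavelength = solve_dispersion(
            self.H, self.T, g=self.g, tol=self.tol, formula=self.formula, d=self.d
        )
        self.k = 2.0 * math.pi / self.wavelength
        self.regime = classify_regime(self.d, self.wavelength)

    @property
    def surface_amplitude(self) -> float:
        """Deep-water orbital speed amplitude at the surface, pi H / T (m/s)."""
        return math.pi * self.H / self.T


def orbital_velocity(
    state: WaveState, z: float, theta: float = 0.0
) -> tuple[float, float]:
    """Deep-water orbital velocity components at depth z (m, z <= 0).

    Returns ``(u, w)`` with ``u = (pi H/T) e^{k z} cos(theta)`` and
    ``w = (pi H/T) e^{k z} sin(theta)``; ``theta`` is the phase in
    degrees.  The amplitude ``sqrt(u^2 + w^2)`` is phase-invariant.
    """
    if state.regime != DEEP:
        raise ValueError(
            "orbital velocity implemented for deep-water states only "
            f"(regime={state.regime!r}: d={state.d:g} m <= lambda/2={state.wavelength / 2:g} m)"
        )
    if z > 1e-12:
        raise ValueError("z is measured downward from the surface and must be <= 0")
    amp = state.surface_amplitude * math.exp(state.k * z)
    th = math.radians(theta)
    return amp * math.cos(th), amp * math.sin(th)


def orbital_amplitude_profile(
    state: WaveState, heights: np.ndarray, water_depth: float | None = None
) -> np.ndarray:
    """Orbital-speed amplitude (theta = 0 envelope) per height above the seabed.

    Heights are converted with ``z = height − water_depth``; the profile
    decays exponentially toward the bed and equals ``pi H / T`` at the
    surface.
    """
    d = state.d if water_depth is None else water_depth
    h = np.asarray(heights, dtype=float)
    if np.any(h < 0) or np.any(h > d + 1e-9):
        raise ValueError("heights must lie between the seabed (0) and the surface (d)")
    if state.regime != DEEP:
        raise ValueError("amplitude profile implemented for deep-water states only")
    z = h - d
    return state.surface_amplitude * np.exp(state.k * z)
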