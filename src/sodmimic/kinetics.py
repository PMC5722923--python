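"""Rate laws for catalyzed superoxide decay and Ni(II)-peptide degradation.

In a stopped-flow SOD activity assay the superoxide concentration a(t)
decays by two parallel routes: second-order self-disproportionation
(rate constant k2, M^-1 s^-1) and pseudo-first-order catalyzed decay
(k_obs, s^-1):

    -da/dt = k2 a^2 + k_obs a

with the closed-form solution (C an offset in the same units as a):

    a(t) = a0 e^(-k_obs t) / ((k2/k_obs) a0 (1 - e^(-k_obs t)) + 1) + C

The catalytic term decomposes as k_obs = k1 + b*k3, where k1 is the
background first-order rate, b the catalyst concentration and
k3 = k_cat the second-order catalytic rate constant — the slope of
k_obs against b.

Degradation of the Ni(II)-peptide chromophore itself is modeled as a
first-order decay A(t) = A_inf + (A0 - A_inf) e^(-k t) with half-life
ln 2 / k.

Units: seconds and molar throughout; absorbance conversion happens only
at I/O boundaries via Beer–Lambert.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "SuperoxideKineticParams",
    "ActivityDecomposition",
    "FirstOrderDecayParams",
    "superoxide_rate",
    "superoxide_decay_closed",
    "superoxide_decay_ode",
    "kobs_from_concentration",
    "first_order_decay",
    "half_life",
    "absorbance_to_concentration",
    "concentration_to_absorbance",
]

# below this k_obs the closed form is evaluated through its k_obs -> 0
# limit, the classical second-order law a0/(1 + k2 a0 t) + C
_KOBS_LIMIT = 1e-9


@dataclass(frozen=True)
class SuperoxideKineticParams:
    """Parameters of the mixed-order superoxide decay."""

    a0: float  # initial superoxide concentration, M
    k2: float  # self-disproportionation rate, M^-1 s^-1
    k_obs: float  # first-order catalytic rate, s^-1
    C: float = 0.0  # offset, same units as a

    def __post_init__(self):
        if self.a0 <= 0:
            raise ValueError("a0 must be positive")
        if self.k2 < 0 or self.k_obs < 0:
            raise ValueError("rate constants must be non-negative")


@dataclass(frozen=True)
class ActivityDecomposition:
    """k_obs = k1 + b * k3 with k3 = k_cat."""

    k1: float  # background first-order rate, s^-1
    k3: float  # catalytic second-order rate constant (k_cat), M^-1 s^-1
    b: float  # catalyst concentration, M

    def __post_init__(self):
        if self.k1 < 0 or self.b < 0:
            raise ValueError("k1 and b must be non-negative")


@dataclass(frozen=True)
class FirstOrderDecayParams:
    A0: float  # initial signal
    A_inf: float  # plateau
    k: float  # rate, s^-1

    def __post_init__(self):
        if self.k <= 0:
            raise ValueError("decay rate k must be positive")


def superoxide_rate(a, p: SuperoxideKineticParams):
    """da/dt = -(k2 a^2 + k_obs a); non-positive for a >= 0."""
    a = np.asarray(a, dtype=float)
    return -(p.k2 * a**2 + p.k_obs * a)


def superoxide_decay_closed(t, p: SuperoxideKineticParams):
    """Closed-form a(t) of the mixed-order decay; a(0) = a0 + C.

    Overflow-safe for large k_obs*t (tends to C) and continuous at
    k_obs -> 0, where the series limit a0/(1 + k2 a0 t) + C is used.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    if p.k_obs < _KOBS_LIMIT:
        return p.a0 / (1.0 + p.k2 * p.a0 * t) + p.C
    kt = p.k_obs * t
    e = np.exp(-np.minimum(kt, 700.0))
    # (1 - e^{-kt})/k_obs computed via expm1 for small kt accuracy
    growth = -np.expm1(-kt) / p.k_obs
    return p.a0 * e / (p.k2 * p.a0 * growth + 1.0) + p.C


def superoxide_decay_ode(
    t_grid, p: SuperoxideKineticParams, rtol: float = 1e-12, atol_scale: float = 1e-14
):
    """Numerical integration of the rate equation on ``t_grid``.

    High-accuracy adaptive integration (DOP853); serves as the
    independent oracle for the closed form.  The offset C is added after
    integrating the pure decay.  Raises ``RuntimeError`` on solver
    failure — never returns silently wrong values.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 2 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be increasing with >= 2 points")
    if t_grid[0] < 0:
        raise ValueError("t_grid must start at t >= 0")
    sol = solve_ivp(
        lambda t, a: -(p.k2 * a**2 + p.k_obs * a),
        (t_grid[0], t_grid[-1]),
        [p.a0],
        t_eval=t_grid,
        method="DOP853",
        rtol=rtol,
        atol=atol_scale * p.a0,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return sol.y[0] + p.C


def kobs_from_concentration(d: ActivityDecomposition) -> float:
    """Apparent first-order rate at catalyst concentration b."""
    return d.k1 + d.b * d.k3


def first_order_decay(t, p: FirstOrderDecayParams):
    """A(t) = A_inf + (A0 - A_inf) e^(-k t)."""
    t = np.asarray(t, dtype=float)
    return p.A_inf + (p.A0 - p.A_inf) * np.exp(-p.k * t)


def half_life(k: float) -> float:
    """t_1/2 = ln 2 / k for a first-order process."""
    if k <= 0:
        raise ValueError("rate constant must be positive")
    return float(np.log(2.0) / k)


def absorbance_to_concentration(A, epsilon: float, path: float = 1.0):
    """Beer–Lambert: c = A / (epsilon * path)."""
    if epsilon <= 0 or path <= 0:
        raise ValueError("epsilon and path must be positive")
    return np.asarray(A, dtype=float) / (epsilon * path)


def concentration_to_absorbance(c, epsilon: float, path: float = 1.0):
    """Inverse Beer–Lambert: A = epsilon * path * c."""
    if epsilon <= 0 or path <= 0:
        raise ValueError("epsilon and path must be positive")
    return np.asarray(c, dtype=float) * epsilon * path
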