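"""Normalised Hill force-velocity mechanics for mixed fibre populations.

Slow (type I) and fast (type II) muscle fibres follow the same concentric
Hill hyperbola once force is expressed relative to isometric force ``F0``
and shortening velocity relative to the maximum unloaded velocity
``V_max``:

    f(u) = (1 - u) / (1 + u / k),      u = v / V_max in [0, 1]

where ``k = a / F0`` is the dimensionless curvature.  Fast fibres differ
from slow fibres chiefly through a higher ``V_max``; with equal curvature
and a threefold velocity ratio, a pure fast population produces exactly
three times the peak mechanical power of a slow one.  A whole muscle is
modelled as an area-fraction-weighted mixture of the two populations
sharing a common fibre length, each population contributing zero force
beyond its own ``V_max``.

Only the concentric branch is modelled; eccentric (lengthening) input is
rejected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "DEFAULT_CURVATURE",
    "DEFAULT_VMAX_RATIO",
    "FibreParams",
    "MixtureParams",
    "hill_force",
    "optimal_velocity_fraction",
    "peak_normalised_power",
    "mixture_force",
    "mixture_peak_power",
]

#: Default Hill curvature a/F0, shared by both fibre types.
DEFAULT_CURVATURE = 0.25

#: Default ratio of fast-fibre to slow-fibre maximum shortening velocity.
#: With equal curvature this makes the fast:slow peak-power ratio exactly 3.
DEFAULT_VMAX_RATIO = 3.0


@dataclass(frozen=True)
class FibreParams:
    """Hill parameters of one fibre population.

    Parameters
    ----------
    vmax_norm
        Maximum unloaded shortening velocity in fibre lengths per second
        (must be positive).
    curvature_k
        Dimensionless Hill curvature ``a / F0`` (must be positive).
    """

    vmax_norm: float
    curvature_k: float

    def __post_init__(self) -> None:
        if not self.vmax_norm > 0:
            raise ValueError(f"vmax_norm must be > 0, got {self.vmax_norm}")
        if not self.curvature_k > 0:
            raise ValueError(f"curvature_k must be > 0, got {self.curvature_k}")


@dataclass(frozen=True)
class MixtureParams:
    """Two-population fibre mixture with type-II area fraction ``phi``."""

    type_i: FibreParams
    type_ii: FibreParams
    phi: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.phi <= 1.0:
            raise ValueError(f"phi must lie in [0, 1], got {self.phi}")
        if self.type_ii.vmax_norm < self.type_i.vmax_norm:
            raise ValueError(
                "type II fibres must be at least as fast as type I "
                f"({self.type_ii.vmax_norm} < {self.type_i.vmax_norm})"
            )


def _check_curvature(k: float) -> None:
    if not k > 0:
        raise ValueError(f"curvature k must be > 0, got {k}")


def hill_force(u, k: float):
    """Normalised Hill force ``F/F0`` at normalised velocity ``u = v/V_max``.

    Returns ``(1 - u) / (1 + u/k)`` for ``u`` in [0, 1] and 0 beyond
    ``V_max``.  Eccentric input (``u < 0``) is not modelled and raises.
    Accepts scalars or arrays.
    """
    _check_curvature(k)
    u_arr = np.asarray(u, dtype=float)
    if np.any(u_arr < 0):
        raise ValueError("negative (eccentric) velocities are not modelled")
    f = np.where(u_arr >= 1.0, 0.0, (1.0 - u_arr) / (1.0 + u_arr / k))
    return f if f.ndim else float(f)


def optimal_velocity_fraction(k: float) -> float:
    """Velocity fraction ``u* = v*/V_max`` maximising power ``u f(u)``.

    Closed form ``u* = sqrt(k (k + 1)) - k``; lies in (0, 0.5) and tends
    to 0.5 as the hyperbola degenerates to a straight line (k -> inf).
    """
    _check_curvature(k)
    return math.sqrt(k * (k + 1.0)) - k


def peak_normalised_power(k: float) -> float:
    """Peak of ``u f(u)`` in units of ``F0 V_max``; increasing in ``k``."""
    u_star = optimal_velocity_fraction(k)
    return u_star * hill_force(u_star, k)


def mixture_force(v_abs, mix: MixtureParams, fibre_length: float):
    """Normalised force of a fibre mixture at absolute velocity ``v_abs``.

    Each population is evaluated on its own normalised velocity scale
    (``V_max`` in m/s is ``vmax_norm * fibre_length``) and clamped to zero
    beyond its own ``V_max``; contributions are weighted by area fraction:
    ``(1 - phi) f_I + phi f_II``.

    Parameters
    ----------
    v_abs
        Fibre shortening velocity in m/s (scalar or array, >= 0).
    mix
        Mixture parameters.
    fibre_length
        Optimal fibre length in metres (> 0).
    """
    if not fibre_length > 0:
        raise ValueError(f"fibre_length must be > 0, got {fibre_length}")
    v = np.asarray(v_abs, dtype=float)
    if np.any(v < 0):
        raise ValueError("negative (eccentric) velocities are not modelled")
    v_i = mix.type_i.vmax_norm * fibre_length
    v_ii = mix.type_ii.vmax_norm * fibre_length
    f = (1.0 - mix.phi) * hill_force(v / v_i, mix.type_i.curvature_k)
    f = f + mix.phi * hill_force(v / v_ii, mix.type_ii.curvature_k)
    return f if np.ndim(f) else float(f)


def mixture_peak_power(
    mix: MixtureParams, f0: float, fibre_length: float
) -> tuple[float, float]:
    """Peak mechanical power of a fibre mixture and the velocity achieving it.

    Power is ``P(v) = f0 * mixture_force(v) * v``; the peak is located by a
    coarse grid bracket followed by bounded scalar refinement (the mixture
    power curve can develop two local maxima for small type-II fractions,
    so a pure local search is not trusted).

    Returns
    -------
    (peak_power_w, velocity_m_s)
    """
    if not f0 > 0:
        raise ValueError(f"f0 must be > 0, got {f0}")
    v_hi = (mix.type_ii if mix.phi > 0 else mix.type_i).vmax_norm * fibre_length

    def neg_power(v: float) -> float:
        return -f0 * mixture_force(v, mix, fibre_length) * v

    grid = np.linspace(0.0, v_hi, 513)
    p_grid = f0 * mixture_force(grid, mix, fibre_length) * grid
    i = int(np.argmax(p_grid))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid.size - 1)]
    res = minimize_scalar(
        neg_power, bounds=(lo, hi), method="bounded", options={"xatol": 1e-6}
    )
    v_star = float(res.x)
    return -float(res.fun), v_star
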