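"""Quasi-steady fluid law ``p_c = f_f(A_c, p_d)`` for the Starling-resistor rig.

Air is drawn from a stagnant room (gauge 0) through a clean upstream tube
(area ``A1``), the flexible tube whose narrowest section has area ``A_c``,
and a clean downstream tube (area ``A2``), into a large suction plenum at
gauge pressure ``p_d < 0``.  The plenum is so large that the downstream jet
dumps into it: the jet's static pressure equals ``p_d`` and its dynamic head
is lost.

The core is a quasi-one-dimensional Bernoulli balance.  When the throat
narrows past a threshold the flow separates downstream of it, modelled as a
Borda-Carnot sudden-expansion loss ramped in by a smoothstep separation
fraction sigma(A_c/A2).  This closure reproduces the qualitative features of
the measured law: near the open state the law is lossless Bernoulli and the
choke pressure plunges as the throat narrows, while deep collapse throttles
the flowrate so that the choke pressure recovers toward ``p_d`` — giving the
law a single interior minimum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .geometry import Material, TubeGeometry
from .tube_law import CollapseExponents, DEFAULT_EXPONENTS, collapse_state

__all__ = [
    "RigConfig",
    "FluidLawPoint",
    "FluidSolverError",
    "separation_fraction",
    "lossless_law",
    "fluid_law_eval",
    "fluid_law_slope",
    "dynamic_pressure_ratio",
    "fluid_law_table",
]


class FluidSolverError(RuntimeError):
    """Raised when the flowrate solver cannot bracket a solution."""


@dataclass(frozen=True)
class RigConfig:
    """Rig geometry, gas and loss-model parameters.

    ``A1``/``A2`` are the clean-tube areas (equal by default), ``rho`` the
    gas density.  The separation fraction rises smoothly from 0 at area
    ratio ``r_on`` to 1 at ``r_full``; ``K`` is the Borda-Carnot loss
    coefficient.  All pressures are gauge relative to the room (= external
    pressure of the flexible tube).
    """

    A1: float
    A2: float
    rho: float = 1.2
    r_on: float = 0.8
    r_full: float = 0.5
    K: float = 1.0

    def __post_init__(self) -> None:
        if not (self.A1 > 0 and self.A2 > 0):
            raise ValueError("clean-tube areas must be positive")
        if not self.rho > 0:
            raise ValueError("gas density must be positive")
        if not (0.0 < self.r_full < self.r_on <= 1.0):
            raise ValueError("loss ramp requires 0 < r_full < r_on <= 1")
        if self.K < 0:
            raise ValueError("loss coefficient K must be >= 0")

    @classmethod
    def for_tube(cls, geom: TubeGeometry, **kwargs) -> "RigConfig":
        """Clean tubes matched to the flexible tube's unstrained bore."""
        area = geom.reference_area
        return cls(A1=area, A2=area, **kwargs)


@dataclass(frozen=True)
class FluidLawPoint:
    """State of the fluid at one (A_c, p_d) operating point."""

    A_c: float
    p_d: float
    Q: float  # flowrate, m^3/s
    p_1: float  # upstream-station static pressure, Pa
    p_2: float  # downstream-station static pressure, Pa
    p_c: float  # choke-point static pressure, Pa
    sigma: float  # separation fraction in [0, 1]


def separation_fraction(rig: RigConfig, A_c: float) -> float:
    """Smoothstep separation fraction sigma(A_c/A2) in [0, 1]."""
    r = A_c / rig.A2
    if r >= rig.r_on:
        return 0.0
    if r <= rig.r_full:
        return 1.0
    t = (rig.r_on - r) / (rig.r_on - rig.r_full)
    return t * t * (3.0 - 2.0 * t)


def _no_flow(A_c: float, p_d: float) -> FluidLawPoint:
    return FluidLawPoint(A_c=A_c, p_d=p_d, Q=0.0, p_1=0.0, p_2=0.0, p_c=0.0, sigma=0.0)


def _point_from_Q(rig: RigConfig, p_d: float, A_c: float, Q: float, sigma: float) -> FluidLawPoint:
    v1 = Q / rig.A1
    vc = Q / A_c
    p_1 = -0.5 * rig.rho * v1**2  # Bernoulli from the stagnant room
    p_c = p_1 + 0.5 * rig.rho * v1**2 - 0.5 * rig.rho * vc**2
    return FluidLawPoint(A_c=A_c, p_d=p_d, Q=Q, p_1=p_1, p_2=p_d, p_c=p_c, sigma=sigma)


def lossless_law(rig: RigConfig, p_d: float, A_c: float) -> FluidLawPoint:
    """Fully lossless Bernoulli fluid law.

    The flowrate is set by the plenum suction alone (independent of A_c):
    ``Q = A2 sqrt(-2 p_d / rho)``; the choke pressure follows Bernoulli and
    tends to minus infinity as the throat closes.
    """
    if A_c <= 0:
        raise ValueError("throat area must be positive")
    if p_d >= 0:
        return _no_flow(A_c, p_d)
    Q = rig.A2 * math.sqrt(-2.0 * p_d / rig.rho)
    return _point_from_Q(rig, p_d, A_c, Q, sigma=0.0)


def _budget_residual(rig: RigConfig, p_d: float, A_c: float, sigma: float, Q: float) -> float:
    """Stagnation-to-plenum energy budget; zero at the operating flowrate.

    room stagnation (0) = p_d + 1/2 rho (Q/A2)^2
                          + sigma K 1/2 rho (Q/A_c)^2 (1 - A_c/A2)^2
    """
    loss = sigma * rig.K * 0.5 * rig.rho * (Q / A_c) ** 2 * (1.0 - A_c / rig.A2) ** 2
    return p_d + 0.5 * rig.rho * (Q / rig.A2) ** 2 + loss


def fluid_law_eval(rig: RigConfig, p_d: float, A_c: float) -> FluidLawPoint:
    """Fluid law with the separation-loss closure.

    Solves the station-to-station energy budget for Q on the bracket
    ``[0, Q_lossless]`` (losses can only reduce the flowrate), then returns
    the choke pressure from the lossless upstream Bernoulli leg.
    """
    if A_c <= 0:
        raise ValueError("throat area must be positive")
    if p_d >= 0:
        return _no_flow(A_c, p_d)
    sigma = separation_fraction(rig, A_c)
    Q_ll = rig.A2 * math.sqrt(-2.0 * p_d / rig.rho)
    if sigma == 0.0:
        return _point_from_Q(rig, p_d, A_c, Q_ll, sigma)
    f_lo = _budget_residual(rig, p_d, A_c, sigma, 0.0)
    f_hi = _budget_residual(rig, p_d, A_c, sigma, Q_ll)
    if not (f_lo < 0.0 <= f_hi or f_lo <= 0.0 < f_hi):
        raise FluidSolverError(
            f"flowrate not bracketed on [0, {Q_ll:.6g}] "
            f"(residuals {f_lo:.6g}, {f_hi:.6g})"
        )
    Q = brentq(
        lambda q: _budget_residual(rig, p_d, A_c, sigma, q),
        0.0,
        Q_ll,
        xtol=1e-300,
        rtol=1e-14,
    )
    return _point_from_Q(rig, p_d, A_c, Q, sigma)


def fluid_law_slope(rig: RigConfig, p_d: float, A_c: float, rel_step: float = 1e-6) -> float:
    """Numeric slope ``d f_f / d A_c`` at fixed p_d (central difference)."""
    dA = A_c * rel_step
    hi = fluid_law_eval(rig, p_d, A_c + dA).p_c
    lo = fluid_law_eval(rig, p_d, A_c - dA).p_c
    return (hi - lo) / (2.0 * dA)


def dynamic_pressure_ratio(
    geom: TubeGeometry,
    mat: Material,
    rig: RigConfig,
    Q: float,
    area: float | None = None,
    exps: CollapseExponents = DEFAULT_EXPONENTS,
) -> float:
    """Ratio of throat dynamic pressure to the collapse-pressure magnitude.

    ``(1/2 rho (Q/area)^2) / |p_c*|`` with ``area`` defaulting to the
    contact area ``A_c*`` — the tube is assumed at the brink of total
    collapse when assessing onset.  Scales with 1/area^2: shrinking the
    area tenfold multiplies the ratio by exactly 100.
    """
    if Q < 0:
        raise ValueError("flowrate must be >= 0")
    state = collapse_state(geom, mat, exps)
    if area is None:
        area = state.A_c_star
    q_dyn = 0.5 * rig.rho * (Q / area) ** 2
    return q_dyn / abs(state.p_c_star)


def fluid_law_table(
    rig: RigConfig, p_d: float, areas: np.ndarray | None = None, n: int = 200
) -> pd.DataFrame:
    """Tabulate the fluid law over an area sweep (columns A_c, p_c, Q, sigma)."""
    if areas is None:
        areas = np.linspace(rig.A2 / n, rig.A2, n)
    rows = [fluid_law_eval(rig, p_d, float(A)) for A in np.asarray(areas, dtype=float)]
    return pd.DataFrame(
        {
            "A_c_m2": [r.A_c for r in rows],
            "p_c_pa": [r.p_c for r in rows],
            "Q_m3s": [r.Q for r in rows],
            "sigma": [r.sigma for r in rows],
        }
    )
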