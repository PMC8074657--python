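"""Equilibria of tube and fluid, static stability, and suction sweeps.

With the plenum suction ``p_d`` held fixed, the system is in equilibrium at
areas ``A_c0`` where the tube law and the fluid law intersect:
``f_t(A_c0) = f_f(A_c0, p_d)``.  An equilibrium is *statically unstable*
when a small further narrowing of the throat lowers the fluid pressure
below what the tube needs to hold that shape, i.e. when

    d f_f / d A_c  >  d f_t / d A_c        (at A_c = A_c0)

(the boundary case of equal slopes is classified stable: the criterion is a
strict inequality).  A slow suction ramp moves the system through a
sequence of such quasi-steady equilibria.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .fluid_law import RigConfig, fluid_law_eval, fluid_law_slope
from .geometry import Material, TubeGeometry
from .tube_law import (
    CollapseExponents,
    DEFAULT_EXPONENTS,
    DEFAULT_MASTER_CURVE,
    MasterCurve,
    collapse_state,
    open_area,
    tube_law_eval,
    tube_law_slope,
)

__all__ = [
    "EquilibriumState",
    "NoEquilibriumError",
    "StabilityResult",
    "SuctionSweep",
    "find_equilibrium",
    "static_stability",
    "sweep_suction",
]


class NoEquilibriumError(RuntimeError):
    """No intersection of tube and fluid law in the physical area bracket."""


@dataclass(frozen=True)
class EquilibriumState:
    """One intersection of the tube law and the fluid law."""

    p_d: float
    A_c0: float
    p_c0: float
    Q: float
    slope_t: float  # d f_t / d A_c at A_c0, Pa/m^2
    slope_f: float  # d f_f / d A_c at A_c0, Pa/m^2
    residual: float  # |f_t - f_f| at A_c0, Pa
    statically_unstable: bool
    quasi_steady: bool  # True for the largest-area root at this p_d


@dataclass(frozen=True)
class StabilityResult:
    unstable: bool
    margin: float  # slope_t - slope_f; > 0 means stable


def static_stability(state: EquilibriumState) -> StabilityResult:
    """Classify an equilibrium; unstable iff slope_f exceeds slope_t strictly."""
    margin = state.slope_t - state.slope_f
    return StabilityResult(unstable=state.slope_f > state.slope_t, margin=margin)


def _make_state(
    geom, mat, rig, p_d, A, curve, exps, quasi_steady: bool
) -> EquilibriumState:
    pt = fluid_law_eval(rig, p_d, A)
    p_t = tube_law_eval(geom, mat, A, curve, exps)
    st = tube_law_slope(geom, mat, A, curve, exps)
    sf = fluid_law_slope(rig, p_d, A)
    return EquilibriumState(
        p_d=p_d,
        A_c0=A,
        p_c0=pt.p_c,
        Q=pt.Q,
        slope_t=st,
        slope_f=sf,
        residual=abs(p_t - pt.p_c),
        statically_unstable=sf > st,
        quasi_steady=quasi_steady,
    )


def find_equilibrium(
    geom: TubeGeometry,
    mat: Material,
    rig: RigConfig,
    p_d: float,
    curve: MasterCurve = DEFAULT_MASTER_CURVE,
    exps: CollapseExponents = DEFAULT_EXPONENTS,
    n_scan: int = 200,
    rtol: float = 8.9e-16,
) -> list[EquilibriumState]:
    """All equilibria at one suction level, largest area first.

    Roots of ``f_t(A) - f_f(A, p_d)`` are located by a sign-change scan on
    an ``n_scan``-point area grid between just above the contact area and
    the open-tube area, then polished by Brent's method.  The largest-area
    root is flagged as the quasi-steady branch.  ``p_d >= 0`` returns the
    no-flow anchor (open tube, zero flow).
    """
    if p_d > 0:
        raise ValueError("p_d must be <= 0 (suction, gauge)")
    A_open = open_area(geom, exps)
    if p_d == 0.0:
        st = tube_law_slope(geom, mat, A_open, curve, exps)
        return [
            EquilibriumState(
                p_d=0.0, A_c0=A_open, p_c0=0.0, Q=0.0,
                slope_t=st, slope_f=0.0, residual=0.0,
                statically_unstable=False, quasi_steady=True,
            )
        ]
    A_star = collapse_state(geom, mat, exps, curve.contact_area, curve.contact_pressure).A_c_star
    lo = A_star * (1.0 + 1e-6)
    grid = np.linspace(lo, A_open, n_scan)

    def diff(A: float) -> float:
        return tube_law_eval(geom, mat, A, curve, exps) - fluid_law_eval(rig, p_d, A).p_c

    vals = np.array([diff(float(A)) for A in grid])
    roots: list[float] = []
    for i in range(len(grid) - 1):
        if vals[i] == 0.0:
            roots.append(float(grid[i]))
        elif vals[i] * vals[i + 1] < 0.0:
            roots.append(
                float(
                    brentq(diff, float(grid[i]), float(grid[i + 1]), xtol=1e-300, rtol=rtol)
                )
            )
    if vals[-1] == 0.0:
        roots.append(float(grid[-1]))
    if not roots:
        regime = "fully collapsed" if vals[-1] < 0 else "fully open"
        raise NoEquilibriumError(
            f"no equilibrium for p_d = {p_d:.6g} Pa: tube law and fluid law do "
            f"not intersect on [{lo:.6g}, {A_open:.6g}] m^2 ({regime} regime)"
        )
    roots = sorted(set(roots), reverse=True)
    return [
        _make_state(geom, mat, rig, p_d, A, curve, exps, quasi_steady=(i == 0))
        for i, A in enumerate(roots)
    ]


@dataclass
class SuctionSweep:
    """Quasi-steady equilibria along a suction schedule.

    ``states[i]`` is the quasi-steady equilibrium at ``p_d[i]`` or None if
    none exists there; per-point failures are recorded in ``errors``.
    """

    p_d: np.ndarray
    states: list[EquilibriumState | None]
    errors: dict[int, str]

    def to_frame(self) -> "pd.DataFrame":
        import pandas as pd

        rows = []
        for pd_val, st in zip(self.p_d, self.states):
            if st is None:
                rows.append({"p_d_pa": pd_val})
            else:
                rows.append(
                    {
                        "p_d_pa": pd_val,
                        "A_c0_m2": st.A_c0,
                        "p_c0_pa": st.p_c0,
                        "Q_m3s": st.Q,
                        "slope_t": st.slope_t,
                        "slope_f": st.slope_f,
                        "unstable": st.statically_unstable,
                    }
                )
        return pd.DataFrame(rows)


def sweep_suction(
    geom: TubeGeometry,
    mat: Material,
    rig: RigConfig,
    p_d_grid,
    curve: MasterCurve = DEFAULT_MASTER_CURVE,
    exps: CollapseExponents = DEFAULT_EXPONENTS,
    jump_tol: float = 0.25,
) -> SuctionSweep:
    """Follow the quasi-steady branch across a suction schedule.

    The grid must be monotone with at least two points.  Errors at
    individual points are recorded and the sweep continues.  A relative
    area jump larger than ``jump_tol`` between neighbouring points raises a
    branch-jump warning (the quasi-steady assumption is then suspect).
    """
    p_d_grid = np.asarray(p_d_grid, dtype=float)
    if p_d_grid.ndim != 1 or p_d_grid.size < 2:
        raise ValueError("p_d grid must be 1-d with at least 2 points")
    d = np.diff(p_d_grid)
    if not (np.all(d >= 0) or np.all(d <= 0)):
        raise ValueError("p_d grid must be monotone")
    states: list[EquilibriumState | None] = []
    errors: dict[int, str] = {}
    for i, p_d in enumerate(p_d_grid):
        try:
            states.append(find_equilibrium(geom, mat, rig, min(float(p_d), 0.0), curve, exps)[0])
        except (NoEquilibriumError, ValueError, RuntimeError) as exc:
            states.append(None)
            errors[i] = str(exc)
    prev = None
    for i, st in enumerate(states):
        if st is None:
            continue
        if prev is not None and abs(st.A_c0 - prev.A_c0) > jump_tol * prev.A_c0:
            warnings.warn(
                f"branch jump between sweep points {i - 1} and {i}: area moved "
                f"{prev.A_c0:.4g} -> {st.A_c0:.4g} m^2",
                stacklevel=2,
            )
        prev = st
    return SuctionSweep(p_d=p_d_grid, states=states, errors=errors)
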