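"""Generalized dimensionless tube law for short, stretched elastic tubes.

The tube law ``p_c = f_t(A_c)`` relates the transmural pressure (inside minus
outside, gauge; negative compresses the tube) to the minimum cross-sectional
area of the tube in static equilibrium.  For thin tubes of finite length held
in axial tension, measurements for many geometries collapse onto a single
master curve when plotted in the dimensionless groups

    Pi_A = (A_c / (pi a^2)) * (l/l0)^alpha
    Pi_p = (p_c / (E/(1-nu^2))) * (l/l0)^beta * (h/a)^gamma * (l0/a)^delta

with fitted exponents alpha = 1.0, beta = -2.0, gamma = -1.0, delta = 1.0.
Total collapse (opposite walls touching) occurs at Pi_A* = 0.27 +- 0.07 and
Pi_p* = -0.12 +- 0.02; these constants let the collapse pressure and area of
an arbitrary tube — including a lung airway — be predicted from its geometry
and material alone.

This module provides the nondimensionalization (and its exact inverse), the
master curve, the collapse state, dimensional evaluation of the law, and the
exponent-fitting optimization that recovers the exponents from a dataset of
measured (or synthetic) tube-law curves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq
from sklearn.isotonic import IsotonicRegression

from .geometry import Material, TubeGeometry

__all__ = [
    "CollapseExponents",
    "CollapseState",
    "MasterCurve",
    "TubeLawCurve",
    "ExponentFit",
    "BelowContactError",
    "IdentifiabilityError",
    "DEFAULT_EXPONENTS",
    "CONTACT_AREA_CONST",
    "CONTACT_PRESSURE_CONST",
    "nondim_area",
    "dim_area",
    "nondim_pressure",
    "dim_pressure",
    "collapse_state",
    "open_area",
    "tube_law_eval",
    "tube_law_slope",
    "fit_exponents",
    "estimate_contact_constants",
]

#: Contact constants of the master curve (dimensionless).
CONTACT_AREA_CONST = 0.27
CONTACT_PRESSURE_CONST = -0.12


class BelowContactError(ValueError):
    """Raised when an area below the wall-contact area is passed to the law."""


class IdentifiabilityError(ValueError):
    """Raised when a dataset cannot identify the collapse exponents."""


@dataclass(frozen=True)
class CollapseExponents:
    """Exponents of the dimensionless collapse.

    ``alpha`` acts on (l/l0) next to the area group; ``beta``, ``gamma`` and
    ``delta`` act on (l/l0), (h/a) and (l0/a) next to the pressure group.
    Defaults are the fitted optimum values.
    """

    alpha: float = 1.0
    beta: float = -2.0
    gamma: float = -1.0
    delta: float = 1.0

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma", "delta"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"exponent {name} must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha, self.beta, self.gamma, self.delta])


DEFAULT_EXPONENTS = CollapseExponents()


@dataclass(frozen=True)
class CollapseState:
    """Area and pressure at which opposite tube walls first touch."""

    A_c_star: float  # contact area, m^2 (> 0)
    p_c_star: float  # contact transmural pressure, Pa (< 0)

    def __post_init__(self) -> None:
        if not self.A_c_star > 0:
            raise ValueError("contact area must be positive")
        if not self.p_c_star < 0:
            raise ValueError("contact pressure must be negative (compressive)")


def _area_scale(geom: TubeGeometry, exps: CollapseExponents) -> float:
    """Multiplier turning A_c/(pi a^2) into Pi_A."""
    return geom.stretch**exps.alpha


def _pressure_scale(geom: TubeGeometry, exps: CollapseExponents) -> float:
    """Multiplier turning p_c/(E/(1-nu^2)) into Pi_p."""
    return (
        geom.stretch**exps.beta
        * (geom.h / geom.a) ** exps.gamma
        * (geom.l0 / geom.a) ** exps.delta
    )


def nondim_area(geom: TubeGeometry, A_c, exps: CollapseExponents = DEFAULT_EXPONENTS):
    """Dimensionless area group ``Pi_A = (A_c/(pi a^2)) (l/l0)^alpha``."""
    A_c = np.asarray(A_c, dtype=float)
    if np.any(A_c <= 0):
        raise ValueError("cross-sectional area must be positive")
    out = A_c / geom.reference_area * _area_scale(geom, exps)
    return float(out) if out.ndim == 0 else out


def dim_area(geom: TubeGeometry, pi_A, exps: CollapseExponents = DEFAULT_EXPONENTS):
    """Exact inverse of :func:`nondim_area`."""
    pi_A = np.asarray(pi_A, dtype=float)
    out = pi_A * geom.reference_area / _area_scale(geom, exps)
    return float(out) if out.ndim == 0 else out


def nondim_pressure(
    geom: TubeGeometry, mat: Material, p_c, exps: CollapseExponents = DEFAULT_EXPONENTS
):
    """Dimensionless pressure group
    ``Pi_p = (p_c/(E/(1-nu^2))) (l/l0)^beta (h/a)^gamma (l0/a)^delta``."""
    p_c = np.asarray(p_c, dtype=float)
    out = p_c / mat.effective_modulus * _pressure_scale(geom, exps)
    return float(out) if out.ndim == 0 else out


def dim_pressure(
    geom: TubeGeometry, mat: Material, pi_p, exps: CollapseExponents = DEFAULT_EXPONENTS
):
    """Exact inverse of :func:`nondim_pressure`."""
    pi_p = np.asarray(pi_p, dtype=float)
    out = pi_p * mat.effective_modulus / _pressure_scale(geom, exps)
    return float(out) if out.ndim == 0 else out


def collapse_state(
    geom: TubeGeometry,
    mat: Material,
    exps: CollapseExponents = DEFAULT_EXPONENTS,
    area_const: float = CONTACT_AREA_CONST,
    pressure_const: float = CONTACT_PRESSURE_CONST,
) -> CollapseState:
    """Predict the total-collapse area and pressure of a tube.

    ``A_c* = C_A pi a^2 (l/l0)^(-alpha)`` and
    ``p_c* = C_p (E/(1-nu^2)) (l/l0)^(-beta) (h/a)^(-gamma) (l0/a)^(-delta)``,
    with the dimensionless contact constants ``C_A`` (default 0.27) and
    ``C_p`` (default -0.12).
    """
    return CollapseState(
        A_c_star=dim_area(geom, area_const, exps),
        p_c_star=dim_pressure(geom, mat, pressure_const, exps),
    )


def open_area(geom: TubeGeometry, exps: CollapseExponents = DEFAULT_EXPONENTS) -> float:
    """Area of the open tube at zero transmural pressure (Pi_A = 1).

    Axial stretch reduces the open area: ``pi a^2 (l/l0)^(-alpha)``.
    """
    return dim_area(geom, 1.0, exps)


class MasterCurve:
    """Monotone master tube law ``Pi_A(Pi_p)`` with a contact plateau.

    The curve is anchored at the open tube (0, 1) and the contact point
    (``Pi_p*``, ``Pi_A*``), with a monotone cubic (PCHIP) through
    configurable interior knots in between, and a plateau ``Pi_A = Pi_A*``
    for ``Pi_p <= Pi_p*`` (walls in contact).  The interior knot placement
    is a modelling choice; users can supply their own knots.
    """

    def __init__(self, knots: Sequence[Sequence[float]]):
        knots = np.asarray(knots, dtype=float)
        if knots.ndim != 2 or knots.shape[1] != 2 or knots.shape[0] < 2:
            raise ValueError("knots must be an (n >= 2, 2) array of (Pi_p, Pi_A)")
        order = np.argsort(knots[:, 0])
        knots = knots[order]
        if np.any(np.diff(knots[:, 0]) <= 0) or np.any(np.diff(knots[:, 1]) <= 0):
            raise ValueError("knots must be strictly increasing in both Pi_p and Pi_A")
        self.knots = knots
        self._interp = PchipInterpolator(knots[:, 0], knots[:, 1])
        self._dinterp = self._interp.derivative()

    @classmethod
    def default(
        cls,
        contact_pressure: float = CONTACT_PRESSURE_CONST,
        contact_area: float = CONTACT_AREA_CONST,
        interior: Sequence[Sequence[float]] = (
            (-0.09, 0.40),
            (-0.06, 0.60),
            (-0.03, 0.82),
        ),
    ) -> "MasterCurve":
        """Default curve anchored at (0, 1) and the contact point.

        The interior knots, scaled by the contact constants, give the
        characteristic shape of a collapsible-tube law: stiff near the open
        state, compliant through partial collapse.
        """
        interior = np.asarray(interior, dtype=float)
        scale_p = contact_pressure / CONTACT_PRESSURE_CONST
        scale_a = (interior[:, 1] - 1.0) * (1.0 - contact_area) / (1.0 - CONTACT_AREA_CONST)
        knots = np.vstack(
            [
                [contact_pressure, contact_area],
                np.column_stack([interior[:, 0] * scale_p, 1.0 + scale_a]),
                [0.0, 1.0],
            ]
        )
        return cls(knots)

    @property
    def contact_pressure(self) -> float:
        """Dimensionless contact pressure ``Pi_p*`` (most negative knot)."""
        return float(self.knots[0, 0])

    @property
    def contact_area(self) -> float:
        """Dimensionless contact area (plateau value) ``Pi_A*``."""
        return float(self.knots[0, 1])

    def area(self, pi_p, clamp: bool = True):
        """Evaluate ``Pi_A(Pi_p)``; below contact the plateau value applies."""
        pi_p = np.asarray(pi_p, dtype=float)
        top = float(self.knots[-1, 0])
        if np.any(pi_p > top + 1e-12):
            raise ValueError(f"Pi_p above the curve domain (max {top})")
        clamped = np.clip(pi_p, self.contact_pressure, top)
        if not clamp and np.any(pi_p < self.contact_pressure):
            raise BelowContactError(
                f"Pi_p below the contact pressure Pi_p* = {self.contact_pressure}"
            )
        out = self._interp(clamped)
        return float(out) if out.ndim == 0 else out

    def pressure(self, pi_A) -> float:
        """Inverse of :meth:`area` (scalar): ``Pi_p`` such that
        ``Pi_A(Pi_p) = pi_A``.  Exact inverse by root finding on the
        interpolant itself."""
        pi_A = float(pi_A)
        lo, hi = self.contact_area, float(self.knots[-1, 1])
        tol = 1e-12
        if pi_A < lo - 1e-12:
            raise BelowContactError(
                f"Pi_A = {pi_A} below the contact area Pi_A* = {lo}"
            )
        if pi_A > hi + 1e-12:
            raise ValueError(f"Pi_A = {pi_A} above the open-tube value {hi}")
        pi_A = min(max(pi_A, lo), hi)
        if pi_A <= lo + tol:
            return self.contact_pressure
        if pi_A >= hi - tol:
            return float(self.knots[-1, 0])
        return float(
            brentq(
                lambda x: float(self._interp(x)) - pi_A,
                self.contact_pressure,
                float(self.knots[-1, 0]),
                xtol=1e-15,
                rtol=8.9e-16,
            )
        )

    def d_area_d_pressure(self, pi_p):
        """Analytic slope ``dPi_A/dPi_p`` of the interpolant."""
        pi_p = np.asarray(pi_p, dtype=float)
        out = np.where(
            pi_p < self.contact_pressure, 0.0, self._dinterp(np.clip(pi_p, self.contact_pressure, None))
        )
        return float(out) if out.ndim == 0 else out


DEFAULT_MASTER_CURVE = MasterCurve.default()


@dataclass(frozen=True)
class TubeLawCurve:
    """One measured (or synthesized) tube-law curve for a single tube.

    ``p_c`` and ``A_c`` are co-monotone sample arrays (more suction, smaller
    area); ``sigma_A`` optionally carries per-sample area uncertainties.
    Pressures must be strictly monotone; areas must follow the same overall
    direction, but sample-to-sample inversions from measurement noise are
    tolerated.
    """

    geometry: TubeGeometry
    material: Material
    p_c: np.ndarray
    A_c: np.ndarray
    sigma_A: np.ndarray | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.p_c, dtype=float)
        A = np.asarray(self.A_c, dtype=float)
        object.__setattr__(self, "p_c", p)
        object.__setattr__(self, "A_c", A)
        if p.shape != A.shape or p.ndim != 1 or p.size < 2:
            raise ValueError("p_c and A_c must be 1-d arrays of equal length >= 2")
        if np.any(A <= 0):
            raise ValueError("areas must be positive")
        dp = np.diff(p)
        if not (np.all(dp > 0) or np.all(dp < 0)):
            raise ValueError("p_c samples must be strictly monotone")
        if (A[np.argmax(p)] - A[np.argmin(p)]) <= 0:
            raise ValueError("tube law must be monotone: A_c must co-vary with p_c")
        if self.sigma_A is not None:
            s = np.asarray(self.sigma_A, dtype=float)
            object.__setattr__(self, "sigma_A", s)
            if s.shape != A.shape:
                raise ValueError("sigma_A must match A_c in shape")


def tube_law_eval(
    geom: TubeGeometry,
    mat: Material,
    A_c: float,
    curve: MasterCurve = DEFAULT_MASTER_CURVE,
    exps: CollapseExponents = DEFAULT_EXPONENTS,
) -> float:
    """Dimensional tube law ``p_c = f_t(A_c)`` in Pa.

    Nondimensionalizes the area, inverts the master curve and
    redimensionalizes the resulting pressure.  Valid for areas between the
    contact area ``A_c*`` and the open-tube area.
    """
    pi_A = nondim_area(geom, float(A_c), exps)
    if pi_A < curve.contact_area - 1e-12:
        a_star = dim_area(geom, curve.contact_area, exps)
        raise BelowContactError(
            f"A_c = {A_c:.6g} m^2 is below the contact area A_c* = {a_star:.6g} m^2"
        )
    pi_p = curve.pressure(pi_A)
    return dim_pressure(geom, mat, pi_p, exps)


def tube_law_slope(
    geom: TubeGeometry,
    mat: Material,
    A_c: float,
    curve: MasterCurve = DEFAULT_MASTER_CURVE,
    exps: CollapseExponents = DEFAULT_EXPONENTS,
) -> float:
    """Analytic slope ``d f_t / d A_c`` (Pa / m^2) of the tube law."""
    pi_A = nondim_area(geom, float(A_c), exps)
    pi_p = curve.pressure(pi_A)
    dA_dp = curve.d_area_d_pressure(pi_p)
    if dA_dp <= 0:
        return math.inf
    # chain rule through both nondimensionalizations
    dpi_A_dA = _area_scale(geom, exps) / geom.reference_area
    dp_dpi_p = mat.effective_modulus / _pressure_scale(geom, exps)
    return dp_dpi_p * (1.0 / dA_dp) * dpi_A_dA


# ---------------------------------------------------------------------------
# Exponent fitting (dimensional-collapse optimization)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExponentFit:
    """Result of the collapse-exponent optimization."""

    exponents: CollapseExponents
    residual: float  # normalized collapse misfit at the optimum
    contact_area_const: float  # C_A estimated from the collapsed cloud
    contact_pressure_const: float  # C_p estimated from the collapsed cloud
    n_evaluations: int = 0


def _curve_features(curves: Sequence[TubeLawCurve]):
    """Precompute per-curve log geometry ratios and scaled samples."""
    feats = []
    for c in curves:
        g, m = c.geometry, c.material
        feats.append(
            (
                math.log(g.stretch),
                math.log(g.h / g.a),
                math.log(g.l0 / g.a),
                c.A_c / g.reference_area,
                c.p_c / m.effective_modulus,
            )
        )
    return feats


def collapse_misfit(curves: Sequence[TubeLawCurve], exps: CollapseExponents) -> float:
    """Normalized misfit of the pooled dimensionless cloud.

    All samples are nondimensionalized with ``exps``, a monotone reference
    curve is fitted to the pooled cloud (isotonic regression of Pi_A on
    Pi_p), and the objective is the mean squared vertical deviation divided
    by the pooled Pi_A variance.  The normalization removes the trivial
    shrinkage of the residual under extreme area exponents.
    """
    feats = _curve_features(curves)
    return _misfit_from_features(feats, exps.as_array())


_ISO = IsotonicRegression(increasing=True, out_of_bounds="clip")


def _misfit_from_features(feats, e: np.ndarray) -> float:
    alpha, beta, gamma, delta = e
    xs, ys = [], []
    for log_ll0, log_ha, log_l0a, base_A, base_p in feats:
        ys.append(base_A * math.exp(alpha * log_ll0))
        xs.append(
            base_p * math.exp(beta * log_ll0 + gamma * log_ha + delta * log_l0a)
        )
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    var = float(np.var(y))
    if var < 1e-30:
        return 1.0
    order = np.argsort(x, kind="stable")
    fit = _ISO.fit_transform(x[order], y[order])
    return float(np.mean((fit - y[order]) ** 2)) / var


def _check_identifiable(curves: Sequence[TubeLawCurve]) -> None:
    ratios = {
        "l/l0": [c.geometry.stretch for c in curves],
        "h/a": [c.geometry.h / c.geometry.a for c in curves],
        "l0/a": [c.geometry.l0 / c.geometry.a for c in curves],
    }
    for name, vals in ratios.items():
        if np.ptp(vals) < 1e-9 * max(abs(v) for v in vals):
            raise IdentifiabilityError(
                f"dataset cannot identify the exponents: the ratio {name} is "
                "constant across the dataset (need >= 2 distinct values)"
            )


def fit_exponents(
    curves: Sequence[TubeLawCurve],
    bounds: tuple[float, float] = (-3.0, 3.0),
    grid_step: float = 0.25,
    coarse_step: float = 1.0,
) -> ExponentFit:
    """Recover the collapse exponents from a dataset of tube-law curves.

    An exhaustive coarse grid search over ``bounds`` (step ``coarse_step``)
    is followed by a local refinement at ``grid_step`` resolution around the
    coarse optimum.  The objective is :func:`collapse_misfit`; ties are
    broken by the smallest L1 norm of the exponent vector.  Contact
    constants are then estimated from the most-collapsed sample of each
    curve, nondimensionalized with the fitted exponents.

    Requires at least two distinct values of each of l/l0, h/a and l0/a
    across the dataset; otherwise raises :class:`IdentifiabilityError`.
    """
    if len(curves) < 2:
        raise IdentifiabilityError("need at least two curves to fit exponents")
    _check_identifiable(curves)
    lo, hi = bounds
    if not hi > lo:
        raise ValueError("bounds must satisfy hi > lo")
    feats = _curve_features(curves)
    n_eval = 0

    def search(axes: list[np.ndarray]) -> tuple[np.ndarray, float]:
        nonlocal n_eval
        best_e, best_val, best_l1 = None, math.inf, math.inf
        for ea in axes[0]:
            for eb in axes[1]:
                for eg in axes[2]:
                    for ed in axes[3]:
                        e = np.array([ea, eb, eg, ed])
                        val = _misfit_from_features(feats, e)
                        n_eval += 1
                        l1 = float(np.abs(e).sum())
                        if val < best_val - 1e-15 or (
                            abs(val - best_val) <= 1e-15 and l1 < best_l1
                        ):
                            best_e, best_val, best_l1 = e, val, l1
        return best_e, best_val

    coarse_axes = [np.arange(lo, hi + coarse_step / 2, coarse_step)] * 4
    e0, _ = search(coarse_axes)
    fine_axes = [
        np.clip(np.arange(c - coarse_step, c + coarse_step + grid_step / 2, grid_step), lo, hi)
        for c in e0
    ]
    e1, val1 = search([np.unique(ax) for ax in fine_axes])
    exps = CollapseExponents(*e1)
    c_area, c_press = estimate_contact_constants(curves, exps)
    return ExponentFit(
        exponents=exps,
        residual=val1,
        contact_area_const=c_area,
        contact_pressure_const=c_press,
        n_evaluations=n_eval,
    )


def estimate_contact_constants(
    curves: Iterable[TubeLawCurve], exps: CollapseExponents = DEFAULT_EXPONENTS
) -> tuple[float, float]:
    """Estimate (C_A, C_p) from the most-collapsed sample of each curve.

    Each curve's smallest-area sample approximates the wall-contact point;
    its dimensionless coordinates are averaged over the dataset.
    """
    pi_As, pi_ps = [], []
    for c in curves:
        i = int(np.argmin(c.A_c))
        pi_As.append(nondim_area(c.geometry, c.A_c[i], exps))
        pi_ps.append(nondim_pressure(c.geometry, c.material, c.p_c[i], exps))
    return float(np.mean(pi_As)), float(np.mean(pi_ps))
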