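"""Collapse-risk maps over a per-generation model of the human airway tree.

The airways are described generation by generation (0 = trachea): each
generation has a number of parallel airways of a given length, radius, wall
thickness and axial stretch.  Summing the areas of all airways reached at a
given depth gives a cumulative cross-sectional area ``A(x)``; conservation
of volumetric flux then gives the per-generation velocity

    v(x) = A_i v_i / A(x),

with ``A_i``, ``v_i`` the tracheal inlet area and velocity.  Two
dimensionless maps locate where wheezing can start: the collapse-ratio map
``P_drive / |p_c*|`` (is the transmural pressure enough to collapse the
airway?) and the dynamic-ratio map ``(1/2 rho v^2) / |p_c*|`` (is the flow
strong enough to drive oscillation?), both using the generalized tube law's
collapse pressure for each generation's geometry.

The packaged default table is synthetic: a representative symmetric
dichotomy with classical morphometric diameters, branch lengths within
about four diameters, uniform wall thickness ratio h/a = 0.1 and uniform
axial stretch 1.25 (airway-by-airway values are not part of this package).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import CMH2O_PA, Material, TubeGeometry
from .tube_law import CollapseExponents, DEFAULT_EXPONENTS, collapse_state

__all__ = [
    "AirwayGeneration",
    "AirwayTree",
    "GenerationMap",
    "load_airway_tree",
    "default_airway_tree",
    "velocity_profile",
    "collapse_ratio_map",
    "dynamic_ratio_map",
]

_REQUIRED_COLUMNS = (
    "generation",
    "count",
    "length_m",
    "radius_m",
    "wall_thickness_m",
    "stretch",
)


@dataclass(frozen=True)
class AirwayGeneration:
    """One generation of the airway tree."""

    index: int
    count: int
    l: float  # stretched branch length, m
    a: float  # unstrained radius, m
    h: float  # wall thickness, m
    stretch: float  # l / l0
    x: float  # cumulative entry depth of this generation, m

    def geometry(self) -> TubeGeometry:
        return TubeGeometry(l=self.l, l0=self.l / self.stretch, a=self.a, h=self.h)

    @property
    def total_area(self) -> float:
        """Cumulative (summed over parallel airways) open area, m^2."""
        return self.count * np.pi * self.a**2


@dataclass(frozen=True)
class AirwayTree:
    """Ordered generations plus the tracheal inlet reference."""

    generations: tuple[AirwayGeneration, ...]

    @property
    def inlet_area(self) -> float:
        return self.generations[0].total_area

    def cumulative_area(self) -> np.ndarray:
        """``A(x)`` per generation (piecewise constant), m^2."""
        return np.array([g.total_area for g in self.generations])


@dataclass(frozen=True)
class GenerationMap:
    """A dimensionless scalar per generation."""

    generations: np.ndarray  # generation indices
    values: np.ndarray
    name: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"generation": self.generations, self.name: self.values})


def load_airway_tree(source) -> AirwayTree:
    """Read and validate a per-generation airway table.

    ``source`` is a path or a DataFrame with columns: generation, count,
    length_m, radius_m, wall_thickness_m, stretch.  Generations must be
    consecutive from 0 (trachea first) with positive dimensions; entry
    depths are accumulated from the branch lengths.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, comment="#")
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"airway table is missing required columns: {missing}")
    df = df.sort_values("generation").reset_index(drop=True)
    if list(df["generation"]) != list(range(len(df))):
        raise ValueError("generations must be consecutive integers starting at 0")
    if len(df) < 2:
        raise ValueError("airway table needs at least 2 generations")
    if (df[["count", "length_m", "radius_m", "wall_thickness_m"]] <= 0).any().any():
        raise ValueError("airway counts and dimensions must be positive")
    if (df["stretch"] < 1.0).any():
        raise ValueError("airways are in tension: stretch must be >= 1")
    depths = np.concatenate([[0.0], np.cumsum(df["length_m"].to_numpy())[:-1]])
    gens = tuple(
        AirwayGeneration(
            index=int(r.generation),
            count=int(r.count),
            l=float(r.length_m),
            a=float(r.radius_m),
            h=float(r.wall_thickness_m),
            stretch=float(r.stretch),
            x=float(x),
        )
        for r, x in zip(df.itertuples(), depths)
    )
    tree = AirwayTree(generations=gens)
    areas = tree.cumulative_area()
    if np.any(areas < tree.inlet_area * (1.0 - 1e-12)):
        raise ValueError(
            "cumulative area must not fall below the tracheal inlet area "
            "(branching increases total area)"
        )
    return tree


def default_airway_tree() -> AirwayTree:
    """The packaged synthetic per-generation table (trachea + 8 generations)."""
    text = resources.files("wheezekit.data").joinpath(
        "airway_generations_synthetic.csv"
    ).read_text()
    return load_airway_tree(pd.read_csv(io.StringIO(text), comment="#"))


def velocity_profile(tree: AirwayTree, v_i: float) -> np.ndarray:
    """Per-generation velocity ``v = A_i v_i / A(x)`` (m/s).

    Volumetric flux ``A(x) v(x)`` is conserved exactly across generations.
    """
    if not v_i > 0:
        raise ValueError("tracheal inlet velocity must be positive")
    return tree.inlet_area * v_i / tree.cumulative_area()


def _collapse_pressures(
    tree: AirwayTree, mat: Material, exps: CollapseExponents
) -> np.ndarray:
    return np.array(
        [abs(collapse_state(g.geometry(), mat, exps).p_c_star) for g in tree.generations]
    )


def collapse_ratio_map(
    tree: AirwayTree,
    mat: Material,
    P_drive: float = 20.0 * CMH2O_PA,
    exps: CollapseExponents = DEFAULT_EXPONENTS,
) -> GenerationMap:
    """Per-generation ``P_drive / |p_c*|``.

    ``P_drive`` is the largest transmural pressure magnitude any airway can
    see (an upper bound: real pressure drops along the tree make it
    smaller).  The default is the normal-breathing bound of 20 cmH2O;
    forced expiration can more than double it.  Values below 1 mean the
    airway cannot collapse, ruling out wheeze at that drive.
    """
    if P_drive < 0:
        raise ValueError("driving pressure magnitude must be >= 0")
    ratios = P_drive / _collapse_pressures(tree, mat, exps)
    return GenerationMap(
        generations=np.array([g.index for g in tree.generations]),
        values=ratios,
        name="collapse_ratio",
    )


def dynamic_ratio_map(
    tree: AirwayTree,
    mat: Material,
    rho: float = 1.2,
    v_i: float | None = None,
    Q_mouth: float = 6.5e-3,
    exps: CollapseExponents = DEFAULT_EXPONENTS,
) -> GenerationMap:
    """Per-generation ``(1/2 rho v(x)^2) / |p_c*|`` for uncollapsed airways.

    ``v_i`` defaults to ``Q_mouth / A_i`` (expiratory mouth flowrate over
    tracheal area; normal expiration reaches 6.5-11.5 l/s).  Because the
    ratio is quadratic in velocity, collapsing an airway to a tenth of its
    area multiplies its ratio by a hundred — which is what lifts a quietly
    breathing lung into the oscillation-capable band during forced
    expiration.
    """
    if v_i is None:
        v_i = Q_mouth / tree.inlet_area
    v = velocity_profile(tree, v_i)
    ratios = 0.5 * rho * v**2 / _collapse_pressures(tree, mat, exps)
    return GenerationMap(
        generations=np.array([g.index for g in tree.generations]),
        values=ratios,
        name="dynamic_ratio",
    )
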