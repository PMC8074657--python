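"""Dimensional description of a thin-walled elastic tube and its wall material.

A tube is cut to an unstrained length ``l0``, has unstrained radius ``a``
(diameter ``d = 2a``) and wall thickness ``h``, and is mounted axially
stretched to a length ``l >= l0`` — airways in the lung are held in axial
tension, and the bench model reproduces that.  All quantities are SI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

#: Conversion factor: 1 cmH2O in pascal (exact, conventional value).
CMH2O_PA = 98.0665


@dataclass(frozen=True)
class TubeGeometry:
    """Geometry of a stretched thin-walled elastic tube.

    Parameters
    ----------
    l : float
        Mounted (stretched) length in metres.
    l0 : float
        Unstrained length in metres; ``l >= l0``.
    a : float
        Unstrained radius in metres.
    h : float
        Wall thickness in metres; must satisfy ``h < a`` (thin wall).
    """

    l: float
    l0: float
    a: float
    h: float

    def __post_init__(self) -> None:
        for name in ("l", "l0", "a", "h"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)!r}")
        if self.l < self.l0:
            raise ValueError(
                f"tubes are held in tension: l={self.l} must be >= l0={self.l0}"
            )
        if not self.h < self.a:
            raise ValueError(f"thin-wall assumption requires h < a (h={self.h}, a={self.a})")

    @property
    def stretch(self) -> float:
        """Axial stretch ratio ``l / l0`` (>= 1)."""
        return self.l / self.l0

    @property
    def strain(self) -> float:
        """Axial engineering strain ``(l - l0) / l0``."""
        return self.l / self.l0 - 1.0

    @property
    def reference_area(self) -> float:
        """Unstrained fully-open cross-sectional area ``pi a**2`` (m^2)."""
        return math.pi * self.a**2


@dataclass(frozen=True)
class Material:
    """Linear-elastic wall material.

    Parameters
    ----------
    E : float
        Young's modulus in Pa.
    nu : float
        Poisson's ratio, in [0, 0.5].  Rubber and lung tissue are close to
        incompressible (nu = 0.5).
    rho_s : float
        Wall density in kg/m^3.
    """

    E: float = 1.0e6
    nu: float = 0.5
    rho_s: float = 1000.0

    def __post_init__(self) -> None:
        if not self.E > 0:
            raise ValueError(f"E must be positive, got {self.E!r}")
        if not 0.0 <= self.nu <= 0.5:
            raise ValueError(f"nu must be in [0, 0.5], got {self.nu!r}")
        if not self.rho_s > 0:
            raise ValueError(f"rho_s must be positive, got {self.rho_s!r}")

    @property
    def effective_modulus(self) -> float:
        """Plane-strain modulus ``E / (1 - nu^2)`` (Pa).

        Thin-shell deformation energy depends on E and nu only through this
        combination, which is why it is the pressure scale of the
        dimensionless tube law.
        """
        return self.E / (1.0 - self.nu**2)
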