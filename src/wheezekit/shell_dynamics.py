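"""Linear dynamics of a thin cylindrical shell under axial pre-tension.

The tube wall is modelled as a thin elastic cylindrical shell (radius ``a``,
thickness ``h``, density ``rho_s``) with harmonic displacements
``exp(i(k x + m theta - omega t))``: ``k`` is the axial wavenumber, ``m``
the azimuthal mode number (m = 2 is the elliptical flattening mode seen at
onset).  The operator is the Donnell-Mushtari thin-shell operator with the
Morley-Koiter bending correction, which restores the classical
inextensional ring frequencies at k = 0, plus a geometric-stiffness term
``n_x lambda^2`` on the radial equation from the axial pre-stress resultant
``N_x`` (airways, like the bench tubes, are held in axial tension).

With lambda = k a, the dimensionless eigenproblem is ``K q = Omega^2 q``
for the symmetric 3x3 stiffness matrix K(lambda, m), where
``Omega^2 = rho_s (1 - nu^2) a^2 omega^2 / E``.  The smallest branch gives
the frequencies and, through d(omega)/dk, the group velocity used as the
upstream elastic wave speed in the flutter onset predictor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import Material, TubeGeometry

__all__ = [
    "PrestressSpec",
    "ShellWave",
    "ShellStabilityError",
    "dispersion_omega",
    "dispersion_spectrum",
    "group_velocity",
    "modal_frequency",
    "dispersion_branch",
]


class ShellStabilityError(RuntimeError):
    """A negative squared eigenfrequency: the parameterization is unstable."""


@dataclass(frozen=True)
class PrestressSpec:
    """Axial pre-stress resultant ``N_x`` in N/m (>= 0 for stretched tubes)."""

    N_x: float

    def __post_init__(self) -> None:
        if self.N_x < 0:
            raise ValueError("stretched tubes carry tensile (>= 0) axial pre-stress")

    @classmethod
    def from_geometry(cls, geom: TubeGeometry, mat: Material) -> "PrestressSpec":
        """Membrane tension from the mounted stretch:
        ``N_x = (E/(1-nu^2)) h (l - l0)/l0``."""
        return cls(N_x=mat.effective_modulus * geom.h * geom.strain)

    def dimensionless(self, geom: TubeGeometry, mat: Material) -> float:
        """``n_x = N_x / ((E/(1-nu^2)) h)`` — equals the strain when derived
        from the geometry."""
        return self.N_x / (mat.effective_modulus * geom.h)


@dataclass(frozen=True)
class ShellWave:
    """A point on the lowest dispersion branch."""

    m: int
    k: float
    omega: float  # rad/s
    c_g: float  # m/s


def _shell_matrix(lam: float, n: int, beta2: float, nx: float, nu: float) -> np.ndarray:
    """Symmetric dimensionless shell stiffness matrix at (lambda, n)."""
    bend = beta2 * (lam**2 + n**2 - 1.0) ** 2
    return np.array(
        [
            [lam**2 + 0.5 * (1 - nu) * n**2, 0.5 * (1 + nu) * lam * n, nu * lam],
            [0.5 * (1 + nu) * lam * n, 0.5 * (1 - nu) * lam**2 + n**2, float(n)],
            [nu * lam, float(n), 1.0 + bend + nx * lam**2],
        ]
    )


def _d_shell_matrix_dlam(lam: float, n: int, beta2: float, nx: float, nu: float) -> np.ndarray:
    dbend = 4.0 * beta2 * lam * (lam**2 + n**2 - 1.0)
    return np.array(
        [
            [2.0 * lam, 0.5 * (1 + nu) * n, nu],
            [0.5 * (1 + nu) * n, (1 - nu) * lam, 0.0],
            [nu, 0.0, dbend + 2.0 * nx * lam],
        ]
    )


def _params(geom: TubeGeometry, mat: Material, prestress: PrestressSpec | None):
    if prestress is None:
        prestress = PrestressSpec.from_geometry(geom, mat)
    beta2 = geom.h**2 / (12.0 * geom.a**2)
    nx = prestress.dimensionless(geom, mat)
    # omega = Omega * freq_scale
    freq_scale = math.sqrt(mat.E / (mat.rho_s * (1.0 - mat.nu**2))) / geom.a
    return beta2, nx, freq_scale


def dispersion_spectrum(
    geom: TubeGeometry,
    mat: Material,
    prestress: PrestressSpec | None = None,
    m: int = 2,
    k: float = 0.0,
) -> np.ndarray:
    """All three branch frequencies (rad/s, ascending) at (m, k)."""
    if m < 0 or int(m) != m:
        raise ValueError("azimuthal mode number m must be a non-negative integer")
    if k < 0:
        raise ValueError("axial wavenumber k must be >= 0")
    beta2, nx, scale = _params(geom, mat, prestress)
    eig = np.linalg.eigvalsh(_shell_matrix(k * geom.a, int(m), beta2, nx, mat.nu))
    if eig[0] < -1e-12 * max(1.0, abs(eig[-1])):
        raise ShellStabilityError(
            f"negative squared eigenfrequency {eig[0]:.3g} at (m={m}, k={k}): "
            "unstable shell parameterization"
        )
    return np.sqrt(np.clip(eig, 0.0, None)) * scale


def dispersion_omega(
    geom: TubeGeometry,
    mat: Material,
    prestress: PrestressSpec | None = None,
    m: int = 2,
    k: float = 0.0,
) -> float:
    """Smallest real eigenfrequency (rad/s) of the shell at (m, k)."""
    return float(dispersion_spectrum(geom, mat, prestress, m, k)[0])


def group_velocity(
    geom: TubeGeometry,
    mat: Material,
    prestress: PrestressSpec | None = None,
    m: int = 2,
    k: float | None = None,
) -> float:
    """Group velocity ``d omega / d k`` (m/s) of the lowest branch.

    Analytic via first-order eigenvalue perturbation (Hellmann-Feynman):
    ``d Omega^2 / d lambda = q^T (dK/dlambda) q`` for the unit eigenvector
    q of the lowest branch.  Defaults to the half-wavelength standing-wave
    wavenumber ``k = pi / l``.
    """
    if k is None:
        k = math.pi / geom.l
    if not k > 0:
        raise ValueError("group velocity needs k > 0")
    beta2, nx, scale = _params(geom, mat, prestress)
    lam = k * geom.a
    K = _shell_matrix(lam, int(m), beta2, nx, mat.nu)
    w, V = np.linalg.eigh(K)
    if w[0] < -1e-12 * max(1.0, abs(w[-1])):
        raise ShellStabilityError(
            f"negative squared eigenfrequency at (m={m}, k={k})"
        )
    q = V[:, 0]
    dOm2 = float(q @ _d_shell_matrix_dlam(lam, int(m), beta2, nx, mat.nu) @ q)
    Om = math.sqrt(max(w[0], 0.0))
    if Om == 0.0:
        raise ShellStabilityError(f"zero eigenfrequency at (m={m}, k={k}); c_g undefined")
    # omega = Om * scale, lam = k a  ->  d omega/d k = a scale dOm/dlam
    return geom.a * scale * dOm2 / (2.0 * Om)


def modal_frequency(
    geom: TubeGeometry,
    mat: Material,
    prestress: PrestressSpec | None = None,
    m: int = 2,
) -> float:
    """Lowest standing-wave frequency (Hz) of the mounted tube.

    Pinned ends select the half-wavelength axial wavenumber ``k = pi / l``.
    A purely structural quantity: no rig or flow parameters enter.
    """
    return dispersion_omega(geom, mat, prestress, m, k=math.pi / geom.l) / (2.0 * math.pi)


def dispersion_branch(
    geom: TubeGeometry,
    mat: Material,
    prestress: PrestressSpec | None = None,
    m: int = 2,
    k_grid=None,
) -> list[ShellWave]:
    """Lowest branch along a k grid, tracked by eigenvector continuity.

    At each step the branch is continued by maximum overlap with the
    previous eigenvector, which guards against mislabeling at branch
    crossings; a warning-free traversal implies a continuous branch.
    """
    if k_grid is None:
        k_grid = np.linspace(math.pi / geom.l / 4, 4 * math.pi / geom.l, 50)
    k_grid = np.asarray(k_grid, dtype=float)
    beta2, nx, scale = _params(geom, mat, prestress)
    waves: list[ShellWave] = []
    q_prev = None
    for k in k_grid:
        lam = float(k) * geom.a
        K = _shell_matrix(lam, int(m), beta2, nx, mat.nu)
        w, V = np.linalg.eigh(K)
        if q_prev is None:
            idx = 0
        else:
            idx = int(np.argmax(np.abs(V.T @ q_prev)))
        q = V[:, idx]
        q_prev = q
        Om2 = float(w[idx])
        if Om2 < 0:
            raise ShellStabilityError(f"negative squared eigenfrequency at k={k}")
        dOm2 = float(q @ _d_shell_matrix_dlam(lam, int(m), beta2, nx, mat.nu) @ q)
        Om = math.sqrt(Om2)
        cg = geom.a * scale * dOm2 / (2.0 * Om) if Om > 0 else math.nan
        waves.append(ShellWave(m=int(m), k=float(k), omega=Om * scale, c_g=cg))
    return waves
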