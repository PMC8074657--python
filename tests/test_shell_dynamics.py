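"""Shell dispersion relation, group velocity, modal frequencies."""

import math

import numpy as np
import pytest

import wheezekit as wk
from wheezekit.shell_dynamics import (
    PrestressSpec,
    ShellStabilityError,
    dispersion_branch,
    dispersion_omega,
    group_velocity,
    modal_frequency,
)


class TestDispersion:
    def test_ring_mode_matches_thin_ring_formula(self, bench_tube, rubber):
        # closed-form oracle: inextensional flexural ring mode with
        # extensional correction, omega^2 = (E h^2 / (12 (1-nu^2) rho a^4))
        #                                  * n^2 (n^2-1)^2 / (n^2 + 1)
        n = 2
        omega = dispersion_omega(bench_tube, rubber, m=n, k=0.0)
        ring = math.sqrt(
            rubber.E
            * bench_tube.h**2
            / (12 * (1 - rubber.nu**2) * rubber.rho_s * bench_tube.a**4)
            * n**2
            * (n**2 - 1) ** 2
            / (n**2 + 1)
        )
        assert omega == pytest.approx(ring, rel=1e-2)

    def test_frequency_scales_with_sqrt_modulus(self, bench_tube):
        soft = wk.Material(E=1e6, nu=0.5, rho_s=1000.0)
        stiff = wk.Material(E=2e6, nu=0.5, rho_s=1000.0)
        k = math.pi / bench_tube.l
        # prestress derived from the geometry scales with E automatically
        assert dispersion_omega(bench_tube, stiff, m=2, k=k) == pytest.approx(
            math.sqrt(2.0) * dispersion_omega(bench_tube, soft, m=2, k=k), rel=1e-12
        )

    def test_tension_stiffening(self, bench_tube, rubber):
        k = math.pi / bench_tube.l
        base = PrestressSpec.from_geometry(bench_tube, rubber)
        taut = PrestressSpec(N_x=2.0 * base.N_x)
        assert dispersion_omega(bench_tube, rubber, taut, m=2, k=k) > dispersion_omega(
            bench_tube, rubber, base, m=2, k=k
        )

    def test_rigid_body_mode_is_zero_not_an_error(self, bench_tube, rubber):
        # m = 0, k = 0: rigid translation/rotation, zero frequency
        assert dispersion_omega(bench_tube, rubber, m=0, k=0.0) == 0.0

    def test_invalid_mode_inputs(self, bench_tube, rubber):
        with pytest.raises(ValueError):
            dispersion_omega(bench_tube, rubber, m=-1, k=1.0)
        with pytest.raises(ValueError):
            dispersion_omega(bench_tube, rubber, m=2, k=-1.0)

    def test_lowest_branch_continuous_in_k(self, bench_tube, rubber):
        waves = dispersion_branch(bench_tube, rubber, m=2)
        om = np.array([w.omega for w in waves])
        k = np.array([w.k for w in waves])
        rel_jump = np.abs(np.diff(om)) / om[:-1]
        dk = np.diff(k) / k[:-1]
        assert np.all(rel_jump < 5 * dk + 0.05)

    def test_geometric_scaling(self, rubber):
        # scaling every length by s leaves the dimensionless problem
        # unchanged, so omega scales by 1/s
        g1 = wk.TubeGeometry(l=23e-3, l0=20.4e-3, a=3e-3, h=0.35e-3)
        g2 = wk.TubeGeometry(l=46e-3, l0=40.8e-3, a=6e-3, h=0.7e-3)
        w1 = dispersion_omega(g1, rubber, m=2, k=math.pi / g1.l)
        w2 = dispersion_omega(g2, rubber, m=2, k=math.pi / g2.l)
        assert w2 == pytest.approx(w1 / 2.0, rel=1e-12)


class TestGroupVelocity:
    def test_matches_finite_difference(self, bench_tube, rubber):
        for m in (0, 1, 2):
            for frac in (0.5, 1.0, 2.0):
                k = frac * math.pi / bench_tube.l
                dk = k * 1e-4
                fd = (
                    dispersion_omega(bench_tube, rubber, m=m, k=k + dk)
                    - dispersion_omega(bench_tube, rubber, m=m, k=k - dk)
                ) / (2 * dk)
                assert group_velocity(bench_tube, rubber, m=m, k=k) == pytest.approx(
                    fd, rel=1e-6
                )

    def test_string_limit_on_decoupled_radial_branch(self):
        # axisymmetric radial branch of a zero-Poisson, vanishing-bending
        # shell: Omega^2 = 1 + eps lam^2, so at large lam the group velocity
        # approaches the tensioned-membrane speed sqrt(N_x / (rho_s h))
        a = 5e-3
        geom = wk.TubeGeometry(l=0.065, l0=0.05, a=a, h=0.05e-3)
        mat = wk.Material(E=1e6, nu=0.0, rho_s=1000.0)
        c_membrane = math.sqrt(
            PrestressSpec.from_geometry(geom, mat).N_x / (mat.rho_s * geom.h)
        )
        rel = [
            abs(group_velocity(geom, mat, m=0, k=lam / a) / c_membrane - 1.0)
            for lam in (6.0, 10.0, 16.0)
        ]
        assert rel[2] < rel[1] < rel[0]
        assert rel[2] < 0.02

    def test_nonnegative_on_lowest_branch(self, bench_tube, rubber):
        waves = dispersion_branch(bench_tube, rubber, m=2)
        assert all(w.c_g >= 0.0 for w in waves)

    def test_requires_positive_wavenumber(self, bench_tube, rubber):
        with pytest.raises(ValueError):
            group_velocity(bench_tube, rubber, m=2, k=0.0)


class TestModalFrequency:
    def test_consistent_with_dispersion_at_half_wavelength(self, bench_tube, rubber):
        f = modal_frequency(bench_tube, rubber, m=2)
        omega = dispersion_omega(bench_tube, rubber, m=2, k=math.pi / bench_tube.l)
        assert f == pytest.approx(omega / (2 * math.pi), rel=1e-12)

    def test_single_positive_frequency_for_bench_tube(self, bench_tube, rubber):
        f = modal_frequency(bench_tube, rubber, m=2)
        assert f > 0.0
        # oracle: the standing-wave frequency sits on the lowest branch,
        # below the branch values at any shorter wavelength
        ks = np.linspace(math.pi / bench_tube.l, 6 * math.pi / bench_tube.l, 200)
        branch = [dispersion_omega(bench_tube, rubber, m=2, k=float(k)) for k in ks]
        assert 2 * math.pi * f == pytest.approx(min(branch), rel=1e-9)

    def test_string_scaling_halves_with_doubled_length(self):
        # tension-dominated limit (m = 1 flexural branch, bending
        # negligible, pre-stress held fixed): f proportional to 1/l
        a = 5e-3
        mat = wk.Material(E=1e6, nu=0.0, rho_s=1000.0)
        pre = PrestressSpec(N_x=500.0)
        g1 = wk.TubeGeometry(l=0.25, l0=0.2, a=a, h=0.05e-3)
        g2 = wk.TubeGeometry(l=0.5, l0=0.4, a=a, h=0.05e-3)
        f1 = modal_frequency(g1, mat, pre, m=1)
        f2 = modal_frequency(g2, mat, pre, m=1)
        assert f1 / f2 == pytest.approx(2.0, rel=0.05)
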