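"""Tube-law nondimensionalization, master curve, collapse state, exponent fit."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import wheezekit as wk
from wheezekit.tube_law import (
    BelowContactError,
    CollapseExponents,
    IdentifiabilityError,
    MasterCurve,
    collapse_misfit,
    collapse_state,
    dim_area,
    dim_pressure,
    nondim_area,
    nondim_pressure,
    open_area,
    tube_law_eval,
    tube_law_slope,
)
from wheezekit.synthetic_data import TubeLawDatasetSpec, generate_tube_law_dataset


@st.composite
def geometries(draw):
    l0 = draw(st.floats(5e-3, 5e-2))
    stretch = draw(st.floats(1.0, 1.5))
    a = draw(st.floats(1e-3, 1e-2))
    h_frac = draw(st.floats(0.02, 0.3))
    return wk.TubeGeometry(l=stretch * l0, l0=l0, a=a, h=h_frac * a)


class TestNondimensionalization:
    def test_unstrained_open_tube_maps_to_one(self):
        g = wk.TubeGeometry(l=20e-3, l0=20e-3, a=3e-3, h=0.3e-3)
        assert nondim_area(g, math.pi * (3e-3) ** 2) == pytest.approx(1.0, rel=1e-12)

    def test_contact_area_group_is_the_contact_constant(self, bench_tube):
        A = 0.27 * bench_tube.reference_area * bench_tube.l0 / bench_tube.l
        assert nondim_area(bench_tube, A) == pytest.approx(0.27, rel=1e-12)

    def test_zero_pressure_maps_to_zero(self, bench_tube, rubber):
        assert nondim_pressure(bench_tube, rubber, 0.0) == 0.0

    def test_bench_tube_collapse_pressure_group(self, bench_tube, rubber):
        # hand evaluation of the pressure group at the measured collapse
        # pressure of the bench tube gives the contact constant
        assert nondim_pressure(bench_tube, rubber, -3489.0) == pytest.approx(-0.12, abs=2e-4)

    def test_pressure_group_linear_in_inverse_modulus(self, bench_tube):
        soft = wk.Material(E=1e6, nu=0.5)
        stiff = wk.Material(E=2e6, nu=0.5)
        p = -500.0
        assert nondim_pressure(bench_tube, stiff, p) == pytest.approx(
            nondim_pressure(bench_tube, soft, p) / 2.0, rel=1e-12
        )

    def test_nonpositive_area_rejected(self, bench_tube):
        with pytest.raises(ValueError):
            nondim_area(bench_tube, -1e-6)

    @given(geometries(), st.floats(1e-7, 1e-4), st.floats(-5000, -1))
    def test_nondim_dim_are_exact_inverses(self, g, A, p):
        m = wk.Material()
        assert dim_area(g, nondim_area(g, A)) == pytest.approx(A, rel=1e-12)
        assert dim_pressure(g, m, nondim_pressure(g, m, p)) == pytest.approx(p, rel=1e-12)


class TestCollapseState:
    def test_bench_tube_contact_area(self, bench_tube, rubber):
        st_ = collapse_state(bench_tube, rubber)
        assert st_.A_c_star == pytest.approx(6.77e-6, rel=1e-3)

    def test_bench_tube_contact_pressure(self, bench_tube, rubber):
        st_ = collapse_state(bench_tube, rubber)
        assert st_.p_c_star == pytest.approx(-3.49e3, rel=1e-3)

    def test_contact_pressure_vanishes_with_wall_thickness(self, rubber):
        mags = []
        for h in (0.5e-3, 0.25e-3, 0.1e-3, 0.02e-3):
            g = wk.TubeGeometry(l=23e-3, l0=20.4e-3, a=3e-3, h=h)
            mags.append(abs(collapse_state(g, rubber).p_c_star))
        assert mags == sorted(mags, reverse=True)
        # linear in h/a: magnitude proportional to h
        assert mags[0] / mags[1] == pytest.approx(2.0, rel=1e-12)


class TestMasterCurveAndEval:
    def test_open_tube_anchor(self, bench_tube, rubber):
        assert tube_law_eval(bench_tube, rubber, open_area(bench_tube)) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_contact_point_matches_collapse_state(self, bench_tube, rubber):
        st_ = collapse_state(bench_tube, rubber)
        assert tube_law_eval(bench_tube, rubber, st_.A_c_star) == pytest.approx(
            st_.p_c_star, rel=1e-9
        )

    def test_contact_consistency_for_other_geometries(self, rubber):
        for l0, a, h_frac, stretch in [(10e-3, 2e-3, 0.05, 1.05), (40e-3, 5e-3, 0.2, 1.4)]:
            g = wk.TubeGeometry(l=stretch * l0, l0=l0, a=a, h=h_frac * a)
            st_ = collapse_state(g, rubber)
            assert tube_law_eval(g, rubber, st_.A_c_star) == pytest.approx(
                st_.p_c_star, rel=1e-9
            )

    def test_below_contact_raises_naming_the_bound(self, bench_tube, rubber):
        st_ = collapse_state(bench_tube, rubber)
        with pytest.raises(BelowContactError, match="contact area"):
            tube_law_eval(bench_tube, rubber, 0.5 * st_.A_c_star)

    def test_monotone_in_area(self, bench_tube, rubber):
        st_ = collapse_state(bench_tube, rubber)
        areas = np.linspace(st_.A_c_star, open_area(bench_tube), 40)
        ps = [tube_law_eval(bench_tube, rubber, A) for A in areas]
        assert np.all(np.diff(ps) > 0)

    def test_slope_matches_finite_difference(self, bench_tube, rubber):
        st_ = collapse_state(bench_tube, rubber)
        lo, hi = st_.A_c_star, open_area(bench_tube)
        for frac in (0.15, 0.3, 0.5, 0.7, 0.85):
            A = lo + frac * (hi - lo)
            dA = A * 1e-7
            fd = (
                tube_law_eval(bench_tube, rubber, A + dA)
                - tube_law_eval(bench_tube, rubber, A - dA)
            ) / (2 * dA)
            assert tube_law_slope(bench_tube, rubber, A) == pytest.approx(fd, rel=1e-6)

    def test_curve_knots_must_be_monotone(self):
        with pytest.raises(ValueError):
            MasterCurve([(-0.12, 0.4), (-0.06, 0.3), (0.0, 1.0)])

    def test_plateau_below_contact(self):
        curve = MasterCurve.default()
        assert curve.area(-0.5) == pytest.approx(curve.contact_area)
        assert curve.d_area_d_pressure(-0.5) == 0.0


class TestExponentFit:
    def test_single_geometry_is_unidentifiable(self, bench_tube, rubber):
        from wheezekit.tube_law import TubeLawCurve, fit_exponents

        p = np.linspace(0.0, -3000.0, 10)
        A = np.linspace(2.5e-5, 7e-6, 10)
        curves = [
            TubeLawCurve(geometry=bench_tube, material=rubber, p_c=p, A_c=A)
            for _ in range(3)
        ]
        with pytest.raises(IdentifiabilityError, match="l/l0"):
            fit_exponents(curves)

    def test_constant_wall_ratio_named_in_error(self, rubber):
        from wheezekit.tube_law import fit_exponents

        spec = TubeLawDatasetSpec(h_over_a=(0.1, 0.1), seed=0)
        with pytest.warns(UserWarning, match="identify"):
            curves = generate_tube_law_dataset(spec)
        with pytest.raises(IdentifiabilityError, match="h/a"):
            fit_exponents(curves)

    def test_generating_exponents_are_global_minimum_on_coarse_grid(self):
        # brute-force oracle: misfit at the generating exponents must not be
        # beaten anywhere on a 5^4 grid around them (noiseless data)
        curves = generate_tube_law_dataset(TubeLawDatasetSpec(noise=0.0, seed=1))
        truth = CollapseExponents()
        ref = collapse_misfit(curves, truth)
        offsets = (-2.0, -1.0, 0.0, 1.0, 2.0)
        worse = 0
        for da in offsets:
            for db in offsets:
                for dg in offsets:
                    for dd in offsets:
                        if da == db == dg == dd == 0.0:
                            continue
                        e = CollapseExponents(1.0 + da, -2.0 + db, -1.0 + dg, 1.0 + dd)
                        assert collapse_misfit(curves, e) >= ref
                        worse += 1
        assert worse == 5**4 - 1
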