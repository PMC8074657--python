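"""Onset criteria, flutter frequency prediction, tonal onset detection."""

import math

import numpy as np
import pytest

import wheezekit as wk
from wheezekit.fluid_law import dynamic_pressure_ratio
from wheezekit.onset import (
    OnsetThresholds,
    PressureRun,
    SpectrogramParams,
    detect_onset,
    frequency_from_speeds,
    onset_criteria,
    predict_frequency,
    strouhal_number,
)
from wheezekit.tube_law import collapse_state


@pytest.fixture(scope="module")
def band_flow(bench_tube, rubber, rig):
    """A flowrate whose dynamic ratio sits inside the onset band."""
    for Q in np.linspace(1e-4, 3e-3, 100):
        r = dynamic_pressure_ratio(bench_tube, rubber, rig, float(Q))
        if 0.5 <= r <= 2.0:
            return float(Q)
    raise RuntimeError("no in-band flowrate found")


class TestCriteria:
    def test_collapse_point_with_band_flow_fires(self, bench_tube, rubber, rig, band_flow):
        p_star = collapse_state(bench_tube, rubber).p_c_star
        res = onset_criteria(bench_tube, rubber, rig, p_star, band_flow)
        assert res.near_collapse and res.in_band and res.onset

    def test_no_flow_never_fires(self, bench_tube, rubber, rig):
        p_star = collapse_state(bench_tube, rubber).p_c_star
        res = onset_criteria(bench_tube, rubber, rig, p_star, 0.0)
        assert res.dynamic_ratio == 0.0
        assert not res.onset

    def test_open_tube_does_not_fire(self, bench_tube, rubber, rig, band_flow):
        res = onset_criteria(bench_tube, rubber, rig, -10.0, band_flow)
        assert not res.near_collapse and not res.onset

    def test_lung_scale_flag_flips_with_tenth_area(self, rubber):
        # a wide-open airway-sized tube: ratio far below the band; the same
        # flow through a tenth of the area multiplies the ratio by 100 and
        # can lift it into the band
        g = wk.TubeGeometry(l=4.76e-2, l0=3.8e-2, a=6.5e-3, h=0.65e-3)
        rig_g = wk.RigConfig.for_tube(g)
        A = g.reference_area
        Q = 6.5e-4
        thr = OnsetThresholds()
        open_ratio = dynamic_pressure_ratio(g, rubber, rig_g, Q, area=A)
        tenth_ratio = dynamic_pressure_ratio(g, rubber, rig_g, Q, area=A / 10)
        assert open_ratio < thr.dynamic_lo
        assert tenth_ratio == pytest.approx(100.0 * open_ratio, rel=1e-12)
        assert thr.dynamic_lo <= tenth_ratio

    def test_flag_monotone_in_flowrate_below_band_top(
        self, bench_tube, rubber, rig, band_flow
    ):
        p_star = collapse_state(bench_tube, rubber).p_c_star
        thr = OnsetThresholds()
        fired = False
        for Q in np.linspace(band_flow * 0.2, band_flow, 20):
            res = onset_criteria(bench_tube, rubber, rig, p_star, float(Q), thr)
            if fired and res.dynamic_ratio <= thr.dynamic_hi:
                assert res.onset
            fired = fired or res.onset
        assert fired


class TestPrediction:
    def test_direct_formula_arithmetic(self):
        assert frequency_from_speeds(23e-3, 10.0, 20.0, n=1) == pytest.approx(289.86, abs=0.01)

    def test_two_round_trips_halve_the_frequency(self):
        f1 = frequency_from_speeds(23e-3, 10.0, 20.0, n=1)
        f2 = frequency_from_speeds(23e-3, 10.0, 20.0, n=2)
        assert f2 == pytest.approx(f1 / 2.0, rel=1e-12)

    def test_strouhal_round_trip_is_inverse_cycle_count(self, bench_tube, rubber):
        for n in (1, 2):
            pred = predict_frequency(bench_tube, rubber, Q=8e-4, n=n)
            assert pred.strouhal == pytest.approx(1.0 / n, rel=1e-12)
            assert strouhal_number(pred.f, bench_tube.l, pred.v, pred.u) == pytest.approx(
                1.0 / n, rel=1e-12
            )

    def test_strouhal_linear_in_frequency(self):
        assert strouhal_number(200.0, 23e-3, 10.0, 20.0) == pytest.approx(
            2.0 * strouhal_number(100.0, 23e-3, 10.0, 20.0), rel=1e-12
        )

    def test_equal_speeds_symmetric_form(self):
        f, l, v = 150.0, 23e-3, 12.0
        assert strouhal_number(f, l, v, v) == pytest.approx(2.0 * f * l / v, rel=1e-12)

    def test_prediction_requires_flow(self, bench_tube, rubber):
        with pytest.raises(ValueError):
            predict_frequency(bench_tube, rubber, Q=0.0)

    def test_invalid_cycle_count(self):
        with pytest.raises(ValueError):
            frequency_from_speeds(23e-3, 10.0, 20.0, n=3)


def _tone_run(
    fs=51200.0,
    duration=6.0,
    f_tone=164.0,
    t_on=2.0,
    t_off=5.5,
    amp=25.0,
    noise=1.0,
    seed=0,
):
    rng = np.random.default_rng(seed)
    t = np.arange(int(duration * fs)) / fs
    tone = np.where(
        (t >= t_on) & (t < t_off), amp * np.sin(2 * math.pi * f_tone * t), 0.0
    )
    mk = lambda: tone + rng.normal(0.0, noise, t.shape)
    return PressureRun(fs=fs, p_u=rng.normal(0, noise, t.shape), p_1=mk(), p_2=mk(), p_a=mk())


class TestDetection:
    def test_injected_tone_recovered(self):
        run = _tone_run()
        det = detect_onset(run)
        assert det is not None
        assert det.f_onset == pytest.approx(164.0, rel=0.02)
        params = SpectrogramParams()
        window = params.nperseg / run.fs
        hop = window * (1 - params.overlap)
        assert abs(det.t_onset - 2.0) <= window + hop

    def test_noise_only_returns_none(self):
        run = _tone_run(amp=0.0)
        assert detect_onset(run) is None

    def test_short_tone_below_persistence_returns_none(self):
        # 50 cycles at 164 Hz is 0.3 s: below the 100-cycle rule
        run = _tone_run(t_on=2.0, t_off=2.0 + 50 / 164.0)
        assert detect_onset(run) is None

    def test_exactly_sustained_tone_detected(self):
        run = _tone_run(t_on=2.0, t_off=2.0 + 150 / 164.0)
        det = detect_onset(run)
        assert det is not None and det.n_cycles >= 100

    def test_amplitude_invariance(self):
        run = _tone_run()
        scaled = PressureRun(
            fs=run.fs, p_u=1e3 * run.p_u, p_1=1e3 * run.p_1,
            p_2=1e3 * run.p_2, p_a=1e3 * run.p_a,
        )
        d1, d2 = detect_onset(run), detect_onset(scaled)
        assert d1 is not None and d2 is not None
        assert d2.f_onset == pytest.approx(d1.f_onset, rel=1e-9)
        assert d2.t_onset == d1.t_onset

    def test_band_above_nyquist_rejected(self):
        run = _tone_run(fs=800.0, f_tone=100.0)
        with pytest.raises(ValueError, match="too low"):
            detect_onset(run, SpectrogramParams(f_max=500.0))
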