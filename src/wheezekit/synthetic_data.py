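"""Synthetic inputs for the whole pipeline, with known ground truth.

Two generators stand in for the experimental rig:

* :func:`generate_tube_law_dataset` emulates a tube-law measurement
  campaign — many tube geometries, each measured from open to wall contact
  — by sampling a master curve, redimensionalizing with known generating
  exponents, and applying multiplicative (log-normal) area noise.  Because
  the generating exponents and contact constants are known, these datasets
  drive closed-loop recovery tests of the exponent fit.

* :func:`generate_run` emulates one suction-ramp experimental run: the
  plenum pressure is ramped down, held, and ramped back up while the tube
  tracks its quasi-steady equilibria; channel tracks (p_u, p_1, p_2, p_a,
  Q) are synthesized with broadband noise, and a tone is injected at the
  onset of oscillation (either prescribed, or determined by the onset
  criteria with the frequency from the flutter predictor).  After onset the
  mean upstream pressure and the flowrate plateau, as observed on the rig.

Both generators are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .equilibrium import sweep_suction
from .fluid_law import RigConfig
from .geometry import Material, TubeGeometry
from .onset import OnsetThresholds, PressureRun, onset_criteria, predict_frequency
from .tube_law import (
    CollapseExponents,
    DEFAULT_EXPONENTS,
    DEFAULT_MASTER_CURVE,
    MasterCurve,
    TubeLawCurve,
    dim_area,
    dim_pressure,
)

__all__ = [
    "TubeLawDatasetSpec",
    "RunScenario",
    "generate_tube_law_dataset",
    "generate_run",
    "moving_average",
]


@dataclass(frozen=True)
class TubeLawDatasetSpec:
    """Recipe for a synthetic tube-law measurement campaign.

    The geometry grid is the outer product of the three dimensionless
    ratios (defaults span the bench campaign's ranges: stretches 1.05-1.3,
    wall ratios 0.07-0.2, slenderness 4-8 at a 3 mm radius).  ``noise`` is
    the fractional multiplicative area noise per sample.
    """

    stretches: tuple[float, ...] = (1.05, 1.15, 1.3)
    h_over_a: tuple[float, ...] = (0.07, 0.12, 0.2)
    l0_over_a: tuple[float, ...] = (4.0, 6.0, 8.0)
    a: float = 3.0e-3
    material: Material = field(default_factory=Material)
    exponents: CollapseExponents = DEFAULT_EXPONENTS
    curve: MasterCurve = DEFAULT_MASTER_CURVE
    noise: float = 0.0
    samples_per_curve: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise < 0:
            raise ValueError("noise level must be >= 0")
        if self.samples_per_curve < 2:
            raise ValueError("need at least 2 samples per curve")

    def geometries(self) -> list[TubeGeometry]:
        out = []
        for s, ha, l0a in product(self.stretches, self.h_over_a, self.l0_over_a):
            l0 = l0a * self.a
            out.append(TubeGeometry(l=s * l0, l0=l0, a=self.a, h=ha * self.a))
        return out


def generate_tube_law_dataset(spec: TubeLawDatasetSpec) -> list[TubeLawCurve]:
    """Synthesize one tube-law curve per geometry in the spec's grid.

    Each curve samples the master curve at evenly spaced dimensionless
    pressures from the open state down to wall contact, redimensionalized
    with the generating exponents; areas then receive multiplicative
    log-normal noise.  Deterministic for a fixed seed.
    """
    if (
        len(set(spec.stretches)) < 2
        or len(set(spec.h_over_a)) < 2
        or len(set(spec.l0_over_a)) < 2
    ):
        warnings.warn(
            "geometry grid does not span >= 2 values of every ratio; the "
            "dataset will not identify the collapse exponents",
            stacklevel=2,
        )
    rng = np.random.default_rng(spec.seed)
    geoms = spec.geometries()
    curves = []
    for j, geom in enumerate(geoms):
        # Each tube is measured at its own pressure stations (as on a real
        # rig): stagger the interior sampling points per curve, keeping the
        # open-state and wall-contact endpoints.
        t = np.linspace(0.0, 1.0, spec.samples_per_curve)
        if len(geoms) > 1 and spec.samples_per_curve > 2:
            shift = (j / (len(geoms) - 1) - 0.5) * 0.8 / (spec.samples_per_curve - 1)
            t[1:-1] = t[1:-1] + shift
        pi_p = t * spec.curve.contact_pressure
        pi_A = spec.curve.area(pi_p)
        p = dim_pressure(geom, spec.material, pi_p, spec.exponents)
        A = dim_area(geom, pi_A, spec.exponents)
        if spec.noise > 0:
            A = A * rng.lognormal(mean=0.0, sigma=spec.noise, size=A.shape)
        curves.append(
            TubeLawCurve(
                geometry=geom,
                material=spec.material,
                p_c=p,
                A_c=A,
                sigma_A=spec.noise * A if spec.noise > 0 else None,
            )
        )
    return curves


@dataclass(frozen=True)
class RunScenario:
    """Recipe for one virtual suction-ramp run.

    The suction schedule ramps the plenum from 0 to ``p_d_peak`` between
    ``t1`` and ``t2``, holds to ``t3``, and ramps back to 0 at ``t4``.
    Onset is either prescribed (``onset_time``/``onset_freq``) or derived
    from the onset criteria along the ramp, with the tone frequency from
    the flutter predictor.  Amplitudes are in Pa; ``noise_rms`` is the
    broadband (Gaussian) level per high-rate channel.
    """

    geom: TubeGeometry
    mat: Material = field(default_factory=Material)
    rig: RigConfig | None = None
    t1: float = 2.0
    t2: float = 8.0
    t3: float = 12.0
    t4: float = 18.0
    duration: float | None = None  # default t4 + 2 s
    p_d_peak: float = -2000.0
    fs: float = 51200.0
    noise_rms: float = 1.0
    tone_amp: float = 25.0
    tone_ramp_cycles: float = 10.0
    onset_time: float | None = None
    onset_freq: float | None = None
    n_cycles: int = 1  # wave round trips per oscillation cycle (flutter n)
    m_mode: int = 2
    thresholds: OnsetThresholds = field(default_factory=OnsetThresholds)
    control_dt: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.t1 < self.t2 < self.t3 < self.t4):
            raise ValueError("ramp schedule must satisfy 0 <= t1 < t2 < t3 < t4")
        if self.p_d_peak >= 0:
            raise ValueError("p_d_peak must be a suction (negative)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def total_time(self) -> float:
        return self.duration if self.duration is not None else self.t4 + 2.0

    def rig_config(self) -> RigConfig:
        return self.rig if self.rig is not None else RigConfig.for_tube(self.geom)

    def plenum_pressure(self, t) -> np.ndarray:
        """Suction schedule p_d(t), Pa (vectorized)."""
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        up = (t >= self.t1) & (t < self.t2)
        out[up] = self.p_d_peak * (t[up] - self.t1) / (self.t2 - self.t1)
        hold = (t >= self.t2) & (t < self.t3)
        out[hold] = self.p_d_peak
        down = (t >= self.t3) & (t < self.t4)
        out[down] = self.p_d_peak * (self.t4 - t[down]) / (self.t4 - self.t3)
        return out


def moving_average(x: np.ndarray, fs: float, window: float = 1.0) -> np.ndarray:
    """Centered moving average with a ``window``-second boxcar (same length)."""
    n = max(int(round(window * fs)), 1)
    kernel = np.ones(n) / n
    pad = np.pad(x, (n // 2, n - 1 - n // 2), mode="edge")
    return np.convolve(pad, kernel, mode="valid")


def _equilibrium_tracks(scenario: RunScenario, n_levels: int = 80):
    """Quasi-steady (A_c, Q, p_1, p_c) as interpolants over suction level."""
    grid = np.linspace(scenario.p_d_peak, 0.0, n_levels)
    sweep = sweep_suction(scenario.geom, scenario.mat, scenario.rig_config(), grid)
    pd_ok, A, Q, p1, pc = [], [], [], [], []
    for pd_val, st in zip(sweep.p_d, sweep.states):
        if st is None:
            continue
        pd_ok.append(pd_val)
        A.append(st.A_c0)
        Q.append(st.Q)
        p1.append(-0.5 * scenario.rig_config().rho * (st.Q / scenario.rig_config().A1) ** 2)
        pc.append(st.p_c0)
    if len(pd_ok) < 2:
        raise RuntimeError(
            "suction range leaves no quasi-steady equilibria to interpolate; "
            "reduce |p_d_peak|"
        )
    pd_ok = np.asarray(pd_ok)

    def interp(vals):
        vals = np.asarray(vals)
        return lambda p: np.interp(np.asarray(p, dtype=float), pd_ok, vals)

    return interp(A), interp(Q), interp(p1), interp(pc), float(pd_ok[0])


def generate_run(scenario: RunScenario) -> PressureRun:
    """Synthesize one experimental run as a :class:`~wheezekit.onset.PressureRun`.

    The run's ground truth (onset time, tone frequency, schedule) is stored
    in ``run.meta``/``run.markers``.  A scenario whose ramp never satisfies
    the onset criteria yields a valid, tone-free run.
    """
    rng = np.random.default_rng(scenario.seed)
    rig = scenario.rig_config()
    tc = np.arange(0.0, scenario.total_time, scenario.control_dt)
    pd_c = scenario.plenum_pressure(tc)
    A_of, Q_of, p1_of, pc_of, pd_floor = _equilibrium_tracks(scenario)
    pd_eff = np.maximum(pd_c, pd_floor)  # clamp to the feasible suction range
    Q_c = Q_of(pd_eff)
    p1_c = p1_of(pd_eff)
    pc_c = pc_of(pd_eff)

    # --- onset time and frequency -----------------------------------------
    t_o: float | None
    f_o: float | None
    if scenario.onset_time is not None:
        t_o = float(scenario.onset_time)
        if scenario.onset_freq is not None:
            f_o = float(scenario.onset_freq)
        else:
            Q_at = float(np.interp(t_o, tc, Q_c))
            f_o = predict_frequency(
                scenario.geom, scenario.mat, Q=Q_at, n=scenario.n_cycles, m=scenario.m_mode
            ).f
        active = (tc >= t_o) & (pd_c <= float(np.interp(t_o, tc, pd_c)) + 1e-9)
    else:
        fired = np.zeros(tc.shape, dtype=bool)
        for i in range(len(tc)):
            fired[i] = onset_criteria(
                scenario.geom, scenario.mat, rig, float(pc_c[i]), float(Q_c[i]),
                scenario.thresholds,
            ).onset
        if fired.any():
            i0 = int(np.argmax(fired))
            t_o = float(tc[i0])
            f_o = (
                float(scenario.onset_freq)
                if scenario.onset_freq is not None
                else predict_frequency(
                    scenario.geom, scenario.mat, Q=float(Q_c[i0]),
                    n=scenario.n_cycles, m=scenario.m_mode,
                ).f
            )
            active = fired & (tc >= t_o)
        else:
            t_o, f_o = None, None
            active = np.zeros(tc.shape, dtype=bool)

    # --- post-onset plateaus (p_1 and Q stop tracking the suction) --------
    if t_o is not None and active.any():
        t_end = float(tc[np.flatnonzero(active)[-1]])
        p1_hold = float(np.interp(t_o, tc, p1_c))
        Q_hold = 0.9 * float(np.interp(t_o, tc, Q_c))
        mask = (tc >= t_o) & (tc <= t_end)
        p1_c = np.where(mask, p1_hold, p1_c)
        Q_c = np.where(mask, Q_hold, Q_c)

    # --- upsample to the acquisition rate ---------------------------------
    t = np.arange(int(round(scenario.total_time * scenario.fs))) / scenario.fs
    pd_f = scenario.plenum_pressure(t)
    p1_f = np.interp(t, tc, p1_c)
    Q_f = np.interp(t, tc, Q_c)

    tone = np.zeros_like(t)
    if t_o is not None and f_o is not None and active.any():
        t_end = float(tc[np.flatnonzero(active)[-1]]) + scenario.control_dt
        ramp = scenario.tone_ramp_cycles / f_o
        env = np.clip((t - t_o) / ramp, 0.0, 1.0) * np.clip((t_end - t) / ramp, 0.0, 1.0)
        env = 0.5 - 0.5 * np.cos(np.pi * np.clip(env, 0.0, 1.0))  # raised cosine
        env[(t < t_o) | (t > t_end)] = 0.0
        tone = scenario.tone_amp * env * np.sin(2.0 * math.pi * f_o * (t - t_o))

    noise = lambda scale: rng.normal(0.0, scenario.noise_rms * scale, size=t.shape)
    run = PressureRun(
        fs=scenario.fs,
        p_u=noise(0.5),
        p_1=p1_f + tone + noise(1.0),
        p_2=pd_f + 0.5 * tone + noise(1.0),
        p_a=0.4 * tone + noise(1.0),
        Q=Q_f * (1.0 + 0.005 * rng.standard_normal(t.shape)),
        markers={"t_1": scenario.t1, "t_2": scenario.t2, "t_3": scenario.t3, "t_4": scenario.t4},
        meta={
            "t_onset": t_o,
            "f_onset": f_o,
            "p_d_peak": scenario.p_d_peak,
            "seed": scenario.seed,
            "onset_mode": "prescribed" if scenario.onset_time is not None else "criteria",
        },
    )
    return run
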