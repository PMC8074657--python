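"""Onset criteria, flutter frequency prediction, and tonal onset detection.

Self-excited oscillation (the bench analogue of a wheeze) needs two things
at once: the transmural pressure must hold the tube close to total collapse,
and the dynamic pressure of the flow at the narrowest section must be
comparable to the collapse pressure — without flow there is no onset.

At onset, a longitudinal wave travels down the tube at speed ``v`` (a
convected flow structure, estimated by the bulk velocity ``Q / pi a^2``)
and back up at speed ``u`` (an elastic wall wave, estimated by the shell
group velocity), completing ``n`` round trips per opening-closing cycle:

    1/f = n (l/v + l/u),   i.e.  the modified Strouhal number
    S = f (l/v + l/u) = 1/n   for n = 1, 2.

Measurement side: the onset of a run is the first dominant spectrogram tone
sustained for at least 100 cycles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .fluid_law import RigConfig, dynamic_pressure_ratio
from .geometry import Material, TubeGeometry
from .shell_dynamics import PrestressSpec, group_velocity
from .tube_law import CollapseExponents, DEFAULT_EXPONENTS, collapse_state

__all__ = [
    "OnsetThresholds",
    "OnsetAssessment",
    "OnsetPrediction",
    "PressureRun",
    "SpectrogramParams",
    "OnsetDetection",
    "onset_criteria",
    "frequency_from_speeds",
    "predict_frequency",
    "strouhal_number",
    "detect_onset",
]


@dataclass(frozen=True)
class OnsetThresholds:
    """Bands defining 'close to collapse' and 'dynamic pressure comparable'.

    The proximity band reflects that the measured choke pressure at onset
    sits slightly below the collapse pressure in magnitude; the dynamic
    band reflects the narrow range of dynamic-to-collapse pressure ratios
    observed at onset.  Both are configurable.
    """

    proximity_lo: float = 0.8
    proximity_hi: float = 1.0
    dynamic_lo: float = 0.2
    dynamic_hi: float = 5.0


@dataclass(frozen=True)
class OnsetAssessment:
    """Evaluation of the two onset criteria at one operating point."""

    p_c: float
    p_c_star: float
    pressure_proximity: float  # p_c / p_c*  (both negative -> ratio >= 0)
    dynamic_ratio: float  # (1/2 rho v_c^2) / |p_c*|
    near_collapse: bool
    in_band: bool
    onset: bool
    thresholds: OnsetThresholds = field(repr=False, default=OnsetThresholds())


def onset_criteria(
    geom: TubeGeometry,
    mat: Material,
    rig: RigConfig,
    p_c: float,
    Q: float,
    thresholds: OnsetThresholds = OnsetThresholds(),
    exps: CollapseExponents = DEFAULT_EXPONENTS,
) -> OnsetAssessment:
    """Assess both onset conditions for an operating point (p_c, Q)."""
    if Q < 0:
        raise ValueError("flowrate must be >= 0")
    state = collapse_state(geom, mat, exps)
    proximity = p_c / state.p_c_star
    dyn = dynamic_pressure_ratio(geom, mat, rig, Q, exps=exps)
    near = thresholds.proximity_lo <= proximity <= thresholds.proximity_hi
    in_band = thresholds.dynamic_lo <= dyn <= thresholds.dynamic_hi
    return OnsetAssessment(
        p_c=p_c,
        p_c_star=state.p_c_star,
        pressure_proximity=proximity,
        dynamic_ratio=dyn,
        near_collapse=near,
        in_band=in_band,
        onset=near and in_band,
        thresholds=thresholds,
    )


@dataclass(frozen=True)
class OnsetPrediction:
    """Predicted oscillation frequency from the coupled-wave resonance."""

    n: int
    v: float  # downstream (convected) wave speed, m/s
    u: float  # upstream (elastic) wave speed, m/s
    f: float  # predicted frequency, Hz
    strouhal: float  # f (l/v + l/u); 1/n by construction


def frequency_from_speeds(l: float, v: float, u: float, n: int = 1) -> float:
    """``f = 1 / (n (l/v + l/u))`` — n wave round trips per cycle."""
    if n not in (1, 2):
        raise ValueError("cycle count n must be 1 or 2")
    if v <= 0 or u <= 0:
        raise ValueError("wave speeds must be positive")
    return 1.0 / (n * (l / v + l / u))


def strouhal_number(f: float, l: float, v: float, u: float) -> float:
    """Modified Strouhal number ``S = f (l/v + l/u)``."""
    if v <= 0 or u <= 0:
        raise ValueError("wave speeds must be positive")
    return f * (l / v + l / u)


def predict_frequency(
    geom: TubeGeometry,
    mat: Material,
    prestress: PrestressSpec | None = None,
    Q: float = 0.0,
    n: int = 1,
    m: int = 2,
) -> OnsetPrediction:
    """Predict the onset frequency for a tube carrying flowrate Q.

    The downstream speed is the bulk velocity ``v = Q / (pi a^2)``; the
    upstream speed is the shell group velocity at the standing-wave
    wavenumber for azimuthal mode ``m`` (default 2, the flattening mode;
    m = 0 gives the axisymmetric alternative).
    """
    if Q <= 0:
        raise ValueError("prediction needs Q > 0 (no onset without flow)")
    v = Q / geom.reference_area
    u = group_velocity(geom, mat, prestress, m=m)
    f = frequency_from_speeds(geom.l, v, u, n)
    return OnsetPrediction(n=n, v=v, u=u, f=f, strouhal=strouhal_number(f, geom.l, v, u))


# ---------------------------------------------------------------------------
# Signal-level onset detection
# ---------------------------------------------------------------------------


@dataclass
class PressureRun:
    """Multichannel pressure/flow recording of one experimental run.

    High-rate channels (``p_u``, ``p_1``, ``p_2``, ``p_a``, Pa) share the
    sampling rate ``fs``; the flowrate channel ``Q`` may be absent or at
    the same rate.  ``markers`` carries the suction schedule times
    t_1..t_4; ``meta`` is free-form provenance (synthetic scenarios store
    their ground truth here).
    """

    fs: float
    p_u: np.ndarray
    p_1: np.ndarray
    p_2: np.ndarray
    p_a: np.ndarray
    Q: np.ndarray | None = None
    markers: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        n = len(self.p_1)
        for name in ("p_u", "p_2", "p_a"):
            if len(getattr(self, name)) != n:
                raise ValueError("high-rate channels must have equal length")

    @property
    def duration(self) -> float:
        return len(self.p_1) / self.fs

    @property
    def t(self) -> np.ndarray:
        return np.arange(len(self.p_1)) / self.fs

    def channel(self, name: str) -> np.ndarray:
        return getattr(self, name)


@dataclass(frozen=True)
class SpectrogramParams:
    """Spectrogram and tonal-dominance settings for onset detection."""

    nperseg: int = 4096
    overlap: float = 0.75
    dominance_db: float = 20.0  # peak above the frame's median level
    drift_frac: float = 0.10  # tolerated frequency drift along a track
    min_cycles: float = 100.0  # persistence threshold, in tone cycles
    f_min: float = 50.0
    f_max: float | None = None  # default 0.45 fs
    channels: tuple[str, ...] = ("p_1", "p_2", "p_a")


@dataclass(frozen=True)
class OnsetDetection:
    """First sustained dominant tone of a run."""

    t_onset: float  # s, start of the sustained track
    f_onset: float  # Hz
    n_cycles: float  # sustained cycle count (>= the persistence threshold)
    channel: str
    diagnostics: dict = field(repr=False, default_factory=dict)


def _refine_peak(psd: np.ndarray, i: int, freqs: np.ndarray) -> float:
    """Sub-bin peak frequency by parabolic interpolation of log power."""
    if i <= 0 or i >= len(psd) - 1:
        return float(freqs[i])
    with np.errstate(divide="ignore"):
        y = np.log(psd[i - 1 : i + 2] + 1e-300)
    denom = y[0] - 2 * y[1] + y[2]
    if denom >= 0:
        return float(freqs[i])
    shift = 0.5 * (y[0] - y[2]) / denom
    return float(freqs[i] + shift * (freqs[1] - freqs[0]))


def _frame_peaks(x: np.ndarray, fs: float, p: SpectrogramParams):
    """Per-frame dominant tonal peak or NaN; returns (times, freqs)."""
    noverlap = int(p.nperseg * p.overlap)
    freqs, times, Sxx = signal.spectrogram(
        x, fs=fs, window="hann", nperseg=p.nperseg, noverlap=noverlap, mode="psd"
    )
    f_max = p.f_max if p.f_max is not None else 0.45 * fs
    if f_max >= 0.5 * fs:
        raise ValueError(
            f"sampling rate {fs} Hz too low for the requested analysis band "
            f"(top {f_max} Hz reaches the Nyquist frequency)"
        )
    band = (freqs >= p.f_min) & (freqs <= f_max)
    if band.sum() < 8:
        raise ValueError(
            f"sampling rate {fs} Hz too low for the analysis band "
            f"[{p.f_min}, {f_max}] Hz"
        )
    fb = freqs[band]
    peaks = np.full(times.shape, np.nan)
    for j in range(Sxx.shape[1]):
        col = Sxx[band, j]
        i = int(np.argmax(col))
        med = float(np.median(col))
        if med <= 0 or col[i] <= 0:
            continue
        if 10.0 * math.log10(col[i] / med) >= p.dominance_db:
            peaks[j] = _refine_peak(col, i, fb)
    return times, peaks


def _tracks(times: np.ndarray, peaks: np.ndarray, drift: float):
    """Split the per-frame peak sequence into drift-bounded tonal tracks."""
    tracks = []
    start, freqs = None, []
    for j, f in enumerate(peaks):
        if np.isnan(f):
            if freqs:
                tracks.append((start, j - 1, np.array(freqs)))
            start, freqs = None, []
            continue
        if freqs and abs(f - np.median(freqs)) > drift * np.median(freqs):
            tracks.append((start, j - 1, np.array(freqs)))
            start, freqs = j, [f]
        else:
            if not freqs:
                start = j
            freqs.append(f)
    if freqs:
        tracks.append((start, len(peaks) - 1, np.array(freqs)))
    return tracks


def detect_onset(run: PressureRun, params: SpectrogramParams = SpectrogramParams()) -> OnsetDetection | None:
    """Find the earliest dominant tone sustained for the required cycle count.

    Spectrograms of the configured channels are scanned for frames whose
    peak exceeds the dominance threshold over that frame's median level;
    consecutive dominant frames with bounded frequency drift form a track.
    The earliest track lasting at least ``min_cycles / f`` seconds is
    reported (start time referred to the first sample of its first frame).
    Returns None when no such tone exists.  Detection depends only on
    spectral shape, so it is invariant to overall amplitude scaling.
    """
    hop = params.nperseg * (1.0 - params.overlap) / run.fs
    best: OnsetDetection | None = None
    for name in params.channels:
        x = run.channel(name)
        if x is None:
            continue
        times, peaks = _frame_peaks(np.asarray(x, dtype=float), run.fs, params)
        for start, end, freqs in _tracks(times, peaks, params.drift_frac):
            f_med = float(np.median(freqs))
            duration = times[end] - times[start] + hop
            cycles = duration * f_med
            if cycles < params.min_cycles:
                continue
            t0 = float(times[start] - params.nperseg / (2.0 * run.fs))
            det = OnsetDetection(
                t_onset=max(t0, 0.0),
                f_onset=f_med,
                n_cycles=cycles,
                channel=name,
                diagnostics={
                    "n_frames": end - start + 1,
                    "hop_s": hop,
                    "freq_spread_hz": float(np.ptp(freqs)),
                },
            )
            if best is None or det.t_onset < best.t_onset:
                best = det
            break  # earliest track in this channel found
    return best
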