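"""Signal chain applied to each trial before analysis.

Zero-phase Butterworth low-pass filtering (6 Hz for kinematics, 30 Hz for
ground-reaction forces, 15 Hz for IMU channels), stance extraction from the
vertical ground-reaction force, linear interpolation of the stance window
onto 101 points (each point = 1% of stance), 0-1 min-max normalization with
train-set statistics, and sliding-window construction of 18-channel
sequences for the predictor.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .synthetic import IMU_CHANNELS, MotionTrial

__all__ = [
    "FilterSpec",
    "NormalizedCurve",
    "WindowedSequenceSet",
    "MinMaxStats",
    "lowpass_zerophase",
    "detect_stance",
    "time_normalize_101",
    "minmax_01",
    "make_windows",
    "process_trial",
    "STANCE_THRESHOLD_N",
]

log = logging.getLogger(__name__)

STANCE_THRESHOLD_N = 20.0  # conventional contact threshold


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass Butterworth specification (order counts one pass)."""

    cutoff: float  # Hz
    order: int = 4
    two_pass: bool = True

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.order < 2 or self.order % 2:
            raise ValueError("order must be even and >= 2")


KINEMATIC_FILTER = FilterSpec(cutoff=6.0)
GRF_FILTER = FilterSpec(cutoff=30.0)
IMU_FILTER = FilterSpec(cutoff=15.0)


@dataclass
class NormalizedCurve:
    """A 101-point curve; point i sits at i% of the stance phase."""

    values: np.ndarray
    channel: str = ""
    trial_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (101,):
            raise ValueError("a normalized curve has exactly 101 points")


@dataclass
class WindowedSequenceSet:
    """Fixed-length 18-channel subsequences ordered by start index."""

    windows: np.ndarray  # (n_windows, window_len, n_channels)
    window_len: int
    stride: int

    def __len__(self) -> int:
        return self.windows.shape[0]


@dataclass(frozen=True)
class MinMaxStats:
    """Per-channel min/max fitted on the training partition."""

    minimum: np.ndarray
    maximum: np.ndarray
    channels: tuple[str, ...] = ()


def lowpass_zerophase(x: np.ndarray, fs: float, spec: FilterSpec) -> np.ndarray:
    """Forward-backward Butterworth low pass with zero net phase shift.

    Edge transients are suppressed by reflective padding of three times the
    filter order.  With ``two_pass`` the realized magnitude response is the
    square of the single-pass Butterworth response.
    """
    x = np.asarray(x, dtype=float)
    if spec.cutoff >= fs / 2:
        raise ValueError(
            f"cutoff {spec.cutoff} Hz must be below the Nyquist rate {fs / 2} Hz"
        )
    padlen = 3 * spec.order
    n = x.shape[0]
    if n <= padlen:
        raise ValueError(
            f"signal of length {n} is too short for the edge padding "
            f"({padlen} samples); need at least {padlen + 1} samples"
        )
    b, a = sps.butter(spec.order, spec.cutoff, btype="low", fs=fs)
    if spec.two_pass:
        return sps.filtfilt(b, a, x, axis=0, padlen=padlen)
    return sps.lfilter(b, a, x, axis=0)


def detect_stance(vgrf: np.ndarray, threshold: float = STANCE_THRESHOLD_N
                  ) -> tuple[int, int]:
    """Longest contiguous run with vgrf > threshold, as a half-open interval."""
    vgrf = np.asarray(vgrf, dtype=float)
    above = vgrf > threshold
    if not above.any():
        raise ValueError(
            f"no sample exceeds the stance threshold of {threshold} N"
        )
    padded = np.concatenate([[False], above, [False]]).astype(np.int8)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    best = int(np.argmax(ends - starts))
    return int(starts[best]), int(ends[best])


def time_normalize_101(curve: np.ndarray) -> NormalizedCurve:
    """Linear interpolation of a curve onto 101 equally spaced points.

    Endpoints are preserved exactly; a length-101 input is returned
    unchanged.
    """
    curve = np.asarray(curve, dtype=float)
    if curve.ndim != 1 or curve.shape[0] < 2:
        raise ValueError("curve must be 1-D with at least 2 samples")
    n = curve.shape[0]
    if n == 101:
        return NormalizedCurve(curve.copy())
    xi = np.linspace(0.0, n - 1.0, 101)
    return NormalizedCurve(np.interp(xi, np.arange(n), curve))


def minmax_01(values: np.ndarray, fit_stats: MinMaxStats | None = None
              ) -> np.ndarray:
    """Map values to [0, 1] via (x - min) / (max - min).

    When ``fit_stats`` is supplied (training-set statistics applied to
    validation/test data), out-of-range results are logged but not clipped.
    Without statistics a constant channel is an error.
    """
    values = np.asarray(values, dtype=float)
    if fit_stats is None:
        lo = values.min(axis=0)
        hi = values.max(axis=0)
        span = np.asarray(hi - lo, dtype=float)
        if np.any(span <= 0):
            bad = _constant_channel_names(span, None)
            raise ValueError(f"constant channel(s), cannot scale: {bad}")
    else:
        lo, hi = np.asarray(fit_stats.minimum), np.asarray(fit_stats.maximum)
        span = hi - lo
        if np.any(span <= 0):
            bad = _constant_channel_names(np.atleast_1d(span), fit_stats.channels)
            raise ValueError(f"constant channel(s) in fit statistics: {bad}")
    out = (values - lo) / span
    if fit_stats is not None and ((out < 0).any() or (out > 1).any()):
        frac = float(np.mean((out < 0) | (out > 1)))
        log.warning(
            "min-max scaling with train statistics left %.1f%% of values "
            "outside [0, 1] (not clipped)", 100 * frac,
        )
    return out


def _constant_channel_names(span: np.ndarray, channels) -> str:
    idx = np.flatnonzero(np.atleast_1d(span) <= 0)
    if channels:
        return ", ".join(channels[i] for i in idx)
    return ", ".join(f"column {i}" for i in idx)


def make_windows(features: np.ndarray, window_len: int, stride: int = 1
                 ) -> WindowedSequenceSet:
    """Sliding windows over an (T, n_channels) feature series.

    The number of windows is floor((T - window_len) / stride) + 1, ordered
    by start index.
    """
    features = np.asarray(features, dtype=float)
    if features.ndim != 2:
        raise ValueError("features must be 2-D (time, channels)")
    T = features.shape[0]
    if window_len > T:
        raise ValueError(f"window_len {window_len} exceeds series length {T}")
    if window_len < 1 or stride < 1:
        raise ValueError("window_len and stride must be >= 1")
    n = (T - window_len) // stride + 1
    starts = np.arange(n) * stride
    windows = np.stack([features[s:s + window_len] for s in starts])
    return WindowedSequenceSet(windows=windows, window_len=window_len, stride=stride)


# --- per-trial chain ------------------------------------------------------

@dataclass
class ProcessedTrial:
    """Stance-normalized 101-point curves for one trial."""

    trial_id: str
    subject_id: int
    direction: int
    stance: tuple[int, int]
    angles: dict[str, np.ndarray]  # each length 101, degrees
    vgrf: np.ndarray  # length 101, newtons
    imu: np.ndarray  # (101, 18), filtered, raw units
    imu_channels: tuple[str, ...] = field(default=IMU_CHANNELS)


def process_trial(trial: MotionTrial,
                  stance_threshold: float = STANCE_THRESHOLD_N,
                  kinematic_filter: FilterSpec = KINEMATIC_FILTER,
                  grf_filter: FilterSpec = GRF_FILTER,
                  imu_filter: FilterSpec = IMU_FILTER) -> ProcessedTrial:
    """Filter, extract stance, and time-normalize every channel of a trial.

    Kinematic channels are low-passed at 6 Hz, the vGRF at 30 Hz, and the
    IMU channels at 15 Hz; the stance window is then detected on the
    filtered vGRF and all channels are interpolated onto 101 points across
    that window.
    """
    fs = trial.sample_rate
    angle_names = list(trial.angle_curves)
    angle_mat = np.column_stack([trial.angle_curves[n] for n in angle_names])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=FutureWarning)
        angle_f = lowpass_zerophase(angle_mat, fs, kinematic_filter)
        vgrf_f = lowpass_zerophase(trial.vgrf, fs, grf_filter)
        imu_f = lowpass_zerophase(trial.imu, fs, imu_filter)
    vgrf_f = np.clip(vgrf_f, 0.0, None)
    start, stop = detect_stance(vgrf_f, stance_threshold)
    angles = {
        name: time_normalize_101(angle_f[start:stop, i]).values
        for i, name in enumerate(angle_names)
    }
    vgrf_n = time_normalize_101(vgrf_f[start:stop]).values
    imu_n = np.column_stack(
        [time_normalize_101(imu_f[start:stop, i]).values
         for i in range(imu_f.shape[1])]
    )
    return ProcessedTrial(
        trial_id=trial.trial_id,
        subject_id=trial.subject_id,
        direction=int(trial.direction),
        stance=(start, stop),
        angles=angles,
        vgrf=vgrf_n,
        imu=imu_n,
    )
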