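"""Assembly of per-direction sequence datasets for the predictor.

Each trial contributes one 101-step, 18-channel input sequence (the
stance-normalized, 15 Hz-filtered IMU curves) and one 100-interval target
curve.  Two target definitions are supported:

``veccode``
    The coordination-variability curve of one coupling, computed across
    the trial's subject/direction cycles with the vector-coding module.
    Every trial of a subject shares that subject's curve, mirroring a
    pipeline in which the predictor replaces the laboratory computation.

``imu_function``
    A smooth deterministic functional of the trial's own 18 IMU channels
    plus Gaussian observation noise — a benchmark mapping with a known
    signal-to-noise level, used for the headline prediction-accuracy runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._rng import substream
from .preprocessing import ProcessedTrial, process_trial
from .synthetic import MotionTrial
from .vector_coding import (
    Coupling,
    CouplingCurveSet,
    STANDARD_COUPLINGS,
    coefficient_of_correspondence,
)

__all__ = [
    "SequenceDataset",
    "imu_function_targets",
    "build_direction_dataset",
    "veccode_curves_by_subject",
]

# Fixed mixing weights of the benchmark functional; part of the dataset
# definition, independent of any run seed.
_TARGET_MAP_SEED = 20220823


@dataclass
class SequenceDataset:
    """Inputs (n, 101, 18) and target curves (n, 100) for one direction."""

    X: np.ndarray
    Y: np.ndarray
    trial_ids: list[str]
    direction: int
    target_kind: str


# Fixed per-channel scales of the benchmark functional (typical magnitudes
# of the generator's filtered accelerometer / gyroscope channels).
_ACC_SCALE = 7.0  # m/s^2
_GYR_SCALE = 80.0  # deg/s


def imu_function_targets(imu_101: np.ndarray,
                         noise_sd: float = 0.01,
                         rng: np.random.Generator | None = None) -> np.ndarray:
    """Smooth deterministic functional of the 18 IMU channels + noise.

    Channels are divided by fixed typical scales, mixed by fixed weights,
    and squashed to (0.15, 0.85); the value at interval i is read at frame
    i + 1, so the target is a pointwise function of the channel values.
    ``noise_sd`` is expressed as a fraction of the clean targets' span,
    i.e. (up to the small widening the noise itself causes) in the min-max
    scaled units in which the predictor's RMSE is reported.
    """
    imu_101 = np.asarray(imu_101, dtype=float)
    single = imu_101.ndim == 2
    if single:
        imu_101 = imu_101[None]
    n, T, C = imu_101.shape
    from .synthetic import IMU_CHANNELS

    scales = np.array(
        [_ACC_SCALE if "acc" in ch else _GYR_SCALE for ch in IMU_CHANNELS]
    )
    w = substream(_TARGET_MAP_SEED, "target-map").normal(0.0, 1.0, size=C)
    mixed = (imu_101 / scales) @ (w / np.sqrt(C))
    y = 0.5 + 0.35 * np.tanh(mixed)
    y = y[:, 1:]  # align to the 100 frame intervals
    if noise_sd > 0:
        if rng is None:
            raise ValueError("an rng is required when noise_sd > 0")
        span = float(y.max() - y.min())
        y = y + rng.normal(0.0, noise_sd * span, size=y.shape)
    return y[0] if single else y


def veccode_curves_by_subject(processed: list[ProcessedTrial],
                              coupling: Coupling) -> dict[int, np.ndarray]:
    """Coordination-variability curve per subject from that subject's
    cycles (all trials assumed to share one direction)."""
    by_subject: dict[int, list[ProcessedTrial]] = {}
    for p in processed:
        by_subject.setdefault(p.subject_id, []).append(p)
    curves = {}
    for subject, plist in by_subject.items():
        prox = np.stack([p.angles[coupling.proximal_channel] for p in plist])
        dist = np.stack([p.angles[coupling.distal_channel] for p in plist])
        cvc = coefficient_of_correspondence(
            CouplingCurveSet(prox, dist, coupling=coupling,
                             direction=plist[0].direction)
        )
        curves[subject] = cvc.r
    return curves


def build_direction_dataset(trials: list[MotionTrial], direction: int,
                            target: str = "imu_function",
                            coupling: Coupling = STANDARD_COUPLINGS[0],
                            noise_sd: float = 0.01,
                            seed: int = 0) -> SequenceDataset:
    """Process one direction's trials into an LSTM-ready dataset."""
    selected = [t for t in trials if int(t.direction) == int(direction)]
    if not selected:
        raise ValueError(f"no trials for direction {direction}")
    processed = [process_trial(t) for t in selected]
    X = np.stack([p.imu for p in processed])  # (n, 101, 18)
    ids = [p.trial_id for p in processed]

    if target == "imu_function":
        rng = substream(seed, "target-noise", direction)
        Y = imu_function_targets(X, noise_sd=noise_sd, rng=rng)
    elif target == "veccode":
        curves = veccode_curves_by_subject(processed, coupling)
        Y = np.stack([curves[p.subject_id] for p in processed])
    else:
        raise ValueError(f"unknown target kind {target!r}")
    return SequenceDataset(X=X, Y=np.asarray(Y), trial_ids=ids,
                           direction=int(direction), target_kind=target)
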