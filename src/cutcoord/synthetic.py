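"""Seeded synthetic cutting-movement trials.

The study design this generator emulates: subjects perform planted-foot
change-of-direction (cutting) movements at three direction conditions (90,
135, 180 degrees).  Each trial carries joint/segment angle curves, a
vertical ground-reaction-force (vGRF) curve, and 18 raw IMU channels
(3 sensors x 3 accelerometer + 3 gyroscope axes).  Inter-cycle variability
is injected as a smooth stochastic perturbation whose standard deviation
follows a "U"-shaped envelope over the cycle (high during braking, low
mid-cycle, high again late), with the late-swing portion scaled per
direction so that the 135/180-degree conditions are more variable than the
90-degree condition — the structure the downstream vector-coding and
statistical-mapping stages are designed to detect.

All randomness flows through named substreams of ``GeneratorConfig.seed``:
identical configs produce byte-identical datasets.
"""

from __future__ import annotations

import dataclasses
import enum
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._rng import substream
from .templates import ANGLE_CHANNELS, template_matrix

__all__ = [
    "DirectionCondition",
    "DIRECTIONS",
    "GeneratorConfig",
    "MotionTrial",
    "IMU_CHANNELS",
    "generate_trial",
    "generate_dataset",
    "save_dataset",
    "load_dataset",
]


class DirectionCondition(enum.IntEnum):
    """Cutting-movement direction: the turn angle in degrees."""

    DEG90 = 90
    DEG135 = 135
    DEG180 = 180


DIRECTIONS: tuple[DirectionCondition, ...] = (
    DirectionCondition.DEG90,
    DirectionCondition.DEG135,
    DirectionCondition.DEG180,
)

_SENSORS = ("pelvis", "thigh", "calf")
_SENSOR_SOURCE = {"pelvis": "hip", "thigh": "thigh", "calf": "leg"}
_AXES = ("x", "y", "z")  # mapped to the three anatomical planes fe/aa/rot
_PLANES = ("fe", "aa", "rot")

IMU_CHANNELS: tuple[str, ...] = tuple(
    f"{sensor}_{kind}_{axis}"
    for sensor in _SENSORS
    for kind in ("acc", "gyr")
    for axis in _AXES
)


def _default_swing_scale() -> dict[int, float]:
    return {90: 1.0, 135: 1.6, 180: 1.6}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition parameters of the synthetic generator.

    Defaults mirror the emulated protocol: 25 subjects, 9 cycles per
    subject and direction (225 trials per direction), one shared 200 Hz
    time base for kinematics and IMU.  ``noise_sd_angles`` is the pointwise
    standard deviation (degrees) of the smooth inter-cycle perturbation at
    envelope value 1; ``swing_variability_scale`` multiplies the late-swing
    part of that envelope per direction.
    """

    n_subjects: int = 25
    cycles_per_subject: int = 9
    sample_rate: float = 200.0  # Hz, shared by kinematics and IMU
    noise_sd_angles: float = 2.0  # degrees
    noise_sd_imu: float = 0.05  # m/s^2 on accelerometers; x10 deg/s on gyros
    phase_jitter_sd: float = 0.008  # SD of per-cycle phase shift, cycle fraction
    amp_jitter_sd: float = 0.03  # sigma of per-cycle lognormal amplitude factor
    swing_variability_scale: dict[int, float] = field(
        default_factory=_default_swing_scale
    )
    swing_window: tuple[float, float] = (0.65, 1.0)  # cycle fraction
    subject_heterogeneity: float = 0.05
    body_weight_n: float = 700.0
    cycle_duration_s: float = 1.0
    pad_s: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.cycles_per_subject < 2:
            raise ValueError(
                "cycles_per_subject must be >= 2 (the coefficient of "
                "correspondence needs at least two cycles)"
            )
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        for name in ("noise_sd_angles", "noise_sd_imu", "phase_jitter_sd",
                     "amp_jitter_sd", "subject_heterogeneity"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for d, v in self.swing_variability_scale.items():
            if int(d) not in (90, 135, 180):
                raise ValueError(f"unknown direction {d} in swing_variability_scale")
            if v < 0:
                raise ValueError("swing_variability_scale values must be >= 0")

    def replace(self, **kwargs) -> "GeneratorConfig":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def noiseless(cls, **kwargs) -> "GeneratorConfig":
        """A config with every inter-cycle variability source switched off.

        Cycles of the same subject and direction are then identical, so all
        downstream coordination-variability curves equal 1 at every frame.
        """
        defaults = dict(
            noise_sd_angles=0.0,
            noise_sd_imu=0.0,
            phase_jitter_sd=0.0,
            amp_jitter_sd=0.0,
            swing_variability_scale={90: 0.0, 135: 0.0, 180: 0.0},
        )
        defaults.update(kwargs)
        return cls(**defaults)


@dataclass
class MotionTrial:
    """One synthetic cutting-movement trial on a common raw time base."""

    subject_id: int
    direction: DirectionCondition
    cycle: int
    sample_rate: float
    angle_curves: dict[str, np.ndarray]  # degrees
    vgrf: np.ndarray  # newtons, >= 0
    imu: np.ndarray  # (T, 18), channel order IMU_CHANNELS

    @property
    def trial_id(self) -> str:
        return f"s{self.subject_id:03d}_d{int(self.direction)}_c{self.cycle:02d}"

    def __post_init__(self) -> None:
        T = len(self.vgrf)
        if self.imu.shape != (T, len(IMU_CHANNELS)):
            raise ValueError(
                f"imu must have shape ({T}, {len(IMU_CHANNELS)}), got {self.imu.shape}"
            )
        for name, curve in self.angle_curves.items():
            if len(curve) != T:
                raise ValueError(f"angle channel {name!r} not on the shared time base")
        if np.any(self.vgrf < 0):
            raise ValueError("vgrf must be non-negative everywhere")


# --- variability envelope -------------------------------------------------

def _variability_envelope(s: np.ndarray, config: GeneratorConfig,
                          direction: DirectionCondition) -> np.ndarray:
    """Pointwise SD multiplier: U-shaped base + direction-scaled swing bump."""
    base = 0.35 + 0.65 * np.exp(-((s - 0.08) / 0.10) ** 2)
    lo, hi = config.swing_window
    center = 0.5 * (lo + hi)
    width = max(0.5 * (hi - lo), 1e-6)
    # flat-topped bump so the injected effect covers the late-swing band
    bump = np.exp(-(((s - center) / width) ** 4))
    scale = config.swing_variability_scale.get(int(direction), 1.0)
    return base + scale * bump


def _smooth_noise_basis(s: np.ndarray, n_bumps: int = 12,
                        width: float = 0.06) -> np.ndarray:
    """Gaussian-bump basis, row-normalized so unit coefficients give SD 1."""
    centers = (np.arange(n_bumps) + 0.5) / n_bumps
    phi = np.exp(-((s[:, None] - centers[None, :]) / width) ** 2)
    norm = np.sqrt(np.sum(phi**2, axis=1, keepdims=True))
    return phi / np.maximum(norm, 1e-12)


# --- trial construction ---------------------------------------------------

def _subject_effects(config: GeneratorConfig, subject_id: int):
    rng = substream(config.seed, "subject", subject_id)
    amp = rng.normal(1.0, config.subject_heterogeneity, size=len(ANGLE_CHANNELS))
    # offset SD: 2 degrees at the default heterogeneity of 0.05
    offset = rng.normal(0.0, 1.0, size=len(ANGLE_CHANNELS)) * (
        40.0 * config.subject_heterogeneity
    )
    return amp, offset


def _vgrf_profile(s: np.ndarray) -> np.ndarray:
    """Two-peak contact profile in body weights, tapered to zero at the edges."""
    taper_in = 0.5 * (1.0 - np.cos(np.pi * np.clip(s / 0.04, 0.0, 1.0)))
    taper_out = 0.5 * (1.0 - np.cos(np.pi * np.clip((1.0 - s) / 0.04, 0.0, 1.0)))
    body = (
        0.45
        + 1.30 * np.exp(-((s - 0.15) / 0.08) ** 2)
        + 0.90 * np.exp(-((s - 0.45) / 0.10) ** 2)
    )
    return body * taper_in * taper_out


def generate_trial(config: GeneratorConfig, subject_id: int,
                   direction: DirectionCondition, rng: np.random.Generator,
                   cycle: int = 0) -> MotionTrial:
    """Generate one trial (one movement cycle with zero-force padding).

    The angle model per channel c and cycle j is

        theta_cj(s) = off_c + A_c * a_cj * template_c(s + delta_j)
                      + sd * env_dir(s) * sum_k e_kcj phi_k(s)

    with subject effects (off_c, A_c), per-cycle lognormal amplitude a_cj,
    per-cycle phase shift delta_j, and a smooth Gaussian-bump perturbation
    whose pointwise SD is ``noise_sd_angles`` times the direction-dependent
    envelope.  IMU channels are deterministic functions of the segment
    angles (gyro = first derivative; accel = lever x angular acceleration
    + gravity projection) plus white sensor noise.
    """
    direction = DirectionCondition(int(direction))
    fs = config.sample_rate
    n_cyc = int(round(config.cycle_duration_s * fs))
    n_pad = int(round(config.pad_s * fs))
    s = np.arange(n_cyc) / (n_cyc - 1)

    subj_amp, subj_off = _subject_effects(config, subject_id)

    delta = rng.normal(0.0, config.phase_jitter_sd) if config.phase_jitter_sd else 0.0
    amp_j = (
        np.exp(rng.normal(0.0, config.amp_jitter_sd, size=len(ANGLE_CHANNELS)))
        if config.amp_jitter_sd
        else np.ones(len(ANGLE_CHANNELS))
    )

    base = template_matrix(np.clip(s + delta, 0.0, 1.0), int(direction))
    curves = subj_off[None, :] + subj_amp[None, :] * amp_j[None, :] * base

    if config.noise_sd_angles > 0:
        from .templates import _DIRECTION_MOD
        phi = _smooth_noise_basis(s)
        env = _variability_envelope(s, config, direction)
        coeff = rng.normal(0.0, 1.0, size=(phi.shape[1], len(ANGLE_CHANNELS)))
        # perturbation scales with the direction's movement amplitude so the
        # relative (signal-to-noise) variability is comparable across
        # conditions before the swing scaling is applied
        amp_mod = _DIRECTION_MOD[int(direction)][0]
        curves = curves + (config.noise_sd_angles * amp_mod
                           * env[:, None] * (phi @ coeff))

    # pad angle channels by holding the end values (foot off the plate)
    pad0 = np.repeat(curves[:1, :], n_pad, axis=0)
    pad1 = np.repeat(curves[-1:, :], n_pad, axis=0)
    full = np.vstack([pad0, curves, pad1])
    angle_curves = {name: full[:, i].copy() for i, name in enumerate(ANGLE_CHANNELS)}

    # vGRF: two-peak contact profile, zero outside the cycle
    grf_amp = (
        np.exp(rng.normal(0.0, config.amp_jitter_sd))
        if config.amp_jitter_sd
        else 1.0
    )
    vgrf_cycle = config.body_weight_n * grf_amp * _vgrf_profile(s)
    vgrf = np.concatenate([np.zeros(n_pad), vgrf_cycle, np.zeros(n_pad)])
    vgrf = np.clip(vgrf, 0.0, None)

    # IMU channels from segment/joint angle derivatives
    dt = 1.0 / fs
    imu = np.empty((len(vgrf), len(IMU_CHANNELS)))
    col = 0
    for sensor in _SENSORS:
        src = _SENSOR_SOURCE[sensor]
        angles = [angle_curves[f"{src}_{plane}"] for plane in _PLANES]
        rad = [np.deg2rad(a) for a in angles]
        for a_rad in rad:  # accelerometer: lever arm 0.3 m + gravity projection
            alpha = np.gradient(np.gradient(a_rad, dt), dt)
            imu[:, col] = 0.3 * alpha + 9.81 * np.sin(a_rad)
            col += 1
        for a_deg in angles:  # gyroscope: angular velocity in deg/s
            imu[:, col] = np.gradient(a_deg, dt)
            col += 1
    if config.noise_sd_imu > 0:
        noise = rng.normal(0.0, 1.0, size=imu.shape)
        sd = np.array(
            [config.noise_sd_imu if "acc" in ch else 10.0 * config.noise_sd_imu
             for ch in IMU_CHANNELS]
        )
        imu = imu + noise * sd[None, :]

    return MotionTrial(
        subject_id=subject_id,
        direction=direction,
        cycle=cycle,
        sample_rate=fs,
        angle_curves=angle_curves,
        vgrf=vgrf,
        imu=imu,
    )


def generate_dataset(
    config: GeneratorConfig,
    directions: tuple[DirectionCondition, ...] = DIRECTIONS,
) -> tuple[list[MotionTrial], pd.DataFrame]:
    """Generate all trials plus a manifest table.

    Emits ``n_subjects * cycles_per_subject`` trials per direction.  With
    the default sizing (25 subjects x 9 cycles) this reproduces 225 trials
    per direction, 675 in total.  The manifest holds one row per trial
    (subject_id, direction, cycle, trial_id).
    """
    trials: list[MotionTrial] = []
    rows = []
    for direction in directions:
        direction = DirectionCondition(int(direction))
        for subject in range(1, config.n_subjects + 1):
            for cycle in range(1, config.cycles_per_subject + 1):
                rng = substream(config.seed, "trial", subject, int(direction), cycle)
                trial = generate_trial(config, subject, direction, rng, cycle=cycle)
                trials.append(trial)
                rows.append(
                    {
                        "subject_id": subject,
                        "direction": int(direction),
                        "cycle": cycle,
                        "trial_id": trial.trial_id,
                    }
                )
    manifest = pd.DataFrame(rows)
    return trials, manifest


# --- disk round trip ------------------------------------------------------

def save_dataset(trials: list[MotionTrial], manifest: pd.DataFrame,
                 outdir: str | Path, seed_log: dict | None = None) -> Path:
    """Write one CSV per trial plus manifest.csv and seeds.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for trial in trials:
        df = pd.DataFrame({name: c for name, c in trial.angle_curves.items()})
        df["vgrf"] = trial.vgrf
        for i, ch in enumerate(IMU_CHANNELS):
            df[ch] = trial.imu[:, i]
        path = outdir / f"{trial.trial_id}.csv"
        df.to_csv(path, index=False)
        paths.append(path.name)
    manifest = manifest.copy()
    manifest["file"] = paths
    manifest.to_csv(outdir / "manifest.csv", index=False)
    (outdir / "seeds.json").write_text(json.dumps(seed_log or {}, indent=2))
    return outdir


def load_dataset(outdir: str | Path,
                 sample_rate: float = 200.0) -> tuple[list[MotionTrial], pd.DataFrame]:
    """Read back a dataset written by :func:`save_dataset`."""
    outdir = Path(outdir)
    manifest = pd.read_csv(outdir / "manifest.csv")
    trials = []
    for row in manifest.itertuples():
        df = pd.read_csv(outdir / row.file)
        trials.append(
            MotionTrial(
                subject_id=int(row.subject_id),
                direction=DirectionCondition(int(row.direction)),
                cycle=int(row.cycle),
                sample_rate=sample_rate,
                angle_curves={c: df[c].to_numpy() for c in ANGLE_CHANNELS},
                vgrf=df["vgrf"].to_numpy(),
                imu=df[list(IMU_CHANNELS)].to_numpy(),
            )
        )
    return trials, manifest
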