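"""Inter-joint coordination variability via vector coding.

For a coupling (proximal angle, distal angle) observed over k movement
cycles, each normalized to 101 frames, the frame-to-frame change defines a
vector on the angle-angle plane for each of the 100 frame intervals.  The
Tepavac/Field-Fote coefficient of correspondence decomposes the cycle-to-
cycle consistency of those vectors at interval i into

    a_i  — directional consistency: the circular mean resultant length of
           the vector orientations across cycles,
    m_i  — magnitude consistency: 1 - SD(l)/mean(l) of the vector lengths
           across cycles (population SD), clipped to [0, 1],
    r_i  = a_i * m_i  in [0, 1],

with r = 1 meaning every cycle traces the same angle-angle step and r = 0
meaning no correspondence.  Intervals where every cycle's vector is zero
are assigned r = 1 (no movement is perfectly repeatable); zero-length
vectors are excluded from the circular mean but kept in the magnitude
statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Coupling",
    "STANDARD_COUPLINGS",
    "CouplingCurveSet",
    "CoordinationVariabilityCurve",
    "frame_vectors",
    "coefficient_of_correspondence",
    "summarize_variability",
    "curves_to_frame",
    "curve_set_from_frame",
]


@dataclass(frozen=True)
class Coupling:
    """A proximal/distal channel pair analyzed on the angle-angle plane."""

    name: str
    proximal_channel: str
    distal_channel: str


#: The three couplings analyzed by default: thigh abduction-adduction vs
#: leg (shank) flexion-extension, hip rotation vs knee flexion-extension,
#: and knee flexion-extension vs ankle rotation.
STANDARD_COUPLINGS: tuple[Coupling, ...] = (
    Coupling("ThighAA_LegFE", "thigh_aa", "leg_fe"),
    Coupling("HipR_KneeFE", "hip_rot", "knee_fe"),
    Coupling("KneeFE_AnkleR", "knee_fe", "ankle_rot"),
)

_STANDARD_NAMES = {c.name for c in STANDARD_COUPLINGS}


@dataclass
class CouplingCurveSet:
    """k cycles x 101 frames of paired (proximal, distal) angles, degrees."""

    proximal: np.ndarray  # (k, 101)
    distal: np.ndarray  # (k, 101)
    coupling: Coupling | None = None
    direction: int | None = None
    allow_custom: bool = False

    def __post_init__(self) -> None:
        self.proximal = np.asarray(self.proximal, dtype=float)
        self.distal = np.asarray(self.distal, dtype=float)
        if self.proximal.shape != self.distal.shape:
            raise ValueError("proximal and distal arrays must share a shape")
        if self.proximal.ndim != 2 or self.proximal.shape[1] != 101:
            raise ValueError("curves must have shape (k, 101)")
        if self.proximal.shape[0] < 2:
            raise ValueError("the coefficient of correspondence needs k >= 2 cycles")
        if (self.coupling is not None and not self.allow_custom
                and self.coupling.name not in _STANDARD_NAMES):
            raise ValueError(
                f"coupling {self.coupling.name!r} is not one of the standard "
                "couplings; pass allow_custom=True to analyze it anyway"
            )

    @property
    def n_cycles(self) -> int:
        return self.proximal.shape[0]


@dataclass
class CoordinationVariabilityCurve:
    """Per-interval coefficient of correspondence and its two components."""

    r: np.ndarray  # (100,)
    a: np.ndarray  # (100,)
    m: np.ndarray  # (100,)
    coupling: Coupling | None = None
    direction: int | None = None


def frame_vectors(curves: CouplingCurveSet) -> np.ndarray:
    """Frame-to-frame (d proximal, d distal) vectors, shape (k, 100, 2)."""
    if not (np.isfinite(curves.proximal).all() and np.isfinite(curves.distal).all()):
        bad = np.argwhere(
            ~(np.isfinite(curves.proximal) & np.isfinite(curves.distal))
        )[0]
        raise ValueError(
            f"non-finite angle at cycle {int(bad[0])}, frame {int(bad[1])}"
        )
    dp = np.diff(curves.proximal, axis=1)
    dd = np.diff(curves.distal, axis=1)
    return np.stack([dp, dd], axis=-1)


def coefficient_of_correspondence(curves: CouplingCurveSet
                                  ) -> CoordinationVariabilityCurve:
    """Coefficient of correspondence r = a * m across cycles.

    Vectorized over the 100 frame intervals; see the module docstring for
    the decomposition and the zero-vector conventions.
    """
    vec = frame_vectors(curves)  # (k, 100, 2)
    lengths = np.hypot(vec[..., 0], vec[..., 1])  # (k, 100)
    nonzero = lengths > 0.0

    # directional consistency: mean resultant length over nonzero vectors
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_t = np.where(nonzero, vec[..., 0] / np.where(nonzero, lengths, 1.0), 0.0)
        sin_t = np.where(nonzero, vec[..., 1] / np.where(nonzero, lengths, 1.0), 0.0)
    n_nonzero = nonzero.sum(axis=0)  # (100,)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_cos = cos_t.sum(axis=0) / n_nonzero
        mean_sin = sin_t.sum(axis=0) / n_nonzero
    a = np.hypot(mean_cos, mean_sin)

    # magnitude consistency: 1 - coefficient of variation (population SD)
    mean_l = lengths.mean(axis=0)
    sd_l = lengths.std(axis=0)  # population SD
    with np.errstate(invalid="ignore", divide="ignore"):
        m = 1.0 - sd_l / mean_l
    m = np.clip(m, 0.0, 1.0)

    all_zero = n_nonzero == 0
    a = np.where(all_zero, 1.0, a)
    m = np.where(all_zero, 1.0, m)
    r = a * m
    return CoordinationVariabilityCurve(
        r=r, a=a, m=m, coupling=curves.coupling, direction=curves.direction
    )


def summarize_variability(curve: CoordinationVariabilityCurve,
                          window: tuple[float, float] = (0.0, 100.0)
                          ) -> tuple[float, float]:
    """(mean, max) of r over a stride-percent window.

    Interval i (0-based) spans i%..(i+1)% of the stride; an interval is in
    the window when its midpoint lies inside [window[0], window[1]].
    """
    lo, hi = window
    if not (0.0 <= lo < hi <= 100.0):
        raise ValueError("window must satisfy 0 <= lo < hi <= 100")
    mid = np.arange(100) + 0.5
    mask = (mid >= lo) & (mid <= hi)
    if not mask.any():
        raise ValueError("window contains no frame interval")
    vals = curve.r[mask]
    return float(vals.mean()), float(vals.max())


# --- CSV interchange ------------------------------------------------------

def curves_to_frame(curve: CoordinationVariabilityCurve) -> pd.DataFrame:
    """Long-format table (interval, a, m, r) for CSV export."""
    return pd.DataFrame(
        {"interval": np.arange(100), "a": curve.a, "m": curve.m, "r": curve.r}
    )


def curve_set_from_frame(df: pd.DataFrame, coupling: Coupling | None = None,
                         direction: int | None = None,
                         allow_custom: bool = False) -> CouplingCurveSet:
    """Build a CouplingCurveSet from long-format columns
    (cycle, frame, proximal, distal)."""
    wide_p = df.pivot(index="cycle", columns="frame", values="proximal")
    wide_d = df.pivot(index="cycle", columns="frame", values="distal")
    return CouplingCurveSet(
        proximal=wide_p.to_numpy(),
        distal=wide_d.to_numpy(),
        coupling=coupling,
        direction=direction,
        allow_custom=allow_custom,
    )


def write_summary(curve: CoordinationVariabilityCurve, path: str | Path,
                  window: tuple[float, float] = (0.0, 100.0)) -> None:
    mean, mx = summarize_variability(curve, window)
    payload = {
        "coupling": curve.coupling.name if curve.coupling else None,
        "direction": curve.direction,
        "window_stride_pct": list(window),
        "mean_r": mean,
        "max_r": mx,
    }
    Path(path).write_text(json.dumps(payload, indent=2))
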