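"""Synthetic joint/segment angle templates.

Truncated four-term Fourier series per channel, evaluated over normalized
movement-cycle time s in [0, 1].  The coefficients below are synthetic
fixture constants chosen to give smooth, plausibly-shaped lower-limb curves
for a planted-foot change-of-direction movement; they carry no biological
claim and are not fit to any measured data.  Direction conditions (90, 135,
180 degrees) modulate amplitude and offset so the three conditions share a
family of shapes without being identical.
"""

from __future__ import annotations

import numpy as np

__all__ = ["ANGLE_CHANNELS", "evaluate_template", "template_matrix"]

# name -> (a0, (a1..a4), (b1..b4)), degrees
_TEMPLATES: dict[str, tuple[float, tuple[float, ...], tuple[float, ...]]] = {
    "hip_fe": (25.0, (-15.0, 4.0, 1.0, 0.2), (12.0, -3.0, 0.8, 0.2)),
    "hip_aa": (-5.0, (4.0, -1.5, 0.5, 0.1), (-5.0, 1.5, 0.4, 0.1)),
    "hip_rot": (5.0, (-6.0, 2.5, 0.8, 0.2), (5.0, -2.0, 0.5, 0.1)),
    "knee_fe": (35.0, (-20.0, 6.0, 2.0, 0.5), (10.0, -4.0, 1.0, 0.3)),
    "knee_aa": (2.0, (2.0, -1.0, 0.3, 0.1), (3.0, -0.8, 0.2, 0.05)),
    "knee_rot": (2.0, (-4.0, 1.5, 0.5, 0.1), (4.0, -1.2, 0.4, 0.1)),
    "ankle_fe": (5.0, (-8.0, 5.0, 1.5, 0.4), (9.0, -2.0, 0.6, 0.2)),
    "ankle_aa": (0.0, (3.0, -1.0, 0.3, 0.1), (-3.0, 1.0, 0.3, 0.1)),
    "ankle_rot": (-3.0, (-5.0, 2.0, 0.7, 0.2), (6.0, -1.5, 0.5, 0.1)),
    "thigh_fe": (20.0, (-12.0, 3.5, 1.0, 0.2), (10.0, -2.5, 0.7, 0.2)),
    "thigh_aa": (-4.0, (5.0, -2.0, 0.6, 0.2), (-6.0, 2.0, 0.5, 0.1)),
    "thigh_rot": (3.0, (-4.0, 1.5, 0.5, 0.1), (5.0, -1.5, 0.4, 0.1)),
    "leg_fe": (30.0, (-18.0, 5.0, 1.5, 0.4), (14.0, -4.0, 1.0, 0.3)),
    "leg_aa": (1.0, (2.5, -1.0, 0.3, 0.1), (-2.5, 1.0, 0.3, 0.1)),
    "leg_rot": (-1.0, (-3.0, 1.2, 0.4, 0.1), (4.0, -1.0, 0.3, 0.1)),
}

ANGLE_CHANNELS: tuple[str, ...] = tuple(_TEMPLATES)

# direction -> (amplitude factor, additive offset in degrees)
_DIRECTION_MOD: dict[int, tuple[float, float]] = {
    90: (1.00, 0.0),
    135: (1.08, 1.5),
    180: (1.15, 3.0),
}


def evaluate_template(name: str, s: np.ndarray, direction: int) -> np.ndarray:
    """Evaluate one channel template at normalized cycle times ``s``."""
    a0, a, b = _TEMPLATES[name]
    amp, off = _DIRECTION_MOD[int(direction)]
    s = np.asarray(s, dtype=float)
    out = np.full_like(s, a0)
    for k in range(1, 5):
        w = 2.0 * np.pi * k * s
        out = out + a[k - 1] * np.cos(w) + b[k - 1] * np.sin(w)
    return amp * out + off


def template_matrix(s: np.ndarray, direction: int) -> np.ndarray:
    """All channel templates stacked as columns, shape (len(s), n_channels)."""
    return np.column_stack(
        [evaluate_template(name, s, direction) for name in ANGLE_CHANNELS]
    )
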