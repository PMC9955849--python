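"""Labeled synthetic bounding-box sessions for the fall-detection pipeline.

Each session follows the acquisition protocol the classifier is meant for: a
subject walks, rotates in place for about 30 s (the pre-fall dizziness
surrogate), then falls onto a mattress and lies prone.  Sessions are rendered
as 60 FPS bounding-box streams under two camera geometries (mounting heights
1.6 m and 3.1 m); camera height changes the perspective box scale but not
the centroid path, since both cameras aim at the subject.  Subject heights
are drawn from Normal(1.586 m, 0.143 m), the cohort statistics the protocol
mirrors.

The fall is a constant-acceleration template: the centroid drops by a fixed
fraction of the frame over ~0.7 s (about 40 frames at 60 FPS — the transit
the staged alarm is timed against) while the box aspect flips from upright to
prone.  Detection jitter is additive Gaussian noise on every box corner.
No images are rendered; the stream is exactly what a detector would emit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .trajectory_features import BBox

MEAN_SUBJECT_HEIGHT = 1.586  # meters
SD_SUBJECT_HEIGHT = 0.143
CAMERA_HEIGHTS = (1.6, 3.1)  # meters


@dataclass
class SessionSpec:
    """Parameters of one recorded session."""

    fps: float = 60.0
    walk_s: float = 10.0
    spin_s: float = 30.0
    fall_s: float = 0.7
    rest_s: float = 5.0
    camera_height: float = 1.6
    subject_height: float = MEAN_SUBJECT_HEIGHT
    noise_sd: float = 2.0  # pixels, detector jitter on each box corner
    frame_size: Tuple[int, int] = (640, 480)
    transition_frames: int = 40  # pre-impact frames labeled "transition"
    seed: int = 0

    def __post_init__(self):
        if self.fps <= 0:
            raise ValueError("invalid rate")
        if min(self.walk_s, self.spin_s, self.fall_s, self.rest_s) < 0:
            raise ValueError("durations must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class Session:
    """A simulated stream plus its per-frame ground truth."""

    spec: SessionSpec
    bboxes: List[BBox]
    labels: List[str]  # normal | transition | falling, one per frame
    impact_time: Optional[float]  # None for fall-free sessions

    @property
    def frame_size(self) -> Tuple[int, int]:
        return self.spec.frame_size


# kinematic template constants (normalized image units)
_WALK_X0 = 0.2
_WALK_VX = 0.04  # units / s
_FALL_DROP = 0.25  # centroid drop during the fall
_HORIZ_DIST = 3.5  # meters, camera to subject
_SPIN_AMP = 0.004
_SPIN_POS_HZ = 0.5
_SPIN_TURN_S = 3.0
_GAIT_BOB_AMP = 0.008  # vertical centroid bob while stepping
_GAIT_BOB_HZ = 1.9
_SPIN_SWAY_AMP = 0.006  # slow postural sway while rotating in place
_SPIN_SWAY_HZ = 0.4


def _box_scale(spec: SessionSpec) -> Tuple[float, float]:
    """Apparent box height/width fractions: size ~ 1 / camera-subject distance."""
    dist = float(
        np.hypot(_HORIZ_DIST, spec.camera_height - spec.subject_height / 2.0)
    )
    h = min(0.9 * spec.subject_height / dist, 0.8)
    return h, 0.35 * h


def _stand_height(spec: SessionSpec) -> float:
    """Standing centroid row: cameras are tilted to center the subject, so
    mounting height leaves only a small residual offset of the body row
    (image y grows downward; a higher camera sees the body slightly lower)."""
    drop = spec.camera_height - spec.subject_height / 2.0
    return 0.5 + 0.02 * (drop - 0.9) / 2.5


def simulate_session(spec: SessionSpec) -> Session:
    """Render one session; deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    fps = spec.fps
    n_walk = int(round(spec.walk_s * fps))
    n_spin = int(round(spec.spin_s * fps))
    n_fall = int(round(spec.fall_s * fps))
    n_rest = int(round(spec.rest_s * fps))
    n = n_walk + n_spin + n_fall + n_rest
    if n == 0:
        raise ValueError("empty input")

    h0, w0 = _box_scale(spec)
    y_stand = _stand_height(spec) + (0.01 * rng.standard_normal() if spec.noise_sd > 0 else 0.0)
    gait_phase = rng.uniform(0, 2 * np.pi) if spec.noise_sd > 0 else 0.0
    cx = np.empty(n)
    cy = np.full(n, y_stand)
    bh = np.full(n, h0)
    bw = np.full(n, w0)

    # walk: constant-velocity centroid with a small vertical gait bob
    tw = np.arange(n_walk) / fps
    cx[:n_walk] = np.minimum(_WALK_X0 + _WALK_VX * tw, 0.9)
    cy[:n_walk] += _GAIT_BOB_AMP * np.sin(2 * np.pi * _GAIT_BOB_HZ * tw + gait_phase)
    x_end = cx[n_walk - 1] if n_walk else _WALK_X0

    # spin: near-stationary centroid with postural sway, box width oscillating
    ts = np.arange(n_spin) / fps
    sl = slice(n_walk, n_walk + n_spin)
    cx[sl] = x_end + _SPIN_AMP * np.sin(2 * np.pi * _SPIN_POS_HZ * ts)
    cy[sl] += _SPIN_SWAY_AMP * np.sin(2 * np.pi * _SPIN_SWAY_HZ * ts + gait_phase)
    bw[sl] = h0 * (0.35 + 0.15 * np.abs(np.sin(2 * np.pi * ts / _SPIN_TURN_S)))

    # fall: constant-acceleration drop to mattress contact (80% of the drop
    # over 80% of the phase), then a constant-deceleration settle to rest;
    # the velocity profile is continuous and the aspect ratio flips.
    n_contact = int(round(0.8 * n_fall)) if n_fall else 0
    if n_fall:
        u = np.arange(1, n_fall + 1) / n_fall  # phase fraction
        tf = np.where(
            u <= 0.8,
            0.8 * (u / 0.8) ** 2,
            1.0 - 0.2 * ((1.0 - u) / 0.2) ** 2,
        )
        fl = slice(n_walk + n_spin, n_walk + n_spin + n_fall)
        cx[fl] = x_end
        cy[fl] = y_stand + _FALL_DROP * tf
        bh[fl] = h0 * (1.0 - 0.65 * tf)
        bw[fl] = w0 + (0.75 * h0 - w0) * tf

    # prone rest
    if n_rest:
        rl = slice(n_walk + n_spin + n_fall, n)
        cx[rl] = x_end
        cy[rl] = y_stand + _FALL_DROP
        bh[rl] = 0.35 * h0
        bw[rl] = 0.75 * h0

    W, H = spec.frame_size
    corners = np.empty((n, 4))
    corners[:, 0] = (cx - bw / 2) * W  # x_min
    corners[:, 1] = (cy - bh / 2) * H  # y_min
    corners[:, 2] = (cx + bw / 2) * W  # x_max
    corners[:, 3] = (cy + bh / 2) * H  # y_max
    if spec.noise_sd > 0:
        corners = corners + rng.normal(0.0, spec.noise_sd, size=corners.shape)
    corners[:, 2] = np.maximum(corners[:, 2], corners[:, 0] + 1.0)
    corners[:, 3] = np.maximum(corners[:, 3], corners[:, 1] + 1.0)
    conf = np.clip(0.95 + 0.02 * rng.standard_normal(n), 0.0, 1.0)

    t = np.arange(n) / fps
    bboxes = [
        BBox(
            frame_index=i,
            t=float(t[i]),
            x_min=float(corners[i, 0]),
            y_min=float(corners[i, 1]),
            x_max=float(corners[i, 2]),
            y_max=float(corners[i, 3]),
            confidence=float(conf[i]),
        )
        for i in range(n)
    ]

    labels = ["normal"] * n
    impact_time: Optional[float] = None
    if n_fall:
        # impact = the body coming to rest on the mattress (the fall/rest
        # phase boundary); mattress contact precedes it by the settle time
        impact_frame = n_walk + n_spin + n_fall
        impact_time = impact_frame / fps
        for i in range(max(impact_frame - spec.transition_frames, 0), impact_frame):
            labels[i] = "transition"
        for i in range(impact_frame, n):
            labels[i] = "falling"
    return Session(spec=spec, bboxes=bboxes, labels=labels, impact_time=impact_time)


def draw_subject_heights(n: int, rng: np.random.Generator) -> np.ndarray:
    """Cohort heights ~ Normal(1.586, 0.143) meters."""
    return rng.normal(MEAN_SUBJECT_HEIGHT, SD_SUBJECT_HEIGHT, size=n)


def simulate_cohort(
    n_subjects: int = 15,
    overrides: Optional[Dict] = None,
    seed: int = 0,
) -> List[Session]:
    """Per-subject sessions under both camera geometries (2 streams/subject).

    Subject heights are drawn once per subject; every session gets an
    independent sub-seed, so the cohort is deterministic given ``seed``.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    base = SessionSpec(**(overrides or {}))
    rng = np.random.default_rng(seed)
    heights = draw_subject_heights(n_subjects, rng)
    sub_seeds = rng.integers(0, 2**31 - 1, size=(n_subjects, len(CAMERA_HEIGHTS)))
    sessions: List[Session] = []
    for i in range(n_subjects):
        for j, cam in enumerate(CAMERA_HEIGHTS):
            spec = replace(
                base,
                camera_height=cam,
                subject_height=float(heights[i]),
                seed=int(sub_seeds[i, j]),
            )
            sessions.append(simulate_session(spec))
    return sessions
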