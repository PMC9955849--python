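"""Bounding-box streams -> windowed centroid features -> attended 2-D samples.

A detector (out of scope here) emits one bounding box per frame.  Each box is
reduced to its centroid in normalized image coordinates, augmented with
backward-difference speeds, grouped into 21-frame sliding windows
(BBox(t)..BBox(t+20)), and passed through a light self-attention block:

* per-frame feature vector  f(t) = (x, y, vx, vy)
* gate                      c(t) = 4 * softmax(G f(t) + b)
* gated feature             o(t) = c(t) (.) f(t) + f(t)      (residual add)
* pooling                   mean of o(t) over the 21 frames
* projection                s = P^T pooled                    (s is 2-D)

The rescale by 4 makes the all-equal gate the identity multiplier, so an
untrained block is a benign residual doubling.  The 2-D samples ``s`` are what
the mixture model clusters and what the posture maps plot.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from . import _tape as T

WINDOW_LEN = 21  # BBox(t) .. BBox(t+20)
N_FEATURES = 4  # x, y, vx, vy
FEATURE_DIM = 2


@dataclass(frozen=True)
class BBox:
    """One detected bounding box, in pixel coordinates."""

    frame_index: int
    t: float
    x_min: float
    y_min: float
    x_max: float
    y_max: float
    confidence: float = 1.0

    def __post_init__(self):
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError("degenerate box: max corner must exceed min corner")


@dataclass(frozen=True)
class CentroidSample:
    """Centroid position (normalized [0,1] image coords) and speed at time t."""

    t: float
    x: float
    y: float
    vx: float
    vy: float

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.vx, self.vy])


@dataclass(frozen=True)
class FeatureWindow:
    """Exactly 21 consecutive centroid samples, dated by the first sample."""

    samples: Tuple[CentroidSample, ...]
    t_anchor: float

    def __post_init__(self):
        if len(self.samples) != WINDOW_LEN:
            raise ValueError(f"a feature window holds exactly {WINDOW_LEN} samples")

    def as_array(self) -> np.ndarray:
        return np.stack([s.as_array() for s in self.samples])


@dataclass
class AttentionParams:
    """Trainable parameters of the feature-gating attention block."""

    gate_weights: np.ndarray  # (4, 4)
    gate_bias: np.ndarray  # (4,)
    projection: np.ndarray  # (4, 2), maps pooled features to the sample space

    def __post_init__(self):
        self.gate_weights = np.asarray(self.gate_weights, dtype=float).reshape(
            N_FEATURES, N_FEATURES
        )
        self.gate_bias = np.asarray(self.gate_bias, dtype=float).reshape(N_FEATURES)
        self.projection = np.asarray(self.projection, dtype=float).reshape(
            N_FEATURES, FEATURE_DIM
        )
        if not all(
            np.all(np.isfinite(a))
            for a in (self.gate_weights, self.gate_bias, self.projection)
        ):
            raise ValueError("numerical failure: attention parameters must be finite")

    @classmethod
    def default(cls, rng: Optional[np.random.Generator] = None) -> "AttentionParams":
        """Identity gates; projection picks (y, vy), the fall-relevant pair.

        Vertical position separates upright from prone postures and vertical
        speed flags the fall transit, so this is a sensible starting point
        that training then refines.  With zero gate weights the block is a
        pure residual doubling of the pooled features.
        """
        gw = np.zeros((N_FEATURES, N_FEATURES))
        gb = np.zeros(N_FEATURES)
        proj = np.zeros((N_FEATURES, FEATURE_DIM))
        proj[1, 0] = 1.0  # y   -> s1
        proj[3, 1] = 1.0  # vy  -> s2
        if rng is not None:
            gw = gw + 0.01 * rng.standard_normal(gw.shape)
            gb = gb + 0.01 * rng.standard_normal(gb.shape)
        return cls(gw, gb, proj)


@dataclass
class FeatureVector:
    """One attended 2-D sample; the point the mixture model sees."""

    s: np.ndarray
    t: float = 0.0
    label: Optional[str] = None
    normalized: bool = False

    def __post_init__(self):
        self.s = np.asarray(self.s, dtype=float).reshape(FEATURE_DIM)
        if not np.all(np.isfinite(self.s)):
            raise ValueError("numerical failure: non-finite feature vector")


# ---------------------------------------------------------------------------
# centroid extraction and windowing


def extract_centroids(
    stream: Sequence[BBox],
    fps: float,
    frame_size: Tuple[float, float],
) -> List[CentroidSample]:
    """Box midpoints in normalized coordinates plus backward-difference speeds.

    Speeds are the first-order backward difference of normalized position
    scaled by the frame rate; the first sample of a stream has zero speed.
    """
    if len(stream) == 0:
        raise ValueError("empty input")
    width, height = frame_size
    if width <= 0 or height <= 0:
        raise ValueError("frame_size must be positive")
    t = np.array([b.t for b in stream])
    frames = np.array([b.frame_index for b in stream])
    if np.any(np.diff(t) <= 0) or np.any(np.diff(frames) <= 0):
        raise ValueError("unsorted stream")

    x = np.array([(b.x_min + b.x_max) / 2.0 for b in stream]) / width
    y = np.array([(b.y_min + b.y_max) / 2.0 for b in stream]) / height
    vx = np.zeros_like(x)
    vy = np.zeros_like(y)
    vx[1:] = np.diff(x) * fps
    vy[1:] = np.diff(y) * fps
    return [
        CentroidSample(float(t[i]), float(x[i]), float(y[i]), float(vx[i]), float(vy[i]))
        for i in range(len(stream))
    ]


def make_windows(
    samples: Sequence[CentroidSample],
    stride: int = 1,
    fps: Optional[float] = None,
) -> List[FeatureWindow]:
    """Sliding 21-sample windows; windows spanning a detection gap are dropped.

    A gap is a step between consecutive samples larger than two frame
    intervals (2/fps); fps is inferred from the median step when not given.
    """
    n = len(samples)
    if n < WINDOW_LEN:
        raise ValueError("stream too short")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    t = np.array([s.t for s in samples])
    dt = np.diff(t)
    if fps is None:
        fps = 1.0 / float(np.median(dt))
    max_gap = 2.0 / fps * (1.0 + 1e-9)

    windows: List[FeatureWindow] = []
    for start in range(0, n - WINDOW_LEN + 1, stride):
        if np.any(dt[start : start + WINDOW_LEN - 1] > max_gap):
            continue
        chunk = tuple(samples[start : start + WINDOW_LEN])
        windows.append(FeatureWindow(chunk, t_anchor=chunk[0].t))
    return windows


def window_array(windows: Sequence[FeatureWindow]) -> np.ndarray:
    """Stack windows into the (n_windows, 21, 4) tensor the trainer consumes."""
    return np.stack([w.as_array() for w in windows])


@dataclass
class ChannelScaler:
    """Per-channel z-scoring of the (x, y, vx, vy) window features.

    Positions are bounded in [0,1] while backward-difference speeds scale
    with the frame rate, so the raw channels live on very different scales;
    standardizing them (statistics fitted on training windows only) puts the
    attended samples on an O(1) footing, which the fixed-step trainer needs.
    """

    means: np.ndarray  # (4,)
    stds: np.ndarray  # (4,)

    def __post_init__(self):
        self.means = np.asarray(self.means, dtype=float).reshape(N_FEATURES)
        self.stds = np.asarray(self.stds, dtype=float).reshape(N_FEATURES)
        if np.any(self.stds <= 0):
            raise ValueError("degenerate axis")

    @classmethod
    def fit(cls, windows: np.ndarray) -> "ChannelScaler":
        flat = np.asarray(windows, dtype=float).reshape(-1, N_FEATURES)
        stds = flat.std(axis=0)
        if np.any(stds <= 0):
            raise ValueError("degenerate axis")
        return cls(flat.mean(axis=0), stds)

    def transform(self, windows: np.ndarray) -> np.ndarray:
        return (np.asarray(windows, dtype=float) - self.means) / self.stds

    def to_dict(self) -> dict:
        return {"means": self.means.tolist(), "stds": self.stds.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "ChannelScaler":
        return cls(np.array(d["means"]), np.array(d["stds"]))


# ---------------------------------------------------------------------------
# attention block


def attention_graph(F, gate_weights, gate_bias, projection):
    """Attention forward pass on tape variables (or constants).

    ``F`` has shape (batch, 21, 4); the result has shape (batch, 2).  Shared
    by the plain forward pass and the training loop so there is a single code
    path for the block.
    """
    F = T.as_var(F)
    G = T.as_var(gate_weights)
    b = T.as_var(gate_bias)
    P = T.as_var(projection)
    logits = T.add(T.matmul(F, T.vswapaxes(G, -1, -2)), b)
    gates = T.mul(4.0, T.vsoftmax(logits, axis=-1))
    gated = T.add(T.mul(gates, F), F)  # residual add
    pooled = T.vmean(gated, axis=-2)
    return T.matmul(pooled, P)


def attention_forward_batch(F: np.ndarray, params: AttentionParams) -> np.ndarray:
    """Vectorized numpy forward pass: (n, 21, 4) windows -> (n, 2) samples."""
    F = np.asarray(F, dtype=float)
    logits = F @ params.gate_weights.T + params.gate_bias
    logits -= logits.max(axis=-1, keepdims=True)
    e = np.exp(logits)
    gates = 4.0 * e / e.sum(axis=-1, keepdims=True)
    pooled = (gates * F + F).mean(axis=-2)
    s = pooled @ params.projection
    if not np.all(np.isfinite(s)):
        raise ValueError("numerical failure")
    return s


def attention_forward(window: FeatureWindow, params: AttentionParams) -> FeatureVector:
    """Apply the attention block to one window; deterministic given params."""
    s = attention_forward_batch(window.as_array()[None], params)[0]
    return FeatureVector(s=s, t=window.t_anchor)
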