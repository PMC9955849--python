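"""End-to-end orchestration: sessions -> windows -> fit -> labeled detector.

A trained :class:`FallDetector` bundles the variational state, the expected
mixture in raw feature space, the post-hoc cluster-to-region tags (majority
vote of labeled training windows, ties toward the more severe label), the
min-max normalization fitted on training features, and the acquisition
geometry (fps, frame size) needed to featurize new streams.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .alarm import AlarmEvent, alarm_state_machine
from .posture_maps import NormalizationRecord, transform_gmm
from .svi_gmm import (
    FitConfig,
    FitResult,
    GMMParams,
    VariationalState,
    assign_cluster_labels,
    expected_gmm,
    posterior_responsibility,
    svi_fit,
)
from .synthetic import Session
from .trajectory_features import (
    BBox,
    ChannelScaler,
    FeatureVector,
    attention_forward_batch,
    extract_centroids,
    make_windows,
    window_array,
)


def featurize_session(
    session: Session, stride: int = 1
) -> Tuple[np.ndarray, List[str], np.ndarray]:
    """Windows (n,21,4), per-window ground-truth labels (at the anchor frame)
    and anchor times for one session."""
    spec = session.spec
    samples = extract_centroids(session.bboxes, spec.fps, session.frame_size)
    windows = make_windows(samples, stride=stride, fps=spec.fps)
    X = window_array(windows)
    times = np.array([w.t_anchor for w in windows])
    labels = [session.labels[int(round(t * spec.fps))] for t in times]
    return X, labels, times


@dataclass
class FallDetector:
    """A trained posture classifier with alarm plumbing."""

    state: VariationalState
    gmm: GMMParams  # expected mixture in raw (unnormalized) feature space
    cluster_tags: Dict[int, str]
    norm: NormalizationRecord
    scaler: ChannelScaler
    fps: float
    frame_size: Tuple[int, int]
    loss_trace: Optional[np.ndarray] = None

    # training -----------------------------------------------------------
    @classmethod
    def train(
        cls,
        sessions: Sequence[Session],
        config: Optional[FitConfig] = None,
        seed: int = 0,
    ) -> "FallDetector":
        cfg = config or FitConfig()
        blocks = [featurize_session(s) for s in sessions]
        X = np.concatenate([b[0] for b in blocks])
        labels = [t for b in blocks for t in b[1]]
        scaler = ChannelScaler.fit(X)
        Xz = scaler.transform(X)
        result = svi_fit(Xz, cfg, seed=seed)
        feats = attention_forward_batch(Xz, result.state.attention)
        gmm = expected_gmm(result.state)
        tags = assign_cluster_labels(gmm, feats, labels)
        mins, maxs = feats.min(axis=0), feats.max(axis=0)
        spec = sessions[0].spec
        return cls(
            state=result.state,
            gmm=gmm,
            cluster_tags=tags,
            norm=NormalizationRecord(mins, maxs),
            scaler=scaler,
            fps=spec.fps,
            frame_size=sessions[0].frame_size,
            loss_trace=result.loss_trace,
        )

    # inference ----------------------------------------------------------
    def featurize_stream(
        self, bboxes: Sequence[BBox], stride: int = 1
    ) -> List[FeatureVector]:
        samples = extract_centroids(bboxes, self.fps, self.frame_size)
        windows = make_windows(samples, stride=stride, fps=self.fps)
        Xz = self.scaler.transform(window_array(windows))
        feats = attention_forward_batch(Xz, self.state.attention)
        return [
            FeatureVector(s=feats[i], t=w.t_anchor) for i, w in enumerate(windows)
        ]

    def predict_labels(self, feats: Sequence[FeatureVector]) -> List[str]:
        """Posture region per sample by the posterior argmax."""
        X = np.stack([f.s for f in feats])
        r = posterior_responsibility(X, self.gmm)
        return [self.cluster_tags[int(k)] for k in r.argmax(axis=1)]

    def alarm_events(
        self,
        bboxes: Sequence[BBox],
        threshold: float = 0.5,
        persistence: int = 3,
    ) -> List[AlarmEvent]:
        feats = self.featurize_stream(bboxes)
        return alarm_state_machine(
            feats, self.gmm, self.cluster_tags, threshold, persistence
        )

    def normalized_gmm(self) -> GMMParams:
        """The mixture expressed on the min-max-normalized map square."""
        return transform_gmm(self.gmm, self.norm)

    # serialization ------------------------------------------------------
    def to_json(self, path=None) -> str:
        doc = {
            "schema_version": 1,
            "state": json.loads(self.state.to_json()),
            "cluster_tags": {str(k): v for k, v in self.cluster_tags.items()},
            "norm": self.norm.to_dict(),
            "scaler": self.scaler.to_dict(),
            "fps": self.fps,
            "frame_size": list(self.frame_size),
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "FallDetector":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            doc = json.loads(source)
        else:
            with open(source) as fh:
                doc = json.load(fh)
        state = VariationalState.from_json(json.dumps(doc["state"]))
        return cls(
            state=state,
            gmm=expected_gmm(state),
            cluster_tags={int(k): v for k, v in doc["cluster_tags"].items()},
            norm=NormalizationRecord.from_dict(doc["norm"]),
            scaler=ChannelScaler.from_dict(doc["scaler"]),
            fps=float(doc["fps"]),
            frame_size=tuple(doc["frame_size"]),
        )


def evaluate_detector(
    detector: FallDetector, sessions: Sequence[Session]
) -> Dict[str, object]:
    """Window-level evaluation of a detector on held-out sessions."""
    from .evaluation import accuracy, confusion_from_streams, multiclass_accuracy

    predicted: List[str] = []
    truth: List[str] = []
    for session in sessions:
        X, labels, _ = featurize_session(session)
        feats = attention_forward_batch(
            detector.scaler.transform(X), detector.state.attention
        )
        r = posterior_responsibility(feats, detector.gmm)
        predicted.extend(detector.cluster_tags[int(k)] for k in r.argmax(axis=1))
        truth.extend(labels)
    counts = confusion_from_streams(predicted, truth)
    return {
        "counts": counts,
        "binary_accuracy": accuracy(counts),
        "label_accuracy": multiclass_accuracy(predicted, truth),
        "n_windows": len(truth),
    }
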