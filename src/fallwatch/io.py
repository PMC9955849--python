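"""File round-tripping: bounding-box streams, labels, features, alarm logs.

Formats are deliberately plain: CSV with mandatory headers for streams and
tabular outputs, JSON for specs, models and manifests.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .alarm import AlarmEvent, region_posteriors
from .synthetic import Session, SessionSpec
from .trajectory_features import BBox, FeatureVector

BBOX_COLUMNS = ["frame", "t", "x_min", "y_min", "x_max", "y_max", "confidence"]


def write_bbox_csv(bboxes: Sequence[BBox], path) -> None:
    df = pd.DataFrame(
        {
            "frame": [b.frame_index for b in bboxes],
            "t": [b.t for b in bboxes],
            "x_min": [b.x_min for b in bboxes],
            "y_min": [b.y_min for b in bboxes],
            "x_max": [b.x_max for b in bboxes],
            "y_max": [b.y_max for b in bboxes],
            "confidence": [b.confidence for b in bboxes],
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")  # exact float round trip


def read_bbox_csv(path) -> List[BBox]:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        raise ValueError(f"parse error: {exc}") from exc
    missing = set(BBOX_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"parse error: line 1: missing columns {sorted(missing)}")
    for col in BBOX_COLUMNS:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            # +2: one for the header, one for 1-based numbering
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise ValueError(f"parse error: line {line}: bad value in column '{col}'")
        df[col] = coerced
    return [
        BBox(
            frame_index=int(row.frame),
            t=float(row.t),
            x_min=float(row.x_min),
            y_min=float(row.y_min),
            x_max=float(row.x_max),
            y_max=float(row.y_max),
            confidence=float(row.confidence),
        )
        for row in df.itertuples()
    ]


def write_labels_csv(labels: Sequence[str], path) -> None:
    pd.DataFrame({"frame": range(len(labels)), "label": list(labels)}).to_csv(
        path, index=False
    )


def read_labels_csv(path) -> List[str]:
    df = pd.read_csv(path)
    if "label" not in df.columns:
        raise ValueError("parse error: line 1: missing columns ['label']")
    return list(df["label"].astype(str))


def write_session(session: Session, directory, stem: str) -> Dict[str, str]:
    """Write the stream CSV, labels CSV and session JSON; return the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "stream": str(directory / f"{stem}.bboxes.csv"),
        "labels": str(directory / f"{stem}.labels.csv"),
        "session": str(directory / f"{stem}.session.json"),
    }
    write_bbox_csv(session.bboxes, paths["stream"])
    write_labels_csv(session.labels, paths["labels"])
    with open(paths["session"], "w") as fh:
        json.dump(
            {"spec": asdict(session.spec), "impact_time": session.impact_time},
            fh,
            indent=1,
        )
    return paths


def read_session(session_json_path) -> Session:
    path = Path(session_json_path)
    with open(path) as fh:
        doc = json.load(fh)
    spec_doc = doc["spec"]
    spec_doc["frame_size"] = tuple(spec_doc["frame_size"])
    spec = SessionSpec(**spec_doc)
    stem = path.name.removesuffix(".session.json")
    bboxes = read_bbox_csv(path.parent / f"{stem}.bboxes.csv")
    labels = read_labels_csv(path.parent / f"{stem}.labels.csv")
    return Session(spec=spec, bboxes=bboxes, labels=labels, impact_time=doc["impact_time"])


def write_features_csv(points: Sequence[FeatureVector], path) -> None:
    pd.DataFrame(
        {
            "t": [p.t for p in points],
            "s1": [p.s[0] for p in points],
            "s2": [p.s[1] for p in points],
            "label": [p.label or "" for p in points],
        }
    ).to_csv(path, index=False, float_format="%.17g")


def write_alarm_csv(
    events: Sequence[AlarmEvent], labels: Dict[int, str], path
) -> None:
    rows = []
    for e in events:
        p = region_posteriors(e.posterior, labels)
        rows.append(
            {
                "t_enter": e.t_enter,
                "state": e.state,
                "trigger_index": e.trigger_index,
                "p_normal": p["normal"],
                "p_transition": p["transition"],
                "p_falling": p["falling"],
            }
        )
    pd.DataFrame(
        rows,
        columns=["t_enter", "state", "trigger_index", "p_normal", "p_transition", "p_falling"],
    ).to_csv(path, index=False)


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_manifest(directory, subcommand: str, seed, config: dict, inputs) -> str:
    from . import __version__

    doc = {
        "tool": "fallwatch",
        "version": __version__,
        "numpy_version": np.__version__,
        "subcommand": subcommand,
        "seed": seed,
        "config": config,
        "config_hash": config_hash(config),
        "inputs": sorted(str(p) for p in inputs),
    }
    path = Path(directory) / "manifest.json"
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, default=str)
    return str(path)
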