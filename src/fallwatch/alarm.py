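"""Staged fall alarms from streaming feature vectors.

Each attended sample is mapped to a posture region through the posterior
responsibilities; a small state machine escalates to Warning1 (transition
region) or Warning2 (falling region) once ``persistence`` consecutive samples
agree, and de-escalates under the same rule.  Samples whose winning
responsibility falls below the confidence threshold are "uncertain" and
neither advance nor reset the persistence counter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np

from .svi_gmm import GMMParams, posterior_responsibility
from .trajectory_features import FeatureVector

SEVERITY = {"normal": 0, "transition": 1, "falling": 2}
STATE_OF_REGION = {"normal": "normal", "transition": "warning1", "falling": "warning2"}
EXIT_CODE = {"normal": 0, "warning1": 1, "warning2": 2}


@dataclass
class AlarmEvent:
    """One state transition of the alarm machine."""

    state: str  # normal | warning1 | warning2
    t_enter: float
    trigger_index: int
    posterior: np.ndarray  # per-cluster responsibilities at the trigger


def classify_point(
    s,
    params: GMMParams,
    labels: Dict[int, str],
    threshold: float = 0.5,
) -> str:
    """Region of the winning cluster, or "uncertain" below the threshold.

    Ties in the argmax go to the lowest cluster index.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    r = posterior_responsibility(s, params)
    k = int(np.argmax(r))
    return labels[k] if r[k] >= threshold else "uncertain"


def region_posteriors(r: np.ndarray, labels: Dict[int, str]) -> Dict[str, float]:
    """Aggregate cluster responsibilities into per-region probabilities."""
    out = {region: 0.0 for region in SEVERITY}
    for k, tag in labels.items():
        out[tag] += float(r[k])
    return out


def alarm_state_machine(
    points: Sequence[FeatureVector],
    params: GMMParams,
    labels: Dict[int, str],
    threshold: float = 0.5,
    persistence: int = 3,
) -> List[AlarmEvent]:
    """Run the escalation machine over a time-ordered stream.

    A transition (in either direction) fires when ``persistence`` consecutive
    confident classifications land in the same region different from the
    current one; the event is stamped with the time and index of the point
    that completed the run.
    """
    if persistence < 1:
        raise ValueError("persistence must be >= 1")
    times = [p.t for p in points]
    if any(b < a for a, b in zip(times, times[1:])):
        raise ValueError("unsorted stream")

    events: List[AlarmEvent] = []
    current = "normal"
    pending: Optional[str] = None
    count = 0
    for i, p in enumerate(points):
        r = posterior_responsibility(p, params)
        k = int(np.argmax(r))
        if r[k] < threshold:
            continue  # uncertain: freeze the counter
        region = labels[k]
        state = STATE_OF_REGION[region]
        if state == current:
            pending, count = None, 0
            continue
        if state == pending:
            count += 1
        else:
            pending, count = state, 1
        if count >= persistence:
            events.append(
                AlarmEvent(state=state, t_enter=p.t, trigger_index=i, posterior=r)
            )
            current = state
            pending, count = None, 0
    return events


def lead_time(n_points: int, fps: float) -> float:
    """Seconds spanned by ``n_points`` consecutive centroid samples.

    The characteristic fall transit of ~40 points at 60 FPS gives 0.667 s.
    """
    if fps <= 0:
        raise ValueError("invalid rate")
    if n_points < 0:
        raise ValueError("n_points must be >= 0")
    return n_points / fps


_STATE_RANK = {"normal": 0, "warning1": 1, "warning2": 2}


def highest_severity(events: Sequence[AlarmEvent]) -> str:
    """Most severe state reached over a stream ("normal" when no events)."""
    best = "normal"
    for e in events:
        if _STATE_RANK[e.state] > _STATE_RANK[best]:
            best = e.state
    return best


def first_warning2_time(events: Sequence[AlarmEvent]) -> Optional[float]:
    for e in events:
        if e.state == "warning2":
            return e.t_enter
    return None
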