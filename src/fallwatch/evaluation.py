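"""Confusion-count metrics and model-comparison diagnostics.

Per-sample posture predictions are binarized (alert-centric: transition and
falling count as positive) into standard 2x2 confusion counts, from which
accuracy is computed.  Held-out log-likelihood comparisons across cluster
counts (K = 2 vs 3) and covariance structures (diagonal vs full) reproduce
the model-selection arithmetic behind the choice of a full-covariance
three-component mixture.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, FrozenSet, Iterable, List, Sequence, Tuple

import numpy as np

from .svi_gmm import FitConfig, _coerce_points, expected_gmm, gmm_log_likelihood, svi_fit

POSITIVE_DEFAULT = frozenset({"transition", "falling"})


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def accuracy(counts: ConfusionCounts) -> float:
    """(TP + TN) / total, kept at full precision (round only for display)."""
    if counts.total == 0:
        raise ValueError("empty counts")
    return (counts.tp + counts.tn) / counts.total


def confusion_from_streams(
    predicted: Sequence[str],
    truth: Sequence[str],
    positive: FrozenSet[str] = POSITIVE_DEFAULT,
) -> ConfusionCounts:
    """Binarize two aligned label streams and tally the 2x2 counts."""
    if len(predicted) != len(truth):
        raise ValueError("misaligned streams")
    tp = tn = fp = fn = 0
    for p, t in zip(predicted, truth):
        pp, tt = p in positive, t in positive
        if pp and tt:
            tp += 1
        elif not pp and not tt:
            tn += 1
        elif pp:
            fp += 1
        else:
            fn += 1
    return ConfusionCounts(tp, tn, fp, fn)


def multiclass_accuracy(predicted: Sequence[str], truth: Sequence[str]) -> float:
    if len(predicted) != len(truth):
        raise ValueError("misaligned streams")
    if len(predicted) == 0:
        raise ValueError("empty counts")
    return float(np.mean([p == t for p, t in zip(predicted, truth)]))


def heldout_loglik(
    train,
    test,
    variants: Sequence[Tuple[int, str]] = ((2, "diagonal"), (2, "full"), (3, "diagonal"), (3, "full")),
    config: FitConfig | None = None,
    seed: int = 0,
) -> Dict[Tuple[int, str], float]:
    """Fit each (K, covariance_mode) variant on ``train`` with a shared seed
    and report its mean log-likelihood on ``test`` under the expected
    mixture."""
    base = config or FitConfig()
    out: Dict[Tuple[int, str], float] = {}
    for K, mode in variants:
        key = (K, mode)
        if key in out:  # duplicate variants are free and identical by seed
            continue
        cfg = replace(base, K=K, covariance_mode=mode)
        result = svi_fit(train, cfg, seed=seed)
        params = expected_gmm(result.state)
        X_test, _ = _coerce_points(test)
        out[key] = float(np.mean(gmm_log_likelihood(X_test, params)))
    return out
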