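"""Annotation scoring: accuracy, Cohen's kappa, macro F1, adjusted Rand.

Conventions: "unknown" predictions count as incorrect unless the true label
lies outside the set of known (marker-bearing) types, in which case
"unknown" is the right call; macro F1 averages one-vs-rest F1 over the
types present in the truth.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import adjusted_rand_score, cohen_kappa_score

from .types import UNKNOWN_LABEL


@dataclass
class MetricReport:
    kappa: float
    mf1: float
    acc: float
    ari: float
    per_type_f1: dict[str, float]
    n_unknown: int

    def to_dict(self) -> dict:
        return {"kappa": self.kappa, "mf1": self.mf1, "acc": self.acc,
                "ari": self.ari, "n_unknown": self.n_unknown}


def _check(pred, true) -> tuple[list[str], list[str]]:
    pred = [str(x) for x in pred]
    true = [str(x) for x in true]
    if len(pred) != len(true):
        raise ValueError(f"length mismatch: {len(pred)} vs {len(true)}")
    if not pred:
        raise ValueError("empty label vectors")
    return pred, true


def _effective_truth(true: list[str], known_types: list[str] | None) -> list[str]:
    """Truth labels with types outside the known set mapped to "unknown"."""
    if known_types is None:
        return true
    known = set(known_types)
    return [t if t in known else UNKNOWN_LABEL for t in true]


def accuracy(pred, true, known_types: list[str] | None = None) -> float:
    """Exact-match proportion.  With ``known_types`` given, an "unknown"
    prediction is correct when the true label is outside that set."""
    pred, true = _check(pred, true)
    true = _effective_truth(true, known_types)
    return float(np.mean([p == t for p, t in zip(pred, true)]))


def cohens_kappa(pred, true, known_types: list[str] | None = None) -> float:
    """Chance-corrected agreement ``(p_o - p_e) / (1 - p_e)``.

    Degenerate marginals with ``p_e = 1`` (both raters constant on one
    class) return 0 with a warning.
    """
    pred, true = _check(pred, true)
    true = _effective_truth(true, known_types)
    if len(set(pred)) == 1 and set(pred) == set(true):
        warnings.warn("both label vectors are constant; kappa undefined, "
                      "returning 0", stacklevel=2)
        return 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        k = cohen_kappa_score(true, pred)
    if np.isnan(k):
        warnings.warn("kappa undefined (chance agreement is 1); returning 0",
                      stacklevel=2)
        return 0.0
    return float(k)


def per_type_f1(pred, true, known_types: list[str] | None = None
                ) -> dict[str, float]:
    """One-vs-rest F1 for every type present in the truth."""
    pred, true = _check(pred, true)
    true = _effective_truth(true, known_types)
    out: dict[str, float] = {}
    for t in sorted(set(true)):
        tp = sum(1 for p, y in zip(pred, true) if p == t and y == t)
        fp = sum(1 for p, y in zip(pred, true) if p == t and y != t)
        fn = sum(1 for p, y in zip(pred, true) if p != t and y == t)
        denom = 2 * tp + fp + fn
        out[t] = 2 * tp / denom if denom else 0.0
    return out


def mean_f1(pred, true, known_types: list[str] | None = None) -> float:
    """Unweighted mean of per-type F1 over truth-present types."""
    scores = per_type_f1(pred, true, known_types)
    return float(np.mean(list(scores.values())))


def adjusted_rand_index(pred, true) -> float:
    """Chance-adjusted Rand index between the two partitions."""
    pred, true = _check(pred, true)
    return float(adjusted_rand_score(true, pred))


def score(pred, true, known_types: list[str] | None = None) -> MetricReport:
    """All four metrics plus per-type F1 and the unknown count."""
    pred, true = _check(pred, true)
    return MetricReport(
        kappa=cohens_kappa(pred, true, known_types),
        mf1=mean_f1(pred, true, known_types),
        acc=accuracy(pred, true, known_types),
        ari=adjusted_rand_index(pred, true),
        per_type_f1=per_type_f1(pred, true, known_types),
        n_unknown=sum(1 for p in pred if p == UNKNOWN_LABEL),
    )
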