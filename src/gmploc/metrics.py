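"""Five standard multi-label evaluation metrics.

Given ground truth y (N x K binary), binary predictions y_hat and real
scores f_hat:

* Hamming loss: fraction of label decisions that are wrong,
  normalized by N*K.
* One-error: fraction of samples whose top-ranked label is not
  relevant.
* Coverage: mean over samples of the deepest rank occupied by a
  relevant label (rank 1 = highest score; no minus-one correction by
  default).
* Ranking loss: mean fraction of (relevant, irrelevant) label pairs
  with the irrelevant score >= the relevant score; samples with no
  irrelevant (or no relevant) label are excluded from the mean.
* Average precision: mean over samples of the precision of the
  relevant labels at their own ranks.

Ranks are deterministic: ties are broken toward the lower label index.
Lower is better for all but average precision.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

__all__ = [
    "PredictionSet", "MetricsReport", "rank_labels", "hamming_loss",
    "one_error", "coverage", "ranking_loss", "average_precision",
    "evaluate_all",
]

logger = logging.getLogger(__name__)


@dataclass
class PredictionSet:
    scores: np.ndarray       # (N, K) real
    predictions: np.ndarray  # (N, K) binary
    truth: np.ndarray        # (N, K) binary, every row has >= 1 relevant label

    def __post_init__(self):
        self.scores = np.atleast_2d(np.asarray(self.scores, dtype=float))
        self.predictions = np.atleast_2d(np.asarray(self.predictions, dtype=int))
        self.truth = np.atleast_2d(np.asarray(self.truth, dtype=int))
        if not (self.scores.shape == self.predictions.shape == self.truth.shape):
            raise ValueError("scores, predictions and truth must share one N x K shape")
        if self.scores.shape[0] == 0:
            raise ValueError("empty prediction set")
        if (self.truth.sum(axis=1) == 0).any():
            raise ValueError("every sample must have at least one relevant label")

    @property
    def n_samples(self) -> int:
        return self.scores.shape[0]

    @property
    def n_labels(self) -> int:
        return self.scores.shape[1]


@dataclass
class MetricsReport:
    hl: float
    oe: float
    co: float
    rl: float
    ap: float
    n_samples: int = 0
    n_labels: int = 0
    fold: int | None = None
    arm: str | None = None

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.hl, self.oe, self.co, self.rl, self.ap)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def rank_labels(scores: np.ndarray) -> np.ndarray:
    """Ranks per row: 1 = highest score, ties to the lower label index."""
    s = np.atleast_2d(np.asarray(scores, dtype=float))
    if not np.isfinite(s).all():
        raise ValueError("scores must be finite")
    n, k = s.shape
    idx = np.arange(k)
    ranks = np.empty((n, k), dtype=int)
    for i in range(n):
        order = np.lexsort((idx, -s[i]))  # score desc, then index asc
        ranks[i, order] = idx + 1
    return ranks if np.asarray(scores).ndim > 1 else ranks[0]


def hamming_loss(pred: PredictionSet, normalize_labels: bool = True) -> float:
    """Disagreement count, divided by N*K (or by N only when
    normalize_labels=False, the literal unnormalized form)."""
    wrong = (pred.predictions != pred.truth).sum()
    denom = pred.n_samples * (pred.n_labels if normalize_labels else 1)
    return float(wrong) / denom


def one_error(pred: PredictionSet) -> float:
    ranks = rank_labels(pred.scores)
    top_is_relevant = (pred.truth * (ranks == 1)).sum(axis=1) > 0
    return float(1.0 - top_is_relevant.mean())


def coverage(pred: PredictionSet, minus_one: bool = False) -> float:
    ranks = rank_labels(pred.scores)
    deepest = np.where(pred.truth == 1, ranks, 0).max(axis=1)
    return float(deepest.mean()) - (1.0 if minus_one else 0.0)


def ranking_loss(pred: PredictionSet) -> float:
    """Mean fraction of mis-ordered (relevant, irrelevant) pairs.

    A pair is mis-ordered when the irrelevant score is >= the relevant
    score. Samples with every label relevant are excluded (their pair
    denominator is zero)."""
    vals = []
    for i in range(pred.n_samples):
        rel = pred.truth[i] == 1
        irr = ~rel
        n_rel, n_irr = int(rel.sum()), int(irr.sum())
        if n_irr == 0:
            continue
        bad = (pred.scores[i, irr][None, :] >= pred.scores[i, rel][:, None]).sum()
        vals.append(bad / (n_rel * n_irr))
    if not vals:
        logger.warning("ranking_loss: no sample had both relevant and "
                       "irrelevant labels")
        return float("nan")
    if len(vals) < pred.n_samples:
        logger.warning("ranking_loss: excluded %d sample(s) with all labels "
                       "relevant", pred.n_samples - len(vals))
    return float(np.mean(vals))


def average_precision(pred: PredictionSet) -> float:
    """Mean precision of the relevant labels at their own ranks: for
    each relevant label j, |{relevant k with score >= score_j}| / rank_j."""
    ranks = rank_labels(pred.scores)
    vals = []
    for i in range(pred.n_samples):
        rel = np.flatnonzero(pred.truth[i] == 1)
        per_label = []
        for j in rel:
            higher = ((pred.scores[i] >= pred.scores[i, j]) & (pred.truth[i] == 1)).sum()
            per_label.append(higher / ranks[i, j])
        vals.append(np.mean(per_label))
    return float(np.mean(vals))


def evaluate_all(pred: PredictionSet, fold: int | None = None,
                 arm: str | None = None) -> MetricsReport:
    return MetricsReport(
        hl=hamming_loss(pred),
        oe=one_error(pred),
        co=coverage(pred),
        rl=ranking_loss(pred),
        ap=average_precision(pred),
        n_samples=pred.n_samples,
        n_labels=pred.n_labels,
        fold=fold,
        arm=arm,
    )
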