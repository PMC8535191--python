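"""Discrimination metrics: rank AUC, TSS, and the training-presence threshold."""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

__all__ = ["auc", "tss", "ten_percentile_threshold"]


def auc(presence_scores: np.ndarray, background_scores: np.ndarray) -> float:
    """Rank-based (Mann–Whitney) AUC with ties counted 1/2.

    The probability that a random presence outscores a random background
    point, ties worth half.
    """
    pos = np.asarray(presence_scores, dtype=float)
    neg = np.asarray(background_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("need at least one presence and one background score")
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2
    return float(u / (pos.size * neg.size))


def tss(sensitivity: float, specificity: float) -> float:
    """True skill statistic: sensitivity + specificity − 1 (range [−1, 1])."""
    return sensitivity + specificity - 1.0


def ten_percentile_threshold(training_scores: np.ndarray, percentile: float = 10.0) -> float:
    """The ⌈p/100·m⌉-th smallest training presence score.

    The binarization threshold below which (at most) the lowest ``percentile``
    percent of training presences fall.  With m = 10 evenly spaced scores and
    p = 10 this is the 1st smallest; with m = 20, the 2nd smallest.
    """
    s = np.sort(np.asarray(training_scores, dtype=float))
    if s.size == 0:
        raise ValueError("no training scores")
    k = int(np.ceil(percentile / 100.0 * s.size))
    k = min(max(k, 1), s.size)
    return float(s[k - 1])
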