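"""Three-class assembly of binary classifiers: one-vs-rest and decision tree.

One-vs-rest compares the three binary scores on the probability scale and
takes the argmax; exact ties resolve with priority hard > soft > normal
(safety first: a missed hard brake costs more than a spurious one). The
decision-tree cascade first tests hard-vs-rest against K1, then
soft-vs-normal against K2, with strict ">" comparisons as specified.
"""

from __future__ import annotations

import numpy as np

from .data import CLASSES

#: tie priority for one-vs-rest: listed first wins
TIE_PRIORITY = ("hard", "soft", "normal")


def decide_ovr(y_normal, y_soft, y_hard, tie_priority=TIE_PRIORITY) -> str:
    """Class with the maximal one-vs-rest score (Ra); ties by priority."""
    scores = {"normal": y_normal, "soft": y_soft, "hard": y_hard}
    best = max(scores.values())
    for cls in tie_priority:
        if scores[cls] == best:
            return cls
    raise RuntimeError("unreachable")


def decide_ovr_batch(scores: np.ndarray, tie_priority=TIE_PRIORITY) -> np.ndarray:
    """Vectorized one-vs-rest over an (n, 3) score array in CLASSES order."""
    scores = np.asarray(scores, dtype=float)
    pr = np.array([tie_priority.index(c) for c in CLASSES])  # lower = wins ties
    best = scores.max(axis=1, keepdims=True)
    is_best = scores == best
    rank = np.where(is_best, pr[None, :], len(CLASSES))
    idx = rank.argmin(axis=1)
    return np.array(CLASSES)[idx]


def decide_tree(y_hard, y_soft_vs_normal, k1: float, k2: float) -> str:
    """Cascade (Rb): hard if y1 > K1, else soft if y2 > K2, else normal."""
    if y_hard > k1:
        return "hard"
    if y_soft_vs_normal > k2:
        return "soft"
    return "normal"


def decide_tree_batch(y_hard: np.ndarray, y_soft_vs_normal: np.ndarray,
                      k1: float, k2: float) -> np.ndarray:
    y1 = np.asarray(y_hard, dtype=float)
    y2 = np.asarray(y_soft_vs_normal, dtype=float)
    out = np.where(y1 > k1, "hard", np.where(y2 > k2, "soft", "normal"))
    return out.astype(object).astype(str)
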