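"""Fusion of EEG-based and EMG-based information.

Feature-level fusion (FL) min-max normalizes each modality's selected
features with training-fold extrema and concatenates EEG-then-EMG.
Classifier-level fusion combines the two per-modality probabilities: AND
(CL1), OR (CL2), or a naive-Bayes product with equal class priors (CL3).
Sequential models (SE1/SE2) assign whole binary subproblems to one modality
each and are assembled in :mod:`brakesense.models`.

For multiclass score comparison the CL rules also expose a fused score on
the probability scale: min(p1, p2) for AND, max(p1, p2) for OR and the
normalized posterior for Bayes — each consistent with its decision rule at
the 0.5 threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

TARGET, NONTARGET = 1, -1


@dataclass
class MinMaxNormalizer:
    """Per-feature min-max scaling with training extrema; test values clipped."""

    mins: np.ndarray
    maxs: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "MinMaxNormalizer":
        X = np.asarray(X, dtype=float)
        mins, maxs = X.min(axis=0), X.max(axis=0)
        if np.any(maxs == mins):
            logger.warning(
                "%d constant feature(s) map to 0 under min-max normalization",
                int((maxs == mins).sum()),
            )
        return cls(mins=mins, maxs=maxs)

    def transform(self, X: np.ndarray) -> np.ndarray:
        span = self.maxs - self.mins
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(span > 0, (np.asarray(X) - self.mins) / span, 0.0)
        return np.clip(out, 0.0, 1.0)


@dataclass
class FeatureFusion:
    """Fitted feature-level fusion: normalize each block, concatenate EEG|EMG."""

    eeg_norm: MinMaxNormalizer
    emg_norm: MinMaxNormalizer

    @classmethod
    def fit(cls, eeg_feats: np.ndarray, emg_feats: np.ndarray) -> "FeatureFusion":
        return cls(MinMaxNormalizer.fit(eeg_feats), MinMaxNormalizer.fit(emg_feats))

    def transform(self, eeg_feats: np.ndarray, emg_feats: np.ndarray) -> np.ndarray:
        return np.concatenate(
            [self.eeg_norm.transform(eeg_feats), self.emg_norm.transform(emg_feats)],
            axis=-1,
        )


def fuse_features(eeg_feats, emg_feats, fusion: FeatureFusion) -> np.ndarray:
    return fusion.transform(eeg_feats, emg_feats)


def fuse_and(d1: int, d2: int) -> int:
    """Target iff both classifiers say target."""
    return TARGET if (d1 == TARGET and d2 == TARGET) else NONTARGET


def fuse_or(d1: int, d2: int) -> int:
    """Target iff at least one classifier says target."""
    return TARGET if (d1 == TARGET or d2 == TARGET) else NONTARGET


@dataclass
class FusionDecision:
    strategy: str
    p1: float
    p2: float
    g_out: int
    posterior: float  # P(target | F1, F2); NaN when both products vanish


def fuse_bayes(p1: float, p2: float, priors=(0.5, 0.5)) -> FusionDecision:
    """Naive-Bayes combination of two target probabilities.

    Likelihood products prior*p1*p2 vs prior*(1-p1)(1-p2); the larger wins.
    Exact ties (including both products zero) resolve to nontarget — the
    conservative choice for a braking alarm.
    """
    if not (0 <= p1 <= 1 and 0 <= p2 <= 1):
        raise ValueError("probabilities must lie in [0, 1]")
    pt = priors[0] * p1 * p2
    pn = priors[1] * (1.0 - p1) * (1.0 - p2)
    total = pt + pn
    if total == 0:
        logger.warning("conflicting saturated probabilities; tie broken to nontarget")
        posterior = float("nan")
    else:
        posterior = pt / total
    g_out = TARGET if pt > pn else NONTARGET
    return FusionDecision("CL3_BAYES", p1, p2, g_out, posterior)


def fused_score(strategy: str, p1: np.ndarray, p2: np.ndarray,
                priors=(0.5, 0.5)) -> np.ndarray:
    """Probability-scale fused score for multiclass comparison (vectorized)."""
    p1, p2 = np.asarray(p1, dtype=float), np.asarray(p2, dtype=float)
    if strategy == "fl":
        raise ValueError("feature-level fusion scores come from its single classifier")
    if strategy == "cl1":
        return np.minimum(p1, p2)
    if strategy == "cl2":
        return np.maximum(p1, p2)
    if strategy == "cl3":
        pt = priors[0] * p1 * p2
        pn = priors[1] * (1 - p1) * (1 - p2)
        total = pt + pn
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(total > 0, pt / np.where(total > 0, total, 1.0), 0.0)
    raise ValueError(f"unknown classifier-level strategy {strategy!r}")
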