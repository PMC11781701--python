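"""Regularized linear discriminant analysis with a piecewise-linear
probability map.

The discriminant is y = psi' x with psi = S'^{-1} (v1 - v2), where v1/v2 are
the class feature means and S' = (1-lambda) S + lambda omega I shrinks the
pooled within-class covariance S toward a sphere of matched scale
(omega = trace(S)/g). The shrinkage weight lambda is picked from the grid
0.1..1.0 (step 0.1) by inner stratified cross-validation on the training
data, ties going to the smaller lambda.

Scores map to probabilities by a piecewise-linear stretch anchored at the
decision threshold (midpoint of the projected class means) and the training
score extrema: P(thre) = 1/2, P(ymax) = 1, P(ymin) = 0, clamped outside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

LAMBDA_GRID = tuple(np.round(np.arange(0.1, 1.01, 0.1), 10))


@dataclass
class RldaModel:
    psi: np.ndarray  # projection vector, length g
    lambda_reg: float
    class_means: tuple  # (v1 target, v2 nontarget)
    within_class_cov: np.ndarray
    shrunk_cov: np.ndarray
    nu: float  # omega = trace(S)/g
    dim: int
    thre: float
    ymax: float
    ymin: float

    def scores(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X) @ self.psi

    def decide(self, X: np.ndarray) -> np.ndarray:
        """+1 target / -1 nontarget; the boundary y = thre counts as target."""
        return np.where(self.scores(X) >= self.thre, 1, -1)


@dataclass
class ProbOutput:
    y: float
    p: float
    decision: int  # +1 target, -1 nontarget


def _fit_single(X: np.ndarray, labels: np.ndarray, lam: float) -> RldaModel:
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels)
    t, nt = X[y == 1], X[y == -1]
    if len(t) == 0 or len(nt) == 0:
        raise ValueError("both classes required")
    n, g = X.shape
    if n <= 2:
        raise ValueError("need more than two samples")
    v1, v2 = t.mean(axis=0), nt.mean(axis=0)
    ct, cn = t - v1, nt - v2
    S = (ct.T @ ct + cn.T @ cn) / max(n - 2, 1)
    omega = np.trace(S) / g
    S_shrunk = (1.0 - lam) * S + lam * omega * np.eye(g)
    psi = np.linalg.solve(S_shrunk, v1 - v2)
    thre = 0.5 * (psi @ v1 + psi @ v2)
    scores = X @ psi
    return RldaModel(
        psi=psi,
        lambda_reg=lam,
        class_means=(v1, v2),
        within_class_cov=S,
        shrunk_cov=S_shrunk,
        nu=omega,
        dim=g,
        thre=thre,
        ymax=float(scores.max()),
        ymin=float(scores.min()),
    )


def fit_rlda(
    X: np.ndarray,
    labels: np.ndarray,
    lambda_grid=LAMBDA_GRID,
    inner_folds: int = 5,
    seed: int = 0,
) -> RldaModel:
    """Fit RLDA, selecting lambda by inner stratified CV accuracy.

    With a single-value grid the inner CV is skipped. Ties favor smaller
    lambda (the grid is scanned in ascending order).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels)
    grid = list(lambda_grid)
    if len(grid) > 1:
        n_splits = min(inner_folds, int(np.bincount((y == 1).astype(int)).min()))
        n_splits = max(n_splits, 2)
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        accs = np.zeros(len(grid))
        folds = list(skf.split(X, y))
        for i, lam in enumerate(grid):
            hits = total = 0
            for tr, te in folds:
                try:
                    model = _fit_single(X[tr], y[tr], lam)
                except ValueError:
                    continue
                hits += int((model.decide(X[te]) == y[te]).sum())
                total += len(te)
            accs[i] = hits / total if total else 0.0
        best = grid[int(np.argmax(accs))]  # argmax takes the first (smallest) tie
    else:
        best = grid[0]
    return _fit_single(X, y, best)


def score_to_probability(y, model: RldaModel):
    """Map raw scores to [0, 1] by the anchored piecewise-linear stretch.

    Scalar in, :class:`ProbOutput` out; array in, probability array out.
    """
    arr = np.asarray(y, dtype=float)
    p = _prob(arr, model.thre, model.ymax, model.ymin)
    if np.ndim(y) == 0:
        return ProbOutput(y=float(arr), p=float(p), decision=1 if arr >= model.thre else -1)
    return p


def _prob(y: np.ndarray, thre: float, ymax: float, ymin: float) -> np.ndarray:
    upper = ymax - thre
    lower = thre - ymin
    if upper <= 0 or lower <= 0:
        logger.warning("degenerate probability map (thre at a training extremum)")
    with np.errstate(invalid="ignore", divide="ignore"):
        hi = np.where(
            upper > 0,
            0.5 + 0.5 * (np.minimum(ymax, y) - thre) / upper,
            1.0,
        )
        lo = np.where(
            lower > 0,
            0.5 - 0.5 * (thre - np.maximum(ymin, y)) / lower,
            0.0,
        )
    return np.clip(np.where(y >= thre, hi, lo), 0.0, 1.0)


def predict_proba(model: RldaModel, X: np.ndarray) -> np.ndarray:
    """P(target) for each row of X."""
    return _prob(model.scores(X), model.thre, model.ymax, model.ymin)
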