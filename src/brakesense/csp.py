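"""Two-class common spatial patterns (CSP).

CSP finds spatial filters extremizing the variance ratio between two
classes. Per-epoch covariances are trace-normalized, E = X Xᵀ / tr(X Xᵀ),
averaged per class into Et and En, and the mixed covariance Em = Et + En is
whitened by G = Λm^{-1/2} Fmᵀ. The whitened class covariances Ht = G Et Gᵀ
and Hn = G En Gᵀ share eigenvectors J with complementary eigenvalues
(λt + λn = I), so components with λt far from 1/2 discriminate the classes.
The filter bank is Jᵀ G, rows ordered by descending λt; the m/2 most
target-dominant and m/2 most nontarget-dominant rows are retained as the
projection onto m "virtual channels".

A small ridge (relative 1e-6) is added to the class-mean covariances:
common-average-referenced data are exactly rank-deficient, and the ridge
keeps the whitener finite. All stored invariants are algebraic in the
ridged matrices, so they hold to machine precision regardless.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import linalg

logger = logging.getLogger(__name__)


@dataclass
class CspModel:
    """A fitted CSP projection and its full derivation record."""

    projection: np.ndarray  # (m, C) retained filters, descending lambda_t
    projection_eigvals: np.ndarray  # lambda_t of the retained rows
    full_projection: np.ndarray  # (C, C) complete filter bank, descending lambda_t
    class_cov_target: np.ndarray  # Et (ridged class-mean covariance)
    class_cov_nontarget: np.ndarray  # En
    mixed_cov: np.ndarray  # Em = Et + En
    mixed_eigvecs: np.ndarray  # Fm
    mixed_eigvals: np.ndarray  # lambda_m
    whitener: np.ndarray  # G = lambda_m^(-1/2) Fm^T
    whitened_target: np.ndarray  # Ht = G Et G^T
    whitened_nontarget: np.ndarray  # Hn
    common_eigvecs: np.ndarray  # J, columns, descending lambda_t
    eigvals_target: np.ndarray  # lambda_t, descending
    eigvals_nontarget: np.ndarray  # lambda_n = 1 - lambda_t
    m: int

    @property
    def n_channels(self) -> int:
        return self.full_projection.shape[1]


def trace_normalized_cov(x: np.ndarray) -> np.ndarray:
    """E = X Xᵀ / trace(X Xᵀ); scale-invariant per-epoch covariance."""
    cov = x @ x.T
    tr = np.trace(cov)
    if tr <= 0:
        raise ValueError("zero-energy epoch has no normalized covariance")
    return cov / tr


def _mean_cov(epochs, ridge: float) -> np.ndarray:
    covs = [trace_normalized_cov(np.asarray(e, dtype=float)) for e in epochs]
    mean = np.mean(covs, axis=0)
    C = mean.shape[0]
    return mean + ridge * (np.trace(mean) / C) * np.eye(C)


def _fix_signs(rows: np.ndarray) -> np.ndarray:
    """Deterministic row signs: largest-magnitude entry made positive."""
    idx = np.argmax(np.abs(rows), axis=1)
    signs = np.sign(rows[np.arange(rows.shape[0]), idx])
    signs[signs == 0] = 1.0
    return rows * signs[:, None]


def fit_csp(target_epochs, nontarget_epochs, m: int, ridge: float = 1e-6) -> CspModel:
    """Fit CSP on two lists of (C, L) epochs, retaining ``m`` virtual channels.

    ``m`` must be even and at most C; the retained rows are the m/2 with the
    largest and m/2 with the smallest target eigenvalue. Ties in the
    eigenvalue ordering are broken by original index (stable sort).
    """
    if len(target_epochs) < 2 or len(nontarget_epochs) < 2:
        raise ValueError("need at least two epochs per class")
    C = np.asarray(target_epochs[0]).shape[0]
    if m % 2 or not (2 <= m <= C):
        raise ValueError(f"m must be even with 2 <= m <= {C}, got {m}")

    Et = _mean_cov(target_epochs, ridge)
    En = _mean_cov(nontarget_epochs, ridge)
    Em = Et + En

    lam_m, Fm = linalg.eigh(Em)
    tiny = lam_m <= 1e-12 * lam_m.max()
    if tiny.any():
        eps = 1e-10 * np.trace(Em) / C
        logger.warning("singular mixed covariance; regularizing with eps=%.3g", eps)
        Em = Em + eps * np.eye(C)
        Et = Et + 0.5 * eps * np.eye(C)
        En = En + 0.5 * eps * np.eye(C)
        lam_m, Fm = linalg.eigh(Em)

    G = (Fm / np.sqrt(lam_m)).T  # lambda_m^(-1/2) Fm^T
    Ht = G @ Et @ G.T
    Hn = G @ En @ G.T

    lam_t, J = linalg.eigh(Ht)
    # descending lambda_t with stable tie-break on the ascending-order index
    order = np.argsort(-lam_t, kind="stable")
    lam_t = lam_t[order]
    J = J[:, order]
    W_full = _fix_signs(J.T @ G)

    half = m // 2
    keep = np.concatenate([np.arange(half), np.arange(C - half, C)])
    return CspModel(
        projection=W_full[keep],
        projection_eigvals=lam_t[keep],
        full_projection=W_full,
        class_cov_target=Et,
        class_cov_nontarget=En,
        mixed_cov=Em,
        mixed_eigvecs=Fm,
        mixed_eigvals=lam_m,
        whitener=G,
        whitened_target=Ht,
        whitened_nontarget=Hn,
        common_eigvecs=J,
        eigvals_target=lam_t,
        eigvals_nontarget=1.0 - lam_t,
        m=m,
    )


def project(model: CspModel, x: np.ndarray) -> np.ndarray:
    """Project epochs onto the retained virtual channels: Xe = W X.

    Accepts a single (C, L) epoch or a batch (..., C, L).
    """
    x = np.asarray(x)
    if x.shape[-2] != model.n_channels:
        raise ValueError(
            f"channel mismatch: model has {model.n_channels}, data has {x.shape[-2]}"
        )
    return model.projection @ x
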