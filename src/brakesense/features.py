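"""Temporal/spectral features on CSP-projected signals and DCC selection.

Temporal EEG features are the projected amplitudes themselves; temporal EMG
features are the linear envelope (rectification followed by a second-order
2 Hz Butterworth low-pass). Spectral features are the one-second
rectangular-window periodogram restricted to an analysis band; at 1 s
windows the bin spacing is exactly 1 Hz, and band restriction keeps the
integer bins in [low, high] inclusive (so the 0.5 Hz lower EEG edge maps to
bin 1 — no sub-Hz bin exists).

Feature selection ranks every scalar feature by its sample distance
correlation with the +/-1 class-label vector: pairwise absolute differences
are double-centered and the distance covariance/variances assembled from
their products; dCor = dCov / sqrt(dVar(A) dVar(B)), which is zero for
independent pairs (in the population) and 1 for a feature that copies the
labels. The top W features are kept; scores are learned on training folds
only and reused on test folds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

logger = logging.getLogger(__name__)

#: EEG analysis bands for the spectral-feature restriction (Hz).
BANDS = {
    "delta": (0.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 50.0),
    "full": (0.5, 60.0),
}
EMG_SPECTRAL_BAND = (15.0, 90.0)


@dataclass
class FeatureVector:
    """Flattened feature values with per-entry provenance names."""

    values: np.ndarray  # (..., n_features)
    kind: str  # eeg_temporal | eeg_spectral | emg_temporal | emg_spectral
    names: list
    band: tuple | None = None


def _flatten(projected: np.ndarray) -> np.ndarray:
    return projected.reshape(*projected.shape[:-2], -1)


def temporal_features_eeg(projected: np.ndarray) -> FeatureVector:
    """Row-major flattening of projected EEG amplitudes (Xet)."""
    m, L = projected.shape[-2:]
    names = [(c, t) for c in range(m) for t in range(L)]
    return FeatureVector(_flatten(projected), "eeg_temporal", names)


def linear_envelope(x: np.ndarray, fs: float, cutoff: float = 2.0, order: int = 2) -> np.ndarray:
    """Rectify then zero-phase low-pass: the classic EMG linear envelope."""
    sos = sps.butter(order, cutoff, btype="lowpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.abs(x), axis=-1)


def temporal_features_emg(projected: np.ndarray, fs: float) -> FeatureVector:
    """Linear envelope of each virtual EMG channel (Ylmt), flattened."""
    env = linear_envelope(projected, fs)
    M, L = projected.shape[-2:]
    names = [(c, t) for c in range(M) for t in range(L)]
    return FeatureVector(_flatten(env), "emg_temporal", names)


def spectral_features(projected: np.ndarray, fs: float, band) -> FeatureVector:
    """Per-channel periodogram PSD restricted to ``band``, flattened.

    Rectangular window, no detrending: the full spectrum then satisfies
    Parseval (sum PSD x bin width = mean square). The 1 s window makes the
    bins integer frequencies; [low, high] is inclusive.
    """
    low, high = band
    if not (0 <= low < high <= fs / 2):
        raise ValueError(f"band {band} outside [0, Nyquist={fs / 2}]")
    freqs, psd = sps.periodogram(projected, fs=fs, window="boxcar", detrend=False, axis=-1)
    mask = (freqs >= low) & (freqs <= high)
    psd = psd[..., mask]
    kept = freqs[mask]
    m = projected.shape[-2]
    names = [(c, float(f)) for c in range(m) for f in kept]
    return FeatureVector(_flatten(psd), "spectral", names, band=(low, high))


@dataclass
class FeatureSelector:
    """Distance-correlation ranking of features against class labels."""

    scores: np.ndarray
    selected_indices: np.ndarray
    W: int


def dcc_scores(features: np.ndarray, labels: np.ndarray, W: int | None = None,
               chunk: int = 256) -> FeatureSelector:
    """Score every feature column by distance correlation with the labels.

    ``labels`` must be a +/-1 vector containing both classes. Zero-variance
    features score 0 by convention. ``W`` defaults to all features; ties in
    the ranking break toward the lower original index.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=float)
    n, f = X.shape
    if n < 4:
        raise ValueError("need at least 4 samples for distance correlation")
    if np.unique(y).size < 2:
        raise ValueError("labels must contain both classes")

    b = np.abs(y[:, None] - y[None, :])
    D = b - b.mean(axis=1, keepdims=True) - b.mean(axis=0, keepdims=True) + b.mean()
    dvar_b = np.sqrt((D**2).mean())

    scores = np.zeros(f)
    # chunked over features: the (n, n, k) difference tensors stay small
    for start in range(0, f, chunk):
        block = X[:, start : start + chunk]
        a = np.abs(block[:, None, :] - block[None, :, :])  # (n, n, k)
        a_c = (
            a
            - a.mean(axis=1, keepdims=True)
            - a.mean(axis=0, keepdims=True)
            + a.mean(axis=(0, 1), keepdims=True)
        )
        dcov2 = np.tensordot(a_c, D, axes=([0, 1], [0, 1])) / (n * n)
        dvar2_a = (a_c**2).mean(axis=(0, 1))
        denom = np.sqrt(dvar2_a) * dvar_b
        with np.errstate(invalid="ignore", divide="ignore"):
            r2 = np.where(denom > 0, dcov2 / denom, 0.0)
        scores[start : start + block.shape[1]] = np.sqrt(np.clip(r2, 0.0, None))

    if W is None:
        W = f
    if W > f:
        logger.warning("W=%d exceeds %d available features; clamped", W, f)
        W = f
    order = np.argsort(-scores, kind="stable")  # stable: ties -> lower index
    return FeatureSelector(scores=scores, selected_indices=order[:W], W=W)


def select_features(selector: FeatureSelector, features: np.ndarray) -> np.ndarray:
    """Keep the selected columns, in descending-score order."""
    return np.asarray(features)[..., selector.selected_indices]
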