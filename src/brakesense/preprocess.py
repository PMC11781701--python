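"""Signal conditioning: bandpass, downsample, artifact suppression, baseline, CAR.

Offline pipeline order is fixed: bandpass (at the raw rate, maximizing
anti-aliasing margin) -> downsample to the common 200 Hz analysis rate ->
linear artifact suppression on EEG -> per-epoch baseline correction ->
common average reference. Offline filtering is zero-phase
(forward-backward); the pseudo-online stream path uses causal single-pass
filters instead, since a real-time decoder cannot look ahead.

The artifact-suppression stage replaces interactive independent-component
screening with a deterministic rule: ICA components whose correlation with
the frontal-channel mean exceeds 0.7 in magnitude, or whose power fraction
below 3 Hz exceeds 0.6, are zeroed and the signal remixed. The fitted
unmixing/remix pair is stored and reapplied verbatim to unseen data.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps
from sklearn.decomposition import FastICA

from .data import Epoch, RecordingSession

logger = logging.getLogger(__name__)

FRONTAL_SITES = ("F3", "Fz", "F4")


@dataclass
class PreprocConfig:
    eeg_band: tuple = (0.5, 60.0)
    emg_band: tuple = (15.0, 90.0)
    filter_order: int = 6
    fs_target: float = 200.0
    baseline_ms: float = 100.0
    car_enabled: bool = True
    artifact_suppression: str = "auto"  # "off" or "auto"
    ica_seed: int = 0

    def validate(self) -> None:
        if self.filter_order < 2 or self.filter_order % 2:
            raise ValueError("filter_order must be even and >= 2")
        for band in (self.eeg_band, self.emg_band):
            if not (0 < band[0] < band[1]):
                raise ValueError(f"invalid band {band}")
        if self.artifact_suppression not in ("off", "auto"):
            raise ValueError("artifact_suppression must be 'off' or 'auto'")

    def hash(self) -> str:
        payload = json.dumps(
            {k: list(v) if isinstance(v, tuple) else v for k, v in vars(self).items()},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _butter_sos(band, order: int, fs: float):
    low, high = band
    if not (0 < low < high < fs / 2):
        raise ValueError(f"band {band} outside (0, Nyquist={fs / 2}) at fs={fs}")
    # order counts per band edge (scipy N), giving the flat passband the
    # amplitude contracts assume
    return sps.butter(order, band, btype="bandpass", fs=fs, output="sos")


def bandpass(x: np.ndarray, band, order: int, fs: float, zero_phase: bool = True) -> np.ndarray:
    """Butterworth bandpass along the last axis; zero-phase by default."""
    sos = _butter_sos(band, order, fs)
    if zero_phase:
        return sps.sosfiltfilt(sos, x, axis=-1)
    return sps.sosfilt(sos, x, axis=-1)


def downsample(x: np.ndarray, fs_from: float, fs_to: float, zero_phase: bool = True) -> np.ndarray:
    """Anti-aliased integer-factor decimation along the last axis."""
    factor = fs_from / fs_to
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError(f"fs_from/fs_to must be an integer factor, got {factor}")
    factor = int(round(factor))
    if factor == 1:
        return x.copy()
    # offline: linear-phase FIR (exact DC, compensated delay); stream: IIR
    # single-pass for minimal group delay
    ftype = "fir" if zero_phase else "iir"
    return sps.decimate(x, factor, ftype=ftype, axis=-1, zero_phase=zero_phase)


def baseline_correct(x: np.ndarray, fs: float, baseline_ms: float = 100.0) -> np.ndarray:
    """Subtract each channel's mean over the first ``baseline_ms`` of the epoch."""
    n_base = int(round(baseline_ms * fs / 1000.0))
    if n_base < 1 or n_base > x.shape[-1]:
        raise ValueError("epoch shorter than the baseline window")
    return x - x[..., :n_base].mean(axis=-1, keepdims=True)


def car(x: np.ndarray) -> np.ndarray:
    """Common average reference: subtract the cross-channel mean per sample."""
    if x.shape[-2] < 2:
        raise ValueError("CAR needs at least two channels")
    return x - x.mean(axis=-2, keepdims=True)


@dataclass
class ArtifactSuppressor:
    """Fitted linear artifact remover: x_clean = (x - mean) @ P + mean (per sample).

    ``projection`` is the C x C matrix unmix -> zero flagged components ->
    remix; storing it makes test-time application a single matrix product.
    """

    projection: np.ndarray
    mean: np.ndarray
    flagged: np.ndarray
    mode: str = "auto"

    def apply(self, x: np.ndarray) -> np.ndarray:
        if self.mode == "off" or self.projection is None:
            return x
        centered = x - self.mean[:, None]
        return self.projection.T @ centered + self.mean[:, None]


def _lowfreq_power_fraction(s: np.ndarray, fs: float, f_cut: float = 3.0) -> np.ndarray:
    freqs, psd = sps.periodogram(s, fs=fs, axis=-1)
    total = psd.sum(axis=-1)
    low = psd[..., freqs < f_cut].sum(axis=-1)
    return np.where(total > 0, low / np.maximum(total, 1e-30), 0.0)


def fit_artifact_suppressor(
    eeg: np.ndarray,
    fs: float,
    channel_names,
    mode: str = "auto",
    seed: int = 0,
    corr_threshold: float = 0.7,
    lowfreq_threshold: float = 0.6,
    max_fit_samples: int = 40000,
) -> ArtifactSuppressor:
    """Fit the deterministic ICA-based artifact remover on training EEG.

    The decomposition is estimated on a uniform subsample of at most
    ``max_fit_samples`` points (component criteria are second-order stable
    under decimation); the resulting projection applies to every sample.
    Falls back to the identity (with a warning) if the decomposition fails,
    e.g. on rank-deficient input.
    """
    C, T = eeg.shape
    if mode == "off":
        return ArtifactSuppressor(None, np.zeros(C), np.zeros(0, bool), mode="off")
    if T < 30 * C:
        logger.warning("too few samples for stable ICA (%d < %d); identity fallback", T, 30 * C)
        return ArtifactSuppressor(np.eye(C), eeg.mean(axis=1), np.zeros(C, bool))
    frontal_idx = [i for i, n in enumerate(channel_names) if n in FRONTAL_SITES]
    frontal = eeg[frontal_idx].mean(axis=0) if frontal_idx else eeg.mean(axis=0)
    stride = max(1, T // max_fit_samples)
    fit_eeg = eeg[:, ::stride]
    try:
        ica = FastICA(n_components=C, random_state=seed, max_iter=500, tol=1e-4)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ica.fit(fit_eeg.T)
        sources = (eeg - ica.mean_[:, None]).T @ ica.components_.T
        sources = sources.T  # (C, T)
    except Exception:  # rank-deficient or non-convergent input
        logger.warning("ICA decomposition failed; identity fallback")
        return ArtifactSuppressor(np.eye(C), eeg.mean(axis=1), np.zeros(C, bool))

    fstd = frontal.std()
    corr = np.zeros(C)
    if fstd > 0:
        fc = (frontal - frontal.mean()) / fstd
        sstd = sources.std(axis=1)
        sc = (sources - sources.mean(axis=1, keepdims=True)) / np.maximum(
            sstd[:, None], 1e-30
        )
        corr = np.abs(sc @ fc) / sources.shape[1]
    lowfrac = _lowfreq_power_fraction(sources, fs)
    flagged = (corr > corr_threshold) | (lowfrac > lowfreq_threshold)
    if flagged.any():
        logger.info("artifact suppression removing %d/%d components", flagged.sum(), C)

    mask = np.where(flagged, 0.0, 1.0)
    # unmixing rows W (components_), mixing columns A: x ~ A s + mean.
    projection = ica.components_.T @ np.diag(mask) @ ica.mixing_.T  # right-multiply form
    return ArtifactSuppressor(projection, ica.mean_, flagged)


def preprocess_session(
    session: RecordingSession,
    cfg: PreprocConfig,
    suppressor: ArtifactSuppressor | None = None,
    causal: bool = False,
) -> tuple:
    """Filter, downsample and artifact-clean a continuous session.

    Returns ``(session_at_fs_target, suppressor)``. Epoch-level steps
    (baseline correction, CAR) are applied later by :func:`finalize_epoch`.
    When ``causal`` is true, single-pass filters are used (stream contract);
    a suppressor fitted on training data must then be supplied (or mode off).
    """
    cfg.validate()
    zero_phase = not causal
    eeg = bandpass(session.eeg, cfg.eeg_band, cfg.filter_order, session.fs, zero_phase)
    emg = bandpass(session.emg, cfg.emg_band, cfg.filter_order, session.fs, zero_phase)
    eeg = downsample(eeg, session.fs, cfg.fs_target, zero_phase)
    emg = downsample(emg, session.fs, cfg.fs_target, zero_phase)
    if suppressor is None:
        if causal and cfg.artifact_suppression != "off":
            raise ValueError("causal mode requires a pre-fitted artifact suppressor")
        suppressor = fit_artifact_suppressor(
            eeg, cfg.fs_target, session.eeg_channels,
            mode=cfg.artifact_suppression, seed=cfg.ica_seed,
        )
    eeg = suppressor.apply(eeg)
    out = RecordingSession(
        eeg=eeg,
        emg=emg,
        fs=cfg.fs_target,
        events=list(session.events),
        labels=list(session.labels),
        eeg_channels=list(session.eeg_channels),
        emg_channels=list(session.emg_channels),
    )
    return out, suppressor


def finalize_epoch(epoch: Epoch, cfg: PreprocConfig) -> Epoch:
    """Per-epoch steps on an already filtered/downsampled segment: BC then CAR."""
    eeg = baseline_correct(epoch.eeg, epoch.fs, cfg.baseline_ms)
    emg = baseline_correct(epoch.emg, epoch.fs, cfg.baseline_ms)
    if cfg.car_enabled:
        eeg = car(eeg)
        emg = car(emg)
    if not (np.isfinite(eeg).all() and np.isfinite(emg).all()):
        raise ValueError("non-finite values after preprocessing")
    return replace(epoch, eeg=eeg, emg=emg)


def finalize_windows(eeg: np.ndarray, emg: np.ndarray, fs: float, cfg: PreprocConfig):
    """Vectorized BC + CAR over batched (n, C, L) sliding windows."""
    eeg = baseline_correct(eeg, fs, cfg.baseline_ms)
    emg = baseline_correct(emg, fs, cfg.baseline_ms)
    if cfg.car_enabled:
        eeg = car(eeg)
        emg = car(emg)
    return eeg, emg
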