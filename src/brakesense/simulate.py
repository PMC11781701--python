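"""Synthetic driving-session generator.

Emulates the statistical structure the decoding pipeline assumes of a
driving-simulator recording: 16-channel EEG and 8-channel EMG at 1000 Hz,
60 trials per virtual subject of which half contain a hard-braking episode
and half a soft-braking episode. Class-specific EEG activity is modelled as
band-limited noise packets with per-class band gains and scalp topographies
riding on 1/f background plus a posterior alpha rhythm; EMG activity as a
15-90 Hz noise burst under a trapezoidal envelope whose peak scales
hard > soft > normal. Neural and myoelectric activity precede the
pedal-deflection marker by a configurable lead.

All randomness flows from a single seed through named substreams so any
one source (trial timing, noise, normal-epoch placement) can be pinned in
tests independently of the others.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .data import CLASSES, Epoch, Event, RecordingSession

logger = logging.getLogger(__name__)

EEG_SITES = (
    "P3", "P8", "P7", "P4", "Pz", "C4", "Cz", "C3",
    "O1", "Oz", "O2", "F4", "Fz", "F3", "T7", "T8",
)
# soleus, lateral/medial gastrocnemius, tibialis anterior, rectus femoris,
# biceps brachii, vastus medialis/lateralis — kept short for EDF's 16-char labels
EMG_MUSCLES = (
    "SOL", "GAS_LAT", "TIB_ANT", "RECT_FEM", "BIC_BR", "GAS_MED", "VAST_MED", "VAST_LAT",
)

#: EEG rhythm bands (Hz) in canonical order: delta, theta, alpha, beta, gamma.
EEG_BANDS = ((0.5, 4.0), (4.0, 8.0), (8.0, 13.0), (13.0, 30.0), (30.0, 50.0))

# Scalp weighting templates over EEG_SITES (central/parietal emphasis for
# the braking response, occipital for the background alpha rhythm).
_CENTRAL_TOPO = np.array(
    [0.7, 0.3, 0.3, 0.7, 0.9, 1.0, 1.0, 1.0, 0.4, 0.4, 0.4, 0.6, 0.7, 0.6, 0.3, 0.3]
)
_PARIETAL_TOPO = np.array(
    [1.0, 0.6, 0.6, 1.0, 1.0, 0.7, 0.7, 0.7, 0.6, 0.6, 0.6, 0.3, 0.3, 0.3, 0.4, 0.4]
)
_OCCIPITAL_TOPO = np.array(
    [0.5, 0.3, 0.3, 0.5, 0.5, 0.2, 0.2, 0.2, 1.0, 1.0, 1.0, 0.1, 0.1, 0.1, 0.2, 0.2]
)
_FRONTAL_TOPO = np.array(
    [0.05, 0.0, 0.0, 0.05, 0.1, 0.2, 0.25, 0.2, 0.0, 0.0, 0.0, 0.9, 1.0, 0.9, 0.1, 0.1]
)

# Relative burst strength per muscle (leg muscles drive braking; arm low).
# Hard braking recruits the plantar flexors forcefully; soft braking is a
# gentler, dorsiflexor-weighted press, so the two differ in pattern as well
# as overall amplitude.
_EMG_WEIGHTS_HARD = np.array([1.0, 0.9, 0.85, 0.8, 0.25, 0.9, 0.7, 0.7])
_EMG_WEIGHTS_SOFT = np.array([0.25, 0.3, 0.7, 0.45, 0.15, 0.3, 0.5, 0.4])


@dataclass
class ClassProfile:
    """Per-class signal signature.

    eeg_band_gains: relative gain per rhythm band (delta..gamma);
    eeg_topo: per-channel scalp weights of the transient response;
    emg_burst: per-muscle burst amplitudes relative to EMG background RMS.
    """

    eeg_band_gains: np.ndarray
    eeg_topo: np.ndarray
    emg_burst: np.ndarray


def default_class_profiles() -> dict:
    """Signatures making the three intentions separable in second moments."""
    return {
        "hard": ClassProfile(
            eeg_band_gains=np.array([1.0, 0.8, 0.3, 0.5, 0.3]),
            eeg_topo=_CENTRAL_TOPO.copy(),
            emg_burst=_EMG_WEIGHTS_HARD.copy(),
        ),
        "soft": ClassProfile(
            eeg_band_gains=np.array([0.45, 0.35, 0.55, 0.2, 0.1]),
            eeg_topo=_PARIETAL_TOPO.copy(),
            emg_burst=_EMG_WEIGHTS_SOFT.copy(),
        ),
        "normal": ClassProfile(
            eeg_band_gains=np.zeros(5),
            eeg_topo=np.zeros(16),
            emg_burst=np.zeros(8),
        ),
    }


def complementary_profiles() -> dict:
    """Diagnostic signatures with strictly complementary modalities.

    EEG responds to hard braking only (soft trials look like normal driving
    cortically), while the EMG burst is identical for hard and soft braking
    (pedal contact looks the same myoelectrically) and absent in normal
    driving. A single-modality decoder therefore cannot exceed ~2/3
    three-class accuracy, while a hybrid that routes hard-vs-rest to EEG
    and soft-vs-normal to EMG can solve the task; useful for probing what
    fusion actually buys.
    """
    hard_eeg = np.array([1.2, 0.9, 0.4, 0.6, 0.3])
    burst = _EMG_WEIGHTS_HARD.copy()
    return {
        "hard": ClassProfile(eeg_band_gains=hard_eeg, eeg_topo=_CENTRAL_TOPO.copy(),
                             emg_burst=burst),
        "soft": ClassProfile(eeg_band_gains=np.zeros(5), eeg_topo=np.zeros(16),
                             emg_burst=burst.copy()),
        "normal": ClassProfile(eeg_band_gains=np.zeros(5), eeg_topo=np.zeros(16),
                               emg_burst=np.zeros(8)),
    }


@dataclass
class SimulationConfig:
    """Study conditions for one virtual subject.

    Defaults follow the experimental protocol being emulated: 60 trials,
    30 of them hard-braking, raw sampling at 1000 Hz, and class activity
    leading the pedal-deflection marker by ~300 ms.
    """

    n_trials: int = 60
    n_hard_trials: int = 30
    fs_raw: float = 1000.0
    trial_duration_s: float = 15.0
    stimulus_window_s: tuple = (12.0, 12.8)
    eeg_channels: tuple = EEG_SITES
    emg_channels: tuple = EMG_MUSCLES
    snr_eeg: float = 0.9
    snr_emg: float = 3.0
    neural_lead_ms: float = 300.0
    emg_lead_ms: float = 300.0
    lead_jitter_ms: float = 20.0
    reaction_median_s: float = 0.7
    reaction_sigma: float = 0.2
    eeg_background_rms: float = 10.0  # microvolts
    emg_background_rms: float = 5.0  # microvolts
    alpha_amp: float = 4.0  # background 10 Hz rhythm, occipital
    blink_rate_hz: float = 0.1  # frontal low-frequency artifact bumps
    blink_amp: float = 35.0
    class_profiles: dict = field(default_factory=default_class_profiles)
    keep_clean: bool = False  # stash noise-free templates in session.aux
    seed: int = 0

    def validate(self) -> None:
        if not (0 <= self.n_hard_trials <= self.n_trials):
            raise ValueError("n_hard_trials must satisfy 0 <= n_hard <= n_trials")
        if self.fs_raw <= 2 * 90.0:
            raise ValueError("fs_raw must exceed twice the highest generated frequency")
        if self.trial_duration_s <= 0:
            raise ValueError("trial duration must be positive")
        max_lead = max(self.neural_lead_ms, self.emg_lead_ms) / 1000.0
        if max_lead >= self.trial_duration_s:
            raise ValueError("activity lead exceeds trial length")
        lo, hi = self.stimulus_window_s
        if not (0 < lo <= hi < self.trial_duration_s):
            raise ValueError("stimulus window must lie inside the trial")
        for name, prof in self.class_profiles.items():
            if name not in CLASSES:
                raise ValueError(f"unknown class profile {name!r}")


def _substreams(seed: int) -> dict:
    """Named, independent random substreams derived from one seed."""
    names = ("timing", "reaction", "eeg_noise", "emg_noise", "response",
             "artifacts", "normal_epochs")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _pink_noise(rng: np.random.Generator, n_channels: int, n: int,
                fs: float) -> np.ndarray:
    """1/f-amplitude noise, unit RMS per channel, flattened below 1 Hz."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = 1.0 / np.sqrt(np.maximum(freqs, 1.0))
    scale[0] = 0.0
    spec = rng.standard_normal((n_channels, freqs.size)) + 1j * rng.standard_normal(
        (n_channels, freqs.size)
    )
    x = np.fft.irfft(spec * scale, n=n, axis=1)
    rms = np.sqrt(np.mean(x**2, axis=1, keepdims=True))
    return x / np.maximum(rms, 1e-30)


def _band_noise(rng: np.random.Generator, n: int, band: tuple, fs: float) -> np.ndarray:
    """Band-limited unit-RMS noise packet (one row)."""
    x = rng.standard_normal(n)
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    y = sps.sosfiltfilt(sos, x)
    rms = np.sqrt(np.mean(y**2))
    return y / max(rms, 1e-30)


def _smooth_envelope(n: int, fs: float, ramp_s: float = 0.1) -> np.ndarray:
    """Trapezoid with raised-cosine ramps, length n."""
    ramp = max(1, min(int(round(ramp_s * fs)), n // 2))
    env = np.ones(n)
    up = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
    env[:ramp] = up
    env[-ramp:] = up[::-1]
    return env


def simulate_session(cfg: SimulationConfig) -> RecordingSession:
    """Generate one virtual subject's continuous EEG+EMG session.

    Hard trials carry a hard stimulus, an EEG transient and an EMG burst
    starting ``neural_lead_ms``/``emg_lead_ms`` before the pedal-deflection
    marker; soft trials are analogous with the soft class profile; normal
    trials carry background only. Identical config+seed gives bit-identical
    output.
    """
    cfg.validate()
    rngs = _substreams(cfg.seed)
    fs = cfg.fs_raw
    n_trial = int(round(cfg.trial_duration_s * fs))
    n_total = n_trial * cfg.n_trials
    n_eeg = len(cfg.eeg_channels)
    n_emg = len(cfg.emg_channels)

    # Trial classes: hard trials and soft trials interleaved at random.
    labels = ["hard"] * cfg.n_hard_trials + ["soft"] * (cfg.n_trials - cfg.n_hard_trials)
    order = rngs["timing"].permutation(cfg.n_trials)
    labels = [labels[i] for i in order]

    # --- background activity -------------------------------------------------
    eeg = cfg.eeg_background_rms * _pink_noise(rngs["eeg_noise"], n_eeg, n_total, fs)
    t = np.arange(n_total) / fs
    alpha_phase = rngs["eeg_noise"].uniform(0, 2 * np.pi)
    eeg += (
        cfg.alpha_amp
        * _OCCIPITAL_TOPO[: n_eeg, None]
        * np.sin(2 * np.pi * 10.0 * t + alpha_phase)[None, :]
    )

    emg_sos = sps.butter(4, (15.0, 90.0), btype="bandpass", fs=fs, output="sos")
    emg = sps.sosfiltfilt(
        emg_sos, rngs["emg_noise"].standard_normal((n_emg, n_total)), axis=1
    )
    emg *= cfg.emg_background_rms / np.sqrt(np.mean(emg**2, axis=1, keepdims=True))

    eeg_clean = np.zeros_like(eeg) if cfg.keep_clean else None
    emg_env = np.zeros(n_total) if cfg.keep_clean else None

    # --- per-trial events and class activity ---------------------------------
    events = []
    for k, lab in enumerate(labels):
        t0 = k * cfg.trial_duration_s
        events.append(Event(time_s=t0, kind="trial_start", trial_id=k))
        stim = t0 + rngs["timing"].uniform(*cfg.stimulus_window_s)
        rt = cfg.reaction_median_s * math.exp(
            cfg.reaction_sigma * rngs["reaction"].standard_normal()
        )
        pedal = stim + rt
        if pedal >= t0 + cfg.trial_duration_s - 0.8:
            pedal = t0 + cfg.trial_duration_s - 0.8  # keep activity inside the trial
        events.append(Event(time_s=stim, kind=f"{lab}_stimulus", trial_id=k))
        events.append(Event(time_s=pedal, kind=f"pedal_{lab}_onset", trial_id=k))

        prof = cfg.class_profiles[lab]
        jitter = cfg.lead_jitter_ms / 1000.0 * rngs["response"].uniform(-1, 1)

        # EEG transient: band-mixture packet from lead before pedal to 0.4 s after.
        lead = cfg.neural_lead_ms / 1000.0 + jitter
        start = int(round((pedal - lead) * fs))
        stop = min(int(round((pedal + 0.4) * fs)), n_total)
        npk = stop - start
        if npk > 8 and cfg.snr_eeg > 0 and np.any(prof.eeg_band_gains):
            packet = np.zeros(npk)
            for gain, band in zip(prof.eeg_band_gains, EEG_BANDS):
                if gain > 0:
                    packet += gain * _band_noise(rngs["response"], npk, band, fs)
            packet *= _smooth_envelope(npk, fs)
            burst = (
                cfg.snr_eeg
                * cfg.eeg_background_rms
                * prof.eeg_topo[:n_eeg, None]
                * packet[None, :]
            )
            eeg[:, start:stop] += burst
            if eeg_clean is not None:
                eeg_clean[:, start:stop] += burst

        # EMG burst: enveloped band noise from lead before pedal to 0.4 s after.
        lead_m = cfg.emg_lead_ms / 1000.0 + jitter
        m_start = int(round((pedal - lead_m) * fs))
        m_stop = min(int(round((pedal + 0.4) * fs)), n_total)
        nmk = m_stop - m_start
        if nmk > 8 and cfg.snr_emg > 0 and np.any(prof.emg_burst):
            # independent carrier per muscle: bursts survive CAR, as real
            # (uncorrelated) myoelectric activity does
            carrier = np.stack(
                [_band_noise(rngs["response"], nmk, (15.0, 90.0), fs) for _ in range(n_emg)]
            )
            env = _smooth_envelope(nmk, fs)
            burst = (
                cfg.snr_emg
                * cfg.emg_background_rms
                * prof.emg_burst[:n_emg, None]
                * carrier
                * env[None, :]
            )
            emg[:, m_start:m_stop] += burst
            if emg_env is not None:
                emg_env[m_start:m_stop] = np.maximum(emg_env[m_start:m_stop], env)

    # --- frontal blink-like artifacts (low-frequency bumps) ------------------
    if cfg.blink_rate_hz > 0 and cfg.blink_amp > 0:
        n_blinks = rngs["artifacts"].poisson(cfg.blink_rate_hz * n_total / fs)
        width = int(round(0.3 * fs))
        bump = np.hanning(width)
        for _ in range(n_blinks):
            c = rngs["artifacts"].integers(0, max(1, n_total - width))
            amp = cfg.blink_amp * rngs["artifacts"].uniform(0.7, 1.3)
            eeg[:, c : c + width] += amp * _FRONTAL_TOPO[:n_eeg, None] * bump[None, :]

    aux = {}
    if cfg.keep_clean:
        aux = {"eeg_clean": eeg_clean, "emg_envelope": emg_env}
    session = RecordingSession(
        eeg=eeg,
        emg=emg,
        fs=fs,
        events=events,
        labels=labels,
        eeg_channels=list(cfg.eeg_channels),
        emg_channels=list(cfg.emg_channels),
        aux=aux,
    )
    session.validate()
    return session


def extract_offline_samples(
    session: RecordingSession,
    normal_interval_s: tuple = (-11.0, -4.0),
    seed: int = 0,
) -> list:
    """Cut the offline training samples out of a continuous session.

    Per braking trial, the 1 s segment ending at the pedal-deflection onset
    becomes a hard/soft sample. Per *hard* trial an additional 1 s normal
    sample is drawn uniformly from the 11-to-4-seconds-before-pedal-onset
    interval, giving a balanced 30/30/30 design at default conditions.
    Trials too short for the requested interval are skipped with a warning.
    """
    fs = session.fs
    L = int(round(fs))
    rng = np.random.default_rng(seed)
    lo, hi = normal_interval_s
    if not (lo < hi <= 0):
        raise ValueError("normal interval must be negative and ordered")
    epochs = []

    trial_start = {e.trial_id: e.time_s for e in session.events_of_kind("trial_start")}
    for cls in ("hard", "soft"):
        for ev in session.events_of_kind(f"pedal_{cls}_onset"):
            end = int(round(ev.time_s * fs))
            if end - L < 0 or end > session.n_samples:
                logger.warning("trial %d too short for a braking epoch; skipped", ev.trial_id)
                continue
            epochs.append(
                Epoch(
                    eeg=session.eeg[:, end - L : end].copy(),
                    emg=session.emg[:, end - L : end].copy(),
                    fs=fs,
                    label=cls,
                    t0=(end - L) / fs,
                    trial_id=ev.trial_id,
                )
            )
            if cls == "hard":
                # Start offset in [lo, hi-1] s so the 1 s window ends by hi.
                offset = rng.uniform(lo, hi - 1.0)
                start = int(round((ev.time_s + offset) * fs))
                if start < int(round(trial_start.get(ev.trial_id, 0.0) * fs)):
                    logger.warning(
                        "trial %d too short for a normal-driving epoch; skipped",
                        ev.trial_id,
                    )
                    continue
                epochs.append(
                    Epoch(
                        eeg=session.eeg[:, start : start + L].copy(),
                        emg=session.emg[:, start : start + L].copy(),
                        fs=fs,
                        label="normal",
                        t0=start / fs,
                        trial_id=ev.trial_id,
                    )
                )
    return epochs
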