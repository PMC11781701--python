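"""Generator contracts: determinism, event bookkeeping, epoch extraction,
spectral shape of the background, and label-signal consistency."""

from collections import Counter

import numpy as np
import pytest
from scipy import signal as sps

from brakesense.data import CLASSES
from brakesense.simulate import (
    SimulationConfig,
    extract_offline_samples,
    simulate_session,
)


def small_cfg(**kw):
    base = dict(n_trials=8, n_hard_trials=4, seed=5)
    base.update(kw)
    return SimulationConfig(**base)


def test_same_seed_same_session():
    a = simulate_session(small_cfg())
    b = simulate_session(small_cfg())
    np.testing.assert_array_equal(a.eeg, b.eeg)
    np.testing.assert_array_equal(a.emg, b.emg)
    assert a.labels == b.labels
    assert [(e.time_s, e.kind) for e in a.events] == [(e.time_s, e.kind) for e in b.events]


def test_different_seed_differs():
    a = simulate_session(small_cfg())
    b = simulate_session(small_cfg(seed=6))
    assert not np.array_equal(a.eeg, b.eeg)


def test_event_bookkeeping(default_session):
    s = default_session
    assert len(s.events_of_kind("hard_stimulus")) == 30
    assert len(s.events_of_kind("soft_stimulus")) == 30
    assert len(s.events_of_kind("trial_start")) == 60
    s.validate()  # strictly increasing times, stimulus precedes pedal
    for ev in s.braking_events():
        assert ev.reaction_s >= 0


@pytest.mark.parametrize(
    "bad",
    [
        dict(n_hard_trials=10, n_trials=5),
        dict(trial_duration_s=-1.0),
        dict(neural_lead_ms=20000.0),
        dict(fs_raw=100.0),
    ],
)
def test_invalid_config_rejected(bad):
    with pytest.raises(ValueError):
        SimulationConfig(**bad).validate()


def test_zero_emg_snr_classes_indistinguishable():
    """With burst amplitude zero, hard/soft/normal EMG variance ratios ~ 1."""
    cfg = small_cfg(n_trials=20, n_hard_trials=10, snr_emg=0.0, seed=9)
    session = simulate_session(cfg)
    epochs = extract_offline_samples(session, seed=1)
    var = {c: [] for c in CLASSES}
    for e in epochs:
        var[e.label].append(e.emg.var())
    ratio = np.mean(var["hard"]) / np.mean(var["normal"])
    assert 0.9 < ratio < 1.1


def test_neural_lead_matches_config():
    """Noise-free EEG template switches on ~neural_lead_ms before pedal onset."""
    cfg = small_cfg(keep_clean=True, neural_lead_ms=300.0, lead_jitter_ms=20.0)
    session = simulate_session(cfg)
    clean = session.aux["eeg_clean"]
    onsets = []
    for ev in session.events_of_kind("pedal_hard_onset") + session.events_of_kind(
        "pedal_soft_onset"
    ):
        pedal_idx = int(round(ev.time_s * session.fs))
        seg = np.abs(clean[:, : pedal_idx]).sum(axis=0)
        active = np.nonzero(seg > 0)[0]
        start = active[active > pedal_idx - int(session.fs)].min()
        onsets.append((pedal_idx - start) / session.fs * 1000.0)
    assert abs(np.mean(onsets) - 300.0) < 20.0 + 5.0  # within jitter
    assert max(onsets) <= 300.0 + 20.0 + 2.0


def test_offline_sample_design(default_session):
    """Default conditions give the balanced 30/30/30 offline sample set."""
    epochs = extract_offline_samples(default_session, seed=2)
    counts = Counter(e.label for e in epochs)
    assert counts == {"hard": 30, "soft": 30, "normal": 30}
    L = int(round(default_session.fs))
    assert all(e.n_samples == L for e in epochs)


def test_braking_epoch_indexing(default_session):
    """Braking epochs end exactly at round(pedal_onset * fs)."""
    epochs = extract_offline_samples(default_session, seed=2)
    pedal = {
        ("hard", e.trial_id): e.time_s
        for e in default_session.events_of_kind("pedal_hard_onset")
    }
    pedal.update(
        {
            ("soft", e.trial_id): e.time_s
            for e in default_session.events_of_kind("pedal_soft_onset")
        }
    )
    fs = default_session.fs
    for ep in epochs:
        if ep.label == "normal":
            continue
        end = int(round(ep.t0 * fs)) + ep.n_samples
        assert end == int(round(pedal[(ep.label, ep.trial_id)] * fs))


def test_normal_epoch_placement(default_session):
    """Normal windows start in [-11, -5] s relative to the hard pedal onset
    (so the 1 s window ends by -4 s), reproducibly for a fixed seed."""
    epochs = extract_offline_samples(default_session, seed=2)
    again = extract_offline_samples(default_session, seed=2)
    pedal = {
        e.trial_id: e.time_s for e in default_session.events_of_kind("pedal_hard_onset")
    }
    offsets = [
        ep.t0 - pedal[ep.trial_id] for ep in epochs if ep.label == "normal"
    ]
    assert all(-11.0 - 1e-6 <= o <= -5.0 + 1e-6 for o in offsets)
    offsets2 = [ep.t0 - pedal[ep.trial_id] for ep in again if ep.label == "normal"]
    assert offsets == offsets2


def test_eeg_background_is_pink(default_session):
    """Welch PSD of the EEG background decays with frequency (1/f-like)."""
    x = default_session.eeg[0, :100000]
    f, p = sps.welch(x, fs=default_session.fs, nperseg=4096)
    band = lambda lo, hi: p[(f >= lo) & (f < hi)].mean()
    assert band(2, 6) > band(20, 30) > band(60, 90)


def test_emg_energy_concentrated_in_band(default_session):
    """EMG background carries most of its power inside 15-90 Hz."""
    x = default_session.emg[0, :100000]
    f, p = sps.welch(x, fs=default_session.fs, nperseg=4096)
    inside = p[(f >= 15) & (f <= 90)].sum()
    assert inside / p.sum() > 0.95


def test_energy_detector_floor():
    """High-SNR EMG energy thresholding separates hard from normal >= 99%."""
    cfg = SimulationConfig(seed=13, n_trials=40, n_hard_trials=20, snr_emg=8.0)
    session = simulate_session(cfg)
    epochs = extract_offline_samples(session, seed=1)
    hard = np.array([e.emg.var() for e in epochs if e.label == "hard"])
    normal = np.array([e.emg.var() for e in epochs if e.label == "normal"])
    thr = (hard.mean() + normal.mean()) / 2
    acc = ((hard > thr).sum() + (normal <= thr).sum()) / (len(hard) + len(normal))
    assert acc >= 0.99


def test_short_trials_skipped_with_warning(caplog):
    """Trials too short for the normal-sampling interval are skipped."""
    # pedal onset ~3.7-4.4 s into each 6 s trial: the normal-sampling window
    # (ending >= 4 s before the pedal) can never fit inside the trial
    cfg = SimulationConfig(
        n_trials=6, n_hard_trials=3, trial_duration_s=6.0,
        stimulus_window_s=(3.0, 3.3), seed=3,
    )
    session = simulate_session(cfg)
    with caplog.at_level("WARNING"):
        epochs = extract_offline_samples(session, seed=1)
    assert sum(1 for e in epochs if e.label == "normal") == 0
    assert any("too short" in r.message for r in caplog.records)
    assert sum(1 for e in epochs if e.label == "hard") == 3
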