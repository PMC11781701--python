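"""Session persistence: EDF for the signals, CSV for the event table.

The writer emits plain EDF (fixed ASCII header, little-endian int16 data
records of 1 s) with per-channel symmetric physical scaling in microvolts;
16-bit quantization is the only loss. Reading goes through mne's EDF
reader, which keeps the round trip honest: what we write must be what a
standard tool reads back. Header date/time fields are fixed so identical
sessions serialize byte-identically.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import Event, RecordingSession

_DIG_MAX = 32767


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")[:width]
    return b + b" " * (width - len(b))


def write_edf(path, signals: np.ndarray, fs: float, labels: list) -> None:
    """Write channels-by-time ``signals`` (microvolts) as EDF.

    The record duration is 1 s, so ``fs`` must be an integer; trailing
    samples beyond the last whole second are dropped.
    """
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    ns, n_samples = signals.shape
    n_records = n_samples // fs
    if n_records < 1:
        raise ValueError("need at least one second of data")
    data = np.asarray(signals[:, : n_records * fs], dtype=float)

    phys_max = np.maximum(np.abs(data).max(axis=1), 1.0)
    scaled = np.round(data / phys_max[:, None] * _DIG_MAX).astype("<i2")

    header = b"".join(
        [
            _pad("0", 8),
            _pad("X X X X", 80),
            _pad("Startdate 01-JAN-2000 X X X", 80),
            _pad("01.01.00", 8),
            _pad("00.00.00", 8),
            _pad(str(256 * (ns + 1)), 8),
            _pad("", 44),
            _pad(str(n_records), 8),
            _pad("1", 8),
            _pad(str(ns), 4),
        ]
    )
    fields = [
        [_pad(lab, 16) for lab in labels],
        [_pad("", 80)] * ns,  # transducer
        [_pad("uV", 8)] * ns,
        [_pad(f"{-m:.6g}"[:8], 8) for m in phys_max],
        [_pad(f"{m:.6g}"[:8], 8) for m in phys_max],
        [_pad(str(-_DIG_MAX), 8)] * ns,
        [_pad(str(_DIG_MAX), 8)] * ns,
        [_pad("", 80)] * ns,  # prefiltering
        [_pad(str(fs), 8)] * ns,
        [_pad("", 32)] * ns,
    ]
    with open(path, "wb") as fh:
        fh.write(header)
        for block in fields:
            fh.writelines(block)
        # data records: per record, all samples of signal 1, then signal 2, ...
        view = scaled.reshape(ns, n_records, fs)
        fh.write(np.ascontiguousarray(view.transpose(1, 0, 2)).tobytes())


def read_edf(path) -> tuple:
    """Read an EDF file via mne; returns (signals in microvolts, fs, labels)."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return raw.get_data() * 1e6, float(raw.info["sfreq"]), list(raw.ch_names)


def write_events_csv(path, session: RecordingSession) -> None:
    """Event table: time_s, kind, trial_id, plus the trial label on its start row."""
    rows = []
    for e in sorted(session.events, key=lambda ev: ev.time_s):
        label = session.labels[e.trial_id] if e.kind == "trial_start" else ""
        rows.append({"time_s": e.time_s, "kind": e.kind, "trial_id": e.trial_id,
                     "label": label})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_events_csv(path) -> tuple:
    """Returns (events, labels) from a CSV written by :func:`write_events_csv`."""
    df = pd.read_csv(path, keep_default_na=False)
    events = [
        Event(time_s=float(r.time_s), kind=str(r.kind), trial_id=int(r.trial_id))
        for r in df.itertuples()
    ]
    starts = df[df.kind == "trial_start"].sort_values("trial_id")
    labels = [str(lab) for lab in starts.label]
    return events, labels


def write_session(session: RecordingSession, edf_path, events_path) -> None:
    """Persist a session as EDF signals plus a CSV event table."""
    labels = [f"EEG {c}" for c in session.eeg_channels] + [
        f"EMG {c}" for c in session.emg_channels
    ]
    write_edf(edf_path, np.vstack([session.eeg, session.emg]), session.fs, labels)
    write_events_csv(events_path, session)


def load_session(edf_path, events_path) -> RecordingSession:
    """Load a session written by :func:`write_session`."""
    signals, fs, labels = read_edf(edf_path)
    eeg_idx = [i for i, l in enumerate(labels) if l.startswith("EEG ")]
    emg_idx = [i for i, l in enumerate(labels) if l.startswith("EMG ")]
    events, trial_labels = read_events_csv(events_path)
    return RecordingSession(
        eeg=signals[eeg_idx],
        emg=signals[emg_idx],
        fs=fs,
        events=events,
        labels=trial_labels,
        eeg_channels=[labels[i].removeprefix("EEG ") for i in eeg_idx],
        emg_channels=[labels[i].removeprefix("EMG ") for i in emg_idx],
    )
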