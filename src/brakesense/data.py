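"""Core containers: continuous recording sessions, event markers, epochs.

A :class:`RecordingSession` is the unit of exchange between the simulator,
the preprocessing stage and the pseudo-online evaluator: multichannel EEG
and EMG arrays (microvolts) at a common sampling rate, plus a marker table
of trial starts, braking stimuli and pedal-deflection onsets.

An :class:`Epoch` is one fixed-length labelled segment (1 s windows for
both offline training samples and pseudo-online sliding windows).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: The three driving-intention classes, in score order (class 1, 2, 3).
CLASSES = ("normal", "soft", "hard")

EVENT_KINDS = (
    "trial_start",
    "soft_stimulus",
    "hard_stimulus",
    "pedal_soft_onset",
    "pedal_hard_onset",
)


@dataclass(frozen=True)
class Event:
    """A session marker: absolute time in seconds, kind, owning trial."""

    time_s: float
    kind: str
    trial_id: int

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")


@dataclass
class BrakingEvent:
    """One braking episode: stimulus onset and the pedal deflection it caused."""

    kind: str  # "hard" or "soft"
    stimulus_s: float
    pedal_s: float
    trial_id: int

    @property
    def reaction_s(self) -> float:
        return self.pedal_s - self.stimulus_s


@dataclass
class RecordingSession:
    """Continuous EEG+EMG recording with event markers.

    Attributes
    ----------
    eeg, emg : ndarray
        Channel-by-time arrays in microvolts, sharing ``fs``.
    fs : float
        Sampling rate in Hz.
    events : list of Event
        Markers, strictly increasing in time within each trial.
    labels : list of str
        Per-trial class (``normal``/``soft``/``hard``).
    aux : dict
        Optional generator-side ground truth (noise-free class templates),
        populated only when the simulator is asked to keep it.
    """

    eeg: np.ndarray
    emg: np.ndarray
    fs: float
    events: list
    labels: list
    eeg_channels: list = field(default_factory=list)
    emg_channels: list = field(default_factory=list)
    aux: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.eeg.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def events_of_kind(self, kind: str) -> list:
        return [e for e in self.events if e.kind == kind]

    def braking_events(self) -> list:
        """Pair each braking stimulus with its pedal-deflection onset."""
        out = []
        for cls in ("soft", "hard"):
            stim = {e.trial_id: e for e in self.events_of_kind(f"{cls}_stimulus")}
            pedal = {e.trial_id: e for e in self.events_of_kind(f"pedal_{cls}_onset")}
            for tid, s in stim.items():
                if tid in pedal:
                    out.append(
                        BrakingEvent(
                            kind=cls,
                            stimulus_s=s.time_s,
                            pedal_s=pedal[tid].time_s,
                            trial_id=tid,
                        )
                    )
        out.sort(key=lambda b: b.stimulus_s)
        return out

    def validate(self) -> None:
        """Check marker bookkeeping invariants; raise ValueError on violation."""
        if self.eeg.shape[1] != self.emg.shape[1]:
            raise ValueError("EEG and EMG sample counts differ")
        by_trial: dict = {}
        for e in self.events:
            by_trial.setdefault(e.trial_id, []).append(e)
        for tid, evs in by_trial.items():
            times = [e.time_s for e in evs]
            if any(b <= a for a, b in zip(times, times[1:])):
                raise ValueError(f"event times not strictly increasing in trial {tid}")
            kinds = {e.kind: e.time_s for e in evs}
            for cls in ("soft", "hard"):
                if f"pedal_{cls}_onset" in kinds:
                    if f"{cls}_stimulus" not in kinds:
                        raise ValueError(
                            f"pedal_{cls}_onset without {cls}_stimulus in trial {tid}"
                        )
                    if kinds[f"pedal_{cls}_onset"] < kinds[f"{cls}_stimulus"]:
                        raise ValueError(f"negative reaction time in trial {tid}")


@dataclass
class Epoch:
    """One fixed-length labelled multichannel segment.

    ``eeg`` is the EEG sample matrix (Xt, channels x samples) and ``emg``
    the EMG matrix (Yt), both in microvolts at the shared rate ``fs``.
    """

    eeg: np.ndarray
    emg: np.ndarray
    fs: float
    label: str
    t0: float = 0.0
    trial_id: int = -1

    @property
    def n_samples(self) -> int:
        return self.eeg.shape[1]

    def copy(self) -> "Epoch":
        return replace(self, eeg=self.eeg.copy(), emg=self.emg.copy())


def stack_epochs(epochs, modality: str) -> np.ndarray:
    """Stack a list of epochs into an (n_epochs, C, L) array for one modality."""
    return np.stack([getattr(e, modality) for e in epochs])


def labels_of(epochs) -> np.ndarray:
    return np.array([e.label for e in epochs])
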