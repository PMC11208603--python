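"""Shared in-memory containers for traces, sessions, hypnograms and alignments."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Vigilance states, in the order used throughout the package.
STATES = ("wake", "nrem", "rem")

#: Trial outcomes of the go/no-go task.
OUTCOMES = ("impulsive", "hit", "miss")


@dataclass
class Trace:
    """A single-channel, regularly sampled signal.

    Parameters
    ----------
    values
        Signal samples (raw fluorescence, ΔF/F or z-units; see ``units``).
    rate
        Sampling rate in Hz.
    t0
        Time of the first sample, in seconds.
    channel_role
        ``"calcium"`` or ``"isosbestic"`` for photometry channels.
    units
        Free-text unit record (``"raw"``, ``"dff"``, ``"z"``).
    """

    values: np.ndarray
    rate: float
    t0: float = 0.0
    channel_role: str = "calcium"
    units: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if self.values.ndim != 1:
            raise ValueError("Trace values must be one-dimensional")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        """Duration in seconds."""
        return self.n / self.rate

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.rate

    def with_values(self, values: np.ndarray, units: str | None = None) -> "Trace":
        return replace(self, values=np.asarray(values, dtype=float),
                       units=self.units if units is None else units)


@dataclass
class PhotometrySession:
    """Two-channel photometry recording with LED duty-cycle metadata.

    ``led_blocks`` lists the (start_s, end_s) intervals during which the
    excitation LEDs were on; samples outside these intervals are dark.
    """

    calcium: Trace
    isosbestic: Trace | None = None
    led_blocks: list[tuple[float, float]] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    @property
    def rate(self) -> float:
        return self.calcium.rate

    @property
    def duration(self) -> float:
        return self.calcium.duration


class Hypnogram:
    """Ordered, contiguous state intervals on a fixed epoch grid.

    Stored as a table with columns ``state``, ``start_s``, ``end_s``.
    Intervals are non-overlapping and tile the scored period.
    """

    def __init__(self, intervals: pd.DataFrame, epoch_s: float = 4.0):
        required = {"state", "start_s", "end_s"}
        if not required.issubset(intervals.columns):
            raise ValueError(f"hypnogram needs columns {sorted(required)}")
        iv = intervals.sort_values("start_s").reset_index(drop=True)
        if len(iv) and not np.allclose(iv["end_s"].to_numpy()[:-1],
                                       iv["start_s"].to_numpy()[1:]):
            raise ValueError("hypnogram intervals must be contiguous")
        self.intervals = iv
        self.epoch_s = float(epoch_s)

    @classmethod
    def from_epochs(cls, states: np.ndarray, epoch_s: float = 4.0,
                    t0: float = 0.0) -> "Hypnogram":
        """Build from a per-epoch state sequence by run-length encoding."""
        states = np.asarray(states)
        if states.size == 0:
            raise ValueError("empty state sequence")
        change = np.flatnonzero(states[1:] != states[:-1]) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [states.size]])
        df = pd.DataFrame({
            "state": states[starts],
            "start_s": t0 + starts * epoch_s,
            "end_s": t0 + ends * epoch_s,
        })
        return cls(df, epoch_s=epoch_s)

    def to_epochs(self) -> np.ndarray:
        """Expand back to one state label per epoch."""
        out = []
        for state, s, e in self.intervals.itertuples(index=False):
            out.extend([state] * int(round((e - s) / self.epoch_s)))
        return np.asarray(out, dtype=object)

    def state_at(self, t: float | np.ndarray) -> np.ndarray:
        """State label(s) at time(s) ``t``; ``"unscored"`` outside the grid."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        starts = self.intervals["start_s"].to_numpy()
        ends = self.intervals["end_s"].to_numpy()
        states = self.intervals["state"].to_numpy()
        idx = np.searchsorted(starts, t, side="right") - 1
        out = np.full(t.shape, "unscored", dtype=object)
        ok = (idx >= 0) & (t < ends[np.clip(idx, 0, len(ends) - 1)])
        out[ok] = states[idx[ok]]
        return out

    @property
    def start_s(self) -> float:
        return float(self.intervals["start_s"].iloc[0])

    @property
    def end_s(self) -> float:
        return float(self.intervals["end_s"].iloc[-1])

    def occupancy(self) -> pd.Series:
        """Fraction of scored time per state."""
        dur = self.intervals["end_s"] - self.intervals["start_s"]
        total = dur.sum()
        occ = dur.groupby(self.intervals["state"]).sum() / total
        return occ.reindex(STATES, fill_value=0.0)

    def __len__(self) -> int:
        return len(self.intervals)

    def __repr__(self) -> str:  # pragma: no cover
        occ = ", ".join(f"{s}={v:.1%}" for s, v in self.occupancy().items())
        return f"<Hypnogram {self.start_s:.0f}–{self.end_s:.0f}s: {occ}>"


@dataclass
class SleepRecording:
    """Polysomnography channels with tone events and (optional) ground truth.

    ``tones`` has one row per tone: ``onset_s``, ``level_db`` and, when the
    recording is synthetic, ground-truth columns ``state_true``,
    ``awakening_true`` and the latent ACCp baseline ``accp_pre``.
    """

    eeg_frontal: Trace
    eeg_parietal: Trace
    emg: Trace
    hypnogram: Hypnogram | None = None
    tones: pd.DataFrame | None = None
    photometry: PhotometrySession | None = None
    meta: dict = field(default_factory=dict)

    @property
    def rate(self) -> float:
        return self.eeg_frontal.rate

    @property
    def duration(self) -> float:
        return self.eeg_frontal.duration


@dataclass
class AlignedMatrix:
    """Trials × samples matrix of signal aligned to an event.

    The window convention is half-open ``[window[0], window[1])`` seconds
    relative to the event, with the event sample included at t = 0.
    Excluded trials stay in the matrix but are flagged with a reason code.
    """

    data: np.ndarray
    rate: float
    window: tuple[float, float]
    event_kind: str
    excluded: np.ndarray
    reasons: np.ndarray
    trial_index: np.ndarray

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def times(self) -> np.ndarray:
        return self.window[0] + np.arange(self.data.shape[1]) / self.rate

    def included(self) -> np.ndarray:
        """Rows of non-excluded trials."""
        return self.data[~self.excluded]
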