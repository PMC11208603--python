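"""On-disk formats: CSV trial tables, HDF5 traces, interval-CSV hypnograms.

Trace files store one dataset per channel with a ``rate`` attribute;
hypnograms are three-column CSV (state, start_s, end_s); configs are TOML.
"""

from __future__ import annotations

import tomllib
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from engage.types import AlignedMatrix, Hypnogram, PhotometrySession, \
    SleepRecording, Trace


def save_trials(trials: pd.DataFrame, path) -> None:
    trials.to_csv(path, index=False)


def load_trials(path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_photometry(session: PhotometrySession, path) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("calcium", data=session.calcium.values)
        d.attrs["rate"] = session.calcium.rate
        if session.isosbestic is not None:
            d = f.create_dataset("isosbestic", data=session.isosbestic.values)
            d.attrs["rate"] = session.isosbestic.rate
        f.create_dataset("led_blocks",
                         data=np.asarray(session.led_blocks, dtype=float)
                         .reshape(-1, 2))


def load_photometry(path) -> PhotometrySession:
    with h5py.File(path, "r") as f:
        cal = Trace(f["calcium"][:], float(f["calcium"].attrs["rate"]),
                    channel_role="calcium")
        iso = None
        if "isosbestic" in f:
            iso = Trace(f["isosbestic"][:],
                        float(f["isosbestic"].attrs["rate"]),
                        channel_role="isosbestic")
        blocks = [tuple(b) for b in f["led_blocks"][:]] \
            if "led_blocks" in f else []
    return PhotometrySession(calcium=cal, isosbestic=iso, led_blocks=blocks)


def save_sleep(rec: SleepRecording, path) -> None:
    with h5py.File(path, "w") as f:
        for name in ("eeg_frontal", "eeg_parietal", "emg"):
            tr: Trace = getattr(rec, name)
            d = f.create_dataset(name, data=tr.values)
            d.attrs["rate"] = tr.rate


def load_sleep(path, hypnogram_path=None, tones_path=None) -> SleepRecording:
    with h5py.File(path, "r") as f:
        traces = {name: Trace(f[name][:], float(f[name].attrs["rate"]))
                  for name in ("eeg_frontal", "eeg_parietal", "emg")}
    hyp = load_hypnogram(hypnogram_path) if hypnogram_path else None
    tones = pd.read_csv(tones_path) if tones_path else None
    return SleepRecording(hypnogram=hyp, tones=tones, **traces)


def save_hypnogram(hyp: Hypnogram, path) -> None:
    hyp.intervals.to_csv(path, index=False)


def load_hypnogram(path, epoch_s: float = 4.0) -> Hypnogram:
    return Hypnogram(pd.read_csv(path), epoch_s=epoch_s)


def save_aligned(matrix: AlignedMatrix, path) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("data", data=matrix.data)
        d.attrs["rate"] = matrix.rate
        d.attrs["window"] = matrix.window
        d.attrs["event_kind"] = matrix.event_kind
        f.create_dataset("excluded", data=matrix.excluded)
        f.create_dataset("reasons",
                         data=np.asarray(matrix.reasons, dtype="S32"))
        f.create_dataset("trial_index", data=matrix.trial_index)


def load_aligned(path) -> AlignedMatrix:
    with h5py.File(path, "r") as f:
        d = f["data"]
        return AlignedMatrix(
            data=d[:], rate=float(d.attrs["rate"]),
            window=tuple(d.attrs["window"]),
            event_kind=str(d.attrs["event_kind"]),
            excluded=f["excluded"][:].astype(bool),
            reasons=np.array([r.decode() for r in f["reasons"][:]],
                             dtype=object),
            trial_index=f["trial_index"][:])


def load_config(path) -> dict:
    with open(Path(path), "rb") as f:
        return tomllib.load(f)
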