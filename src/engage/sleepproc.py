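"""Sleep staging and tone-evoked arousal analysis.

Staging codifies the standard manual criteria into a threshold cascade on
4-s epoch features: phasic EMG → wake; low frontal high/low power ratio
(power > 25 Hz ÷ power < 5 Hz) → NREM; parietal theta dominance → REM;
otherwise wake. Thresholds are fitted per recording by a two-component
split of each (log) feature, so staging is invariant to affine rescaling
of the raw channels, followed by 3-epoch minimum-duration smoothing.

A tone delivered during NREM is classified as an awakening when wake-like
EEG desynchronization (power ratio above the wake-side threshold, without
dominant theta) begins within 3 s of onset, persists for at least 2 s, and
is accompanied by EMG activation. Maintained trials whose slow-wave
activity (< 10 Hz) drops after the tone (pre/post ratio > 1.5 over 5-s
windows) are excluded as ambiguous.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from engage.types import STATES, Hypnogram, Trace


# ---------------------------------------------------------------- features

def _band_power(psd: np.ndarray, freqs: np.ndarray, lo: float | None,
                hi: float | None) -> np.ndarray:
    sel = np.ones_like(freqs, dtype=bool)
    if lo is not None:
        sel &= freqs > lo
    if hi is not None:
        sel &= freqs < hi
    return psd[..., sel].sum(axis=-1)


def compute_epoch_features(eeg_f: Trace, eeg_p: Trace, emg: Trace,
                           epoch_s: float = 4.0) -> pd.DataFrame:
    """Per-epoch staging features.

    Returns a frame with ``start_s``, ``power_ratio`` (frontal power > 25 Hz
    ÷ power < 5 Hz), ``theta_delta`` (parietal 5–10 Hz ÷ < 5 Hz) and
    ``emg_rms``. Band powers come from a per-epoch periodogram.
    """
    if not (eeg_f.n == eeg_p.n == emg.n) or not (eeg_f.rate == eeg_p.rate == emg.rate):
        raise ValueError("channels must share length and rate")
    rate = eeg_f.rate
    spe = int(round(epoch_s * rate))
    n_epochs = eeg_f.n // spe
    if n_epochs < 1:
        raise ValueError("recording shorter than one epoch")

    def epochs(tr: Trace) -> np.ndarray:
        return tr.values[:n_epochs * spe].reshape(n_epochs, spe)

    freqs, psd_f = signal.periodogram(epochs(eeg_f), fs=rate, axis=1)
    _, psd_p = signal.periodogram(epochs(eeg_p), fs=rate, axis=1)
    eps = np.finfo(float).tiny
    ratio = _band_power(psd_f, freqs, 25.0, None) / \
        (_band_power(psd_f, freqs, None, 5.0) + eps)
    theta = _band_power(psd_p, freqs, 5.0, 10.0) / \
        (_band_power(psd_p, freqs, None, 5.0) + eps)
    rms = np.sqrt((epochs(emg) ** 2).mean(axis=1))
    return pd.DataFrame({
        "start_s": np.arange(n_epochs) * epoch_s + eeg_f.t0,
        "power_ratio": ratio,
        "theta_delta": theta,
        "emg_rms": rms,
    })


# ---------------------------------------------------------------- staging

def _two_means_threshold(values: np.ndarray) -> tuple[float, float]:
    """1-D 2-means split; returns (threshold, center separation), log10 scale."""
    x = np.log10(np.asarray(values, dtype=float) + np.finfo(float).tiny)
    lo, hi = np.percentile(x, [10, 90])
    for _ in range(100):
        mid = (lo + hi) / 2.0
        lo_new = x[x <= mid].mean() if np.any(x <= mid) else lo
        hi_new = x[x > mid].mean() if np.any(x > mid) else hi
        if np.isclose(lo_new, lo) and np.isclose(hi_new, hi):
            break
        lo, hi = lo_new, hi_new
    return 10 ** ((lo + hi) / 2.0), hi - lo


@dataclass
class StageThresholds:
    """Per-recording staging thresholds (raw feature units)."""

    emg: float
    power_ratio: float
    theta_delta: float


#: Fallback thresholds for degenerate (unimodal) recordings, in the z-unit
#: scale of the synthetic generator.
FALLBACK_THRESHOLDS = StageThresholds(emg=0.4, power_ratio=0.3, theta_delta=3.0)

#: Minimum log10 separation of the two means for a split to count as bimodal.
MIN_SEPARATION = 0.3


def fit_stage_thresholds(features: pd.DataFrame) -> StageThresholds:
    """Fit the three cascade thresholds by two-component splits.

    EMG and the frontal power ratio are split over all epochs; the parietal
    theta/delta ratio is split over low-EMG (sleep) epochs only, where the
    NREM/REM contrast is not diluted by wake. Unimodal features fall back
    to fixed thresholds with a warning.
    """
    thr_emg, sep_emg = _two_means_threshold(features["emg_rms"])
    thr_ratio, sep_ratio = _two_means_threshold(features["power_ratio"])
    sleep = features["emg_rms"] < thr_emg
    if sleep.sum() >= 10:
        thr_theta, sep_theta = _two_means_threshold(
            features.loc[sleep, "theta_delta"])
    else:
        thr_theta, sep_theta = FALLBACK_THRESHOLDS.theta_delta, 0.0
    out = StageThresholds(emg=thr_emg, power_ratio=thr_ratio,
                          theta_delta=thr_theta)
    for name, sep, fallback in (("emg", sep_emg, FALLBACK_THRESHOLDS.emg),
                                ("power_ratio", sep_ratio,
                                 FALLBACK_THRESHOLDS.power_ratio),
                                ("theta_delta", sep_theta,
                                 FALLBACK_THRESHOLDS.theta_delta)):
        if sep < MIN_SEPARATION:
            warnings.warn(f"feature {name!r} looks unimodal; using the "
                          "fixed fallback threshold")
            setattr(out, name, fallback)
    return out


def _smooth_min_duration(states: np.ndarray, min_epochs: int = 3) -> np.ndarray:
    """Merge state runs shorter than ``min_epochs`` into the preceding run."""
    states = states.copy()
    changed = True
    while changed:
        changed = False
        # run-length encode
        change = np.flatnonzero(states[1:] != states[:-1]) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [states.size]])
        for k in range(len(starts)):
            if ends[k] - starts[k] < min_epochs:
                donor = states[starts[k] - 1] if starts[k] > 0 else (
                    states[ends[k]] if ends[k] < states.size else states[starts[k]])
                if donor != states[starts[k]]:
                    states[starts[k]:ends[k]] = donor
                    changed = True
                    break
    return states


def stage_sleep(features: pd.DataFrame,
                thresholds: StageThresholds | None = None,
                epoch_s: float = 4.0,
                min_epochs: int = 3) -> Hypnogram:
    """Rule-based staging of epoch features into a hypnogram.

    Cascade per epoch: EMG above threshold → wake; else power ratio below
    threshold → NREM; else theta/delta above threshold → REM; else wake.
    """
    if thresholds is None:
        thresholds = fit_stage_thresholds(features)
    emg = features["emg_rms"].to_numpy()
    ratio = features["power_ratio"].to_numpy()
    theta = features["theta_delta"].to_numpy()
    states = np.where(
        emg > thresholds.emg, "wake",
        np.where(ratio < thresholds.power_ratio, "nrem",
                 np.where(theta > thresholds.theta_delta, "rem", "wake")))
    states = _smooth_min_duration(states.astype(object), min_epochs)
    return Hypnogram.from_epochs(states, epoch_s=epoch_s,
                                 t0=float(features["start_s"].iloc[0]))


# ------------------------------------------------------------- arousals

def _sliding_ratio(values: np.ndarray, rate: float, win_s: float = 1.0,
                   step_s: float = 0.25) -> tuple[np.ndarray, np.ndarray]:
    """Frontal power ratio in sliding windows; returns (centers_idx, ratio)."""
    win = int(round(win_s * rate))
    step = int(round(step_s * rate))
    starts = np.arange(0, values.size - win + 1, step)
    segs = np.stack([values[s:s + win] for s in starts])
    freqs, psd = signal.periodogram(segs, fs=rate, axis=1)
    eps = np.finfo(float).tiny
    ratio = _band_power(psd, freqs, 25.0, None) / \
        (_band_power(psd, freqs, None, 5.0) + eps)
    return starts + win // 2, ratio


def classify_arousal(eeg_f: Trace, emg: Trace, onset_s: float,
                     thresholds: StageThresholds,
                     eeg_p: Trace | None = None,
                     respond_within_s: float = 3.0,
                     min_duration_s: float = 2.0,
                     emg_factor: float = 2.0,
                     pre_s: float = 4.0,
                     post_s: float = 8.0) -> str:
    """Classify one NREM tone trial as ``awakening`` / ``maintained``.

    Awakening requires a desynchronized run (sliding power ratio above the
    recording's wake-side threshold, without dominant parietal theta when
    ``eeg_p`` is given) starting within ``respond_within_s`` of tone onset,
    persisting at least ``min_duration_s``, with EMG RMS during the run
    exceeding ``emg_factor`` × the pre-onset level. Trials too close to the
    recording edge return ``"edge"``; trials already desynchronized before
    onset return ``"pre_desync"`` (not scorable as NREM-maintained).
    """
    rate = eeg_f.rate
    i_on = int(round((onset_s - eeg_f.t0) * rate))
    i0 = i_on - int(round((pre_s + 1.0) * rate))
    i1 = i_on + int(round(post_s * rate))
    if i0 < 0 or i1 > eeg_f.n or i_on < int(5 * rate) or \
            i_on > eeg_f.n - int(5 * rate):
        return "edge"
    centers, ratio = _sliding_ratio(eeg_f.values[i0:i1], rate)
    t = (centers + i0 - i_on) / rate  # window centers relative to onset
    desync = ratio > thresholds.power_ratio
    theta_ratio = None
    if eeg_p is not None:
        _, theta_ratio = _sliding_ratio_band(eeg_p.values[i0:i1], rate)

    # already awake / desynchronized before the tone: not scorable as a
    # tone-evoked transition (catches tones landing right after a natural
    # NREM→wake transition)
    pre = t < 0
    recent = (t >= -1.0) & (t < 0)
    if (pre.any() and desync[pre].mean() > 0.5) or desync[recent].any():
        return "pre_desync"

    # first desync run starting in (0, respond_within_s]
    step_s = float(np.median(np.diff(centers))) / rate
    post_idx = np.flatnonzero((t > 0) & desync)
    if post_idx.size == 0:
        return "maintained"
    runs = np.split(post_idx, np.flatnonzero(np.diff(post_idx) > 1) + 1)
    for run in runs:
        start, dur = t[run[0]], (run.size - 1) * step_s + 1.0  # window width
        if start > respond_within_s:
            break
        if dur < min_duration_s:
            continue
        # "without dominant theta": the run must not be REM-like overall
        if theta_ratio is not None and \
                np.median(theta_ratio[run]) > thresholds.theta_delta:
            continue
        run_i0 = i0 + centers[run[0]]
        run_i1 = i0 + centers[run[-1]]
        pre_rms = np.sqrt(np.mean(
            emg.values[i_on - int(pre_s * rate):i_on] ** 2))
        run_rms = np.sqrt(np.mean(emg.values[run_i0:run_i1 + 1] ** 2))
        if run_rms > emg_factor * pre_rms:
            return "awakening"
    return "maintained"


def _sliding_ratio_band(values: np.ndarray, rate: float, win_s: float = 1.0,
                        step_s: float = 0.25) -> tuple[np.ndarray, np.ndarray]:
    """Sliding parietal theta/delta ratio (5–10 Hz ÷ < 5 Hz)."""
    win = int(round(win_s * rate))
    step = int(round(step_s * rate))
    starts = np.arange(0, values.size - win + 1, step)
    segs = np.stack([values[s:s + win] for s in starts])
    freqs, psd = signal.periodogram(segs, fs=rate, axis=1)
    eps = np.finfo(float).tiny
    ratio = _band_power(psd, freqs, 5.0, 10.0) / \
        (_band_power(psd, freqs, None, 5.0) + eps)
    return starts + win // 2, ratio


def swa_power(eeg_f: Trace, onset_s: float, side: str,
              window_s: float = 5.0, band_hi: float = 10.0) -> float:
    """Slow-wave (< ``band_hi`` Hz) power in a 5-s window before/after onset."""
    rate = eeg_f.rate
    i_on = int(round((onset_s - eeg_f.t0) * rate))
    w = int(round(window_s * rate))
    seg = (eeg_f.values[i_on - w:i_on] if side == "pre"
           else eeg_f.values[i_on:i_on + w])
    if seg.size < w:
        raise ValueError("window leaves the recording span")
    freqs, psd = signal.periodogram(seg, fs=rate)
    return float(_band_power(psd, freqs, None, band_hi))


def filter_ambiguous_maintained(swa_pre: float, swa_post: float,
                                max_ratio: float = 1.5) -> bool:
    """Keep (True) or exclude (False) a maintained trial by the SWA ratio.

    Excluded when pre/post slow-wave power ratio exceeds ``max_ratio`` —
    i.e. SWA dropped after the tone, so sleep was not purely maintained.
    A degenerate zero post-power also excludes.
    """
    if swa_post <= 0:
        return False
    return (swa_pre / swa_post) <= max_ratio


def process_arousal_session(rec, thresholds: StageThresholds | None = None,
                            hypnogram: Hypnogram | None = None,
                            epoch_s: float = 4.0) -> pd.DataFrame:
    """Run the full arousal pipeline on one recording.

    Stages the recording (unless a scored hypnogram is supplied), assigns
    each tone its vigilance state from the last full epoch preceding onset,
    classifies NREM trials with :func:`classify_arousal` and applies the
    SWA-ratio exclusion to maintained trials. Returns the tone table with
    ``state`` and ``outcome`` columns (awakening / maintained / excluded /
    ignored / edge / pre_desync).
    """
    if rec.tones is None or not len(rec.tones):
        raise ValueError("recording has no tone events")
    features = compute_epoch_features(rec.eeg_frontal, rec.eeg_parietal,
                                      rec.emg, epoch_s)
    if thresholds is None:
        thresholds = fit_stage_thresholds(features)
    if hypnogram is None:
        hypnogram = stage_sleep(features, thresholds, epoch_s)

    out = rec.tones.copy()
    states, outcomes = [], []
    for onset in out["onset_s"]:
        # state from the last complete epoch before onset
        t_pre = (np.floor(onset / epoch_s) - 1) * epoch_s + epoch_s / 2
        state = str(hypnogram.state_at(t_pre)[0])
        states.append(state)
        if state != "nrem":
            outcomes.append("ignored")
            continue
        verdict = classify_arousal(rec.eeg_frontal, rec.emg, float(onset),
                                   thresholds, eeg_p=rec.eeg_parietal)
        if verdict == "maintained":
            pre = swa_power(rec.eeg_frontal, float(onset), "pre")
            post = swa_power(rec.eeg_frontal, float(onset), "post")
            if not filter_ambiguous_maintained(pre, post):
                verdict = "excluded"
        outcomes.append(verdict)
    out["state"] = states
    out["outcome"] = outcomes
    return out


# ----------------------------------------------------- summary statistics

def weighted_group_mean(per_mouse_means, per_mouse_counts) -> float:
    """Trial-count-weighted mean across mice.

    Weights are n_i / mean(n), so the weighted mean is Σ n_i x_i / Σ n_i.
    """
    x = np.asarray(per_mouse_means, dtype=float)
    n = np.asarray(per_mouse_counts, dtype=float)
    if x.size == 0:
        raise ValueError("no mice supplied")
    if np.any(n <= 0):
        raise ValueError("trial counts must be positive")
    w = n / n.mean()
    return float(np.sum(w * x) / np.sum(w))


def state_mean_activity(photometry_z: Trace, hyp: Hypnogram) -> pd.Series:
    """Mean photometry z per vigilance state over the hypnogram epochs."""
    t_lo = max(photometry_z.t0, hyp.start_s)
    t_hi = min(photometry_z.t0 + photometry_z.duration, hyp.end_s)
    if t_hi <= t_lo:
        raise ValueError("trace and hypnogram do not overlap")
    out = {}
    for state in STATES:
        vals = []
        for st, s, e in hyp.intervals.itertuples(index=False):
            if st != state:
                continue
            i0 = int(round((max(s, t_lo) - photometry_z.t0) * photometry_z.rate))
            i1 = int(round((min(e, t_hi) - photometry_z.t0) * photometry_z.rate))
            if i1 > i0:
                vals.append(photometry_z.values[i0:i1])
        if vals:
            out[state] = float(np.concatenate(vals).mean())
        else:
            warnings.warn(f"state {state!r} absent from the hypnogram")
            out[state] = np.nan
    return pd.Series(out)


def arousal_baseline_contrast(tone_trials: pd.DataFrame
                              ) -> tuple[float, pd.DataFrame]:
    """Weighted maintained-minus-awakening pre-tone baseline contrast.

    ``tone_trials`` needs columns ``mouse``, ``outcome`` and
    ``pre_baseline``. Per-mouse outcome means are combined across mice with
    trial-count weights; mice lacking one outcome class are dropped from
    the paired table with a warning. Returns (contrast, per-mouse table).
    """
    df = tone_trials[tone_trials["outcome"].isin(["maintained", "awakening"])]
    if df.empty:
        raise ValueError("no scorable tone trials")
    per = df.groupby(["mouse", "outcome"])["pre_baseline"] \
        .agg(["mean", "count"]).unstack("outcome")
    complete = per["mean"].notna().all(axis=1)
    if not complete.all():
        dropped = list(per.index[~complete])
        warnings.warn(f"mice lacking an outcome class dropped: {dropped}")
    per = per[complete]
    if per.empty:
        raise ValueError("no mouse has both outcome classes")
    counts = per["count"].sum(axis=1).to_numpy()
    contrast = (weighted_group_mean(per[("mean", "maintained")], counts)
                - weighted_group_mean(per[("mean", "awakening")], counts))
    table = pd.DataFrame({
        "maintained": per[("mean", "maintained")],
        "awakening": per[("mean", "awakening")],
        "n_trials": counts,
    })
    return float(contrast), table


def select_analysis_window(trace: Trace, start_s: float,
                           duration_s: float) -> Trace:
    """Crop a trace to an analysis window (e.g. the 2-h post-injection span
    starting 30 min after a chemogenetic injection)."""
    i0 = int(round((start_s - trace.t0) * trace.rate))
    i1 = i0 + int(round(duration_s * trace.rate))
    if i0 < 0 or i1 > trace.n:
        raise ValueError("analysis window exceeds the recording span")
    out = trace.with_values(trace.values[i0:i1])
    out.t0 = start_s
    return out
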