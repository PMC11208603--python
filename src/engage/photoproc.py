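"""Fiber-photometry preprocessing and peri-event alignment.

The standard chain, applied per LED-ON block, is:

1. :func:`detrend_polynomial` — subtract a 5th-order polynomial fit of the
   bleaching drift (offset-preserving: the fit's mean is added back so the
   trace keeps its amplitude scale and the ΔF/F baseline stays positive).
2. :func:`compute_dff` — ΔF/F = (F − F0)/F0 with F0 the 1st percentile.
3. :func:`zscore_session` — z-score against the whole block.
4. optionally :func:`isosbestic_correct` — subtract the z-scored isosbestic
   channel sample-by-sample to cancel shared motion artifacts.

Processed traces are then cut into 20-s windows [−5, 15) s around
behavioral events (:func:`align_events`), from which the 4-s pre-trial
baseline is read out (:func:`pretrial_activity`) and corrected for
session-to-session offsets (:func:`correct_session_baseline`).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from engage.types import AlignedMatrix, PhotometrySession, Trace


def detrend_polynomial(trace: Trace, order: int = 5) -> Trace:
    """Remove a least-squares polynomial trend, preserving the mean level.

    The fitted polynomial minus its own mean is subtracted, so the residual
    is orthogonal to the (centered) polynomial basis but the trace keeps its
    raw amplitude scale — required for the subsequent percentile-based ΔF/F
    baseline to be well defined.
    """
    if trace.n <= order + 1:
        raise ValueError(f"trace too short for order-{order} detrend")
    t = np.linspace(-1.0, 1.0, trace.n)  # scaled abscissa for conditioning
    coef = np.polynomial.polynomial.polyfit(t, trace.values, order)
    fit = np.polynomial.polynomial.polyval(t, coef)
    return trace.with_values(trace.values - (fit - fit.mean()))


def compute_dff(trace: Trace, percentile: float = 1.0) -> Trace:
    """ΔF/F with the 1st-percentile value of the trace as F0.

    The percentile uses linear interpolation between order statistics
    (numpy's default convention). F0 must be positive: run the
    offset-preserving :func:`detrend_polynomial` first, not a mean-removing
    detrend, or the baseline is ill-posed.
    """
    f0 = float(np.percentile(trace.values, percentile))
    if f0 <= 0:
        raise ValueError(
            "F0 (1st percentile) must be positive; detrend with the "
            "offset-preserving convention before computing ΔF/F")
    return trace.with_values((trace.values - f0) / f0, units="dff")


def zscore_session(trace: Trace) -> Trace:
    """Z-score against the mean and s.d. of the entire trace."""
    sd = float(np.std(trace.values))
    if sd == 0:
        raise ValueError("cannot z-score a constant trace")
    return trace.with_values((trace.values - trace.values.mean()) / sd,
                             units="z")


def isosbestic_correct(signal_z: Trace, control_z: Trace,
                       scale: str = "unit") -> Trace:
    """Subtract the z-scored isosbestic control channel sample-by-sample.

    In z-units the sample-wise-F0 correction reduces to subtraction:
    motion artifacts common to both channels cancel, while the
    calcium-dependent response survives. ``scale="unit"`` subtracts the
    control as-is (valid when artifacts dominate both channels equally in
    z-units); ``scale="fit"`` first rescales the control by its
    least-squares projection onto the signal, which cancels shared
    artifacts even when the two channels carry different artifact-to-signal
    ratios.
    """
    if signal_z.n != control_z.n:
        raise ValueError("channel length mismatch")
    if signal_z.rate != control_z.rate:
        raise ValueError("channel rate mismatch")
    ctl = control_z.values
    if scale == "fit":
        var = np.var(ctl)
        beta = float(np.cov(signal_z.values, ctl)[0, 1] / var) if var > 0 else 0.0
        ctl = beta * ctl
    elif scale != "unit":
        raise ValueError("scale must be 'unit' or 'fit'")
    return signal_z.with_values(signal_z.values - ctl)


def segment_led_blocks(session: PhotometrySession,
                       flat_threshold: float = 1e-6) -> list[tuple[int, int]]:
    """Sample-index (start, stop) pairs of the LED-ON blocks.

    Uses the session's recorded block boundaries when present; otherwise
    detects OFF periods as flatline runs below ``flat_threshold``.
    """
    rate = session.rate
    if session.led_blocks:
        blocks = [(int(round(s * rate)), int(round(e * rate)))
                  for s, e in session.led_blocks]
    else:
        on = np.abs(session.calcium.values) > flat_threshold
        edges = np.flatnonzero(np.diff(on.astype(int)))
        starts = ([0] if on[0] else []) + list(edges[~on[edges]] + 1)
        stops = list(edges[on[edges]] + 1) + ([on.size] if on[-1] else [])
        blocks = list(zip(starts, stops))
    blocks = [(s, e) for s, e in blocks if e > s]
    if not blocks:
        raise ValueError("no LED-ON block found")
    return blocks


def preprocess_session(session: PhotometrySession, order: int = 5,
                       isosbestic: bool | None = None,
                       isosbestic_scale: str = "fit",
                       correct_before_zscore: bool = False) -> Trace:
    """Run detrend → ΔF/F → z-score independently per LED-ON block.

    Returns a session-spanning z-unit trace with NaN in LED-OFF gaps.
    With ``isosbestic`` (default: on when the channel exists) the z-scored
    control channel is subtracted per block; ``correct_before_zscore``
    instead subtracts in ΔF/F units and re-z-scores, for sessions where the
    artifact scale differs between channels.
    """
    if isosbestic is None:
        isosbestic = session.isosbestic is not None
    if isosbestic and session.isosbestic is None:
        raise ValueError("no isosbestic channel recorded")
    out = np.full(session.calcium.n, np.nan)
    for s, e in segment_led_blocks(session):
        def chain(values: np.ndarray) -> Trace:
            tr = Trace(values, session.rate)
            return zscore_session(compute_dff(detrend_polynomial(tr, order)))

        sig = chain(session.calcium.values[s:e])
        if isosbestic:
            ctl = chain(session.isosbestic.values[s:e])
            sig = isosbestic_correct(sig, ctl, scale=isosbestic_scale)
            if correct_before_zscore:
                sig = zscore_session(sig)
        out[s:e] = sig.values
    return Trace(out, session.rate, units="z")


def align_events(trace: Trace, events: np.ndarray,
                 window: tuple[float, float] = (-5.0, 15.0),
                 event_kind: str = "trial_onset",
                 early_lick_s: np.ndarray | None = None,
                 early_lick_threshold: float = 1.0) -> AlignedMatrix:
    """Cut the trace into trials × samples windows around each event.

    The window is half-open [pre, post) seconds relative to the event, with
    the event sample at t = 0. Events whose window leaves the trace span
    are flagged ``"edge"``. For sensory-response analyses pass
    ``early_lick_s`` (per-trial first impulsive-lick time relative to the
    event, NaN when none): trials with a lick before
    ``early_lick_threshold`` seconds are flagged ``"early_lick"`` so lick
    responses cannot masquerade as sensory ones.
    """
    events = np.asarray(events, dtype=float)
    if events.size == 0:
        warnings.warn("empty event list; returning empty alignment")
    rate = trace.rate
    pre, post = window
    n_samp = int(round((post - pre) * rate))
    data = np.zeros((events.size, n_samp))
    excluded = np.zeros(events.size, dtype=bool)
    reasons = np.full(events.size, "", dtype=object)
    for i, ev in enumerate(events):
        i0 = int(round((ev + pre - trace.t0) * rate))
        i1 = i0 + n_samp
        if i0 < 0 or i1 > trace.n:
            excluded[i] = True
            reasons[i] = "edge"
            continue
        seg = trace.values[i0:i1]
        if np.isnan(seg).any():
            excluded[i] = True
            reasons[i] = "led_off"
            continue
        data[i] = seg
    if early_lick_s is not None:
        early = np.asarray(early_lick_s, dtype=float) < early_lick_threshold
        early &= ~excluded
        excluded |= early
        reasons[early] = "early_lick"
    return AlignedMatrix(data=data, rate=rate, window=window,
                         event_kind=event_kind, excluded=excluded,
                         reasons=reasons,
                         trial_index=np.arange(events.size))


def pretrial_activity(matrix: AlignedMatrix, window_s: float = 4.0) -> np.ndarray:
    """Per-trial mean of the signal in the ``window_s`` seconds before t=0.

    Excluded trials return NaN.
    """
    pre = matrix.window[0]
    if pre > -window_s:
        raise ValueError("alignment window does not cover the pre-event span")
    i0 = int(round((-window_s - pre) * matrix.rate))
    i1 = int(round((0.0 - pre) * matrix.rate))
    out = matrix.data[:, i0:i1].mean(axis=1)
    out[matrix.excluded] = np.nan
    return out


def correct_session_baseline(pretrial: np.ndarray, outcome: np.ndarray,
                             session_id: np.ndarray) -> np.ndarray:
    """Remove per-session offsets from pre-trial baselines.

    Fits ``baseline ~ outcome + session`` by OLS with hit as the reference
    outcome and subtracts only the intercept and session effects, so the
    mean baseline of hit trials in each session lands at ~zero while
    outcome contrasts are untouched.
    """
    pretrial = np.asarray(pretrial, dtype=float)
    outcome = np.asarray(outcome)
    session_id = np.asarray(session_id)
    if np.unique(outcome).size < 2:
        raise ValueError("need at least two outcome levels")
    for sess in np.unique(session_id):
        if not np.any(outcome[session_id == sess] == "hit"):
            warnings.warn(f"session {sess!r} has no hit trials; its offset "
                          "is the pooled-model estimate")

    ok = np.isfinite(pretrial)
    out_levels = [o for o in np.unique(outcome) if o != "hit"]
    sess_levels = list(np.unique(session_id))[1:]
    cols = [np.ones(pretrial.size)]
    cols += [(outcome == o).astype(float) for o in out_levels]
    cols += [(session_id == s).astype(float) for s in sess_levels]
    X = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(X[ok], pretrial[ok], rcond=None)
    offset = X[:, [0] + list(range(1 + len(out_levels), X.shape[1]))] @ \
        np.concatenate([[beta[0]], beta[1 + len(out_levels):]])
    return pretrial - offset
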