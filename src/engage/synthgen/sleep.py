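"""Synthetic 12-h sleep sessions: Markov hypnograms, EEG/EMG, tone arousals.

The vigilance-state sequence is a first-order Markov chain on 4-s epochs
whose transition matrix can be calibrated to hit target stationary
occupancies exactly. EEG channels are synthesized as band-limited Gaussian
noise (delta < 5 Hz, theta 5–10 Hz, high > 25 Hz) mixed with state-dependent
amplitudes — staging features depend only on band powers, so no oscillatory
phase realism is attempted. Tone-evoked awakenings follow a per-dB logistic
of the latent ACCp baseline, calibrated so the marginal awakening
probability over NREM trials equals the configured per-dB value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, signal, special

from engage.types import STATES, Hypnogram, SleepRecording, Trace

_W, _N, _R = 0, 1, 2  # state codes: wake, nrem, rem

#: Undisturbed-sleep occupancies (fraction of scored time), wake/NREM/REM.
#: 34.4 / 54.0 / 8.1 percent, renormalized to sum to one.
DEFAULT_OCCUPANCY = (0.344 / 0.965, 0.540 / 0.965, 0.081 / 0.965)

#: Awakening probability by tone level (dB SPL) marginal over NREM trials.
DEFAULT_AWAKENING_P = {65: 0.081, 80: 0.198}


def stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (left eigenvector)."""
    P = np.asarray(P, dtype=float)
    w, v = np.linalg.eig(P.T)
    i = np.argmin(np.abs(w - 1.0))
    pi = np.real(v[:, i])
    pi = pi / pi.sum()
    if np.any(pi < -1e-9):
        raise ValueError("no valid stationary distribution")
    return np.clip(pi, 0.0, None) / np.clip(pi, 0.0, None).sum()


def calibrated_transition_matrix(occupancy=DEFAULT_OCCUPANCY,
                                 nrem_bout_epochs: float = 45.0,
                                 rem_bout_epochs: float = 20.0) -> np.ndarray:
    """Transition matrix with the given stationary occupancy.

    Uses the physiological transition topology wake→NREM, NREM→{wake, REM},
    REM→wake. Given the target occupancy π and the mean NREM and REM bout
    lengths (in 4-s epochs), the remaining rates follow from the balance
    equations, so π is the stationary distribution exactly.
    """
    pw, pn, pr = (float(x) for x in occupancy)
    if not np.isclose(pw + pn + pr, 1.0):
        raise ValueError("occupancy must sum to 1")
    b = 1.0 / nrem_bout_epochs          # NREM leave rate
    c = 1.0 / rem_bout_epochs           # REM leave rate
    f = pr * c / (pn * b)               # NREM→REM branching fraction
    a = pn * b / pw                     # wake leave rate
    if not (0 < a < 1 and 0 < f < 1):
        raise ValueError("bout lengths incompatible with occupancy")
    P = np.array([
        [1 - a, a, 0.0],
        [b * (1 - f), 1 - b, b * f],
        [c, 0.0, 1 - c],
    ])
    return P


@dataclass
class SleepGenConfig:
    """Generation parameters for one sleep session.

    ``eeg_band_powers`` maps state → (delta, theta, high) RMS amplitude per
    channel; ``awakening_p`` gives the marginal awakening probability per
    tone level; ``arousal_coupling`` scales how strongly the latent ACCp
    baseline tilts individual awakening odds (higher ACCp → sleep
    maintained), with the per-dB intercept recalibrated so the marginal
    stays at ``awakening_p``.
    """

    transition_matrix: np.ndarray = field(
        default_factory=calibrated_transition_matrix)
    epoch_s: float = 4.0
    duration_h: float = 12.0
    rate: float = 100.0
    tones: bool = False
    tone_interval: tuple[float, float] = (60.0, 0.5)  # mean, jitter (s)
    tone_levels: tuple[int, ...] = (65, 80)
    awakening_p: dict = field(default_factory=lambda: dict(DEFAULT_AWAKENING_P))
    arousal_coupling: float = 1.0
    wake_after_tone_epochs: float = 5.0   # mean forced-wake bout (epochs)
    awake_latency_s: tuple[float, float] = (0.5, 2.0)
    frontal_powers: dict = field(default_factory=lambda: {
        "wake": (0.4, 0.4, 1.0), "nrem": (2.2, 0.6, 0.25),
        "rem": (0.4, 0.7, 0.9)})
    parietal_powers: dict = field(default_factory=lambda: {
        "wake": (0.4, 0.5, 0.9), "nrem": (2.0, 0.7, 0.25),
        "rem": (0.35, 2.2, 0.6)})
    emg_levels: dict = field(default_factory=lambda: {
        "wake": 1.0, "nrem": 0.12, "rem": 0.04})
    accp_state_offset: dict = field(default_factory=lambda: {
        "wake": -0.3, "nrem": 0.3, "rem": 0.0})
    accp_rho: float = 0.95
    accp_sd: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        P = np.asarray(self.transition_matrix, dtype=float)
        if P.shape != (3, 3) or not np.allclose(P.sum(axis=1), 1.0):
            raise ValueError("transition matrix rows must sum to 1")
        if np.any(P < 0):
            raise ValueError("transition probabilities must be nonnegative")
        self.transition_matrix = P
        p = [self.awakening_p[k] for k in sorted(self.awakening_p)]
        if any(b <= a for a, b in zip(p, p[1:])):
            raise ValueError("awakening probability must increase with dB")


_GH_X, _GH_W = np.polynomial.hermite_e.hermegauss(64)
_GH_W = _GH_W / _GH_W.sum()


def _calibrate_intercept(p_target: float, coupling: float, b_mean: float,
                         b_sd: float) -> float:
    """Intercept c with E_b[expit(c − coupling·b)] = p_target, b ~ N(μ, σ²)."""

    def mean_p(c: float) -> float:
        b = b_mean + b_sd * _GH_X
        return float(np.sum(_GH_W * special.expit(c - coupling * b)))

    return optimize.brentq(lambda c: mean_p(c) - p_target, -30.0, 30.0)


def _band_noise(n: int, rate: float, lo: float | None, hi: float | None,
                rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited to (lo, hi) Hz."""
    x = rng.standard_normal(n)
    nyq = rate / 2.0
    if lo is not None and hi is not None:
        sos = signal.butter(4, [lo / nyq, hi / nyq], btype="band", output="sos")
    elif hi is not None:
        sos = signal.butter(4, hi / nyq, btype="low", output="sos")
    else:
        sos = signal.butter(4, lo / nyq, btype="high", output="sos")
    y = signal.sosfiltfilt(sos, x)
    return y / y.std()


def _tone_schedule(duration_s: float, gen: SleepGenConfig,
                   rng: np.random.Generator) -> pd.DataFrame:
    mean, jitter = gen.tone_interval
    onsets = []
    t = mean + rng.uniform(-jitter, jitter)
    while t < duration_s - 30.0:
        onsets.append(t)
        t += mean + rng.uniform(-jitter, jitter)
    onsets = np.asarray(onsets)
    levels = rng.choice(list(gen.tone_levels), size=onsets.size)
    return pd.DataFrame({"onset_s": onsets, "level_db": levels})


def simulate_sleep_session(gen: SleepGenConfig) -> SleepRecording:
    """Simulate one session: hypnogram, EEG/EMG, latent ACCp, tone outcomes.

    Returns a :class:`SleepRecording` whose ``hypnogram`` is the ground
    truth (awakening-inserted wake included), whose ``tones`` table carries
    ground-truth columns ``state_true``, ``awakening_true``, ``latency_s``
    and the latent pre-tone baseline ``accp_pre``, and whose
    ``meta["accp_z"]`` holds the latent ACCp trace in z-units.
    """
    rng = np.random.default_rng(gen.seed)
    epoch_s = gen.epoch_s
    n_epochs = int(round(gen.duration_h * 3600.0 / epoch_s))
    duration_s = n_epochs * epoch_s
    P = gen.transition_matrix

    tones = (_tone_schedule(duration_s, gen, rng) if gen.tones
             else pd.DataFrame(columns=["onset_s", "level_db"]))
    tone_epoch = (tones["onset_s"].to_numpy() / epoch_s).astype(int)
    tones_by_epoch: dict[int, list[int]] = {}
    for i, ep in enumerate(tone_epoch):
        tones_by_epoch.setdefault(ep, []).append(i)

    # latent ACCp: state offset + AR(1), advanced per epoch
    rho, sd = gen.accp_rho, gen.accp_sd
    ar = np.empty(n_epochs)
    ar[0] = rng.standard_normal() * sd
    innov = rng.standard_normal(n_epochs) * sd * np.sqrt(1 - rho**2)
    for k in range(1, n_epochs):
        ar[k] = rho * ar[k - 1] + innov[k]

    intercepts = {
        int(db): _calibrate_intercept(
            p, gen.arousal_coupling,
            gen.accp_state_offset["nrem"], sd)
        for db, p in gen.awakening_p.items()
    }

    pi0 = stationary_distribution(P)
    states = np.empty(n_epochs, dtype=np.int64)
    states[0] = rng.choice(3, p=pi0)
    tone_rows: list[dict] = []
    sub_epoch_wake: list[tuple[float, float]] = []  # awakening onset overrides
    forced_wake = 0  # remaining forced wake epochs after an awakening
    forced_nrem = 0  # hold NREM through the scoring window after maintained
    mean_wake = gen.wake_after_tone_epochs

    for k in range(n_epochs):
        if k > 0:
            if forced_wake > 0:
                states[k] = _W
                forced_wake -= 1
            elif forced_nrem > 0 and states[k - 1] == _N:
                states[k] = _N
                forced_nrem -= 1
            else:
                states[k] = rng.choice(3, p=P[states[k - 1]])
                forced_nrem = 0
        accp_k = gen.accp_state_offset[STATES[states[k]]] + ar[k]
        for i in tones_by_epoch.get(k, ()):
            row = {"state_true": STATES[states[k]], "accp_pre": accp_k,
                   "awakening_true": False, "latency_s": np.nan}
            if states[k] == _N and forced_wake == 0:
                db = int(tones.at[i, "level_db"])
                p_awake = special.expit(
                    intercepts[db] - gen.arousal_coupling * accp_k)
                if rng.random() < p_awake:
                    lat = rng.uniform(*gen.awake_latency_s)
                    onset = float(tones.at[i, "onset_s"])
                    row["awakening_true"] = True
                    row["latency_s"] = lat
                    # wake-like EEG/EMG from onset+latency to the epoch edge,
                    # then forced wake epochs so the bout persists
                    sub_epoch_wake.append((onset + lat,
                                           (k + 1) * epoch_s))
                    forced_wake = max(1, int(rng.geometric(1.0 / mean_wake)))
                else:
                    # maintained ground truth: sleep actually persists
                    # through the 3-s scoring window, as a scorer would
                    # require before labeling the trial maintained
                    forced_nrem = 1
            tone_rows.append(row)

    hyp = Hypnogram.from_epochs(np.asarray(STATES, dtype=object)[states],
                                epoch_s=epoch_s)

    # --- signal synthesis ------------------------------------------------
    n = int(round(duration_s * gen.rate))
    spe = int(round(epoch_s * gen.rate))  # samples per epoch

    def gains(table: dict, col: int) -> np.ndarray:
        per_state = np.array([table[s][col] for s in STATES])
        return np.repeat(per_state[states], spe)

    bands = {"delta": (0.5, 5.0), "theta": (5.0, 10.0), "high": (25.0, 49.0)}
    eeg = {}
    for name, powers in (("frontal", gen.frontal_powers),
                         ("parietal", gen.parietal_powers)):
        total = np.zeros(n)
        for col, (lo, hi) in enumerate(bands.values()):
            g = gains(powers, col)
            wake_level = powers["wake"][col]
            for s, e in sub_epoch_wake:
                g[int(s * gen.rate):int(e * gen.rate)] = wake_level
            total += g * _band_noise(n, gen.rate, lo, hi, rng)
        eeg[name] = total

    emg_state = np.array([gen.emg_levels[s] for s in STATES])
    g_emg = np.repeat(emg_state[states], spe)
    for s, e in sub_epoch_wake:
        i0, i1 = int(s * gen.rate), int(e * gen.rate)
        g_emg[i0:i1] = gen.emg_levels["wake"]
        # brief activation burst at awakening onset
        g_emg[i0:min(i1, i0 + int(2.0 * gen.rate))] *= 2.0
    emg = g_emg * _band_noise(n, gen.rate, 10.0, 49.0, rng)

    accp_trace = Trace(np.repeat(
        np.array([gen.accp_state_offset[s] for s in STATES])[states] + ar, spe),
        gen.rate, units="z")

    tone_df = pd.concat(
        [tones.reset_index(drop=True), pd.DataFrame(tone_rows)], axis=1)

    return SleepRecording(
        eeg_frontal=Trace(eeg["frontal"], gen.rate, units="z"),
        eeg_parietal=Trace(eeg["parietal"], gen.rate, units="z"),
        emg=Trace(emg, gen.rate, units="z"),
        hypnogram=hyp,
        tones=tone_df,
        meta={"accp_z": accp_trace, "config": gen,
              "states_true": states.copy()},
    )
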