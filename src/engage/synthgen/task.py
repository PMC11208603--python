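"""ENGAGE go/no-go trial-sequence generation.

A session is a sequence of automatically initiated trials. Each trial opens
with a broadband-noise No-Go cue, followed after a random delay by a pure-tone
Go cue at one of four attenuation levels; half the trials carry a tone-cloud
mask and a quarter a visual aid flashed with the Go cue.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class TaskConfig:
    """Parameters of an ENGAGE session.

    Defaults mirror the standard protocol: 360 trials initiated every 20 s
    (a 2-h session), four equally probable Go-cue intensities, tone cloud on
    50% of trials, visual aid on 25%, delay uniform on [0.5, 3.0] s and a
    1.5-s response window. ``reward_volume`` (µl) is metadata only.
    """

    n_trials: int = 360
    intensities: tuple[int, ...] = (1, 2, 3, 4)
    p_cloud: float = 0.5
    p_aid: float = 0.25
    delay_range: tuple[float, float] = (0.5, 3.0)
    response_window: float = 1.5
    trial_interval: float = 20.0
    reward_volume: float = 4.0
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if not (0.0 <= self.p_cloud <= 1.0 and 0.0 <= self.p_aid <= 1.0):
            raise ValueError("p_cloud and p_aid must be probabilities in [0, 1]")
        if not self.delay_range[0] < self.delay_range[1]:
            raise ValueError("delay_range must be an increasing pair")

    @property
    def session_duration(self) -> float:
        """Nominal session duration in seconds (trials × initiation interval)."""
        return self.n_trials * self.trial_interval


def _stratified_flags(n: int, p: float, rng: np.random.Generator) -> np.ndarray:
    """Boolean flags hitting the marginal probability as exactly as n allows."""
    k = int(round(n * p))
    flags = np.zeros(n, dtype=bool)
    flags[:k] = True
    rng.shuffle(flags)
    return flags


def gen_trial_sequence(config: TaskConfig) -> pd.DataFrame:
    """Generate the stimulus side of a trial table.

    Columns: ``trial``, ``onset_s``, ``intensity``, ``cloud``, ``aid``,
    ``delay_s``. With ``config.stratified`` (default) the cloud/aid flags and
    intensities are assigned by stratified shuffling so the session marginals
    match the configured probabilities as closely as the trial count allows;
    otherwise each trial is drawn independently.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_trials
    if config.stratified:
        cloud = _stratified_flags(n, config.p_cloud, rng)
        aid = _stratified_flags(n, config.p_aid, rng)
        reps = -(-n // len(config.intensities))  # ceil division
        intensity = np.tile(np.asarray(config.intensities), reps)[:n]
        rng.shuffle(intensity)
    else:
        cloud = rng.random(n) < config.p_cloud
        aid = rng.random(n) < config.p_aid
        intensity = rng.choice(config.intensities, size=n)
    lo, hi = config.delay_range
    return pd.DataFrame({
        "trial": np.arange(n),
        "onset_s": np.arange(n) * config.trial_interval,
        "intensity": intensity.astype(int),
        "cloud": cloud,
        "aid": aid,
        "delay_s": rng.uniform(lo, hi, size=n),
    })
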