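"""A latent-engagement behavioral agent for the ENGAGE task.

The agent carries a slow AR(1) engagement process across trials and a latent
ACCp-activity proxy that is a negative affine transform of engagement plus
noise. Per-trial outcome probabilities are linear in the latent proxy,
clipped to [0, 1]: impulsive errors become *more* likely when the proxy is
low (hyper-engagement), misses more likely when it is high (disengagement).
Two presets bundle the parameters into the explorer / exploiter phenotypes:
explorers impulse more, are more cloud-susceptible and show strong
latent-to-outcome coupling; exploiters respond mainly to salient cues
(loud tones, visual aid) and are weakly coupled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd


@dataclass
class AgentParams:
    """Generative parameters of one simulated mouse.

    ``psychometric`` maps the four Go-cue intensities to base detection
    probabilities; ``impulsive_gain`` / ``miss_gain`` are the slopes of
    P(impulsive) (decreasing) and P(miss) (increasing) in the latent ACCp
    proxy; ``coupling`` is the magnitude of the (negative) correlation
    between the proxy and latent engagement.
    """

    engagement_rho: float = 0.9
    engagement_sd: float = 1.0  # stationary s.d. of the AR(1) process
    impulsive_base: float = 0.15
    impulsive_gain: float = 0.10
    miss_gain: float = 0.10
    psychometric: tuple[float, ...] = (0.45, 0.60, 0.75, 0.85)
    cloud_penalty: float = 0.10      # detection loss under the tone cloud
    cloud_impulse: float = 0.06      # impulsivity increase under the cloud
    aid_boost: float = 0.10          # detection gain from the visual aid
    coupling: float = 0.7
    proxy_noise_sd: float | None = None  # default: sqrt(1 - coupling^2)
    impulsive_lick_tau: float = 1.0  # s, exponential lick-latency scale
    rt_mu: float = -0.9              # lognormal location of hit RT (s)
    rt_sigma: float = 0.4
    strategy: str = "explorer"

    def __post_init__(self) -> None:
        if not 0.0 < self.engagement_rho < 1.0:
            raise ValueError("engagement_rho must lie in (0, 1)")
        base = [self.impulsive_base, *self.psychometric]
        if any(p < 0.0 or p > 1.0 for p in base):
            raise ValueError("base outcome probabilities must lie in [0, 1]")
        if not 0.0 <= self.coupling <= 1.0:
            raise ValueError("coupling must lie in [0, 1]")


def explorer_params(**overrides) -> AgentParams:
    """Preset: engages all trial types, impulses often, strongly coupled."""
    p = AgentParams(
        impulsive_base=0.20,
        impulsive_gain=0.12,
        miss_gain=0.12,
        psychometric=(0.45, 0.60, 0.75, 0.85),
        cloud_penalty=0.12,
        cloud_impulse=0.08,
        aid_boost=0.08,
        coupling=0.8,
        strategy="explorer",
    )
    return replace(p, **overrides)


def exploiter_params(**overrides) -> AgentParams:
    """Preset: attends only salient cues, rarely impulses, weakly coupled."""
    p = AgentParams(
        impulsive_base=0.05,
        impulsive_gain=0.03,
        miss_gain=0.04,
        psychometric=(0.15, 0.30, 0.70, 0.90),
        cloud_penalty=0.04,
        cloud_impulse=0.01,
        aid_boost=0.25,
        coupling=0.25,
        strategy="exploiter",
    )
    return replace(p, **overrides)


def _latents(n: int, params: AgentParams, rng: np.random.Generator
             ) -> tuple[np.ndarray, np.ndarray]:
    """AR(1) engagement and the negatively coupled ACCp proxy, unit variance."""
    rho, sd = params.engagement_rho, params.engagement_sd
    innov = rng.standard_normal(n) * sd * np.sqrt(1.0 - rho**2)
    e = np.empty(n)
    e[0] = rng.standard_normal() * sd
    for t in range(1, n):
        e[t] = rho * e[t - 1] + innov[t]
    noise_sd = (np.sqrt(max(0.0, 1.0 - params.coupling**2))
                if params.proxy_noise_sd is None else params.proxy_noise_sd)
    b = -params.coupling * e / sd + noise_sd * rng.standard_normal(n)
    return e, b


def simulate_agent(trials: pd.DataFrame, params: AgentParams,
                   seed: int = 0) -> pd.DataFrame:
    """Roll the agent over a stimulus table, adding latents and outcomes.

    Adds columns ``engagement`` (e_t), ``accp_pre`` (latent ACCp proxy b_t),
    ``outcome`` (impulsive / hit / miss), ``lick_s`` (first-lick time
    relative to trial onset; NaN on miss), ``rt_s`` (reaction time: from the
    Go cue on hits, from trial onset on impulsive errors) and ``cue_s``
    (Go-cue time relative to trial onset, i.e. the delay).
    """
    required = {"intensity", "cloud", "aid", "delay_s"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"trial table lacks stimulus columns: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    n = len(trials)
    e, b = _latents(n, params, rng)

    intens = trials["intensity"].to_numpy()
    levels = sorted(np.unique(intens))
    if len(levels) > len(params.psychometric):
        raise ValueError("more intensity levels than psychometric entries")
    base_det = np.asarray(params.psychometric)[
        np.searchsorted(levels, intens)]
    cloud = trials["cloud"].to_numpy(dtype=bool)
    aid = trials["aid"].to_numpy(dtype=bool)
    delay = trials["delay_s"].to_numpy(dtype=float)

    p_imp = np.clip(params.impulsive_base - params.impulsive_gain * b
                    + params.cloud_impulse * cloud, 0.0, 1.0)
    p_hit = np.clip(base_det + params.aid_boost * aid
                    - params.cloud_penalty * cloud - params.miss_gain * b,
                    0.0, 1.0)

    u = rng.random(n)
    impulsive = u < p_imp
    hit = ~impulsive & (rng.random(n) < p_hit)

    outcome = np.where(impulsive, "impulsive", np.where(hit, "hit", "miss"))
    lick = np.full(n, np.nan)
    rt = np.full(n, np.nan)

    # impulsive lick: truncated-exponential latency within (0, delay]
    tau = params.impulsive_lick_tau
    ui = rng.random(impulsive.sum())
    d = delay[impulsive]
    lick_imp = -tau * np.log1p(-ui * (1.0 - np.exp(-d / tau)))
    lick[impulsive] = lick_imp
    rt[impulsive] = lick_imp

    # hit lick: lognormal RT after the Go cue, truncated to the window
    nh = int(hit.sum())
    rt_hit = np.minimum(rng.lognormal(params.rt_mu, params.rt_sigma, nh), 1.5)
    rt[hit] = rt_hit
    lick[hit] = delay[hit] + rt_hit

    out = trials.copy()
    out["engagement"] = e
    out["accp_pre"] = b
    out["outcome"] = outcome
    out["cue_s"] = delay
    out["lick_s"] = lick
    out["rt_s"] = rt
    out["strategy"] = params.strategy
    return out
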