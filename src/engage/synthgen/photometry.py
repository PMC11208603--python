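"""Synthetic two-channel fiber photometry with known event kernels.

The calcium channel is a multiplicative model: a slow bleaching drift scaled
by (1 + the summed kernel responses to labeled event trains), plus sensor
noise and optional motion artifacts. The isosbestic channel shares the drift
shape and the artifacts but carries no kernel response, mirroring its role
as a calcium-independent motion control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from engage.types import PhotometrySession, Trace


def calcium_kernel(rate: float, duration: float = 2.0, amplitude: float = 1.0,
                   tau_rise: float = 0.1, tau_decay: float = 0.6) -> np.ndarray:
    """Double-exponential impulse response, peak-normalized then scaled.

    A generic GCaMP-like kernel: fast rise, slow decay, ``amplitude`` in
    fractional (ΔF/F-like) units.
    """
    t = np.arange(int(round(duration * rate))) / rate
    k = np.exp(-t / tau_decay) - np.exp(-t / tau_rise)
    peak = k.max()
    if peak <= 0:
        raise ValueError("degenerate kernel (check time constants)")
    return amplitude * k / peak


@dataclass
class PhotometryGenConfig:
    """Generation parameters for a photometry session.

    ``rate`` defaults to 100 Hz, a desk-scale stand-in for the 1017.25-Hz
    acquisition rate (the signal band is < 4 Hz, so 100 Hz is comfortably
    oversampled); set ``rate=1017.25`` to mirror acquisition. ``kernels``
    maps event labels to impulse-response arrays sampled at ``rate``.
    """

    rate: float = 100.0
    kernels: dict = field(default_factory=dict)
    drift_dc: float = 10.0
    drift_amp: float = 2.0
    drift_tau: float = 1200.0  # s, bleaching time constant
    noise_sd: float = 0.02     # in raw-F units
    artifact_rate: float = 0.0  # shared transients per hour
    artifact_amp: float = 1.0
    led_cycle: tuple[float, float] | None = None  # (on_min, off_min), e.g. (90, 30)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate <= 8.0:
            raise ValueError("rate must exceed twice the 4-Hz signal band")


def _drift(t: np.ndarray, cfg: PhotometryGenConfig) -> np.ndarray:
    return cfg.drift_dc + cfg.drift_amp * np.exp(-t / cfg.drift_tau)


def _led_blocks(duration: float, cycle: tuple[float, float] | None
                ) -> list[tuple[float, float]]:
    if cycle is None:
        return [(0.0, duration)]
    on_s, off_s = cycle[0] * 60.0, cycle[1] * 60.0
    blocks, t = [], 0.0
    while t < duration:
        blocks.append((t, min(t + on_s, duration)))
        t += on_s + off_s
    return blocks


def simulate_photometry(events: dict[str, np.ndarray],
                        gen: PhotometryGenConfig,
                        duration_s: float | None = None) -> PhotometrySession:
    """Synthesize calcium + isosbestic traces from labeled event times.

    Parameters
    ----------
    events
        Mapping of event label → array of event times (s). Labels present in
        ``gen.kernels`` drive a kernel response in the calcium channel.
    duration_s
        Session length; default covers the last event plus the longest
        kernel plus 5 s.
    """
    rng = np.random.default_rng(gen.seed)
    max_ev = max((np.max(v) for v in events.values() if len(v)), default=0.0)
    max_k = max((len(k) / gen.rate for k in gen.kernels.values()), default=0.0)
    if duration_s is None:
        duration_s = max_ev + max_k + 5.0
    n = int(round(duration_s * gen.rate))
    if any(len(k) > n for k in gen.kernels.values()):
        raise ValueError("kernel longer than session")
    for name, times in events.items():
        times = np.asarray(times, dtype=float)
        if len(times) and (times.min() < 0 or times.max() > duration_s):
            raise ValueError(f"event times for {name!r} outside session span")
    t = np.arange(n) / gen.rate

    response = np.zeros(n)
    for name, kernel in gen.kernels.items():
        times = np.asarray(events.get(name, ()), dtype=float)
        if not len(times):
            continue
        train = np.zeros(n)
        idx = np.clip(np.round(times * gen.rate).astype(int), 0, n - 1)
        np.add.at(train, idx, 1.0)
        response += np.convolve(train, kernel)[:n]

    drift = _drift(t, gen)
    calcium = drift * (1.0 + response)
    isosbestic = drift.copy()
    if gen.noise_sd > 0:
        calcium = calcium + rng.normal(0.0, gen.noise_sd, n)
        isosbestic = isosbestic + rng.normal(0.0, gen.noise_sd, n)

    if gen.artifact_rate > 0:
        n_art = rng.poisson(gen.artifact_rate * duration_s / 3600.0)
        art = np.zeros(n)
        width = max(1, int(round(0.2 * gen.rate)))
        shape = np.exp(-np.arange(width) / (0.05 * gen.rate))
        for _ in range(n_art):
            i0 = rng.integers(0, max(1, n - width))
            amp = gen.artifact_amp * rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 1.5)
            art[i0:i0 + width] += amp * shape
        calcium = calcium + art
        isosbestic = isosbestic + art

    blocks = _led_blocks(duration_s, gen.led_cycle)
    if gen.led_cycle is not None:
        mask = np.zeros(n, dtype=bool)
        for s, e in blocks:
            mask[int(round(s * gen.rate)):int(round(e * gen.rate))] = True
        calcium = np.where(mask, calcium, 0.0)
        isosbestic = np.where(mask, isosbestic, 0.0)

    return PhotometrySession(
        calcium=Trace(calcium, gen.rate, channel_role="calcium"),
        isosbestic=Trace(isosbestic, gen.rate, channel_role="isosbestic"),
        led_blocks=blocks,
        meta={"events": {k: np.asarray(v, dtype=float) for k, v in events.items()},
              "config": gen},
    )
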