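"""Synthetic epidural volley recordings.

Cortical stimulation through a multi-contact probe evokes a descending
corticospinal volley recorded at the spinal dorsum: a direct (D) wave from
axonal activation whose latency does not depend on stimulus depth, followed
by the first indirect (I1) trans-synaptic wave whose latency shortens as
the stimulus moves deeper (superficial stimulation recruits corticospinal
cells ~0.5 ms later).  Traces are modelled as Gaussian bumps on the
configured latencies plus white noise; amplitude grows mildly with stimulus
intensity while latencies stay fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .._rng import as_rng
from ..errors import ConfigError

__all__ = ["VolleySimConfig", "VolleySweep", "default_depth_map", "simulate_volley_sweep"]


def default_depth_map(
    n_contacts: int = 16,
    spacing_um: float = 150.0,
    d_latency: float = 2.0,
    shallow_interval: float = 1.9,
    deep_interval: float = 1.4,
) -> dict[float, float]:
    """Default I1-latency map over probe contact depths (µm below surface).

    The D-to-I1 interval grades linearly from `shallow_interval` at the
    surface to `deep_interval` at the deepest contact, so the shallowest
    I1 is 0.5 ms later than the deepest by default and every interval lies
    within the physiological 1.4-2.0 ms range.
    """
    depths = np.arange(n_contacts) * spacing_um
    span = depths[-1] - depths[0]
    return {
        float(d): d_latency + shallow_interval
        - (shallow_interval - deep_interval) * (d / span)
        for d in depths
    }


@dataclass(frozen=True)
class VolleySimConfig:
    """Epidural volley simulator parameters (times in ms, rate in kHz)."""

    d_latency: float = 2.0
    i_wave_period: float = 1.7
    i1_latency_by_depth: Mapping[float, float] = field(default_factory=default_depth_map)
    noise_sd: float = 0.05
    sampling_rate_khz: float = 25.0
    duration: float = 10.0
    d_amplitude: float = 1.0
    i1_amplitude: float = 0.8
    wave_sigma: float = 0.12
    intensity_gain: float = 0.05  # fractional amplitude growth per mA above minimum
    block_latency_jitter_sd: float = 0.02  # per-block timing drift, ms

    def __post_init__(self):
        if self.d_latency <= 0:
            raise ConfigError("d_latency must be positive")
        if not (1.4 <= self.i_wave_period <= 2.0):
            raise ConfigError("i_wave_period must lie in [1.4, 2.0] ms")
        depths = sorted(self.i1_latency_by_depth)
        lats = [self.i1_latency_by_depth[d] for d in depths]
        if any(b > a for a, b in zip(lats, lats[1:])):
            raise ConfigError("i1_latency_by_depth must be non-increasing with depth")


@dataclass
class VolleySweep:
    """Simulated volley traces per (depth, intensity): arrays (n_trials, n_samples)."""

    t: np.ndarray  # ms post-stimulus
    traces: dict[tuple[float, float], np.ndarray]
    config: VolleySimConfig

    def mean_trace(self, depth: float, intensity: float) -> np.ndarray:
        return self.traces[(depth, intensity)].mean(axis=0)


def simulate_volley_sweep(
    config: VolleySimConfig,
    depths: Sequence[float] | None = None,
    intensities: Sequence[float] = (2.0, 2.5, 3.0, 4.0, 5.0),
    n_trials: int = 100,
    seed=None,
) -> VolleySweep:
    """Simulate epidural volleys for each (stimulus depth, intensity) pair.

    Depths must be keys of the configured I1 latency map.  The D wave sits
    at `d_latency` at every depth; the I1 wave follows the map.  Each
    (depth, intensity) block carries a small common timing drift
    (`block_latency_jitter_sd`), mimicking slow preparation drift between
    recording blocks.  Averaging the `n_trials` noisy repeats reduces the
    noise SD by sqrt(n_trials).
    """
    rng = as_rng(seed)
    if depths is None:
        depths = sorted(config.i1_latency_by_depth)
    for d in depths:
        if d not in config.i1_latency_by_depth:
            raise ConfigError(f"unknown depth key: {d!r}")
    n = int(round(config.duration * config.sampling_rate_khz)) + 1
    t = np.arange(n) / config.sampling_rate_khz
    i_min = min(intensities)
    traces: dict[tuple[float, float], np.ndarray] = {}
    for depth in depths:
        i1_lat = config.i1_latency_by_depth[depth]
        for intensity in intensities:
            drift = (
                rng.normal(0.0, config.block_latency_jitter_sd)
                if config.block_latency_jitter_sd > 0
                else 0.0
            )
            clean = config.d_amplitude * np.exp(
                -0.5 * ((t - config.d_latency - drift) / config.wave_sigma) ** 2
            ) + config.i1_amplitude * np.exp(
                -0.5 * ((t - i1_lat - drift) / config.wave_sigma) ** 2
            )
            gain = 1.0 + config.intensity_gain * (intensity - i_min)
            noise = (
                rng.normal(0.0, config.noise_sd, size=(n_trials, n))
                if config.noise_sd > 0
                else np.zeros((n_trials, n))
            )
            traces[(float(depth), float(intensity))] = gain * clean + noise
    return VolleySweep(t=t, traces=traces, config=config)
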