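"""Synthetic subthreshold EPSP traces.

Layer-5 pyramidal cells receive excitatory input either on basal dendrites
(stimulation nearby, in deep layers) or on apical dendrites (stimulation of
superficial layers 1/2).  Dendritic cable filtering makes the apical EPSP
rise more slowly, so its somatic peak occurs later even though the two
inputs are of similar amplitude.  The simulator represents each compound
EPSP with a difference-of-exponentials kernel

    V(t) = A * [exp(-(t - t0)/tau_decay) - exp(-(t - t0)/tau_rise)] / k

for t >= t0, scaled by `k` so the peak equals the configured amplitude `A`.
The analytic peak time of the kernel (relative to onset `t0`) is

    t* = tau_rise * tau_decay / (tau_decay - tau_rise) * ln(tau_decay/tau_rise)

which degenerates to the alpha-function peak `t* -> tau` as
`tau_rise -> tau_decay`.

The default superficial/deep kinetics pair is calibrated so that the
population-mean peak-time difference (superficial minus deep) equals
2.0 ms; the onset split between the two sites is a free choice (the stimulus
artifact obscures onsets in real recordings) and defaults to 0.2 ms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
from scipy.optimize import brentq

from .._rng import as_rng
from ..errors import ConfigError

__all__ = [
    "EpspKinetics",
    "kernel_peak_offset",
    "default_kinetics",
    "simulate_epsp_trace",
    "simulate_epsp_population",
]

Site = Literal["superficial", "deep"]

#: Default calibration constants (ms / mV).
DEFAULT_DECAY_TAU = 15.0
DEFAULT_DEEP_RISE_TAU = 1.5
DEFAULT_DEEP_ONSET = 1.0
DEFAULT_ONSET_SPLIT = 0.2  # superficial onset minus deep onset
DEFAULT_AMPLITUDE = 6.0
DEFAULT_PEAK_SHIFT = 2.0  # superficial minus deep somatic peak time


@dataclass(frozen=True)
class EpspKinetics:
    """Kinetics of a compound EPSP evoked from one stimulation site.

    Parameters
    ----------
    amplitude : float
        Peak depolarization, mV (>= 0).
    rise_tau, decay_tau : float
        Rise and decay time constants, ms; ``0 < rise_tau < decay_tau``.
    onset_latency : float
        Delay from the stimulus to the start of the EPSP, ms (>= 0).
    site : {"superficial", "deep"}
        Which layers were stimulated.
    """

    amplitude: float
    rise_tau: float
    decay_tau: float
    onset_latency: float
    site: Site = "deep"

    def __post_init__(self):
        if self.amplitude < 0:
            raise ConfigError("EPSP amplitude must be >= 0")
        if not (0 < self.rise_tau < self.decay_tau):
            raise ConfigError("require 0 < rise_tau < decay_tau")
        if self.onset_latency < 0:
            raise ConfigError("onset_latency must be >= 0")

    @property
    def peak_time(self) -> float:
        """Analytic somatic peak time relative to the stimulus, ms."""
        return self.onset_latency + kernel_peak_offset(self.rise_tau, self.decay_tau)


def kernel_peak_offset(rise_tau: float, decay_tau: float) -> float:
    """Peak time of the difference-of-exponentials kernel relative to onset."""
    return (
        rise_tau * decay_tau / (decay_tau - rise_tau) * math.log(decay_tau / rise_tau)
    )


def _rise_tau_for_peak_offset(target: float, decay_tau: float) -> float:
    """Solve for the rise constant giving a desired onset-to-peak time."""
    lo, hi = 1e-4, decay_tau * (1 - 1e-9)
    f = lambda r: kernel_peak_offset(r, decay_tau) - target
    return brentq(f, lo, hi, xtol=1e-10)


def default_kinetics(
    peak_shift: float = DEFAULT_PEAK_SHIFT,
    onset_split: float = DEFAULT_ONSET_SPLIT,
    amplitude: float = DEFAULT_AMPLITUDE,
) -> dict[Site, EpspKinetics]:
    """Default superficial/deep kinetics pair.

    The deep (basal-input) EPSP uses the fast default rise constant; the
    superficial (apical-input) rise constant is solved so that the analytic
    peak-time difference equals ``peak_shift`` (default 2.0 ms), of which
    ``onset_split`` is carried by a later superficial onset and the rest by
    slower rise kinetics.  Amplitudes are equal between sites.
    """
    deep = EpspKinetics(
        amplitude=amplitude,
        rise_tau=DEFAULT_DEEP_RISE_TAU,
        decay_tau=DEFAULT_DECAY_TAU,
        onset_latency=DEFAULT_DEEP_ONSET,
        site="deep",
    )
    target_offset = kernel_peak_offset(deep.rise_tau, deep.decay_tau) + peak_shift - onset_split
    if target_offset <= 0:
        raise ConfigError("peak_shift/onset_split combination is infeasible")
    sup_rise = _rise_tau_for_peak_offset(target_offset, DEFAULT_DECAY_TAU)
    superficial = EpspKinetics(
        amplitude=amplitude,
        rise_tau=sup_rise,
        decay_tau=DEFAULT_DECAY_TAU,
        onset_latency=DEFAULT_DEEP_ONSET + onset_split,
        site="superficial",
    )
    return {"deep": deep, "superficial": superficial}


def epsp_waveform(t: np.ndarray, kinetics: EpspKinetics) -> np.ndarray:
    """Noiseless EPSP voltage (mV) on an arbitrary time grid (ms)."""
    v = np.zeros_like(t, dtype=float)
    if kinetics.amplitude == 0:
        return v
    tt = t - kinetics.onset_latency
    m = tt > 0
    raw = np.exp(-tt[m] / kinetics.decay_tau) - np.exp(-tt[m] / kinetics.rise_tau)
    peak = math.exp(
        -kernel_peak_offset(kinetics.rise_tau, kinetics.decay_tau) / kinetics.decay_tau
    ) - math.exp(
        -kernel_peak_offset(kinetics.rise_tau, kinetics.decay_tau) / kinetics.rise_tau
    )
    v[m] = kinetics.amplitude * raw / peak
    return v


def simulate_epsp_trace(
    kinetics: EpspKinetics,
    duration: float = 100.0,
    noise_sd: float = 0.0,
    seed=None,
    sampling_rate_khz: float = 25.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one averaged EPSP trace.

    Returns ``(t, v)``: time in ms from the stimulus (t=0) and voltage in mV
    relative to a 0 mV baseline.  Deterministic given `seed`; with
    ``noise_sd=0`` the peak equals ``kinetics.amplitude`` to within grid
    quantization (< 1 %).
    """
    if duration <= 0:
        raise ConfigError("duration must be positive")
    n = int(round(duration * sampling_rate_khz)) + 1
    t = np.arange(n) / sampling_rate_khz
    v = epsp_waveform(t, kinetics)
    if noise_sd > 0:
        v = v + as_rng(seed).normal(0.0, noise_sd, size=n)
    return t, v


def simulate_epsp_population(
    n_cells: int,
    kinetics: dict[Site, EpspKinetics] | None = None,
    duration: float = 100.0,
    noise_sd: float = 0.05,
    rise_cv: float = 0.06,
    amplitude_cv: float = 0.15,
    onset_jitter_sd: float = 0.05,
    seed=None,
    sampling_rate_khz: float = 25.0,
) -> dict[Site, list[tuple[np.ndarray, np.ndarray]]]:
    """Simulate per-cell averaged EPSP traces for both stimulation sites.

    Cell-to-cell variability multiplies rise constants and amplitudes by
    lognormal factors (shared between sites within a cell, as dendritic
    geometry is a cell property) and jitters onsets.  Returns, per site, a
    list of ``(t, v)`` traces, one per cell.
    """
    if n_cells < 1:
        raise ConfigError("n_cells must be >= 1")
    kin = default_kinetics() if kinetics is None else kinetics
    rng = as_rng(seed)
    out: dict[Site, list[tuple[np.ndarray, np.ndarray]]] = {s: [] for s in kin}
    for _ in range(n_cells):
        rise_f = rng.lognormal(0.0, rise_cv)
        amp_f = rng.lognormal(0.0, amplitude_cv)
        onset_d = rng.normal(0.0, onset_jitter_sd)
        for site, k in kin.items():
            cell_k = replace(
                k,
                rise_tau=k.rise_tau * rise_f,
                amplitude=k.amplitude * amp_f,
                onset_latency=max(0.0, k.onset_latency + onset_d),
            )
            out[site].append(
                simulate_epsp_trace(
                    cell_k, duration, noise_sd, rng, sampling_rate_khz
                )
            )
    return out
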