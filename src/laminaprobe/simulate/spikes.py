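"""Synthetic evoked spike trains from a population of layer-5 cells.

Spike generation follows the threshold-crossing picture behind the EPSP
simulator: a stimulus evokes a compound EPSP, and the cell fires when the
noiseless deep-input EPSP crosses the cell's spike threshold.  The extra
trans-synaptic delay seen with superficial stimulation is applied as an
explicit, calibrated shift (`superficial_extra_delay`, default 0.6 ms)
rather than re-derived from kinetics, because it is the quantity the
simulator must reproduce.  Cyclical re-excitation through local circuits
produces later response peaks at multiples of `i_wave_period`; these later
peaks share their timing between the two stimulation sites (only the first
wave distinguishes superficial from deep input).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

from .._rng import as_rng
from ..errors import ConfigError
from .epsp import EpspKinetics, Site, default_kinetics, epsp_waveform

__all__ = ["CellSimConfig", "CellSpikes", "SpikeTrainSet", "simulate_population_spikes"]


@dataclass(frozen=True)
class CellSimConfig:
    """Parameters of the evoked-spiking simulator.

    `spike_threshold` is in mV above rest; `threshold_jitter_sd` spreads
    thresholds across cells; `cell_latency_sd` spreads base response
    latencies across cells (conduction and synaptic-distance
    heterogeneity, shared between stimulation sites within a cell);
    `latency_jitter_sd` jitters individual spike times across trials.
    `superficial_extra_delay` is the calibrated
    first-spike latency shift for superficial relative to deep stimulation.
    Later response waves recur at `i_wave_period` with per-wave emission
    probabilities `spike_probs` (first wave first).
    """

    kinetics: Mapping[Site, EpspKinetics] = field(default_factory=default_kinetics)
    spike_threshold: float = 4.0
    threshold_jitter_sd: float = 0.5
    cell_latency_sd: float = 0.1
    latency_jitter_sd: float = 0.25
    n_trials: int = 200
    superficial_extra_delay: float = 0.6
    i_wave_period: float = 1.7
    spike_probs: Sequence[float] = (0.9, 0.5, 0.25)

    def __post_init__(self):
        if self.n_trials < 1:
            raise ConfigError("n_trials must be >= 1")
        if self.threshold_jitter_sd < 0 or self.latency_jitter_sd < 0:
            raise ConfigError("jitter SDs must be >= 0")
        if self.superficial_extra_delay < 0:
            raise ConfigError("superficial_extra_delay must be >= 0")
        if not (1.0 <= self.i_wave_period <= 3.0):
            raise ConfigError("i_wave_period outside plausible range")


@dataclass
class CellSpikes:
    """Spike trains of one cell: per site, one array of spike times per trial."""

    trains: dict[Site, list[np.ndarray]]
    subthreshold: bool = False
    first_spike_latency: dict[Site, float] | None = None


@dataclass
class SpikeTrainSet:
    """Evoked spike trains for a population of cells.

    Spike times are in ms relative to the stimulus.  `n_trials` records the
    per-site trial count used for PSTH normalization.
    """

    cells: list[CellSpikes]
    n_trials: dict[Site, int]

    @property
    def sites(self) -> tuple[Site, ...]:
        return tuple(self.n_trials)

    def spiking_cells(self) -> list[CellSpikes]:
        return [c for c in self.cells if not c.subthreshold]


def _threshold_crossing(kinetics: EpspKinetics, threshold: float) -> float | None:
    """First time (ms post-stimulus) the noiseless EPSP crosses `threshold`."""
    if threshold <= 0:
        return kinetics.onset_latency
    if threshold >= kinetics.amplitude:
        return None
    peak_t = kinetics.peak_time
    f = lambda t: epsp_waveform(np.array([t]), kinetics)[0] - threshold
    return float(brentq(f, kinetics.onset_latency + 1e-9, peak_t, xtol=1e-9))


def simulate_population_spikes(
    config: CellSimConfig, n_cells: int, seed=None
) -> SpikeTrainSet:
    """Simulate evoked spike trains for `n_cells` layer-5 cells.

    Each cell draws a spike threshold; the deep-stimulation first-spike
    latency is the threshold crossing of the deep EPSP, and the superficial
    latency adds `superficial_extra_delay`.  Each trial emits wave-`k`
    spikes with probability ``spike_probs[k]`` at the wave time plus
    Gaussian latency jitter; waves beyond the first occur at
    ``deep_latency + k * i_wave_period`` for both sites.  Cells whose
    threshold exceeds the EPSP peak are flagged subthreshold and emit no
    spikes.
    """
    if n_cells < 2:
        raise ConfigError("n_cells must be >= 2")
    rng = as_rng(seed)
    deep_kin = config.kinetics["deep"]
    cells: list[CellSpikes] = []
    for _ in range(n_cells):
        theta = config.spike_threshold + rng.normal(0.0, config.threshold_jitter_sd)
        cell_offset = rng.normal(0.0, config.cell_latency_sd)
        base = _threshold_crossing(deep_kin, theta)
        if base is None:
            cells.append(
                CellSpikes(
                    trains={s: [np.empty(0) for _ in range(config.n_trials)]
                            for s in config.kinetics},
                    subthreshold=True,
                )
            )
            continue
        base = max(0.0, base + cell_offset)
        first = {
            "deep": base,
            "superficial": base + config.superficial_extra_delay,
        }
        trains: dict[Site, list[np.ndarray]] = {}
        for site in config.kinetics:
            site_trains = []
            for _trial in range(config.n_trials):
                times = []
                for k, p in enumerate(config.spike_probs):
                    if rng.random() < p:
                        t0 = first[site] if k == 0 else base + k * config.i_wave_period
                        times.append(
                            max(0.0, t0 + rng.normal(0.0, config.latency_jitter_sd))
                        )
                site_trains.append(np.sort(np.asarray(times)))
            trains[site] = site_trains
        cells.append(CellSpikes(trains=trains, subthreshold=False,
                                first_spike_latency=first))
    return SpikeTrainSet(
        cells=cells, n_trials={s: config.n_trials for s in config.kinetics}
    )
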