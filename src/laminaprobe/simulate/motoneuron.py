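"""Motoneuron-pool recruitment model for H-reflex conditioning by TMS.

The conditioning principle: peripheral nerve stimulation (PNS) sends an
afferent volley that reaches the spinal motoneuron pool at a fixed time and
recruits the most excitable fraction of the pool, producing an H-reflex in
the EMG.  A TMS pulse launches a sequence of descending corticospinal
volley components; a component whose spinal arrival falls inside the
temporal-summation window just before/at the afferent arrival adds to the
afferent drive and recruits extra motoneurons, facilitating the H-reflex.

Delay convention: a TMS-PNS delay of ``d`` ms means TMS fires at
``PNS time - d``; negative delays mean TMS is triggered *after* PNS.  The
fastest descending component (circuit ``deep_early``, arrival offset 0)
first coincides with the afferent volley at the delay

    EFD0_true = corticospinal_conduction - afferent_arrival

so with the defaults (10.5 ms conduction, 14.0 ms afferent arrival) the
true earliest facilitation delay is -3.5 ms.  The ``superficial_late``
component follows 0.6 ms later, and later I waves after that; as the delay
becomes less negative, successively more components coincide and
recruitment grows (temporal summation).

Each motoneuron has a threshold drawn from a truncated normal distribution
in arbitrary excitability units; it fires when afferent plus coincident
descending drive (plus trial noise) exceeds its threshold.  Fired units add
a biphasic Hanning-windowed motor-unit action potential (MUAP) to the EMG
at the afferent arrival plus a per-unit efferent conduction delay.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.optimize import brentq

from .._rng import as_rng
from ..errors import CalibrationError, ConfigError

__all__ = [
    "VolleyComponent",
    "MotoneuronPoolConfig",
    "EmgTrace",
    "MotoneuronPool",
    "calibrate_afferent_strength",
    "simulate_conditioning_trial",
    "simulate_efd_session",
]

Circuit = Literal["deep_early", "superficial_late", "later_waves"]


@dataclass(frozen=True)
class VolleyComponent:
    """One descending volley component.

    `arrival_offset` is the spinal arrival time relative to the fastest
    component (ms); `strength` is the excitatory drive it contributes, in
    the same excitability units as motoneuron thresholds.
    """

    arrival_offset: float
    strength: float
    circuit: Circuit

    def __post_init__(self):
        if self.strength < 0:
            raise ConfigError("volley strength must be >= 0")
        if self.arrival_offset < 0:
            raise ConfigError("arrival_offset must be >= 0")


DEFAULT_VOLLEYS: tuple[VolleyComponent, ...] = (
    VolleyComponent(0.0, 0.15, "deep_early"),
    VolleyComponent(0.6, 0.10, "superficial_late"),
    VolleyComponent(1.7, 0.12, "later_waves"),
    VolleyComponent(3.4, 0.10, "later_waves"),
)


@dataclass(frozen=True)
class MotoneuronPoolConfig:
    """Motoneuron pool and EMG parameters.

    Thresholds are truncated-normal in arbitrary excitability units.
    ``afferent_strength=None`` means "calibrate so the unconditioned
    recruitment fraction (H/Mmax) sits at the midpoint of
    `h_over_mmax_band`".  Times are ms, EMG in µV, sampling in kHz.
    """

    n_units: int = 120
    threshold_mean: float = 1.0
    threshold_sd: float = 0.3
    threshold_floor: float = 0.05
    afferent_strength: float | None = None
    afferent_arrival: float = 14.0
    corticospinal_conduction: float = 10.5
    volley_components: tuple[VolleyComponent, ...] = DEFAULT_VOLLEYS
    summation_window: float = 2.0
    efferent_delay_mean: float = 3.5
    efferent_delay_sd: float = 0.3
    muap_duration: float = 3.0
    emg_noise_sd: float = 3.0
    mmax_amplitude: float = 2000.0
    m_wave_fraction: float = 0.08
    m_wave_latency: float = 6.5
    drive_noise_sd: float = 0.04
    unit_noise_sd: float = 0.02
    h_over_mmax_band: tuple[float, float] = (0.15, 0.25)
    trace_duration: float = 100.0
    stimulus_time: float = 55.0
    sampling_rate_khz: float = 10.0

    def __post_init__(self):
        if self.n_units < 50:
            raise ConfigError("n_units must be >= 50")
        if self.summation_window <= 0:
            raise ConfigError("summation_window must be positive")
        if self.stimulus_time < 50.0:
            raise ConfigError("need >= 50 ms of pre-stimulus baseline")

    @property
    def true_efd0(self) -> float:
        """Delay at which the fastest descending component first coincides."""
        return self.corticospinal_conduction - self.afferent_arrival + min(
            c.arrival_offset for c in self.volley_components
        )

    def threshold_distribution(self) -> stats.rv_frozen:
        a = (self.threshold_floor - self.threshold_mean) / self.threshold_sd
        return stats.truncnorm(a, np.inf, loc=self.threshold_mean, scale=self.threshold_sd)


def calibrate_afferent_strength(
    config: MotoneuronPoolConfig, target: float | None = None
) -> float:
    """Root-find the afferent drive giving a target unconditioned H/Mmax.

    The expected recruitment fraction of the pool under afferent drive `S`
    is the threshold CDF at `S`; the default target is the midpoint of the
    configured H/Mmax band (15-25 % -> 20 %).
    """
    if target is None:
        target = sum(config.h_over_mmax_band) / 2
    dist = config.threshold_distribution()
    f = lambda s: dist.cdf(s) - target
    lo = config.threshold_floor
    hi = config.threshold_mean + 8 * config.threshold_sd
    try:
        return float(brentq(f, lo, hi, xtol=1e-10))
    except ValueError as e:  # pragma: no cover - defensive
        raise CalibrationError(f"afferent calibration failed: {e}") from e


@dataclass
class EmgTrace:
    """Unrectified surface EMG at a fixed sampling rate.

    `samples` are µV; markers are sample indices into `samples`.
    """

    samples: np.ndarray
    sampling_rate_hz: float = 10_000.0
    stimulus_sample: int = 0
    tms_sample: int | None = None
    fixation_offset_sample: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.samples)
        for name in ("stimulus_sample", "tms_sample", "fixation_offset_sample"):
            v = getattr(self, name)
            if v is not None and not (0 <= v < n):
                raise ConfigError(f"{name} outside trace")

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sampling_rate_hz

    def time_ms(self) -> np.ndarray:
        """Time axis in ms relative to the stimulus marker."""
        return (np.arange(len(self.samples)) - self.stimulus_sample) * self.dt_ms


def _muap_kernel(n_samples: int) -> np.ndarray:
    """Biphasic MUAP: one sine cycle under a Hanning window, unit peak."""
    x = np.sin(2 * np.pi * np.arange(n_samples) / n_samples)
    k = x * np.hanning(n_samples)
    return k / np.abs(k).max()


class MotoneuronPool:
    """A realized pool: sampled thresholds, efferent delays and MUAP shapes.

    Thresholds and per-unit conduction delays are drawn once (per simulated
    subject); trial-to-trial variability enters through common drive noise
    and small per-unit noise in :meth:`recruit`.
    """

    def __init__(self, config: MotoneuronPoolConfig, seed=None):
        self.config = config
        rng = as_rng(seed)
        dist = config.threshold_distribution()
        self.thresholds = dist.rvs(size=config.n_units, random_state=rng)
        self.efferent_delays = rng.normal(
            config.efferent_delay_mean, config.efferent_delay_sd, size=config.n_units
        ).clip(min=0.5)
        self.afferent_strength = (
            config.afferent_strength
            if config.afferent_strength is not None
            else calibrate_afferent_strength(config)
        )
        self.unit_amplitude = config.mmax_amplitude / config.n_units
        n_k = max(4, int(round(config.muap_duration * config.sampling_rate_khz)))
        self.muap = _muap_kernel(n_k)

    @property
    def true_onset_ms(self) -> float:
        """Earliest possible H-reflex EMG onset, ms post-stimulus."""
        return self.config.afferent_arrival + float(self.efferent_delays.min())

    def coincident_drive(self, delay: float | None, gains: Mapping[str, float] | None) -> float:
        """Summed descending drive coinciding with the afferent volley."""
        if delay is None:
            return 0.0
        cfg = self.config
        gains = gains or {}
        drive = 0.0
        for comp in cfg.volley_components:
            arrival = -delay + cfg.corticospinal_conduction + comp.arrival_offset
            # 1 ns guard so grid delays landing exactly on the coincidence
            # boundary are counted despite float rounding
            eps = 1e-9
            if (cfg.afferent_arrival - cfg.summation_window - eps
                    <= arrival <= cfg.afferent_arrival + eps):
                g = gains.get(comp.circuit, 1.0)
                if g <= 0:
                    raise ConfigError("gains must be > 0")
                drive += comp.strength * g
        return drive

    def recruit(
        self, delay: float | None, gains: Mapping[str, float] | None, rng
    ) -> np.ndarray:
        """Boolean mask of motoneurons fired on one trial."""
        cfg = self.config
        drive = (
            self.afferent_strength
            + self.coincident_drive(delay, gains)
            + rng.normal(0.0, cfg.drive_noise_sd)
            + rng.normal(0.0, cfg.unit_noise_sd, size=cfg.n_units)
        )
        return drive >= self.thresholds

    def emg_trace(
        self,
        fired: np.ndarray,
        rng,
        noise_sd: float | None = None,
        trace_duration: float | None = None,
        stimulus_time: float | None = None,
        tms_delay: float | None = None,
        meta: dict | None = None,
    ) -> EmgTrace:
        """Render one trial's EMG from a recruitment mask."""
        cfg = self.config
        dur = cfg.trace_duration if trace_duration is None else trace_duration
        stim = cfg.stimulus_time if stimulus_time is None else stimulus_time
        sd = cfg.emg_noise_sd if noise_sd is None else noise_sd
        fs = cfg.sampling_rate_khz
        n = int(round(dur * fs))
        samples = rng.normal(0.0, sd, size=n) if sd > 0 else np.zeros(n)
        stim_sample = int(round(stim * fs))
        # small direct M-wave, fixed latency, independent of conditioning
        if cfg.m_wave_fraction > 0:
            m0 = stim_sample + int(round(cfg.m_wave_latency * fs))
            mk = self.muap * cfg.m_wave_fraction * cfg.mmax_amplitude
            end = min(n, m0 + len(mk))
            if m0 < n:
                samples[m0:end] += mk[: end - m0]
        for i in np.flatnonzero(fired):
            s0 = stim_sample + int(round((cfg.afferent_arrival + self.efferent_delays[i]) * fs))
            end = min(n, s0 + len(self.muap))
            if s0 < n:
                samples[s0:end] += self.unit_amplitude * self.muap[: end - s0]
        tms_sample = None
        if tms_delay is not None:
            ts = stim_sample - int(round(tms_delay * fs))
            tms_sample = ts if 0 <= ts < n else None
        return EmgTrace(
            samples=samples,
            sampling_rate_hz=fs * 1000.0,
            stimulus_sample=stim_sample,
            tms_sample=tms_sample,
            meta=meta or {},
        )


def simulate_conditioning_trial(
    pool: MotoneuronPool | MotoneuronPoolConfig,
    delay: float | None,
    gains: Mapping[str, float] | None = None,
    seed=None,
) -> tuple[EmgTrace, dict]:
    """Simulate one conditioning trial.

    `delay=None` gives the unconditioned H-reflex (PNS alone).  Returns the
    EMG trace and a trial record with the recruitment ground truth.
    Deterministic given `seed`.
    """
    rng = as_rng(seed)
    if isinstance(pool, MotoneuronPoolConfig):
        pool = MotoneuronPool(pool, rng)
    fired = pool.recruit(delay, gains, rng)
    meta = {
        "delay_condition": "unconditioned" if delay is None else "conditioned",
        "delay_ms": delay,
        "recruited_count": int(fired.sum()),
        "recruited_fraction": float(fired.mean()),
    }
    trace = pool.emg_trace(fired, rng, tms_delay=delay, meta=meta)
    return trace, meta


def simulate_efd_session(
    pool: MotoneuronPool | MotoneuronPoolConfig,
    delays: Sequence[float],
    n_blocks: int = 15,
    gains: Mapping[str, float] | None = None,
    seed=None,
) -> tuple[list[dict], dict[str, EmgTrace]]:
    """Simulate one delay-identification stage (rough or fine search).

    Stimuli are delivered in `n_blocks` randomized blocks, each containing
    every delay plus one unconditioned trial.  Returns the trial records
    (with block index, condition and trace id) and the trace archive.
    """
    rng = as_rng(seed)
    if isinstance(pool, MotoneuronPoolConfig):
        pool = MotoneuronPool(pool, rng)
    conditions: list[float | None] = [None, *delays]
    records: list[dict] = []
    traces: dict[str, EmgTrace] = {}
    trial_id = 0
    for block in range(n_blocks):
        order = rng.permutation(len(conditions))
        for idx in order:
            delay = conditions[idx]
            trace, meta = simulate_conditioning_trial(pool, delay, gains, rng)
            emg_id = f"efd_{trial_id:05d}"
            rec = {
                "trial_id": trial_id,
                "block": block,
                "emg_id": emg_id,
                "stimulus_sample": trace.stimulus_sample,
                **meta,
            }
            records.append(rec)
            traces[emg_id] = trace
            trial_id += 1
    return records, traces
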