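"""Full task-session simulator: staircase task x H-reflex conditioning.

Each simulated trial is one dot-motion trial during which a conditioning
probe is delivered at a task epoch (cue onset, 400 ms after cue onset, or
300 ms after the waiting-period onset) with one of three delay conditions:
unconditioned (PNS alone), EFD0 (fastest descending component coincident)
or EFD+0.6 (the component 0.6 ms later also coincident).

Cortical excitability modulation by the task is expressed as multiplicative
gains on the circuit strengths, keyed by (epoch, cue difficulty, cue
direction).  The default encodes the layer-selective effect the probing is
designed to detect: during early discrimination (cue+400ms), easy flexion
cues raise the superficial_late circuit gain only — so downstream analysis
should find an easy-vs-difficult facilitation difference only at
(cue+400ms, EFD+0.6, flexion).

Reaction-time EMG bursts are embedded after the fixation-offset marker,
with easy-cue responses faster than difficult ones; a configurable fraction
of trials carries inflated background EMG to exercise the exclusion rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .._rng import as_rng
from ..errors import ConfigError
from .motoneuron import EmgTrace, MotoneuronPool, MotoneuronPoolConfig
from .staircase import TaskSimConfig, simulate_staircase_session

__all__ = ["ExperimentProtocol", "default_modulation", "simulate_experiment"]

EPOCHS = ("cue_onset", "cue+400ms", "delay+300ms")
DELAY_CONDITIONS = ("unconditioned", "EFD0", "EFD+0.6")


def default_modulation() -> dict[tuple[str, str, str], dict[str, float]]:
    """Default task gains: easy flexion cues at cue+400ms boost the late circuit."""
    return {("cue+400ms", "easy", "flexion"): {"superficial_late": 1.6}}


@dataclass(frozen=True)
class ExperimentProtocol:
    """Trial plan: which epochs/delay conditions, and trials per condition.

    A condition is one (epoch, delay condition, cue difficulty) cell; cue
    direction is drawn by the task (roughly balanced).  ``trials_per_condition``
    defaults to 20.
    """

    epochs: tuple[str, ...] = ("cue_onset", "cue+400ms")
    delay_conditions: tuple[str, ...] = DELAY_CONDITIONS
    trials_per_condition: int = 20
    contamination_fraction: float = 0.0

    def __post_init__(self):
        if not self.epochs or not self.delay_conditions:
            raise ConfigError("protocol must list at least one epoch and delay condition")
        for e in self.epochs:
            if e not in EPOCHS:
                raise ConfigError(f"unknown epoch {e!r}")
        for d in self.delay_conditions:
            if d not in DELAY_CONDITIONS:
                raise ConfigError(f"unknown delay condition {d!r}")
        if not (0 <= self.contamination_fraction < 1):
            raise ConfigError("contamination_fraction must be in [0, 1)")

    @property
    def n_trials(self) -> int:
        return (
            len(self.epochs)
            * len(self.delay_conditions)
            * 2  # difficulties
            * self.trials_per_condition
        )


# trial-timeline constants (ms); probing timing relative to task events is
# abstracted into the epoch label, so one fixed trace layout serves all epochs
TRACE_DURATION = 500.0
STIMULUS_TIME = 60.0
FIXATION_OFFSET_TIME = 150.0
RT_MEANS = {"easy": 173.0, "difficult": 226.0}
RT_SDS = {"easy": 25.0, "difficult": 30.0}
RT_SUBJECT_SD = 15.0
RT_BURST_DURATION = 120.0
RT_BURST_SD = 40.0  # µV, amplitude of the response burst noise
CONTAMINATION_NOISE_FACTOR = 6.0


def simulate_experiment(
    task: TaskSimConfig,
    pool: MotoneuronPoolConfig | MotoneuronPool,
    protocol: ExperimentProtocol,
    seed=None,
    efd0: float | None = None,
    modulation: Mapping[tuple[str, str, str], Mapping[str, float]] | None = None,
    keep_traces: bool = True,
) -> tuple[pd.DataFrame, dict[str, EmgTrace]]:
    """Simulate one subject's probed task session.

    The dot-motion trials come from the adaptive staircase session; probe
    conditions are assigned by crossing the protocol's epochs x delay
    conditions x difficulties, `trials_per_condition` each, pseudo-randomly
    interleaved.  ``efd0`` is the delay used for the EFD0 condition
    (defaults to the pool's true coincidence delay, as if the two-step
    search had been run beforehand); EFD+0.6 is ``efd0 + 0.6``.

    Returns the trial table (one row per trial, columns documented in
    :mod:`laminaprobe.io`) and the EMG archive keyed by ``emg_id``
    (empty when ``keep_traces=False``).
    """
    rng = as_rng(seed)
    if isinstance(pool, MotoneuronPoolConfig):
        pool = MotoneuronPool(pool, rng)
    if efd0 is None:
        efd0 = pool.config.true_efd0
    modulation = default_modulation() if modulation is None else modulation

    # build the pseudo-randomized condition sequence
    cells = [
        (e, d, diff)
        for e in protocol.epochs
        for d in protocol.delay_conditions
        for diff in ("difficult", "easy")
    ]
    sequence = [c for c in cells for _ in range(protocol.trials_per_condition)]
    order = rng.permutation(len(sequence))
    sequence = [sequence[i] for i in order]

    # run a staircase session long enough to drive every trial, split by
    # difficulty so each probe trial consumes a matching task trial
    task_n = max(task.n_trials, 4 * len(sequence))
    task_cfg = TaskSimConfig(
        observer=task.observer,
        targets=task.targets,
        step_pct=task.step_pct,
        n_trials=task_n,
        initial_coherence=task.initial_coherence,
    )
    task_trials, _states = simulate_staircase_session(task_cfg, rng)
    by_difficulty = {
        d: task_trials[task_trials.difficulty == d].reset_index(drop=True)
        for d in ("difficult", "easy")
    }
    cursor = {"difficult": 0, "easy": 0}

    delay_for = {
        "unconditioned": None,
        "EFD0": efd0,
        "EFD+0.6": efd0 + 0.6,
    }
    fs = pool.config.sampling_rate_khz
    subject_rt_offset = rng.normal(0.0, RT_SUBJECT_SD)

    records = []
    traces: dict[str, EmgTrace] = {}
    for trial_id, (epoch, delay_cond, difficulty) in enumerate(sequence):
        tt = by_difficulty[difficulty].iloc[cursor[difficulty] % len(by_difficulty[difficulty])]
        cursor[difficulty] += 1
        direction = tt.direction
        gains = dict(modulation.get((epoch, difficulty, direction), {}))
        delay = delay_for[delay_cond]
        contaminated = bool(rng.random() < protocol.contamination_fraction)
        noise_sd = pool.config.emg_noise_sd * (
            CONTAMINATION_NOISE_FACTOR if contaminated else 1.0
        )
        fired = pool.recruit(delay, gains, rng)
        trace = pool.emg_trace(
            fired,
            rng,
            noise_sd=noise_sd,
            trace_duration=TRACE_DURATION,
            stimulus_time=STIMULUS_TIME,
            tms_delay=delay,
        )
        trace.fixation_offset_sample = int(round(FIXATION_OFFSET_TIME * fs))
        # embed the response burst at fixation offset + reaction time
        rt_true = max(
            60.0,
            rng.normal(RT_MEANS[difficulty] + subject_rt_offset, RT_SDS[difficulty]),
        )
        burst0 = int(round((FIXATION_OFFSET_TIME + rt_true) * fs))
        burst1 = min(len(trace.samples), burst0 + int(round(RT_BURST_DURATION * fs)))
        if burst0 < len(trace.samples):
            trace.samples[burst0:burst1] += rng.normal(
                0.0, RT_BURST_SD, size=burst1 - burst0
            )
        emg_id = f"task_{trial_id:05d}"
        records.append(
            {
                "trial_id": trial_id,
                "epoch": epoch,
                "delay_condition": delay_cond,
                "delay_ms": delay,
                "cue_difficulty": difficulty,
                "cue_direction": direction,
                "response": tt.response,
                "correct": bool(tt.correct),
                "coherence_pct": float(tt.coherence_pct),
                "rt_true_ms": rt_true,
                "emg_id": emg_id,
                "stimulus_sample": trace.stimulus_sample,
                "contaminated": contaminated,
                "recruited_count": int(fired.sum()),
            }
        )
        if keep_traces:
            traces[emg_id] = trace
    return pd.DataFrame(records), traces
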