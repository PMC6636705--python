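"""Adaptive coherence control for the random-dot motion task.

Two randomly interleaved difficulty levels are run, each with its own
weighted up/down staircase (Kaernbach-style): after a correct response the
coherence decreases by ``step * (1 - target)`` and after an error it
increases by ``step * target``.  The zero-drift equilibrium of this rule is
exactly P(correct) = target, so the difficult staircase converges to 55 %
correct and the easy one to 80 % by default.

The simulated observer is a two-alternative forced-choice logistic
psychometric function with a lapse rate:

    P(correct | c) = 0.5 + (0.5 - lapse/2) * [1 + exp(-(c - c50)/slope)]^-1 ... (2AFC)

implemented as ``0.5 + (0.5 - lapse) * logistic((c - c50)/slope)`` with
coherence `c` in percent, clipped to [0, 100].  An optional linear drift of
`c50` over the session models perceptual learning: the controller then
tracks the improving observer and coherence trajectories decline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .._rng import as_rng
from ..errors import ConfigError

__all__ = ["ObserverConfig", "TaskSimConfig", "StaircaseState", "simulate_staircase_session"]

DIFFICULTIES = ("difficult", "easy")


@dataclass(frozen=True)
class ObserverConfig:
    """Simulated observer: logistic psychometric function of coherence (%)."""

    c50: float = 30.0
    slope: float = 8.0
    lapse: float = 0.02
    drift_total: float = 6.0  # total c50 decrease over the session (learning)

    def __post_init__(self):
        if self.slope <= 0:
            raise ConfigError("observer slope must be > 0")
        if not (0 <= self.lapse < 0.5):
            raise ConfigError("lapse must be in [0, 0.5)")

    def p_correct(self, coherence: float, progress: float = 0.0) -> float:
        """P(correct) at a coherence; `progress` in [0,1] applies the drift."""
        c50 = self.c50 - self.drift_total * progress
        z = (coherence - c50) / self.slope
        return 0.5 + (0.5 - self.lapse) / (1.0 + np.exp(-z))


@dataclass(frozen=True)
class TaskSimConfig:
    """Dot-motion session simulator parameters."""

    observer: ObserverConfig = field(default_factory=ObserverConfig)
    targets: Mapping[str, float] = field(
        default_factory=lambda: {"difficult": 0.55, "easy": 0.80}
    )
    step_pct: float = 1.0
    n_trials: int = 4000
    initial_coherence: Mapping[str, float] = field(
        default_factory=lambda: {"difficult": 25.0, "easy": 50.0}
    )

    def __post_init__(self):
        for k, t in self.targets.items():
            if not (0.5 < t < 1.0):
                raise ConfigError(f"target accuracy for {k!r} must be in (0.5, 1)")
            if t >= 1.0 - self.observer.lapse:
                raise ConfigError(
                    f"target {t} for {k!r} exceeds the observer's achievable range"
                )
        if self.step_pct <= 0:
            raise ConfigError("step_pct must be positive")


@dataclass
class StaircaseState:
    """Trajectory of one difficulty's staircase."""

    difficulty: str
    target: float
    coherence_history: list[float] = field(default_factory=list)
    correct_history: list[bool] = field(default_factory=list)

    @property
    def coherence(self) -> float:
        return self.coherence_history[-1]


def simulate_staircase_session(
    config: TaskSimConfig, seed=None
) -> tuple[pd.DataFrame, dict[str, StaircaseState]]:
    """Run one adaptive session against the simulated observer.

    Difficulties alternate randomly (50/50) across `n_trials` trials; cue
    direction is random.  Returns the trial table (trial, difficulty,
    direction, coherence_pct, p_correct, correct, response) and the final
    staircase states with full trajectories.
    """
    rng = as_rng(seed)
    states = {
        d: StaircaseState(d, config.targets[d]) for d in config.targets
    }
    coherence = {d: float(config.initial_coherence.get(d, 30.0)) for d in config.targets}
    rows = []
    difficulties = list(config.targets)
    for trial in range(config.n_trials):
        diff = difficulties[rng.integers(len(difficulties))]
        target = config.targets[diff]
        c = float(np.clip(coherence[diff], 0.0, 100.0))
        progress = trial / max(1, config.n_trials - 1)
        p = float(config.observer.p_correct(c, progress))
        correct = bool(rng.random() < p)
        direction = "flexion" if rng.random() < 0.5 else "extension"
        response = direction if correct else (
            "extension" if direction == "flexion" else "flexion"
        )
        rows.append(
            {
                "trial": trial,
                "difficulty": diff,
                "direction": direction,
                "coherence_pct": c,
                "p_correct": p,
                "correct": correct,
                "response": response,
            }
        )
        st = states[diff]
        st.coherence_history.append(c)
        st.correct_history.append(correct)
        if correct:
            coherence[diff] = c - config.step_pct * (1.0 - target)
        else:
            coherence[diff] = c + config.step_pct * target
        coherence[diff] = float(np.clip(coherence[diff], 0.0, 100.0))
    return pd.DataFrame(rows), states
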