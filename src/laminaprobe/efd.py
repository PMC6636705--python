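"""H-reflex quantification and the two-step earliest-facilitation-delay search.

The earliest facilitation delay (EFD 0 ms) is the TMS-PNS delay at which
the fastest descending corticospinal volley first coincides with the
afferent volley at the motoneuron pool.  It is found in two stages:

* rough search: delays -5.0 .. -2.0 ms in 0.5 ms steps (7 delays) plus an
  unconditioned condition, 15 trials each, delivered in 15 randomized
  blocks of 8;
* fine search: 11 delays in 0.1 ms steps spanning the 1 ms interval
  anchored at the rough hit (extending toward more negative delays by
  default), same criterion.

At each stage the earliest facilitation is the most negative delay whose
conditioned H-reflex RMS is significantly higher than the unconditioned
RMS (paired t test, p < alpha, uncorrected by design) *and* whose next two
less-negative scheduled delays are also significantly higher — the
three-delay rule is the procedure's own guard against outliers.

H-reflexes are quantified as the RMS of the unrectified EMG over the first
0.5 ms from the reflex onset, after zeroing the trace at the onset sample;
this confines the measure to the earliest, monosynaptic component of the
reflex.  The onset is determined once per dataset from the superimposed
unconditioned reflexes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import ConfigError, OnsetError, SearchError
from .simulate.motoneuron import EmgTrace

__all__ = [
    "DelaySchedule",
    "HReflexMeasurement",
    "DelayStats",
    "EarliestFacilitation",
    "EfdResult",
    "rough_schedule",
    "fine_schedule",
    "detect_onset",
    "quantify_hreflex",
    "stage_rms_from_records",
    "find_earliest_facilitation",
    "run_two_step_search",
]

RMS_WINDOW_MS = 0.5
BACKGROUND_WINDOW_MS = 50.0


@dataclass(frozen=True)
class DelaySchedule:
    """Delay grid for one search stage."""

    stage: str  # "rough" | "fine"
    delays: tuple[float, ...]
    trials_per_delay: int = 15
    includes_unconditioned: bool = True

    def __post_init__(self):
        if self.trials_per_delay < 2:
            raise ConfigError("trials_per_delay must be >= 2")
        if list(self.delays) != sorted(self.delays):
            raise ConfigError("delays must be sorted most-negative first")

    @property
    def n_conditions(self) -> int:
        return len(self.delays) + int(self.includes_unconditioned)


def rough_schedule(trials_per_delay: int = 15) -> DelaySchedule:
    """Rough stage: -5.0 .. -2.0 ms in 0.5 ms steps (7 delays + unconditioned)."""
    delays = tuple(np.round(np.arange(-5.0, -1.75, 0.5), 10))
    return DelaySchedule("rough", delays, trials_per_delay)


def fine_schedule(
    anchor: float, trials_per_delay: int = 15, more_negative: bool = True
) -> DelaySchedule:
    """Fine stage: 11 delays in 0.1 ms steps spanning 1 ms around the rough hit.

    With ``more_negative=True`` (default) the grid runs from ``anchor - 1``
    to ``anchor``; flipping the flag extends toward less negative delays
    instead.
    """
    if more_negative:
        delays = anchor - 1.0 + 0.1 * np.arange(11)
    else:
        delays = anchor + 0.1 * np.arange(11)
    return DelaySchedule("fine", tuple(np.round(delays, 10)), trials_per_delay)


# ---------------------------------------------------------------------------
# H-reflex quantification


@dataclass
class HReflexMeasurement:
    """One trial's H-reflex measure."""

    onset_time: float  # ms post-stimulus
    rms: float  # µV over the first 0.5 ms from onset, onset-zeroed
    background_emg: float  # mean rectified µV over 50 ms pre-stimulus


def detect_onset(
    traces: Sequence[EmgTrace],
    k: float = 3.0,
    sustain_ms: float = 0.3,
    reflex_window_ms: tuple[float, float] = (10.0, 40.0),
    override: float | None = None,
) -> float:
    """Determine the H-reflex onset (ms post-stimulus) for a dataset.

    The across-trial mean rectified EMG is compared against its
    pre-stimulus baseline; the onset is the first time within the reflex
    window that it exceeds ``baseline mean + k * baseline SD`` sustained
    for `sustain_ms`.  One onset serves all trials of the dataset (the
    automated stand-in for per-subject visual onset determination).  An
    `override` (e.g. a visually determined onset) is returned verbatim.
    """
    if override is not None:
        return float(override)
    if len(traces) < 5:
        raise ConfigError("need >= 5 unconditioned traces for onset detection")
    fs_khz = traces[0].sampling_rate_hz / 1000.0
    stim = traces[0].stimulus_sample
    mean_rect = np.mean([np.abs(tr.samples) for tr in traces], axis=0)
    b0 = max(0, stim - int(round(BACKGROUND_WINDOW_MS * fs_khz)))
    baseline = mean_rect[b0:stim]
    thr = baseline.mean() + k * baseline.std()
    i0 = stim + int(round(reflex_window_ms[0] * fs_khz))
    i1 = min(len(mean_rect), stim + int(round(reflex_window_ms[1] * fs_khz)))
    sustain = max(1, int(round(sustain_ms * fs_khz)))
    above = mean_rect[i0:i1] > thr
    run = 0
    for j, a in enumerate(above):
        run = run + 1 if a else 0
        if run >= sustain:
            onset_idx = i0 + j - sustain + 1
            return (onset_idx - stim) / fs_khz
    raise OnsetError(
        "no sustained threshold crossing in the reflex window; "
        "supply a manual onset via override="
    )


def quantify_hreflex(trace: EmgTrace, onset_ms: float) -> HReflexMeasurement:
    """Quantify one trial's H-reflex.

    RMS is computed on the unrectified samples over ``[onset, onset+0.5 ms)``
    after subtracting the value at the onset sample (baseline-offset
    correction); background EMG is the mean rectified activity over the
    50 ms before the stimulus.
    """
    fs_khz = trace.sampling_rate_hz / 1000.0
    i0 = trace.stimulus_sample + int(round(onset_ms * fs_khz))
    n_win = int(round(RMS_WINDOW_MS * fs_khz))
    if i0 < 0 or i0 + n_win > len(trace.samples):
        raise ConfigError("RMS window exceeds trace")
    window = trace.samples[i0 : i0 + n_win].astype(float)
    window = window - window[0]
    rms = float(np.sqrt(np.mean(window**2)))
    b0 = max(0, trace.stimulus_sample - int(round(BACKGROUND_WINDOW_MS * fs_khz)))
    background = float(np.mean(np.abs(trace.samples[b0 : trace.stimulus_sample])))
    return HReflexMeasurement(onset_ms, rms, background)


def stage_rms_from_records(
    records: Sequence[Mapping],
    traces: Mapping[str, EmgTrace],
    onset_ms: float | None = None,
) -> tuple[dict[float, np.ndarray], np.ndarray]:
    """Compute per-delay and unconditioned RMS arrays from session records.

    Records are the output of :func:`laminaprobe.simulate.simulate_efd_session`
    (or a table with the same fields); trials are ordered by block so the
    arrays are paired block-wise.  The onset is detected from the
    unconditioned traces unless given.
    """
    uncond = sorted(
        (r for r in records if r["delay_condition"] == "unconditioned"),
        key=lambda r: r["block"],
    )
    if onset_ms is None:
        onset_ms = detect_onset([traces[r["emg_id"]] for r in uncond])
    uncond_rms = np.array(
        [quantify_hreflex(traces[r["emg_id"]], onset_ms).rms for r in uncond]
    )
    by_delay: dict[float, np.ndarray] = {}
    delays = sorted({r["delay_ms"] for r in records if r["delay_ms"] is not None})
    for d in delays:
        rs = sorted(
            (r for r in records if r["delay_ms"] == d), key=lambda r: r["block"]
        )
        by_delay[d] = np.array(
            [quantify_hreflex(traces[r["emg_id"]], onset_ms).rms for r in rs]
        )
    return by_delay, uncond_rms


# ---------------------------------------------------------------------------
# earliest-facilitation criterion


@dataclass
class DelayStats:
    """Per-delay facilitation statistics (paired against unconditioned)."""

    delay: float
    mean_conditioned: float
    mean_unconditioned: float
    p_value: float
    significant_higher: bool


@dataclass
class EarliestFacilitation:
    delay: float
    at_schedule_edge: bool
    stats: list[DelayStats]


def _delay_stats(
    cond: np.ndarray, uncond: np.ndarray, delay: float, alpha: float
) -> DelayStats:
    if len(cond) != len(uncond):
        raise ConfigError("paired design requires equal trial counts per delay")
    if len(cond) < 2:
        raise ConfigError("need >= 2 trials per delay")
    t, p = stats.ttest_rel(cond, uncond)
    higher = bool(cond.mean() > uncond.mean())
    return DelayStats(
        delay=delay,
        mean_conditioned=float(cond.mean()),
        mean_unconditioned=float(uncond.mean()),
        p_value=float(p),
        significant_higher=bool(p < alpha) and higher,
    )


def find_earliest_facilitation(
    delay_rms: Mapping[float, np.ndarray],
    uncond_rms: np.ndarray,
    schedule: DelaySchedule,
    alpha: float = 0.05,
) -> EarliestFacilitation | None:
    """Scan delays from most negative to least for the earliest facilitation.

    Returns the first delay that is significantly higher than unconditioned
    (paired t, p < alpha, uncorrected) with its next two scheduled delays
    also significantly higher; None if no delay qualifies.  A hit within
    the last two schedule positions (fewer than two successors available)
    is returned with ``at_schedule_edge=True``.
    """
    all_stats = [
        _delay_stats(np.asarray(delay_rms[d], dtype=float),
                     np.asarray(uncond_rms, dtype=float), d, alpha)
        for d in schedule.delays
    ]
    n = len(all_stats)
    for i, st in enumerate(all_stats):
        if not st.significant_higher:
            continue
        successors = all_stats[i + 1 : i + 3]
        if len(successors) < 2:
            return EarliestFacilitation(st.delay, at_schedule_edge=True, stats=all_stats)
        if all(s.significant_higher for s in successors):
            return EarliestFacilitation(st.delay, at_schedule_edge=False, stats=all_stats)
    return None


@dataclass
class EfdResult:
    """Outcome of the two-step search."""

    rough_efd: float
    fine_efd: float  # == EFD 0 ms
    rough_stats: list[DelayStats]
    fine_stats: list[DelayStats]
    rough_edge: bool = False
    fine_edge: bool = False

    @property
    def efd_plus_06(self) -> float:
        """EFD +0.6 ms: the delay probing the later I1 component."""
        return self.fine_efd + 0.6

    def to_dict(self) -> dict:
        def rows(sts):
            return [
                {
                    "delay_ms": s.delay,
                    "mean_conditioned": s.mean_conditioned,
                    "mean_unconditioned": s.mean_unconditioned,
                    "p_value": s.p_value,
                    "significant_higher": s.significant_higher,
                }
                for s in sts
            ]

        return {
            "rough_efd_ms": self.rough_efd,
            "fine_efd_ms": self.fine_efd,
            "efd_plus_0p6_ms": self.efd_plus_06,
            "rough_edge": self.rough_edge,
            "fine_edge": self.fine_edge,
            "rough_stats": rows(self.rough_stats),
            "fine_stats": rows(self.fine_stats),
        }


StageData = tuple[Mapping[float, np.ndarray], np.ndarray]
CollectFn = Callable[[DelaySchedule], StageData]


def run_two_step_search(
    collect: CollectFn,
    alpha: float = 0.05,
    trials_per_delay: int = 15,
    fine_more_negative: bool = True,
    max_reanchor: int = 2,
) -> EfdResult:
    """Run the rough-then-fine search.

    `collect` runs one stage: given a :class:`DelaySchedule` it must return
    ``(delay_rms, uncond_rms)`` — per-delay conditioned RMS arrays paired
    block-wise with the unconditioned array.  In a simulation `collect`
    wraps the conditioning simulator; with recorded data it wraps
    :func:`stage_rms_from_records` over the stage's trial table.

    If the fine stage finds no facilitation, the rough hit was most likely
    a chance positive one grid step before the true onset (its successors
    are then genuinely facilitated, so the three-delay rule cannot reject
    it); in that case the fine grid is re-anchored at the next significant
    rough delay, at most `max_reanchor` times.
    """
    rough = rough_schedule(trials_per_delay)
    delay_rms, uncond_rms = collect(rough)
    hit = find_earliest_facilitation(delay_rms, uncond_rms, rough, alpha)
    if hit is None:
        raise SearchError(
            "rough search found no earliest facilitation; cannot anchor the fine grid"
        )
    anchor = hit.delay
    rough_sig = [s.delay for s in hit.stats if s.significant_higher]
    for attempt in range(max_reanchor + 1):
        fine = fine_schedule(anchor, trials_per_delay, fine_more_negative)
        f_delay_rms, f_uncond_rms = collect(fine)
        f_hit = find_earliest_facilitation(f_delay_rms, f_uncond_rms, fine, alpha)
        if f_hit is not None:
            return EfdResult(
                rough_efd=anchor,  # the anchor the fine stage confirmed
                fine_efd=f_hit.delay,
                rough_stats=hit.stats,
                fine_stats=f_hit.stats,
                rough_edge=hit.at_schedule_edge,
                fine_edge=f_hit.at_schedule_edge,
            )
        later = [d for d in rough_sig if d > anchor]
        if not later:
            break
        anchor = later[0]
    raise SearchError("fine search found no earliest facilitation")
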