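"""Human task-epoch analyses: exclusion, reaction time, facilitation stats.

H-reflex facilitation is the conditioned reflex expressed as a percentage
of the unconditioned test reflex (conditioned / unconditioned x 100 %);
cue-related modulation is the facilitation with easy cues as a percentage
of the facilitation with difficult cues.  Both ratios are formed from
per-subject means — the subject is the unit of analysis — and compared
with paired t tests whose raw p-values are reported alongside a
Bonferroni-corrected significance flag over the pre-planned family.

Trials whose 50 ms pre-stimulation background EMG exceeds the resting
(delay-identification session) mean by more than 2 SD are excluded, so
background-EMG drift cannot masquerade as a cortical excitability change.
Reaction time is the interval from fixation-point offset to a sustained
rise of the rectified EMG more than 4 SD above the baseline mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.stats.multitest import multipletests

from .efd import detect_onset, quantify_hreflex
from .errors import ConfigError
from .simulate.motoneuron import EmgTrace

__all__ = [
    "resting_baseline",
    "exclude_trials",
    "reaction_time",
    "facilitation",
    "cue_modulation",
    "annotate_hreflex",
    "subject_facilitation",
    "compare_conditions",
]


def resting_baseline(background_emg: Sequence[float], min_trials: int = 50) -> tuple[float, float]:
    """Mean and SD of pre-stimulation background EMG in the resting session."""
    bg = np.asarray(background_emg, dtype=float)
    if bg.size < min_trials:
        raise ConfigError(f"resting baseline needs >= {min_trials} trials")
    return float(bg.mean()), float(bg.std(ddof=1))


def exclude_trials(
    trials: pd.DataFrame,
    resting_mean: float,
    resting_sd: float,
    background_column: str = "background_emg",
) -> pd.DataFrame:
    """Flag trials whose background EMG exceeds the resting mean + 2 SD.

    Returns a copy with boolean ``excluded`` and string ``exclusion_reason``
    columns; excluded trials are retained for audit.  Re-running on the
    kept subset is a no-op (the threshold is fixed by the resting session,
    not recomputed).
    """
    if background_column not in trials.columns:
        raise ConfigError(f"missing background column {background_column!r}")
    if trials[background_column].isna().any():
        raise ConfigError("missing background EMG measurements")
    out = trials.copy()
    threshold = resting_mean + 2.0 * resting_sd
    over = out[background_column] > threshold
    out["excluded"] = over
    out["exclusion_reason"] = np.where(over, "background_emg", "")
    return out


def reaction_time(
    trace: EmgTrace,
    baseline_window_ms: tuple[float, float] = (0.0, 50.0),
    k: float = 4.0,
    sustain_ms: float = 10.0,
    envelope_ms: float = 5.0,
) -> float | None:
    """Reaction time (ms) from fixation offset to sustained EMG onset.

    The rectified EMG is smoothed with a trailing moving-average envelope
    (`envelope_ms`) and must exceed ``baseline mean + k * baseline SD``
    (default 4 SD, SD of the envelope) continuously for `sustain_ms`; the
    baseline statistics come from the start-of-trace window.  Returns None
    (absent) if no sustained crossing follows the fixation offset.
    """
    if trace.fixation_offset_sample is None:
        raise ConfigError("trace has no fixation offset marker")
    fs_khz = trace.sampling_rate_hz / 1000.0
    n_env = max(1, int(round(envelope_ms * fs_khz)))
    rect = np.convolve(np.abs(trace.samples), np.ones(n_env) / n_env, mode="full")[
        : len(trace.samples)
    ]
    b0 = int(round(baseline_window_ms[0] * fs_khz))
    b1 = int(round(baseline_window_ms[1] * fs_khz))
    base = rect[b0:b1]
    thr = base.mean() + k * base.std()
    start = trace.fixation_offset_sample
    above = rect[start:] > thr
    sustain = max(1, int(round(sustain_ms * fs_khz)))
    # first run of `sustain` consecutive supra-threshold samples
    run = 0
    for j, a in enumerate(above):
        run = run + 1 if a else 0
        if run >= sustain:
            return (j - sustain + 1) / fs_khz
    return None


def facilitation(conditioned: Sequence[float], unconditioned: Sequence[float]) -> float:
    """H-reflex facilitation in percent: 100 * mean(cond) / mean(uncond)."""
    cond = np.asarray(conditioned, dtype=float)
    uncond = np.asarray(unconditioned, dtype=float)
    if cond.size == 0 or uncond.size == 0:
        raise ConfigError("facilitation requires non-empty samples")
    if uncond.mean() <= 0:
        raise ConfigError("unconditioned mean must be > 0")
    return float(100.0 * cond.mean() / uncond.mean())


def cue_modulation(facilitation_easy: float, facilitation_difficult: float) -> float:
    """Cue-related modulation: easy facilitation as % of difficult facilitation."""
    if facilitation_difficult <= 0:
        raise ConfigError("difficult-cue facilitation must be > 0")
    return float(100.0 * facilitation_easy / facilitation_difficult)


def annotate_hreflex(
    trials: pd.DataFrame,
    traces: Mapping[str, EmgTrace],
    onset_ms: float | None = None,
    with_rt: bool = True,
) -> tuple[pd.DataFrame, float]:
    """Add H-reflex RMS, background EMG and reaction time to a trial table.

    The reflex onset is detected once from the unconditioned traces (or
    passed in) and reused for every trial.  Returns the annotated copy and
    the onset used.
    """
    if onset_ms is None:
        uncond_ids = trials.loc[
            trials.delay_condition == "unconditioned", "emg_id"
        ].tolist()
        onset_ms = detect_onset([traces[i] for i in uncond_ids])
    rms, bg, rts = [], [], []
    for _, row in trials.iterrows():
        tr = traces[row.emg_id]
        m = quantify_hreflex(tr, onset_ms)
        rms.append(m.rms)
        bg.append(m.background_emg)
        if with_rt:
            rt = reaction_time(tr) if tr.fixation_offset_sample is not None else None
            rts.append(np.nan if rt is None else rt)
    out = trials.copy()
    out["hreflex_rms"] = rms
    out["background_emg"] = bg
    if with_rt:
        out["rt_ms"] = rts
    return out, onset_ms


def subject_facilitation(
    trials: pd.DataFrame,
    by: tuple[str, ...] = ("epoch", "cue_difficulty", "cue_direction"),
    unconditioned_by: tuple[str, ...] = ("epoch",),
) -> pd.DataFrame:
    """Per-condition facilitation for one subject.

    For every cell of `by`, each conditioned delay condition's mean
    H-reflex RMS is expressed as a percentage of the unconditioned mean of
    the enclosing `unconditioned_by` cell.  The unconditioned test reflex
    is a cue-independent reference, so by default it is pooled within each
    probing epoch: cue-specific comparisons then share a denominator and
    its sampling noise cancels in paired contrasts.  Expects an annotated,
    exclusion-filtered table.
    """
    required = {"delay_condition", "hreflex_rms", *by, *unconditioned_by}
    missing = required - set(trials.columns)
    if missing:
        raise ConfigError(f"trial table missing columns: {sorted(missing)}")
    if not set(unconditioned_by) <= set(by):
        raise ConfigError("unconditioned_by must be a subset of by")
    uncond_means = (
        trials.loc[trials.delay_condition == "unconditioned"]
        .groupby(list(unconditioned_by))
        .hreflex_rms.agg(["mean", "size"])
    )
    rows = []
    for keys, cell in trials.groupby(list(by)):
        keys = keys if isinstance(keys, tuple) else (keys,)
        ukey = tuple(k for k, name in zip(keys, by) if name in unconditioned_by)
        ukey = ukey[0] if len(ukey) == 1 else ukey
        if ukey not in uncond_means.index:
            continue
        u_mean = float(uncond_means.loc[ukey, "mean"])
        u_n = int(uncond_means.loc[ukey, "size"])
        for cond_name, sub in cell.groupby("delay_condition"):
            if cond_name == "unconditioned":
                continue
            rows.append(
                {
                    **dict(zip(by, keys)),
                    "delay_condition": cond_name,
                    "facilitation_pct": facilitation(
                        sub.hreflex_rms.to_numpy(), [u_mean]
                    ),
                    "n_conditioned": len(sub),
                    "n_unconditioned": u_n,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class ComparisonResult:
    name: str
    t: float
    p_raw: float
    p_bonferroni: float
    significant: bool
    n: int
    mean_difference: float
    normality_p: float
    levene_p: float


def compare_conditions(
    comparisons: Mapping[str, tuple[Sequence[float], Sequence[float]]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Paired t tests over a pre-planned family with Bonferroni control.

    Each entry maps a comparison name to paired per-subject value vectors
    (e.g. easy vs difficult facilitation).  Raw p-values are reported; the
    ``significant`` flag holds at the Bonferroni-adjusted family-wise
    alpha.  Lilliefors normality (of the paired differences) and Levene
    variance-homogeneity p-values are attached as diagnostics, not gates.
    """
    if not comparisons:
        raise ConfigError("empty comparison family")
    names, raw_p, rows = [], [], []
    for name, (a, b) in comparisons.items():
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if a.shape != b.shape:
            raise ConfigError(f"unpaired lengths in comparison {name!r}")
        if a.size < 3:
            raise ConfigError("need >= 3 subjects per comparison")
        t, p = stats.ttest_rel(a, b)
        diff = a - b
        if np.ptp(diff) == 0:
            norm_p = 1.0
            t = 0.0 if diff[0] == 0 else t
            p = 1.0 if diff[0] == 0 else p
        else:
            norm_p = float(lilliefors(diff)[1])
        lev_p = float(stats.levene(a, b)[1]) if (np.ptp(a) or np.ptp(b)) else 1.0
        names.append(name)
        raw_p.append(float(p))
        rows.append(
            {
                "comparison": name,
                "t": float(t),
                "p_raw": float(p),
                "n": int(a.size),
                "mean_difference": float(diff.mean()),
                "normality_p": norm_p,
                "levene_p": lev_p,
            }
        )
    reject, p_adj, _, _ = multipletests(raw_p, alpha=alpha, method="bonferroni")
    table = pd.DataFrame(rows)
    table["p_bonferroni"] = p_adj
    table["significant"] = reject
    table["family_size"] = len(raw_p)
    return table
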