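"""Population PSTH and latency analysis.

Implements the in vitro / in vivo analysis chain: EPSP and passive-membrane
measurements, trial-normalized population PSTHs (0.1 ms bins over the first
10 ms post-stimulus), zero-phase 400-2000 Hz band-pass filtering (a proxy
for the low/band-pass filtering that tissue applies between a population
spike response and the epidural field it generates), first-peak latency
extraction, a Monte Carlo shuffle test for latency differences between
stimulation sites, and D/I1 volley latency measurement with a one-way
ANOVA for depth effects.

The filter is a forward-backward (zero-phase) 2nd-order Butterworth
band-pass, so measured latencies carry no group delay.  "First peak" is
operationalized as the first local maximum, after an artifact-blanking
interval (default 0.5 ms), whose height exceeds a configurable fraction
(default 25 %) of the post-blanking global maximum; ties go to the
earliest bin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal, stats

from ._rng import as_rng
from .errors import ConfigError, FitError, LaminaProbeError
from .simulate.spikes import SpikeTrainSet

__all__ = [
    "Psth",
    "FilteredPsth",
    "LatencyTestResult",
    "PassiveProperties",
    "EpspMeasurement",
    "VolleyLatencies",
    "AnovaResult",
    "measure_epsp",
    "measure_passive",
    "compile_population_psth",
    "bandpass_psth",
    "bandpass_heights",
    "first_peak_latency",
    "first_peak_latencies",
    "monte_carlo_latency_test",
    "volley_latencies",
    "one_way_anova",
]

BIN_WIDTH_MS = 0.1
WINDOW_MS = 10.0
DEFAULT_BAND = (400.0, 2000.0)


# ---------------------------------------------------------------------------
# intracellular measurements


@dataclass
class EpspMeasurement:
    """EPSP amplitude/peak measurement from an averaged voltage trace."""

    amplitude: float
    peak_time: float | None  # ms post-stimulus; None for a flat trace
    derivative_time: np.ndarray  # ms, 2-12 ms window
    derivative: np.ndarray  # mV/ms


def measure_epsp(
    t: np.ndarray,
    v: np.ndarray,
    stimulus_time: float = 0.0,
    reference_window: tuple[float, float] = (68.0, 72.0),
    flat_tol: float = 1e-9,
) -> EpspMeasurement:
    """Measure an averaged EPSP trace.

    Amplitude is the difference between the peak mean voltage after the
    stimulus and the mean voltage near the 70 ms post-stimulus reference
    point.  Also returns the first time-derivative over the 2-12 ms
    post-stimulus window (the rise-rate view that separates proximal from
    distal synaptic input).
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    rel = t - stimulus_time
    if rel[-1] < 70.0:
        raise ConfigError("trace must span >= 70 ms post-stimulus")
    ref_mask = (rel >= reference_window[0]) & (rel <= reference_window[1])
    reference = float(v[ref_mask].mean())
    post = rel > 0
    dmask = (rel >= 2.0) & (rel <= 12.0)
    deriv = np.gradient(v[dmask], t[dmask])
    if np.ptp(v[post]) <= flat_tol:
        return EpspMeasurement(0.0, None, rel[dmask], deriv)
    i_peak = int(np.argmax(v[post]))
    amplitude = float(v[post][i_peak] - reference)
    peak_time = float(rel[post][i_peak])
    return EpspMeasurement(amplitude, peak_time, rel[dmask], deriv)


@dataclass
class PassiveProperties:
    """Passive membrane properties from a hyperpolarizing current step."""

    input_resistance: float  # MOhm
    membrane_time_constant: float  # ms


def measure_passive(
    t: np.ndarray,
    v: np.ndarray,
    injected_current: float,
    fit_range: tuple[float, float] = (0.10, 0.90),
) -> PassiveProperties:
    """Measure input resistance and membrane time constant.

    `v` is the voltage deflection (mV, relative to the pre-step baseline)
    in response to a hyperpolarizing step of `injected_current` (nA,
    magnitude).  R = deltaV / I from the steady-state deflection; tau from
    the gradient of the logarithm of the initial part of the deflection
    (linear fit of ``log(V_ss - V)`` over the portion of the charging curve
    where the remaining deflection is within `fit_range` of the total).
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    v_ss = float(np.mean(v[t >= t[-1] * 0.9]))
    delta_v = abs(v_ss)
    if delta_v <= 0:
        raise FitError("no steady-state deflection")
    if delta_v >= 10.0:
        warnings.warn(
            "deflection >= 10 mV: outside the small-signal range", stacklevel=2
        )
    resistance = delta_v / abs(injected_current)
    residual = np.abs(v_ss) - np.abs(v)  # remaining charge, decays as exp(-t/tau)
    frac = residual / delta_v
    mask = (frac > fit_range[0]) & (frac < fit_range[1]) & (t > 0)
    if mask.sum() < 3:
        raise FitError("too few samples on the charging curve for a tau fit")
    y = np.log(residual[mask])
    slope, _ = np.polyfit(t[mask], y, 1)
    if slope >= 0:
        raise FitError("non-monotonic initial segment: tau fit failed")
    return PassiveProperties(resistance, -1.0 / slope)


# ---------------------------------------------------------------------------
# PSTH compilation and filtering


@dataclass
class Psth:
    """Trial-normalized population PSTH on a fixed 0.1 ms grid (0-10 ms).

    `heights` are spikes per bin per stimulus, averaged across cells with
    equal weight (each cell's histogram is first divided by its own trial
    count); their sum equals the population-mean spike count per stimulus
    within the window.
    """

    bin_edges: np.ndarray
    heights: np.ndarray
    site: str = ""
    n_cells: int = 0

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2


@dataclass
class FilteredPsth:
    """Band-passed PSTH on the same grid; zero mean by construction."""

    bin_edges: np.ndarray
    heights: np.ndarray
    band: tuple[float, float]
    filter_descriptor: str = ""
    site: str = ""

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2


def _cell_histograms(
    spikes: SpikeTrainSet, site: str, bin_edges: np.ndarray
) -> np.ndarray:
    """Per-cell trial-normalized histograms, shape (n_cells, n_bins)."""
    rows = []
    for cell in spikes.spiking_cells():
        trains = cell.trains.get(site)
        if not trains:
            continue
        all_times = np.concatenate(trains) if trains else np.empty(0)
        h, _ = np.histogram(all_times, bins=bin_edges)
        rows.append(h / len(trains))
    if not rows:
        raise ConfigError(f"no spiking cells with trials at site {site!r}")
    return np.asarray(rows, dtype=float)


def compile_population_psth(
    spikes: SpikeTrainSet,
    site: str,
    window_ms: float = WINDOW_MS,
    bin_width_ms: float = BIN_WIDTH_MS,
) -> Psth:
    """Compile the population PSTH for one stimulation site.

    Each cell's spike times (all trials pooled) are binned over
    ``[0, window_ms)`` and divided by that cell's trial count; the
    normalized histograms are then averaged across cells with equal
    weight.  Spikes outside the window are discarded.
    """
    n_bins = int(round(window_ms / bin_width_ms))
    bin_edges = np.arange(n_bins + 1) * bin_width_ms
    per_cell = _cell_histograms(spikes, site, bin_edges)
    return Psth(
        bin_edges=bin_edges,
        heights=per_cell.mean(axis=0),
        site=site,
        n_cells=per_cell.shape[0],
    )


def _design_bandpass(
    band: tuple[float, float], fs_hz: float, order: int = 2
) -> np.ndarray:
    lo, hi = band
    nyq = fs_hz / 2
    if not (0 < lo < hi < nyq):
        raise ConfigError(f"band edges {band} outside (0, Nyquist={nyq:g})")
    return signal.butter(order, [lo, hi], btype="bandpass", fs=fs_hz, output="sos")


def bandpass_heights(
    heights: np.ndarray,
    band: tuple[float, float] = DEFAULT_BAND,
    fs_hz: float = 10_000.0,
    order: int = 2,
) -> np.ndarray:
    """Zero-phase band-pass along the last axis (forward-backward IIR).

    Odd-reflection edge padding (scipy's default for ``sosfiltfilt``) keeps
    edge transients small; the forward-backward pass cancels group delay so
    peak latencies are unbiased.
    """
    sos = _design_bandpass(band, fs_hz, order)
    return signal.sosfiltfilt(sos, np.asarray(heights, dtype=float), axis=-1)


def bandpass_psth(
    psth: Psth, band: tuple[float, float] = DEFAULT_BAND, order: int = 2
) -> FilteredPsth:
    """Band-pass a PSTH (400-2000 Hz default) with a zero-phase filter."""
    widths = np.diff(psth.bin_edges)
    if not np.allclose(widths, widths[0]):
        raise ConfigError("PSTH grid must be uniform")
    fs_hz = 1000.0 / widths[0]
    return FilteredPsth(
        bin_edges=psth.bin_edges,
        heights=bandpass_heights(psth.heights, band, fs_hz, order),
        band=band,
        filter_descriptor=f"butter(order={order}, band={band}, zero-phase)",
        site=psth.site,
    )


# ---------------------------------------------------------------------------
# peak latency


def first_peak_latencies(
    heights: np.ndarray,
    bin_centers: np.ndarray,
    min_fraction: float = 0.25,
    blank_ms: float = 0.5,
    interpolate: bool = True,
) -> np.ndarray:
    """Vectorized first-peak latency over the last axis; NaN where no peak.

    A qualifying peak is a local maximum after `blank_ms` whose height
    *and* topographic prominence both exceed ``min_fraction`` times the
    post-blanking global maximum — the prominence requirement rejects
    low-lying ripples of the band-pass filter that happen to clear the
    height threshold.  With ``interpolate=True`` the peak time is refined
    below the bin width by fitting a parabola through the peak bin and its
    neighbours, so the latency is a continuous quantity rather than a
    multiple of the grid step (a symmetric peak is returned unchanged).
    """
    h = np.atleast_2d(np.asarray(heights, dtype=float))
    centers = np.asarray(bin_centers, dtype=float)
    valid = centers >= blank_ms
    hv = h[:, valid]
    cv = centers[valid]
    out = np.full(h.shape[0], np.nan)
    if hv.shape[1] < 3:
        return out
    dt = cv[1] - cv[0]
    for r in range(hv.shape[0]):
        row = hv[r]
        gmax = row.max()
        if gmax <= 0:
            continue
        peaks, _ = signal.find_peaks(
            row, height=min_fraction * gmax, prominence=min_fraction * gmax
        )
        if peaks.size == 0:
            continue
        c = int(peaks[0])
        lat = cv[c]
        if interpolate and 0 < c < row.size - 1:
            denom = row[c - 1] - 2 * row[c] + row[c + 1]
            if denom < 0:
                shift = 0.5 * (row[c - 1] - row[c + 1]) / denom
                lat = lat + float(np.clip(shift, -0.5, 0.5)) * dt
        out[r] = lat
    return out


def first_peak_latency(
    fp: FilteredPsth | np.ndarray,
    bin_centers: np.ndarray | None = None,
    min_fraction: float = 0.25,
    blank_ms: float = 0.5,
) -> float | None:
    """Latency (ms) of the first qualifying peak, or None if absent."""
    if isinstance(fp, FilteredPsth):
        heights, centers = fp.heights, fp.bin_centers
    else:
        if bin_centers is None:
            raise ConfigError("bin_centers required for a bare array")
        heights, centers = fp, bin_centers
    lat = first_peak_latencies(heights, centers, min_fraction, blank_ms)[0]
    return None if np.isnan(lat) else float(lat)


# ---------------------------------------------------------------------------
# Monte Carlo shuffle test


@dataclass
class LatencyTestResult:
    """Result of the Monte Carlo shuffle test on first-peak latencies."""

    observed_difference: float
    null_differences: np.ndarray
    p_value: float  # two-sided, add-one corrected
    p_one_sided: float
    n_shuffles: int
    n_degenerate: int = 0


def _group_first_peak(
    mat: np.ndarray, centers: np.ndarray, band, fs_hz, min_fraction, blank_ms
) -> np.ndarray:
    filt = bandpass_heights(mat, band, fs_hz)
    return first_peak_latencies(filt, centers, min_fraction, blank_ms)


def monte_carlo_latency_test(
    psths_a: Sequence[np.ndarray] | np.ndarray,
    psths_b: Sequence[np.ndarray] | np.ndarray,
    bin_centers: np.ndarray,
    n_shuffles: int = 1000,
    seed=None,
    band: tuple[float, float] = DEFAULT_BAND,
    min_fraction: float = 0.25,
    blank_ms: float = 0.5,
    max_degenerate_fraction: float = 0.10,
) -> LatencyTestResult:
    """Shuffle test for the first-peak latency difference between two groups.

    `psths_a` / `psths_b` are per-cell trial-normalized PSTHs (rows).  The
    observed statistic is the first-peak latency of the filtered group-A
    average minus that of group B.  Under the null, cell PSTHs are randomly
    reassigned to two groups of the original sizes; each shuffled pair is
    averaged, filtered and peak-measured identically.  The two-sided
    p-value uses the add-one rule ``(#{|null| >= |obs|} + 1)/(n + 1)``.
    """
    a = np.atleast_2d(np.asarray(psths_a, dtype=float))
    b = np.atleast_2d(np.asarray(psths_b, dtype=float))
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ConfigError("each group needs >= 2 cells")
    centers = np.asarray(bin_centers, dtype=float)
    fs_hz = 1000.0 / (centers[1] - centers[0])
    rng = as_rng(seed)

    obs = _group_first_peak(
        np.vstack([a.mean(axis=0), b.mean(axis=0)]),
        centers, band, fs_hz, min_fraction, blank_ms,
    )
    if np.isnan(obs).any():
        raise LaminaProbeError("observed filtered PSTH has no qualifying peak")
    observed = float(obs[0] - obs[1])

    pool = np.vstack([a, b])
    na, n_tot = a.shape[0], a.shape[0] + b.shape[0]
    perms = np.asarray([rng.permutation(n_tot) for _ in range(n_shuffles)])
    mean_a = pool[perms[:, :na]].mean(axis=1)
    mean_b = pool[perms[:, na:]].mean(axis=1)
    lat_a = _group_first_peak(mean_a, centers, band, fs_hz, min_fraction, blank_ms)
    lat_b = _group_first_peak(mean_b, centers, band, fs_hz, min_fraction, blank_ms)
    null = lat_a - lat_b
    bad = np.isnan(null)
    n_degenerate = int(bad.sum())
    if n_degenerate > max_degenerate_fraction * n_shuffles:
        raise LaminaProbeError(
            f"{n_degenerate}/{n_shuffles} shuffles produced degenerate filtered "
            "PSTHs (no qualifying peak); check calibration or peak criteria"
        )
    null = null[~bad]
    n_valid = null.size
    p_two = (np.sum(np.abs(null) >= abs(observed) - 1e-12) + 1) / (n_valid + 1)
    if observed >= 0:
        p_one = (np.sum(null >= observed - 1e-12) + 1) / (n_valid + 1)
    else:
        p_one = (np.sum(null <= observed + 1e-12) + 1) / (n_valid + 1)
    return LatencyTestResult(
        observed_difference=observed,
        null_differences=null,
        p_value=float(p_two),
        p_one_sided=float(p_one),
        n_shuffles=n_valid,
        n_degenerate=n_degenerate,
    )


# ---------------------------------------------------------------------------
# epidural volley latencies


@dataclass
class VolleyLatencies:
    """D and I1 wave latencies (ms post-stimulus) from one averaged trace."""

    d_latency: float
    i1_latency: float | None
    i1_absent: bool = False

    @property
    def d_i1_interval(self) -> float | None:
        return None if self.i1_latency is None else self.i1_latency - self.d_latency


def volley_latencies(
    t: np.ndarray,
    trace: np.ndarray,
    band: tuple[float, float] = DEFAULT_BAND,
    blank_ms: float = 0.5,
    min_fraction: float = 0.25,
    i1_min_gap_ms: float = 1.0,
) -> VolleyLatencies:
    """Measure D and I1 latencies from an averaged epidural trace.

    The trace is band-pass filtered (zero phase); the D wave is the first
    qualifying peak after the blanking interval and I1 the next qualifying
    peak at least `i1_min_gap_ms` after the D wave.  A missing I1 is
    flagged rather than raised.
    """
    t = np.asarray(t, dtype=float)
    dt = t[1] - t[0]
    fs_hz = 1000.0 / dt
    filt = bandpass_heights(np.asarray(trace, dtype=float), band, fs_hz)
    d_lat = first_peak_latencies(filt, t, min_fraction, blank_ms)[0]
    if np.isnan(d_lat):
        raise LaminaProbeError("no qualifying D wave found")
    i1_lat = first_peak_latencies(filt, t, min_fraction, d_lat + i1_min_gap_ms)[0]
    if np.isnan(i1_lat):
        return VolleyLatencies(float(d_lat), None, i1_absent=True)
    return VolleyLatencies(float(d_lat), float(i1_lat))


# ---------------------------------------------------------------------------
# ANOVA


@dataclass
class AnovaResult:
    F: float
    p: float
    df_between: int
    df_within: int
    degenerate: bool = False


def one_way_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """Classic one-way fixed-effects ANOVA across groups of latencies."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(len(g) < 2 for g in arrays):
        raise ConfigError("need >= 2 groups with >= 2 values each")
    df_b = len(arrays) - 1
    df_w = sum(len(g) for g in arrays) - len(arrays)
    if all(np.ptp(g) == 0 for g in arrays):
        means = [g[0] for g in arrays]
        if np.ptp(means) == 0:
            return AnovaResult(0.0, 1.0, df_b, df_w, degenerate=True)
        return AnovaResult(np.inf, 0.0, df_b, df_w, degenerate=True)
    F, p = stats.f_oneway(*arrays)
    return AnovaResult(float(F), float(p), df_b, df_w)
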