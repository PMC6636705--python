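"""PSTH compilation, filtering, peak latency, shuffle test, ANOVA."""

import numpy as np
import pytest
from scipy import signal as sig

from laminaprobe.errors import ConfigError, FitError, LaminaProbeError
from laminaprobe.psth import (
    bandpass_heights,
    bandpass_psth,
    compile_population_psth,
    first_peak_latency,
    measure_epsp,
    measure_passive,
    monte_carlo_latency_test,
    one_way_anova,
)
from laminaprobe.simulate import CellSimConfig, simulate_population_spikes
from laminaprobe.simulate.spikes import CellSpikes, SpikeTrainSet

from helpers import PSTH_CENTERS, PSTH_EDGES


def _single_cell_set(times_by_trial, site="deep"):
    trains = {site: [np.asarray(t, dtype=float) for t in times_by_trial]}
    return SpikeTrainSet(
        cells=[CellSpikes(trains=trains)], n_trials={site: len(times_by_trial)}
    )


class TestCompile:
    def test_single_spike_lands_in_its_bin(self):
        spikes = _single_cell_set([[2.05]])
        psth = compile_population_psth(spikes, "deep")
        assert psth.heights[20] == 1.0  # bin [2.0, 2.1)
        assert psth.heights.sum() == 1.0

    def test_trial_normalization(self):
        spikes = _single_cell_set([[2.05], [2.05], []])
        psth = compile_population_psth(spikes, "deep")
        assert psth.heights[20] == pytest.approx(2 / 3)

    def test_cells_averaged_with_equal_weight(self):
        active = CellSpikes(trains={"deep": [np.array([1.55])]})
        silent = CellSpikes(trains={"deep": [np.array([])]})
        spikes = SpikeTrainSet(cells=[active, silent], n_trials={"deep": 1})
        psth = compile_population_psth(spikes, "deep")
        assert psth.heights[15] == pytest.approx(0.5)
        assert psth.n_cells == 2

    def test_identical_cells_equal_single_cell(self):
        """Averaging k identical cells reproduces the single-cell PSTH."""
        one = _single_cell_set([[1.23, 4.56], [7.89]])
        psth1 = compile_population_psth(one, "deep")
        cells = [CellSpikes(trains={"deep": [np.array([1.23, 4.56]), np.array([7.89])]})
                 for _ in range(5)]
        many = SpikeTrainSet(cells=cells, n_trials={"deep": 2})
        psth5 = compile_population_psth(many, "deep")
        np.testing.assert_allclose(psth5.heights, psth1.heights)

    def test_out_of_window_spikes_discarded(self):
        psth = compile_population_psth(_single_cell_set([[12.0, 3.0]]), "deep")
        assert psth.heights.sum() == 1.0

    def test_empty_set_rejected(self):
        with pytest.raises(ConfigError):
            compile_population_psth(
                SpikeTrainSet(cells=[], n_trials={"deep": 0}), "deep"
            )


class TestBandpass:
    def test_passband_sinusoid_retained(self):
        t = PSTH_CENTERS / 1000.0  # seconds
        x = np.sin(2 * np.pi * 1000.0 * t)
        y = bandpass_heights(x)
        core = slice(20, 80)  # away from edges
        gain = np.sqrt(np.mean(y[core] ** 2) / np.mean(x[core] ** 2))
        assert gain == pytest.approx(1.0, abs=0.05)

    def test_dc_rejected(self):
        y = bandpass_heights(np.full(100, 3.7))
        assert np.max(np.abs(y)) < 1e-6

    def test_zero_phase_gaussian_bump(self):
        """Symmetric bump: filtered first major peak stays at the center."""
        bump = np.exp(-0.5 * ((PSTH_CENTERS - 5.0) / 0.2) ** 2)
        filt = bandpass_heights(bump)
        lat = first_peak_latency(filt, PSTH_CENTERS, blank_ms=3.0)
        assert lat == pytest.approx(5.0, abs=0.05)
        # cross-check against an independent forward-backward realization
        b, a = sig.butter(2, [400, 2000], btype="bandpass", fs=10_000)
        ref = sig.filtfilt(b, a, bump)
        assert np.argmax(ref) == pytest.approx(np.argmax(filt), abs=1)

    def test_band_edges_validated(self):
        psth = compile_population_psth(_single_cell_set([[2.0]]), "deep")
        with pytest.raises(ConfigError):
            bandpass_psth(psth, band=(400.0, 6000.0))


class TestFirstPeak:
    def test_single_bump(self):
        h = np.exp(-0.5 * ((PSTH_CENTERS - 3.05) / 0.15) ** 2)
        assert first_peak_latency(h, PSTH_CENTERS) == pytest.approx(3.05, abs=0.02)

    def test_two_equal_bumps_takes_first(self):
        h = np.exp(-0.5 * ((PSTH_CENTERS - 3.05) / 0.1) ** 2) + np.exp(
            -0.5 * ((PSTH_CENTERS - 4.55) / 0.1) ** 2
        )
        assert first_peak_latency(h, PSTH_CENTERS) == pytest.approx(3.05, abs=0.02)

    def test_small_early_ripple_ignored(self):
        h = 0.1 * np.exp(-0.5 * ((PSTH_CENTERS - 1.05) / 0.1) ** 2) + np.exp(
            -0.5 * ((PSTH_CENTERS - 4.05) / 0.1) ** 2
        )
        assert first_peak_latency(h, PSTH_CENTERS) == pytest.approx(4.05, abs=0.02)

    def test_no_peak_returns_none(self):
        assert first_peak_latency(np.zeros(100), PSTH_CENTERS) is None

    def test_blanking_excludes_early_artifact(self):
        h = 5.0 * np.exp(-0.5 * ((PSTH_CENTERS - 0.25) / 0.05) ** 2) + np.exp(
            -0.5 * ((PSTH_CENTERS - 2.55) / 0.1) ** 2
        )
        assert first_peak_latency(h, PSTH_CENTERS) == pytest.approx(2.55, abs=0.02)


class TestMonteCarlo:
    def test_identical_group_copies_null_identity(self, rng):
        """Group B an exact copy of group A: observed difference 0, p = 1."""
        cells = np.exp(
            -0.5 * ((PSTH_CENTERS - 2.55) / 0.2) ** 2
        ) + rng.normal(0, 0.01, size=(6, 100))
        res = monte_carlo_latency_test(cells, cells.copy(), PSTH_CENTERS, seed=0)
        assert res.observed_difference == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_groups_too_small_rejected(self):
        with pytest.raises(ConfigError):
            monte_carlo_latency_test(
                np.ones((1, 100)), np.ones((4, 100)), PSTH_CENTERS
            )

    def test_shuffles_preserve_group_sizes_and_p_range(self, default_spikes):
        from laminaprobe.psth import _cell_histograms

        a = _cell_histograms(default_spikes, "superficial", PSTH_EDGES)
        b = _cell_histograms(default_spikes, "deep", PSTH_EDGES)
        res = monte_carlo_latency_test(a, b, PSTH_CENTERS, n_shuffles=200, seed=5)
        assert res.n_shuffles + res.n_degenerate == 200
        assert 1 / 201 <= res.p_value <= 1.0

    def test_degenerate_shuffles_abort(self):
        # one responsive cell per group: shuffles putting both in the same
        # group leave the other group flat (no peak) in ~45% of draws,
        # exceeding the 10% degeneracy budget
        bump = np.exp(-0.5 * ((PSTH_CENTERS - 2.55) / 0.2) ** 2)
        group = np.vstack([bump, np.zeros((5, 100))])
        with pytest.raises(LaminaProbeError, match="degenerate"):
            monte_carlo_latency_test(
                group, group.copy(), PSTH_CENTERS, n_shuffles=200, seed=0
            )

    def test_flat_observed_groups_abort(self):
        flat = np.zeros((8, 100))
        with pytest.raises(LaminaProbeError, match="no qualifying peak"):
            monte_carlo_latency_test(flat[:4], flat[4:], PSTH_CENTERS, seed=0)


class TestAnova:
    def test_identical_groups(self):
        g = [1.0, 2.0, 3.0]
        res = one_way_anova([g, g, g])
        assert res.F == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_matches_brute_force_sums_of_squares(self):
        groups = [[6.0, 8.0, 4.0, 5.0], [8.0, 12.0, 9.0, 11.0], [13.0, 9.0, 11.0, 8.0]]
        res = one_way_anova(groups)
        # brute-force F from definitional sums of squares
        allv = np.concatenate(groups)
        gm = allv.mean()
        ssb = sum(len(g) * (np.mean(g) - gm) ** 2 for g in groups)
        ssw = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups)
        f_ref = (ssb / 2) / (ssw / (len(allv) - 3))
        assert res.F == pytest.approx(f_ref)

    def test_shifted_mean_detected(self, rng):
        g1 = rng.normal(0, 1, 200)
        g2 = rng.normal(0, 1, 200)
        g3 = rng.normal(0.8, 1, 200)
        assert one_way_anova([g1, g2, g3]).p < 0.01

    def test_degenerate_all_constant(self):
        res = one_way_anova([[1.0, 1.0], [1.0, 1.0]])
        assert res.degenerate and res.F == 0.0 and res.p == 1.0


class TestMeasureEpsp:
    def test_flat_trace_zero_amplitude(self):
        t = np.arange(0, 100.0, 0.04)
        m = measure_epsp(t, np.zeros_like(t))
        assert m.amplitude == 0.0 and m.peak_time is None

    def test_short_trace_rejected(self):
        t = np.arange(0, 50.0, 0.04)
        with pytest.raises(ConfigError):
            measure_epsp(t, np.zeros_like(t))

    def test_derivative_window(self):
        t = np.arange(0, 100.0, 0.04)
        m = measure_epsp(t, np.sin(t))
        assert m.derivative_time[0] >= 2.0 and m.derivative_time[-1] <= 12.0


class TestMeasurePassive:
    def test_ideal_rc_recovered(self):
        t = np.arange(0, 1000.0, 0.04)
        v = -0.08 * 100.0 * (1 - np.exp(-t / 15.0))
        pp = measure_passive(t, v, 0.08)
        assert pp.input_resistance == pytest.approx(100.0, rel=1e-3)
        assert pp.membrane_time_constant == pytest.approx(15.0, rel=1e-3)

    def test_doubled_current_doubles_deflection_not_resistance(self):
        t = np.arange(0, 1000.0, 0.04)
        v1 = -0.04 * 100.0 * (1 - np.exp(-t / 15.0))
        v2 = -0.08 * 100.0 * (1 - np.exp(-t / 15.0))
        r1 = measure_passive(t, v1, 0.04).input_resistance
        r2 = measure_passive(t, v2, 0.08).input_resistance
        assert r1 == pytest.approx(r2, rel=1e-6)

    def test_noisy_tau_recovered_within_five_percent(self, rng):
        t = np.arange(0, 1000.0, 0.04)
        clean = -0.08 * 100.0 * (1 - np.exp(-t / 15.0))
        taus = [
            measure_passive(t, clean + rng.normal(0, 0.1, t.size), 0.08).membrane_time_constant
            for _ in range(50)
        ]
        assert np.median(taus) == pytest.approx(15.0, rel=0.05)

    def test_large_deflection_warns(self):
        t = np.arange(0, 1000.0, 0.04)
        v = -0.2 * 100.0 * (1 - np.exp(-t / 15.0))
        with pytest.warns(UserWarning):
            measure_passive(t, v, 0.2)

    def test_nonexponential_rejected(self):
        t = np.arange(0, 1000.0, 0.04)
        with pytest.raises(FitError):
            measure_passive(t, np.zeros_like(t), 0.1)
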