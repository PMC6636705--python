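"""H-reflex quantification and the two-step EFD search."""

import numpy as np
import pytest

from laminaprobe.efd import (
    DelaySchedule,
    EarliestFacilitation,
    detect_onset,
    find_earliest_facilitation,
    fine_schedule,
    quantify_hreflex,
    rough_schedule,
    run_two_step_search,
    stage_rms_from_records,
)
from laminaprobe.errors import ConfigError, OnsetError, SearchError
from laminaprobe.simulate import (
    EmgTrace,
    MotoneuronPool,
    MotoneuronPoolConfig,
    simulate_conditioning_trial,
    simulate_efd_session,
)


def _trace(samples, stim=550):
    return EmgTrace(samples=np.asarray(samples, float), stimulus_sample=stim)


class TestSchedules:
    def test_rough_grid(self):
        sch = rough_schedule()
        assert sch.delays == (-5.0, -4.5, -4.0, -3.5, -3.0, -2.5, -2.0)
        assert sch.n_conditions == 8  # 7 delays + unconditioned
        assert sch.trials_per_delay == 15

    def test_fine_grid_anchored_more_negative(self):
        sch = fine_schedule(-3.5)
        assert len(sch.delays) == 11
        assert sch.delays[0] == pytest.approx(-4.5)
        assert sch.delays[-1] == pytest.approx(-3.5)
        assert np.allclose(np.diff(sch.delays), 0.1)

    def test_fine_grid_flipped_direction(self):
        sch = fine_schedule(-3.5, more_negative=False)
        assert sch.delays[0] == pytest.approx(-3.5)
        assert sch.delays[-1] == pytest.approx(-2.5)

    def test_unsorted_delays_rejected(self):
        with pytest.raises(ConfigError):
            DelaySchedule("rough", (-2.0, -5.0))


class TestQuantify:
    def test_constant_trace_zeroed_to_zero_rms(self):
        tr = _trace(np.full(1000, 7.5))
        m = quantify_hreflex(tr, onset_ms=20.0)
        assert m.rms == 0.0

    def test_hand_computed_window(self):
        samples = np.zeros(1000)
        i0 = 550 + 200  # onset 20 ms post-stimulus
        samples[i0 : i0 + 5] = [0.0, 3.0, -4.0, 0.0, 0.0]
        m = quantify_hreflex(_trace(samples), onset_ms=20.0)
        assert m.rms == pytest.approx(np.sqrt(5.0))

    def test_zeroing_removes_offset(self):
        samples = np.full(1000, 2.0)
        i0 = 550 + 200
        samples[i0 : i0 + 5] = [2.0, 5.0, -2.0, 2.0, 2.0]
        m = quantify_hreflex(_trace(samples), onset_ms=20.0)
        assert m.rms == pytest.approx(np.sqrt(5.0))

    def test_background_is_mean_rectified_pre_stimulus(self):
        samples = np.zeros(1000)
        samples[50:550] = -3.0
        m = quantify_hreflex(_trace(samples), onset_ms=20.0)
        assert m.background_emg == pytest.approx(3.0)

    def test_window_outside_trace_rejected(self):
        with pytest.raises(ConfigError):
            quantify_hreflex(_trace(np.zeros(600)), onset_ms=20.0)


class TestOnset:
    def test_constructed_onset_recovered_within_two_bins(self, rng):
        """Reflex starting exactly at a known sample: detected onset within
        0.2 ms of the true start."""
        from laminaprobe.simulate.motoneuron import _muap_kernel

        start = 550 + 172  # 17.2 ms post-stimulus
        kernel = 120.0 * _muap_kernel(30)
        traces = []
        for _ in range(10):
            samples = rng.normal(0, 2.0, 1000)
            samples[start : start + 30] += kernel
            traces.append(EmgTrace(samples=samples, stimulus_sample=550))
        onset = detect_onset(traces)
        assert onset == pytest.approx(17.2, abs=0.2)

    def test_simulated_onset_near_earliest_unit_arrival(self, default_pool):
        rng = np.random.default_rng(0)
        traces = [
            simulate_conditioning_trial(default_pool, None, seed=rng)[0]
            for _ in range(15)
        ]
        onset = detect_onset(traces)
        # detection waits for the across-trial mean to clear threshold, so
        # the onset sits at or shortly after the earliest unit arrival
        assert default_pool.true_onset_ms - 0.2 <= onset <= default_pool.true_onset_ms + 0.8

    def test_flat_noise_raises(self, rng):
        traces = [
            EmgTrace(samples=rng.normal(0, 3.0, 1000), stimulus_sample=550)
            for _ in range(10)
        ]
        with pytest.raises(OnsetError):
            detect_onset(traces)

    def test_override_returned_verbatim(self):
        assert detect_onset([], override=17.25) == 17.25

    def test_too_few_traces_rejected(self, rng):
        with pytest.raises(ConfigError):
            detect_onset([_trace(rng.normal(0, 1, 1000))] * 3)


class TestCriterion:
    @staticmethod
    def _stage(delay_effects, n=15, seed=0, sd=1.0):
        rng = np.random.default_rng(seed)
        uncond = rng.normal(10.0, sd, n)
        delay_rms = {
            d: rng.normal(10.0 + eff, sd, n) for d, eff in delay_effects.items()
        }
        return delay_rms, uncond

    def test_null_data_returns_none(self):
        sch = rough_schedule()
        effects = {d: 0.0 for d in sch.delays}
        hits = 0
        for seed in range(40):
            delay_rms, uncond = self._stage(effects, seed=seed)
            if find_earliest_facilitation(delay_rms, uncond, sch) is not None:
                hits += 1
        assert hits <= 2  # compound criterion keeps false positives rare

    def test_strong_facilitation_from_minus_3p5(self):
        sch = rough_schedule()
        effects = {d: (8.0 if d >= -3.5 else 0.0) for d in sch.delays}
        delay_rms, uncond = self._stage(effects)
        hit = find_earliest_facilitation(delay_rms, uncond, sch)
        assert isinstance(hit, EarliestFacilitation)
        assert hit.delay == -3.5
        assert not hit.at_schedule_edge

    def test_single_significant_delay_without_successors_is_rejected(self):
        sch = rough_schedule()
        effects = {d: (8.0 if d == -4.0 else 0.0) for d in sch.delays}
        delay_rms, uncond = self._stage(effects)
        assert find_earliest_facilitation(delay_rms, uncond, sch) is None

    def test_edge_hit_flagged(self):
        sch = rough_schedule()
        effects = {d: (8.0 if d >= -2.5 else 0.0) for d in sch.delays}
        delay_rms, uncond = self._stage(effects)
        hit = find_earliest_facilitation(delay_rms, uncond, sch)
        assert hit.delay == -2.5 and hit.at_schedule_edge

    def test_suppression_not_accepted_as_facilitation(self):
        sch = rough_schedule()
        effects = {d: (-8.0 if d >= -3.5 else 0.0) for d in sch.delays}
        delay_rms, uncond = self._stage(effects)
        assert find_earliest_facilitation(delay_rms, uncond, sch) is None

    def test_unpaired_lengths_rejected(self):
        sch = rough_schedule()
        delay_rms = {d: np.ones(10) for d in sch.delays}
        with pytest.raises(ConfigError):
            find_earliest_facilitation(delay_rms, np.ones(12), sch)


class TestTwoStep:
    @staticmethod
    def _collector(pool, rng):
        def collect(schedule):
            records, traces = simulate_efd_session(
                pool,
                schedule.delays,
                n_blocks=schedule.trials_per_delay,
                seed=rng.integers(2**31),
            )
            return stage_rms_from_records(records, traces)

        return collect

    def test_default_pool_recovers_minus_3p5(self):
        pool = MotoneuronPool(MotoneuronPoolConfig(), seed=5)
        rng = np.random.default_rng(0)
        res = run_two_step_search(self._collector(pool, rng))
        assert res.rough_efd == -3.5
        assert res.fine_efd == pytest.approx(-3.5)
        assert res.efd_plus_06 == pytest.approx(-2.9)
        assert len(res.fine_stats) == 11

    def test_offgrid_truth_recovered_to_one_tenth_ms(self):
        truth = -3.73
        cfg = MotoneuronPoolConfig(afferent_arrival=10.5 - truth)
        pool = MotoneuronPool(cfg, seed=8)
        rng = np.random.default_rng(2)
        res = run_two_step_search(self._collector(pool, rng))
        assert abs(res.fine_efd - (-3.7)) <= 0.1 + 1e-9

    def test_reproducible_across_identical_seeds(self):
        for _ in range(2):
            pool = MotoneuronPool(MotoneuronPoolConfig(), seed=5)
            rng = np.random.default_rng(0)
            res = run_two_step_search(self._collector(pool, rng))
            assert res.fine_efd == pytest.approx(-3.5)

    def test_no_rough_hit_aborts(self):
        # zero descending strengths: no facilitation anywhere
        from laminaprobe.simulate import VolleyComponent

        comps = tuple(
            VolleyComponent(c.arrival_offset, 0.0, c.circuit)
            for c in MotoneuronPoolConfig().volley_components
        )
        pool = MotoneuronPool(MotoneuronPoolConfig(volley_components=comps), seed=1)
        rng = np.random.default_rng(3)
        with pytest.raises(SearchError, match="rough"):
            run_two_step_search(self._collector(pool, rng))
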