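"""Motoneuron-pool recruitment model and conditioning trials."""

import numpy as np
import pytest

from laminaprobe.efd import detect_onset, quantify_hreflex
from laminaprobe.errors import ConfigError
from laminaprobe.simulate import (
    MotoneuronPool,
    MotoneuronPoolConfig,
    VolleyComponent,
    calibrate_afferent_strength,
    simulate_conditioning_trial,
    simulate_efd_session,
)


def test_unconditioned_recruitment_in_target_band(default_pool):
    rng = np.random.default_rng(0)
    frac = np.mean([default_pool.recruit(None, None, rng).mean() for _ in range(300)])
    lo, hi = default_pool.config.h_over_mmax_band
    assert lo <= frac <= hi


def test_afferent_calibration_hits_band_midpoint():
    cfg = MotoneuronPoolConfig()
    s = calibrate_afferent_strength(cfg)
    assert cfg.threshold_distribution().cdf(s) == pytest.approx(0.20, abs=1e-6)


def test_null_conditioning_matches_unconditioned():
    """All volley strengths zero: conditioned trials are distributionally
    identical to unconditioned (facilitation 100%)."""
    comps = tuple(
        VolleyComponent(c.arrival_offset, 0.0, c.circuit)
        for c in MotoneuronPoolConfig().volley_components
    )
    pool = MotoneuronPool(MotoneuronPoolConfig(volley_components=comps), seed=3)
    rng = np.random.default_rng(0)
    cond = [pool.recruit(pool.config.true_efd0, None, rng).sum() for _ in range(400)]
    unc = [pool.recruit(None, None, rng).sum() for _ in range(400)]
    assert np.mean(cond) == pytest.approx(np.mean(unc), rel=0.05)


def test_half_ms_before_earliest_coincidence_no_facilitation(default_pool):
    d = default_pool.config.true_efd0 - 0.5
    assert default_pool.coincident_drive(d, None) == 0.0


def test_recruitment_monotone_in_delay_across_volley_span(default_pool):
    """Temporal summation: coincident drive non-decreasing as the delay
    becomes less negative over the volley-arrival span."""
    efd0 = default_pool.config.true_efd0
    delays = np.round(np.arange(efd0 - 1.0, efd0 + 1.5 + 1e-9, 0.1), 10)
    drives = [default_pool.coincident_drive(d, None) for d in delays]
    assert all(b >= a for a, b in zip(drives, drives[1:]))


def test_doubling_superficial_gain_counts(default_pool):
    """Brute-force recruitment: doubling the superficial_late gain adds
    units at EFD+0.6 but not at EFD0 (component not yet coincident)."""
    efd0 = default_pool.config.true_efd0

    def count(delay, gain):
        rng = np.random.default_rng(42)  # same noise draws for both gains
        return default_pool.recruit(delay, {"superficial_late": gain}, rng).sum()

    assert count(efd0 + 0.6, 2.0) > count(efd0 + 0.6, 1.0)
    assert count(efd0, 2.0) == count(efd0, 1.0)


def test_recruited_never_exceeds_pool_size(default_pool):
    rng = np.random.default_rng(5)
    fired = default_pool.recruit(-2.0, {"deep_early": 50.0}, rng)
    assert fired.sum() <= default_pool.config.n_units


def test_emg_scales_linearly_with_count_for_nonoverlapping_muaps():
    cfg = MotoneuronPoolConfig(
        efferent_delay_sd=0.0, emg_noise_sd=0.0, m_wave_fraction=0.0
    )
    pool = MotoneuronPool(cfg, seed=0)
    # spread delays manually so MUAPs cannot overlap
    pool.efferent_delays = 3.0 + 4.0 * np.arange(cfg.n_units)
    rng = np.random.default_rng(0)
    amps = []
    for k in (5, 10, 20):
        fired = np.zeros(cfg.n_units, bool)
        fired[:k] = True
        tr = pool.emg_trace(fired, rng, trace_duration=600.0)
        amps.append(np.abs(tr.samples).sum())
    assert amps[1] == pytest.approx(2 * amps[0], rel=1e-6)
    assert amps[2] == pytest.approx(4 * amps[0], rel=1e-6)


def test_hreflex_rms_increases_with_recruited_count(default_pool):
    """RMS over the onset window grows with the number of recruited units."""
    rng = np.random.default_rng(1)
    uncond = [
        simulate_conditioning_trial(default_pool, None, seed=rng)[0] for _ in range(15)
    ]
    onset = detect_onset(uncond)
    rms_by_drive = []
    for extra in (0.0, 0.15, 0.35):
        gains = {"deep_early": 1.0 + extra / 0.15} if extra else None
        vals = []
        for _ in range(80):
            tr, _ = simulate_conditioning_trial(
                default_pool, default_pool.config.true_efd0, gains, seed=rng
            )
            vals.append(quantify_hreflex(tr, onset).rms)
        rms_by_drive.append(np.mean(vals))
    assert rms_by_drive[0] < rms_by_drive[1] < rms_by_drive[2]


def test_conditioning_trial_deterministic():
    cfg = MotoneuronPoolConfig()
    t1, m1 = simulate_conditioning_trial(cfg, -3.5, seed=11)
    t2, m2 = simulate_conditioning_trial(cfg, -3.5, seed=11)
    np.testing.assert_array_equal(t1.samples, t2.samples)
    assert m1 == m2


def test_session_block_structure():
    records, traces = simulate_efd_session(
        MotoneuronPoolConfig(), delays=(-5.0, -4.5), n_blocks=4, seed=0
    )
    assert len(records) == 4 * 3  # 2 delays + unconditioned per block
    for b in range(4):
        block = [r for r in records if r["block"] == b]
        assert sorted(
            (r["delay_ms"] if r["delay_ms"] is not None else 99) for r in block
        ) == [-5.0, -4.5, 99]
    assert set(traces) == {r["emg_id"] for r in records}


def test_pool_validation():
    with pytest.raises(ConfigError):
        MotoneuronPoolConfig(n_units=10)
    with pytest.raises(ConfigError):
        MotoneuronPoolConfig(summation_window=0.0)
    with pytest.raises(ConfigError):
        VolleyComponent(0.0, -1.0, "deep_early")
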