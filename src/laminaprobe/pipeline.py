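"""End-to-end pipeline: simulate -> psth / efd / task stages.

`run_pipeline` executes the configured stages against synthetic data under
one root seed, writes each stage's outputs (JSON/CSV) into the output
directory and returns a :class:`~laminaprobe.io.RunManifest` describing
the run.  Identical config + seed reproduce identical outputs.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from ._rng import child_seeds
from .efd import run_two_step_search, stage_rms_from_records
from .errors import DependencyError
from .io import RunManifest, write_trial_table
from .psth import (
    bandpass_psth,
    compile_population_psth,
    first_peak_latency,
    monte_carlo_latency_test,
    one_way_anova,
    volley_latencies,
)
from .simulate import (
    CellSimConfig,
    ExperimentProtocol,
    MotoneuronPool,
    MotoneuronPoolConfig,
    TaskSimConfig,
    VolleySimConfig,
    simulate_efd_session,
    simulate_experiment,
    simulate_population_spikes,
    simulate_volley_sweep,
)
from .task import (
    annotate_hreflex,
    compare_conditions,
    exclude_trials,
    resting_baseline,
    subject_facilitation,
)

logger = logging.getLogger("laminaprobe")

__all__ = ["run_pipeline"]

DEFAULT_STAGES = ("invitro", "invivo", "efd", "task")


def _stage_invitro(cfg: dict, seed: int, outdir: Path) -> dict:
    n_cells = cfg.get("n_cells", 24)
    spikes = simulate_population_spikes(
        CellSimConfig(n_trials=cfg.get("n_trials", 100)), n_cells, seed
    )
    psths = {s: compile_population_psth(spikes, s) for s in spikes.sites}
    lat = {
        s: first_peak_latency(bandpass_psth(p)) for s, p in psths.items()
    }
    from .psth import _cell_histograms  # per-cell PSTHs for the shuffle test

    edges = psths["deep"].bin_edges
    centers = psths["deep"].bin_centers
    test = monte_carlo_latency_test(
        _cell_histograms(spikes, "superficial", edges),
        _cell_histograms(spikes, "deep", edges),
        centers,
        n_shuffles=cfg.get("n_shuffles", 1000),
        seed=seed + 1,
    )
    result = {
        "first_peak_latency_ms": lat,
        "superficial_minus_deep_ms": lat["superficial"] - lat["deep"],
        "monte_carlo_p_two_sided": test.p_value,
        "monte_carlo_p_one_sided": test.p_one_sided,
        "n_cells": n_cells,
    }
    (outdir / "invitro_latency.json").write_text(json.dumps(result, indent=2))
    return result


def _stage_invivo(cfg: dict, seed: int, outdir: Path) -> dict:
    vcfg = VolleySimConfig()
    sweep = simulate_volley_sweep(vcfg, n_trials=cfg.get("n_trials", 100), seed=seed)
    rows = []
    for (depth, intensity), arr in sweep.traces.items():
        vl = volley_latencies(sweep.t, arr.mean(axis=0))
        rows.append(
            {
                "depth_um": depth,
                "intensity_mA": intensity,
                "d_latency_ms": vl.d_latency,
                "i1_latency_ms": vl.i1_latency,
            }
        )
    table = pd.DataFrame(rows)
    table.to_csv(outdir / "invivo_latencies.csv", index=False)
    d_groups = [g.d_latency_ms.to_numpy() for _, g in table.groupby("depth_um")]
    anova_d = one_way_anova(d_groups)
    i1 = table.groupby("depth_um").i1_latency_ms.mean()
    result = {
        "d_wave_anova_p": anova_d.p,
        "i1_shallow_minus_deep_ms": float(i1.iloc[0] - i1.iloc[-1]),
    }
    (outdir / "invivo_summary.json").write_text(json.dumps(result, indent=2))
    return result


def _stage_efd(cfg: dict, seed: int, outdir: Path) -> dict:
    pool = MotoneuronPool(MotoneuronPoolConfig(), seed)
    rng_seed = [seed + 1]

    def collect(schedule):
        records, traces = simulate_efd_session(
            pool, schedule.delays, n_blocks=schedule.trials_per_delay, seed=rng_seed[0]
        )
        rng_seed[0] += 1
        return stage_rms_from_records(records, traces)

    result = run_two_step_search(collect, alpha=cfg.get("alpha", 0.05))
    (outdir / "efd_result.json").write_text(json.dumps(result.to_dict(), indent=2))
    return result.to_dict()


def _stage_task(cfg: dict, seed: int, outdir: Path, efd0: float | None) -> dict:
    if efd0 is None:
        raise DependencyError(
            "task stage requires an EFD 0 ms estimate: run the efd stage or set task.efd0"
        )
    pool_cfg = MotoneuronPoolConfig()
    pool = MotoneuronPool(pool_cfg, seed)
    protocol = ExperimentProtocol(
        epochs=tuple(cfg.get("epochs", ("cue_onset", "cue+400ms"))),
        trials_per_condition=cfg.get("trials_per_condition", 20),
        contamination_fraction=cfg.get("contamination_fraction", 0.05),
    )
    trials, traces = simulate_experiment(
        TaskSimConfig(n_trials=cfg.get("task_trials", 2000)),
        pool,
        protocol,
        seed=seed + 1,
        efd0=efd0,
    )
    # resting baseline from a short unconditioned resting session
    rest_records, rest_traces = simulate_efd_session(
        pool, delays=(), n_blocks=60, seed=seed + 2
    )
    _, rest_uncond = stage_rms_from_records(rest_records, rest_traces)
    rest_bg = [
        np.mean(np.abs(rest_traces[r["emg_id"]].samples[: 500]))
        for r in rest_records
    ]
    m, sd = resting_baseline(rest_bg)
    annotated, onset = annotate_hreflex(trials, traces)
    flagged = exclude_trials(annotated, m, sd)
    kept = flagged[~flagged.excluded]
    facil = subject_facilitation(kept)
    write_trial_table(flagged, outdir / "task_trials.csv")
    facil.to_csv(outdir / "task_facilitation.csv", index=False)
    result = {
        "onset_ms": onset,
        "n_trials": int(len(flagged)),
        "n_excluded": int(flagged.excluded.sum()),
    }
    (outdir / "task_summary.json").write_text(json.dumps(result, indent=2))
    return result


def run_pipeline(config: dict, seed: int, outdir) -> RunManifest:
    """Run the configured stages and write outputs + manifest to `outdir`.

    `config` keys: ``stages`` (subset of invitro/invivo/efd/task, in
    order) and per-stage option dicts.  Stage failures halt the run with
    the stage named in the exception context.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = config.get("stages", list(DEFAULT_STAGES))
    seeds = dict(zip(DEFAULT_STAGES, child_seeds(seed, len(DEFAULT_STAGES))))
    manifest = RunManifest(root_seed=seed, config=config, component_seeds=seeds)
    efd0 = config.get("task", {}).get("efd0")
    for stage in stages:
        t0 = time.perf_counter()
        logger.info("stage %s: seed %d", stage, seeds[stage])
        if stage == "invitro":
            _stage_invitro(config.get("invitro", {}), seeds[stage], outdir)
        elif stage == "invivo":
            _stage_invivo(config.get("invivo", {}), seeds[stage], outdir)
        elif stage == "efd":
            res = _stage_efd(config.get("efd", {}), seeds[stage], outdir)
            efd0 = res["fine_efd_ms"]
        elif stage == "task":
            _stage_task(config.get("task", {}), seeds[stage], outdir, efd0)
        else:
            raise DependencyError(f"unknown stage {stage!r}")
        logger.info("stage %s done in %.1f s", stage, time.perf_counter() - t0)
    for p in sorted(outdir.iterdir()):
        if p.is_file() and p.name != "manifest.json":
            manifest.record_output(p)
    manifest.save(outdir / "manifest.json")
    return manifest
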