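"""Shared fixtures: synthetic peak maps and a small simulated study."""
from __future__ import annotations

import math

import numpy as np
import pytest

import mbrquant as mq


def build_peak_map(
    run_id: str = "R1",
    peaks: list[tuple[float, float, float, float]] = (),
    rt_span: tuple[float, float] = (0.0, 10.0),
    interval: float = 0.02,
    baseline: float = 0.0,
    baseline_mz: float | None = None,
    span_sigmas: float = 4.0,
) -> mq.RunPeakMap:
    """Peak map with Gaussian features given as (mz, apex_rt, sigma, area).

    ``baseline`` adds a constant intensity at ``baseline_mz`` over the whole
    RT span.  Peak heights are chosen so the analytic area equals ``area``.
    """
    scans = np.arange(rt_span[0], rt_span[1] + interval / 2, interval)
    mzs, rts, ys = [], [], []
    for mz, apex, sigma, area in peaks:
        height = area / (sigma * math.sqrt(2 * math.pi))
        sel = np.abs(scans - apex) <= span_sigmas * sigma
        t = scans[sel]
        mzs.append(np.full(t.size, mz))
        rts.append(t)
        ys.append(height * np.exp(-0.5 * ((t - apex) / sigma) ** 2))
    if baseline > 0 and baseline_mz is not None:
        mzs.append(np.full(scans.size, baseline_mz))
        rts.append(scans)
        ys.append(np.full(scans.size, baseline))
    if not mzs:
        return mq.RunPeakMap(run_id=run_id, mz=np.empty(0), rt=np.empty(0),
                             intensity=np.empty(0))
    return mq.RunPeakMap(
        run_id=run_id,
        mz=np.concatenate(mzs),
        rt=np.concatenate(rts),
        intensity=np.concatenate(ys),
    )


@pytest.fixture(scope="session")
def small_sim() -> mq.SimulatedExperiment:
    """A small two-organism study: 3 H + 3 HY runs, 240 ions."""
    cfg = mq.SimConfig(n_runs_h=3, n_runs_hy=3, n_proteins=40,
                       ions_per_protein=6, noise_features=5000,
                       noise_pool=2000, seed=123)
    return mq.simulate_experiment(cfg)


@pytest.fixture(scope="session")
def small_result(small_sim) -> mq.PipelineResult:
    cfg = mq.PipelineConfig(ion_fdr=0.05, peptide_fdr=0.05, protein_fdr=0.05)
    return mq.run_pipeline(small_sim.peak_maps, small_sim.psms, cfg)
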