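"""Shared fixtures: one mid-size simulated data set and one full pipeline
run, reused across test modules to keep the suite fast."""

from __future__ import annotations

import numpy as np
import pytest

import prokdyn as pk
from prokdyn.pipeline import PipelineConfig, run_pipeline
from prokdyn.simulate import simulate_expression, simulate_genome, simulate_tracks


@pytest.fixture(scope="session")
def sim_bundle():
    """Default-condition simulation: 300 genes, seed 1."""
    cfg = pk.SimulationConfig(seed=1, n_genes=300)
    rng = cfg.rng()
    genome, annotation, truth = simulate_genome(cfg, rng)
    tracks = simulate_tracks(genome, annotation, truth, cfg, rng)
    counts, lfq = simulate_expression(truth, cfg, rng)
    return {"config": cfg, "genome": genome, "annotation": annotation,
            "truth": truth, "tracks": tracks, "counts": counts, "lfq": lfq}


@pytest.fixture(scope="session")
def pipeline_results(tmp_path_factory):
    """Full end-to-end run at default scale (300 genes)."""
    outdir = tmp_path_factory.mktemp("pipeline")
    cfg = PipelineConfig(outdir=str(outdir), simulation=pk.SimulationConfig(seed=1, n_genes=300))
    results = run_pipeline(cfg)
    results["outdir"] = outdir
    return results


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
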