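"""End-to-end synthetic pipeline: simulate -> growth -> dynamics -> operons
-> TSS/motifs -> clustering -> cross-omics, with TSV exports and a run
manifest."""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import SimulationConfig
from .core import GroundTruth
from . import clustering, crossomics, dynamics, growth, io, motifs, operons, simulate, tss

log = logging.getLogger("prokdyn")


@dataclass
class PipelineConfig:
    outdir: str = "prokdyn_out"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    # operon calling
    d_max: int = 500
    f_min: float = 0.5
    # TSS detection / assignment
    min_starts: float = 10
    fold_bg: float = 5.0
    bg_window: int = 50
    max_upstream: int = 500
    # motifs
    motif_width: int = 6
    n_restarts: int = 20
    # clustering
    k_max: int = 50
    # growth phases (lag_end, growth_end, transition_end)
    phase_boundaries: tuple[float, float, float] = (24.0, 120.0, 144.3)
    lags: tuple[int, ...] = (0, 1)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = io.read_yaml(path)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        sim = raw.pop("simulation", {})
        if isinstance(sim, dict):
            sim_known = {f.name for f in dataclasses.fields(SimulationConfig)}
            bad = set(sim) - sim_known
            if bad:
                raise ValueError(f"unknown simulation keys: {sorted(bad)}")
            gp = sim.pop("growth_params", None)
            sim_cfg = SimulationConfig(**sim)
            if gp:
                sim_cfg.growth_params = simulate.GrowthParams(**gp)  # type: ignore[attr-defined]
            raw["simulation"] = sim_cfg
        return cls(**raw)


class StageError(RuntimeError):
    def __init__(self, stage: str, exc: Exception):
        super().__init__(f"[{stage}] {exc}")
        self.stage = stage


def _expand_minus35(model: motifs.MotifModel, mask: np.ndarray, n: int) -> motifs.MotifModel:
    """Lift a -35 model fitted on the -10-hit subset back onto all windows."""
    offsets = np.full(n, -1)
    hit = np.zeros(n, dtype=bool)
    idx = np.nonzero(mask)[0]
    offsets[idx] = model.offsets
    hit[idx] = model.hit
    return motifs.MotifModel(model.width, model.freq, offsets, hit,
                             float(hit.mean()), model.gamma, model.ll_trace,
                             model.degenerate)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the whole synthetic analysis; returns the result bundle and
    writes TSV twins of every overview table plus a run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    sim = config.simulation

    def stage(name):
        log.info("stage: %s", name)

    try:
        stage("simulate")
        rng = sim.rng()
        genome, annotation, truth = simulate.simulate_genome(sim, rng)
        tracks = simulate.simulate_tracks(genome, annotation, truth, sim, rng)
        counts, lfq = simulate.simulate_expression(truth, sim, rng)
        series = simulate.simulate_growth(sim)
        io.write_fasta(genome, outdir / "genome.fasta")
        io.write_annotation(annotation, outdir / "annotation.gff3")
        for strand, suffix in (("+", "plus"), ("-", "minus")):
            io.write_bedgraph(tracks.coverage[strand], outdir / f"coverage_{suffix}.bedgraph")
            io.write_bedgraph(tracks.five_prime[strand], outdir / f"fiveprime_{suffix}.bedgraph")
        io.write_matrix(counts, outdir / "transcript_counts.tsv")
        io.write_matrix(lfq, outdir / "protein_lfq.tsv")
        io.write_table(lfq.meta.reset_index(names="feature"), outdir / "protein_meta.tsv")
        io.write_ground_truth(truth, outdir / "truth")
        io.write_table(series.to_frame(), outdir / "growth.tsv")
        results.update(genome=genome, annotation=annotation, truth=truth,
                       tracks=tracks, counts=counts, lfq=lfq, growth_series=series)
    except Exception as exc:
        raise StageError("simulate", exc) from exc

    try:
        stage("growth")
        rates = growth.specific_product_formation(series)
        phases = growth.annotate_phases(series.t, config.phase_boundaries)
        io.write_table(growth.rates_to_frame(rates), outdir / "specific_product_formation.tsv")
        results.update(rates=rates, phases=phases)
    except Exception as exc:
        raise StageError("growth", exc) from exc

    try:
        stage("dynamics")
        normed, size_factors = dynamics.size_factor_normalize(counts)
        m_table = dynamics.compute_m_values(normed)
        records = dynamics.test_significance(normed, m_table)
        retained = dynamics.filter_dynamic(records)
        overview_t = dynamics.significance_overview(records)
        lfq_filtered, cascade_report = dynamics.proteome_filter_cascade(lfq)
        pm_table = dynamics.compute_m_values(lfq_filtered)
        p_records = dynamics.test_significance(lfq_filtered, pm_table, log_transform=False)
        overview_p = dynamics.significance_overview(p_records)
        io.write_table(records, outdir / "transcript_abundance.tsv")
        io.write_table(p_records, outdir / "protein_abundance.tsv")
        io.write_table(overview_t, outdir / "transcript_overview.tsv")
        io.write_table(overview_p, outdir / "protein_overview.tsv")
        results.update(m_table=m_table, records=records, retained=retained,
                       overview_transcript=overview_t, overview_protein=overview_p,
                       lfq_filtered=lfq_filtered, cascade_report=cascade_report,
                       protein_records=p_records, size_factors=size_factors)
    except Exception as exc:
        raise StageError("dynamics", exc) from exc

    try:
        stage("tss")
        candidates = tss.detect_tss(tracks.five_prime, config.min_starts,
                                    config.fold_bg, config.bg_window)
        assigned = tss.assign_primary_tss(candidates, annotation,
                                          config.max_upstream, genome)
        io.write_table(tss.tss_to_frame(assigned), outdir / "tss.tsv")
        results.update(tss_candidates=candidates, tss_assigned=assigned)
    except Exception as exc:
        raise StageError("tss", exc) from exc

    try:
        stage("operons")
        combined_cov = {s: tracks.coverage[s] for s in ("+", "-")}
        primaries, mono = operons.call_primary_operons(annotation, combined_cov,
                                                       config.d_max, config.f_min)
        by_gene = tss.tss_by_gene(assigned)
        primaries = operons.validate_operons(primaries, by_gene)
        subs = operons.derive_sub_operons(primaries, by_gene)
        summary = operons.summarize_operons(primaries, subs, mono, by_gene)
        io.write_table(operons.operons_to_frame(primaries + subs), outdir / "operons.tsv")
        io.write_yaml(dataclasses.asdict(summary), outdir / "operon_summary.yaml")
        results.update(primary_operons=primaries, sub_operons=subs,
                       monocistronic=mono, operon_summary=summary)
    except Exception as exc:
        raise StageError("operons", exc) from exc

    try:
        stage("motifs")
        windows = tss.extract_upstream_windows(assigned, genome)
        usable = [w for w in windows if len(w) >= config.motif_width]
        m10 = motifs.em_motif_search(usable, config.motif_width,
                                     config.n_restarts, seed=sim.seed)
        mask = m10.hit
        prefixes = [w[:int(o)] for w, o, h in zip(usable, m10.offsets, mask) if h]
        prefixes = [p for p in prefixes if len(p) >= config.motif_width]
        m35_full = None
        if len(prefixes) >= 10:
            sub_mask = np.zeros(len(usable), dtype=bool)
            j = 0
            for i, (w, o, h) in enumerate(zip(usable, m10.offsets, mask)):
                if h and len(w[:int(o)]) >= config.motif_width:
                    sub_mask[i] = True
            m35 = motifs.em_motif_search(prefixes, config.motif_width,
                                         config.n_restarts, seed=sim.seed + 1)
            m35_full = _expand_minus35(m35, sub_mask, len(usable))
        spacers = tss.spacer_statistics(m10, m35_full, [len(w) for w in usable])
        rbs = tss.rbs_and_start_stats(assigned, genome, annotation,
                                      seed=sim.seed, n_restarts=config.n_restarts)
        io.write_table(m10.freq_frame(), outdir / "minus10_matrix.tsv", index=True)
        if m35_full is not None:
            io.write_table(m35_full.freq_frame(), outdir / "minus35_matrix.tsv", index=True)
        results.update(minus10=m10, minus35=m35_full, spacers=spacers, rbs=rbs,
                       minus10_consensus=motifs.consensus_string(m10),
                       minus35_consensus=(motifs.consensus_string(m35_full)
                                          if m35_full else None))
    except Exception as exc:
        raise StageError("motifs", exc) from exc

    try:
        stage("cluster")
        m_sig = m_table[m_table["feature"].isin(retained)]
        profiles = clustering.prepare_profiles(m_sig, sim.n_timepoints)
        solution = clustering.cluster_profiles_klward(profiles, config.k_max)
        means, sizes = clustering.cluster_profiles(solution, profiles)
        enrich = clustering.category_enrichment(solution, counts.meta["category"])
        io.write_table(solution.assignments.rename("cluster").rename_axis("feature").reset_index(),
                       outdir / "transcript_clusters.tsv")
        io.write_table(means, outdir / "cluster_means.tsv", index=True)
        io.write_table(enrich, outdir / "cluster_enrichment.tsv")
        results.update(profiles=profiles, cluster_solution=solution,
                       cluster_means=means, cluster_sizes=sizes, enrichment=enrich)
    except Exception as exc:
        raise StageError("cluster", exc) from exc

    try:
        stage("crossomics")
        t_prof = clustering.prepare_profiles(m_table, sim.n_timepoints)
        p_prof = clustering.prepare_profiles(
            results["protein_records"][["feature", "time", "M"]].assign(
                M=results["protein_records"]["M"]), sim.n_timepoints)
        paired = crossomics.pair_features(t_prof, p_prof)
        t_sol, p_sol = crossomics.combined_clustering(paired, config.k_max)
        C = crossomics.co_occurrence(t_sol, p_sol)
        lag_tables = pd.concat([crossomics.lagged_pearson(paired, lag)
                                for lag in config.lags], ignore_index=True)
        io.write_table(C.round(1), outdir / "co_occurrence.tsv", index=True)
        io.write_table(lag_tables, outdir / "lag_correlation.tsv")
        results.update(paired=paired, t_solution=t_sol, p_solution=p_sol,
                       co_occurrence=C, lag_correlation=lag_tables)
    except Exception as exc:
        raise StageError("crossomics", exc) from exc

    manifest = {"version": __version__, "seed": sim.seed,
                "n_genes": sim.n_genes, "parameters": _manifest_params(config)}
    io.write_yaml(manifest, outdir / "manifest.yaml")
    results["manifest"] = manifest
    return results


def _manifest_params(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    d["simulation"] = config.simulation.to_dict()
    return _plainify(d)


def _plainify(obj):
    if isinstance(obj, dict):
        return {k: _plainify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plainify(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
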