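"""Synthetic-data generator with known ground truth.

Emulates the statistical structure of a growth-phase multi-omics study of a
high-GC filamentous actinomycete: an operon-dominated genome with planted
transcription start sites and -10/-35 promoter hexamers, strand-specific
whole-transcriptome coverage and 5'-read-start tracks, negative-binomial
transcript counts and log-normal protein LFQ intensities built from named
time-course archetypes, a one-time-point transcript-to-protein delay for a
configurable fraction of coupled genes, and logistic growth with
growth-coupled product formation.

All randomness flows from a single explicitly passed ``numpy`` generator
(defaulting to ``config.rng()``); the same seed gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .config import SimulationConfig
from .core import BASES, ExpressionMatrix, GeneFeature, GroundTruth, PlantedTSS
from .growth import GrowthSeries

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


class SizingError(ValueError):
    """Requested genome is too short for the requested gene layout."""


@dataclass
class Tracks:
    """Strand-specific per-position tracks (index 0 = genomic position 1)."""

    coverage: dict[str, np.ndarray]
    five_prime: dict[str, np.ndarray]


# ---------------------------------------------------------------------------
# genome, annotation, ground truth
# ---------------------------------------------------------------------------

def _sample_transcript_sizes(config: SimulationConfig, rng: np.random.Generator) -> list[int]:
    sizes, total = [], 0
    bins = np.array(sorted(config.operon_size_probs))
    probs = np.array([config.operon_size_probs[b] for b in bins])
    while total < config.n_genes:
        b = int(rng.choice(bins, p=probs))
        size = int(rng.integers(5, 8)) if b >= 5 else b
        size = min(size, config.n_genes - total)
        sizes.append(size)
        total += size
    return sizes


def _plant(seq: np.ndarray, pos0: int, bases: str, strand: str) -> None:
    """Overwrite genome sequence with ``bases`` given in transcript
    orientation; ``pos0`` is the 0-based genomic index of the motif's
    leftmost genomic base."""
    if strand == "+":
        for k, b in enumerate(bases):
            seq[pos0 + k] = b
    else:
        for k, b in enumerate(bases):
            seq[pos0 + len(bases) - 1 - k] = _COMPLEMENT[b]


def _draw_motif(pwm: np.ndarray, rng: np.random.Generator) -> str:
    return "".join(BASES[rng.choice(4, p=pwm[:, i])] for i in range(pwm.shape[1]))


def simulate_genome(config: SimulationConfig, rng: np.random.Generator | None = None
                    ) -> tuple[str, list[GeneFeature], GroundTruth]:
    """Generate a genome sequence, a non-overlapping annotation and the
    planted ground truth (operon map, TSS/promoters, archetype labels,
    transcript-protein coupling)."""
    config.validate()
    rng = config.rng() if rng is None else rng

    sizes = _sample_transcript_sizes(config, rng)
    margin = 700

    # --- layout pass: transcripts left to right along the genome
    transcripts = []  # (tid, strand, [GeneFeature genomic order])
    cursor = margin
    gene_no = 0
    for ti, size in enumerate(sizes):
        cursor += int(rng.integers(*config.inter_transcript_gap))
        strand = "+" if rng.random() < 0.5 else "-"
        genes = []
        for gi in range(size):
            if gi > 0:
                cursor += int(rng.integers(*config.intra_operon_gap))
            length = int(rng.integers(*config.gene_length_range))
            gene_no += 1
            genes.append(GeneFeature(f"g{gene_no:04d}", strand, cursor + 1, cursor + length))
            cursor += length
        transcripts.append((f"tx{ti:04d}", strand, genes))

    required = cursor + margin
    if config.genome_length is None:
        genome_length = required
    elif config.genome_length < required:
        raise SizingError(
            f"genome_length={config.genome_length} too short for "
            f"{config.n_genes} genes (need >= {required})")
    else:
        genome_length = config.genome_length

    gc = config.gc_content
    seq = rng.choice(np.array(BASES), size=genome_length,
                     p=[(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])

    # --- planting pass: TSS, promoters, RBS
    tss_list: list[PlantedTSS] = []
    s10_lo, s10_hi = config.spacer10_range
    s35_lo, s35_hi = config.spacer_35_10_range

    def plant_tss(gene: GeneFeature, utr: int, internal: bool, space: int) -> None:
        strand = gene.strand
        spacer10 = int(np.clip(round(rng.normal(*config.spacer10_mean_sd)), s10_lo, s10_hi))
        with_35 = (not internal) and rng.random() < config.minus35_prob
        spacer35 = int(np.clip(round(rng.normal(*config.spacer_35_10_mean_sd)), s35_lo, s35_hi)) \
            if with_35 else None
        need = utr + spacer10 + 6 + ((spacer35 + 6) if with_35 else 0) + 2
        if need > space:           # not enough intergenic room; shrink the UTR
            utr = max(0, space - (need - utr))
            if utr == 0 and space < spacer10 + 8:
                return             # no room at all, skip this promoter
        if strand == "+":
            tss = gene.start - utr
            start_idx = tss - 1
            m10_left = tss - spacer10 - 6 - 1   # 0-based leftmost index
            m35_left = None if spacer35 is None else m10_left - spacer35 - 6
        else:
            tss = gene.end + utr
            start_idx = tss - 1
            m10_left = tss + spacer10           # 0-based index of leftmost base
            m35_left = None if spacer35 is None else m10_left + 6 + spacer35
        base = BASES[rng.choice(4, p=config.purine_start_probs)]
        seq[start_idx] = base if strand == "+" else _COMPLEMENT[base]
        _plant(seq, m10_left, _draw_motif(config.minus10_pwm, rng), strand)
        if m35_left is not None:
            _plant(seq, m35_left, _draw_motif(config.minus35_pwm, rng), strand)
        leaderless = utr <= 3
        if not leaderless and utr > 10 and rng.random() < config.rbs_prob:
            gap = int(rng.integers(5, min(10, utr - 5) + 1))  # RBS 3' end -> TLS
            if strand == "+":
                _plant(seq, gene.start - gap - 5 - 1, "GGAGG", strand)
            else:
                _plant(seq, gene.end + gap, "GGAGG", strand)
        tss_list.append(PlantedTSS(tss, strand, gene.id, utr, leaderless, internal,
                                   with_35, spacer10, spacer35))

    all_feats = [g for _, _, genes in transcripts for g in genes]
    for i, (tid, strand, genes) in enumerate(transcripts):
        tx_order = genes if strand == "+" else genes[::-1]
        first = tx_order[0]
        if strand == "+":
            prev_end = 0 if first is all_feats[0] else all_feats[all_feats.index(first) - 1].end
            space = first.start - prev_end - 1
        else:
            idx = all_feats.index(first)
            next_start = genome_length if idx == len(all_feats) - 1 else all_feats[idx + 1].start
            space = next_start - first.end - 1
        if rng.random() < config.promoter_fraction:
            utr = (int(rng.integers(0, 4)) if rng.random() < config.leaderless_prob
                   else int(np.clip(round(rng.exponential(config.utr_scale)),
                                    *config.utr_length_range)))
            plant_tss(first, utr, internal=False, space=space)
        for j, gene in enumerate(tx_order[1:], start=1):
            if rng.random() < config.internal_tss_prob:
                prev = tx_order[j - 1]
                gap = (gene.start - prev.end - 1) if strand == "+" else (prev.start - gene.end - 1)
                utr_hi = min(config.utr_length_range[1], gap - 14)
                if rng.random() < config.leaderless_prob or utr_hi < 4:
                    utr = int(rng.integers(0, 4))
                else:
                    utr = int(np.clip(round(rng.exponential(config.utr_scale)), 4, utr_hi))
                plant_tss(gene, utr, internal=True, space=gap)

    operon_map = {g.id: tid for tid, _, genes in transcripts for g in genes}
    arch_names = list(config.archetype_set)
    tx_arch = {tid: arch_names[int(rng.integers(len(arch_names)))]
               for tid, _, _ in transcripts}
    cluster_labels = {g.id: tx_arch[operon_map[g.id]] for g in all_feats}
    gene_levels = {g.id: float(rng.lognormal(3.0, 0.5)) for g in all_feats}
    coupled = [(g.id, bool(rng.random() < config.protein_lag_fraction))
               for g in all_feats if rng.random() < config.protein_detection_rate]

    truth = GroundTruth(operon_map, tss_list, cluster_labels, coupled, gene_levels)
    return "".join(seq), all_feats, truth


# ---------------------------------------------------------------------------
# coverage and 5'-read-start tracks
# ---------------------------------------------------------------------------

def simulate_tracks(genome: str, annotation: list[GeneFeature], truth: GroundTruth,
                    config: SimulationConfig, rng: np.random.Generator | None = None) -> Tracks:
    """Whole-transcriptome coverage and 5'-read-start pile-ups per strand.

    Gene spans carry coverage proportional to the gene's planted expression
    level; intergenic spans inside an operon carry ``operon_span_fraction``
    of the smaller flanking gene coverage (transcripts span their internal
    gaps); planted TSS produce a read-start spike of ``tss_signal`` counts
    over a thin Poisson background.
    """
    rng = config.rng() if rng is None else rng
    L = len(genome)
    cov = {"+": np.zeros(L), "-": np.zeros(L)}
    fp = {"+": np.zeros(L), "-": np.zeros(L)}

    for g in annotation:
        cov[g.strand][g.start - 1:g.end] += truth.gene_levels.get(g.id, 1.0)

    by_tx: dict[str, list[GeneFeature]] = {}
    for g in annotation:
        by_tx.setdefault(truth.operon_map[g.id], []).append(g)
    for genes in by_tx.values():
        genes = sorted(genes, key=lambda g: g.start)
        for a, b in zip(genes, genes[1:]):
            lvl = config.operon_span_fraction * min(truth.gene_levels.get(a.id, 1.0),
                                                    truth.gene_levels.get(b.id, 1.0))
            cov[a.strand][a.end:b.start - 1] += lvl

    for strand in ("+", "-"):
        fp[strand] += rng.poisson(config.tss_background, L)
    for t in truth.tss_list:
        fp[t.strand][t.pos - 1] += config.tss_signal

    return Tracks(cov, fp)


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def _shift_one(shape: np.ndarray) -> np.ndarray:
    """Delay a profile by one time point; the first point is held."""
    return np.concatenate([[shape[0]], shape[:-1]])


def simulate_expression(truth: GroundTruth, config: SimulationConfig,
                        rng: np.random.Generator | None = None
                        ) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Transcript count and protein LFQ matrices around the planted
    archetype mean profiles.

    Counts are gamma-Poisson (negative binomial) with shared dispersion
    around archetype mean x library size; with ``nb_dispersion == 0`` (and
    ``library_size_cv == 0``) the exact means are returned.  Proteins exist
    only for coupled genes; flagged pairs follow the transcript archetype
    delayed by one time point; missingness applies to the LFQ layer only.
    """
    rng = config.rng() if rng is None else rng
    genes = list(truth.cluster_labels)
    T, R = config.n_timepoints, config.n_replicates
    shapes = {}
    for name, shape in config.archetype_set.items():
        shapes[name] = np.asarray(shape, dtype=float)
    for lab in set(truth.cluster_labels.values()):
        if lab not in shapes:
            raise KeyError(f"unknown archetype {lab!r}")

    cols = pd.MultiIndex.from_product([list(config.times), range(1, R + 1)],
                                      names=["time", "replicate"])
    lib = (rng.lognormal(0.0, config.library_size_cv, size=(T, R))
           if config.library_size_cv > 0 else np.ones((T, R)))

    base = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, size=len(genes))
    mean = np.stack([base[i] * shapes[truth.cluster_labels[g]][:, None] * lib
                     for i, g in enumerate(genes)])            # (G, T, R)
    if config.nb_dispersion > 0:
        lam = rng.gamma(1.0 / config.nb_dispersion, config.nb_dispersion * mean)
        counts = rng.poisson(lam).astype(float)
    else:
        counts = mean
    count_values = pd.DataFrame(counts.reshape(len(genes), T * R), index=genes, columns=cols)

    categories = rng.choice(list("CEGJKNOPT"), size=len(genes))
    count_meta = pd.DataFrame({"category": categories}, index=genes)
    count_mat = ExpressionMatrix(count_values, "transcript_counts", count_meta)

    prot_genes = [g for g, _ in truth.coupled_pairs]
    lagged = {g: flag for g, flag in truth.coupled_pairs}
    pbase = rng.lognormal(16.0, 1.0, size=len(prot_genes))
    pvals = np.empty((len(prot_genes), T, R))
    for i, g in enumerate(prot_genes):
        shape = shapes[truth.cluster_labels[g]]
        if lagged[g]:
            shape = _shift_one(shape)
        m = pbase[i] * shape[:, None] * np.ones((T, R))
        if config.lfq_sigma > 0:
            m = m * np.exp(rng.normal(0.0, config.lfq_sigma, size=(T, R)))
        pvals[i] = m
    if config.missing_rate > 0 and len(prot_genes):
        mask = rng.random(pvals.shape) < config.missing_rate
        pvals[mask] = np.nan
    lfq_values = pd.DataFrame(pvals.reshape(len(prot_genes), T * R),
                              index=prot_genes, columns=cols)

    n_p = len(prot_genes)
    upc = rng.choice([1, 2, 3, 4, 5, 6, 8, 10], size=n_p,
                     p=[0.08, 0.2, 0.2, 0.15, 0.12, 0.1, 0.08, 0.07])
    fraction = rng.choice(["cellular", "both", "extracellular"], size=n_p, p=[0.7, 0.2, 0.1])
    localization = rng.choice(["cytosolic", "membrane", "extracellular"],
                              size=n_p, p=[0.75, 0.15, 0.10])
    lfq_meta = pd.DataFrame({"unique_peptide_count": upc, "fraction": fraction,
                             "localization": localization,
                             "category": count_meta.loc[prot_genes, "category"]
                             if n_p else []}, index=prot_genes)
    lfq_mat = ExpressionMatrix(lfq_values, "protein_lfq", lfq_meta)
    return count_mat, lfq_mat


# ---------------------------------------------------------------------------
# growth curve
# ---------------------------------------------------------------------------

def simulate_growth(config: SimulationConfig) -> GrowthSeries:
    """Logistic biomass and growth-coupled product on the configured grid.

    The specific rate q(t) is a gamma-shaped pulse peaking at
    ``growth_params.t_peak``; product accumulates as the integral of
    q(t) X(t), hence is non-decreasing and flat in stationary phase.
    """
    gp = config.growth_params
    gp.validate()
    t_end = max(config.times)
    dense = np.linspace(0.0, t_end, int(t_end * 4) + 1)
    a = (gp.capacity - gp.x0) / gp.x0
    X = gp.capacity / (1.0 + a * np.exp(-gp.rate * dense))
    q = gp.q_max * (dense / gp.t_peak) * np.exp(1.0 - dense / gp.t_peak)
    P = cumulative_trapezoid(q * X, dense, initial=0.0)
    Xs = np.interp(config.times, dense, X)
    Ps = np.interp(config.times, dense, P)
    return GrowthSeries(np.asarray(config.times, dtype=float), Xs, Ps)
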