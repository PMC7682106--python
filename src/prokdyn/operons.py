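"""Operon calling from annotation plus combined coverage evidence.

Two adjacent same-strand genes are joined into one transcript when they are
close (intergenic distance <= ``d_max``) and the combined whole-
transcriptome coverage never collapses between them (minimum intergenic
coverage >= ``f_min`` x the smaller flanking-gene mean coverage).  Maximal
joined runs of >= 2 genes are primary operons; everything else is
monocistronic.  A primary operon whose first gene (in transcription order)
carries a TSS is experimentally validated; a TSS at a posterior gene spawns
a sub-operon running from that gene to the operon end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GeneFeature
from .dynamics import summarize_significance


@dataclass
class Operon:
    genes: list[str]            # transcription order
    strand: str
    klass: str = "primary"      # 'primary' | 'sub'
    validated: bool = False
    anchor_tss: int | None = None
    parent: str | None = None
    id: str = ""

    def __post_init__(self) -> None:
        if self.klass == "primary" and len(self.genes) < 2:
            raise ValueError("primary operon needs >= 2 genes")


@dataclass
class OperonSummary:
    n_primary: int
    n_sub: int
    n_monocistronic: int
    primary_by_size: dict[str, int] = field(default_factory=dict)
    sub_by_size: dict[str, int] = field(default_factory=dict)
    n_validated: int = 0
    pct_validated: float = 0.0
    n_mono_with_tss: int = 0
    pct_mono_with_tss: float = 0.0


def _size_bin(n: int) -> str:
    return str(n) if n < 5 else ">=5"


def _mean_cov(coverage: dict[str, np.ndarray], g: GeneFeature) -> float:
    return float(coverage[g.strand][g.start - 1:g.end].mean())


def call_primary_operons(annotation: list[GeneFeature], coverage: dict[str, np.ndarray],
                         d_max: int = 500, f_min: float = 0.5,
                         include_rna_genes: bool = True
                         ) -> tuple[list[Operon], list[str]]:
    """Join genes into primary operons; return (operons, monocistronic ids).

    ``coverage`` maps strand to a dense per-position array of the combined
    (summed over time points) whole-transcriptome coverage, position 1 at
    index 0.  RNA genes participate by default; set ``include_rna_genes``
    False to restrict joining to CDS.
    """
    for strand in ("+", "-"):
        if strand not in coverage:
            raise ValueError(f"missing coverage for strand {strand}")
    feats = sorted(annotation, key=lambda g: g.start)
    if not include_rna_genes:
        feats = [g for g in feats if g.type == "CDS"]

    runs: list[list[GeneFeature]] = []
    current: list[GeneFeature] = []
    for g in feats:
        if not current:
            current = [g]
            continue
        prev = current[-1]
        joined = False
        if g.strand == prev.strand:
            gap = g.start - prev.end - 1
            if gap <= d_max:
                if gap <= 0:
                    joined = True
                else:
                    span = coverage[g.strand][prev.end:g.start - 1]
                    floor = f_min * min(_mean_cov(coverage, prev), _mean_cov(coverage, g))
                    joined = bool(span.min() >= floor)
        if joined:
            current.append(g)
        else:
            runs.append(current)
            current = [g]
    if current:
        runs.append(current)

    operons, mono = [], []
    n_op = 0
    for run in runs:
        if len(run) >= 2:
            n_op += 1
            order = run if run[0].strand == "+" else run[::-1]
            operons.append(Operon([g.id for g in order], run[0].strand,
                                  id=f"op{n_op:04d}"))
        else:
            mono.append(run[0].id)
    return operons, mono


def validate_operons(operons: list[Operon], tss_by_gene: dict[str, list]) -> list[Operon]:
    """Flag a primary operon as experimentally validated when a TSS is
    assigned to its first gene (transcription order); record the anchor."""
    for op in operons:
        hits = tss_by_gene.get(op.genes[0], [])
        op.validated = bool(hits)
        op.anchor_tss = getattr(hits[0], "pos", hits[0]) if hits else None
    return operons


def derive_sub_operons(operons: list[Operon], tss_by_gene: dict[str, list]) -> list[Operon]:
    """One sub-operon per internal-TSS gene position: the suffix of the
    parent primary operon starting at that gene (duplicates collapsed)."""
    subs = []
    seen = set()
    for op in operons:
        for j, gene in enumerate(op.genes):
            if j == 0 or gene not in tss_by_gene or not tss_by_gene[gene]:
                continue
            key = (op.id, j)
            if key in seen:
                continue
            seen.add(key)
            hits = tss_by_gene[gene]
            subs.append(Operon(op.genes[j:], op.strand, klass="sub",
                               validated=True,
                               anchor_tss=getattr(hits[0], "pos", hits[0]),
                               parent=op.id, id=f"{op.id}.s{j}"))
    return subs


def summarize_operons(operons: list[Operon], sub_operons: list[Operon],
                      monocistronic: list[str], tss_by_gene: dict[str, list]) -> OperonSummary:
    by_size: dict[str, int] = {}
    for op in operons:
        by_size[_size_bin(len(op.genes))] = by_size.get(_size_bin(len(op.genes)), 0) + 1
    sub_size: dict[str, int] = {}
    for op in sub_operons:
        sub_size[_size_bin(len(op.genes))] = sub_size.get(_size_bin(len(op.genes)), 0) + 1
    n_val = sum(op.validated for op in operons)
    n_mono_tss = sum(bool(tss_by_gene.get(g)) for g in monocistronic)
    return OperonSummary(
        n_primary=len(operons), n_sub=len(sub_operons), n_monocistronic=len(monocistronic),
        primary_by_size=by_size, sub_by_size=sub_size,
        n_validated=n_val,
        pct_validated=summarize_significance(n_val, len(operons)) if operons else 0.0,
        n_mono_with_tss=n_mono_tss,
        pct_mono_with_tss=(summarize_significance(n_mono_tss, len(monocistronic))
                           if monocistronic else 0.0))


def operons_to_frame(operons: list[Operon]) -> pd.DataFrame:
    return pd.DataFrame({
        "operon": [op.id for op in operons],
        "class": [op.klass for op in operons],
        "strand": [op.strand for op in operons],
        "validated": [op.validated for op in operons],
        "anchor_tss": [op.anchor_tss for op in operons],
        "parent": [op.parent for op in operons],
        "genes": [",".join(op.genes) for op in operons],
    })
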