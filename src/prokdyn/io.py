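"""Readers and writers for the standard formats at the pipeline boundary.

Internal coordinates are 1-based inclusive; GFF3 shares that convention,
bedGraph is 0-based half-open and is converted on the way in and out.  TSV
is the universal tabular format (UTF-8, '.' decimal separator, NA for
missing).
"""

from __future__ import annotations

import os
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import ExpressionMatrix, GeneFeature, GroundTruth, PlantedTSS, long_to_matrix, matrix_to_long


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(sequence: str, path: str | Path, seqid: str = "chr") -> None:
    SeqIO.write([SeqRecord(Seq(sequence), id=seqid, description="")], str(path), "fasta")


def read_fasta(path: str | Path) -> tuple[str, str]:
    """Return (seqid, sequence) of the first record."""
    rec = next(SeqIO.parse(str(path), "fasta"))
    return rec.id, str(rec.seq).upper()


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def write_annotation(features: list[GeneFeature], path: str | Path, seqid: str = "chr") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in features:
            attrs = f"ID={g.id}"
            fh.write("\t".join([seqid, "prokdyn", g.type, str(g.start), str(g.end),
                                ".", g.strand, ".", attrs]) + "\n")


def read_annotation(path: str | Path) -> list[GeneFeature]:
    """GFF3 -> GeneFeature list (1-based inclusive coordinates preserved)."""
    _validate_gff3(path)
    db = gffutils.create_db(str(path), dbfn=":memory:", keep_order=True,
                            merge_strategy="create_unique")
    out = []
    for f in db.all_features(order_by="start"):
        fid = f.attributes.get("ID", [f.id])[0]
        out.append(GeneFeature(fid, f.strand, f.start, f.end, f.featuretype))
    return out


def _validate_gff3(path: str | Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise ValueError(f"{path}:{lineno}: malformed GFF3 line (needs >= 8 fields)")
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end < start:
                raise ValueError(f"{path}:{lineno}: end < start")
            if fields[6] not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: strand required")


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------

def write_bedgraph(track: np.ndarray, path: str | Path, seqid: str = "chr") -> None:
    """Dense per-position track (index 0 = position 1) -> bedGraph with
    0-based half-open intervals; zero runs are omitted."""
    track = np.asarray(track)
    with open(path, "w") as fh:
        if len(track) == 0:
            return
        boundaries = np.nonzero(np.diff(track) != 0)[0] + 1
        starts = np.concatenate([[0], boundaries])
        ends = np.concatenate([boundaries, [len(track)]])
        for s, e in zip(starts, ends):
            v = track[s]
            if v != 0:
                fh.write(f"{seqid}\t{s}\t{e}\t{v:g}\n")


def read_bedgraph(path: str | Path, length: int | None = None,
                  count_track: bool = True) -> np.ndarray:
    """bedGraph (0-based half-open) -> dense 1-based array; overlapping
    intervals are summed."""
    try:
        df = pd.read_csv(path, sep="\t", comment="#",
                         names=["chrom", "start", "end", "value"])
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=["chrom", "start", "end", "value"])
    if len(df) and count_track and (df["value"] < 0).any():
        raise ValueError("negative values in a count track")
    L = length if length is not None else (int(df["end"].max()) if len(df) else 0)
    out = np.zeros(L)
    for _, row in df.iterrows():
        out[int(row["start"]):int(row["end"])] += row["value"]
    return out


# ---------------------------------------------------------------------------
# expression matrices / tables
# ---------------------------------------------------------------------------

def write_matrix(mat: ExpressionMatrix, path: str | Path) -> None:
    matrix_to_long(mat).to_csv(path, sep="\t", index=False, na_rep="NA")


def read_matrix(path: str | Path, layer: str, meta_path: str | Path | None = None
                ) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    meta = pd.read_csv(meta_path, sep="\t", index_col=0) if meta_path else None
    return long_to_matrix(df, layer, meta)


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, na_rep="NA")


# ---------------------------------------------------------------------------
# ground truth round-trip
# ---------------------------------------------------------------------------

def write_ground_truth(truth: GroundTruth, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"gene": list(truth.operon_map), "operon": list(truth.operon_map.values()),
                  "archetype": [truth.cluster_labels[g] for g in truth.operon_map],
                  "level": [truth.gene_levels.get(g, np.nan) for g in truth.operon_map]
                  }).to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
    pd.DataFrame({"pos": [t.pos for t in truth.tss_list],
                  "strand": [t.strand for t in truth.tss_list],
                  "gene": [t.gene for t in truth.tss_list],
                  "utr_length": [t.utr_length for t in truth.tss_list],
                  "leaderless": [t.leaderless for t in truth.tss_list],
                  "internal": [t.internal for t in truth.tss_list],
                  "has_minus35": [t.has_minus35 for t in truth.tss_list],
                  "spacer10": [t.spacer10 for t in truth.tss_list],
                  "spacer35": [t.spacer35 for t in truth.tss_list],
                  }).to_csv(outdir / "truth_tss.tsv", sep="\t", index=False)
    pd.DataFrame({"gene": [g for g, _ in truth.coupled_pairs],
                  "lagged": [f for _, f in truth.coupled_pairs]
                  }).to_csv(outdir / "truth_coupling.tsv", sep="\t", index=False)


def read_ground_truth(outdir: str | Path) -> GroundTruth:
    outdir = Path(outdir)
    genes = pd.read_csv(outdir / "truth_genes.tsv", sep="\t")
    tss = pd.read_csv(outdir / "truth_tss.tsv", sep="\t")
    coup = pd.read_csv(outdir / "truth_coupling.tsv", sep="\t")
    tss_list = [PlantedTSS(int(r.pos), r.strand, r.gene, int(r.utr_length),
                           bool(r.leaderless), bool(r.internal), bool(r.has_minus35),
                           None if pd.isna(r.spacer10) else int(r.spacer10),
                           None if pd.isna(r.spacer35) else int(r.spacer35))
                for r in tss.itertuples()]
    return GroundTruth(dict(zip(genes["gene"], genes["operon"])), tss_list,
                       dict(zip(genes["gene"], genes["archetype"])),
                       list(zip(coup["gene"], coup["lagged"].astype(bool))),
                       dict(zip(genes["gene"], genes["level"])))


# ---------------------------------------------------------------------------
# YAML config echo
# ---------------------------------------------------------------------------

def write_yaml(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False, default_flow_style=None)


def read_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
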