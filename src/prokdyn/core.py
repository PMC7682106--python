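"""Shared domain objects used across the pipeline stages.

Coordinates are 1-based inclusive and strand-explicit everywhere inside the
package; conversion to/from 0-based half-open happens only at the bedGraph
I/O boundary (see :mod:`prokdyn.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class GeneFeature:
    """A genomic feature (CDS or RNA gene), 1-based inclusive coordinates."""

    id: str
    strand: str
    start: int
    end: int
    type: str = "CDS"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start > self.end:
            raise ValueError(f"feature {self.id}: start {self.start} > end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def tls(self) -> int:
        """Translation start site: first base of the start codon."""
        return self.start if self.strand == "+" else self.end


@dataclass
class PlantedTSS:
    """Ground-truth transcription start site planted by the simulator."""

    pos: int
    strand: str
    gene: str
    utr_length: int
    leaderless: bool
    internal: bool = False
    has_minus35: bool = True
    spacer10: int | None = None
    spacer35: int | None = None


@dataclass
class GroundTruth:
    """Everything the simulator planted, for downstream recovery checks.

    ``operon_map`` maps every gene to its transcript id (monocistronic genes
    get their own singleton transcript). ``coupled_pairs`` lists genes with a
    detectable protein, with a flag marking the one-time-point translation
    delay.
    """

    operon_map: dict[str, str]
    tss_list: list[PlantedTSS]
    cluster_labels: dict[str, str]
    coupled_pairs: list[tuple[str, bool]]
    gene_levels: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        genes = list(self.operon_map)
        if len(genes) != len(set(genes)):
            raise ValueError("every gene must appear exactly once in operon_map")


class ExpressionMatrix:
    """feature x time x replicate abundance table for one omics layer.

    ``values`` is a DataFrame indexed by feature id with a (time, replicate)
    column MultiIndex. ``layer`` is ``transcript_counts`` or ``protein_lfq``.
    ``meta`` holds per-feature metadata (fraction, localization,
    unique_peptide_count, category).
    """

    LAYERS = ("transcript_counts", "protein_lfq")

    def __init__(self, values: pd.DataFrame, layer: str, meta: pd.DataFrame | None = None,
                 normalized: bool = False):
        if layer not in self.LAYERS:
            raise ValueError(f"unknown layer {layer!r}")
        if not isinstance(values.columns, pd.MultiIndex) or values.columns.nlevels != 2:
            raise ValueError("values must have a (time, replicate) column MultiIndex")
        arr = values.to_numpy(dtype=float)
        finite = arr[np.isfinite(arr)]
        if not normalized:
            if layer == "transcript_counts" and (finite < 0).any():
                raise ValueError("counts must be non-negative")
            if layer == "protein_lfq" and (finite < 0).any():
                raise ValueError("LFQ intensities must be positive or missing")
        self.values = values
        self.layer = layer
        self.normalized = normalized
        self.meta = meta if meta is not None else pd.DataFrame(index=values.index)

    @property
    def features(self) -> pd.Index:
        return self.values.index

    @property
    def times(self) -> list:
        return list(dict.fromkeys(self.values.columns.get_level_values(0)))

    @property
    def replicates(self) -> list:
        return sorted(set(self.values.columns.get_level_values(1)))

    def replicate_mean(self) -> pd.DataFrame:
        """feature x time matrix of replicate means (NaN-aware)."""
        out = self.values.T.groupby(level=0).mean().T
        return out[self.times]

    def copy_with(self, values: pd.DataFrame, normalized: bool | None = None) -> "ExpressionMatrix":
        norm = self.normalized if normalized is None else normalized
        return ExpressionMatrix(values, self.layer, self.meta.loc[values.index], norm)


def long_to_matrix(df: pd.DataFrame, layer: str, meta: pd.DataFrame | None = None,
                   value_col: str = "value") -> ExpressionMatrix:
    """Build an :class:`ExpressionMatrix` from a long (feature, time, replicate,
    value) table, the on-disk TSV layout."""
    wide = df.pivot_table(index="feature", columns=["time", "replicate"],
                          values=value_col, aggfunc="first", dropna=False)
    return ExpressionMatrix(wide, layer, meta)


def matrix_to_long(mat: ExpressionMatrix) -> pd.DataFrame:
    long = mat.values.stack(["time", "replicate"], future_stack=True).rename("value").reset_index()
    long = long.rename(columns={"level_0": "feature"})
    if "feature" not in long.columns:
        long.columns = ["feature", "time", "replicate", "value"]
    return long
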