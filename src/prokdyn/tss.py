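"""TSS detection, primary-TSS assignment, 5'-UTR classes and promoter
statistics.

A transcription start site announces itself as a pile-up of read 5' ends in
a 5'-enriched library.  A position is a candidate when its read-start count
reaches ``min_starts`` and stands ``fold_bg``-fold above the local upstream
background.  Each CDS receives at most one primary TSS: the strongest
candidate within ``max_upstream`` nt upstream of its translation start site
(TLS); a TSS-to-TLS distance of at most 3 nt marks a leaderless transcript
(no room for a Shine-Dalgarno sequence).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GeneFeature
from .motifs import MotifModel, ZoopsEM

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

LEADERLESS_MAX_UTR = 3


def revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


@dataclass
class TSSRecord:
    position: int               # 1-based
    strand: str
    read_start_count: float
    assigned_feature: str | None = None
    utr_length: int | None = None
    leaderless: bool | None = None
    start_nucleotide: str | None = None


@dataclass
class SpacerStats:
    spacer_type: str            # 'minus10_to_TSS' | 'minus35_to_minus10'
    mean: float
    sd: float
    histogram: dict[int, int]
    n: int


def detect_tss(five_prime: dict[str, np.ndarray], min_starts: float = 10,
               fold_bg: float = 5.0, bg_window: int = 50) -> list[TSSRecord]:
    """Candidate TSS from per-strand 5'-read-start tracks.

    The background for a position is the mean start count over the
    ``bg_window`` nt immediately upstream in transcription direction
    (left of the position on '+', right on '-').
    """
    out = []
    for strand, track in five_prime.items():
        track = np.asarray(track, dtype=float)
        L = len(track)
        cs = np.concatenate([[0.0], np.cumsum(track)])
        pos_idx = np.nonzero(track >= min_starts)[0]
        for i in pos_idx:
            if strand == "+":
                lo, hi = max(0, i - bg_window), i
            else:
                lo, hi = i + 1, min(L, i + 1 + bg_window)
            n = hi - lo
            bg = (cs[hi] - cs[lo]) / n if n > 0 else 0.0
            if track[i] >= fold_bg * bg:
                out.append(TSSRecord(int(i + 1), strand, float(track[i])))
    return sorted(out, key=lambda t: t.position)


def assign_primary_tss(candidates: list[TSSRecord], annotation: list[GeneFeature],
                       max_upstream: int = 500, genome: str | None = None
                       ) -> list[TSSRecord]:
    """Assign each CDS its primary TSS.

    Every candidate first claims the nearest downstream TLS on its strand
    within ``max_upstream`` nt (this resolves overlapping claims); among a
    gene's claimants the highest read-start count wins, ties going to the
    TSS closer to the TLS.  Returned records carry the assigned feature,
    5'-UTR length, leaderless flag and (when the genome is given) the
    transcribed base at the TSS.
    """
    plus_tls = sorted([(g.tls, g) for g in annotation if g.strand == "+"])
    minus_tls = sorted([(g.tls, g) for g in annotation if g.strand == "-"])
    claims: dict[str, list[TSSRecord]] = {}
    for cand in candidates:
        best: tuple[int, GeneFeature] | None = None
        if cand.strand == "+":
            for tls, g in plus_tls:
                d = tls - cand.position
                if 0 <= d <= max_upstream:
                    best = (d, g)
                    break
        else:
            for tls, g in reversed(minus_tls):
                d = cand.position - tls
                if 0 <= d <= max_upstream:
                    best = (d, g)
                    break
        if best is not None:
            claims.setdefault(best[1].id, []).append(cand)

    assigned = []
    genes = {g.id: g for g in annotation}
    for gid, cands in claims.items():
        g = genes[gid]
        def dist(c: TSSRecord) -> int:
            return (g.tls - c.position) if g.strand == "+" else (c.position - g.tls)
        primary = min(cands, key=lambda c: (-c.read_start_count, dist(c)))
        d = dist(primary)
        primary.assigned_feature = gid
        primary.utr_length = int(d)
        primary.leaderless = d <= LEADERLESS_MAX_UTR
        if genome is not None:
            base = genome[primary.position - 1]
            primary.start_nucleotide = base if g.strand == "+" else revcomp(base)
        assigned.append(primary)
    return sorted(assigned, key=lambda t: t.position)


def extract_upstream_windows(tss_list: list[TSSRecord], genome: str, length: int = 50
                             ) -> list[str]:
    """Strand-aware windows of ``length`` nt immediately upstream of each
    TSS, excluding the TSS base itself; truncated (with a warning) at
    contig edges.  Minus-strand windows are reverse-complemented into
    transcript orientation."""
    out = []
    L = len(genome)
    for t in tss_list:
        if t.strand == "+":
            lo = max(0, t.position - 1 - length)
            win = genome[lo:t.position - 1]
        else:
            hi = min(L, t.position + length)
            win = revcomp(genome[t.position:hi])
        if len(win) < length:
            warnings.warn(f"window for TSS at {t.position} truncated to {len(win)} nt")
        out.append(win)
    return out


def spacer_statistics(minus10: MotifModel, minus35: MotifModel | None,
                      window_lengths: list[int] | np.ndarray) -> dict[str, SpacerStats]:
    """Spacer-length statistics from motif hit offsets.

    The -10-to-TSS spacer is the exclusive gap between the -10 hexamer's 3'
    end and the TSS (= window end, since windows exclude the TSS base); the
    -35-to--10 spacer is the exclusive gap between the -35 3' end and the
    -10 5' start, computed only for windows carrying both motifs.
    """
    window_lengths = np.asarray(window_lengths)
    out: dict[str, SpacerStats] = {}

    def stats(values: np.ndarray, kind: str) -> SpacerStats:
        if len(values) == 0:
            return SpacerStats(kind, float("nan"), float("nan"), {}, 0)
        hist: dict[int, int] = {}
        for v in values:
            hist[int(v)] = hist.get(int(v), 0) + 1
        return SpacerStats(kind, float(values.mean()), float(values.std(ddof=0)),
                           dict(sorted(hist.items())), int(len(values)))

    m10 = minus10.hit
    s10 = window_lengths[m10] - (minus10.offsets[m10] + minus10.width)
    out["minus10_to_TSS"] = stats(s10[s10 >= 0], "minus10_to_TSS")

    if minus35 is not None:
        both = m10 & minus35.hit
        s35 = minus10.offsets[both] - (minus35.offsets[both] + minus35.width)
        out["minus35_to_minus10"] = stats(s35[s35 >= 0], "minus35_to_minus10")
    return out


def rbs_and_start_stats(tss_list: list[TSSRecord], genome: str,
                        annotation: list[GeneFeature], rbs_window: int = 20,
                        min_utr: int = 10, width: int = 6, seed: int = 0,
                        n_restarts: int = 20) -> dict:
    """Ribosome-binding-site fraction and TSS start-nucleotide distribution.

    The RBS search runs the ZOOPS EM on the last ``rbs_window`` nt of each
    leadered 5'-UTR longer than ``min_utr`` nt (the Shine-Dalgarno
    positional range upstream of the TLS); the start-nucleotide
    distribution covers all assigned TSS.
    """
    genes = {g.id: g for g in annotation}
    windows = []
    for t in tss_list:
        if t.assigned_feature is None or t.leaderless or (t.utr_length or 0) <= min_utr:
            continue
        g = genes[t.assigned_feature]
        span = min(rbs_window, t.utr_length)
        if g.strand == "+":
            win = genome[g.tls - 1 - span:g.tls - 1]
        else:
            win = revcomp(genome[g.tls:g.tls + span])
        if len(win) >= width:
            windows.append(win)

    result: dict = {"n_searched_utrs": len(windows), "rbs_fraction": float("nan"),
                    "rbs_consensus": None, "rbs_model": None}
    if len(windows) >= 10:
        model = ZoopsEM(width=width, seed=seed, n_restarts=n_restarts).fit_model(windows)
        from .motifs import consensus_string
        result.update(rbs_fraction=model.fraction_with_hit,
                      rbs_consensus=consensus_string(model), rbs_model=model)

    bases = [t.start_nucleotide for t in tss_list if t.start_nucleotide]
    dist = {b: 0 for b in "ACGT"}
    for b in bases:
        dist[b] += 1
    n = max(len(bases), 1)
    result["start_nucleotide_counts"] = dist
    result["start_nucleotide_fractions"] = {b: c / n for b, c in dist.items()}
    result["purine_fraction"] = (dist["A"] + dist["G"]) / n if bases else float("nan")
    return result


def tss_to_frame(tss_list: list[TSSRecord]) -> pd.DataFrame:
    return pd.DataFrame({
        "position": [t.position for t in tss_list],
        "strand": [t.strand for t in tss_list],
        "read_start_count": [t.read_start_count for t in tss_list],
        "feature": [t.assigned_feature for t in tss_list],
        "utr_length": [t.utr_length for t in tss_list],
        "leaderless": [t.leaderless for t in tss_list],
        "start_nucleotide": [t.start_nucleotide for t in tss_list],
    })


def tss_by_gene(tss_list: list[TSSRecord]) -> dict[str, list[TSSRecord]]:
    out: dict[str, list[TSSRecord]] = {}
    for t in tss_list:
        if t.assigned_feature:
            out.setdefault(t.assigned_feature, []).append(t)
    return out
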