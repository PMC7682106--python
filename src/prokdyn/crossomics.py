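"""Transcriptome-proteome comparison: paired clustering, co-occurrence and
lagged correlation.

Only features quantified in both layers enter.  Each layer is clustered
independently (Ward + KL selection, k_max 50); the co-occurrence matrix
reports, for each transcriptome cluster i and proteome cluster j, the
percentage of i's members assigned to j (rows sum to 100).  Lagged Pearson
correlation compares transcript M-values at time t with protein M-values
at time t + lag across the paired features: a positive lag probes the
transcription-to-translation delay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .clustering import ClusterSolution, cluster_profiles_klward


@dataclass
class PairedFeatureSet:
    features: pd.Index
    transcript: pd.DataFrame        # feature x time replicate-mean M-values
    protein: pd.DataFrame
    n_transcript_only: int
    n_protein_only: int

    def __post_init__(self) -> None:
        if not self.transcript.index.equals(self.protein.index):
            raise ValueError("paired layers must share one feature index")
        if list(self.transcript.columns) != list(self.protein.columns):
            raise ValueError("paired layers must share the time axis")


def pair_features(transcript: pd.DataFrame, protein: pd.DataFrame) -> PairedFeatureSet:
    """Intersect the two layers on feature id (profiles are feature x time
    tables of M-values)."""
    common = transcript.index.intersection(protein.index)
    if len(common) == 0:
        raise ValueError(
            f"no shared features: {len(transcript)} transcript-only, "
            f"{len(protein)} protein-only")
    return PairedFeatureSet(common, transcript.loc[common], protein.loc[common],
                            len(transcript.index.difference(common)),
                            len(protein.index.difference(common)))


def combined_clustering(paired: PairedFeatureSet, k_max: int = 50,
                        k_transcript: int | None = None, k_protein: int | None = None
                        ) -> tuple[ClusterSolution, ClusterSolution]:
    """Cluster each layer independently over the paired feature set."""
    if len(paired.features) < 3:
        raise ValueError("need at least 3 paired features")
    t_sol = cluster_profiles_klward(paired.transcript.dropna(axis=0), k_max, k_transcript)
    p_sol = cluster_profiles_klward(paired.protein.dropna(axis=0), k_max, k_protein)
    return t_sol, p_sol


def co_occurrence(t_solution: ClusterSolution, p_solution: ClusterSolution
                  ) -> pd.DataFrame:
    """C[i, j] = 100 x |{f: T(f)=i and P(f)=j}| / |{f: T(f)=i}|.

    Rows (transcriptome clusters) sum to 100 exactly before rounding.
    """
    common = t_solution.assignments.index.intersection(p_solution.assignments.index)
    if len(common) == 0:
        raise ValueError("solutions share no features; empty transcriptome clusters")
    t = t_solution.assignments.loc[common]
    p = p_solution.assignments.loc[common]
    table = pd.crosstab(t, p)
    sizes = table.sum(axis=1)
    if (sizes == 0).any():
        raise ValueError("empty transcriptome cluster")
    C = table.div(sizes, axis=0) * 100.0
    C.index.name = "transcript_cluster"
    C.columns.name = "protein_cluster"
    return C


def lagged_pearson(paired: PairedFeatureSet, lag: int = 0, min_pairs: int = 3
                   ) -> pd.DataFrame:
    """Pearson r across paired features between transcript M at t and
    protein M at t + lag, for every valid time-point pair.

    Features missing either value are excluded pairwise; time pairs with
    fewer than ``min_pairs`` complete features get NaN.
    """
    times = list(paired.transcript.columns)
    if lag >= len(times) or lag < 0:
        raise ValueError("lag must lie in [0, n_timepoints)")
    rows = []
    for i in range(len(times) - lag):
        t_t, t_p = times[i], times[i + lag]
        x = paired.transcript[t_t]
        y = paired.protein[t_p]
        ok = x.notna() & y.notna()
        n = int(ok.sum())
        excluded_var = 0
        if n >= min_pairs and (x[ok].std() == 0 or y[ok].std() == 0):
            excluded_var = n
            r = np.nan
        elif n >= min_pairs:
            r = float(stats.pearsonr(x[ok], y[ok]).statistic)
        else:
            r = np.nan
        rows.append({"lag": lag, "transcript_time": t_t, "protein_time": t_p,
                     "r": r, "n": n, "n_zero_variance": excluded_var})
    return pd.DataFrame(rows)


def lag_comparison(paired: PairedFeatureSet, lags: tuple[int, ...] = (0, 1)) -> pd.DataFrame:
    """Mean Pearson r per lag (NaN-aware) over all valid time pairs."""
    frames = [lagged_pearson(paired, lag) for lag in lags]
    table = pd.concat(frames, ignore_index=True)
    mean_r = table.groupby("lag")["r"].mean().rename("mean_r").reset_index()
    return mean_r
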