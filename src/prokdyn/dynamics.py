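"""Pooled-reference relative-abundance tables with significance calls.

The pooled-reference design compares every time point against the mean
abundance over all time points, so a relative abundance of one (M = 0)
means "at the average level over the cultivation".  For each feature f and
time t the M-value is

    M_{f,t} = log2( mean_reps(value_{f,t}) / reference_f ),
    reference_f = mean over time points of the replicate-mean abundance,

which forces mean_t 2^{M_{f,t}} = 1 for every feature.  Significance per
(feature, time) is a Welch two-sample t-test of the time point's replicate
values against the pooled replicate values of all other time points (log
scale), Benjamini-Hochberg adjusted across all tests of a layer with the
significance boundary p_adj < 0.05 (strict).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import ExpressionMatrix

ALPHA = 0.05

MODIFICATION_TYPES = ("oxidation", "N-terminal acetylation", "phosphorylation", "pyro-Glu")
_MOD_DISPLAY = {"oxidation": "Oxidation", "N-terminal acetylation": "Acetylation",
                "phosphorylation": "Phosphorylation", "pyro-Glu": "Gln → pyro-Glu"}


# ---------------------------------------------------------------------------
# normalization and M-values
# ---------------------------------------------------------------------------

def size_factor_normalize(matrix: ExpressionMatrix) -> tuple[ExpressionMatrix, pd.Series]:
    """Median-of-ratios size-factor normalization of a count matrix.

    Size factors are the per-sample median ratio to the per-feature
    geometric-mean pseudo-reference (features with a zero anywhere are
    ignored for factor estimation), rescaled so the factors' geometric mean
    is exactly 1.  Returns the normalized matrix and the factors.
    """
    vals = matrix.values.to_numpy(dtype=float)
    if np.any(np.nansum(vals, axis=0) == 0):
        raise ValueError("all-zero sample; size factors undefined")
    with np.errstate(divide="ignore"):
        log_vals = np.log(vals)
    usable = np.all(np.isfinite(log_vals), axis=1)
    if not usable.any():
        raise ValueError("no feature with nonzero counts in every sample")
    log_ref = log_vals[usable].mean(axis=1)
    factors = np.exp(np.median(log_vals[usable] - log_ref[:, None], axis=0))
    factors = factors / np.exp(np.mean(np.log(factors)))
    norm = matrix.values / factors
    return matrix.copy_with(norm), pd.Series(factors, index=matrix.values.columns, name="size_factor")


def compute_m_values(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Long (feature, time, M) table of log2 fold changes against the
    all-time-points mean (the pooled reference).

    For abundance-scale matrices M = log2(mean_reps / reference) with
    reference the mean over time of the replicate means; features whose
    reference is zero get NaN M-values and a ``flagged`` mark.  For
    matrices already on a log scale (``normalized`` z-scores from the
    proteome cascade) the same contrast is the difference to the per-
    feature time mean, so that mean_t M = 0 replaces the ratio identity
    mean_t 2^M = 1."""
    repmean = matrix.replicate_mean()
    if matrix.normalized:
        m = repmean.sub(repmean.mean(axis=1), axis=0)
        ref = pd.Series(1.0, index=repmean.index)
    else:
        ref = repmean.mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            m = np.log2(repmean.div(ref, axis=0))
        m[ref <= 0] = np.nan
    out = m.stack().rename("M").reset_index()
    out.columns = ["feature", "time", "M"]
    out["flagged"] = out["feature"].map(ref <= 0).astype(bool)
    return out


# ---------------------------------------------------------------------------
# significance testing
# ---------------------------------------------------------------------------

def test_significance(matrix: ExpressionMatrix, m_table: pd.DataFrame | None = None,
                      log_transform: bool | None = None, alpha: float = ALPHA) -> pd.DataFrame:
    """Per (feature, time) Welch t-test against all other time points.

    ``log_transform=None`` picks log2(x+1) for the count layer and leaves
    already-normalized protein values untouched.  Benjamini-Hochberg
    adjustment runs across every computed test of the layer; ``significant``
    means p_adj strictly below ``alpha``.  Cells with fewer than two
    replicates get no p-value and are never significant.
    """
    if log_transform is None:
        log_transform = matrix.layer == "transcript_counts" or not matrix.normalized
    vals = matrix.values
    if log_transform:
        vals = np.log2(vals + (1.0 if matrix.layer == "transcript_counts" else 0.0))
    times = matrix.times
    arr = {t: vals.xs(t, axis=1, level="time").to_numpy(dtype=float) for t in times}
    rows = []
    for fi, feature in enumerate(matrix.features):
        per_time = {t: arr[t][fi][np.isfinite(arr[t][fi])] for t in times}
        for t in times:
            a = per_time[t]
            b = np.concatenate([per_time[u] for u in times if u != t]) if len(times) > 1 \
                else np.array([])
            if len(a) < 2 or len(b) < 2:
                p = np.nan
            elif np.ptp(a) == 0 and np.ptp(b) == 0 and a.mean() == b.mean():
                p = 1.0
            else:
                p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
                if math.isnan(p):   # zero variance in both groups, distinct means
                    p = 0.0 if a.mean() != b.mean() else 1.0
            rows.append((feature, t, p))
    records = pd.DataFrame(rows, columns=["feature", "time", "p"])
    records["p_adj"] = benjamini_hochberg(records["p"].to_numpy())
    records["significant"] = records["p_adj"] < alpha
    if m_table is not None:
        records = m_table.merge(records, on=["feature", "time"], how="left")
    return records


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values; NaNs pass through unadjusted."""
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def filter_dynamic(records: pd.DataFrame) -> pd.Index:
    """Features retained for clustering: significant at >= 1 time point."""
    keep = records.groupby("feature")["significant"].any()
    return keep.index[keep]


# ---------------------------------------------------------------------------
# proteome filter cascade
# ---------------------------------------------------------------------------

def proteome_filter_cascade(matrix: ExpressionMatrix, min_unique_peptides: int = 2
                            ) -> tuple[ExpressionMatrix, dict]:
    """The proteome filtering rules, in order:

    1. drop proteins identified with fewer than ``min_unique_peptides``
       unique peptides;
    2. blank every (protein, time) cell in which the protein was not
       quantified in all replicates;
    3. z-normalize each protein's retained log2 intensities.

    Returns the filtered matrix (values are per-feature z-scores of log2
    intensity) and a report with per-rule removal counts, including how many
    retained proteins keep data at >= 6 of 7 time points.
    """
    report: dict[str, int] = {"n_input": len(matrix.features)}
    upc = matrix.meta.get("unique_peptide_count")
    if upc is None:
        raise ValueError("unique_peptide_count metadata required")
    keep = matrix.features[upc >= min_unique_peptides]
    report["removed_few_peptides"] = len(matrix.features) - len(keep)
    vals = matrix.values.loc[keep].copy()

    n_rep = len(matrix.replicates)
    blanked = 0
    for t in matrix.times:
        block = vals.xs(t, axis=1, level="time")
        incomplete = block.notna().sum(axis=1) < n_rep
        blanked += int(incomplete.sum())
        cols = [c for c in vals.columns if c[0] == t]
        vals.loc[incomplete[incomplete].index, cols] = np.nan
    report["cells_blanked"] = blanked

    log_vals = np.log2(vals)
    mu = log_vals.mean(axis=1)
    sd = log_vals.std(axis=1, ddof=0)
    z = log_vals.sub(mu, axis=0).div(sd.replace(0.0, np.nan), axis=0)

    per_time = pd.concat({t: z.xs(t, axis=1, level="time").notna().any(axis=1)
                          for t in matrix.times}, axis=1)
    report["n_retained"] = len(z)
    report["n_at_least_6_of_7"] = int((per_time.sum(axis=1) >= max(len(matrix.times) - 1, 1)).sum())
    out = ExpressionMatrix(z, matrix.layer, matrix.meta.loc[keep], normalized=True)
    return out, report


def fraction_reconciliation(cellular: set[str], extracellular: set[str],
                            localization: pd.Series) -> tuple[pd.Series, dict]:
    """Assign each detected protein to a fraction.

    Proteins detected in both fractions and predicted extracellular (signal
    peptide) are treated as genuinely extracellular and removed from the
    cellular set; all other both-fraction proteins keep ``both``;
    single-fraction proteins keep their fraction.  Unknown localization
    labels are treated as cytosolic (with a warning count in the report).
    """
    import warnings

    known = {"cytosolic", "membrane", "extracellular"}
    assignment = {}
    counts = {"cellular": 0, "extracellular": 0, "both": 0,
              "both_reassigned_extracellular": 0, "unknown_labels": 0}
    for prot in sorted(cellular | extracellular):
        loc = localization.get(prot, "cytosolic")
        if loc not in known:
            warnings.warn(f"unknown localization {loc!r} for {prot}; treated as cytosolic")
            counts["unknown_labels"] += 1
            loc = "cytosolic"
        if prot in cellular and prot in extracellular:
            if loc == "extracellular":
                assignment[prot] = "extracellular"
                counts["both_reassigned_extracellular"] += 1
                counts["extracellular"] += 1
            else:
                assignment[prot] = "both"
                counts["both"] += 1
        elif prot in cellular:
            assignment[prot] = "cellular"
            counts["cellular"] += 1
        else:
            assignment[prot] = "extracellular"
            counts["extracellular"] += 1
    return pd.Series(assignment, name="fraction"), counts


# ---------------------------------------------------------------------------
# overview summaries
# ---------------------------------------------------------------------------

def summarize_significance(n: int, denominator: int, decimals: int = 1) -> float:
    """Percentage n/denominator, rounded half away from zero."""
    if denominator <= 0:
        raise ZeroDivisionError("denominator must be positive")
    if not 0 <= n <= denominator:
        raise ValueError("need 0 <= n <= denominator")
    x = 100.0 * n / denominator
    scale = 10 ** decimals
    return math.floor(abs(x) * scale + 0.5) / scale * (1 if x >= 0 else -1)


def significance_overview(records: pd.DataFrame, denominator: int | None = None) -> pd.DataFrame:
    """Per-time-point counts and percentages of significantly increased
    (M > 0) and decreased (M < 0) features."""
    if denominator is None:
        denominator = records["feature"].nunique()
    rows = []
    for t, grp in records.groupby("time", sort=True):
        sig = grp[grp["significant"].fillna(False)]
        n_up = int((sig["M"] > 0).sum())
        n_down = int((sig["M"] < 0).sum())
        rows.append({"time": t, "n_up": n_up, "n_down": n_down,
                     "denominator": denominator,
                     "pct_up": summarize_significance(n_up, denominator),
                     "pct_down": summarize_significance(n_down, denominator)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# post-translational modifications
# ---------------------------------------------------------------------------

@dataclass
class ModificationRecord:
    protein: str
    type: str
    time_points: list[str] = field(default_factory=list)
    residue: str | None = None

    def __post_init__(self) -> None:
        if self.type not in MODIFICATION_TYPES:
            raise ValueError(f"unknown modification type {self.type!r}")


def ptm_summary(records: list[ModificationRecord], exclude_oxidation: bool = True) -> pd.DataFrame:
    """Per-protein overview of modification types and the time points at
    which each was observed.  With ``exclude_oxidation`` (the publication-
    table view) oxidation records are dropped."""
    rows = []
    for rec in records:
        if exclude_oxidation and rec.type == "oxidation":
            continue
        rows.append({"protein": rec.protein, "modification": _MOD_DISPLAY[rec.type],
                     "time_points": "; ".join(rec.time_points)})
    if not rows:
        return pd.DataFrame(columns=["protein", "modification", "time_points"])
    df = pd.DataFrame(rows)
    return (df.groupby(["protein", "modification"], sort=True)["time_points"]
            .apply(lambda s: "; ".join(x for x in s if x)).reset_index())
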