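"""Simulation and pipeline configuration.

The simulator defaults encode the study conditions this package emulates: a
high-GC actinomycete genome, seven cultivation time points in three
biological replicates, an operon-dominated transcriptional architecture with
a ~14% leaderless-transcript fraction, TAnnnT / nTGACn promoter hexamers at
their observed spacings, and growth-coupled product formation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

#: The study's sampling grid (hours after inoculation).
DEFAULT_TIMES = (24.0, 47.8, 72.3, 96.5, 120.0, 144.3, 168.0)

#: Named mean-profile shapes (relative abundance multipliers on the 7-point
#: grid). Each archetype is a qualitative time-course class: transient
#: lag-phase expression, the ribosomal-protein-like monotone decline, a
#: growth-phase or transition-phase peak, late stationary induction, and a
#: flat (null) profile.
ARCHETYPES: dict[str, tuple[float, ...]] = {
    "lag_peak": (3.0, 0.6, 0.3, 0.3, 0.4, 0.6, 1.2),
    "monotone_decrease": (2.5, 2.0, 1.4, 1.0, 0.7, 0.5, 0.35),
    "growth_peak": (0.6, 1.8, 2.4, 1.8, 1.0, 0.6, 0.5),
    "transition_peak": (0.4, 0.6, 1.0, 1.6, 2.4, 1.8, 1.0),
    "stationary_rise": (0.5, 0.4, 0.5, 0.7, 1.0, 1.8, 3.0),
    "flat": (1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0),
}


def _default_minus10_pwm() -> np.ndarray:
    """Base-frequency matrix (rows A,C,G,T) for the -10 hexamer.

    Consensus TAnnnT with per-position conservation matching the reported
    motif (T 63.6% at position 1, A 90.8% at position 2, T 85.7% at
    position 6); unconstrained middle positions are near-uniform.
    """
    pwm = np.full((4, 6), 0.25)
    def col(base_idx, frac):
        c = np.full(4, (1.0 - frac) / 3.0)
        c[base_idx] = frac
        return c
    pwm[:, 0] = col(3, 0.636)   # T
    pwm[:, 1] = col(0, 0.908)   # A
    pwm[:, 5] = col(3, 0.857)   # T
    return pwm


def _default_minus35_pwm() -> np.ndarray:
    """nTGACn with T 67.9%, G 83.7%, A 53.0%, C 82.0% at positions 2-5."""
    pwm = np.full((4, 6), 0.25)
    def col(base_idx, frac):
        c = np.full(4, (1.0 - frac) / 3.0)
        c[base_idx] = frac
        return c
    pwm[:, 1] = col(3, 0.679)   # T
    pwm[:, 2] = col(2, 0.837)   # G
    pwm[:, 3] = col(0, 0.530)   # A
    pwm[:, 4] = col(1, 0.820)   # C
    return pwm


@dataclass
class GrowthParams:
    """Logistic growth plus growth-coupled product formation.

    Biomass follows X(t) = K / (1 + ((K - X0)/X0) exp(-r t)).  The specific
    product formation rate is a gamma-shaped pulse
    q(t) = q_max (t/t_peak) exp(1 - t/t_peak) peaking at ``t_peak`` hours,
    and product accumulates as P(t) = integral of q(t) X(t) dt, so P is
    non-decreasing and production ceases in stationary phase.
    """

    x0: float = 0.2          # g/L inoculum CDW
    rate: float = 0.045      # 1/h logistic rate
    capacity: float = 12.0   # g/L CDW plateau
    q_max: float = 4.5e-4    # g product / g CDW / h at the pulse peak
    t_peak: float = 40.0     # h, pulse maximum

    def validate(self) -> None:
        if self.rate <= 0 or self.capacity <= 0 or self.x0 <= 0 or self.t_peak <= 0:
            raise ValueError("growth parameters must be positive")
        if self.q_max < 0:
            raise ValueError("production coupling must be non-negative")


@dataclass
class SimulationConfig:
    """Knobs of the synthetic-data generator; defaults are the study
    conditions (see module docstring and docs/methods.md)."""

    seed: int = 0
    n_genes: int = 300
    genome_length: int | None = None            # auto-sized when None
    gc_content: float = 0.71
    # distribution over genes-per-transcript {1,2,3,4,>=5}; mono-dominated
    # with mean operon size ~2.7 genes as in the emulated architecture
    operon_size_probs: dict[int, float] = field(
        default_factory=lambda: {1: 0.82, 2: 0.12, 3: 0.03, 4: 0.02, 5: 0.01})
    internal_tss_prob: float = 0.4       # per posterior operon gene
    promoter_fraction: float = 0.4       # transcripts receiving a TSS+promoter
    minus35_prob: float = 0.7            # promoters that also carry a -35 box
    leaderless_prob: float = 0.14
    utr_length_range: tuple[int, int] = (4, 494)
    utr_scale: float = 80.0              # nt, exponential scale of leadered UTRs
    rbs_prob: float = 0.93               # leadered UTRs (>10 nt) with an RBS
    purine_start_probs: tuple[float, float, float, float] = (0.242, 0.123, 0.512, 0.123)  # A,C,G,T at the TSS
    minus10_pwm: np.ndarray = field(default_factory=_default_minus10_pwm)
    minus35_pwm: np.ndarray = field(default_factory=_default_minus35_pwm)
    spacer10_mean_sd: tuple[float, float] = (6.2, 1.1)
    spacer10_range: tuple[int, int] = (4, 9)
    spacer_35_10_mean_sd: tuple[float, float] = (17.6, 2.5)
    spacer_35_10_range: tuple[int, int] = (14, 22)
    # gene layout (nt)
    gene_length_range: tuple[int, int] = (300, 1500)
    intra_operon_gap: tuple[int, int] = (20, 80)
    inter_transcript_gap: tuple[int, int] = (250, 600)
    # tracks
    tss_signal: float = 50.0             # read starts at a planted TSS
    tss_background: float = 0.05         # mean background read starts/nt
    operon_span_fraction: float = 0.8    # intergenic coverage vs flanking genes
    # expression
    times: tuple[float, ...] = DEFAULT_TIMES
    n_timepoints: int = 7
    n_replicates: int = 3
    archetype_set: dict[str, tuple[float, ...]] = field(default_factory=lambda: dict(ARCHETYPES))
    baseline_log_mean: float = 5.0
    baseline_log_sd: float = 1.0
    nb_dispersion: float = 0.05
    library_size_cv: float = 0.1         # between-sample library size variation
    lfq_sigma: float = 0.2               # log-scale sd of protein intensities
    protein_detection_rate: float = 0.3  # genes with a quantified protein
    protein_lag_fraction: float = 0.5    # coupled genes delayed one time point
    missing_rate: float = 0.1            # LFQ missingness
    growth_params: GrowthParams = field(default_factory=GrowthParams)

    def validate(self) -> None:
        probs = [self.internal_tss_prob, self.promoter_fraction, self.minus35_prob,
                 self.leaderless_prob, self.rbs_prob, self.protein_detection_rate,
                 self.protein_lag_fraction, self.missing_rate, self.gc_content]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if abs(sum(self.operon_size_probs.values()) - 1.0) > 1e-9:
            raise ValueError("operon_size_probs must sum to 1")
        if abs(sum(self.purine_start_probs) - 1.0) > 1e-9:
            raise ValueError("purine_start_probs must sum to 1")
        lo, hi = self.utr_length_range
        if not (4 <= lo <= hi <= 494):
            raise ValueError("utr_length_range must lie within [4, 494]")
        if self.n_timepoints < 3:
            raise ValueError("need at least 3 time points")
        if len(self.times) != self.n_timepoints:
            raise ValueError("times must have n_timepoints entries")
        for name, shape in self.archetype_set.items():
            if len(shape) != self.n_timepoints:
                raise ValueError(f"archetype {name!r} has wrong length")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be non-negative")
        self.growth_params.validate()

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["minus10_pwm"] = self.minus10_pwm.tolist()
        d["minus35_pwm"] = self.minus35_pwm.tolist()
        return d
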