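# Methods

This note records the models behind `prokdyn`, the defaults and why they
were chosen, what the synthetic-data generator does and does not emulate,
and the numerical conventions a maintainer needs to know.

## Study design being modeled

The package targets bioreactor time courses of a filamentous, high-GC
actinomycete: seven sampling times (24.0, 47.8, 72.3, 96.5, 120.0, 144.3,
168.0 h) in three biological replicates, spanning lag, growth, transition
and stationary phase. Transcript abundances are expressed relative to a
pooled reference — physically, RNA pooled from all time points; here,
emulated as the per-feature mean over time — so M = 0 means "at the average
level over the cultivation". The proteome contributes cytosolic and
extracellular fractions quantified by label-free intensities.

## Growth and product formation

Biomass follows a logistic curve X(t) = K / (1 + ((K − X0)/X0)·e^(−rt))
with defaults X0 = 0.2 g L⁻¹, r = 0.045 h⁻¹, K = 12 g L⁻¹ — a plateau and
time-to-plateau typical of slow mycelial growth over a one-week
fermentation. No closed form for the production rate is assumed by the
analysis code; the simulator needs one, and uses a gamma-shaped pulse
q(t) = q_max·(t/t_peak)·e^(1 − t/t_peak) with t_peak = 40 h and
q_max = 4.5·10⁻⁴ g g⁻¹ h⁻¹, chosen so that the interval-wise rate peaks in
the first third of the sampling grid and declines monotonically into
stationary phase — the canonical growth-coupled production profile.
Product accumulates as P(t) = ∫ q(t)X(t)dt (trapezoidal on a 0.25 h grid),
hence is non-decreasing and flat once q vanishes.

`specific_product_formation` divides the product increment by the
arithmetic mean of the two endpoint CDW values and the interval length.
"Mean cell dry weight" is not otherwise pinned down; the endpoint mean is
the simplest estimator and makes the telescoping identity
Σ q_i·X̄_i·Δt_i = P_end − P_start exact, which the tests verify at machine
precision. Replicates are averaged before rate computation.

Phase labels use three ordered boundaries (lag_end, growth_end,
transition_end) = (24, 120, 144.3) h by default, with the convention
t ≤ lag_end → lag, lag_end < t < growth_end → growth,
growth_end ≤ t ≤ transition_end → transition, t > transition_end →
stationary. The boundary time 144.3 h is deliberately assigned to the
transition phase; times outside the configured range fall into the nearest
phase with a warning rather than erroring.

## Abundance tables and significance

Counts are normalized by median-of-ratios size factors (geometric-mean
pseudo-reference over features with no zeros; factors rescaled to
geometric mean exactly 1, so a globally scaled sample is equalized and the
factors are comparable across runs). The NB count model itself is not
re-fit here; normalization plus a replicate-level test stands in for a
dedicated differential-expression engine, keeping the pipeline
self-contained and one consistent test across both omics layers.

M-values: M_{f,t} = log₂(mean_reps(x)/x̄_f) on the abundance scale, which
forces mean_t 2^M = 1 per feature. Proteome values reach this step as
per-feature z-scores of log₂ LFQ (already log-scale), so the same contrast
becomes the difference to the per-feature time mean and the identity turns
into mean_t M = 0. Features with a zero reference are flagged and excluded
from M computation rather than producing infinities.

Significance per (feature, time) is a Welch two-sample t-test of the time
point's replicates against the pooled replicates of all other time points
— the "one time point vs. the rest" contrast implied by the pooled
reference. Welch rather than pooled-variance because homoscedasticity
across growth phases is implausible. Counts are tested on log₂(x+1).
Benjamini–Hochberg runs across all tests within a layer; the boundary is
strict (p_adj < 0.05, an exact 0.05 is not significant). Cells with fewer
than two replicate values get no p-value and are never significant.
Features with no significant time point are excluded from clustering; on a
pure-noise (flat-archetype) simulation ≥ 95% of features are excluded,
which the suite checks.

Proteome filter cascade, in order: (1) drop proteins with < 2 unique
peptides; (2) blank every (protein, time) cell not quantified in all
replicates; (3) z-normalize each protein's log₂ intensities over its
retained cells. Rules 1 and 2 commute (tested). Proteins observed in both
the cellular and extracellular fraction but carrying an extracellular
localization label (signal peptide) are reassigned to the extracellular
set only; unknown labels fall back to cytosolic with a warning.

Percentages in all overview tables are rounded half away from zero to one
decimal (the convention matching counts like 1421/8364 → 17.0 and
4143/4228 → 98.0).

## Operon and TSS inference

Operon joining: adjacent same-strand genes are joined when the intergenic
distance is ≤ d_max = 500 nt and the minimum combined coverage over the
gap is ≥ f_min = 0.5 × the smaller flanking-gene mean coverage. Both
thresholds are exposed; they are this package's stand-in for spanning-read
evidence in coverage space. Coverage is summed over all time points first,
which rescues operons expressed only in one phase. Transcription order is
left-to-right on +, right-to-left on −; sub-operons are suffixes of their
parent in that order, one per internal-TSS gene, duplicates collapsed.
rRNA/tRNA features participate in joining by default (toggleable).

TSS detection: a position is a candidate when its 5′-read-start count is
≥ min_starts = 10 and ≥ fold_bg = 5 × the mean count over the
bg_window = 50 nt immediately upstream (strand-aware). These thresholds
are this package's deterministic replacement for interactive curation; on
the simulator's planted signal (50 read starts over a 0.05/nt background)
recall and precision are ≈ 1. Each CDS takes the strongest candidate
within max_upstream = 500 nt of its TLS (a candidate first claims the
nearest downstream TLS, which resolves overlapping claims); ties break
toward the TSS closer to the TLS, for determinism. UTR ≤ 3 nt ⇒
leaderless.

## Promoter motifs (ZOOPS EM)

The motif model is a position frequency matrix over {A,C,G,T} with a
0-order background estimated from the windows. Per window the latent
variable is "no site" (probability 1−γ) or a site at one of the valid
offsets (uniform offset prior, γ split evenly). E-step: posterior over
offsets + no-site; M-step: weighted base counts with pseudocount 0.25 per
cell, γ re-estimated as the mean posterior site probability (clipped to
[10⁻⁶, 1−10⁻⁶]). Iteration stops when the log-likelihood gain is < 10⁻⁶
or after 500 iterations; the likelihood is monotone (tested). 20 restarts,
each seeded deterministically and initialized from a random window
subsequence (0.625 on the observed base); the best final likelihood wins.
A window "has" the motif when its posterior site probability is ≥ 0.5; the
reported offset is the posterior argmax. Degenerate input (a single
distinct base) is flagged rather than fitted. The −35 search runs on the
window prefixes upstream of each −10 hit, which keeps the second motif
from re-finding the first.

Spacers are exclusive gaps: −10 3′ end → TSS (window end, since windows
exclude the TSS base) and −35 3′ end → −10 5′ start, the latter only for
windows with both hits. The RBS search reuses the same EM on the last
≤ 20 nt of leadered 5′-UTRs longer than 10 nt — the Shine–Dalgarno
positional range.

## Clustering and model selection

Availability rule: ≥ ⌈2/3·n_t⌉ observed time points (≥ 5 of 7). Missing
interior values are linearly interpolated, which equals the
mean-of-neighbors rule for single gaps; for runs of two or more missing
interior points linear interpolation is the natural extension of that
rule. Missing boundary points copy the nearest observed value.

Ward linkage runs on Euclidean input with the standard variance-minimizing
Lance–Williams update ("Ward on Euclidean" convention); the test suite
pins this choice against an exhaustive greedy oracle that evaluates the
SSE increase of every candidate merge directly. W_k is the total squared
Euclidean distance to cluster centroids after cutting the tree at k. The
Krzanowski–Lai index is maximized over k ∈ [2, k_max] (k_max = 50 in the
full pipeline; W is computed up to k_max+1 so DIFF(k+1) exists); entries
with DIFF(k+1) = 0 are skipped, ties break toward smaller k (parsimony),
and a nearly flat KL trace draws a low-contrast warning. The index is
scale-invariant (scaling profiles by c scales every W_k by c², leaving KL
unchanged), which the suite checks.

Cluster–category enrichment is a hypergeometric upper-tail test per
(cluster, category) with BH across all pairs — the test itself is a
package choice, made for its exactness at small cluster sizes.

## Cross-omics

Only features present in both layers enter (counts of the excluded are
reported). Each layer is clustered independently with the same
Ward + KL machinery. Co-occurrence C[i,j] is the percentage of
transcriptome cluster i inside proteome cluster j; rows sum to 100 by
construction. Lagged Pearson correlation is computed across features
between transcript M at t and protein M at t+lag, per valid time pair,
replicate-mean M per (feature, time), pairwise deletion of missing values,
undefined below 3 complete pairs. The per-time-point-across-features
orientation is the package's contract; a per-feature-across-time mode can
be built from the same paired profiles.

## The synthetic-data generator

What it emulates: a ~0.71 GC genome (realized GC lands in the 0.69–0.73
band); a mono-cistron-dominated transcript-size distribution (82% size 1,
mean operon size ≈ 2.7); promoters for 40% of transcripts; internal TSS at
40% of posterior operon genes; 14% leaderless TSS, leadered UTRs
exponential (scale 80 nt) clipped to [4, 494] nt so ~90% are < 200 nt;
−10/−35 hexamers drawn column-wise from frequency matrices whose
conserved positions match the TAnnnT (63.6/90.8/85.7%) and nTGACn
(67.9/83.7/53.0/82.0%) conservation levels, at spacers N(6.2, 1.1) and
N(17.6, 2.5) nt (clipped); 70% of promoters carry a −35 box; RBS (GGAGG)
in 93% of leadered UTRs > 10 nt; purine TSS starts at 75.4% (A 24.2%,
G 51.2%); gamma-Poisson counts with shared dispersion 0.05 around
archetype mean × library size (CV 0.1 between samples — the between-
replicate variation is a knob because no published value pins it);
log-normal LFQ (σ = 0.2) for 30% of genes, half of them delayed by one
time point (the first protein time point holds the first transcript
value); 10% LFQ missingness. Six expression archetypes cover the
qualitative cluster shapes: lag peak, monotone decrease, growth peak,
transition peak, stationary rise, flat.

What it does not emulate: read-level sequencing noise (coverage tracks are
deterministic given gene levels; only the 5′ background is Poisson), codon
structure or start codons (the TLS is positional), mapping artifacts,
antisense transcription, condition-specific operon structure, peptide-level
proteomics noise, or batch effects. Archetype labels are shared within an
operon (co-transcription), but transcript abundance is simulated per gene,
not per transcript. Passing recovery tests therefore shows the inference
machinery is correct under the stated noise model — not that it is robust
to every artifact of real libraries.

All randomness flows from one `numpy` Generator seeded by `config.seed`
and passed explicitly through the stages; the same seed reproduces every
output bit-for-bit.

## Problem sizes and runtime

The default synthetic scale is 300 genes (≈ 380 kb genome, ~130 TSS,
~90 detected proteins), which exercises every stage and runs end-to-end in
a few seconds; the cluster-count recovery study uses 500 features with
five planted archetypes, and the acceptance script's lag study uses 150
genes with full delay coupling. These sizes were chosen so the whole
verification cycle stays interactive while keeping every per-stage sample
size large enough for the binomial tolerances used in the tests.

## Known limitations

* The operon joining rule is coverage-based; paired-end spanning evidence
  would be stronger where coverage dips inside real operons.
* EM motif offsets on weakly conserved planted motifs are noisier than
  curated promoter sets, so end-to-end spacer statistics have larger
  dispersion than the planted values; the spacer machinery itself is exact
  (verified on constructed hit sets).
* The KL index can overshoot k on unlucky geometry even with well-separated
  clusters (observed in ~5% of seeded recovery runs); inspecting the KL
  trace rather than trusting the argmax alone is advisable on real data.
* The transcript significance test is a replicate-level t-test, not a
  count-model test; at very low counts its power differs from NB-based
  engines.
* `fcluster`-cut Ward trees can in principle differ from strictly greedy
  merging when merge heights tie exactly; ties have measure zero for
  continuous data and do not occur in the tested regimes.
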