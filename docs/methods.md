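# Methods

## Problem setting

Patch-seq transcriptomes are mixtures: mostly the recorded neuron, plus mRNA
from microglial processes sampled through the pipette. The pipeline treats
contamination as a per-cell latent fraction and asks three questions — how
much (scoring), what it looks like transcriptionally (signatures,
enrichment), and what it covaries with (variance partitioning, ephys
association).

## Contamination score

For cell *c* of neuron type *N* and contaminant *M* (microglia),
`CS = clip((P − d_NM) / (d_MM − d_NM), 0, 1)` where `P` is the cell's summed
log2(CPM + 1) over the *M* off-marker panel and `d_NM`, `d_MM` are medians
of that sum over dissociated reference cells of type *N* and over
dissociated *M* cells. Conventions:

- **Pseudocount 1** in log2(CPM + 1), so zero counts map to exactly 0.
- **Medians** use the midpoint rule for even group sizes.
- **Clipping**: negative numerators (cell below its clean reference) are 0;
  values above the contaminant reference median are 1. Both boundaries are
  exact, not approximate.
- Reference medians come from the dissociated reference only, never from
  Patch-seq cells, and are computed once per neuron type.
- A reference in which `d_MM ≤ d_NM` is rejected as degenerate (the
  denominator must be positive).

Marker panels can be supplied as JSON or derived from a labelled reference:
the specificity of gene *g* for type *T* is mean log2 CPM in *T* minus the
maximum mean over all other types; the top-*n* genes with positive
specificity are taken (default n = 50), ties broken lexicographically by
gene id. Mitochondrial-flagged genes are removed before any normalization.

## Signatures

High/low groups are the top/bottom score quartiles (deciles available for
cohorts where high contamination is rare); boundary ties join the extreme
group. Differential expression uses the two-sided Wilcoxon rank-sum test —
exact by full label enumeration when both groups have ≤ 10 cells, otherwise
the tie-corrected normal approximation; genes constant across both groups
get p = 1. The fold change is computed on de-logged means with the
pseudocount re-added: `log2((mean CPM_high + 1) / (mean CPM_low + 1))`. A
gene passes at |log2FC| > 2.5 and p < 0.01 (unadjusted, as is conventional
for this contrast; a BH column is available downstream). The three
signatures are then pure set algebra: Patch-seq contamination (up-in-high
passing genes), general microglia (up in dissociated microglia vs pooled
neurons under the same machinery), shared (intersection) and Patch-seq
distinct (difference).

The clustering-association check selects the top-variance genes (default
2000), z-scales per gene, reduces to 20 principal components, clusters with
seeded k-means (default k = 4), and reports the one-way R² of contamination
score on cluster labels. The clustering algorithm is deliberately a config
detail; only the score–cluster association is a contract.

## Enrichment

Upper-tail hypergeometric test: with universe size U (genes measured after
filtering — not genome-wide, and recorded in the output), set size K (after
intersection with the universe), query size n and overlap k,
p = P(X ≥ k), X ~ Hypergeom(U, K, n), computed exactly. Only enrichment
(not depletion) is tested. BH step-up q-values across the collection.

## Mixed models and variance partitioning

All mixed models are Gaussian with independent random intercepts, fit by
REML (statsmodels MixedLM; crossed random factors are encoded as variance
components within a single all-spanning group). Fully aliased fixed terms
are dropped with a warning; non-converged fits are flagged and refused
downstream.

Covariate preparation: break-in time is hours since the donor's first
recorded cell (a donor's only cell gets 0); histology marker scores are
binned low (≤ 1) / high (> 1); transcriptomic-type labels collapse to their
first two tokens (subclass + first marker gene); types with < 20 cells are
excluded (configurable); continuous covariates are z-scaled with the sample
SD; rows with missing values in any used column are dropped and counted.

Nakagawa decomposition: with σ²_f the variance (n−1 denominator) of the
fixed-effect predictions, σ²_α the summed random-intercept variances and
σ²_ε the residual variance, R²m = σ²_f / (σ²_f + σ²_α + σ²_ε) and
R²c = (σ²_f + σ²_α) / (σ²_f + σ²_α + σ²_ε). Each fixed factor's share is
R²m(full) − R²m(reduced) where the reduced model *replaces* the factor with
a random intercept rather than dropping it; for continuous covariates the
replacement intercept is over quintile bins, which keeps the
replace-not-drop scheme estimable (the natural reading for categorical
factors does not extend to continuous ones). Negative differences — which
can arise because R² differences are not guaranteed non-negative — are
clipped to 0 and flagged. The donor share is R²c(full) − R²m(full), which is
non-negative by construction.

## Ephys association

Right-skewed features (input resistance, rheobase, AP half-width by
default) are log10-scaled; every feature is then standardized to mean 0,
sample SD 1. The contamination score is deliberately not standardized, so
betas are comparable across cohorts with different score spreads. Each
feature is modeled independently (no cross-feature multiplicity
correction): `feature ~ score + scale(depth) + (1 | t-type) + (1 | donor)`,
with a depth-free variant for datasets lacking depth. The p value for the
contamination beta uses the normal approximation on β̂/SE and the CI is
β̂ ± 1.96·SE; with the cohort sizes used here this is indistinguishable
from degree-of-freedom-corrected alternatives, and the calibration tests
below bound its error empirically. Univariate statistics: Pearson r with
two-sided t-based p, Kruskal–Wallis with χ² p, and the same rank-sum test
as the DE machinery for binary groupings.

## Synthetic-data generator

The generator is first-class, tested code; its defaults define the study
conditions used throughout the tests.

**Expression.** A gene catalog assigns each of 1000 genes one class: 50
markers per cell type (5 neuron types, microglia, astrocytes), a 40-gene
activated program, 13 mitochondrial genes, housekeeping remainder. Marker
genes have expected count 40 in their own type and 1 elsewhere (an 8×
specificity margin by construction); housekeeping 5 everywhere;
mitochondrial 50 everywhere; the activated program is exactly 0 in every
reference type. Counts are negative binomial (gamma–Poisson) with a single
global dispersion 0.3 and log-normal library-size factors of mean 1 scaled
to a 20,000-count expected library — standard single-cell stand-ins; the
real cohorts are observational and define no generative model, so all
distributional choices here are explicit stand-ins.

**Contamination.** Each of 1000 Patch-seq cells (50 donors × 20 cells)
draws logit(f) = 0.5 + u_donor + v_type + (−0.15)·break-in hours +
(−0.0015)·depth μm + ε, with u ~ N(0, 1²), v ~ N(0, 0.3²), ε ~ N(0, 0.5²).
Donor effects dominate, and break-in and depth effects are negative,
matching the qualitative structure reported for human cohorts; the
intercept puts the mean fraction near 0.26, in the range of reported human
means. Break-in times accumulate as exponential gaps (mean 0.75 h) within a
donor; depth is uniform on 100–1000 μm. The expected expression of a cell
is the convex mixture (1 − f)·λ_neuron + f·λ_microglia*, where λ_microglia*
is the dissociated microglial profile plus the activated program at 2⁵
expected counts — mixing at the mean level keeps the oracle analytic and
matches the score's linear logic. Donor-level histology scores co-vary with
the donor effect so the binned IBA1/GFAP association exists in truth.

**Ephys.** Each feature's latent value is baseline + scale·(γ·f + donor +
type + noise) with the bracket's variance built near 1
(donor SD 0.3, type SD 0.2, residual SD 0.9), so the configured γ is the
effect on the standardized scale the downstream model estimates; log10-
tagged features are emitted as 10^latent. Defaults carry effects of the
sign and magnitude reported for real cohorts (input resistance γ = −0.68,
AP trough +0.65, resting potential +0.24, rheobase +0.30) plus a null
feature (AP half-width, γ = 0) for type-I checks.

**What the generator does not emulate**: read-level sampling, per-gene
dispersion, dropout/zero inflation beyond NB sampling, multiple
contaminant sources (astrocyte contamination is held near zero, consistent
with it being a minor source in practice), batch or platform effects, and
raw voltage traces. Passing recovery tests therefore demonstrates that the
pipeline's inference machinery is correct under its assumed structure, not
that real data satisfy that structure.

## Verification and problem sizes

Every stage is tested against an independent oracle: exact enumeration for
the hypergeometric and rank-sum tests, hand step-up for BH, the balanced
one-way ANOVA moment estimator for REML variance components, OLS for the
zero-group-variance limit, one-way ANOVA R² for the single-factor variance
share, and ground-truth recovery on the generator for scores, signatures
and ephys effects. Calibration studies use reduced problem sizes chosen to
keep the suite quick while leaving comfortable statistical margins: the
ephys calibration runs 200 simulations of 240 cells (12 donors) and checks
≥ 85% CI coverage of the configured effect and a ≤ 8% type-I rate for the
null feature; the variance-partition ordering check runs 20 simulations of
225 cells with donor SD ≥ 3× any other effect. Determinism is bit-exact:
identical seeds give identical datasets and byte-identical pipeline
outputs.

## Known limitations

- The score is a monotone but nonlinear proxy of the true fraction (marker
  sums saturate on the log scale), so its absolute level overstates f in
  the mid-range; rank-based guarantees (Spearman ≥ 0.9) are the honest
  contract.
- Continuous-covariate reduced models (quintile bins) are one defensible
  reading of "replace with a random intercept"; shares for continuous
  factors should be read as approximate.
- Contamination scores are modeled as Gaussian responses despite living in
  [0, 1]; with the observed spreads this is the standard pragmatic choice,
  but heavily boundary-concentrated cohorts would warrant a generalized
  model, which is out of scope.
- One contaminant type per run; astrocyte scoring requires a second pass
  with an astrocyte panel.
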