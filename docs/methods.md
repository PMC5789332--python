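# Methods

`metaboflux` re-implements, as a tested pipeline, an expression-profiling
analysis of rat cerebellar granule neurons (CGNs) exposed to
cerebrospinal fluid (CSF) from multiple-sclerosis (MS) and neuromyelitis
optica (NMO) patients. Its scientific core is the **Cumulative Flux
Index (CFI)**, a multiplicative pathway score that summarises how the
transcriptional state of glycolysis, the TCA cycle and the electron
transport chain (ETC) is expected to scale metabolic flux.

## The CFI model

For a pathway P with enzymes g ∈ P, let r_g be the linear fold change of
gene g in a disease group versus control. The pathway score is

    CFI(P) = ∏_{g ∈ P} f_g,   f_g = r_g if g is called up- or
                              downregulated, else 1,

and the total CFI is the product over the three pathways. The score is a
simplified, linear cumulative reading of flux control: each enzyme's
transcript ratio is treated as an independent local scaling of its
catalysed step, so unchanged enzymes are flux-neutral and the pathway
collapses (or expands) as the product of its significant changes. No
kinetic or constraint-based flux model is attempted; metabolic-control
flux coefficients proper are out of scope. Consequences used as checks:
a single-gene change sets its pathway's CFI to that gene's factor; a
fully unchanged network has CFI exactly 1; the total is permutation
invariant and strictly monotone in every significant factor.

Two documented inconsistencies of the published summary table are
carried, not reconciled: the G+/M+ row's printed total (1.4e-5) differs
~14% from the product of its printed pathway values (1.59e-5), and the
NMO row's upregulated factors (three genes sharing a glycolysis index of
1.9656, i.e. ~1.25 each) sit below the study's own 2-fold callability
cutoff.

## Differential expression

Statistics run on log2 expression. Per gene: one-way fixed-effects ANOVA
across all six groups, then Tukey HSD contrasts of each disease group
against control, using the studentized-range distribution with the
Tukey–Kramer standard error (exactly equal to the pooled t-test when
only two groups exist — pinned to 1e-9 in tests). Benjamini–Hochberg
correction is applied per group contrast across genes, to the Tukey
p-values; the family choice is a design decision (the study names FDR
but not the family). A gene is called up (down) when its linear fold
change is ≥2 (≤0.5) and both the omnibus and the contrast p are <0.01
with q<0.1. Fold changes are ratios of geometric group means, consistent
with the log-scale tests; an arithmetic variant exists for sensitivity
checks only.

## Preprocessing

Stage order is fixed: NormExp background correction → 75th-percentile
scaling → pooled 30%-quantile low-expression filter → probe-to-gene
collapse by median.

*NormExp.* An observed spot intensity is modelled as X = B + S with
B ~ N(μ, σ²) scanner background and S ~ Exp(mean α) true signal.
Parameters are fitted per array by maximising the closed-form
convolution log-likelihood (moment starting values μ+α = mean,
σ²+α² = variance, 2α³ = third central moment; Nelder–Mead with a BFGS
polish — deterministic given the input). The corrected value is the
posterior mean E[S|X=x] = m + σφ(m/σ)/Φ(m/σ), m = x − μ − σ²/α,
evaluated in log space so it stays positive and strictly increasing far
into the left tail; a 20-point quadrature oracle pins the closed form at
1e-6 relative. At n = 10⁴ points the maximum-likelihood σ̂ still carries
~5–10% sampling error when α ≫ σ (background barely shapes the
likelihood); μ̂ and α̂ recover to ~1%.

*Scaling.* Each array is scaled so its 75th percentile equals the
geometric mean of all arrays' 75th percentiles — inter-array comparable
while retaining absolute scale for fold changes (a deliberate departure
from scaling to 1).

*Filter.* The threshold is the 0.30 quantile of all matrix entries
pooled; a row survives if its median across samples clears it. The row
statistic is a design decision (median, for robustness) since only the
pooled quantile is prescribed. A companion removal log records every
dropped row.

*Collapse.* Probes mapping to one gene collapse by per-sample median
(pinned against the mean dialect by a skewed-triple test).

## Reference genes

geNorm M: for candidate j, the mean over other candidates k of the
sample SD (n−1) of log2(x_j/x_k); computed via the covariance identity
Var(L_j−L_k) = V_jj + V_kk − 2V_jk and checked against a double-loop
oracle at 1e-12. The stepwise ranking removes the highest-M candidate
until two remain (ties: lexicographically last id removed, recorded).
M is invariant under per-sample scaling by construction.

NormFinder-style stability: log2 expression is decomposed into gene,
group, gene×group and residual terms. Per gene, intergroup variation is
the variance of the interaction effects, estimated by method of moments
with the double-centring bias and the sampling noise of cell means
subtracted (the estimator solves E[m_i] = (1−2/J)τ_i² + τ̄²/J exactly;
unbiased pre-truncation, verified by simulation); negative estimates are
truncated to zero, which inflates near-zero components by ~+0.02 at
three groups of four — a floor the tests account for. Intragroup
variation is the mean within-cell residual variance; stability is
√(inter + intra), lowest most stable.

Normalization divides each sample by the geometric mean of its control
genes (Tfrc, B2m for the headline pipeline — the study's stated
selection; both ranking methods are provided to re-derive it on
synthetic data). The operation is idempotent and removes per-sample
scale exactly. With only two controls of CV 0.1 it adds a shared
per-group log offset of SD ≈ 0.05 (natural log) to every fold change —
visible as correlated scatter in pathway products.

## Synthetic data generator

The generator emulates the study design: groups CTRL, RMS G+/M−,
RMS G+/M+, Spinal MS, PPMS, NMO; 4 independent culture replicates per
group (the study states 3–4; 4 is the default, configurable); one-color
intensities = truncated-at-zero Normal(100, 10) background plus
exponential-family signal with per-gene mean α·b_g·fc, α = 50.

The exponential variate is each gene's *latent baseline*, drawn once per
experiment — the hierarchical reading of the NormExp convolution (the
exponential describes the across-gene signal distribution on an array,
not replicate noise). Conditional on it, replicates vary by a mean-one
log-normal multiplier with CV 0.1 (biological + assay noise), and every
spot signal keeps its exponential marginal. Measured genes (planted,
stable and reference-panel candidates) have the baseline pinned at the
prior mean 1 and draw base expression b_g from the upper 0.6 decades of
the 2-decade log-uniform range: assayed genes are assayed because they
are reliably expressed, and the low-expression filter must not silently
delete a pathway gene planted down in most groups. Background-population
genes span the full range with random exponential baselines, so the
filter and the per-array NormExp fits have realistic work.

Planted disease effects reproduce the published qualitative pattern:
downregulated genes share their pathway's printed CFI equally on the log
scale (all implied factors fall in 0.23–0.33, clearing the ≤0.5 cutoff);
upregulated genes are planted at 2.5 (the published ~1.25 up-factors are
not callable under the study's own 2-fold rule, see above). The
reference-panel scenario perturbs the 8 non-control candidates with
signed log2 shifts of magnitude U(0.5, 1.5) per disease group,
rejection-sampled to ≥0.4 anchored-SD separation from flatness and from
each other — every candidate genuinely tracks treatment and no two are
spuriously co-regulated (a co-regulated pair is a known blind spot of
pairwise-ratio rankings and not the scenario emulated).

What the generator does **not** emulate: probe-level array artifacts
beyond an optional k-probes-per-gene expansion with technical scatter,
spatial effects, dye chemistry, laboratory batch covariates, and any
dependence structure between genes beyond the planted effects. Passing
recovery tests therefore demonstrates the statistical machinery under a
well-specified noise model, not robustness to real-array artifacts.

## Problem sizes and numerical choices

Simulated experiments default to 120 genes × 24 samples; the 50-seed
end-to-end recovery study and the 200-seed reference-gene study use
seeds 1–50 and 0–199 respectively, and the whole suite runs in a few
minutes on one core (the studentized-range survival function dominates,
at ~12 ms per evaluation). Pattern recovery is scored over all 55
pathway-gene × disease-group cells; pathway-CFI recovery is scored as
the geometric mean across seeds, because one n=4 experiment carries
15–25% sampling error on a multi-gene product — the seed-averaged value
isolates bias from noise. Degenerate inputs fail loudly: constant
columns in the NormExp fit, singleton groups in ANOVA/NormFinder,
all-rows-filtered matrices, non-positive expression in any log-scale
step, missing pathway genes in the CFI. The pipeline validates its
configuration before executing anything and leaves a
`MANIFEST.partial` marker on abort.

## Cohort module

The packaged 59-patient table transcribes the published clinical table
verbatim (`N.A.`/`U.` preserved as explicit missing markers, never
zeros). Summaries report n, female share and mean/SD (n−1) of age, EDSS
and progression time under three grouping schemes; CIS is counted within
relapsing MS in the classical scheme (required to reproduce the
published n=18) and spinal cases are assigned by their clinical course.
Between-group tests: chi-square without continuity correction on
gender×group, one-way ANOVA for ≥3 groups, pooled-variance t-test for
two (Welch by flag). The severity score (MSSS) is carried as printed
only — recomputing it needs an external population reference table. Two
published numbers are knowingly irreproducible from the printed records
and documented as such: the control mean age (40.3 printed vs 38.8
recomputed) and, consequently, the age ANOVA p (0.04 printed vs 0.078
recomputed).

## Network module

The interaction graph is read from a STRING-format edge list (integer
0–999 or float 0–1 score dialects auto-detected), thresholded at
combined score 0.4 ("medium confidence" — the study states none),
deduplicated keeping the maximum score, with database aliases resolved
(LOC689343 → Pk, ENSRNOG00000015290 → Tpi). The packaged edge list over
the 13 network genes is synthetic (hermetic tests; the live STRING
service is never queried) — see `data/string_edges_synthetic.tsv`.
Annotation attaches each node's up/down/nc call and the conventional
red/blue/grey colour without touching topology; GraphML export
round-trips losslessly.
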