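# Methods

This note records the statistical model behind each stage, the defaults and
why they were chosen, what the synthetic data do and do not emulate, and the
numerical decisions a maintainer would otherwise have to rediscover.

## Synthetic cohorts

The generator draws per-gene baselines μ_g ~ N(7, 1.5) on the log2 scale
(typical microarray intensities sit around 4–12 with unit-order spread) and
builds each sample as

    x = μ_g + effect·1[informative]·1[disease] + γ_cg + δ_cg·ε,

with γ_cg ~ N(0, batch_shift_sd), δ_cg ~ LogNormal(0, batch_scale_sd) drawn
once per (cohort, gene) and ε ~ N(0, noise_sd). This is exactly the
location/scale model the batch correction assumes, which is deliberate: it
makes harmonization well-specified so parameter recovery is a sharp test of
the implementation rather than of model mismatch.

Reference conditions (the package defaults): three training cohorts of
30 disease + 30 control samples, 2,000 genes, 5 informative genes with a
log2 effect of 2, batch_shift_sd = 1.0, batch_scale_sd = 0.25,
noise_sd = 1.0, plus two held-out validation cohorts of 20 + 20 generated
from the same gene-level truth. The batch scales were chosen so that the
raw merged data are dominated by cohort structure (cross-batch ANOVA
rejects for ~75% of genes; PCA separates cohorts with silhouette ≈ 0.97),
which is the regime multi-cohort microarray merges actually present.

The companion target fixture assigns each of 10 compounds a 10-gene list
drawing half (hit_fraction 0.5) from the informative genes and half from
random decoys, standing in for a target-prediction export. With 5
informative genes, each compound's 5 "hit" draws cover the full planted set,
so the candidate panel provably contains every informative gene that is
differentially expressed — the property the overlap tests score against.

What the generator does **not** emulate: probe-level effects, missing
values, intensity-dependent variance, count (RNA-seq) distributions,
correlated gene modules, or label noise. Passing tests therefore
demonstrate correctness of the machinery under its stated model, not
robustness to the full messiness of public expression data.

## Harmonization

Surrogate variables are estimated by SVD of the residuals after regressing
every gene on the condition design. The number of components k is chosen by
permutation parallel analysis: each residual row is permuted independently
and **re-projected onto the design's residual space** before computing the
null variance shares; without the re-projection the null shares are biased
low and pure-noise data yield spurious components. A component is kept
while its share exceeds the (1 − α) null quantile, stopping at the first
failure (α = 0.05, 20 permutations by default). Surrogates are reported as
diagnostics and may be passed to the correction as covariates; by default
they are not, since the two-step ordering leaves the coupling a user
choice (both modes are exposed).

The batch correction is the standard parametric empirical-Bayes
location/scale procedure: per-gene standardization against the
batch + condition design, per-batch location/scale estimation on the
standardized residuals, method-of-moments priors (Normal for location,
inverse-gamma for scale), and fixed-point iteration of the shrunk
estimates to a 1e-6 max-change tolerance (100 iteration cap; convergence
is typically < 20). Degenerate genes — zero variance inside any batch —
cannot support scale estimation; they are flagged and restored unadjusted.
A batch containing a single condition makes batch and condition
inseparable and is rejected outright.

Two numerical facts worth recording. First, with shrinkage disabled the
correction reduces to per-gene per-batch standardize-then-restore and is
oracle-checkable to 1e-8. Second, a *post hoc* batch ANOVA on corrected
data is strongly conservative (rejection ≈ 0, not ≈ α) because the
estimated batch means have been removed almost exactly; the EB shrinkage
residual is of order δ*²/(nτ² + δ*²) ≈ 5% of the raw estimate and far
below the test's detection threshold. Tests therefore assert the one-sided
bound (rejection falls to at most α) and, for idempotence, exact
second-pass vanishing of the batch estimates only on the no-shrinkage
path, with strong contraction (< 0.25×) on the EB path.

PCA diagnostics operate on the gene-centered matrix without scaling; the
sign of each component is fixed by making its largest-magnitude loading
positive so coordinates are reproducible.

## Differential expression

Moderated t: the pooled per-gene variance s_g² (d = n₁ + n₂ − 2 df) gets an
inverse-gamma(a, b) prior fitted across genes by moments
(a = m²/v + 2, b = m(a − 1) from the mean m and variance v of the s_g²),
and the test uses the posterior-mean variance on d + 2a df. When the
across-gene variance is degenerate the prior collapses to effectively no
shrinkage. Note the moderated and unmoderated statistics only converge at
large n when true gene variances are heterogeneous; with identical true
variances the prior df grows with the data and permanent shrinkage is the
*correct* EB behavior, not a bug.

BH adjustment is the literal step-up, preserving ties, restored to input
order. Default DEG call: |log2FC| ≥ 1 and q < 0.05, both configurable —
the thresholds are a convention, and the discovery counts on real cohorts
depend on them strongly.

## Overlap and enrichment

The candidate panel is the intersection of the DEG set with the union of
compound target lists, with per-gene compound provenance and lexicographic
ordering. Over-representation is an upper-tail hypergeometric
P(X ≥ k | N, K, n) over a user-declared universe (all study genes by
default), BH-corrected across the collection — equivalent to one-sided
Fisher exact on the 2×2 table, which the tests verify to 1e-12
exhaustively for N ≤ 25.

## Model zoo

Each of the 12 families is wrapped behind a common interface (scaling
pipelines for the linear/margin models); componentwise logit boosting,
PLS-logistic and forward-AIC stepwise logistic are implemented in-package
as small scikit-learn-compatible estimators since no installed library
provides them. The realized spec list is 12 standalones plus every enabled
selector × classifier pair (default selector: lasso, giving 24 specs); the
manifest records the realized count, which is configuration-dependent
rather than a fixed constant.

Nested CV: outer stratified 5-fold; inside each outer-training set the
selector (if any) is fitted first, then a small grid is tuned by inner
stratified 5-fold on AUC with ties resolved toward the stronger
regularization. The grids are deliberately small (one to two values per
family) to keep a 24-spec zoo tractable on one CPU; they are registry
entries, not hard-coded. Out-of-fold probabilities are assembled so every
sample is predicted exactly once by a model that never saw it.

Importances: |standardized coefficient| for the penalized/linear/LDA/
stepwise/boosted-linear families; impurity importances for the tree
ensembles; out-of-fold permutation importance (10 repeats, held-out
columns permuted per fold) for SVM, naive Bayes and PLS-logistic, whose
raw parameters do not rank features meaningfully. "Selected" means nonzero
coefficient (sparse families), stepwise inclusion, or importance above the
75th percentile (dense families). AUC is computed as the Mann-Whitney rank
statistic with half credit for ties. External cohorts are scored by the
full-training refit; panel genes missing from a validation study are
mean-imputed from training (coverage below 50% warns).

## Stacking

Base models pass the gate on **training OOF AUC** (the only leakage-safe
quantity available before validation data are touched); the published gate
value 0.945 is the default. Meta-features are the raw OOF probabilities —
bounded, monotone in the base scores, and exactly what the base models
emit. The meta-learner is logistic regression fitted by IRLS with a small
ridge penalty (1e-4) on the slopes only: near-perfect base models make the
meta-problem separable, and the penalty keeps coefficients finite without
materially biasing the fit. Convergence is a 1e-8 gradient max-norm, 200
iteration cap. The reported training AUC of the stack is in-sample with
respect to the meta-learner (one level of cross-validation, as is
conventional when a single training AUC is quoted); the comparison table
scores stacking against the best single model and the unweighted
probability average on training OOF and on each validation cohort.

## Redundancy-weighted ranking

Spearman ρ between model importance vectors uses average ranks; a constant
vector's correlation is defined as 0 (and flagged by placement in a
singleton cluster). Clusters are connected components of the graph with
edges ρ > 0.85 — the simplest rule consistent with "clustered" — and every
member of a cluster of size c weighs 1/c, the unique simple choice that
makes wsf exactly invariant to cloning a model. Models with an all-zero
importance vector keep weight 1 but contribute no selections. Ranking is
by descending wsf with lexicographic tie-break.

## Kernel SHAP

Coalition values average model predictions over background replacements of
the masked features (feature-independence approximation). Weights follow
the Shapley kernel; the infinite weights of the empty and full coalitions
are handled by imposing the efficiency constraint exactly (the constrained
WLS is solved by eliminating the last feature). Panels of ≤ 12 genes are
enumerated exhaustively — deterministic and, at the reference panel size of
5, also the cheapest option; the batched solver shares the coalition design
across all instances. Larger panels use seeded paired sampling (each
coalition with its complement) with sizes drawn from the kernel. The
explained function is the full stacked ensemble's disease probability
(refit base models composed with the meta-learner). The background is a
seeded subsample of at most 32 training samples in the pipeline (a
bias/cost compromise; the explicit API takes any background). Global
ranking is mean |SHAP| over all training samples — absolute values so
opposite-signed contributions cannot cancel. Interaction indices are exact
second-difference enumerations, supported to 10 features, with main
effects on the diagonal so rows sum to the Shapley values.

## Compound screen

The formula grammar is deliberately narrow (element symbol + optional
count; no parentheses, charges or isotopes) because that is what formula
tables contain; errors carry the offending position. Monoisotopic masses
use embedded lightest-isotope constants (IUPAC 2021) for
C/H/N/O/S/P/F/Cl/Br/I; the published screening table's molecular weights
match the monoisotopic (not average) sums, so that is the validated path,
with average masses reported alongside. The SDF reader handles V2000
connection tables by fixed columns, counts hydrogens as written, and makes
no implicit-H inference. The default rule set (MW ≤ 500, HBD ≤ 5,
HBA ≤ 10, logP ≤ 5) is an explicit local proxy for web-service
pharmacokinetics screens, which cannot be recomputed offline; rules whose
descriptors are absent are skipped with a warning, and the biflavonoids in
the built-in panel legitimately fail the weight rule — the rule set is
configurable for exactly that reason.

## Pipeline and determinism

Every stochastic operation derives its seed from SHA-256 of
(global seed, stage name), so one integer reproduces the whole run
bit-for-bit, including solver-internal randomness (liblinear/saga are
seeded explicitly). Stage artifacts are plain text; the manifest records
parameters, seeds and SHA-256 hashes of outputs, and `verify_manifest`
detects tampering. Configuration is a validated dataclass loadable from
YAML; unknown keys and missing input paths fail before any stage runs.

## Known limitations

- The Gaussian location/scale world is exactly the corrector's model;
  real-data robustness (outliers, heteroscedasticity, probe effects) is
  untested by design.
- Importance definitions differ per family; wsf compares selection sets,
  not raw importances, which softens but does not remove that
  heterogeneity.
- The stack's training AUC is optimistic by one level of selection (gate +
  meta-fit on the same OOF matrix); an honest outer loop would nest the
  entire stacking procedure.
- Kernel SHAP's background-replacement masking assumes feature
  independence; correlated panels attribute shared signal arbitrarily
  among correlated genes.
- The drug-likeness proxy is not a pharmacokinetics model; its verdicts
  depend entirely on user-supplied descriptors.
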