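# Methods

`mirsig` implements the full discovery computation behind a serum
circulating-miRNA (c-miRNA) diagnostic signature for pancreatobiliary
cancer (PBca): microarray preprocessing with internal-control
normalization, a two-cohort robustness filter, weighted coexpression
module analysis against clinical traits, ridge-discriminant marker
ranking, and an exhaustive Fisher-discriminant combination search
evaluated by repeated cross-validation against CA19-9. A synthetic cohort
generator reproduces the statistical structure each stage relies on, so
the entire pipeline is testable without any cohort download.

## Preprocessing

**Positive calls.** For each sample the negative-control signals are
sorted, exactly one highest and one lowest value are removed, and the
call threshold is `mean + 2·SD` (sample SD, n−1) of the remainder. A
probe is called positive when its linear signal strictly exceeds the
threshold; missing signals are never calls. The platform's phrasing is
singular ("the highest and least intense signals"), which we read as one
of each; whether the SD uses n or n−1 is not specified anywhere we know
of, so we use the unbiased convention and treat the choice as a
convention, not a result.

**Imputation.** A missing signal is replaced by the mean of that miRNA's
non-missing linear signals over samples of the same analysis set.
Observed values are never modified, so each miRNA's observed-sample mean
is preserved. Imputation runs on the raw linear scale, before the log
transform, because the platform's rule averages signals, not log signals.

**Normalization.** Each log2 signal is reduced by the per-sample mean of
the three log2 internal-control signals (miR-149-3p, miR-2861, miR-4463;
"Int-con"). Subtraction in log space makes the normalized matrix exactly
invariant to per-sample multiplicative rescaling, and the Int-con value
itself serves downstream as a proxy for total serum miRNA concentration.

## Robustness filter

A miRNA is *robust* when

1. its positive-call rate in the exploratory set exceeds the call-rate
   threshold (default 0.90; the source protocol quotes 90% in one place
   and 99% in another, so the value is configuration, not code),
2. the OLS regression of its log2 signal on Int-con has Pearson
   rsq > 0.5 in **both** of two independent healthy cohorts
   (exploratory healthy vs a reference population), and
3. the two cohort slopes differ by less than 0.1 in absolute value.

All inequalities are strict. The regression uses the *un-normalized*
log2 signal: a well-behaved miRNA tracks total serum miRNA concentration
with slope ≈ 1 in any healthy population, and consistency of that slope
across populations is what the filter screens for. (Running the same
regression on normalized levels would remove the concentration component
and drive every rsq to ≈ 0, leaving nothing robust — a degenerate
reading we reject.) A constant response is reported as slope 0, rsq 0;
a constant Int-con is an error.

## Coexpression modules

The network stage is written from first principles:

* **Adjacency**: unsigned, `a_ij = |cor(x_i, x_j)|^β` with soft power
  β = 5 (a signed variant is available; unsigned is the method's
  historical default and the protocol does not state signedness).
* **Topological overlap**:
  `TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij)` with
  `k_i = Σ_{u≠i} a_iu`; the clustering input is `1 − TOM`.
* **Clustering**: average linkage (scipy), followed by a dynamic tree
  cut in the spirit of the hybrid algorithm. We mark an internal node a
  *qualifying split* when its merge height exceeds the larger child's
  core height — the 0.9-quantile of the child subtree's merge heights —
  by more than a gap threshold, and at least one child is large enough
  to form a module. Modules are the maximal subtrees containing no
  qualifying split, subject to the minimum size (default 10). The gap
  threshold is mapped from `deep_split` (0→0.30, 1→0.225, 2→0.15,
  3→0.10, 4→0.05 dissimilarity units, default level 3): higher
  sensitivity splits finer, matching the parameter's usual meaning.
  Leftover miRNAs are assigned to the nearest module by average
  dissimilarity when they are closer to it than to the overall average
  dissimilarity (a PAM-like sweep); otherwise they stay unassigned
  (label 0). Bit-identical agreement with any reference tree-cut
  implementation is not a goal; planted-partition recovery is the
  accuracy surface, and the suite requires ≥ 90% agreement on the
  default synthetic cohort.
* **Eigengenes**: first principal component of the module's
  standardized member profiles, scaled to unit variance and oriented so
  its mean correlation with members is positive.
* **Module–trait analysis**: Pearson r with two-sided p from
  `t = r·√((n−2)/(1−r²))`. Traits: disease status (0/1), log2 CEA, log2
  CA19-9, ordinal cT (0–4), cN (0–2), cM (0–2), serum storage time at
  room temperature (the disturbance factor), and platelet count
  (carried for inspection but not used by the selection rule, since no
  decision rule is stated for it).
* **Selection**: a module is *rejected* as a processing artifact when
  its storage-time correlation is significant (α = 0.05) **and**
  exceeds, in absolute value, its strongest disease-trait correlation.
  A non-rejected module is *disease-related* when at least one disease
  trait is significant at α = 0.05. Disease-related miRNAs are the
  union of members of disease-related modules. No module merging by
  eigengene similarity is performed (the procedure we follow reports
  its module count without any mention of merging).

## Ridge marker ranking

The disease discriminant is L2-penalized least squares of the 0/1 label
on standardized expression — a ridge linear-discriminant direction. We
deliberately use the squared-error reading of "ridge discriminant"
(logistic is available behind a flag). λ is selected by 10-fold
stratified cross-validation over a 100-point descending log grid spanning
`[1e−4, 10]·s₁²` (s₁ = the design's largest singular value). By default
we take the most-regularized λ within one standard error of the minimum
CV error: on block-correlated designs the CV curve is flat for about a
decade around its minimum, and inside that flat region the minimizer
drifts into weakly-identified territory where individual coefficients —
the quantity being ranked — are dominated by noise. The 1-SE choice is
the standard remedy for exactly this situation; the strict minimizer
remains available (`lambda_rule="min"`). The 16 miRNAs with the largest
absolute standardized coefficients become the diagnostic markers; exact
ties break lexicographically. Fold assignment is computed on samples
sorted by (label, sample id), so results are invariant to input row
order.

## Signature search

For every subset of 5 of the 16 markers (4368 subsets), Fisher's linear
discriminant `w = S_pooled⁻¹(μ_case − μ_control)` is fit with the
unbiased pooled covariance, and three decision constants are derived
from the training scores:

* **max-separation** — the midpoint of the projected class means (the
  equal-priors, equal-covariance Bayes cutpoint; the source does not
  define "maximize the separation", so we use the canonical choice);
* **sens80** — the largest observed score value keeping training
  sensitivity ≥ 80% (nearest-rank lower quantile of case scores; ties
  at the cutpoint push the constant down so the guarantee holds);
* **spec80** — the smallest value reaching training specificity ≥ 80%
  (nearest-rank upper quantile of control scores).

Three constants per subset give 13,104 discriminants. Each subset is
scored by 5-fold stratified cross-validation repeated 10 times — 50
held-out evaluations; weights and constants are refit on every training
4/5. Held-out sensitivity, specificity and AUC (Mann–Whitney with ties
counted ½) are averaged over the 50 groups; the AUC 95% CI is the
normal approximation `mean ± 1.96·SD/√50` (no CI method is stated for
the cross-validated AUC; this is the simplest defensible estimator and
is documented as distinct from the DeLong CI used on fixed sets). The
CA19-9 AUC is computed on the same held-out folds. A discriminant is
selected when mean sensitivity > 0.80 and mean specificity > 0.80
(strict, as "exceeded 80%"), the AUC CI lower bound is ≥ 0.80
(non-strict, as "0.8 or higher"), and the mean AUC beats CA19-9. The
reported signature refits weights and constant on the full exploratory
set, yielding a fixed linear index with cutoff 0. Subset sizes 3–6 are
supported for the variable-count sweep.

The search driver vectorizes the per-fold work across subsets (batched
5×5 solves and rank-based AUCs); a plain fold-by-fold single-subset path
is kept as the reference implementation and the two are required to
agree to 1e-12 in the test suite.

## Evaluation

Fixed signatures are linear indices `Σ w_i x_i + c`, positive above the
cutoff (0 for the index, 37 U/mL for CA19-9). AUCs on fixed sets carry
DeLong placement-value CIs; paired comparisons (index vs CA19-9 on the
same samples) use the paired DeLong test. The combined rule is
`index > 0 OR CA19-9 ≥ 37 U/mL`; its sensitivity can only rise and its
specificity only fall relative to the individual rules, which the suite
checks as an invariant. Subgroup AUCs compare case subgroups (cT strata,
CA19-9 strata < 15 / 15–37 / ≥ 37 U/mL, or any metadata column) against
the full healthy control set. Group-difference tests are classical
equal-variance two-tailed t-tests on the linear or log2 scale.

## Pre-analytic QC

The time-course summary reports, for each time point versus baseline,
the subject-averaged change in normalized level per miRNA and the
mean ± SD of those changes across miRNAs (sample SD). The degradation
model is linear in time beyond a 120-minute room-temperature lag,
reflecting the finding that serum processing within 2 h is stable. The
embedding stage runs 2-D t-SNE (default perplexity 30, fixed seed) on a
marker panel and scores label separation by the mean silhouette in the
embedding — a quantitative stand-in for the visual "distributed in the
same area" judgment; the separated/not-separated threshold is left to
configuration (default 0.25) because any such cut is a reporting choice.

## Synthetic cohorts

`generate_dataset` draws, per sample: a log2 concentration factor
(SD 2.0) shared by every target probe and tracked by the three
internal-control probes (noise SD 0.1); per-module latent factors with
loadings chosen so within-module pairwise correlation equals the target
(default 0.7), via `λ² / (λ² + σ²) = ρ`; a uniform disease shift on
designated modules (defaults +0.9 / −0.9 log2 on two modules of a
12-module, 600-miRNA layout); degradation `slope · max(0, t − 120 min)`
on a disturbance module (default 0.02 log2/min); per-miRNA baseline
offsets (SD 1.0) around a log2 base of 9; and measurement noise
(SD 0.4). Negative-control probes are pure linear-scale noise
(N(20, 5), clipped at 0) and set the positive-call thresholds; linear
signals below the detection threshold (default 4) are censored to
missing, deliberately far below the call threshold — on this kind of
platform a spot can be measured yet not "called", and missingness is
rare. Clinical traits follow a log2-normal CA19-9 (healthy mean 3.8,
SD 1.1, disease effect +1.5 — giving a synthetic CA19-9 AUC near 0.83,
the regime in which the signature must outperform it), log2-normal CEA,
and categorical cT/cN/cM among cases. The default cohort is 150 healthy
+ 134 PBca (exploratory), with independent streams for validation
(50 + 47), independent-validation (50 + 46) and reference/time-course
sets that share the same planted miRNA parameters.

Noise scales were fixed once, from the structure of the printed
thresholds: with concentration SD 2.0 and residual SD ≈ 0.6, the
two-cohort slope-difference sampling SE at n = 150 is ≈ 0.04, so a truly
robust miRNA sits well inside the |Δslope| < 0.1 criterion, and the
robust fraction lands near the ~64% the original cohort reports; with
the earlier-sketched narrower concentration spread the filter would
reject whole modules by sampling noise alone, which no working platform
would tolerate. Storage times are uniform on 15–180 min so that the
disturbance trait actually varies in the cohort.

**What the generator does not emulate:** hemolysis and platelet-release
mechanisms, per-facility batch structure, miRNA-specific biology,
heavy-tailed signal distributions, or per-member heterogeneous disease
effects (effects are uniform within a module, which makes the "top-16
markers" exchangeable within their modules). Passing tests therefore
demonstrate that the computation recovers planted structure under the
model's assumptions — not that the signature generalizes to real serum
data, which requires the deposited cohort.

## Problem sizes and numerical choices

The default study conditions (284 exploratory samples, 600 miRNAs,
full 5-of-16 search with 50 CV groups) run in a few seconds per seed;
the recovery and null suites use 10 seeds each. Degenerate inputs are
errors, not silent repairs: constant expression rows, singular pooled
covariances (an optional εI ridge is off by default), single-class
folds, missing internal controls. Constant traits report r = 0, p = 1
with a flag. Quantile constants use the nearest-rank convention with an
absolute 1e-9 guard against floating-point edge effects at exact
multiples. Stochastic components (folds, t-SNE, the generator) are
seeded everywhere, and fold construction depends only on the seed and
the label-sorted sample order.
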