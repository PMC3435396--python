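# Methods

## Model and score

A candidate model is an ordered set of biallelic SNPs with nonnegative
integer weights. Genotypes are coded by minor-allele count (0/1/2), where
major/minor are decided from allele counts pooled over both phenotype
groups — pooling makes the encoding identical for cases and controls (a
requirement of the score below) and independent of VCF REF/ALT
orientation. Exact count ties are broken toward the lexicographically
later allele so the encoding is deterministic.

For subject *i* the score is the log-ratio of the probability of the
subject's multi-SNP genotype under the case-generating versus the
control-generating distribution,

    S_i = Σ_j w_j [ ln P₁(g_ij) − ln P₂(g_ij) ],

with two modeling commitments:

* **Conditional independence across SNPs** (naive-Bayes factorization).
  The joint genotype probability is the product of per-SNP genotype-class
  probabilities, so the log-ratio is a weighted sum of per-SNP terms. A
  joint (haplotype/LD-aware) model is out of scope.
* **Weights enter multiplicatively** on the per-SNP log-ratio. With the
  default one bit per weight this reduces exactly to SNP
  inclusion/exclusion.

Genotype-class probabilities are estimated per group as
(count + α)/(n + 3α) with pseudocount α = 0.5 by default; α = 0 gives the
MLE but can produce zero probabilities, which are flagged at estimation
time and raise only if actually looked up during scoring. A missing
genotype contributes 0 to the score (likelihood ratio 1: no evidence).
Monomorphic SNPs are retained; their two group distributions are equal up
to smoothing, so they contribute ≈0 rather than erroring. Scores are in
natural-log units; the downstream t-test is scale-invariant, so the base
is a display choice only.

## Fitness

The fitness of a model is the two-sided p-value of a two-sample t-test
between case and control score distributions. Welch's unequal-variance
form is the default because real cohort sizes are unequal; the pooled
form is available (`equal_var=True`). p-values are computed in natural
log space, with the deep tail of the Student-t survival function
evaluated through the leading incomplete-beta series once the standard
routine underflows (|log p| up to ~10⁴ is representable), so models can
be ranked far beyond double-precision underflow. Ties at the
floating-point limit break by larger |t|, then by fewer active SNPs.
Degenerate comparisons (both samples constant) map to t = 0, p = 1 when
equal and to the smallest positive double when unequal, flagged.

### In-sample bias, measured

The training fitness is an in-sample quantity: each group is scored with
probabilities fitted to itself. The group-1 mean of the per-SNP log-ratio
equals +KL(p̂₁‖p̂₂) and the group-2 mean equals −KL(p̂₂‖p̂₁), so the mean
separation is the symmetrized KL divergence — strictly positive under
the null for every SNP. The consequence, verified by simulation in the
test suite, is E[t²] ≈ 2k for a random k-SNP null model (each SNP
contributes roughly a 2-df association chi-square), and adding *any* SNP
increases the in-sample t². Three design consequences follow:

1. Nominal fitness p-values are **ranking devices, not significance
   statements**. Calibrated inference comes from the permutation test
   and from frozen-model transfer, both of which are exact under their
   respective nulls (verified: permutation empirical p is KS-uniform
   under exchangeable scores; fitness against tables frozen from
   independent data is KS-uniform under the null).
2. A search run long enough on pure-noise data will reach any fixed
   nominal threshold: with 200 candidate SNPs the best of 200 random
   10-SNP starting models already has t² ≈ 45–50 (nominal p ≈ 10⁻¹¹).
   The matched-null benchmark reports this rate rather than hiding it.
3. Trained models accrete noise SNPs when run past the point where the
   true signal is exhausted; on the planted benchmark the median final
   model holds most of the SNP set. Parsimony is therefore a property of
   early stopping at a target fitness, not of the search itself; the
   planted-recovery benchmark reports the median model size alongside
   the recovery fraction.

## Genetic algorithm

Chromosomes are bit vectors of length n_snps × bits_per_weight
(MSB-first unsigned weights; one bit by default). Defaults: population
200, 500 generations, ~10 active SNPs per initial chromosome (each with
a uniformly drawn nonzero weight), crossover rate 1.0, per-bit mutation
1/L. Each generation the population is ranked by fitness, the bottom
half is discarded, and each offspring is produced by uniform crossover
of two distinct surviving parents followed by per-bit mutation;
offspring decoding to the all-zero (unscoreable) model are re-mutated.
This truncation scheme is the default; canonical CHC-family ingredients
(HUX crossover, incest prevention, cataclysmic restart) are exposed
behind flags for users who want the stricter elitist variant, since the
precise historical variant is not recoverable.

`desired_fitness` is `None` by default: the search always runs
`max_generations` and returns the best-ever chromosome, matching the
canonical study protocol of evolving the full span and taking the final
best. Setting it (usually to the Bonferroni-corrected level) enables
early stopping. Identical bit patterns are evaluated once per run
(fitness cache); per-group frequency tables do not depend on the
weights, so they are estimated once per run and every evaluation is a
weighted sum of precomputed per-SNP contributions plus a t-test. Runs
are bit-reproducible given (data, config, seed), and the returned best
fitness is re-derived from the decoded model through the scalar scoring
path as an integrity check.

## Permutation test and verdict

Holding every subject's score fixed, case/control labels are shuffled
preserving group sizes; each round's Welch p (compared in log space) at
or below the observed one counts as "as extreme". The empirical p-value
uses the (b+1)/(N+1) estimator — never exactly zero — and reports the
conventional "<1/N" bound string when b = 0 (e.g. "<1e-05" at 100,000
rounds).

With two control groups, each case-vs-control permutation p is banded:
significant below the Bonferroni-corrected level, borderline up to 0.05
(inclusive), non-significant above. Both significant → strong
association; either non-significant → none; otherwise moderate. The
trained model is additionally applied, with its score function *frozen*
from the training pair, to the control-vs-control comparison; if that
fitness p crosses the study-wide fitness threshold the verdict is
flagged invalid — the model separates cohorts, not disease. Freezing is
essential here: re-estimating frequencies on the two control groups
would reintroduce the in-sample bias and flag every model invalid
(measured: an 81-SNP model refit on two null control halves shows
|t| ≈ √(2·81) ≈ 12.7). The same frozen tables drive the case-vs-second-
control transfer comparison, which is also how replication in an
independent cohort works: same model, same frequencies, new subjects.

## Risk modeling

Disease state is regressed on model scores by maximum-likelihood
logistic regression (IRLS; separation and non-convergence are flagged on
the result, not raised). With several models, all pairwise products of
score variables can be added and classical forward-stepwise selection
with backward checks applied (Wald-p entry/stay at 0.05/0.05, the common
default in clinical-statistics software). Diagnostics: Hosmer–Lemeshow
over deciles of fitted risk (df = groups − 2; empty-expectation groups
merged with a logged note), and the c-statistic as the tie-aware rank
(AUC) formulation.

The risk/score-class diagram discretizes the pooled score range into 12
equal-width bins (equal-frequency available by flag; the equal-width
reading is the simplest for "discretized into bins" and makes the x-axis
interpretable in score units) and applies Bayes' rule per bin. The prior
π defaults to the sample case fraction — with that choice the table
satisfies Σ P(bin)·P(D|bin) = π exactly (law of total probability, an
asserted invariant) — but is explicitly overridable because case-control
sampling fractions are a design choice, not population prevalence; any
published absolute-risk range read off such a diagram reflects the
cohort ratio unless π is set to prevalence.

## Synthetic data

The generators emulate the statistical structure the method assumes:
independent biallelic SNPs in Hardy–Weinberg proportions with MAFs drawn
uniformly from a configurable range (default 0.05–0.5), optional iid
missingness, three effect mechanisms — none (null), per-SNP case-group
MAF shifts δ (HWE re-derived; an odds-ratio wrapper converts OR → δ),
and the two-of-three-loci heterogeneity model (risk genotype = carrying
at least one minor allele, configurable; affected with penetrance 0.9 if
at least two of three loci carry it, else 0.05; rejection sampling until
the requested group sizes are reached). All generators are deterministic
given the seed, and the shifted generator with an empty effect list is
bit-identical to the null generator.

What they deliberately do **not** emulate: linkage disequilibrium and
haplotype structure, population stratification, genotyping batch
effects, call-rate/HWE QC artifacts, covariates. Passing benchmarks on
these cohorts therefore demonstrates the statistical machinery
(encoding, scoring, search, calibration, risk), not robustness to the
confounders of real cohort data.

### Benchmark conditions

Chosen once as the package's standard evaluation conditions
(`kbas.benchmarks`):

* Planted-marker search: 200 SNPs, 5 causal at control MAF 0.20 with
  case shift δ = 0.09 — at 1000 subjects per group a single causal SNP
  has Welch p ≈ 10⁻¹⁰ — default GA configuration, 20 seeds. Reported:
  fraction of seeds recovering ≥ 4/5 causal SNPs, median model size.
* Matched null search: same sizes, no effect, early stop at 6.944×10⁻⁹;
  reported: fraction of seeds reaching that nominal level (see the
  in-sample bias discussion — this measures the bias, and is corrected
  by the permutation/transfer machinery, not by the search).
* Permutation calibration: 500 replicates of iid N(0,1) scores for
  50 + 50 subjects, 199 rounds each, KS test against uniform.
* Heterogeneity: three loci at MAF 0.3, penetrances 0.9/0.05,
  1000 per group; reported: log₁₀ gap between the median single-locus
  fitness p and the joint 3-locus fitness p.
* Risk diagram: 8 planted effects (base MAF 0.25, δ = 0.1), 2000 per
  group, scored with the true model; reported: Spearman of posterior vs
  bin index, conservation error, c-statistic.

## Numerical notes and limitations

* Frequency tables validate simplex-sum to 1e-12; contributions are
  computed once per (pair, α) and reused across all chromosome
  evaluations.
* Permutation rounds are processed in blocks bounded to ~32 MB of
  permuted scores.
* The Hosmer–Lemeshow grouping uses stable argsort, so tied fitted
  probabilities group deterministically.
* Equal-width risk bins assign each score by right-open interval, with
  the maximum score in the last bin; a degenerate (constant) score
  vector collapses to one bin with a logged note.
* The stepwise procedure is the classical Wald-p heuristic; it inherits
  that heuristic's known multiplicity optimism and is not a substitute
  for preregistered model choice.
* Replication across genotyping platforms by LD-based SNP substitution
  is out of scope: transfer requires the model's SNPs to exist in the
  target cohort.
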