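# Methods

## The model

`lboost` implements two ensemble classifiers over Boolean rules for binary
(case/control) responses and binary predictors, together with the
simulation machinery used to study how well they *recover* the causal rule.

A **logic-regression tree** is a strictly binary AND/OR tree whose leaves
are possibly complemented predictors (`X3`, `!X7`). A tree predicts class 1
on a row iff its Boolean expression is true there. Every tree can be
rewritten as a disjunction of conjunctions; the minimal conjunctions
implying the tree's function are its **prime implicants** (PIs) — the
interpretable units, e.g. `X1&X2` for a two-SNP interaction. PI extraction
is exact: Quine–McCluskey over the truth table restricted to the tree's
variables (at most 8, so at most 256 assignments). This yields *all* prime
implicants, including consensus terms that plain DNF expansion plus
absorption misses; degenerate trees (contradictions and tautologies) have
no PI of size ≥ 1 and yield the empty set.

Single trees are fit by **simulated annealing** on weighted
misclassification. The score lives on the count scale (n × weighted error;
for uniform weights, the number misclassified). The move set is the
standard logic-regression neighborhood — replace a leaf's variable, flip a
complement, flip an operator, grow a leaf into a branch, prune a leaf —
with infeasible moves excluded and the move type drawn uniformly from the
feasible set. The cooling schedule is geometric on the log10 scale from
10^2 to 10^-2 over 50,000 iterations by default. The start temperature is
calibrated so that roughly 90% of proposals are accepted on
100-SNP/n≈400 data (the suite asserts the rate lies in [0.80, 0.99]); at
the end temperature essentially no uphill move is accepted. Equal-score
proposals are always accepted so the chain drifts across the large
plateaus a misclassification score produces; the best tree visited is
returned. The engine maintains the tree in a heap layout with bit-packed
node evaluations (Python integers as n-bit masks) and a per-byte weighted
popcount table, recomputing only the path from a modified node to the
root; it is cross-checked against a direct tree evaluator by randomized
move-sequence tests.

**LBoost** boosts these trees inside a K-fold cross-validation frame. Per
fold, on the training 4/5ths: weights start uniform; each of A rounds
draws a size cap S uniformly from {1,…,8} (random sizes help small PIs),
anneal-fits a tree under the current weights, computes its weighted error
e (clamped to [ε, 0.5−ε], ε = 1/(2·n_train)), sets the tree weight
α = ½·ln((1−e)/e), and multiplies weights by exp(+α) on misclassified and
exp(−α) on correct rows before renormalizing — after which the just-fitted
tree's weighted error is exactly ½ (an identity the suite asserts to
1e-10). Cross-validated prediction maps tree outputs to ±1 and takes the
sign of the α-weighted vote (ties → class 0); the CV misclassification
rate over all held-out predictions estimates model error. Defaults K = 5,
A = 20 (100 trees).

**Logic Forest**, the bagging baseline, fits the same annealed trees on
bootstrap resamples (duplicate rows weighted by multiplicity) and records
each tree's out-of-bag (OOB) rows. Its importance V.LF of a PI is the sum
of OOB accuracies of the trees containing it, divided by the total number
of trees B.

**PI importance for LBoost (V.LB)** is permutation-based. Each tree, on
its own fold's held-out rows, is the OR of its PI columns. For PI j in
tree b: permute j's column, re-form the OR, and take the rise in held-out
misclassification over the unpermuted baseline. V.LB sums these
contributions over the trees containing the PI and divides by the total
K·A trees. The normalization mirrors V.LF deliberately: the
cross-tree aggregation admits several natural forms (per-tree mean,
frequency-weighted sum), and in our experiments the frequency-weighted
form is what turns boosting's repeated selection of a weak rare rule into
a stable rank, while a per-tree mean is drowned by the single-permutation
noise of the many PIs that occur exactly once (each contribution is a multiple of
1/n_k). One permutation per (tree, PI) is the definition; `reps` averages
several for variance reduction.

**Empirical p-values** use a column-permutation null: the observed V.LB is
compared with replicates in which the PI's column is first replaced by a
permutation of itself (severing the association while preserving marginal
frequency) before V.LB is recomputed; add-one corrected, one-sided.
Re-fitting whole forests under label permutation would be the stricter
null but is computationally out of reach and is not what the importance
measure conditions on.

## The simulator

Data mimic a 100-SNP case-control panel with one or two causal two-locus
interactions under Hardy–Weinberg equilibrium and no LD. An interaction is
dominant-dominant (DD: at least one minor allele at both loci, carrier
probability (1−(1−m)²)² at MAF m) or recessive-recessive (RR: two copies
at both loci, m⁴). Non-causal MAFs are Uniform(0.05, 0.5); causal pairs
share a MAF in {0.1, 0.3, 0.5}; causal loci occupy recorded columns (0,1)
and (2,3). All SNPs are recoded to one binary indicator — dominant coding
for DD studies, recessive coding for RR studies.

Disease follows the **liability threshold model**, standardized to unit
total variance: each interaction's carrier indicator contributes variance
h² = 0.02 (displacement d = √(h²/(p(1−p))), centered), the residual is
normal with the complementary variance, and disease is liability above
Φ⁻¹(1−prevalence) with prevalence 0.1 — the normal-quantile threshold
convention, under which the marginal prevalence is exact only to a few
parts per thousand (the marginal is a normal mixture). This convention
reproduces the package's reference table of penetrances and odds ratios
(see the tests) to four decimals, including the
saturated RR/MAF-0.1 row (f1 = 1.0000, f0 = 0.0975), which an
exact-marginal threshold solve cannot (it would force f0 = 0.0999 by the
law of total probability). `LiabilitySolution.implied_h2()` inverts the
penetrances back to the variance ratio as a consistency check (degenerate
for the saturated row); `implied_prevalence()` exposes the approximation
error, asserted below 2.5e-3.

Two samplers share this population model. `simulate_dataset` draws n
subjects prospectively — used for calibration, where empirical prevalence
and penetrances are checked against the analytic values.
`simulate_case_control` rejection-samples to n/2 cases and n/2 controls —
the design of the recovery experiments and of matched case-control
association studies. The distinction matters: at prevalence 0.1 every DD
penetrance is below ½, so in a prospective sample the Bayes-optimal
misclassification tree is the constant 0 and *no* rule-based method can
recover anything; only under case-control balance is the carrier stratum
majority-case and the interaction representable by a tree.

## Recovery experiments

A causal PI is *recovered* when its canonical key ranks among the top 20
PIs by absolute importance (20 ≈ 0.4% of the C(100,2) = 4950 two-locus
pairs). `run_experiment` simulates replicate datasets, fits LBoost and/or
Logic Forest with the same total tree count, ranks PIs, and aggregates
recovery proportions with Wilson 95% intervals (chosen because they are
well behaved near 0/1, where rare-PI recovery lives). Replicates derive independent seeds from (seed, n, replicate), so
results are invariant to execution order; failed replicates are warned
about and excluded from denominators, never silently dropped.

## Problem sizes and what the tests show

The test suite runs reduced problem sizes chosen to exercise every code
path and identity while keeping a desk-scale run: annealing optimality is
checked on exhaustively enumerable instances (p ≤ 4, ≤ 2 leaves, 100
seeded runs at the full 50,000-iteration schedule); simulator calibration
at n = 200,000; the PI-algebra oracle on 1,000 random trees; null
calibration of recovery at 30 replicates of a reduced model and of
p-values across 40 small null fits; and the boosting-vs-bagging contrast
at the smoke scale (RR MAF 0.3, n = 800, 10 replicates, 5,000-iteration
annealing, directional assertion only).

Passing these shows the algebra, the identities, the calibrations and the
null behavior, but deliberately not full-scale power: at 5,000 annealing
iterations in a 200-literal space the chain rarely proposes the specific
two-move refinement that plants a rare conjunction, so both ensembles
recover a rare RR interaction at near-zero rates at smoke scale. At the
full 50,000-iteration schedule on balanced n = 2400 data we observe the
boosted forest containing the rare RR/MAF-0.3 PI in more trees than the
bagged forest (0/0/2/4 versus 0/0/0/0 of 100 across four replicates), the
qualitative boosting advantage the method targets, though at lower
absolute recovery rates than a full 500-replicate power study would
measure.

Known limitations: no LD, covariates, genotyping error or missing data;
the exponential-reweighting equations follow the standard discrete
AdaBoost forms, and absolute recovery rates are sensitive to that choice; tautological trees carry no
PI and are flagged rather than scored; new-data prediction outside the CV
frame averages all K·A trees, a convenience not used by any recovery
path.
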