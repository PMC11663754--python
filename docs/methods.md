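# Methods

This note records how the pipeline's components are specified, which
design choices were genuinely open, and what the synthetic studies do
and do not demonstrate.

## Additive value model and elicitation

A respondent's preferences over pathogens are modelled additively:
point values *v(c, ℓ)* per criterion *c* and ordinal level ℓ, with
*v(c, 1) = 0*, monotone non-decreasing levels, and top-level values
summing to 100 (percent scale).  Level monotonicity is **non-strict**:
a respondent may genuinely value two adjacent levels equally, and
nothing in the elicitation forces separation unless their answers do.

PAPRIKA elicitation asks only undominated trade-offs between
alternatives differing on exactly two criteria.  After cancelling tied
criteria, every such question is an ordering of two *level
differences* `D[c, hi, lo] = v[c, hi] − v[c, lo]` on different
criteria.  The session therefore tracks strict and weak reachability
over the set of level differences (10 per criterion for 5 levels, 80
nodes for the default scheme), seeded with nested-interval dominance
(`D[c, hi, lo] ≥ D[c, hi', lo']` when `[lo', hi'] ⊆ [lo, hi]`).
Transitive chains through these nodes — including substitution through
indifference classes — are exactly the implications propagated.  This
closure is **sound but deliberately incomplete**: entailments that
require re-summing a difference across its interval decomposition
(e.g. combining `D[a,3,2] > D[b,2,1]` and `D[a,2,1] > D[b,3,2]` into
`D[a,3,1] > D[b,3,1]`) are not chased; such comparisons are simply
asked.  The trade is a few hundred extra questions per simulated
respondent in exchange for microsecond-scale updates, which is what
makes studies with hundreds of simulated respondents practical.
Completion means every cross-criterion difference pair is determined,
i.e. all pairwise rankings of two-criterion alternatives are known.

**Question order.** The commercial implementations keep their
question-selection heuristics private, so the order here is the
package's own: increasing total level span (adjacent-level trade-offs
first), lexicographic within a span.  A greedy
most-implications-eliminated rule was considered and rejected: scoring
every candidate question requires a closure dry-run per candidate per
answer, which is orders of magnitude slower while changing nothing
about the elicited relation — only about how many questions reach it.

**What completion does and does not determine.** All pairwise rankings
of alternatives differing on at most two criteria are fixed at
completion.  Rankings of alternatives differing on three or more
criteria are *not* all entailed — no finite two-criterion elicitation
can pin them down — so recovery guarantees in the tests are stated
over the elicited comparison space, and full-profile rankings under
solved values should be read as model-based interpolation.

## Value solving

Point values are solved by linear programming in two stages:

1. **Maximin separation.**  Maximise the minimum gap ε over all strict
   answers (equalities hard, monotonicity and normalisation enforced).
   ε may be negative: a contradictory answer set (see below) then
   solves to its least-violated system instead of failing.
2. **Central selection.**  The maximin face is typically a large
   polytope; any vertex of it is a legitimate but arbitrary estimate.
   Among maximin-optimal systems the solver returns the one minimising
   the L1 distance to the uniform value system (equal weights, equal
   level spacing) — a deterministic, least-committal choice.

With noisy respondents a contradiction can slip past the conservative
closure, making a positive ε infeasible.  Forcing every answer to hold
weakly (ε = 0) lets the handful of wrong answers warp the solution
toward degenerate 100/0 weightings, so inconsistent sessions instead
get a **soft-margin** solve: minimise the total shortfall below a
1-point target gap, letting a few answers be violated outright while
the rest hold with a margin, then apply the same central selection on
the optimal face.  Such systems are flagged `consistent=False`.  An
everywhere-indifferent respondent is a degenerate special case (their
equalities force a flat value function, contradicting the 100-point
normalisation); the equalities then also become soft, and by symmetry
the solution returns equal weights.

Tolerances: 1e-9 for constraint-satisfaction checks, 1e-6 for reported
invariants (weights summing to 100); soft-margin target 1 point on the
0–100 scale; LP solved with HiGHS.

## Scoring and aggregation

Quantitative criteria are scored within a region by **rank-based
quintiles** (ties share the lower level); an absolute log-spaced
threshold mode is available by configuration.  Quantile binning is the
default because the scoring compares each pathogen to the others in
the exercise, not to external cutoffs.  Qualitative criteria are input
data scored against an external rubric; provenance codes
(`regional_data`, `inferred`, `preliminary`) travel with every cell
and flag downstream reports (e.g. cytomegalovirus burden scores) but
never change arithmetic.

Regional weights are arithmetic means of the respondents' full
point-value tables, so heterogeneity in level spacing is preserved;
by linearity this is identical to averaging per-respondent totals.
Regional lists keep the ten highest-total pathogens, **including**
any pathogen tied with the tenth (annotated) rather than dropping an
arbitrary one.  The global list is the union of regional top-tens,
ordered by (number of regions, best regional rank, name).

Leave-one-out robustness removes a criterion's additive contribution
without renormalising the remaining weights: rankings are invariant to
scale, so renormalisation could not change any order, and omission is
then a plain column-zeroing that an independent oracle can replicate.

## Cluster analysis

The composite indicator takes, per respondent, the point values at the
Medium and Very-high levels of each criterion (16 features),
standardises them, and keeps the smallest PCA prefix explaining at
least 80% of variance.  These are the only respondent-level quantities
defined per criterion at a level, and using two levels per criterion
captures both the weight and the shape of each criterion's value
curve while avoiding the exact collinearity of weights that sum
to 100.

K-means (10 restarts, fixed seed) runs for k = 2..10; the consensus k
is the mode of four selectors, ties to the smaller k:

- **elbow** — maximum discrete second difference of the
  within-cluster sum of squares, with the single-cluster point
  included so an elbow at k = 2 is visible;
- **silhouette** — maximum mean silhouette;
- **gap statistic** — Tibshirani's one-standard-error rule against 50
  uniform reference draws over the score bounding box, including the
  single-cluster model (a preference for one cluster becomes a vote
  for the smallest candidate, annotated);
- **index battery** — Calinski–Harabasz maximum and Davies–Bouldin
  minimum, the smaller of the two when they disagree.  This is a
  two-index stand-in for a full 30-index battery, which is out of
  scope; the consensus mechanism is what matters.

Cluster labels are arbitrary, so all reporting identifies clusters by
**profile** — the criteria dominating the cluster's mean weights —
never by index.

Membership is modelled with a binomial GLM (logit link) on the
covariate set, odds ratios with Wald 95% CIs.  Perfect separation is
screened for explicitly and separated terms are reported as
non-estimable rather than as huge finite odds ratios.

The minimum detectable odds ratio solves the **Fleiss
continuity-corrected two-proportion power equation** by bisection
(tolerance 1e-6) for the comparison-cluster prevalence nearest the
reference prevalence that achieves the target power, in both
directions, and converts to odds ratios.  The continuity-corrected
form is used because it is the standard conservative choice for
two-group binary comparisons at these sample sizes; a Monte-Carlo
oracle in the tests confirms the solved prevalence yields the nominal
rejection rate under the corresponding z-test.

## Survey statistics

Screening keeps, per respondent identity, the first fully completed
submission; duplicates are detected by a case-folded,
whitespace-stripped hash of name and email (a deterministic,
privacy-preserving automation of manual screening), and
straight-lining means the same verdict position — always first or
always second — on every trade-off.  Counts satisfy
`received = analysed + incomplete + duplicates + straightlined +
other_invalid` exactly, and reported percentages round half-up to
integers.  The Fisher exact p-value is the probability-mass two-sided
definition, computed by full enumeration of the hypergeometric
support (mid-p is not used).  Adjusted mean differences come from
per-criterion OLS on the full covariate set with normal-theory CIs;
perfectly collinear terms are detected by rank screening and reported
as aliased.  Completion bias uses a logistic GEE with exchangeable
working correlation over repeated submissions and robust sandwich
errors; with one submission per respondent it reduces to the plain
GLM (asserted to 1e-6 in the tests).  No multiple-testing adjustment
is applied anywhere, deliberately; read individual CIs accordingly.

## Synthetic studies

The generator emulates the structure the analysis assumes, with
defaults fixed at the study conditions: 577 respondents, completion
probability ≈49% (logistic intercept −0.031), 2% duplicate and 2%
straight-liner contamination among completers (≈11 invalid responses
expected among ≈284 complete), a 65/35 two-cluster mixture of
preference profiles, 5% verdict-flip choice error, 26 pathogens in
six regions with cross-region severity correlation 0.8 and five
pathogens boosted to be globally dominant.

Respondent weights are Dirichlet draws around the cluster-mean
profiles (sum-to-100 by construction) with concentration 40, and
interior level values are Dirichlet stick-breaking of each weight.
The profile means put antimicrobial resistance and outbreak
disruption heaviest in the majority cluster and the two mortality
criteria heaviest in the minority cluster, with top weights of 17–19%.
Concentration 40 gives within-cluster weight SDs near 5 points and
**total** SDs (mixture included) near 6–8 points, matching the scale
of criterion-weight dispersion such surveys report; the same choice
makes the two profiles separable (≈3σ in feature space), which is
what the consensus-k and recovery guards require.  Covariates are
drawn independently of cluster by default (margins matching the
surveyed population: ~25% Gavi-eligible, expertise mostly in
epidemiology and vaccine R&D, academic and government organisations
most common); noncompletion is logistic in the covariates with
coefficients defaulting to zero, so both null and biased completion
scenarios are available.

Simulated answers follow the respondent's true value sums, flipped
with the choice-error probability; ties produce indifference when
enabled.  A flipped verdict the session rejects as contradictory falls
back to the true verdict (and failing that, to any verdict the session
accepts), so noise never crashes a session.  Straight-liners always
choose the first alternative — a consistent lexicographic-style
preference, which the session therefore never rejects — and are
detected downstream by the screening rules, not by a generator-side
shortcut.

**What passing tests show.**  The synthetic data are well-specified
for the pipeline by construction: additive preferences, Dirichlet
weight dispersion, covariates independent of cluster, missingness
driven by a known logistic model.  Passing the end-to-end guards
therefore demonstrates internal correctness (each stage computes what
it claims on data satisfying its assumptions), not that real survey
respondents are additive, two-clustered, or ignorable in their
noncompletion.  Real studies should treat the cluster count, the
membership nulls, and the completion-bias conclusions as
data-dependent questions, not package guarantees.

## Problem sizes used in the checks

The standing test suite runs the full scheme (8 criteria × 5 levels)
with 100 noiseless respondents for recovery, exhaustive oracles on all
schemes up to 3×3, one complete 577-respondent study for the
end-to-end guards, and 200 replicates for GLM/GEE coverage
calibration — sizes chosen to match the study's own scale where the
claim depends on it and to stay small where it does not.

## Known limitations

- The question-selection order is deterministic but not
  question-count-optimal; simulated sessions answer ~300 questions on
  the full scheme where a smarter adaptive order could ask fewer.
  The elicited relation is unaffected.
- Solved point values are identified only up to the elicited
  comparison space; interior level values of rarely-contrasted
  criteria lean on the uniform-projection tie-break.
- The gap statistic's uniform reference is drawn over the bounding box
  of the PCA scores; strongly non-box-shaped score clouds could bias
  its vote.
- The NbClust-style fourth voter uses two indices, not thirty.
- GEE results assume the exchangeable working correlation is adequate
  for repeated submissions; with at most a couple of submissions per
  respondent this is hard to check.
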