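# Methods

## The risk model

Non-target risk is modelled as a chain of conditional contingencies — a
precision tree.  For an introduced parasitoid and one non-target host, the
overall per-generation parasitism outcome is the product along a branch:
spatial overlap (probability P1), temporal overlap (P2), and the parasitism
rate given contact (P3, a probability distribution on [0, 1]).  The data
model allows further multiplicative contingency nodes (an ordered list of
named probabilities, e.g. host-stage susceptibility or split dispersal
routes) but the canonical tree has depth three.

Two scenario presets bracket the plausible range.  The *worst case* sets
P1 = P2 = 1: the agent fully invades the non-target's habitat and is active
year-round, attacking the non-target at the rates recorded for its target
hosts.  The *average outcome* keeps P2 = 1 (in an aseasonal climate both moth
larvae and parasitoids are perennially active) but takes the published
habitat records at face value, P1 = 0 when no records place the agent in
non-target habitat; the branch product is then exactly zero and no outcome
distribution exists.

### Monte Carlo propagation and gating

Forecasts are produced by simulation, 2000 trials per forecast by default
(the precedent trial count for this design; any count can be passed).  Each
trial draws a rate from P3.  Two gating semantics are offered because the
upstream contingencies are events, while branch arithmetic multiplies
probabilities:

- **bernoulli** (default): each contingency is realized per trial as an
  independent indicator, outcome = I1 · I2 · r.  This is the event reading —
  in a given realization the agent either reaches the habitat or does not.
- **multiplier**: outcome = p1 · p2 · r, pure branch-product arithmetic.

Both have expectation p1 · p2 · E[P3] (the `point_risk`), and both produce
identically zero forecasts when any branch probability is zero.  Degenerate
probabilities (0 or 1) short-circuit, so zero branches are exact, not merely
almost-surely zero.

## Rate distributions (the P3 input)

Observed parasitism proportions are fitted with one of four families:

- **beta** (default) — MLE with both shapes free (`alpha`, `beta` > 0).
  Proportions on [0, 1] with unimodal right-skewed spread are the typical
  shape of parasitism-rate collections, and the beta is the standard bounded
  conjugate choice.  The likelihood diverges at the boundaries, so values are
  nudged inward to [ε, 1 − ε] with ε = 1e-4 before fitting — consistent with
  the source tables, which already code non-detections as 0.001 rather
  than 0.
- **truncated normal** on [0, 1] — direct two-parameter MLE (Nelder–Mead on
  (μ, log σ)).
- **empirical** — bootstrap resampling of the observed values; fit-free, used
  as the reference alternative whenever a parametric choice would be
  contestable.
- **degenerate** — a point mass; returned automatically (with a flag) when a
  sample has fewer than two distinct values, since no spread can be
  estimated.

Goodness of fit is the Kolmogorov–Smirnov distance between sample ECDF and
fitted CDF; `select_best_fit` picks the candidate with the smallest distance,
ties broken by fixed precedence beta > truncated normal > empirical.
Exceedance probabilities use the strict inequality P(X > t): "falls above the
threshold" is read strictly, which matters only for point masses sitting
exactly at the threshold.

The 0.40 exceedance of the apparent-mortality forecast is *fit-dependent*:
the beta-MLE route gives ≈ 26 % (analytically, Beta(2.36, 5.42) has
P(X > 0.4) = 0.261), while counting the 25 table values directly gives
8/25 = 32 %.  Both routes are always reported side by side; the package never
silently substitutes one for the other.

## Competing-risks mortality

Field samples measure *apparent mortality* dᵢ — the raw proportion killed by
factor i.  Contemporaneous factors compete for the same individuals, so dᵢ
understates the factor's stand-alone impact.  Under the constant-hazards
model (each factor a constant hazard λᵢ over one interval), the *marginal
attack rate* is

    mᵢ = 1 − (1 − d)^(dᵢ/d),   d = total apparent mortality,

with the exact identities mᵢ ≥ dᵢ (equality iff dᵢ ∈ {0, d}) and
∏ᵢ(1 − mᵢ) = 1 − d (total survival), checked to 1e-12 in the tests.  The
life-table entry point refuses cohorts with no survivors: at d = 1 the
correction is undefined and the split of mortality among factors is pure
convention; silent imputation would hide a data problem.  The single-interval
correction is the only one exposed — no stage-structured decomposition.

The synthetic cohort generator is this model run forward: hazards
λᵢ = −log(1 − mᵢ) act simultaneously, an individual dies with probability
1 − exp(−Σλ), and the cause is allocated hazard-proportionally (the factor
whose exponential event time comes first).  Because generator and correction
share the generative model, marginal rates round-trip exactly in expectation;
tests check recovery within three binomial standard errors.

## Rank tests

Forecast and observed distributions are compared with the Mann–Whitney
rank-sum test (two groups) and the Kruskal–Wallis ANOVA on ranks (more than
two), both computed from mid-ranks with the standard tie corrections.  The
statistic assembly is implemented here (scipy is only an independent
cross-check in the tests); mid-ranks come from `scipy.stats.rankdata`.

- The reported `rank_sum_T` is the rank sum of the smaller group (first group
  on a size tie).  With 2000-trial forecasts this reaches the millions —
  which is how published "t" values of that magnitude from statistics
  packages should be read (rank sums, not t statistics).
- The normal approximation uses the tie-corrected variance and, by default,
  **no continuity correction**: the package's comparisons are between
  Monte Carlo forecasts of thousands of trials, where the correction is
  negligible; it is switchable for small-sample use.
- For pooled N ≤ 12 both tests switch to the exact permutation null (every
  assignment of the pooled observations to the groups is enumerated; the
  two-sided rank-sum p counts assignments with |U − μ| at least the observed
  deviation).  Property tests verify the exact path against naive
  enumeration, and the type-I error of the asymptotic path
  (n₁ = n₂ = 50, α = 0.05) against its nominal level.
- No multiple-testing adjustment is applied to pairwise comparisons; the
  workflow reports omnibus tests plus individually interpreted pairwise
  tests, and any adjustment policy is left to the caller.

## Packaged data and screening

The survey tables (25 apparent-mortality values and 18 marginal attack rates
per agent) and the five host lists ship as CSV fixtures, values identical to
print.  Non-detections in the apparent table are coded 0.001 in the source; a
documented flag (`treat_point001_as_zero`, default off) recodes them, keeping
fidelity to print as the default and reinterpretation explicit.  The survey
tables do not record which elevation stratum each datum came from, so fixture
records carry stratum `unspecified`.  Host-list origins outside the
closed vocabulary (question-marked entries, one obvious misprint) map to
`uncertain`/`adventive`; the native-range lists print no origin column and
are stored as `uncertain`.

Taxonomic screening (`taxonomic_overlap_flag`) returns the highest level —
genus, family, or none — at which a non-target taxon overlaps a host list,
by case-insensitive string match on the plain binomials (genus = first token;
no synonymy resolution or taxonomy-database lookups).  Genus-level overlap is
the strongest pre-introduction warning: a congeneric host on the
native-range list predicts attack on the non-target congener.

## Synthetic surveys

The survey generator emulates stratified field surveys: per site within an
elevation stratum, a true rate is drawn from Beta(α, β) (optionally
zero-inflated — a site the agent never colonized yields structural zeros),
and the observed rate is Binomial(hosts_per_site, rate)/hosts_per_site.  It
reproduces the sampling noise and zero-inflation of real surveys but not
spatial autocorrelation between sites, host-density dependence, or phenology;
passing round-trip tests therefore demonstrates estimator correctness under
the assumed model, not robustness to those field realities.

## Numerical and reproducibility choices

- All randomness flows through `numpy.random.default_rng(seed)`; no global
  state.  Pipeline runs derive per-scenario child seeds (< 2³¹) from one
  master seed, and reports embed every seed in a provenance block; reruns are
  byte-identical.
- Conservation identity tolerance 1e-12 (pure arithmetic); dominance checks
  allow 1e-12 slack for float rounding, with strictness asserted away from
  the endpoints where underflow cannot bite.
- Test problem sizes: microsimulation oracles use 2×10⁵–10⁶ individuals,
  parameter-recovery tests 5000 draws, type-I-error simulation 2000
  replicates at n = 50 — sizes at which binomial standard errors are small
  enough to make the assertions sharp while the whole suite stays fast.

## Known limitations

- The elevation-stratified literature parasitism datasets behind the
  per-elevation forecasts of the original study system are unpublished;
  those forecasts are reproducible in mechanism (the pipeline runs any
  stratified table) but not in value.
- The family its original fitting software chose for the apparent-mortality
  distribution is unrecorded; the 0.40-exceedance is therefore reported by
  two routes (beta MLE and empirical counting) rather than matched to one
  number.
- Marginal-rate conversion assumes contemporaneous constant hazards within a
  single interval; sequential (stage-structured) mortality is out of scope.
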