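# Methods

This note documents the statistical procedures implemented in
`multipattern`, the modelling choices made where the design was genuinely
open, and what the synthetic-data experiments do and do not demonstrate.

## Cohort model

The unit of analysis is a **closed cohort**: all multimorbid adults (≥2
chronic conditions from a fixed catalog, ages 18–65) at baseline, followed
over two four-year periods (three waves).  Nobody enters after baseline;
patients leave only through death or loss to follow-up (inactive
registration status).  Both exits are absorbing, and a patient who would
qualify for both in the same period is booked as dead (death is evaluated
first; the choice affects only bookkeeping labels, since both are
exclusions).  Chronic-condition sets are **cumulative**: a condition once
recorded with active status stays in the patient's profile at every later
wave.  Cumulative attrition percentages are always reported against the
baseline n; wave-level shares (pattern sizes, mortality within a pattern)
use the wave or pattern size as denominator, rounded to 2 decimals in
table output.

Per-wave analysis datasets keep only currently-included patients and the
conditions whose prevalence among them is at or above a threshold
(default 1.0%, inclusive at the boundary, so a condition carried by
exactly 1% of the wave is retained).

Utilisation is summarised per follow-up period with two deduplicated
counts: distinct fourth-level ATC groups (the chemical-subgroup tier,
operationalised as the first five characters of the code — the standard
ATC string layout) and distinct acute-condition labels.  Both counts are
invariant to record order and to repetition multiplicity.

## Pattern discovery

Patients are clustered per wave on their binary condition profiles using
k-means with the Jaccard metric.  Two non-obvious mechanics:

* **Distance to centroids.** Lloyd iteration requires distances between a
  binary profile and a real-valued centroid, so assignment uses the
  generalised (Tanimoto) Jaccard distance
  `1 − Σ min(x_j, c_j) / Σ max(x_j, c_j)`; on two binary vectors this is
  exactly the set Jaccard distance, so the metric the patients are
  compared with is honoured while centroid updates (within-cluster means,
  i.e. cluster prevalence vectors) keep their usual fixed-point behaviour.
  Two all-empty profiles are defined to be at distance 0 (identical
  patients); after the multimorbidity filter the case cannot arise.
* **Determinism.** Restart r of `n_init` (default 10) uses the nested
  seed `(seed, r)`, so enlarging `n_init` never changes earlier restarts
  and the best-of-restarts inertia is non-increasing in `n_init`.
  Assignment ties break toward the lowest cluster index; an emptied
  cluster is re-seeded to the point farthest from its assigned centroid.
  Iteration stops at an assignment fixed point, a centroid shift below
  `tol` (default 1e-6), or `max_iter` (default 100).

**Choosing k.** For each candidate k (default 2–5) we record the
Caliński–Harabasz index — computed with Euclidean dispersion about the
column-mean centroids, its standard definition; no Jaccard-adapted CH is
defined here, and the selection report records this — and a validity
flag: every cluster must contain at least one essential condition (below).
The chosen k is the smallest valid candidate whose CH is within a
configurable fraction (default 10%) of the best valid CH.  This
operationalises "the lowest number of patterns consistent with the CH
index"; the full CH curve and per-k validity are always reported so a
human reviewer can override the mechanical choice, which in practice is a
clinician-consensus step.  Zero within-cluster dispersion (duplicate-row
or singleton clusters) returns a +inf sentinel rather than an error.

## Pattern characterisation

For each pattern, every condition's observed prevalence (OP, within the
pattern) is compared with its expected prevalence (EP, in the wave
population) via the prevalence ratio PR = OP/EP.  EP is computed on the
**same wave's** analysed population, not frozen at baseline: each wave is
an independent cross-section of the surviving cohort.  A condition is
**essential** to a pattern iff

* PR ≥ 2.0 and OP ≥ 10%, or
* OP ≥ 20% and PR ≥ 1.5,

all comparisons inclusive.  Note that with a single cluster PR ≡ 1 and no
condition can be essential, whatever its prevalence — an intended
consequence of the rule: a lone cluster has no distinctive profile.
Candidate pattern names are mechanical — the top two essential conditions
by PR, ties broken alphabetically, "unspecific" when the essential set is
empty; real pattern naming is a consensus activity out of scope here.

An exact bookkeeping identity ties profiles together: for every
condition, `Σ_p size_p · OP_p = n · EP`, because both sides count the
condition's carriers.  The test suite asserts it to 1e-12.

Between-pattern descriptive comparisons use Pearson's chi-squared (sex ×
pattern, no continuity correction), one-way ANOVA for age and
chronic-disease counts, and pairwise Welch t-tests judged at the
Bonferroni-adjusted level α = 0.05/m for the m pairwise comparisons.
Zero-variance groups are flagged and the affected test is skipped.

## Trajectories

Patterns are re-derived independently per wave, so "the same" pattern in
two waves is a nominal correspondence only; flows are computed on raw
per-wave labels, never on name matching.  For each consecutive wave pair
the flow table counts pattern→pattern moves plus pattern→Death and
pattern→Lost for patients exiting in between; the eight-year endpoint
table links baseline labels directly to final-wave labels, with exits
routed to the absorbing state of the patient's **first** event.
Conservation holds by construction: each non-absorbing node's outflow
equals its size, and absorbing nodes never flow onward.  The alluvial
rendering allocates vertical extent proportionally to node sizes (2%
proportionality is asserted on the layout in tests) with smoothstep
ribbons; Death/Lost nodes are drawn by default since their handling is
part of the design, and can be dropped from the flow table upstream if a
figure without them is wanted.

## Association models

Mortality: binary logistic regression of death-by-horizon on pattern
dummies, age in years (linear — the adjustment is deliberately minimal;
age-band dummies can be passed by pre-transforming the covariate) and
sex.  The reference pattern is auto-selected as the one with the lowest
crude mortality at the modelled horizon.  Patients lost to follow-up
before the horizon have unknown vital status and are excluded by default
(`include_lost_as_alive=True` re-includes them as a sensitivity check).
Fitting is Newton/IRLS (statsmodels) to tolerance 1e-8 within 100
iterations; perfect separation and non-convergence raise explicit errors.
Effects are reported as OR = exp(β) with Wald 95% CIs exp(β ± 1.96·SE).

Acute diseases: multinomial logistic regression with pattern membership
as the outcome, the acute-disease indicator (any diagnosis of the label
in the period) plus age and sex as covariates, and the smallest pattern
(lowest wave prevalence) as baseline category.  With two patterns this
reduces exactly to the binary model, which the tests assert.  The
acute-disease scan applies no multiplicity correction — results are
descriptive screens at p < 0.05 and are flagged as such in output.

## Synthetic-data generator

The generator emulates the structure the analysis assumes — not any real
population's margins.  Per patient: a latent cluster from
`cluster_weights`; baseline conditions Bernoulli from that cluster's row
of `prevalence_matrix`, with rejection sampling (simple and exact for a
Bernoulli model) until ≥2 conditions when `multimorbid_only`; per period,
death from a logistic model in age, sex and cluster, then loss among
survivors at `lost_rate`; incident conditions from `incidence_matrix`
among active survivors (sets only grow); Poisson numbers of acute events
and dispensations with labels/codes drawn with replacement, so
within-period duplicates occur and the dedup rules are genuinely
exercised.  Ages are uniform on 18–65 and advance 4 years per wave.
Identical configs (incl. seed) yield byte-identical cohorts.

Default rates are chosen once to echo a realistic chronic-disease cohort
of this age band: female fraction 0.578, per-period loss ~2%, ~5 distinct
acute conditions and ~11 dispensed ATC-4 groups per 4-year period, a
130-condition catalog.  The incidence mechanism for new chronic disease
during follow-up is a free modelling knob (no published estimate is
targeted).  The demonstration config plants three overlapping
prevalence blocks (cardio-metabolic-like, hypertensive-like, and a
mental-health/unspecific block) strong enough that the CH-parsimony rule
can resolve them; the planted-recovery experiments use cleaner disjoint
0.9/0.05 blocks.

**What passing tests show — and don't.** The synthetic cohorts have
conditionally independent conditions given cluster, uniform ages,
covariate-independent cluster membership, and missingness (loss to
follow-up) independent of everything.  Real EHR cohorts violate all of
these: conditions correlate within patients beyond cluster structure,
pattern membership is strongly age- and sex-structured, and attrition is
informative.  Passing recovery tests therefore validate the *computations*
(the estimators recover what was planted under the stated model), not the
clinical transportability of any particular pattern.

## Experiment sizes and numerical choices

* Planted-block clustering recovery: 3 blocks at 0.9/0.05 over 30
  conditions, n = 3,000 per cohort, k candidates 2–5, 20 seeds (the
  package's standard benchmark size; results are insensitive to n here
  because the blocks are near-noiseless).
* Odds-ratio recovery: planted pattern log-OR log(1.16), n = 50,000,
  per-period baseline mortality ≈ 20% (chosen so the Wald SE on the log
  odds ratio is ≈ 0.02 and the recovery experiment is informative at the
  ±0.05 level on the OR scale; this is a power choice for the experiment,
  not a claim about realistic mortality).
* Null coverage: 200 replicates of n = 1,500.
* Tolerances: mixture identity 1e-12; oracle equivalence of clustering
  and CH 1e-9; logistic coefficients vs an independent optimiser 1e-6.
* Degenerate inputs: empty waves, ATC codes shorter than 5 characters,
  zero expected prevalence, k exceeding the number of distinct patient
  profiles, perfect separation, and zero-variance comparison groups all
  raise typed errors rather than propagating NaNs.

## Known limitations

* k-means under a non-Euclidean metric with mean-centroid updates is a
  heuristic: the update step minimises Euclidean, not Jaccard,
  within-cluster distance, so each Lloyd pass is not guaranteed to
  monotonically decrease the Jaccard objective (restarts and the
  best-of-restarts rule mitigate this; on separated data the optima
  coincide, which the exhaustive-search tests confirm at small n).
* The CH index is computed in Euclidean geometry while clustering is
  Jaccard-based; the two are consistent on binary data in practice but
  the mismatch is a known conceptual wrinkle, recorded in the selection
  report.
* Trajectory tables treat pattern identity across waves as nominal; no
  transition-probability model (e.g. Markov) is fitted.
* Association models are cross-sectional logistic fits with minimal
  adjustment (age, sex); they are association screens, not causal
  estimates, and no survival-time or competing-risks structure is used.
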