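# Methods

This note documents the models and conventions behind `mcitriage`: what is
computed, which choices were open and how they were fixed, and what results
on synthetic data do and do not show.

## Coded vignettes

A vignette reduces one casualty to the answers every triage query would
receive. Answers are coded `"1"` (yes), `"0"` (no) and `"n"` (the result
cannot be derived from the record); the ESI resource query additionally
admits `"2"` with the reading 0 = no resources, 1 = one resource, 2 = many
resources. All seven algorithms share one flat canonical query vocabulary
(`vocabulary.py`); queries that algorithms phrase differently but that
probe the same finding are merged through an alias table (unstable pelvis →
pelvic fracture, respiratory rate > 30/min → > 29/min, FAST variants → one
FAST column), so a single vignette row serves every algorithm.

Conventions: vignette sets are tabular — every row answers the same query
set — which is what keeps `save → load` bit-identical without silent fill
values; a missing answer for a query an algorithm needs is a validation
error, never an implicit `"n"`; reference categories are restricted to
T1/T2/T3 (expectant/blue and deceased are algorithm outcomes, not
admissible entrance-triage references).

## Expert-consensus reference

The gold standard per vignette is the median of the panel's ratings on the
urgency rank scale T1 = 1 < T2 = 2 < T3 = 3. With an even panel (the
emulated study panel has 36 raters) the sample median can be half-integer;
no published rule covers this case, so the package makes an explicit
choice: **ties round toward the more urgent category** (floor on the rank
scale). This is the safety-conservative direction — triage doctrine prefers
overtriage to undertriage for potentially red patients — and every
tie-rounded vignette is flagged in the agreement summary so the sensitivity
of downstream results to the rule can be audited. Agreement is reported as
the simple fraction of raters matching the median; no chance-corrected
coefficient is computed.

## Decision-tree engine

Algorithms are data, not code: JSON files with binary predicate nodes, one
ternary resource-node kind (ESI only), and leaves carrying a category or an
ESI level (1 → T1, 2 → T2, 3–5 → T3). Validation rejects cycles, missing
or extra branches, unreachable nodes, dangling references, resource nodes
outside ESI and special outcomes (T4/DECEASED) in secondary algorithms.
DAGs with shared sub-branches are allowed; the step count of a traversal is
the number of query nodes on the realized path (the leaf is free), and the
three-way ESI resource node counts as one step.

**`n` handling.** How the original computerized evaluation resolved
non-derivable answers is not documented. The engine makes the policy
explicit and selectable: the default treats `n` as "no" (a finding that
cannot be derived cannot trigger a discriminant); alternatives are "yes"
(n → many resources for the ESI node) and "error". Every policy hit is
counted per traversal and summed per run in the log, so the influence of
the ambiguity is always visible.

**Fixtures are reconstructions.** The exact node-by-node content of the
seven algorithms is published only in supplementary material and primary
sources not shipped here. The bundled definitions are synthetic
reconstructions built from the algorithms' well-known structure (the mSTaRT
sieve order; PRIOR's walk-item-last design; ESI's decision points A–D; BER's
8 red + 9 yellow discriminant lists; PETRA's full vital-sign assessment
before any red decision) and are *gated by every published step-count
constraint*: BER's longest path is 17 queries ending green, JorD's is 11,
mSTaRT/MTS/PETRA place a green leaf at step 1, ESI reaches level 1 in one
step, and every PETRA red decision takes exactly 6 steps. Category
assignments and step counts are therefore structurally faithful; individual
discriminant wording inside the yellow lists is a best reconstruction, and
each fixture carries a provenance note saying so.

## Diagnostic quality and mistriage

For each algorithm and category c the problem is collapsed one-vs-rest:
positive = reference c, test-positive = assigned c. Sensitivity =
TP/(TP+FN), specificity = TN/(TN+FP), PPV = TP/(TP+FP), NPV = TN/(TN+FN),
Youden J = sensitivity + specificity − 1 (held as an exact identity).
Metrics with an empty denominator are emitted as explicit nulls, never 0
or 1. T4/DECEASED assignments are negatives of every category and rank
below T3, so a red patient assigned DECEASED is simultaneously a false
negative for T1 and an undertriage.

Mistriage is ordinal: among reference-c patients, overtriage = assigned
strictly more urgent, undertriage = strictly less urgent. Structurally,
overtriage(T1) = 0 always, and under the default generator (which never
produces apnoeic green casualties) undertriage(T3) = 0; for T1,
undertriage = 1 − sensitivity exactly.

Step statistics (median, Q1, Q3 per mistriage stratum) use **linear
interpolation between order statistics**. Published tables do not name
their quantile convention and conventions differ exactly where strata are
small, so printed interquartile bounds are matched structurally, not
bit-exactly; the rule is stated here and in the report metadata. Empty
strata are reported as "None". Inferential statistics on step counts
(ANOVA-type comparisons) are out of scope; the long per-vignette step table
is exported so any external test can be applied.

## Time projection

Given per-category per-patient durations d_c (seconds), a cohort size N and
a category distribution f (which may contain a `dead` stratum that accrues
no triage time), total_c = N · f_c · d_c / 60 minutes and share_c =
total_c / Σ_living total. The shipped scenario constants are the published
per-patient durations for PRIOR (27/28/42 s for T1/T2/T3) and mSTaRT
(35/20/10 s) with a 100-patient drill distribution (15/20/60/5 % dead) and
the aggregate German MCI distribution (7/19/74 %). These reproduce the
reference projections: 42 min (PRIOR) vs 10 min (mSTaRT) for the green
category alone, and an 81 % green time share for PRIOR under the German
mix.

## Published benchmark tables and integer back-solution

`published.py` carries the printed per-algorithm test-quality tables of the
original 210-vignette validation study (rounded to two decimals, mistriage
percentages to one). Because the category denominators (49/45/116,
themselves recovered from the printed percentages: 42.9 % = 21/49,
35.6 % = 16/45, 2.6 % = 3/116) are known, the printed cells
*over-determine* the integer one-vs-rest confusion cells:
`reconstruct_confusion` enumerates all (TP, TN) pairs and keeps those whose
full-precision sensitivity, specificity, PPV, NPV, Youden and mistriage
percentage all round (half-up) to the printed values, raising if the
solution is absent or ambiguous. The printed Youden values are consistent
with full-precision computation (e.g. MTS T1: 28/49 + 160/161 − 1 = 0.565
prints as 0.57, not the 0.56 that rounded inputs would give), which the
back-solver reproduces.

## Synthetic data generator

The generator emulates the statistical shape of the undeposited reference
set; its defaults are the study conditions, not tuning knobs.

* **Category mix**: 49/45/116 over T1/T2/T3 at n = 210 (largest-remainder
  integer allocation, so counts deviate from quotas by < 1 at any n).
* **Feature model**: per-category probabilities of answer "1" and "n" for
  every canonical query, plus a per-category distribution over ESI resource
  counts. T1 rows carry vital-threat findings (absent radial pulse,
  respiratory rate > 29, not obeying commands, positive FAST) with high
  probability; T3 rows walk with high probability; `n` appears at a low
  base rate, higher for FAST (often simply not performed outside the red
  stream). Features are sampled independently given the category; a short
  documented consistency pass then repairs clinically incoherent
  combinations (absent breathing/pulse, airway obstruction or unresponsive
  ⇒ not walking; walking ⇒ no immediate life-saving intervention; the
  after-airway-opening query is fixed to "yes" when breathing is
  spontaneous).
* **Rater error model**: each expert rates each vignette independently as
  the true rank perturbed one step toward a neighbour with probability
  `adjacent_error` (split evenly where two neighbours exist) and two steps
  (T1↔T3) with probability `extreme_error`. With 36 raters and adjacent
  error 0.2 the median recovers the latent truth in ≥ 99.9 % of vignettes
  (the one-sided binomial tail of ≥ 19/36 same-direction errors is far
  below 10⁻³), which the acceptance suite verifies by Monte Carlo at
  n = 10 000.

All randomness flows through `numpy.random.default_rng(seed)`; identical
seeds give identical sets across platforms.

**What synthetic results do not show.** The feature model is a declared
stand-in, not an estimate of any real casualty population: real vignettes
have correlated injury patterns, and the published per-algorithm
sensitivities/specificities depend on that structure. Synthetic runs
demonstrate that the machinery is correct (structural zeros, identities,
step accounting, consensus behaviour) and reproduce qualitative findings
(red detection is easier than yellow discrimination for every algorithm;
the longest algorithms discriminate yellow best) — they are not a
re-measurement of the published table values.

## Problem sizes

The default test and acceptance runs use the study-scale set (n = 210,
36 raters) for pipeline checks, n = 10 000 vignettes for the
sensitivity-ordering and consensus-recovery simulations, 1 000 fuzzed sets
for the metric oracle-equivalence suite and 300 random answer vectors per
algorithm for traversal fuzzing; the full suite completes in well under a
minute on one CPU.

## Known limitations

* Fixture discriminant wording inside the yellow lists is reconstructed,
  not transcribed (see above); anyone holding the original supplementary
  tables can drop in replacement JSON definitions without code changes.
* The tie-rounding rule for even panels is a documented choice; the
  original study's handling is unknown.
* Printed interquartile bounds of step counts are quantile-method
  dependent and only matched structurally.
* No confidence intervals are attached to the diagnostic metrics, and no
  inferential step-count statistics are computed.
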