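# Methods

## Model structure and assumptions

The core object is a decision tree whose root is a decision node over the
four surveillance strategies; each strategy subtree is a chain of chance
nodes, one per scheduled observation event over a 5-year horizon. The
model makes the following assumptions:

1. Surveillance targets distant (stage IV) recurrence only; loco-regional
   recurrence pathways are out of scope.
2. A first distant recurrence occurs at most once; diagnosis is absorbing
   and the patient is censored from further follow-up.
3. Distant recurrence arises with a constant hazard per arm, derived from
   the arm's 5-year cumulative probability (λ = −ln(1−p)/H). A recurrence
   arising inside an interval is assumed present at the next scheduled
   visit; events and their costs accrue at visit times.
4. Imaging visits test the true status with fixed per-visit sensitivity
   and specificity, independent across visits. Missed (false-negative)
   recurrences persist and are re-tested at every subsequent visit; a
   recurrence can therefore be caught late or remain undetected at the
   horizon. This persistence is what makes schedule frequency matter.
5. Positive findings — true or false — trigger a composite confirmatory
   work-up (FNAB, repeat whole-body PET/CT, other tests). The work-up is
   also attached to false-negative imaging results, reflecting clinician
   investigation of equivocal findings; clinical (non-imaging) misses
   trigger nothing.
6. Everyone with diagnosed distant disease is treated; treatment cost
   attaches only under the correct-diagnosis outcome (see below).
7. The no-imaging arm is followed with twice-yearly clinical reviews; a
   present recurrence is detected at a review with probability
   `clinical_detection_prob`, and clinical review raises no false alarms
   unless `clinical_fp_rate` is configured.
8. Radiation-attributable malignancy, palliative/end-of-life costs,
   survival and quality-of-life outcomes, and imaging anxiety are out of
   scope.

Internally each strategy subtree is a rooted DAG: continuation subtrees
are shared between branches, keyed by (visit index, patient state) with
states {disease-free/no error yet, disease-free/error occurred,
recurrent-undetected}. This keeps the node count linear in the number of
visits — a literal tree expansion of the 3–4-monthly arm (20 visits) has
millions of paths. Evaluation memoizes on node identity; the exhaustive
path enumerator exists as an independent test oracle for small trees.

## Outcome definitions

Two effectiveness metrics, each in two modes (`metric_mode`):

* **proportion** (default): `correct_diagnosis` is the probability that a
  patient's recurrence status is correctly resolved — no recurrence, or a
  recurrence diagnosed within the horizon. `error_avoided` is the
  probability of completing follow-up with no diagnostic error, an error
  being any false-positive episode or any false-negative test of an
  established recurrence.
* **difference**: the literal tally differences E[TP]−E[FN] and
  E[TN]−E[FP] over the horizon. These live on a count scale (the expected
  number of true-negative reviews can exceed 1) and are provided because
  the outcome is sometimes defined this way in words even when reported
  values look like proportions; both candidate readings are implemented
  rather than guessing one.

A structural note: with visits tiling the horizon and missed recurrences
re-tested at every later visit, the proportion-scale correct-diagnosis
effectiveness is bounded below by roughly 0.93–0.95 at realistic test
performance for any recurrence probability, and the relation
effect(prevalence) is U-shaped (very high hazards push recurrences early,
where the schedule has many chances to catch them). Published-style
effectiveness values in the high 0.80s are therefore not exactly
reproducible by calibrating prevalence alone; the calibration routine
reports its residuals honestly instead of silently clamping.

## Costs and discounting

Unit costs are 2020 AUD. The packaged base case uses: whole-body PET/CT
AUD 1,128.75 per scan (PET/low-dose-CT item plus adjunctive localisation
CT); stage-IV treatment AUD 115,072 per diagnosed patient;
a composite confirmatory work-up of AUD 1,500 (FNAB ≈ AUD 75–110, repeat
PET/CT ≈ AUD 1,129, plus ancillary tests, rounded to a single composite);
clinic visit AUD 90 (specialist attendance). A single multiplicative CPI
factor (`cpi_factor`, default 1.0) converts raw price-year costs to 2020
AUD at load time; nothing is fetched at run time.

Costs are discounted at 5%/year (the Australian health-technology-
assessment convention) as 1/(1+r)^t with t in fractional years — a cost at
18 months uses t = 1.5 — rather than step-function year bins. Effects are
*not* discounted by default: the effectiveness measures are diagnostic
proportions over a fixed horizon, not time-streams of utility, and
discounting them would distort the proportion scale. A
`discount_effects` flag provides the override.

Because the diagnostic-error analysis prices the diagnostic cascade and
not disease management, stage-IV treatment costs enter only the
correct-diagnosis costing; `StrategyOutcome` therefore carries one
expected cost per outcome metric.

## Incremental analysis

Strategies are compared two ways: the comparator-anchored table (all
increments against no-imaging, the published layout) and the standard
sequential frontier table. Strict dominance removes any strategy with
cost ≥ and effect ≤ some alternative (one inequality strict); extended
dominance then removes strategies iteratively until sequential ICERs along
the cost-sorted frontier strictly increase. Exact ties in both cost and
effect are retained and flagged. A zero effect increment is never
reported as a division: such rows carry a status label (dominated, or
cost-saving-at-equal-effect). ICERs above AUD 1M are rendered "Over AUD
1 M" in display tables while the numeric value is kept in machine-readable
output. NMB maximization and the ICER-threshold rule agree on the
frontier; the test suite checks this equivalence on random instances.

## Sensitivity analysis

One-way DSA re-evaluates the comparator-anchored ICER at the low and high
end of one parameter's range (all others at base, originals never
mutated) and ranks parameters by absolute ICER swing; swing ties keep
their input order.

PSA assigns beta distributions to probabilities and test performance and
gamma distributions to costs, parameterized by method-of-moments from
(mean, SE); infeasible moments (SE² ≥ mean(1−mean) for a beta) are
rejected at specification time. Parameters are sampled independently — no
correlation structure, and sensitivity/specificity are not jointly
constrained to an ROC curve — matching common practice when no
correlation information is available. Each parameter draws from its own
substream derived from the master seed and a hash of the parameter path,
so adding a parameter never perturbs the other parameters' draws. Out-of-
domain draws (e.g., a cumulative probability of exactly 1) are resampled
and counted, never clamped. The default run uses 10,000 replications and
a WTP grid of 0–200,000 in steps of 1,000. The CEAC at each WTP is the
fraction of draws in which a strategy maximizes NMB, ties broken by
strategy order — so at WTP 0 the CEAC equals the probability of being
cheapest.

## Synthetic cohort

The generator emulates the structure of the four follow-up groups
(146/47/284/346 patients): per-patient exponential recurrence times per
group hazard, the group's visit schedule, per-visit confusion-matrix
results, absorbing detection, and overdispersed extra-investigation
counts (negative-binomial per positive finding, mean 5.0, dispersion 0.6).
A loss-to-follow-up hazard (default 0.44/year) emulates the combined
administrative censoring and attrition visible in observed scan counts:
with recurrence hazard λ and attrition a, the expected attended scans are
(visits/year)·(1−e^{−5(λ+a)})/(λ+a), and 0.44/year reproduces the
intensive arm's observed mean of ~6.3 scans; the value was derived from
that closed form, not tuned against tests. Sub-stage labels (IIIA–D) are
generated for realism but do not modify hazards by default.

What the generator does **not** emulate: per-substage risk gradients,
non-constant (e.g., early-peaked) recurrence hazards beyond what the
config allows, visit-level scheduling noise, and the observed idiosyncrasy
that the 12-monthly group averaged more scans (4.3) than the 6-monthly
group (3.7) — a cohort artefact no common generating process reproduces.
Passing the cohort tests therefore shows the estimators recover the
generating process, not that real follow-up data behave this way.

Estimation: hazard MLE = events / person-time at risk (person-time to the
earlier of recurrence and end of follow-up), Wald intervals on the
log-hazard scale with an exact Poisson upper bound when no events occur;
Se/Sp from pooled per-visit tallies against true status with logit-scale
Wald intervals, falling back to exact beta intervals at the boundary.

## Calibration

`calibrate()` fits free parameters (dotted parameter paths, all bounded)
to target outputs by minimizing the sum of squared standardized residuals
with bounded Powell search from the current parameter values. It is
deterministic given the starting point. Convergence requires both
optimizer success and a maximum standardized residual below 1e−4;
anything else is reported as non-converged with the best-found point and
residuals — infeasible targets (e.g., a proportion above 1, or the
effectiveness floor discussed above) surface this way rather than raising.

## Numerical choices

* Chance-node branch probabilities must sum to 1 within 1e−9 (absolute);
  probabilities are never silently renormalized.
* Payoffs accrue on nodes; a path's cost is the sum of its node payoffs.
* Tree serialization (JSON) round-trips losslessly for trees; shared
  subtrees are expanded on write, which preserves value but not sharing.
* Validation reports all violations without raising; evaluation rejects
  an invalid tree naming the first violation.
* Degenerate inputs: a strategy scheduling neither scans nor reviews is
  rejected; an empty patient group reports absent statistics, not zeros;
  zero person-time is a hard error.
* Money is rendered to whole AUD and effects to 4 decimals in display
  tables; machine-readable CSVs keep full precision.

## Problem sizes

The test suite and acceptance script use 1,000 random trees for the
rollback-vs-enumeration oracle, 1,000 inputs for the moment-fit round
trips, 10,000 PSA replications, 2,000 patients per group (10 replicate
cohorts in the recovery test), and the 823-patient study-sized cohort for
resource-use summaries. These sizes keep every Monte-Carlo check's
standard error far below its assertion tolerance.

## Known limitations

* The decision tree is a fixed-horizon chain, not a state-transition
  model: no competing mortality, no post-diagnosis pathway.
* Constant hazards are a simplification; melanoma recurrence hazards
  peak early. Piecewise-constant hazards can be emulated per-arm via the
  cohort config but not in the decision model itself.
* The two printed effectiveness scales cannot both be reproduced exactly
  under the implemented definitions (correct-diagnosis effectiveness is
  necessarily ≥ first-opportunity detection); the package documents and
  reports the residuals instead of reverse-engineering undisclosed
  formulas.
* PSA treats parameters as independent; correlated sampling is a hook,
  not a feature.
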