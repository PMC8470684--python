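# Methods

## Model overview

`brcacost` is a decision-analytic cost model, not an effectiveness model: it
prices diagnostic-therapeutic paths for a BRCA1/2-mutation carrier with a
first breast-cancer diagnosis and asks which path minimises expected
discounted lifetime cost to the health service.  The reference patient is a
woman diagnosed at 40 (starting age `N(40, 2.5²)`, rounded to whole years and
clamped to the 20–79 support of the risk tables); the horizon is 35 annual
cycles with 3% discounting (year 0 undiscounted, year *t* divided by
`1.03^t`, no half-cycle correction).  All patients in the model are mutation
carriers: the population positivity rate (U(0.10, 0.20)) is carried in the
parameter set for cohort-weighting extensions but does not gate the base
analysis, because non-carriers never enter the path comparison.

Ten paths are modelled.  Six are leaf strategies (11, 12, 21, 22, 31, 32 —
combinations of quadrantectomy / unilateral mastectomy / bilateral mastectomy
with intensive or ultrasound follow-up, before or after the test result);
three are "no preference" aggregate nodes (10, 20, 30) priced as
share-weighted mixtures of their two children; Path 0 is standard care
without counseling or testing (historical 70/30 quadrantectomy/mastectomy
split, ultrasound follow-up, all hazards active), which is never
optimal-selectable and contributes zero savings by convention.

## Stochastic structure

Patient-level draws: starting age; counseling and testing as **sequential
Bernoulli gates** (testing is only reachable through counseling, so the
untested share is `1 − 0.45² = 79.75%` at the historical uptakes — the
reading that simultaneously matches the reported baseline untested share of
~79% and the 55% Path-0 share when counseling alone becomes universal); and a
patient-level complication risk `q ~ U(0.10, 0.20)` applied independently per
operation.

Within-trajectory events per annual cycle, in fixed order (follow-up,
recurrence workup, tumor event, residual-gland event, implant replacement —
the ordering affects only the audit log, since all charges land in the same
annual bucket):

* **Recurrence workup** (all paths): detection 5% → biopsy EUR 52.08 →
  positive 60% → recurrence surgery EUR 4,583.  No radiotherapy is attached
  to recurrence surgery.
* **Tumor events** in tissue still under surveillance.  A conserved affected
  breast (path 11 and the Path-0 quadrantectomy variant) carries the
  age-stratified annual new-incidence risk *and* the contralateral (CBC)
  risk, combined as independent hazards; after unilateral mastectomy (21/31)
  only the CBC risk remains; risk-reducing paths (12/22/32) carry neither.
  This is the central structural choice: surveillance keeps cancer hazards
  alive, prophylactic surgery extinguishes them — with the new-incidence
  table dormant, breast conservation would strictly dominate on cost and the
  model would have nothing to trade off.  The alternative flat-chain-only
  reading remains available (`engine.relapse_model = detection_chain_only`).
* **Event treatment** is risk-reducing completion: all remaining intact
  breast tissue is removed in one operation (bilateral tariff if two sides
  remain, unilateral if one), with reconstruction, complications at the
  patient's `q`, radiotherapy at the after-mastectomy probability (0.40), and
  follow-up dropping to ultrasound thereafter.  The completion reading
  reflects the strong observed preference of diagnosed carriers for
  risk-reducing surgery once a tumor event occurs.
* **Complications**: any complicated operation is billed at its complication
  tariff plus the EUR 4,924 plastic-surgery repair charge (the tariff item
  covers "plastic surgery after complications or implant replacement", so the
  repair applies to complicated quadrantectomies as well as reconstructions).
* **Residual-gland carcinoma** after prophylactic surgery: the 5% lifetime
  probability is converted to the constant annual hazard `h` solving
  `1 − (1 − h)^35 = 0.05` and is active on the templates that perform
  prophylactic surgery at year 0 (12/22/32), at most once per lifetime,
  billed as recurrence surgery.
* **Implant replacement**: EUR 4,924 every 15 years from the most recent
  reconstruction (years 15 and 30 for a year-0 reconstruction); an event
  reconstruction restarts the cycle.  The 15-year default follows the tariff
  description; the plausible 10–15-year range is exposed as
  `engine.implant_replacement_interval_years`, a fixed interval rather than a
  random draw.

Ages beyond 79 reuse the 70–79 bracket probabilities for the remaining
horizon (relevant only to older starting ages in the sweep).

## Pricing modes and the decision rule

Two pricing modes share identical cash-flow timing:

* **stochastic** (headline): one realised history per patient per path.  All
  paths for a patient share a single bundle of uniform draws from her private
  sub-stream — maximal common random numbers, with nested hazard tests — so
  per-patient cost differences between paths reflect structure and realised
  events, never independent sampling noise.  The per-iteration optimum is the
  realised minimum, and savings `max(asis − optimal, 0)` inherit the full
  spread of realised histories (which is what gives the savings distribution
  its zero floor and long right tail).
* **expected**: every Bernoulli branch replaced by its probability weight.
  Exact in closed form because each path's tumor-event process has a single
  absorbing transition.  Expected mode is the oracle in the equivalence tests
  (Monte Carlo mean within 3 SE of the analytic expectation at 10,000
  replicates per path) and is available as a headline mode
  (`engine.mode = expected`); a policy variant that decides on expected costs
  but realises the consequences is selectable via
  `engine.decision_basis = expected`.

**Tie handling.** Paths 21 and 31 are clinically identical trajectories and
price identically under common random numbers; exact ties resolve to the
post-test label.  When both children of a decision node lie within
`engine.tie_tolerance` of the minimum, the parent "no preference" node
(10/20/30) is reported instead of a leaf.  The default tolerance is EUR 2,500:
the study this model operationalises treats the two post-test options as
economically interchangeable while their own mean cost gap is ≈ EUR 1,700, so
a tolerance that encodes that indifference must exceed that gap; EUR 250
(≈ one year of intensive follow-up) and other values are scanned by
`sensitivity_scan`.

**"As is" sampling.** The printed historical shares cannot all be marginal
(26% post-test plus a 70/30 pre-test split); the model reads 26% as the
marginal probability of operating after the test, with the 70/30 split inside
the remaining 74%, then applies the conditional second-level shares
(20/80, 20/80, 70/30).

## Scenario analyses

Scenario 1 sets counseling uptake to 1.0; scenario 2 sets both gates to 1.0,
optionally sweeping the starting-age mean over 20–70 (SD unchanged);
scenario 3 prices the two post-test strategies on a common all-tested cohort
and reports, besides the full-cost summaries and the paired difference, the
**one-sided excess cost** of each trajectory over the other
(`E[(X_a − X_b)⁺]`).  The excess reading is reported because it is the only
statistic of this comparison whose distribution has a zero minimum and a
subadditive pair of means differing by the paired mean difference — the shape
of the published scenario-3 block; full lifetime costs necessarily exceed the
index-surgery tariff and cannot have a zero minimum.

## What the synthetic cohort does and does not emulate

The cohort generator *is* the study population model: it reproduces exactly
the stated stochastic structure (Normal starting age, sequential Bernoulli
uptake gates, Uniform complication risk, age-bracket hazards) with
per-patient reproducible sub-streams.  It does not emulate features of real
registry data — correlated uptake and age, secular trends in tariffs,
non-adherence to follow-up schedules, competing mortality (patients live
through the full horizon; the model prices costs only).  Passing tests
therefore demonstrate the internal correctness of the pricing and decision
machinery and the faithfulness of the declared input distributions, not the
external validity of the cost estimates for any particular clinic.

## Problem sizes and numerics

Headline runs and the reproduction script use 10,000 iterations (binomial SE
≤ 0.5 percentage points on any reported share); the age sweep in the test
suite uses 4,000 per age and unit tests use 10²–10³.  Results are
bit-reproducible given a master seed: each patient owns two `SeedSequence`
sub-streams (attributes, events), so records do not depend on cohort size or
iteration order.  Monetary arithmetic is floating point with two-decimal
presentation at I/O; NPV totals are recomputable from the stored annual
vectors to 1e-9 relative tolerance.

## Known limitations

* The annual event model is under-specified by the published description; the
  choices above (live new-incidence hazard, completion surgery, repair charge
  on any complication, tie tolerance) are this package's own resolutions, and
  `sensitivity_scan` quantifies how the headline statistics move across them.
  Under the defaults, the reproduction script matches the published
  structural shares and baseline/scenario-1 summaries, while the scenario-2
  savings probability runs ~9 percentage points high and the "no preference"
  node receives less reporting mass than published — the realised per-patient
  gap between the post-test options is often wider than the tie tolerance
  even though their expected costs nearly tie.
* No quality-of-life weighting, mortality, ovarian/pancreatic extrapolation,
  currency conversion or inflation indexing.
* Aggregate nodes are priced as share-weighted mixtures of their children;
  they are reporting constructs, not separately realisable strategies.
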