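# Methods

## Cohort model

An *episode* is one new clinical suspicion of bacterial infection in an
immunocompromised child: a qualifying blood culture, a residual serum
sample, the five-biomarker panel (IL-8, CCL3, HSPA1B, GZMB, MMP-8, pg/mL),
demographics, care location, 72-hour clinical events, infection status,
and 28-day vital status. Three predicates define the analysis population
and outcomes:

* **Immunocompromise** (eligibility): neutropenia (ANC < 0.5 K/mcL,
  strict inequality), chemotherapy or myeloablative radiation within 7
  days, or a solid-organ / bone-marrow transplant *together with*
  immunosuppression exposure within 7 days. A missing ANC contributes
  nothing; there are no age cutoffs (ages are only validated ≥ 0).
* **Clinical deterioration within 72 h** (primary outcome): ICU transfer,
  new respiratory support (HFNC/NIPPV/invasive), crystalloid ≥ 60 mL/kg
  in 24 h (≥ 3 L at ≥ 50 kg), new vasoactives, new altered mental status,
  or death. The predicate is monotone in its inputs; weight ≤ 0 is an
  invalid record, not "false".
* **Sample selection**: a residual sample qualifies within ±6 h of the
  culture (the window is taken as symmetric; the source protocol does not
  say); the closest qualifies, and an exact tie goes to the *earlier*
  sample, deterministically favoring pre-culture specimens. Repeat
  enrollments must be ≥ 24 h apart; the spacing filter is greedy against
  the last *kept* sample, which matches a protocol that only spaces
  samples actually utilized.

Missing biomarker values are an explicit state (`None`; CSV empty cell or
`NA`), never zero. Timestamps are ISO-8601 in CSV. Numeric cells are
written with 12 significant digits (6 is the documented round-trip
guarantee).

## Synthetic cohorts

The generator emulates a 400-episode / 293-subject population: 83 subjects
re-enroll (weeks-to-months between episodes), 15.25% of episodes are in an
ICU at evaluation, 15% deteriorate, 5.25% (21/400) die by 28 days, 37%
have confirmed bacterial infection, age is log-normal with median 7.8 y,
platelets log-normal with median 80 K/mcL (IQR ≈ 33–190).

Outcomes follow a conditional chain — location → deterioration → death and
infection — with anchors P(det | ICU) = 0.52, P(death | det) = 0.20,
P(infected | det) = 0.62; the complementary conditionals are solved so the
marginals are exact. This reproduces the strong location/outcome and
deterioration/mortality associations of the emulated population without
extra parameters. Death within 72 h is a rare sub-event of deterioration
∩ death (≈1% of deteriorations), so `death_72h ⇒ death_28d` holds by
construction.

Biomarkers are log-normal (concentrations are positive and right-skewed).
Stable-stratum medians (250, 30, 2000, 20, 3000 pg/mL for IL-8, CCL3,
HSPA1B, GZMB, MMP-8) are order-of-magnitude conventions; the event-stratum
log-shifts (+1.0, +1.0, −0.3, 0.0, +0.5) encode only the observed
*directions* (IL-8/CCL3 up, HSPA1B down). No stratified medians are
available to estimate magnitudes from, so parameter-recovery tests treat
these as ground truth of the simulation, not of any real population.

In **tree mode** biomarkers are drawn first from the stable-stratum
distributions and each episode's outcome probability equals its terminal
rate under a supplied truth tree — the basis of all recovery experiments.
Event flags for deteriorated episodes are drawn at the observed
manifestation frequencies (vasoactives 27%, respiratory 26%, ICU transfer
25% — ward episodes only, AMS 13%, fluids 11%) and re-drawn from the
categorical if none fired, so the label always agrees with the predicate.
Crystalloid volumes keep a 1% margin away from the threshold so the 0.1 mL
recording precision cannot flip the criterion.

All randomness flows from one master seed through five named substreams
(structure, demographics, outcomes, markers, events); identical seeds give
bit-identical cohorts.

What the generator does **not** emulate: correlated biomarker panels,
longitudinal trajectories, antibiotic exposure, location-dependent marker
levels, or informative missingness. Tests passing on these cohorts
demonstrate the correctness and calibration of the machinery, not clinical
performance on real patients.

## Tree derivation

Binary CART with weighted Gini impurity. Candidate thresholds are
midpoints between consecutive distinct sorted values; `x ≤ t` goes left,
`x > t` right (so published ">" cutpoints name the right branch). Balanced
class weights `n/(2n_c)` are the default: with 5–15% prevalence,
unweighted Gini rarely produces the high-sensitivity trees this analysis
targets. Growth stops at `max_depth = 4`, `min_node_size = 20`, purity, or
no admissible gain — defaults sized so ~400-episode cohorts yield trees of
about five terminal nodes. Equal-gain ties break to the alphabetically
first variable, then the smallest threshold, making the fit independent of
row order and invariant (up to threshold relabeling) under monotone
predictor transforms.

**Pruning** builds the weakest-link cost-complexity sequence (risk = total
weighted leaf impurity) and evaluates each candidate complexity by pooled
10-fold cross-validation: grow on nine folds, prune to the candidate
alpha, assign held-out episodes their terminal rate, pool all out-of-fold
risks into one AUC. The selected subtree is the *smallest within one
Hanley–McNeil standard error of the best* CV AUC. The one-SE margin is
deliberate: maximizing alone keeps near-zero-value splits, because at
large n extra splits marginally refine the inexact placement of true
thresholds and win by amounts well inside noise; with the margin, a
two-split embedded truth is recovered at its true size in 9 of 10
replicates (n = 4,000).

The **summary cross-validated AUC** pools all out-of-fold predictions into
a single AUC rather than averaging per-fold AUCs — with ~21 events across
10 folds, per-fold AUCs are too unstable to average. Stratified fold
assignment is seeded (`cv_seed`) and requires at least one event per fold;
fewer events than folds is a refusal, not a silent degradation.

## Risk models

A fitted tree freezes into a portable JSON TreeSpec: nodes with counts,
event rates, split rules, and terminal risk labels, validated for
structural integrity (single root, two children per split, conservation of
`n` and `n_event`, rate consistency to 1e-9, known predictors only). The
high-risk rule — terminal rate strictly above the cohort baseline rate —
reproduces low/high labels of the kind published for both outcomes
(deterioration baseline 15%: 22–52% nodes high, 2–3.8% low; mortality
baseline 5.25%: 13% and 24% high). A missing value on a consulted
predictor is a hard, named error; no imputation or surrogate splits.
Published external models (e.g. transcribed PERSEVERE cutpoints) can be
applied by supplying their TreeSpec files; none are shipped because the
source material does not print them.

## Evaluation statistics

* **Proportion CIs**: 95% continuity-corrected Wilson. This choice is
  pinned by an end-point check: for 21/21 it gives a lower bound of
  0.8076 → "81%", where the plain Wilson interval gives 0.847.
* **Likelihood ratios**: LR⁺ = sens/(1−spec), LR⁻ = (1−sens)/spec, CIs by
  the standard log-transform method; any zero denominator (including LR⁻
  with zero false negatives) is an explicit *undefined* marker.
* **AUROC**: trapezoidal over unique-threshold ROC points — provably equal
  to the tie-corrected Mann–Whitney statistic divided by n₁n₀ (fuzz-tested
  to 1e-10) — with a Hanley–McNeil 95% CI. Hanley–McNeil is a documented
  convention isolated behind one function; a different CI method can be
  swapped in without touching callers.
* **χ² (2×2)**: Yates continuity correction, each cell contributing
  `max(0, |O−E| − ½)² / E`, 1 df. The correction term is clamped at zero,
  so an exactly independent table scores 0. The corrected statistic — not
  uncorrected Pearson — reproduces the reference values for the four
  reconstructed cohort cross-tabulations (41.2, 75.8, 17.2, 27.5), and its
  type-I error at cohort-like margins is conservative (≤ 5.5% at nominal
  5%, 10,000 simulated tables).
* **Mann–Whitney U**: midrank ties; exact enumeration of all group
  assignments for pooled n ≤ 12, otherwise a normal approximation with
  tie-corrected variance (no continuity correction — matched against
  scipy's asymptotic method with `use_continuity=False`).
* **Descriptives**: medians and quartiles by linear interpolation.
* p-values print as `<0.001` below one thousandth, three significant
  figures otherwise; formatting lives only in the report layer.

## Problem sizes in the test suite

Unit and property tests run on 400-episode default cohorts. The heavier
checks use: 100 cohorts × 400 episodes for prevalence calibration; n =
10,000 for demographic medians and tree-mode stratum rates; n = 50,000 for
the degenerate-truth law-of-large-numbers check; 10 replicates of n =
4,000 for first-split recovery (threshold within ±15% of the embedded 1070
pg/mL cutpoint); 20 seeds × n = 1,000 for the no-signal null (mean CV AUC
0.50 ± 0.05); 1,000 fuzz cases for the AUC/rank-statistic identity; and
10,000 simulated tables for χ² type-I error. The full suite completes in
well under five minutes on one CPU.

## Known limitations

* Real-data quantities (the published AUROCs of 0.81/0.87 and CV AUCs of
  0.72/0.77, stratified biomarker medians, the exact published tree
  figures) cannot be recomputed here: the clinical dataset is not public.
  The recovery experiments substitute simulations with embedded ground
  truth.
* The original commercial CART software's priors, costs, and pruning rule
  are not public; this implementation's defaults are declared conventions
  and are not claimed to replicate that software's internals.
* One published descriptive p-value (0.06 for sex, 46% vs 43%) is not
  consistent with any standard 2×2 test at those counts and is not
  reproduced.
* Whether the mid-risk terminal of a published mortality tree counted as
  test-positive in its printed characteristics is unstated; the
  baseline-rate rule implies it does (perfect sensitivity is only
  achievable if all deaths fall in the above-baseline nodes), and that
  rule is applied uniformly here.
* Generator effect sizes are conventions (see above); calibration tests
  validate marginal prevalences and medians, not joint biomarker
  structure.
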