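# sepsitree

Decision-tree risk stratification for immunocompromised children evaluated
for bacterial infection.

Immunocompromised pediatric patients — neutropenic, on chemotherapy, or
transplanted — deteriorate quickly once infected, and most of them are on a
general ward, not in an ICU, when the first blood culture is drawn.
`sepsitree` implements the full analysis pipeline for deriving and
evaluating biomarker-based risk models in this setting: it models
*episodes* of suspected infection (a blood culture plus a residual serum
sample carrying five biomarker concentrations — IL-8, CCL3, HSPA1B, GZMB,
MMP-8, in pg/mL), defines the composite 72-hour **clinical deterioration**
outcome and 28-day mortality, derives binary decision trees over the
biomarkers plus age and platelet count, and reports the full battery of
diagnostic statistics. Because episode-level clinical datasets of this kind
are not public, the package includes a first-class synthetic cohort
generator calibrated to the population it emulates, so every stage is
testable end to end.

## What it computes

**CART.** Trees are grown by recursive binary partitioning minimizing
weighted Gini impurity `1 − Σ p̃_c²`; candidate thresholds are midpoints of
consecutive distinct observed values, the left branch takes `x ≤ t` and the
right `x > t`. Balanced class weights (inverse prevalence) let 5–15%
outcomes drive the splits. Cost-complexity pruning selects, among the
nested subtree sequence, the smallest subtree whose pooled 10-fold
cross-validated AUC is within one standard error of the best. Each terminal
node's training event rate is the assigned risk, and a terminal is labeled
**high risk** exactly when its rate exceeds the cohort baseline rate.

**Evaluation.** Sensitivity, specificity, PPV and NPV with 95%
continuity-corrected Wilson intervals; LR⁺ = sens/(1−spec) and
LR⁻ = (1−sens)/spec with log-method intervals; AUROC by the trapezoidal
rule (identical to the tie-corrected Mann–Whitney statistic over n₁n₀)
with a Hanley–McNeil CI; Yates-corrected χ² for 2×2 tables; Mann–Whitney
U with exact small-sample p-values; median/IQR descriptives.

**Synthesis.** Default synthetic cohorts reproduce the emulated study
conditions: 400 episodes over 293 subjects (83 enrolled repeatedly,
samples ≥ 24 h apart), 15% deterioration, 5.25% 28-day mortality, 15.25%
ICU location, 37% bacterial infection, age median 7.8 y, platelet median
80 K/mcL, log-normal biomarkers shifted in the event stratum. A *tree*
mode draws biomarkers first and makes each episode's outcome probability
equal its terminal-node rate under an embedded truth tree, giving
recovery experiments a known ground truth.

## Worked example

```
sepsitree all --seed 7 --out-dir out/
```

simulates a 400-episode cohort, derives and evaluates trees for both
outcomes, and writes `out/report.md`. With seed 7 the deterioration model
is:

```
node 1 n=400, events=64 (16.0%)
  if il8 <= 1582.27: node 2 n=346, events=40 (11.6%)
    if ccl3 <= 55.539: terminal node 4 [low risk] n=224, events=11 (4.9%)
    if ccl3 > 55.539: terminal node 5 [high risk] n=122, events=29 (23.8%)
  if il8 > 1582.27: terminal node 3 [high risk] n=54, events=24 (44.4%)
```

Read: 400 training episodes with 64 deteriorations (16%); episodes with
IL-8 above ~1582 pg/mL form a 44% risk terminal node, and among the rest a
CCL3 split separates a 4.9% low-risk group from a 23.8% high-risk group
("high" = above the 16% baseline). The accompanying test characteristics
(classifying high-risk terminals as test-positive):

```
Model          Sensitivity  Specificity  PPV          NPV          Positive LR    Negative LR
deterioration  83% (71–91)  63% (58–69)  30% (24–38)  95% (91–97)  2.3 (1.9–2.7)  0.3 (0.2–0.5)
```

with AUROC 0.763 (0.691–0.834) and a summary 10-fold cross-validated AUC
of 0.698 — the familiar shape of a screening model: high sensitivity and
NPV at modest specificity.

The same library surface is available programmatically:

```python
from sepsitree import default_paper_config, generate_cohort, cohort_to_frame
from sepsitree.cart import CartConfig, derive_tree

frame = cohort_to_frame(generate_cohort(default_paper_config(seed=7)))
tree, cv_auc = derive_tree(frame, "deterioration", CartConfig(cv_seed=0))
```

Published single-cutpoint rules can be applied through the portable
TreeSpec JSON format (schema in `src/sepsitree/data/treespec.schema.json`;
examples under `examples/`).

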