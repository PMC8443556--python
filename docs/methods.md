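# Methods

## Problem setting

Vestibular schwannoma (VS) is a benign, slowly growing tumor of the 8th
cranial nerve.  Patients under a *wait-and-scan* (WaS) protocol return for
periodic checkups — pure-tone audiometry of both ears, speech audiometry of
the diseased ear, and MRI-based tumor descriptors (maximal 1D size in mm and
the four-level Koos grade) — until either the follow-up continues uneventfully
or the team decides on *active treatment* (surgery or radiotherapy).  The
package supports that decision along two complementary tracks:

* **CBR** (case-based reasoning): each checkup is an independent, anonymized
  sample; the question is whether a *single* examination predicts the need
  for active treatment.
* **PDA** (personalized dynamic analysis): each patient's whole follow-up is
  one sample, summarized by temporal metrics; the question is which *changes*
  matter.

## Data model

A checkup record carries thresholds at the eight audiometric frequencies
0.25–8 kHz per ear (dB HL), SRT/SDS/MDL/MDR speech measures, size, Koos
grade, and the decision label (WaS/Active).  Time is stored in **days since
the patient's first checkup**; with day-based time the longitudinal tree's
size-slope threshold of 0.0064 (≈ 2.3 mm/year) has natural units of mm/day.
Helpers convert to months (365.25/12 days per month).

Missingness is a tri-state: *present*, *missing*, or *present at the
audiometer ceiling*.  Saturated measurements (default ceiling 110 dB,
configurable per reader call since instrument limits vary) are stored at the
ceiling and flagged — they are informative ("could not hear"), not absent.
Cleaning (`clean_complete`) only drops records; no value is ever imputed,
keeping the pipeline free of distributional assumptions.

## Derived features

**Row-based (per checkup).**  For each ear X ∈ {VS, H} and range n ∈ {4, 8}
(basic = frequencies up to and including 4 kHz; full = all eight):

* `PTA_X_ARn` — mean threshold over the range (dB);
* `PTA_X_SRn`, `PTA_X_IRn` — slope and intercept of an ordinary
  least-squares line through the audiogram;
* `PTA_D_ARn = PTA_VS_ARn − PTA_H_ARn` — the inter-ear asymmetry.

The regression abscissa is frequency in kHz on a linear scale; this is the
plainest reading of a "linear fit of pure-tone thresholds" and is what makes
the reference tree's slope thresholds (2.3, 6.7, 7.1 dB/kHz) land inside the
observed slope range.  Because the choice changes slope units, `log2khz`
(octave-scaled, audiologically common) and `index` abscissae are available
but not default.  A metric is missing whenever any in-range threshold is
missing (completeness rule, no partial means).

**Column-based (per patient).**  Each base variable's series over the
checkups is summarized by `_AC` (mean), `_SC`/`_IC` (OLS slope per day and
intercept at the first checkup), `_LD` (last minus previous checkup), and
`_TD` (last minus first).  The *last difference* reads the latest change —
the longitudinal tree's "any change in Koos grade since the previous
checkup".  Summaries cover the whole recorded follow-up including the final
checkup at which an Active decision is made: those measurements were taken
while the patient was still under observation, and excluding them would
discard exactly the change that triggers the decision.  A series uses only
the checkups where the variable is present; a single-point series has
`AC = IC = value`, `TD = 0`, and missing `SC`/`LD`.

Numerical note: slopes whose magnitude is below 1e−12 of the data scale are
snapped to exactly 0.  A constant series must have slope 0; `polyfit`
otherwise returns ±1e−18 residue whose *sign* is noise, which matters when a
threshold such as "slope < 0.01" separates "no change" from "change".

## Consensus feature selection

Five supervised rankers — CART-style decision tree, random forest, gradient
boosting, logistic regression, LASSO (scikit-learn implementations; the
contract is the ranking, ties broken by column order) — each nominate their
top-10 variables.  The consensus table records, per variable, the occurrence
count **Num** across lists and the average rank **Avg** over the lists that
contain it; displayed Avg is rounded to one decimal, half away from zero
(rank sum 13 over 4 lists → 3.3).  A variable is a candidate when
**Num ≥ 3 or Avg ≤ 5**.  The final minimal sets are expert judgments, not an
algorithm; the shipped defaults are the published shortlists
(`CBR_EXPERT_FINAL` = {Koos, SRT, PTA_VS_SR8, PTA_H_SR8, PTA_D_AR4};
`PDA_EXPERT_FINAL` = {Koos_LD, Size_SC, PTA_D_AR4_SC, PTA_VS_AR4_SC}), and
`select_candidates` accepts any override.

## Decision trees and missing-value routing

Trees are explicit node lists: rule `variable {≥, <, =} threshold`, true and
false child ids, an optional missing route, and Yes/No leaves.  Routing is a
deterministic descent; comparisons are threshold-inclusive exactly as the
rules read, `=` is exact equality, and a missing input follows the node's
missing route or raises a routing error if the node has none — refusing is
safer than a silent guess.  Only variables on the traversed path are ever
inspected, so a record can be classified from a partial workup.

Two reference trees ship with the package.  The static (CBR) tree has 13
nodes over the five expert variables; its root and two other nodes route
missing values with the "≥" branch.  Child orientation was validated against
the eight published worked inferences (full node paths and predictions), not
against table column order, which differs between the two source layouts.
The longitudinal (PDA) tree is two rules deep: any Koos change since the
previous checkup → treat; otherwise a size slope ≥ 0.0064 mm/day → treat;
else continue monitoring.  Printed per-node sample counts are carried as
annotations only.

**Induction.**  `learn_tree` grows a tree greedily: candidate thresholds are
midpoints between consecutive observed values; split quality is the 2×2
chi-square statistic (default, no continuity correction) or Gini impurity
decrease; rows with a missing split value follow the branch holding the
majority of non-missing rows, and that branch is recorded as the node's
missing route.  Ties break by feature column order, then lower threshold, so
induction is deterministic.  `learn_tree_validated` fits depths 1–4 and keeps
the depth with the best validation accuracy (ties favour the shallower
tree); its default minimum leaf of 10 reflects the ~90-sample balanced
training sets this pipeline produces — smaller leaves let the tree carve out
clusters of mislabeled patients.

## Evaluation

ACC, TPR, TNR, PPV are computed from the confusion counts with Active/Yes as
the positive class; any undefined ratio is reported as missing, never as 0.
AUC is the area under the ROC curve (tie-aware, equal to the normalized
Mann–Whitney statistic; the test suite checks it against exhaustive pairwise
comparison); ASE is the mean squared difference between the 0/1 target and
the continuous classifier output.  Classifiers without continuous outputs
contribute a degenerate two-point ROC, flagged in the report.

Datasets are balanced by seeded down-sampling of the majority class to the
minority count, then split 50:30:20 into train/validation/test with
largest-remainder rounding per class, so partitions keep equal class ratios
up to rounding.  A class with fewer than five members is refused.  The
benchmark grid crosses the five rankers plus fixed expert sets with six
classifier families (tree, random forest, gradient boosting, logistic
regression, RBF-kernel SVM, small MLP); selection is fit on the training
partition, per-cell reports carry test metrics and the average of the train
and validation partition metrics (metric-level average, not pooled samples),
and a failing cell is recorded as missing.  No multiple-testing correction
is applied anywhere, matching the source methodology.

## Synthetic cohorts

The generator emulates the cohort the analysis was designed for: 93 patients
by default, ~43% eventually treated; 3–8 roughly yearly checkups (medians 3
for treated, 5 for WaS patients); audiograms worse in the diseased ear with
a high-frequency-weighted offset; tumor sizes around 12 mm; Koos grades
skewed low in the WaS group and non-decreasing in time (tumors are not
modelled as shrinking); SRT linked to the diseased ear's low-frequency mean
plus noise and capped at the 110 dB ceiling; audiometric fields missing at a
configurable rate (5% default).  Koos grade and size are never missing —
checkups are MRI-driven — which keeps the label mechanism fully observed.

Outcomes follow a **planted rule** mirroring the longitudinal reference
tree: every treated patient either gains one Koos grade at the decision
checkup or has a size slope drawn from 0.009–0.030 mm/day (or both); WaS
patients have neither (slopes capped at 0.004 mm/day).  At label noise 0 the
reference tree therefore reproduces every generated outcome from the derived
features — the end-to-end consistency the tests assert.  Label noise flips a
patient's recorded outcome with the given probability *without* touching the
mechanisms, emulating decisions driven by preferences and judgment outside
the recorded variables.  Hearing deterioration is faster in the treated
group in the mean (4 vs 2 dB/year, s.d. 2) but deliberately overlapping:
hearing is a correlate of the outcome, not its mechanism, and a generator
whose audiometric slopes separate the classes outright would let every
learner bypass the planted rule.

What passing on synthetic cohorts does **not** show: the generator's
conditional independences (audiometry given group, size given mechanism) are
far cleaner than clinical reality, its missingness is random rather than
informative, and real treatment decisions are not a deterministic function
of two variables plus coin flips.  Synthetic results validate the machinery
and its statistical behavior, not clinical performance.

## Known limitations and accuracy under label noise

With noisy labels, any predictor's test errors include the flipped patients
in the test partition; the expected test accuracy of even the true rule is
1 − (realized flip fraction).  At 5% label noise and ~34-patient test sets
(200 patients, balanced, 20% test), "accuracy ≥ 0.9" allows at most three
flipped test patients while ~1.8 are expected, so single replicates fall
below 0.9 roughly 15% of the time for the *optimal* predictor; replicate
counts of such threshold events are correspondingly variable.  The test
suite's end-to-end check states this condition exactly as specified and is
expected to sit near its boundary.

Other limitations: the exact published column compositions (38-dim static,
24-dim longitudinal vectors) are configuration-dependent and not enumerated
in full by the source tables, so vector composition is config-driven; the
reference trees' per-node sample counts are annotations, not reproducible
without the original cohort; and the speech-audiometry linkage in the
generator (SRT from low-frequency thresholds) is an assumption, documented
as such.
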