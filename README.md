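# schwannoma

Decision support for vestibular-schwannoma (VS) treatment from longitudinal
checkup data.

VS is a benign tumor of the 8th cranial nerve.  Patients under a
*wait-and-scan* protocol are re-examined roughly yearly — pure-tone
audiometry of both ears, speech audiometry, and MRI descriptors (maximal 1D
size, Koos grade 1–4) — until the team decides on active treatment (surgery
or radiotherapy).  This package implements, end to end, a two-track analysis
of such cohorts for clinicians and biostatisticians:

* **CBR** (case-based reasoning) — can a *single* checkup predict the need
  for active treatment?  Each record is expanded with audiogram summaries
  per ear X ∈ {VS, H} and frequency range n ∈ {4, 8}: the mean `PTA_X_ARn`,
  the fitted slope/intercept `PTA_X_SRn` / `PTA_X_IRn`, and the inter-ear
  asymmetry `PTA_D_ARn = PTA_VS_ARn − PTA_H_ARn`.
* **PDA** (personalized dynamic analysis) — which *changes* drive the
  decision?  Each patient's history is summarized per variable by its
  time-average `_AC`, slope `_SC` (units/day), intercept `_IC`, last
  difference `_LD`, and total difference `_TD`.

On top of the feature layer the package provides ensemble-consensus feature
selection (five supervised rankers; a variable is shortlisted when it
appears in ≥ 3 top-10 lists or has average rank ≤ 5), binary decision trees
with explicit missing-value ("or N/A") routing — including the two published
reference trees and a deterministic chi-square/Gini learner — the
ACC/TPR/TNR/PPV/AUC/ASE metric suite with balanced 50:30:20 partitioning, a
selector × classifier benchmark grid, and a synthetic cohort generator so
the whole pipeline runs and is tested without patient data.

The longitudinal reference tree is two rules deep and reads directly as
clinical guidance: *if the Koos grade changed since the previous checkup,
treat; otherwise, if the tumor grows faster than 0.0064 mm/day
(≈ 2.3 mm/year), treat; else keep monitoring.*

## Worked example

Route a single checkup record (Koos 2, SRT 30 dB, diseased-ear audiogram
slope 4.7 dB/kHz, healthy-ear slope 0.2 dB/kHz, inter-ear asymmetry 5 dB)
through the static reference tree:

```sh
$ schwannoma route --tree cbr \
    --features '{"Koos": 2, "SRT": 30, "PTA_VS_SR8": 4.7, "PTA_H_SR8": 0.2, "PTA_D_AR4": 5.0}'
path: 1, 3, 6, 8
decision: Yes
```

The record descends root → node 3 (slope ≥ 2.3, so the diseased ear's
audiogram falls off with frequency) → node 6 (healthy ear unaffected) and
reaches leaf 8: active treatment is recommended.  Missing inputs follow the
tree's "or N/A" routes where the rule defines one, and raise an error
otherwise.

Aggregate the bundled longitudinal top-10 rankings into the consensus table
(`Num` = in how many of the five rankers' top-10 lists the variable occurs,
`Avg` = its mean rank there):

```sh
$ schwannoma consensus --reference pda
     variable  Num  Avg  selected
      Koos_LD    5  2.0      True
      Size_LD    4  1.5      True
      Size_SC    4  4.5      True
PTA_VS_AR4_SC    3  5.3      True
      Koos_TD    3  6.7      True
...
```

The Koos last-difference appears in every list (Num 5, mean rank 2.0) — the
change in tumor grading since the previous checkup is the dominant
longitudinal predictor, followed by the size dynamics.

Simulate a 93-patient cohort, derive per-patient temporal features, and
check the reference tree against the generated outcomes:

```sh
$ schwannoma simulate --n-patients 93 --seed 7 --label-noise 0 --out cohort.csv
wrote 93 patients / 412 checkups to cohort.csv
$ schwannoma derive-features cohort.csv --layout pda --out pda.csv
$ schwannoma evaluate pda.csv --target outcome --tree pda
{
  "acc": 1.0,
  "tpr": 1.0,
  "tnr": 1.0,
  "ppv": 1.0,
  ...
}
```

With label noise 0 the generator's planted mechanisms (a Koos step at the
decision checkup, or growth above the slope threshold) are exactly what the
tree tests, so every patient is classified correctly; at the default 5%
label noise accuracy drops to about 0.95 — the flipped labels are
irreducible.  See `docs/methods.md` for the model, parameter and design
discussion.

The same functionality is available as a library:

```python
from schwannoma import read_cohort, build_pda_dataset, pda_reference_tree, route

cohort = read_cohort("cohort.csv")
pda = build_pda_dataset(cohort)
trace = route(pda_reference_tree(), pda.iloc[0].to_dict())
print(trace.path, trace.decision)
```

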