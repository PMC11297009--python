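# spatsig

Spatial immune-interplay analysis for multiplex-immunofluorescence (mIF)
tissue-microarray data, and a prognostic **spatial immune signature (SIS)**
for recurrence risk.

## The problem

In solid tumors, the *position* of immune cells carries prognostic
information that plain abundances miss: a regulatory T cell (Treg) sitting
30 μm from a tumor cell is doing different biology than one 300 μm away.
Modern mIF platforms produce per-cell tables — coordinates plus marker
positivity (CK, CD4, CD8, FOXP3; or CK, FOXP3, PD-1, PD-L1) — for small
tissue cores taken from the invasive margin (IM) and tumor center (TC) of
each patient.  `spatsig` turns those tables into per-patient spatial
features, selects the prognostic ones, and builds a linear risk score with a
full survival evaluation, for analysts working on tumor-microenvironment
cohorts with recurrence-free-survival (RFS) follow-up.

## The metrics and the signature

For phenotypes A (source) and B (target) in one core:

* density  D(A) = n(A) / area, in cells/mm²;
* mean nearest-neighbor distance
  N(A→B) = (1/n(A)) · Σᵢ min_j ‖aᵢ − bⱼ‖, in μm (smaller = stronger
  spatial association; a cell never pairs with itself);
* proximity score
  P(A→B, r) = (1/N(B)) · Σⱼ #{aᵢ : ‖aᵢ − bⱼ‖ ≤ r}, the mean count of A
  cells within r = 30 μm of each B cell.

Per-patient features are named on a fixed grammar, e.g.
`N(CD4Treg_to_Tumor)@IM`.  Feature selection intersects three shortlists
fitted on a stratified 70% training split: L1-penalized Cox regression
(penalty by 10-fold cross-validated partial-likelihood deviance, top ten
nonzero coefficients), XGBoost (gain importance, top ten) and a random
forest (impurity importance, top ten), both fitted to the recurrence
indicator.  The signature is

SIS = Σₖ βₖ · zₖ(feature)

with βₖ the multivariate Cox coefficients of the intersected features
(z-scored on the training split) and a high/low cutoff chosen by
outcome-driven log-rank maximization (X-tile style).  Evaluation covers
Kaplan–Meier curves with log-rank tests per split, a multivariate Cox model
(stage + SIS group), and Uno-type IPCW time-dependent AUCs at 1/3/5 years.

Because no real cohort ships with the package, a synthetic cohort generator
produces TMA-like cores (clustered tumor cells, immune cells with tunable
attraction toward targets) and exponential survival with known planted
effects, so the whole chain is testable against ground truth.

## Worked example

```sh
spatsig run-all --n 120 --seed 7 --outdir demo
```

prints

```
intersection: ['D(CD8Treg)@IM', 'N(CD4Treg_to_Tumor)@IM', 'P(CD4Treg_to_CD4all)@IM']
train: n=84 events=34 logrank_p=1.43e-07 auc={'12mo': 0.7288091396966317, '36mo': 0.7320125461316472, '60mo': 0.8640371482410723}
validation: n=36 events=14 logrank_p=0.414 auc={'12mo': 0.6515151515151515, '36mo': 0.6135950563431479, '60mo': 0.5860592876411468}
entire: n=120 events=48 logrank_p=2.32e-07 auc={'12mo': 0.7144770787924843, '36mo': 0.7011318336328964, '60mo': 0.7946549099329072}
```

Reading this: on a 120-patient synthetic cohort the three algorithms agree
on three features (two of them planted prognostic effects — the CD4+ Treg
distance to tumor cells and a CD8+ Treg feature); the SIS separates high-
from low-risk patients decisively in the training split and the entire
cohort (log-rank p < 1e-6) while the 36-patient validation split is
underpowered at this size (p = 0.41); time-dependent AUCs of ~0.6–0.86 say
the continuous score ranks recurrences well above chance at all three
horizons.  `demo/` holds every intermediate table (metrics, features, split,
selection, model, scores, report.json).

The same stages are importable as a library:

```python
from spatsig import simulate_cohort, split_cohort, select_features, fit_signature

cohort = simulate_cohort(261, seed=1)
split = split_cohort(cohort.patients, ratio=0.7, seed=1)
train = cohort.patients[split == "train"]
sel = select_features(cohort.features.loc[train.patient_id],
                      train.rfs_months, train.event)
model = fit_signature(cohort.features.loc[train.patient_id],
                      train.rfs_months, train.event, sel.ordered_intersection)
scores = model.score(cohort.features)
```

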