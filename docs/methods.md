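# Methods

This note documents the models, conventions and numerical choices behind
`spatsig`, in the order data flows through the package.

## Phenotype gating

Marker positivity arrives as booleans; intensity thresholding is upstream
and out of scope.  Gates follow a fixed hierarchy chosen to mirror the
mutually exclusive phenotyping output of commercial mIF software:

1. CK⁺ cells are tumor cells and are excluded from every T-cell gate
   (including FOXP3⁺ gating — a CK⁺FOXP3⁺ cell is a tumor cell).
2. Within CK⁻ cells, CD4 and CD8 lineages are exclusive; CD4⁺CD8⁺ double
   positives belong to neither and count as "other".
3. FOXP3 splits each lineage into Treg (FOXP3⁺) and Tcon (FOXP3⁻);
   `CD4all`/`CD8all` are the whole lineages, so target sets like
   "Tregs to CD4⁺ T cells" include the Tregs of that lineage.
4. `PD1pos`/`PDL1pos` are purely marker-based (PD-L1 is expressed on tumor
   cells too).

How real phenotyping software resolves double positives is generally
undocumented; this hierarchy is a declared convention, not an attempt to
reverse-engineer any particular tool.

## Spatial metrics

All three metrics are computed per core on a local μm frame with the origin
at the window corner.

* **Density** `D(A)` — gate count divided by window area, reported per mm²
  (coordinates in μm, hence the 10⁶ conversion).
* **mNND** `N(A→B)` — mean over A cells of the Euclidean distance to the
  nearest B cell, via a KD-tree on the target set.  When the two gates can
  overlap (e.g. `CD4Treg → CD4all`) the query cell is never its own
  neighbor: the second-nearest neighbor is substituted whenever the nearest
  hit is the cell itself.  The metric is undefined (missing, never zero)
  when either gate is empty, or when the only target is the source cell
  itself.
* **Proximity score** `P(A→B, r)` — mean over B cells of the number of A
  cells within the **closed** ball of radius r (default 30 μm; ties have
  measure zero in real data but a convention must be fixed for integer
  counts).  Self-counting is excluded the same way.  Undefined when B is
  empty; an empty source set gives 0 (a defined absence of neighbors).

Two deliberate asymmetries to be aware of: `N(A→B) ≠ N(B→A)` in general,
and the proximity score iterates over *target* cells while counting *source*
cells — descriptions of such scores in the literature sometimes invert this
direction in prose; the formula implemented here is exactly the one above.

**No edge correction** is applied: cells near the core boundary have
truncated neighborhoods, which biases mNND slightly upward and proximity
slightly downward relative to an infinite-plane ideal.  This matches common
practice for core-level mIF summaries, where all cores share the same
geometry and the bias cancels in comparisons.  The metric functions accept a
`wrap=True` (toroidal) mode used only to validate the generator against
closed-form Poisson expectations, where edge effects would confound the
check; the analysis pipeline never wraps.

Undefined metrics propagate as missing values into the feature matrix.  A
core with no CD8⁺ Tregs carries no information about CD8⁺-Treg interactions;
imputing 0 would claim maximal interaction.  Imputation (training-split
median) happens only at the model-fitting boundary.

## Synthetic cohort generator

The generator exists so every downstream stage can be tested against known
ground truth; it emulates TMA data at the order-of-magnitude level only.

**Geometry.** 1000 × 1000 μm windows (1 mm², the scale of a TMA core), one
IM and one TC core per patient per panel.

**Tumor cells.** Thomas-type cluster process: Poisson parents (10/mm²),
each tumor cell displaced from a uniformly chosen parent by an isotropic
Gaussian (σ = 35 μm), wrapped toroidally so the marginal intensity equals
the requested one exactly.

**Immune cells.** Counts are Poisson (intensity × area).  Placement is a
mixture governed by an attraction coefficient ρ ∈ [−1, 1] per
(source, target) pair: with probability |ρ| the cell is displaced from a
uniformly chosen target cell by an isotropic Gaussian (σ = 20 μm) when
ρ > 0, or rejection-sampled away from all targets (beyond 2σ, 50 tries)
when ρ < 0; otherwise uniform.  ρ = 0 is complete spatial randomness, under
which the closed forms E[mNND] = 1/(2√λ) and E[P] = λπr² hold with toroidal
wrap — the tests verify both within 5%.  The mechanism was chosen over
Gibbs pairwise-interaction processes because it samples exactly, and its
effect on both mNND and proximity is monotone in ρ.

**Default intensities** (cells/mm², log-normal patient jitter, σ = 0.25 on
the log): tumor 800, CD4⁺ Tcon 300, CD8⁺ Tcon 200, CD4⁺ Treg 150, CD8⁺
Treg 15 — making CD4⁺ Tregs ≈ 91% of the regulatory compartment, the
proportion reported for NSCLC tissue.  Panel 2: FOXP3⁺ 60–300 (a uniform
latent draw), PD-1⁺ 200, PD-L1⁺ 250.  Per-patient attraction draws
ρ ~ U(0, 0.8) on CD4Treg→Tumor, CD4Tcon→Tumor, CD8Treg→Tumor and
CD8Treg→CD4all create the across-patient feature variance; in panel 2 the
FOXP3⁺ intensity and the PDL1→PD1 attraction share one latent draw,
planting the association between Treg burden and checkpoint interplay that
the panel-2 analysis is meant to detect.

**Survival.** Recurrence times are exponential with hazard
h₀·exp(Σ β·z + β_stage·1[stage III]), h₀ = 0.01/month; censoring is an
independent exponential (0.012/month) truncated at 84 months, giving
roughly 40–47% observed events over a 7-year follow-up.  Features enter
z-scored so the β are per-SD log-hazards and comparable across metrics.
Default planted effects sit on the four signature features
(+0.32, +0.35, −0.40, −0.46) with β_stage = ln 2.26.  The magnitudes are
half the typical high-vs-low group log-HRs of such features: a group
contrast spans roughly two standard deviations of the feature, so per-SD
coefficients of about half the contrast reproduce a dichotomized-signature
hazard ratio in the 2–4 range and time-dependent AUCs around 0.6–0.8 —
the regime published spatial signatures live in.  (Planting the group-level
log-HRs directly as per-SD effects makes the signature separate almost
perfectly, which is useless as a test condition.)

Clinical covariates are drawn at the marginal frequencies of an operable
NSCLC surgical cohort (stage I–II 81.6%, male 64.4%, LUAD 65.9%, …).

**What the generator does not emulate** — and hence what passing tests do
not show about real data: tissue morphology (vessels, stroma/tumor
compartments), marker-intensity noise and segmentation errors, batch
effects across TMAs, non-exponential hazards, and informative censoring.
Conclusions from the synthetic pipeline are about the correctness of the
computations, not about biology.

A lightweight companion, `simulate_feature_cohort`, draws iid standard
normal features with planted β and the same survival machinery.  It bypasses
spatial simulation on purpose: power and coverage checks need hundreds of
replicates, and the spatial layer adds nothing to what they measure.

## Splitting, selection, signature

* **Split**: stratified (default on stage group) with largest-remainder
  allocation so the training size is exactly round(0.7·n) — 183/78 at
  n = 261 — and per-stratum proportions match within one patient.  Strata
  smaller than 2 merge into the largest stratum with a warning.
* **LASSO**: penalized Cox (features feed a survival signature; a logistic
  variant is available by config).  The penalty path comes from coxnet; the
  penalty is chosen at minimum 10-fold cross-validated partial-likelihood
  deviance, computed with a Breslow log-likelihood on held-out linear
  predictors.  Up to ten nonzero-coefficient features are kept, ranked by
  |coefficient|.
* **XGBoost / random forest**: fitted to the binary event indicator
  (survival forests are out of scope); importance is gain for XGBoost and
  impurity for the forest, each truncated to ten.  Hyperparameters are fixed
  defaults recorded in `SelectionConfig` (200 trees, depth 3, lr 0.1;
  500 trees, min leaf 3) — unremarkable values, not tuned per dataset.
* **Standardization** (median imputation + z-score) is fitted on the
  training split only and applied unchanged to validation data.
* **Signature**: multivariate Cox coefficients of the intersected features
  on the training split; the high/low cutoff is the optimal cutpoint of the
  training scores.  Scoring is strictly linear, so score(a·v) = a·score(v).

Whether the final coefficients should come from the training split or the
whole cohort is a genuinely open design point; the training split is the
default here because it keeps the validation split untouched by any fitting
decision.

## Survival machinery

Kaplan–Meier, log-rank and Cox fits are delegated to lifelines (Efron tie
handling, the better default when event times tie); the time-dependent AUC
is the Uno-type IPCW cumulative/dynamic estimator from scikit-survival,
with censoring weights from the evaluated sample unless a reference sample
is supplied.  Medians that the curve never reaches are reported explicitly
as "not reached" (`None`), never as a number.

The **optimal cutpoint** emulates outcome-driven dichotomization: scan all
midpoints between consecutive distinct score values leaving ≥ 10% of
subjects per arm, keep the one maximizing the two-group log-rank chi-square
(a hand-rolled O(n) routine, cross-checked against lifelines in the tests),
break exact ties toward the more balanced split.  The p-value at the chosen
cutoff is **not** corrected for the scan and is optimistic; it is reported
as descriptive only.  Maximally selected statistics are intrinsically noisy
near a planted boundary — a single short-lived low-risk subject adjacent to
the boundary can genuinely move the argmax by one order statistic — so
recovery guarantees are stated in terms of misclassified subjects, not the
exact cut value.

Because the study design runs many feature-level log-rank tests without
multiplicity correction (as such analyses are usually reported), the run
report records the number of feature-level tests performed so a reader can
apply their own correction.

## Degenerate inputs and numerical conventions

Zero-area windows, negative times, constant covariates, empty groups, empty
splits, ratio = 1, zero events, constant scores and panel/marker mismatches
all raise early with named diagnostics; pipeline stages wrap failures with
the stage name.  Constant features z-score to 0 (std replaced by 1).  All
randomness flows from one `numpy.random.Generator` per entry point, so a
seed reproduces a cohort byte-for-byte.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run at desk scale, chosen as the
smallest sizes at which each property is decidable: oracle equivalence on
100 random cores of ≤ 500 cells; closed-form Poisson limits on 60 cores at
λ = 300/mm²; Cox coverage at n = 400 × 100 replicates; selection recovery at
n = 400 with 4 signal / 40 null features × 25 replicates; the end-to-end
pipeline at n = 90–261 patients.

## Known limitations

* Metrics carry no edge correction (see above) and no envelope-based
  inference (Ripley-type statistics are out of scope).
* The LASSO/boosting/forest shortlists treat recurrence as a binary label
  for the tree learners, discarding time — faithful to the study design the
  package implements, but not the only defensible choice.
* The signature assumes proportional hazards and linearity in the z-scored
  features; no diagnostics beyond fit convergence are run.
* The generator's realism is calibrated only to orders of magnitude typical
  of TMA data; it is a test harness, not a tissue model.
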