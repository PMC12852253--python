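# Methods

This note records the modelling choices behind `dualqsar`, what the
synthetic data does and does not emulate, and the numerical conventions
used throughout.

## Activity scale and labelling

IC50 values are stored in mol/L; the working scale is
pIC50 = −log₁₀(IC50 [M]).  Tables are exchanged with IC50 in nM (the
ChEMBL convention); the unit conversion happens only inside the pIC50
transform.  The dual label is strict: class 1 requires pIC50 > 6.0 for
*both* targets, so a compound at exactly 6.00 on either target is
class 0.  Real activity tables sometimes print boundary values rounded
to 6.00; the strict rule is applied to the stored value, not the
printed one.

## Curation

Order of operations: (1) missing/non-numeric IC50, unparsable SMILES,
ambiguous stereochemistry; (2) salts/mixtures (any multi-component
SMILES) and metal-containing compounds; (3) duplicate resolution;
(4) Tanimoto redundancy.  The audit trail records the survivor count
after each pass and is required to be non-increasing.

* **Metals** are defined by exclusion from the organic subset
  {H, B, C, N, O, F, Si, P, S, Cl, Se, Br, I}; the list is
  configurable.
* **Ambiguous stereochemistry** means at least one potential
  tetrahedral stereocenter left unassigned by the structure backend.
  This is deliberately aggressive (many real drug-like molecules have
  unannotated stereocenters); it can be disabled per call.
* **Duplicates** are keyed on (compound_id, target); the
  maximum-pIC50 record wins, exact ties keep the first record in input
  order.  Median aggregation across assays was considered and rejected:
  the keep-the-most-potent rule is the one the downstream labelling
  assumes.
* **Redundancy** uses a greedy leader pass in stable input order with
  ECFP6 Tanimoto ≥ 0.80: a record is dropped iff it is that similar to
  an already-retained record.  Greedy-by-input-order is deterministic
  and seed-free; any maximal-independent-set variant would change the
  survivor set, so the choice is fixed and documented.  The pass is
  idempotent and guarantees no retained pair at or above the threshold.

## Fingerprints

ECFP6 = Morgan radius 3 folded to 2048 bits; MACCS = the 166 predefined
keys (the backend's unused bit 0 is dropped); path-based = 1024-bit
topological fingerprint; combined = MACCS ∥ ECFP6 (2214 bits, MACCS
first).  PubChem 881-bit keys are declared in the interface but have no
backend implementation here and raise a clear error; externally
computed descriptor tables (e.g. Mordred) enter through the same matrix
interface.  Tanimoto over two all-zero vectors is defined as 1.0 (two
empty bit sets are identical); this matters only for degenerate inputs.
Lipinski compliance is strict (<), so MW = 500 counts as a violation.

## Feature selection

Mutual information uses the plug-in (empirical contingency) estimator
for binary/discrete features, in nats — a feature identical to a
balanced binary label scores ln 2 ≈ 0.693 — with the k-NN estimator
available for continuous imports.  Top-200 retention, ties broken by
stable feature order.

RF-RFE refits a balanced random forest and drops the `step` (default 1)
least-important features per iteration until exactly 50 remain; the
history logs every drop.  Boruta appends a column-shuffled shadow copy
of the design, scores a hit when a real feature beats the *maximum*
shadow importance, and decides each feature by a two-sided binomial
test (α = 0.05, default 100 iterations); undecided features are
reported tentative.  Because a fixed-size subset is sometimes needed
for model comparability, an optional `n_target` truncates/pads the
confirmed set by mean importance — the statistical decision remains the
default output.  Selection is meant to be fit inside the training
split; fitting once on the full dataset is available for comparability
but leaks label information into the feature choice.

## Imbalance handling

SMOTE synthesizes minority points x + λ(x′ − x), λ ~ U(0,1), toward one
of the k = 5 nearest minority neighbours, up to class balance; the
Tomek step then removes majority members of cross-class mutual-nearest-
neighbour pairs.  Synthetic points are convex combinations of real
minority pairs by construction.  Resampling is applied to training
folds only — the leakage canary below checks that this stays true.

## Metrics and model ranking

The panel is accuracy, precision, recall, F1, MCC (0 when its
denominator vanishes), rank-based ROC-AUC and step-wise-interpolated
PR-AUC (average precision; the trapezoidal PR area is optimistically
biased and not used).  Single-class truth flags the AUCs as NaN rather
than raising.  Model ranking is hierarchical — recall for the positive
class first, because a missed active is the expensive error in
early-phase screening — with ties broken by the composite
0.4·F1 + 0.3·PR-AUC + 0.2·MCC + 0.1·Recall (weights sum to 1, the
score is monotone in each component).  The best-F1 threshold scan
enumerates all distinct score cut-points and resolves ties to the
highest threshold.

R²/MAE/MSE are computed from predictions; Q² is the cross-validated R²
over out-of-fold predictions and therefore requires the estimator and
design matrix, not just a prediction vector — the API reflects that.

The train/test split is stratified 80/20 with a fixed seed
(configurable); grid search uses 5-fold stratified CV inside the
training data with small default grids.

## Applicability domain

Leverage is the hat-matrix diagonal h = x(XᵀX)⁻xᵀ with a pseudo-inverse
(rank-deficient designs are fine; training leverages sum to rank X).
The threshold is h\* = 3(p+1)/n with p the *effective* feature count.
For 2048–2214-bit binary fingerprints (n < p) the raw hat matrix is
degenerate, so the default AD space projects onto principal components
explaining 95% of variance, capped at 150 (`space="pca"`); the raw
pseudo-inverse space is available as `raw-pinv` and the report always
carries the p actually used.  The residual scale is the training
residual RMSE; "standard deviations" in Williams-plot practice is
ambiguous between RMSE and the SD of residuals, and RMSE is the
convention adopted here.  Boundaries are inclusive: h = h\* and
|residual| = 3 are in-domain.

## Candidate selection

Cross-target propagation applies each target's regression model to the
other target's dataset, with leverage computed against the predicting
model's training set; only h ≤ h\* predictions are AD-compliant.  The
selection rule is: classifier probability ≥ 0.999 (raw, uncalibrated
model probability), predicted pIC50 at or above the 95th percentile of
the *full* regression output distribution for each target (inclusive
linear-interpolation quantile; the candidate subset would be a biased
population), and AD compliance for both models.  Selection is monotone
in both thresholds.  Output is sorted by mean predicted pIC50.

## Attribution

Tree ensembles are explained by exact decision-path attributions: the
change in node value at each split is credited to the split feature, so
base + Σ contributions equals the model output identically (random
forests are explained in probability space, gradient boosting
classifiers in raw margin space, regressors in the response scale).
Linear models decompose exactly as coef·(x − background mean).  These
are *not* Shapley values — no sampling, no background marginalization —
but they satisfy the same additivity contract exactly and at negligible
cost.  One behavioural consequence matters for reporting: over all
rows, the contributions of a split feature average to approximately
zero (children deviations are frequency-weighted around the parent
value), so the direction of a feature's effect is taken from the rows
that carry the feature (above-average feature value) when the feature
matrix is supplied.  Margin-based kernel models (SVM) are not
explainable by this mechanism and are rejected with a clear error.

Folded ECFP bits can collide; the bit→substructure map returns *every*
atom environment that set a bit rather than silently picking one.
MACCS bits map to their predefined SMARTS keys.

## Docking post-analysis

Ki = exp(ΔG/RT) with R = 1.98720×10⁻³ kcal mol⁻¹ K⁻¹ and T = 298.15 K
(RT = 0.59248 kcal/mol, the AutoDock convention).  With ΔG printed to
two decimals, recomputed Ki values agree with printed ones to ~1%; one
bundled table row (CHEMBL1651126/AChE) is internally inconsistent by
14% — its printed Ki implies ΔG = −13.13 rather than the printed
−13.22 — and is documented rather than "corrected".  Pearson r uses
the two-sided t-test with n−2 df.  Redocking RMSD is computed in the
shared receptor frame without superposition or symmetry correction
(optional), pass iff RMSD < 2.0 Å strictly.  Interaction (H-bond
residue) lists are stored verbatim; no geometric interaction detection
is performed.

## The synthetic data generator

Molecules are assembled by string substitution of 1–3 substituent
fragments into scaffold attachment slots, then canonicalized; every
product is a valid single-component SMILES and structures are unique
within a run.  Latent potency per target is
baseline + Σ fragment weights + N(0, noise_sd), reported as IC50 in nM.

Defaults (chosen once, as the study conditions): 500 compounds,
dual-fraction target 0.27 (a 1:2.7 class imbalance), overlap fraction
0.5 between the two target tables, noise 0.30 pIC50 units (typical
inter-assay IC50 reproducibility), artifact rates salt 3% / mixture 2% /
metal 2% / missing-IC50 3% / duplicate 5%, analogue rate 6%.
Baselines are 4.8; dual-driver fragments carry weights 2.3–2.6 on both
targets, single-target drivers 1.7–2.2 on one target, and weak
modulators ±0.1–0.7.  Dual drivers are deliberately the strongest
fragments so that planted dual actives occupy the top of both potency
distributions — the regime in which a top-5%-of-both selection rule is
meaningful at all.  Mode assignment (dual / AChE-active / BACE1-active /
inactive) is drawn before assembly and structure collisions retry only
the assembly, so the realized class mix is unbiased; the realized dual
fraction averages 0.26 over seeds (target ± 0.05).

Injected artifacts carry a hidden flag so curation recall (target
≥ 95%) and clean-record loss (≤ 1%) can be scored exactly.  Analogues
are single-substituent homologations rebuilt on the base compound's own
scaffold, preferring the largest molecules so that some pairs exceed
Tanimoto 0.80; because the redundancy filter removes an arbitrary
member of each such pair, analogue bases are excluded from the
clean-loss score.

What the generator does **not** emulate: real medicinal-chemistry
diversity (19 fragments × 11 scaffolds is a toy space), activity
cliffs, assay heterogeneity beyond i.i.d. Gaussian noise, correlated
measurement error between targets, and any real binding physics.
Passing tests therefore demonstrate that the *pipeline machinery* is
correct and leakage-free on data whose generating process matches its
assumptions — not that the models would reach any particular accuracy
on ChEMBL data.

## Problem sizes and determinism

Default problem sizes (500 compounds for the full pipeline run,
400-compound canary study, 10-seed property checks) were chosen so that
the entire suite runs in a couple of minutes on one CPU while keeping
the binomial/Gaussian sampling noise of each property test well below
its decision margin — e.g. the leakage canary's |MCC| bound of 0.15 is
only meaningful when the hold-out is large enough that a truly
uninformative model scores ≈ sqrt(2/π)/√n_test ≪ 0.15, hence the
~420-compound fully-overlapping canary dataset with a ~105-compound
hold-out.  All stochastic components (generator, resampling, model
seeds, shadow shuffles) are driven by explicit integer seeds; identical
seed and configuration give byte-identical synthetic tables.

## Known limitations

* Boruta's output size is intrinsically variable; the fixed-size option
  exists only for model-comparability and pads from tentative (then
  best rejected) features, which weakens its statistical guarantee.
* The leverage AD in PCA space depends on the projection; p_effective
  and the space used are always reported, but h\* values are not
  comparable across spaces.
* Raw classifier probabilities near 0.999 are not calibrated; the
  selection threshold is a ranking device, not a probability statement.
* The path-attribution direction convention (carrier mean) is
  well-defined for binary features; for dense continuous descriptors a
  correlation-based convention may be preferable.
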