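# Methods

## The model

The Disease State Index is a one-vs-one ensemble. For every ordered pair of
diagnostic classes (i, j) a two-class scorer is trained; a subject's total
index for class i is the average of the K−1 pairwise indices DSI(i, j), the
argmax class is the prediction, and the maximum total index is the decision's
confidence. The two-class scorer is built from three primitives.

**Fitness.** For one feature, the empirical error-rate fitness with polarity
+1 (positive class tends higher) is

    FN(x) = (#{pos < x} + ½·#{pos = x}) / n_pos
    FP(x) = (#{neg > x} + ½·#{neg = x}) / n_neg
    fitness(x) = FN(x) / (FN(x) + FP(x)),

with all inequalities mirrored for polarity −1, and fitness = ½ when
FN + FP = 0 (a value in the gap between two perfectly separated training
samples — the maximally uncertain point). Polarity is set by comparing class
means; an exact tie defaults to +1. The estimator is the plain empirical
form, with no kernel smoothing: it is deterministic, cheap, checkable against
exhaustive counting, and — because of the midpoint tie weights — exactly
antisymmetric under swapping the two classes. We make no claim of bit-level
identity with any deployed variant of the method, whose internal estimator
conventions are not fully published; smoothed or parametric fitness variants
are deliberately out of scope.

**Relevance.** Every tree node (feature leaf or modality branch) is weighted
by the clamped Youden index of its training scores at the 0.5 cutoff:
`max(0, sensitivity + specificity − 1)`, with midpoint weight for scores at
the cutoff. Clamping keeps the composite a convex combination. Internal-node
relevance is recomputed from that node's own composite training scores at
every level rather than inherited from leaves, which keeps deep and shallow
branches comparable.

**Composite.** A node's score is the relevance-weighted mean of its
children's scores, skipping children that are missing or have zero relevance;
a node with no usable child is itself missing. A subject with no usable
feature anywhere scores 0.5 at the root and is flagged rather than rejected,
so cross-validation folds stay intact and the flag surfaces in reports.

### Numerical conventions

- *Cutoff ties.* Scores within 1e-9 of the 0.5 relevance cutoff are counted
  as ties (weight ½). Composite scores that are exactly 0.5 analytically land
  on either side of the cutoff after floating-point rounding, and the
  rounding differs between the (i, j) and (j, i) orderings; the tie band
  keeps the pair-reversal identity DSI(j, i) = 1 − DSI(i, j) exact to ~1e-15
  in practice rather than merely approximate.
- *Argmax ties* in the multiclass decision are broken by the configured class
  order (first class wins) and logged. Ties have probability zero with
  continuous features but occur systematically for all-missing subjects.
- *Total-index normalization.* The default divides the pairwise sum by K−1 —
  a true mean over the K−1 competitors, so the index spans [0, 1] and the
  published confidence cut-offs (up to 0.85) are attainable. A `"classes"`
  mode dividing by K is selectable; it caps the index at (K−1)/K.
- *Reversal self-check.* After training, the classifier verifies
  DSI(i, j) + DSI(j, i) = 1 on a sample of training rows and warns above
  1e-9 (exactly tied class means are the one case that can break it).

### Pair-specific feature filtering

Two clinically motivated restrictions are applied when training each pairwise
model: structural MRI features are excluded from every pair involving the
vascular-dementia class (vascular dementia has no specific structural
signature), and features generated to separate one specific class pair (the
pairwise tensor/voxel-based morphometry scores) are used only for that pair.
Both are tags on the feature hierarchy, configurable per feature. By default
all automatic MRI features are structural except those in a configurable
vascular list (vascular burden measures), and of the visual ratings the
atrophy scales (MTA, GCA) are structural while white-matter measures
(Fazekas, lacunes) are not. A feature that is entirely missing in one class
of a pair is dropped from that pairwise model with a logged warning.

## Nuisance normalization

Each corrected feature is residualized against a modality-specific covariate
set — NP: age, sex, education; CSF: age, sex; AMRI: age, sex, scanner type;
VMRI: none — by ordinary least squares fitted **on the control class only**,
then subtracting the fitted expectation from every subject. Education (the
7-level Verhage scale) enters as a numeric ordinal — it is ordered, and one
parameter is a better use of ~100 controls than six indicator columns.
Scanner enters as two indicators with the 1.0 T level as reference, since the
systematic offsets observed in practice separate 1.0 T from the rest.
Underdetermined or rank-deficient fits leave the feature uncorrected with a
warning. At application time a missing covariate is replaced by the
control-group mean of the affected design columns, keeping the subject
usable.

Within cross-validation the regressions are refitted inside each training
fold on that fold's controls (no leakage from held-out subjects); a
full-cohort mode is available for replicating simpler recipes. For the
pairwise (two-class) ablations, where most pairs contain no controls,
normalization is fitted once on the full cohort's controls up front.

## Evaluation

Performance is measured by accuracy and balanced accuracy (mean of per-class
sensitivities, which equals 100/K for random guessing and is reported as
undefined once any class has no evaluated subjects), from 10-fold
cross-validation stratified by diagnosis with a fixed seed — stratification
keeps the smallest class (24 subjects in the emulated case mix) present in
every training split. The rejection analysis sorts out-of-fold predictions by
confidence (ties broken by subject id), retains the top ⌈(1−p)·n⌉ subjects
for each excluded fraction p — the ceiling convention matches the published
251-of-504 retained at p = 0.5 — and recomputes the metrics; the cut-off
reported for each p is the minimum retained confidence. Percent metrics are
rendered with one decimal in reports; machine-readable outputs keep full
precision.

One inconsistency in the published half-cohort table is worth recording: its
printed AD sensitivity (98.1%) does not follow from its own confusion-matrix
row (98 of 105 = 93.3%), while the row *is* consistent with the printed
balanced accuracy (93.6%). The packaged fixture trusts the matrix; the
discrepancy is documented here, not reconciled.

## Synthetic cohorts

The generator emulates the structure of a tertiary memory-clinic cohort, not
its content: 504 subjects split 118/223/92/47/24 over CN/AD/FTLD/DLB/VaD;
per-class age distributions (61±9 … 69±6 years), female proportions
(0.38/0.54/0.45/0.13/0.38) and scanner mix (85:98:321 across 1.0/1.5/3.0 T);
a 29-feature panel (12 NP tests, 3 CSF biomarkers, 4 visual ratings, 10
automatic MRI quantifications, two of them pair-restricted); and
class-conditional missingness of the NP tests at the observed per-test rates
(e.g. the functional-disability questionnaire is absent for 60% of controls
but only 7% of AD subjects), making missingness informative about class as in
real data.

Features are Gaussian within class: class mean + linear covariate effects
(age, education and sex effects of 0.01–0.12 sd per unit; a −0.4 sd offset
for 1.0 T scans on automatic MRI features) + unit-variance noise. The
`preset_separable(delta)` preset assigns features round-robin to classes and
gives each feature mean `delta`·sd in its class, so every class pair differs
by `delta` sd on at least 10 features spread over modalities; `delta = 0`
(`preset_null`) is the exact chance-level cohort.

What the simulator does **not** reproduce — and therefore what passing tests
do not show about clinical data: inter-feature correlation within a subject
(real biomarkers are strongly correlated), heavy-tailed and ordinal marginals
(visual ratings are small integers, not Gaussians), truly
missing-not-at-random mechanisms (missingness here is independent Bernoulli
given class), and realistic effect-size profiles. Synthetic results validate
the machinery (recovery under known separation, chance-level behaviour under
the null, confound removal), not clinical accuracy.

## Problem sizes in the packaged checks

The recovery experiments use 100 subjects/class for the high-separation check
(delta = 5, 10-fold CV), 40 subjects/class over 20 seeds for the null cohort
and over 3 seeds per point for the separation sweep, and 100 six-per-class
cohorts for the reversal-identity sweep — sizes at which the Monte-Carlo
spread of each reported mean is well inside the margins being asserted.

## Known limitations

- Features are treated independently; interactions between measurements are
  invisible to the fitness/relevance machinery by construction.
- Relevance is estimated on training data and is optimistically biased for
  small classes; no shrinkage is applied.
- Class priors default to uniform ("all diagnoses equally likely a priori");
  a prior-weight hook exists on the total index but no calibration of the
  confidence into a posterior probability is attempted.
- Mixed-dementia (multi-label) output and prevalence-calibrated posteriors
  are out of scope.
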