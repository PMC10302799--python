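# Methods

## The translation cascade

The pipeline treats biomarker discovery in a rare disease as a staged
filtering problem over four linked case-control feature tables: discovery
tissue and validation tissue in a model organism, serum paired with the
discovery animals, and human plasma. The premise is that pathology-driven
metabolic shifts are strongest at the site of disease and become diluted in
the circulation, so the tissue comparison carries the statistical burden and
the peripheral stages act as progressively stricter replication filters.
Each stage keeps a feature only if it is already a survivor of the previous
stage (features matched across tables by shared identifier, or by m/z +
retention-time tolerance for data where identifiers do not carry across),
giving monotone attrition by construction.

Thresholds are strict inequalities on raw p-values: discovery p < 0.05,
validation p < 0.05 with the same direction of change, serum p < 0.1, human
p < 0.05 with serum/human direction concordance. The looser serum threshold
reflects the higher variability of the circulating metabolome and the
stage's role as replication of an already validated signature rather than
fresh discovery. Direction agreement is deliberately *not* required between
tissue and serum — a metabolite consumed by diseased tissue can rise in
blood while falling in muscle — but *is* required between animal serum and
human plasma: a circulating marker that changes direction across species is
treated as a confounded signal and rejected. Concordance is evaluated as
sign(log FC) equality; an exactly flat fold change (FC = 1) fails it.

**No multiple-testing correction is applied anywhere.** All thresholds act
on raw p-values; the cascade's specificity comes from requiring survival in
four independent cohorts (expected null pass rate ≈ 0.05 × 0.05 × 0.1 ×
0.05 ≈ 10⁻⁵), not from per-stage FDR control. Survivor counts at any single
stage should therefore not be read as discoveries in their own right.

## Per-feature statistics

Each feature is compared between groups with a normality-routed test:
Welch's unequal-variance t-test when both groups pass Shapiro-Wilk at
α = 0.05 (routing is per feature and per group; groups of fewer than three
observations cannot be tested and are not rejected), otherwise the
Mann-Whitney U-test — exact by null-distribution enumeration for combined
n ≤ 12 without ties, otherwise the normal approximation with tie and
continuity corrections. Degenerate inputs follow the conventions p = 1 for
two zero-variance groups with equal means and p = 0 with different means.
A two-group Gaussian linear model on log10 intensities (equivalent to a
pooled-variance t-test) is available as an alternative mode for users who
prefer a single parametric route.

Fold change is the ratio of arithmetic group means on raw (pre-log)
intensities, case over control, so FC < 1 means lower in disease; a
geometric-mean mode exists for heavily skewed data. A zero control mean
makes the ratio undefined and is raised, never silently coerced.

## Feature-definition filters

A feature is kept when its mean intensity over all analytical samples is at
least 5× (inclusive) its mean over extraction blanks — "at least 5 times"
reads as ≥ — and when it is detected (intensity strictly > 0) in every
analytical sample of at least one group. The blank ratio uses the global
analytical mean rather than per-group means; QC injections are ignored by
both filters. Blank filtering runs first, then presence; the two commute on
tables with complete blank rows, and both are idempotent.

## Chemometrics

Intensities are log10-transformed and scaled to unit column variance
(zero-variance columns are dropped with a warning; non-positive intensities
are an error pointing at the presence filter). Two-class PLS-DA is fitted by
NIPALS with X- and y-deflation on a centred 0/1 dummy response; for a single
response the weight vector per component is X'y normalised, and successive
score vectors are mutually orthogonal. R²X(cum)/R²Y(cum) are cumulative
explained sums of squares.

Predictive power is Q²(cum) from stratified k-fold cross-validation
(default 7 folds; round-robin assignment within class after a seeded
shuffle), combined across components with the multiplicative convention
Q²(cum) = 1 − Π_a (PRESS_a / SS_{a−1}), where SS_{a−1} is the full-data
model's y residual after a−1 components. This convention punishes
uninformative components hard (their PRESS/SS ratio exceeds 1), which is
why the component count is chosen by a gain rule: components are added only
while each improves Q²(cum) by more than 0.01, capped at 5. Scaling
parameters are estimated once on the full matrix before cross-validation,
matching how these diagnostics are conventionally produced by chemometrics
software; Q² is therefore a model diagnostic, not a fully nested
generalisation estimate.

Model significance is CV-ANOVA: F = ((SS_tot − PRESS)/A)/(PRESS/(N−1−A))
with A components, p from F(A, N−1−A), computed on the cross-validated
predictive residuals. Exact agreement with proprietary implementations of
these diagnostics is not expected — fold assignment and degrees-of-freedom
details differ between programs — so published caption values are treated
as qualitative reference points, not reproduction targets. The scores-plot
class-difference statistic is reported as |mean t₁(case) − mean
t₁(control)| / range(t₁) × 100, documented as one reasonable interpretation
of a "% of t[1]" separation.

PCA (via scikit-learn, full SVD) provides the unsupervised overview.

## Synthetic studies

The generator emulates the study design the cascade was built for: a
discovery muscle cohort of 9 disease vs 8 control animals, serum from the
same animals (sample identifiers shared 1:1, the paired design), an
independent validation muscle cohort (8 vs 8; the original validation
cohort size is not on record), and a human plasma cohort of 51 patients vs
14 controls. The three feature universes overlap per a configurable
seven-region Venn structure whose defaults are the observed region counts
(327 muscle-only, 365/1556 plasma-only mouse/human, 231 muscle∩mouse-plasma
only, 1182 mouse∩human plasma only, 1549 in all three); the
muscle∩human-plasma-only region was not reported and defaults to 0,
configurable.

Intensities follow a multiplicative log-normal model: one baseline
10^N(5, 0.5) per feature, times the planted fold change for the case group,
times (1 + ε) per sample with ε ~ N(0, cv), truncated at zero. Defaults:
cv = 0.2 (a realistic relative spread for untargeted peak areas, and the
condition used by the recovery suites), blanks at 2% of baseline (three
rows), four pooled-QC rows carrying the analytical mean. QC rows are
generated for reporting realism only; no QC-based drift correction is
modelled. Because the baseline is drawn once per feature, a noiseless table
realises planted fold changes exactly, which the unit tests exploit.

Planted effects carry a role so recovery can be scored: `true_cbm`
(perturbed in all four matrices, serum/human concordant), `muscle_only`
(invisible in the circulation), `discordant_serum` (flips tissue→serum;
legal, must survive), `discordant_human` (flips serum→human; must be
rejected), `null`. Default magnitudes are FC 0.64 / 1.5625 (|log₂FC| ≈
0.64), inside the observed nine-candidate panel's fold-change range.

What the generator does **not** model — and hence what passing tests do not
demonstrate about real data: batch effects and run-order drift, missing
values (presence-filter tests inject zeros explicitly), correlated features
(adducts, isotopologues, pathway co-regulation; every feature is drawn
independently), heavy-tailed or skewed biological variation beyond the
Gaussian relative error, and imperfect cross-matrix feature identity (the
generator controls identifiers, so matching is exact unless the m/z + RT
mode is exercised deliberately). Recovery rates on synthetic studies are
accordingly upper bounds on what the cascade would achieve on real cohorts.

## Classifier evaluation

The panel forest mirrors the small-cohort design: training on all controls
plus 14 seed-randomly chosen cases, testing on the same controls plus all
remaining cases (with 14 controls and 51 cases: 28 train, 51 test). Only
the cases are truly out-of-sample; every report embeds the control-reuse
caveat, and specificity estimates should be read as optimistic. The forest
is scikit-learn's RandomForestClassifier, 500 trees, mtry = ⌊√p⌋, unlimited
depth, bootstrap bagging with the out-of-bag error as the internal estimate.
Class votes are thresholded at 0.5 for the confusion matrix and swept for
the ROC (AUC by trapezoid). Variable importance defaults to seeded
permutation importance (mean training-set accuracy drop over feature
permutations); a per-tree out-of-bag variant would need internals
scikit-learn does not expose, and for panels of mutually redundant features
single-feature permutation is near-flat by construction — the impurity mode
is the informative view there.

## Numerical and design choices

- Features are anonymous `HILIC_n` / `RP_n` identifiers throughout;
  chemical annotation is out of scope.
- Thresholds are strict (<); the blank ratio is inclusive (≥).
- Cross-table matching defaults to identifier equality; the m/z + RT mode
  matches greedily by smallest ppm distance, then RT distance, then ID,
  and is injective.
- The translation source defaults to the validated set; translating
  directly from the discovery set is available as a config switch (both
  logged).
- All randomness flows from a single seed via spawned child generators;
  identical seed + config gives bit-identical tables and byte-identical
  JSON summaries.
- Simulation-based test suites use a 2000-feature overlap structure (same
  cohort sizes, same noise model) so multi-seed loops stay fast; the
  single-run analysis drivers use the full default universe sizes.

## Known limitations

Q² and CV-ANOVA values are convention-dependent and not comparable across
software at the third decimal. The cascade's survivor counts inherit the
raw-p design choice; users wanting FDR control must apply it upstream of
the thresholds. The generator's independence assumptions make multivariate
diagnostics (Q², classifier AUC) look cleaner than real correlated
metabolomes would.
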