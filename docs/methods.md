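# Methods

## Normative patch scoring

Each patient is compared with an individually selected normative subgroup:
all reference subjects of the same sex whose age lies within ±2 years of
the patient's (bounds inclusive). Per patch, the patient's mean cortical
thickness is standardized against the matched reference using the sample
standard deviation (ddof = 1), and converted to a left-tail p-value by
exact permutation. For a single patient against n_ref exchangeable
reference values, the only exhaustive, replacement-free permutation test is
the rank test: under the null, the patient's position among the n_ref + 1
values is uniform, so

    p = (1 + #{reference values ≤ patient value}) / (n_ref + 1),

a discrete value in {1/(n_ref+1), …, 1}. The test is one-sided toward
thinness — thickness above the norm is never flagged, because only atrophy
is of interest. Ties between patient and reference values count toward the
≤ set, which is the conservative direction (larger p, fewer thin calls).
A patch is called *significantly thin* when p < 0.05, strictly, with no
multiple-comparison correction across the 1000 patches: the thin-patch
fraction (TPF) is deliberately an uncorrected tally whose null level is
known exactly (see Calibration below), not a family of confirmatory tests.

Degenerate patches (zero reference SD) have undefined z; they are reported,
logged, and excluded from thin calling. With continuous thickness values
they essentially never occur; they matter only for pathological inputs.

Reference-size guards: below `min_ref = 10` matched subjects, matching
fails loudly. Between 10 and 19, scoring proceeds but a warning is issued,
because min p = 1/(n_ref+1) > 0.05 means no patch can ever be called thin;
n_ref ≥ 20 is needed for the test to have any resolution at α = 0.05.

### Calibration

Under exchangeability, P(p < α) per patch is exactly
#{k : k < α(n_ref+1)}/(n_ref+1) (e.g. 1/31 at n_ref = 30 — not the nominal
0.05). The expected null whole-brain TPF equals this quantity, averaged
over patients' reference sizes. The acceptance suite verifies both the
per-patch law (10,000 null cases) and the mean-TPF expectation (200 null
patients with n_ref ≥ 40, tolerance ±0.01: the mean TPF has a Monte-Carlo
SE of ≈0.004 because the shared subject effect correlates thin calls
within a patient).

## ROI restriction

A domain-specific patch set is derived in two steps: a statistical surface
map is matched to its best-fitting candidate network map by spatial Pearson
correlation over shared finite vertices (signed similarity, ties to the
lowest index, zero-variance candidates excluded), and the winning map —
binarized — is projected onto the patch parcellation. A patch is included
when at least 50% of its labeled vertices fall inside the mask; the
threshold is a parameter because no principled value exists for it, and the
projection is a deliberately minimal overlap rule rather than a
reimplementation of any published task-to-network cross-mapping pipeline.
Hand- and leg-related sets are combined by union before restriction.
Patch sets are stored as plain text, one 1-based patch label per line, with
provenance in `#` comments.

## Association models

Baseline clinical scores are modeled by OLS on the TPF plus confounders:
age (years), sex (female dummy, male reference), handedness (L and A
dummies, right-handed reference — the majority category), and symptom
duration (months). Ordinal scores are treated as continuous, matching
standard practice for these scales at cohort size ~135. The TPF p-value is
the two-sided t-test on its coefficient; restricted and whole-brain models
of the same outcome are compared by adjusted R² computed from the fitted
design's actual regressor count (six non-intercept columns when all
handedness levels are present; absent levels contribute no column).
Rank-deficient designs fail with the collinear column named rather than
silently dropping it.

The extremity motor subscore sums the 14 lateralized sub-items of the
motor exam that involve the limbs: rigidity of the four extremities (neck
rigidity excluded), finger tapping, hand movements, pronation–supination,
toe tapping, and leg agility, each 0–4 per side — range 0–56. Missing
sub-items raise an error; no imputation.

## Progression

A patient progresses on a measure when the score strictly worsens between
baseline and follow-up: any increase for the motor scores, any decrease
for the cognitive score; zero change is non-progression under both rules.
Visit distributions are compared with the Wilcoxon signed-rank test using
the classic zero-drop rule (not Pratt's; the choice is flagged in output),
midranks for ties, and V = the sum of ranks of positive differences
(follow-up − baseline). The two-sided p is min(1, 2·min(P(V ≤ v),
P(V ≥ v))), computed exactly for up to 25 nonzero differences by building
the full sign-assignment distribution via convolution over doubled
midranks (equivalent to enumerating all 2^n assignments), and by normal
approximation with tie-correction of the variance and a 0.5 continuity
correction beyond that. The 25-pair cutoff keeps the exact branch
instantaneous while covering every test the suite performs exactly;
at the boundary the approximation agrees with the exact p to ~0.01.

## Classification

For each outcome × horizon cell, an SVM predicts progressor status from
baseline patch z-scores. The sample is split 80/20 (test size =
round(0.2·n)), stratified by default with largest-remainder per-class
apportionment (class counts within one subject of proportionality).
In restricted mode the ROI patch set is the feature set, unchanged; in
whole-brain mode the same number of patches (default 79) is selected on
the **training split only** by absolute pooled-variance t-statistic, ties
toward the lower patch index, undefined statistics (zero variance) ranked
last. The filter was chosen for transparency and oracle-testability.
Hyperparameters (C ∈ {0.01…100}, gamma ∈ {1e-4…10}, log-spaced) are tuned
by stratified fivefold cross-validation on the training split, ties toward
the smallest C then gamma; the winner is refit on the full training split
and evaluated once on the held-out 20%. The RBF kernel is the default with
a linear option: the tuned-kernel description and the "linear classifier"
label conflict in the design this follows, and the RBF reading was
implemented as primary. Accuracy is the fraction of correctly classified
held-out cases. The absence of train→test leakage is enforced by
construction and verified by a bit-identity test under test-label
perturbation.

## Synthetic cohorts

The generator produces the structure the analysis assumes, with defaults
fixed at the study conditions the package targets:

| parameter | default | rationale |
|---|---|---|
| n_normative | 650 | large population-representative reference cohort |
| n_patients | 135 | early-disease cohort with complete 3-visit follow-up |
| n_patches | 1000 | standard parcellation resolution |
| age_range | 40–80 y | spans the patient age distribution; with 650 subjects it yields matched subgroups of n_ref ≈ 30, enough for thin calls (n_ref ≥ 20); a wider range would thin the matching windows below that resolution |
| baseline thickness | 2.5 mm | typical cortical mean |
| age_slope | −0.005 mm/y | typical adult thinning rate |
| sex_offset | +0.02 mm (F) | small female-thicker offset |
| subject_sd / patch_noise_sd | 0.08 / 0.12 mm | between-subject global vs. within-subject patch variability |
| atrophy_scale | 0.15 mm per unit severity | subtle early-disease atrophy, ~1 SD of combined noise at severity 1 |
| severity | half-normal(1) | nonnegative, right-skewed disability typical of early cohorts |
| extremity score | round(6 + 12·severity + N(0,3)), clamped 0–56 | median ≈ 13, IQR ≈ 10 at baseline |
| total motor | extremity + independent non-extremity component | guarantees total ≥ extremity |
| cognitive score | round(N(27.5, 2)), clamped 0–30 | independent of severity by design |
| motor drift | (−1 + 2.5·severity) per year + N(0,3) | see below |
| cognitive drift | −0.3 per year + N(0,1.5) | slow decline, severity-independent |

Patient thickness follows the normative model minus `atrophy_scale ×
severity` on the ROI patches only; all thickness is floored at 0.1 mm
(logged) to keep z-scores finite. Ages are uniform in the normative
cohort and truncated-normal (63.5 ± 6.8 y) in patients, kept 4 years
inside the normative range so every matching window is fully covered.
Scores are generated continuous, then rounded and clamped to their ordinal
scales.

Motor progression combines a small negative nonspecific drift (practice
and early-treatment effects) with a severity-proportional worsening term.
This coupling is a deliberate modeling choice: it makes baseline atrophy
genuinely predictive of future motor decline — the planted signal the
classifier stage is supposed to recover — while the negative offset keeps
both progressors and non-progressors well represented at both horizons
(~53% / ~67% motor progressors at 1 / 3 years). The parameters were set so
median trajectories rise by roughly +1 and +3 extremity points at 1 and 3
years with class balance as above. Cognitive scores and their drift are
independent of severity, making the cognitive outcome a built-in negative
control; the joint distribution of motor and cognitive decline in real
cohorts is not characterized here, and this independence is an assumption,
not a claim about patients.

What the generator does **not** emulate: spatial autocorrelation between
neighboring patches, site/scanner effects, heteroscedastic age effects,
floor/ceiling pathologies of real ordinal scales beyond simple clamping,
and dropout (every synthetic patient has all three visits). Passing tests
therefore demonstrate the statistical machinery — calibration, identities,
recovery of planted structure, leakage-freedom, determinism — not clinical
performance on real data.

## Problem sizes and determinism

The test suite runs the full-scale configuration (650 × 1000 normative
matrix, 135 patients) for the calibration and recovery experiments — 100
replicates for the model-comparison experiment, 200 patients for null TPF
calibration, 20 seeds for the planted classifier — and a reduced fixture
(240 × 120, 30 patients) for pipeline and unit tests; these sizes were
chosen so the entire suite completes in about a minute while keeping
Monte-Carlo error well inside the asserted tolerances. All randomness
flows through explicit integer seeds (numpy Generator); the pipeline
writes a manifest with the configuration hash and SHA-256 of every output
file, and two runs with the same configuration are byte-identical.

## Known limitations

- The exact rank p-value has resolution 1/(n_ref+1); with the default
  normative density, patches are called thin only when the patient falls
  below every matched reference value. This is faithful to the design but
  makes per-patch power depend on local normative density.
- The ROI projection is a minimal overlap rule; reproducing any particular
  published patch set requires the external maps that defined it.
- Model comparison uses adjusted R² descriptively (no inference on the
  difference between non-nested models).
- Classifier accuracies on small held-out sets (~27 subjects) carry wide
  binomial error; the package reports per-cell predictions so users can
  pool or interval-estimate as needed.
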