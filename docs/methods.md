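# Methods

## Smell-vector extraction

A QCM trace is a channels × timepoints matrix of resonance-frequency
readings (Hz) sampled at 10 Hz; the shutter-open index marks the start of
odorant exposure and is a required input rather than a constant, because
recordings differ in how many pre-exposure readings they contain.  Per
channel, independently of all others:

- *base* = mean of the readings before the shutter index (a configurable
  window can restrict this to the last *w* pre-shutter readings).  Using
  the mean rather than a single reading makes the baseline robust to
  single-sample noise at the 10 Hz rate.
- *peak* = the reading with the maximal absolute deviation from base over
  the whole trace.
- feature = |base − peak|.

The absolute value makes the feature independent of the sign convention of
the recording (adsorption lowers the resonance frequency, but plotted
"frequency change" data can carry either sign), and gives two useful exact
properties: adding a constant to a channel leaves its feature unchanged,
and scaling a channel's deviations by c scales the feature by |c|.
Replicates (three per molecule in the measurement protocol) are averaged
element-wise.  No drift or temperature compensation is applied.

## Synthetic data

The generators plant known ground truth so every downstream stage has an
oracle; one global seed expands into fixed per-operation substreams, so
adding a stage never perturbs earlier draws.

**Traces.** Channel c reads base[c] + Gaussian noise before onset; from the
onset the signal moves toward base[c] − magnitude[c] along an exponential
rise (time constant 25 samples by default) with optional exponential decay
(120 samples), emulating the rise-and-relax shape of measured channel
responses.  The rise/decay profile is normalized to peak at exactly 1 and
the default base frequencies (~10 MHz) and magnitudes (10–200 Hz) are
integer-valued, so on noiseless traces the extracted feature equals the
planted magnitude *exactly* in floating point — the basis of the exactness
oracle.  Default noise is 2 Hz; sensor drift is deliberately not modeled.

**Cohorts.** Each molecule draws a latent factor vector z ~ N(0, I_d) with
d = 5 by default, matching the effective dimensionality of the measured
e-nose table (35 channels → 5 PCs at the 95 % cutoff).  Modality m's
features are z·L_m plus Gaussian noise (sd 0.3; the loading columns carry
≈ d units of signal variance, so noise holds ≈ 2 % of per-column variance
and the planted factors dominate the PCA, as in the measured data).
Descriptor j is Bernoulli with logit a_j + s·(z·w_j): s is the signal
strength (0 = labels independent of all features, the null cohort; 3 = the
default signal condition), w_j are unit weight vectors drawn around one
center per planted descriptor group (so grouped descriptors co-occur), and
a_j is the logit of the target prevalence scaled by √(1 + πs²/8), the
logistic-normal correction that keeps the marginal prevalence near its
target at any s.  Default prevalences follow the measured cohort's
long-tailed profile: top two descriptors at 55/114 and 52/114, geometric
decay to a floor of 2.5/114, leaving most descriptors with fewer than 12
positives out of 114.  Descriptors that draw zero positives in a finite
cohort are excluded from evaluation by the harness (logged), exactly as a
zero-positive descriptor would be on measured data.

**Embeddings.** Each planted group gets an orthogonalized center; a word's
vector is separation·center plus isotropic noise of unit expected norm,
normalized to unit length.  The noise scaling makes separation
dimension-free (expected within-group cosine ≈ s²/(s²+1)); separation 5–6
yields exact recovery of the planted partition, separation 0 yields pure
noise.  What passing recovery tests shows is that the clustering stage is
correct, not that real word embeddings separate odor vocabulary this
cleanly — real descriptor similarities are far weaker and linkage-sensitive.

**Spectra.** Stick spectra on integer m/z bins (EI spectra are
unit-resolution): each molecule gets exactly ⌈sparsity·n_bins⌉ peaks with
uniform(1, 100) intensities; peak positions are repaired so the cohort
union covers all configured bins whenever capacity allows, making the
downstream matrix width equal the bin count.

## Preprocessing

Min-max scaling maps each column to [0,1]; constant columns map to 0 and
the fitted ranges are retained for reuse.  PCA (full SVD) keeps the
smallest rank m whose cumulative explained-variance ratio reaches the
cutoff, with an exact tie including the component ("keep 95 %" read as ≥)
and a 1e−12 tolerance absorbing floating-point error at the boundary.
Scores are centered; no unit-variance scaling beyond the min-max step.  The
default cutoff is 0.95; the qualitative clustering analysis reuses the same
configured cutoff.  The normalizer and PCA are fit on the full cohort
before cross-validation, reproducing the study workflow; this leaks
fold-independent scale information, and a rigorous per-fold refit is the
natural extension (the fitted-range and reduction objects support it) but
is not the default because the reference protocol is.

## Prediction and evaluation

Each descriptor gets its own classifier.  The one-class SVM (scikit-learn's
solver behind the module's contract) is trained on the *majority* class
only — molecules without the descriptor; a validation point scored
out-of-class is predicted descriptor-present.  ν upper-bounds the fraction
of training points left outside the frontier and lower-bounds the
support-vector fraction; tests assert both at n = 200 with tolerance 0.05.
The binary SVM baseline trains on both classes and falls back to a
constant prediction when a training fold is single-class.

Folds are stratified by an in-package splitter that deals shuffled
positives and negatives round-robin into k folds: with fewer positives
than folds (the common case here) per-class shuffling keeps every fold's
positive count within one of any other, while library stratified splitters
reject classes smaller than k outright.  The default plan is k = 10
repeated 3 times, seeded and reproducible.  F1 and recall come from
validation-fold confusion counts with the 0/0 → 0 convention, which keeps
means defined for rare-positive folds; per-descriptor mean F1 over the 30
folds is the headline statistic.  Whether the reference protocol stratified
its folds or tuned hyperparameters inside the CV is not recorded; both are
explicit arguments here.  The default hyperparameter grid spans the
standard operating range (ν ∈ {0.01, 0.05, 0.1, 0.2, 0.3, 0.5}, RBF γ ∈
{scale, 0.01, 0.1, 1}; C ∈ {0.1, 1, 10, 100}), with ties resolved toward
smaller ν (or C) then smaller γ, numeric γ before the data-dependent scale
heuristic.

Featurizations are compared by a two-sided paired t-test on per-descriptor
mean F1: t = mean(d)/(sd(d)/√n), df = n − 1.  Identical result vectors are
flagged exactly-equal rather than producing NaN; zero-variance nonzero
differences report t = ±∞, p = 0.

## Grouping and composition

Descriptor grouping embeds each descriptor (multi-word terms as the mean of
their token vectors; out-of-vocabulary tokens raise rather than guess),
builds the cosine-similarity matrix, and cuts an average-linkage
agglomerative tree on distance 1 − similarity.  Average linkage is the
conventional reading for similarity-derived distances; the linkage is an
argument because the choice changes partitions of weakly separated
vocabularies, and group indices are assigned by decreasing member count so
naming is stable across runs.  Group targets are the logical OR of member
descriptors; groups positive for every sample have no measurable
false-positive rate and are excluded.

Molecule clustering uses Ward linkage on Euclidean distances in PC space —
Ward's variance criterion pairs naturally with the elbow rule.  The elbow
is automated as the interior k maximizing the second difference
W(k−1) − 2W(k) + W(k+1) of the within-cluster sum of squares (ties to the
smallest k; a curvature-free curve, e.g. identical points, yields the
smallest k in the range), and the W(k) curve is emitted for manual review.
Composition percentages divide each top descriptor's in-cluster positives
by its total positives, so rows sum to 100 exactly.

## Problem sizes and checks

The test suite and the acceptance script run entirely on generated data:
cohorts of 114–200 molecules with 20–93 descriptors, 6 label permutations
for the null reference, and 10×3 CV — sizes at which the full suite
completes in well under a minute apart from the signal-recovery study
(~20 s), while keeping ≥ 30 evaluable descriptors for the paired tests.
The signal-recovery design fixes the generator seed across signal levels so
cohorts differ only through the label-generating coupling.  Numbers
reported anywhere in this repository are produced by those runs, not
transcribed.

## Known limitations

- The synthetic cohort shares the study's label statistics and low-rank
  feature structure but not the chemistry: passing tests validate the
  pipeline's correctness, not the empirical ranking of featurizations on
  measured data.
- The measured-cohort reproduction (counts, reduced dimensions) requires
  the study's supplementary workbook, which cannot be redistributed; the
  converter is deliberately tolerant of its spreadsheet layout because that
  layout is not formally documented.
- Exact composition percentages and group memberships are
  linkage-sensitive; the implemented defaults (average linkage for labels,
  Ward for molecules) are conventional choices, exposed as arguments.
- The molecular-descriptor backend is pluggable; descriptor counts are
  backend- and version-dependent, so tests pin the width of the installed
  backend rather than any nominal count.
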