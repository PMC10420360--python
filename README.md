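# smellbench

Which featurization of an odorant best predicts how it smells?  This
package benchmarks five representations of aroma molecules — QCM e-nose
**smell vectors**, bit and count **Morgan fingerprints** (radius 3, 1024
bits), numeric **molecular descriptors**, and EI **mass spectra** — on the
task of predicting expert-assigned odor descriptors ("sweet", "floral",
"waxy", ...), both descriptor-by-descriptor and for embedding-derived
descriptor groups.  It is aimed at machine-olfaction researchers who want a
tested, reproducible harness for this comparison, including a synthetic-data
generator that stands in for sensor measurements with known ground truth.

## The pipeline

1. **E-nose featurization.** A quartz-crystal-microbalance channel's
   resonance frequency drops as odorant mass adsorbs onto its receptor
   membrane.  A measurement is a 35-channel × 300-timepoint trace (10 Hz
   sampling); each channel is summarized by |base − peak|, where *base* is
   the mean pre-shutter reading and *peak* the reading deviating most from
   it.  Three replicate vectors are averaged per molecule.
2. **Preprocessing.** Each feature table is min-max scaled to [0,1] and
   PCA-reduced to the smallest rank whose cumulative explained-variance
   ratio reaches 0.95.  The 35 correlated e-nose channels collapse to ~5
   components.
3. **Prediction.** The label matrix is long-tailed (top descriptors ≈ 55/52
   positives out of 114 molecules, most below 12), so each descriptor gets
   its own classifier and the imbalance-robust model is a **one-class SVM**
   trained on the majority (descriptor-absent) class only:

   min<sub>w,b,ξ</sub> ½‖w‖² + (1/νn) Σᵢ ξᵢ − b  s.t.  w·φ(xᵢ) ≥ b − ξᵢ, ξᵢ ≥ 0, ν ∈ (0,1]

   A point scored out-of-class (w·φ(x) − b < 0) is predicted
   descriptor-present.  ν upper-bounds the training-outlier fraction and
   lower-bounds the support-vector fraction (the ν-property, asserted by the
   tests).  Evaluation is mean F1/recall over stratified 10-fold CV repeated
   3 times; featurizations are compared by paired t-tests on per-descriptor
   mean F1.
4. **Descriptor grouping.** Descriptors are clustered by average-linkage
   agglomerative clustering on 1 − cosine similarity between their word
   vectors; a molecule is group-positive if it carries any member
   descriptor, and group predictors are evaluated in ROC space.
5. **Cluster composition.** Molecules are Ward-clustered in PC space (count
   chosen by the elbow of the within-cluster sum of squares) and each top
   descriptor's positives are apportioned across clusters as percentages.

## Worked example

The numbered drivers under `analysis/` run the full study on the synthetic
cohort (114 molecules × 93 long-tailed descriptors) and write tables under
`results/`:

```bash
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_featurize_traces.py --seed 1
python analysis/03_preprocess_features.py
python analysis/04_predict_descriptors.py --seed 1
```

prints, among other things:

```
cohort: 114 molecules x 93 descriptors
top descriptors: 58 and 52 positives (study cohort: 55 'sweet', 52 'floral')
81 of 93 descriptors have <12 positives
noiseless extraction max |error|: 0.0 Hz (exact recovery)
   feature_set  original_dimension  reduced_dimension  cumulative_variance
         enose                  35                  5               0.9798
signal-recovery control (n=200, 40 descriptors):
  signal 0 macro F1 0.1210 (null 0.1192, z=+0.27)
  signal 3 macro F1 0.2102 (null 0.1110, paired t=6.26, one-sided p=1.55e-07)
```

Read: the generator reproduces the study's label statistics; smell-vector
extraction recovers planted shift magnitudes exactly on noiseless traces;
the correlated e-nose channels reduce to 5 PCs at the 95 % cutoff; and the
evaluation harness scores at chance when labels are independent of features
(z = +0.27 against a label-permutation null) while planted signal is
detected decisively (one-sided paired p ≈ 10⁻⁷).  Drivers 05 and 06 run the
descriptor-group and cluster-composition analyses; `smellbench --help`
exposes the same stages as subcommands.

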