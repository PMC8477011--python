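# mklfuse

Kernel-level fusion of multimodal neuroimaging feature tables for
case/control classification.

Studies of neurodevelopmental disorders increasingly tabulate each
subject's brain as several feature tables — structural MRI morphometry
and intensity measures, DTI diffusivity measures, resting-state
functional-connectivity z-scores — acquired on different scanners.
`mklfuse` is for researchers who want to ask: *do these modalities
carry complementary diagnostic signal, and which features drive it?*
It fuses the modalities inside the kernel of a support vector machine
instead of concatenating raw features, and wraps the whole procedure in
a leakage-safe, repeated nested cross-validation.

## The model

Each modality *m* contributes a Gram matrix *K_m* (linear or RBF on
standardized, selected features); the classifier is the SVM dual on the
convex combination *K = Σ_m w_m K_m*:

    min_α  ½ Σᵢⱼ αᵢαⱼyᵢyⱼ Σ_m w_m k_m(xᵢᵐ, xⱼᵐ) − Σᵢ αᵢ
    s.t.   Σᵢ αᵢyᵢ = 0,  0 ≤ αᵢ ≤ C,        w_m ≥ 0,  Σ_m w_m = 1

    f(x) = sign( Σᵢ α*ᵢ yᵢ Σ_m w*_m k_m(xᵢᵐ, xᵐ) + b* )

Weights *w* are searched exhaustively on a simplex grid (stride 0.1)
jointly with *C* (10⁻⁴…10³) by inner-CV AUC; *w_m = 0* expresses a
missing or unhelpful modality. Around the classifier sit three
pipeline stages, each fitted on training folds only:

- **Harmonization** — parametric empirical-Bayes location/scale batch
  correction (matches Bioconductor `sva::ComBat`), protecting age and
  sex effects.
- **All-relevant selection** — shadow-feature selection per modality
  with a random-forest importance provider, plus a Binomial(p̂, N)
  stability test of selection frequencies across CV runs with Holm
  correction.
- **Evaluation** — 10×10-fold nested CV with paired baselines
  (unimodal SVMs, early fusion, bimodal/trimodal fusion), metrics at
  probability cutoff 0.5 (Platt-calibrated) and rank-based AUC.

A synthetic cohort generator reproduces the statistical shape of a
matched case/control imaging study (matched sex/race, ~116 per group,
feature pools of 1184/1182/338, scanner batches, block-correlated
noise, sparse planted effects), so the full pipeline is testable
without access-restricted data.

## Worked example

```sh
mklfuse simulate --out data --seed 7
mklfuse run-all --data data --config examples/quick.yaml --out results --seed 7
```

or, the same scaled-down comparison in Python:

```python
from mklfuse import (SyntheticConfig, generate_cohort, PipelineSettings,
                     CVPlan, ModelSpec, SelectionConfig, TrainConfig,
                     run_experiment)

cohort = generate_cohort(SyntheticConfig(
    n_case=80, n_control=80, n_female_per_group=31,
    modality_dims={"sMRI": 12, "DTI": 12, "rsfMRI": 12},
    n_informative={"sMRI": 4, "DTI": 4, "rsfMRI": 4},
    effect_size=0.5, n_batches=2, seed=7))

settings = PipelineSettings(
    selection=SelectionConfig(ensemble_size=35, max_iterations=20),
    train=TrainConfig(weight_stride=0.2, c_grid=(1e-3, 0.1, 10.0)))

report = run_experiment(
    cohort, settings, CVPlan(outer_folds=10, inner_folds=5, repeats=1, seed=0),
    models=[ModelSpec("MKL3", ("sMRI", "DTI", "rsfMRI"), "mkl"),
            ModelSpec("uni-sMRI", ("sMRI",), "mkl"),
            ModelSpec("uni-DTI", ("DTI",), "mkl"),
            ModelSpec("uni-rsfMRI", ("rsfMRI",), "mkl")])
print(report.summary[["model", "auc", "accuracy"]].to_string(index=False))
```

which prints (one repeat of 10-fold CV on the synthetic cohort above):

```
     model      auc  accuracy
      MKL3 0.667188    0.5375
   uni-DTI 0.590625    0.5500
uni-rsfMRI 0.617188    0.4125
  uni-sMRI 0.618750    0.4250
```

Read: each modality carries four weak markers (half a pooled SD), so a
single modality separates cases from controls only modestly (AUC
0.59–0.62); the trimodal fused kernel, which can see all twelve,
reaches AUC 0.67. The 0.5-cutoff accuracies are noisier than AUC at
this signal strength (the threshold sits in the densest part of the
score distribution), which is why AUC is the primary criterion. On a
null cohort (no planted effect, or permuted labels) the same pipeline
returns AUC ≈ 0.5. Per-fold metrics, fused-weight tables and
per-modality selection-stability reports (frequency, binomial p,
Holm-adjusted p) are written alongside the summary by the CLI.

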