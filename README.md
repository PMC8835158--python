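# eegdyn

Spatio-temporal dynamics of resting-state EEG: **microstate** analysis
(temporal dimension), **omega spatial complexity** (spatial dimension),
two-group statistics, and nested cross-validated **SVM** classification —
with a synthetic-cohort generator that plants known ground truth so the
whole chain can be validated end to end.

The package is aimed at researchers studying large-scale brain-network
dynamics in clinical-screening settings (the motivating application is
subclinical depression in resting eyes-closed EEG), and at anyone who
needs a tested, reproducible reference implementation of TAAHC microstate
segmentation or eigenvalue-entropy spatial complexity.

## The measures

**Microstates.** Resting EEG decomposes into a few quasi-stable scalp
topographies (~60–120 ms lifetimes, conventionally four classes A–D).
With GFP(t) = √(Σᵢ(vᵢ(t) − v̄(t))²/n) the spatial standard deviation of
the scalp map, topographies at GFP peaks are clustered by the
Topographic Atomize & Agglomerate Hierarchical Clustering algorithm
(polarity ignored, K = 4), every sample is labelled by back-fitting, and
the label stream is summarised as per-class **duration**, **occurrence**,
**contribution** and the 4×4 **transition** matrix, with global explained
variance (GEV) as fit index.

**Omega complexity.** Per frequency bin, the cross-spectral matrix
C(f) = ⟨u(f)u(f)ᴴ⟩ over 2-s epochs has eigenvalues λᵢ; with
λ′ᵢ = λᵢ/Σλ,

&nbsp;&nbsp;&nbsp;&nbsp;Ω = exp(−Σᵢ λ′ᵢ ln λ′ᵢ)

ranges from 1 (one spatial mode — full synchronization) to K, the number
of channels (no synchronization). Band values average per-bin Ω over
seven bands (δ 1–3.5 … γ 30–45 Hz) at three scopes: global (30
channels), anterior and posterior (7 channels each).

**Classification.** Z-scored feature sets (microstate-only, omega-only,
combined) feed linear and Gaussian-RBF SVMs tuned by grid search inside
nested cross-validation (leave-one-out outer, stratified 5-fold inner),
reporting out-of-fold accuracy and pooled ROC/AUC.

## Worked example

```python
from eegdyn import (CohortSpec, make_cohort, cohort_features,
                    evaluate_feature_sets, ClassifierConfig)
from eegdyn.stats import group_battery

cohort = make_cohort(CohortSpec(n_per_group=(12, 12), seed=7))
features = cohort_features(cohort)
print(features.groupby("group")[["occ_B", "dur_C", "contrib_C",
                                 "omega_global_beta2"]].mean().round(2))
```

```
       occ_B  dur_C  contrib_C  omega_global_beta2
group
HC      2.62   85.4      23.96               17.25
ScD     2.96   72.0      20.02               16.81
```

The generator planted a higher class-B occurrence, a shorter class-C
duration (hence lower contribution), and stronger beta-2/gamma
synchronization (lower omega) in the "ScD" group — all four recovered
with the right sign. The statistical battery and classifier quantify
this:

```python
print(group_battery(features)["global_omega"].round(3))
print(evaluate_feature_sets(
    features, config=ClassifierConfig(kernels=("linear",), seed=7)))
```

```
  band      t  df     p  cohens_d
 beta2  4.940  22 0.000     2.017
 gamma  4.939  22 0.000     2.016   (non-planted bands: p > 0.1 except
 ...                                 carrier-adjacent side effects)

feature_set kernel  accuracy  auc
 microstate linear      0.92 1.00
      omega linear      0.83 0.93
   combined linear      1.00 1.00
```

Accuracy/AUC are out-of-fold nested-CV estimates; the combined set is at
least as good as either single set, mirroring the motivation for joint
spatio-temporal features.

The same pipeline runs from the shell:

```bash
eegdyn run-all --out results/ --seed 7
eegdyn simulate --out cohort/ --n-per-group 12 12 --seed 7
eegdyn omega --in cohort/ --out omega.csv
```

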