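# mdsp — multilinear discriminative spatial patterns for MRCP EEG

Movement-related cortical potentials (MRCPs) are slow (< ~7 Hz) negative
EEG shifts that precede voluntary movement. Detecting them — e.g. telling a
left from a right finger tap before the movement happens — is a classic
brain–computer-interface problem. The standard feature extractor is the
**discriminative spatial patterns (DSP)** filter: for trials
X_i ∈ R^{c×t} (channels × time) with class means M_j and grand mean M, it
maximizes the Fisher ratio

    J(U) = tr(Uᵀ S_b U) / tr(Uᵀ S_w U),
    S_w = Σ_j Σ_{i: y_i=j} (X_i − M_j)(X_i − M_j)ᵀ,
    S_b = Σ_j n_j (M_j − M)(M_j − M)ᵀ,

solved by the top generalized eigenvectors of (S_b, S_w). DSP filters only
the spatial (channel) mode and ignores the trial's temporal and spectral
structure.

**MDSP** generalizes this to trials that are tensors of any order h ≥ 2 —
channels × time, or channels × time × wavelet scales after a continuous
wavelet transform (CWT). It learns one projection matrix per mode,
U_k ∈ R^{m_k × m_k′}, jointly maximizing

    J(U_1..U_h) = Σ_j n_j ‖(M_j − M) ×_1 U_1 ⋯ ×_h U_h‖²_F
                  / Σ_j Σ_{i: y_i=j} ‖(X_i − M_j) ×_1 U_1 ⋯ ×_h U_h‖²_F

by alternating optimization: with all modes but k fixed, the criterion is an
ordinary Fisher quotient in U_k whose scatter matrices are built from
mode-k unfoldings of the partially projected tensors, so each update is a
generalized eigenvalue solve. Convergence is tracked by the summed relative
projection change err(t) = Σ_k ‖U_k^t − U_k^{t−1}‖_F / ‖U_k^{t−1}‖²_F
(threshold 0.01, cap 50 sweeps). A new trial is classified by the nearest
projected class-mean tensor in Frobenius distance.

The package provides:

- `mdsp.tensor_core` — mode-k unfolding/folding and mode-k products;
- `mdsp.dsp` — the classical DSP baseline (`DSP` estimator);
- `mdsp.mdsp` — the alternating multilinear solver (`MDSP` estimator,
  scikit-learn compatible: `fit` / `predict` / `transform`,
  serialization to a `.npz` archive);
- `mdsp.classify` — nearest-projected-prototype prediction and metrics;
- `mdsp.tensorize` — zero-phase Butterworth low-pass, resampling, sliding
  windows, complex-Gaussian CWT expansion to channels × time × scales;
- `mdsp.synthetic` — seeded generators: planted low-multilinear-rank
  datasets with known ground truth, and MRCP-like lateralized
  pre-movement drifts in 1/f noise;
- `mdsp.model_selection` — repeated stratified (optionally grouped)
  cross-validation and filter-count grid search with the
  discard-on-non-convergence rule;
- a CLI (`mdsp simulate|tensorize|fit|predict|evaluate|cv|grid`).

## Worked example

Recover a planted rank-(2,2,2) discriminative structure from noisy tensor
trials and classify held-out trials:

```python
import numpy as np
from mdsp import (MDSP, PlantedSpec, planted_dataset,
                  subspace_recovery_score, score)

X, y, bases = planted_dataset(PlantedSpec(
    shape=(16, 50, 10), ranks=(2, 2, 2), trials_per_class=100,
    amplitude=1.0, noise_sd=0.3, seed=7))
train = np.r_[0:80, 100:180]
test = np.r_[80:100, 180:200]

est = MDSP(n_filters=2).fit(X[train], y[train])
print("converged:", est.converged_, "after", est.n_iter_, "sweeps")
print("per-mode recovery angles (rad):",
      np.round(subspace_recovery_score(est.model_.projections, bases), 3))
metrics = score(est.predict(X[test]), y[test])
print("held-out accuracy:", metrics["accuracy"], " F1:", metrics["f1"])
```

prints

```
converged: True after 5 sweeps
per-mode recovery angles (rad): [0.185 0.3   0.097]
held-out accuracy: 1.0  F1: 1.0
```

The angles are the largest principal angles between each learned mode
subspace and the planted one (0 = perfect recovery); the time mode (50-dim)
is hardest because its within-class scatter is estimated from the fewest
effective samples. Classification saturates long before exact subspace
recovery — only the dominant discriminative direction must be found.

The same estimator runs the EEG pipeline end to end:

```bash
mdsp simulate mrcp --out raw --seed 1 --noise-sd 0.3
mdsp tensorize --in raw --out tens --epoch-start -0.5 --epoch-stop 0
mdsp cv --in tens --dims 3,3,3 --folds 5 --repeats 5
```

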