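# Methods

## Model

Trials are tensors **X**_i ∈ R^{m_1×…×m_h} (h ≥ 2) with class labels
y_i ∈ {1..p}. With class-mean tensors **M**_j and grand mean **M**, MDSP
seeks one projection per mode, U_k ∈ R^{m_k×m_k′}, maximizing the
multilinear Fisher ratio of projected between-class to within-class scatter
(Frobenius norms of the fully projected mean deviations vs. trial
deviations). The problem is nonconvex jointly; the solver alternates over
modes. Holding all modes but k fixed, both norms become quadratic forms in
U_k through the mode-k unfoldings of the partially projected tensors:

    S_b^(k) = Σ_j n_j B_j^(k) B_j^(k)ᴴ,  B_j = (M_j − M) ×_{d≠k} U_d
    S_w^(k) = Σ_i W_i^(k) W_i^(k)ᴴ,      W_i = (X_i − M_j(i)) ×_{d≠k} U_d

and the conditionally optimal U_k is the top-m_k′ generalized eigenvectors
of (S_b^(k), S_w^(k) + ridge·I). For h = 2 with the second mode at identity
this is exactly classical DSP, which the test suite asserts.

Assumptions inherited from the Fisher criterion: class-conditional
distributions differing in mean, within-class variation adequately
summarized by second moments, and (for optimality of the eigen-solution)
within-class noise shared across classes. Alternating optimization carries
no global-convergence guarantee; convergence is monitored empirically.

Classification is nearest projected class mean:
j* = argmin_j ‖X ×_1 U_1 ⋯ ×_h U_h − M_j ×_1 U_1 ⋯ ×_h U_h‖_F. The test
feature is deliberately *not* centered by the grand mean (the 2-D DSP
feature map F = Uᵀ(X − M) is); the asymmetry is part of the method's
definition. Ties go to the lowest class label. Test-time centering and
prototypes always reuse training-set means.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `dims` (m_k′) | — | per-mode filter counts; 2–4 per mode is the useful range on rank-2-like structure, redundant filters add noise |
| `epsilon` | 0.01 | threshold on err(t) = Σ_k ‖U_k^t − U_k^{t−1}‖_F / ‖U_k^{t−1}‖_F² (unitless) |
| `t_max` | 50 | sweep cap; hitting it flags the fit non-convergent (model still returned; grid search discards such parameter combinations) |
| `reg` | 1e-8 | relative ridge: ridge = reg · tr(S_w^(k))/m_k; needed whenever n < m_k + p. Near-singular scatters (e.g. strongly correlated CWT scales at high SNR) can need 1e-3–1e-2 to keep the alternation from oscillating |
| `init` | identity | first m_k′ identity columns; deterministic, and makes the first mode-1 update a plain DSP solve. `random` (seeded orthonormal) for robustness studies |
| low-pass | 7 Hz, order 5 | zero-phase (forward–backward) Butterworth, the MRCP band |
| windows | 0.5 s length, 0.1 s step | step read as the hop; a flag reinterprets 0.1 s as the overlap (0.4 s hop) since the protocol phrasing admits both |
| CWT | cgau4, 10 scales | complex Gaussian mother wavelet (order 4 chosen; any cgau order fits the description), scales log-spaced to cover 0.5–7 Hz pseudo-frequency at the working rate. Coefficient modulus is the shipped default; complex coefficients are supported, entering the scatters as Hermitian outer products with real projections taken from the real parts of the (Hermitian) scatters |
| CV | 5 folds × 5 repeats | repeated stratified k-fold; with sliding windows, grouped by source epoch by default so windows of one epoch never straddle train/test |

## Numerical choices

- **Unfolding convention.** Column index Σ_{d≠k} (i_d−1)·Π_{d′<d,d′≠k} m_{d′}
  (lowest remaining mode fastest). Any self-consistent choice gives the
  same subspaces; this one is documented for bit-comparability.
- **Generalized eigensolve.** `scipy.linalg.eigh` on the symmetric-definite
  pencil rather than forming S_w⁻¹S_b; agrees with the explicit product to
  fp tolerance (tested). The ratio-trace identity (objective = eigenvalue
  sum) is asserted.
- **Ridge floor.** The relative ridge is scaled by tr(S_w)/m_k; when that
  trace is numerically zero (noiseless data leaves only float residue) the
  scale falls back to tr(S_b)/m_k, otherwise the solve would run against
  rounding garbage.
- **Eigenvector normalization.** Columns are rescaled to unit Euclidean
  norm and sign-canonicalized (largest-magnitude entry positive, ties to
  the lowest index). The Fisher ratio-trace is invariant under per-column
  rescaling, so this is pure normalization — but it is what makes err(t)
  meaningful: the solver's B-orthonormal scaling diverges geometrically on
  degenerate (noiseless) within-scatter, and sign flips would make err(t)
  oscillate spuriously.
- **Convergence error.** err_k = ‖ΔU_k‖_F/‖U_k^{t−1}‖_F² (not its square;
  both vanish together), measured against the previous sweep, after
  canonicalization. The full per-sweep trace (per-mode errors, total,
  objective) is stored on the model and serialized.
- **Degenerate cases.** Single-class between-scatter yields a warning and
  all-zero eigenvalues; m_k′ = m_k everywhere is allowed (basis change);
  eigenvalue ties preserve the stable sort order, and only the spanned
  subspace is the contract under degeneracy.
- **Metrics.** Binary precision/recall/F1 report the second sorted label
  as positive (a documented convention, nothing more); multiclass scalars
  are macro averages.

## Synthetic data

`planted_dataset` draws shared random orthonormal bases Q_k (m_k × r_k) and
per-class Gaussian cores; the class-mean tensor is the lifted core rescaled
to per-element RMS `amplitude`, so `noise_sd/amplitude` is the element-level
noise-to-signal ratio, and trials add iid Gaussian noise. Isotropic noise
makes the Fisher model exactly correct, so this generator measures the
estimator, not model mismatch. `mrcp_trials` emulates only the defining
features of pre-movement EEG: a linear negative ramp (default −8 units at
the event, onset 0.4 s before it — the negativity-slope component) on a
lateralized channel triple (F4/C4/P4 vs F3/C3/P3 of a 19-electrode 10–20
montage, contralateral to the tapping hand), plus 1/f background noise on
all channels at 100 Hz over a −2..0 s epoch, 40 trials/class. It has no
volume conduction, no artifacts, no latency jitter, no per-subject
variability — passing tests therefore show the pipeline recovers this class
of structure, not that real-EEG accuracies transfer.

## Study sizes and observed behaviour

The synthetic study uses: planted recovery at shape (16, 50, 10), rank 2
per mode, 40 trials/class, noise-to-signal 0.1, 10 seeds; a 50-dataset
convergence suite at shape (12, 20, 8), 20 trials/class, noise 0.3; and the
end-to-end MRCP run at 40 trials/class with the analysis windows starting
in [−0.8, −0.5] s (sliding windows covering the negativity slope, mirroring
the protocol of selecting the pre-movement window; grouped CV, 5 folds × 2
repeats). All of these converge reliably and classify at or near 100%;
under permuted labels every configuration stays within 3 binomial sd of
chance.

A quantified limitation: exact subspace *identification* is much harder
than classification. The span of the generalized eigenvectors is
S_w⁻¹·colspace(S_b), so sampling anisotropy of the estimated within-scatter
tilts the recovered span by roughly √(m_k / N_k) radians, where N_k is the
number of projected mode-k sample columns — independent of the noise level.
At 40 trials/class the 50-dim time mode sits at ~0.4–0.5 rad and shrinks
like 1/√n (≈0.19 at 200, ≈0.08 at 1000 trials/class), while held-out
accuracy is already perfect. Recovery-angle expectations must therefore be
calibrated to sample size, not to SNR.

## Known limitations

- Non-convergent alternation is possible and expected on ill-conditioned
  inputs (the discard rule exists for this); magnitude-CWT tensors at high
  SNR are the common trigger, mitigated by a visible ridge.
- The CWT scale values and complex-Gaussian order are package choices, not
  reconstructions of any particular acquisition setup.
- Real-EEG ingestion (EDF etc.) is an extension point: convert to the
  trial-archive layout first.
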