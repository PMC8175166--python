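"""Classical discriminative spatial patterns (DSP) on 2-D EEG trials.

DSP seeks spatial filters ``U`` (columns of a c x d matrix, d <= c) that
maximize the Fisher ratio of between-class to within-class scatter of
channels-by-time trials:

    S_w = sum_j sum_{i: y_i = j} (X_i - M_j)(X_i - M_j)^T
    S_b = sum_j n_j (M_j - M)(M_j - M)^T
    J(U) = tr(U^T S_b U) / tr(U^T S_w U)

maximized by the generalized eigenvectors of (S_b, S_w) with the d largest
eigenvalues.  Filtered features are F_i = U^T (X_i - M) with M the training
grand mean (test trials are centered by the *training* mean).

The within-class scatter is singular whenever n < c + p, so an optional
relative ridge ``reg * tr(S_w)/c * I`` is added before the eigensolve;
``reg=0`` reproduces the unregularized criterion verbatim on well-posed
inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin

__all__ = [
    "class_means",
    "scatter_matrices",
    "fit_dsp",
    "dsp_features",
    "DspModel",
    "DSP",
]


# ---------------------------------------------------------------------------
# shared linear-algebra helpers (also used by the multilinear solver)
# ---------------------------------------------------------------------------

def canonicalize_signs(U: np.ndarray) -> np.ndarray:
    """Flip each column's sign so its largest-magnitude entry is positive.

    Ties on magnitude are broken by the lowest row index (argmax's first hit).
    Makes eigenvector-based models reproducible and convergence errors
    meaningful across iterations.
    """
    U = np.array(U, copy=True)
    for j in range(U.shape[1]):
        i = int(np.argmax(np.abs(U[:, j])))
        if U[i, j].real < 0:
            U[:, j] = -U[:, j]
    return U


def effective_ridge(S_w: np.ndarray, reg: float,
                    S_b: np.ndarray | None = None) -> float:
    """Absolute ridge from the relative coefficient ``reg``.

    Scaled by the mean diagonal of ``S_w`` so ``reg`` is unit-free.  When
    ``S_w`` is numerically zero (noiseless data leaves only float residue,
    many orders below the between-class scale), the scale falls back to the
    mean diagonal of ``S_b`` — without the floor the ridge would collapse
    and the eigensolve would run against rounding garbage.
    """
    if reg < 0:
        raise ValueError(f"reg must be >= 0, got {reg}")
    c = S_w.shape[0]
    scale = float(np.trace(S_w).real) / c
    ref = float(np.trace(S_b).real) / c if S_b is not None else 0.0
    if scale <= 1e-12 * ref or scale <= 0:
        scale = ref if ref > 0 else 1.0
    return reg * scale


def top_generalized_eigvecs(
    S_b: np.ndarray, S_w: np.ndarray, d: int, reg: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Top-``d`` eigenpairs of ``S_b u = lambda (S_w + ridge I) u``.

    Both inputs are Hermitian PSD; complex-valued scatters are reduced to
    their real parts (still symmetric PSD) so that projection matrices stay
    real.  Returns ``(U, eigenvalues)`` with eigenvalues sorted descending
    and columns rescaled to unit Euclidean norm, then sign-canonicalized.
    Unit columns (rather than the solver's B-orthonormal scaling) leave the
    ratio-trace objective unchanged — it is invariant under per-column
    rescaling — and pin the scale so convergence errors between successive
    iterates are well defined.
    """
    S_b = np.asarray(S_b).real
    S_w = np.asarray(S_w).real
    c = S_b.shape[0]
    if d > c:
        raise ValueError(f"requested d={d} filters but only {c} dimensions")
    ridge = effective_ridge(S_w, reg, S_b)
    S_w_reg = S_w + ridge * np.eye(c)
    S_b = 0.5 * (S_b + S_b.T)
    S_w_reg = 0.5 * (S_w_reg + S_w_reg.T)
    try:
        w, V = scipy.linalg.eigh(S_b, S_w_reg)
    except (scipy.linalg.LinAlgError, np.linalg.LinAlgError) as exc:
        raise np.linalg.LinAlgError(
            "within-class scatter is singular; pass reg > 0 to regularize"
        ) from exc
    order = np.argsort(w)[::-1][:d]
    V = V[:, order] / np.linalg.norm(V[:, order], axis=0, keepdims=True)
    return canonicalize_signs(V), w[order]


# ---------------------------------------------------------------------------
# DSP proper
# ---------------------------------------------------------------------------

def _validate_trials(trials, labels):
    """Check a labeled matrix set; return (X (n,c,t), y, classes, counts)."""
    X = np.asarray(trials)
    y = np.asarray(labels)
    if X.ndim != 3:
        raise ValueError(
            f"expected trials as an (n, channels, time) array, got shape {X.shape}"
        )
    if y.shape != (X.shape[0],):
        raise ValueError(
            f"labels length {y.shape} does not match {X.shape[0]} trials"
        )
    classes, counts = np.unique(y, return_counts=True)
    if classes.size == 0:
        raise ValueError("no trials given")
    return X, y, classes, counts


def class_means(trials, labels):
    """Per-class mean matrices ``M_j`` and the grand mean ``M``."""
    X, y, classes, _ = _validate_trials(trials, labels)
    M_j = [X[y == j].mean(axis=0) for j in classes]
    return M_j, X.mean(axis=0)


def scatter_matrices(trials, labels):
    """Within-class and between-class scatter matrices ``(S_w, S_b)``.

    Complex trials use Hermitian outer products, so both matrices are
    Hermitian PSD.
    """
    X, y, classes, counts = _validate_trials(trials, labels)
    M_j, M = class_means(trials, labels)
    c = X.shape[1]
    dtype = np.result_type(X.dtype, np.float64)
    S_w = np.zeros((c, c), dtype=dtype)
    S_b = np.zeros((c, c), dtype=dtype)
    for j, n_j, Mj in zip(classes, counts, M_j):
        D = X[y == j] - Mj
        for Di in D:
            S_w += Di @ Di.conj().T
        B = Mj - M
        S_b += n_j * (B @ B.conj().T)
    return S_w, S_b


@dataclass
class DspModel:
    """Fitted DSP filter bank.

    Attributes
    ----------
    U : (c, d) array — spatial filters, columns sorted by descending
        generalized eigenvalue, sign-canonicalized.
    eigenvalues : (d,) descending Fisher-ratio eigenvalues.
    class_means : list of (c, t) per-class mean matrices.
    grand_mean : (c, t) training grand mean used for centering.
    S_w, S_b : (c, c) scatter matrices.
    classes : class labels in the order of ``class_means``.
    """

    U: np.ndarray
    eigenvalues: np.ndarray
    class_means: list = field(repr=False)
    grand_mean: np.ndarray = field(repr=False)
    S_w: np.ndarray = field(repr=False)
    S_b: np.ndarray = field(repr=False)
    classes: np.ndarray = None


def fit_dsp(trials, labels, d: int, reg: float = 1e-8) -> DspModel:
    """Fit DSP: top-``d`` generalized eigenvectors of ``(S_b, S_w + ridge I)``."""
    X, y, classes, counts = _validate_trials(trials, labels)
    if reg == 0 and not np.any(counts >= 2):
        raise ValueError(
            "every class has a single trial, so S_w = 0; pass reg > 0"
        )
    M_j, M = class_means(trials, labels)
    S_w, S_b = scatter_matrices(trials, labels)
    U, w = top_generalized_eigvecs(S_b, S_w, d, reg)
    return DspModel(
        U=U, eigenvalues=w, class_means=M_j, grand_mean=M,
        S_w=S_w, S_b=S_b, classes=classes,
    )


def dsp_features(model: DspModel, X: np.ndarray) -> np.ndarray:
    """Spatially filtered feature ``U^T (X - M)`` for one trial."""
    X = np.asarray(X)
    if X.shape != model.grand_mean.shape:
        raise ValueError(
            f"trial shape {X.shape} does not match model's "
            f"{model.grand_mean.shape}"
        )
    return model.U.T @ (X - model.grand_mean)


class DSP(ClassifierMixin, TransformerMixin, BaseEstimator):
    """Discriminative-spatial-patterns filter as a scikit-learn estimator.

    ``fit`` expects ``X`` of shape (n_trials, channels, time) and integer
    labels ``y``.  ``transform`` returns the filtered features flattened to
    (n_trials, d * time); ``predict`` assigns the class whose filtered mean
    matrix is nearest in Frobenius distance.

    Parameters
    ----------
    n_filters : number of spatial filters d (d <= channels).
    reg : relative ridge added to S_w; 0 disables regularization.
    """

    def __init__(self, n_filters: int = 2, reg: float = 1e-8):
        self.n_filters = n_filters
        self.reg = reg

    def fit(self, X, y):
        self.model_ = fit_dsp(X, y, d=self.n_filters, reg=self.reg)
        self.classes_ = self.model_.classes
        m = self.model_
        self.prototypes_ = [m.U.T @ (Mj - m.grand_mean) for Mj in m.class_means]
        return self

    def _features(self, X):
        X = np.asarray(X)
        return np.stack([dsp_features(self.model_, Xi) for Xi in X])

    def transform(self, X):
        F = self._features(X)
        return F.reshape(F.shape[0], -1)

    def predict(self, X):
        F = self._features(X)
        D = np.stack(
            [np.linalg.norm(F - P, axis=(1, 2)) for P in self.prototypes_],
            axis=1,
        )
        return self.classes_[np.argmin(D, axis=1)]
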