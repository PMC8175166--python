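"""Multilinear discriminative spatial patterns (MDSP).

MDSP generalizes the DSP spatial filter to trials that are tensors of any
order h >= 2 (e.g. channels x time, or channels x time x wavelet scales).
It learns one projection matrix per mode, ``U_k`` of shape (m_k, m_k'),
jointly maximizing the multilinear Fisher ratio

    J(U_1..U_h) = sum_j n_j ||(M_j - M) x_1 U_1 ... x_h U_h||_F^2
                  -----------------------------------------------
                  sum_j sum_{i: y_i=j} ||(X_i - M_j) x_1 U_1 ... x_h U_h||_F^2

where M_j and M are the class and grand mean tensors.  The problem is
nonconvex in the joint variables, so the solver alternates: holding all
modes but k fixed, the criterion reduces to an ordinary Fisher quotient in
U_k whose scatter matrices are built from mode-k unfoldings of the
partially projected tensors, and the optimal U_k is the top generalized
eigenvectors of that (S_b^(k), S_w^(k)) pencil — exactly a DSP solve per
mode.  Modes are swept in ascending order (Gauss–Seidel: each update sees
the latest other modes).

Convergence is monitored by the relative change of the projections,

    err_k(t) = ||U_k^t - U_k^{t-1}||_F / ||U_k^{t-1}||_F^2 ,
    err(t)   = sum_k err_k(t),

computed on sign-canonicalized matrices (eigenvector sign flips would
otherwise make the error oscillate spuriously).  The fit stops when
err(t) <= epsilon (default 0.01) or after t_max sweeps (default 50); a
non-convergent fit is returned flagged, not raised — model-selection layers
discard such parameter combinations.

Convergence of the alternating scheme is not guaranteed in general; the
trace recorded on the model supports empirical monitoring.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin

from .dsp import canonicalize_signs, top_generalized_eigvecs
from .tensor_core import mode_product, multi_mode_product, unfold

__all__ = [
    "FitConfig",
    "MdspModel",
    "class_mean_tensors",
    "mode_scatter",
    "update_mode",
    "convergence_error",
    "fit_mdsp",
    "project",
    "save_model",
    "load_model",
    "MDSP",
]


@dataclass
class FitConfig:
    """Knobs of the alternating fit.

    dims : per-mode target sizes (m_1', ..., m_h'), 1 <= m_k' <= m_k.
    epsilon : convergence threshold on the summed relative change err(t).
    t_max : sweep cap; hitting it without err <= epsilon flags the model
        non-convergent.
    reg : relative ridge on each within-class scatter (see dsp module).
    init : 'identity' (first m_k' identity columns; deterministic, makes the
        very first mode-1 update a plain DSP solve) or 'random'
        (seeded random orthonormal columns, for robustness studies).
    seed : RNG seed, used only by the random init.
    """

    dims: tuple
    epsilon: float = 0.01
    t_max: int = 50
    reg: float = 1e-8
    init: str = "identity"
    seed: int | None = None

    def __post_init__(self):
        self.dims = tuple(int(d) for d in self.dims)
        if any(d < 1 for d in self.dims):
            raise ValueError(f"dims must all be >= 1, got {self.dims}")
        if not self.epsilon > 0:
            raise ValueError(f"epsilon must be > 0, got {self.epsilon}")
        if self.t_max < 1:
            raise ValueError(f"t_max must be >= 1, got {self.t_max}")
        if self.init not in ("identity", "random"):
            raise ValueError(f"init must be 'identity' or 'random', got {self.init!r}")


@dataclass
class MdspModel:
    """Fitted MDSP model: per-mode projections plus means and fit trace."""

    projections: list  # U_1..U_h, each (m_k, m_k')
    class_means: list  # p tensors M_j, input shape
    grand_mean: np.ndarray = field(repr=False)
    classes: np.ndarray = None
    trace: list = field(default_factory=list, repr=False)
    converged: bool = False
    iterations_run: int = 0
    config: FitConfig | None = None

    @property
    def order(self) -> int:
        return len(self.projections)

    @property
    def input_shape(self) -> tuple:
        return tuple(U.shape[0] for U in self.projections)

    @property
    def output_shape(self) -> tuple:
        return tuple(U.shape[1] for U in self.projections)


def _validate_tensor_set(trials, labels, min_classes=1):
    X = np.asarray(trials)
    y = np.asarray(labels)
    if X.ndim < 3:
        raise ValueError(
            f"expected trials stacked as an (n, m_1, ..., m_h) array with "
            f"h >= 2, got shape {X.shape}"
        )
    if y.shape != (X.shape[0],):
        raise ValueError(f"labels length mismatch: {y.shape[0]} vs {X.shape[0]} trials")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < min_classes:
        raise ValueError(f"need at least {min_classes} classes, got {classes.size}")
    return X, y, classes, counts


def class_mean_tensors(trials, labels):
    """Per-class mean tensors and the grand mean tensor."""
    X, y, classes, _ = _validate_tensor_set(trials, labels)
    return [X[y == j].mean(axis=0) for j in classes], X.mean(axis=0)


def mode_scatter(trials, labels, projections, mode: int):
    """Partially projected scatter pencil ``(S_b^(k), S_w^(k))`` for one mode.

    Every class-mean deviation ``M_j - M`` (resp. trial deviation
    ``X_i - M_j``) is projected through all modes except ``mode``, unfolded
    along ``mode``, and accumulated as Hermitian outer products.  With these
    matrices the multilinear Fisher numerator equals ``tr(U_k^T S_b^(k) U_k)``
    and the denominator ``tr(U_k^T S_w^(k) U_k)`` for any U_k.
    """
    X, y, classes, counts = _validate_tensor_set(trials, labels)
    h = X.ndim - 1
    if not 1 <= mode <= h:
        raise IndexError(f"mode {mode} out of range for order-{h} trials")
    if len(projections) != h:
        raise ValueError(f"expected {h} projection matrices, got {len(projections)}")
    for k, U in enumerate(projections, start=1):
        if k != mode and U is not None and U.shape[0] != X.shape[k]:
            raise ValueError(
                f"projection for mode {k} has {U.shape[0]} rows, "
                f"expected {X.shape[k]}"
            )
    M_j, M = class_mean_tensors(trials, labels)
    m_k = X.shape[mode]
    dtype = np.result_type(X.dtype, np.float64)
    S_b = np.zeros((m_k, m_k), dtype=dtype)
    S_w = np.zeros((m_k, m_k), dtype=dtype)
    for j, n_j, Mj in zip(classes, counts, M_j):
        B = unfold(multi_mode_product(Mj - M, projections, skip=mode), mode)
        S_b += n_j * (B @ B.conj().T)
        for Xi in X[y == j]:
            W = unfold(multi_mode_product(Xi - Mj, projections, skip=mode), mode)
            S_w += W @ W.conj().T
    return S_b, S_w


def update_mode(trials, labels, projections, mode: int, m_k_prime: int,
                reg: float = 1e-8):
    """Conditionally optimal ``U_k``: top generalized eigenvectors of the
    mode-k scatter pencil with all other modes held fixed."""
    S_b, S_w = mode_scatter(trials, labels, projections, mode)
    if np.trace(S_b).real <= 0:
        warnings.warn(
            f"mode-{mode} between-class scatter is zero; the Fisher "
            "objective is degenerate and all eigenvalues are 0",
            RuntimeWarning,
            stacklevel=2,
        )
    U, _ = top_generalized_eigvecs(S_b, S_w, m_k_prime, reg)
    return U


def convergence_error(U_prev: np.ndarray, U_curr: np.ndarray) -> float:
    """Relative projection change ``||U_t - U_{t-1}||_F / ||U_{t-1}||_F^2``.

    Both arguments are sign-canonicalized first so that eigenvector sign
    flips do not register as change.
    """
    U_prev = np.asarray(U_prev)
    U_curr = np.asarray(U_curr)
    if U_prev.shape != U_curr.shape:
        raise ValueError(f"shape mismatch: {U_prev.shape} vs {U_curr.shape}")
    denom = np.linalg.norm(U_prev)
    if denom == 0:
        raise ValueError("previous projection has zero norm")
    U_prev = canonicalize_signs(U_prev)
    U_curr = canonicalize_signs(U_curr)
    return float(np.linalg.norm(U_curr - U_prev) / denom**2)


def _objective(X, y, classes, counts, M_j, M, projections) -> float:
    """Full multilinear Fisher ratio at the current projections."""
    num = 0.0
    den = 0.0
    for j, n_j, Mj in zip(classes, counts, M_j):
        num += n_j * np.linalg.norm(multi_mode_product(Mj - M, projections)) ** 2
        for Xi in X[y == j]:
            den += np.linalg.norm(multi_mode_product(Xi - Mj, projections)) ** 2
    return float(num / den) if den > 0 else float("inf")


def _init_projections(shape, dims, init, seed):
    rng = np.random.default_rng(seed)
    U = []
    for m_k, d_k in zip(shape, dims):
        if init == "identity":
            U.append(np.eye(m_k)[:, :d_k])
        else:
            A = rng.standard_normal((m_k, m_k))
            Q, _ = np.linalg.qr(A)
            U.append(canonicalize_signs(Q[:, :d_k]))
    return U


def fit_mdsp(trials, labels, config: FitConfig) -> MdspModel:
    """Alternating eigen-optimization of all mode projections.

    Sweeps modes 1..h repeatedly, each ``update_mode`` seeing the latest
    values of the other modes, until the summed relative change err(t)
    drops to ``config.epsilon`` or ``config.t_max`` sweeps have run.  The
    returned model carries the full per-sweep trace (per-mode errors, total
    error, Fisher objective) and a ``converged`` flag; non-convergence is
    reported, never raised.
    """
    X, y, classes, counts = _validate_tensor_set(trials, labels, min_classes=2)
    h = X.ndim - 1
    shape = X.shape[1:]
    if len(config.dims) != h:
        raise ValueError(
            f"config.dims has {len(config.dims)} entries for order-{h} trials"
        )
    for k, (m_k, d_k) in enumerate(zip(shape, config.dims), start=1):
        if d_k > m_k:
            raise ValueError(
                f"mode-{k} target size {d_k} exceeds input size {m_k}"
            )
    M_j, M = class_mean_tensors(trials, labels)
    U = _init_projections(shape, config.dims, config.init, config.seed)

    trace = []
    converged = False
    t = 0
    for t in range(1, config.t_max + 1):
        U_prev = [u.copy() for u in U]
        for k in range(1, h + 1):
            U[k - 1] = update_mode(X, y, U, k, config.dims[k - 1], config.reg)
        errs = tuple(
            convergence_error(up, uc) for up, uc in zip(U_prev, U)
        )
        err = float(sum(errs))
        obj = _objective(X, y, classes, counts, M_j, M, U)
        trace.append({"t": t, "err_k": errs, "err": err, "objective": obj})
        if err <= config.epsilon:
            converged = True
            break

    return MdspModel(
        projections=U,
        class_means=M_j,
        grand_mean=M,
        classes=classes,
        trace=trace,
        converged=converged,
        iterations_run=t,
        config=config,
    )


def project(model: MdspModel, X: np.ndarray) -> np.ndarray:
    """Project one trial: ``F = X x_1 U_1 ... x_h U_h`` (no centering)."""
    X = np.asarray(X)
    if X.shape != model.input_shape:
        raise ValueError(
            f"trial shape {X.shape} does not match model input "
            f"{model.input_shape}"
        )
    return multi_mode_product(X, model.projections)


# ---------------------------------------------------------------------------
# serialization: one .npz archive of named dense arrays + JSON metadata
# ---------------------------------------------------------------------------

def save_model(model: MdspModel, path) -> None:
    arrays = {}
    for k, Uk in enumerate(model.projections, start=1):
        arrays[f"U_{k}"] = Uk
    for j, Mj in zip(model.classes, model.class_means):
        arrays[f"class_mean_{j}"] = Mj
    arrays["grand_mean"] = model.grand_mean
    arrays["classes"] = np.asarray(model.classes)
    if model.trace:
        arrays["trace_err_k"] = np.array([r["err_k"] for r in model.trace])
        arrays["trace_err"] = np.array([r["err"] for r in model.trace])
        arrays["trace_objective"] = np.array([r["objective"] for r in model.trace])
    meta = {
        "order": model.order,
        "input_shape": list(model.input_shape),
        "output_shape": list(model.output_shape),
        "n_classes": len(model.class_means),
        "converged": bool(model.converged),
        "iterations_run": int(model.iterations_run),
        "config": asdict(model.config) if model.config else None,
    }
    arrays["meta_json"] = np.array(json.dumps(meta))
    np.savez(path, **arrays)


def load_model(path) -> MdspModel:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta_json"]))
        classes = z["classes"]
        projections = [z[f"U_{k}"] for k in range(1, meta["order"] + 1)]
        class_means = [z[f"class_mean_{j}"] for j in classes]
        trace = []
        if "trace_err" in z:
            for i in range(len(z["trace_err"])):
                trace.append(
                    {
                        "t": i + 1,
                        "err_k": tuple(z["trace_err_k"][i]),
                        "err": float(z["trace_err"][i]),
                        "objective": float(z["trace_objective"][i]),
                    }
                )
        cfg = FitConfig(**meta["config"]) if meta["config"] else None
        return MdspModel(
            projections=projections,
            class_means=class_means,
            grand_mean=z["grand_mean"],
            classes=classes,
            trace=trace,
            converged=meta["converged"],
            iterations_run=meta["iterations_run"],
            config=cfg,
        )


class MDSP(ClassifierMixin, TransformerMixin, BaseEstimator):
    """MDSP as a scikit-learn estimator.

    ``fit`` expects ``X`` stacked as (n_trials, m_1, ..., m_h) with h >= 2
    and integer labels ``y``.  ``transform`` returns projected trials
    flattened to (n_trials, prod m_k'); ``predict`` assigns the class whose
    projected mean tensor is nearest in Frobenius distance, ties broken by
    the lowest class label.

    Parameters
    ----------
    n_filters : int or tuple — per-mode projected sizes m_k'; an int is
        broadcast to every mode.
    epsilon, t_max, reg, init, seed : see :class:`FitConfig`.

    Attributes (after fit)
    ----------------------
    model_ : the underlying :class:`MdspModel`.
    classes_ : sorted class labels.
    prototypes_ : projected class-mean tensors, one per class.
    converged_ : whether the alternating fit reached err <= epsilon.
    n_iter_ : sweeps run.
    """

    def __init__(self, n_filters=2, epsilon: float = 0.01, t_max: int = 50,
                 reg: float = 1e-8, init: str = "identity", seed=None):
        self.n_filters = n_filters
        self.epsilon = epsilon
        self.t_max = t_max
        self.reg = reg
        self.init = init
        self.seed = seed

    def _config(self, h: int) -> FitConfig:
        dims = self.n_filters
        if np.isscalar(dims):
            dims = (int(dims),) * h
        return FitConfig(
            dims=tuple(dims), epsilon=self.epsilon, t_max=self.t_max,
            reg=self.reg, init=self.init, seed=self.seed,
        )

    def fit(self, X, y):
        X = np.asarray(X)
        self.model_ = fit_mdsp(X, y, self._config(X.ndim - 1))
        self.classes_ = self.model_.classes
        self.prototypes_ = [
            project(self.model_, Mj) for Mj in self.model_.class_means
        ]
        self.converged_ = self.model_.converged
        self.n_iter_ = self.model_.iterations_run
        return self

    def transform(self, X):
        X = np.asarray(X)
        F = np.stack([project(self.model_, Xi) for Xi in X])
        return F.reshape(F.shape[0], -1)

    def predict(self, X):
        X = np.asarray(X)
        F = np.stack([project(self.model_, Xi) for Xi in X])
        axes = tuple(range(1, F.ndim))
        D = np.stack(
            [np.sqrt(np.sum(np.abs(F - P) ** 2, axis=axes))
             for P in self.prototypes_],
            axis=1,
        )
        # argmin returns the first minimum -> lowest class label wins ties
        return self.classes_[np.argmin(D, axis=1)]
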