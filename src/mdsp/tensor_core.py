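"""Order-agnostic dense tensor algebra: mode-k unfolding/folding and mode-k products.

Modes are numbered 1..h throughout, matching the convention of the
multilinear-algebra literature; the translation to NumPy's 0-based axes
happens only inside this module.

Unfolding convention
--------------------
``unfold(t, k)`` returns the matrix whose row ``i`` collects every element of
``t`` with mode-k index ``i``.  Columns are ordered lexicographically over the
remaining modes with the *lowest* remaining mode index varying fastest::

    col(i_1, ..., i_h) = sum_{d != k} (i_d - 1) * prod_{d' < d, d' != k} m_{d'}

(1-based indices).  Any self-consistent convention yields the same subspaces
downstream; this one is fixed so that ``fold`` is its exact inverse and so
that unfolded matrices are bit-comparable across implementations.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "check_tensor",
    "unfold",
    "fold",
    "mode_product",
    "multi_mode_product",
]


def check_tensor(t: np.ndarray, min_order: int = 2) -> np.ndarray:
    """Validate and return a dense tensor of order >= ``min_order``.

    Raises ``ValueError`` on non-finite entries or insufficient order.
    """
    t = np.asarray(t)
    if t.ndim < min_order:
        raise ValueError(f"tensor order {t.ndim} < required minimum {min_order}")
    if t.size and not np.all(np.isfinite(t)):
        raise ValueError("tensor contains non-finite elements")
    return t


def _check_mode(t: np.ndarray, mode: int) -> int:
    if not 1 <= mode <= t.ndim:
        raise IndexError(
            f"mode {mode} out of range for tensor of order {t.ndim} "
            f"(modes are 1-based)"
        )
    return mode - 1


def unfold(t: np.ndarray, mode: int) -> np.ndarray:
    """Mode-k unfolding of ``t`` into an (m_k, prod of other sizes) matrix."""
    t = np.asarray(t)
    ax = _check_mode(t, mode)
    # Move mode k in front; Fortran-order ravel of the remaining axes makes
    # the lowest remaining mode index vary fastest along columns.
    return np.moveaxis(t, ax, 0).reshape(t.shape[ax], -1, order="F")


def fold(m: np.ndarray, mode: int, shape: tuple[int, ...]) -> np.ndarray:
    """Inverse of :func:`unfold`: rebuild a tensor of ``shape`` from its
    mode-k unfolding."""
    m = np.asarray(m)
    shape = tuple(int(s) for s in shape)
    if not 1 <= mode <= len(shape):
        raise IndexError(
            f"mode {mode} out of range for target order {len(shape)}"
        )
    ax = mode - 1
    rest = shape[:ax] + shape[ax + 1 :]
    expected = (shape[ax], int(np.prod(rest)) if rest else 1)
    if m.shape != expected:
        raise ValueError(
            f"matrix shape {m.shape} does not match mode-{mode} unfolding "
            f"{expected} of target shape {shape}"
        )
    t = m.reshape((shape[ax],) + rest, order="F")
    return np.moveaxis(t, 0, ax)


def mode_product(t: np.ndarray, u: np.ndarray, mode: int) -> np.ndarray:
    """Mode-k product ``t x_k u`` contracting mode k of ``t`` with the rows
    of ``u``.

    ``u`` has shape (m_k, m_k'); the result's mode-k size is m_k'.  Equals
    ``fold(u.T @ unfold(t, k), k, new_shape)``; the transpose is plain
    (non-conjugated), so complex tensors transform linearly.
    """
    t = np.asarray(t)
    u = np.asarray(u)
    ax = _check_mode(t, mode)
    if u.ndim != 2:
        raise ValueError(f"mode-{mode} factor must be a matrix, got ndim={u.ndim}")
    if u.shape[0] != t.shape[ax]:
        raise ValueError(
            f"mode-{mode} dimension mismatch: tensor has m_{mode}={t.shape[ax]}, "
            f"matrix has {u.shape[0]} rows"
        )
    out = np.tensordot(t, u, axes=([ax], [0]))
    # tensordot appends the contracted output axis; restore mode order.
    return np.moveaxis(out, -1, ax)


def multi_mode_product(
    t: np.ndarray,
    mats: list[np.ndarray | None],
    skip: int | None = None,
) -> np.ndarray:
    """Apply ``mode_product`` along every mode in turn.

    ``mats[k-1]`` is the factor for mode k; an entry of ``None`` (or a mode
    equal to ``skip``) leaves that mode untouched.  Products along distinct
    modes commute, so the application order does not affect the result.
    """
    t = np.asarray(t)
    if len(mats) != t.ndim:
        raise ValueError(
            f"expected {t.ndim} per-mode matrices, got {len(mats)}"
        )
    if skip is not None:
        _check_mode(t, skip)
    out = t
    for k, u in enumerate(mats, start=1):
        if u is None or k == skip:
            continue
        out = mode_product(out, u, k)
    return out
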