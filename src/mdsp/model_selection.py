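"""Cross-validation and parameter search for MDSP pipelines.

The protocol is repeated stratified k-fold (default 5 x 5-fold).  When the
trials are sliding windows cut from longer epochs, fold assignment can be
grouped by source epoch so that windows of one epoch never straddle the
train/test boundary (temporal-leakage guard); this is the default whenever
group ids are supplied.

Parameter search evaluates every candidate per-mode filter-count
combination (optionally crossed with candidate analysis windows) by
cross-validation and ranks the convergent ones by mean accuracy.  A
combination in which *any* fold's alternating fit fails to converge is
excluded from the ranking and only reported flagged — non-coordinating
filter combinations are discarded rather than trusted.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

from .classify import score
from .mdsp import MDSP

__all__ = ["GridSpec", "cross_validate", "grid_search"]


class GridSpec:
    """Search space: per-mode filter-count candidates and a CV scheme.

    dims_grid : iterable of per-mode size tuples, e.g.
        ``[(d, d, d) for d in range(1, 9)]``; or a dict mapping each mode to
        its candidate counts, expanded as a cartesian product.
    window_starts : optional labels of alternative analysis windows (the
        caller supplies one dataset per label).
    folds, repeats, seed : the CV scheme.
    """

    def __init__(self, dims_grid, window_starts=None, folds: int = 5,
                 repeats: int = 5, seed: int = 0):
        if isinstance(dims_grid, dict):
            modes = sorted(dims_grid)
            dims_grid = list(itertools.product(*(dims_grid[m] for m in modes)))
        self.dims_grid = [tuple(int(d) for d in dims) for dims in dims_grid]
        if not self.dims_grid:
            raise ValueError("empty filter-count grid")
        self.window_starts = window_starts
        if folds < 2:
            raise ValueError(f"folds must be >= 2, got {folds}")
        self.folds = folds
        self.repeats = repeats
        self.seed = seed


def _splits(y, groups, folds, repeats, seed):
    y = np.asarray(y)
    X_idx = np.zeros((len(y), 1))
    for r in range(repeats):
        rs = seed + r
        if groups is not None:
            cv = StratifiedGroupKFold(n_splits=folds, shuffle=True,
                                      random_state=rs)
            yield from cv.split(X_idx, y, groups)
        else:
            cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rs)
            yield from cv.split(X_idx, y)


def cross_validate(trials, labels, dims, *, folds: int = 5, repeats: int = 5,
                   seed: int = 0, groups=None, epsilon: float = 0.01,
                   t_max: int = 50, reg: float = 1e-8) -> dict:
    """Repeated stratified k-fold evaluation of an MDSP fit.

    Everything — class means, scatters, projections, prototypes — is
    derived from the training split only.  Returns per-fold metric records
    plus summary statistics and an ``all_converged`` flag.
    """
    X = np.asarray(trials)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if np.any(counts < folds):
        small = classes[counts < folds]
        raise ValueError(
            f"classes {small.tolist()} have fewer than folds={folds} trials"
        )
    records = []
    for i, (tr, te) in enumerate(_splits(y, groups, folds, repeats, seed)):
        est = MDSP(n_filters=dims, epsilon=epsilon, t_max=t_max, reg=reg)
        est.fit(X[tr], y[tr])
        metrics = score(est.predict(X[te]), y[te])
        records.append(
            {
                "fold": i,
                "n_test": len(te),
                "accuracy": metrics["accuracy"],
                "f1": metrics["f1"],
                "converged": bool(est.converged_),
                "n_iter": int(est.n_iter_),
            }
        )
    acc = np.array([r["accuracy"] for r in records])
    return {
        "folds": records,
        "mean_accuracy": float(acc.mean()),
        "sd_accuracy": float(acc.std(ddof=1)) if len(acc) > 1 else 0.0,
        "all_converged": all(r["converged"] for r in records),
    }


def grid_search(datasets, grid: GridSpec, *, epsilon: float = 0.01,
                t_max: int = 50, reg: float = 1e-8,
                groups=None) -> pd.DataFrame:
    """Evaluate every (window, filter-count) combination by CV and rank.

    ``datasets`` is either one ``(trials, labels)`` / ``(trials, labels,
    groups)`` tuple, or a dict mapping a window-start label to such tuples
    (one per entry of ``grid.window_starts``).  Rows where any fold failed
    to converge carry ``excluded=True`` and ``rank=NaN``.  Convergent rows
    are ranked by mean accuracy, ties broken by fewer total filters, then
    by lexicographically smaller dims.  If no combination converges, the
    table is returned with every row excluded (no exception).
    """
    if not isinstance(datasets, dict):
        datasets = {"": datasets}
    rows = []
    for wlabel, data in datasets.items():
        if len(data) == 3:
            X, y, g = data
        else:
            (X, y), g = data, groups
        for dims in grid.dims_grid:
            res = cross_validate(
                X, y, dims, folds=grid.folds, repeats=grid.repeats,
                seed=grid.seed, groups=g, epsilon=epsilon, t_max=t_max,
                reg=reg,
            )
            rows.append(
                {
                    "window_start": wlabel,
                    "dims": dims,
                    "total_filters": int(sum(dims)),
                    "mean_accuracy": res["mean_accuracy"],
                    "sd_accuracy": res["sd_accuracy"],
                    "all_converged": res["all_converged"],
                    "excluded": not res["all_converged"],
                }
            )
    table = pd.DataFrame(rows)
    table["rank"] = np.nan
    ok = ~table["excluded"]
    if ok.any():
        order = table[ok].sort_values(
            by=["mean_accuracy", "total_filters", "dims"],
            ascending=[False, True, True],
            kind="mergesort",
        ).index
        table.loc[order, "rank"] = np.arange(1, len(order) + 1)
    return table
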