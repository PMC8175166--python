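"""Nearest-projected-class-mean classification over MDSP features.

A test trial X is projected through the learned mode projections and
assigned to the class whose projected mean tensor is closest in Frobenius
distance:

    j* = argmin_j || X x_1 U_1 ... x_h U_h  -  M_j x_1 U_1 ... x_h U_h ||_F

Note the deliberate asymmetry with the DSP feature map: the test feature is
centered against projected class means only, never against the grand mean.
Complex-valued features use the modulus-based Frobenius norm.  Ties go to
the lowest class label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import (
    accuracy_score,
    precision_recall_fscore_support,
)

from .mdsp import MdspModel, project

__all__ = ["ProjectedPrototypes", "fit_prototypes", "predict", "score"]


@dataclass
class ProjectedPrototypes:
    """Class-mean tensors mapped through the fitted projections."""

    prototypes: list  # p tensors of the model's output shape
    class_ids: np.ndarray


def fit_prototypes(model: MdspModel) -> ProjectedPrototypes:
    """Project every class mean through the model's mode projections."""
    return ProjectedPrototypes(
        prototypes=[project(model, Mj) for Mj in model.class_means],
        class_ids=np.asarray(model.classes),
    )


def predict(protos: ProjectedPrototypes, model: MdspModel, X: np.ndarray):
    """Class of the nearest projected prototype for one trial."""
    F = project(model, X)
    d = np.array([np.linalg.norm(F - P) for P in protos.prototypes])
    return protos.class_ids[int(np.argmin(d))]  # first min: lowest id wins


def score(predictions, truth) -> dict:
    """Confusion-matrix metrics: accuracy plus per-class and macro
    precision/recall/F1.

    For binary problems the scalar ``precision``/``recall``/``f1`` keys
    report the *second* of the two sorted labels as the positive class
    (a documented convention, not a community standard); multiclass scalars
    are macro averages.
    """
    y_pred = np.asarray(predictions)
    y_true = np.asarray(truth)
    if y_pred.shape != y_true.shape:
        raise ValueError(
            f"length mismatch: {y_pred.shape[0]} predictions vs "
            f"{y_true.shape[0]} truth labels"
        )
    labels = np.unique(np.concatenate([y_true, y_pred]))
    prec, rec, f1, support = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, zero_division=0
    )
    macro = {
        "precision": float(prec.mean()),
        "recall": float(rec.mean()),
        "f1": float(f1.mean()),
    }
    if labels.size == 2:
        scalar = {"precision": float(prec[1]), "recall": float(rec[1]),
                  "f1": float(f1[1])}
    else:
        scalar = macro
    return {
        "accuracy": float(accuracy_score(y_true, y_pred)),
        **scalar,
        "macro": macro,
        "per_class": {
            str(lab): {
                "precision": float(p),
                "recall": float(r),
                "f1": float(f),
                "support": int(s),
            }
            for lab, p, r, f, s in zip(labels, prec, rec, f1, support)
        },
    }
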