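"""Multiclass (softmax) logistic regression baseline.

The comparison model for the factorization-based risk predictor: an
L2-regularized multinomial logistic regression trained by full-batch
gradient descent with Armijo backtracking, predicting the four-level risk
category from the remaining encoded features.  Missing features are
mean-imputed and all features standardized internally (the non-negativity
constraint of the factorization does not apply here).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MLRModel", "fit_mlr", "predict_mlr"]


@dataclass
class MLRModel:
    """Fitted softmax regression: ``weights`` is (features+1) x classes,
    first row the intercept; features are standardized with the stored
    means/scales before the linear map."""

    weights: np.ndarray
    classes: np.ndarray
    regularization: float
    feature_mean: np.ndarray
    feature_scale: np.ndarray
    n_iter: int
    converged: bool


def _softmax(Z: np.ndarray) -> np.ndarray:
    Z = Z - Z.max(axis=1, keepdims=True)
    E = np.exp(Z)
    return E / E.sum(axis=1, keepdims=True)


def _prepare(features: np.ndarray, mean: np.ndarray, scale: np.ndarray) -> np.ndarray:
    F = np.array(features, dtype=float)
    nan = np.isnan(F)
    if nan.any():
        F[nan] = np.broadcast_to(mean, F.shape)[nan]
    return (F - mean) / scale


def _loss_grad(W, Xd, Y, lam):
    n = Xd.shape[0]
    P = _softmax(Xd @ W)
    loss = -np.sum(Y * np.log(np.maximum(P, 1e-300))) / n
    loss += 0.5 * lam * np.sum(W[1:] ** 2)
    G = Xd.T @ (P - Y) / n
    G[1:] += lam * W[1:]
    return loss, G


def fit_mlr(
    features: np.ndarray,
    labels: np.ndarray,
    lam: float = 1e-3,
    max_iter: int = 2000,
    seed: int = 0,
    grad_tol: float = 1e-6,
) -> MLRModel:
    """Fit by gradient descent to gradient norm < ``grad_tol`` or ``max_iter``.

    ``labels`` may be any hashable class codes (e.g. risk levels 1..4); at
    least two distinct classes must be present.  Rows with missing features
    are completed by column-mean imputation before standardization.  The
    zero initialization makes the fit deterministic; ``seed`` is accepted
    for interface symmetry with the solver.
    """
    del seed
    F = np.array(features, dtype=float)
    labels = np.asarray(labels)
    if F.ndim != 2 or F.shape[0] != labels.shape[0]:
        raise ValueError("features must be 2-D with one row per label")
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("need >= 2 distinct classes to fit")

    col_mean = np.nanmean(F, axis=0)
    if np.isnan(col_mean).any():
        raise ValueError("a feature column is entirely missing")
    nan = np.isnan(F)
    F[nan] = np.broadcast_to(col_mean, F.shape)[nan]
    scale = F.std(axis=0)
    scale[scale == 0] = 1.0

    Xd = np.column_stack([np.ones(F.shape[0]), (F - col_mean) / scale])
    Y = (labels[:, None] == classes[None, :]).astype(float)

    W = np.zeros((Xd.shape[1], classes.size))
    loss, G = _loss_grad(W, Xd, Y, lam)
    converged = False
    it = 0
    step = 1.0
    for it in range(1, max_iter + 1):
        gnorm2 = float(np.sum(G * G))
        if np.sqrt(gnorm2) < grad_tol:
            converged = True
            break
        # Armijo backtracking from the last accepted step size.
        step = min(step * 2.0, 1e6)
        while True:
            W_new = W - step * G
            loss_new, G_new = _loss_grad(W_new, Xd, Y, lam)
            if loss_new <= loss - 1e-4 * step * gnorm2 or step < 1e-14:
                break
            step *= 0.5
        W, loss, G = W_new, loss_new, G_new

    return MLRModel(
        weights=W,
        classes=classes,
        regularization=lam,
        feature_mean=col_mean,
        feature_scale=scale,
        n_iter=it,
        converged=converged,
    )


def predict_mlr(
    model: MLRModel, features: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Predicted class and class-probability vector per row.

    Probabilities are the softmax of the linear scores; the argmax tie
    breaks toward the lower class code (lower risk level).
    """
    F = np.atleast_2d(np.asarray(features, dtype=float))
    if F.shape[1] != model.feature_mean.shape[0]:
        raise ValueError(
            f"feature dimension {F.shape[1]} does not match training "
            f"dimension {model.feature_mean.shape[0]}"
        )
    Xd = np.column_stack(
        [np.ones(F.shape[0]), _prepare(F, model.feature_mean, model.feature_scale)]
    )
    P = _softmax(Xd @ model.weights)
    # classes are sorted ascending, argmax returns the first maximizer.
    return model.classes[np.argmax(P, axis=1)], P
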