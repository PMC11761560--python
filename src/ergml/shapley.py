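"""Interventional Shapley-value attribution.

The value of a coalition S for an instance x is the expected model output
when the features in S are fixed at x and the remaining features are drawn
from a background sample: v(S) = mean_b f(x_S, b_{~S}).  Two estimators are
provided:

* ``method="exact"`` enumerates all 2^p coalitions with the Shapley kernel
  weights — feasible for p up to ~15 and used as the high-precision path for
  small models.
* ``method="permutation"`` averages marginal contributions along randomly
  drawn feature orderings.  Because the contributions along one ordering
  telescope, the estimator satisfies local accuracy (additivity)
  phi.sum() = f(x) - E[f(X)] exactly for any number of permutations.

Both operate on an arbitrary scalar-valued ``predict`` callable, so the same
machinery explains probability outputs of any classifier family.
"""

from __future__ import annotations

from math import factorial
from typing import Callable

import numpy as np

__all__ = ["shapley_values", "model_shapley"]

Predict = Callable[[np.ndarray], np.ndarray]


def _coalition_value_matrix(
    predict: Predict, X: np.ndarray, background: np.ndarray, masks: np.ndarray
) -> np.ndarray:
    """v(S) for every instance (rows of X) and every mask (rows of masks).

    Returns an array of shape (n_masks, n_instances).  Model calls are
    batched: one predict() per mask over n_instances * n_background rows.
    """
    n_inst, p = X.shape
    n_bg = background.shape[0]
    out = np.empty((masks.shape[0], n_inst))
    tiled_bg = np.tile(background, (n_inst, 1))  # (n_inst*n_bg, p)
    for m_i, mask in enumerate(masks):
        z = tiled_bg.copy()
        if mask.any():
            rep = np.repeat(X[:, mask], n_bg, axis=0)
            z[:, mask] = rep
        vals = np.asarray(predict(z), dtype=float)
        out[m_i] = vals.reshape(n_inst, n_bg).mean(axis=1)
    return out


def _exact(predict: Predict, X: np.ndarray, background: np.ndarray) -> np.ndarray:
    n_inst, p = X.shape
    n_masks = 1 << p
    masks = np.zeros((n_masks, p), dtype=bool)
    for s in range(n_masks):
        for j in range(p):
            masks[s, j] = bool(s >> j & 1)
    v = _coalition_value_matrix(predict, X, background, masks)

    phi = np.zeros((n_inst, p))
    w = [factorial(s) * factorial(p - s - 1) / factorial(p) for s in range(p)]
    for s in range(n_masks):
        size = bin(s).count("1")
        for j in range(p):
            if s >> j & 1:
                continue
            phi[:, j] += w[size] * (v[s | (1 << j)] - v[s])
    return phi


def _permutation(
    predict: Predict,
    X: np.ndarray,
    background: np.ndarray,
    n_permutations: int,
    rng: np.random.Generator,
) -> np.ndarray:
    n_inst, p = X.shape
    phi = np.zeros((n_inst, p))
    half = max(n_permutations // 2, 1)
    for _ in range(half):
        order = rng.permutation(p)
        for perm in (order, order[::-1]):  # antithetic pair
            masks = np.zeros((p + 1, p), dtype=bool)
            for step, j in enumerate(perm):
                masks[step + 1] = masks[step]
                masks[step + 1, j] = True
            v = _coalition_value_matrix(predict, X, background, masks)
            for step, j in enumerate(perm):
                phi[:, j] += v[step + 1] - v[step]
    return phi / (2 * half)


def shapley_values(
    predict: Predict,
    X: np.ndarray,
    background: np.ndarray,
    method: str = "auto",
    n_permutations: int = 8,
    seed: int = 0,
    exact_max_features: int = 12,
) -> tuple[np.ndarray, float]:
    """Shapley attributions of a scalar model output.

    Parameters
    ----------
    predict
        Maps an (n, p) array to n scalar outputs (e.g. a class probability).
    X
        Instances to explain, shape (n_instances, p).
    background
        Reference sample defining the feature distribution, shape (m, p).
    method
        "exact", "permutation", or "auto" (exact when p <= exact_max_features).

    Returns
    -------
    (phi, base)
        ``phi`` with shape (n_instances, p) and the base value
        ``base = mean(predict(background))``.  For both estimators
        ``base + phi.sum(axis=1)`` equals the background-marginalised model
        output of each instance up to floating-point error.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    background = np.atleast_2d(np.asarray(background, dtype=float))
    if X.shape[1] != background.shape[1]:
        raise ValueError("X and background must have the same number of features")
    p = X.shape[1]
    if method == "auto":
        method = "exact" if p <= exact_max_features else "permutation"

    base = float(np.mean(np.asarray(predict(background), dtype=float)))
    if method == "exact":
        phi = _exact(predict, X, background)
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        phi = _permutation(predict, X, background, n_permutations, rng)
    else:
        raise ValueError(f"unknown method {method!r}")
    return phi, base


def model_shapley(
    model,
    X: np.ndarray,
    background: np.ndarray,
    class_index: int | None = None,
    **kwargs,
) -> tuple[np.ndarray, float]:
    """Shapley values of a classifier's predicted probability.

    ``class_index`` selects the class column of ``predict_proba``; defaults
    to the last class (the positive class for binary problems).
    """
    if not hasattr(model, "predict_proba"):
        raise ValueError(
            f"model {type(model).__name__} lacks predict_proba; a probability "
            "output is required for Shapley attribution"
        )
    n_classes = len(model.classes_)
    ci = n_classes - 1 if class_index is None else class_index

    def predict(z: np.ndarray) -> np.ndarray:
        return model.predict_proba(z)[:, ci]

    return shapley_values(predict, X, background, **kwargs)
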