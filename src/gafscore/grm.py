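"""Pure mathematics of the logistic graded response model.

All functions accept scalar or array ``theta`` and broadcast over it.  The
cumulative ("boundary") probability of responding in category k+1 or higher
is P*_k(theta) = logistic(a * theta + d_k); category probabilities are the
successive differences P(k) = P*_{k-1} - P*_k with P*_0 = 1 and P*_K = 0.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np
from scipy.special import expit

from .bank import ItemParameters, LoadingRecord

__all__ = [
    "cumulative_probabilities",
    "category_probabilities",
    "expected_item_score",
    "expected_test_score",
    "item_information",
    "test_information",
    "slope_to_loading",
    "loading_to_slope",
    "modal_category_set",
    "default_theta_grid",
    "LOGISTIC_SCALING",
]

#: Logistic/normal-ogive scaling constant used for the slope <-> loading map.
LOGISTIC_SCALING = 1.702


def default_theta_grid(lo: float = -6.0, hi: float = 6.0, step: float = 0.01) -> np.ndarray:
    """Default latent-trait grid for grid-based operations."""
    return np.linspace(lo, hi, int(round((hi - lo) / step)) + 1)


def _check_theta(theta) -> np.ndarray:
    theta = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(theta)):
        raise ValueError("theta must be finite")
    return theta


def cumulative_probabilities(item: ItemParameters, theta) -> np.ndarray:
    """Boundary probabilities P*_k(theta), shape ``theta.shape + (K-1,)``.

    Non-increasing in k for every theta (the intercepts are ordered).
    """
    theta = _check_theta(theta)
    d = np.asarray(item.d)
    return expit(item.a * theta[..., None] + d)


def category_probabilities(item: ItemParameters, theta) -> np.ndarray:
    """Category probabilities P(k), shape ``theta.shape + (K,)``; rows sum to 1."""
    theta = _check_theta(theta)
    pstar = cumulative_probabilities(item, theta)
    shape = theta.shape
    full = np.concatenate(
        [np.ones(shape + (1,)), pstar, np.zeros(shape + (1,))], axis=-1
    )
    return full[..., :-1] - full[..., 1:]


def expected_item_score(item: ItemParameters, theta) -> np.ndarray:
    """Expected score ES(theta) = sum_k k * P(k), on the 1..K metric."""
    p = category_probabilities(item, theta)
    k = np.arange(1, item.K + 1)
    return p @ k


def expected_test_score(bank: Sequence[ItemParameters], theta) -> np.ndarray:
    """Expected sum score over the bank."""
    if len(bank) == 0:
        raise ValueError("empty item bank")
    theta = _check_theta(theta)
    return sum(expected_item_score(it, theta) for it in bank)


def _boundary_weights(item: ItemParameters, theta) -> tuple[np.ndarray, np.ndarray]:
    """Category probs and padded boundary derivatives w_k = P*(1-P*)."""
    theta = _check_theta(theta)
    pstar = cumulative_probabilities(item, theta)
    shape = theta.shape
    full = np.concatenate(
        [np.ones(shape + (1,)), pstar, np.zeros(shape + (1,))], axis=-1
    )
    p = full[..., :-1] - full[..., 1:]
    w = full * (1.0 - full)  # zero at the padded boundaries
    return p, w


def item_information(item: ItemParameters, theta) -> np.ndarray:
    """Fisher information of one item.

    I(theta) = sum_k (dP(k)/dtheta)^2 / P(k), where
    dP(k)/dtheta = a * [w_{k-1} - w_k] and w_k = P*_k (1 - P*_k).
    Categories with vanishing probability contribute 0 (limit convention).
    """
    p, w = _boundary_weights(item, theta)
    dp = item.a * (w[..., :-1] - w[..., 1:])
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, dp * dp / np.where(p > 0, p, 1.0), 0.0)
    return terms.sum(axis=-1)


def test_information(bank: Sequence[ItemParameters], theta) -> np.ndarray:
    """Test information = sum of item informations."""
    if len(bank) == 0:
        raise ValueError("empty item bank")
    theta = _check_theta(theta)
    return sum(item_information(it, theta) for it in bank)


def slope_to_loading(a: float, scaling: float = LOGISTIC_SCALING) -> LoadingRecord:
    """Convert a logistic slope to a standardized factor loading.

    lambda = (a/D) / sqrt(1 + (a/D)^2) with D = 1.702, the constant that maps
    the logistic metric onto the normal-ogive metric underlying the loading.
    """
    if not np.isfinite(a):
        raise ValueError("slope must be finite")
    astar = a / scaling
    lam = astar / np.sqrt(1.0 + astar * astar)
    return LoadingRecord(lam=float(lam), h2=float(lam * lam))


def loading_to_slope(lam: float, scaling: float = LOGISTIC_SCALING) -> float:
    """Inverse of :func:`slope_to_loading`; requires |lambda| < 1."""
    if not np.isfinite(lam) or abs(lam) >= 1.0:
        raise ValueError("loading must satisfy |lambda| < 1")
    return float(scaling * lam / np.sqrt(1.0 - lam * lam))


def modal_category_set(item: ItemParameters, theta_grid=None) -> set[int]:
    """Categories that are the strictly most probable response somewhere.

    A category is modal at a grid point only when its probability strictly
    exceeds all others (ties excluded).  The grid must span at least [-6, 6].
    """
    if theta_grid is None:
        theta_grid = default_theta_grid()
    grid = np.asarray(theta_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty theta grid")
    if grid.min() > -6.0 + 1e-9 or grid.max() < 6.0 - 1e-9:
        raise ValueError("theta grid must span at least [-6, 6]")
    p = category_probabilities(item, grid)
    best = p.max(axis=1, keepdims=True)
    strict = (p >= best) & (np.sum(p >= best, axis=1, keepdims=True) == 1)
    return {int(k) + 1 for k in np.unique(np.nonzero(strict)[1])}
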