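"""Independent oracles shared by the test suite.

These deliberately avoid the package's optimizer and estimators: the grid
search below refines a brute-force mesh over parameter space, so agreement
with the Nelder-Mead fits is a genuine two-route check.
"""

from __future__ import annotations

import itertools

import numpy as np

from paceshape.mortality import log_likelihood

# broad transformed-parameter boxes per model: (low, high) per coordinate,
# log-scale for positive parameters, raw for the sign-free Gompertz rate b
_BOXES = {
    "exponential": [(-9.0, 0.0)],
    "weibull": [(-25.0, 0.0), (-2.0, 2.5)],  # log a, log b
    "gompertz": [(-18.0, 0.0), (-0.5, 1.0)],  # log a, b
    "logistic": [(-18.0, 0.0), (-0.5, 1.0), (-9.0, 2.5)],  # log a, b, log s
}


def _natural(model: str, theta: np.ndarray) -> np.ndarray:
    if model in ("exponential", "weibull"):
        return np.exp(theta)
    if model == "gompertz":
        return np.array([np.exp(theta[0]), theta[1]])
    return np.array([np.exp(theta[0]), theta[1], np.exp(theta[2])])


def grid_mle_loglik(
    model: str,
    lifespans,
    mode: str = "exact",
    n_grid: int = 13,
    rounds: int = 7,
) -> float:
    """Maximized log-likelihood by iteratively refined brute-force grid search."""
    boxes = [list(b) for b in _BOXES[model]]
    best_ll, best_theta = -np.inf, None
    for _ in range(rounds):
        axes = [np.linspace(lo, hi, n_grid) for lo, hi in boxes]
        for theta in itertools.product(*axes):
            theta = np.asarray(theta)
            ll = log_likelihood(model, _natural(model, theta), lifespans, mode)
            if ll > best_ll:
                best_ll, best_theta = ll, theta
        # zoom each axis to +/- 1.5 grid steps around the incumbent
        for d, (lo, hi) in enumerate(boxes):
            step = (hi - lo) / (n_grid - 1)
            boxes[d] = [best_theta[d] - 1.5 * step, best_theta[d] + 1.5 * step]
    return float(best_ll)


def lag1_correlation(y: np.ndarray) -> float:
    """Empirical lag-1 autocorrelation of a binary series."""
    y = np.asarray(y, dtype=float)
    return float(np.corrcoef(y[:-1], y[1:])[0, 1])
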