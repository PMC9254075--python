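"""Parametric mortality models: hazard, survivorship, likelihood, MLE, AICc.

Four standard demographic models of age-specific mortality are provided.
With age ``x`` in days and hazard ``mu(x)`` per day:

===========  ==========  =======================================  ==========================================
model        parameters  hazard mu(x)                             survivorship S(x)
===========  ==========  =======================================  ==========================================
exponential  b           b                                        exp(-b x)
gompertz     a, b        a e^{bx}                                 exp(-(a/b)(e^{bx} - 1))
weibull      a, b        a b x^{b-1}                              exp(-a x^b)
logistic     a, b, s     a e^{bx} / (1 + (a s/b)(e^{bx} - 1))     (1 + (a s/b)(e^{bx} - 1))^{-1/s}
===========  ==========  =======================================  ==========================================

The exponential model is the no-senescence reference (constant hazard).
The logistic model is a Gompertz hazard that decelerates to a plateau;
its ``s -> 0`` limit is the Gompertz model and is evaluated by a series
expansion for ``s < 1e-6``.  The Gompertz ``b -> 0`` limit likewise
reduces to the exponential.  These nestings imply the maximized
log-likelihoods are ordered logistic >= gompertz >= exponential.

Lifespans observed on a daily census can be treated as exact event times
(``mode="exact"``, the default: density ``mu(t) S(t)``) or as
interval-censored onto days (``mode="interval"``: mass ``S(t-1) - S(t)``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import optimize

MODEL_NAMES = ("exponential", "weibull", "gompertz", "logistic")
Mode = Literal["exact", "interval"]

#: s below this is treated as the Gompertz limit of the logistic model
_S_TINY = 1e-6
#: |b| below this is treated as the b -> 0 limit (constant hazard factor)
_B_TINY = 1e-12


class ParameterError(ValueError):
    """Model parameters outside their domain."""


@dataclass(frozen=True)
class MortalityModelSpec:
    """Name, parameter count and symbols of one mortality model."""

    name: str
    k: int
    param_names: tuple[str, ...]


MODEL_SPECS: dict[str, MortalityModelSpec] = {
    "exponential": MortalityModelSpec("exponential", 1, ("b",)),
    "weibull": MortalityModelSpec("weibull", 2, ("a", "b")),
    "gompertz": MortalityModelSpec("gompertz", 2, ("a", "b")),
    "logistic": MortalityModelSpec("logistic", 3, ("a", "b", "s")),
}


def _check_params(model: str, params: Sequence[float]) -> np.ndarray:
    if model not in MODEL_SPECS:
        raise ParameterError(f"unknown model {model!r}; expected one of {MODEL_NAMES}")
    p = np.asarray(params, dtype=float)
    spec = MODEL_SPECS[model]
    if p.shape != (spec.k,):
        raise ParameterError(
            f"{model} takes {spec.k} parameter(s) {spec.param_names}, got {p.shape}"
        )
    if not np.all(np.isfinite(p)):
        raise ParameterError(f"{model}: non-finite parameters {p}")
    if model == "exponential" and p[0] <= 0:
        raise ParameterError("exponential: b must be > 0")
    if model == "weibull" and (p[0] <= 0 or p[1] <= 0):
        raise ParameterError("weibull: a and b must be > 0")
    if model == "gompertz" and p[0] <= 0:
        raise ParameterError("gompertz: a must be > 0")
    if model == "logistic" and (p[0] <= 0 or p[2] < 0):
        raise ParameterError("logistic: a must be > 0 and s >= 0")
    return p


def _gomp_cumhaz(a: float, b: float, x: np.ndarray) -> np.ndarray:
    # (a/b)(e^{bx} - 1), continuous at b = 0 where it equals a*x
    if abs(b) < _B_TINY:
        return a * x
    return (a / b) * np.expm1(b * x)


def cumulative_hazard(model: str, params: Sequence[float], x) -> np.ndarray:
    """Integrated hazard H(x) = -log S(x)."""
    p = _check_params(model, params)
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("age must be >= 0")
    if model == "exponential":
        return p[0] * x
    if model == "gompertz":
        return _gomp_cumhaz(p[0], p[1], x)
    if model == "weibull":
        return p[0] * np.power(x, p[1])
    a, b, s = p
    # H = log1p(s * G)/s with G the Gompertz integrated hazard; as s -> 0
    # this reduces to G itself, and log1p keeps it accurate for tiny s*G
    g = _gomp_cumhaz(a, b, x)
    if s == 0.0:
        return g
    inner = s * g
    with np.errstate(invalid="ignore", over="ignore"):
        h = np.log1p(inner) / s
    h = np.where(inner <= -1.0, np.inf, h)
    return np.where(inner == 0.0, g, h)


def survivorship(model: str, params: Sequence[float], x) -> np.ndarray:
    """S(x): probability of surviving beyond age x; S(0) = 1, non-increasing."""
    return np.exp(-cumulative_hazard(model, params, x))


def hazard(model: str, params: Sequence[float], x) -> np.ndarray:
    """Instantaneous mortality rate mu(x) per day."""
    p = _check_params(model, params)
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("age must be >= 0")
    if model == "exponential":
        return np.full_like(x, p[0])
    if model == "gompertz":
        return p[0] * np.exp(p[1] * x)
    if model == "weibull":
        a, b = p
        if b < 1 and np.any(x == 0):
            raise ValueError("weibull hazard with b < 1 diverges at x = 0")
        return a * b * np.power(x, b - 1)
    a, b, s = p
    # denominator 1 + (a s / b)(e^{bx} - 1) = 1 + s * G, valid for all s >= 0
    with np.errstate(over="ignore"):
        return a * np.exp(b * x) / (1.0 + s * _gomp_cumhaz(a, b, x))


def log_likelihood(
    model: str, params: Sequence[float], lifespans: Sequence[int], mode: Mode = "exact"
) -> float:
    """Log-likelihood of observed lifespans under one mortality model.

    ``exact`` evaluates the density at the recorded day,
    sum(log mu(t) + log S(t)); ``interval`` treats a death recorded on day
    ``t`` as having occurred in ``(t-1, t]``, sum(log(S(t-1) - S(t))).
    Returns ``-inf`` (never raises) when any observation has zero or
    negative mass, so numerical optimizers can recover.
    """
    t_all = np.asarray(lifespans, dtype=float)
    if t_all.size == 0 or np.any(t_all <= 0):
        raise ValueError("lifespans must be positive")
    # daily lifespans repeat heavily; evaluating once per distinct value and
    # weighting by multiplicity gives an identical sum far faster
    t, counts = np.unique(t_all, return_counts=True)
    return _ll_aggregated(model, params, t, counts, mode)


def _ll_aggregated(
    model: str,
    params: Sequence[float],
    t: np.ndarray,
    counts: np.ndarray,
    mode: Mode,
) -> float:
    """log-likelihood over pre-aggregated (distinct value, multiplicity) pairs."""
    try:
        if mode == "exact":
            with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
                mu = hazard(model, params, t)
                h = cumulative_hazard(model, params, t)
                terms = np.log(mu) - h
        elif mode == "interval":
            with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
                mass = survivorship(model, params, t - 1.0) - survivorship(
                    model, params, t
                )
                terms = np.log(mass)
        else:
            raise ValueError(f"unknown likelihood mode {mode!r}")
    except ValueError as err:
        if "diverges" in str(err):
            return -math.inf
        raise
    if not np.all(np.isfinite(terms)):
        return -math.inf
    return float(np.dot(counts, terms))


def aicc(deviance: float, k: int, n: int) -> float:
    """Akaike information criterion with small-sample correction.

    AICc = deviance + 2k + 2k(k+1)/(n - k - 1), deviance = -2 log L.
    """
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return deviance + 2 * k + 2 * k * (k + 1) / (n - k - 1)


@dataclass
class MortalityFit:
    """A fitted mortality model with its information-criterion bookkeeping."""

    model: MortalityModelSpec
    params: np.ndarray
    loglik: float
    n: int
    converged: bool
    mode: Mode
    optimizer_report: str = ""

    @property
    def deviance(self) -> float:
        return -2.0 * self.loglik

    @property
    def aicc(self) -> float:
        return aicc(self.deviance, self.model.k, self.n)


# optimization runs on unconstrained coordinates; positive parameters are
# log-transformed, sign-free ones (the Gompertz/logistic rate b) are raw
def _to_natural(model: str, theta: np.ndarray) -> np.ndarray:
    if model == "exponential":
        return np.exp(theta)
    if model == "weibull":
        return np.exp(theta)
    if model == "gompertz":
        return np.array([math.exp(theta[0]), theta[1]])
    return np.array([math.exp(theta[0]), theta[1], math.exp(theta[2])])


def _start_points(
    model: str, t: np.ndarray, n_starts: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Moment-informed central start, nested-limit starts, seeded perturbations.

    Each model gets a deterministic start at its reduction to the simpler
    nested model (Gompertz/Weibull at the exponential limit, logistic at
    the Gompertz limit), which guarantees the maximized log-likelihoods
    respect the nesting hierarchy up to optimizer tolerance.
    """
    mean = float(np.mean(t))
    b_exp = 1.0 / mean
    centers = {
        "exponential": [math.log(b_exp)],
        "weibull": [math.log(b_exp) - 1.0, math.log(2.0)],
        "gompertz": [math.log(0.2 * b_exp), 0.1],
        "logistic": [math.log(0.2 * b_exp), 0.1, math.log(0.5)],
    }[model]
    nested = {
        "exponential": [],
        # b = 1 (constant hazard) at the exponential MLE rate
        "weibull": [[math.log(b_exp), 0.0]],
        # b -> 0 limit: hazard ~ a = exponential MLE rate
        "gompertz": [[math.log(b_exp), 1e-3]],
        # s -> 0 limit of the logistic is the Gompertz model
        "logistic": [
            [math.log(b_exp), 1e-3, math.log(1e-6)],
            [math.log(0.2 * b_exp), 0.1, math.log(1e-6)],
        ],
    }[model]
    center = np.array(centers)
    starts = [center] + [np.array(s) for s in nested]
    while len(starts) < n_starts:
        starts.append(center + rng.normal(scale=1.0, size=center.size))
    return starts


def fit_mortality(
    model: str,
    lifespans: Sequence[int],
    mode: Mode = "exact",
    n_starts: int = 20,
    seed: int = 0,
    tol: float = 1e-8,
    extra_starts: Sequence[Sequence[float]] = (),
) -> MortalityFit:
    """Maximum-likelihood fit of one mortality model by multi-start search.

    A Nelder-Mead search over unconstrained (log-transformed) coordinates is
    run from ``n_starts`` seeded starting points; the best terminal point is
    returned.  ``converged`` is True if at least one start terminated
    normally at the returned optimum.
    """
    spec = MODEL_SPECS[model]
    t = np.asarray(lifespans, dtype=float)
    if t.size < spec.k + 2:
        raise ValueError(
            f"need at least {spec.k + 2} lifespans to fit {model}, got {t.size}"
        )
    if spec.k > 1 and np.all(t == t[0]):
        raise ValueError(f"cannot fit {model}: all lifespans identical")

    # closed form for the exponential/exact case: b_hat = n / sum(t)
    if model == "exponential" and mode == "exact":
        b_hat = t.size / float(np.sum(t))
        ll = log_likelihood(model, [b_hat], t, mode)
        return MortalityFit(
            spec, np.array([b_hat]), ll, t.size, True, mode, "closed-form MLE"
        )

    rng = np.random.default_rng(seed)
    t_uniq, t_counts = np.unique(t, return_counts=True)

    def negll(theta: np.ndarray) -> float:
        p = _to_natural(model, theta)
        if not np.all(np.isfinite(p)):
            return math.inf
        return -_ll_aggregated(model, p, t_uniq, t_counts, mode)

    def _to_theta(p: np.ndarray) -> np.ndarray:
        if model in ("exponential", "weibull"):
            return np.log(p)
        if model == "gompertz":
            return np.array([math.log(p[0]), p[1]])
        return np.array([math.log(p[0]), p[1], math.log(max(p[2], 1e-12))])

    starts = _start_points(model, t, n_starts, rng)
    starts += [_to_theta(np.asarray(p, dtype=float)) for p in extra_starts]

    best = None
    best_ok = False
    for theta0 in starts:
        res = optimize.minimize(
            negll,
            theta0,
            method="Nelder-Mead",
            options={"xatol": 1e-7, "fatol": tol, "maxiter": 1200},
        )
        if not math.isfinite(res.fun):
            continue
        if best is None or res.fun < best.fun - 1e-12:
            best, best_ok = res, bool(res.success)
        elif abs(res.fun - best.fun) <= 1e-12 and res.success:
            best_ok = True
    if best is None:
        return MortalityFit(
            spec,
            np.full(spec.k, np.nan),
            -math.inf,
            t.size,
            False,
            mode,
            "all starts failed",
        )
    params = _to_natural(model, best.x)
    return MortalityFit(
        spec,
        params,
        -float(best.fun),
        t.size,
        best_ok,
        mode,
        f"Nelder-Mead, {n_starts} starts, nfev={best.nfev}",
    )


@dataclass
class ModelComparison:
    """AICc ranking of the four mortality models on one lifespan sample."""

    fits: dict[str, MortalityFit]
    delta_aicc: dict[str, float] = field(default_factory=dict)
    best: str = ""

    def table(self):
        """Comparison as a DataFrame ordered by AICc (Model, Parameters,
        Deviance, AICc, dAICc)."""
        import pandas as pd

        rows = [
            {
                "Model": name.capitalize(),
                "Parameters": f.model.k,
                "Deviance": f.deviance,
                "AICc": f.aicc,
                "dAICc": self.delta_aicc[name],
                "Converged": f.converged,
            }
            for name, f in self.fits.items()
        ]
        return (
            pd.DataFrame(rows)
            .sort_values(["AICc", "Parameters"])
            .reset_index(drop=True)
        )


def compare_models(
    lifespans: Sequence[int],
    mode: Mode = "exact",
    n_starts: int = 20,
    seed: int = 0,
) -> ModelComparison:
    """Fit all four mortality models and rank them by AICc.

    The best model is the converged fit with the lowest AICc; exact ties
    are broken in favor of fewer parameters (parsimony).  Each model is
    additionally started at its nested predecessor's fitted parameters
    (exponential -> gompertz -> logistic; exponential -> weibull), so the
    maximized log-likelihoods respect the nesting hierarchy.
    """
    fits: dict[str, MortalityFit] = {}
    fits["exponential"] = fit_mortality(
        "exponential", lifespans, mode, n_starts=n_starts, seed=seed
    )
    b_exp = fits["exponential"].params[0]
    fits["weibull"] = fit_mortality(
        "weibull",
        lifespans,
        mode,
        n_starts=n_starts,
        seed=seed,
        extra_starts=[(b_exp, 1.0)],
    )
    fits["gompertz"] = fit_mortality(
        "gompertz",
        lifespans,
        mode,
        n_starts=n_starts,
        seed=seed,
        extra_starts=[(b_exp, 1e-4)],
    )
    a_g, b_g = fits["gompertz"].params
    fits["logistic"] = fit_mortality(
        "logistic",
        lifespans,
        mode,
        n_starts=n_starts,
        seed=seed,
        extra_starts=[(a_g, b_g, 1e-7), (a_g, b_g, 0.5)],
    )
    converged = {n: f for n, f in fits.items() if f.converged}
    if not converged:
        raise RuntimeError("no mortality model converged")
    best = min(converged.values(), key=lambda f: (f.aicc, f.model.k)).model.name
    base = fits[best].aicc
    delta = {n: f.aicc - base for n, f in fits.items()}
    return ModelComparison(fits=fits, delta_aicc=delta, best=best)
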