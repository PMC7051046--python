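"""Discrete site-rate distributions and the equiprobable variance bound.

A continuous distribution of site-specific rate multipliers (most often a
unit-mean gamma) is routinely approximated by ``K`` equiprobable categories.
For any non-negative discrete random variable with mean ``mu`` taking ``K``
equiprobable values, the variance is bounded by ``(K - 1) * mu**2``, the raw
moment of order ``n`` by ``K**(n-1) * mu**n``, and hence the coefficient of
variation by ``sqrt(K - 1)``.  This module houses the discrete distributions
themselves, gamma discretization, moment summaries, and the bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammainc, gammaincinv
from scipy.optimize import minimize

__all__ = [
    "DiscreteRateDistribution",
    "GammaSpec",
    "MomentSummary",
    "discretize_gamma",
    "moments",
    "variance_upper_bound",
    "moment_upper_bound",
    "cv_upper_bound",
    "is_at_bound",
    "max_variance_equiprobable",
    "gamma_plugin_cv",
]

_WEIGHT_TOL = 1e-12


class InvalidParameterError(ValueError):
    """A distribution or bound was requested with an out-of-domain parameter."""


class ComputationError(RuntimeError):
    """A numerical routine failed to produce a usable result."""


class UndefinedCVError(ZeroDivisionError):
    """CV requested for a zero-mean distribution."""


@dataclass(frozen=True)
class DiscreteRateDistribution:
    """``K`` non-negative rate multipliers with probability weights.

    Rates are stored sorted ascending (``0 <= X_1 <= ... <= X_K``); weights
    are strictly positive and sum to one.  The ``equiprobable`` property is
    the structural condition under which the variance bound applies.
    """

    rates: tuple[float, ...]
    weights: tuple[float, ...]

    def __post_init__(self):
        r = np.asarray(self.rates, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if r.ndim != 1 or w.shape != r.shape or r.size == 0:
            raise InvalidParameterError("rates and weights must be equal-length 1-D")
        if np.any(r < 0):
            raise InvalidParameterError("rates must be non-negative")
        if np.any(np.diff(r) < 0):
            raise InvalidParameterError("rates must be sorted ascending")
        if np.any(w <= 0):
            raise InvalidParameterError("weights must be strictly positive")
        if abs(w.sum() - 1.0) > _WEIGHT_TOL:
            raise InvalidParameterError(f"weights sum to {w.sum()}, not 1")
        object.__setattr__(self, "rates", tuple(float(x) for x in r))
        object.__setattr__(self, "weights", tuple(float(x) for x in w))

    @classmethod
    def from_unsorted(cls, rates, weights) -> "DiscreteRateDistribution":
        """Build from unsorted categories, sorting jointly by rate."""
        order = np.argsort(np.asarray(rates, dtype=float), kind="stable")
        r = np.asarray(rates, dtype=float)[order]
        w = np.asarray(weights, dtype=float)[order]
        return cls(tuple(r), tuple(w / w.sum()))

    @classmethod
    def equiprobable_from_rates(cls, rates) -> "DiscreteRateDistribution":
        k = len(rates)
        return cls(tuple(sorted(float(x) for x in rates)), (1.0 / k,) * k)

    @property
    def k(self) -> int:
        return len(self.rates)

    @property
    def equiprobable(self) -> bool:
        return all(abs(w - 1.0 / self.k) <= _WEIGHT_TOL for w in self.weights)

    @property
    def mean(self) -> float:
        return float(np.dot(self.rates, self.weights))

    @property
    def variance(self) -> float:
        r = np.asarray(self.rates)
        return float(np.dot(self.weights, r * r) - self.mean**2)

    @property
    def cv(self) -> float:
        m = self.mean
        if m <= 0:
            raise UndefinedCVError("CV undefined for zero-mean distribution")
        return float(np.sqrt(max(self.variance, 0.0)) / m)

    def rescaled_to_mean(self, mu: float = 1.0) -> "DiscreteRateDistribution":
        m = self.mean
        if m <= 0:
            raise UndefinedCVError("cannot rescale a zero-mean distribution")
        return DiscreteRateDistribution(
            tuple(x * mu / m for x in self.rates), self.weights
        )

    def to_json_dict(self) -> dict:
        return {"rates": list(self.rates), "weights": list(self.weights)}

    @classmethod
    def from_json_dict(cls, obj: dict) -> "DiscreteRateDistribution":
        return cls(tuple(obj["rates"]), tuple(obj["weights"]))


@dataclass(frozen=True)
class GammaSpec:
    """Unit-mean gamma with shape ``alpha`` (rate parameter equals ``alpha``).

    The continuous CV is ``1 / sqrt(alpha)``.
    """

    alpha: float

    def __post_init__(self):
        if not (self.alpha > 0):
            raise InvalidParameterError(f"alpha must be > 0, got {self.alpha}")

    @property
    def continuous_cv(self) -> float:
        return 1.0 / np.sqrt(self.alpha)


@dataclass(frozen=True)
class MomentSummary:
    mean: float
    variance: float
    raw_moments: dict = field(default_factory=dict)
    cv: float = float("nan")


def discretize_gamma(
    spec: GammaSpec, k: int, method: str = "interval_mean"
) -> DiscreteRateDistribution:
    """Discretize a unit-mean gamma into ``k`` equiprobable categories.

    ``interval_mean`` represents category ``i`` by the conditional mean of
    the gamma on the quantile interval ``((i-1)/k, i/k]``, computed via the
    regularized incomplete gamma function with shape ``alpha + 1``;
    ``interval_median`` uses the ``(2i-1)/(2k)`` quantile.  Either way the
    result is renormalized so the weighted mean is exactly 1 (the bound
    statements all hold the mean fixed).
    """
    if isinstance(spec, (int, float)):
        spec = GammaSpec(float(spec))
    if not (isinstance(k, (int, np.integer)) and k >= 1):
        raise InvalidParameterError(f"k must be a positive integer, got {k}")
    a = spec.alpha
    if k == 1:
        return DiscreteRateDistribution((1.0,), (1.0,))
    with np.errstate(all="ignore"):
        if method == "interval_mean":
            edges = gammaincinv(a, np.arange(1, k) / k) / a
            f1 = gammainc(a + 1.0, a * edges)
            f1 = np.concatenate(([0.0], f1, [1.0]))
            rates = k * np.diff(f1)
        elif method == "interval_median":
            q = (2.0 * np.arange(1, k + 1) - 1.0) / (2.0 * k)
            rates = gammaincinv(a, q) / a
        else:
            raise InvalidParameterError(f"unknown discretization method {method!r}")
    if not np.all(np.isfinite(rates)) or np.any(rates < 0):
        raise ComputationError(
            f"incomplete-gamma evaluation failed for alpha={a}, k={k}"
        )
    m = rates.mean()
    if m <= 0:
        raise ComputationError(f"degenerate discretization for alpha={a}, k={k}")
    rates = np.sort(rates / m)
    return DiscreteRateDistribution(tuple(rates), (1.0 / k,) * k)


def moments(dist: DiscreteRateDistribution, max_order: int = 2) -> MomentSummary:
    """Raw moments ``E(X^n) = sum_i w_i x_i^n`` up to ``max_order``, plus CV."""
    if max_order < 1:
        raise InvalidParameterError("max_order must be >= 1")
    r = np.asarray(dist.rates)
    w = np.asarray(dist.weights)
    raw = {n: float(np.dot(w, r**n)) for n in range(1, max_order + 1)}
    mean = raw[1]
    e2 = raw.get(2, float(np.dot(w, r * r)))
    var = max(e2 - mean**2, 0.0)
    cv = float(np.sqrt(var) / mean) if mean > 0 else float("nan")
    return MomentSummary(mean=mean, variance=var, raw_moments=raw, cv=cv)


def _check_k(k) -> int:
    if not (isinstance(k, (int, np.integer)) and k >= 1):
        raise InvalidParameterError(f"k must be an integer >= 1, got {k}")
    return int(k)


def variance_upper_bound(k: int, mu: float) -> float:
    """Largest possible variance of a K-point equiprobable non-negative
    distribution with mean ``mu``: ``(K - 1) * mu**2``."""
    k = _check_k(k)
    if mu < 0:
        raise InvalidParameterError("mu must be non-negative")
    return (k - 1) * mu**2


def moment_upper_bound(k: int, mu: float, n: int) -> float:
    """Bound on the raw moment of order ``n``: ``K**(n-1) * mu**n``."""
    k = _check_k(k)
    if mu < 0:
        raise InvalidParameterError("mu must be non-negative")
    if not (isinstance(n, (int, np.integer)) and n >= 1):
        raise InvalidParameterError(f"n must be an integer >= 1, got {n}")
    return float(k ** (n - 1) * mu**n)


def cv_upper_bound(k: int) -> float:
    """Largest possible CV under equiprobable discretization: ``sqrt(K - 1)``."""
    k = _check_k(k)
    return float(np.sqrt(k - 1))


def is_at_bound(dist: DiscreteRateDistribution, relative_tolerance: float = 1e-3) -> bool:
    """Whether an equiprobable distribution's CV has (numerically) reached
    the ``sqrt(K - 1)`` ceiling.

    Fitted distributions land very close to — but, in floating point, not
    exactly on — the bound, so saturation is judged with a small relative
    tolerance.
    """
    if not dist.equiprobable:
        raise InvalidParameterError("at-bound test is defined for equiprobable distributions")
    if not (0 < relative_tolerance < 0.1):
        raise InvalidParameterError("relative_tolerance must lie in (0, 0.1)")
    return dist.cv >= (1.0 - relative_tolerance) * cv_upper_bound(dist.k)


def gamma_plugin_cv(spec: GammaSpec) -> float:
    """Plug-in CV ``1/sqrt(alpha)`` of the *continuous* gamma.

    Deliberately a separate name: the package's reported CVs come from the
    discretized distribution itself, which is what the bound constrains.
    """
    if isinstance(spec, (int, float)):
        spec = GammaSpec(float(spec))
    return spec.continuous_cv


def max_variance_equiprobable(
    k: int, mu: float, n_starts: int = 24, seed: int = 0
) -> tuple[float, DiscreteRateDistribution]:
    """Numerically maximize variance over equiprobable K-point non-negative
    distributions with fixed mean ``mu``.

    Brute-force oracle for the analytic bound: multi-start SLSQP on the
    simplex ``{x >= 0, sum x = K mu}`` maximizing ``sum x_i^2 / K - mu^2``.
    The objective is convex, so the maximum sits at a vertex — all mass on
    one support point, ``(0, ..., 0, K mu)``.
    """
    k = _check_k(k)
    if not (2 <= k <= 6):
        raise InvalidParameterError("oracle implemented for K in [2, 6]")
    if not (mu > 0):
        raise InvalidParameterError("mu must be positive")
    rng = np.random.default_rng(seed)
    total = k * mu

    def neg_var(x):
        return -(np.dot(x, x) / k - mu**2)

    def neg_var_grad(x):
        return -2.0 * x / k

    cons = {"type": "eq", "fun": lambda x: x.sum() - total,
            "jac": lambda x: np.ones(k)}
    best_val, best_x = -np.inf, None
    for s in range(n_starts):
        x0 = rng.dirichlet(np.ones(k)) * total if s else np.full(k, mu)
        res = minimize(
            neg_var, x0, jac=neg_var_grad, method="SLSQP",
            bounds=[(0.0, total)] * k, constraints=[cons],
            options={"maxiter": 200, "ftol": 1e-14},
        )
        if res.success and -res.fun > best_val:
            best_val, best_x = -res.fun, res.x
    if best_x is None:
        raise ComputationError(f"SLSQP failed to converge for k={k}, mu={mu}")
    best_x = np.clip(best_x, 0.0, None)
    best_x *= total / best_x.sum()
    dist = DiscreteRateDistribution.equiprobable_from_rates(best_x)
    return float(best_val), dist
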