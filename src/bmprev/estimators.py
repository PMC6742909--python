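"""Point estimators for the benchmark-multiplier method.

The benchmark-multiplier method estimates the size of a disease population
from two quantities: the absolute size of a well-enumerated subgroup (the
*benchmark*, ``N_x``) and that subgroup's share of the whole disease
population (the *multiplier*, ``pi``), estimated from a sample of size ``n``
taken to reflect the target population.  The naive estimator is the ratio
``N_x / pi``; because ``pi`` is itself estimated, the ratio is biased
upward and a finite-sample correction of order ``1/n`` is subtracted::

    total = N_x / pi - (1/n) * N_x * (1/pi - 1)

Totals are converted to a rate per 100,000 persons at risk for reporting.

All functions here are pure scalar/array computations; estimates are kept
as real numbers, with rounding to whole persons applied only at the
reporting stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "EstimationInputs",
    "naive_estimate",
    "bias_corrected_estimate",
    "per_100k",
]


def _check_multiplier(multiplier_fraction) -> None:
    m = np.asarray(multiplier_fraction, dtype=float)
    if np.any(m <= 0.0) or np.any(m > 1.0):
        raise ValueError(
            f"multiplier_fraction must lie in (0, 1], got {multiplier_fraction!r}"
        )


def _check_benchmark(benchmark_count) -> None:
    b = np.asarray(benchmark_count, dtype=float)
    if np.any(b < 0.0):
        raise ValueError(f"benchmark_count must be >= 0, got {benchmark_count!r}")


def naive_estimate(benchmark_count, multiplier_fraction):
    """Naive benchmark-multiplier estimate of the total disease population.

    Parameters
    ----------
    benchmark_count : float or array_like
        Size of the specific subgroup (``N_x``), persons. Must be >= 0.
    multiplier_fraction : float or array_like
        The subgroup's share of the disease population (``pi``), in (0, 1].

    Returns
    -------
    float or ndarray
        ``benchmark_count / multiplier_fraction``; always at least
        ``benchmark_count``.
    """
    _check_benchmark(benchmark_count)
    _check_multiplier(multiplier_fraction)
    out = np.asarray(benchmark_count, dtype=float) / np.asarray(
        multiplier_fraction, dtype=float
    )
    return float(out) if out.ndim == 0 else out


def bias_corrected_estimate(benchmark_count, multiplier_fraction, multiplier_sample_size):
    """Bias-corrected benchmark-multiplier estimate.

    Subtracts the finite-sample correction term
    ``(1/n) * N_x * (1/pi - 1)`` from the naive ratio, where ``n`` is the
    sample size of the multiplier dataset.  The result never exceeds the
    naive estimate and equals it when ``pi == 1`` (the correction term
    vanishes).  A correction that would drive the estimate below zero
    (possible only for very small ``n`` and ``pi``) is floored at 0 with a
    warning, since a negative person-count is meaningless.

    Parameters
    ----------
    benchmark_count : float or array_like
        Size of the specific subgroup (``N_x``), persons.
    multiplier_fraction : float or array_like
        The subgroup's share of the disease population (``pi``), in (0, 1].
    multiplier_sample_size : int
        Size ``n`` of the multiplier dataset; must be >= 1.

    Returns
    -------
    float or ndarray
        The bias-corrected total count estimate.
    """
    _check_benchmark(benchmark_count)
    _check_multiplier(multiplier_fraction)
    n = multiplier_sample_size
    if not np.all(np.asarray(n) >= 1):
        raise ValueError(f"multiplier_sample_size must be >= 1, got {n!r}")
    b = np.asarray(benchmark_count, dtype=float)
    m = np.asarray(multiplier_fraction, dtype=float)
    est = b / m - (b * (1.0 / m - 1.0)) / np.asarray(n, dtype=float)
    if np.any(est < 0.0):
        warnings.warn(
            "bias-corrected estimate fell below zero and was floored at 0 "
            "(tiny multiplier sample combined with a tiny multiplier fraction)",
            RuntimeWarning,
            stacklevel=2,
        )
        est = np.maximum(est, 0.0)
    return float(est) if np.ndim(est) == 0 else est


def per_100k(total_count, population_at_risk):
    """Convert a total count into a rate per 100,000 persons at risk."""
    p = np.asarray(population_at_risk, dtype=float)
    if np.any(p <= 0.0):
        raise ValueError(f"population_at_risk must be > 0, got {population_at_risk!r}")
    out = np.asarray(total_count, dtype=float) / p * 100_000.0
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class EstimationInputs:
    """The four scalar inputs of a benchmark-multiplier estimation.

    Attributes
    ----------
    benchmark_count : float
        ``N_x``, persons in the specific subgroup (>= 0).
    multiplier_fraction : float
        ``pi``, the subgroup's share of the disease population, in (0, 1].
    multiplier_sample_size : int
        ``n``, the size of the multiplier dataset (>= 1).
    population_at_risk : float
        Target-population size, persons (> 0).
    """

    benchmark_count: float
    multiplier_fraction: float
    multiplier_sample_size: int
    population_at_risk: float

    def __post_init__(self) -> None:
        _check_benchmark(self.benchmark_count)
        _check_multiplier(self.multiplier_fraction)
        if self.multiplier_sample_size < 1:
            raise ValueError(
                f"multiplier_sample_size must be >= 1, got {self.multiplier_sample_size}"
            )
        if self.population_at_risk <= 0:
            raise ValueError(
                f"population_at_risk must be > 0, got {self.population_at_risk}"
            )

    def naive(self) -> float:
        return naive_estimate(self.benchmark_count, self.multiplier_fraction)

    def bias_corrected(self) -> float:
        return bias_corrected_estimate(
            self.benchmark_count, self.multiplier_fraction, self.multiplier_sample_size
        )

    def rate_per_100k(self) -> float:
        return per_100k(self.bias_corrected(), self.population_at_risk)
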