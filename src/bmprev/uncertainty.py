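"""Monte Carlo uncertainty propagation for the benchmark-multiplier estimate.

Both estimation parameters — the benchmark count ``N_x`` and the multiplier
fraction ``pi`` — carry uncertainty that is not captured by a single point
value.  Each is therefore described by a sampling distribution (uniform,
centred on the point value with a relative half-width ``delta``), the
estimation is carried out separately per disease-duration stratum, the
stratum estimates are summed into the total, and the whole process is
repeated many times.  The percentiles of the resulting replicate
distribution form the reported interval.

Stream layout
-------------
One root seed governs the whole run.  Each (stratum, parameter) pair draws
from its own substream derived deterministically from
``SeedSequence(seed, spawn_key=(stratum_index, parameter_index))``, so
adding or removing a stratum never perturbs the draws of the others.  In
``shared`` mode a single unit deviation per parameter (drawn from a
dedicated substream) is applied to every stratum's centre.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .estimators import bias_corrected_estimate

__all__ = [
    "UncertaintySpec",
    "BenchmarkStratum",
    "PrevalenceDistribution",
    "IntervalSummary",
    "draw_parameter",
    "run_resampling",
    "summarize",
]

#: spawn-key namespace for the shared-deviation streams; far above any
#: realistic stratum index, so the two namespaces can never collide.
_SHARED_KEY = 1 << 20

_SIZE, _MULTIPLIER = 0, 1

_SHARING_ALIASES = {
    "independent": "independent",
    "per-stratum-independent": "independent",
    "shared": "shared",
    "shared-across-strata": "shared",
}


@dataclass(frozen=True)
class UncertaintySpec:
    """A uniform sampling distribution for one uncertain parameter.

    Values are drawn uniformly from
    ``[center * (1 - relative_half_width), center * (1 + relative_half_width)]``.
    ``relative_half_width = 0`` degenerates to the point value.
    """

    center: float
    relative_half_width: float = 0.0
    family: str = "uniform"

    def __post_init__(self) -> None:
        if self.center <= 0:
            raise ValueError(f"center must be > 0, got {self.center}")
        if self.relative_half_width < 0:
            raise ValueError(
                f"relative_half_width must be >= 0, got {self.relative_half_width}"
            )
        if self.family != "uniform":
            raise ValueError(
                f"unsupported sampling family {self.family!r}; supported: 'uniform'"
            )

    @property
    def support(self) -> tuple[float, float]:
        d = self.relative_half_width
        return (self.center * (1.0 - d), self.center * (1.0 + d))

    def from_unit_deviation(self, u):
        """Map unit deviation(s) ``u`` in [-1, 1] onto the support."""
        return self.center * (1.0 + self.relative_half_width * np.asarray(u))


def draw_parameter(spec: UncertaintySpec, rng: np.random.Generator) -> float:
    """Draw one value from ``spec``, advancing ``rng`` deterministically."""
    return float(spec.from_unit_deviation(rng.uniform(-1.0, 1.0)))


@dataclass(frozen=True)
class BenchmarkStratum:
    """One disease-duration stratum of the estimation.

    Carries the stratum's benchmark-size distribution and its multiplier
    distribution; the multiplier centre must lie in (0, 1].
    """

    label: str
    size_spec: UncertaintySpec
    multiplier_spec: UncertaintySpec

    def __post_init__(self) -> None:
        if not (0.0 < self.multiplier_spec.center <= 1.0):
            raise ValueError(
                f"stratum {self.label!r}: multiplier center must be in (0, 1], "
                f"got {self.multiplier_spec.center}"
            )


@dataclass(frozen=True)
class PrevalenceDistribution:
    """Replicate totals from a resampling run, with its provenance."""

    replicate_totals: np.ndarray
    replicates: int
    seed: int
    sharing_mode: str = "independent"

    def __post_init__(self) -> None:
        totals = np.asarray(self.replicate_totals, dtype=float)
        object.__setattr__(self, "replicate_totals", totals)
        if totals.shape != (self.replicates,):
            raise ValueError(
                f"replicate_totals has length {totals.shape}, expected ({self.replicates},)"
            )

    def quantile(self, q) -> float | np.ndarray:
        out = np.quantile(self.replicate_totals, q, method="linear")
        return float(out) if np.ndim(out) == 0 else out


@dataclass(frozen=True)
class IntervalSummary:
    """Empirical percentile interval (lower, median, upper) at a level."""

    level: float
    lower: float
    median: float
    upper: float

    def __post_init__(self) -> None:
        if not (self.lower <= self.median <= self.upper):
            raise ValueError("interval must satisfy lower <= median <= upper")

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def rounded(self, multiple: int = 50) -> "IntervalSummary":
        """Display rounding of all three points to the nearest multiple."""

        def r(x: float) -> float:
            return float(multiple * np.floor(x / multiple + 0.5))

        return IntervalSummary(self.level, r(self.lower), r(self.median), r(self.upper))


def _normalize_sharing(sharing_mode: str) -> str:
    try:
        return _SHARING_ALIASES[sharing_mode]
    except KeyError:
        raise ValueError(
            f"unknown sharing_mode {sharing_mode!r}; "
            f"expected one of {sorted(_SHARING_ALIASES)}"
        ) from None


def _substream(seed: int, *spawn_key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=spawn_key))


def run_resampling(
    strata: Sequence[BenchmarkStratum],
    multiplier_sample_size: int,
    replicates: int,
    seed: int,
    sharing_mode: str = "independent",
) -> PrevalenceDistribution:
    """Propagate parameter uncertainty through the stratified estimation.

    Per replicate, every stratum's benchmark count and multiplier fraction
    are drawn from their uniform distributions (independently per stratum
    in ``independent`` mode; from one shared unit deviation per parameter
    in ``shared`` mode), the bias-corrected estimate is computed per
    stratum with ``n = multiplier_sample_size``, and the stratum estimates
    are summed into the replicate total.

    Parameters
    ----------
    strata : sequence of BenchmarkStratum
        At least one stratum; multiplier centres must be in (0, 1].
    multiplier_sample_size : int
        ``n`` of the bias correction, held fixed across strata and
        replicates.
    replicates : int
        Number of Monte Carlo repetitions (>= 1).
    seed : int
        Root seed; identical (strata, n, replicates, seed, sharing_mode)
        reproduce the replicate totals bit-for-bit.
    sharing_mode : {'independent', 'shared'}
        Aliases 'per-stratum-independent' and 'shared-across-strata' are
        accepted.
    """
    if len(strata) == 0:
        raise ValueError("run_resampling requires at least one stratum")
    labels = [s.label for s in strata]
    if len(set(labels)) != len(labels):
        raise ValueError(f"stratum labels must be unique, got {labels}")
    if replicates < 1:
        raise ValueError(f"replicates must be >= 1, got {replicates}")
    mode = _normalize_sharing(sharing_mode)

    if mode == "shared":
        u_size = _substream(seed, _SHARED_KEY, _SIZE).uniform(-1.0, 1.0, replicates)
        u_mult = _substream(seed, _SHARED_KEY, _MULTIPLIER).uniform(-1.0, 1.0, replicates)

    totals = np.zeros(replicates, dtype=float)
    for i, stratum in enumerate(strata):
        if mode == "independent":
            us = _substream(seed, i, _SIZE).uniform(-1.0, 1.0, replicates)
            um = _substream(seed, i, _MULTIPLIER).uniform(-1.0, 1.0, replicates)
        else:
            us, um = u_size, u_mult
        sizes = stratum.size_spec.from_unit_deviation(us)
        fractions = stratum.multiplier_spec.from_unit_deviation(um)
        # multiplier support may brush 1.0 exactly but never exceed it for
        # valid specs (center <= 1 requires center*(1+delta) <= 1 only when
        # delta > 0); clip defensively against float round-off.
        fractions = np.clip(fractions, None, 1.0)
        totals += bias_corrected_estimate(sizes, fractions, multiplier_sample_size)

    return PrevalenceDistribution(
        replicate_totals=totals,
        replicates=replicates,
        seed=seed,
        sharing_mode=mode,
    )


def summarize(distribution: PrevalenceDistribution, level: float = 0.95) -> IntervalSummary:
    """Empirical percentile interval of the replicate distribution.

    Uses linear interpolation between order statistics (the same
    convention as ``numpy.quantile(..., method='linear')``); the interval
    endpoints are the (1-level)/2 and 1-(1-level)/2 percentiles.
    """
    totals = distribution.replicate_totals
    if totals.size == 0:
        raise ValueError("cannot summarize an empty distribution")
    if not (0.0 < level < 1.0):
        raise ValueError(f"level must be in (0, 1), got {level}")
    alpha = (1.0 - level) / 2.0
    lower, median, upper = np.quantile(
        totals, [alpha, 0.5, 1.0 - alpha], method="linear"
    )
    return IntervalSummary(level=level, lower=float(lower), median=float(median), upper=float(upper))
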