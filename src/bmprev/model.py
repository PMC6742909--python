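"""Benchmark-multiplier prevalence model with Monte Carlo uncertainty.

The model is specified by a set of disease-duration strata (each carrying a
uniform sampling distribution for its benchmark count and for the
multiplier fraction), the multiplier sample size ``n`` and, optionally, the
target-population size.  ``fit()`` runs the stratified resampling and
returns a results object holding the replicate distribution, percentile
intervals, rates per 100,000 and a text summary.

Typical use::

    model = BenchmarkMultiplierModel.from_estimates(
        benchmark_count=9_503, multiplier_fraction=0.621,
        multiplier_sample_size=1_567, population_at_risk=8_420_000,
        n_strata=5,
    )
    res = model.fit(replicates=100_000, seed=12345)
    print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .estimators import bias_corrected_estimate, naive_estimate, per_100k
from .registry import (
    DMT_LAST_12_MONTHS,
    RegistryDataset,
    SubgroupExtraction,
    augment_benchmark,
    extract_subgroup,
)
from .uncertainty import (
    BenchmarkStratum,
    IntervalSummary,
    PrevalenceDistribution,
    UncertaintySpec,
    run_resampling,
    summarize,
)

__all__ = [
    "BenchmarkMultiplierModel",
    "BenchmarkMultiplierResults",
    "build_duration_strata",
]


def build_duration_strata(
    benchmark: RegistryDataset,
    multiplier_center: float,
    band_years: int = 5,
    delta_benchmark: float = 0.05,
    delta_multiplier: float = 0.05,
) -> list[BenchmarkStratum]:
    """Split a benchmark dataset into disease-duration strata.

    Records are binned into ``band_years``-wide duration bands; each
    nonempty band becomes a stratum whose benchmark-size centre is the band
    count and whose multiplier centre is the (global) ``multiplier_center``.
    Records with unknown duration form their own ``unknown`` stratum.
    """
    if band_years < 1:
        raise ValueError(f"band_years must be >= 1, got {band_years}")
    dur = benchmark.df.get("disease_duration_years")
    if dur is None:
        counts = {"all durations": len(benchmark.df)}
    else:
        dur = pd.to_numeric(dur, errors="coerce")
        known = dur.dropna()
        bands = (known // band_years).astype(int)
        counts = {
            f"{b * band_years}-{(b + 1) * band_years} y": int(c)
            for b, c in bands.value_counts().sort_index().items()
        }
        n_unknown = int(dur.isna().sum())
        if n_unknown:
            counts["unknown duration"] = n_unknown
    strata = [
        BenchmarkStratum(
            label=label,
            size_spec=UncertaintySpec(count, delta_benchmark),
            multiplier_spec=UncertaintySpec(multiplier_center, delta_multiplier),
        )
        for label, count in counts.items()
        if count > 0
    ]
    if not strata:
        raise ValueError(f"{benchmark.source_name}: no nonempty duration stratum")
    return strata


class BenchmarkMultiplierModel:
    """Stratified benchmark-multiplier model of a disease population size.

    Parameters
    ----------
    strata : sequence of BenchmarkStratum
        Disease-duration strata; stratum benchmark-size centres sum to the
        overall benchmark count.
    multiplier_sample_size : int
        ``n`` of the bias correction (size of the multiplier dataset),
        held fixed across strata and replicates.
    population_at_risk : float, optional
        Target-population size; required for rates per 100,000.
    sharing_mode : {'independent', 'shared'}
        Whether each stratum draws its own parameter deviations per
        replicate (default) or all strata share one deviation per
        parameter.
    """

    def __init__(
        self,
        strata: Sequence[BenchmarkStratum],
        multiplier_sample_size: int,
        population_at_risk: float | None = None,
        sharing_mode: str = "independent",
    ) -> None:
        if len(strata) == 0:
            raise ValueError("model needs at least one stratum")
        if multiplier_sample_size < 1:
            raise ValueError(
                f"multiplier_sample_size must be >= 1, got {multiplier_sample_size}"
            )
        if population_at_risk is not None and population_at_risk <= 0:
            raise ValueError(f"population_at_risk must be > 0, got {population_at_risk}")
        self.strata = list(strata)
        self.multiplier_sample_size = int(multiplier_sample_size)
        self.population_at_risk = population_at_risk
        self.sharing_mode = sharing_mode
        self.diagnostics: dict = {}

    # ------------------------------------------------------------------
    # constructors
    # ------------------------------------------------------------------
    @classmethod
    def from_estimates(
        cls,
        benchmark_count: float,
        multiplier_fraction: float,
        multiplier_sample_size: int,
        population_at_risk: float | None = None,
        delta_benchmark: float = 0.05,
        delta_multiplier: float = 0.05,
        n_strata: int = 1,
        stratum_weights: Sequence[float] | None = None,
        sharing_mode: str = "independent",
    ) -> "BenchmarkMultiplierModel":
        """Build a model directly from summary parameters.

        The benchmark count is split over ``n_strata`` equal strata, or
        according to ``stratum_weights`` when given (weights are
        normalised).  A single global multiplier centre is applied to every
        stratum.
        """
        if stratum_weights is None:
            if n_strata < 1:
                raise ValueError(f"n_strata must be >= 1, got {n_strata}")
            stratum_weights = [1.0] * n_strata
        w = np.asarray(stratum_weights, dtype=float)
        if np.any(w <= 0):
            raise ValueError("stratum_weights must be positive")
        w = w / w.sum()
        strata = [
            BenchmarkStratum(
                label=f"stratum {i + 1}",
                size_spec=UncertaintySpec(benchmark_count * wi, delta_benchmark),
                multiplier_spec=UncertaintySpec(multiplier_fraction, delta_multiplier),
            )
            for i, wi in enumerate(w)
        ]
        return cls(strata, multiplier_sample_size, population_at_risk, sharing_mode)

    @classmethod
    def from_datasets(
        cls,
        multiplier: RegistryDataset,
        benchmark: RegistryDataset,
        reference: RegistryDataset | None = None,
        *,
        predicate=DMT_LAST_12_MONTHS,
        population_at_risk: float | None = None,
        augment_strata: Sequence[str] = ("region",),
        duration_band_years: int = 5,
        delta_benchmark: float = 0.05,
        delta_multiplier: float = 0.05,
        sharing_mode: str = "independent",
    ) -> "BenchmarkMultiplierModel":
        """Build a model from registry datasets.

        The multiplier fraction and its sample size come from applying the
        subgroup ``predicate`` to the ``multiplier`` dataset.  When a
        ``reference`` dataset (with an ``in_benchmark`` flag) is given, the
        benchmark is first augmented by per-cell inverse-coverage
        replication over ``augment_strata``; the (augmented) benchmark is
        then split into disease-duration strata.
        """
        extraction: SubgroupExtraction = extract_subgroup(multiplier, predicate)
        if extraction.share <= 0:
            raise ValueError(
                f"{multiplier.source_name}: subgroup share is 0; cannot form a multiplier"
            )
        if reference is not None:
            benchmark = augment_benchmark(benchmark, reference, augment_strata)
        strata = build_duration_strata(
            benchmark,
            multiplier_center=extraction.share,
            band_years=duration_band_years,
            delta_benchmark=delta_benchmark,
            delta_multiplier=delta_multiplier,
        )
        model = cls(strata, extraction.n, population_at_risk, sharing_mode)
        model.diagnostics = {
            "multiplier_source": multiplier.source_name,
            "benchmark_source": benchmark.source_name,
            "multiplier_share": extraction.share,
            "multiplier_n": extraction.n,
            "multiplier_excluded": extraction.n_excluded,
            "benchmark_total": len(benchmark),
        }
        return model

    # ------------------------------------------------------------------
    # point estimates
    # ------------------------------------------------------------------
    @property
    def benchmark_total(self) -> float:
        return float(sum(s.size_spec.center for s in self.strata))

    @property
    def point_estimate(self) -> float:
        """Sum of per-stratum bias-corrected estimates at the centres."""
        return float(
            sum(
                bias_corrected_estimate(
                    s.size_spec.center,
                    s.multiplier_spec.center,
                    self.multiplier_sample_size,
                )
                for s in self.strata
            )
        )

    @property
    def naive_point_estimate(self) -> float:
        return float(
            sum(
                naive_estimate(s.size_spec.center, s.multiplier_spec.center)
                for s in self.strata
            )
        )

    # ------------------------------------------------------------------
    def fit(
        self, replicates: int = 100_000, seed: int | None = None, level: float = 0.95
    ) -> "BenchmarkMultiplierResults":
        """Run the stratified resampling and return the results object."""
        if seed is None:
            seed = int(np.random.SeedSequence().generate_state(1)[0] % (2**31))
        distribution = run_resampling(
            self.strata,
            multiplier_sample_size=self.multiplier_sample_size,
            replicates=replicates,
            seed=seed,
            sharing_mode=self.sharing_mode,
        )
        return BenchmarkMultiplierResults(model=self, distribution=distribution, level=level)


@dataclass
class BenchmarkMultiplierResults:
    """Fitted benchmark-multiplier model: replicate distribution + summaries."""

    model: BenchmarkMultiplierModel
    distribution: PrevalenceDistribution
    level: float = 0.95

    @property
    def point_estimate(self) -> float:
        return self.model.point_estimate

    def interval(self, level: float | None = None) -> IntervalSummary:
        """Empirical percentile interval of the total count."""
        return summarize(self.distribution, self.level if level is None else level)

    def rate_interval(self, level: float | None = None) -> IntervalSummary:
        """Percentile interval of the rate per 100,000 persons at risk."""
        pop = self._population()
        iv = self.interval(level)
        return IntervalSummary(
            level=iv.level,
            lower=per_100k(iv.lower, pop),
            median=per_100k(iv.median, pop),
            upper=per_100k(iv.upper, pop),
        )

    @property
    def rate_per_100k(self) -> float:
        return per_100k(self.point_estimate, self._population())

    def _population(self) -> float:
        if self.model.population_at_risk is None:
            raise ValueError("model has no population_at_risk; rates unavailable")
        return self.model.population_at_risk

    def summary(self, round_to: int = 50) -> str:
        """Human-readable summary table of the fitted model."""
        m = self.model
        iv = self.interval()
        rv = iv.rounded(round_to)
        pct = f"{self.level * 100:g}%"
        lines = [
            "         Benchmark-Multiplier Prevalence Estimation",
            "=" * 62,
            f"Strata:              {len(m.strata)} ({m.strata[0].label} ... {m.strata[-1].label})",
            f"Benchmark total:     {m.benchmark_total:,.1f}",
            f"Multiplier n:        {m.multiplier_sample_size:,d}",
            f"Sharing mode:        {m.sharing_mode}",
            f"Replicates:          {self.distribution.replicates:,d}   Seed: {self.distribution.seed}",
            "-" * 62,
            f"Total persons (naive):           {m.naive_point_estimate:,.1f}",
            f"Total persons (bias-corrected):  {m.point_estimate:,.1f}",
            f"{pct} interval (raw):      {iv.lower:,.1f} - {iv.upper:,.1f}   median {iv.median:,.1f}",
            f"{pct} interval (to {round_to}):    {rv.lower:,.0f} - {rv.upper:,.0f}",
        ]
        if m.population_at_risk is not None:
            ri = self.rate_interval()
            lines += [
                f"Population at risk:  {m.population_at_risk:,.0f}",
                f"Rate per 100,000:    {self.rate_per_100k:.1f}   "
                f"({pct}: {ri.lower:.1f} - {ri.upper:.1f})",
            ]
        lines.append("=" * 62)
        return "\n".join(lines)

    def plot(self, ax=None, bins: int = 60):
        """Histogram of the replicate totals with the interval marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        totals = self.distribution.replicate_totals
        ax.hist(totals, bins=bins, weights=np.full(totals.size, 100.0 / totals.size))
        iv = self.interval()
        for x in (iv.lower, iv.upper):
            ax.axvline(x, linestyle="--", color="k")
        ax.set_xlabel("estimated total persons with disease")
        ax.set_ylabel("% of replicates")
        ax.set_title(f"{self.level * 100:g}% interval: {iv.lower:,.0f} - {iv.upper:,.0f}")
        return ax

    def to_dict(self, round_to: int = 50) -> dict:
        """Machine-readable key-value summary."""
        iv = self.interval()
        rv = iv.rounded(round_to)
        out = {
            "point_estimate": self.point_estimate,
            "naive_estimate": self.model.naive_point_estimate,
            "level": self.level,
            "interval_lower": iv.lower,
            "interval_median": iv.median,
            "interval_upper": iv.upper,
            "interval_lower_rounded": rv.lower,
            "interval_upper_rounded": rv.upper,
            "replicates": self.distribution.replicates,
            "seed": self.distribution.seed,
            "sharing_mode": self.distribution.sharing_mode,
            "n_strata": len(self.model.strata),
            "benchmark_total": self.model.benchmark_total,
            "multiplier_sample_size": self.model.multiplier_sample_size,
        }
        if self.model.population_at_risk is not None:
            ri = self.rate_interval()
            out.update(
                population_at_risk=self.model.population_at_risk,
                rate_per_100k=self.rate_per_100k,
                rate_lower=ri.lower,
                rate_upper=ri.upper,
            )
        return out
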