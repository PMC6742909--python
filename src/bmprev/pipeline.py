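"""Configuration-driven end-to-end estimation runs and report rendering.

A run is described by a :class:`RunConfig` (loadable from a YAML file):
the case definition, index period, target-population size, the paths of
the multiplier / benchmark / reference tables, the sampling-distribution
half-widths, the replicate count and the seed.  :func:`run_pipeline`
executes dataset comparison, benchmark augmentation, subgroup extraction,
stratified resampling and interval summarisation, and returns (and
optionally writes) a report bundle whose every number is reproducible from
the config plus the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, PositiveInt

from .estimators import per_100k
from .model import BenchmarkMultiplierModel, BenchmarkMultiplierResults
from .registry import ComparisonReport, RegistryDataset, compare_datasets
from .uncertainty import PrevalenceDistribution

__all__ = [
    "RunConfig",
    "PipelineError",
    "ReportBundle",
    "RatesTable",
    "run_pipeline",
    "age_sex_rates",
    "render_comparison",
]


class PipelineError(RuntimeError):
    """An error in a named pipeline stage; no partial outputs are written."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


class RunConfig(BaseModel):
    """Full specification of one estimation run."""

    case_definition: str = "persons with clinically definite MS"
    index_period: str = "2016"
    population_at_risk: PositiveInt
    predicate: str = "dmt_last_12mo"
    multiplier_path: Path
    benchmark_path: Path
    reference_path: Path | None = None
    delta_benchmark: float = Field(0.05, ge=0.0)
    delta_multiplier: float = Field(0.05, ge=0.0)
    replicates: PositiveInt = 100_000
    seed: int = 0
    sharing_mode: str = "independent"
    augment_strata: list[str] = ["region"]
    duration_band_years: PositiveInt = 5
    level: float = Field(0.95, gt=0.0, lt=1.0)
    round_to: PositiveInt = 50
    compare_variables: list[str] = [
        "sex",
        "age_years",
        "disease_type",
        "dmt_type",
        "disease_duration_years",
        "region",
    ]
    out_dir: Path | None = None

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


@dataclass
class ReportBundle:
    """Everything one pipeline run produces."""

    config: RunConfig
    results: BenchmarkMultiplierResults
    comparison: ComparisonReport
    run_log: dict

    def summary_text(self) -> str:
        return self.results.summary(round_to=self.config.round_to)

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write the bundle: summary (YAML), comparison (CSV), replicate
        quantiles (CSV), run log (JSON) and the plain-text report."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "summary": out_dir / "summary.yaml",
            "comparison": out_dir / "comparison.csv",
            "quantiles": out_dir / "quantiles.csv",
            "report": out_dir / "report.txt",
            "run_log": out_dir / "run_log.json",
        }
        with open(paths["summary"], "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.results.to_dict(self.config.round_to), fh, sort_keys=False)
        self.comparison.write_csv(paths["comparison"])
        qs = np.linspace(0.0, 1.0, 201)
        pd.DataFrame(
            {"quantile": qs, "total": self.results.distribution.quantile(qs)}
        ).to_csv(paths["quantiles"], index=False)
        paths["report"].write_text(self.summary_text() + "\n", encoding="utf-8")
        with open(paths["run_log"], "w", encoding="utf-8") as fh:
            json.dump(self.run_log, fh, indent=2, default=str)
        return paths


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(name, exc) from exc

    return wrap


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute a full estimation run from a configuration.

    Stages: load datasets → dataset comparison → benchmark augmentation
    (when a reference is given) → subgroup extraction → stratified
    resampling → summaries.  Any stage error is surfaced as a
    :class:`PipelineError` naming the stage, and nothing is written.
    """

    def load() -> tuple[RegistryDataset, RegistryDataset, RegistryDataset | None]:
        for p in (config.multiplier_path, config.benchmark_path, config.reference_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"input table not found: {p}")
        multiplier = RegistryDataset.read_csv(config.multiplier_path)
        benchmark = RegistryDataset.read_csv(config.benchmark_path)
        reference = (
            RegistryDataset.read_csv(config.reference_path)
            if config.reference_path is not None
            else None
        )
        return multiplier, benchmark, reference

    multiplier, benchmark, reference = _stage("load")(load)

    comparison = _stage("compare")(
        compare_datasets, multiplier, benchmark, config.compare_variables
    )

    model = _stage("prepare")(
        BenchmarkMultiplierModel.from_datasets,
        multiplier,
        benchmark,
        reference,
        predicate=config.predicate,
        population_at_risk=config.population_at_risk,
        augment_strata=config.augment_strata,
        duration_band_years=config.duration_band_years,
        delta_benchmark=config.delta_benchmark,
        delta_multiplier=config.delta_multiplier,
        sharing_mode=config.sharing_mode,
    )

    results = _stage("estimate")(
        model.fit, replicates=config.replicates, seed=config.seed, level=config.level
    )

    run_log = {
        "case_definition": config.case_definition,
        "index_period": config.index_period,
        "seed": config.seed,
        "replicates": config.replicates,
        "sharing_mode": config.sharing_mode,
        "level": config.level,
        "delta_benchmark": config.delta_benchmark,
        "delta_multiplier": config.delta_multiplier,
        "population_at_risk": config.population_at_risk,
        "predicate": config.predicate,
        **model.diagnostics,
        "strata": [
            {
                "label": s.label,
                "benchmark_center": s.size_spec.center,
                "benchmark_support": list(s.size_spec.support),
                "multiplier_center": s.multiplier_spec.center,
                "multiplier_support": list(s.multiplier_spec.support),
            }
            for s in model.strata
        ],
        "drawn_totals": {
            "min": float(results.distribution.replicate_totals.min()),
            "mean": float(results.distribution.replicate_totals.mean()),
            "max": float(results.distribution.replicate_totals.max()),
        },
    }
    bundle = ReportBundle(config=config, results=results, comparison=comparison, run_log=run_log)
    if config.out_dir is not None:
        _stage("write")(bundle.write, config.out_dir)
    return bundle


@dataclass(frozen=True)
class RatesTable:
    """Per (age band, sex) cell: estimated count, population and rate."""

    df: pd.DataFrame  # columns: age_band, sex, count, population, rate_per_100k

    def __post_init__(self) -> None:
        required = {"age_band", "sex", "count", "population", "rate_per_100k"}
        if not required <= set(self.df.columns):
            raise ValueError(f"rates table missing columns {required - set(self.df.columns)}")
        recomputed = self.df["count"] / self.df["population"] * 100_000.0
        if not np.allclose(recomputed, self.df["rate_per_100k"], rtol=1e-9, atol=1e-9):
            raise ValueError("rate_per_100k inconsistent with count/population")

    @property
    def total_count(self) -> float:
        return float(self.df["count"].sum())

    def to_csv(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        self.df.to_csv(path, index=False)

    def to_text(self) -> str:
        return self.df.to_string(index=False, float_format=lambda x: f"{x:,.1f}")


def age_sex_rates(
    total: PrevalenceDistribution | float,
    allocation: Mapping[tuple[str, str], float] | pd.DataFrame,
    population_table: pd.DataFrame,
) -> RatesTable:
    """Allocate the estimated total to (age band, sex) cells and rate them.

    ``allocation`` gives per-cell proportions (must sum to 1 within 1e-6);
    ``population_table`` must cover every allocated cell with columns
    ``age_band``, ``sex``, ``population``.  When ``total`` is a replicate
    distribution its median is allocated.
    """
    if isinstance(total, PrevalenceDistribution):
        total_value = float(total.quantile(0.5))
    else:
        total_value = float(total)

    if isinstance(allocation, pd.DataFrame):
        allocation = {
            (r["age_band"], r["sex"]): r["proportion"] for _, r in allocation.iterrows()
        }
    props = np.asarray(list(allocation.values()), dtype=float)
    if abs(props.sum() - 1.0) > 1e-6:
        raise ValueError(f"allocation proportions must sum to 1, got {props.sum()!r}")

    pop = population_table.set_index(["age_band", "sex"])["population"]
    rows = []
    for (band, sex), prop in allocation.items():
        if (band, sex) not in pop.index:
            raise ValueError(f"population table lacks cell {(band, sex)}")
        cell_pop = float(pop.loc[(band, sex)])
        if cell_pop <= 0:
            raise ValueError(f"cell {(band, sex)} has non-positive population {cell_pop}")
        count = total_value * prop
        rows.append(
            {
                "age_band": band,
                "sex": sex,
                "count": count,
                "population": cell_pop,
                "rate_per_100k": per_100k(count, cell_pop),
            }
        )
    return RatesTable(df=pd.DataFrame(rows))


def empirical_allocation(dataset: RegistryDataset, age_bands: Mapping[str, tuple[int, int]]) -> dict:
    """Empirical (age band, sex) proportions of a dataset — the default
    allocation source for age/sex-specific rates."""
    df = dataset.df.dropna(subset=["age_years", "sex"])
    if df.empty:
        raise ValueError(f"{dataset.source_name}: no records with age and sex")

    def band_of(age: float) -> str | None:
        for label, (lo, hi) in age_bands.items():
            if lo <= age <= hi:
                return label
        return None

    bands = df["age_years"].map(band_of)
    ok = bands.notna()
    counts = (
        pd.DataFrame({"age_band": bands[ok], "sex": df.loc[ok, "sex"]})
        .value_counts()
        .sort_index()
    )
    return (counts / counts.sum()).to_dict()


def render_comparison(a, b=None) -> str:
    """Render a comparison as aligned text.

    Either a single :class:`ComparisonReport`, or two :class:`RatesTable`
    objects joined on (age band, sex) with a difference column (e.g. an
    earlier published rates table against the current estimate).
    """
    if isinstance(a, ComparisonReport) and b is None:
        if len(a.variables) == 0:
            raise ValueError("comparison report has no variables to render")
        return a.to_text()
    if isinstance(a, RatesTable) and isinstance(b, RatesTable):
        left = a.df.set_index(["age_band", "sex"])
        right = b.df.set_index(["age_band", "sex"])
        missing = set(left.index).symmetric_difference(right.index)
        if missing:
            raise ValueError(f"rates tables have mismatched cells: {sorted(missing)}")
        joined = pd.DataFrame(
            {
                "rate_a": left["rate_per_100k"],
                "rate_b": right["rate_per_100k"].reindex(left.index),
            }
        )
        joined["difference"] = joined["rate_b"] - joined["rate_a"]
        return joined.reset_index().to_string(index=False, float_format=lambda x: f"{x:,.1f}")
    raise TypeError("render_comparison takes a ComparisonReport or two RatesTable objects")
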