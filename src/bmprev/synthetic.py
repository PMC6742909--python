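"""Synthetic multi-source registry generator with known true prevalence.

Real reimbursement and patient registries for chronic diseases are rarely
shareable, so every stage of the estimation pipeline is exercised on
synthetic data instead.  The generator creates a ground-truth disease
population of known size and derives three linked sources from it, mirroring
the roles the estimation needs:

``multiplier_sample``
    a simple random sample of the population (stands in for a
    patient-centred registry reflecting the target population),
``benchmark``
    the treated subgroup thinned by a known coverage (stands in for a
    reimbursement registry that sees only part of the treatment market),
``reference``
    the complete treated subgroup with a membership flag marking who is in
    the benchmark (stands in for a dispensing database that sees both
    reimbursement channels).

Default marginals emulate a national MS population: sex share, age bands,
disease course mix, treatment mix among treated persons, regional
distribution, and a right-skewed disease-duration distribution
(log-normal, median 8.1 years, IQR 3.8-14.2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd
import yaml

from .registry import RegistryDataset

__all__ = [
    "SyntheticConfig",
    "SourceBundle",
    "generate_population",
    "derive_sources",
    "write_sources",
]

_Z_QUARTILE = 0.6744897501960817  # standard-normal 75th percentile

#: age-band → (low, high) inclusive bounds for uniform age draws
AGE_BANDS: Mapping[str, tuple[int, int]] = {
    "19-49": (19, 49),
    "50-64": (50, 64),
    "65+": (65, 84),
}

DEFAULT_MARGINALS: dict[str, dict[str, float]] = {
    "sex": {"female": 0.736, "male": 0.264},
    "age_band": {"19-49": 0.555, "50-64": 0.345, "65+": 0.100},
    "region": {
        "Lake Geneva region": 0.141,
        "Midlands": 0.246,
        "North-western Switzerland": 0.165,
        "Eastern Switzerland": 0.138,
        "Ticino": 0.030,
        "Central Switzerland": 0.095,
        "Zurich": 0.185,
    },
    "disease_type": {"RRMS": 0.722, "SPMS": 0.168, "PPMS": 0.110},
    # conditional on dmt_status == current-12mo (renormalised treated mix)
    "dmt_type_given_current": {"injectable": 0.245, "oral": 0.597, "infusion": 0.158},
    # conditional on not current (split of the untreated remainder)
    "dmt_status_given_not_current": {"never": 0.364, "past": 0.636},
}


@dataclass
class SyntheticConfig:
    """Configuration of one synthetic generation run.

    Defaults reproduce a realistic national use case: a true disease
    population of 15,300 persons of whom 62.1% are on treatment, a
    multiplier sample of 1,567, and a benchmark source covering 65% of the
    treated subgroup.
    """

    true_total: int = 15_300
    dmt_share: float = 0.621
    multiplier_sample_size: int = 1_567
    benchmark_coverage: float = 0.65
    marginals: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_MARGINALS.items()}
    )
    duration_median: float = 8.1
    duration_q1: float = 3.8
    duration_q3: float = 14.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_total < 1:
            raise ValueError(f"true_total must be >= 1, got {self.true_total}")
        for p, name in (
            (self.dmt_share, "dmt_share"),
            (self.benchmark_coverage, "benchmark_coverage"),
        ):
            if not (0.0 < p <= 1.0):
                raise ValueError(f"{name} must be in (0, 1], got {p}")
        if self.multiplier_sample_size < 1:
            raise ValueError("multiplier_sample_size must be >= 1")
        for var, probs in self.marginals.items():
            vals = np.asarray(list(probs.values()), dtype=float)
            if np.any(vals < 0) or abs(vals.sum() - 1.0) > 1e-9:
                raise ValueError(
                    f"marginal {var!r} probabilities must be >= 0 and sum to 1, "
                    f"got sum {vals.sum()!r}"
                )
        if not (0 < self.duration_q1 <= self.duration_median <= self.duration_q3):
            raise ValueError("duration quartiles must satisfy 0 < q1 <= median <= q3")

    @property
    def duration_lognormal(self) -> tuple[float, float]:
        """(mu, sigma) of the log-normal matching the stated median and
        inter-quartile spread (sigma from the q3/q1 ratio)."""
        mu = float(np.log(self.duration_median))
        sigma = float(np.log(self.duration_q3 / self.duration_q1) / (2 * _Z_QUARTILE))
        return mu, sigma

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        with open(path, encoding="utf-8") as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        data = {
            "true_total": self.true_total,
            "dmt_share": self.dmt_share,
            "multiplier_sample_size": self.multiplier_sample_size,
            "benchmark_coverage": self.benchmark_coverage,
            "marginals": self.marginals,
            "duration_median": self.duration_median,
            "duration_q1": self.duration_q1,
            "duration_q3": self.duration_q3,
            "seed": self.seed,
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def _categorical(rng: np.random.Generator, probs: Mapping[str, float], size: int) -> np.ndarray:
    cats = np.asarray(list(probs.keys()), dtype=object)
    p = np.asarray(list(probs.values()), dtype=float)
    return cats[rng.choice(len(cats), size=size, p=p / p.sum())]


def generate_population(config: SyntheticConfig) -> RegistryDataset:
    """Generate the ground-truth disease population.

    Exactly ``config.true_total`` records; categorical fields drawn from
    the configured marginals, treatment status current within the index
    year with probability ``dmt_share`` independently per record, and
    disease duration from the calibrated log-normal.  Deterministic given
    ``config.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(0,)))
    n = config.true_total
    m = config.marginals

    band = _categorical(rng, m["age_band"], n)
    lows = np.array([AGE_BANDS[b][0] for b in band])
    highs = np.array([AGE_BANDS[b][1] for b in band])
    age = rng.integers(lows, highs + 1)

    current = rng.random(n) < config.dmt_share
    status = np.where(
        current, "current-12mo", _categorical(rng, m["dmt_status_given_not_current"], n)
    )
    dmt_type = np.where(current, _categorical(rng, m["dmt_type_given_current"], n), "none")

    mu, sigma = config.duration_lognormal
    duration = rng.lognormal(mu, sigma, n)

    df = pd.DataFrame(
        {
            "person_id": [f"P{i:06d}" for i in range(n)],
            "sex": _categorical(rng, m["sex"], n),
            "age_years": age,
            "region": _categorical(rng, m["region"], n),
            "disease_type": _categorical(rng, m["disease_type"], n),
            "dmt_status": status,
            "dmt_type": dmt_type,
            "disease_duration_years": np.round(duration, 2),
        }
    )
    return RegistryDataset(df=df, source_name="synthetic-population", coverage=1.0)


class SourceBundle(NamedTuple):
    """The three linked sources derived from one synthetic population."""

    multiplier: RegistryDataset
    benchmark: RegistryDataset
    reference: RegistryDataset


def derive_sources(population: RegistryDataset, config: SyntheticConfig) -> SourceBundle:
    """Derive the linked multiplier, benchmark and reference sources.

    * multiplier: simple random sample (without replacement) of size
      ``multiplier_sample_size`` from the population;
    * benchmark: each treated person retained independently with
      probability ``benchmark_coverage``;
    * reference: all treated persons, with ``in_benchmark`` flagging those
      the benchmark retained.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(1,)))
    df = population.df
    if config.multiplier_sample_size > len(df):
        raise ValueError(
            f"multiplier_sample_size {config.multiplier_sample_size} exceeds "
            f"population size {len(df)}"
        )
    idx = rng.choice(len(df), size=config.multiplier_sample_size, replace=False)
    multiplier = RegistryDataset(
        df=df.iloc[np.sort(idx)].reset_index(drop=True),
        source_name="synthetic-multiplier",
    )

    treated = df[df["dmt_status"] == "current-12mo"].reset_index(drop=True)
    retained = rng.random(len(treated)) < config.benchmark_coverage
    benchmark = RegistryDataset(
        df=treated[retained].reset_index(drop=True),
        source_name="synthetic-benchmark",
        coverage=config.benchmark_coverage,
    )
    reference = RegistryDataset(
        df=treated.assign(in_benchmark=retained),
        source_name="synthetic-reference",
        coverage=1.0,
    )
    return SourceBundle(multiplier=multiplier, benchmark=benchmark, reference=reference)


def write_sources(bundle: SourceBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write the three sources as CSV files; returns the paths."""
    out_dir = Path(out_dir)
    paths = {}
    for name, ds in bundle._asdict().items():
        p = out_dir / f"{name}.csv"
        ds.to_csv(p)
        paths[name] = p
    return paths
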