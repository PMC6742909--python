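"""Patient-level registry tables: reading, subgroup extraction, benchmark
augmentation and descriptive dataset comparison.

A registry dataset is a pandas DataFrame with one row per person plus
source metadata (name, assumed coverage of its target group).  The
canonical column dictionary:

======================  =====================================================
column                  values
======================  =====================================================
person_id               opaque unique identifier (string)
sex                     female | male | unknown
age_years               non-negative integer, or empty for unknown
region                  free-text label (e.g. Swiss major region)
disease_type            RRMS | SPMS | PPMS | CIS | other | unknown
dmt_status              never | past | current-12mo
dmt_type                none | injectable | oral | infusion | other
disease_duration_years  non-negative real (years since first symptoms),
                        or empty for unknown
in_benchmark            (reference datasets only) boolean membership flag
pseudo                  (augmented benchmarks only) True for pseudo-records
======================  =====================================================

Files are plain comma-separated tables with a header row, UTF-8 encoded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CORE_COLUMNS",
    "RegistryDataset",
    "SubgroupPredicate",
    "SubgroupExtraction",
    "DMT_LAST_12_MONTHS",
    "PREDICATES",
    "extract_subgroup",
    "augment_benchmark",
    "compare_datasets",
    "ComparisonReport",
]

CORE_COLUMNS = (
    "person_id",
    "sex",
    "age_years",
    "region",
    "disease_type",
    "dmt_status",
    "dmt_type",
    "disease_duration_years",
)

SEX_LEVELS = ("female", "male", "unknown")
DISEASE_TYPES = ("RRMS", "SPMS", "PPMS", "CIS", "other", "unknown")
DMT_STATUSES = ("never", "past", "current-12mo")
DMT_TYPES = ("none", "injectable", "oral", "infusion", "other")


@dataclass
class RegistryDataset:
    """Patient-level rows from one data source plus source metadata.

    Parameters
    ----------
    df : pandas.DataFrame
        One row per person; must contain a unique ``person_id`` column.
    source_name : str
        Name of the source (e.g. a treatment registry).
    coverage : float or None
        Assumed fraction of its target group the source contains, in
        (0, 1]; None when unknown.
    """

    df: pd.DataFrame
    source_name: str = "unnamed"
    coverage: float | None = None

    def __post_init__(self) -> None:
        if "person_id" not in self.df.columns:
            raise ValueError(f"{self.source_name}: missing 'person_id' column")
        if self.df["person_id"].duplicated().any():
            dupes = self.df.loc[self.df["person_id"].duplicated(), "person_id"]
            raise ValueError(
                f"{self.source_name}: duplicate person_id values, e.g. {dupes.iloc[0]!r}"
            )
        if self.coverage is not None and not (0.0 < self.coverage <= 1.0):
            raise ValueError(f"coverage must be in (0, 1], got {self.coverage}")
        # treatment type and status must agree where both are present
        if {"dmt_status", "dmt_type"} <= set(self.df.columns):
            untreated = self.df["dmt_status"].isin(["never", "past"])
            typed = self.df["dmt_type"].notna() & (self.df["dmt_type"] != "none")
            bad = untreated & typed
            if bad.any():
                raise ValueError(
                    f"{self.source_name}: {int(bad.sum())} records have "
                    "dmt_type set although dmt_status is never/past"
                )

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n(self) -> int:
        return len(self.df)

    @classmethod
    def read_csv(
        cls, path: str | Path, source_name: str | None = None, coverage: float | None = None
    ) -> "RegistryDataset":
        path = Path(path)
        df = pd.read_csv(path, dtype={"person_id": str})
        if "in_benchmark" in df.columns:
            df["in_benchmark"] = df["in_benchmark"].astype(bool)
        if "pseudo" in df.columns:
            df["pseudo"] = df["pseudo"].astype(bool)
        return cls(df=df, source_name=source_name or path.stem, coverage=coverage)

    def to_csv(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        self.df.to_csv(path, index=False)

    def with_records(self, df: pd.DataFrame) -> "RegistryDataset":
        """A copy carrying the same source metadata over new records."""
        return replace(self, df=df.reset_index(drop=True))


@dataclass(frozen=True)
class SubgroupPredicate:
    """A decidable subgroup membership rule over registry records.

    ``columns`` lists the fields the rule needs; records with a missing
    value in any of them are excluded from both numerator and denominator
    of the share and reported in the exclusion tally.
    """

    name: str
    columns: tuple[str, ...]
    rule: Callable[[pd.DataFrame], pd.Series]

    def __call__(self, df: pd.DataFrame) -> pd.Series:
        return self.rule(df).astype(bool)


#: persons who received a disease-modifying therapy within the index year
DMT_LAST_12_MONTHS = SubgroupPredicate(
    name="dmt_last_12mo",
    columns=("dmt_status",),
    rule=lambda df: df["dmt_status"] == "current-12mo",
)

PREDICATES: Mapping[str, SubgroupPredicate] = {DMT_LAST_12_MONTHS.name: DMT_LAST_12_MONTHS}


@dataclass(frozen=True)
class SubgroupExtraction:
    """Result of a subgroup extraction: the subgroup rows, its share of the
    decidable records, the decidable sample size, and the exclusion tally."""

    subgroup: "RegistryDataset"
    share: float
    n: int
    n_excluded: int

    def __iter__(self):  # allow (subgroup, share, n) unpacking
        return iter((self.subgroup, self.share, self.n))


def _resolve_predicate(predicate) -> SubgroupPredicate:
    if isinstance(predicate, SubgroupPredicate):
        return predicate
    if isinstance(predicate, str):
        try:
            return PREDICATES[predicate]
        except KeyError:
            raise ValueError(
                f"unknown predicate {predicate!r}; known: {sorted(PREDICATES)}"
            ) from None
    raise TypeError(f"predicate must be a SubgroupPredicate or name, got {predicate!r}")


def extract_subgroup(
    dataset: RegistryDataset, predicate: SubgroupPredicate | str = DMT_LAST_12_MONTHS
) -> SubgroupExtraction:
    """Extract a subgroup and estimate its share of the dataset.

    The share is the multiplier fraction ``pi`` when the dataset reflects
    the target population; ``n`` is the number of records on which the
    predicate was decidable (records missing a required field are excluded
    from numerator and denominator and counted in ``n_excluded``).
    """
    pred = _resolve_predicate(predicate)
    if len(dataset) == 0:
        raise ValueError(f"{dataset.source_name}: cannot extract a subgroup from an empty dataset")
    missing_cols = [c for c in pred.columns if c not in dataset.df.columns]
    if missing_cols:
        raise ValueError(
            f"{dataset.source_name}: predicate {pred.name!r} needs missing column(s) {missing_cols}"
        )
    decidable = dataset.df[list(pred.columns)].notna().all(axis=1)
    usable = dataset.df[decidable]
    n = len(usable)
    if n == 0:
        raise ValueError(
            f"{dataset.source_name}: predicate {pred.name!r} is decidable on no record"
        )
    mask = pred(usable)
    count = int(mask.sum())
    if count == 0:
        warnings.warn(
            f"{dataset.source_name}: predicate {pred.name!r} matched no record; "
            "a zero share is unusable as a multiplier",
            RuntimeWarning,
            stacklevel=2,
        )
    subgroup = dataset.with_records(usable[mask])
    return SubgroupExtraction(
        subgroup=subgroup,
        share=count / n,
        n=n,
        n_excluded=int((~decidable).sum()),
    )


def _cell_groups(df: pd.DataFrame, strata_vars: Sequence[str]):
    if len(strata_vars) == 0:
        yield ("__all__",), df
        return
    for key, group in df.groupby(list(strata_vars), dropna=False, sort=True):
        if not isinstance(key, tuple):
            key = (key,)
        yield key, group


def augment_benchmark(
    benchmark: RegistryDataset,
    reference: RegistryDataset,
    strata_vars: Sequence[str] = ("region",),
    flag_column: str = "in_benchmark",
) -> RegistryDataset:
    """Complement an under-covering benchmark with pseudo-records.

    The reference dataset sees the benchmark's whole target group and
    carries a boolean flag marking which of its records fall inside the
    benchmark's covered universe.  For each cell of the
    ``strata_vars`` cross-classification the coverage is estimated as
    flagged / total among reference records, and the benchmark cell is
    scaled to ``round(observed / coverage)`` by replicating existing
    records of the cell round-robin in ``person_id`` order.  Pseudo-records
    are marked ``pseudo=True`` and get derived person ids, so the output
    still satisfies the uniqueness invariant.

    A cell with benchmark records but no reference records falls back to
    the global coverage with a warning; a nonempty cell with coverage 0 is
    an error.
    """
    strata_vars = list(strata_vars)
    if flag_column not in reference.df.columns:
        raise ValueError(
            f"{reference.source_name}: reference needs boolean flag column {flag_column!r}"
        )
    for v in strata_vars:
        for ds in (benchmark, reference):
            if v not in ds.df.columns:
                raise ValueError(f"{ds.source_name}: stratification variable {v!r} missing")

    ref_flags = reference.df[flag_column].astype(bool)
    global_coverage = float(ref_flags.mean()) if len(reference.df) else np.nan

    ref_cov: dict[tuple, float] = {}
    for key, group in _cell_groups(reference.df, strata_vars):
        ref_cov[key] = float(group[flag_column].astype(bool).mean())

    pieces = [benchmark.df.assign(pseudo=False)]
    for key, group in _cell_groups(benchmark.df, strata_vars):
        observed = len(group)
        if key not in ref_cov:
            warnings.warn(
                f"{benchmark.source_name}: cell {key} has no reference records; "
                f"falling back to global coverage {global_coverage:.4f}",
                RuntimeWarning,
                stacklevel=2,
            )
            coverage = global_coverage
        else:
            coverage = ref_cov[key]
        if not np.isfinite(coverage) or coverage <= 0.0:
            raise ValueError(
                f"{benchmark.source_name}: cell {key} has {observed} benchmark "
                f"records but estimated coverage {coverage}; cannot augment"
            )
        target = int(np.floor(observed / coverage + 0.5))
        extra = target - observed
        if extra <= 0:
            continue
        ordered = group.sort_values("person_id", kind="mergesort").reset_index(drop=True)
        # round-robin replication: record k of the cell supplies pseudo-copies
        # k, k+observed, k+2*observed, ...; remainder goes to lowest person_id
        src = ordered.iloc[np.arange(extra) % observed].copy()
        copy_no = np.arange(extra) // observed + 1
        src["person_id"] = [
            f"{pid}-p{c}" for pid, c in zip(src["person_id"], copy_no)
        ]
        src["pseudo"] = True
        pieces.append(src)

    out = pd.concat(pieces, ignore_index=True)
    return replace(benchmark, df=out, source_name=f"{benchmark.source_name}-augmented")


@dataclass(frozen=True)
class ComparisonReport:
    """Aligned descriptive statistics of two datasets over named variables.

    For categorical variables the per-category proportions (over
    non-missing values) of both datasets and their absolute difference;
    for numeric variables the median and interquartile range of both.
    """

    name_a: str
    name_b: str
    variables: tuple[str, ...]
    categorical: Mapping[str, pd.DataFrame] = field(default_factory=dict)
    numeric: Mapping[str, pd.DataFrame] = field(default_factory=dict)
    missing_counts: Mapping[str, tuple[int, int]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table of all comparisons (one row per category/statistic)."""
        rows = []
        for var in self.variables:
            if var in self.categorical:
                tab = self.categorical[var]
                for cat, row in tab.iterrows():
                    rows.append(
                        dict(variable=var, item=str(cat), kind="proportion",
                             **{self.name_a: row[self.name_a],
                                self.name_b: row[self.name_b],
                                "abs_difference": row["abs_difference"]})
                    )
            else:
                tab = self.numeric[var]
                for stat, row in tab.iterrows():
                    rows.append(
                        dict(variable=var, item=str(stat), kind="statistic",
                             **{self.name_a: row[self.name_a],
                                self.name_b: row[self.name_b],
                                "abs_difference": row["abs_difference"]})
                    )
        return pd.DataFrame(rows)

    def to_text(self) -> str:
        lines = [f"Dataset comparison: {self.name_a} vs {self.name_b}", ""]
        for var in self.variables:
            miss = self.missing_counts.get(var, (0, 0))
            lines.append(f"{var}  (missing: {miss[0]} / {miss[1]})")
            tab = self.categorical.get(var, self.numeric.get(var))
            lines.append(tab.to_string(float_format=lambda x: f"{x:.4f}"))
            lines.append("")
        return "\n".join(lines)

    def write_csv(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(path, index=False)


def compare_datasets(
    a: RegistryDataset, b: RegistryDataset, variables: Sequence[str]
) -> ComparisonReport:
    """Compare two datasets over named variables, Table-1 style.

    Categorical variables yield category proportions per dataset (summing
    to 1 over non-missing values) and the absolute difference per
    category; numeric variables yield median and interquartile range
    (linear-interpolation quartiles).  Missing values are excluded per
    variable and their counts reported.
    """
    if len(variables) == 0:
        raise ValueError("compare_datasets needs at least one variable")
    for v in variables:
        for ds in (a, b):
            if v not in ds.df.columns:
                raise ValueError(f"variable {v!r} absent from dataset {ds.source_name!r}")

    name_a, name_b = a.source_name, b.source_name
    if name_a == name_b:
        name_a, name_b = f"{name_a} (a)", f"{name_b} (b)"

    categorical: dict[str, pd.DataFrame] = {}
    numeric: dict[str, pd.DataFrame] = {}
    missing: dict[str, tuple[int, int]] = {}
    for v in variables:
        col_a, col_b = a.df[v], b.df[v]
        missing[v] = (int(col_a.isna().sum()), int(col_b.isna().sum()))
        col_a, col_b = col_a.dropna(), col_b.dropna()
        if pd.api.types.is_numeric_dtype(a.df[v]) and pd.api.types.is_numeric_dtype(b.df[v]):
            stats = {}
            for name, col in ((name_a, col_a), (name_b, col_b)):
                q1, med, q3 = np.quantile(col.to_numpy(float), [0.25, 0.5, 0.75], method="linear")
                stats[name] = pd.Series({"median": med, "q1": q1, "q3": q3})
            tab = pd.DataFrame(stats)
            tab["abs_difference"] = (tab.iloc[:, 0] - tab.iloc[:, 1]).abs()
            numeric[v] = tab
        else:
            pa = col_a.value_counts(normalize=True)
            pb = col_b.value_counts(normalize=True)
            cats = sorted(set(pa.index) | set(pb.index), key=str)
            tab = pd.DataFrame(
                {name_a: pa.reindex(cats, fill_value=0.0),
                 name_b: pb.reindex(cats, fill_value=0.0)}
            )
            tab["abs_difference"] = (tab.iloc[:, 0] - tab.iloc[:, 1]).abs()
            categorical[v] = tab

    return ComparisonReport(
        name_a=name_a,
        name_b=name_b,
        variables=tuple(variables),
        categorical=categorical,
        numeric=numeric,
        missing_counts=missing,
    )
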