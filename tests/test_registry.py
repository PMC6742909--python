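"""Tests for registry datasets, subgroup extraction, benchmark augmentation
and descriptive dataset comparison."""

import numpy as np
import pandas as pd
import pytest

from bmprev import (
    RegistryDataset,
    SubgroupPredicate,
    augment_benchmark,
    compare_datasets,
    extract_subgroup,
)

from conftest import make_registry


def dmt_mix(n: int, n_current: int) -> dict:
    status = ["current-12mo"] * n_current + ["never"] * (n - n_current)
    dmt_type = ["oral"] * n_current + ["none"] * (n - n_current)
    return {"dmt_status": status, "dmt_type": dmt_type}


class TestRegistryDataset:
    def test_duplicate_person_ids_rejected(self):
        df = pd.DataFrame({"person_id": ["a", "a"]})
        with pytest.raises(ValueError, match="duplicate person_id"):
            RegistryDataset(df=df, source_name="dup")

    def test_treatment_type_status_consistency_enforced(self):
        with pytest.raises(ValueError, match="dmt_type"):
            make_registry(2, dmt_status=["never", "past"], dmt_type=["oral", "none"])

    def test_csv_roundtrip(self, tmp_path):
        ds = make_registry(5, **dmt_mix(5, 3))
        ds.df["in_benchmark"] = [True, False, True, False, True]
        path = tmp_path / "reg.csv"
        ds.to_csv(path)
        back = RegistryDataset.read_csv(path, source_name="fixture")
        pd.testing.assert_frame_equal(
            back.df, ds.df, check_dtype=False, check_like=True
        )

    def test_coverage_validation(self):
        with pytest.raises(ValueError, match="coverage"):
            make_registry(1, coverage=1.5)


class TestExtractSubgroup:
    def test_multiplier_share_at_use_case_scale(self):
        # 973 of 1,567 persons on treatment within the index year
        ds = make_registry(1567, **dmt_mix(1567, 973))
        sub, share, n = extract_subgroup(ds, "dmt_last_12mo")
        assert n == 1567
        assert round(share, 3) == 0.621
        assert len(sub) == 973
        assert share * n == pytest.approx(973, abs=1e-9)

    def test_all_records_match(self):
        ds = make_registry(10)
        _, share, n = extract_subgroup(ds)
        assert share == 1.0 and n == 10

    def test_hand_counted_small_fixture(self):
        ds = make_registry(16, **dmt_mix(16, 6))
        _, share, _ = extract_subgroup(ds)
        assert share == pytest.approx(0.375)

    def test_missing_fields_excluded_and_tallied(self):
        status = ["current-12mo"] * 4 + ["never"] * 4 + [None] * 2
        types = ["oral"] * 4 + ["none"] * 6
        ds = make_registry(10, dmt_status=status, dmt_type=types)
        res = extract_subgroup(ds)
        assert res.n == 8
        assert res.n_excluded == 2
        assert res.share == pytest.approx(0.5)

    def test_zero_matches_warn(self):
        ds = make_registry(5, dmt_status="never", dmt_type="none")
        with pytest.warns(RuntimeWarning, match="matched no record"):
            res = extract_subgroup(ds)
        assert res.share == 0.0

    def test_empty_dataset_and_unknown_predicate(self):
        empty = RegistryDataset(df=pd.DataFrame({"person_id": []}), source_name="e")
        with pytest.raises(ValueError, match="empty"):
            extract_subgroup(empty)
        with pytest.raises(ValueError, match="unknown predicate"):
            extract_subgroup(make_registry(3), "nope")

    def test_custom_predicate(self):
        oral = SubgroupPredicate("oral", ("dmt_type",), lambda df: df["dmt_type"] == "oral")
        ds = make_registry(4, **dmt_mix(4, 1))
        _, share, _ = extract_subgroup(ds, oral)
        assert share == pytest.approx(0.25)


def make_reference(n_total: int, n_flagged: int, region: str = "Midlands"):
    ref = make_registry(n_total, source_name="reference", region=region)
    ref.df["person_id"] = [f"F{i:05d}" for i in range(n_total)]
    ref.df["in_benchmark"] = [True] * n_flagged + [False] * (n_total - n_flagged)
    return ref


class TestAugmentBenchmark:
    def test_full_coverage_is_identity(self):
        bench = make_registry(20, source_name="bench")
        ref = make_reference(30, 30)
        out = augment_benchmark(bench, ref, ["region"])
        assert len(out) == 20
        assert not out.df["pseudo"].any()
        pd.testing.assert_frame_equal(out.df.drop(columns="pseudo"), bench.df)

    def test_reproduces_printed_single_cell_totals(self):
        # 6,057 observed records; reference implies coverage 6,057/9,503
        bench = make_registry(6057, source_name="bench")
        ref = make_reference(9503, 6057)
        out = augment_benchmark(bench, ref, [])
        assert len(out) == 9503
        assert int(out.df["pseudo"].sum()) == 9503 - 6057

    def test_two_cell_arithmetic(self):
        bench = make_registry(20, region=["A"] * 10 + ["B"] * 10, source_name="bench")
        ref = make_registry(30, region=["A"] * 20 + ["B"] * 10, source_name="ref")
        ref.df["person_id"] = [f"F{i}" for i in range(30)]
        ref.df["in_benchmark"] = [True] * 10 + [False] * 10 + [True] * 10
        out = augment_benchmark(bench, ref, ["region"])
        assert len(out) == 30  # 10/0.5 + 10/1.0
        by_region = out.df.groupby("region").size()
        assert by_region["A"] == 20 and by_region["B"] == 10

    def test_pseudo_records_keep_ids_unique_and_marked(self):
        bench = make_registry(7, source_name="bench")
        ref = make_reference(21, 7)
        out = augment_benchmark(bench, ref, [])
        assert out.df["person_id"].is_unique
        assert int(out.df["pseudo"].sum()) == 14
        # round-robin: every source record replicated twice
        origins = out.df.loc[out.df["pseudo"], "person_id"].str.split("-p").str[0]
        assert origins.value_counts().eq(2).all()

    def test_idempotent_once_coverage_is_one(self):
        bench = make_registry(10, source_name="bench")
        ref = make_reference(25, 10)
        once = augment_benchmark(bench, ref, [])
        ref2 = once.with_records(once.df.assign(in_benchmark=True))
        twice = augment_benchmark(once, ref2, [])
        assert len(twice) == len(once) == 25

    def test_total_is_sum_of_per_cell_targets(self):
        rng = np.random.default_rng(0)
        regions = rng.choice(["A", "B", "C"], size=60)
        bench = make_registry(60, region=regions, source_name="bench")
        ref_regions = np.repeat(["A", "B", "C"], 50)
        ref = make_registry(150, region=ref_regions, source_name="ref")
        ref.df["person_id"] = [f"F{i}" for i in range(150)]
        ref.df["in_benchmark"] = rng.random(150) < 0.7
        out = augment_benchmark(bench, ref, ["region"])
        expected = 0
        for region, group in bench.df.groupby("region"):
            cov = ref.df.loc[ref.df["region"] == region, "in_benchmark"].mean()
            expected += int(np.floor(len(group) / cov + 0.5))
        assert len(out) == expected >= len(bench)

    def test_unseen_cell_falls_back_to_global_coverage(self):
        bench = make_registry(10, region=["A"] * 8 + ["Z"] * 2, source_name="bench")
        ref = make_reference(16, 8, region="A")
        with pytest.warns(RuntimeWarning, match="global coverage"):
            out = augment_benchmark(bench, ref, ["region"])
        assert len(out) == 16 + 4  # 8/0.5 + 2/0.5

    def test_zero_coverage_cell_is_error(self):
        bench = make_registry(5, source_name="bench")
        ref = make_reference(10, 0)
        with pytest.raises(ValueError, match="coverage"):
            augment_benchmark(bench, ref, [])

    def test_missing_flag_or_stratum_column(self):
        bench = make_registry(5, source_name="bench")
        ref = make_registry(5, source_name="ref")
        ref.df["person_id"] = [f"F{i}" for i in range(5)]
        with pytest.raises(ValueError, match="in_benchmark"):
            augment_benchmark(bench, ref, [])
        ref.df["in_benchmark"] = True
        with pytest.raises(ValueError, match="bogus"):
            augment_benchmark(bench, ref, ["bogus"])


class TestCompareDatasets:
    def test_identical_datasets_have_zero_differences(self):
        a = make_registry(50, source_name="a")
        b = make_registry(50, source_name="b")
        rep = compare_datasets(a, b, ["sex", "region", "age_years"])
        frame = rep.to_frame()
        assert (frame["abs_difference"].abs() < 1e-12).all()

    def test_female_share_difference_in_percentage_points(self):
        # 78.0% vs 71.3% female -> 6.7 percentage points apart
        a = make_registry(1000, sex=["female"] * 780 + ["male"] * 220, source_name="a")
        b = make_registry(1000, sex=["female"] * 713 + ["male"] * 287, source_name="b")
        rep = compare_datasets(a, b, ["sex"])
        tab = rep.categorical["sex"]
        assert tab.loc["female", "abs_difference"] == pytest.approx(0.067, abs=1e-12)

    def test_proportions_sum_to_one_per_dataset(self):
        a = make_registry(30, sex=["female"] * 10 + ["male"] * 15 + [None] * 5, source_name="a")
        b = make_registry(40, source_name="b")
        rep = compare_datasets(a, b, ["sex"])
        tab = rep.categorical["sex"]
        assert tab[rep.name_a].sum() == pytest.approx(1.0, abs=1e-9)
        assert tab[rep.name_b].sum() == pytest.approx(1.0, abs=1e-9)
        assert rep.missing_counts["sex"] == (5, 0)

    def test_numeric_variable_quartile_convention(self):
        a = make_registry(5, disease_duration_years=[1, 2, 3, 4, 100], source_name="a")
        b = make_registry(5, disease_duration_years=[1, 2, 3, 4, 100], source_name="b")
        rep = compare_datasets(a, b, ["disease_duration_years"])
        tab = rep.numeric["disease_duration_years"]
        assert tab.loc["median", rep.name_a] == 3.0
        assert tab.loc["q1", rep.name_a] == 2.0  # linear interpolation
        assert tab.loc["q3", rep.name_a] == 4.0

    def test_symmetric_up_to_sign(self):
        a = make_registry(10, sex=["female"] * 7 + ["male"] * 3, source_name="a")
        b = make_registry(10, sex=["female"] * 4 + ["male"] * 6, source_name="b")
        ab = compare_datasets(a, b, ["sex"]).categorical["sex"]["abs_difference"]
        ba = compare_datasets(b, a, ["sex"]).categorical["sex"]["abs_difference"]
        pd.testing.assert_series_equal(ab, ba)

    def test_absent_variable_is_named_in_error(self):
        a, b = make_registry(3, source_name="a"), make_registry(3, source_name="b")
        with pytest.raises(ValueError, match="'ghost'"):
            compare_datasets(a, b, ["ghost"])

    def test_report_renderings(self):
        a = make_registry(8, source_name="a")
        b = make_registry(8, source_name="b")
        rep = compare_datasets(a, b, ["sex", "age_years"])
        assert "sex" in rep.to_text()
        frame = rep.to_frame()
        assert set(frame["variable"]) == {"sex", "age_years"}
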