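"""ROI statistics, table assembly, two-step selection, group comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from mpmri.features import (
    assemble_table,
    compare_groups,
    correlation_filter,
    roi_statistics,
    select_features,
    variance_filter,
)


def as_map(values):
    arr = np.asarray(values, dtype=float)
    return arr.reshape(-1, 1, 1), np.ones((arr.size, 1, 1), dtype=bool)


class TestROIStatistics:
    def test_percentile_convention(self):
        stats = roi_statistics(*as_map([1, 2, 3, 4]))
        assert stats["p25"] == pytest.approx(1.75)
        assert stats["median"] == pytest.approx(2.5)
        assert stats["p75"] == pytest.approx(3.25)

    def test_constant_map(self):
        stats = roi_statistics(*as_map([5, 5, 5]))
        assert stats["mean"] == stats["median"] == stats["p25"] == stats["p75"] == 5
        assert stats["std"] == 0.0

    def test_single_voxel(self):
        stats = roi_statistics(*as_map([2.5]))
        assert all(stats[k] == 2.5 for k in ("mean", "median", "p25", "p75"))
        assert stats["std"] == 0.0

    def test_invalid_voxels_excluded(self):
        vol, mask = as_map([1, 2, 3, np.nan])
        stats = roi_statistics(vol, mask)
        assert stats["mean"] == pytest.approx(2.0)

    def test_empty_mask_raises(self):
        vol, mask = as_map([1.0])
        with pytest.raises(ValueError):
            roi_statistics(vol, ~mask)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(vals=st.lists(st.floats(-50, 50), min_size=2, max_size=30))
    def test_percentiles_match_sort_interpolate_oracle(self, vals):
        vol, mask = as_map(vals)
        stats = roi_statistics(vol, mask)
        assert stats["p25"] == pytest.approx(oracles.percentile(vals, 25), abs=1e-9)
        assert stats["median"] == pytest.approx(oracles.percentile(vals, 50), abs=1e-9)
        assert stats["p75"] == pytest.approx(oracles.percentile(vals, 75), abs=1e-9)


def toy_table(n=8, seed=0):
    rng = np.random.default_rng(seed)
    ids = [f"P{i}" for i in range(n)]
    imaging = pd.DataFrame(
        rng.standard_normal((n, 5)), index=ids, columns=[f"img{j}" for j in range(5)]
    )
    clinical = pd.DataFrame(
        rng.integers(0, 2, (n, 4)).astype(float), index=ids,
        columns=["age_over_40", "premenopausal", "stage_iii", "grade_iii"],
    )
    labels = pd.Series([1] * (n // 2) + [0] * (n - n // 2), index=ids, name="pcr")
    return ids, imaging, clinical, labels


class TestAssembleTable:
    def test_views_partition_columns(self):
        ids, imaging, clinical, labels = toy_table()
        table = assemble_table(ids, imaging, clinical, labels)
        assert list(table.imaging.columns) == list(imaging.columns)
        assert table.clinical.shape[1] == 4
        assert table.combined.shape[1] == imaging.shape[1] + 4

    def test_duplicate_patient_rejected(self):
        ids, imaging, clinical, labels = toy_table()
        dup = [ids[0], ids[0]] + ids[2:]
        imaging.index = dup
        clinical.index = dup
        labels.index = dup
        with pytest.raises(ValueError, match="duplicate"):
            assemble_table(dup, imaging, clinical, labels)

    def test_missing_modality_rejected(self):
        ids, imaging, clinical, labels = toy_table()
        with pytest.raises(ValueError, match="clinical"):
            assemble_table(ids, imaging, clinical.iloc[:-1], labels)


class TestVarianceFilter:
    def test_constant_column_removed(self):
        df = pd.DataFrame({"a": [1.0, 1, 1, 1], "b": [0.0, 1, 0, 1]})
        res = variance_filter(df)
        assert res.retained == ["b"]
        assert set(res.removed["name"]) == {"a"}

    def test_threshold_is_inclusive(self):
        # raw scaling so the variance value itself is controlled exactly:
        # var([0.3, -0.3, 0.3, -0.3], ddof=1) = 0.12; scale to land on 0.1
        x = np.array([0.3, -0.3, 0.3, -0.3]) * np.sqrt(0.1 / 0.12)
        df = pd.DataFrame({"exact": x, "keep": [0.0, 10.0, 0.0, 10.0]})
        res = variance_filter(df, threshold=0.1, scaling="raw")
        assert "exact" in set(res.removed["name"])  # <= is inclusive
        assert res.retained == ["keep"]

    def test_high_variance_retained_raw(self):
        df = pd.DataFrame({"a": [0.0, 1.0, 2.0, 3.0]})
        res = variance_filter(df, scaling="raw")
        assert res.retained == ["a"]

    def test_all_removed_raises(self):
        df = pd.DataFrame({"a": [1.0, 1, 1], "b": [2.0, 2, 2]})
        with pytest.raises(ValueError, match="every column"):
            variance_filter(df)


class TestCorrelationFilter:
    def test_highest_variance_of_perfect_pair_kept(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(20)
        df = pd.DataFrame({"X": x, "Y": 2 * x})
        res = correlation_filter(df, scaling="raw")
        assert res.retained == ["Y"]
        assert res.removed.iloc[0]["name"] == "X"
        assert res.removed.iloc[0]["partner"] == "Y"

    def test_triplicated_columns_single_survivor(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(20)
        df = pd.DataFrame({"a": x, "b": 3 * x, "c": 2 * x})
        res = correlation_filter(df, scaling="raw")
        assert res.retained == ["b"]

    def test_orthogonal_columns_all_kept(self):
        df = pd.DataFrame({"a": [1.0, -1, 1, -1], "b": [1.0, 1, -1, -1]})
        res = correlation_filter(df)
        assert res.retained == ["a", "b"]


class TestSelectFeatures:
    def make_fixture(self):
        from conftest import make_selection_fixture

        df = make_selection_fixture()
        # fixture preconditions: informative pairs below the 0.8 threshold,
        # scaled variance above 0.1
        inf = df[[f"inf{j:02d}" for j in range(10)]]
        corr = inf.corr().to_numpy()
        np.fill_diagonal(corr, 0.0)
        assert np.abs(corr).max() < 0.8
        scaled = (inf - inf.min()) / (inf.max() - inf.min())
        assert scaled.var(ddof=1).min() > 0.1
        return df

    def test_exactly_informative_columns_survive(self):
        df = self.make_fixture()
        res = select_features(df)
        assert sorted(res.retained) == [f"inf{j:02d}" for j in range(10)]
        reasons = dict(zip(res.removed["name"], res.removed["reason"]))
        assert all(reasons[f"const{j}"] == "low_variance" for j in range(5))
        assert all(reasons[f"dup{j}"] == "correlated" for j in range(5))

    def test_idempotent(self):
        df = self.make_fixture()
        first = select_features(df)
        second = select_features(df[first.retained])
        assert second.retained == first.retained
        assert len(second.removed) == 0

    def test_retained_correlations_below_threshold(self):
        df = self.make_fixture()
        res = select_features(df)
        corr = df[res.retained].corr().to_numpy()
        np.fill_diagonal(corr, 0.0)
        assert np.nanmax(np.abs(corr)) <= 0.8


class TestCompareGroups:
    def test_identical_groups(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 1, 2, 3]})
        labels = pd.Series([1, 1, 1, 0, 0, 0], index=df.index)
        res = compare_groups(df, labels)
        assert res.loc["x", "t"] == pytest.approx(0.0, abs=1e-12)
        assert res.loc["x", "p"] == pytest.approx(1.0)

    def test_closed_form_pooled_t(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 2, 3, 4]})
        labels = pd.Series([1, 1, 1, 0, 0, 0], index=df.index)
        res = compare_groups(df, labels)
        assert res.loc["x", "t"] == pytest.approx(-1.2247, abs=1e-4)
        assert res.loc["x", "p"] == pytest.approx(0.2879, abs=1e-4)

    def test_small_group_rejected(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4]})
        labels = pd.Series([1, 0, 0, 0], index=df.index)
        with pytest.raises(ValueError, match="at least 2"):
            compare_groups(df, labels)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        a=st.lists(st.floats(-10, 10), min_size=2, max_size=10),
        b=st.lists(st.floats(-10, 10), min_size=2, max_size=10),
    )
    def test_matches_textbook_closed_form(self, a, b):
        if np.var(a + b) == 0:
            return  # degenerate constant case covered elsewhere
        df = pd.DataFrame({"x": a + b})
        labels = pd.Series([1] * len(a) + [0] * len(b), index=df.index)
        res = compare_groups(df, labels)
        t, p = oracles.pooled_t(a, b)
        if not np.isfinite(t):
            return
        assert res.loc["x", "t"] == pytest.approx(t, rel=1e-9, abs=1e-9)
        assert res.loc["x", "p"] == pytest.approx(p, rel=1e-9, abs=1e-12)
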