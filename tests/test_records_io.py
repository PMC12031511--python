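"""Dataset format round-trips and federated moment-sharing arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fedprog.records_io import (FormatError, SchemaError,
                                StandardizationMetadata,
                                compute_local_moments, impute,
                                load_institution_dataset, merge_moments,
                                read_moments, standardize,
                                write_institution_dataset, write_moments)


def assert_datasets_equal(a, b):
    assert a.institution_id == b.institution_id
    assert a.task == b.task
    assert a.feature_names == b.feature_names
    assert a.static_names == b.static_names
    assert len(a.records) == len(b.records)
    for ra, rb in zip(a.records, b.records):
        assert ra.patient_id == rb.patient_id
        assert np.array_equal(ra.observed_mask, rb.observed_mask)
        assert np.array_equal(ra.dynamics[ra.observed_mask],
                              rb.dynamics[rb.observed_mask])
        assert np.array_equal(ra.demographics, rb.demographics)
        assert ra.mortality == rb.mortality
        if ra.los_remaining is None:
            assert rb.los_remaining is None
        else:
            assert np.array_equal(ra.los_remaining, rb.los_remaining)


class TestRoundTrip:
    def test_write_then_load_is_identity(self, tiny_dataset, tmp_path):
        write_institution_dataset(tiny_dataset, tmp_path / "d")
        assert_datasets_equal(load_institution_dataset(tmp_path / "d"),
                              tiny_dataset)

    def test_synthetic_cohort_round_trips(self, small_cohort, tmp_path):
        _, datasets, _, _ = small_cohort
        write_institution_dataset(datasets[0], tmp_path / "s")
        assert_datasets_equal(load_institution_dataset(tmp_path / "s"),
                              datasets[0])

    def test_empty_cell_becomes_unobserved(self, tmp_path):
        d = tmp_path / "d"
        d.mkdir()
        (d / "manifest.json").write_text(
            '{"institution_id": "x", "task": "mortality", "features": '
            '[{"name": "a", "kind": "dynamic_numeric"},'
            ' {"name": "b", "kind": "dynamic_numeric"},'
            ' {"name": "age", "kind": "static_demographic"}]}')
        # one (feature, time) pair missing entirely: a at t=1
        (d / "timeseries.csv").write_text(
            "patient_id,time_index,feature,value\n"
            "p,0,a,1.0\np,2,a,3.0\np,0,b,4.0\np,1,b,5.0\np,2,b,6.0\n")
        (d / "demographics.csv").write_text("patient_id,age\np,50\n")
        (d / "labels.csv").write_text(
            "patient_id,time_index,mortality,los_remaining\n"
            "p,0,1,\np,1,1,\np,2,1,\n")
        ds = load_institution_dataset(d)
        assert ds.records[0].observed_mask.sum() == 5
        assert not ds.records[0].observed_mask[0, 1]

    def test_los_column_read_verbatim(self, tmp_path):
        d = tmp_path / "d"
        d.mkdir()
        (d / "manifest.json").write_text(
            '{"institution_id": "x", "task": "los", "features": '
            '[{"name": "a", "kind": "dynamic_numeric"}]}')
        (d / "timeseries.csv").write_text(
            "patient_id,time_index,feature,value\np,0,a,1.0\n")
        (d / "demographics.csv").write_text("patient_id\np\n")
        (d / "labels.csv").write_text(
            "patient_id,time_index,mortality,los_remaining\n"
            "p,0,,5\np,1,,4\np,2,,3\n")
        ds = load_institution_dataset(d)
        assert np.array_equal(ds.records[0].los_remaining, [5.0, 4.0, 3.0])

    def test_missing_file_is_format_error(self, tmp_path):
        (tmp_path / "d").mkdir()
        with pytest.raises(FormatError, match="manifest.json"):
            load_institution_dataset(tmp_path / "d")

    def test_unknown_feature_is_schema_error(self, tiny_dataset, tmp_path):
        write_institution_dataset(tiny_dataset, tmp_path / "d")
        ts = (tmp_path / "d" / "timeseries.csv")
        ts.write_text(ts.read_text() + "p1,0,ghost,1.0\n")
        with pytest.raises(SchemaError, match="ghost"):
            load_institution_dataset(tmp_path / "d")

    def test_non_numeric_value_reports_row(self, tiny_dataset, tmp_path):
        write_institution_dataset(tiny_dataset, tmp_path / "d")
        ts = (tmp_path / "d" / "timeseries.csv")
        lines = ts.read_text().splitlines()
        lines[1] = lines[1].rsplit(",", 1)[0] + ",oops"
        ts.write_text("\n".join(lines) + "\n")
        with pytest.raises(SchemaError, match="row 2"):
            load_institution_dataset(tmp_path / "d")


class TestMoments:
    def test_direct_sums(self, tiny_dataset):
        # creat observed values: p1 {1, 3}, p2 {2, 4}
        m = compute_local_moments(tiny_dataset, ["creat"])
        assert m["creat"] == (4, 10.0, 30.0)

    def test_all_masked_is_zero_triple(self, tiny_dataset):
        for rec in tiny_dataset.records:
            rec.observed_mask[:] = False
        m = compute_local_moments(tiny_dataset, ["hr"])
        assert m["hr"] == (0, 0.0, 0.0)

    def test_unrecorded_feature_raises(self, tiny_dataset):
        with pytest.raises(SchemaError, match="not recorded"):
            compute_local_moments(tiny_dataset, ["lactate"])

    def test_two_site_merge_matches_pooled_oracle(self):
        # site A holds {1, 3}, site B holds {5}
        meta = merge_moments([{"f": (2, 4.0, 10.0)}, {"f": (1, 5.0, 25.0)}])
        pooled = np.array([1.0, 3.0, 5.0])
        assert meta.mean["f"] == pytest.approx(pooled.mean())
        assert meta.std["f"] == pytest.approx(pooled.std())   # population
        assert meta.std["f"] == pytest.approx(1.63299, abs=1e-5)

    def test_single_site_merge_is_identity(self, tiny_dataset):
        m = compute_local_moments(tiny_dataset, ["creat"])
        meta = merge_moments([m])
        vals = np.array([1.0, 3.0, 2.0, 4.0])
        assert meta.mean["creat"] == pytest.approx(vals.mean())
        assert meta.std["creat"] == pytest.approx(vals.std())

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(values=st.lists(st.floats(-50, 50), min_size=1, max_size=40),
           n_sites=st.integers(1, 5), data=st.data())
    def test_partitioned_merge_equals_pooled(self, values, n_sites, data):
        """Any partition of a value multiset merges to the pooled moments."""
        assignment = [data.draw(st.integers(0, n_sites - 1))
                      for _ in values]
        sites = []
        for s in range(n_sites):
            vs = np.array([v for v, a in zip(values, assignment) if a == s])
            sites.append({"f": (len(vs), float(vs.sum()),
                                float((vs ** 2).sum()))})
        meta = merge_moments(sites)
        pooled = np.asarray(values)
        assert meta.count["f"] == len(values)
        assert meta.mean["f"] == pytest.approx(pooled.mean(), abs=1e-10)
        assert meta.std["f"] == pytest.approx(pooled.std(), abs=1e-8)
        # merge order never matters (to summation round-off)
        meta2 = merge_moments(list(reversed(sites)))
        assert meta2.mean["f"] == pytest.approx(meta.mean["f"], abs=1e-10)
        assert meta2.std["f"] == pytest.approx(meta.std["f"], abs=1e-10)

    def test_zero_count_is_degenerate(self):
        meta = merge_moments([{"f": (0, 0.0, 0.0)}])
        assert meta.is_degenerate("f")

    def test_moments_json_round_trip(self, tiny_dataset, tmp_path):
        m = compute_local_moments(tiny_dataset, ["creat", "hr"])
        write_moments(m, tmp_path / "m.json")
        assert read_moments(tmp_path / "m.json") == m


class TestStandardize:
    def make_meta(self, mean, std, count=10):
        return StandardizationMetadata({"f": count}, {"f": mean}, {"f": std})

    def test_z_scores(self, tiny_dataset):
        meta = merge_moments([{f: compute_local_moments(tiny_dataset, [f])[f]
                               for f in tiny_dataset.feature_names}])
        out = standardize(tiny_dataset, meta)
        vals = np.array([1.0, 3.0, 2.0, 4.0])   # creat observed values
        expected = (vals - vals.mean()) / vals.std()
        got = np.concatenate([
            r.dynamics[0][r.observed_mask[0]] for r in out.records])
        assert np.allclose(got, expected, atol=1e-4)

    def test_value_at_mean_maps_to_zero(self, tiny_dataset):
        meta = merge_moments([{f: compute_local_moments(tiny_dataset, [f])[f]
                               for f in tiny_dataset.feature_names}])
        # hr observed: p1 {0.5}, p2 {1.0, 2.0}; inject the mean and check
        mu = meta.mean["hr"]
        tiny_dataset.records[0].dynamics[1, 0] = mu
        out = standardize(tiny_dataset, meta)
        assert out.records[0].dynamics[1, 0] == pytest.approx(0.0)

    def test_degenerate_std_passes_through(self, tiny_dataset):
        meta = StandardizationMetadata(
            {f: 0 for f in tiny_dataset.feature_names},
            {f: 0.0 for f in tiny_dataset.feature_names},
            {f: 0.0 for f in tiny_dataset.feature_names})
        out = standardize(tiny_dataset, meta)
        for ra, rb in zip(out.records, tiny_dataset.records):
            assert np.array_equal(ra.dynamics, rb.dynamics)

    def test_standardized_example_hand_values(self):
        # {1, 3, 5} pooled: z-scores -1.2247, 0, 1.2247
        meta = self.make_meta(3.0, np.array([1.0, 3.0, 5.0]).std())
        z = (np.array([1.0, 3.0, 5.0]) - meta.mean["f"]) / meta.std["f"]
        assert np.allclose(z, [-1.2247, 0.0, 1.2247], atol=1e-4)


class TestImpute:
    def test_masked_cells_filled_with_zero_and_mask_kept(self, tiny_dataset):
        out = impute(tiny_dataset)
        assert out.records[0].dynamics[1, 1] == 0.0
        assert not out.records[0].observed_mask[1, 1]   # missingness survives

    def test_fully_observed_record_unchanged(self, tiny_dataset):
        rec = tiny_dataset.records[0]
        rec.observed_mask[:] = True
        before = rec.dynamics.copy()
        out = impute(tiny_dataset)
        assert np.array_equal(out.records[0].dynamics, before)

    def test_demographic_mode_fill(self, tiny_dataset):
        tiny_dataset.records[0].demographics[1] = np.nan
        out = impute(tiny_dataset, demographic_fill={1: 1.0})
        assert out.records[0].demographics[1] == 1.0
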