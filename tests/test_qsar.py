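"""Tagging, descriptor vectors, cleaning rules, and descriptor CSV I/O."""

import math

import numpy as np
import pandas as pd
import pytest

import chemflow as cf
from chemflow import qsar


def make_table(data, uids=None, columns=None):
    uids = uids or [f"m-{i + 1:06d}" for i in range(len(data))]
    columns = columns or [f"d{j}" for j in range(len(data[0]))]
    t = pd.DataFrame(data, index=uids, columns=columns, dtype=float)
    t.index.name = "uid"
    return t


class TestTagging:
    def test_untagged_get_sequential_uids(self, smiles_set):
        tagged = cf.tag_molecules(smiles_set(["C", "CC", "CCC"]))
        assert [r.uid for r in tagged] == ["m-000001", "m-000002", "m-000003"]

    def test_already_tagged_unchanged(self, smiles_set):
        molset = smiles_set(["C", "CC"])
        for i, r in enumerate(molset):
            r.uid = f"keep-{i}"
        tagged = cf.tag_molecules(molset)
        assert [r.uid for r in tagged] == ["keep-0", "keep-1"]

    def test_mixed_tagging_no_collisions(self, smiles_set):
        molset = smiles_set(["C", "CC", "CCC"])
        molset[1].uid = "m-000001"  # occupies the first generated id
        tagged = cf.tag_molecules(molset)
        uids = [r.uid for r in tagged]
        assert len(set(uids)) == 3
        assert uids[1] == "m-000001"

    def test_duplicate_preexisting_uids_rejected(self, smiles_set):
        molset = smiles_set(["C", "CC"])
        molset[0].uid = molset[1].uid = "dup"
        with pytest.raises(ValueError, match="dup"):
            cf.tag_molecules(molset)


class TestDescriptors:
    def test_atom_count_and_ring_count(self, smiles_set):
        molset = cf.tag_molecules(smiles_set(["CCO", "c1ccccc1"]))
        table = cf.compute_descriptors(molset, ["atom_count", "ring_count"])
        assert table.loc["m-000001", "atom_count"] == 3
        assert table.loc["m-000002", "ring_count"] == 1

    def test_columns_follow_selection_order(self, smiles_set):
        molset = cf.tag_molecules(smiles_set(["CCO"]))
        sel = ["tpsa", "atom_count", "gasteiger_charges", "ring_count"]
        table = cf.compute_descriptors(molset, sel)
        assert list(table.columns) == [
            "tpsa", "atom_count", "gasteiger_charge_min", "gasteiger_charge_max",
            "gasteiger_charge_mean", "ring_count",
        ]

    def test_unknown_or_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            cf.DescriptorSelection(["no-such-descriptor"])
        with pytest.raises(ValueError):
            cf.DescriptorSelection([])

    def test_failing_descriptor_yields_missing_cell_and_log(self, smiles_set, caplog, monkeypatch):
        def boom(mol):
            raise RuntimeError("deliberate failure")

        monkeypatch.setitem(qsar.DESCRIPTOR_REGISTRY, "tpsa", boom)
        molset = cf.tag_molecules(smiles_set(["CCO"]))
        with caplog.at_level("WARNING"):
            table = cf.compute_descriptors(molset, ["atom_count", "tpsa"])
        assert math.isnan(table.loc["m-000001", "tpsa"])
        assert table.loc["m-000001", "atom_count"] == 3
        assert any("tpsa" in r.message for r in caplog.records)

    def test_registry_spans_at_least_fifteen_descriptors(self):
        assert len(cf.descriptor_names()) >= 15


class TestCleaning:
    def test_constant_column_removed(self):
        t = make_table([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]])
        clean, report = cf.clean_vectors(t)
        assert list(clean.columns) == ["d0"]
        assert ("d1", "constant component (min == max)") in report.removed_columns

    def test_infinity_row_removed(self):
        # keep the column (tolerant column threshold) so the row rule fires
        policy = cf.CleaningPolicy(component_missing_fraction_max=1.0)
        t = make_table([[1.0, 2.0], [math.inf, 3.0], [4.0, 5.0]])
        clean, report = cf.clean_vectors(t, policy)
        assert "m-000002" not in clean.index
        assert ("m-000002", "contains Infinity") in report.removed_rows

    def test_nan_row_removed(self):
        policy = cf.CleaningPolicy(component_missing_fraction_max=1.0)
        t = make_table([[1.0, 2.0], [math.nan, 3.0], [4.0, 5.0]])
        clean, _ = cf.clean_vectors(t, policy)
        assert list(clean.index) == ["m-000001", "m-000003"]

    def test_clean_table_identity(self):
        t = make_table([[1.0, 2.0], [3.0, 4.0], [5.0, 0.5]])
        clean, report = cf.clean_vectors(t)
        pd.testing.assert_frame_equal(clean, t)
        assert report.n_rows_removed == 0 and report.n_columns_removed == 0

    def test_idempotence(self):
        t = make_table(
            [[1.0, 2.0, 7.0], [2.0, math.inf, 7.0], [3.0, 4.0, 8.0], [4.0, 5.0, 8.0]]
        )
        once, _ = cf.clean_vectors(t)
        twice, report = cf.clean_vectors(once)
        pd.testing.assert_frame_equal(once, twice)
        assert report.n_rows_removed == 0 and report.n_columns_removed == 0

    def test_conservation_counts(self):
        t = make_table(
            [[1.0, 2.0, 7.0], [2.0, math.nan, 7.0], [3.0, 4.0, 7.0], [4.0, 5.0, 7.0]]
        )
        clean, report = cf.clean_vectors(t)
        assert clean.shape[0] + report.n_rows_removed == t.shape[0]
        assert clean.shape[1] + report.n_columns_removed == t.shape[1]

    def test_degenerate_output_is_an_error(self):
        t = make_table([[1.0], [1.0]])  # lone constant column
        with pytest.raises(ValueError, match="degenerate"):
            cf.clean_vectors(t)

    def test_bad_policy_fractions_rejected(self):
        with pytest.raises(ValueError):
            cf.CleaningPolicy(component_missing_fraction_max=1.5)


class TestCSV:
    def test_round_trip_identity(self, tmp_path):
        rng = np.random.default_rng(0)
        t = make_table(rng.normal(size=(10, 5)).tolist())
        path = tmp_path / "t.csv"
        cf.write_csv(t, path)
        back = cf.read_csv(path)
        pd.testing.assert_frame_equal(back, t)

    def test_header_contract(self, tmp_path):
        t = make_table([[1.0, 2.0]], columns=["a", "b"])
        cf.write_csv(t, tmp_path / "t.csv")
        assert (tmp_path / "t.csv").read_text().splitlines()[0] == "uid,a,b"

    def test_empty_table_is_header_only(self, tmp_path):
        t = pd.DataFrame(columns=["a", "b"], dtype=float)
        t.index.name = "uid"
        cf.write_csv(t, tmp_path / "e.csv")
        assert (tmp_path / "e.csv").read_text().strip() == "uid,a,b"

    def test_nan_and_infinity_cells_survive(self, tmp_path):
        t = make_table([[math.nan, math.inf, -math.inf, 1.5]])
        path = tmp_path / "n.csv"
        cf.write_csv(t, path)
        text = path.read_text()
        assert "NaN" in text and "Infinity" in text
        back = cf.read_csv(path)
        assert math.isnan(back.iloc[0, 0])
        assert back.iloc[0, 1] == math.inf
        assert back.iloc[0, 2] == -math.inf
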