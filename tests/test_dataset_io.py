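"""Dataset reading, cleaning, activity binning and splitting."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from selectscreen.dataset_io import (
    ActivityDataset,
    CompoundRecord,
    assign_activity_class,
    assign_activity_classes,
    class_histogram,
    clean_dataset,
    read_activity_table,
    split_dataset,
    write_activity_table,
)


def oracle_class(p: float) -> int:
    """Brute-force interval lookup for the seven pChEMBL bins."""
    edges = [(0.0, 4.0, 1), (4.0, 5.0, 2), (5.0, 6.0, 3), (6.0, 7.0, 4),
             (7.0, 8.0, 5), (8.0, 9.0, 6), (9.0, float("inf"), 7)]
    for lo, hi, cls in edges:
        if lo <= p < hi:
            return cls
    raise AssertionError(p)


class TestActivityBinning:
    @pytest.mark.parametrize(
        "pchembl,expected",
        [(3.5, 1), (9.2, 7), (0.0, 1), (5.0, 3), (4.0, 2), (8.999, 6), (9.0, 7)],
    )
    def test_known_bin_assignments(self, pchembl, expected):
        assert assign_activity_class(pchembl) == expected

    def test_negative_pchembl_rejected(self):
        with pytest.raises(ValueError):
            assign_activity_class(-0.1)
        with pytest.raises(ValueError):
            assign_activity_classes(np.array([1.0, -2.0]))

    @given(st.floats(min_value=0.0, max_value=12.0, allow_nan=False))
    @settings(max_examples=300, deadline=None)
    def test_matches_interval_oracle(self, p):
        assert assign_activity_class(p) == oracle_class(p)

    def test_sweep_monotone_and_covers_seven_classes(self):
        rng = np.random.default_rng(0)
        values = np.sort(rng.uniform(0.0, 12.0, size=10_000))
        classes = assign_activity_classes(values)
        assert np.array_equal(classes, [oracle_class(v) for v in values])
        assert (np.diff(classes) >= 0).all()
        assert set(classes.tolist()) == set(range(1, 8))


class TestReadWrite:
    def _write_csv(self, path, rows, header="compound_id,smiles,pchembl,receptor"):
        path.write_text("\n".join([header, *rows]) + "\n")
        return path

    def test_well_formed_table_identity_read(self, tmp_path):
        f = self._write_csv(
            tmp_path / "a.csv",
            ["C1,CCO,6.5,R1", "C2,c1ccccc1,7.2,R1", "C3,CCN,0.0,R1"],
        )
        ds = read_activity_table(f)
        assert [r.compound_id for r in ds] == ["C1", "C2", "C3"]
        assert ds.pchembl_values().tolist() == [6.5, 7.2, 0.0]

    def test_row_without_pchembl_dropped(self, tmp_path):
        f = self._write_csv(
            tmp_path / "a.csv", ["C1,CCO,6.5,R1", "C2,CCN,,R1", "C3,CCC,5.0,R1"]
        )
        ds = read_activity_table(f)
        assert len(ds) == 2
        assert ds.ids() == ["C1", "C3"]

    def test_header_only_gives_empty_dataset(self, tmp_path):
        f = self._write_csv(tmp_path / "a.csv", [])
        assert len(read_activity_table(f)) == 0

    def test_missing_mandatory_column_is_fatal(self, tmp_path):
        f = (tmp_path / "a.csv")
        f.write_text("compound_id,smiles\nC1,CCO\n")
        with pytest.raises(ValueError, match="pchembl"):
            read_activity_table(f)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_activity_table(tmp_path / "nope.csv")

    def test_chembl_dialect(self, tmp_path):
        f = tmp_path / "a.csv"
        f.write_text(
            "Molecule ChEMBL ID,Smiles,pChEMBL Value\nCHEMBL1,CCO,6.5\n"
        )
        ds = read_activity_table(f, dialect="chembl", receptor="CXCR3")
        assert ds.records[0].compound_id == "CHEMBL1"
        assert ds.receptor == "CXCR3"

    def test_smi_library(self, tmp_path):
        f = tmp_path / "lib.smi"
        f.write_text("CCO mol1\nc1ccccc1 mol2\n")
        ds = read_activity_table(f)
        assert ds.ids() == ["mol1", "mol2"]
        assert all(r.pchembl == 0.0 for r in ds)

    def test_round_trip_preserves_fields(self, tmp_path, labeled_toy_dataset):
        path = tmp_path / "rt.csv"
        write_activity_table(labeled_toy_dataset, path)
        back = read_activity_table(path)
        assert back.ids() == labeled_toy_dataset.ids()
        assert back.smiles() == labeled_toy_dataset.smiles()
        np.testing.assert_allclose(
            back.pchembl_values(), labeled_toy_dataset.pchembl_values()
        )


class TestClean:
    def test_duplicate_id_keeps_first(self):
        ds = ActivityDataset("R", [
            CompoundRecord("C1", "CCO", 5.0),
            CompoundRecord("C1", "CCO", 5.0),
            CompoundRecord("C1", "CCC", 9.0),
        ])
        out = clean_dataset(ds)
        assert len(out) == 1
        assert out.records[0].pchembl == 5.0

    def test_smiles_spellings_canonicalized_identically(self):
        ds = ActivityDataset("R", [
            CompoundRecord("C1", "OCC", 5.0),
            CompoundRecord("C2", "CCO", 5.0),
        ])
        out = clean_dataset(ds)
        assert out.records[0].smiles == out.records[1].smiles

    def test_invalid_smiles_dropped(self):
        ds = ActivityDataset("R", [
            CompoundRecord("C1", "C((", 5.0),
            CompoundRecord("C2", "CCO", 5.0),
        ])
        out = clean_dataset(ds)
        assert out.ids() == ["C2"]

    def test_idempotent(self, labeled_toy_dataset):
        once = clean_dataset(labeled_toy_dataset)
        twice = clean_dataset(once)
        assert once.ids() == twice.ids()
        assert once.smiles() == twice.smiles()
        assert [r.activity_class for r in once] == [r.activity_class for r in twice]

    def test_clean_assigns_classes(self, labeled_toy_dataset):
        assert all(r.activity_class is not None for r in labeled_toy_dataset)


class TestSplit:
    def _dataset(self, n):
        return ActivityDataset("R", [
            CompoundRecord(f"C{i}", "CCO", 5.0, activity_class=3) for i in range(n)
        ])

    def test_eighty_twenty_on_1000(self):
        split = split_dataset(self._dataset(1000), fraction=0.8, seed=1)
        assert len(split.train_indices) == 800
        assert len(split.validation_indices) == 200

    def test_same_seed_reproducible(self):
        ds = self._dataset(57)
        assert split_dataset(ds, seed=9) == split_dataset(ds, seed=9)

    def test_partition_law(self):
        ds = self._dataset(101)
        split = split_dataset(ds, fraction=0.8, seed=3)
        train, val = set(split.train_indices), set(split.validation_indices)
        assert train.isdisjoint(val)
        assert train | val == set(range(101))

    def test_stratified_split_balances_classes(self, tiny_dataset):
        split = split_dataset(tiny_dataset, fraction=0.8, seed=4, stratify=True)
        classes = tiny_dataset.classes()
        for cls in np.unique(classes):
            idx = np.flatnonzero(classes == cls)
            n_train = len(set(split.train_indices) & set(idx.tolist()))
            assert n_train == int(round(0.8 * len(idx)))

    @pytest.mark.parametrize("fraction", [0.0, 1.0, -0.2, 1.5])
    def test_fraction_out_of_range(self, fraction):
        with pytest.raises(ValueError):
            split_dataset(self._dataset(10), fraction=fraction, seed=0)

    def test_too_small_dataset(self):
        with pytest.raises(ValueError):
            split_dataset(self._dataset(1), seed=0)


class TestHistogram:
    def test_single_class(self):
        ds = ActivityDataset("R", [
            CompoundRecord(f"C{i}", "CCO", 9.5, activity_class=7) for i in range(3)
        ])
        counts = class_histogram(ds)
        assert counts[7] == 3
        assert sum(counts.values()) == 3

    def test_empty_dataset_all_zero(self):
        counts = class_histogram(ActivityDataset("R", []))
        assert counts == {k: 0 for k in range(1, 8)}

    def test_hand_tally(self, labeled_toy_dataset):
        counts = class_histogram(labeled_toy_dataset)
        # values: 0.0,3.9->1 | 4.0,4.5->2 | 5.5->3 | 6.5->4 | 7.5->5 | 8.5->6 | 9.0,10.2->7
        assert counts == {1: 2, 2: 2, 3: 1, 4: 1, 5: 1, 6: 1, 7: 2}
        assert sum(counts.values()) == len(labeled_toy_dataset)

    def test_unlabeled_record_is_an_error(self):
        ds = ActivityDataset("R", [CompoundRecord("C9", "CCO", 5.0)])
        with pytest.raises(ValueError, match="C9"):
            class_histogram(ds)
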