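"""Specimen-table I/O and the nested dataset cascade."""

import numpy as np
import pandas as pd
import pytest

from ilta.assemblage_io import (
    Assemblage,
    DamageObservation,
    LeafSpecimen,
    SchemaError,
    build_dataset4,
    filter_dataset2,
    read_assemblage,
    read_incidence_matrix,
    sample_dataset3,
    tukey_fences,
    write_assemblage,
    write_incidence_matrix,
)
from tests.conftest import make_leaf


class TestReadWrite:
    def test_parses_dt_column(self, tmp_path):
        path = tmp_path / "toy.csv"
        path.write_text(
            "specimen_id,site,dts\n"
            "a,Sf,\n"
            "b,Sf,2\n"
            "c,Sf,\n"
        )
        a = read_assemblage(path)
        assert len(a) == 3
        assert a.specimens[1].dt_numbers == [2]
        assert not a.specimens[0].damaged

    def test_wide_incidence_columns(self, tmp_path):
        path = tmp_path / "wide.csv"
        path.write_text(
            "specimen_id,site,X2,X12\n"
            "a,Sf,1,0\n"
            "b,Sf,1,1\n"
        )
        a = read_assemblage(path)
        assert a.specimens[0].dt_numbers == [2]
        assert sorted(a.specimens[1].dt_numbers) == [2, 12]

    def test_duplicate_ids_rejected(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text("specimen_id,site\na,Sf\na,Sf\n")
        with pytest.raises(SchemaError, match="a"):
            read_assemblage(path)

    def test_missing_mandatory_column_named(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("specimen_id,foo\na,1\n")
        with pytest.raises(SchemaError, match="site"):
            read_assemblage(path)

    def test_non_numeric_trait_names_specimen(self, tmp_path):
        path = tmp_path / "bad2.csv"
        path.write_text(
            "specimen_id,site,leaf_area_mm2\nleafX,Sf,not-a-number\n"
        )
        with pytest.raises(SchemaError, match="leafX"):
            read_assemblage(path)

    def test_round_trip_preserves_fields(self, tmp_path, toy_assemblage):
        toy_assemblage.specimens[0].leaf_area_mm2 = 1234.567890123
        toy_assemblage.specimens[0].lma_gm2 = 83.2
        toy_assemblage.specimens[0].lma_source = "measured"
        path = tmp_path / "rt.csv"
        write_assemblage(toy_assemblage, path)
        back = read_assemblage(path)
        assert len(back) == len(toy_assemblage)
        for orig, new in zip(toy_assemblage, back):
            assert new.specimen_id == orig.specimen_id
            assert new.site == orig.site
            assert new.dt_numbers == orig.dt_numbers
            if orig.leaf_area_mm2 is not None:
                assert new.leaf_area_mm2 == pytest.approx(
                    orig.leaf_area_mm2, abs=1e-9
                )


class TestInvariants:
    def test_area_index_bounds(self):
        with pytest.raises(ValueError):
            make_leaf(0, area_index=1.2)

    def test_lma_requires_source(self):
        with pytest.raises(ValueError):
            make_leaf(0, lma_gm2=80.0, lma_source="missing")

    def test_damaged_area_cannot_exceed_leaf_area(self):
        with pytest.raises(ValueError):
            make_leaf(
                0, leaf_area_mm2=100.0,
                damage=[DamageObservation(2, damaged_area_mm2=200.0)],
            )


class TestDataset2:
    def test_boundary_is_inclusive(self):
        leaves = [
            make_leaf(i, preserved_fraction=f)
            for i, f in enumerate([0.5, 0.7, 0.9])
        ]
        out = filter_dataset2(Assemblage("x", leaves))
        assert [s.preserved_fraction for s in out] == [0.7, 0.9]

    def test_empty_input(self):
        assert len(filter_dataset2(Assemblage("x", []))) == 0

    def test_idempotent(self, toy_assemblage):
        once = filter_dataset2(toy_assemblage)
        twice = filter_dataset2(once)
        assert [s.specimen_id for s in once] == [
            s.specimen_id for s in twice
        ]


class TestDataset3:
    def test_deterministic_under_seed(self):
        leaves = [make_leaf(i) for i in range(5)]
        a = Assemblage("x", leaves)
        first = sample_dataset3(a, 2, seed=42)
        second = sample_dataset3(a, 2, seed=42)
        assert [s.specimen_id for s in first] == [
            s.specimen_id for s in second
        ]
        assert len(first) == 2

    def test_per_site_counts(self, toy_assemblage):
        out = sample_dataset3(toy_assemblage, 3, seed=0)
        frame = out.to_frame()
        assert frame.groupby("site").size().tolist() == [3, 3]

    def test_small_site_takes_all_with_warning(self):
        a = Assemblage("x", [make_leaf(i) for i in range(3)])
        with pytest.warns(UserWarning, match="taking all"):
            out = sample_dataset3(a, 10, seed=0)
        assert len(out) == 3

    def test_nonpositive_n_rejected(self, toy_assemblage):
        with pytest.raises(ValueError):
            sample_dataset3(toy_assemblage, 0, seed=0)


class TestDataset4:
    def test_tukey_fence_flags_extreme_value(self):
        # quartiles of {10,10,11,12,1000}: Q1=10, Q3=12 -> fences [7, 15]
        lo, hi = tukey_fences([10, 10, 11, 12, 1000])
        assert lo == pytest.approx(7.0)
        assert hi == pytest.approx(15.0)

    def test_outlier_removed_and_ledger_sums(self):
        sizes = [500.0, 510.0, 520.0, 530.0, 540.0, 550.0, 9000.0]
        leaves = [
            make_leaf(
                i, leaf_area_mm2=size, leaf_length_mm=30.0,
                leaf_width_mm=20.0, lma_gm2=80.0 + i,
                lma_source="measured",
            )
            for i, size in enumerate(sizes)
        ]
        a = Assemblage("x", leaves)
        out, ledger = build_dataset4(a, min_group=1)
        assert ledger["outlier"] == 1
        assert sum(ledger.values()) == len(a) - len(out)
        assert all(s.leaf_area_mm2 < 9000 for s in out)

    def test_homogeneous_complete_set_is_identity(self):
        leaves = [
            make_leaf(
                i, leaf_area_mm2=500.0 + i, leaf_length_mm=30.0,
                leaf_width_mm=20.0, lma_gm2=80.0, lma_source="measured",
            )
            for i in range(6)
        ]
        a = Assemblage("x", leaves)
        out, ledger = build_dataset4(a, min_group=1)
        assert len(out) == len(a)
        assert sum(ledger.values()) == 0

    def test_rare_species_and_tct_removed(self):
        common = [
            make_leaf(
                i, leaf_area_mm2=500.0 + i, leaf_length_mm=30.0,
                leaf_width_mm=20.0, lma_gm2=80.0, lma_source="measured",
            )
            for i in range(6)
        ]
        rare = make_leaf(
            99, fossil_species="Rarus unicus", tct_combined="A",
            leaf_area_mm2=505.0, leaf_length_mm=30.0, leaf_width_mm=20.0,
            lma_gm2=80.0, lma_source="measured",
        )
        a = Assemblage("x", common + [rare])
        out, ledger = build_dataset4(a, min_group=5)
        assert len(out) == 6
        assert ledger["rare_species"] == 1

    def test_cascade_nesting(self, toy_assemblage):
        for s in toy_assemblage:
            s.leaf_area_mm2 = 500.0
            s.leaf_length_mm = 30.0
            s.leaf_width_mm = 20.0
            s.lma_gm2 = 80.0
            s.lma_source = "measured"
        d2 = filter_dataset2(toy_assemblage)
        d3 = sample_dataset3(d2, 4, seed=1)
        d4, _ = build_dataset4(d3, min_group=1)
        ids = lambda a: {s.specimen_id for s in a}  # noqa: E731
        assert ids(d4) <= ids(d3) <= ids(d2) <= ids(toy_assemblage)


class TestIncidenceMatrix:
    def test_columns_and_cells(self):
        leaves = [make_leaf(0), make_leaf(1)]
        leaves[0].damage.append(DamageObservation(2))
        leaves[1].damage.append(DamageObservation(2))
        leaves[1].damage.append(DamageObservation(12))
        matrix = write_incidence_matrix(Assemblage("x", leaves))
        assert list(matrix.columns) == ["specimen_id", "X2", "X12"]
        assert matrix[["X2", "X12"]].to_numpy().tolist() == [[1, 0], [1, 1]]

    def test_no_damage_yields_zero_columns(self):
        matrix = write_incidence_matrix(
            Assemblage("x", [make_leaf(0), make_leaf(1)])
        )
        assert list(matrix.columns) == ["specimen_id"]
        assert len(matrix) == 2

    def test_round_trip(self, tmp_path, toy_assemblage):
        path = tmp_path / "m.csv"
        written = write_incidence_matrix(toy_assemblage, path)
        back = read_incidence_matrix(path)
        pd.testing.assert_frame_equal(written, back)
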