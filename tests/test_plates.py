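import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gpxscreen.errors import (
    PlateFormatError,
    PlateIntegrityError,
    ValidationError,
)
from gpxscreen.plates import (
    Assay,
    Channel,
    PlateFormat,
    PlateRecord,
    Read,
    WellRecord,
    WellRole,
    build_dose_series,
    label_to_row_col,
    read_plate_table,
    well_label,
    write_plate_table,
)


class TestDoseSeries:
    @pytest.mark.parametrize(
        "top,n,fold,expected_low,rel_tol",
        [
            (49.8e-6, 7, 3, 68.3e-9, 0.005),  # primary screen series
            (49.8e-6, 11, 3, 842.5e-12, 0.015),  # follow-up series
            (1.0, 2, 10, 0.1, 1e-12),
        ],
    )
    def test_series_endpoints(self, top, n, fold, expected_low, rel_tol):
        ds = build_dose_series(top, n, fold)
        assert ds.n_points == n
        assert ds.top == top
        assert ds.bottom == pytest.approx(expected_low, rel=rel_tol)

    @pytest.mark.parametrize(
        "top,n,fold", [(0.0, 7, 3), (-1e-6, 7, 3), (1e-6, 1, 3), (1e-6, 7, 1.0)]
    )
    def test_invalid_series_rejected(self, top, n, fold):
        with pytest.raises(ValidationError):
            build_dose_series(top, n, fold)

    @given(
        top=st.floats(1e-9, 1e-2),
        n=st.integers(2, 16),
        fold=st.floats(1.1, 10.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_geometric_ratio_property(self, top, n, fold):
        ds = build_dose_series(top, n, fold)
        for hi, lo in zip(ds.concentrations, ds.concentrations[1:]):
            assert math.isclose(hi / lo, fold, rel_tol=1e-9)


class TestWellLabels:
    @pytest.mark.parametrize(
        "row,col,fmt,label",
        [
            (1, 1, PlateFormat.w1536, "A01"),
            (26, 48, PlateFormat.w1536, "Z48"),
            (27, 1, PlateFormat.w1536, "AA01"),
            (32, 48, PlateFormat.w1536, "AF48"),
            (16, 24, PlateFormat.w384, "P24"),
            (8, 12, PlateFormat.w96, "H12"),
        ],
    )
    def test_known_labels(self, row, col, fmt, label):
        assert well_label(row, col, fmt) == label
        assert label_to_row_col(label, fmt) == (row, col)

    @pytest.mark.parametrize("fmt", list(PlateFormat))
    def test_label_mapping_is_bijective(self, fmt):
        seen = set()
        for row in range(1, fmt.n_rows + 1):
            for col in range(1, fmt.n_columns + 1):
                label = well_label(row, col, fmt)
                assert label not in seen
                seen.add(label)
                assert label_to_row_col(label, fmt) == (row, col)
        assert len(seen) == fmt.capacity

    def test_out_of_geometry_rejected(self):
        with pytest.raises(ValidationError):
            well_label(33, 1, PlateFormat.w1536)
        with pytest.raises(PlateIntegrityError):
            label_to_row_col("Z99", PlateFormat.w384)


def _make_plate(plate_id="p1", n_wells=6, fmt=PlateFormat.w96, reads_per_well=2):
    wells = []
    roles = [WellRole.neg_control, WellRole.pos_control]
    for i in range(n_wells):
        row, col = (i % fmt.n_rows) + 1, (i // fmt.n_rows) + 1
        role = roles[i % 2] if i < 4 else WellRole.sample
        wells.append(
            WellRecord(
                plate_id=plate_id,
                well=well_label(row, col, fmt),
                row=row,
                column=col,
                role=role,
                compound_id=f"c{i}" if role == WellRole.sample else None,
                concentration=1e-6 * (i + 1) if role == WellRole.sample else None,
                reads=[
                    Read(Channel.nadph_340_450, 60.0 * t, 1000.0 + i + t)
                    for t in range(reads_per_well)
                ],
            )
        )
    return PlateRecord(
        plate_id=plate_id,
        format=fmt,
        assay=Assay.gpx1,
        wells=wells,
        read_times=(0.0, 60.0),
    )


class TestPlateTableIO:
    def test_round_trip_identity(self, tmp_path):
        plate = _make_plate()
        path = tmp_path / "plates.csv"
        write_plate_table([plate], path)
        back = read_plate_table(path, min_controls=(2, 2))
        assert len(back) == 1
        got = back[0]
        assert got.plate_id == plate.plate_id
        assert got.format == plate.format
        assert got.assay == plate.assay
        by_label = {w.well: w for w in got.wells}
        for w in plate.wells:
            g = by_label[w.well]
            assert (g.row, g.column, g.role, g.compound_id) == (
                w.row,
                w.column,
                w.role,
                w.compound_id,
            )
            assert g.concentration == w.concentration
            assert g.reads == w.reads

    def test_write_is_deterministic(self, tmp_path):
        plate = _make_plate()
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_plate_table([plate], p1)
        write_plate_table([plate], p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_row_cardinality(self, tmp_path):
        plate = _make_plate(n_wells=5, reads_per_well=2)
        path = tmp_path / "p.csv"
        write_plate_table([plate], path)
        lines = path.read_text().splitlines()
        assert len(lines) == 1 + 2 * 5

    def test_empty_collection_writes_header_only(self, tmp_path):
        path = tmp_path / "empty.csv"
        write_plate_table([], path)
        lines = path.read_text().splitlines()
        assert len(lines) == 1
        assert lines[0].startswith("plate,")

    def test_missing_column_is_format_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("plate,well,role\np1,A01,sample\n")
        with pytest.raises(PlateFormatError, match="missing required column"):
            read_plate_table(path)

    def test_out_of_geometry_well_is_integrity_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        plate = _make_plate(fmt=PlateFormat.w384)
        write_plate_table([plate], path)
        text = path.read_text().replace("A01", "Z99")
        path.write_text(text)
        with pytest.raises(PlateIntegrityError):
            read_plate_table(path, min_controls=(0, 0))

    def test_duplicate_read_is_integrity_error(self, tmp_path):
        path = tmp_path / "dup.csv"
        plate = _make_plate()
        write_plate_table([plate], path)
        lines = path.read_text().splitlines()
        lines.append(lines[1])
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(PlateIntegrityError, match="duplicate read"):
            read_plate_table(path, min_controls=(0, 0))

    @given(
        n_samples=st.integers(0, 12),
        seedval=st.integers(0, 10_000),
    )
    @settings(max_examples=25, deadline=None)
    def test_round_trip_property(self, tmp_path_factory, n_samples, seedval):
        import numpy as np

        rng = np.random.default_rng(seedval)
        fmt = PlateFormat.w96
        wells = []
        labels = [(r, c) for r in range(1, 9) for c in range(1, 13)]
        rng.shuffle(labels)
        for i, (r, c) in enumerate(labels[: n_samples + 4]):
            if i < 2:
                role = WellRole.neg_control
            elif i < 4:
                role = WellRole.pos_control
            else:
                role = WellRole.sample
            wells.append(
                WellRecord(
                    plate_id="pp",
                    well=well_label(r, c, fmt),
                    row=r,
                    column=c,
                    role=role,
                    compound_id=f"x{i}" if role == WellRole.sample else None,
                    concentration=float(rng.uniform(1e-9, 1e-4))
                    if role == WellRole.sample
                    else None,
                    reads=[
                        Read(
                            Channel.nadph_340_450,
                            float(t * 60),
                            float(rng.uniform(0, 1e5)),
                        )
                        for t in range(2)
                    ],
                )
            )
        plate = PlateRecord("pp", fmt, Assay.gpx1, wells, (0.0, 60.0))
        path = tmp_path_factory.mktemp("rt") / "p.csv"
        write_plate_table([plate], path)
        back = read_plate_table(path, min_controls=(2, 2))[0]
        assert {w.well for w in back.wells} == {w.well for w in plate.wells}
        orig = {w.well: w for w in plate.wells}
        for w in back.wells:
            assert w.reads == orig[w.well].reads
            assert w.concentration == orig[w.well].concentration


class TestPlateValidation:
    def test_control_count_invariant(self, small_screen):
        plates, _, _ = small_screen
        for plate in plates:
            n_pos = len(plate.wells_by_role(WellRole.pos_control))
            n_neg = len(plate.wells_by_role(WellRole.neg_control))
            assert n_pos == 64 and n_neg == 64
            plate.validate()  # 64/64 default for w1536

    def test_concentration_role_consistency(self):
        with pytest.raises(ValidationError):
            WellRecord("p", "A01", 1, 1, WellRole.sample, "c1", None)
        with pytest.raises(ValidationError):
            WellRecord("p", "A01", 1, 1, WellRole.pos_control, None, 1e-6)

    def test_duplicate_well_rejected(self):
        plate = _make_plate()
        plate.wells.append(plate.wells[0])
        with pytest.raises(PlateIntegrityError, match="duplicate well"):
            plate.validate(min_controls=(0, 0))
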