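"""I/O layer: layout geometry, image normalisation, CSV dialects."""
import numpy as np
import pandas as pd
import pytest

from platephen.exceptions import ConfigError, FormatError, ParameterError
from platephen.plate_io import (
    AbsorbancePlate,
    PlateLayout,
    Treatment,
    TreatmentMap,
    read_absorbance_csv,
    read_plate_image,
    read_results_table,
    write_absorbance_csv,
    write_plate_image,
    write_results_table,
)


class TestPlateLayout:
    def test_labels_follow_row_letter_column_number(self):
        layout = PlateLayout(8, 12, (58, 58), 92, 40)
        labels = layout.labels()
        assert len(labels) == 96
        assert labels[0] == "A1" and labels[11] == "A12" and labels[-1] == "H12"
        assert layout.well_center("A1") == (58.0, 58.0)
        assert layout.well_center("B2") == (150.0, 150.0)

    def test_all_wells_resolve_inside_the_image(self, small_layout):
        h, w = small_layout.image_shape()
        for label in small_layout.labels():
            r0, r1, c0, c1 = small_layout.well_bbox(label)
            assert 0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w
            assert small_layout.well_mask(label).any()

    def test_well_regions_pairwise_disjoint(self, small_layout):
        h, w = small_layout.image_shape()
        cover = np.zeros((h, w), dtype=int)
        for label in small_layout.labels():
            r0, r1, c0, c1 = small_layout.well_bbox(label)
            cover[r0:r1, c0:c1][small_layout.well_mask(label)] += 1
        assert cover.max() == 1

    def test_overlapping_pitch_rejected(self):
        with pytest.raises(ParameterError):
            PlateLayout(2, 2, (50, 50), 60, 40)

    def test_yaml_round_trip(self, small_layout, tmp_path):
        p = tmp_path / "layout.yaml"
        small_layout.to_yaml(p)
        again = PlateLayout.from_yaml(p)
        assert again == small_layout


class TestReadPlateImage:
    @pytest.mark.parametrize(
        "dtype,scale,pixel,expected",
        [
            (np.uint8, 255, (0, 255, 0), (0.0, 1.0, 0.0)),
            (np.uint16, 65535, (65535, 0, 0), (1.0, 0.0, 0.0)),
        ],
    )
    def test_bit_depths_map_linearly_onto_unit_interval(
        self, tmp_path, small_layout, dtype, scale, pixel, expected
    ):
        h, w = small_layout.image_shape()
        arr = np.full((h, w, 3), scale // 2, dtype=dtype)
        arr[0, 0] = pixel
        # 16-bit RGB goes through TIFF (PIL's PNG writer is 8-bit only)
        path = tmp_path / ("im8.png" if dtype == np.uint8 else "im16.tif")
        import imageio.v3 as iio

        iio.imwrite(path, arr)
        img = read_plate_image(path, small_layout, timestamp_h=2.0)
        assert np.allclose(img.pixels[0, 0], expected)
        assert 0.0 <= img.pixels.min() and img.pixels.max() <= 1.0
        assert img.timestamp_h == 2.0

    def test_grayscale_input_is_a_format_error_naming_the_path(self, tmp_path, small_layout):
        import imageio.v3 as iio

        h, w = small_layout.image_shape()
        path = tmp_path / "gray.png"
        iio.imwrite(path, np.zeros((h, w), dtype=np.uint8))
        with pytest.raises(FormatError, match="gray.png"):
            read_plate_image(path, small_layout)

    def test_missing_file_is_io_error(self, small_layout, tmp_path):
        with pytest.raises(IOError):
            read_plate_image(tmp_path / "nope.png", small_layout)

    def test_write_read_round_trip_16bit(self, tmp_path, small_layout):
        rng = np.random.default_rng(0)
        h, w = small_layout.image_shape()
        pix = rng.random((h, w, 3))
        from platephen.plate_io import PlateImage

        path = tmp_path / "rt.tif"
        write_plate_image(PlateImage(pix, 0.0, small_layout), path, bit_depth=16)
        again = read_plate_image(path, small_layout)
        assert np.abs(again.pixels - pix).max() < 1.0 / 65535


class TestAbsorbanceCSV:
    def _plate(self):
        wells = [f"{r}{c}" for r in "ABCDEFGH" for c in range(1, 13)]
        rng = np.random.default_rng(1)
        return AbsorbancePlate(
            pd.Series(rng.uniform(0.1, 1.0, 96), index=wells),
            pd.Series(rng.uniform(0.02, 0.1, 96), index=wells),
            plate_id="p1",
        )

    @pytest.mark.parametrize("dialect", ["long", "grid8x12"])
    def test_round_trip_preserves_values(self, tmp_path, dialect):
        plate = self._plate()
        path = tmp_path / "abs.csv"
        write_absorbance_csv(plate, path, dialect=dialect)
        again = read_absorbance_csv(path)  # dialect auto-detected
        assert list(again.wells) == list(plate.wells)
        assert np.abs((again.a570 - plate.a570).to_numpy()).max() < 1e-9
        assert np.abs((again.a690 - plate.a690).to_numpy()).max() < 1e-9

    def test_uniform_grid(self, tmp_path):
        lines = []
        for wl in (570, 690):
            lines.append(f"wavelength,{wl}")
            lines.append("," + ",".join(str(i) for i in range(1, 13)))
            for letter in "ABCDEFGH":
                lines.append(letter + ",0.5" * 12)
        path = tmp_path / "grid.csv"
        path.write_text("\n".join(lines))
        plate = read_absorbance_csv(path)
        assert len(plate.wells) == 96
        assert (plate.a570 == 0.5).all() and (plate.a690 == 0.5).all()

    def test_long_rows(self, tmp_path):
        path = tmp_path / "long.csv"
        path.write_text("well,wavelength,value\nA1,570,0.9\nA1,690,0.2\n")
        plate = read_absorbance_csv(path)
        assert plate.a570["A1"] == 0.9 and plate.a690["A1"] == 0.2
        assert plate.net["A1"] == pytest.approx(0.7)

    def test_duplicate_well_rejected(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text("well,wavelength,value\nA1,570,0.9\nA1,570,0.8\nA1,690,0.2\n")
        with pytest.raises(FormatError, match="duplicate"):
            read_absorbance_csv(path)

    def test_missing_wavelength_block_rejected(self, tmp_path):
        lines = ["wavelength,570", "," + ",".join(str(i) for i in range(1, 13))]
        lines += [letter + ",0.5" * 12 for letter in "ABCDEFGH"]
        path = tmp_path / "half.csv"
        path.write_text("\n".join(lines))
        with pytest.raises(FormatError, match="690"):
            read_absorbance_csv(path)


class TestResultsTable:
    def test_round_trip_and_header(self, tmp_path):
        df = pd.DataFrame({"well": ["A1"], "value": [0.123456789012]})
        path = tmp_path / "out.csv"
        write_results_table(df, path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 2 and lines[0] == "well,value"
        again = read_results_table(path)
        assert abs(again["value"][0] - 0.123456789012) < 1e-9

    def test_empty_table_is_an_error_not_an_empty_file(self, tmp_path):
        path = tmp_path / "empty.csv"
        with pytest.raises(ParameterError):
            write_results_table(pd.DataFrame(), path)
        assert not path.exists()


class TestTreatmentMap:
    def test_yaml_round_trip_and_validation(self, tmp_path, small_layout):
        tm = TreatmentMap(
            {w: Treatment("Put", 0.1, "NaCl75") for w in small_layout.labels()}
        )
        path = tmp_path / "treat.yaml"
        tm.to_yaml(path)
        again = TreatmentMap.from_yaml(path, layout=small_layout)
        assert again == tm

    def test_missing_well_rejected(self, tmp_path, small_layout):
        tm = TreatmentMap({"A1": Treatment()})
        path = tmp_path / "short.yaml"
        tm.to_yaml(path)
        with pytest.raises(ConfigError, match="missing wells"):
            TreatmentMap.from_yaml(path, layout=small_layout)

    def test_unknown_condition_rejected(self):
        with pytest.raises(ConfigError):
            Treatment("Put", 0.1, "NaCl999")
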