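"""Domain types, validation, YAML round trip, and the packaged seed dataset."""

import numpy as np
import pytest
import yaml

import tg43seed as t
from tg43seed.errors import FormatError, ValidationError
from tg43seed.sources import _data_path, load_consensus_dataset, save_consensus_dataset

# The published dosimetry tables for the IR06 Pd-103 seed, as printed.
G_RADII = [0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 5.0]
G_COLUMNS = {
    "perspex_mc": [1.448, 1.000, 0.817, 0.668, 0.422, 0.264, 0.156],
    "perspex_tld": [1.49, 1.000, 0.841, 0.689, 0.431, 0.276, 0.168],
    "water_mc": [1.42, 1.000, 0.822, 0.668, 0.426, 0.264, 0.161],
}
F_RADII = [0.25, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 5.0]
F_ANGLES = [0, 10, 20, 30, 40, 50, 60, 70, 80, 90]
F_VALUES = [
    [0.053, 0.074, 0.616, 0.854, 0.924, 0.959, 0.979, 0.992, 0.998, 1.000],
    [0.132, 0.165, 0.472, 0.701, 0.845, 0.927, 0.964, 0.985, 0.996, 1.000],
    [0.190, 0.242, 0.491, 0.686, 0.816, 0.903, 0.956, 0.982, 0.996, 1.000],
    [0.229, 0.281, 0.512, 0.692, 0.813, 0.899, 0.952, 0.982, 0.995, 1.000],
    [0.265, 0.309, 0.526, 0.696, 0.814, 0.896, 0.950, 0.982, 0.996, 1.000],
    [0.294, 0.345, 0.545, 0.705, 0.815, 0.897, 0.949, 0.981, 0.997, 1.000],
    [0.319, 0.369, 0.558, 0.709, 0.818, 0.895, 0.948, 0.979, 0.995, 1.000],
    [0.337, 0.392, 0.568, 0.715, 0.820, 0.900, 0.948, 0.981, 0.995, 1.000],
]
F_MEASURED = {
    1.5: [0.209, 0.656, 0.920],
    2.0: [0.253, 0.675, 0.921],
    3.0: [0.270, 0.681, 0.925],
    5.0: [0.301, 0.682, 0.905],
}


class TestPackagedDataset:
    def test_consensus_lambda_value(self, ir06):
        assert ir06.lambda_consensus == 0.690
        assert ir06.lambda_exp.value == 0.689
        assert ir06.lambda_mc.value == 0.691
        assert ir06.lambda_mc_water.value == 0.692

    def test_radial_table_cells_match_published(self, ir06):
        for name, expected in G_COLUMNS.items():
            table = ir06.g_tables[name]
            np.testing.assert_array_equal(table.radii, G_RADII)
            np.testing.assert_array_equal(table.g_values, expected)

    def test_anisotropy_cells_match_published(self, ir06):
        np.testing.assert_array_equal(ir06.F_table.radii, F_RADII)
        np.testing.assert_array_equal(ir06.F_table.angles, F_ANGLES)
        np.testing.assert_array_equal(ir06.F_table.F_values, F_VALUES)

    def test_sparse_measured_anisotropy_is_separate(self, ir06):
        fm = ir06.F_measured
        np.testing.assert_array_equal(fm.angles, [0, 30, 60])
        for i, r in enumerate(fm.radii):
            np.testing.assert_array_equal(fm.F_values[i], F_MEASURED[r])

    def test_seed_geometry_dimensions(self, ir06):
        geo = ir06.geometry
        assert geo.physical_length == 0.47
        assert geo.active_length == 0.30
        assert (geo.capsule_outer_diameter, geo.capsule_inner_diameter) == (0.08, 0.07)
        assert geo.end_cap_thickness == 0.06
        assert (geo.bead_count, geo.bead_diameter) == (5, 0.06)
        assert geo == t.default_seed_geometry()

    def test_nuclide(self, ir06):
        assert ir06.nuclide.name == "Pd-103"
        assert ir06.nuclide.half_life_days == pytest.approx(17.0, rel=0.01)


class TestLoaderValidation:
    @pytest.fixture
    def doc(self):
        return yaml.safe_load(_data_path("ir06.yaml").read_text())

    def _write(self, tmp_path, doc):
        p = tmp_path / "edited.yaml"
        p.write_text(yaml.safe_dump(doc))
        return p

    def test_broken_normalization_rejected(self, doc, tmp_path):
        doc["g_table"]["columns"]["water_mc"][1] = 0.99  # g(1 cm) must be 1
        with pytest.raises(ValidationError, match="normalization"):
            load_consensus_dataset(self._write(tmp_path, doc))

    def test_reordered_radii_rejected(self, doc, tmp_path):
        gt = doc["g_table"]
        gt["radii"] = gt["radii"][::-1]
        for col in gt["columns"].values():
            col.reverse()
        with pytest.raises(ValidationError, match="radii not increasing"):
            load_consensus_dataset(self._write(tmp_path, doc))

    def test_missing_section_is_format_error(self, doc, tmp_path):
        del doc["lambda"]
        with pytest.raises(FormatError, match="lambda"):
            load_consensus_dataset(self._write(tmp_path, doc))

    def test_unparseable_document(self, tmp_path):
        p = tmp_path / "bad.yaml"
        p.write_text("source: [unclosed")
        with pytest.raises(FormatError):
            load_consensus_dataset(p)

    def test_inconsistent_consensus_rejected(self, doc, tmp_path):
        doc["lambda"]["consensus"] = 0.75  # not the average of 0.689 and 0.691
        with pytest.raises(ValidationError, match="average"):
            load_consensus_dataset(self._write(tmp_path, doc))

    def test_round_trip_is_lossless(self, ir06, tmp_path):
        out = tmp_path / "rt.yaml"
        save_consensus_dataset(ir06, out)
        back = load_consensus_dataset(out)
        assert back.lambda_consensus == ir06.lambda_consensus
        assert back.lambda_exp == ir06.lambda_exp
        for name in ir06.g_tables:
            np.testing.assert_array_equal(
                back.g_tables[name].g_values, ir06.g_tables[name].g_values
            )
        np.testing.assert_array_equal(back.F_table.F_values, ir06.F_table.F_values)
        np.testing.assert_array_equal(back.F_measured.F_values, ir06.F_measured.F_values)
        assert back.geometry == ir06.geometry


class TestGridValidation:
    def test_well_formed_grid_has_no_violations(self, geometry_grid):
        assert t.validate_grid(geometry_grid) == []

    def test_negative_value_names_cell(self, geometry_grid):
        geometry_grid.values[1, 2] = -0.5
        violations = t.validate_grid(geometry_grid)
        assert len(violations) == 1
        assert "(1, 2)" in violations[0]

    def test_shape_mismatch_names_expected_shape(self, geometry_grid):
        geometry_grid.values = geometry_grid.values[:, :-1]
        violations = t.validate_grid(geometry_grid)
        assert len(violations) == 1
        assert "(5, 4)" in violations[0]

    def test_nonincreasing_radii_reported(self, geometry_grid):
        geometry_grid.radii = geometry_grid.radii[::-1]
        assert any("radii not increasing" in v for v in t.validate_grid(geometry_grid))

    def test_validate_never_raises_on_garbage(self):
        grid = t.DoseRateGrid(radii=[[1.0]], angles=[0.0], values=[[1.0]])
        assert t.validate_grid(grid)  # reports, does not raise


class TestTypeInvariants:
    def test_mass_fractions_must_sum_to_one(self):
        with pytest.raises(ValidationError, match="mass fractions"):
            t.SeedGeometry(
                physical_length=0.47, active_length=0.3,
                capsule_outer_diameter=0.08, capsule_inner_diameter=0.07,
                end_cap_thickness=0.06, bead_count=5, bead_diameter=0.06,
                core_mass_fractions={"H": 0.5, "C": 0.4},
            )

    def test_active_length_cannot_exceed_physical(self):
        with pytest.raises(ValidationError, match="active_length"):
            t.SeedGeometry(
                physical_length=0.3, active_length=0.47,
                capsule_outer_diameter=0.08, capsule_inner_diameter=0.07,
                end_cap_thickness=0.06, bead_count=5, bead_diameter=0.06,
            )

    def test_anisotropy_reference_column_must_be_unity(self):
        with pytest.raises(ValidationError, match="90"):
            t.AnisotropyTable(
                radii=[1.0, 2.0], angles=[0.0, 90.0],
                F_values=[[0.2, 1.0], [0.3, 0.999]],
            )

    def test_radial_table_normalization_enforced(self):
        with pytest.raises(ValidationError, match="normalization"):
            t.RadialDoseTable(radii=[0.5, 1.0, 2.0], g_values=[1.4, 0.99, 0.7])

    def test_nonpositive_half_life_rejected(self):
        with pytest.raises(ValidationError):
            t.Nuclide(name="X", half_life_days=0.0)
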