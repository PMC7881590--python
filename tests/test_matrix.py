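"""Matrix builder: m/z grid, interpolation, assembly, trace CSV round trips."""

import numpy as np
import pandas as pd
import pytest

from chickn import (
    DataMatrix,
    MzGrid,
    Spectrum,
    assemble_matrix,
    build_mz_grid,
    export_trace_csv,
    interpolate_spectrum,
    load_trace_csv,
    read_spectra,
)

from conftest import write_mzml, write_mzxml


class TestMzGrid:
    @pytest.mark.parametrize(
        "resolution,expected_gap",
        [(240_000, 0.0005), (60_000, 0.002)],
    )
    def test_first_gap_matches_resolution(self, resolution, expected_gap):
        grid = build_mz_grid(400.0, 410.0, resolution)
        assert grid.nodes[1] - grid.nodes[0] == pytest.approx(expected_gap, rel=1e-12)

    def test_gap_recursion_holds_everywhere(self):
        grid = build_mz_grid(400.0, 1400.0, 60_000)
        gaps = np.diff(grid.nodes)
        lhs = gaps * 60_000 / 0.015
        rhs = grid.nodes[:-1] ** 1.5
        assert np.allclose(lhs, rhs, rtol=1e-9)
        # nodes strictly increasing, gaps monotonically increasing with m
        assert np.all(gaps > 0)
        assert np.all(np.diff(gaps) > 0)

    def test_covers_range(self):
        grid = build_mz_grid(400.0, 1400.0, 60_000)
        assert grid.nodes[0] == 400.0
        assert grid.nodes[-1] >= 1400.0 - (grid.nodes[-1] - grid.nodes[-2])

    @pytest.mark.parametrize(
        "args", [(0, 500, 60000), (-5, 500, 60000), (500, 400, 60000), (400, 500, 0)]
    )
    def test_invalid_arguments_rejected(self, args):
        with pytest.raises(ValueError):
            build_mz_grid(*args)


class TestInterpolation:
    def test_node_at_recorded_peak_keeps_intensity(self):
        grid = MzGrid(np.array([100.0, 100.5, 101.0]), 1.0, (100.0, 101.0))
        spec = Spectrum([100.0, 100.5, 101.0], [3.0, 10.0, 7.0], 1.0)
        out = interpolate_spectrum(spec, grid)
        assert out == pytest.approx([3.0, 10.0, 7.0])

    def test_midpoint_is_linear_average(self):
        grid = MzGrid(np.array([100.5]), 1.0, (100.5, 100.5))
        spec = Spectrum([100.0, 101.0], [0.0, 10.0], 1.0)
        assert interpolate_spectrum(spec, grid)[0] == pytest.approx(5.0)

    def test_outside_support_is_zero(self):
        grid = MzGrid(np.array([50.0, 100.5, 200.0]), 1.0, (50.0, 200.0))
        spec = Spectrum([100.0, 101.0], [4.0, 10.0], 1.0)
        out = interpolate_spectrum(spec, grid)
        assert out[0] == 0.0 and out[2] == 0.0

    def test_unsorted_spectrum_rejected(self):
        grid = MzGrid(np.array([100.0]), 1.0, (100.0, 100.0))
        with pytest.raises(ValueError):
            interpolate_spectrum(Spectrum([101.0, 100.0], [1.0, 1.0], 0.0), grid)


class TestAssembly:
    def test_empty_columns_removed(self):
        grid = build_mz_grid(400.0, 500.0, 10_000)
        # all peaks confined to a narrow window -> few surviving columns
        spectra = [
            Spectrum([450.0, 450.1], [5.0, 8.0], float(t)) for t in range(3)
        ]
        mat = assemble_matrix(spectra, grid)
        assert mat.shape[0] == 3
        assert mat.shape[1] <= np.sum((grid.nodes >= 449.9) & (grid.nodes <= 450.2))
        assert np.all(np.asarray(mat.values).max(axis=0) > 0)

    def test_identical_spectra_give_constant_columns(self):
        grid = build_mz_grid(400.0, 500.0, 10_000)
        spectra = [Spectrum([450.0, 451.0], [5.0, 8.0], float(t)) for t in range(4)]
        mat = assemble_matrix(spectra, grid)
        values = np.asarray(mat.values)
        assert np.allclose(values, values[0])

    def test_degenerate_inputs_rejected(self):
        grid = build_mz_grid(400.0, 500.0, 10_000)
        with pytest.raises(ValueError):
            assemble_matrix([], grid)
        with pytest.raises(ValueError):
            assemble_matrix([Spectrum([450.0], [0.0], 0.0)], grid)

    def test_rows_sorted_by_retention_time(self):
        grid = build_mz_grid(400.0, 500.0, 10_000)
        spectra = [
            Spectrum([450.0, 450.2], [2.0, 2.0], 5.0),
            Spectrum([450.0, 450.2], [1.0, 1.0], 1.0),
        ]
        mat = assemble_matrix(spectra, grid)
        assert list(mat.row_times) == [1.0, 5.0]
        assert np.asarray(mat.values)[0].max() == pytest.approx(1.0)


class TestTraceCsv:
    def _toy_csv(self, path):
        pd.DataFrame(
            {
                "mz": [400.1, 400.1, 402.5, 402.5, 405.0, 405.0],
                "rt": [10.0, 20.0, 10.0, 20.0, 10.0, 20.0],
                "intensity": [5.0, 7.0, 3.0, 4.0, 9.0, 2.0],
                "trace": [1, 1, 2, 2, -1, -1],
                "envelope": [100, 100, 100, 100, -1, -1],
            }
        ).to_csv(path, index=False)

    def test_noise_traces_dropped(self, tmp_path):
        path = tmp_path / "toy.csv"
        self._toy_csv(path)
        mat, truth = load_trace_csv(path, return_truth=True)
        assert mat.shape == (2, 2)
        assert mat.provenance == "trace_csv"
        assert list(truth) == [100, 100]

    def test_all_noise_is_an_error(self, tmp_path):
        path = tmp_path / "noise.csv"
        pd.DataFrame(
            {"mz": [1.0], "rt": [1.0], "intensity": [1.0], "trace": [-1], "envelope": [-1]}
        ).to_csv(path, index=False)
        with pytest.raises(ValueError, match="noise"):
            load_trace_csv(path)

    def test_missing_columns_is_a_format_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"mz": [1.0], "rt": [1.0]}).to_csv(path, index=False)
        with pytest.raises(ValueError, match="missing"):
            load_trace_csv(path)

    def test_round_trip_preserves_nonzero_entries(self, tmp_path, small_matrix):
        mat, _ = small_matrix
        out = tmp_path / "export.csv"
        export_trace_csv(mat, out)
        values = np.asarray(mat.values)
        assert len(pd.read_csv(out)) == np.count_nonzero(values)
        # export uses the 0-based column index as the trace label, so the
        # loader must not treat trace 0 as noise for an exact round trip
        back = load_trace_csv(out, noise_labels=(-1,))
        nz_cols = np.flatnonzero(values.any(axis=0))
        assert back.shape[1] == len(nz_cols)
        orig = values[:, nz_cols]
        assert np.array_equal(np.asarray(back.values)[orig > 0], orig[orig > 0])

    def test_tiny_matrix_exports_expected_rows(self, tmp_path):
        mat = DataMatrix(
            np.array([[1.0, 0.0], [0.0, 2.0]]), [0.0, 1.0], [400.0, 401.0], "synthetic"
        )
        out = tmp_path / "tiny.csv"
        export_trace_csv(mat, out)
        df = pd.read_csv(out)
        assert len(df) == 2
        assert sorted(df["trace"]) == [0, 1]


class TestSpectrumFiles:
    SCANS = [
        (1, 10.0, [400.0, 400.5, 401.0], [5.0, 50.0, 5.0]),
        (2, 11.0, [200.0, 201.0], [99.0, 99.0]),  # MS2, must be skipped
        (1, 12.0, [400.0, 400.5, 401.0], [6.0, 60.0, 6.0]),
    ]

    def test_mzml_reader_selects_ms1(self, tmp_path):
        path = tmp_path / "toy.mzML"
        write_mzml(path, self.SCANS)
        spectra = read_spectra(path, fmt="mzml")
        assert len(spectra) == 2
        assert spectra[0].retention_time == pytest.approx(10.0)
        assert spectra[1].intensity.max() == pytest.approx(60.0)

    def test_mzxml_reader_selects_ms1(self, tmp_path):
        path = tmp_path / "toy.mzXML"
        write_mzxml(path, self.SCANS)
        spectra = read_spectra(path, fmt="mzxml")
        assert len(spectra) == 2
        assert spectra[0].retention_time == pytest.approx(10.0)
        assert np.allclose(spectra[0].mz, [400.0, 400.5, 401.0])


class TestHdf5Backing:
    def test_round_trip_and_lazy_column_access(self, tmp_path, small_matrix):
        mat, _ = small_matrix
        path = tmp_path / "matrix.h5"
        mat.to_hdf5(path)
        lazy = DataMatrix.from_hdf5(path)
        assert lazy.shape == mat.shape
        # column access without loading everything, in arbitrary order
        idx = np.array([5, 2, 9])
        assert np.allclose(lazy.columns(idx), np.asarray(mat.values)[:, idx])
        assert np.allclose(lazy.column(3), mat.column(3))
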