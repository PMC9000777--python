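"""Dataset container invariants and IO/restructuring operations."""

import numpy as np
import pytest

from aquarocket.dataset import SampleMeta, SpectralDataError, SpectralDataset, instrument_grid
from aquarocket import spectra_io

from conftest import make_dataset


class TestDatasetInvariants:
    def test_wavelengths_must_increase(self):
        with pytest.raises(SpectralDataError, match="increasing"):
            make_dataset([[1.0, 2.0]], wavelengths=[1400.0, 1300.0])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(SpectralDataError, match="shape"):
            SpectralDataset(
                np.array([1300.0, 1400.0]),
                np.ones((2, 2)),
                "absorbance",
                [SampleMeta("A", 0)],
            )

    def test_reflectance_range_enforced(self):
        with pytest.raises(SpectralDataError, match=r"\(0, 1\]"):
            make_dataset([[0.5, 1.2]], mode="reflectance")

    def test_unknown_treatment_rejected(self):
        with pytest.raises(SpectralDataError, match="treatment"):
            SampleMeta("D", 0)

    def test_instrument_grid_matches_acquisition_convention(self):
        grid = instrument_grid()
        assert grid.size == 125
        assert grid[0] == 900.0 and grid[-1] == 1600.0
        assert np.allclose(np.diff(grid), 700.0 / 124)


class TestRoundTrips:
    @pytest.mark.parametrize("dialect", ["wide_csv", "long_csv"])
    def test_write_read_identity(self, tmp_path, dialect, rng):
        ds = make_dataset(rng.uniform(0.1, 0.9, (6, 10)), mode="reflectance")
        path = tmp_path / "spectra.csv"
        spectra_io.write_spectra(ds, path, dialect)
        back = spectra_io.read_spectra(path, dialect)
        assert back.mode == ds.mode
        np.testing.assert_allclose(back.wavelengths, ds.wavelengths, rtol=0, atol=1e-12)
        np.testing.assert_allclose(back.values, ds.values, rtol=1e-15)
        assert back.samples == ds.samples

    def test_cross_dialect_round_trip(self, tmp_path, rng):
        ds = make_dataset(rng.normal(size=(4, 8)))
        wide, long = tmp_path / "w.csv", tmp_path / "l.csv"
        spectra_io.write_spectra(ds, wide, "wide_csv")
        spectra_io.write_spectra(spectra_io.read_spectra(wide), long, "long_csv")
        back = spectra_io.read_spectra(long, "long_csv")
        np.testing.assert_allclose(back.values, ds.values, rtol=1e-15)

    def test_empty_file_is_an_error(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("treatment,day,bag,side,replicate,1300,1400\n")
        with pytest.raises(SpectralDataError, match="no spectra"):
            spectra_io.read_spectra(path)

    def test_zero_spectra_not_writable(self, tmp_path):
        ds = make_dataset(np.empty((0, 3)), meta=[])
        with pytest.raises(SpectralDataError, match="0 spectra"):
            spectra_io.write_spectra(ds, tmp_path / "x.csv")

    def test_non_monotone_header_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "treatment,day,bag,side,replicate,1400,1300\nA,0,1,front,1,0.1,0.2\n"
        )
        with pytest.raises(SpectralDataError, match="increasing"):
            spectra_io.read_spectra(path)

    def test_unknown_treatment_in_file_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "treatment,day,bag,side,replicate,1300,1400\nZ,0,1,front,1,0.1,0.2\n"
        )
        with pytest.raises(SpectralDataError, match="metadata"):
            spectra_io.read_spectra(path)


class TestModeConversion:
    @pytest.mark.parametrize("r,expected", [(1.0, 0.0), (0.1, 1.0), (0.01, 2.0)])
    def test_log_identities(self, r, expected):
        ds = make_dataset([[r, r]], mode="reflectance")
        out = spectra_io.reflectance_to_absorbance(ds)
        assert out.mode == "absorbance"
        np.testing.assert_allclose(out.values, expected, atol=1e-12)

    def test_inverse_restores_reflectance(self, rng):
        ds = make_dataset(rng.uniform(0.05, 0.95, (5, 12)), mode="reflectance")
        back = spectra_io.absorbance_to_reflectance(
            spectra_io.reflectance_to_absorbance(ds)
        )
        np.testing.assert_allclose(back.values, ds.values, rtol=1e-12)

    def test_wrong_mode_rejected(self):
        ds = make_dataset([[0.5, 0.5]], mode="absorbance")
        with pytest.raises(SpectralDataError, match="not reflectance"):
            spectra_io.reflectance_to_absorbance(ds)


class TestSubtractReference:
    def test_self_subtraction_zeroes(self, rng):
        row = rng.normal(size=6)
        ds = make_dataset(np.tile(row, (3, 1)))
        out = spectra_io.subtract_reference(ds, ds)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-15)
        assert out.samples == ds.samples

    def test_constant_reference_shifts_rows(self, rng):
        ds = make_dataset(rng.normal(size=(4, 5)))
        r0 = rng.normal(size=5)
        ref = make_dataset(np.tile(r0, (10, 1)))
        out = spectra_io.subtract_reference(ds, ref)
        np.testing.assert_allclose(out.values, ds.values - r0, rtol=1e-12)

    def test_linearity_of_successive_subtraction(self, rng):
        ds = make_dataset(rng.normal(size=(4, 5)))
        ref1 = make_dataset(rng.normal(size=(3, 5)))
        ref2 = make_dataset(rng.normal(size=(2, 5)))
        twice = spectra_io.subtract_reference(
            spectra_io.subtract_reference(ds, ref1), ref2
        )
        combined = make_dataset(
            [ref1.values.mean(axis=0) + ref2.values.mean(axis=0)]
        )
        once = spectra_io.subtract_reference(ds, combined)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-12)

    def test_grid_mismatch_rejected(self, rng):
        ds = make_dataset(rng.normal(size=(2, 5)))
        ref = make_dataset(rng.normal(size=(2, 5)), wavelengths=np.linspace(900, 1000, 5))
        with pytest.raises(SpectralDataError, match="grid"):
            spectra_io.subtract_reference(ds, ref)


class TestTruncate:
    def test_first_overtone_window(self):
        ds = make_dataset(np.ones((2, 125)), wavelengths=instrument_grid())
        out = spectra_io.truncate(ds, 1300.0, 1600.0)
        assert out.wavelengths.min() >= 1300.0
        assert out.wavelengths.max() <= 1600.0
        assert out.n_wavelengths < 125

    def test_full_range_is_identity(self, rng):
        ds = make_dataset(rng.normal(size=(2, 10)))
        out = spectra_io.truncate(ds, ds.wavelengths[0], ds.wavelengths[-1])
        np.testing.assert_array_equal(out.values, ds.values)

    def test_empty_range_rejected(self, rng):
        ds = make_dataset(rng.normal(size=(2, 10)))
        with pytest.raises(SpectralDataError, match="no wavelengths"):
            spectra_io.truncate(ds, 2000.0, 2100.0)


class TestAverageBy:
    def test_checkpoint_collapse(self, rng):
        meta = [
            SampleMeta("A", 4, bag=str(b), side=s, replicate=r)
            for b in (1, 2, 3)
            for s in ("front", "back")
            for r in range(1, 11)
        ]
        ds = make_dataset(rng.normal(size=(60, 5)), meta=meta)
        out = spectra_io.average_by(ds, ("treatment", "day"))
        assert out.n_spectra == 1
        assert out.samples[0].replicate == 60
        np.testing.assert_allclose(out.values[0], ds.values.mean(axis=0), rtol=1e-12)

    def test_singleton_groups_are_identity(self, rng):
        meta = [SampleMeta("A", 0, bag=str(i), side="front") for i in range(4)]
        ds = make_dataset(rng.normal(size=(4, 5)), meta=meta)
        out = spectra_io.average_by(ds, ("treatment", "day", "bag"))
        np.testing.assert_allclose(out.values, ds.values, atol=0)

    def test_symmetric_pair_averages_to_zero(self, rng):
        x = rng.normal(size=5)
        ds = make_dataset(np.vstack([x, -x]))
        out = spectra_io.average_by(ds, ("treatment", "day"))
        np.testing.assert_allclose(out.values, 0.0, atol=1e-15)

    def test_empty_keys_rejected(self, rng):
        ds = make_dataset(rng.normal(size=(2, 3)))
        with pytest.raises(ValueError, match="non-empty"):
            spectra_io.average_by(ds, ())

    def test_side_then_bag_hierarchy_unbiased(self, rng):
        # unbalanced sides: checkpoint mean must weight sides equally
        meta = [
            SampleMeta("A", 0, bag="1", side="front", replicate=1),
            SampleMeta("A", 0, bag="1", side="front", replicate=2),
            SampleMeta("A", 0, bag="1", side="front", replicate=3),
            SampleMeta("A", 0, bag="1", side="back", replicate=1),
        ]
        ds = make_dataset(np.array([[0.0], [0.0], [0.0], [4.0]]),
                          wavelengths=[1400.0], meta=meta)
        out = spectra_io.checkpoint_means(ds)
        np.testing.assert_allclose(out.values, [[2.0]])  # (0 + 4) / 2, not 1.0
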