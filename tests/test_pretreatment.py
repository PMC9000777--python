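"""Pretreatment operators: exactness on polynomials, scatter-correction
recovery, normalization round trips and metadata preservation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aquarocket import pretreatment as pt
from aquarocket.dataset import SampleMeta
from aquarocket.pretreatment import PretreatmentError

from conftest import make_dataset


def uniform_ds(f, n=125, lo=900.0, hi=1600.0, rows=1):
    wl = np.linspace(lo, hi, n)
    vals = np.tile(f(wl), (rows, 1))
    return make_dataset(vals, wavelengths=wl)


class TestMovingAverage:
    def test_constant_preserved_on_trimmed_grid(self):
        ds = uniform_ds(lambda wl: np.full_like(wl, 3.5))
        out = pt.moving_average(ds, 15)
        assert out.n_wavelengths == 125 - 14
        np.testing.assert_allclose(out.values, 3.5, atol=1e-12)

    def test_linear_trend_preserved(self):
        ds = uniform_ds(lambda wl: 0.2 + 0.003 * wl)
        out = pt.moving_average(ds, 15)
        np.testing.assert_allclose(out.values[0], 0.2 + 0.003 * out.wavelengths, rtol=1e-12)

    @pytest.mark.parametrize("window", [2, 1, 127])
    def test_invalid_window_rejected(self, window):
        ds = uniform_ds(np.sin)
        with pytest.raises(PretreatmentError):
            pt.moving_average(ds, window)


class TestSavitzkyGolay:
    def test_exact_second_derivative_of_quadratic(self):
        ds = uniform_ds(lambda wl: 0.5 * wl**2 - 3 * wl + 1)
        out = pt.sg_derivative(ds, window=21, polyorder=2, deriv=2)
        np.testing.assert_allclose(out.values, 1.0, rtol=1e-8)

    def test_constant_has_zero_first_derivative(self):
        ds = uniform_ds(lambda wl: np.full_like(wl, 2.0))
        out = pt.sg_derivative(ds, window=11, polyorder=2, deriv=1)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)

    def test_smoothing_mode_reproduces_polynomial(self):
        ds = uniform_ds(lambda wl: 1e-6 * wl**2)
        out = pt.sg_derivative(ds, window=15, polyorder=2, deriv=0)
        np.testing.assert_allclose(out.values[0], 1e-6 * out.wavelengths**2, rtol=1e-10)

    def test_sine_matches_analytic_second_derivative(self):
        wl = np.arange(1000.0, 1200.0)  # unit spacing
        ds = make_dataset([np.sin(wl / 50.0)], wavelengths=wl)
        out = pt.sg_derivative(ds, window=11, polyorder=2, deriv=2)
        analytic = -np.sin(out.wavelengths / 50.0) / 2500.0
        np.testing.assert_allclose(out.values[0], analytic, rtol=1e-3, atol=1e-7)

    def test_nonuniform_grid_rejected(self):
        wl = np.array([1300.0, 1301.0, 1303.0, 1310.0, 1330.0, 1331.0, 1332.0])
        ds = make_dataset([np.ones(7)], wavelengths=wl)
        with pytest.raises(Exception, match="uniform"):
            pt.sg_derivative(ds, window=3, polyorder=1, deriv=1)

    def test_deriv_above_polyorder_rejected(self):
        ds = uniform_ds(np.sin)
        with pytest.raises(PretreatmentError):
            pt.sg_derivative(ds, window=11, polyorder=1, deriv=2)


class TestNorrisGap:
    def test_exact_slope_on_linear(self):
        ds = uniform_ds(lambda wl: 0.004 * wl - 1.0)
        out = pt.norris_gap(ds, gap=21)
        assert out.n_wavelengths == 125 - 20
        np.testing.assert_allclose(out.values, 0.004, rtol=1e-10)

    def test_zero_on_constant(self):
        ds = uniform_ds(lambda wl: np.full_like(wl, 0.7))
        np.testing.assert_allclose(pt.norris_gap(ds, 21).values, 0.0, atol=1e-15)

    def test_symmetric_difference_exact_on_quadratic(self):
        # brute-force symmetric difference oracle
        ds = uniform_ds(lambda wl: wl**2)
        out = pt.norris_gap(ds, gap=21)
        g = 10
        wl = ds.wavelengths
        oracle = (ds.values[0, 2 * g:] - ds.values[0, : 125 - 2 * g]) / (
            wl[2 * g:] - wl[: 125 - 2 * g]
        )
        np.testing.assert_allclose(out.values[0], oracle, rtol=0, atol=0)
        np.testing.assert_allclose(out.values[0], 2 * out.wavelengths, rtol=1e-12)

    def test_agrees_with_sg_on_smooth_spectra(self):
        # feature much wider than either derivative span, so both operators
        # approximate the same analytic derivative closely
        ds = uniform_ds(lambda wl: np.exp(-0.5 * ((wl - 1250) / 150.0) ** 2))
        ng = pt.norris_gap(ds, gap=11)
        sg = pt.sg_derivative(ds, window=11, polyorder=2, deriv=1)
        scale = np.abs(sg.values).max()
        np.testing.assert_allclose(ng.values[0], sg.values[0], atol=0.02 * scale)

    def test_gap_too_large_rejected(self):
        ds = make_dataset([np.arange(10.0)], wavelengths=np.arange(10.0) + 1300)
        with pytest.raises(PretreatmentError, match="gap"):
            pt.norris_gap(ds, gap=21)


class TestSNV:
    def test_rows_standardized(self, rng):
        ds = make_dataset(rng.normal(size=(5, 30)))
        out = pt.snv(ds)
        np.testing.assert_allclose(out.values.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.values.std(axis=1, ddof=1), 1.0, rtol=1e-12)

    @settings(derandomize=True, deadline=None, max_examples=25)
    @given(
        a=st.floats(min_value=0.1, max_value=10.0),
        b=st.floats(min_value=-5.0, max_value=5.0),
    )
    def test_affine_invariance(self, a, b):
        rng = np.random.default_rng(99)
        x = rng.normal(size=(3, 20))
        base = pt.snv(make_dataset(x))
        scaled = pt.snv(make_dataset(a * x + b))
        np.testing.assert_allclose(scaled.values, base.values, rtol=1e-9, atol=1e-9)

    def test_constant_row_rejected(self):
        ds = make_dataset(np.ones((1, 10)))
        with pytest.raises(PretreatmentError, match="sample 0"):
            pt.snv(ds)


class TestMSC:
    def test_noiseless_affine_distortions_recovered(self, rng):
        ref = np.sort(rng.uniform(0.2, 1.0, 40))
        slopes = np.array([0.5, 2.0, 1.3, 0.8])
        offsets = np.array([-0.1, 0.3, 0.05, -0.2])
        X = slopes[:, None] * ref + offsets[:, None]
        ds = make_dataset(X)
        out, coeffs = pt.msc(ds, reference=ref)
        np.testing.assert_allclose(out.values, np.tile(ref, (4, 1)), atol=1e-10)
        # independent least-squares oracle per row
        for i in range(4):
            a_o, b_o = np.polyfit(ref, X[i], 1)
            assert abs(coeffs[i, 0] - a_o) < 1e-10
            assert abs(coeffs[i, 1] - b_o) < 1e-10
        np.testing.assert_allclose(coeffs[:, 0], slopes, atol=1e-10)
        np.testing.assert_allclose(coeffs[:, 1], offsets, atol=1e-10)

    def test_reference_maps_to_itself(self, rng):
        ref = rng.uniform(0.2, 1.0, 25)
        ds = make_dataset(np.vstack([ref, 2 * ref]))
        out, coeffs = pt.msc(ds, reference=ref)
        np.testing.assert_allclose(out.values[0], ref, atol=1e-12)
        np.testing.assert_allclose(coeffs[0], [1.0, 0.0], atol=1e-12)

    def test_idempotent_with_fixed_reference(self, rng):
        ref = np.sort(rng.uniform(0.2, 1.0, 30))
        ds = make_dataset(rng.uniform(0.1, 1.2, (5, 30)))
        once, _ = pt.msc(ds, reference=ref)
        twice, _ = pt.msc(once, reference=ref)
        np.testing.assert_allclose(twice.values, once.values, rtol=1e-10)

    def test_zero_variance_reference_rejected(self, rng):
        ds = make_dataset(rng.normal(size=(3, 10)))
        with pytest.raises(PretreatmentError, match="variance"):
            pt.msc(ds, reference=np.ones(10))

    def test_negative_slope_warns(self, rng):
        ref = np.sort(rng.uniform(0.2, 1.0, 20))
        ds = make_dataset(np.vstack([ref, -ref]))
        with pytest.warns(RuntimeWarning, match="slope"):
            pt.msc(ds, reference=ref)


class TestAquaNormalize:
    def test_columns_standardized(self, rng):
        ds = make_dataset(rng.normal(size=(20, 15)))
        out, stats = pt.aqua_normalize(ds)
        np.testing.assert_allclose(out.values.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(out.values.std(axis=0, ddof=1), 1.0, atol=1e-10)
        assert stats.n == 20

    def test_symmetric_pair(self, rng):
        x = rng.normal(size=12)
        ds = make_dataset(np.vstack([x, -x]))
        out, _ = pt.aqua_normalize(ds)
        sd = np.abs(x) * np.sqrt(2.0)  # column sd of {x, -x} with ddof=1
        np.testing.assert_allclose(out.values[0], x / sd, rtol=1e-12)
        np.testing.assert_allclose(out.values[0], -out.values[1], atol=1e-12)

    def test_inverse_restores_input(self, rng):
        ds = make_dataset(rng.normal(loc=0.5, size=(10, 8)))
        out, stats = pt.aqua_normalize(ds)
        back = pt.aqua_denormalize(out, stats)
        np.testing.assert_allclose(back.values, ds.values, rtol=1e-12)

    def test_identical_spectra_rejected(self):
        ds = make_dataset(np.tile(np.linspace(0, 1, 10), (2, 1)))
        with pytest.raises(PretreatmentError, match="nm"):
            pt.aqua_normalize(ds)


class TestPipelines:
    def test_presets_cover_documented_chains(self):
        assert [s.kind for s in pt.PRESETS["pca_prep"]] == [
            "moving_average", "norris_gap", "truncate",
        ]
        assert [s.kind for s in pt.PRESETS["pls_prep"]] == ["snv", "sg_derivative"]
        assert [s.kind for s in pt.PRESETS["aqua_prep"]] == [
            "sg_derivative", "msc", "truncate", "aqua_normalize",
        ]

    def test_metadata_preserved_and_order_stable(self, rng):
        meta = [
            SampleMeta("A", 0, "1", "front", 1),
            SampleMeta("B", 4, "2", "back", 2),
            SampleMeta("C", 13, "3", "front", 3),
        ]
        ds = make_dataset(
            rng.uniform(0.1, 1.0, (3, 125)),
            wavelengths=np.linspace(900, 1600, 125),
            meta=meta,
        )
        for preset in ("pca_prep", "pls_prep"):
            out, _ = pt.apply_pipeline(ds, preset)
            assert out.samples == meta

    def test_side_info_exposes_normalization_stats(self, rng):
        ds = make_dataset(rng.uniform(0.1, 1.0, (6, 125)),
                          wavelengths=np.linspace(900, 1600, 125))
        out, side = pt.apply_pipeline(ds, "aqua_prep")
        stats = side["3:aqua_normalize"]
        assert stats.mu.size == out.n_wavelengths

    def test_steps_from_yaml_style_config(self):
        steps = pt.steps_from_config(
            [{"kind": "snv"}, {"kind": "moving_average", "window": 5}]
        )
        assert steps[0].kind == "snv"
        assert steps[1].params == {"window": 5}

    def test_unknown_preset_rejected(self, rng):
        ds = make_dataset(rng.normal(size=(2, 10)))
        with pytest.raises(PretreatmentError, match="preset"):
            pt.apply_pipeline(ds, "nope")
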