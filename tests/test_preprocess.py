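"""Preprocessing chain: binning, RIP alignment, cropping, baseline, unfold."""

import dataclasses
import logging

import numpy as np
import pytest

from imsferm.preprocess import (
    AxisMap,
    GCIMSSpectrum,
    PreprocessConfig,
    average_duplicates,
    baseline_correct,
    bin_retention,
    crop,
    default_drift_grid,
    detect_rip,
    normalize_and_resample,
    preprocess_pipeline,
    refold,
    unfold,
)
from imsferm.simulate import GeneratorConfig, generate_dataset

from conftest import make_gaussian_spectrum


def spectrum_from(intensity, rt=None, dt=None, **kwargs):
    intensity = np.asarray(intensity, float)
    r, d = intensity.shape
    return GCIMSSpectrum(
        sample_id=kwargs.pop("sample_id", "s"),
        replicate_id=kwargs.pop("replicate_id", "a"),
        intensity=intensity,
        retention_axis=rt if rt is not None else np.arange(r, dtype=float),
        drift_axis=dt if dt is not None else np.arange(d, dtype=float) + 1.0,
        **kwargs,
    )


class TestBinRetention:
    def test_factor_one_is_identity(self):
        spec = spectrum_from(np.arange(12.0).reshape(4, 3))
        assert bin_retention(spec, 1) is spec

    def test_constant_rows_stay_constant(self):
        spec = spectrum_from(np.full((10, 4), 7.0))
        out = bin_retention(spec, 5)
        assert out.intensity.shape == (2, 4)
        assert np.allclose(out.intensity, 7.0)

    def test_mean_of_five_rows(self):
        spec = spectrum_from(np.array([[1.0], [2.0], [3.0], [4.0], [5.0]]))
        out = bin_retention(spec, 5)
        assert out.intensity.shape == (1, 1)
        assert out.intensity[0, 0] == pytest.approx(3.0)

    def test_trailing_partial_bin_kept(self):
        spec = spectrum_from(np.arange(7.0).reshape(7, 1))
        out = bin_retention(spec, 5)
        assert out.intensity.shape == (2, 1)
        assert out.intensity[1, 0] == pytest.approx(5.5)  # mean of rows 5, 6

    def test_factor_exceeding_rows_rejected(self):
        spec = spectrum_from(np.zeros((3, 2)))
        with pytest.raises(ValueError, match="factor"):
            bin_retention(spec, 5)


class TestDetectRip:
    def _with_rip(self, rip_ms=2.40, shift=0.0):
        dt = np.arange(2.0, 3.0, 0.01) + shift
        rt = np.arange(0.0, 50.0, 1.0)
        rip = 100.0 * np.exp(-0.5 * ((dt - rip_ms - shift) / 0.03) ** 2)
        analyte = 30.0 * np.outer(
            np.exp(-0.5 * ((rt - 25.0) / 4.0) ** 2),
            np.exp(-0.5 * ((dt - 2.7 - shift) / 0.02) ** 2),
        )
        return spectrum_from(analyte + rip, rt=rt, dt=dt)

    def test_planted_rip_recovered_within_one_step(self):
        spec = self._with_rip()
        assert detect_rip(spec) == pytest.approx(2.40, abs=0.011)

    def test_translation_equivariance(self):
        base = detect_rip(self._with_rip())
        shifted = detect_rip(self._with_rip(shift=0.05))
        assert shifted - base == pytest.approx(0.05, abs=0.011)

    def test_flat_spectrum_rejected(self):
        spec = spectrum_from(np.zeros((5, 20)))
        with pytest.raises(ValueError, match="flat"):
            detect_rip(spec)


class TestNormalizeAndResample:
    def test_values_preserved_on_grid_nodes(self):
        grid = default_drift_grid(1.0, 1.5, 101)
        rip = 2.0
        spec = make_gaussian_spectrum(
            dt_axis=grid * rip, dt_center=1.25 * rip, dt_sigma=0.05 * rip
        )
        out = normalize_and_resample(spec, rip, grid)
        assert np.allclose(out.intensity, spec.intensity, atol=1e-9)
        assert out.drift_units == "riprel"

    def test_riprel_invariance_under_drift_scale(self):
        grid = default_drift_grid(1.0, 1.4, 81)
        spec1 = make_gaussian_spectrum(
            dt_axis=np.linspace(1.9, 3.0, 120), dt_center=2.5, dt_sigma=0.06
        )
        c = 1.7
        spec2 = dataclasses.replace(spec1, drift_axis=spec1.drift_axis * c)
        out1 = normalize_and_resample(spec1, 2.0, grid)
        out2 = normalize_and_resample(spec2, 2.0 * c, grid)
        assert np.allclose(out1.intensity, out2.intensity, atol=1e-9)

    def test_peak_centroid_survives_resampling(self):
        rip = 7.5
        dt = np.arange(7.0, 15.2, 0.018)
        spec = make_gaussian_spectrum(
            dt_axis=dt, dt_center=1.50 * rip, dt_sigma=0.008 * rip
        )
        grid = default_drift_grid()
        out = normalize_and_resample(spec, rip, grid)
        profile = out.intensity.sum(axis=0)
        centroid = (grid * profile).sum() / profile.sum()
        step = grid[1] - grid[0]
        assert abs(centroid - 1.50) < step / 2

    def test_grid_beyond_source_range_rejected(self):
        spec = make_gaussian_spectrum(dt_axis=np.linspace(2.0, 3.0, 50))
        with pytest.raises(ValueError, match="beyond"):
            normalize_and_resample(spec, 2.0, np.linspace(0.5, 1.5, 50))


class TestCrop:
    def test_bounds_inclusive(self):
        grid = np.linspace(1.0, 2.1, 111)
        spec = make_gaussian_spectrum(
            rt_axis=np.linspace(100.0, 700.0, 61), dt_axis=grid
        )
        spec = dataclasses.replace(spec, drift_units="riprel")
        out = crop(spec)
        assert out.drift_axis.min() >= 1.03 and out.drift_axis.max() <= 2.0
        assert out.retention_axis.min() >= 150.0
        assert out.retention_axis.max() <= 600.0

    def test_inside_bounds_is_identity(self):
        spec = make_gaussian_spectrum(
            rt_axis=np.linspace(200.0, 500.0, 31),
            dt_axis=np.linspace(1.1, 1.9, 41),
        )
        spec = dataclasses.replace(spec, drift_units="riprel")
        out = crop(spec)
        assert np.array_equal(out.intensity, spec.intensity)

    def test_empty_result_rejected(self):
        spec = make_gaussian_spectrum(
            rt_axis=np.linspace(700.0, 800.0, 11),
            dt_axis=np.linspace(1.1, 1.9, 21),
        )
        spec = dataclasses.replace(spec, drift_units="riprel")
        with pytest.raises(ValueError, match="empty"):
            crop(spec)


class TestBaselineCorrect:
    def test_constant_spectrum_maps_to_zero(self):
        spec = spectrum_from(np.full((40, 60), 3.0))
        out = baseline_correct(spec)
        assert np.abs(out.intensity).max() < 1e-9 * 3.0

    def test_peak_on_ramp_keeps_its_volume(self):
        rt = np.arange(0.0, 100.0, 1.0)
        dt = np.arange(2.0, 3.0, 0.01)
        clean = make_gaussian_spectrum(rt_axis=rt, dt_axis=dt)
        ramp = np.outer(0.2 * rt, np.ones(dt.size))
        ramped = dataclasses.replace(
            clean, intensity=clean.intensity + ramp
        )
        v_clean = baseline_correct(clean).intensity.sum()
        v_ramped = baseline_correct(ramped).intensity.sum()
        assert v_ramped == pytest.approx(v_clean, rel=0.05)

    def test_output_nonnegative(self):
        rng = np.random.default_rng(0)
        spec = spectrum_from(rng.normal(5.0, 2.0, size=(50, 80)))
        assert baseline_correct(spec).intensity.min() >= 0.0

    def test_window_below_three_points_rejected(self):
        spec = spectrum_from(np.ones((5, 5)))
        with pytest.raises(ValueError, match="window"):
            baseline_correct(spec)


class TestAverageDuplicates:
    def test_identical_duplicates_pass_through(self):
        a = make_gaussian_spectrum(sample_id="s1")
        b = dataclasses.replace(a, replicate_id="b")
        (out,) = average_duplicates([a, b])
        assert np.array_equal(out.intensity, a.intensity)

    def test_mean_of_v_and_3v(self):
        a = make_gaussian_spectrum(sample_id="s1")
        b = dataclasses.replace(
            a, replicate_id="b", intensity=3.0 * a.intensity
        )
        (out,) = average_duplicates([a, b])
        assert np.allclose(out.intensity, 2.0 * a.intensity)
        assert out.metadata["n_replicates"] == 2

    def test_single_replicate_warns(self, caplog):
        a = make_gaussian_spectrum(sample_id="lonely")
        with caplog.at_level(logging.WARNING, logger="imsferm.preprocess"):
            (out,) = average_duplicates([a])
        assert "single replicate" in caplog.text
        assert np.array_equal(out.intensity, a.intensity)

    def test_axis_mismatch_rejected(self):
        a = make_gaussian_spectrum(sample_id="s1")
        b = dataclasses.replace(
            a, replicate_id="b", drift_axis=a.drift_axis * 1.01
        )
        with pytest.raises(ValueError, match="axes"):
            average_duplicates([a, b])


class TestUnfoldRefold:
    def test_two_by_two_example(self):
        from imsferm.preprocess import SpectrumCube

        cube = SpectrumCube(
            intensity=np.array([[[1.0, 2.0], [3.0, 4.0]]]),
            retention_axis=np.array([0.0, 1.0]),
            drift_axis=np.array([1.1, 1.2]),
            sample_ids=["s"],
            class_labels=[None],
        )
        mat = unfold(cube)
        assert np.array_equal(mat.values[0], [1.0, 2.0, 3.0, 4.0])
        assert np.array_equal(
            refold(mat.values[0], mat.axis_map), cube.intensity[0]
        )

    def test_random_cube_round_trip_exact(self):
        from imsferm.preprocess import SpectrumCube

        rng = np.random.default_rng(5)
        cube = SpectrumCube(
            intensity=rng.uniform(0, 1, size=(3, 7, 11)),
            retention_axis=np.arange(7.0),
            drift_axis=np.arange(11.0) + 1,
            sample_ids=[f"s{i}" for i in range(3)],
            class_labels=[None] * 3,
        )
        mat = unfold(cube)
        for s in range(3):
            assert np.array_equal(
                refold(mat.values[s], mat.axis_map), cube.intensity[s]
            )

    def test_axis_map_is_retention_major(self):
        amap = AxisMap(n_retention=4, n_drift=6)
        assert amap.to_indices(0) == (0, 0)
        assert amap.to_indices(6) == (1, 0)
        assert amap.to_column(1, 0) == 6
        with pytest.raises(IndexError):
            amap.to_indices(24)

    def test_wrong_vector_length_rejected(self):
        with pytest.raises(ValueError, match="R\\*D"):
            refold(np.zeros(5), AxisMap(2, 3))


@pytest.fixture(scope="module")
def small_dataset():
    config = GeneratorConfig(samples_per_class=2, seed=11)
    return generate_dataset(config), config


class TestPipeline:
    def test_one_row_per_sample_and_nonnegative(self, small_dataset):
        (spectra, truth), _ = small_dataset
        cube, unfolded = preprocess_pipeline(spectra)
        assert cube.shape[0] == len(truth.samples)
        assert unfolded.values.min() >= 0.0

    def test_planted_positions_inside_cropped_axes(self, small_dataset):
        (spectra, truth), _ = small_dataset
        cube, _ = preprocess_pipeline(spectra)
        for name, (rt, dt) in truth.positions.items():
            assert cube.retention_axis.min() <= rt <= cube.retention_axis.max()
            assert cube.drift_axis.min() <= dt <= cube.drift_axis.max()

    def test_invariance_under_global_drift_rescale(self, small_dataset):
        (spectra, _), _ = small_dataset
        scaled = [
            dataclasses.replace(s, drift_axis=s.drift_axis * 1.3)
            for s in spectra
        ]
        cube1, _ = preprocess_pipeline(spectra)
        cube2, _ = preprocess_pipeline(scaled)
        scale = np.abs(cube1.intensity).max()
        assert np.abs(cube1.intensity - cube2.intensity).max() < 1e-8 * scale

    def test_fewer_than_two_samples_rejected(self):
        spec = make_gaussian_spectrum()
        with pytest.raises(ValueError, match="2 samples"):
            preprocess_pipeline([spec])
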