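"""Generator correctness: the synthetic data must encode exactly the
ground truth it reports."""

import numpy as np
import pandas as pd
import pytest

from ctecv import phantom as ph
from ctecv.errors import ValidationError


# ---------------------------------------------------------------------------
# paired CT
# ---------------------------------------------------------------------------

class TestPairedCT:
    def test_pre_phase_intensities(self, clean_phantom):
        spec, pre, _, truth = clean_phantom
        geom = truth.geometry
        bg = ~geom.epi_mask
        assert np.all(pre.data[bg] == spec.background_hu)
        assert np.all(pre.data[geom.endo_mask] == spec.hu_blood_pre)
        assert np.all(pre.data[geom.myo_mask] == spec.hu_myo_pre)

    def test_blood_pool_enhancement_exact(self, clean_phantom):
        spec, pre, delayed, truth = clean_phantom
        diff = delayed.data - pre.data
        assert np.allclose(diff[truth.geometry.endo_mask], spec.delta_hu_blood)

    def test_segment_enhancement_inverts_ecv_equation(self, clean_phantom):
        spec, pre, delayed, truth = clean_phantom
        diff = delayed.data - pre.data
        labels = truth.geometry.labels
        for seg in range(1, 17):
            want = truth.true_ecv[seg - 1] * spec.delta_hu_blood / (1 - spec.hematocrit)
            got = diff[labels == seg]
            assert np.allclose(got, want), f"segment {seg}"
            assert np.isclose(want, truth.delta_hu_myo[seg - 1])

    def test_texture_cancels_in_aligned_subtraction(self, noiseless_phantom):
        spec, pre, delayed, truth = noiseless_phantom
        diff = delayed.data - pre.data
        assert np.allclose(diff[truth.geometry.endo_mask], spec.delta_hu_blood)
        # pre voxels inside the wall vary (texture present)
        assert pre.data[truth.geometry.myo_mask].std() > 5.0

    def test_noise_level_and_determinism(self):
        spec = ph.PhantomSpec(noise_sd=10.0)
        pre1, d1, _ = ph.generate_paired_ct(spec)
        pre2, d2, _ = ph.generate_paired_ct(spec)
        assert np.array_equal(pre1.data, pre2.data)
        assert np.array_equal(d1.data, d2.data)
        clean, _, _ = ph.generate_paired_ct(ph.PhantomSpec(noise_sd=0.0))
        resid = pre1.data - clean.data
        assert abs(resid.std() - 10.0) < 0.2
        # pre and delayed noise are independent
        other = d1.data - ph.generate_paired_ct(ph.PhantomSpec(noise_sd=0.0))[1].data
        assert abs(np.corrcoef(resid.ravel(), other.ravel())[0, 1]) < 0.01

    def test_lesion_painted_in_requested_band(self):
        from ctecv.lvmodel import wall_depth
        les = ph.Lesion(segment=8, depth_max=0.5, delta_hu=60.0)
        spec = ph.PhantomSpec(noise_sd=0.0, texture_sd_hu=0.0, lesions=(les,))
        pre, delayed, truth = ph.generate_paired_ct(spec)
        m = truth.lesion_masks[0]
        assert m.any()
        assert np.all(truth.geometry.labels[m] == 8)
        depth = wall_depth(truth.geometry)
        assert np.nanmax(depth[m]) <= 0.5
        base = truth.delta_hu_myo[7]
        assert np.allclose((delayed.data - pre.data)[m], base + 60.0)

    def test_misalignment_truth_transform_matches_warp(self):
        # the stored transform, applied to the unwarped delayed volume,
        # reproduces the generated delayed volume exactly
        import SimpleITK as sitk
        mis = ph.Misalignment(translation_mm=(3.0, -2.0, 1.0))
        spec = ph.PhantomSpec(noise_sd=0.0, misalignment=mis)
        _, delayed, truth = ph.generate_paired_ct(spec)
        spec0 = ph.PhantomSpec(noise_sd=0.0)
        _, delayed0, _ = ph.generate_paired_ct(spec0)
        img = delayed0.to_sitk()
        warped = sitk.Resample(img, img, truth.resample_transform,
                               sitk.sitkLinear, spec.background_hu,
                               sitk.sitkFloat64)
        assert np.allclose(sitk.GetArrayFromImage(warped).T, delayed.data,
                           atol=1e-8)

    @pytest.mark.parametrize("bad", [
        dict(hematocrit=0.0),
        dict(hematocrit=1.2),
        dict(true_ecv=(0.3,) * 15),
        dict(true_ecv=(0.3,) * 15 + (1.5,)),
        dict(endo_radius=26.0, epi_radius=26.0),
        dict(lv_center=(10.0, 48.0, 66.0)),   # LV sticks out of the grid
        dict(noise_sd=-1.0),
        dict(long_axis_extent=5.0),
    ])
    def test_spec_validation(self, bad):
        with pytest.raises(ValidationError):
            ph.PhantomSpec(**bad)

    def test_lesion_segment_out_of_range(self):
        spec = ph.PhantomSpec(lesions=(ph.Lesion(17, 0.5, 60.0),))
        with pytest.raises(ValidationError):
            ph.generate_paired_ct(spec)


# ---------------------------------------------------------------------------
# perfusion series
# ---------------------------------------------------------------------------

class TestPerfusionSeries:
    def test_shapes_and_truth(self):
        spec = ph.PhantomSpec()
        mbf = np.linspace(60, 120, 16)
        t, art, tissue, truth = ph.generate_perfusion_series(spec, mbf)
        assert tissue.shape == (16, t.size)
        assert art.shape == t.shape
        assert np.array_equal(truth.true_mbf, mbf)
        assert art.max() == pytest.approx(200.0, rel=1e-6)

    def test_tissue_slope_encodes_mbf(self):
        spec = ph.PhantomSpec()
        mbf = np.full(16, 90.0)
        t, art, tissue, _ = ph.generate_perfusion_series(spec, mbf, dt=0.05)
        slope = np.gradient(tissue[0], t).max()
        assert slope == pytest.approx(90.0 / 6000.0 * art.max(), rel=1e-3)

    @pytest.mark.parametrize("kwargs", [
        dict(dt=0.0), dict(true_mbf=np.ones(15)), dict(true_mbf=np.zeros(16)),
    ])
    def test_validation(self, kwargs):
        spec = ph.PhantomSpec()
        args = dict(true_mbf=np.full(16, 80.0))
        args.update(kwargs)
        with pytest.raises(ValidationError):
            ph.generate_perfusion_series(spec, **args)


# ---------------------------------------------------------------------------
# calcium volume
# ---------------------------------------------------------------------------

class TestCalciumVolume:
    def test_background_below_threshold_and_plaque_present(self):
        spec = ph.PhantomSpec(seed=3)
        plq = [ph.Plaque((20.0, 20.0, 3.0), 12.0, 450.0)]
        vol, truth = ph.generate_calcium_volume(spec, plq)
        k = 1  # 3 mm / 3 mm slices
        assert (vol.data >= 130).sum() == 12
        assert vol.data[:, :, k].max() == 450.0
        assert len(truth.plaques) == 1
        assert truth.plaques[0]["area_mm2"] == pytest.approx(12.0)
        assert truth.plaques[0]["peak_hu"] == 450.0

    def test_overlap_warns_and_merges(self):
        spec = ph.PhantomSpec()
        plq = [ph.Plaque((20.0, 20.0, 0.0), 10.0, 300.0),
               ph.Plaque((21.0, 20.0, 0.0), 10.0, 500.0)]
        with pytest.warns(UserWarning, match="overlap"):
            _, truth = ph.generate_calcium_volume(spec, plq)
        assert len(truth.plaques) == 1
        assert truth.plaques[0]["peak_hu"] == 500.0

    @pytest.mark.parametrize("plaque", [
        ph.Plaque((20.0, 20.0, 0.0), 10.0, 100.0),    # below 130 HU
        ph.Plaque((20.0, 20.0, 0.0), -1.0, 300.0),
        ph.Plaque((20.0, 20.0, 99.0), 10.0, 300.0),   # slice out of grid
    ])
    def test_validation(self, plaque):
        with pytest.raises(ValidationError):
            ph.generate_calcium_volume(ph.PhantomSpec(), [plaque])


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

class TestCohort:
    def test_shape_and_groups(self):
        df = ph.generate_cohort(ph.CohortParams(seed=1))
        assert len(df) == 40
        assert (df["group"].value_counts() == 20).all()
        for col in ["male", "hypertension", "diabetes", "prior_mi"]:
            assert df[col].isin([0, 1]).all()
        pd.testing.assert_frame_equal(df, ph.generate_cohort(ph.CohortParams(seed=1)))

    def test_moments_and_correlation_at_large_n(self):
        df = ph.generate_cohort(ph.CohortParams(n_per_group=4000, seed=2))
        hd = df[df["group"] == "HD"]
        assert hd["ecv_pct"].mean() == pytest.approx(33.8, abs=0.3)
        assert hd["ecv_pct"].std() == pytest.approx(4.7, abs=0.3)
        r = np.corrcoef(hd["ecv_pct"], hd["lavi_ml_m2"])[0, 1]
        assert r == pytest.approx(0.54, abs=0.05)

    @pytest.mark.parametrize("kwargs", [
        dict(n_per_group=1), dict(ecv_lavi_correlation=1.0),
    ])
    def test_validation(self, kwargs):
        with pytest.raises(ValidationError):
            ph.CohortParams(**kwargs)
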