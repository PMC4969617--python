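import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from nanoheat.exceptions import ValidationError
from nanoheat.pet import (PETVolume, ROIMask, cohort_summary,
                          low_uptake_volume, percent_id_per_gram,
                          relative_change, respond, uptake_stats)
from nanoheat.synthetic import (PETPhantomSpec, make_pet_phantom,
                                make_response_phantom_pair)


def _volume(data, dims=(1.0, 1.0, 1.0), timepoint=""):
    return PETVolume(np.asarray(data, float), dims, timepoint)


def _full_roi(shape):
    return ROIMask(np.ones(shape, bool))


class TestUptakeStats:
    def test_constant_roi(self):
        vol = _volume(np.full((4, 4, 4), 5.0))
        assert uptake_stats(vol, _full_roi((4, 4, 4))) == (5.0, 5.0, 0.0)

    def test_two_voxel_hand_arithmetic(self):
        data = np.zeros((1, 1, 4))
        data[0, 0, :2] = [2.0, 4.0]
        mask = np.zeros((1, 1, 4), bool)
        mask[0, 0, :2] = True
        mean, mx, sd = uptake_stats(_volume(data), ROIMask(mask))
        assert (mean, mx) == (3.0, 4.0)
        assert sd == pytest.approx(np.sqrt(2.0))

    def test_gaussian_phantom_mean_within_clt_bound(self):
        vol, roi, _ = make_pet_phantom(PETPhantomSpec(seed=11))
        mean, _, sd = uptake_stats(vol, roi)
        n = roi.n_voxels
        assert abs(mean - 6.0) < 3.0 / np.sqrt(n)
        assert sd == pytest.approx(1.0, rel=0.05)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            uptake_stats(_volume(np.ones((2, 2, 2))), _full_roi((3, 3, 3)))

    def test_empty_roi_rejected(self):
        with pytest.raises(ValidationError, match="empty"):
            ROIMask(np.zeros((2, 2, 2), bool))


class TestLowUptakeVolume:
    def test_constant_uptake_gives_zero_with_warning(self):
        vol = _volume(np.full((4, 4, 4), 5.0))
        with pytest.warns(UserWarning, match="degenerate"):
            res = low_uptake_volume(vol, _full_roi((4, 4, 4)))
        assert res.v_low_mm3 == 0.0

    def test_gaussian_fraction_matches_normal_tail(self):
        vol, roi, _ = make_pet_phantom(PETPhantomSpec(seed=2))
        res = low_uptake_volume(vol, roi)
        p = norm.cdf(-1.5)
        frac = res.v_low_mm3 / res.roi_volume_mm3
        se = np.sqrt(p * (1 - p) / roi.n_voxels)
        assert abs(frac - p) < 3.0 * se

    def test_cold_lesion_volume_recovered(self):
        # lesion ~10% of a ~700 mm3 tumor, far below the bulk uptake
        spec = PETPhantomSpec(lesion_radius_mm=2.56, lesion_uptake=0.1,
                              seed=4)
        vol, roi, truth = make_pet_phantom(spec)
        res = low_uptake_volume(vol, roi)
        assert res.v_low_mm3 == pytest.approx(truth["lesion_volume_mm3"],
                                              rel=0.10)

    def test_affine_uptake_invariance_is_exact(self):
        vol, roi, _ = make_pet_phantom(PETPhantomSpec(seed=9))
        res0 = low_uptake_volume(vol, roi)
        scaled = _volume(2.5 * vol.data + 1.0, vol.voxel_dims_mm)
        res1 = low_uptake_volume(scaled, roi)
        assert res1.v_low_mm3 == res0.v_low_mm3

    def test_v_low_monotone_in_lesion_size(self):
        # monotone once the lesion dominates the Gaussian tail of the
        # bulk; below that the threshold shift can trade tail voxels
        # against lesion voxels (see docs/methods.md)
        v_lows = []
        for r in (1.5, 2.0, 2.5, 3.0):
            spec = PETPhantomSpec(lesion_radius_mm=r, lesion_uptake=0.1,
                                  seed=21)
            vol, roi, _ = make_pet_phantom(spec)
            res = low_uptake_volume(vol, roi)
            assert res.v_low_mm3 <= res.roi_volume_mm3
            v_lows.append(res.v_low_mm3)
        assert all(b >= a for a, b in zip(v_lows, v_lows[1:]))


class TestRelativeChange:
    def test_identical_volumes_give_unity(self):
        vol, roi, _ = make_pet_phantom(
            PETPhantomSpec(core_radius_mm=2.0, seed=3))
        res = low_uptake_volume(vol, roi)
        assert relative_change(res, res) == 1.0

    def test_scripted_pair_triples_v_low(self):
        baseline, day0, roi, truth = make_response_phantom_pair(seed=5)
        rb = low_uptake_volume(baseline, roi)
        rd = low_uptake_volume(day0, roi)
        assert relative_change(rd, rb) == pytest.approx(3.0, rel=0.10)

    def test_zero_baseline_is_undefined(self):
        vol, roi, _ = make_pet_phantom(PETPhantomSpec(bulk_sd=0.0, seed=0))
        with pytest.warns(UserWarning):
            res0 = low_uptake_volume(vol, roi)
        with pytest.raises(ValidationError, match="baseline"):
            relative_change(res0, res0)

    def test_respond_series_carries_relative_changes(self):
        baseline, day0, roi, _ = make_response_phantom_pair(seed=8)
        results = respond(baseline, [day0], roi)
        assert results[0].relative_change is None
        assert results[1].relative_change == pytest.approx(
            results[1].v_low_mm3 / results[0].v_low_mm3)


class TestCohortSummary:
    def test_known_group_means_recovered(self):
        df = pd.DataFrame({
            "group": ["AuNS", "AuNS", "saline", "saline"],
            "relative_change": [3.0, 5.0, 1.0, 1.2],
        })
        out = cohort_summary(df).set_index("group")
        assert out.loc["AuNS", "mean"] == 4.0
        assert out.loc["saline", "mean"] == pytest.approx(1.1)
        assert not out["sd_undefined"].any()

    def test_single_animal_group_flags_sd(self):
        df = pd.DataFrame({"group": ["g"], "relative_change": [2.0]})
        out = cohort_summary(df)
        assert out.loc[0, "mean"] == 2.0
        assert out.loc[0, "sd"] == 0.0 and bool(out.loc[0, "sd_undefined"])

    def test_row_order_invariance(self):
        df = pd.DataFrame({
            "group": ["b", "a", "b", "a"],
            "relative_change": [2.0, 1.0, 4.0, 3.0],
        })
        out1 = cohort_summary(df)
        out2 = cohort_summary(df.iloc[::-1].reset_index(drop=True))
        pd.testing.assert_frame_equal(out1, out2)


def test_percent_id_per_gram_helper():
    out = percent_id_per_gram(np.array([1000.0]), injected_dose_Bq=1e7,
                              body_weight_g=20.0)
    assert out[0] == pytest.approx(100.0 * 1000.0 / 1e7 * 20.0)
    with pytest.raises(ValidationError):
        percent_id_per_gram(np.array([1.0]), 0.0, 20.0)
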