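import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pqlung.texture_features import (
    FEATURE_NAMES, FeatureDataset, RoiWindow,
    air_fraction, build_dataset, extract_features, feature_map,
    roi_mean, roi_window, slice_correlation,
)
from pqlung.volume_io import BinaryMask, CTVolume, MaskRole


def brute_force_features(values):
    """Independent direct-formula evaluation of the window statistics."""
    v = np.asarray(values, dtype=float)
    n = len(v)
    mean = sum(v) / n
    var = sum((x - mean) ** 2 for x in v) / n
    sd = var ** 0.5
    if sd == 0:
        skew = kurt = 0.0
    else:
        skew = (sum((x - mean) ** 3 for x in v) / n) / sd ** 3
        kurt = (sum((x - mean) ** 4 for x in v) / n) / sd ** 4 - 3.0
    air = sum(1 for x in v if x < -825.0) / n
    return mean, sd, max(v), min(v), skew, kurt, air


def _full_lung_volume(hu):
    vol = CTVolume(hu, (1.25, 0.7, 0.7))
    lung = BinaryMask(np.ones(hu.shape, bool), MaskRole.lung, spacing_mm=vol.spacing_mm)
    return vol, lung


class TestRoiPrimitives:
    def test_full_window_is_49_pixels(self):
        hu = np.full((3, 9, 9), -850.0)
        vol, lung = _full_lung_volume(hu)
        win = roi_window(vol, lung, (1, 4, 4))
        assert win.n_valid == 49
        assert roi_mean(win) == pytest.approx(-850.0)

    def test_roi_mean_divisor_49(self):
        # 48 pixels at -1000 and one at -20 -> (48*(-1000) + (-20)) / 49 = -980
        hu = np.full((3, 9, 9), -1000.0)
        hu[1, 4, 4] = -20.0
        vol, lung = _full_lung_volume(hu)
        win = roi_window(vol, lung, (1, 4, 4))
        assert roi_mean(win) == pytest.approx(-980.0)

    def test_boundary_window_divides_by_valid_count(self):
        hu = np.full((3, 9, 9), -700.0)
        bits = np.zeros(hu.shape, bool)
        bits[1, 2:7, 2:8] = True  # 30 in-lung pixels inside the 7x7 at (1,4,4)
        vol = CTVolume(hu, (1, 1, 1))
        lung = BinaryMask(bits, MaskRole.lung)
        win = roi_window(vol, lung, (1, 4, 4))
        assert win.n_valid == 30
        assert roi_mean(win) == pytest.approx(-700.0)

    def test_empty_window_invalid(self):
        with pytest.raises(ValueError, match="empty"):
            RoiWindow(values=np.array([]), n_valid=0, center=(0, 0, 0))

    @pytest.mark.parametrize("means,expected", [
        ((-700.0, -700.0, -700.0), 0.0),        # equal slices -> both factors zero
        ((-800.0, -700.0, -800.0), 10000.0),    # isolated bright slice
        ((-800.0, -700.0, -600.0), -10000.0),   # monotone ramp
    ])
    def test_slice_correlation_product(self, means, expected):
        assert slice_correlation(*means) == pytest.approx(expected)

    def test_air_fraction_counts(self):
        hu = np.full((3, 9, 9), -500.0)
        hu[1, 2:4, 2:7] = -900.0  # 10 of 49 pixels below the air threshold
        vol, lung = _full_lung_volume(hu)
        win = roi_window(vol, lung, (1, 4, 4))
        assert air_fraction(win) == pytest.approx(10 / 49)
        assert air_fraction(RoiWindow(np.full(49, -1000.0), 49, (0, 0, 0))) == 1.0
        assert air_fraction(RoiWindow(np.full(49, -300.0), 49, (0, 0, 0))) == 0.0

    def test_air_fraction_threshold_monotone(self):
        rng = np.random.default_rng(0)
        win = RoiWindow(rng.uniform(-1000, 0, 49), 49, (0, 0, 0))
        fracs = [air_fraction(win, threshold=t) for t in (-900, -825, -700, -500)]
        assert fracs == sorted(fracs)


class TestExtractFeatures:
    def test_constant_region(self):
        hu = np.full((3, 9, 9), -850.0)
        vol, lung = _full_lung_volume(hu)
        fv = extract_features(vol, lung, (1, 4, 4))
        assert fv.sd == 0.0 and fv.skewness == 0.0 and fv.kurtosis == 0.0
        assert fv.max == fv.min == fv.mean == fv.center_hu == -850.0
        assert fv.rco == 0.0

    def test_center_outside_lung_rejected(self):
        hu = np.full((3, 9, 9), -850.0)
        vol = CTVolume(hu, (1, 1, 1))
        bits = np.ones(hu.shape, bool)
        bits[1, 4, 4] = False
        with pytest.raises(ValueError, match="outside"):
            extract_features(vol, BinaryMask(bits, MaskRole.lung), (1, 4, 4))

    def test_statistics_match_brute_force_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(50):
            hu = rng.uniform(-1100, 100, (3, 9, 9))
            vol, lung = _full_lung_volume(hu)
            fv = extract_features(vol, lung, (1, 4, 4))
            win = roi_window(vol, lung, (1, 4, 4))
            mean, sd, vmax, vmin, skew, kurt, air = brute_force_features(win.values)
            assert fv.mean == pytest.approx(mean, rel=1e-9)
            assert fv.sd == pytest.approx(sd, rel=1e-9)
            assert fv.max == vmax and fv.min == vmin
            assert fv.skewness == pytest.approx(skew, rel=1e-9)
            assert fv.kurtosis == pytest.approx(kurt, rel=1e-9)
            assert fv.air_fraction == air

    def test_first_slice_uses_one_sided_rco(self):
        rng = np.random.default_rng(5)
        hu = rng.uniform(-900, -600, (4, 9, 9))
        vol, lung = _full_lung_volume(hu)
        fv = extract_features(vol, lung, (0, 4, 4))
        m0 = roi_mean(roi_window(vol, lung, (0, 4, 4)))
        m1 = roi_mean(roi_window(vol, lung, (1, 4, 4)))
        assert fv.rco == pytest.approx((m0 - m1) ** 2)

    def test_rco_detects_single_slice_structure(self):
        hu = np.full((5, 9, 9), -850.0)
        hu[2] = -400.0  # structure on one slice only: partial-volume signature
        vol, lung = _full_lung_volume(hu)
        on = extract_features(vol, lung, (2, 4, 4)).rco
        off = extract_features(vol, lung, (1, 4, 4)).rco
        assert on == pytest.approx(450.0 ** 2)
        assert on > abs(off) - 1e-9


class TestFeatureMap:
    def test_matches_per_pixel_extraction(self, training_phantom):
        _, volume, truth = training_phantom
        lung = truth["lung"]
        coords, feats = feature_map(volume, lung)
        rng = np.random.default_rng(2)
        for idx in rng.choice(len(coords), 40, replace=False):
            fv = extract_features(volume, lung, tuple(coords[idx]))
            np.testing.assert_allclose(feats[idx], fv.to_array(), rtol=1e-7, atol=1e-6)

    def test_feature_count_is_nine(self, training_phantom):
        _, volume, truth = training_phantom
        _, feats = feature_map(volume, truth["lung"])
        assert feats.shape[1] == len(FEATURE_NAMES) == 9


class TestBuildDataset:
    def test_labels_match_truth_masks(self, training_phantom):
        _, volume, truth = training_phantom
        normal = truth["lung"].bits & ~truth["injured"].bits & ~truth["vessel"].bits
        ds = build_dataset(volume, truth["lung"],
                           {"injured": truth["injured"].bits, "noninjured": normal})
        counts = ds.class_counts
        assert counts["injured"] == int(truth["injured"].bits.sum())
        assert counts["noninjured"] == int(normal.sum())

    def test_empty_label_set_rejected(self, training_phantom):
        _, volume, truth = training_phantom
        empty = np.zeros(volume.shape, bool)
        with pytest.raises(ValueError, match="empty"):
            build_dataset(volume, truth["lung"], {"injured": empty})

    def test_labels_outside_lung_rejected(self, training_phantom):
        _, volume, truth = training_phantom
        outside = ~truth["lung"].bits
        with pytest.raises(ValueError, match="outside"):
            build_dataset(volume, truth["lung"], {"injured": outside})

    def test_single_class_flagged(self, training_phantom):
        _, volume, truth = training_phantom
        with pytest.warns(UserWarning, match="single-class"):
            build_dataset(volume, truth["lung"], {"injured": truth["injured"].bits})

    def test_csv_round_trip(self, training_phantom, tmp_path):
        _, volume, truth = training_phantom
        normal = truth["lung"].bits & ~truth["injured"].bits & ~truth["vessel"].bits
        ds = build_dataset(volume, truth["lung"],
                           {"injured": truth["injured"].bits, "noninjured": normal})
        ds.to_csv(tmp_path / "f.csv")
        back = FeatureDataset.from_csv(tmp_path / "f.csv")
        np.testing.assert_allclose(back.features, ds.features, rtol=1e-12)
        np.testing.assert_array_equal(back.labels, ds.labels)


@given(st.lists(st.floats(min_value=-1100, max_value=200), min_size=2, max_size=49),
       st.randoms(use_true_random=False))
@settings(max_examples=60, deadline=None)
def test_air_fraction_permutation_invariant(values, rnd):
    win = RoiWindow(np.array(values), len(values), (0, 0, 0))
    shuffled = list(values)
    rnd.shuffle(shuffled)
    win2 = RoiWindow(np.array(shuffled), len(values), (0, 0, 0))
    assert air_fraction(win) == air_fraction(win2)


@given(st.floats(min_value=-1000, max_value=0),
       st.floats(min_value=-1000, max_value=0),
       st.floats(min_value=-1000, max_value=0))
@settings(max_examples=100, deadline=None)
def test_rco_sign_flip_on_neighbour_swap(prev, cur, nxt):
    # swapping the temporal neighbours preserves the product
    assert slice_correlation(prev, cur, nxt) == pytest.approx(
        slice_correlation(nxt, cur, prev))
    if prev == cur == nxt:
        assert slice_correlation(prev, cur, nxt) == 0.0
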