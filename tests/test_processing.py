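"""Recalibration, peak picking/alignment, images, hotspot and ratio tests."""

import numpy as np
import pytest

from pctracer import (
    IonImage,
    MSIDataset,
    RegionMask,
    Spectrum,
    extract_ion_image,
    hotspot_clip,
    mean_spectrum,
    overlay_channels,
    pick_and_align_peaks,
    ratio_image,
    recalibrate_lock_mass,
)

LOCK = 756.551374


def _shifted_spectrum(ppm):
    mz = np.array([400.0, LOCK, 900.0]) * (1.0 + ppm * 1e-6)
    return Spectrum(mz, np.array([1.0, 10.0, 2.0]), (0, 0))


# --- lock-mass recalibration -------------------------------------------------


def test_recalibration_inverts_a_uniform_ppm_shift():
    rec, found = recalibrate_lock_mass(_shifted_spectrum(+5.0), LOCK, 20.0)
    assert found
    assert rec.mz[1] == pytest.approx(LOCK, abs=1e-5)
    np.testing.assert_allclose(rec.mz, [400.0, LOCK, 900.0], rtol=1e-9)


def test_recalibration_is_a_fixed_point_when_calibrated():
    s = _shifted_spectrum(0.0)
    rec, found = recalibrate_lock_mass(s, LOCK, 20.0)
    assert found
    np.testing.assert_allclose(rec.mz, s.mz, rtol=1e-9)


def test_recalibration_absent_lock_returns_unchanged():
    s = Spectrum([400.0, 500.0], [1.0, 1.0], (0, 0))
    rec, found = recalibrate_lock_mass(s, LOCK, 20.0)
    assert not found
    assert rec is s


def test_recalibration_picks_most_intense_candidate():
    mz = np.array([LOCK * (1 - 8e-6), LOCK * (1 + 4e-6)])
    s = Spectrum(mz, np.array([1.0, 50.0]), (0, 0))
    rec, found = recalibrate_lock_mass(s, LOCK, 20.0)
    assert found
    assert rec.mz[1] == pytest.approx(LOCK, abs=1e-6)


# --- peak picking and alignment ---------------------------------------------


def _dataset_from_peaks(pixel_peaks, ncols=None):
    """pixel_peaks: list (per pixel) of (mz, intensity) lists."""
    n = len(pixel_peaks)
    ncols = ncols or n
    spectra = []
    for i, peaks in enumerate(pixel_peaks):
        peaks = sorted(peaks)
        mz = np.array([p[0] for p in peaks])
        inten = np.array([p[1] for p in peaks])
        spectra.append(Spectrum(mz, inten, (i % ncols, i // ncols)))
    return MSIDataset(spectra, (ncols, (n + ncols - 1) // ncols))


def _oracle_pick(dataset, rel_thresh, min_freq, tol_ppm):
    """Brute-force O(n^2) replica of the greedy alignment rule."""
    base = max(s.intensities.max() for s in dataset if len(s))
    floor = rel_thresh * base
    peaks = [
        (m, i, px)
        for px, s in enumerate(dataset)
        for m, i in zip(s.mz, s.intensities)
        if i >= floor
    ]
    features = []
    remaining = list(peaks)
    while remaining:
        seed = max(remaining, key=lambda p: p[1])
        members = [
            p for p in remaining if abs(p[0] - seed[0]) / seed[0] * 1e6 <= tol_ppm
        ]
        remaining = [p for p in remaining if p not in members]
        w = sum(p[1] for p in members)
        cmz = sum(p[0] * p[1] for p in members) / w
        vec = np.zeros(len(dataset))
        for m, i, px in members:
            vec[px] += i
        features.append((cmz, vec))
    kept = [f for f in features if (f[1] > 0).mean() >= min_freq]
    kept.sort(key=lambda f: f[0])
    return kept


def test_low_frequency_feature_kept_above_min():
    ds = _dataset_from_peaks(
        [[(500.0, 100.0), (600.0, 50.0)], [(500.0, 90.0)], [(500.0, 95.0)]]
    )
    table = pick_and_align_peaks(ds, 0.0005, 0.005, 3.0)
    # 600 present in 1/3 pixels (33%) -> retained at min_frequency 0.5%
    assert np.any(np.isclose(table.mz, 600.0, atol=0.01))


def test_subthreshold_peak_dropped_everywhere():
    ds = _dataset_from_peaks(
        [[(500.0, 1e5), (600.0, 1.0)], [(500.0, 1e5), (600.0, 1.0)]]
    )
    table = pick_and_align_peaks(ds, 0.0005, 0.005, 3.0)
    assert not np.any(np.isclose(table.mz, 600.0, atol=0.01))


def test_alignment_merges_within_and_splits_beyond_tolerance():
    close = _dataset_from_peaks(
        [[(700.0, 10.0)], [(700.0 * (1 + 2e-6), 10.0)]]
    )
    assert pick_and_align_peaks(close, 0.0005, 0.005, 3.0).n_features == 1
    far = _dataset_from_peaks([[(700.0, 10.0)], [(700.0 * (1 + 5e-6), 10.0)]])
    assert pick_and_align_peaks(far, 0.0005, 0.005, 3.0).n_features == 2


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_alignment_equals_brute_force_oracle(seed, rng):
    r = np.random.default_rng(seed)
    n_pixels = int(r.integers(2, 6))
    pixel_peaks = []
    centers = r.uniform(400, 900, 8)
    for _ in range(n_pixels):
        peaks = {}
        for c in centers:
            if r.random() < 0.7:
                m = float(c * (1 + r.normal(0, 1e-6)))
                peaks[m] = float(r.uniform(1, 100))
        pixel_peaks.append(sorted(peaks.items()))
    total = sum(len(p) for p in pixel_peaks)
    assert total <= 100
    if not any(pixel_peaks):
        pytest.skip("degenerate draw")
    ds = _dataset_from_peaks(pixel_peaks)
    table = pick_and_align_peaks(ds, 0.0005, 0.005, 3.0)
    oracle = _oracle_pick(ds, 0.0005, 0.005, 3.0)
    assert table.n_features == len(oracle)
    for (omz, ovec), tmz, tvec in zip(oracle, table.mz, table.intensities):
        assert tmz == pytest.approx(omz, abs=1e-9)
        np.testing.assert_allclose(tvec, ovec)


def test_empty_dataset_rejected():
    with pytest.raises(ValueError):
        pick_and_align_peaks(MSIDataset([], (0, 0)))


def test_mean_spectrum_examples():
    ds = _dataset_from_peaks(
        [
            [(500.0, 0.0), (600.0, 8.0)],
            [(500.0, 10.0)],
            [(500.0, 10.0)],
            [(500.0, 10.0)],
        ],
        ncols=2,
    )
    table = pick_and_align_peaks(ds, 0.0, 0.0, 3.0)
    ms = mean_spectrum(ds, table)
    by_mz = dict(zip(np.round(ms.mz, 1), ms.intensities))
    assert by_mz[500.0] == pytest.approx(7.5)  # (0+10+10+10)/4
    assert by_mz[600.0] == pytest.approx(2.0)  # present in 1 of 4 at 8


# --- ion images --------------------------------------------------------------


def test_extract_ion_image_tic_and_raw():
    ds = _dataset_from_peaks([[(500.0, 4.0), (600.0, 36.0)]])
    img = extract_ion_image(ds, 500.0, 3.0, "tic")
    assert img.values[0, 0] == pytest.approx(0.1)  # 4 / 40
    raw = extract_ion_image(ds, 500.0, 3.0, "none")
    assert raw.values[0, 0] == pytest.approx(4.0)
    assert extract_ion_image(ds, 800.0, 3.0, "none").values[0, 0] == 0.0


def test_extract_sums_multiple_in_window_peaks():
    ds = _dataset_from_peaks([[(500.0, 3.0), (500.0005, 5.0)]])
    img = extract_ion_image(ds, 500.00025, 3.0, "none")
    assert img.values[0, 0] == pytest.approx(8.0)


def test_extract_rejects_bad_tolerance():
    ds = _dataset_from_peaks([[(500.0, 1.0)]])
    with pytest.raises(ValueError):
        extract_ion_image(ds, 500.0, 0.0)


def test_tic_normalized_features_sum_to_one(rng):
    """Summing TIC images over every feature window recovers 1 per pixel."""
    centers = [500.0, 600.0, 700.0, 800.0]
    pixel_peaks = [
        [(c, float(rng.uniform(1, 50))) for c in centers] for _ in range(4)
    ]
    ds = _dataset_from_peaks(pixel_peaks, ncols=2)
    table = pick_and_align_peaks(ds, 0.0, 0.0, 3.0)
    total = np.zeros(ds.grid_shape[::-1])
    for mz in table.mz:
        total += extract_ion_image(ds, mz, 3.0, "tic").values
    np.testing.assert_allclose(total, 1.0, atol=1e-9)


def test_extract_is_additive_over_disjoint_windows():
    ds = _dataset_from_peaks([[(500.0, 3.0), (502.0, 5.0)]])
    a = extract_ion_image(ds, 500.0, 3.0, "none").values
    b = extract_ion_image(ds, 502.0, 3.0, "none").values
    both = (
        extract_ion_image(ds, 500.0, 3.0, "none").values
        + extract_ion_image(ds, 502.0, 3.0, "none").values
    )
    np.testing.assert_allclose(a + b, both)


# --- hotspot clipping --------------------------------------------------------


def test_hotspot_constant_image_unchanged():
    img = IonImage(np.full((4, 4), 3.0), 500.0, 3.0)
    out = hotspot_clip(img, 0.99)
    np.testing.assert_array_equal(out.values, img.values)
    assert out.clipped_quantile == 0.99


def test_hotspot_quantile_oracle_and_monotonicity():
    vals = np.concatenate([np.ones(100), [1000.0]])
    img = IonImage(vals.reshape(1, -1), 500.0, 3.0)
    out = hotspot_clip(img, 0.99)
    expected_q = np.quantile(vals, 0.99)  # type-7 linear interpolation
    assert out.values.max() == pytest.approx(expected_q)
    assert np.all(out.values <= img.values)
    below = img.values <= expected_q
    np.testing.assert_array_equal(out.values[below], img.values[below])


def test_hotspot_is_idempotent():
    rng = np.random.default_rng(0)
    img = IonImage(rng.lognormal(0, 1, (8, 8)), 500.0, 3.0)
    once = hotspot_clip(img, 0.99)
    twice = hotspot_clip(once, 0.99)
    np.testing.assert_allclose(twice.values, once.values)


def test_hotspot_preserves_missing_pixels():
    vals = np.array([[1.0, np.nan], [2.0, 100.0]])
    out = hotspot_clip(IonImage(vals, 500.0, 3.0), 0.5)
    assert np.isnan(out.values[0, 1])


def test_hotspot_all_missing_rejected():
    with pytest.raises(ValueError):
        hotspot_clip(IonImage(np.full((2, 2), np.nan), 500.0, 3.0), 0.99)


# --- ratio images ------------------------------------------------------------


def test_ratio_image_constant_fraction():
    base = np.arange(1.0, 5.0).reshape(2, 2)
    num = IonImage(0.01 * base, 765.6079, 3.0)
    den = IonImage(base, 756.5514, 3.0)
    out = ratio_image(num, den)
    np.testing.assert_allclose(out.values, 0.01)
    assert out.normalization == "denominator"


def test_ratio_image_zero_denominator_missing():
    num = IonImage(np.array([[1.0, 1.0]]), 765.0, 3.0)
    den = IonImage(np.array([[0.0, 2.0]]), 756.0, 3.0)
    out = ratio_image(num, den)
    assert np.isnan(out.values[0, 0]) and out.values[0, 1] == pytest.approx(0.5)


def test_ratio_image_scale_invariance():
    rng = np.random.default_rng(1)
    a = rng.uniform(1, 10, (3, 3))
    b = rng.uniform(1, 10, (3, 3))
    r1 = ratio_image(IonImage(a, 1, 1), IonImage(b, 2, 1)).values
    r7 = ratio_image(IonImage(7 * a, 1, 1), IonImage(7 * b, 2, 1)).values
    np.testing.assert_allclose(r1, r7)


def test_ratio_image_shape_mismatch():
    with pytest.raises(ValueError):
        ratio_image(IonImage(np.ones((2, 2)), 1, 1), IonImage(np.ones((3, 3)), 2, 1))


# --- overlays ----------------------------------------------------------------


def test_overlay_single_constant_red():
    img = IonImage(np.full((2, 2), 5.0), 500.0, 3.0)
    rgb = overlay_channels([img], ["red"], high_quantile=None)
    np.testing.assert_allclose(rgb[..., 0], 1.0)
    np.testing.assert_allclose(rgb[..., 1:], 0.0)


def test_overlay_disjoint_masks_do_not_mix():
    a = np.zeros((2, 2)); a[0, 0] = 1.0
    b = np.zeros((2, 2)); b[1, 1] = 1.0
    rgb = overlay_channels(
        [IonImage(a, 1, 1), IonImage(b, 2, 1)], ["red", "green"], high_quantile=None
    )
    assert not np.any((rgb[..., 0] > 0) & (rgb[..., 1] > 0))


def test_overlay_rejects_too_many_channels():
    imgs = [IonImage(np.ones((2, 2)), i, 1) for i in range(4)]
    with pytest.raises(ValueError):
        overlay_channels(imgs, ["red", "green", "blue", "cyan"])


def test_region_mask_shape_enforced():
    mask = RegionMask(np.ones((2, 2), dtype=bool))
    with pytest.raises(ValueError):
        mask.require_shape((3, 3))
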