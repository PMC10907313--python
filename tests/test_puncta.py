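"""Puncta chain: thresholds, filtering stages, component calling, colocalization."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import memrecruit as mr
from memrecruit.puncta import (Punctum, PunctaPipelineConfig,
                               minimum_cross_entropy_threshold)


# ---------------------------------------------------------------------------
# oracles


def cross_entropy(values, t):
    lo, hi = values[values <= t], values[values > t]
    out = 0.0
    if lo.size and lo.mean() > 0:
        out -= lo.sum() * np.log(lo.mean())
    if hi.size and hi.mean() > 0:
        out -= hi.sum() * np.log(hi.mean())
    return out


def intra_class_variance(values, t):
    lo, hi = values[values <= t], values[values > t]
    out = 0.0
    if lo.size:
        out += lo.size * lo.var()
    if hi.size:
        out += hi.size * hi.var()
    return out


def brute_force_threshold(values, objective):
    vals = np.unique(values)
    cands = [(vals[i] + vals[i + 1]) / 2 for i in range(len(vals) - 1)]
    scores = [objective(values, t) for t in cands]
    return cands[int(np.argmin(scores))]


def flood_fill_components(mask, connectivity):
    """Independent component labeling by explicit stack-based flood fill."""
    if connectivity == 4:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        steps = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                 if (dr, dc) != (0, 0)]
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    H, W = mask.shape
    for r in range(H):
        for c in range(W):
            if not mask[r, c] or seen[r, c]:
                continue
            stack = [(r, c)]
            seen[r, c] = True
            comp = []
            while stack:
                cr, cc = stack.pop()
                comp.append((cr, cc))
                for dr, dc in steps:
                    nr, nc = cr + dr, cc + dc
                    if 0 <= nr < H and 0 <= nc < W and mask[nr, nc] \
                            and not seen[nr, nc]:
                        seen[nr, nc] = True
                        stack.append((nr, nc))
            comps.append(frozenset(comp))
    return comps


def box(r0, c0, r1, c1):
    return (r0, c0, r1, c1)


def make_punctum(i, bbox):
    return Punctum(i, 0, "A", 9, ((bbox[0] + bbox[2]) / 2, (bbox[1] + bbox[3]) / 2),
                   bbox)


# ---------------------------------------------------------------------------
# background threshold


def test_constant_crop_background_is_that_constant_with_warning():
    with pytest.warns(UserWarning):
        assert mr.estimate_background(np.full((16, 16), 10.0)) == 10.0


def test_bimodal_background_threshold_lies_between_modes():
    img = np.concatenate([np.full(128, 10.0), np.full(128, 100.0)]).reshape(16, 16)
    t = mr.estimate_background(img)
    assert 10.0 < t < 100.0


def test_cross_entropy_threshold_matches_exhaustive_oracle():
    rng = np.random.default_rng(1)
    for _ in range(25):
        img = rng.integers(0, 256, size=(24, 24)).astype(np.uint8)
        t = minimum_cross_entropy_threshold(img)
        tb = brute_force_threshold(img.ravel().astype(float), cross_entropy)
        assert np.array_equal(img > t, img > tb)


def test_background_estimate_separates_background_from_puncta():
    rng = np.random.default_rng(3)
    b = 80.0
    crop = rng.normal(b, 6.0, size=(60, 60))
    signal = np.zeros_like(crop, dtype=bool)
    for r, c in [(10, 12), (40, 45), (22, 50)]:  # sparse bright puncta, <5% area
        crop[r:r + 3, c:c + 3] += 500.0
        signal[r:r + 3, c:c + 3] = True
    crop = np.clip(crop, 0, None)
    est = mr.estimate_background(crop)
    # the level lies between the modes: subtracting it zeroes every background
    # pixel while leaving every punctum pixel positive
    assert crop[~signal].max() < est < crop[signal].min()


# ---------------------------------------------------------------------------
# subtraction, denoising, equalisation, binarisation


def test_background_subtraction_clamps_at_zero():
    img = np.array([[7.0, 10.0, 100.0]])
    out = mr.subtract_background(img, 10.0)
    assert out.tolist() == [[0.0, 0.0, 90.0]]
    with pytest.raises(ValueError):
        mr.subtract_background(img, -1.0)


def test_subtraction_promotes_unsigned_input():
    img = np.array([[5, 20]], dtype=np.uint16)
    out = mr.subtract_background(img, 10.0)
    assert out.tolist() == [[0.0, 10.0]]


def test_denoise_preserves_constants():
    img = np.full((40, 40), 17.0)
    assert np.allclose(mr.denoise(img), img)


def test_denoise_impulse_spreads_mass_without_gain():
    img = np.zeros((41, 41))
    img[20, 20] = 100.0
    cfg = PunctaPipelineConfig(denoise_strength=0.0)  # isolate the blur
    out = mr.denoise(img, cfg)
    assert out.max() < img.max()
    assert abs(out.sum() - img.sum()) / img.sum() < 0.01
    assert (out >= 0).all()


def test_denoise_improves_snr_against_noiseless_reference():
    rng = np.random.default_rng(7)
    clean = np.zeros((48, 48))
    rr, cc = np.mgrid[0:48, 0:48]
    clean += 90.0 * np.exp(-((rr - 24) ** 2 + (cc - 24) ** 2) / (2 * 2.0 ** 2))
    noisy = clean + rng.normal(0, 30.0, clean.shape)  # SNR ~ 3
    out = mr.denoise(np.clip(noisy, 0, None))
    mse_before = np.mean((np.clip(noisy, 0, None) - clean) ** 2)
    mse_after = np.mean((out - clean) ** 2)
    assert mse_after < mse_before


def test_equalize_constant_stays_constant():
    out = mr.equalize_contrast(np.full((8, 8), 3.0))
    assert np.unique(out).size == 1


def test_equalize_preserves_two_level_ordering():
    img = np.where(np.arange(100).reshape(10, 10) < 40, 5.0, 9.0)
    out = mr.equalize_contrast(img)
    assert np.unique(out).size == 2
    assert out[img == 5.0].max() < out[img == 9.0].min()


def test_equalize_spans_full_8bit_range():
    rng = np.random.default_rng(0)
    img = rng.normal(50, 10, size=(32, 32))
    out = mr.equalize_contrast(img)
    assert out.dtype == np.uint8
    assert out.min() == 0 and out.max() == 255


def test_binarize_half_and_half():
    img = np.concatenate([np.zeros(50), np.full(50, 255.0)]).reshape(10, 10)
    mask = mr.binarize(img)
    assert mask.sum() == 50
    assert mask[img == 255.0].all()


def test_binarize_constant_is_empty_with_warning():
    with pytest.warns(UserWarning):
        assert not mr.binarize(np.full((8, 8), 9.0)).any()


def test_binarize_mask_idempotent():
    rng = np.random.default_rng(2)
    img = rng.integers(0, 256, size=(20, 20)).astype(float)
    mask = mr.binarize(img)
    assert np.array_equal(mr.binarize(mask.astype(float)), mask)


def test_otsu_matches_exhaustive_intra_class_variance_minimizer():
    # tri-level toy image
    img = np.array([[10] * 6 + [80] * 3 + [200] * 3], dtype=float).reshape(4, 3)
    from skimage.filters import threshold_otsu
    t = threshold_otsu(img)
    tb = brute_force_threshold(img.ravel(), intra_class_variance)
    assert np.array_equal(img > t, img > tb)


# ---------------------------------------------------------------------------
# component calling


def test_six_pixel_component_is_a_punctum():
    mask = np.zeros((10, 10), dtype=bool)
    mask[2, 2:8] = True
    out = mr.find_puncta(mask, 0, "A")
    assert len(out) == 1 and out[0].pixel_count == 6


def test_five_pixel_component_is_rejected():
    mask = np.zeros((10, 10), dtype=bool)
    mask[2, 2:7] = True
    assert mr.find_puncta(mask, 0, "A") == []


def test_diagonal_touch_depends_on_connectivity():
    mask = np.zeros((10, 10), dtype=bool)
    mask[1:3, 1:3] = True  # 4 pixels
    mask[3:5, 3:5] = True  # 4 pixels, touching only diagonally
    out8 = mr.find_puncta(mask, 0, "A", PunctaPipelineConfig(connectivity=8))
    assert len(out8) == 1 and out8[0].pixel_count == 8
    out4 = mr.find_puncta(mask, 0, "A", PunctaPipelineConfig(connectivity=4))
    assert out4 == []


def test_bbox_and_centroid_are_image_frame_closed_intervals():
    mask = np.zeros((10, 10), dtype=bool)
    mask[2:4, 3:6] = True
    (p,) = mr.find_puncta(mask, 7, "B", origin=(100, 200))
    assert p.bbox == (102, 203, 103, 205)
    assert p.guv_id == 7 and p.channel == "B"
    assert p.bbox[0] <= p.centroid[0] <= p.bbox[2]
    assert p.bbox[1] <= p.centroid[1] <= p.bbox[3]


@given(st.integers(0, 2**32 - 1), st.sampled_from([4, 8]))
@settings(max_examples=120, deadline=None)
def test_component_labeling_matches_flood_fill_oracle(seed, connectivity):
    rng = np.random.default_rng(seed)
    mask = rng.random((32, 32)) < 0.35
    got = mr.find_puncta(mask, 0, "A", PunctaPipelineConfig(connectivity=connectivity))
    oracle = [c for c in flood_fill_components(mask, connectivity) if len(c) > 5]
    assert len(got) == len(oracle)
    def comp_key(comp):
        rows = [p[0] for p in comp]
        cols = [p[1] for p in comp]
        return (min(rows), min(cols), max(rows), max(cols), len(comp))
    oracle_keys = sorted(comp_key(c) for c in oracle)
    got_keys = sorted(p.bbox + (p.pixel_count,) for p in got)
    assert got_keys == oracle_keys


# ---------------------------------------------------------------------------
# bounding boxes and colocalization


@pytest.mark.parametrize("a, b, expected", [
    (box(0, 0, 10, 10), box(5, 5, 15, 15), True),
    (box(0, 0, 10, 10), box(11, 0, 20, 10), False),
    (box(0, 0, 10, 10), box(10, 10, 20, 20), True),  # corner touch counts
])
def test_boxes_overlap_convention(a, b, expected):
    assert mr.boxes_overlap(a, b) is expected
    assert mr.boxes_overlap(b, a) is expected


def test_malformed_box_rejected():
    with pytest.raises(ValueError):
        mr.boxes_overlap(box(5, 0, 1, 10), box(0, 0, 1, 1))


def test_colocalization_counts_in_higher_count_channel():
    pa = [make_punctum(i, box(20 * i, 20 * i, 20 * i + 2, 20 * i + 2))
          for i in range(3)]
    pb = [make_punctum(0, box(1, 1, 3, 3)), make_punctum(1, box(21, 21, 23, 23)),
          make_punctum(2, box(60, 60, 62, 62)), make_punctum(3, box(70, 70, 72, 72)),
          make_punctum(4, box(80, 80, 82, 82))]
    assert mr.colocalization_fraction(pa, pb) == pytest.approx(0.4)


def test_identical_bbox_sets_fully_colocalized():
    pa = [make_punctum(i, box(10 * i, 0, 10 * i + 2, 2)) for i in range(4)]
    pb = [make_punctum(i, p.bbox) for i, p in enumerate(pa)]
    assert mr.colocalization_fraction(pa, pb) == 1.0


def test_empty_channels_are_undefined_not_zero():
    assert mr.colocalization_fraction([], []) is None
    assert mr.colocalization_fraction([], [make_punctum(0, box(0, 0, 1, 1))]) == 0.0


@given(st.integers(0, 2**32 - 1))
@settings(max_examples=60, deadline=None)
def test_colocalization_fraction_bounded_and_symmetric(seed):
    rng = np.random.default_rng(seed)
    def random_puncta(n):
        out = []
        for i in range(n):
            r, c = rng.integers(0, 60, 2)
            h, w = rng.integers(1, 6, 2)
            out.append(make_punctum(i, box(int(r), int(c), int(r + h), int(c + w))))
        return out
    pa = random_puncta(int(rng.integers(0, 6)))
    pb = random_puncta(int(rng.integers(0, 6)))
    v1 = mr.colocalization_fraction(pa, pb)
    v2 = mr.colocalization_fraction(pb, pa)
    assert v1 == v2
    if v1 is not None:
        assert 0.0 <= v1 <= 1.0


# ---------------------------------------------------------------------------
# whole-GUV analysis


def test_noiseless_planted_puncta_counted_exactly(noiseless_field, detector):
    image, truth = noiseless_field
    dets = mr.detect_guvs(image["lipid"], detector)
    planted = {gi: sum(1 for p in truth.puncta if p.guv_index == gi)
               for gi in range(len(truth.guvs))}
    matched = 0
    for det in dets:
        g_idx = int(np.argmin([np.hypot(det.center[0] - g.center[0],
                                        det.center[1] - g.center[1])
                               for g in truth.guvs]))
        rec = mr.analyze_guv(image, det)
        assert rec.punctum_count["A"] == planted[g_idx]
        assert rec.has_punctum["A"] == (planted[g_idx] > 0)
        matched += 1
    assert matched == 3


def test_fully_colocalized_puncta_report_unit_fraction():
    cfg = mr.ImagingSimConfig(image_shape=(260, 260), n_guvs=1, puncta_per_guv=2,
                              fixed_puncta_count=True, n_protein_channels=2,
                              coloc_fraction=1.0, seed=6)
    image, _ = mr.generate_guv_image(cfg)
    (det,) = mr.detect_guvs(image["lipid"], mr.DetectorParams(10, 40))
    rec = mr.analyze_guv(image, det)
    assert rec.punctum_count["A"] == rec.punctum_count["B"] == 2
    assert rec.coloc_fraction == 1.0


def test_noise_only_guvs_rarely_show_puncta(detector):
    false_pos = 0
    n_rep = 60
    for s in range(n_rep):
        cfg = mr.ImagingSimConfig(image_shape=(180, 180), n_guvs=1, puncta_per_guv=0,
                                  noise=mr.NoiseModel(gaussian_sd=30.0, poisson=True),
                                  seed=900 + s)
        image, _ = mr.generate_guv_image(cfg)
        dets = mr.detect_guvs(image["lipid"], detector)
        if not dets:
            continue
        rec = mr.analyze_guv(image, dets[0])
        false_pos += rec.has_punctum.get("A", False)
    assert false_pos / n_rep <= 0.05


def test_pipeline_stages_never_emit_negative_intensities():
    rng = np.random.default_rng(11)
    crop = np.clip(rng.normal(60, 15, (48, 48)), 0, None)
    crop[20:24, 20:24] += 400.0
    level = mr.estimate_background(crop)
    sub = mr.subtract_background(crop, level)
    den = mr.denoise(sub)
    eq = mr.equalize_contrast(den)
    for stage in (sub, den, eq):
        assert (np.asarray(stage, dtype=float) >= 0).all()


def test_exact_recovery_of_separated_puncta():
    """Noiseless puncta of radius >= 2 px with >= 4 px edge gaps are counted exactly."""
    cfg = mr.ImagingSimConfig(image_shape=(300, 300), n_guvs=1, puncta_per_guv=4,
                              fixed_puncta_count=True, punctum_radius=2.0,
                              radius_range=(30.0, 34.0), seed=19)
    image, truth = mr.generate_guv_image(cfg)
    centers = [p.center for p in truth.puncta]
    gaps_ok = all(
        np.hypot(a[0] - b[0], a[1] - b[1]) >= 2 * 2.0 + 4.0
        for i, a in enumerate(centers) for b in centers[i + 1:])
    if not gaps_ok:
        pytest.skip("draw placed puncta closer than the separation premise")
    (det,) = mr.detect_guvs(image["lipid"], mr.DetectorParams(10, 40))
    rec = mr.analyze_guv(image, det)
    assert rec.punctum_count["A"] == len(centers)
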