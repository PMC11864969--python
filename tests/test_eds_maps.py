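"""Ratio maps, median filtering, LUT rendering, registration, overlays."""

import numpy as np
import pytest

from foramphos import eds_maps as em
from foramphos.biovolume import ValidationError


def single_pixel_stack(i_p=30.0, cps=130.0, i_other=50.0):
    return em.ElementCountMaps(
        counts={"P": np.full((1, 1), i_p), "Ca": np.full((1, 1), i_other)},
        cps=np.full((1, 1), cps),
    )


# --- ratio maps -----------------------------------------------------------

def test_ratio_single_pixel():
    # denominator = CPS − ΣI = 130 − 80 = 50
    r = em.ratio_map(single_pixel_stack(), "P")
    assert r.mask.all()
    assert r.values[0, 0] == pytest.approx(0.6)


def test_degenerate_denominator_masked():
    r = em.ratio_map(single_pixel_stack(cps=80.0), "P")
    assert not r.mask[0, 0]


def test_cps_below_characteristic_sum_masked_not_clipped():
    r = em.ratio_map(single_pixel_stack(cps=70.0), "P")
    assert not r.mask[0, 0]
    assert r.values[0, 0] == 0.0


def test_absent_element_raises_keyerror():
    with pytest.raises(KeyError):
        em.ratio_map(single_pixel_stack(), "Mg")


def test_shape_mismatch_rejected():
    with pytest.raises(ValidationError):
        em.ElementCountMaps(counts={"P": np.zeros((2, 2))}, cps=np.zeros((3, 3)))


def test_phantom_pixel_with_consistent_background():
    """S = 40, B_i = 10 and a denominator equal to B_i give R = S/B + 1 = 5."""
    # two elements, peak fractions equal to the out-of-peak fraction, so
    # CPS − ΣI equals the element's own under-peak background exactly
    b = 10.0
    stack = em.ElementCountMaps(
        counts={"P": np.full((1, 1), 40.0 + b), "Ca": np.full((1, 1), b)},
        cps=np.full((1, 1), (40.0 + b) + b + b),
    )
    r = em.ratio_map(stack, "P")
    assert r.values[0, 0] == pytest.approx(5.0)


@pytest.mark.parametrize("k", [0.5, 3.0, 1000.0])
def test_scale_invariance(k):
    """Multiplying all counts and CPS by k leaves R unchanged."""
    rng = np.random.default_rng(2)
    counts = {el: rng.uniform(5, 50, (8, 8)) for el in ("P", "Ca", "Mg")}
    cps = sum(counts.values()) + rng.uniform(20, 80, (8, 8))
    base = em.ratio_map(em.ElementCountMaps(counts=counts, cps=cps), "P")
    scaled = em.ratio_map(
        em.ElementCountMaps(
            counts={el: k * v for el, v in counts.items()}, cps=k * cps
        ),
        "P",
        epsilon=em.DEFAULT_EPSILON * k,
    )
    assert np.array_equal(base.mask, scaled.mask)
    assert np.allclose(base.values[base.mask], scaled.values[scaled.mask])


def test_monotone_in_target_intensity():
    r1 = em.ratio_map(single_pixel_stack(i_p=30.0, cps=130.0), "P").values[0, 0]
    # raise I_P and CPS together so the denominator stays fixed at 50
    r2 = em.ratio_map(single_pixel_stack(i_p=40.0, cps=140.0), "P").values[0, 0]
    assert r2 > r1


def test_exclude_target_denominator_option():
    stack = single_pixel_stack(i_p=30.0, cps=130.0, i_other=50.0)
    r = em.ratio_map(stack, "P", denominator="exclude_target")
    assert r.values[0, 0] == pytest.approx(30.0 / 80.0)


# --- median filter --------------------------------------------------------

def brute_force_median(values, mask, radius):
    """Independent per-pixel reference: valid neighbours, clipped window."""
    out = values.copy()
    n, m = values.shape
    for i in range(n):
        for j in range(m):
            if not mask[i, j]:
                continue
            window = []
            for di in range(-radius, radius + 1):
                for dj in range(-radius, radius + 1):
                    a, b = i + di, j + dj
                    if 0 <= a < n and 0 <= b < m and mask[a, b]:
                        window.append(values[a, b])
            out[i, j] = np.median(window)
    return out


def test_constant_map_unchanged():
    r = em.RatioMap(np.full((5, 5), 2.5), np.ones((5, 5), bool), "P")
    assert np.allclose(em.median_filter(r).values, 2.5)


def test_salt_pixel_removed():
    v = np.ones((5, 5))
    v[2, 2] = 100.0
    r = em.median_filter(em.RatioMap(v, np.ones((5, 5), bool), "P"))
    assert r.values[2, 2] == 1.0


def test_median_filter_matches_brute_force():
    rng = np.random.default_rng(4)
    for radius in (1, 2):
        values = rng.uniform(0, 10, (12, 9))
        mask = rng.uniform(size=(12, 9)) > 0.2
        r = em.median_filter(em.RatioMap(values, mask, "P"), radius=radius)
        want = brute_force_median(values, mask, radius)
        assert np.allclose(r.values, want)
        assert np.array_equal(r.mask, mask)


def test_masked_pixels_preserved():
    values = np.arange(9.0).reshape(3, 3)
    mask = np.ones((3, 3), bool)
    mask[1, 1] = False
    r = em.median_filter(em.RatioMap(values, mask, "P"))
    assert r.values[1, 1] == values[1, 1]
    assert not r.mask[1, 1]


# --- LUT quantization -----------------------------------------------------

def test_sixteen_distinct_classes():
    values = np.arange(16.0).reshape(4, 4)
    classes, rgba = em.lut_quantize(em.RatioMap(values, np.ones((4, 4), bool), "P"))
    assert sorted(np.unique(classes)) == list(range(16))
    assert rgba.shape == (4, 4, 4)
    assert (rgba[..., 3] == 255).all()


def test_constant_map_single_class():
    classes, _ = em.lut_quantize(em.RatioMap(np.full((3, 3), 7.0), np.ones((3, 3), bool), "P"))
    assert (classes == 0).all()


def test_requantization_idempotent():
    rng = np.random.default_rng(8)
    values = rng.uniform(0, 5, (10, 10))
    mask = np.ones((10, 10), bool)
    classes1, _ = em.lut_quantize(em.RatioMap(values, mask, "P"))
    classes2, _ = em.lut_quantize(em.RatioMap(classes1.astype(float), mask, "P"))
    assert np.array_equal(classes1, classes2)


def test_masked_pixels_transparent():
    values = np.arange(4.0).reshape(2, 2)
    mask = np.array([[True, False], [True, True]])
    classes, rgba = em.lut_quantize(em.RatioMap(values, mask, "P"))
    assert classes[0, 1] == -1
    assert rgba[0, 1, 3] == 0


def test_all_masked_rejected():
    with pytest.raises(ValidationError):
        em.lut_quantize(em.RatioMap(np.ones((2, 2)), np.zeros((2, 2), bool), "P"))


def test_grey_values_untouched():
    values = np.arange(9.0).reshape(3, 3)
    r = em.RatioMap(values.copy(), np.ones((3, 3), bool), "P")
    em.lut_quantize(r)
    assert np.array_equal(r.values, values)


# --- similarity registration ---------------------------------------------

def procrustes_oracle(src, dst):
    """Closed-form least-squares similarity fit, independent of the
    implementation path: centre, scale via cross-terms, rotation via SVD
    restricted to det=+1 with isotropic scaling."""
    src = np.asarray(src, float)
    dst = np.asarray(dst, float)
    mu_s, mu_d = src.mean(0), dst.mean(0)
    xs, xd = src - mu_s, dst - mu_d
    cov = xd.T @ xs / len(src)
    u, s, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(u @ vt))
    D = np.diag([1.0, d])
    rot = u @ D @ vt
    var_s = (xs**2).sum() / len(src)
    scale = np.trace(np.diag(s) @ D) / var_s
    trans = mu_d - scale * rot @ mu_s
    return scale, rot, trans


def test_identity_registration():
    pts = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
    t = em.register_similarity(pts, pts)
    assert t.scale == pytest.approx(1.0)
    assert t.rotation_deg == pytest.approx(0.0, abs=1e-9)
    assert t.translation == pytest.approx((0.0, 0.0), abs=1e-9)
    assert t.residual_rms == pytest.approx(0.0, abs=1e-9)


def test_rotation_and_scale_recovered_exactly():
    pts = np.array([[1.0, 0.0], [0.0, 1.0], [2.0, 3.0]])
    # rotate 90° CCW and scale ×2: (x, y) → (−2y, 2x)
    dst = np.stack([-2 * pts[:, 1], 2 * pts[:, 0]], axis=1)
    t = em.register_similarity(pts, dst)
    assert t.scale == pytest.approx(2.0)
    assert abs(t.rotation_deg) == pytest.approx(90.0)
    assert t.residual_rms == pytest.approx(0.0, abs=1e-9)


def test_noisy_registration_matches_procrustes_oracle():
    rng = np.random.default_rng(6)
    src = rng.uniform(0, 100, (5, 2))
    theta = np.deg2rad(25.0)
    R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    true_scale, true_t = 1.4, np.array([5.0, -3.0])
    dst = true_scale * src @ R.T + true_t + rng.normal(0, 0.5, (5, 2))
    t = em.register_similarity(src, dst)
    o_scale, o_rot, o_trans = procrustes_oracle(src, dst)
    assert t.scale == pytest.approx(o_scale, rel=1e-9)
    o_angle = np.rad2deg(np.arctan2(o_rot[1, 0], o_rot[0, 0]))
    assert t.rotation_deg == pytest.approx(o_angle, abs=1e-9)
    assert np.asarray(t.translation) == pytest.approx(o_trans, abs=1e-9)
    # and the fit sits within the jitter of the constructed truth
    assert t.scale == pytest.approx(true_scale, abs=0.05)
    assert t.rotation_deg == pytest.approx(25.0, abs=2.0)


def test_coincident_points_rejected():
    pts = np.array([[1.0, 1.0], [1.0, 1.0]])
    with pytest.raises(ValidationError):
        em.register_similarity(pts, pts)


def test_too_few_points_rejected():
    with pytest.raises(ValidationError):
        em.register_similarity(np.array([[0.0, 0.0]]), np.array([[1.0, 1.0]]))


def test_apply_transform_moves_image():
    img = np.zeros((20, 20))
    img[5, 5] = 1.0
    t = em.SimilarityTransform(scale=1.0, rotation_deg=0.0, translation=(3.0, 2.0))
    out = em.apply_transform(img, t)
    assert out[7, 8] == pytest.approx(1.0)  # (x+3, y+2) → (row+2, col+3)


# --- overlay --------------------------------------------------------------

def _rendered_constant(shape, rgb, opaque=True):
    rgba = np.zeros(shape + (4,), dtype=np.uint8)
    rgba[..., :3] = rgb
    rgba[..., 3] = 255 if opaque else 0
    return rgba


def test_alpha_zero_returns_base():
    base = np.full((4, 4), 0.5)
    out = em.overlay(base, _rendered_constant((4, 4), (255, 0, 0)), alpha=0.0)
    assert np.allclose(out, 0.5)


def test_alpha_one_shows_overlay_on_opaque_pixels():
    base = np.full((4, 4), 1.0)
    out = em.overlay(base, _rendered_constant((4, 4), (255, 0, 0)), alpha=1.0)
    assert np.allclose(out[..., 0], 1.0)
    assert np.allclose(out[..., 1], 0.0)


def test_blend_is_exact_linear_combination():
    base = np.full((2, 2), 0.4)
    rendered = _rendered_constant((2, 2), (255, 255, 255))
    out = em.overlay(base, rendered, alpha=0.25)
    # overlay rgb scales to base range (max 0.4): 0.75·0.4 + 0.25·0.4 = 0.4
    assert np.allclose(out, 0.75 * 0.4 + 0.25 * 0.4)


def test_transparent_pixels_show_base():
    base = np.full((2, 2), 0.8)
    rendered = _rendered_constant((2, 2), (255, 0, 0))
    rendered[0, 0, 3] = 0
    out = em.overlay(base, rendered, alpha=1.0)
    assert np.allclose(out[0, 0], 0.8)
    assert out[1, 1, 1] == pytest.approx(0.0)


def test_shape_mismatch_rejected_overlay():
    with pytest.raises(ValidationError):
        em.overlay(np.zeros((3, 3)), _rendered_constant((2, 2), (0, 0, 0)), 0.5)
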