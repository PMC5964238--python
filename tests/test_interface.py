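"""Interface accumulation and four-ROI polarization quantification."""

import numpy as np
import pytest

from casig.interface import (ConjugateAnnotation, accumulation_ratio,
                             membrane_profile_mfi, polarization_rois,
                             polyline_band_pixels)
from casig.sim import (ConjugateGeometry, simulate_conjugate_image,
                       simulate_polarized_image)


def brute_band_pixels(shape, polyline, width):
    """Loop-based band membership: distance of each pixel center to every
    segment, no vectorisation shortcuts."""
    h, w = shape
    half = width / 2.0
    out = set()
    for py in range(h):
        for px in range(w):
            dmin = np.inf
            for a, b in zip(polyline[:-1], polyline[1:]):
                a, b = np.asarray(a, float), np.asarray(b, float)
                ab = b - a
                denom = ab @ ab
                t = 0.0 if denom == 0 else np.clip(
                    ((px - a[0]) * ab[0] + (py - a[1]) * ab[1]) / denom, 0, 1)
                d = np.hypot(px - (a[0] + t * ab[0]), py - (a[1] + t * ab[1]))
                dmin = min(dmin, d)
            if dmin <= half:
                out.add((px, py))
    return out


# --------------------------------------------------------- membrane bands
def test_uniform_image_mfi():
    img = np.full((30, 30), 100.0)
    poly = np.array([[5.0, 15.0], [25.0, 15.0]])
    assert membrane_profile_mfi(img, poly, 10.0) == pytest.approx(100.0)


def test_band_pixels_match_bruteforce_enumeration():
    shape = (24, 24)
    poly = np.array([[4.0, 6.0], [18.0, 9.0], [12.0, 20.0]])
    for width in (1.0, 4.0, 10.0):
        mask = polyline_band_pixels(shape, poly, width)
        got = {(x, y) for y, x in zip(*np.nonzero(mask))}
        assert got == brute_band_pixels(shape, poly, width)


def test_band_mean_on_step_image_matches_enumeration():
    img = np.zeros((24, 24))
    img[:, 12:] = 500.0  # vertical step
    poly = np.array([[4.0, 10.0], [20.0, 10.0]])
    width = 6.0
    pix = brute_band_pixels(img.shape, poly, width)
    expected = np.mean([img[y, x] for x, y in pix])
    assert membrane_profile_mfi(img, poly, width) == pytest.approx(expected)


def test_width_one_on_single_pixel_line():
    img = np.zeros((20, 20))
    img[10, 2:18] = 500.0
    poly = np.array([[2.0, 10.0], [17.0, 10.0]])
    assert membrane_profile_mfi(img, poly, 1.0) == pytest.approx(500.0)


def test_empty_band_rejected():
    img = np.zeros((10, 10))
    poly = np.array([[50.0, 50.0], [60.0, 60.0]])  # fully outside
    with pytest.raises(ValueError, match="no pixels"):
        membrane_profile_mfi(img, poly, 2.0)


# ----------------------------------------------------- accumulation ratio
def test_uniform_membrane_ratio_one():
    img, ann = simulate_conjugate_image(1.0)
    assert accumulation_ratio(img, ann) == pytest.approx(1.0, abs=1e-9)


def test_known_enrichment_recovered_exactly():
    img, ann = simulate_conjugate_image(3.0)
    assert accumulation_ratio(img, ann) == pytest.approx(3.0, abs=1e-6)


def test_zero_rest_band_raises():
    img, ann = simulate_conjugate_image(2.0)
    img[:] = 0.0
    with pytest.raises(ValueError, match="undefined"):
        accumulation_ratio(img, ann)


def test_intensity_scale_invariance():
    img, ann = simulate_conjugate_image(2.0)
    r1 = accumulation_ratio(img, ann)
    r2 = accumulation_ratio(img * 37.5, ann)
    assert r1 == pytest.approx(r2, abs=1e-9)


@pytest.mark.parametrize("k", [0.5, 2.0, 3.0])
def test_uniform_offset_moves_ratio_toward_one(k):
    """Adding a constant background pulls the ratio toward 1 — why
    background handling matters for enrichment estimates."""
    img, ann = simulate_conjugate_image(k)
    r0 = accumulation_ratio(img, ann)
    r1 = accumulation_ratio(img + 200.0, ann)
    assert abs(r1 - 1.0) < abs(r0 - 1.0)


def test_noisy_recovery_within_five_percent(rng):
    """Median estimate over noisy conjugates within 5% of true k."""
    for k in (1.5, 2.0, 3.0):
        est = [accumulation_ratio(*simulate_conjugate_image(k, noise="poisson",
                                                            rng=rng))
               for _ in range(30)]
        assert abs(np.median(est) / k - 1.0) < 0.05


def test_rejects_nonpositive_enrichment():
    with pytest.raises(ValueError, match="positive"):
        simulate_conjugate_image(0.0)


# ------------------------------------------------------------ polarization
def test_uniform_image_quarters():
    img = np.full((200, 200), 55.0)
    ann = ConjugateAnnotation(center=(100.0, 100.0), direction=(0.0, -1.0),
                              roi_size_px=30.0)
    pol = polarization_rois(img, ann)
    assert np.allclose(pol.percentages, 25.0, atol=1e-9)
    assert pol.front_back == pytest.approx(0.0, abs=1e-9)
    assert pol.side_side == pytest.approx(0.0, abs=1e-9)


def test_all_intensity_at_interface():
    img, ann = simulate_polarized_image([1.0, 0.0, 0.0, 0.0])
    pol = polarization_rois(img, ann)
    assert pol.pct_interface == pytest.approx(100.0)
    assert pol.front_back == pytest.approx(100.0)


def test_percentages_match_pixel_sum_oracle():
    """A gradient along the interface axis: percentages equal brute-force
    means over the same square ROIs."""
    geo = ConjugateGeometry(center=(100.0, 100.0), interface_angle_deg=-90.0)
    yy, xx = np.mgrid[0:200, 0:200]
    img = (200.0 - yy).astype(float)  # linear gradient along -y
    ann = ConjugateAnnotation(center=(100.0, 100.0), direction=(0.0, -1.0),
                              roi_size_px=20.0, roi_offset_px=30.0)
    pol = polarization_rois(img, ann)
    u = np.array([0.0, -1.0])
    v = np.array([1.0, 0.0])  # +90 deg from u
    mfis = []
    for c in [np.array([100.0, 100.0]) + 30 * u,
              np.array([100.0, 100.0]) - 30 * u,
              np.array([100.0, 100.0]) + 30 * v,
              np.array([100.0, 100.0]) - 30 * v]:
        vals = [img[y, x] for y in range(200) for x in range(200)
                if abs((x - c[0]) * u[0] + (y - c[1]) * u[1]) <= 10
                and abs((x - c[0]) * v[0] + (y - c[1]) * v[1]) <= 10]
        mfis.append(np.mean(vals))
    expected = 100.0 * np.asarray(mfis) / np.sum(mfis)
    assert np.allclose(pol.percentages, expected, atol=1e-9)
    assert pol.front_back > 0  # brighter toward the interface


def test_rotation_by_90_degrees_invariant():
    """Rotating image and annotation together by 90 deg leaves results
    unchanged (axis-aligned rotation, no interpolation)."""
    img, ann = simulate_polarized_image([3.0, 1.0, 2.0, 1.0])
    pol = polarization_rois(img, ann)
    # numpy rot90 maps (x, y) -> (y, H-1-x); direction rotates likewise
    rot_img = np.rot90(img, k=-1).copy()
    h = img.shape[0]
    cx, cy = ann.center
    rot_ann = ConjugateAnnotation(center=(h - 1 - cy, cx),
                                  direction=(-ann.direction[1], ann.direction[0]),
                                  roi_size_px=ann.roi_size_px,
                                  roi_offset_px=ann.roi_offset_px)
    pol_rot = polarization_rois(rot_img, rot_ann)
    assert np.allclose(pol.percentages, pol_rot.percentages, atol=1e-9)


def test_roi_fully_outside_rejected():
    img = np.full((60, 60), 1.0)
    ann = ConjugateAnnotation(center=(5.0, 5.0), direction=(0.0, -1.0),
                              roi_size_px=8.0, roi_offset_px=30.0)
    with pytest.raises(ValueError, match="outside"):
        polarization_rois(img, ann)


def test_annotation_json_round_trip(tmp_path):
    img, ann = simulate_conjugate_image(2.0)
    path = tmp_path / "ann.json"
    ann.to_json(path)
    back = ConjugateAnnotation.from_json(path)
    assert np.allclose(back.interface, ann.interface)
    assert np.allclose(back.rest, ann.rest)
    assert accumulation_ratio(img, back) == pytest.approx(
        accumulation_ratio(img, ann), abs=1e-12)
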