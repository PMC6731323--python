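"""DAB segmentation, centroiding, subtractive clustering and circle
scoring."""

import numpy as np
import pytest

from skimage.draw import disk as sk_disk

from ki67net.hotspot import (
    SubtractiveClustering,
    band_proliferation,
    centroids,
    extract_dab,
    score_circles,
    subtractive_cluster,
)
from ki67net.synthetic import DAB_RGB, GLASS_LEVEL


def dab_scene(h=300, w=300):
    """White canvas with helpers to paint DAB-coloured discs."""
    img = np.full((h, w, 3), int(GLASS_LEVEL), np.uint8)
    return img


class TestExtractDab:
    def test_no_dab_gives_empty_mask(self):
        img = dab_scene()
        mask = extract_dab(img, np.ones(img.shape[:2], bool))
        assert not mask.any()

    def test_disc_area_recovered_within_ten_percent(self):
        img = dab_scene()
        rr, cc = sk_disk((150, 150), 40)
        img[rr, cc] = DAB_RGB.astype(np.uint8)
        mask = extract_dab(img, np.ones(img.shape[:2], bool))
        assert abs(mask.sum() - len(rr)) / len(rr) < 0.10

    def test_dab_outside_tumour_mask_removed(self):
        img = dab_scene()
        rr, cc = sk_disk((60, 60), 20)
        img[rr, cc] = DAB_RGB.astype(np.uint8)
        tumour = np.zeros(img.shape[:2], bool)
        tumour[150:, 150:] = True
        mask = extract_dab(img, tumour)
        assert not mask.any()

    def test_haematoxylin_not_picked_up(self):
        from ki67net.synthetic import HAEMATOXYLIN_RGB

        img = dab_scene()
        rr, cc = sk_disk((150, 150), 40)
        img[rr, cc] = HAEMATOXYLIN_RGB.astype(np.uint8)
        mask = extract_dab(img, np.ones(img.shape[:2], bool))
        assert not mask.any()

    def test_empty_tumour_mask_warns(self):
        img = dab_scene()
        with pytest.warns(UserWarning, match="empty tumour mask"):
            mask = extract_dab(img, np.zeros(img.shape[:2], bool))
        assert not mask.any()

    def test_misaligned_mask_rejected(self):
        with pytest.raises(ValueError, match="misaligned"):
            extract_dab(dab_scene(), np.ones((10, 10), bool))


def flood_fill_components(mask):
    """Brute-force 8-connected component labelling (BFS oracle)."""
    mask = np.asarray(mask, bool)
    seen = np.zeros_like(mask)
    comps = []
    for start in zip(*np.nonzero(mask)):
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            r, c = stack.pop()
            comp.append((r, c))
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr, cc = r + dr, c + dc
                    if (
                        0 <= rr < mask.shape[0]
                        and 0 <= cc < mask.shape[1]
                        and mask[rr, cc]
                        and not seen[rr, cc]
                    ):
                        seen[rr, cc] = True
                        stack.append((rr, cc))
        comps.append(np.asarray(comp, float))
    return comps


class TestCentroids:
    def test_symmetric_square(self):
        mask = np.zeros((20, 20), bool)
        mask[10:13, 10:13] = True
        np.testing.assert_allclose(centroids(mask), [[11, 11]])

    def test_empty_mask(self):
        assert len(centroids(np.zeros((5, 5), bool))) == 0

    def test_matches_flood_fill_oracle(self):
        rng = np.random.default_rng(1)
        mask = np.zeros((60, 60), bool)
        for _ in range(6):
            r, c = rng.integers(5, 55, 2)
            rr, cc = sk_disk((r, c), rng.integers(2, 5), shape=mask.shape)
            mask[rr, cc] = True
        got = sorted(map(tuple, np.round(centroids(mask), 6)))
        comps = flood_fill_components(mask)
        want = sorted(
            (float(np.round(c[:, 1].mean(), 6)), float(np.round(c[:, 0].mean(), 6)))
            for c in comps
        )
        assert len(got) == len(want)
        np.testing.assert_allclose(got, want, atol=1e-6)


class TestSubtractiveClustering:
    def test_single_point_is_its_own_centre(self):
        pts = np.array([[5.0, 7.0]])
        np.testing.assert_array_equal(subtractive_cluster(pts), pts)

    def test_empty_input(self):
        assert len(subtractive_cluster(np.empty((0, 2)))) == 0

    def test_identical_points_one_centre(self):
        pts = np.tile([3.0, 4.0], (20, 1))
        centres = subtractive_cluster(pts, ra=10)
        assert len(centres) == 1
        np.testing.assert_allclose(centres[0], [3, 4])

    def test_two_separated_blobs_two_centres(self):
        rng = np.random.default_rng(0)
        a = rng.normal((0, 0), 5, (50, 2))
        b = rng.normal((1000, 0), 5, (50, 2))
        centres = subtractive_cluster(np.vstack([a, b]), ra=50)
        assert len(centres) == 2
        dists_a = np.linalg.norm(centres - [0, 0], axis=1)
        dists_b = np.linalg.norm(centres - [1000, 0], axis=1)
        assert dists_a.min() < 20 and dists_b.min() < 20

    def test_parameter_validation(self):
        pts = np.zeros((4, 2))
        with pytest.raises(ValueError):
            subtractive_cluster(pts, ra=-1)
        with pytest.raises(ValueError):
            subtractive_cluster(pts, ra=10, rb=5)
        with pytest.raises(ValueError):
            subtractive_cluster(pts, accept_ratio=0.1, reject_ratio=0.5)

    def test_estimator_interface(self):
        rng = np.random.default_rng(3)
        X = np.vstack(
            [rng.normal((0, 0), 3, (30, 2)), rng.normal((200, 200), 3, (30, 2))]
        )
        est = SubtractiveClustering(ra=40).fit(X)
        assert est.cluster_centers_.shape == (2, 2)
        assert set(est.labels_[:30]) != set(est.labels_[30:])
        # sklearn param plumbing
        assert SubtractiveClustering(**est.get_params()).get_params() == est.get_params()


def brute_force_disc_ratio(dab, cx, cy, diameter):
    """Independent per-pixel count with the same strict-interior disc
    convention as the implementation."""
    r = diameter / 2.0
    inside = dab_count = 0
    h, w = dab.shape
    for y in range(max(0, int(cy - r) - 2), min(h, int(cy + r) + 3)):
        for x in range(max(0, int(cx - r) - 2), min(w, int(cx + r) + 3)):
            if (x - cx) ** 2 + (y - cy) ** 2 < r * r:
                inside += 1
                dab_count += bool(dab[y, x])
    return dab_count / inside if inside else 0.0


class TestScoreCircles:
    def test_fully_positive_disc(self):
        dab = np.ones((200, 200), bool)
        rep = score_circles(dab, [[100, 100]], 100, 0.2)
        assert rep.circles.ki67_ratio[0] == 1.0
        assert bool(rep.circles.is_hotspot[0])

    def test_fully_negative_disc(self):
        dab = np.zeros((200, 200), bool)
        rep = score_circles(dab, [[100, 100]], 100, 0.2)
        assert rep.circles.ki67_ratio[0] == 0.0
        assert not rep.circles.is_hotspot[0]

    def test_exact_half_filled_disc(self):
        dab = np.zeros((300, 300), bool)
        rr, cc = sk_disk((150, 150), 50)
        half = len(rr) // 2
        dab[rr[:half], cc[:half]] = True
        rep = score_circles(dab, [[150, 150]], 100, 0.2)
        assert abs(rep.circles.ki67_ratio[0] - 0.5) <= 1.0 / len(rr)

    def test_agrees_with_brute_force_on_random_discs(self):
        rng = np.random.default_rng(7)
        dab = rng.random((300, 300)) < 0.3
        for _ in range(20):
            cx, cy = rng.uniform(10, 290, 2)
            d = rng.uniform(30, 120)
            rep = score_circles(dab, [[cx, cy]], d, 0.2)
            rr, cc = sk_disk((cy, cx), d / 2, shape=dab.shape)
            oracle = brute_force_disc_ratio(dab, cx, cy, d)
            assert abs(rep.circles.ki67_ratio[0] - oracle) <= 1.0 / max(len(rr), 1)

    def test_translation_invariance(self):
        rng = np.random.default_rng(8)
        dab = np.zeros((400, 400), bool)
        rr, cc = sk_disk((120, 130), 35)
        dab[rr, cc] = True
        r1 = score_circles(dab, [[130, 120]], 80).circles.ki67_ratio[0]
        shifted = np.roll(np.roll(dab, 50, axis=0), 70, axis=1)
        r2 = score_circles(shifted, [[200, 170]], 80).circles.ki67_ratio[0]
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_border_clipped_circle_uses_clipped_area(self):
        dab = np.ones((200, 200), bool)
        rep = score_circles(dab, [[0, 0]], 100, 0.2)
        assert rep.circles.ki67_ratio[0] == 1.0  # clipped denominator

    def test_centre_outside_image_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            score_circles(np.zeros((50, 50), bool), [[100, 10]], 20)

    def test_non_positive_diameter_rejected(self):
        with pytest.raises(ValueError):
            score_circles(np.zeros((50, 50), bool), [[10, 10]], 0)


class TestOverlay:
    def test_hotspot_circles_drawn_in_red(self):
        from ki67net.hotspot import render_hotspot_overlay

        dab = np.zeros((200, 200), bool)
        rr, cc = sk_disk((100, 100), 40)
        dab[rr, cc] = True
        rep = score_circles(dab, [[100, 100], [30, 30]], 60, 0.2, all_centroids=centroids(dab))
        img = render_hotspot_overlay(np.full((200, 200, 3), 248, np.uint8), rep)
        assert (img == (220, 30, 30)).all(-1).any()  # hotspot outline
        assert (img == (120, 120, 120)).all(-1).any()  # non-hotspot outline
        assert (img == (40, 60, 230)).all(-1).any()  # centroid dots


class TestBanding:
    def make_report(self, ratios):
        dab = np.zeros((50, 50), bool)
        rep = score_circles(dab, [[25, 25]] * len(ratios), 10)
        rep.circles["ki67_ratio"] = ratios
        return rep

    def test_interval_lookup(self):
        rep = band_proliferation(self.make_report([0.18]), (0.1, 0.15, 0.2))
        assert rep.circles.band[0] == "medium"

    def test_cutoff_value_goes_to_upper_band(self):
        rep = band_proliferation(self.make_report([0.2]), (0.1, 0.15, 0.2))
        assert rep.circles.band[0] == "high"

    def test_zero_ratios_lowest_band(self):
        rep = band_proliferation(self.make_report([0.0, 0.0]), (0.1, 0.15, 0.2))
        assert (rep.circles.band == "negligible").all()

    def test_non_monotone_cutoffs_rejected(self):
        with pytest.raises(ValueError):
            band_proliferation(self.make_report([0.1]), (0.2, 0.1))
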