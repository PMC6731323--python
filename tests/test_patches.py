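"""Tissue rule, patch extraction, augmentation and training-set upkeep."""

import numpy as np
import pytest

import ki67net as k
from ki67net.annotations import AnnotationSet, Region
from ki67net.patches import AUGMENT_OPS, PatchSet, TileGrid, TissueRule, augment
from ki67net.synthetic import PseudoSlide, RegionSpec, SlideSpec, generate_pseudo_slide


def rect_region(x0, y0, x1, y1, label="tumour", rid=1):
    return Region(
        np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]], float), label, rid
    )


class TestIsTissue:
    def test_pure_glass_is_not_tissue(self):
        assert not k.is_tissue(np.full((64, 64, 3), 255, np.uint8))

    def test_black_is_tissue(self):
        assert k.is_tissue(np.zeros((64, 64, 3), np.uint8))

    def test_half_bright_patch_mean_arithmetic(self):
        patch = np.full((64, 64, 3), 255, np.uint8)
        patch[32:] = 200  # mean = 227.5 < 235
        assert k.is_tissue(patch)

    def test_wrong_shape_rejected(self):
        with pytest.raises(ValueError):
            k.is_tissue(np.zeros((64, 64), np.uint8))

    def test_threshold_bounds_validated(self):
        with pytest.raises(ValueError):
            TissueRule(mi_threshold=300)

    def test_agrees_with_direct_mean_on_random_patches(self):
        rng = np.random.default_rng(0)
        rule = TissueRule()
        for _ in range(100):
            patch = rng.integers(180, 256, (64, 64, 3)).astype(np.uint8)
            assert k.is_tissue(patch, rule) == (patch.mean() < 235)


class TestTileGrid:
    def test_origin_lattice(self):
        grid = TileGrid(64, 32)
        origins = grid.origins(128, 96)
        assert (origins % 32 == 0).all()
        assert origins.max(0).tolist() == [64, 32]

    def test_stride_bounds(self):
        with pytest.raises(ValueError):
            TileGrid(64, 0)
        with pytest.raises(ValueError):
            TileGrid(64, 128)


@pytest.fixture(scope="module")
def full_tumour_slide():
    spec = SlideSpec(
        640, 640,
        (RegionSpec(((0, 0), (640, 0), (640, 640), (0, 640)), "tumour", 0.1),),
        rng_seed=2,
    )
    return generate_pseudo_slide(spec)


class TestExtraction:

    def test_full_coverage_grid_count(self, full_tumour_slide):
        slide, gt = full_tumour_slide
        ps = k.extract_labelled_patches(slide, gt.annotation_set, TileGrid(64, 64))
        assert len(ps) == 100
        assert (ps.labels == "tumour").all()

    def test_positions_on_lattice_and_inside(self, full_tumour_slide):
        slide, gt = full_tumour_slide
        ps = k.extract_labelled_patches(slide, gt.annotation_set, TileGrid(64, 32))
        assert (ps.positions % 32 == 0).all()
        assert (ps.positions <= 640 - 64).all()

    def test_boundary_straddling_patch_skipped_at_full_purity(self):
        # tumour on [0, 300), stroma on [300, 640): the straddling column of
        # tiles is dropped when purity is 1.0
        spec = SlideSpec(
            640, 640,
            (
                RegionSpec(((0, 0), (300, 0), (300, 640), (0, 640)), "tumour", 0.1),
                RegionSpec(((300, 0), (640, 0), (640, 640), (300, 640)), "stroma"),
            ),
            rng_seed=4,
        )
        slide, gt = generate_pseudo_slide(spec)
        mask = k.rasterise(gt.annotation_set, 1)
        ps = k.extract_labelled_patches(
            slide, gt.annotation_set, TileGrid(64, 64), purity=1.0
        )
        for (x, y), label in zip(ps.positions, ps.labels):
            window = mask[y : y + 64, x : x + 64]
            assert len(np.unique(window)) == 1
        # the x=256 column straddles the 300 boundary and must be absent
        assert 256 not in set(ps.positions[:, 0])

    def test_all_glass_slide_yields_empty_set(self):
        white = PseudoSlide(np.full((256, 256, 3), 250, np.uint8))
        ann = AnnotationSet([rect_region(0, 0, 256, 256)], slide_dims=(256, 256))
        ps = k.extract_labelled_patches(white, ann, TileGrid(64, 64))
        assert len(ps) == 0

    def test_empty_annotation_warns_and_returns_empty(self, full_tumour_slide):
        slide, _ = full_tumour_slide
        with pytest.warns(UserWarning, match="empty annotation"):
            ps = k.extract_labelled_patches(
                slide, AnnotationSet([], slide_dims=(640, 640)), TileGrid(64, 64)
            )
        assert len(ps) == 0

    def test_higher_purity_yields_subset(self, small_slide):
        slide, gt = small_slide
        strict = k.extract_labelled_patches(
            slide, gt.annotation_set, TileGrid(64, 32), purity=0.95
        )
        loose = k.extract_labelled_patches(
            slide, gt.annotation_set, TileGrid(64, 32), purity=0.75
        )
        loose_pos = {tuple(p) for p in loose.positions}
        assert all(tuple(p) in loose_pos for p in strict.positions)

    def test_purity_out_of_range_rejected(self, small_slide):
        slide, gt = small_slide
        with pytest.raises(ValueError, match="purity"):
            k.extract_labelled_patches(
                slide, gt.annotation_set, TileGrid(64, 64), purity=0.4
            )

    def test_infiltrate_task_labels(self, small_slide):
        slide, gt = small_slide
        ps = k.extract_labelled_patches(
            slide, gt.annotation_set, TileGrid(64, 32), task="infiltrate"
        )
        assert set(np.unique(ps.labels)) <= {"infiltrate", "non-infiltrate"}

    def test_class_counts_report(self, small_slide):
        slide, gt = small_slide
        ps = k.extract_labelled_patches(slide, gt.annotation_set, TileGrid(64, 32))
        counts = ps.class_counts()
        assert counts.sum() == len(ps)
        assert set(counts.index) <= {"tumour", "non-tumour"}


def toy_patchset(n, label="tumour", size=64, seed=0):
    rng = np.random.default_rng(seed)
    return PatchSet(
        rng.integers(0, 255, (n, size, size, 3)).astype(np.uint8),
        np.asarray([label] * n),
        np.zeros((n, 2), int),
        np.asarray(["s"] * n),
    )


class TestAugment:
    def test_no_ops_is_identity(self):
        ps = toy_patchset(5)
        out = augment(ps, [])
        np.testing.assert_array_equal(out.patches, ps.patches)

    def test_hflip_doubles_and_is_involution(self):
        ps = toy_patchset(4)
        out = augment(ps, ["hflip"])
        assert len(out) == 8
        flipped_twice = AUGMENT_OPS["hflip"](out.patches[4:])
        np.testing.assert_array_equal(flipped_twice, ps.patches)

    def test_all_five_ops_count(self):
        out = augment(toy_patchset(10), list(AUGMENT_OPS))
        assert len(out) == 60

    def test_labels_preserved(self):
        ps = toy_patchset(3, label="non-tumour")
        out = augment(ps, ["rot90", "vflip"])
        assert (out.labels == "non-tumour").all()

    def test_unknown_op_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            augment(toy_patchset(2), ["sharpen"])

    def test_rotations_compose_correctly(self):
        p = toy_patchset(1).patches
        r1 = AUGMENT_OPS["rot90"](AUGMENT_OPS["rot90"](p))
        np.testing.assert_array_equal(r1, AUGMENT_OPS["rot180"](p))


class TestAppendFalseRegions:
    def test_empty_append_is_noop(self):
        train = toy_patchset(10)
        out = k.append_false_regions(train)
        assert len(out) == 10

    def test_fp_fn_counts_and_labels(self):
        train = toy_patchset(100, label="tumour")
        fp = toy_patchset(10, label="tumour", seed=1)  # pathologist: actually not
        fn = toy_patchset(5, label="non-tumour", seed=2)  # pathologist: missed tumour
        out = k.append_false_regions(train, false_positives=fp, false_negatives=fn)
        assert len(out) == 115
        counts = out.class_counts()
        assert counts["tumour"] == 105
        assert counts["non-tumour"] == 10

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            k.append_false_regions(
                toy_patchset(4), false_positives=toy_patchset(2, size=32)
            )
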