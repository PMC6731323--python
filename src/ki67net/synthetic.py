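"""Synthetic IHC pseudo-slide generator with exact ground truth.

Emulates the appearance of a Ki67-stained breast tissue section scanned at
~0.5 um/px: near-white glass, pale stroma, haematoxylin-blue nuclei, and
DAB-brown Ki67-positive nuclei inside tumour regions. Region geometry is
given as labelled polygons; every slide is produced together with the
matching annotation set, a downsampled label mask (rasterised from the same
polygons, so mask and annotations agree exactly), a full-resolution binary
mask of DAB-positive nuclei, and the nucleus table itself.

The generator is deliberately stylised — filled ellipses with colour and
size jitter on flat noisy backgrounds — but its classes have overlapping
colour statistics and realistic nuclear densities, which is what the
downstream tissue rule, classifier, stain separation and hotspot scoring
need in order to be exercised meaningfully.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely import Polygon, Point
from skimage.draw import ellipse as _ellipse

from .annotations import AnnotationSet, Region, rasterise

__all__ = [
    "RegionSpec",
    "SlideSpec",
    "PseudoSlide",
    "GroundTruth",
    "generate_pseudo_slide",
    "plant_hotspot",
    "demo_slide_spec",
    "benchmark_slide_spec",
    "hotspot_benchmark_spec",
]

REGION_CLASSES = ("stroma", "benign", "tumour", "infiltrate")

#: canonical annotation label for each synthetic region class
CLASS_TO_LABEL = {
    "stroma": "non-tumour",
    "benign": "non-tumour",
    "tumour": "tumour",
    "infiltrate": "infiltrate",
}

#: rendering order mirrors rasterisation priority (higher paints last)
_CLASS_PRIORITY = {"stroma": 0, "benign": 0, "tumour": 1, "infiltrate": 2}

GLASS_LEVEL = 248.0
GLASS_NOISE = 2.0

HAEMATOXYLIN_RGB = np.array([70.0, 80.0, 160.0])
DAB_RGB = np.array([110.0, 70.0, 30.0])
INFILTRATE_NUCLEUS_RGB = np.array([55.0, 60.0, 130.0])

#: per-class tissue appearance: background colour, nuclei per 1000 px^2,
#: nucleus semi-major axis range (px)
APPEARANCE = {
    "stroma": {"base": (228.0, 215.0, 225.0), "density": 0.4, "radius": (2.0, 4.0)},
    "benign": {"base": (222.0, 208.0, 219.0), "density": 1.2, "radius": (3.0, 5.0)},
    "tumour": {"base": (216.0, 200.0, 213.0), "density": 11.0, "radius": (5.5, 7.5)},
    "infiltrate": {"base": (226.0, 213.0, 223.0), "density": 12.0, "radius": (2.0, 3.0)},
}


@dataclass(frozen=True)
class RegionSpec:
    """One tissue region: a polygon, its class, and (for tumour) the
    fraction of its nuclei that are Ki67-positive."""

    polygon: tuple
    region_class: str
    ki67_fraction: float = 0.0
    density: float | None = None  # nuclei per 1000 px^2; class default if None
    radius: tuple[float, float] | None = None  # semi-axis range; class default

    def __post_init__(self):
        if self.region_class not in REGION_CLASSES:
            raise ValueError(
                f"unknown region class {self.region_class!r}; "
                f"choose from {REGION_CLASSES}"
            )
        if not 0.0 <= self.ki67_fraction <= 1.0:
            raise ValueError("ki67_fraction must be in [0, 1]")


@dataclass(frozen=True)
class SlideSpec:
    width_px: int
    height_px: int
    tissue_regions: tuple = ()
    microns_per_px: float = 0.5
    rng_seed: int = 0
    mask_downsample: int = 8
    slide_id: str = "synthetic"

    def __post_init__(self):
        if self.width_px < 256 or self.height_px < 256:
            raise ValueError("canvas must be at least 256x256")
        if self.microns_per_px <= 0:
            raise ValueError("microns_per_px must be positive")

    def annotation_set(self) -> AnnotationSet:
        regions = [
            Region(np.asarray(rs.polygon, float), CLASS_TO_LABEL[rs.region_class], i + 1)
            for i, rs in enumerate(self.tissue_regions)
        ]
        return AnnotationSet(regions, slide_dims=(self.width_px, self.height_px))


def slide_spec_to_yaml(spec: SlideSpec, path=None) -> str:
    """Serialise a SlideSpec (regions as vertex lists) to YAML."""
    import yaml

    doc = {
        "width_px": spec.width_px,
        "height_px": spec.height_px,
        "microns_per_px": spec.microns_per_px,
        "rng_seed": spec.rng_seed,
        "mask_downsample": spec.mask_downsample,
        "slide_id": spec.slide_id,
        "tissue_regions": [
            {
                "polygon": [[float(x), float(y)] for x, y in rs.polygon],
                "region_class": rs.region_class,
                "ki67_fraction": rs.ki67_fraction,
                **({"density": rs.density} if rs.density is not None else {}),
                **({"radius": list(rs.radius)} if rs.radius is not None else {}),
            }
            for rs in spec.tissue_regions
        ],
    }
    text = yaml.safe_dump(doc, sort_keys=False)
    if path is not None:
        from pathlib import Path

        Path(path).write_text(text)
    return text


def slide_spec_from_yaml(source) -> SlideSpec:
    """Load a SlideSpec from a YAML string or file path."""
    import os

    import yaml

    if isinstance(source, (str, bytes)) and not os.path.exists(str(source)):
        doc = yaml.safe_load(source)
    else:
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    regions = tuple(
        RegionSpec(
            polygon=tuple((float(x), float(y)) for x, y in r["polygon"]),
            region_class=r["region_class"],
            ki67_fraction=r.get("ki67_fraction", 0.0),
            density=r.get("density"),
            radius=tuple(r["radius"]) if "radius" in r else None,
        )
        for r in doc.get("tissue_regions", [])
    )
    return SlideSpec(
        width_px=doc["width_px"],
        height_px=doc["height_px"],
        tissue_regions=regions,
        microns_per_px=doc.get("microns_per_px", 0.5),
        rng_seed=doc.get("rng_seed", 0),
        mask_downsample=doc.get("mask_downsample", 8),
        slide_id=doc.get("slide_id", "synthetic"),
    )


@dataclass
class PseudoSlide:
    image: np.ndarray  # (H, W, 3) uint8
    microns_per_px: float = 0.5
    slide_id: str = "synthetic"

    @property
    def shape(self):
        return self.image.shape


@dataclass
class GroundTruth:
    label_mask: np.ndarray  # uint8 at `downsample` (0 glass, 1 non-tumour, 2 tumour, 3 infiltrate)
    downsample: int
    annotation_set: AnnotationSet
    ki67_positive_mask: np.ndarray  # bool, full resolution
    nuclei: pd.DataFrame  # x, y, rx, ry, angle, dab, region, region_class


def _upsample(mask: np.ndarray, factor: int, h: int, w: int) -> np.ndarray:
    return np.repeat(np.repeat(mask, factor, 0), factor, 1)[:h, :w]


def _region_index_map(spec: SlideSpec) -> np.ndarray:
    """Full-resolution map of region indices (1-based, 0 = glass), with
    overlaps resolved by the same priority as mask rasterisation."""
    idx = np.zeros((spec.height_px, spec.width_px), np.int32)
    order = sorted(
        range(len(spec.tissue_regions)),
        key=lambda i: _CLASS_PRIORITY[spec.tissue_regions[i].region_class],
    )
    ann = spec.annotation_set()
    from shapely import contains_xy

    for i in order:
        poly = ann.regions[i].shapely()
        minx, miny, maxx, maxy = poly.bounds
        j0, j1 = max(int(minx) - 1, 0), min(int(maxx) + 2, spec.width_px)
        i0, i1 = max(int(miny) - 1, 0), min(int(maxy) + 2, spec.height_px)
        xs = np.arange(j0, j1) + 0.5
        ys = np.arange(i0, i1) + 0.5
        gx, gy = np.meshgrid(xs, ys)
        inside = contains_xy(poly, gx.ravel(), gy.ravel()).reshape(gy.shape)
        idx[i0:i1, j0:j1][inside] = i + 1
    return idx


def _sample_nuclei(spec: SlideSpec, idx_map: np.ndarray, rng) -> pd.DataFrame:
    rows = []
    for i, rs in enumerate(spec.tissue_regions):
        app = APPEARANCE[rs.region_class]
        density = rs.density if rs.density is not None else app["density"]
        rmin, rmax = rs.radius if rs.radius is not None else app["radius"]
        ys, xs = np.nonzero(idx_map == i + 1)
        area = len(xs)
        n = int(round(area * density / 1000.0))
        if n == 0:
            raise ValueError(
                f"region {i + 1} ({rs.region_class}): density {density} "
                f"per 1000 px^2 over {area} px^2 yields zero nuclei"
            )
        pick = rng.integers(0, area, n)
        rx = rng.uniform(rmin, rmax, n)
        ry = rx * rng.uniform(0.7, 1.0, n)
        angle = rng.uniform(0.0, np.pi, n)
        dab = np.zeros(n, bool)
        n_pos = int(round(rs.ki67_fraction * n))
        if n_pos:
            dab[rng.permutation(n)[:n_pos]] = True
        rows.append(
            pd.DataFrame(
                {
                    "x": xs[pick].astype(float),
                    "y": ys[pick].astype(float),
                    "rx": rx,
                    "ry": ry,
                    "angle": angle,
                    "dab": dab,
                    "region": i + 1,
                    "region_class": rs.region_class,
                }
            )
        )
    if not rows:
        return pd.DataFrame(
            columns=["x", "y", "rx", "ry", "angle", "dab", "region", "region_class"]
        )
    return pd.concat(rows, ignore_index=True)


def _nucleus_colour(row, rng) -> np.ndarray:
    if row.dab:
        base = DAB_RGB
        jitter = rng.normal(0.0, 5.0, 3)
    elif row.region_class == "infiltrate":
        base = INFILTRATE_NUCLEUS_RGB
        jitter = rng.normal(0.0, 6.0, 3)
    else:
        base = HAEMATOXYLIN_RGB
        jitter = rng.normal(0.0, 6.0, 3)
    return np.clip(base + jitter, 0.0, 255.0)


def _render_nucleus(image, tissue, ki67_mask, row, colour):
    rr, cc = _ellipse(
        row.y, row.x, row.ry, row.rx, shape=image.shape[:2], rotation=row.angle
    )
    if len(rr) == 0:
        return
    keep = tissue[rr, cc]
    rr, cc = rr[keep], cc[keep]
    image[rr, cc] = colour
    if ki67_mask is not None:
        if row.dab:
            ki67_mask[rr, cc] = True
        else:
            ki67_mask[rr, cc] = False


def generate_pseudo_slide(spec: SlideSpec) -> tuple[PseudoSlide, GroundTruth]:
    """Render a pseudo-slide and its exact ground truth.

    Deterministic for a fixed ``spec.rng_seed``. Raises if any polygon
    leaves the canvas or a region's nucleus density rounds to zero nuclei.
    """
    ann = spec.annotation_set()
    ann.validate_inside(spec.width_px, spec.height_px)
    rng = np.random.default_rng(spec.rng_seed)
    h, w = spec.height_px, spec.width_px

    # glass stays near-white: noise is clipped so no background pixel
    # drops below 240 on any channel
    image = np.clip(rng.normal(GLASS_LEVEL, GLASS_NOISE, (h, w, 3)), 240.0, 255.0)
    idx_map = _region_index_map(spec)

    order = sorted(
        range(len(spec.tissue_regions)),
        key=lambda i: _CLASS_PRIORITY[spec.tissue_regions[i].region_class],
    )
    for i in order:
        rs = spec.tissue_regions[i]
        sel = idx_map == i + 1
        npx = int(sel.sum())
        if npx == 0:
            continue
        base = np.asarray(APPEARANCE[rs.region_class]["base"])
        image[sel] = base + rng.normal(0.0, 4.0, (npx, 3))

    nuclei = _sample_nuclei(spec, idx_map, rng) if spec.tissue_regions else pd.DataFrame(
        columns=["x", "y", "rx", "ry", "angle", "dab", "region", "region_class"]
    )
    label_mask = rasterise(ann, spec.mask_downsample)
    ki67_mask = np.zeros((h, w), bool)
    tissue = idx_map > 0
    # nuclei are clipped to the tissue footprint *as seen at the mask
    # downsample* so full-resolution DAB never leaks outside the label mask
    tissue &= _upsample(label_mask > 0, spec.mask_downsample, h, w)
    for row in nuclei.itertuples():
        colour = _nucleus_colour(row, rng)
        _render_nucleus(image, tissue, ki67_mask, row, colour)
    slide = PseudoSlide(
        np.clip(image, 0, 255).astype(np.uint8),
        microns_per_px=spec.microns_per_px,
        slide_id=spec.slide_id,
    )
    gt = GroundTruth(label_mask, spec.mask_downsample, ann, ki67_mask, nuclei)
    return slide, gt


def realised_ki67_fraction(gt: GroundTruth, region: int | None = None) -> float:
    """Fraction of rendered nuclei labelled DAB-positive (by nucleus count)."""
    nuc = gt.nuclei
    if region is not None:
        nuc = nuc[nuc.region == region]
    if len(nuc) == 0:
        return 0.0
    return float(nuc.dab.mean())


def plant_hotspot(
    slide: PseudoSlide,
    gt: GroundTruth,
    centre: tuple[float, float],
    radius_px: int,
    ki67_fraction: float,
    rng_seed: int = 0,
) -> tuple[PseudoSlide, GroundTruth]:
    """Raise (or lower) the Ki67-positive nucleus fraction to
    ``ki67_fraction`` inside the disc of ``radius_px`` around ``centre``
    (x, y), re-rendering the flipped nuclei and updating the masks.

    ``centre`` must lie inside a tumour region; ``radius_px == 0`` is a
    documented no-op returning unchanged copies.
    """
    if not 0.0 <= ki67_fraction <= 1.0:
        raise ValueError("ki67_fraction must be in [0, 1]")
    pt = Point(*centre)
    if not any(
        r.shapely().contains(pt) for r in gt.annotation_set.by_label("tumour")
    ):
        raise ValueError(f"hotspot centre {centre} is not inside a tumour region")
    new_slide = PseudoSlide(slide.image.copy(), slide.microns_per_px, slide.slide_id)
    nuclei = gt.nuclei.copy()
    new_gt = GroundTruth(
        gt.label_mask.copy(), gt.downsample, gt.annotation_set,
        gt.ki67_positive_mask.copy(), nuclei,
    )
    if radius_px == 0:
        return new_slide, new_gt
    if radius_px < 0:
        raise ValueError("radius_px must be >= 0")

    cx, cy = centre
    in_disc = (
        (nuclei.x - cx) ** 2 + (nuclei.y - cy) ** 2 <= radius_px**2
    ) & (nuclei.region_class == "tumour")
    n = int(in_disc.sum())
    if n == 0:
        warnings.warn("no tumour nuclei inside the hotspot disc; nothing planted")
        return new_slide, new_gt
    target = int(round(ki67_fraction * n))
    rng = np.random.default_rng(rng_seed)
    idx = nuclei.index[in_disc]
    pos = idx[nuclei.loc[idx, "dab"]]
    neg = idx[~nuclei.loc[idx, "dab"]]
    flipped = []
    if target > len(pos):
        flipped = list(rng.permutation(neg)[: target - len(pos)])
        nuclei.loc[flipped, "dab"] = True
    elif target < len(pos):
        flipped = list(rng.permutation(pos)[: len(pos) - target])
        nuclei.loc[flipped, "dab"] = False
    if not flipped:
        return new_slide, new_gt

    h, w = slide.image.shape[:2]
    tissue = rasterise(gt.annotation_set, 1) > 0
    tissue &= _upsample(gt.label_mask > 0, gt.downsample, h, w)
    for row in nuclei.loc[flipped].itertuples():
        colour = _nucleus_colour(row, rng)
        _render_nucleus(new_slide.image, tissue, None, row, colour)
    # rebuild the DAB mask from the nucleus table in draw order (overlapping
    # ellipses make incremental erasure unreliable)
    ki67_mask = np.zeros_like(gt.ki67_positive_mask)
    for row in nuclei.itertuples():
        rr, cc = _ellipse(
            row.y, row.x, row.ry, row.rx, shape=ki67_mask.shape, rotation=row.angle
        )
        keep = tissue[rr, cc]
        ki67_mask[rr[keep], cc[keep]] = bool(row.dab)
    new_gt.ki67_positive_mask = ki67_mask
    new_gt.nuclei = nuclei
    return new_slide, new_gt


def _blob(cx, cy, r, rng, n_vert=14, wobble=0.25, bounds=None) -> tuple:
    """Irregular star-convex polygon around (cx, cy), optionally clipped to
    a (width, height) canvas."""
    theta = np.linspace(0.0, 2 * np.pi, n_vert, endpoint=False)
    radii = r * (1.0 + rng.uniform(-wobble, wobble, n_vert))
    xs = cx + radii * np.cos(theta)
    ys = cy + radii * np.sin(theta)
    if bounds is not None:
        w, h = bounds
        xs = np.clip(xs, 1.0, w - 1.0)
        ys = np.clip(ys, 1.0, h - 1.0)
    return tuple(zip(xs, ys))


def benchmark_slide_spec(
    seed: int, width: int = 2048, height: int = 2048, tumour_ki67: float = 0.15
) -> SlideSpec:
    """The standard evaluation layout: a large stroma field, three tumour
    nests, a benign epithelial island and a lymphocytic infiltrate field.
    Used for training-patch harvests and whole-slide benchmarks."""
    rng = np.random.default_rng(seed)
    w, h = width, height
    m = min(w, h)
    regions = (
        RegionSpec(_blob(0.50 * w, 0.50 * h, 0.45 * m, rng, n_vert=18, bounds=(w, h)), "stroma"),
        RegionSpec(_blob(0.35 * w, 0.38 * h, 0.24 * m, rng), "tumour", ki67_fraction=tumour_ki67),
        RegionSpec(_blob(0.68 * w, 0.60 * h, 0.17 * m, rng), "tumour", ki67_fraction=tumour_ki67),
        RegionSpec(_blob(0.30 * w, 0.76 * h, 0.13 * m, rng), "tumour", ki67_fraction=tumour_ki67),
        RegionSpec(_blob(0.55 * w, 0.83 * h, 0.11 * m, rng), "benign"),
        RegionSpec(_blob(0.72 * w, 0.26 * h, 0.11 * m, rng), "infiltrate"),
    )
    return SlideSpec(w, h, regions, rng_seed=seed)


def hotspot_benchmark_spec(
    seed: int, width: int = 1024, height: int = 1024, ambient_ki67: float = 0.05
) -> SlideSpec:
    """A tumour field with low ambient Ki67, ready for hotspot planting."""
    rng = np.random.default_rng(seed)
    w, h = width, height
    regions = (
        RegionSpec(_blob(0.5 * w, 0.5 * h, 0.45 * min(w, h), rng, bounds=(w, h)), "stroma"),
        RegionSpec(
            _blob(0.5 * w, 0.5 * h, 0.32 * min(w, h), rng),
            "tumour",
            ki67_fraction=ambient_ki67,
        ),
    )
    return SlideSpec(w, h, regions, rng_seed=seed)


def demo_slide_spec(
    width: int = 1024,
    height: int = 1024,
    seed: int = 0,
    tumour_ki67: float = 0.15,
    with_infiltrate: bool = True,
) -> SlideSpec:
    """A representative slide layout: a stroma field occupying most of the
    canvas, one large and one small tumour nest, a benign epithelial
    island, and optionally a lymphocytic infiltrate field."""
    rng = np.random.default_rng(seed)
    w, h = width, height
    regions = [
        RegionSpec(
            _blob(0.50 * w, 0.50 * h, 0.42 * min(w, h), rng, bounds=(w, h)), "stroma"
        ),
        RegionSpec(
            _blob(0.38 * w, 0.40 * h, 0.20 * min(w, h), rng),
            "tumour",
            ki67_fraction=tumour_ki67,
        ),
        RegionSpec(
            _blob(0.70 * w, 0.65 * h, 0.11 * min(w, h), rng),
            "tumour",
            ki67_fraction=tumour_ki67,
        ),
        RegionSpec(_blob(0.30 * w, 0.74 * h, 0.10 * min(w, h), rng), "benign"),
    ]
    if with_infiltrate:
        regions.append(
            RegionSpec(_blob(0.68 * w, 0.30 * h, 0.09 * min(w, h), rng), "infiltrate")
        )
    return SlideSpec(
        width_px=w, height_px=h, tissue_regions=tuple(regions), rng_seed=seed
    )
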