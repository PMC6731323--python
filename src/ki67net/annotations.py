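"""Polygon annotations: ImageScope-style XML I/O and mask rasterisation.

Annotations are labelled polygons in level-0 pixel coordinates (0-based,
x rightwards, y downwards). The closed label vocabulary is
``tumour | non-tumour | infiltrate``; free-text layer names from the XML
are mapped onto it through a configurable mapping. Rasterisation labels a
pixel by the highest-priority polygon covering its *centre*
(infiltrate > tumour > non-tumour > background).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from lxml import etree
from shapely import Polygon, contains_xy

__all__ = [
    "LABELS",
    "LABEL_VALUES",
    "Region",
    "AnnotationSet",
    "read_imagescope_xml",
    "write_imagescope_xml",
    "rasterise",
]

LABELS = ("tumour", "non-tumour", "infiltrate")

#: integer code of each label in rasterised masks (0 = background/glass)
LABEL_VALUES = {"non-tumour": 1, "tumour": 2, "infiltrate": 3}

#: priority used to resolve overlapping polygons (higher wins)
_PRIORITY = {"non-tumour": 0, "tumour": 1, "infiltrate": 2}

#: default free-text -> canonical label mapping for ImageScope layers
DEFAULT_LABEL_MAP = {
    "tumour": "tumour",
    "tumor": "tumour",
    "non-tumour": "non-tumour",
    "non-tumor": "non-tumour",
    "nontumour": "non-tumour",
    "nontumor": "non-tumour",
    "benign": "non-tumour",
    "stroma": "non-tumour",
    "infiltrate": "infiltrate",
    "lymphocytic infiltrate": "infiltrate",
}


@dataclass(frozen=True)
class Region:
    polygon: np.ndarray  # (n, 2) float, level-0 pixel coordinates
    label: str
    region_id: int

    def __post_init__(self):
        poly = np.asarray(self.polygon, dtype=float)
        object.__setattr__(self, "polygon", poly)
        if poly.ndim != 2 or poly.shape[1] != 2 or len(poly) < 3:
            raise ValueError("polygon needs >= 3 (x, y) vertices")
        if self.label not in LABELS:
            raise ValueError(
                f"unknown label {self.label!r}; known labels: {', '.join(LABELS)}"
            )
        if not Polygon(poly).is_valid:
            raise ValueError(
                f"region {self.region_id}: polygon is self-intersecting or degenerate"
            )

    def shapely(self) -> Polygon:
        return Polygon(self.polygon)

    def area(self) -> float:
        """Shoelace area in px^2."""
        x, y = self.polygon[:, 0], self.polygon[:, 1]
        return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


@dataclass
class AnnotationSet:
    regions: list[Region] = field(default_factory=list)
    slide_dims: tuple[int, int] = (0, 0)  # (width, height)

    def __len__(self):
        return len(self.regions)

    def by_label(self, label: str) -> list[Region]:
        return [r for r in self.regions if r.label == label]

    def validate_inside(self, width: int, height: int) -> None:
        for r in self.regions:
            x, y = r.polygon[:, 0], r.polygon[:, 1]
            if x.min() < 0 or y.min() < 0 or x.max() > width or y.max() > height:
                raise ValueError(
                    f"region {r.region_id} extends outside the "
                    f"{width}x{height} canvas"
                )


def read_imagescope_xml(path, label_map=None) -> AnnotationSet:
    """Parse an ImageScope-style annotation file.

    Layout: Annotations/Annotation/Regions/Region/Vertices/Vertex with X, Y
    attributes. The region label is taken from the Region ``Text``
    attribute if present, else the enclosing Annotation ``Name``, and fed
    through ``label_map`` (case-insensitive; defaults cover common
    tumour/non-tumour/infiltrate spellings).
    """
    label_map = {k.lower(): v for k, v in (label_map or DEFAULT_LABEL_MAP).items()}
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as e:
        raise ValueError(f"malformed annotation XML in {path}: {e}") from e
    root = tree.getroot()
    if root.tag != "Annotations":
        raise ValueError(f"expected root element 'Annotations', found '{root.tag}'")
    w = int(float(root.get("Width", 0)))
    h = int(float(root.get("Height", 0)))
    regions, rid = [], 0
    for ann in root.iter("Annotation"):
        layer_name = ann.get("Name", "")
        for reg in ann.iter("Region"):
            raw = reg.get("Text") or layer_name
            key = raw.strip().lower()
            if key not in label_map:
                raise ValueError(
                    f"unmapped region label {raw!r}; known labels: "
                    f"{sorted(set(label_map))}"
                )
            verts = [
                (float(v.get("X")), float(v.get("Y")))
                for v in reg.iter("Vertex")
            ]
            if len(verts) < 3:
                raise ValueError(
                    f"Region {reg.get('Id', rid)} has fewer than 3 Vertex elements"
                )
            rid += 1
            regions.append(
                Region(np.asarray(verts), label_map[key], int(reg.get("Id", rid)))
            )
    return AnnotationSet(regions, slide_dims=(w, h))


def write_imagescope_xml(ann: AnnotationSet, path) -> None:
    """Write ImageScope-style XML; one Annotation layer per label."""
    root = etree.Element(
        "Annotations",
        Width=str(ann.slide_dims[0]),
        Height=str(ann.slide_dims[1]),
    )
    for label in LABELS:
        regs = ann.by_label(label)
        if not regs:
            continue
        layer = etree.SubElement(root, "Annotation", Name=label)
        regions_el = etree.SubElement(layer, "Regions")
        for r in regs:
            reg_el = etree.SubElement(
                regions_el, "Region", Id=str(r.region_id), Text=label
            )
            verts_el = etree.SubElement(reg_el, "Vertices")
            for x, y in r.polygon:
                etree.SubElement(verts_el, "Vertex", X=repr(float(x)), Y=repr(float(y)))
    etree.ElementTree(root).write(
        str(path), pretty_print=True, xml_declaration=True, encoding="utf-8"
    )


def rasterise(
    ann: AnnotationSet, downsample: int = 1, dims: tuple[int, int] | None = None
) -> np.ndarray:
    """Label mask at the given downsample.

    A pixel (row i, col j) takes the code of the highest-priority polygon
    containing its centre ``((j + 0.5) * d, (i + 0.5) * d)`` in level-0
    coordinates; uncovered pixels are 0. Mask dims are
    ``ceil(slide_dims / d)``.
    """
    if downsample < 1 or int(downsample) != downsample:
        raise ValueError("downsample must be a positive integer")
    d = int(downsample)
    width, height = dims if dims is not None else ann.slide_dims
    gw, gh = math.ceil(width / d), math.ceil(height / d)
    mask = np.zeros((gh, gw), dtype=np.uint8)
    for region in sorted(ann.regions, key=lambda r: _PRIORITY[r.label]):
        poly = region.shapely()
        minx, miny, maxx, maxy = poly.bounds
        j0 = max(int(minx / d - 1), 0)
        j1 = min(int(maxx / d + 1) + 1, gw)
        i0 = max(int(miny / d - 1), 0)
        i1 = min(int(maxy / d + 1) + 1, gh)
        if j0 >= j1 or i0 >= i1:
            continue
        xs = (np.arange(j0, j1) + 0.5) * d
        ys = (np.arange(i0, i1) + 0.5) * d
        gx, gy = np.meshgrid(xs, ys)
        inside = contains_xy(poly, gx.ravel(), gy.ravel()).reshape(gy.shape)
        mask[i0:i1, j0:j1][inside] = LABEL_VALUES[region.label]
    return mask
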