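"""Whole-slide inference: overlapping-tile scoring, probability-map
assembly, infiltrate exclusion, binarisation and pseudo-colour rendering.

The probability map lives on the stride lattice: cell (i, j) covers slide
pixels [j*stride, (j+1)*stride) x [i*stride, (i+1)*stride). Every tissue
tile contributes its tumour probability to all cells it covers and
overlapping contributions are averaged. Cells never covered by a tissue
tile are background (coverage 0), which is distinct from probability 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .patches import TissueRule, is_tissue

__all__ = [
    "ProbabilityMap",
    "ColourBinning",
    "infer_slide",
    "exclude_infiltrate",
    "binarise",
    "render_pseudocolour",
]


@dataclass
class ProbabilityMap:
    probs: np.ndarray  # (gh, gw) float32, mean tumour probability per cell
    coverage: np.ndarray  # (gh, gw) int, number of tiles that scored the cell
    stride_px: int
    patch_size: int
    slide_id: str = "slide"
    excluded: np.ndarray | None = None  # cells forced non-tumour by infiltrate

    @property
    def covered(self) -> np.ndarray:
        return self.coverage > 0

    def check_geometry(self, other: "ProbabilityMap") -> None:
        if (
            self.probs.shape != other.probs.shape
            or self.stride_px != other.stride_px
            or self.patch_size != other.patch_size
        ):
            raise ValueError(
                f"probability map geometry mismatch: "
                f"{self.probs.shape}@{self.stride_px} vs "
                f"{other.probs.shape}@{other.stride_px}"
            )

    def to_fullres_mask(self, binary_cells: np.ndarray, width: int, height: int):
        """Expand a cell-level boolean array to level-0 pixels."""
        full = np.repeat(
            np.repeat(binary_cells, self.stride_px, 0), self.stride_px, 1
        )
        return full[:height, :width]


@dataclass(frozen=True)
class ColourBinning:
    """Pseudo-colour bins for tumour probability. Half-open on the upper
    edge: the bin colour applies for ``edge_low < p <= edge_high``, so red
    is strictly ``p > 0.75``."""

    edges: tuple[float, ...] = (0.55, 0.65, 0.75)
    colours: tuple = (
        (60, 90, 220),  # non-tumour: blue
        (250, 220, 40),  # yellow
        (245, 140, 30),  # orange
        (220, 40, 40),  # red
    )

    def __post_init__(self):
        e = self.edges
        if any(e[i] >= e[i + 1] for i in range(len(e) - 1)):
            raise ValueError("bin edges must be strictly increasing")
        if len(self.colours) != len(e) + 1:
            raise ValueError("need one colour per bin")

    def bin_index(self, p) -> np.ndarray:
        """0 = lowest (non-tumour) bin; edge values fall in the lower bin."""
        return np.searchsorted(np.asarray(self.edges), np.asarray(p), side="left")


def infer_slide(
    slide,
    model,
    stride_px: int = 32,
    rule: TissueRule = TissueRule(),
    positive_label: str = "tumour",
    batch_size: int = 25,
) -> ProbabilityMap:
    """Score every tissue tile of the slide and assemble the averaged
    tumour probability map. Glass tiles (mean intensity >= threshold) are
    skipped and leave zero coverage."""
    image = slide.image if hasattr(slide, "image") else np.asarray(slide)
    h, w = image.shape[:2]
    patch = int(getattr(model, "patch_size", 64))
    if h < patch or w < patch:
        raise ValueError(f"slide {w}x{h} is smaller than one {patch}x{patch} patch")
    if patch % stride_px != 0:
        raise ValueError("stride must divide the patch size")

    classes = list(getattr(model, "classes_"))
    if positive_label not in classes:
        raise ValueError(f"model classes {classes} lack label {positive_label!r}")
    pos_idx = classes.index(positive_label)

    gw, gh = w // stride_px, h // stride_px
    acc = np.zeros((gh, gw), np.float64)
    cov = np.zeros((gh, gw), np.int32)
    span = patch // stride_px

    xs = np.arange(0, w - patch + 1, stride_px)
    ys = np.arange(0, h - patch + 1, stride_px)
    origins = [
        (x, y)
        for y in ys
        for x in xs
        if image[y : y + patch, x : x + patch].mean() < rule.mi_threshold
    ]
    for k in range(0, len(origins), batch_size):
        chunk = origins[k : k + batch_size]
        tiles = np.stack([image[y : y + patch, x : x + patch] for x, y in chunk])
        probs = model.predict_proba(tiles)[:, pos_idx]
        for (x, y), p in zip(chunk, probs):
            ci, cj = y // stride_px, x // stride_px
            acc[ci : ci + span, cj : cj + span] += p
            cov[ci : ci + span, cj : cj + span] += 1
    probs = np.where(cov > 0, acc / np.maximum(cov, 1), 0.0).astype(np.float32)
    return ProbabilityMap(
        probs, cov, stride_px, patch, slide_id=getattr(slide, "slide_id", "slide")
    )


def exclude_infiltrate(
    tumour_map: ProbabilityMap,
    infiltrate_map: ProbabilityMap,
    threshold: float = 0.5,
) -> ProbabilityMap:
    """Force cells with infiltrate probability >= threshold to non-tumour
    (p = 0) and flag them. Idempotent."""
    tumour_map.check_geometry(infiltrate_map)
    hit = infiltrate_map.covered & (infiltrate_map.probs >= threshold)
    probs = tumour_map.probs.copy()
    probs[hit] = 0.0
    excluded = (
        hit if tumour_map.excluded is None else (tumour_map.excluded | hit)
    )
    return ProbabilityMap(
        probs,
        tumour_map.coverage.copy(),
        tumour_map.stride_px,
        tumour_map.patch_size,
        tumour_map.slide_id,
        excluded=excluded,
    )


def binarise(pmap: ProbabilityMap, threshold: float = 0.55) -> np.ndarray:
    """Binary tumour mask at cell resolution: covered cells with
    p > threshold (threshold 1.0 therefore yields an empty mask)."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    return (pmap.probs > threshold) & pmap.covered


def render_pseudocolour(
    pmap: ProbabilityMap,
    bins: ColourBinning = ColourBinning(),
    slide=None,
    opacity: float = 0.55,
) -> np.ndarray:
    """Paint each covered cell its probability-bin colour over the slide
    (or over white if no slide is given); uncovered cells are untouched."""
    gh, gw = pmap.probs.shape
    s = pmap.stride_px
    if slide is not None:
        image = slide.image if hasattr(slide, "image") else np.asarray(slide)
        canvas = image[: gh * s, : gw * s].astype(np.float64).copy()
    else:
        canvas = np.full((gh * s, gw * s, 3), 255.0)
    idx = bins.bin_index(pmap.probs)
    colour_lut = np.asarray(bins.colours, np.float64)
    cell_colours = colour_lut[idx]  # (gh, gw, 3)
    cell_full = np.repeat(np.repeat(cell_colours, s, 0), s, 1)
    covered_full = np.repeat(np.repeat(pmap.covered, s, 0), s, 1)
    canvas[covered_full] = (
        (1 - opacity) * canvas[covered_full] + opacity * cell_full[covered_full]
    )
    return np.clip(canvas, 0, 255).astype(np.uint8)
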