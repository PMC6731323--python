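"""Tissue detection, sliding-window patch extraction, labelling from
annotations, dihedral augmentation, and training-set maintenance.

Tissue is detected with the mean-intensity rule: a 64x64 patch whose mean
over all pixels and channels is below 235 is tissue, anything brighter is
glass. Patches are labelled from the annotation mask only when at least a
``purity`` fraction of their pixels carries the same label, which drops
boundary-straddling patches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotations import AnnotationSet, rasterise

__all__ = [
    "TissueRule",
    "TileGrid",
    "PatchSet",
    "is_tissue",
    "extract_labelled_patches",
    "augment",
    "append_false_regions",
    "AUGMENT_OPS",
]


@dataclass(frozen=True)
class TissueRule:
    """Mean-intensity (MI) tissue cut-off; MI < threshold means tissue."""

    mi_threshold: float = 235.0

    def __post_init__(self):
        if not 0.0 < self.mi_threshold < 255.0:
            raise ValueError("mi_threshold must be in (0, 255)")


@dataclass(frozen=True)
class TileGrid:
    """Sliding-window lattice: 64x64 tiles at a fixed stride from (0, 0)."""

    patch_size: int = 64
    stride_px: int = 64

    def __post_init__(self):
        if not 1 <= self.stride_px <= self.patch_size:
            raise ValueError("stride must satisfy 1 <= stride <= patch size")

    def origins(self, width: int, height: int) -> np.ndarray:
        """All (x, y) tile origins fully inside a width x height slide."""
        xs = np.arange(0, width - self.patch_size + 1, self.stride_px)
        ys = np.arange(0, height - self.patch_size + 1, self.stride_px)
        gx, gy = np.meshgrid(xs, ys)
        return np.column_stack([gx.ravel(), gy.ravel()])


@dataclass
class PatchSet:
    """Labelled RGB patches with provenance."""

    patches: np.ndarray  # (n, S, S, 3) uint8
    labels: np.ndarray  # (n,) str
    positions: np.ndarray  # (n, 2) int, tile origins (x, y)
    slide_ids: np.ndarray  # (n,) str

    def __post_init__(self):
        n = len(self.patches)
        if not (len(self.labels) == len(self.positions) == len(self.slide_ids) == n):
            raise ValueError("patches, labels, positions, slide_ids lengths differ")

    def __len__(self):
        return len(self.patches)

    @classmethod
    def empty(cls, patch_size: int = 64) -> "PatchSet":
        return cls(
            np.empty((0, patch_size, patch_size, 3), np.uint8),
            np.empty(0, dtype="<U16"),
            np.empty((0, 2), int),
            np.empty(0, dtype="<U64"),
        )

    def class_counts(self) -> pd.Series:
        """Per-class patch counts (the class-balance report)."""
        return pd.Series(self.labels).value_counts().sort_index()

    def subset(self, idx) -> "PatchSet":
        return PatchSet(
            self.patches[idx], self.labels[idx], self.positions[idx], self.slide_ids[idx]
        )

    @staticmethod
    def concatenate(sets: list["PatchSet"]) -> "PatchSet":
        sizes = {s.patches.shape[1:] for s in sets if len(s)}
        if len(sizes) > 1:
            raise ValueError(f"patch dimension mismatch: {sizes}")
        return PatchSet(
            np.concatenate([s.patches for s in sets]),
            np.concatenate([s.labels for s in sets]),
            np.concatenate([s.positions for s in sets]),
            np.concatenate([s.slide_ids for s in sets]),
        )

    def save(self, directory) -> None:
        """Persist as PNGs plus a CSV manifest (slide_id, x, y, label)."""
        from PIL import Image

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        rows = []
        for i in range(len(self)):
            name = f"patch_{i:06d}.png"
            Image.fromarray(self.patches[i]).save(directory / name)
            rows.append(
                {
                    "file": name,
                    "slide_id": self.slide_ids[i],
                    "x": int(self.positions[i, 0]),
                    "y": int(self.positions[i, 1]),
                    "label": self.labels[i],
                }
            )
        pd.DataFrame(rows).to_csv(directory / "manifest.csv", index=False)

    @classmethod
    def load(cls, directory) -> "PatchSet":
        from PIL import Image

        directory = Path(directory)
        manifest = pd.read_csv(directory / "manifest.csv")
        patches = np.stack(
            [np.asarray(Image.open(directory / f)) for f in manifest["file"]]
        ) if len(manifest) else np.empty((0, 64, 64, 3), np.uint8)
        return cls(
            patches,
            manifest["label"].to_numpy(str),
            manifest[["x", "y"]].to_numpy(int),
            manifest["slide_id"].to_numpy(str),
        )


def is_tissue(patch: np.ndarray, rule: TissueRule = TissueRule()) -> bool:
    """True iff the patch mean intensity over all pixels and channels is
    below the rule's threshold."""
    patch = np.asarray(patch)
    if patch.ndim != 3 or patch.shape[2] != 3:
        raise ValueError(f"expected an (S, S, 3) RGB patch, got shape {patch.shape}")
    return float(patch.mean()) < rule.mi_threshold


# label groupings for the two classifier tasks
_TASKS = {
    "tumour": {"positive": (2,), "negative": (1, 3), "names": ("tumour", "non-tumour")},
    "infiltrate": {
        "positive": (3,),
        "negative": (1, 2),
        "names": ("infiltrate", "non-infiltrate"),
    },
}


def extract_labelled_patches(
    slide,
    ann: AnnotationSet,
    grid: TileGrid = TileGrid(),
    purity: float = 0.9,
    rule: TissueRule = TissueRule(),
    task: str = "tumour",
) -> PatchSet:
    """Slide a window over the annotated slide and emit pure tissue patches.

    A tile becomes a patch with label L only when at least ``purity`` of
    its pixels fall in regions labelled L (classes grouped per ``task``)
    and the tissue rule holds. Tiles failing either test are skipped.
    """
    if not 0.5 < purity <= 1.0:
        raise ValueError("purity must be in (0.5, 1.0]")
    if task not in _TASKS:
        raise ValueError(f"task must be one of {sorted(_TASKS)}")
    image = slide.image if hasattr(slide, "image") else np.asarray(slide)
    h, w = image.shape[:2]
    if len(ann) == 0:
        warnings.warn("empty annotation set; returning an empty PatchSet")
        return PatchSet.empty(grid.patch_size)
    mask = rasterise(ann, 1, dims=(w, h))
    pos_vals = _TASKS[task]["positive"]
    neg_vals = _TASKS[task]["negative"]
    pos_name, neg_name = _TASKS[task]["names"]
    s = grid.patch_size
    min_px = purity * s * s
    patches, labels, positions = [], [], []
    for x, y in grid.origins(w, h):
        tile = image[y : y + s, x : x + s]
        if not is_tissue(tile, rule):
            continue
        window = mask[y : y + s, x : x + s]
        counts = np.bincount(window.ravel(), minlength=4)
        if counts[list(pos_vals)].sum() >= min_px:
            label = pos_name
        elif counts[list(neg_vals)].sum() >= min_px:
            label = neg_name
        else:
            continue
        patches.append(tile)
        labels.append(label)
        positions.append((x, y))
    if not patches:
        return PatchSet.empty(s)
    sid = getattr(slide, "slide_id", "slide")
    return PatchSet(
        np.stack(patches),
        np.asarray(labels),
        np.asarray(positions),
        np.asarray([sid] * len(patches)),
    )


AUGMENT_OPS = {
    "hflip": lambda p: p[:, :, ::-1, :],
    "vflip": lambda p: p[:, ::-1, :, :],
    "rot90": lambda p: np.rot90(p, 1, axes=(1, 2)),
    "rot180": lambda p: np.rot90(p, 2, axes=(1, 2)),
    "rot270": lambda p: np.rot90(p, 3, axes=(1, 2)),
}


def augment(patchset: PatchSet, ops: list[str], seed: int | None = None) -> PatchSet:
    """Append dihedral transforms of every patch; output size is
    ``len(patchset) * (1 + len(ops))``. Labels and provenance are copied.
    The transforms are deterministic; ``seed`` is accepted for interface
    symmetry with the stochastic stages."""
    unknown = [op for op in ops if op not in AUGMENT_OPS]
    if unknown:
        raise ValueError(
            f"unknown augmentation ops {unknown}; choose from {sorted(AUGMENT_OPS)}"
        )
    out = [patchset]
    for op in ops:
        out.append(
            PatchSet(
                np.ascontiguousarray(AUGMENT_OPS[op](patchset.patches)),
                patchset.labels.copy(),
                patchset.positions.copy(),
                patchset.slide_ids.copy(),
            )
        )
    return PatchSet.concatenate(out)


def append_false_regions(
    train: PatchSet,
    false_positives: PatchSet | None = None,
    false_negatives: PatchSet | None = None,
) -> PatchSet:
    """Retraining-loop bookkeeping: append pathologist-flagged false
    regions to the training set. False-positive patches re-enter labelled
    ``non-tumour``, false negatives labelled ``tumour``. Duplicate
    positions are allowed (the same tile may legitimately recur)."""
    parts = [train]
    for ps, label in ((false_positives, "non-tumour"), (false_negatives, "tumour")):
        if ps is None or len(ps) == 0:
            continue
        relabelled = PatchSet(
            ps.patches,
            np.asarray([label] * len(ps)),
            ps.positions,
            ps.slide_ids,
        )
        parts.append(relabelled)
    return PatchSet.concatenate(parts)
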