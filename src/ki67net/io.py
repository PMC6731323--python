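"""Small I/O helpers for slides, masks and probability maps."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

from .inference import ProbabilityMap
from .synthetic import PseudoSlide


def save_slide(slide: PseudoSlide, path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(
            path,
            slide.image,
            resolution=(1e4 / slide.microns_per_px, 1e4 / slide.microns_per_px),
        )
    else:
        Image.fromarray(slide.image).save(path)


def load_slide(path, microns_per_px: float = 0.5) -> PseudoSlide:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        image = tifffile.imread(path)
    else:
        image = np.asarray(Image.open(path).convert("RGB"))
    return PseudoSlide(image, microns_per_px=microns_per_px, slide_id=path.stem)


def save_mask(mask: np.ndarray, path) -> None:
    """Single-channel PNG; boolean masks become 0/255, label masks are
    stored verbatim."""
    arr = np.asarray(mask)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8) * 255
    Image.fromarray(arr.astype(np.uint8), mode="L").save(path)


def load_mask(path, binary: bool = False) -> np.ndarray:
    arr = np.asarray(Image.open(path))
    return arr > 0 if binary else arr


def save_probability_map(pmap: ProbabilityMap, path) -> None:
    """Floating TIFF plus a JSON geometry sidecar."""
    path = Path(path)
    tifffile.imwrite(path, pmap.probs.astype(np.float32))
    sidecar = {
        "stride_px": pmap.stride_px,
        "patch_size": pmap.patch_size,
        "slide_id": pmap.slide_id,
        "coverage": pmap.coverage.tolist(),
        "excluded": pmap.excluded.tolist() if pmap.excluded is not None else None,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def load_probability_map(path) -> ProbabilityMap:
    path = Path(path)
    probs = tifffile.imread(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    excluded = meta.get("excluded")
    return ProbabilityMap(
        probs=np.asarray(probs, np.float32),
        coverage=np.asarray(meta["coverage"], np.int32),
        stride_px=int(meta["stride_px"]),
        patch_size=int(meta["patch_size"]),
        slide_id=meta.get("slide_id", "slide"),
        excluded=None if excluded is None else np.asarray(excluded, bool),
    )
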