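"""Ki67 proliferation hotspot identification inside the tumour mask.

Pipeline: Ruifrok-Johnston H-DAB colour deconvolution of the RGB slide and
thresholding of the DAB optical density gives a binary mask of
Ki67-positive (DAB-brown) nuclei, restricted to the tumour mask; connected
components yield nucleus centroids; Chiu-style subtractive clustering over
the centroids proposes candidate centres; a 100-px-diameter circle is drawn
at each centre and its Ki67 ratio (DAB area over circle area) computed; a
circle whose ratio exceeds 20% is called a hotspot.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.color import rgb2hed
from skimage.draw import disk as _disk
from skimage.morphology import disk as _disk_selem, opening as _opening, remove_small_objects
from sklearn.base import BaseEstimator, ClusterMixin

__all__ = [
    "extract_dab",
    "centroids",
    "subtractive_cluster",
    "SubtractiveClustering",
    "score_circles",
    "band_proliferation",
    "render_hotspot_overlay",
    "HotspotReport",
]


def extract_dab(
    image: np.ndarray,
    tumour_mask: np.ndarray,
    od_threshold: float = 0.15,
    min_area_px: int = 20,
    morph_radius: int = 1,
) -> np.ndarray:
    """Binary mask of DAB-positive nuclei inside the tumour mask.

    The DAB channel of the H-DAB colour deconvolution is thresholded at
    ``od_threshold`` optical density, cleaned with a morphological opening
    (disc radius ``morph_radius``) and small-component removal
    (< ``min_area_px``), and intersected with ``tumour_mask``.
    """
    image = np.asarray(image)
    tumour_mask = np.asarray(tumour_mask, bool)
    if image.shape[:2] != tumour_mask.shape:
        raise ValueError(
            f"image {image.shape[:2]} and tumour mask {tumour_mask.shape} misaligned"
        )
    if not tumour_mask.any():
        warnings.warn("empty tumour mask; returning an empty DAB mask")
        return np.zeros_like(tumour_mask)
    dab_od = rgb2hed(image)[:, :, 2]
    mask = dab_od > od_threshold
    if morph_radius > 0:
        mask = _opening(mask, _disk_selem(morph_radius))
    if min_area_px > 1:
        # drop components strictly smaller than min_area_px
        mask = remove_small_objects(mask, max_size=min_area_px - 1)
    return mask & tumour_mask


def centroids(mask: np.ndarray) -> np.ndarray:
    """(x, y) pixel-mean centroid of every 8-connected component."""
    mask = np.asarray(mask, bool)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), int))
    if n == 0:
        return np.empty((0, 2))
    cy_cx = ndimage.center_of_mass(mask, labels, np.arange(1, n + 1))
    arr = np.asarray(cy_cx)
    return arr[:, ::-1]  # (row, col) -> (x, y)


def _potentials(points: np.ndarray, alpha: float, chunk: int = 512) -> np.ndarray:
    n = len(points)
    pot = np.empty(n)
    for i in range(0, n, chunk):
        d2 = ((points[i : i + chunk, None, :] - points[None, :, :]) ** 2).sum(-1)
        pot[i : i + chunk] = np.exp(-alpha * d2).sum(1)
    return pot


def subtractive_cluster(
    points: np.ndarray,
    ra: float = 200.0,
    rb: float | None = None,
    accept_ratio: float = 0.5,
    reject_ratio: float = 0.15,
    max_centres: int = 200,
) -> np.ndarray:
    """Chiu's subtractive clustering over 2-D points.

    Each point starts with potential ``P_i = sum_j exp(-4 |x_i-x_j|^2 / ra^2)``.
    The highest-potential point becomes a centre; potentials are then
    reduced by ``P_c * exp(-4 |x_i-x_c|^2 / rb^2)`` and the process
    repeats. A candidate with ``P > accept_ratio * P_1`` is accepted
    outright, one with ``P < reject_ratio * P_1`` stops the search, and the
    grey zone is resolved by Chiu's distance criterion
    ``d_min/ra + P/P_1 >= 1``.
    """
    points = np.asarray(points, float)
    if points.ndim != 2 or (len(points) and points.shape[1] != 2):
        raise ValueError("points must be an (n, 2) array")
    if len(points) == 0:
        return np.empty((0, 2))
    if len(points) == 1:
        return points.copy()
    if ra <= 0:
        raise ValueError("ra must be positive")
    rb = 1.5 * ra if rb is None else rb
    if rb <= ra:
        raise ValueError("rb must exceed ra")
    if not 0.0 < reject_ratio < accept_ratio < 1.0:
        raise ValueError("need 0 < reject_ratio < accept_ratio < 1")

    pot = _potentials(points, 4.0 / ra**2)
    first = None
    centres = []
    while len(centres) < max_centres:
        c = int(np.argmax(pot))
        p_c = pot[c]
        if first is None:
            first = p_c
            accept = True
        elif p_c > accept_ratio * first:
            accept = True
        elif p_c < reject_ratio * first:
            break
        else:
            d_min = np.sqrt(
                min(((points[c] - cc) ** 2).sum() for cc in centres)
            )
            if d_min / ra + p_c / first >= 1.0:
                accept = True
            else:
                pot[c] = 0.0
                continue
        if accept:
            centres.append(points[c].copy())
            d2 = ((points - points[c]) ** 2).sum(1)
            pot = pot - p_c * np.exp(-4.0 * d2 / rb**2)
            np.maximum(pot, 0.0, out=pot)
            if not pot.any():
                break
    return np.asarray(centres)


class SubtractiveClustering(BaseEstimator, ClusterMixin):
    """Scikit-learn wrapper around :func:`subtractive_cluster`.

    Fitted attributes: ``cluster_centers_`` (the selected points) and
    ``labels_`` (nearest-centre assignment of every input point).
    """

    def __init__(self, ra=200.0, rb=None, accept_ratio=0.5, reject_ratio=0.15,
                 max_centres=200):
        self.ra = ra
        self.rb = rb
        self.accept_ratio = accept_ratio
        self.reject_ratio = reject_ratio
        self.max_centres = max_centres

    def fit(self, X, y=None):
        X = np.asarray(X, float)
        self.cluster_centers_ = subtractive_cluster(
            X, self.ra, self.rb, self.accept_ratio, self.reject_ratio,
            self.max_centres,
        )
        if len(self.cluster_centers_):
            d2 = ((X[:, None, :] - self.cluster_centers_[None]) ** 2).sum(-1)
            self.labels_ = d2.argmin(1)
        else:
            self.labels_ = np.full(len(X), -1)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


@dataclass
class HotspotReport:
    centroids: np.ndarray  # (n, 2) DAB nucleus centroids (x, y)
    cluster_centres: np.ndarray  # (m, 2)
    circles: pd.DataFrame  # cx, cy, diameter_px, ki67_ratio, is_hotspot [, band]
    hotspot_threshold: float = 0.20

    def hotspots(self) -> pd.DataFrame:
        return self.circles[self.circles.is_hotspot]

    def to_json(self) -> str:
        import json

        return json.dumps(
            {
                "hotspot_threshold": self.hotspot_threshold,
                "n_centroids": len(self.centroids),
                "cluster_centres": self.cluster_centres.tolist(),
                "circles": self.circles.to_dict(orient="records"),
            },
            indent=2,
        )


def score_circles(
    dab_mask: np.ndarray,
    centres: np.ndarray,
    diameter_px: float = 100.0,
    threshold: float = 0.20,
    all_centroids: np.ndarray | None = None,
) -> HotspotReport:
    """Ki67 ratio (DAB area / circle area) of the disc around each centre.

    Circles clipped by the image border use the clipped pixel count as the
    denominator. A circle is a hotspot when its ratio exceeds ``threshold``.
    """
    if diameter_px <= 0:
        raise ValueError("diameter must be positive")
    dab_mask = np.asarray(dab_mask, bool)
    h, w = dab_mask.shape
    centres = np.asarray(centres, float).reshape(-1, 2)
    rows = []
    for cx, cy in centres:
        if not (0 <= cx < w and 0 <= cy < h):
            raise ValueError(f"circle centre ({cx}, {cy}) outside the {w}x{h} image")
        rr, cc = _disk((cy, cx), diameter_px / 2.0, shape=(h, w))
        ratio = float(dab_mask[rr, cc].mean()) if len(rr) else 0.0
        rows.append(
            {
                "cx": cx,
                "cy": cy,
                "diameter_px": diameter_px,
                "ki67_ratio": ratio,
                "is_hotspot": ratio > threshold,
            }
        )
    circles = pd.DataFrame(
        rows, columns=["cx", "cy", "diameter_px", "ki67_ratio", "is_hotspot"]
    )
    return HotspotReport(
        centroids=all_centroids if all_centroids is not None else centres,
        cluster_centres=centres,
        circles=circles,
        hotspot_threshold=threshold,
    )


def render_hotspot_overlay(slide, report: HotspotReport) -> np.ndarray:
    """Annotated RGB image: DAB nucleus centroids as blue dots, cluster
    circles outlined (red for hotspots, grey otherwise)."""
    from skimage.draw import circle_perimeter, disk as _fill

    image = slide.image if hasattr(slide, "image") else np.asarray(slide)
    canvas = image.copy()
    h, w = canvas.shape[:2]
    for x, y in np.asarray(report.centroids).reshape(-1, 2):
        rr, cc = _fill((y, x), 3, shape=(h, w))
        canvas[rr, cc] = (40, 60, 230)
    for row in report.circles.itertuples():
        colour = (220, 30, 30) if row.is_hotspot else (120, 120, 120)
        radius = int(round(row.diameter_px / 2))
        for dr in (0, 1):  # 2-px stroke
            rr, cc = circle_perimeter(
                int(round(row.cy)), int(round(row.cx)), max(radius - dr, 1),
                shape=(h, w),
            )
            canvas[rr, cc] = colour
    return canvas


DEFAULT_BAND_NAMES = ("negligible", "low", "medium", "high")


def band_proliferation(
    report: HotspotReport,
    bands: tuple[float, ...],
    names: tuple[str, ...] | None = None,
) -> HotspotReport:
    """Assign each circle a proliferation band by its Ki67 ratio.

    ``bands`` are strictly increasing cut-offs (each <= 1); a ratio equal
    to a cut-off falls in the upper band. With n cut-offs there are n+1
    bands, named via ``names`` (defaults cover the 3-cut-off case).
    """
    bands = tuple(bands)
    if any(b1 >= b2 for b1, b2 in zip(bands, bands[1:])) or (
        bands and bands[-1] > 1.0
    ):
        raise ValueError("bands must be strictly increasing cut-offs ending <= 1")
    if names is None:
        if len(bands) + 1 == len(DEFAULT_BAND_NAMES):
            names = DEFAULT_BAND_NAMES
        else:
            names = tuple(f"band_{i}" for i in range(len(bands) + 1))
    if len(names) != len(bands) + 1:
        raise ValueError("need one name per band")
    idx = np.searchsorted(np.asarray(bands), report.circles["ki67_ratio"], side="right")
    circles = report.circles.copy()
    circles["band"] = np.asarray(names)[idx]
    return HotspotReport(
        report.centroids, report.cluster_centres, circles, report.hotspot_threshold
    )
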