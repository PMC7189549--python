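"""Heatmap-to-score conversion: threshold, clean, label blobs, normalize.

The quantitative score for one slide, pathology class and region is

    cnn_score = blob_count / region_area_px

where blobs are the connected components of the thresholded,
morphologically cleaned confidence heatmap, and the area is the number of
heatmap-resolution pixels in the scored region (whole tissue or gray
matter).  When scoring a sub-region, its binary mask is applied to the
heatmap *before* thresholding and blob detection, so deposits outside the
region are removed entirely (and deposits straddling the boundary are
truncated, possibly split).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import ndimage

DEFAULT_THRESHOLDS = {"cored": 0.9, "diffuse": 0.9, "caa": 0.9}


@dataclass(frozen=True)
class MorphologyParams:
    """Threshold + binary clean-up parameters.

    ``thresholds`` maps class name to probability threshold; the structuring
    element is a cross ('cross') or square ('square') of odd ``element_size``;
    ``connectivity`` 4 or 8 controls blob labeling adjacency.
    """

    thresholds: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_THRESHOLDS)
    )
    element: str = "cross"
    element_size: int = 3
    opening_iterations: int = 1
    closing_iterations: int = 1
    connectivity: int = 8

    def __post_init__(self):
        for cls, t in self.thresholds.items():
            if not 0.0 <= t <= 1.0:
                raise ValueError(f"threshold for {cls!r} outside [0, 1]")
        if self.opening_iterations < 0 or self.closing_iterations < 0:
            raise ValueError("iterations must be >= 0")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.element not in ("cross", "square"):
            raise ValueError("element must be 'cross' or 'square'")
        if self.element_size < 1 or self.element_size % 2 == 0:
            raise ValueError("element_size must be odd and positive")

    def structuring_element(self) -> np.ndarray:
        s = self.element_size
        if self.element == "square":
            return np.ones((s, s), dtype=bool)
        el = np.zeros((s, s), dtype=bool)
        el[s // 2, :] = True
        el[:, s // 2] = True
        return el


@dataclass(frozen=True)
class RegionMask:
    """Binary region raster aligned to the heatmap grid."""

    mask: np.ndarray
    label: str = "whole_tissue"

    @property
    def area_px(self) -> int:
        return int(np.count_nonzero(self.mask))


@dataclass(frozen=True)
class ScoreResult:
    slide_id: str
    pathology: str
    region: str
    blob_count: int
    region_area_px: int
    cnn_score: float

    def __post_init__(self):
        if self.region_area_px <= 0:
            raise ValueError("region area must be positive")
        if self.blob_count < 0:
            raise ValueError("blob count must be non-negative")


def threshold_heatmap(channel, threshold: float) -> np.ndarray:
    """Binary raster: probability >= threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    return np.asarray(channel) >= threshold


def clean_binary(raster, params: MorphologyParams) -> np.ndarray:
    """Morphological opening then closing; zero iterations means identity."""
    out = np.asarray(raster, dtype=bool)
    el = params.structuring_element()
    if params.opening_iterations > 0:
        out = ndimage.binary_opening(out, structure=el, iterations=params.opening_iterations)
    if params.closing_iterations > 0:
        out = ndimage.binary_closing(out, structure=el, iterations=params.closing_iterations)
    return out


def _label_structure(connectivity: int) -> np.ndarray:
    if connectivity == 4:
        return ndimage.generate_binary_structure(2, 1)
    if connectivity == 8:
        return ndimage.generate_binary_structure(2, 2)
    raise ValueError("connectivity must be 4 or 8")


def label_blobs(raster, connectivity: int = 8):
    """Connected-component labeling.

    Returns ``(labels, count, centroids)``: an int raster with components
    numbered 1..count and a list of (row, col) float centroids in component
    order.
    """
    raster = np.asarray(raster, dtype=bool)
    labels, count = ndimage.label(raster, structure=_label_structure(connectivity))
    if count:
        rr, cc = np.nonzero(labels)
        lab = labels[rr, cc]
        npix = np.bincount(lab, minlength=count + 1)[1:]
        sum_r = np.bincount(lab, weights=rr, minlength=count + 1)[1:]
        sum_c = np.bincount(lab, weights=cc, minlength=count + 1)[1:]
        centroids = list(zip((sum_r / npix).tolist(), (sum_c / npix).tolist()))
    else:
        centroids = []
    return labels, int(count), centroids


def compute_score(
    heatmap,
    class_id: str,
    params: MorphologyParams,
    region: RegionMask,
    slide_id: str = "slide",
) -> ScoreResult:
    """Full scoring of one heatmap channel restricted to one region.

    The region mask is applied to the probability raster before
    thresholding, then opening/closing and blob labeling run; the score is
    blob count divided by region pixel area.
    """
    hm = np.asarray(heatmap)
    if hm.ndim == 3:
        from .synthetic import CLASS_NAMES

        hm = hm[..., CLASS_NAMES.index(class_id)]
    if region.mask.shape != hm.shape:
        raise ValueError("region mask not aligned to heatmap")
    area = region.area_px
    if area == 0:
        raise ValueError("empty region mask: score undefined")
    thr = params.thresholds.get(class_id)
    if thr is None:
        raise ValueError(f"no threshold configured for class {class_id!r}")
    masked = np.where(region.mask, hm, 0.0)
    binary = threshold_heatmap(masked, thr)
    # a threshold of exactly 0 marks every pixel; the region mask still rules
    binary &= region.mask.astype(bool)
    cleaned = clean_binary(binary, params)
    _, count, _ = label_blobs(cleaned, params.connectivity)
    return ScoreResult(
        slide_id=slide_id,
        pathology=class_id,
        region=region.label,
        blob_count=count,
        region_area_px=area,
        cnn_score=count / area,
    )


def percent_change(gm: ScoreResult, wt: ScoreResult) -> float:
    """Signed percent change of the gray-matter score vs the whole-tissue one.

    Returns NaN (missing) when the whole-tissue score is zero, for which
    relative change is undefined.
    """
    if gm.slide_id != wt.slide_id or gm.pathology != wt.pathology:
        raise ValueError("scores must refer to the same slide and class")
    if wt.cnn_score == 0:
        return float("nan")
    return 100.0 * (gm.cnn_score - wt.cnn_score) / wt.cnn_score
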