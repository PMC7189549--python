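"""Field-of-view (FOV) scoring and top-n convergence analysis.

Traditional CERAD practice rates the single densest microscope field
(roughly a 10x objective, ~4 mm^2).  This module emulates that: square
windows of fixed physical area slide across the confidence heatmap, each
window receives its own local density score, and the top-n non-overlapping
windows are compared against the whole-tissue score across a cohort.

Blobs are detected once on the whole heatmap and assigned to windows by
centroid membership, so a blob is never double-counted within a window and
blob counts over any non-overlapping tiling sum to the global count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .scoring import MorphologyParams, clean_binary, label_blobs, threshold_heatmap


@dataclass(frozen=True)
class FOVConfig:
    """Geometry of the field-of-view grid.

    ``window_size_px`` and ``window_stride_px`` are in heatmap pixels;
    ``wsi_stride`` is the number of slide pixels per heatmap pixel and
    ``mpp`` the microns per slide pixel, so one window spans
    ``window_size_px * wsi_stride * mpp`` microns per side.  With the
    defaults (251, 16, 0.5) that is 2008 um, i.e. ~4 mm^2 per window.
    """

    window_size_px: int = 251
    window_stride_px: int = 16
    mpp: float = 0.5
    wsi_stride: int = 16

    def __post_init__(self):
        if self.window_size_px < 1 or self.window_stride_px < 1:
            raise ValueError("window size and stride must be positive")

    @property
    def window_area_mm2(self) -> float:
        side_mm = self.window_size_px * self.wsi_stride * self.mpp * 1e-3
        return side_mm**2


@dataclass(frozen=True)
class FOVWindow:
    row: int
    col: int
    window_size: int
    blob_count: int
    tissue_area_px: int
    fov_score: float


def compute_fov_scores(
    heatmap,
    class_id: str,
    params: MorphologyParams,
    tissue_mask,
    config: FOVConfig | None = None,
):
    """Score every grid window that contains at least one blob centroid.

    Blobs come from a single global threshold -> clean -> label pass; a blob
    belongs to a window iff its centroid lies inside the window's half-open
    pixel extent.  ``tissue_area_px`` counts tissue-mask pixels inside the
    window.  Windows not fully inside the heatmap are skipped so every
    window has the same physical area.
    """
    config = config or FOVConfig()
    hm = np.asarray(heatmap)
    if hm.ndim == 3:
        from .synthetic import CLASS_NAMES

        hm = hm[..., CLASS_NAMES.index(class_id)]
    h, w = hm.shape
    size, stride = config.window_size_px, config.window_stride_px
    if size > h or size > w:
        raise ValueError("window larger than heatmap")

    thr = params.thresholds[class_id]
    binary = threshold_heatmap(hm, thr) & np.asarray(tissue_mask, dtype=bool)
    cleaned = clean_binary(binary, params)
    _, count, centroids = label_blobs(cleaned, params.connectivity)

    # rasterize centroids and build integral images for O(1) window sums
    cent = np.zeros((h, w), dtype=np.int64)
    for r, c in centroids:
        cent[int(np.floor(r)), int(np.floor(c))] += 1

    def integral(a):
        ii = np.zeros((h + 1, w + 1), dtype=np.int64)
        ii[1:, 1:] = np.cumsum(np.cumsum(a, 0), 1)
        return ii

    ii_cent = integral(cent)
    ii_tis = integral(np.asarray(tissue_mask, dtype=np.int64))

    rows = np.arange(0, h - size + 1, stride)
    cols = np.arange(0, w - size + 1, stride)

    def window_sums(ii):
        return (
            ii[np.ix_(rows + size, cols + size)]
            - ii[np.ix_(rows + size, cols)]
            - ii[np.ix_(rows, cols + size)]
            + ii[np.ix_(rows, cols)]
        )

    counts = window_sums(ii_cent)
    areas = window_sums(ii_tis)

    windows = []
    for i, r in enumerate(rows):
        for j, c in enumerate(cols):
            n_blobs = int(counts[i, j])
            if n_blobs < 1:
                continue
            area = int(areas[i, j])
            score = n_blobs / area if area > 0 else 0.0
            windows.append(
                FOVWindow(
                    row=int(r),
                    col=int(c),
                    window_size=size,
                    blob_count=n_blobs,
                    tissue_area_px=area,
                    fov_score=score,
                )
            )
    return windows


def _overlaps(a: FOVWindow, b: FOVWindow) -> bool:
    return (
        a.row < b.row + b.window_size
        and b.row < a.row + a.window_size
        and a.col < b.col + b.window_size
        and b.col < a.col + a.window_size
    )


def select_top_n_nonoverlapping(windows, n: int):
    """Greedy pick of up to ``n`` non-overlapping windows by descending score.

    Ties are broken by row-major origin order.  May return fewer than ``n``
    when no further disjoint window exists.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ranked = sorted(windows, key=lambda fw: (-fw.fov_score, fw.row, fw.col))
    selected: list = []
    for fw in ranked:
        if len(selected) == n:
            break
        if all(not _overlaps(fw, s) for s in selected):
            selected.append(fw)
    return selected


def mean_top_n_score(windows, n: int) -> float:
    """Mean fov_score over the top-n non-overlapping windows (0 if none)."""
    selected = select_top_n_nonoverlapping(windows, n)
    if not selected:
        return 0.0
    return float(np.mean([fw.fov_score for fw in selected]))


DEFAULT_N_VALUES = (1, 3, 5, 7, 9, 11, 13, 15)


def convergence_table(
    per_slide_windows,
    ordinal_labels,
    whole_tissue_scores,
    n_values=DEFAULT_N_VALUES,
):
    """Rank correlation of mean-top-n FOV scores with ordinal severity.

    ``per_slide_windows``: list (one entry per slide) of FOVWindow lists;
    ``ordinal_labels``: integer-coded severity per slide;
    ``whole_tissue_scores``: the whole-region score per slide.

    Returns a one-row-per-n DataFrame with columns ``n`` and ``spearman``,
    plus rows ``n = 'WT'`` for the whole-tissue correlation and
    ``n = 'max_vs_WT'`` for the correlation between the single highest FOV
    score and the whole-tissue score.  Correlations against constant labels
    are reported as NaN.
    """
    if not n_values:
        raise ValueError("n_values must be non-empty")
    labels = np.asarray(ordinal_labels, dtype=float)
    wt = np.asarray(whole_tissue_scores, dtype=float)
    if len(per_slide_windows) != len(labels) or len(labels) != len(wt):
        raise ValueError("per-slide inputs must have equal length")
    if len(labels) < 3:
        raise ValueError("need at least 3 slides")

    def safe_spearman(x, y):
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return float("nan")
        return float(sps.spearmanr(x, y).statistic)

    rows = []
    top_scores = {}
    for n in n_values:
        s = np.array([mean_top_n_score(ws, n) for ws in per_slide_windows])
        top_scores[n] = s
        rows.append({"n": n, "spearman": safe_spearman(s, labels)})
    rows.append({"n": "WT", "spearman": safe_spearman(wt, labels)})
    max_fov = np.array([mean_top_n_score(ws, 1) for ws in per_slide_windows])
    rows.append({"n": "max_vs_WT", "spearman": safe_spearman(max_fov, wt)})
    return pd.DataFrame(rows)
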