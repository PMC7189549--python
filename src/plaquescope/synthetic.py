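"""Synthetic slide, heatmap, tile and cohort generation with known ground truth.

Real amyloid-beta whole-slide images (4G8 immunohistochemistry, DAB chromogen,
hematoxylin counterstain) are gigapixel scans with manually assigned ordinal
pathology scores.  This module fabricates slide-like data in which every
quantity the scoring pipeline estimates -- deposit counts, tissue and
gray-matter geometry, ordinal severity levels -- is planted and therefore
known exactly.  Two generation routes exist:

* ``generate_heatmap`` plants supra-threshold blobs directly on a raster at
  heatmap resolution, bypassing any classifier.  This is the route used to
  test the scoring, field-of-view and statistics stages in isolation.
* ``generate_slide_image`` renders an RGB image (pale background, bluish
  tissue, brown deposits) for testing color normalization, tissue
  segmentation and the classifier loop.

Identical spec + seed always reproduces bit-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

CLASS_NAMES = ("cored", "diffuse", "caa")

#: default ordinal severity vocabulary, least to most severe
ORDINAL_LEVELS = ("none", "sparse", "moderate", "frequent")


@dataclass(frozen=True)
class StainParams:
    """Mean/std RGB (0-255) for the three rendered compartments."""

    background_mean: tuple = (244.0, 242.0, 244.0)
    background_std: float = 2.0
    tissue_mean: tuple = (185.0, 178.0, 212.0)   # hematoxylin-dominated
    tissue_std: float = 4.0
    deposit_mean: tuple = (135.0, 92.0, 48.0)    # DAB brown
    deposit_std: float = 5.0


@dataclass(frozen=True)
class SyntheticSlideSpec:
    """Parameters of one synthetic slide.

    ``class_densities`` is expressed as expected deposits per mm^2 of gray
    matter; ``white_matter_leak`` is the fraction of deposits placed in
    tissue outside the gray matter.  ``heatmap_stride`` is the number of
    slide pixels per heatmap pixel (the sliding-window stride), and
    ``window`` the classifier window size, so the heatmap raster derived
    from this slide has ``floor((H - window)/stride) + 1`` rows.
    """

    width_px: int = 4096
    height_px: int = 4096
    mpp: float = 0.5
    class_densities: Mapping[str, float] = field(
        default_factory=lambda: {"cored": 12.0, "diffuse": 8.0, "caa": 4.0}
    )
    gm_fraction: float = 0.6
    white_matter_leak: float = 0.0
    stain_params: StainParams = field(default_factory=StainParams)
    seed: int = 0
    heatmap_stride: int = 16
    window: int = 256
    min_gap_px: int = 6  # 2x the default 3-px morphology element, heatmap px
    background_level: float = 0.05  # sub-threshold murmur inside tissue
    #: spatial clustering of deposits: 0 = uniform; > 0 concentrates deposits
    #: around a random per-slide hotspot with Gaussian weight of this sigma,
    #: expressed as a fraction of the gray-matter linear size
    cluster_sigma_frac: float = 0.0

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("slide dimensions must be positive")
        if not 0.0 <= self.gm_fraction <= 1.0:
            raise ValueError("gm_fraction must be in [0, 1]")
        if not 0.0 <= self.white_matter_leak <= 1.0:
            raise ValueError("white_matter_leak must be in [0, 1]")
        for cls, d in self.class_densities.items():
            if d < 0:
                raise ValueError(f"negative density for class {cls!r}")

    @property
    def heatmap_shape(self) -> tuple:
        h = (self.height_px - self.window) // self.heatmap_stride + 1
        w = (self.width_px - self.window) // self.heatmap_stride + 1
        if h <= 0 or w <= 0:
            raise ValueError("slide smaller than one classifier window")
        return h, w

    @property
    def heatmap_px_area_mm2(self) -> float:
        """Physical area of one heatmap pixel in mm^2."""
        side_um = self.heatmap_stride * self.mpp
        return (side_um * 1e-3) ** 2


@dataclass
class SyntheticGroundTruth:
    """Planted truth for one synthetic slide (at ``resolution`` raster)."""

    resolution: str  # "heatmap" or "slide"
    tissue_mask: np.ndarray
    gm_mask: np.ndarray
    deposit_masks: dict          # class -> bool raster
    counts_tissue: dict          # class -> int, whole-tissue deposit count
    counts_gm: dict              # class -> int, gray-matter-only count
    centroids: dict              # class -> list of (row, col)

    def validate(self) -> None:
        if (self.gm_mask & ~self.tissue_mask).any():
            raise AssertionError("gm_mask not a subset of tissue_mask")
        for cls, m in self.deposit_masks.items():
            if (m & ~self.tissue_mask).any():
                raise AssertionError(f"{cls} deposits outside tissue")
            if self.counts_gm[cls] > self.counts_tissue[cls]:
                raise AssertionError(f"{cls}: gm count exceeds tissue count")


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """A cohort whose planted densities are monotone in an ordinal level."""

    n_slides: int = 40
    ordinal_levels: Sequence[str] = ORDINAL_LEVELS
    density_by_level: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            # deposits per mm^2 of gray matter, CERAD-flavored progression
            "cored": {"none": 0.0, "sparse": 4.0, "moderate": 12.0, "frequent": 25.0},
            "diffuse": {"none": 0.0, "sparse": 3.0, "moderate": 9.0, "frequent": 18.0},
            "caa": {"none": 0.0, "sparse": 2.0, "moderate": 5.0, "frequent": 10.0},
        }
    )
    noise_sd: float = 0.0
    group_assignments: Mapping[str, Mapping] | None = None
    seed: int = 0
    slide_kwargs: Mapping = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.ordinal_levels:
            raise ValueError("ordinal_levels must be non-empty")
        if self.n_slides < len(self.ordinal_levels):
            raise ValueError("need at least one slide per ordinal level")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for cls, dmap in self.density_by_level.items():
            vals = [dmap[lv] for lv in self.ordinal_levels]
            if any(b <= a for a, b in zip(vals, vals[1:])):
                raise ValueError(
                    f"density_by_level[{cls!r}] must be strictly increasing"
                )


# ---------------------------------------------------------------------------
# geometry helpers


def _tissue_and_gm_masks(shape, gm_fraction, margin):
    """Tissue = inset rectangle; gray matter = its left band.

    The gray-matter boundary is vertical, so deposits kept ``margin`` pixels
    away from it can never straddle the boundary -- the guarantee behind the
    partition-conservation property (whole-tissue count = gm + complement).
    """
    h, w = shape
    border = max(1, min(h, w) // 16)
    tissue = np.zeros(shape, dtype=bool)
    tissue[border : h - border, border : w - border] = True
    gm = np.zeros(shape, dtype=bool)
    if gm_fraction > 0:
        tw = w - 2 * border
        gw = int(round(tw * gm_fraction))
        gm[border : h - border, border : border + gw] = True
    return tissue, gm


def _stabilize(stamp):
    """Make a stamp invariant under the default 3x3-cross opening.

    Opening is idempotent, so pre-opening the stamp (and keeping its largest
    connected component) guarantees the scoring stage's default clean-up
    neither erases nor splits a planted deposit.
    """
    from scipy.ndimage import binary_opening, generate_binary_structure, label

    cross = generate_binary_structure(2, 1)
    opened = binary_opening(stamp, structure=cross)
    labels, n = label(opened, structure=generate_binary_structure(2, 2))
    if n == 0:
        # degenerate; fall back to a 5x5 disc, which survives the opening
        yy, xx = np.mgrid[-2:3, -2:3]
        return yy * yy + xx * xx <= 4
    if n > 1:
        sizes = np.bincount(labels.ravel())[1:]
        opened = labels == (int(np.argmax(sizes)) + 1)
    return opened


_STAMP_POOL: dict = {}
_STAMP_POOL_SIZE = 64


def _deposit_footprint(cls, rng):
    """Small boolean stamp for one deposit of the given morphology.

    Stamps are drawn from a fixed per-class pool of pre-stabilized variants
    (the pool is built once with its own fixed seed, so generation stays
    deterministic and the per-deposit morphology cost is amortized).
    """
    pool = _STAMP_POOL.get(cls)
    if pool is None:
        pool_rng = np.random.default_rng(
            np.random.SeedSequence([424242, CLASS_NAMES.index(cls)])
        )
        pool = [_make_footprint(cls, pool_rng) for _ in range(_STAMP_POOL_SIZE)]
        _STAMP_POOL[cls] = pool
    return pool[int(rng.integers(len(pool)))]


def _make_footprint(cls, rng):
    """One fresh stamp: cored = dense disc; diffuse = irregular blob (union
    of jittered discs); caa = ring.  Only cross-class separability matters,
    not realism.  Every stamp is stabilized so the default morphological
    clean-up preserves it as exactly one connected component."""
    if cls == "cored":
        r = int(rng.integers(2, 4))
        size = 2 * r + 1
        yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
        return _stabilize(yy * yy + xx * xx <= r * r)
    if cls == "diffuse":
        r = int(rng.integers(3, 5))
        size = 2 * r + 3
        stamp = np.zeros((size, size), dtype=bool)
        c = size // 2
        yy, xx = np.mgrid[0:size, 0:size]
        for _ in range(3):
            dy, dx = rng.integers(-2, 3, size=2)
            rr = int(rng.integers(2, r + 1))
            stamp |= (yy - c - dy) ** 2 + (xx - c - dx) ** 2 <= rr * rr
        return _stabilize(stamp)
    if cls == "caa":
        r = int(rng.integers(3, 5))
        yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
        d2 = yy * yy + xx * xx
        return _stabilize((d2 <= r * r) & (d2 >= (r - 2) ** 2))
    raise ValueError(f"unknown class {cls!r}")


#: half-extent (px) of the largest stamp per class
_CLASS_EXTENT = {"cored": 3, "diffuse": 6, "caa": 4}


def _place_centers(rng, region_mask, n, separation, margin, weight_fn=None):
    """Rejection-sample ``n`` centers inside region_mask.

    Centers are pairwise > ``separation`` apart (Chebyshev) and at least
    ``margin`` pixels from the region boundary, so footprints neither merge
    with each other nor straddle the boundary.  ``weight_fn`` optionally
    biases site selection (e.g. toward a hotspot) given an (n, 2) array of
    candidate (row, col) positions.
    """
    if n == 0:
        return []
    from scipy.ndimage import minimum_filter

    # square-window minimum = erosion with a Chebyshev ball, matching the
    # Chebyshev separation metric below
    interior = (
        minimum_filter(region_mask, size=2 * margin + 1) if margin else region_mask
    )
    if not interior.any():
        raise ValueError("region too small for requested deposits at minimum gap")
    # sample on a random-offset lattice of pitch separation+1: any two lattice
    # sites are > separation apart (Chebyshev), so placement cannot deadlock
    cell = separation + 1

    def pick(cand):
        if weight_fn is None:
            idx = rng.permutation(len(cand))[:n]
        else:
            w = weight_fn(np.asarray(cand, dtype=float))
            p = np.maximum(w, 1e-12)
            idx = rng.choice(len(cand), size=n, replace=False, p=p / p.sum())
        return [cand[int(i)] for i in idx]

    for _ in range(8):
        off_r = int(rng.integers(cell))
        off_c = int(rng.integers(cell))
        lr, lc = np.nonzero(interior[off_r::cell, off_c::cell])
        cand = list(zip((lr * cell + off_r).tolist(), (lc * cell + off_c).tolist()))
        if len(cand) >= n:
            return pick(cand)
    # densest alignment as a last resort
    lr, lc = np.nonzero(interior[::cell, ::cell])
    cand = list(zip((lr * cell).tolist(), (lc * cell).tolist()))
    if len(cand) < n:
        raise ValueError(
            f"{n} deposits cannot fit in the region at separation {separation}"
        )
    return pick(cand)


def _stamp_at(mask, stamp, center):
    """OR a stamp into mask centered at (row, col), clipped to bounds."""
    h, w = mask.shape
    sh, sw = stamp.shape
    r0 = center[0] - sh // 2
    c0 = center[1] - sw // 2
    rs, cs = max(r0, 0), max(c0, 0)
    re, ce = min(r0 + sh, h), min(c0 + sw, w)
    mask[rs:re, cs:ce] |= stamp[rs - r0 : re - r0, cs - c0 : ce - c0]


def _expected_count(density_per_mm2, area_px, px_area_mm2):
    return int(round(density_per_mm2 * area_px * px_area_mm2))


def _plant_class(rng, spec, cls, shape, tissue, gm, px_area_mm2):
    """Plant one class's deposits; returns (mask, centroids, n_gm, n_total)."""
    density = float(spec.class_densities.get(cls, 0.0))
    gm_area = int(gm.sum())
    n_total = _expected_count(density, gm_area, px_area_mm2)
    n_leak = int(round(n_total * spec.white_matter_leak))
    n_gm = n_total - n_leak

    extent = _CLASS_EXTENT[cls]
    separation = 2 * extent + spec.min_gap_px
    margin = extent + spec.min_gap_px
    mask = np.zeros(shape, dtype=bool)
    centroids = []
    wm = tissue & ~gm

    weight_fn = None
    if spec.cluster_sigma_frac > 0 and gm.any():
        # deposits aggregate in several random patches (as plaques do);
        # per-patch counts are then multinomially noisy, so the densest
        # single field is a noisier severity readout than larger averages
        rows, cols = np.nonzero(gm)
        k = int(rng.integers(3, 9))
        idx = rng.integers(rows.size, size=k)
        hotspots = np.stack([rows[idx], cols[idx]], axis=1).astype(float)
        sigma = spec.cluster_sigma_frac * float(np.sqrt(gm.sum()))

        def weight_fn(cand, _h=hotspots, _s=sigma):
            d2 = ((cand[:, None, :] - _h[None, :, :]) ** 2).sum(axis=2)
            return np.exp(-d2 / (2.0 * _s * _s)).sum(axis=1)

    for region, count in ((gm, n_gm), (wm, n_leak)):
        if count == 0:
            continue
        for center in _place_centers(rng, region, count, separation, margin, weight_fn):
            stamp = _deposit_footprint(cls, rng)
            _stamp_at(mask, stamp, center)
            centroids.append(center)
    return mask, centroids, n_gm, n_gm + n_leak


def generate_heatmap(spec: SyntheticSlideSpec, class_id: str):
    """Plant a confidence heatmap for one pathology class.

    Returns ``(heatmap, ground_truth)`` where ``heatmap`` is a float raster
    in [0, 1] at heatmap resolution whose supra-threshold (>= 0.9) connected
    components are exactly the planted deposits, and ``ground_truth`` holds
    the tissue/gray-matter masks, deposit mask, centroids and counts.
    """
    if class_id not in CLASS_NAMES:
        raise ValueError(f"unknown class {class_id!r}")
    shape = spec.heatmap_shape
    rng = np.random.default_rng(
        np.random.SeedSequence([spec.seed, CLASS_NAMES.index(class_id)])
    )
    # heatmap pixel covers stride x stride slide px
    px_area_mm2 = spec.heatmap_px_area_mm2
    tissue, gm = _tissue_and_gm_masks(shape, spec.gm_fraction, spec.min_gap_px)
    mask, centroids, n_gm, n_total = _plant_class(
        rng, spec, class_id, shape, tissue, gm, px_area_mm2
    )

    heatmap = np.zeros(shape, dtype=np.float32)
    # sub-threshold background murmur inside tissue; planted blobs >= 0.92
    if spec.background_level > 0:
        heatmap[tissue] = rng.uniform(
            0.0, spec.background_level, size=int(tissue.sum())
        ).astype(np.float32)
    heatmap[mask] = rng.uniform(0.92, 0.99, size=int(mask.sum())).astype(np.float32)

    gt = SyntheticGroundTruth(
        resolution="heatmap",
        tissue_mask=tissue,
        gm_mask=gm,
        deposit_masks={class_id: mask},
        counts_tissue={class_id: n_total},
        counts_gm={class_id: n_gm},
        centroids={class_id: centroids},
    )
    gt.validate()
    return heatmap, gt


def generate_slide_image(spec: SyntheticSlideSpec):
    """Render an RGB slide image (uint8, H x W x 3) plus aligned ground truth.

    Background is near-white, tissue is hematoxylin-bluish, deposits are DAB
    brown.  Deposit footprints are scaled up relative to the heatmap route
    (slide resolution is ``heatmap_stride`` times finer).
    """
    shape = (spec.height_px, spec.width_px)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 97]))
    px_area_mm2 = (spec.mpp * 1e-3) ** 2
    # gap scales with resolution so slide-level blobs stay separated too
    gap = spec.min_gap_px * spec.heatmap_stride // 2
    tissue, gm = _tissue_and_gm_masks(shape, spec.gm_fraction, gap)

    sp = spec.stain_params
    img = np.empty(shape + (3,), dtype=np.float32)
    for ch in range(3):
        img[..., ch] = sp.background_mean[ch]
    img += rng.normal(0.0, sp.background_std, size=shape)[..., None]
    n_tissue = int(tissue.sum())
    img[tissue] = np.array(sp.tissue_mean) + rng.normal(
        0.0, sp.tissue_std, size=(n_tissue, 3)
    )

    deposit_masks, counts_t, counts_g, cents = {}, {}, {}, {}
    for cls in CLASS_NAMES:
        density = float(spec.class_densities.get(cls, 0.0))
        n_total = _expected_count(density, int(gm.sum()), px_area_mm2)
        n_leak = int(round(n_total * spec.white_matter_leak))
        n_gm = n_total - n_leak
        mask = np.zeros(shape, dtype=bool)
        centroids = []
        wm = tissue & ~gm
        scale_factor = max(1, spec.heatmap_stride // 4)
        extent = _CLASS_EXTENT[cls] * scale_factor
        for region, count in ((gm, n_gm), (wm, n_leak)):
            if count == 0:
                continue
            # slide-resolution placement: footprints are dilated by the
            # stride/4 factor, so separation and margin scale with them
            for center in _place_centers(rng, region, count, 2 * extent + gap, extent + gap):
                stamp = _deposit_footprint(cls, rng)
                scale = max(1, spec.heatmap_stride // 4)
                stamp = np.kron(stamp, np.ones((scale, scale), dtype=bool))
                _stamp_at(mask, stamp, center)
                centroids.append(center)
        img[mask] = np.array(sp.deposit_mean) + rng.normal(
            0.0, sp.deposit_std, size=(int(mask.sum()), 3)
        )
        deposit_masks[cls] = mask
        counts_t[cls] = n_gm + n_leak
        counts_g[cls] = n_gm
        cents[cls] = centroids

    gt = SyntheticGroundTruth(
        resolution="slide",
        tissue_mask=tissue,
        gm_mask=gm,
        deposit_masks=deposit_masks,
        counts_tissue=counts_t,
        counts_gm=counts_g,
        centroids=cents,
    )
    gt.validate()
    return np.clip(img, 0, 255).astype(np.uint8), gt


def generate_labeled_tiles(image, ground_truth, tile_size, overlap_threshold=1):
    """Cut an image into non-overlapping tiles with multilabel annotations.

    A tile is labeled positive for class ``c`` iff at least
    ``overlap_threshold`` pixels of the class-c deposit mask fall inside it.
    Partial edge tiles are dropped (floor grid).
    Returns a list of ``(tile, label)`` with ``label`` a length-3 uint8 vector
    ordered as ``CLASS_NAMES``.
    """
    h, w = image.shape[:2]
    if tile_size > h or tile_size > w:
        raise ValueError("tile larger than image")
    out = []
    for r in range(0, h - tile_size + 1, tile_size):
        for c in range(0, w - tile_size + 1, tile_size):
            tile = image[r : r + tile_size, c : c + tile_size]
            label = np.zeros(len(CLASS_NAMES), dtype=np.uint8)
            for k, cls in enumerate(CLASS_NAMES):
                m = ground_truth.deposit_masks.get(cls)
                if m is not None:
                    overlap = int(m[r : r + tile_size, c : c + tile_size].sum())
                    label[k] = 1 if overlap >= overlap_threshold else 0
            out.append((tile, label))
    return out


def generate_training_tiles(n, tile_size=256, seed=0, p_positive=0.5):
    """Fabricate ``n`` standalone multilabel tiles with a strong color cue.

    Each class, when present, contributes several blobs in its
    class-specific color (cored: dark brown discs, diffuse: tan patches,
    caa: purple rings) and a small class-specific global tint -- the color
    cast such deposits lend a field of tissue -- so class presence is
    linearly separable from color statistics alone.  A desk-scale sanity
    dataset for the training loop, not a claim about real stain appearance.
    Returns ``(tiles, labels)`` as uint8 arrays of shape (n, T, T, 3) and
    (n, 3).
    """
    rng = np.random.default_rng(seed)
    colors = {
        "cored": (120, 75, 35),
        "diffuse": (215, 185, 60),
        "caa": (110, 60, 110),
    }
    tints = {
        "cored": (9.0, -3.0, -7.0),
        "diffuse": (-9.0, 9.0, -7.0),
        "caa": (3.0, -8.0, 9.0),
    }
    tiles = np.empty((n, tile_size, tile_size, 3), dtype=np.uint8)
    labels = np.zeros((n, 3), dtype=np.uint8)
    for i in range(n):
        img = np.full((tile_size, tile_size, 3), 200.0, dtype=np.float32)
        img += rng.normal(0, 4, size=img.shape)
        present = rng.random(3) < p_positive
        for k, cls in enumerate(CLASS_NAMES):
            if not present[k]:
                continue
            labels[i, k] = 1
            img += np.array(tints[cls], dtype=np.float32)
            for _ in range(int(rng.integers(3, 8))):
                stamp = _deposit_footprint(cls, rng)
                scale = int(rng.integers(6, 13))
                scale = max(1, min(scale, (tile_size - 1) // max(stamp.shape)))
                stamp = np.kron(stamp, np.ones((scale, scale), dtype=bool))
                r = int(rng.integers(0, tile_size - stamp.shape[0]))
                c = int(rng.integers(0, tile_size - stamp.shape[1]))
                sub = img[r : r + stamp.shape[0], c : c + stamp.shape[1]]
                sub[stamp] = np.array(colors[cls], dtype=np.float32)
        tiles[i] = np.clip(img, 0, 255).astype(np.uint8)
    return tiles, labels


def generate_cohort(spec: SyntheticCohortSpec):
    """Assign ordinal levels and noisy densities to a cohort of slides.

    Levels cycle through ``ordinal_levels`` so groups stay balanced.  Per
    slide and class, the realized density is
    ``density_by_level[class][level] + N(0, noise_sd)`` truncated at 0.
    Returns ``(slide_specs, records)`` where ``slide_specs`` is a list of
    :class:`SyntheticSlideSpec` and ``records`` a tidy DataFrame with one row
    per slide carrying its levels, densities and any planted group flags.
    """
    rng = np.random.default_rng(spec.seed)
    levels = list(spec.ordinal_levels)
    rows = []
    slide_specs = []
    for i in range(spec.n_slides):
        slide_id = f"slide_{i:03d}"
        level = levels[i % len(levels)]
        densities = {}
        row = {"slide_id": slide_id}
        for cls in spec.density_by_level:
            base = float(spec.density_by_level[cls][level])
            d = max(0.0, base + rng.normal(0.0, spec.noise_sd))
            densities[cls] = d
            row[f"level_{cls}"] = level
            row[f"level_index_{cls}"] = levels.index(level)
            row[f"density_{cls}"] = d
        if spec.group_assignments and slide_id in spec.group_assignments:
            row.update(spec.group_assignments[slide_id])
        rows.append(row)
        slide_specs.append(
            SyntheticSlideSpec(
                class_densities=densities,
                seed=int(rng.integers(0, 2**31 - 1)),
                **dict(spec.slide_kwargs),
            )
        )
    return slide_specs, pd.DataFrame(rows)


def density_for_exact_count(spec: SyntheticSlideSpec, count: int) -> float:
    """Density (deposits per mm^2 of gray matter) yielding exactly ``count``
    planted deposits for this spec's heatmap-resolution geometry."""
    shape = spec.heatmap_shape
    _, gm = _tissue_and_gm_masks(shape, spec.gm_fraction, spec.min_gap_px)
    gm_area_mm2 = int(gm.sum()) * spec.heatmap_px_area_mm2
    if gm_area_mm2 == 0:
        raise ValueError("no gray matter in this geometry")
    return count / gm_area_mm2


def slide_spec_to_dict(spec: SyntheticSlideSpec) -> dict:
    """YAML-serializable form of a slide spec."""
    d = dataclasses.asdict(spec)
    d["class_densities"] = dict(d["class_densities"])
    return d
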