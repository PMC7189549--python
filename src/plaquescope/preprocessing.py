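"""Color normalization, tissue segmentation and tiling of slide images.

Stain appearance varies between labs and scanners, so all slides are mapped
onto a common reference appearance with Reinhard normalization: pixel values
are converted to the decorrelated l-alpha-beta color space (log-LMS based,
after Ruderman), each channel is shifted and scaled so its mean/std match a
reference image's statistics, and the result is converted back to RGB.

Foreground tissue is segmented by thresholding in lightness-chroma-hue (LCH,
the cylindrical form of CIELAB): stained tissue is darker and more chromatic
than the near-white glass background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import color as skcolor

# RGB -> LMS (Reinhard/Ruderman)
_RGB2LMS = np.array(
    [
        [0.3811, 0.5783, 0.0402],
        [0.1967, 0.7244, 0.0782],
        [0.0241, 0.1288, 0.8444],
    ]
)
_LMS2RGB = np.linalg.inv(_RGB2LMS)
# log-LMS -> l,alpha,beta  (decorrelating rotation with channel scaling)
_A = np.diag([1 / np.sqrt(3), 1 / np.sqrt(6), 1 / np.sqrt(2)]) @ np.array(
    [[1, 1, 1], [1, 1, -2], [1, -1, 0]], dtype=float
)
_A_INV = np.linalg.inv(_A)
_LMS_FLOOR = 1e-6  # avoid log(0) on saturated black pixels


@dataclass(frozen=True)
class LabStats:
    """Per-channel mean and std in l-alpha-beta space of an image."""

    mean: tuple
    std: tuple

    def __post_init__(self):
        if len(self.mean) != 3 or len(self.std) != 3:
            raise ValueError("stats must have three channels")
        if any(s <= 0 for s in self.std):
            raise ValueError("channel standard deviations must be positive")


#: shipped reference appearance (stats of a default 1024x1024 synthetic
#: slide rendering, seed 3); any slide can serve as reference via
#: compute_lab_stats
DEFAULT_REFERENCE_STATS = LabStats(
    mean=(-0.1813, -0.0343, 0.0002),
    std=(0.0813, 0.0208, 0.0016),
)


def _to_float_rgb(image) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an H x W x 3 RGB image")
    if img.size == 0:
        raise ValueError("empty image")
    if img.dtype == np.uint8:
        return img.astype(np.float64) / 255.0
    return np.clip(img.astype(np.float64), 0.0, 1.0)


def rgb_to_lab_ruderman(image) -> np.ndarray:
    """RGB (uint8 or float in [0,1]) -> l-alpha-beta, float H x W x 3."""
    rgb = _to_float_rgb(image)
    lms = rgb @ _RGB2LMS.T
    log_lms = np.log10(np.maximum(lms, _LMS_FLOOR))
    return log_lms @ _A.T


def lab_ruderman_to_rgb(lab) -> np.ndarray:
    """Inverse of :func:`rgb_to_lab_ruderman`; returns float RGB clipped to [0,1]."""
    log_lms = np.asarray(lab) @ _A_INV.T
    lms = np.power(10.0, log_lms)
    rgb = lms @ _LMS2RGB.T
    return np.clip(rgb, 0.0, 1.0)


def compute_lab_stats(image) -> LabStats:
    """Channelwise mean/std of an image in l-alpha-beta space.

    Raises ``ValueError`` on a zero-variance channel (e.g. a constant-color
    image), for which Reinhard normalization is undefined.
    """
    lab = rgb_to_lab_ruderman(image)
    mean = lab.reshape(-1, 3).mean(axis=0)
    std = lab.reshape(-1, 3).std(axis=0)
    if np.any(std <= 1e-12):
        raise ValueError("zero-variance channel: normalization undefined")
    return LabStats(mean=tuple(mean), std=tuple(std))


def reinhard_normalize(image, source: LabStats, reference: LabStats):
    """Map an image's l-alpha-beta statistics onto a reference's.

    Each channel is transformed as ``(x - mu_src) * (sd_ref / sd_src) +
    mu_ref``.  Returns uint8 RGB if the input was uint8, else float in [0,1].
    """
    was_uint8 = np.asarray(image).dtype == np.uint8
    lab = rgb_to_lab_ruderman(image)
    mu_s = np.asarray(source.mean)
    sd_s = np.asarray(source.std)
    mu_r = np.asarray(reference.mean)
    sd_r = np.asarray(reference.std)
    lab = (lab - mu_s) * (sd_r / sd_s) + mu_r
    rgb = lab_ruderman_to_rgb(lab)
    if was_uint8:
        return np.round(rgb * 255.0).astype(np.uint8)
    return rgb


@dataclass(frozen=True)
class LCHThresholds:
    """Inclusive per-channel bounds in lightness-chroma-hue space.

    Lightness in [0, 100], chroma >= 0, hue in degrees [0, 360).
    """

    lightness: tuple = (0.0, 92.0)
    chroma: tuple = (4.0, 200.0)
    hue: tuple = (0.0, 360.0)

    def __post_init__(self):
        for name in ("lightness", "chroma", "hue"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: lower bound exceeds upper bound")


def rgb_to_lch(image) -> np.ndarray:
    """RGB -> (L, C, H) with hue in degrees [0, 360)."""
    lab = skcolor.rgb2lab(_to_float_rgb(image))
    lch = skcolor.lab2lch(lab)
    lch[..., 2] = np.degrees(lch[..., 2]) % 360.0
    return lch


def segment_tissue_lch(image, thresholds: LCHThresholds | None = None):
    """Boolean tissue mask: pixels whose L, C and H all fall inside bounds."""
    if thresholds is None:
        thresholds = LCHThresholds()
    lch = rgb_to_lch(image)
    mask = np.ones(lch.shape[:2], dtype=bool)
    for ch, (lo, hi) in enumerate(
        (thresholds.lightness, thresholds.chroma, thresholds.hue)
    ):
        mask &= (lch[..., ch] >= lo) & (lch[..., ch] <= hi)
    return mask


@dataclass(frozen=True)
class Tile:
    """One tile plus its top-left origin in (padded) slide pixels."""

    row: int
    col: int
    image: np.ndarray


def tile_image(image, tile_size: int, stride: int | None = None, pad: bool = True):
    """Cut an image into row-major tiles of ``tile_size`` at ``stride``.

    With ``pad=True`` the right/bottom edges are padded with white so the
    grid covers the whole image; with ``pad=False`` partial tiles are
    dropped.  Tile count per axis is ``floor((dim - tile_size)/stride) + 1``
    on the (padded) image.
    """
    if stride is None:
        stride = tile_size
    img = np.asarray(image)
    h, w = img.shape[:2]
    if pad:
        def padded(dim):
            if dim < tile_size:
                return tile_size
            # smallest grid-aligned size covering dim
            n = -(-(dim - tile_size) // stride)  # ceil
            return tile_size + n * stride

        ph, pw = padded(h), padded(w)
        if (ph, pw) != (h, w):
            fill = 255 if img.dtype == np.uint8 else 1.0
            shape = (ph, pw) + img.shape[2:]
            canvas = np.full(shape, fill, dtype=img.dtype)
            canvas[:h, :w] = img
            img = canvas
            h, w = ph, pw
    if tile_size > h or tile_size > w:
        raise ValueError("tile larger than (padded) image")
    tiles = []
    for r in range(0, h - tile_size + 1, stride):
        for c in range(0, w - tile_size + 1, stride):
            tiles.append(Tile(row=r, col=c, image=img[r : r + tile_size, c : c + tile_size]))
    return tiles
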