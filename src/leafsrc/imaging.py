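"""Leaf-photograph preprocessing: from raw image to aligned 32x32 contour raster.

The chain mirrors the standard contour-morphometrics recipe for leaf
silhouettes photographed on a near-uniform dark background:

1. grayscale conversion,
2. background suppression by a small intensity threshold,
3. median-filter denoising,
4. footstalk (petiole) removal — the longest narrow protrusion of the
   silhouette is cut off,
5. rotation so the blade's principal axis is vertical, plus a tight crop,
6. Canny contour extraction,
7. crop to the contour extents and bilinear resize to a 32x32 raster
   scaled to [0, 1].

The 32x32 raster is the atom unit for every dictionary downstream: one
raster, flattened row-major, is one dictionary column.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from skimage import feature, filters, measure, morphology, transform

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocessConfig",
    "ContourRaster",
    "PreprocessError",
    "to_grayscale",
    "remove_background",
    "denoise",
    "binarize",
    "remove_footstalk",
    "align_major_axis",
    "extract_contour",
    "normalize_raster",
    "preprocess",
    "load_image",
    "save_raster",
    "foreground_angle",
]

# ITU-R 601 luma weights, the same combination skimage's rgb2gray uses.
_LUMA = np.array([0.2125, 0.7154, 0.0721])


class PreprocessError(ValueError):
    """Raised when a preprocessing stage cannot produce valid output."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"{stage}: {message}")


@dataclass
class PreprocessConfig:
    """Tunable parameters of the preprocessing chain.

    bg_thresh      intensity below which a pixel is treated as background
                   (8-bit scale)
    median_radius  radius in pixels of the disk-shaped median footprint;
                   auto-capped at floor(min(h, w) / 4) so small images
                   survive the filter
    stalk_width    narrowness threshold: protrusions thinner than this are
                   candidate footstalks
    min_stalk_length  protrusions with skeleton shorter than this are kept
    canny_sigma    Gaussian smoothing scale of the Canny edge detector
    out_size       side length of the output raster
    contour_atoms  if True the raster holds the Canny contour; if False the
                   filled aligned silhouette (both are used in the
                   literature; contours are the default)
    """

    bg_thresh: float = 30.0
    median_radius: int = 10
    stalk_width: int = 5
    min_stalk_length: int = 10
    canny_sigma: float = 1.0
    out_size: int = 32
    contour_atoms: bool = True

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PreprocessConfig":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class ContourRaster:
    """Aligned, normalized raster of a single leaf; the dictionary atom unit.

    pixels is a square float array with values in [0, 1] and at least one
    nonzero entry; source_id traces the originating image.
    """

    pixels: np.ndarray
    source_id: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError(f"raster must be square 2-D, got {self.pixels.shape}")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValueError("raster intensities must lie in [0, 1]")
        if not np.any(self.pixels):
            raise ValueError("raster has no foreground")

    @property
    def vector(self) -> np.ndarray:
        """Row-major flattening; one dictionary column."""
        return self.pixels.ravel()


def _check_raw(img: np.ndarray, stage: str) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    if img.size == 0:
        raise PreprocessError(stage, "empty image")
    if img.ndim not in (2, 3):
        raise PreprocessError(stage, f"expected 2-D or 3-D array, got ndim={img.ndim}")
    return img


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """Collapse an RGB image to luminance; grayscale input passes through.

    Intensities keep their input scale (8-bit images stay on [0, 255]).
    """
    img = _check_raw(img, "to_grayscale")
    if img.ndim == 2:
        return img
    if img.shape[2] == 4:  # drop alpha
        img = img[..., :3]
    if img.shape[2] != 3:
        raise PreprocessError("to_grayscale", f"expected 3 channels, got {img.shape[2]}")
    return img @ _LUMA


def remove_background(img: np.ndarray, thresh: float = 30.0) -> np.ndarray:
    """Zero out every pixel darker than `thresh` (8-bit scale)."""
    img = _check_raw(img, "remove_background")
    out = img.copy()
    out[out < thresh] = 0.0
    return out


def denoise(img: np.ndarray, radius: int = 10) -> np.ndarray:
    """Median-filter with a disk footprint of the given radius.

    The radius is capped at floor(min(h, w) / 4): leaf databases contain
    images as small as ~29x21 pixels, which a radius-10 footprint would
    erase outright.
    """
    if radius <= 0:
        raise ValueError(f"median radius must be positive, got {radius}")
    img = _check_raw(img, "denoise")
    cap = max(1, min(img.shape) // 4)
    r = min(int(radius), cap)
    if r < radius:
        logger.debug("median radius capped %d -> %d for image %s", radius, r, img.shape)
    return filters.median(img, footprint=morphology.disk(r), mode="nearest")


def binarize(img: np.ndarray) -> np.ndarray:
    """Foreground mask via Otsu's threshold; all-equal images give an empty mask."""
    img = _check_raw(img, "binarize")
    if img.max() == img.min():
        return np.zeros_like(img, dtype=bool)
    return img > filters.threshold_otsu(img)


def remove_footstalk(
    mask: np.ndarray, stalk_width: int = 5, min_length: int = 10
) -> np.ndarray:
    """Cut off the longest narrow protrusion (the petiole) of a silhouette.

    Narrow structures are found as the difference between the mask and its
    morphological opening with a disk of radius `stalk_width`; connected
    components of that difference are the candidate "chains".  The chain
    with the greatest skeleton length is removed, provided it is at least
    `min_length` long.  The blade is then the largest remaining connected
    component, so blade connectivity is preserved.
    """
    mask = _check_raw(mask, "remove_footstalk") > 0
    if not mask.any():
        raise PreprocessError("remove_footstalk", "no foreground")
    opened = morphology.opening(mask, morphology.disk(stalk_width))
    if not opened.any():
        # whole object is thinner than the narrowness threshold: nothing to cut
        return mask
    chains = measure.label(mask & ~opened)
    best_label, best_len = 0, 0
    for region in measure.regionprops(chains):
        skel_len = int(morphology.skeletonize(chains == region.label).sum())
        if skel_len > best_len:
            best_label, best_len = region.label, skel_len
    out = mask.copy()
    if best_label and best_len >= min_length:
        out &= chains != best_label
        labels = measure.label(out)
        if labels.max() > 1:
            sizes = np.bincount(labels.ravel())[1:]
            out = labels == (1 + int(np.argmax(sizes)))
    return out


def foreground_angle(img: np.ndarray) -> float | None:
    """Angle (degrees, in (-90, 90]) of the foreground's principal axis
    measured from the vertical, via second central moments.  None when the
    foreground is isotropic (no unique major axis)."""
    img = np.asarray(img, dtype=float)
    r, c = np.nonzero(img > 0)
    if r.size == 0:
        raise PreprocessError("align_major_axis", "no foreground")
    w = img[r, c]
    rm, cm = np.average(r, weights=w), np.average(c, weights=w)
    mrr = np.average((r - rm) ** 2, weights=w)
    mcc = np.average((c - cm) ** 2, weights=w)
    mrc = np.average((r - rm) * (c - cm), weights=w)
    scale = mrr + mcc
    if scale == 0 or np.hypot(mrr - mcc, 2 * mrc) < 1e-6 * scale:
        return None
    ang = 0.5 * np.degrees(np.arctan2(2 * mrc, mrr - mcc))
    if ang <= -90.0:
        ang += 180.0
    return ang


def _tight_crop(img: np.ndarray) -> np.ndarray:
    r, c = np.nonzero(img > 0)
    if r.size == 0:
        raise PreprocessError("crop", "no foreground to crop to")
    return img[r.min() : r.max() + 1, c.min() : c.max() + 1]


def align_major_axis(img: np.ndarray) -> np.ndarray:
    """Rotate so the principal axis of the foreground is vertical; crop tight.

    The 180-degree ambiguity of the axis is resolved by placing the heavier
    half of the blade in the lower image half.  Isotropic foregrounds (disks)
    skip the rotation with a logged warning.
    """
    img = _check_raw(img, "align_major_axis")
    ang = foreground_angle(img)
    if ang is None:
        logger.warning("foreground has no unique major axis; skipping rotation")
        return _tight_crop(img)
    out = transform.rotate(img, -ang, resize=True, order=1)
    r, c = np.nonzero(out > 0)
    w = out[r, c]
    rm = np.average(r, weights=w)
    # resolve the 180-degree ambiguity by the along-axis skewness of the
    # foreground mass (blade base down).  A half-mass comparison splits at
    # the centroid and is nearly balanced by construction; the third moment
    # keeps a usable sign margin for asymmetric blades.
    m2 = np.average((r - rm) ** 2, weights=w)
    m3 = np.average((r - rm) ** 3, weights=w)
    if m2 > 0 and m3 / m2**1.5 > 0:
        out = out[::-1, ::-1]  # 180-degree rotation
    return _tight_crop(out)


def extract_contour(img: np.ndarray, sigma: float = 1.0) -> np.ndarray:
    """Canny edge map of the leaf boundary (binary, float 0/1).

    Hysteresis thresholds are fixed at 0.1 / 0.3 of the full intensity
    range, sigma defaults to 1, which keeps the chain deterministic.
    """
    img = _check_raw(img, "extract_contour")
    if not np.any(img):
        raise PreprocessError("extract_contour", "empty foreground")
    span = img.max()
    norm = img / span if span > 0 else img
    # zero-pad so a foreground that touches the image border still yields a
    # closed boundary (the detector cannot mark edges on the border itself)
    pad = 4
    padded = np.pad(norm, pad)
    edges = feature.canny(padded, sigma=sigma, low_threshold=0.1, high_threshold=0.3)
    # on an ideal binary step the two pixels flanking the edge tie in
    # gradient magnitude and non-maximum suppression keeps both; thinning
    # restores the one-pixel boundary
    edges = morphology.thin(edges)
    return edges[pad:-pad, pad:-pad].astype(float)


def normalize_raster(
    img: np.ndarray, out_size: int = 32, source_id: str = ""
) -> ContourRaster:
    """Tight-crop to the foreground extents, bilinear-resize to a square
    raster, rescale intensities to [0, 1]."""
    img = _check_raw(img, "normalize_raster")
    if not np.any(img > 0):
        raise PreprocessError("normalize_raster", "empty contour")
    cropped = _tight_crop(img)
    # bilinear with the antialias prefilter on downscale (the behaviour of
    # MATLAB-style imresize); without the prefilter a one-pixel contour
    # aliases and the raster becomes hypersensitive to sub-pixel shifts
    resized = transform.resize(cropped, (out_size, out_size), order=1)
    peak = resized.max()
    if peak <= 0:
        raise PreprocessError("normalize_raster", "contour vanished during resize")
    return ContourRaster(np.clip(resized / peak, 0.0, 1.0), source_id=source_id)


def preprocess(
    img: np.ndarray, cfg: PreprocessConfig | None = None, source_id: str = ""
) -> ContourRaster:
    """Run the full chain (grayscale -> background -> median -> footstalk ->
    align -> contour -> normalize) and return the 32x32 raster.

    Stage failures re-raise as PreprocessError carrying the stage name.
    """
    cfg = cfg or PreprocessConfig()
    gray = to_grayscale(img)
    clean = remove_background(gray, cfg.bg_thresh)
    smooth = denoise(clean, cfg.median_radius)
    mask = binarize(smooth)
    if not mask.any():
        raise PreprocessError("binarize", "no foreground after background removal")
    blade = remove_footstalk(mask, cfg.stalk_width, cfg.min_stalk_length)
    aligned = align_major_axis(blade.astype(float))
    if cfg.contour_atoms:
        shape_img = extract_contour(aligned, cfg.canny_sigma)
        if not shape_img.any():
            raise PreprocessError("extract_contour", "no edges found")
    else:
        shape_img = aligned
    raster = normalize_raster(shape_img, cfg.out_size, source_id=source_id)
    logger.debug("preprocessed %s -> %s raster", source_id or "<image>", raster.pixels.shape)
    return raster


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG/JPEG/BMP leaf photograph as a float array on the 8-bit scale."""
    import imageio.v3 as iio

    return np.asarray(iio.imread(path), dtype=float)


def save_raster(raster: ContourRaster, path: str | Path, csv: bool = False) -> None:
    """Write a raster as an 8-bit PNG; optionally also a flat 1024-value CSV row."""
    import imageio.v3 as iio

    path = Path(path)
    iio.imwrite(path, np.round(raster.pixels * 255).astype(np.uint8))
    if csv:
        np.savetxt(
            path.with_suffix(".csv"), raster.vector[None, :], delimiter=",", fmt="%.8g"
        )
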