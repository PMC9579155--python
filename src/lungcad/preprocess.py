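"""ROI preprocessing for candidate lung-nodule patches.

Raw grayscale patches are cropped around the candidate, binarized with a
maximum-entropy (Kapur) threshold, and cleaned by keeping only the largest
connected components so that background speckle does not survive into the
downstream feature extractors.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from skimage import measure

__all__ = [
    "RoiImage",
    "BinaryMask",
    "crop_centered",
    "max_entropy_threshold",
    "keep_largest_components",
    "preprocess_sample",
    "load_roi_image",
    "save_mask",
    "write_manifest",
]

#: canonical ROI edge length (pixels)
ROI_SIZE = 64

POSITIVE = "positive"
NEGATIVE = "negative"


@dataclass
class RoiImage:
    """A square 8-bit grayscale patch with its class label.

    ``pixels`` must be a 2-D square integer array with values in [0, 255];
    ``label`` is ``"positive"`` (nodule) or ``"negative"`` (non-nodule).
    """

    pixels: np.ndarray
    label: str = POSITIVE
    source_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] != px.shape[1]:
            raise ValueError(f"ROI must be a square 2-D array, got shape {px.shape}")
        if not np.issubdtype(px.dtype, np.integer):
            if not np.allclose(px, np.round(px)):
                raise ValueError("ROI intensities must be integral")
            px = np.round(px).astype(np.int64)
        if px.min() < 0 or px.max() > 255:
            raise ValueError("ROI intensities must lie in [0, 255]")
        if self.label not in (POSITIVE, NEGATIVE):
            raise ValueError(f"label must be '{POSITIVE}' or '{NEGATIVE}', got {self.label!r}")
        object.__setattr__(self, "pixels", px.astype(np.uint8))

    @property
    def size(self) -> int:
        return self.pixels.shape[0]


@dataclass
class BinaryMask:
    """A binarized ROI together with the threshold that produced it."""

    pixels: np.ndarray
    threshold_used: int
    n_components_kept: int = 0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        vals = np.unique(px)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask values must be 0/1")
        if not 0 <= self.threshold_used <= 255:
            raise ValueError("threshold must lie in [0, 255]")
        object.__setattr__(self, "pixels", px.astype(np.uint8))


def crop_centered(image: np.ndarray, center: tuple[int, int], size: int) -> np.ndarray:
    """Crop a ``size``x``size`` window whose geometric center is ``center``.

    Coordinates are 0-based row/column; the window covers the half-open index
    range ``[c - size//2, c - size//2 + size)`` in each axis.  Parts of the
    window falling outside the image are zero-padded, so candidates near the
    border still yield full-size patches.
    """
    if size <= 0:
        raise ValueError(f"crop size must be positive, got {size}")
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    r, c = center
    if not (0 <= r < image.shape[0] and 0 <= c < image.shape[1]):
        raise ValueError(f"center {center} outside image of shape {image.shape}")

    r0, c0 = r - size // 2, c - size // 2
    patch = np.zeros((size, size), dtype=image.dtype)
    src_r0, src_c0 = max(r0, 0), max(c0, 0)
    src_r1, src_c1 = min(r0 + size, image.shape[0]), min(c0 + size, image.shape[1])
    if src_r0 < src_r1 and src_c0 < src_c1:
        patch[src_r0 - r0:src_r1 - r0, src_c0 - c0:src_c1 - c0] = image[src_r0:src_r1, src_c0:src_c1]
    return patch


def _side_entropy(counts: np.ndarray) -> float:
    """Shannon entropy (nats) of the normalized histogram ``counts``."""
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum())


def max_entropy_threshold(image: np.ndarray | RoiImage) -> int:
    """Kapur maximum-entropy threshold of an 8-bit image.

    Scans every threshold T in [0, 255] and returns the one maximizing the
    sum of Shannon entropies of the sub-histograms below (< T) and above
    (>= T) the threshold, matching the ``pixel >= T -> foreground``
    binarization rule used downstream.  A threshold leaving either side
    empty has no defined entropy on that side and is excluded from the
    scan; ties break toward the smallest T.
    """
    px = image.pixels if isinstance(image, RoiImage) else np.asarray(image)
    px = px.astype(np.int64)
    if px.min() < 0 or px.max() > 255:
        raise ValueError("intensities must lie in [0, 255]")
    if px.min() == px.max():
        raise ValueError("threshold undefined for a constant image")

    counts = np.bincount(px.ravel(), minlength=256).astype(np.float64)
    # cumulative counts and cumulative sum of c*log(c) let every T be scored
    # in one vectorized pass: H = log(C_side) - S_side / C_side per side.
    clogc = np.where(counts > 0, counts * np.log(np.where(counts > 0, counts, 1.0)), 0.0)
    cum = np.cumsum(counts)
    cum_clogc = np.cumsum(clogc)
    total, total_clogc = cum[-1], cum_clogc[-1]

    scores = np.full(256, -np.inf)
    for t in range(256):
        c_lo = cum[t - 1] if t > 0 else 0.0
        s_lo = cum_clogc[t - 1] if t > 0 else 0.0
        c_hi, s_hi = total - c_lo, total_clogc - s_lo
        if c_lo == 0 or c_hi == 0:
            continue  # one-sided split: entropy undefined on the empty side
        scores[t] = (np.log(c_lo) - s_lo / c_lo) + (np.log(c_hi) - s_hi / c_hi)
    return int(np.argmax(scores))  # argmax returns the first (smallest) maximizer


def keep_largest_components(mask: np.ndarray, k: int = 8) -> tuple[np.ndarray, int]:
    """Retain the ``k`` largest 8-connected foreground components.

    Components are ranked by pixel count; equal-size components are ordered
    by the raster index of their first pixel, so the result is deterministic.
    Returns the cleaned mask and the number of components it contains.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    mask = np.asarray(mask)
    binary = mask.astype(bool)
    labels = measure.label(binary, connectivity=2)
    n_comp = labels.max()
    if n_comp <= k:
        return binary.astype(np.uint8), int(n_comp)

    sizes = np.bincount(labels.ravel())[1:]  # skip background
    flat = labels.ravel()
    first_idx = np.full(n_comp + 1, flat.size, dtype=np.int64)
    for idx in range(flat.size):  # raster scan; first occurrence per label
        lab = flat[idx]
        if lab and first_idx[lab] == flat.size:
            first_idx[lab] = idx
    order = sorted(range(1, n_comp + 1), key=lambda lab: (-sizes[lab - 1], first_idx[lab]))
    keep = set(order[:k])
    cleaned = np.isin(labels, list(keep))
    return cleaned.astype(np.uint8), k


def preprocess_sample(
    image: np.ndarray,
    center: tuple[int, int],
    label: str,
    size: int = ROI_SIZE,
    max_components: int = 8,
    source_id: str = "",
) -> tuple[RoiImage, BinaryMask]:
    """Full preprocessing pipeline for one candidate.

    Crop a centered patch, pick the maximum-entropy threshold, binarize with
    ``pixel >= T -> 1`` and keep at most ``max_components`` (default 8)
    connected regions to suppress background speckle.
    """
    patch = crop_centered(image, center, size)
    roi = RoiImage(pixels=patch, label=label, source_id=source_id)
    t = max_entropy_threshold(roi.pixels)
    binary = (roi.pixels >= t).astype(np.uint8)
    cleaned, n_kept = keep_largest_components(binary, max_components)
    return roi, BinaryMask(pixels=cleaned, threshold_used=t, n_components_kept=n_kept)


# ---------------------------------------------------------------------------
# file I/O

def load_roi_image(path: str | Path, label: str = POSITIVE) -> RoiImage:
    """Read an 8-bit grayscale PNG/TIFF as an :class:`RoiImage`."""
    arr = np.asarray(Image.open(path).convert("L"))
    return RoiImage(pixels=arr, label=label, source_id=Path(path).stem)


def save_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a binary mask as an 8-bit PNG with foreground at 255."""
    Image.fromarray((mask.pixels * 255).astype(np.uint8)).save(path)


def write_manifest(rows: list[dict], path: str | Path) -> None:
    """Write a preprocessing manifest CSV (source_id, label, threshold, components)."""
    fields = ["source_id", "label", "threshold_used", "n_components_kept"]
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fields)
        writer.writeheader()
        for row in rows:
            writer.writerow({k: row[k] for k in fields})
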