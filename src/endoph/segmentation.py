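"""Endosome detection and per-punctum measurement.

Segmentation follows the classical punctum recipe: a global Otsu threshold on
the masking channel, 8-connected component labelling, and removal of objects
smaller than 5 pixels.  Per-region statistics (area, centroid, per-channel
mean intensity, equivalent-disk diameter) feed the ratiometric analysis, and
line-profile FWHM measurement quantifies apparent punctum size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import label as sk_label
from skimage.measure import regionprops

from .io import ImagePair

__all__ = [
    "LabeledRegions",
    "otsu_threshold",
    "segment_endosomes",
    "region_stats",
    "background_stats",
    "measure_fwhm",
]

MIN_SIZE_PX = 5  # "at least 5 pixels in size"


@dataclass
class LabeledRegions:
    """Segmentation result: integer label map (0 = background) plus a region
    table with columns label, area_px, cx, cy, eq_diameter_px (and per-channel
    means once :func:`region_stats` has run)."""

    label_map: np.ndarray
    table: pd.DataFrame
    threshold: float
    min_size: int = MIN_SIZE_PX

    def __len__(self) -> int:
        return len(self.table)

    @property
    def mask(self) -> np.ndarray:
        return self.label_map > 0

    def centroids(self) -> np.ndarray:
        """(n, 2) array of (cx, cy) centroids in pixels."""
        return self.table[["cx", "cy"]].to_numpy(dtype=float)


def otsu_threshold(image: np.ndarray, nbins: int = 256) -> float:
    """Global threshold maximising between-class intensity variance.

    Computed on an ``nbins``-bin histogram (256 bins also for 16-bit data,
    i.e. bin width = intensity range / 256).  The returned value is the bin
    edge separating the two optimal classes, so that masking with
    ``image >= threshold`` realises the optimal partition; it always lies
    strictly between the two class extrema.  A constant image has no
    two-class structure and raises ``ValueError``.
    """
    image = np.asarray(image)
    if image.min() == image.max():
        raise ValueError("constant image: Otsu threshold undefined")
    counts, edges = np.histogram(image.ravel(), bins=nbins)
    counts = counts.astype(float)
    centers = (edges[:-1] + edges[1:]) / 2.0
    w0 = np.cumsum(counts)
    w1 = w0[-1] - w0
    csum = np.cumsum(counts * centers)
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = csum / w0
        mu1 = (csum[-1] - csum) / w1
        between = w0 * w1 * (mu0 - mu1) ** 2
    between[~np.isfinite(between)] = -np.inf
    # cut after bin i: classes are bins [0..i] and [i+1..]; threshold = edge
    i = int(np.argmax(between[:-1]))
    return float(edges[i + 1])


def segment_endosomes(
    mask_channel: np.ndarray,
    min_size: int = MIN_SIZE_PX,
    threshold: float | None = None,
) -> LabeledRegions:
    """Detect puncta in one channel.

    Pixels >= the (Otsu) threshold form foreground; 8-connected components
    are labelled and components smaller than ``min_size`` pixels discarded.
    Surviving labels are renumbered consecutively from 1.  Zero surviving
    regions yields an empty result with a warning, not a failure.
    """
    img = np.asarray(mask_channel)
    thr = otsu_threshold(img) if threshold is None else float(threshold)
    fg = img >= thr
    labels = sk_label(fg, connectivity=2)
    props = [p for p in regionprops(labels) if p.area >= min_size]
    lut = np.zeros(labels.max() + 1, dtype=labels.dtype)
    for new_id, p in enumerate(props, start=1):
        lut[p.label] = new_id
    relabeled = lut[labels]
    rows = []
    for new_id, p in enumerate(props, start=1):
        cy, cx = p.centroid
        rows.append(
            {
                "label": new_id,
                "area_px": int(p.area),
                "cx": cx,
                "cy": cy,
                "eq_diameter_px": 2.0 * np.sqrt(p.area / np.pi),
            }
        )
    if not rows:
        warnings.warn("no regions survived segmentation", stacklevel=2)
    table = pd.DataFrame(
        rows, columns=["label", "area_px", "cx", "cy", "eq_diameter_px"]
    )
    return LabeledRegions(
        label_map=relabeled, table=table, threshold=thr, min_size=min_size
    )


def region_stats(regions: LabeledRegions, pair: ImagePair) -> pd.DataFrame:
    """Augment the region table with per-channel mean intensities.

    ``mean_ch1`` is the FP channel, ``mean_ch2`` the dye channel; means are
    arithmetic means over exactly the labelled pixels.
    """
    if regions.label_map.shape != pair.shape:
        raise ValueError("label map and image dimensions differ")
    table = regions.table.copy()
    if len(table) == 0:
        table["mean_ch1"] = pd.Series(dtype=float)
        table["mean_ch2"] = pd.Series(dtype=float)
        regions.table = table
        return table
    ids = table["label"].to_numpy()
    table["mean_ch1"] = ndimage.mean(pair.fp.astype(float), regions.label_map, ids)
    table["mean_ch2"] = ndimage.mean(pair.dye.astype(float), regions.label_map, ids)
    regions.table = table
    return table


def background_stats(
    pair: ImagePair,
    regions: LabeledRegions,
    n_rois: int = 30,
    roi_size: int = 10,
    seed: int = 0,
    max_tries: int = 20000,
) -> dict:
    """Mean background intensity per channel from random square ROIs.

    ROIs (``roi_size`` x ``roi_size``) are placed uniformly at random, fully
    outside the segmentation mask dilated by ``roi_size`` pixels, and mutually
    non-overlapping.  Infeasible placement raises ``RuntimeError``.
    """
    rng = np.random.default_rng(seed)
    h, w = pair.shape
    if roi_size > min(h, w):
        raise RuntimeError("ROI larger than image")
    excl = ndimage.binary_dilation(regions.mask, iterations=roi_size)
    taken = np.zeros((h, w), dtype=bool)
    boxes = []
    tries = 0
    while len(boxes) < n_rois:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not place {n_rois} background ROIs of {roi_size} px"
            )
        tries += 1
        y = int(rng.integers(0, h - roi_size + 1))
        x = int(rng.integers(0, w - roi_size + 1))
        sl = (slice(y, y + roi_size), slice(x, x + roi_size))
        if excl[sl].any() or taken[sl].any():
            continue
        taken[sl] = True
        boxes.append(sl)
    fp_means = np.array([pair.fp[sl].mean() for sl in boxes])
    dye_means = np.array([pair.dye[sl].mean() for sl in boxes])
    return {
        "mean_fp": float(fp_means.mean()),
        "mean_dye": float(dye_means.mean()),
        "sd_fp": float(fp_means.std(ddof=1)) if n_rois > 1 else 0.0,
        "sd_dye": float(dye_means.std(ddof=1)) if n_rois > 1 else 0.0,
        "n_rois": n_rois,
        "roi_size": roi_size,
    }


def _profile_fwhm(profile: np.ndarray, pixel_size_nm: float) -> float:
    """FWHM of a 1-D profile: background from the outer 20% (both tails),
    half-maximum crossings located by linear interpolation around the peak."""
    n = len(profile)
    tail = max(1, int(round(0.2 * n / 2)))
    bg = float(np.median(np.concatenate([profile[:tail], profile[-tail:]])))
    peak_idx = int(np.argmax(profile))
    peak = float(profile[peak_idx])
    if peak <= bg:
        raise ValueError("no peak above background in profile window")
    half = bg + 0.5 * (peak - bg)

    # walk left
    i = peak_idx
    while i > 0 and profile[i] >= half:
        i -= 1
    if profile[i] >= half:
        raise ValueError("profile never falls below half maximum (left side)")
    left = i + (half - profile[i]) / (profile[i + 1] - profile[i])

    j = peak_idx
    while j < n - 1 and profile[j] >= half:
        j += 1
    if profile[j] >= half:
        raise ValueError("profile never falls below half maximum (right side)")
    right = j - 1 + (profile[j - 1] - half) / (profile[j - 1] - profile[j])

    return (right - left) * pixel_size_nm


def measure_fwhm(
    image: np.ndarray,
    centroid: tuple[float, float],
    pixel_size_nm: float,
    axis: str = "auto",
    expected_fwhm_nm: float = 250.0,
) -> float:
    """FWHM (nm) of a punctum from a line profile through its centroid.

    ``centroid`` is (cx, cy) in pixels.  The profile window is 6x the
    expected FWHM; local background is the median of the outer 20% of the
    window.  ``axis`` is ``"x"``, ``"y"`` or ``"auto"`` (the brighter of the
    two).  An object whose profile never drops below half maximum inside the
    window (unresolved or overlapping) raises ``ValueError``.
    """
    img = np.asarray(image, dtype=float)
    h, w = img.shape
    cx, cy = centroid
    ix, iy = int(round(cx)), int(round(cy))
    if not (0 <= ix < w and 0 <= iy < h):
        raise ValueError("centroid outside image")
    half_w = max(3, int(round(3.0 * expected_fwhm_nm / pixel_size_nm)))

    def _window(center, size):
        lo = max(0, center - half_w)
        hi = min(size, center + half_w + 1)
        return lo, hi

    profiles = {}
    x0, x1 = _window(ix, w)
    profiles["x"] = img[iy, x0:x1]
    y0, y1 = _window(iy, h)
    profiles["y"] = img[y0:y1, ix]

    if axis == "auto":
        axis = "x" if profiles["x"].max() >= profiles["y"].max() else "y"
    if axis not in profiles:
        raise ValueError("axis must be 'x', 'y' or 'auto'")
    return _profile_fwhm(profiles[axis], pixel_size_nm)
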