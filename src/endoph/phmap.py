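"""Per-pixel ratiometric pH maps.

Within the endosome mask each pixel's log10(FP/dye) ratio is pushed through
the inverted calibration to give a 32-bit pH image (NaN outside the mask),
plus an 8-bit display image rescaled linearly over the calibration pH range
for use with a linear LUT.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import ImagePair
from .ratiometry import CalibrationCurve, invert_calibration
from .segmentation import LabeledRegions

__all__ = ["PHMap", "build_ph_map", "per_endosome_ph"]


@dataclass
class PHMap:
    """Per-pixel pH estimate plus display rendering.

    ``ph_image`` is float32 with NaN outside the analysed mask;
    ``display_image`` is uint8, 0 outside the mask, affine over the
    calibration pH range inside it.  ``analysed_mask`` marks pixels that
    entered the analysis (in a region, dye > 0, not saturated).
    """

    ph_image: np.ndarray
    display_image: np.ndarray
    analysed_mask: np.ndarray
    calibration: CalibrationCurve
    saturated_mask: np.ndarray

    def lut(self, cmap_name: str = "viridis") -> np.ndarray:
        """(256, 3) linear color lookup table for the display image."""
        import matplotlib

        cmap = matplotlib.colormaps[cmap_name]
        return (cmap(np.linspace(0, 1, 256))[:, :3] * 255).astype(np.uint8)


def build_ph_map(
    pair: ImagePair, regions: LabeledRegions, curve: CalibrationCurve
) -> PHMap:
    """Ratiometric pH image over the segmented mask.

    Pixels with zero dye signal or saturated in either channel are excluded
    from the analysed mask (saturated values no longer carry quantitative
    ratio information).  Display values map ``ph_range`` linearly onto
    [0, 255] and clip outside it.
    """
    if regions.label_map.shape != pair.shape:
        raise ValueError("label map and image dimensions differ")
    saturated = pair.saturated()
    # zero-count pixels in either channel carry no ratio information
    # (log10 of 0 is undefined); exclude them like saturated pixels
    mask = regions.mask & (pair.dye > 0) & (pair.fp > 0) & ~saturated
    if not mask.any():
        warnings.warn("empty analysis mask: pH map contains no pixels", stacklevel=2)
    ph = np.full(pair.shape, np.nan, dtype=np.float32)
    fp = pair.fp.astype(float)
    dye = pair.dye.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_ratio = np.log10(fp[mask] / np.maximum(dye[mask], 1e-12))
    ph[mask] = invert_calibration(curve, log_ratio)

    lo, hi = curve.ph_range
    display = np.zeros(pair.shape, dtype=np.uint8)
    scaled = np.clip((ph[mask] - lo) / (hi - lo), 0.0, 1.0) * 255.0
    display[mask] = np.rint(scaled).astype(np.uint8)
    return PHMap(
        ph_image=ph,
        display_image=display,
        analysed_mask=mask,
        calibration=curve,
        saturated_mask=saturated & regions.mask,
    )


def per_endosome_ph(
    ph_map: PHMap, regions: LabeledRegions, pair: ImagePair | None = None
) -> pd.DataFrame:
    """Per-region pH summaries.

    ``mean_ph`` is the mean of within-region per-pixel pH values (saturated
    and zero-dye pixels excluded).  When ``pair`` is given the table also
    carries ``ph_ratio_of_means``, the pH implied by the region's
    ratio-of-mean-intensities — the statistic used by per-endosome
    calibration.  The two agree only approximately; both are reported.
    """
    labels = regions.label_map
    ids = regions.table["label"].to_numpy()
    rows = []
    for rid in ids:
        sel = (labels == rid) & ph_map.analysed_mask
        n_px = int(sel.sum())
        n_sat = int(((labels == rid) & ph_map.saturated_mask).sum())
        mean_ph = float(np.nanmean(ph_map.ph_image[sel])) if n_px else np.nan
        row = {"label": int(rid), "mean_ph": mean_ph, "n_px": n_px,
               "n_saturated": n_sat}
        if pair is not None:
            if n_px:
                mfp = float(pair.fp.astype(float)[sel].mean())
                mdye = float(pair.dye.astype(float)[sel].mean())
                row["ph_ratio_of_means"] = (
                    invert_calibration(ph_map.calibration, np.log10(mfp / mdye))
                    if mdye > 0 and mfp > 0
                    else np.nan
                )
            else:
                row["ph_ratio_of_means"] = np.nan
        rows.append(row)
    cols = ["label", "mean_ph", "n_px", "n_saturated"]
    if pair is not None:
        cols.append("ph_ratio_of_means")
    return pd.DataFrame(rows, columns=cols)
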