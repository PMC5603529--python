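"""Per-endosome ratiometry and log-linear pH calibration.

For each segmented endosome the FP/dye intensity ratio is summarised as
log10(mean_FP / mean_dye).  Against a pH-clamped calibration series the
per-pH mean log-ratios fall on a line

    log10(R) = a * pH + b,

which is fitted by ordinary least squares on the per-pH means and inverted,
pH = (log10(R) - b) / a, to convert measured ratios into pH estimates.
R^2 is reported on the per-pH mean points (the plotted calibration points);
per-endosome scatter is recorded separately as the per-pH SD.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CalibrationCurve",
    "per_endosome_log_ratio",
    "fit_calibration",
    "invert_calibration",
    "empirical_dynamic_range",
]


@dataclass
class CalibrationCurve:
    """Fitted log10(FP/dye) = slope * pH + intercept with validity range."""

    slope: float
    intercept: float
    r_squared: float
    ph_range: tuple[float, float]
    per_ph: pd.DataFrame = field(repr=False, default=None)
    sensor: str | None = None

    def __post_init__(self):
        lo, hi = self.ph_range
        if not lo < hi:
            raise ValueError("ph_range low must be < high")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("r_squared must be in [0, 1]")

    def in_range(self, pH) -> np.ndarray:
        lo, hi = self.ph_range
        return (np.asarray(pH) >= lo) & (np.asarray(pH) <= hi)

    def predict_log_ratio(self, pH):
        return self.slope * np.asarray(pH, dtype=float) + self.intercept

    def to_dict(self) -> dict:
        d = {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "ph_range": list(self.ph_range),
            "sensor": self.sensor,
        }
        if self.per_ph is not None:
            d["per_ph"] = self.per_ph.to_dict(orient="list")
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationCurve":
        per_ph = pd.DataFrame(d["per_ph"]) if "per_ph" in d else None
        return cls(
            slope=d["slope"],
            intercept=d["intercept"],
            r_squared=d["r_squared"],
            ph_range=tuple(d["ph_range"]),
            per_ph=per_ph,
            sensor=d.get("sensor"),
        )

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path) -> "CalibrationCurve":
        return cls.from_dict(json.loads(Path(path).read_text()))


def per_endosome_log_ratio(region_table: pd.DataFrame) -> np.ndarray:
    """log10(mean_FP / mean_dye) per region.

    Regions with non-positive dye mean cannot be ratioed; they are dropped
    with a warning reporting the count.
    """
    fp = region_table["mean_ch1"].to_numpy(dtype=float)
    dye = region_table["mean_ch2"].to_numpy(dtype=float)
    ok = (dye > 0) & (fp > 0)
    n_bad = int((~ok).sum())
    if n_bad:
        warnings.warn(
            f"dropped {n_bad} region(s) with non-positive channel mean",
            stacklevel=2,
        )
    return np.log10(fp[ok] / dye[ok])


def fit_calibration(
    pH_values,
    log_ratios_per_pH,
    sensor: str | None = None,
) -> CalibrationCurve:
    """OLS fit of per-pH mean log-ratio against pH.

    Parameters
    ----------
    pH_values : sequence of float
        At least 3 distinct calibration pH values.
    log_ratios_per_pH : sequence of array-like
        Per-endosome log10 ratios for each pH value (>= 1 each).
    """
    pH_values = [float(p) for p in pH_values]
    if len(set(pH_values)) < 3:
        raise ValueError("need >= 3 distinct pH values to fit a calibration")
    if len(pH_values) != len(log_ratios_per_pH):
        raise ValueError("pH_values and log_ratios_per_pH lengths differ")
    rows = []
    for p, vals in zip(pH_values, log_ratios_per_pH):
        vals = np.asarray(vals, dtype=float)
        if vals.size < 1:
            raise ValueError(f"no log-ratios for pH {p}")
        rows.append(
            {
                "pH": p,
                "mean_log_ratio": float(vals.mean()),
                "sd_log_ratio": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                "sem_log_ratio": (
                    float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
                ),
                "n": int(vals.size),
            }
        )
    per_ph = pd.DataFrame(rows).sort_values("pH").reset_index(drop=True)
    res = stats.linregress(per_ph["pH"], per_ph["mean_log_ratio"])
    return CalibrationCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        ph_range=(min(pH_values), max(pH_values)),
        per_ph=per_ph,
        sensor=sensor,
    )


def invert_calibration(curve: CalibrationCurve, log_ratio):
    """pH estimate from a log10 ratio: (log_ratio - intercept) / slope.

    Values outside the calibration range are returned as-is; use
    ``curve.in_range`` to flag them (ratiometric variance grows rapidly
    outside the optimal pH range, so out-of-range estimates are unreliable).
    """
    if curve.slope == 0:
        raise ValueError("calibration slope is zero; cannot invert")
    out = (np.asarray(log_ratio, dtype=float) - curve.intercept) / curve.slope
    return float(out) if out.ndim == 0 else out


def empirical_dynamic_range(
    curve: CalibrationCurve, pH_high: float, pH_low: float
) -> float:
    """Fold change implied by the fitted slope: 10**(slope * (high - low))."""
    if not pH_high > pH_low:
        raise ValueError("pH_high must exceed pH_low")
    if not (curve.in_range(pH_high) and curve.in_range(pH_low)):
        raise ValueError("pH values outside the calibration range")
    return float(10.0 ** (curve.slope * (pH_high - pH_low)))
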