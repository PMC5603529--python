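"""pH-dependent fluorophore brightness models and sensor-level quantities.

A ratiometric pH sensor pairs an acid-quenched fluorescent protein (FP) with
an acid-stable organic dye.  The FP's brightness as a function of pH is
modelled as single-site protonation (Henderson-Hasselbalch form)

    B(pH) = floor + (1 - floor) / (1 + 10**(pKa - pH)),

so that at pH = pKa the fluorophore is at half of its saturated brightness.
Dyes default to a constant response; an empirical log-linear attenuation is
available for dyes with a mild measured pH dependence.  The sensor readout is
the FP/dye intensity ratio, which is intensity- and concentration-independent.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

__all__ = [
    "FluorophoreModel",
    "SensorModel",
    "protonation_fraction",
    "relative_brightness",
    "sensor_ratio",
    "dynamic_range",
    "FLUOROPHORES",
    "SENSORS",
    "get_sensor",
    "save_registry",
    "load_registry",
]

_MODES = ("protonation", "constant", "loglinear")


def protonation_fraction(pH, pKa):
    """Fraction of fluorophores in the bright (deprotonated) state.

    Single-site model: ``1 / (1 + 10**(pKa - pH))``.  Strictly increasing in
    pH, strictly decreasing in pKa, confined to (0, 1).

    Parameters
    ----------
    pH, pKa : float or array-like
        Finite pH values.

    Returns
    -------
    float or ndarray
    """
    pH = np.asarray(pH, dtype=float)
    pKa = np.asarray(pKa, dtype=float)
    if not (np.all(np.isfinite(pH)) and np.all(np.isfinite(pKa))):
        raise ValueError("pH and pKa must be finite")
    out = 1.0 / (1.0 + 10.0 ** (pKa - pH))
    if out.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class FluorophoreModel:
    """Parametric relative-brightness-vs-pH response of one fluorophore.

    Parameters
    ----------
    name : str
        Label (e.g. ``"EYFP"``).
    mode : {"protonation", "constant", "loglinear"}
        Functional form of the response.
    pKa : float, optional
        Midpoint of the protonation curve (protonation mode).
    acid_floor : float
        Residual brightness fraction at very low pH, in [0, 1)
        (protonation mode).
    slope : float, optional
        log10-brightness change per pH unit (loglinear mode).
    ref_pH : float
        Anchor pH of the loglinear response (brightness 1 there and above).
    brightness : float
        Relative peak channel brightness in arbitrary units (> 0); acts as an
        effective per-channel gain when rendering images.
    """

    name: str
    mode: str = "protonation"
    pKa: float | None = None
    acid_floor: float = 0.0
    slope: float | None = None
    ref_pH: float = 7.0
    brightness: float = 1.0

    def __post_init__(self):
        if self.mode not in _MODES:
            raise ValueError(f"unknown mode {self.mode!r}; expected one of {_MODES}")
        if self.mode == "protonation":
            if self.pKa is None or not math.isfinite(self.pKa):
                raise ValueError("protonation mode requires a finite pKa")
            if not 0.0 <= self.acid_floor < 1.0:
                raise ValueError("acid_floor must be in [0, 1)")
        if self.mode == "loglinear":
            if self.slope is None or not math.isfinite(self.slope):
                raise ValueError("loglinear mode requires a finite slope")
        if not self.brightness > 0:
            raise ValueError("brightness must be > 0")

    def response(self, pH):
        """Relative brightness at ``pH``, normalised so the maximum over the
        physiological range is 1 (values in (0, 1])."""
        pH = np.asarray(pH, dtype=float)
        if not np.all(np.isfinite(pH)):
            raise ValueError("pH must be finite")
        if self.mode == "constant":
            out = np.ones_like(pH)
        elif self.mode == "protonation":
            out = self.acid_floor + (1.0 - self.acid_floor) * (
                1.0 / (1.0 + 10.0 ** (self.pKa - pH))
            )
        else:  # loglinear, capped at the anchor
            out = np.minimum(1.0, 10.0 ** (self.slope * (pH - self.ref_pH)))
        return float(out) if out.ndim == 0 else out

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "FluorophoreModel":
        return cls(**d)


def relative_brightness(f: FluorophoreModel, pH, ref_pH) -> float:
    """Brightness at ``pH`` relative to the brightness at ``ref_pH``.

    For a constant-mode fluorophore this is 1 for all pH.  The reference
    brightness is strictly positive by model construction, so the ratio is
    always defined.
    """
    return f.response(pH) / f.response(ref_pH)


@dataclass(frozen=True)
class SensorModel:
    """An FP/dye pair: the ratiometric pH probe abstraction.

    ``fp`` is the acid-sensitive numerator channel, ``dye`` the acid-stable
    denominator channel.  ``bleed_through`` is the fraction of FP signal that
    leaks into the dye detection channel during imaging (it does not enter
    the idealised photophysical ratio).  ``label_ratio`` records the dye:protein
    labelling stoichiometry (metadata only).
    """

    name: str
    fp: FluorophoreModel
    dye: FluorophoreModel
    bleed_through: float = 0.05
    label_ratio: float = 2.0

    def __post_init__(self):
        if not 0.0 <= self.bleed_through < 1.0:
            raise ValueError("bleed_through must be in [0, 1)")
        if self.bleed_through > 0.1:
            raise ValueError("bleed_through above 10% is outside the modelled regime")
        if self.fp == self.dye:
            raise ValueError("fp and dye must be distinct models")

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "fp": self.fp.to_dict(),
            "dye": self.dye.to_dict(),
            "bleed_through": self.bleed_through,
            "label_ratio": self.label_ratio,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SensorModel":
        return cls(
            name=d["name"],
            fp=FluorophoreModel.from_dict(d["fp"]),
            dye=FluorophoreModel.from_dict(d["dye"]),
            bleed_through=d.get("bleed_through", 0.05),
            label_ratio=d.get("label_ratio", 2.0),
        )


def sensor_ratio(s: SensorModel, pH) -> float:
    """Idealised FP/dye brightness ratio at ``pH`` (bleed-through excluded)."""
    return s.fp.response(pH) / s.dye.response(pH)


def dynamic_range(s: SensorModel, pH_high: float, pH_low: float) -> float:
    """Fold change of the sensor ratio between ``pH_high`` and ``pH_low``.

    The defining figure of merit of a ratiometric sensor; always >= 1 for an
    acid-quenched numerator.
    """
    if not pH_high > pH_low:
        raise ValueError("pH_high must exceed pH_low")
    return sensor_ratio(s, pH_high) / sensor_ratio(s, pH_low)


# ---------------------------------------------------------------------------
# Default registry.
#
# FP pKa values: EYFP 6.9, EGFP 5.9, sepHluorin 7.1.  Dyes (Abberior STAR400/
# 410/512) are modelled as pH-constant; the mild in-solution attenuation of
# STAR410 (~37% residual at pH 5 vs 7) is available as an optional loglinear
# variant but is not the default.  FP brightness 2.0 vs dye 1.0 encodes the
# effective per-channel acquisition gain (the near-UV dye excitation line is
# kept weak in practice); it scales rendered images only.
# ---------------------------------------------------------------------------

_FP_GAIN = 2.0

FLUOROPHORES: dict[str, FluorophoreModel] = {
    "EYFP": FluorophoreModel("EYFP", mode="protonation", pKa=6.9, brightness=_FP_GAIN),
    "EGFP": FluorophoreModel("EGFP", mode="protonation", pKa=5.9, brightness=_FP_GAIN),
    "sepHluorin": FluorophoreModel(
        "sepHluorin", mode="protonation", pKa=7.1, brightness=_FP_GAIN
    ),
    "STAR400": FluorophoreModel("STAR400", mode="constant"),
    "STAR410": FluorophoreModel("STAR410", mode="constant"),
    "STAR512": FluorophoreModel("STAR512", mode="constant"),
    # log10(0.37)/(-2) per pH unit reproduces the 37% residual at pH 5 vs 7
    "STAR410-loglinear": FluorophoreModel(
        "STAR410-loglinear", mode="loglinear", slope=0.2158991379665025, ref_pH=7.0
    ),
}

SENSORS: dict[str, SensorModel] = {
    "SRpHi1": SensorModel("SRpHi1", FLUOROPHORES["EYFP"], FLUOROPHORES["STAR410"]),
    "SRpHi2": SensorModel("SRpHi2", FLUOROPHORES["EGFP"], FLUOROPHORES["STAR512"]),
    "SRpHi3": SensorModel("SRpHi3", FLUOROPHORES["sepHluorin"], FLUOROPHORES["STAR512"]),
    "SRpHi4": SensorModel("SRpHi4", FLUOROPHORES["EYFP"], FLUOROPHORES["STAR400"]),
}

#: Recommended calibration pH range (low, high) per sensor.
USABLE_PH_RANGE: dict[str, tuple[float, float]] = {
    "SRpHi1": (5.0, 7.0),
    "SRpHi2": (4.5, 6.5),
    "SRpHi3": (5.5, 7.5),
    "SRpHi4": (5.0, 7.0),
}


def get_sensor(name: str) -> SensorModel:
    try:
        return SENSORS[name]
    except KeyError:
        raise KeyError(
            f"unknown sensor {name!r}; available: {sorted(SENSORS)}"
        ) from None


def save_registry(path, sensors: dict[str, SensorModel] | None = None) -> None:
    """Write a sensor registry to JSON."""
    sensors = SENSORS if sensors is None else sensors
    payload = {name: s.to_dict() for name, s in sensors.items()}
    Path(path).write_text(json.dumps(payload, indent=2))


def load_registry(path) -> dict[str, SensorModel]:
    payload = json.loads(Path(path).read_text())
    return {name: SensorModel.from_dict(d) for name, d in payload.items()}
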