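"""Image container and TIFF/CSV/JSON persistence helpers."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile


@dataclass
class ImagePair:
    """A registered two-channel micrograph.

    ``fp`` is the fluorescent-protein (acid-sensitive) channel, ``dye`` the
    acid-stable reference channel.  Both are integer grayscale images of the
    same shape and bit depth.
    """

    fp: np.ndarray
    dye: np.ndarray
    pixel_size_nm: float
    bit_depth: int = 16

    def __post_init__(self):
        if self.fp.shape != self.dye.shape:
            raise ValueError("channel shapes differ")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if not self.pixel_size_nm > 0:
            raise ValueError("pixel_size_nm must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.fp.shape

    @property
    def max_value(self) -> int:
        return 2 ** self.bit_depth - 1

    def saturated(self) -> np.ndarray:
        """Boolean map of pixels saturated in either channel."""
        return (self.fp >= self.max_value) | (self.dye >= self.max_value)


def write_pair(pair: ImagePair, directory, prefix: str = "image") -> tuple[Path, Path]:
    """Write the two channels as grayscale TIFFs; returns the two paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    fp_path = directory / f"{prefix}_fp.tif"
    dye_path = directory / f"{prefix}_dye.tif"
    res = (1e7 / pair.pixel_size_nm, 1e7 / pair.pixel_size_nm)  # px per cm
    for path, chan in ((fp_path, pair.fp), (dye_path, pair.dye)):
        tifffile.imwrite(path, chan, resolution=res, resolutionunit="CENTIMETER")
    return fp_path, dye_path


def read_pair(fp_path, dye_path, pixel_size_nm: float) -> ImagePair:
    """Read two single-channel grayscale TIFFs into an :class:`ImagePair`."""
    fp = tifffile.imread(fp_path)
    dye = tifffile.imread(dye_path)
    bit_depth = 8 if fp.dtype == np.uint8 else 16
    return ImagePair(fp=fp, dye=dye, pixel_size_nm=pixel_size_nm, bit_depth=bit_depth)
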