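"""ROI-based quantification of in-vivo fluorescence images.

Converts an intensity-count image plus a manually traced region of
interest into the scalar signal-area measurement the trajectory model
consumes.  Images are first normalized to a fixed color scale (default
floor 337 counts, ceiling 1020 counts, set from autofluorescence-free
negative controls); a pixel counts toward the signal area when it lies
inside the ROI and strictly above the scale floor.  A generic
stained-area-fraction is provided for endpoint histology readouts such as
Oil red O staining.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

DEFAULT_SCALE_MIN = 337
DEFAULT_SCALE_MAX = 1020


@dataclass
class ImageFrame:
    """A 2-D intensity image with its ROI mask and color-scale bounds."""

    pixels: np.ndarray
    roi_mask: np.ndarray
    scale_min: int = DEFAULT_SCALE_MIN
    scale_max: int = DEFAULT_SCALE_MAX

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        self.roi_mask = np.asarray(self.roi_mask, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if self.pixels.shape != self.roi_mask.shape:
            raise ValueError("pixels and roi_mask shapes differ")
        if np.any(self.pixels < 0):
            raise ValueError("pixel counts must be non-negative")
        if self.scale_min >= self.scale_max:
            raise ValueError("scale_min must be < scale_max")


def normalize_scale(frame: ImageFrame) -> np.ndarray:
    """Map raw counts onto the fixed color scale.

    Returns ``clip((pixels - scale_min) / (scale_max - scale_min), 0, 1)``
    as floats; the scale floor maps to 0 and the ceiling to 1.
    """
    span = float(frame.scale_max - frame.scale_min)
    return np.clip((frame.pixels.astype(float) - frame.scale_min) / span,
                   0.0, 1.0)


def measure_signal_area(frame: ImageFrame) -> int:
    """Signal area in pixels: ROI pixels strictly above the scale floor.

    Pixels exactly at ``scale_min`` are background (negative controls show
    no autofluorescence at the floor) and do not count.  An all-false ROI
    yields 0 with a warning.
    """
    if not frame.roi_mask.any():
        warnings.warn("empty ROI mask: signal area is 0", stacklevel=2)
        return 0
    return int(np.count_nonzero(frame.roi_mask &
                                (frame.pixels > frame.scale_min)))


def stained_area_fraction(stained_mask: np.ndarray,
                          total_mask: np.ndarray) -> float:
    """Fraction of a tissue region covered by stain.

    ``|stained AND total| / |total|``; stained pixels outside the tissue
    region are ignored.
    """
    stained = np.asarray(stained_mask, dtype=bool)
    total = np.asarray(total_mask, dtype=bool)
    if stained.shape != total.shape:
        raise ValueError("stained_mask and total_mask shapes differ")
    denom = int(np.count_nonzero(total))
    if denom == 0:
        raise ValueError("total_mask has no true pixels")
    return float(np.count_nonzero(stained & total)) / denom


# ---------------------------------------------------------------------------
# image I/O (16-bit grayscale TIFF, or whitespace-delimited text matrix)

def read_image(path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile
        arr = tifffile.imread(path)
    else:
        arr = np.loadtxt(path, dtype=int)
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single 2-D image")
    return arr


def write_image(path, pixels: np.ndarray) -> None:
    path = Path(path)
    pixels = np.asarray(pixels)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile
        tifffile.imwrite(path, pixels.astype(np.uint16))
    else:
        np.savetxt(path, pixels.astype(int), fmt="%d")
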