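"""Standard CT muscle-quality metrics: fat/lean areas and lean attenuation.

These are the conventional comparison metrics: pixels above a fat
threshold count as lean tissue, the rest of the in-range soft tissue as
fat, with cross-sectional areas obtained by multiplying counts by the
per-pixel area.  Lean tissue attenuation is the mean HU of the
thresholded (lean) pixels.  The whole-section mean HU is emitted
alongside, since "average HU" conventions differ between studies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .radiodensity import DEFAULT_HU_RANGE, PixelSet

#: Upper edge of the fat attenuation domain — the "maximal density of fat".
DEFAULT_FAT_THRESHOLD = -10.0


@dataclass
class StandardCTMetrics:
    """Per-subject standard CT metrics (areas in mm², attenuations in HU)."""

    subject_id: str
    fat_area: float
    lean_area: float
    lean_mean_hu: float  # NaN when no lean pixels exist
    avg_hu: float
    fat_threshold: float

    @property
    def lean_defined(self) -> bool:
        return np.isfinite(self.lean_mean_hu)


def average_hu(
    pixels: PixelSet, hu_range: tuple[float, float] = DEFAULT_HU_RANGE
) -> float:
    """Arithmetic mean of all in-range soft-tissue HU values."""
    hu = pixels.as_hu().values
    if hu.size == 0:
        raise ValueError("empty pixel set")
    sel = (hu >= hu_range[0]) & (hu <= hu_range[1])
    if not np.any(sel):
        raise ValueError("no pixels inside the analysis range")
    return float(hu[sel].mean())


def standard_metrics(
    pixels: PixelSet,
    fat_threshold: float = DEFAULT_FAT_THRESHOLD,
    hu_range: tuple[float, float] = DEFAULT_HU_RANGE,
) -> StandardCTMetrics:
    """Threshold-based fat/lean segmentation of one cross-section.

    Lean = in-range pixels with HU strictly above ``fat_threshold``; fat =
    the remaining in-range pixels.  Areas are counts × ``pixel_area``.
    With no lean pixels the lean mean is NaN (flagged via
    ``lean_defined``), never silently zero.
    """
    p = pixels.as_hu()
    hu = p.values
    if hu.size == 0:
        raise ValueError("empty pixel set")
    in_range = (hu >= hu_range[0]) & (hu <= hu_range[1])
    hu = hu[in_range]
    lean = hu > fat_threshold
    lean_mean = float(hu[lean].mean()) if np.any(lean) else float("nan")
    return StandardCTMetrics(
        subject_id=p.subject_id,
        fat_area=float(np.sum(~lean)) * p.pixel_area,
        lean_area=float(np.sum(lean)) * p.pixel_area,
        lean_mean_hu=lean_mean,
        avg_hu=float(hu.mean()) if hu.size else float("nan"),
        fat_threshold=fat_threshold,
    )
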