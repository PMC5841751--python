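"""Radiodensity preprocessing: CT-number → HU conversion, binning, smoothing.

A subject's mid-thigh cross-section is reduced to the set of its
soft-tissue pixel values.  Raw CT numbers are mapped onto the Hounsfield
scale by the scanner's affine calibration, histogrammed over the
soft-tissue range (by default 128 bins spanning −200…200 HU, the union of
the fat, connective and muscle attenuation domains) and smoothed into an
empirical density curve that the trimodal model is fitted to.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

#: Affine CT-number → HU calibration used for the study scanner.
HU_SLOPE = 2.26625
HU_INTERCEPT = -190.0

#: Default analysis range: fat + connective + muscle attenuation domains.
DEFAULT_HU_RANGE = (-200.0, 200.0)
DEFAULT_N_BINS = 128


@dataclass
class PixelSet:
    """All soft-tissue pixel values of one subject's cross-section.

    Parameters
    ----------
    subject_id : str
        Opaque subject identifier.
    values : ndarray
        Pixel values, either raw CT numbers or HU depending on ``unit``.
    unit : {"ct_number", "hounsfield"}
        Determines whether the affine calibration still has to be applied
        (exactly once per pixel).
    pixel_area : float
        In-plane area of one pixel in mm²; enters cross-sectional areas.
    """

    subject_id: str
    values: np.ndarray
    unit: str = "hounsfield"
    pixel_area: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            self.values = self.values.ravel()
        if self.unit not in ("ct_number", "hounsfield"):
            raise ValueError(f"unknown pixel unit {self.unit!r}")
        if self.pixel_area <= 0:
            raise ValueError("pixel_area must be positive")

    def __len__(self) -> int:
        return self.values.size

    def as_hu(self) -> "PixelSet":
        """Return an equivalent PixelSet on the Hounsfield scale."""
        if self.unit == "hounsfield":
            return self
        return PixelSet(
            subject_id=self.subject_id,
            values=ct_to_hu(self.values),
            unit="hounsfield",
            pixel_area=self.pixel_area,
        )


@dataclass
class HUHistogram:
    """Fixed-width histogram of a subject's HU values plus smoothed density.

    ``density`` is ``None`` until :func:`smooth_histogram` fills it; it is
    either a unit-area probability density (``normalized=True``) or scaled
    so its integral equals the in-range pixel count.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    total_pixels: int
    n_below_range: int = 0
    n_above_range: int = 0
    density: np.ndarray | None = None
    normalized: bool = True
    bandwidth: float | None = None
    subject_id: str | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        widths = np.diff(self.bin_edges)
        if np.any(widths <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if not np.allclose(widths, widths[0], rtol=1e-9):
            raise ValueError("bins must be uniformly spaced")

    @property
    def n_bins(self) -> int:
        return self.counts.size

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def n_out_of_range(self) -> int:
        return self.n_below_range + self.n_above_range

    @property
    def n_in_range(self) -> int:
        return self.total_pixels - self.n_out_of_range


def ct_to_hu(values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Convert raw CT numbers to Hounsfield units.

    Applies the scanner calibration ``HU = CT × 2.26625 − 190`` elementwise,
    preserving order.  Non-finite inputs are rejected with the offending
    index named.
    """
    arr = np.asarray(values, dtype=float)
    bad = ~np.isfinite(arr)
    if np.any(bad):
        idx = int(np.flatnonzero(bad.ravel())[0])
        raise ValueError(f"non-finite CT number at index {idx}")
    return arr * HU_SLOPE + HU_INTERCEPT


def build_histogram(
    pixels: PixelSet,
    n_bins: int = DEFAULT_N_BINS,
    hu_range: tuple[float, float] = DEFAULT_HU_RANGE,
) -> HUHistogram:
    """Bin a subject's HU values into a fixed-width histogram.

    Bins are half-open ``[edge_i, edge_{i+1})`` with the last bin closed.
    Out-of-range pixels are counted and reported on the result, never
    silently dropped.
    """
    if len(pixels) == 0:
        raise ValueError("empty pixel set")
    if n_bins < 8:
        raise ValueError("n_bins must be >= 8")
    lo, hi = float(hu_range[0]), float(hu_range[1])
    if not lo < hi:
        raise ValueError(f"inverted hu_range ({lo}, {hi})")

    hu = pixels.as_hu().values
    counts, edges = np.histogram(hu, bins=n_bins, range=(lo, hi))
    return HUHistogram(
        bin_edges=edges,
        counts=counts.astype(float),
        total_pixels=hu.size,
        n_below_range=int(np.sum(hu < lo)),
        n_above_range=int(np.sum(hu > hi)),
        subject_id=pixels.subject_id,
    )


def smooth_histogram(
    hist: HUHistogram,
    bandwidth: float | str = "auto",
    normalize: bool = True,
) -> HUHistogram:
    """Smooth binned counts into an empirical density curve.

    A Gaussian kernel of standard deviation ``bandwidth`` (HU; ``"auto"`` =
    two bin widths) is convolved with the counts, and the result is rescaled
    so its trapezoidal integral equals exactly 1 (``normalize=True``) or the
    in-range pixel count.  The kernel choice is recorded in
    ``hist.metadata``.
    """
    if bandwidth == "auto":
        bw = 2.0 * hist.bin_width
    else:
        bw = float(bandwidth)
        if bw <= 0:
            raise ValueError("bandwidth must be positive")
    if hist.counts.sum() <= 0:
        raise ValueError("histogram has no in-range counts to smooth")

    sigma_bins = bw / hist.bin_width
    smoothed = gaussian_filter1d(hist.counts, sigma=sigma_bins, mode="constant")
    smoothed = np.clip(smoothed, 0.0, None)
    area = np.trapezoid(smoothed, hist.bin_centers)
    target = 1.0 if normalize else float(hist.counts.sum())
    density = smoothed * (target / area)

    return HUHistogram(
        bin_edges=hist.bin_edges,
        counts=hist.counts,
        total_pixels=hist.total_pixels,
        n_below_range=hist.n_below_range,
        n_above_range=hist.n_above_range,
        density=density,
        normalized=normalize,
        bandwidth=bw,
        subject_id=hist.subject_id,
        metadata={**hist.metadata, "smoothing": "gaussian_kernel", "bandwidth_hu": bw},
    )


# ---------------------------------------------------------------------------
# I/O helpers


def read_pixel_csv(
    path: str | Path,
    subject_id: str | None = None,
    unit: str = "hounsfield",
    pixel_area: float = 1.0,
) -> PixelSet:
    """Read a one-column delimited text file of pixel values."""
    path = Path(path)
    values = np.loadtxt(path, ndmin=1)
    return PixelSet(
        subject_id=subject_id or path.stem,
        values=values,
        unit=unit,
        pixel_area=pixel_area,
    )


def write_pixel_csv(pixels: PixelSet, path: str | Path) -> None:
    np.savetxt(Path(path), pixels.values, fmt="%.6g")


def read_dicom_pixels(
    path: str | Path,
    mask: np.ndarray | str | Path | None = None,
    subject_id: str | None = None,
) -> PixelSet:
    """Extract HU pixel values from a DICOM slice, optionally inside a mask.

    The DICOM rescale fields are used when present; otherwise the study
    scanner calibration is applied.  ``mask`` may be a boolean array or a
    path to a CSV of 0/1 of the same shape.
    """
    import pydicom

    path = Path(path)
    ds = pydicom.dcmread(str(path))
    raw = ds.pixel_array.astype(float)
    slope = float(getattr(ds, "RescaleSlope", np.nan))
    intercept = float(getattr(ds, "RescaleIntercept", np.nan))
    if np.isfinite(slope) and np.isfinite(intercept):
        hu = raw * slope + intercept
    else:
        hu = ct_to_hu(raw)

    if mask is not None:
        if isinstance(mask, (str, Path)):
            mask = np.loadtxt(Path(mask), delimiter=",") > 0.5
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != hu.shape:
            raise ValueError(
                f"mask shape {mask.shape} does not match image shape {hu.shape}"
            )
        hu = hu[mask]

    spacing = getattr(ds, "PixelSpacing", None)
    pixel_area = float(spacing[0]) * float(spacing[1]) if spacing else 1.0
    return PixelSet(
        subject_id=subject_id or path.stem,
        values=hu.ravel(),
        unit="hounsfield",
        pixel_area=pixel_area,
    )


def write_histogram_csv(hist: HUHistogram, path: str | Path) -> None:
    """Write a histogram as CSV: bin_left, bin_right, bin_center, count, density."""
    centers = hist.bin_centers
    density = hist.density if hist.density is not None else np.full(hist.n_bins, np.nan)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["bin_left", "bin_right", "bin_center", "count", "density"])
        for i in range(hist.n_bins):
            writer.writerow(
                [
                    f"{hist.bin_edges[i]:.6g}",
                    f"{hist.bin_edges[i + 1]:.6g}",
                    f"{centers[i]:.6g}",
                    f"{hist.counts[i]:.6g}",
                    f"{density[i]:.10g}",
                ]
            )
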