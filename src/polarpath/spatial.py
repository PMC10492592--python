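"""Spatial analysis of backscattered polarimetric images.

The central observable is the per-pixel mean number of scattering events of
detected photons, ``N = (event total) / (photon count)`` — a proxy for
sampling depth: less-scattered light has, on average, penetrated less deeply.
Aggregating N over a region gives ``Npp`` ("scattering events per photon per
pixel", the mean of N over the region's pixels), and the percent reduction of
a region's Npp against the full-image Npp quantifies how much shallower the
sampling becomes when only that region is read out.

Regions are specified in physical millimetres on the detector plane, and
rectangle/lobe orientations are measured *relative to the incident
polarization axis* (whose image-frame angle each simulation result records),
because the four-lobed backscatter patterns are tied to the incident
polarization vector rather than to the pixel axes.  A pixel belongs to a
region when its centre falls inside (no partial-area weighting), which makes
every aggregate an exact, enumerable mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "ImageGeometry",
    "RegionSpec",
    "ScatterCountMap",
    "RegionMetric",
    "RadialProfile",
    "LobeProfile",
    "scatter_count_map",
    "region_mask",
    "region_npp",
    "radial_profile",
    "compare_rectangle_orientations",
    "lobe_profile",
    "sum_intensity",
]


@dataclass(frozen=True)
class ImageGeometry:
    """Physical calibration of a detector image.

    The image spans ``field_mm`` in x and ``field_mm * ny / nx`` in y (square
    pixels), centred on the beam axis at (0, 0).  ``pol_axis_deg`` is the
    image-frame angle (deg CCW from +x) of the incident polarization vector;
    region orientation angles are measured from that axis.
    """

    nx: int
    ny: int
    field_mm: float
    pol_axis_deg: float = -45.0

    def __post_init__(self) -> None:
        if self.nx < 1 or self.ny < 1:
            raise ValueError("pixel counts must be >= 1")
        if not self.field_mm > 0:
            raise ValueError("field_mm must be > 0")

    @property
    def pixel_pitch_mm(self) -> float:
        return self.field_mm / self.nx

    def pixel_centers_mm(self) -> Tuple[np.ndarray, np.ndarray]:
        """(X, Y) arrays of pixel-centre coordinates, shape (ny, nx), in mm."""
        p = self.pixel_pitch_mm
        x = (np.arange(self.nx) + 0.5) * p - 0.5 * self.field_mm
        y = (np.arange(self.ny) + 0.5) * p - 0.5 * p * self.ny
        return np.meshgrid(x, y)

    @classmethod
    def from_result(cls, result) -> "ImageGeometry":
        det = result.detector
        return cls(
            nx=det.nx,
            ny=det.ny,
            field_mm=det.field_mm,
            pol_axis_deg=result.pol_axis_deg,
        )


@dataclass(frozen=True)
class RegionSpec:
    """Disc, oriented rectangle or full-image region in physical coordinates.

    ``angle_deg`` (rectangles) is measured from the incident-polarization
    axis, normalized to [0, 180); 90 deg is the axis perpendicular to the
    incident polarization vector.
    """

    kind: str  # "disc" | "oriented_rectangle" | "full_image"
    center_mm: Tuple[float, float] = (0.0, 0.0)
    diameter_mm: Optional[float] = None
    length_mm: Optional[float] = None
    width_mm: Optional[float] = None
    angle_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("disc", "oriented_rectangle", "full_image"):
            raise ValueError(f"unknown region kind {self.kind!r}")
        if self.kind == "disc":
            if self.diameter_mm is None or not self.diameter_mm > 0:
                raise ValueError("disc requires diameter_mm > 0")
        if self.kind == "oriented_rectangle":
            if self.length_mm is None or not self.length_mm > 0:
                raise ValueError("oriented_rectangle requires length_mm > 0")
            if self.width_mm is None or not self.width_mm > 0:
                raise ValueError("oriented_rectangle requires width_mm > 0")
        object.__setattr__(self, "angle_deg", float(self.angle_deg) % 180.0)

    def describe(self) -> str:
        if self.kind == "full_image":
            return "full_image"
        if self.kind == "disc":
            return f"disc(d={self.diameter_mm}mm)"
        return (
            f"rect(l={self.length_mm}mm,w={self.width_mm}mm,"
            f"angle={self.angle_deg}deg)"
        )


@dataclass(frozen=True)
class ScatterCountMap:
    """Per-pixel mean scattering-event count with a validity mask.

    Pixels with fewer detected photons than the chosen minimum are masked and
    excluded from every aggregate (a per-pixel ratio estimator is unstable at
    tiny counts).
    """

    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask must share a shape")


@dataclass(frozen=True)
class RegionMetric:
    """Npp aggregate of a region plus its reduction against the full image."""

    npp: float
    pixel_count: int
    reduction_vs_full: float  # percent, 100 * (1 - npp_region / npp_full)


@dataclass(frozen=True)
class RadialProfile:
    """Azimuthally averaged profile; empty bins carry NaN."""

    bin_centers_mm: np.ndarray
    mean: np.ndarray
    n_pixels: np.ndarray


@dataclass(frozen=True)
class LobeProfile:
    """Azimuthal intensity histogram within an annulus, with detected peaks.

    Angles are degrees relative to the incident-polarization axis, in
    [0, 360).  ``peaks_deg`` are local maxima of the circularly smoothed
    profile that exceed its circular mean, sorted by angle.
    """

    bin_centers_deg: np.ndarray
    mean_intensity: np.ndarray
    peaks_deg: np.ndarray
    peak_heights: np.ndarray


def scatter_count_map(
    event_totals: np.ndarray, photon_counts: np.ndarray, min_photons: float = 5
) -> ScatterCountMap:
    """Per-pixel N = event totals / photon counts, masked below ``min_photons``.

    Works both with unweighted tallies (integer counts) and with
    intensity-weighted channel tallies, where ``photon_counts`` is the channel
    intensity image (photon-equivalent units for unit-weight packets).
    """
    event_totals = np.asarray(event_totals, dtype=float)
    photon_counts = np.asarray(photon_counts, dtype=float)
    if event_totals.shape != photon_counts.shape:
        raise ValueError("event_totals and photon_counts must share a shape")
    mask = photon_counts >= max(min_photons, np.finfo(float).tiny)
    values = np.zeros_like(event_totals)
    np.divide(event_totals, photon_counts, out=values, where=mask)
    return ScatterCountMap(values=values, mask=mask)


def region_mask(region: RegionSpec, geom: ImageGeometry) -> np.ndarray:
    """Boolean pixel-centre-inclusion mask of a region."""
    if region.kind == "full_image":
        return np.ones((geom.ny, geom.nx), dtype=bool)
    X, Y = geom.pixel_centers_mm()
    dx = X - region.center_mm[0]
    dy = Y - region.center_mm[1]
    if region.kind == "disc":
        return dx * dx + dy * dy <= (0.5 * region.diameter_mm) ** 2
    # oriented rectangle: image-frame angle = polarization axis + offset
    alpha = math.radians(geom.pol_axis_deg + region.angle_deg)
    ca, sa = math.cos(alpha), math.sin(alpha)
    along = ca * dx + sa * dy
    across = -sa * dx + ca * dy
    return (np.abs(along) <= 0.5 * region.length_mm) & (
        np.abs(across) <= 0.5 * region.width_mm
    )


def region_npp(
    nmap: ScatterCountMap, region: RegionSpec, geom: ImageGeometry
) -> RegionMetric:
    """Mean N over the region's valid pixels, and its percent reduction.

    The reduction baseline is the full-image Npp of the same map (mean over
    all valid pixels).  Raises when the region covers no valid pixel.
    """
    if nmap.values.shape != (geom.ny, geom.nx):
        raise ValueError("map shape does not match the geometry")
    sel = region_mask(region, geom) & nmap.mask
    n_sel = int(np.count_nonzero(sel))
    if n_sel == 0:
        raise ValueError("region contains no valid pixel")
    npp = float(nmap.values[sel].mean())
    full = float(nmap.values[nmap.mask].mean())
    reduction = 100.0 * (1.0 - npp / full) if full != 0 else 0.0
    return RegionMetric(npp=npp, pixel_count=n_sel, reduction_vs_full=reduction)


def radial_profile(
    values: np.ndarray,
    geom: ImageGeometry,
    bin_width_mm: Optional[float] = None,
    center_mm: Tuple[float, float] = (0.0, 0.0),
    mask: Optional[np.ndarray] = None,
) -> RadialProfile:
    """Mean of ``values`` over annular bins [r, r + dr) around ``center_mm``.

    Default bin width is one pixel pitch.  Bins without valid pixels are NaN.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != (geom.ny, geom.nx):
        raise ValueError("image shape does not match the geometry")
    if mask is None:
        mask = np.ones_like(values, dtype=bool)
    dr = bin_width_mm if bin_width_mm is not None else geom.pixel_pitch_mm
    if not dr > 0:
        raise ValueError("bin_width_mm must be > 0")
    X, Y = geom.pixel_centers_mm()
    r = np.hypot(X - center_mm[0], Y - center_mm[1])
    idx = np.floor(r / dr).astype(int)
    nbins = int(idx[mask].max()) + 1 if mask.any() else 0
    sums = np.bincount(idx[mask], weights=values[mask], minlength=nbins)
    counts = np.bincount(idx[mask], minlength=nbins)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    centers = (np.arange(nbins) + 0.5) * dr
    return RadialProfile(bin_centers_mm=centers, mean=mean, n_pixels=counts)


def compare_rectangle_orientations(
    nmap: ScatterCountMap,
    geom: ImageGeometry,
    length_mm: float,
    width_mm: float,
    angles_deg: Sequence[float],
    center_mm: Tuple[float, float] = (0.0, 0.0),
) -> pd.DataFrame:
    """Sweep one rectangle over orientation angles about the beam centre.

    Angles are degrees from the incident-polarization axis.  Returns a tidy
    frame with one row per angle: ``angle_deg, npp, pixel_count,
    reduction_pct``.
    """
    rows = []
    for angle in angles_deg:
        region = RegionSpec(
            "oriented_rectangle",
            center_mm=center_mm,
            length_mm=length_mm,
            width_mm=width_mm,
            angle_deg=angle,
        )
        metric = region_npp(nmap, region, geom)
        rows.append(
            {
                "angle_deg": float(angle) % 180.0,
                "npp": metric.npp,
                "pixel_count": metric.pixel_count,
                "reduction_pct": metric.reduction_vs_full,
            }
        )
    return pd.DataFrame(rows)


def _circular_smooth(values: np.ndarray, half_window: int = 1) -> np.ndarray:
    out = values.copy()
    n = values.size
    k = 2 * half_window + 1
    acc = np.zeros(n)
    cnt = np.zeros(n)
    for off in range(-half_window, half_window + 1):
        rolled = np.roll(values, off)
        ok = np.isfinite(rolled)
        acc[ok] += rolled[ok]
        cnt += ok
    with np.errstate(invalid="ignore"):
        out = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    return out


def lobe_profile(
    image: np.ndarray,
    geom: ImageGeometry,
    r_inner_mm: float,
    r_outer_mm: float,
    n_bins: int = 72,
    mask: Optional[np.ndarray] = None,
) -> LobeProfile:
    """Azimuthal mean-intensity histogram of an annulus, with peak detection.

    The azimuth of each pixel is taken relative to the incident-polarization
    axis, so four-lobed patterns report peaks at 0/90/180/270 deg (lobes on
    the parallel and perpendicular axes) or at 45/135/225/315 deg.  Peaks are
    local maxima of the 3-bin circularly smoothed profile that exceed the
    profile's mean; ties broken toward larger amplitude by construction.
    """
    image = np.asarray(image, dtype=float)
    if image.shape != (geom.ny, geom.nx):
        raise ValueError("image shape does not match the geometry")
    if not 0 <= r_inner_mm < r_outer_mm:
        raise ValueError("annulus radii must satisfy 0 <= inner < outer")
    if n_bins < 4:
        raise ValueError("need at least 4 azimuthal bins")
    if mask is None:
        mask = np.ones_like(image, dtype=bool)
    X, Y = geom.pixel_centers_mm()
    r = np.hypot(X, Y)
    sel = (r >= r_inner_mm) & (r < r_outer_mm) & mask
    if not sel.any():
        raise ValueError("annulus contains no valid pixel")
    az = np.degrees(np.arctan2(Y, X)) - geom.pol_axis_deg
    az = np.mod(az, 360.0)
    idx = np.minimum((az / (360.0 / n_bins)).astype(int), n_bins - 1)
    sums = np.bincount(idx[sel], weights=image[sel], minlength=n_bins)
    counts = np.bincount(idx[sel], minlength=n_bins)
    with np.errstate(invalid="ignore"):
        prof = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    smooth = _circular_smooth(prof, half_window=1)
    level = np.nanmean(smooth)
    filled = np.where(np.isfinite(smooth), smooth, -np.inf)
    prev = np.roll(filled, 1)
    nxt = np.roll(filled, -1)
    is_peak = (filled > prev) & (filled >= nxt) & (filled > level)
    centers = (np.arange(n_bins) + 0.5) * (360.0 / n_bins)
    return LobeProfile(
        bin_centers_deg=centers,
        mean_intensity=prof,
        peaks_deg=centers[is_peak],
        peak_heights=filled[is_peak],
    )


def sum_intensity(
    image: np.ndarray,
    region: RegionSpec,
    geom: ImageGeometry,
    mask: Optional[np.ndarray] = None,
) -> float:
    """Sum of pixel values whose centres fall inside the region."""
    image = np.asarray(image, dtype=float)
    if image.shape != (geom.ny, geom.nx):
        raise ValueError("image shape does not match the geometry")
    sel = region_mask(region, geom)
    if mask is not None:
        sel &= mask
    if not sel.any():
        raise ValueError("region contains no pixel")
    return float(image[sel].sum())
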