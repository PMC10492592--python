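"""Two-group differentiation statistics for co-linear / cross-circular imaging.

Demineralized (acid-etched) enamel roughens the tooth surface and makes the
sub-surface more strongly scattering, so the reflection-like orthogonalized
component of backscattered light drops: both the co-linear and the
cross-circular channel intensities are expected to be lower on a
demineralized surface than on sound enamel.  This module quantifies that
separation with region-of-interest intensity sums and a t-score

    t = (xbar_1 - xbar_2) / sqrt( S^2 (1/n_1 + 1/n_2) )

where S is the standard deviation of *all* the data points pooled across both
groups (a deliberately simple spread estimate; the classical pooled-variance
form is available as an option).  Because the depth-gating effect is
concentrated near the illumination spot, interior regions — the 3 mm
illumination disc for circular light and its intersection with a 1.5 mm-wide
rectangle perpendicular to the incident polarization for linear light — are
expected to separate the groups more strongly than full-image sums.

A synthetic image generator stands in for tooth measurements so the pipeline
is testable end to end: images are a bright, radially decaying illumination
core over a broader diffuse background, with a per-spot multiplicative
log-normal heterogeneity (shared between the two channels of a spot) and
additive detector noise.  The demineralized class scales the core down by a
per-channel reduction factor; the depolarized background is class-independent
by default, which is what concentrates the class contrast in the interior.
The generator is synthetic: it emulates the direction and geometry of the
effect, not enamel microstructure.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field as dc_field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .spatial import ImageGeometry, RegionSpec, region_mask, sum_intensity

__all__ = [
    "Measurement",
    "TScoreResult",
    "SyntheticToothConfig",
    "ToothImageSet",
    "t_score",
    "roi_metric_battery",
    "polarimetric_map",
    "generate_synthetic_tooth_set",
    "METRIC_NAMES",
]

TOOTH_CHANNELS = ("co_linear", "cross_circular")

METRIC_NAMES = (
    "co_linear_full",
    "co_linear_interior_perpendicular",
    "cross_circular_full",
    "cross_circular_interior_disc",
    "pooled_interior",
)


@dataclass(frozen=True)
class Measurement:
    """One ROI-summed intensity reading from one spot on one sample side."""

    sample_id: str
    side: str  # "normal" | "acidified"
    acid_min: float
    channel: str  # "co_linear" | "cross_circular"
    roi: str
    sum_intensity: float

    def __post_init__(self) -> None:
        if self.side not in ("normal", "acidified"):
            raise ValueError("side must be 'normal' or 'acidified'")
        if self.sum_intensity < 0:
            raise ValueError("sum_intensity must be >= 0")


@dataclass(frozen=True)
class TScoreResult:
    """Group means, pooled spread and the resulting t-score.

    ``p_value`` is a convenience interpretation: two-sided from Student's t
    with ``n1 + n2 - 2`` degrees of freedom.
    """

    mean1: float
    mean2: float
    pooled_std: float
    n1: int
    n2: int
    t: float
    df: int
    p_value: float


def t_score(
    group1: Sequence[float],
    group2: Sequence[float],
    method: str = "all_pooled",
) -> TScoreResult:
    """Two-group t-score with an all-data pooled standard deviation.

    ``method='all_pooled'`` (default) takes S as the sample standard deviation
    of the union of both groups; ``method='classical'`` uses the classical
    pooled-variance estimate.  When every data point is identical (S = 0) the
    score is reported as 0 with a RuntimeWarning instead of dividing by zero.
    """
    x1 = np.asarray(group1, dtype=float)
    x2 = np.asarray(group2, dtype=float)
    if x1.size < 2 or x2.size < 2:
        raise ValueError("each group needs at least 2 data points")
    n1, n2 = x1.size, x2.size
    if method == "all_pooled":
        s = float(np.std(np.concatenate([x1, x2]), ddof=1))
    elif method == "classical":
        s = math.sqrt(
            ((n1 - 1) * np.var(x1, ddof=1) + (n2 - 1) * np.var(x2, ddof=1))
            / (n1 + n2 - 2)
        )
    else:
        raise ValueError("method must be 'all_pooled' or 'classical'")
    diff = float(np.mean(x1) - np.mean(x2))
    if s == 0.0:
        warnings.warn("zero pooled standard deviation; t reported as 0", RuntimeWarning)
        t = 0.0
    else:
        t = diff / (s * math.sqrt(1.0 / n1 + 1.0 / n2))
    df = n1 + n2 - 2
    p = float(2.0 * stats.t.sf(abs(t), df)) if s > 0 else 1.0
    return TScoreResult(
        mean1=float(np.mean(x1)),
        mean2=float(np.mean(x2)),
        pooled_std=s,
        n1=n1,
        n2=n2,
        t=t,
        df=df,
        p_value=p,
    )


# --------------------------------------------------------------------------
# synthetic tooth image sets
# --------------------------------------------------------------------------


def _default_core_amplitude() -> Dict[str, float]:
    return {"co_linear": 1000.0, "cross_circular": 800.0}


def _default_background_amplitude() -> Dict[str, float]:
    return {"co_linear": 250.0, "cross_circular": 200.0}


def _default_reduction() -> Dict[str, float]:
    return {"co_linear": 0.6, "cross_circular": 0.6}


@dataclass
class SyntheticToothConfig:
    """Configuration of the synthetic normal/demineralized image generator.

    The intensity model per spot and channel is::

        image = (core_amp * f_core * exp(-r^2 / 2 sigma_core^2)
                 + bg_amp * f_bg * exp(-r^2 / 2 sigma_bg^2)) * h + noise

    with ``h ~ LogNormal(0, heterogeneity_scale)`` one scalar per spot shared
    by both channels (spot-to-spot variability: positioning, local surface
    condition), additive pixel noise ``N(0, noise_scale)`` clipped at zero,
    and class factors ``f_core = reduction_factor[channel]``,
    ``f_bg = background_reduction`` on the acidified side (both 1 on the
    normal side).  Defaults follow the measurement design of seven teeth with
    two spots per side (28 data points) and a 3 mm illumination core.
    """

    n_samples: int = 7
    spots_per_side: int = 2
    nx: int = 64
    field_mm: float = 10.0
    core_sigma_mm: float = 1.0
    background_sigma_mm: float = 4.0
    core_amplitude: Dict[str, float] = dc_field(default_factory=_default_core_amplitude)
    background_amplitude: Dict[str, float] = dc_field(
        default_factory=_default_background_amplitude
    )
    reduction_factor: Dict[str, float] = dc_field(default_factory=_default_reduction)
    background_reduction: float = 1.0
    heterogeneity_scale: float = 0.15
    noise_scale: float = 2.0
    acid_min: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.spots_per_side < 1:
            raise ValueError("sample and spot counts must be >= 1")
        for ch in TOOTH_CHANNELS:
            f = self.reduction_factor[ch]
            if not 0.0 < f <= 1.0:
                raise ValueError("reduction factors must lie in (0, 1]")
        if not 0.0 < self.background_reduction <= 1.0:
            raise ValueError("background_reduction must lie in (0, 1]")
        if self.heterogeneity_scale < 0 or self.noise_scale < 0:
            raise ValueError("noise scales must be >= 0")

    @property
    def geometry(self) -> ImageGeometry:
        return ImageGeometry(
            nx=self.nx, ny=self.nx, field_mm=self.field_mm, pol_axis_deg=-45.0
        )


@dataclass
class ToothImageSet:
    """Labelled co-linear / cross-circular image pairs per sample-side spot."""

    geometry: ImageGeometry
    images: Dict[Tuple[str, str, int, str], np.ndarray]
    config: SyntheticToothConfig

    def spots(self) -> List[Tuple[str, str, int]]:
        seen: List[Tuple[str, str, int]] = []
        for sample, side, spot, _ in self.images:
            key = (sample, side, spot)
            if key not in seen:
                seen.append(key)
        return seen

    def image(self, sample: str, side: str, spot: int, channel: str) -> np.ndarray:
        return self.images[(sample, side, spot, channel)]


def generate_synthetic_tooth_set(config: SyntheticToothConfig) -> ToothImageSet:
    """Draw a deterministic synthetic normal/acidified polarimetric image set."""
    rng = np.random.default_rng(config.seed)
    geom = config.geometry
    X, Y = geom.pixel_centers_mm()
    r2 = X * X + Y * Y
    core_shape = np.exp(-r2 / (2.0 * config.core_sigma_mm**2))
    bg_shape = np.exp(-r2 / (2.0 * config.background_sigma_mm**2))
    images: Dict[Tuple[str, str, int, str], np.ndarray] = {}
    for i in range(config.n_samples):
        sample = f"tooth{i + 1:02d}"
        for side in ("normal", "acidified"):
            for spot in range(config.spots_per_side):
                h = math.exp(rng.normal(0.0, config.heterogeneity_scale))
                for ch in TOOTH_CHANNELS:
                    f_core = (
                        config.reduction_factor[ch] if side == "acidified" else 1.0
                    )
                    f_bg = (
                        config.background_reduction if side == "acidified" else 1.0
                    )
                    signal = (
                        config.core_amplitude[ch] * f_core * core_shape
                        + config.background_amplitude[ch] * f_bg * bg_shape
                    ) * h
                    noisy = signal + rng.normal(0.0, config.noise_scale, signal.shape)
                    images[(sample, side, spot, ch)] = np.clip(noisy, 0.0, None)
    return ToothImageSet(geometry=geom, images=images, config=config)


# --------------------------------------------------------------------------
# the five-metric battery and the polarimetric map
# --------------------------------------------------------------------------


def _interior_regions(
    beam_diameter_mm: float, rect_width_mm: float
) -> Tuple[RegionSpec, RegionSpec, RegionSpec]:
    """(full, disc, perpendicular rectangle) region set used by the battery."""
    full = RegionSpec("full_image")
    disc = RegionSpec("disc", diameter_mm=beam_diameter_mm)
    rect = RegionSpec(
        "oriented_rectangle",
        length_mm=beam_diameter_mm,
        width_mm=rect_width_mm,
        angle_deg=90.0,
    )
    return full, disc, rect


@dataclass(frozen=True)
class MetricFamily:
    """One ROI metric: per-spot sums for both groups and their t-score."""

    name: str
    channel: str
    region: str
    normal: np.ndarray
    acidified: np.ndarray
    t: TScoreResult


def roi_metric_battery(
    image_set: ToothImageSet,
    beam_diameter_mm: float = 3.0,
    rect_width_mm: float = 1.5,
    method: str = "all_pooled",
) -> Dict[str, MetricFamily]:
    """The five intensity metrics separating normal from acidified sides.

    (a) co-linear full-image sum; (b) co-linear sum over the interior
    perpendicular region (illumination disc intersected with a rectangle of
    half the disc diameter in width, perpendicular to the incident
    polarization); (c) cross-circular full-image sum; (d) cross-circular
    illumination-disc sum; (e) the union of the (b) and (d) data points as one
    doubled-size sample per group.  Each family carries its
    normal-vs-acidified t-score.
    """
    geom = image_set.geometry
    full, disc, rect = _interior_regions(beam_diameter_mm, rect_width_mm)
    disc_mask = region_mask(disc, geom)
    interior_rect_mask = disc_mask & region_mask(rect, geom)

    def spot_sums(channel: str, mask: Optional[np.ndarray]) -> Dict[str, List[float]]:
        out: Dict[str, List[float]] = {"normal": [], "acidified": []}
        for sample, side, spot in image_set.spots():
            img = image_set.image(sample, side, spot, channel)
            if channel not in TOOTH_CHANNELS:
                raise KeyError(channel)
            val = float(img[mask].sum()) if mask is not None else float(img.sum())
            out[side].append(val)
        return out

    for sample, side, spot in image_set.spots():
        for ch in TOOTH_CHANNELS:
            if (sample, side, spot, ch) not in image_set.images:
                raise KeyError(
                    f"spot ({sample}, {side}, {spot}) is missing channel {ch}"
                )

    specs = {
        "co_linear_full": ("co_linear", "full_image", None),
        "co_linear_interior_perpendicular": (
            "co_linear",
            "disc&perpendicular_rect",
            interior_rect_mask,
        ),
        "cross_circular_full": ("cross_circular", "full_image", None),
        "cross_circular_interior_disc": ("cross_circular", "disc", disc_mask),
    }
    families: Dict[str, MetricFamily] = {}
    for name, (channel, region_desc, mask) in specs.items():
        sums = spot_sums(channel, mask)
        normal = np.asarray(sums["normal"])
        acid = np.asarray(sums["acidified"])
        families[name] = MetricFamily(
            name=name,
            channel=channel,
            region=region_desc,
            normal=normal,
            acidified=acid,
            t=t_score(normal, acid, method=method),
        )
    b = families["co_linear_interior_perpendicular"]
    d = families["cross_circular_interior_disc"]
    normal = np.concatenate([b.normal, d.normal])
    acid = np.concatenate([b.acidified, d.acidified])
    families["pooled_interior"] = MetricFamily(
        name="pooled_interior",
        channel="co_linear+cross_circular",
        region="interior regions pooled",
        normal=normal,
        acidified=acid,
        t=t_score(normal, acid, method=method),
    )
    return families


@dataclass(frozen=True)
class PolarimetricMap:
    """Per-spot (co-linear, cross-circular) intensity pairs with class labels."""

    points: pd.DataFrame  # sample_id, side, spot, co_linear, cross_circular
    separability_accuracy: float
    axis: np.ndarray  # first principal axis (unit 2-vector)
    threshold: float  # separating threshold on the principal-axis score


def _best_threshold_accuracy(
    scores: np.ndarray, labels: np.ndarray
) -> Tuple[float, float]:
    """Best single-threshold classification accuracy along a 1-D score."""
    order = np.argsort(scores)
    s = scores[order]
    y = labels[order]
    n = y.size
    best_acc, best_thr = 0.0, float(s[0]) - 1.0
    cuts = np.concatenate([[s[0] - 1.0], 0.5 * (s[1:] + s[:-1]), [s[-1] + 1.0]])
    for thr in cuts:
        pred = s > thr
        acc = max(np.mean(pred == y), np.mean(pred == ~y))
        if acc > best_acc:
            best_acc, best_thr = float(acc), float(thr)
    return best_acc, best_thr


def polarimetric_map(
    image_set: ToothImageSet,
    region: Optional[RegionSpec] = None,
) -> PolarimetricMap:
    """Pair each spot's co-linear and cross-circular sums into a 2-D map.

    Each measured spot contributes one (x, y) = (co-linear, cross-circular)
    point.  The separation summary projects the points on their first
    principal axis and reports the best single-threshold accuracy between the
    normal and acidified classes.
    """
    geom = image_set.geometry
    region = region or RegionSpec("full_image")
    rows = []
    for sample, side, spot in image_set.spots():
        vals = {}
        for ch in TOOTH_CHANNELS:
            if (sample, side, spot, ch) not in image_set.images:
                raise KeyError(f"spot ({sample}, {side}, {spot}) lacks channel {ch}")
            vals[ch] = sum_intensity(image_set.image(sample, side, spot, ch), region, geom)
        rows.append(
            {
                "sample_id": sample,
                "side": side,
                "spot": spot,
                "co_linear": vals["co_linear"],
                "cross_circular": vals["cross_circular"],
            }
        )
    points = pd.DataFrame(rows)
    xy = points[["co_linear", "cross_circular"]].to_numpy()
    centred = xy - xy.mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    axis = vt[0]
    scores = centred @ axis
    labels = (points["side"] == "acidified").to_numpy()
    acc, thr = _best_threshold_accuracy(scores, labels)
    return PolarimetricMap(
        points=points, separability_accuracy=acc, axis=axis, threshold=thr
    )


def battery_summary(families: Mapping[str, MetricFamily]) -> pd.DataFrame:
    """Tidy per-metric summary table (one row per metric family)."""
    rows = []
    for name in METRIC_NAMES:
        fam = families[name]
        rows.append(
            {
                "metric": name,
                "channel": fam.channel,
                "region": fam.region,
                "n_normal": fam.t.n1,
                "n_acidified": fam.t.n2,
                "mean_normal": fam.t.mean1,
                "mean_acidified": fam.t.mean2,
                "pooled_std": fam.t.pooled_std,
                "t_score": fam.t.t,
                "p_value": fam.t.p_value,
            }
        )
    return pd.DataFrame(rows)
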