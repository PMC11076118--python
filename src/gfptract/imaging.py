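"""Fluorescence micrograph quantification.

Implements the measurement chain used to score GFP-sperm occupancy in
two-channel (green/GFP + red/autofluorescence) micrographs of the insect
female reproductive tract:

1. rolling-ball background subtraction of each channel,
2. estimation of a green/red crosstalk ("correction") factor from a
   sperm-free reference region drawn on autofluorescent chitin,
3. scaled subtraction of the red channel from the green channel,
4. intermodes histogram thresholding of the corrected image within a
   polygon region of interest (ROI),
5. occupancy metrics: mean/median intensity, percentage cover of
   above-threshold pixels, and a presence flag.

Images are 14-bit greyscale (values in [0, 16383]) stored as 16-bit
arrays. Polygon ROIs use 0-based pixel coordinates with x rightward and
y downward; a pixel belongs to a ROI iff its centre (x + 0.5, y + 0.5)
lies inside the polygon (even-odd rule).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from functools import lru_cache

import numpy as np
from matplotlib.path import Path as MplPath
from scipy import ndimage
from shapely.geometry import Polygon as ShapelyPolygon

MAX_14BIT = 2**14 - 1

SITE_TOTAL_TRACT = "total_tract"
SITE_SPERMATHECA = "spermatheca"
LABEL_REFERENCE = "autofluorescence_reference"


class ImagingError(ValueError):
    """Base class for quantification failures."""


class DegeneratePolygonError(ImagingError):
    """Polygon has < 3 vertices, zero area, or self-intersects."""


class ReferenceROIError(ImagingError):
    """Autofluorescence reference ROI unusable (red signal ~ 0)."""


class BimodalityError(ImagingError):
    """Intensity histogram never reached exactly two modes."""

    def __init__(self, message: str, n_modes: int | None = None,
                 iterations: int | None = None):
        super().__init__(message)
        self.n_modes = n_modes
        self.iterations = iterations


@dataclass(frozen=True)
class PolygonROI:
    """Labelled closed polygon in 0-based pixel coordinates."""

    label: str
    vertices: np.ndarray  # (n, 2) array of (x, y)

    def __post_init__(self):
        verts = np.asarray(self.vertices, dtype=float)
        if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 3:
            raise DegeneratePolygonError(
                f"ROI '{self.label}' needs >= 3 (x, y) vertices"
            )
        object.__setattr__(self, "vertices", verts)
        poly = ShapelyPolygon(verts)
        if not poly.is_valid or poly.area <= 0:
            raise DegeneratePolygonError(
                f"ROI '{self.label}' is degenerate or self-intersecting"
            )

    @property
    def shapely(self) -> ShapelyPolygon:
        return ShapelyPolygon(self.vertices)

    def scaled(self, factor: float, label: str | None = None) -> "PolygonROI":
        """Shrink/grow about the centroid (used to inset reference ROIs)."""
        c = np.asarray(self.shapely.centroid.coords[0])
        return PolygonROI(label or self.label, c + factor * (self.vertices - c))

    def translated(self, dx: float, dy: float) -> "PolygonROI":
        return PolygonROI(self.label, self.vertices + np.array([dx, dy]))


@dataclass
class ChannelStack:
    """One sample's bright-field + green (GFP) + red (autofluorescence) images.

    Green is collected at 520 +/- 18 nm, red at 624 +/- 20 nm. All channels
    share shape; intensities live on the 14-bit scale.
    """

    brightfield: np.ndarray
    green: np.ndarray
    red: np.ndarray
    bit_depth: int = 14
    exposure_ms: Mapping[str, float] = field(
        default_factory=lambda: {"brightfield": 5.0, "green": 100.0, "red": 150.0}
    )
    site_context: str = SITE_TOTAL_TRACT

    def __post_init__(self):
        shapes = {self.brightfield.shape, self.green.shape, self.red.shape}
        if len(shapes) != 1:
            raise ImagingError("channel shapes differ")
        top = 2**self.bit_depth - 1
        for name in ("brightfield", "green", "red"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.min() < 0 or arr.max() > top:
                raise ImagingError(
                    f"{name} intensities outside [0, {top}]"
                )
            setattr(self, name, arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.green.shape


@dataclass(frozen=True)
class CorrectionFactor:
    """Green/red intensity ratio of autofluorescent (sperm-free) material."""

    int_gfp: float
    int_auto: float

    @property
    def factor(self) -> float:
        return self.int_gfp / self.int_auto


@dataclass(frozen=True)
class OccupancyMetrics:
    """Per-ROI occupancy readout of a corrected GFP image."""

    mean_intensity: float
    median_intensity: float
    percent_cover: float
    presence: bool
    threshold_value: float | None
    roi_area_px: int
    threshold_failed: bool = False


@dataclass(frozen=True)
class QuantConfig:
    """Tunables of the quantification chain."""

    rolling_ball_radius: int = 25
    n_bins: int = 256
    max_smooth_iter: int = 10_000
    min_component_px: int = 4        # "observable" presence criterion
    reference_epsilon: float = 1e-6
    threshold_fallback: str = "empty"  # unimodal histogram => blank tract


def rasterize_roi(roi: PolygonROI, image_shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixels whose centres fall inside the polygon.

    Raises if any vertex lies outside the image bounds or the resulting
    mask is empty.
    """
    h, w = image_shape
    verts = roi.vertices
    if (verts[:, 0].min() < 0 or verts[:, 0].max() > w
            or verts[:, 1].min() < 0 or verts[:, 1].max() > h):
        raise ImagingError(
            f"ROI '{roi.label}' extends outside image of shape {image_shape}"
        )
    ys, xs = np.mgrid[0:h, 0:w]
    centres = np.column_stack([xs.ravel() + 0.5, ys.ravel() + 0.5])
    ring = np.vstack([verts, verts[:1]])
    mask = MplPath(ring).contains_points(centres).reshape(h, w)
    if not mask.any():
        raise DegeneratePolygonError(
            f"ROI '{roi.label}' rasterizes to an empty mask"
        )
    return mask


@lru_cache(maxsize=8)
def _ball_element(radius: int):
    y, x = np.mgrid[-radius:radius + 1, -radius:radius + 1]
    d2 = radius**2 - x**2 - y**2
    footprint = d2 >= 0
    height = np.sqrt(np.maximum(d2, 0.0))
    return height, footprint


def subtract_background(channel: np.ndarray, radius: int = 25) -> np.ndarray:
    """Rolling-ball background subtraction.

    The background is the grayscale opening of the image with a
    ball-shaped structuring element of the given radius — the classical
    rolling-ball definition: erosion then dilation with the ball height
    profile, restricted to the image domain. The background is
    subtracted and negatives are clipped to zero, so the output never
    exceeds the input.
    """
    channel = np.asarray(channel, dtype=float)
    if radius < 1:
        raise ImagingError("rolling-ball radius must be >= 1")
    if 2 * radius + 1 > min(channel.shape):
        raise ImagingError(
            f"rolling-ball radius {radius} too large for image {channel.shape}"
        )
    height, footprint = _ball_element(int(radius))
    eroded = ndimage.grey_erosion(channel, structure=height,
                                  footprint=footprint,
                                  mode="constant", cval=np.inf)
    background = ndimage.grey_dilation(eroded, structure=height,
                                       footprint=footprint,
                                       mode="constant", cval=-np.inf)
    background = np.clip(background, 0, None)
    return np.clip(channel - background, 0, None)


def compute_correction_factor(
    stack: ChannelStack,
    ref_roi: PolygonROI,
    epsilon: float = 1e-6,
) -> CorrectionFactor:
    """Green/red mean-intensity ratio inside the sperm-free reference ROI.

    Int_GFP and Int_Auto are arithmetic means of the (already
    background-subtracted) green and red channels over the rasterized
    reference ROI; the correction factor is Int_GFP / Int_Auto.
    """
    if ref_roi.label != LABEL_REFERENCE:
        raise ImagingError(
            f"reference ROI must be labelled '{LABEL_REFERENCE}', got '{ref_roi.label}'"
        )
    mask = rasterize_roi(ref_roi, stack.shape)
    int_gfp = float(stack.green[mask].mean())
    int_auto = float(stack.red[mask].mean())
    if int_auto <= epsilon:
        raise ReferenceROIError(
            f"reference ROI red intensity {int_auto:.3g} <= {epsilon:g}; "
            "cannot form a correction factor"
        )
    return CorrectionFactor(int_gfp=int_gfp, int_auto=int_auto)


def correct_autofluorescence(
    green: np.ndarray, red: np.ndarray, cf: CorrectionFactor
) -> np.ndarray:
    """Remove autofluorescence crosstalk: max(green - factor * red, 0)."""
    green = np.asarray(green, dtype=float)
    red = np.asarray(red, dtype=float)
    if green.shape != red.shape:
        raise ImagingError(f"shape mismatch: {green.shape} vs {red.shape}")
    return np.clip(green - cf.factor * red, 0, None)


def _local_maxima_runs(h: np.ndarray) -> list[int]:
    """Indices (run centres) of local maxima of a histogram, plateau-aware."""
    padded = np.concatenate([[-np.inf], h, [-np.inf]])
    maxima: list[int] = []
    i = 1
    n = len(h)
    while i <= n:
        j = i
        while j + 1 <= n and padded[j + 1] == padded[i]:
            j += 1
        if padded[i - 1] < padded[i] and padded[j + 1] < padded[i]:
            maxima.append((i + j) // 2 - 1)  # back to 0-based histogram index
        i = j + 1
    return maxima


def intermodes_threshold(
    image: np.ndarray,
    roi_mask: np.ndarray | None = None,
    *,
    n_bins: int = 256,
    value_range: tuple[float, float] = (0.0, 2.0**14),
    max_iter: int = 10_000,
) -> float:
    """Intermodes threshold of the masked intensity histogram.

    The 14-bit intensities are binned linearly into ``n_bins`` bins over
    the full scale. The histogram is repeatedly smoothed with a 3-point
    moving mean until exactly two local maxima remain; the threshold is
    the intensity at the midpoint of the two mode bins. Histograms that
    are unimodal (or never become bimodal within ``max_iter``
    smoothings) raise :class:`BimodalityError`.
    """
    vals = image[roi_mask] if roi_mask is not None else np.ravel(image)
    if vals.size == 0:
        raise ImagingError("empty mask")
    if np.unique(vals).size < 2:
        raise BimodalityError("fewer than two distinct intensities", n_modes=1)
    hist, edges = np.histogram(vals, bins=n_bins, range=value_range)
    centres = (edges[:-1] + edges[1:]) / 2.0
    h = hist.astype(float)
    kernel = np.array([1.0, 1.0, 1.0]) / 3.0
    for it in range(max_iter + 1):
        maxima = _local_maxima_runs(h)
        if len(maxima) == 2:
            return float((centres[maxima[0]] + centres[maxima[1]]) / 2.0)
        if len(maxima) < 2:
            raise BimodalityError(
                f"histogram unimodal after {it} smoothing iterations",
                n_modes=len(maxima), iterations=it,
            )
        h = np.convolve(h, kernel, mode="same")
    raise BimodalityError(
        f"histogram still has {len(maxima)} modes after {max_iter} iterations",
        n_modes=len(maxima), iterations=max_iter,
    )


def occupancy_metrics(
    corrected: np.ndarray,
    roi: PolygonROI,
    config: QuantConfig = QuantConfig(),
) -> OccupancyMetrics:
    """Occupancy metrics of a crosstalk-corrected GFP image within a ROI.

    Mean and median are taken over all ROI pixels. Percentage cover is
    the fraction of ROI pixels strictly above the intermodes threshold,
    times 100. Presence requires at least one 8-connected
    above-threshold component of >= ``min_component_px`` pixels. A
    unimodal histogram (a blank tract) falls back to zero cover with the
    failure flagged.
    """
    mask = rasterize_roi(roi, corrected.shape)
    vals = corrected[mask]
    area = int(mask.sum())
    mean_i = float(vals.mean())
    median_i = float(np.median(vals))
    try:
        thr = intermodes_threshold(
            corrected, mask, n_bins=config.n_bins, max_iter=config.max_smooth_iter
        )
        failed = False
    except BimodalityError:
        if config.threshold_fallback != "empty":
            raise
        return OccupancyMetrics(
            mean_intensity=mean_i, median_intensity=median_i,
            percent_cover=0.0, presence=False, threshold_value=None,
            roi_area_px=area, threshold_failed=True,
        )
    above = (corrected > thr) & mask
    cover = 100.0 * above.sum() / area
    labels, n_comp = ndimage.label(above, structure=np.ones((3, 3), dtype=int))
    presence = False
    if n_comp:
        sizes = np.bincount(labels.ravel())[1:]
        presence = bool((sizes >= config.min_component_px).any())
    return OccupancyMetrics(
        mean_intensity=mean_i, median_intensity=median_i,
        percent_cover=float(cover), presence=presence,
        threshold_value=float(thr), roi_area_px=area, threshold_failed=failed,
    )


@dataclass(frozen=True)
class SampleQuantification:
    """Per-site metrics plus the intermediate scalars of the chain."""

    metrics: dict[str, OccupancyMetrics]
    correction: CorrectionFactor
    log: dict


def quantify_sample(
    stack: ChannelStack,
    rois: Sequence[PolygonROI] | Mapping[str, PolygonROI],
    config: QuantConfig = QuantConfig(),
) -> SampleQuantification:
    """Run the full quantification chain on one sample.

    Fixed order: background-subtract green and red, estimate the
    correction factor from the reference ROI, subtract the scaled red
    channel from green, then score occupancy in the total-tract and
    spermatheca ROIs. The returned log records every intermediate
    scalar (Int_GFP, Int_Auto, factor, per-site thresholds).
    """
    if not isinstance(rois, Mapping):
        rois = {r.label: r for r in rois}
    required = {SITE_TOTAL_TRACT, SITE_SPERMATHECA, LABEL_REFERENCE}
    missing = required - set(rois)
    if missing:
        raise ImagingError(f"missing ROIs: {sorted(missing)}")

    green_bs = subtract_background(stack.green, config.rolling_ball_radius)
    red_bs = subtract_background(stack.red, config.rolling_ball_radius)
    bs_stack = ChannelStack(
        brightfield=stack.brightfield, green=green_bs, red=red_bs,
        bit_depth=stack.bit_depth, exposure_ms=stack.exposure_ms,
        site_context=stack.site_context,
    )
    cf = compute_correction_factor(
        bs_stack, rois[LABEL_REFERENCE], epsilon=config.reference_epsilon
    )
    corrected = correct_autofluorescence(green_bs, red_bs, cf)

    metrics: dict[str, OccupancyMetrics] = {}
    log: dict = {
        "int_gfp": cf.int_gfp,
        "int_auto": cf.int_auto,
        "correction_factor": cf.factor,
        "rolling_ball_radius": config.rolling_ball_radius,
        "sites": {},
    }
    for site in (SITE_TOTAL_TRACT, SITE_SPERMATHECA):
        m = occupancy_metrics(corrected, rois[site], config)
        metrics[site] = m
        log["sites"][site] = {
            "threshold": m.threshold_value,
            "threshold_failed": m.threshold_failed,
            "roi_area_px": m.roi_area_px,
        }
    return SampleQuantification(metrics=metrics, correction=cf, log=log)
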