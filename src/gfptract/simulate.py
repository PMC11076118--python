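"""Ground-truthed synthetic data for the occupancy pipeline.

Two generators:

* :func:`simulate_tract_image` renders a two-channel micrograph of a
  stylized female reproductive tract — punctate GFP sperm-head
  fluorescence in the green channel, chitinous structures fluorescing in
  both channels with a fixed green/red crosstalk ratio, smooth uneven
  illumination, and shot + read noise — together with polygon ROIs and a
  truth record (punctum positions, true sperm mask, injected crosstalk).

* :func:`simulate_experiment` / :func:`simulate_paternity` draw
  per-female occupancy and paternity observations under the 2 (male
  thermal treatment) x 2 (female mating status) x 2 (time point)
  factorial design, with multiplicative treatment effects on the
  response scale and beta-binomially overdispersed proportions.

All randomness flows through ``numpy.random.default_rng(seed)``; a fixed
seed fully determines every output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from shapely.geometry import Point, Polygon as ShapelyPolygon

from .imaging import (
    LABEL_REFERENCE,
    MAX_14BIT,
    SITE_SPERMATHECA,
    SITE_TOTAL_TRACT,
    ChannelStack,
    PolygonROI,
    rasterize_roi,
)

SITES = (SITE_TOTAL_TRACT, SITE_SPERMATHECA)
FACTORS = ("thermal", "female_status", "time")
LEVELS = {
    "thermal": ("control", "heat"),          # 30 C control vs 5-day 41 C
    "female_status": ("virgin", "mated"),    # prior mating to a competitor
    "time": ("30min", "24h"),                # delay before flash-freezing
}

RENDER_CUTOFF_SIGMA = 4.0  # spot truncated (exactly zero) beyond this


def footprint_radius(sigma: float, sharpness: float) -> float:
    """Radius of a punctum's footprint (pixels above 10% of its peak).

    Spots are super-Gaussian, ``A * exp(-(d^2 / 2 sigma^2)^m)``; the 10%
    level sits at ``sigma * sqrt(2) * ln(10)^(1/2m)``.
    """
    return sigma * math.sqrt(2.0) * math.log(10.0) ** (1.0 / (2.0 * sharpness))


class SimulationError(ValueError):
    pass


class ReferencePlacementError(SimulationError):
    """No punctum-free reference ROI could be placed inside a chitin structure."""


# --------------------------------------------------------------------------
# Imaging simulator
# --------------------------------------------------------------------------

def _regular_polygon(cx: float, cy: float, rx: float, ry: float, n: int = 12,
                     phase: float = 0.0) -> np.ndarray:
    ang = phase + np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([cx + rx * np.cos(ang), cy + ry * np.sin(ang)])


def default_scene(image_shape: tuple[int, int]):
    """Deterministic scene geometry scaled to the image.

    Returns (tract polygon, spermatheca polygon, chitin structures) where
    chitin structures are (vertices, red_amplitude) pairs: a 'chitin ring'
    at the base of the spermathecal duct (inside the tract) and an
    ovipositor-like wedge near the posterior edge.
    """
    h, w = image_shape
    s = min(h, w)
    tract = _regular_polygon(0.50 * w, 0.55 * h, 0.42 * w, 0.38 * h, n=16)
    sperm = _regular_polygon(0.30 * w, 0.30 * h, 0.07 * s, 0.07 * s, n=8)
    ring = _regular_polygon(0.44 * w, 0.42 * h, 0.085 * s, 0.075 * s, n=8,
                            phase=0.3)
    ovi = np.array([
        [0.40 * w, 0.90 * h],
        [0.60 * w, 0.90 * h],
        [0.64 * w, 0.985 * h],
        [0.36 * w, 0.985 * h],
    ])
    chitin = [(ring, 3000.0), (ovi, 2500.0)]
    return tract, sperm, chitin


@dataclass
class ImagingParams:
    """Knobs of the micrograph simulator (14-bit intensity scale)."""

    image_shape: tuple[int, int] = (128, 128)
    n_puncta: int = 40
    n_puncta_spermatheca: int = 0  # extra puncta confined to the spermatheca
    punctum_amplitude_range: tuple[float, float] = (3000.0, 6000.0)
    # relative brightness of the spermatheca-confined puncta (lets the two
    # storage sites carry different density signals in one scene)
    punctum_amplitude_scale_spermatheca: float = 1.0
    punctum_sigma: float = 2.0
    # super-Gaussian order of the spot profile; sperm heads image as
    # small flat-topped blobs, not soft Gaussian halos
    punctum_sharpness: float = 8.0
    chitin_structures: list[tuple[np.ndarray, float]] | None = None
    crosstalk_k: float = 0.3
    illumination_field: tuple[float, ...] = (1.0, 0.04, -0.03, -0.06, -0.05, 0.02)
    diffuse_autofluorescence: float = 150.0
    poisson_gain: float = 1.0     # intensity units per detected photon; 0 = off
    read_noise_sd: float = 10.0   # Gaussian read noise; 0 = off
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.punctum_amplitude_range
        if not (0 <= lo <= hi <= MAX_14BIT):
            raise SimulationError("punctum amplitudes must lie in the 14-bit range")
        if self.crosstalk_k <= 0:
            raise SimulationError("crosstalk_k must be > 0")
        if self.n_puncta < 0 or self.n_puncta_spermatheca < 0:
            raise SimulationError("punctum counts must be >= 0")
        if self.punctum_sigma <= 0:
            raise SimulationError("punctum_sigma must be > 0")

    @property
    def noise_enabled(self) -> bool:
        return self.poisson_gain > 0 or self.read_noise_sd > 0


@dataclass
class ImagingTruth:
    """Ground truth behind one simulated micrograph."""

    punctum_coordinates: np.ndarray   # (n, 2) of (x, y)
    punctum_amplitudes: np.ndarray
    crosstalk_k: float
    background_field: np.ndarray      # smooth green background (no puncta/chitin)
    true_sperm_mask: np.ndarray       # union of punctum footprints
    true_cover_percent: dict[str, float]


def _illumination(shape: tuple[int, int], coeffs: tuple[float, ...]) -> np.ndarray:
    h, w = shape
    y, x = np.mgrid[0:h, 0:w]
    X = 2.0 * x / max(w - 1, 1) - 1.0
    Y = 2.0 * y / max(h - 1, 1) - 1.0
    c00, c10, c01, c20, c02, c11 = coeffs
    field = c00 + c10 * X + c01 * Y + c20 * X**2 + c02 * Y**2 + c11 * X * Y
    if field.min() <= 0:
        raise SimulationError("illumination field must be strictly positive")
    return field


def _render_puncta(shape, coords, amps, sigma, sharpness):
    """Truncated super-Gaussian spots and their >=10%-of-peak footprint mask."""
    h, w = shape
    img = np.zeros(shape)
    mask = np.zeros(shape, dtype=bool)
    r = int(math.ceil(RENDER_CUTOFF_SIGMA * sigma))
    fr2 = footprint_radius(sigma, sharpness) ** 2
    cut2 = (RENDER_CUTOFF_SIGMA * sigma) ** 2
    for (x0, y0), a in zip(coords, amps):
        xi, yi = int(round(x0)), int(round(y0))
        x_lo, x_hi = max(xi - r, 0), min(xi + r + 1, w)
        y_lo, y_hi = max(yi - r, 0), min(yi + r + 1, h)
        yy, xx = np.mgrid[y_lo:y_hi, x_lo:x_hi]
        d2 = (xx + 0.5 - x0) ** 2 + (yy + 0.5 - y0) ** 2
        spot = a * np.exp(-((d2 / (2.0 * sigma**2)) ** sharpness))
        spot[d2 > cut2] = 0.0
        # overlapping heads occlude rather than add in projection
        np.maximum(img[y_lo:y_hi, x_lo:x_hi], spot,
                   out=img[y_lo:y_hi, x_lo:x_hi])
        mask[y_lo:y_hi, x_lo:x_hi] |= d2 <= fr2
    return img, mask


def _sample_in_mask(rng, mask, n, amp_range):
    """Positions and amplitudes for n puncta, drawn punctum by punctum.

    Exactly four uniform draws per punctum, so a scene with more puncta
    extends (rather than reshuffles) the scene with fewer: occupancy is
    then monotone in punctum count by construction in noise-free mode.
    """
    idx = np.flatnonzero(mask)
    if idx.size == 0 and n > 0:
        raise SimulationError("placement region rasterizes to an empty mask")
    lo, hi = amp_range
    coords = np.empty((n, 2))
    amps = np.empty(n)
    for i in range(n):
        flat = idx[int(rng.random() * idx.size)]
        y, x = np.unravel_index(flat, mask.shape)
        coords[i] = (x + rng.random(), y + rng.random())
        amps[i] = lo + (hi - lo) * rng.random()
    return coords, amps


def _apply_noise(rng, img, params: ImagingParams) -> np.ndarray:
    out = img
    if params.poisson_gain > 0:
        out = rng.poisson(out / params.poisson_gain) * params.poisson_gain
    if params.read_noise_sd > 0:
        out = out + rng.normal(0.0, params.read_noise_sd, size=img.shape)
    out = np.clip(out, 0, MAX_14BIT)
    if params.noise_enabled:
        out = np.round(out)  # quantized like acquired 14-bit data
    return out


def simulate_tract_image(
    params: ImagingParams,
) -> tuple[ChannelStack, list[PolygonROI], ImagingTruth]:
    """Render one sample: (channels, [tract/spermatheca/reference ROIs], truth).

    The clean physical model is::

        green = illumination * (puncta + crosstalk_k * red_structures)
        red   = illumination * red_structures

    where red_structures combines sharp chitin polygons with a smooth
    diffuse tissue autofluorescence; noise (Poisson shot + Gaussian
    read) and 14-bit clipping/quantization are applied afterwards. The
    reference ROI is placed entirely inside the first chitin structure
    and is guaranteed punctum-free (every punctum's rendered support is
    strictly outside it); if that fails after bounded retries a
    :class:`ReferencePlacementError` is raised.
    """
    rng = np.random.default_rng(params.seed)
    shape = params.image_shape
    tract_v, sperm_v, default_chitin = default_scene(shape)
    chitin = params.chitin_structures
    if chitin is None:
        chitin = default_chitin

    tract_roi = PolygonROI(SITE_TOTAL_TRACT, tract_v)
    sperm_roi = PolygonROI(SITE_SPERMATHECA, sperm_v)
    tract_mask = rasterize_roi(tract_roi, shape)
    sperm_mask = rasterize_roi(sperm_roi, shape)

    # puncta: uniform over the tract, plus optional spermatheca-confined
    # ones. The first chitin structure hosts the reference ROI; sperm
    # avoid it (that is what makes it usable as a sperm-free reference),
    # so puncta keep a clearance from it when space allows.
    clearance = RENDER_CUTOFF_SIGMA * params.punctum_sigma + 1.0
    host_poly = np.asarray(chitin[0][0])
    host_mask = rasterize_roi(PolygonROI("chitin_host", host_poly), shape)
    far_enough = ndimage.distance_transform_edt(~host_mask) > clearance + 1.5

    def _placement(mask):
        trimmed = mask & far_enough
        return trimmed if trimmed.any() else mask

    coords, amps = _sample_in_mask(rng, _placement(tract_mask),
                                   params.n_puncta,
                                   params.punctum_amplitude_range)
    if params.n_puncta_spermatheca:
        extra_c, extra_a = _sample_in_mask(rng, _placement(sperm_mask),
                                           params.n_puncta_spermatheca,
                                           params.punctum_amplitude_range)
        extra_a = extra_a * params.punctum_amplitude_scale_spermatheca
        coords = np.vstack([coords, extra_c])
        amps = np.concatenate([amps, extra_a])
    amps = np.clip(amps, 0, MAX_14BIT)
    puncta_img, sperm_head_mask = _render_puncta(
        shape, coords, amps, params.punctum_sigma, params.punctum_sharpness
    )

    # reference ROI: inset polygon inside the first chitin structure,
    # jittered until no punctum's rendered support can touch it
    ref_base = PolygonROI(LABEL_REFERENCE, host_poly).scaled(0.45)
    host = ShapelyPolygon(host_poly)
    ref_roi = None
    span = 0.35 * math.sqrt(host.area)
    for attempt in range(60):
        if attempt == 0:
            cand = ref_base
        else:
            dx, dy = rng.uniform(-span, span, size=2)
            cand = ref_base.translated(dx, dy)
        cpoly = cand.shapely
        if not host.contains(cpoly):
            continue
        if len(coords) == 0 or all(
            cpoly.distance(Point(x, y)) >= clearance for x, y in coords
        ):
            ref_roi = cand
            break
    if ref_roi is None:
        raise ReferencePlacementError(
            "could not place a punctum-free reference ROI after 60 attempts"
        )

    # channel rendering
    chitin_img = np.zeros(shape)
    for verts, amp in chitin:
        chitin_img += amp * rasterize_roi(
            PolygonROI("chitin", np.asarray(verts)), shape
        )
    chitin_img = ndimage.gaussian_filter(chitin_img, 1.0)
    diffuse = params.diffuse_autofluorescence * ndimage.gaussian_filter(
        tract_mask.astype(float), 8.0
    )
    red_struct = chitin_img + diffuse
    illum = _illumination(shape, params.illumination_field)

    green = illum * (puncta_img + params.crosstalk_k * red_struct)
    red = illum * red_struct
    brightfield = illum * (4000.0 + 4000.0 * ndimage.gaussian_filter(
        tract_mask.astype(float), 3.0
    ) + 0.5 * chitin_img)

    green = _apply_noise(rng, np.clip(green, 0, MAX_14BIT), params)
    red = _apply_noise(rng, np.clip(red, 0, MAX_14BIT), params)
    brightfield = _apply_noise(rng, np.clip(brightfield, 0, MAX_14BIT), params)

    stack = ChannelStack(brightfield=brightfield, green=green, red=red)
    truth = ImagingTruth(
        punctum_coordinates=coords,
        punctum_amplitudes=amps,
        crosstalk_k=params.crosstalk_k,
        background_field=illum * params.crosstalk_k * diffuse,
        true_sperm_mask=sperm_head_mask,
        true_cover_percent={
            SITE_TOTAL_TRACT:
                100.0 * (sperm_head_mask & tract_mask).sum() / tract_mask.sum(),
            SITE_SPERMATHECA:
                100.0 * (sperm_head_mask & sperm_mask).sum() / sperm_mask.sum(),
        },
    )
    return stack, [tract_roi, sperm_roi, ref_roi], truth


# --------------------------------------------------------------------------
# Factorial experiment simulator
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DesignSpec:
    """Cell sizes of the 2x2x2 design.

    ``cell_sizes`` follows the canonical display order: time point
    outermost (30min then 24h), female mating status next (virgin then
    mated), thermal treatment innermost (control then heat).
    """

    cell_sizes: tuple[int, ...] = (23, 25, 24, 25, 22, 24, 23, 24)

    def __post_init__(self):
        if len(self.cell_sizes) != 8 or any(n < 1 for n in self.cell_sizes):
            raise SimulationError("need 8 cell sizes, all >= 1")

    def cells(self) -> Iterator[tuple[dict[str, str], int]]:
        i = 0
        for time in LEVELS["time"]:
            for status in LEVELS["female_status"]:
                for thermal in LEVELS["thermal"]:
                    yield (
                        {"thermal": thermal, "female_status": status, "time": time},
                        self.cell_sizes[i],
                    )
                    i += 1

    @property
    def n_females(self) -> int:
        return sum(self.cell_sizes)


def _site_dict(tract: float, sperm: float) -> dict[str, float]:
    return {SITE_TOTAL_TRACT: tract, SITE_SPERMATHECA: sperm}


@dataclass
class EffectSpec:
    """Generative parameters of the simulated experiment.

    Multiplicative factor effects act on the response scale (expected
    cover proportion, expected mean intensity); 1.0 means no effect.
    Default effect sizes are the study-scale conditions (heat reduces
    tract cover by 32% and intensity by 21%; storage time reduces them
    by 72%/65%; in the spermatheca heat gives -34%/-36% and a prior
    competitor -70%/-58%; paternity odds shift -1.66, i.e. 63% lower P2
    from a 0.60 baseline). Overdispersion parameters are beta-binomial
    intraclass correlations.
    """

    baseline_cover: dict[str, float] = field(
        default_factory=lambda: _site_dict(40.0, 35.0))      # percent
    baseline_intensity: dict[str, float] = field(
        default_factory=lambda: _site_dict(3000.0, 2500.0))  # 14-bit units
    cover_effects: dict[str, dict[str, float]] = field(default_factory=lambda: {
        "thermal": _site_dict(0.68, 0.66),
        "female_status": _site_dict(1.0, 0.30),
        "time": _site_dict(0.28, 1.0),
    })
    intensity_effects: dict[str, dict[str, float]] = field(default_factory=lambda: {
        "thermal": _site_dict(0.79, 0.64),
        "female_status": _site_dict(1.0, 0.42),
        "time": _site_dict(0.35, 1.0),
    })
    cover_overdispersion: float = 0.05
    intensity_noise_sd: float = 500.0
    paternity_baseline: float = 0.60
    paternity_effect: float = -1.66
    paternity_overdispersion: float = 0.10
    brood_size_mean: float = 30.0

    def __post_init__(self):
        for site, b in self.baseline_cover.items():
            if not 0 < b < 100:
                raise SimulationError(f"baseline cover for {site} outside (0, 100)")
        for rho in (self.cover_overdispersion, self.paternity_overdispersion):
            if not 0 <= rho < 1:
                raise SimulationError("overdispersion must lie in [0, 1)")
        if not 0 < self.paternity_baseline < 1:
            raise SimulationError("paternity baseline outside (0, 1)")

    @classmethod
    def null(cls, **overrides) -> "EffectSpec":
        """All factor effects 1.0 (overdispersion kept unless overridden)."""
        ones = {f: _site_dict(1.0, 1.0) for f in FACTORS}
        spec = cls(cover_effects=ones,
                   intensity_effects={f: _site_dict(1.0, 1.0) for f in FACTORS},
                   paternity_effect=0.0)
        return replace(spec, **overrides)

    def expected_cover(self, cell: dict[str, str], site: str) -> float:
        """Expected cover proportion (0-1 scale) for one design cell."""
        p = self.baseline_cover[site] / 100.0
        for f in FACTORS:
            if cell[f] != LEVELS[f][0]:
                p *= self.cover_effects[f][site]
        if not 0 < p < 1:
            raise SimulationError(
                f"expected cover proportion {p:.3f} outside (0, 1) for {cell}"
            )
        return p

    def expected_intensity(self, cell: dict[str, str], site: str) -> float:
        mu = self.baseline_intensity[site]
        for f in FACTORS:
            if cell[f] != LEVELS[f][0]:
                mu *= self.intensity_effects[f][site]
        return mu


def _beta_binomial(rng, n: int, p: float, rho: float) -> int:
    if rho == 0:
        return int(rng.binomial(n, p))
    theta = (1.0 - rho) / rho
    pi = rng.beta(p * theta, (1.0 - p) * theta)
    return int(rng.binomial(n, pi))


def _beta_binomial_array(rng, n: int, p: float, rho: float,
                         size: int) -> np.ndarray:
    if rho == 0:
        return rng.binomial(n, p, size=size)
    theta = (1.0 - rho) / rho
    pi = rng.beta(p * theta, (1.0 - p) * theta, size=size)
    return rng.binomial(n, pi)


def simulate_experiment(
    design: DesignSpec,
    effects: EffectSpec,
    seed: int,
) -> tuple[pd.DataFrame, EffectSpec]:
    """Draw one female x site table under the factorial design.

    Cover is drawn beta-binomially with denominator 100 around the
    cell's expected proportion; mean intensity is Gaussian truncated at
    zero around the cell's expected mean. Returns the records and the
    generative truth (the effects object itself).
    """
    rng = np.random.default_rng(seed)
    frames = []
    fid = 0
    for cell, n in design.cells():
        ids = [f"f{i:04d}" for i in range(fid + 1, fid + n + 1)]
        fid += n
        for site in SITES:
            p = effects.expected_cover(cell, site)
            cover = _beta_binomial_array(rng, 100, p,
                                         effects.cover_overdispersion, n)
            mu = effects.expected_intensity(cell, site)
            sd = effects.intensity_noise_sd
            if sd > 0:
                intensity = stats.truncnorm.rvs(
                    -mu / sd, np.inf, loc=mu, scale=sd, size=n,
                    random_state=rng)
            else:
                intensity = np.full(n, mu)
            frames.append(pd.DataFrame({
                "female_id": ids,
                "thermal": cell["thermal"],
                "female_status": cell["female_status"],
                "time": cell["time"],
                "site": site,
                "cover_percent": cover.astype(float),
                "mean_intensity": intensity,
                "median_intensity": intensity * rng.uniform(0.80, 0.95, size=n),
                "presence": cover > 0,
            }))
    df = (pd.concat(frames, ignore_index=True)
          .sort_values(["female_id", "site"], kind="stable")
          .reset_index(drop=True))
    return df, effects


def simulate_paternity(
    n_control: int = 19,
    n_heat: int = 18,
    effects: EffectSpec = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw the sperm-competition paternity assay.

    Each female's brood size is Poisson; the number of offspring sired
    by the focal (GFP) male — scored by filiform antennae — is drawn
    beta-binomially with the arm-specific paternity proportion. The
    remaining offspring carry the competitor's clubbed-antennae marker.
    """
    if n_control < 1 or n_heat < 1:
        raise SimulationError("need >= 1 female per arm")
    if effects is None:
        effects = EffectSpec()
    rng = np.random.default_rng(seed)
    logit0 = math.log(effects.paternity_baseline / (1 - effects.paternity_baseline))
    p_arm = {
        "control": effects.paternity_baseline,
        "heat": 1.0 / (1.0 + math.exp(-(logit0 + effects.paternity_effect))),
    }
    rows = []
    fid = 0
    for arm, n in (("control", n_control), ("heat", n_heat)):
        for _ in range(n):
            fid += 1
            brood = int(rng.poisson(effects.brood_size_mean))
            filiform = (
                _beta_binomial(rng, brood, p_arm[arm],
                               effects.paternity_overdispersion)
                if brood > 0 else 0
            )
            rows.append({
                "female_id": f"p{fid:04d}",
                "male_treatment": arm,
                "n_filiform": filiform,
                "n_clubbed": brood - filiform,
            })
    return pd.DataFrame(rows)
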