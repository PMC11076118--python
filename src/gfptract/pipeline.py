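"""End-to-end orchestration: simulate -> quantify -> analyse.

A run is driven by a :class:`RunConfig` (loadable from a versioned YAML
file). The flagship mode, :func:`run_full_synthetic`, renders one
two-channel micrograph per simulated female under the 2x2x2 factorial
design, quantifies both storage sites with the imaging chain, fits the
occupancy GLMs and the paternity model, and writes CSV/JSON outputs
plus a manifest (seed, config hash, library versions, per-sample
failures) sufficient to reproduce the run bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .glm import analyze_occupancy, analyze_paternity
from .imaging import (
    SITE_SPERMATHECA,
    SITE_TOTAL_TRACT,
    ImagingError,
    QuantConfig,
    quantify_sample,
    rasterize_roi,
)
from .io import read_channel_stack, read_rois, write_channel_stack, write_rois
from .simulate import (
    FACTORS,
    LEVELS,
    DesignSpec,
    EffectSpec,
    ImagingParams,
    SimulationError,
    default_scene,
    footprint_radius,
    simulate_paternity,
    simulate_tract_image,
)

CONFIG_VERSION = 1


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Configuration of a pipeline run (YAML schema version 1)."""

    mode: str = "full_synthetic"
    seed: int = 0
    output_dir: str = "runs/full"
    write_images: bool = True
    imaging: ImagingParams = field(default_factory=ImagingParams)
    design: DesignSpec = field(default_factory=DesignSpec)
    effects: EffectSpec = field(default_factory=EffectSpec)
    quant: QuantConfig = field(default_factory=QuantConfig)
    n_paternity_control: int = 19
    n_paternity_heat: int = 18
    female_heterogeneity_sd: float = 0.25  # lognormal sd of per-female factor
    config_version: int = CONFIG_VERSION

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        # numpy arrays inside chitin_structures are not JSON/YAML friendly
        img = d["imaging"]
        if img.get("chitin_structures") is not None:
            img["chitin_structures"] = [
                [np.asarray(v).tolist(), float(a)]
                for v, a in img["chitin_structures"]
            ]
        return d

    def sha256(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        version = d.pop("config_version", CONFIG_VERSION)
        if version != CONFIG_VERSION:
            raise ConfigError(f"unsupported config_version {version}")
        try:
            if "imaging" in d:
                img = dict(d["imaging"])
                for key in ("image_shape", "punctum_amplitude_range",
                            "illumination_field"):
                    if key in img:
                        img[key] = tuple(img[key])
                if img.get("chitin_structures") is not None:
                    img["chitin_structures"] = [
                        (np.asarray(v, dtype=float), float(a))
                        for v, a in img["chitin_structures"]
                    ]
                d["imaging"] = ImagingParams(**img)
            if "design" in d:
                des = d["design"]
                if isinstance(des, dict):
                    des = des.get("cell_sizes", DesignSpec().cell_sizes)
                d["design"] = DesignSpec(cell_sizes=tuple(des))
            if "effects" in d:
                d["effects"] = EffectSpec(**d["effects"])
            if "quant" in d:
                d["quant"] = QuantConfig(**d["quant"])
            return cls(**d)
        except (TypeError, SimulationError) as exc:
            raise ConfigError(str(exc)) from exc

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        try:
            payload = yaml.safe_load(Path(path).read_text())
        except yaml.YAMLError as exc:
            raise ConfigError(f"invalid YAML: {exc}") from exc
        if not isinstance(payload, dict):
            raise ConfigError("config file must hold a mapping")
        return cls.from_dict(payload)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


# --------------------------------------------------------------------------
# Effect injection into images
# --------------------------------------------------------------------------

def _site_geometry(imaging: ImagingParams) -> dict[str, float]:
    """Rasterized ROI areas of the default scene (pixels)."""
    tract_v, sperm_v, _ = default_scene(imaging.image_shape)
    from .imaging import PolygonROI
    tract = rasterize_roi(PolygonROI(SITE_TOTAL_TRACT, tract_v),
                          imaging.image_shape).sum()
    sperm = rasterize_roi(PolygonROI(SITE_SPERMATHECA, sperm_v),
                          imaging.image_shape).sum()
    return {SITE_TOTAL_TRACT: float(tract), SITE_SPERMATHECA: float(sperm)}


def _puncta_for_cover(p: float, roi_area: float, sigma: float,
                      sharpness: float) -> float:
    """Expected punctum count whose union footprint covers fraction p.

    Under uniform placement, cover = 1 - (1 - a/A)^N with a the
    single-punctum footprint area; invert for N.
    """
    a = math.pi * footprint_radius(sigma, sharpness) ** 2
    frac = min(a / roi_area, 0.999)
    return math.log(max(1.0 - p, 1e-9)) / math.log(1.0 - frac)


def _cell_multiplier(effects_table: dict, cell: dict, site: str) -> float:
    m = 1.0
    for f in FACTORS:
        if cell[f] != LEVELS[f][0]:
            m *= effects_table[f][site]
    return m


def imaging_params_for_female(
    config: RunConfig, cell: dict[str, str], female_factor: float,
    n_tract: int, n_sperm: int, image_seed: int,
) -> ImagingParams:
    """Per-female imaging parameters with cell effects injected.

    Cover effects act on punctum counts (drawn upstream); intensity
    effects scale punctum amplitudes.
    """
    m_int_tract = _cell_multiplier(config.effects.intensity_effects, cell,
                                   SITE_TOTAL_TRACT)
    m_int_sperm = _cell_multiplier(config.effects.intensity_effects, cell,
                                   SITE_SPERMATHECA)
    lo, hi = config.imaging.punctum_amplitude_range
    scale = m_int_tract * female_factor
    return replace(
        config.imaging,
        n_puncta=n_tract,
        n_puncta_spermatheca=n_sperm,
        punctum_amplitude_range=(min(lo * scale, 16383.0),
                                 min(hi * scale, 16383.0)),
        punctum_amplitude_scale_spermatheca=(
            m_int_sperm / m_int_tract if m_int_tract > 0 else 1.0),
        seed=image_seed,
    )


def _female_table(design: DesignSpec) -> pd.DataFrame:
    rows = []
    fid = 0
    for cell, n in design.cells():
        for _ in range(n):
            fid += 1
            rows.append({"female_id": f"f{fid:04d}", **cell})
    return pd.DataFrame(rows)


def _sha256_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_full_synthetic(config: RunConfig) -> dict:
    """Simulate, quantify, and analyse a complete factorial experiment.

    Returns the manifest (also written to ``manifest.json``). Raises if
    more than 10% of samples fail quantification.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    images_dir = out / "images"
    t0 = time.time()

    females = _female_table(config.design)
    areas = _site_geometry(config.imaging)
    sigma = config.imaging.punctum_sigma
    base_n = {
        site: _puncta_for_cover(config.effects.baseline_cover[site] / 100.0,
                                areas[site], sigma,
                                config.imaging.punctum_sharpness)
        for site in (SITE_TOTAL_TRACT, SITE_SPERMATHECA)
    }

    rng = np.random.default_rng(config.seed)
    ss = np.random.SeedSequence(config.seed)
    image_seeds = [int(s.generate_state(1)[0]) for s in ss.spawn(len(females))]

    metrics_rows = []
    failures = []
    log_lines = []
    for i, rec in enumerate(females.to_dict("records")):
        cell = {f: rec[f] for f in FACTORS}
        g = float(rng.lognormal(0.0, config.female_heterogeneity_sd))
        lam_tract = base_n[SITE_TOTAL_TRACT] * g * _cell_multiplier(
            config.effects.cover_effects, cell, SITE_TOTAL_TRACT)
        lam_sperm = base_n[SITE_SPERMATHECA] * g * _cell_multiplier(
            config.effects.cover_effects, cell, SITE_SPERMATHECA)
        n_tract = int(rng.poisson(lam_tract))
        n_sperm = int(rng.poisson(lam_sperm))
        params = imaging_params_for_female(
            config, cell, g, n_tract, n_sperm, image_seeds[i])
        try:
            stack, rois, truth = simulate_tract_image(params)
            quant = quantify_sample(stack, rois, config.quant)
        except (ImagingError, SimulationError) as exc:
            failures.append({"female_id": rec["female_id"],
                             "reason": f"{type(exc).__name__}: {exc}"})
            continue
        if config.write_images:
            write_channel_stack(images_dir, rec["female_id"], stack)
            write_rois(images_dir / f"{rec['female_id']}_rois.json", rois)
        for site, m in quant.metrics.items():
            metrics_rows.append({
                "female_id": rec["female_id"], **cell, "site": site,
                "cover_percent": m.percent_cover,
                "mean_intensity": m.mean_intensity,
                "median_intensity": m.median_intensity,
                "presence": m.presence,
                "threshold_value": m.threshold_value,
                "threshold_failed": m.threshold_failed,
                "roi_area_px": m.roi_area_px,
                "correction_factor": quant.correction.factor,
                "true_cover_percent": truth.true_cover_percent[site],
            })
        log_lines.append(json.dumps(
            {"female_id": rec["female_id"], **quant.log}, sort_keys=True))

    if len(failures) > 0.10 * len(females):
        raise RuntimeError(
            f"{len(failures)}/{len(females)} samples failed quantification"
        )

    metrics = pd.DataFrame(metrics_rows)
    metrics_path = out / "metrics.csv"
    metrics.to_csv(metrics_path, index=False)
    (out / "quantification_log.jsonl").write_text("\n".join(log_lines) + "\n")

    occupancy = analyze_occupancy(metrics)
    occupancy_table = occupancy.to_table()
    occupancy_table.to_csv(out / "occupancy_models.csv", index=False)
    (out / "occupancy_models.json").write_text(
        json.dumps(occupancy.to_dict(), indent=1, default=float))

    paternity_seed = int(ss.spawn(1)[0].generate_state(1)[0])
    paternity = simulate_paternity(
        config.n_paternity_control, config.n_paternity_heat,
        config.effects, seed=paternity_seed)
    paternity.to_csv(out / "paternity.csv", index=False)
    paternity_report = analyze_paternity(paternity)
    (out / "paternity_model.json").write_text(
        json.dumps(paternity_report.to_dict(), indent=1, default=float))

    manifest = {
        "pipeline": "gfptract full_synthetic",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_sha256": config.sha256(),
        "library_versions": _library_versions(),
        "n_females": int(len(females)),
        "cell_sizes": list(config.design.cell_sizes),
        "n_site_records": int(len(metrics)),
        "n_failures": len(failures),
        "failures": failures,
        "outputs": {
            p.name: _sha256_file(p)
            for p in (metrics_path, out / "occupancy_models.csv",
                      out / "paternity.csv")
        },
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "runtime_s": round(time.time() - t0, 2),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _library_versions() -> dict[str, str]:
    import scipy
    import statsmodels
    return {
        "gfptract": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "statsmodels": statsmodels.__version__,
    }


def run_quantify(input_dir: str | Path, config: RunConfig | None = None,
                 output_csv: str | Path | None = None) -> pd.DataFrame:
    """Quantify every TIFF channel triple + ROI JSON found in a directory.

    Samples are discovered from ``*_green.tif`` filenames; a sample
    missing channels or ROIs, or with an unreadable file, is skipped
    with a recorded reason and the batch continues.
    """
    config = config or RunConfig()
    input_dir = Path(input_dir)
    columns = ["sample_id", "site", "cover_percent", "mean_intensity",
               "median_intensity", "presence", "threshold_value",
               "threshold_failed", "roi_area_px", "correction_factor",
               "skip_reason"]
    rows = []
    sample_ids = sorted(p.name[:-len("_green.tif")]
                        for p in input_dir.glob("*_green.tif"))
    if not sample_ids:
        import warnings
        warnings.warn(f"no samples found in {input_dir}", stacklevel=2)
    for sid in sample_ids:
        try:
            stack = read_channel_stack(input_dir, sid)
            rois = read_rois(input_dir / f"{sid}_rois.json")
            quant = quantify_sample(stack, rois, config.quant)
        except Exception as exc:
            rows.append({"sample_id": sid, "site": None,
                         "skip_reason": f"{type(exc).__name__}: {exc}"})
            continue
        for site, m in quant.metrics.items():
            rows.append({
                "sample_id": sid, "site": site,
                "cover_percent": m.percent_cover,
                "mean_intensity": m.mean_intensity,
                "median_intensity": m.median_intensity,
                "presence": m.presence,
                "threshold_value": m.threshold_value,
                "threshold_failed": m.threshold_failed,
                "roi_area_px": m.roi_area_px,
                "correction_factor": quant.correction.factor,
                "skip_reason": "",
            })
    df = pd.DataFrame(rows, columns=columns)
    if output_csv is not None:
        Path(output_csv).parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(output_csv, index=False)
    return df


def run_analyze(metrics: pd.DataFrame | str | Path,
                output_dir: str | Path | None = None):
    """Run the occupancy GLM chain on a metrics table (or CSV path)."""
    if not isinstance(metrics, pd.DataFrame):
        metrics = pd.read_csv(metrics)
    results = analyze_occupancy(metrics)
    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        results.to_table().to_csv(out / "occupancy_models.csv", index=False)
        (out / "occupancy_models.json").write_text(
            json.dumps(results.to_dict(), indent=1, default=float))
    return results


def load_deposited_metrics(path: str | Path) -> pd.DataFrame:
    """Loader stub for the published experimental dataset.

    Users who obtain the deposited per-female CSV themselves should
    reshape it to the schema consumed by :func:`run_analyze`:
    one row per female x site with columns female_id, thermal
    (control/heat), female_status (virgin/mated), time (30min/24h),
    site (total_tract/spermatheca), cover_percent, mean_intensity,
    median_intensity, presence.
    """
    df = pd.read_csv(path)
    needed = {"female_id", "thermal", "female_status", "time", "site",
              "cover_percent", "mean_intensity"}
    missing = needed - set(df.columns)
    if missing:
        raise ConfigError(
            f"deposited-data CSV lacks required columns: {sorted(missing)}"
        )
    return df
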