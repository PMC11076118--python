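"""File formats: 16-bit TIFF channels, ROI polygon JSON, metrics CSV."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .imaging import MAX_14BIT, ChannelStack, PolygonROI

CHANNELS = ("brightfield", "green", "red")


def write_channel_stack(directory: str | Path, sample_id: str,
                        stack: ChannelStack) -> list[Path]:
    """Write one TIFF per channel (uint16, values in [0, 16383]) plus a
    JSON sidecar with acquisition metadata."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for name in CHANNELS:
        arr = np.asarray(getattr(stack, name))
        data = np.clip(np.round(arr), 0, MAX_14BIT).astype(np.uint16)
        p = directory / f"{sample_id}_{name}.tif"
        tifffile.imwrite(p, data)
        paths.append(p)
    meta = {
        "bit_depth": stack.bit_depth,
        "exposure_ms": dict(stack.exposure_ms),
        "site_context": stack.site_context,
    }
    mp = directory / f"{sample_id}_meta.json"
    mp.write_text(json.dumps(meta, indent=1))
    paths.append(mp)
    return paths


def read_channel_stack(directory: str | Path, sample_id: str) -> ChannelStack:
    directory = Path(directory)
    arrays = {}
    for name in CHANNELS:
        p = directory / f"{sample_id}_{name}.tif"
        if not p.exists():
            raise FileNotFoundError(f"missing channel file {p}")
        arrays[name] = tifffile.imread(p).astype(float)
    meta_path = directory / f"{sample_id}_meta.json"
    kwargs = {}
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        kwargs = {
            "bit_depth": meta.get("bit_depth", 14),
            "exposure_ms": meta.get("exposure_ms",
                                    {"brightfield": 5.0, "green": 100.0,
                                     "red": 150.0}),
            "site_context": meta.get("site_context", "total_tract"),
        }
    return ChannelStack(**arrays, **kwargs)


def write_rois(path: str | Path, rois: list[PolygonROI]) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "rois": [
            {"label": r.label, "vertices": np.asarray(r.vertices).tolist()}
            for r in rois
        ]
    }
    path.write_text(json.dumps(payload, indent=1))
    return path


def read_rois(path: str | Path) -> list[PolygonROI]:
    payload = json.loads(Path(path).read_text())
    return [
        PolygonROI(r["label"], np.asarray(r["vertices"], dtype=float))
        for r in payload["rois"]
    ]
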