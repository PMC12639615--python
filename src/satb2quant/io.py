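"""Readers and writers for every pipeline artifact.

Formats: two-page grayscale TIFF + JSON sidecar for image pairs (masks
in the sidecar are stored as per-row '0'/'1' strings so truth survives a
round trip losslessly as text), comma-separated CSV with a header row
for FRAP recordings and reporter tables (recording metadata such as the
bleach index travels in ``#`` comment lines), and YAML for run
configuration. Unknown config keys are rejected by name.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import tifffile
import yaml

from .synth import FrapRecording, ImagePair, ReporterTable

__all__ = [
    "read_image_pair", "write_image_pair",
    "read_frap_csv", "write_frap_csv",
    "read_reporter_csv", "write_reporter_csv",
    "load_config", "DEFAULT_CONFIG", "file_sha256",
]

PathLike = Union[str, Path]


def _mask_to_text(mask: np.ndarray) -> list[str]:
    return ["".join("1" if v else "0" for v in row) for row in np.asarray(mask)]


def _mask_from_text(rows: list[str]) -> np.ndarray:
    return np.array([[c == "1" for c in row] for row in rows], dtype=bool)


def write_image_pair(pair: ImagePair, path: PathLike) -> Path:
    """Write a two-page grayscale TIFF (protein, dna) plus JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.stack([pair.protein, pair.dna]).astype(np.float32))
    sidecar = {"pixel_size": pair.pixel_size, "seed": pair.seed}
    if pair.truth is not None:
        truth = {}
        for key, val in pair.truth.items():
            if isinstance(val, np.ndarray):
                truth[key] = _mask_to_text(val)
            elif hasattr(val, "__dataclass_fields__"):
                continue  # nested parameter objects are not serialized
            else:
                truth[key] = val
        sidecar["truth"] = truth
    path.with_suffix(".json").write_text(json.dumps(sidecar))
    return path


def read_image_pair(path: PathLike) -> ImagePair:
    """Read a two-page grayscale TIFF and its JSON sidecar if present."""
    path = Path(path)
    arr = tifffile.imread(path)
    if arr.ndim == 3 and arr.shape[-1] in (3, 4) and arr.shape[0] not in (2,):
        raise ValueError("RGB TIFF input; two-page grayscale required")
    if arr.ndim != 3 or arr.shape[0] != 2:
        raise ValueError(
            f"expected a 2-page grayscale TIFF, got shape {arr.shape}")
    protein, dna = arr[0].astype(float), arr[1].astype(float)
    pixel_size, seed, truth = 0.0, None, None
    sidecar_path = path.with_suffix(".json")
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        pixel_size = sidecar.get("pixel_size", 0.0)
        seed = sidecar.get("seed")
        raw = sidecar.get("truth")
        if raw is not None:
            truth = {k: (_mask_from_text(v) if isinstance(v, list) else v)
                     for k, v in raw.items()}
    return ImagePair(protein=protein, dna=dna, pixel_size=pixel_size,
                     truth=truth, seed=seed)


def write_frap_csv(rec: FrapRecording, path: PathLike) -> Path:
    """Write a recording as CSV with bleach index in a header comment."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = []
    if rec.bleach_index is not None:
        lines.append(f"# bleach_index={rec.bleach_index}")
    if rec.truth is not None:
        scalars = {k: v for k, v in rec.truth.items()
                   if isinstance(v, (int, float))}
        lines.append("# truth=" + json.dumps(scalars))
    df = pd.DataFrame({"time_s": rec.t, "roi": rec.roi,
                       "background": rec.background, "control": rec.control})
    path.write_text("\n".join(lines + [df.to_csv(index=False)]))
    return path


def read_frap_csv(path: PathLike) -> FrapRecording:
    path = Path(path)
    bleach_index, truth = None, None
    with open(path) as fh:
        header_lines = 0
        for line in fh:
            if not line.startswith("#"):
                break
            header_lines += 1
            body = line[1:].strip()
            if body.startswith("bleach_index="):
                bleach_index = int(body.split("=", 1)[1])
            elif body.startswith("truth="):
                truth = json.loads(body.split("=", 1)[1])
    df = pd.read_csv(path, skiprows=header_lines)
    return FrapRecording(t=df["time_s"], roi=df["roi"],
                         background=df["background"], control=df["control"],
                         bleach_index=bleach_index, truth=truth)


def write_reporter_csv(table: ReporterTable, path: PathLike) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(f"# control={table.control_label}\n"
                    + table.data.to_csv(index=False))
    return path


def read_reporter_csv(path: PathLike) -> ReporterTable:
    path = Path(path)
    control = "empty_vector"
    with open(path) as fh:
        first = fh.readline()
    skip = 0
    if first.startswith("#"):
        skip = 1
        body = first[1:].strip()
        if body.startswith("control="):
            control = body.split("=", 1)[1]
    df = pd.read_csv(path, skiprows=skip)
    return ReporterTable(data=df, control_label=control)


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "alpha": 0.05,
    "mc_draws": 100_000,
    "output_dir": "results",
    "threshold_overrides": {},  # non-empty => outputs watermarked
    "images": {"per_variant": 20, "width": 128, "height": 128,
               "noise_sd": 0.02},
    "frap": {"n_recordings": 60, "k": 0.04, "mobile_fraction": 0.85,
             "noise_sd": 0.02},
    "reporter": {"n_replicates": 8, "cv": 0.1, "wt_repression": 0.75},
    "rule_version": "v1",
}


def _check_keys(cfg: dict, template: dict, prefix: str = "") -> None:
    for key, val in cfg.items():
        if key not in template:
            raise ValueError(f"invalid config key: {prefix}{key}")
        if isinstance(template[key], dict) and key != "threshold_overrides":
            if not isinstance(val, dict):
                raise ValueError(f"config key {prefix}{key} must be a mapping")
            _check_keys(val, template[key], prefix=f"{prefix}{key}.")


def load_config(path: Optional[PathLike] = None) -> dict:
    """Load a YAML run config, merged over defaults; unknown keys error."""
    cfg = {k: (dict(v) if isinstance(v, dict) else v)
           for k, v in DEFAULT_CONFIG.items()}
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        _check_keys(user, DEFAULT_CONFIG)
        for key, val in user.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    return cfg


def file_sha256(path: PathLike) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
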