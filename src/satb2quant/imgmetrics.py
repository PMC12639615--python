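"""Thresholded-area localization statistics for two-channel nuclei.

The three ratio statistics mirror the Fiji-based quantification of nuclear
SATB2 distribution, with the channel/method pairing hard-wired per metric:

* aggregation ratio   -- protein area (Moments) / DNA area (Minimum)
* colocalization      -- overlap area / protein area (both Moments)
* nuclear fraction    -- overlap area / protein area (protein Li, DNA Otsu)

Ratios with empty denominator masks are reported as missing (NaN), never
as silent zeros, and every ratio is reported alongside the areas and
threshold levels it was computed from. Intensity line profiles use
bilinear interpolation at 1-pixel steps (Plot Profile equivalent).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

from .synth import ImagePair
from .thresh import apply_threshold

__all__ = [
    "LocalizationMetrics",
    "METRIC_METHODS",
    "aggregation_ratio",
    "coloc_ratio",
    "nuclear_fraction",
    "quantify_pair",
    "intensity_profile",
    "batch_quantify",
]

# channel/threshold pairing per metric; these pairings ARE the statistics,
# so overrides must go through the explicit config path in the CLI which
# watermarks output as non-standard.
METRIC_METHODS: Mapping[str, tuple[str, str]] = {
    "aggregation_ratio": ("moments", "minimum"),   # (protein, dna)
    "coloc_ratio": ("moments", "moments"),
    "nuclear_fraction": ("li", "otsu"),
}


@dataclass
class LocalizationMetrics:
    """All three ratio statistics plus the areas and levels behind them."""

    aggregation_ratio: float
    coloc_ratio: float
    nuclear_fraction: float
    areas: dict = field(default_factory=dict)
    levels: dict = field(default_factory=dict)
    notes: list = field(default_factory=list)


def _masks(pair: ImagePair, metric: str):
    pm_method, dm_method = METRIC_METHODS[metric]
    pm = apply_threshold(pair.protein, pm_method)
    dm = apply_threshold(pair.dna, dm_method)
    return pm, dm


def aggregation_ratio(pair: ImagePair) -> float:
    """Protein mask area (Moments) over DNA mask area (Minimum).

    Lower values indicate clustering/aggregation of the protein relative
    to the chromatin-dense area. Missing (NaN) if the DNA mask is empty
    or the Minimum threshold fails on a non-bimodal DNA histogram.
    """
    try:
        pm, dm = _masks(pair, "aggregation_ratio")
    except ValueError:
        return float("nan")
    if dm.area == 0:
        return float("nan")
    return pm.area / dm.area


def coloc_ratio(pair: ImagePair) -> float:
    """Fraction of protein-foreground pixels also DNA-foreground.

    Both masks from the Moments threshold; missing if the protein mask
    is empty.
    """
    pm, dm = _masks(pair, "coloc_ratio")
    if pm.area == 0:
        return float("nan")
    return int((pm.mask & dm.mask).sum()) / pm.area


def nuclear_fraction(pair: ImagePair) -> float:
    """Fraction of protein signal inside the DNA-stain foreground.

    Protein thresholded with Li, DNA with Otsu; missing if the protein
    mask is empty.
    """
    pm, dm = _masks(pair, "nuclear_fraction")
    if pm.area == 0:
        return float("nan")
    return int((pm.mask & dm.mask).sum()) / pm.area


def quantify_pair(pair: ImagePair) -> LocalizationMetrics:
    """Compute all three metrics with full area/level provenance."""
    values: dict[str, float] = {}
    areas: dict[str, int] = {}
    levels: dict[str, int] = {}
    notes: list[str] = []
    for metric in METRIC_METHODS:
        try:
            pm, dm = _masks(pair, metric)
        except ValueError as exc:
            values[metric] = float("nan")
            notes.append(f"{metric}: {exc}")
            continue
        areas[f"{metric}_protein_area"] = pm.area
        areas[f"{metric}_dna_area"] = dm.area
        levels[f"{metric}_protein_level"] = pm.level
        levels[f"{metric}_dna_level"] = dm.level
        overlap = int((pm.mask & dm.mask).sum())
        areas[f"{metric}_overlap_area"] = overlap
        if metric == "aggregation_ratio":
            values[metric] = pm.area / dm.area if dm.area else float("nan")
            if dm.area == 0:
                notes.append("aggregation_ratio: empty DNA mask")
        else:
            values[metric] = overlap / pm.area if pm.area else float("nan")
            if pm.area == 0:
                notes.append(f"{metric}: empty protein mask")
    return LocalizationMetrics(
        aggregation_ratio=values["aggregation_ratio"],
        coloc_ratio=values["coloc_ratio"],
        nuclear_fraction=values["nuclear_fraction"],
        areas=areas, levels=levels, notes=notes)


def intensity_profile(pair: ImagePair, p0: tuple[float, float],
                      p1: tuple[float, float]) -> pd.DataFrame:
    """Sample both channels along a line segment at 1-pixel steps.

    ``p0``/``p1`` are (x, y) pixel coordinates (0-based, row-major
    images). Bilinear interpolation; returns a distance-indexed table
    with both channel intensities, plus micrometers when pixel_size is
    set.
    """
    x0, y0 = p0
    x1, y1 = p1
    h, w = pair.protein.shape
    for x, y in (p0, p1):
        if not (0 <= x <= w - 1 and 0 <= y <= h - 1):
            raise ValueError(f"endpoint ({x}, {y}) outside image")
    length = float(np.hypot(x1 - x0, y1 - y0))
    if length == 0:
        raise ValueError("zero-length segment")
    dist = np.arange(int(np.floor(length)) + 1, dtype=float)
    frac = dist / length
    xs = x0 + frac * (x1 - x0)
    ys = y0 + frac * (y1 - y0)
    coords = np.vstack([ys, xs])
    out = pd.DataFrame({
        "distance_px": dist,
        "protein": map_coordinates(pair.protein, coords, order=1),
        "dna": map_coordinates(pair.dna, coords, order=1),
    })
    if pair.pixel_size:
        out["distance_um"] = out["distance_px"] * pair.pixel_size
    return out


def batch_quantify(groups: Mapping[str, Iterable[ImagePair]]
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Quantify a collection of image pairs grouped by variant.

    Returns a tidy per-image table (one row per image, with metrics,
    areas and levels) and a per-group summary (mean +/- SEM per metric,
    with NaN measurements excluded and their count reported). Unreadable
    images are flagged and the batch continues.
    """
    rows = []
    for group, pairs in groups.items():
        pairs = list(pairs)
        if not pairs:
            raise ValueError(f"group {group!r} contains no images")
        for i, pair in enumerate(pairs):
            row: dict = {"group": group, "image": i, "error": ""}
            try:
                m = quantify_pair(pair)
            except Exception as exc:  # keep the batch going
                warnings.warn(f"image {group}/{i} failed: {exc}")
                row["error"] = str(exc)
                rows.append(row)
                continue
            row.update(aggregation_ratio=m.aggregation_ratio,
                       coloc_ratio=m.coloc_ratio,
                       nuclear_fraction=m.nuclear_fraction)
            row.update(m.areas)
            row.update(m.levels)
            row["notes"] = "; ".join(m.notes)
            rows.append(row)
    per_image = pd.DataFrame(rows)

    summaries = []
    for group, sub in per_image.groupby("group", sort=False):
        entry: dict = {"group": group, "n_images": len(sub)}
        for metric in METRIC_METHODS:
            vals = sub[metric].dropna() if metric in sub else pd.Series(dtype=float)
            entry[f"{metric}_n"] = len(vals)
            entry[f"{metric}_excluded"] = len(sub) - len(vals)
            entry[f"{metric}_mean"] = vals.mean() if len(vals) else float("nan")
            entry[f"{metric}_sem"] = (
                vals.std(ddof=1) / np.sqrt(len(vals))
                if len(vals) > 1 else float("nan"))
        summaries.append(entry)
    return per_image, pd.DataFrame(summaries)
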