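"""Ground-truth synthetic data for the cell-based assay pipeline.

Three generators emulate the study's raw data so every downstream stage
has a known-answer test surface:

* :func:`generate_nucleus_image` -- two-channel (tagged protein + DNA
  stain) single-nucleus micrographs realizing the four nuclear phenotypes
  observed for SATB2 variants: diffuse/granular (WT-like), DNA-cage
  (colocalizing with AT-rich chromatin), anti-DNA aggregates (inverse
  localization), and nuclear condensates (HOX-like punctae).
* :func:`generate_frap_recording` -- single-exponential fluorescence
  recovery with bleach-control photofading, background offset and noise.
* :func:`generate_reporter_table` -- firefly/Renilla dual-luciferase
  counts with log-normal multiplicative noise and a prescribed mean
  repression relative to the empty-vector control.

All generators are deterministic given their seed and carry a ``truth``
block recomputable from their own output by direct counting or closed
form. Images are floating point in [0, 1]; 8-bit quantization is the
thresholding module's job, which keeps ground-truth masks exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt, gaussian_filter

__all__ = [
    "NucleusPhenotype",
    "ImagePair",
    "FrapSimParams",
    "FrapRecording",
    "ReporterSimParams",
    "ReporterTable",
    "PHENOTYPE_LABELS",
    "generate_nucleus_image",
    "generate_frap_recording",
    "generate_reporter_table",
]

PHENOTYPE_LABELS = ("diffuse", "dna_cage", "anti_dna_aggregate", "condensate")

# Default heterochromatin (DNA-foreground) coverage of the nucleus. The
# diffuse phenotype's colocalization equals this fraction by construction
# (no enrichment relative to chromatin).
_DNA_FOREGROUND_FRACTION = 0.40


@dataclass(frozen=True)
class NucleusPhenotype:
    """Target nuclear distribution pattern for the protein channel.

    ``aggregation_level`` sets the protein-mask area relative to the
    DNA-foreground mask area; ``coloc_level`` is the target fraction of
    protein-foreground pixels lying inside DNA foreground;
    ``cytoplasm_fraction`` is the fraction of protein-foreground pixels
    placed outside the nucleus.
    """

    label: str
    aggregation_level: float
    coloc_level: float
    cytoplasm_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.label not in PHENOTYPE_LABELS:
            raise ValueError(f"unknown phenotype label {self.label!r}")
        if not 0.0 <= self.coloc_level <= 1.0:
            raise ValueError("coloc_level must be in [0, 1]")
        if not 0.0 <= self.cytoplasm_fraction <= 1.0:
            raise ValueError("cytoplasm_fraction must be in [0, 1]")
        if self.aggregation_level < 0:
            raise ValueError("aggregation_level must be >= 0")

    @classmethod
    def preset(cls, label: str) -> "NucleusPhenotype":
        """Default parameterization of each observed phenotype class."""
        presets = {
            # WT-like: protein spread over the whole nucleus, chromatin
            # overlap at chance level (= DNA foreground area fraction).
            "diffuse": cls("diffuse", 1.8, _DNA_FOREGROUND_FRACTION, 0.05),
            # cage-like pattern strongly colocalizing with the DNA dye
            "dna_cage": cls("dna_cage", 0.9, 0.85, 0.02),
            # compact clusters in chromatin-poor inner regions
            "anti_dna_aggregate": cls("anti_dna_aggregate", 0.45, 0.08, 0.02),
            # HOX-like nuclear condensates (round punctae)
            "condensate": cls("condensate", 0.25, 0.30, 0.02),
        }
        if label not in presets:
            raise ValueError(f"unknown phenotype label {label!r}")
        return presets[label]


@dataclass
class ImagePair:
    """Registered two-channel single-nucleus image with optional truth."""

    protein: np.ndarray
    dna: np.ndarray
    pixel_size: float = 0.05  # micrometers per pixel (100x + zoom regime)
    truth: Optional[dict] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.protein = np.asarray(self.protein, dtype=float)
        self.dna = np.asarray(self.dna, dtype=float)
        if self.protein.shape != self.dna.shape:
            raise ValueError("protein and dna channels must share dimensions")
        if self.protein.ndim != 2:
            raise ValueError("channels must be 2-D")
        for name, ch in (("protein", self.protein), ("dna", self.dna)):
            if not np.all(np.isfinite(ch)) or np.any(ch < 0):
                raise ValueError(f"{name} channel must be finite and >= 0")


def _ellipse_mask(h: int, w: int, cy: float, cx: float, ry: float, rx: float,
                  theta: float = 0.0) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    y = yy - cy
    x = xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = ct * x + st * y
    v = -st * x + ct * y
    return (u / rx) ** 2 + (v / ry) ** 2 <= 1.0


def _disk(h: int, w: int, cy: float, cx: float, r: float) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r


def _sample_pixels(rng: np.random.Generator, allowed: np.ndarray, n: int,
                   weight: Optional[np.ndarray] = None) -> np.ndarray:
    """Pick ``n`` distinct pixel indices from a boolean region.

    Weighted sampling without replacement via the exponential-sort trick;
    keeps stratum counts exact, which is what makes the truth overlap
    fraction exact by construction.
    """
    idx = np.flatnonzero(allowed)
    if n > idx.size:
        raise ValueError(f"cannot place {n} pixels in a region of {idx.size}")
    if n == 0:
        return np.empty(0, dtype=np.intp)
    if weight is None:
        return rng.choice(idx, size=n, replace=False)
    w = weight.ravel()[idx]
    w = np.clip(w, 1e-12, None)
    keys = rng.exponential(size=idx.size) / w
    return idx[np.argpartition(keys, n - 1)[:n]]


def _blob_weight(rng: np.random.Generator, shape: tuple[int, int],
                 region: np.ndarray, n_centers: int, sigma: float) -> np.ndarray:
    """Sum-of-Gaussians weight map with centers sampled inside ``region``."""
    h, w = shape
    centers = np.flatnonzero(region)
    picks = rng.choice(centers, size=min(n_centers, centers.size), replace=False)
    yy, xx = np.mgrid[0:h, 0:w]
    wmap = np.zeros(shape)
    for p in picks:
        cy, cx = divmod(int(p), w)
        wmap += np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2))
    return wmap


def generate_nucleus_image(phenotype: NucleusPhenotype, width: int = 128,
                           height: int = 128, seed: int = 0, *,
                           noise_sd: float = 0.02,
                           pixel_size: float = 0.05) -> ImagePair:
    """Simulate one two-channel single-nucleus micrograph.

    The DNA channel is an elliptical nucleus with heterochromatin-like
    bright blobs (the DNA-foreground ground truth, emulating AT-rich
    Hoechst-bright chromatin) over a dim nucleoplasm, with 1--3 dark
    nucleolus holes. The protein channel realizes the requested phenotype
    by exact stratified pixel placement: ``coloc_level`` of the protein
    foreground inside DNA foreground, ``cytoplasm_fraction`` outside the
    nucleus, the remainder in chromatin-poor nucleoplasm.

    The ``truth`` block stores the exact generative masks and the exact
    overlap fraction obtained by direct pixel counting. Deterministic
    given ``seed``.
    """
    if width < 64 or height < 64:
        raise ValueError("width and height must be >= 64")
    if phenotype.coloc_level + phenotype.cytoplasm_fraction > 1.0 + 1e-9:
        raise ValueError("coloc_level + cytoplasm_fraction exceed 1")
    rng = np.random.default_rng(seed)
    h, w = height, width

    # --- nucleus geometry ---
    cy = h / 2 + rng.uniform(-0.02, 0.02) * h
    cx = w / 2 + rng.uniform(-0.02, 0.02) * w
    ry = 0.38 * h * rng.uniform(0.92, 1.05)
    rx = 0.42 * w * rng.uniform(0.92, 1.05)
    theta = rng.uniform(0, np.pi)
    nucleus = _ellipse_mask(h, w, cy, cx, ry, rx, theta)

    # nucleoli: 1-3 dark holes, kept off the nuclear rim
    inner = _ellipse_mask(h, w, cy, cx, 0.7 * ry, 0.7 * rx, theta)
    nucleoli = np.zeros((h, w), dtype=bool)
    for _ in range(rng.integers(1, 4)):
        p = rng.choice(np.flatnonzero(inner))
        ncy, ncx = divmod(int(p), w)
        nucleoli |= _disk(h, w, ncy, ncx, rng.uniform(4.0, 7.0))
    nucleoli &= nucleus

    # --- heterochromatin blobs = DNA-foreground truth ---
    avail = nucleus & ~nucleoli
    target = int(round(_DNA_FOREGROUND_FRACTION * avail.sum()))
    het = np.zeros((h, w), dtype=bool)
    guard = 0
    while het.sum() < target and guard < 500:
        p = rng.choice(np.flatnonzero(avail))
        bcy, bcx = divmod(int(p), w)
        het |= _disk(h, w, bcy, bcx, rng.uniform(2.5, 5.5)) & avail
        guard += 1
    dna_fg = het

    # --- protein placement ---
    n_total = int(round(phenotype.aggregation_level * max(dna_fg.sum(), 1)))
    n_cyt = int(round(phenotype.cytoplasm_fraction * n_total))
    n_in = min(int(round(phenotype.coloc_level * n_total)), n_total - n_cyt)
    n_out = n_total - n_cyt - n_in

    nucleoplasm = avail & ~dna_fg
    outside = ~nucleus
    if phenotype.label == "diffuse":
        g = gaussian_filter(rng.standard_normal((h, w)), 3.0)
        wmap = np.exp(1.2 * g)  # mild granularity
        w_in = w_out = wmap
    elif phenotype.label == "dna_cage":
        w_in = w_out = None  # uniform over strata; the cage shape is het's
    elif phenotype.label == "anti_dna_aggregate":
        wmap = _blob_weight(rng, (h, w), inner & nucleoplasm,
                            rng.integers(2, 5), 7.0)
        # inverse localization: clusters keep a margin from chromatin
        wmap = wmap * np.clip(distance_transform_edt(~dna_fg) - 1.0, 0.05, 3.0)
        w_in = w_out = wmap
    else:  # condensate
        wmap = _blob_weight(rng, (h, w), inner & avail,
                            rng.integers(4, 9), 2.5)
        w_in = w_out = wmap

    pmask = np.zeros(h * w, dtype=bool)
    pmask[_sample_pixels(rng, dna_fg, min(n_in, int(dna_fg.sum())), w_in)] = True
    pmask[_sample_pixels(rng, nucleoplasm,
                         min(n_out, int(nucleoplasm.sum())), w_out)] = True
    pmask[_sample_pixels(rng, outside, min(n_cyt, int(outside.sum())))] = True
    protein_fg = pmask.reshape(h, w)

    # --- render intensities ---
    # Masks are rendered crisp (no PSF model); each channel always carries
    # a smooth low-amplitude texture field (chromatin/expression
    # heterogeneity), so histogram modes have finite width even at
    # noise_sd = 0, plus optional white detector noise.
    def texture() -> np.ndarray:
        f = gaussian_filter(rng.standard_normal((h, w)), 1.5)
        return 0.015 * f / f.std()

    dna = np.full((h, w), 0.10)
    dna[nucleus] = 0.16
    dna[nucleoli] = 0.08
    dna = dna + 0.58 * dna_fg + texture()
    dna += noise_sd * rng.standard_normal((h, w))

    protein = np.full((h, w), 0.05)
    protein = protein + 0.65 * protein_fg + texture()
    protein += noise_sd * rng.standard_normal((h, w))

    dna = np.clip(dna, 0.0, 1.0)
    protein = np.clip(protein, 0.0, 1.0)

    n_fg = int(protein_fg.sum())
    overlap = int((protein_fg & dna_fg).sum()) / n_fg if n_fg else float("nan")
    truth = {
        "phenotype": phenotype.label,
        "aggregation_level": phenotype.aggregation_level,
        "coloc_level": phenotype.coloc_level,
        "cytoplasm_fraction": phenotype.cytoplasm_fraction,
        "protein_mask": protein_fg,
        "dna_mask": dna_fg,
        "nucleus_mask": nucleus,
        "overlap_fraction": overlap,
        "noise_sd": noise_sd,
    }
    return ImagePair(protein=protein, dna=dna, pixel_size=pixel_size,
                     truth=truth, seed=seed)


# ---------------------------------------------------------------------------
# FRAP
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FrapSimParams:
    """Parameters of the single-exponential FRAP simulator.

    ``photofade_rate`` multiplies both the bleach ROI and the unbleached
    bleach-control trace by exp(-rate*t), so the bleach-control division
    in the normalization can undo it exactly. ``bleach_depth`` is the
    fraction of pre-bleach signal lost at the bleach frame. The true
    recovery half-time is ln(2)/k.
    """

    k: float = 0.04  # per second
    mobile_fraction: float = 0.85
    n_prebleach: int = 10
    n_postbleach: int = 135  # 145-frame series with 10 pre-bleach frames
    frame_interval: float = 0.5  # seconds
    photofade_rate: float = 0.002  # per second
    noise_sd: float = 0.0
    background_level: float = 0.05
    bleach_depth: float = 0.7
    i_pre: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("k must be > 0")
        if not 0 < self.mobile_fraction <= 1:
            raise ValueError("mobile_fraction must be in (0, 1]")
        if self.n_prebleach < 2 or self.n_postbleach < 10:
            raise ValueError("need >= 2 pre-bleach and >= 10 post-bleach frames")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.photofade_rate < 0 or self.noise_sd < 0 or self.background_level < 0:
            raise ValueError("rates/levels must be >= 0")
        if not 0 < self.bleach_depth <= 1:
            raise ValueError("bleach_depth must be in (0, 1]")

    @property
    def t_half(self) -> float:
        return float(np.log(2) / self.k)


@dataclass
class FrapRecording:
    """Per-frame FRAP traces; ``bleach_index`` is the first post-bleach frame."""

    t: np.ndarray
    roi: np.ndarray
    background: np.ndarray
    control: np.ndarray
    bleach_index: Optional[int] = None
    truth: Optional[dict] = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.roi = np.asarray(self.roi, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        self.control = np.asarray(self.control, dtype=float)
        n = self.t.size
        if not (self.roi.size == self.background.size == self.control.size == n):
            raise ValueError("all traces must have the same length as t")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")
        if self.bleach_index is not None and not 1 <= self.bleach_index < n:
            raise ValueError("bleach_index out of range")


def generate_frap_recording(params: FrapSimParams) -> FrapRecording:
    """Simulate one FRAP recording under the single-exponential model.

    The underlying signal is a pre-bleach plateau at ``i_pre``, an
    instantaneous drop to ``i_pre*(1-bleach_depth)`` at the bleach frame,
    and recovery I(t) = I_b + mobile*(I_pre - I_b)*(1 - exp(-k t)). The
    observed traces are signal*fade + background + noise; the unbleached
    control is i_pre*fade + background + noise.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_prebleach + params.n_postbleach
    t = np.arange(n) * params.frame_interval
    b = params.n_prebleach
    t_post = t - t[b]

    i_b = params.i_pre * (1.0 - params.bleach_depth)
    signal = np.full(n, params.i_pre)
    rec = i_b + params.mobile_fraction * (params.i_pre - i_b) * (
        1.0 - np.exp(-params.k * t_post[b:]))
    signal[b:] = rec

    fade = np.exp(-params.photofade_rate * t)
    noise = lambda: params.noise_sd * rng.standard_normal(n)  # noqa: E731
    roi = signal * fade + params.background_level + noise()
    control = params.i_pre * fade + params.background_level + noise()
    background = params.background_level + noise()

    truth = {
        "k": params.k,
        "mobile_fraction": params.mobile_fraction,
        "t_half": params.t_half,
        "bleach_depth": params.bleach_depth,
        "params": params,
    }
    return FrapRecording(t=t, roi=roi, background=background,
                         control=control, bleach_index=b, truth=truth)


# ---------------------------------------------------------------------------
# Dual-luciferase reporter
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReporterSimParams:
    """Parameters of the dual-luciferase plate simulator.

    ``mean_repression`` is 1 minus the condition's expected activity
    relative to the empty-vector control; ``cv`` is a multiplicative
    log-normal coefficient of variation applied independently to both
    luciferase counts (mean-preserving parameterization, so the expected
    relative activity equals 1 - mean_repression).
    """

    mean_repression: float = 0.0
    n_replicates: int = 8
    cv: float = 0.1
    renilla_mean: float = 5e4
    firefly_control_mean: float = 1e6
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mean_repression < 1.0:
            raise ValueError("mean_repression must be in [0, 1)")
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates")
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if self.renilla_mean <= 0 or self.firefly_control_mean <= 0:
            raise ValueError("luminescence means must be > 0")


@dataclass
class ReporterTable:
    """Tidy firefly/Renilla table plus the designated control label."""

    data: pd.DataFrame  # columns: condition, replicate, firefly, renilla
    control_label: str = "empty_vector"

    def __post_init__(self) -> None:
        required = {"condition", "replicate", "firefly", "renilla"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        ctrl = self.data[self.data["condition"] == self.control_label]
        if len(ctrl) < 2:
            raise ValueError(
                f"control condition {self.control_label!r} needs >= 2 replicates")
        if (self.data["renilla"] <= 0).any():
            raise ValueError("renilla counts must be strictly positive")


def _lognormal_factor(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Mean-1 multiplicative log-normal noise with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv * cv)
    return np.exp(rng.normal(-sigma2 / 2.0, np.sqrt(sigma2), size))


def generate_reporter_table(conditions, control_label: str = "empty_vector",
                            seed: Optional[int] = None) -> ReporterTable:
    """Simulate a dual-luciferase plate for a list of (label, params) pairs.

    Exactly one condition must carry ``control_label`` and have
    mean_repression = 0. Per replicate, firefly counts are drawn around
    firefly_control_mean*(1 - mean_repression) and Renilla counts around
    renilla_mean, both with independent mean-preserving log-normal noise,
    so the expected firefly/Renilla ratio of a condition relative to
    control equals 1 - mean_repression.
    """
    labels = [lab for lab, _ in conditions]
    if labels.count(control_label) != 1:
        raise ValueError(
            f"exactly one condition must be labeled {control_label!r}")
    ctrl_params = dict(conditions)[control_label]
    if ctrl_params.mean_repression != 0.0:
        raise ValueError("control condition must have mean_repression = 0")

    rows = []
    for i, (label, p) in enumerate(conditions):
        local_seed = p.seed if seed is None else seed + i
        rng = np.random.default_rng(local_seed)
        n = p.n_replicates
        firefly = (p.firefly_control_mean * (1.0 - p.mean_repression)
                   * _lognormal_factor(rng, p.cv, n))
        renilla = p.renilla_mean * _lognormal_factor(rng, p.cv, n)
        for r in range(n):
            rows.append((label, r + 1, firefly[r], renilla[r]))
    df = pd.DataFrame(rows, columns=["condition", "replicate",
                                     "firefly", "renilla"])
    return ReporterTable(data=df, control_label=control_label)
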