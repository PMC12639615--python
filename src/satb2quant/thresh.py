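"""Automatic histogram thresholding for 8-bit microscopy images.

Implements the four ImageJ/Fiji auto-threshold algorithms used throughout
the nuclear-localization quantification: Otsu (maximum between-class
variance), Li (iterative minimum cross-entropy), Moments (Tsai
moment-preserving) and Minimum (iterative-smoothing valley detection).

All algorithms operate on 256-bin histograms of min--max quantized images,
and the foreground convention is *strictly greater than* the returned
level, matching the ImageJ binary-output convention the area measurements
inherit. Tie-breaks always select the lowest qualifying level so results
are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ThresholdResult",
    "BinaryMask",
    "quantize_to_8bit",
    "histogram256",
    "otsu_threshold",
    "li_threshold",
    "li_update",
    "moments_threshold",
    "minimum_threshold",
    "apply_threshold",
    "METHODS",
]


@dataclass(frozen=True)
class ThresholdResult:
    """Integer threshold level in [0, 255] plus diagnostic flags."""

    level: int
    method: str
    degenerate: bool = False
    converged: bool = True
    iterations: int = 0

    def __int__(self) -> int:  # allows ``q > result`` style use
        return self.level


@dataclass
class BinaryMask:
    """Boolean foreground mask; foreground <=> quantized intensity > level."""

    mask: np.ndarray
    level: int
    method: str
    degenerate: bool = False

    @property
    def area(self) -> int:
        return int(self.mask.sum())


def quantize_to_8bit(image: np.ndarray) -> np.ndarray:
    """Linearly rescale an intensity image to integers in [0, 255].

    Rescaling is min--max; rounding is round-half-up. A constant image maps
    to all zeros so the downstream strictly-greater-than convention yields
    an empty foreground.
    """
    img = np.asarray(image, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    lo = img.min()
    hi = img.max()
    if hi == lo:
        return np.zeros(img.shape, dtype=np.uint8)
    scaled = (img - lo) / (hi - lo) * 255.0
    return np.clip(np.floor(scaled + 0.5), 0, 255).astype(np.uint8)


def histogram256(quantized: np.ndarray) -> np.ndarray:
    """256-bin integer histogram of an 8-bit image (or of bin indices)."""
    q = np.asarray(quantized)
    if q.size == 0:
        raise ValueError("empty image")
    counts = np.bincount(q.ravel().astype(np.int64), minlength=256)
    if counts.shape[0] > 256:
        raise ValueError("values outside [0, 255]")
    return counts


def _check_hist(hist: np.ndarray) -> np.ndarray:
    h = np.asarray(hist, dtype=float)
    if h.shape != (256,):
        raise ValueError("histogram must have exactly 256 bins")
    if np.any(h < 0):
        raise ValueError("negative histogram counts")
    if h.sum() <= 0:
        raise ValueError("histogram has zero total count")
    return h


def _occupied(h: np.ndarray) -> np.ndarray:
    return np.flatnonzero(h > 0)


def otsu_threshold(hist: np.ndarray) -> ThresholdResult:
    """Otsu's threshold: maximize between-class variance of {<=t}, {>t}.

    Ties are broken by the lowest level. A single-occupied-bin histogram is
    degenerate and returns that bin's index.
    """
    h = _check_hist(hist)
    occ = _occupied(h)
    if occ.size == 1:
        return ThresholdResult(int(occ[0]), "otsu", degenerate=True)
    p = h / h.sum()
    bins = np.arange(256, dtype=float)
    w0 = np.cumsum(p)
    mu0 = np.cumsum(p * bins)
    mu_t = mu0[-1]
    w1 = 1.0 - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        bcv = (mu_t * w0 - mu0) ** 2 / (w0 * w1)
    bcv[~((w0 > 0) & (w1 > 0))] = -np.inf
    level = int(np.argmax(bcv[:255]))
    return ThresholdResult(level, "otsu")


def li_update(hist: np.ndarray, level: float) -> float:
    """One step of the Li & Tam minimum cross-entropy iteration.

    Partitions the histogram at ``level`` (background = bins <= level) and
    returns the updated threshold from the two class means. Gray values
    are shifted by +1 internally so logarithms are defined at bin 0; the
    returned value is back on the [0, 255] gray scale.
    """
    h = _check_hist(hist)
    v = np.arange(256, dtype=float) + 1.0  # shifted gray values, all > 0
    back = v <= (level + 1.0)
    wb = h[back].sum()
    wf = h[~back].sum()
    if wb == 0 or wf == 0:
        return float(level)
    mu_b = (h[back] * v[back]).sum() / wb
    mu_f = (h[~back] * v[~back]).sum() / wf
    t_shifted = (mu_b - mu_f) / (np.log(mu_b) - np.log(mu_f))
    return float(t_shifted - 1.0)


def li_threshold(hist: np.ndarray, max_iter: int = 256) -> ThresholdResult:
    """Li's iterative minimum cross-entropy threshold.

    Iterates the Li & Tam update on integer partitions until the level is
    stationary (change < 0.5 gray levels). Returns the last iterate with
    ``converged=False`` if a limit cycle prevents convergence.
    """
    h = _check_hist(hist)
    occ = _occupied(h)
    if occ.size == 1:
        return ThresholdResult(int(occ[0]), "li", degenerate=True)
    lo, hi = int(occ[0]), int(occ[-1])

    def clamp(t: int) -> int:
        # keep both classes nonempty
        return int(np.clip(t, lo, hi - 1))

    v = np.arange(256, dtype=float)
    level = clamp(int(round((h * v).sum() / h.sum())))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        new = clamp(int(round(li_update(h, level))))
        if new == level:
            converged = True
            break
        level = new
    return ThresholdResult(level, "li", converged=converged, iterations=it)


def moments_threshold(hist: np.ndarray) -> ThresholdResult:
    """Tsai's moment-preserving threshold.

    Finds the two-level image sharing the first three gray-level moments
    with the input, then selects the level at the background-fraction
    percentile of the cumulative histogram (smallest level whose cumulative
    fraction reaches the background mass p0, equivalently where the tail
    fraction drops to the target foreground fraction).
    """
    h = _check_hist(hist)
    occ = _occupied(h)
    if occ.size == 1:
        return ThresholdResult(int(occ[0]), "moments", degenerate=True)
    p = h / h.sum()
    v = np.arange(256, dtype=float)
    m1 = (p * v).sum()
    m2 = (p * v**2).sum()
    m3 = (p * v**3).sum()
    cd = m2 - m1 * m1  # variance; m0 = 1
    if cd <= 1e-12:
        return ThresholdResult(int(np.argmax(h)), "moments", degenerate=True)
    c0 = (-m2 * m2 + m1 * m3) / cd
    c1 = (m1 * m2 - m3) / cd
    disc = c1 * c1 - 4.0 * c0
    if disc < 0:
        return ThresholdResult(int(np.argmax(h)), "moments", degenerate=True)
    z0 = 0.5 * (-c1 - np.sqrt(disc))
    z1 = 0.5 * (-c1 + np.sqrt(disc))
    if z1 == z0:
        return ThresholdResult(int(np.argmax(h)), "moments", degenerate=True)
    p0 = (z1 - m1) / (z1 - z0)  # background (dark-class) fraction
    cum = np.cumsum(p)
    level = int(np.argmax(cum >= p0 - 1e-12))
    return ThresholdResult(level, "moments")


def _local_maxima(y: np.ndarray) -> list[int]:
    """Interior local maxima of a 256-bin histogram, plateau-aware.

    A run of equal values counts as one maximum when both neighbors are
    strictly lower; runs touching bin 0 or 255 are not interior maxima.
    Returns one representative index (run center) per maximum.
    """
    peaks: list[int] = []
    i = 0
    n = y.size
    while i < n:
        j = i
        while j + 1 < n and y[j + 1] == y[i]:
            j += 1
        if (i > 0 and j < n - 1 and y[i - 1] < y[i] and y[j + 1] < y[j]):
            peaks.append((i + j) // 2)
        i = j + 1
    return peaks


def minimum_threshold(hist: np.ndarray, max_iter: int = 10_000) -> ThresholdResult:
    """Minimum-method threshold: smooth until bimodal, cut at the valley.

    The histogram is repeatedly smoothed with a 3-point running mean
    (edge-clamped) until exactly two interior local maxima remain; the
    returned level is the minimum of the smoothed histogram between the
    two modes (lowest index on ties). Raises if the histogram never
    becomes bimodal within the iteration cap (e.g. monotone input).
    """
    h = _check_hist(hist)
    y = h.copy()
    it = 0
    while len(_local_maxima(y)) != 2:
        if it >= max_iter:
            raise ValueError(
                "histogram did not become bimodal after "
                f"{max_iter} smoothing iterations (non-bimodal input)"
            )
        padded = np.empty(258)
        padded[1:-1] = y
        padded[0] = y[0]
        padded[-1] = y[-1]
        y = (padded[:-2] + padded[1:-1] + padded[2:]) / 3.0
        it += 1
    peaks = _local_maxima(y)
    p1, p2 = int(peaks[0]), int(peaks[1])
    level = p1 + int(np.argmin(y[p1 : p2 + 1]))
    return ThresholdResult(level, "minimum", iterations=it)


METHODS = {
    "otsu": otsu_threshold,
    "li": li_threshold,
    "moments": moments_threshold,
    "minimum": minimum_threshold,
}


def apply_threshold(image: np.ndarray, method: str) -> BinaryMask:
    """Quantize, threshold with the named method, and build a binary mask.

    Foreground is strictly above the level. For degenerate (e.g. constant)
    images the level is the single occupied bin, which yields an empty
    mask under the strictly-greater convention; callers treat empty masks
    as missing-value conditions, never as silent zeros.
    """
    if method not in METHODS:
        raise ValueError(f"unknown threshold method {method!r}; "
                         f"choose from {sorted(METHODS)}")
    q = quantize_to_8bit(image)
    res = METHODS[method](histogram256(q))
    return BinaryMask(mask=q > res.level, level=res.level,
                      method=method, degenerate=res.degenerate)
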