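"""FRAP curve normalization and single-exponential recovery fitting.

Normalization follows the double-normalization convention for confocal
FRAP series: framewise background subtraction, division by an unbleached
bleach-control trace (which exactly cancels acquisition photofading),
then full-scale anchoring with the pre-bleach mean at 100% and the
bleach-frame value at 0%. The recovery model is the two-parameter
single-component exponential y(t) = A * (1 - exp(-k t)) fitted on
post-bleach frames (t = 0 at the bleach frame, y(0) = 0 through the
model); the recovery half-time is t_half = ln(2)/k and, on a full-scale
normalized curve, the plateau A is the mobile fraction in percent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from . import stats as _stats
from .synth import FrapRecording

__all__ = [
    "NormalizedCurve",
    "FrapFit",
    "normalize_frap",
    "fit_single_exponential",
    "fit_recording",
    "group_frap_compare",
]

LN2 = float(np.log(2.0))


@dataclass
class NormalizedCurve:
    """Full-scale normalized recovery curve.

    ``t_post``/``y`` cover the post-bleach frames with t_post[0] = 0 and
    y[0] = 0 at the bleach frame; ``y_prebleach`` holds the normalized
    pre-bleach frames, whose mean is 100 exactly by construction.
    """

    t_post: np.ndarray
    y: np.ndarray
    y_prebleach: np.ndarray

    def __post_init__(self) -> None:
        self.t_post = np.asarray(self.t_post, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.y_prebleach = np.asarray(self.y_prebleach, dtype=float)
        if self.t_post.size != self.y.size:
            raise ValueError("t_post and y must have the same length")
        if self.t_post.size and self.t_post[0] != 0.0:
            raise ValueError("t_post must start at the bleach frame (0)")


@dataclass(frozen=True)
class FrapFit:
    """Single-exponential recovery fit; t_half * k = ln(2) exactly."""

    plateau: float  # percent; mobile fraction on a full-scale curve
    k: float        # per second
    t_half: float   # seconds, = ln(2)/k
    r_squared: float
    converged: bool


def _detect_bleach_index(roi: np.ndarray, background: np.ndarray) -> int:
    """Bleach frame = global minimum of the background-subtracted ROI
    trace (earliest on ties)."""
    return int(np.argmin(roi - background))


def normalize_frap(rec: FrapRecording) -> NormalizedCurve:
    """Background-subtract, bleach-control-correct and full-scale anchor.

    Steps: (1) subtract the background trace framewise from both the ROI
    and the control; (2) divide ROI by control (undoes photofading);
    (3) anchor y = 100*(x - x_bleach)/(x_pre - x_bleach) with x_pre the
    mean of the pre-bleach frames and x_bleach the bleach-frame value.
    """
    b = rec.bleach_index
    if b is None:
        b = _detect_bleach_index(rec.roi, rec.background)
        if b < 1:
            raise ValueError("could not locate a bleach event")
    if b < 2:
        raise ValueError("need >= 2 pre-bleach frames")
    roi_c = rec.roi - rec.background
    ctrl_c = rec.control - rec.background
    if np.any(ctrl_c <= 0):
        raise ValueError("bleach-control trace not positive after "
                         "background subtraction")
    x = roi_c / ctrl_c
    x_pre = float(x[:b].mean())
    x_bleach = float(x[b])
    if x_pre <= x_bleach:
        raise ValueError("no bleach depth (pre-bleach mean <= bleach value)")
    y = 100.0 * (x - x_bleach) / (x_pre - x_bleach)
    t_post = rec.t - rec.t[b]
    return NormalizedCurve(t_post=t_post[b:], y=y[b:], y_prebleach=y[:b])


def fit_single_exponential(curve: NormalizedCurve, *,
                           max_nfev: int = 10_000) -> FrapFit:
    """Least-squares fit of y(t) = A*(1 - exp(-k t)) on post-bleach frames.

    Initialization: A0 = mean of the final 10% of frames; k0 from the
    first time the curve crosses A0/2. k is bounded strictly positive.
    A non-converged solver returns its best iterate with the flag down.
    """
    t = curve.t_post
    y = curve.y
    if t.size < 10:
        raise ValueError("need >= 10 post-bleach points")

    tail = max(1, t.size // 10)
    a0 = float(y[-tail:].mean())
    if not np.isfinite(a0) or a0 <= 0:
        a0 = max(float(np.nanmax(y)), 1.0)
    above = np.flatnonzero((y >= a0 / 2.0) & (t > 0))
    k0 = LN2 / float(t[above[0]]) if above.size else LN2 / float(t[-1] / 2.0)

    def resid(p: np.ndarray) -> np.ndarray:
        a, k = p
        return a * (1.0 - np.exp(-k * t)) - y

    res = least_squares(resid, x0=[a0, max(k0, 1e-6)],
                        bounds=([0.0, 1e-12], [np.inf, np.inf]),
                        xtol=1e-8, ftol=1e-8, gtol=1e-8, max_nfev=max_nfev)
    a, k = res.x
    ss_res = float(np.sum(res.fun**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return FrapFit(plateau=float(a), k=float(k), t_half=LN2 / float(k),
                   r_squared=r2, converged=bool(res.status > 0))


def fit_recording(rec: FrapRecording) -> FrapFit:
    """Normalize a raw recording and fit the single-exponential model."""
    return fit_single_exponential(normalize_frap(rec))


def group_frap_compare(fits: Mapping[str, Iterable[FrapFit]],
                       reference: str, *, n_draws: int = 100_000,
                       seed: int = 0) -> pd.DataFrame:
    """Compare per-recording recovery half-times across variant groups.

    Produces per-group summaries (median and boxplot statistics of
    t_half) and Dunnett-adjusted p-values against the reference group.
    Groups with fewer than two fits are excluded with a warning.
    """
    if reference not in fits:
        raise ValueError(f"reference group {reference!r} missing")
    halves: dict[str, np.ndarray] = {}
    for group, group_fits in fits.items():
        vals = np.array([f.t_half for f in group_fits], dtype=float)
        if vals.size < 2:
            warnings.warn(f"group {group!r} has < 2 fits; excluded")
            continue
        halves[group] = vals
    if reference not in halves:
        raise ValueError(f"reference group {reference!r} has < 2 fits")
    if len(halves) < 2:
        raise ValueError("need >= 2 groups with >= 2 fits each")

    data = _stats.GroupedMeasurements(halves, reference=reference)
    summary = _stats.summarize_groups(data)
    dunnett = _stats.dunnett_test(data, n_draws=n_draws, seed=seed)
    out = summary.merge(
        dunnett.table.rename(columns={"group": "group"}), on="group",
        how="left")
    out.attrs["df_error"] = dunnett.df_error
    out.attrs["mse"] = dunnett.mse
    out.attrs["seed"] = seed
    out.attrs["n_draws"] = dunnett.n_draws
    return out
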