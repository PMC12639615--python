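"""One-way ANOVA and Dunnett's many-to-one post hoc test.

This is the sole inferential machinery of the pipeline: every cell-based
readout (image ratios, FRAP half-times, relative luciferase activities)
is compared across variant groups against a single reference with a
one-way ANOVA followed by Dunnett's test.

Dunnett-adjusted p-values are evaluated by seeded Monte-Carlo integration
of the equicorrelated multivariate-t null: with pooled within-group
degrees of freedom nu and group weights lambda_i = n_i/(n_i + n_ref), the
test statistics are jointly t-distributed with correlation
rho_ij = sqrt(lambda_i * lambda_j) (rho = 1/2 in balanced designs). The
construction samples a shared control normal, independent group normals
and a shared chi factor, so the procedure is dimension-agnostic and
reproducible bit-for-bit given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupedMeasurements",
    "AnovaResult",
    "DunnettResult",
    "one_way_anova",
    "dunnett_test",
    "summarize_groups",
]


@dataclass
class GroupedMeasurements:
    """Per-group observation vectors with one designated reference group."""

    groups: Mapping[str, np.ndarray]
    reference: str

    def __post_init__(self) -> None:
        self.groups = {k: np.asarray(v, dtype=float)
                       for k, v in self.groups.items()}
        if len(self.groups) < 2:
            raise ValueError("need at least 2 groups")
        if self.reference not in self.groups:
            raise ValueError(f"reference group {self.reference!r} missing")
        for name, v in self.groups.items():
            if v.ndim != 1 or v.size < 2:
                raise ValueError(f"group {name!r} needs >= 2 observations")
            if not np.all(np.isfinite(v)):
                raise ValueError(f"group {name!r} contains non-finite values")

    @property
    def others(self) -> list[str]:
        return [g for g in self.groups if g != self.reference]


@dataclass(frozen=True)
class AnovaResult:
    F: float
    p_value: float
    df_between: int
    df_within: int
    degenerate: bool = False


def _is_degenerate(ss_within: float, values: np.ndarray) -> bool:
    """Zero within-group variance up to float round-off (relative to the
    overall scale of the data)."""
    scale = float(np.mean(values**2))
    return ss_within <= 1e-12 * max(scale, 1e-300)


def one_way_anova(data: GroupedMeasurements) -> AnovaResult:
    """Standard one-way fixed-effects ANOVA (SS decomposition + F test).

    If the within-group variance is exactly zero everywhere the F
    statistic is undefined and the result is flagged degenerate.
    """
    vecs = list(data.groups.values())
    ns = np.array([v.size for v in vecs])
    total_n = int(ns.sum())
    k = len(vecs)
    if total_n <= k:
        raise ValueError("total n must exceed the number of groups")
    grand = np.concatenate(vecs).mean()
    ss_between = float(sum(n * (v.mean() - grand) ** 2
                           for n, v in zip(ns, vecs)))
    ss_within = float(sum(((v - v.mean()) ** 2).sum() for v in vecs))
    df_b, df_w = k - 1, total_n - k
    if _is_degenerate(ss_within, np.concatenate(vecs)):
        return AnovaResult(float("nan"), float("nan"), df_b, df_w,
                           degenerate=True)
    F = (ss_between / df_b) / (ss_within / df_w)
    return AnovaResult(F, float(sps.f.sf(F, df_b, df_w)), df_b, df_w)


@dataclass
class DunnettResult:
    """Per-comparison Dunnett statistics against the reference group.

    ``table`` has one row per non-reference group: mean difference,
    pooled-t statistic, unadjusted pooled-t p, Monte-Carlo adjusted p
    with its standard error. The adjusted p is clipped from below at the
    unadjusted p (the exact family-wise probability can never be
    smaller than the marginal one, so Monte-Carlo noise is not allowed
    to violate that bound).
    """

    table: pd.DataFrame
    df_error: int
    mse: float
    correlation: np.ndarray
    seed: Optional[int]
    n_draws: int
    degenerate: bool = False


def _mc_max_abs_t(lam: np.ndarray, df: int, n_draws: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Draws of max_j |T_j| under the equicorrelated multivariate-t null."""
    k = lam.size
    z0 = rng.standard_normal(n_draws)
    z = rng.standard_normal((n_draws, k))
    num = np.sqrt(lam) * z0[:, None] + np.sqrt(1.0 - lam) * z
    w = np.sqrt(rng.chisquare(df, n_draws) / df)
    return np.abs(num / w[:, None]).max(axis=1)


def dunnett_test(data: GroupedMeasurements, *, n_draws: int = 100_000,
                 seed: int = 0) -> DunnettResult:
    """Dunnett's two-sided many-to-one comparison via seeded Monte-Carlo.

    t_i = (mean_i - mean_ref) / sqrt(MSE * (1/n_i + 1/n_ref)) with MSE the
    pooled within-group variance; adjusted p_i = P(max_j |T_j| >= |t_i|)
    under the multivariate-t null. With a single comparison the adjusted
    p equals the plain pooled two-sample t p-value (up to Monte-Carlo
    error, and exactly after the lower-bound clip).
    """
    ref = data.groups[data.reference]
    others = data.others
    ns = {g: data.groups[g].size for g in data.groups}
    total_n = sum(ns.values())
    k_total = len(data.groups)
    df = total_n - k_total
    if df < 1:
        raise ValueError("pooled error degrees of freedom must be >= 1")
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in data.groups.values())
    mse = float(ss_within / df)
    degenerate = _is_degenerate(float(ss_within),
                                np.concatenate(list(data.groups.values())))

    lam = np.array([ns[g] / (ns[g] + ns[data.reference]) for g in others])
    corr = np.sqrt(np.outer(lam, lam))
    np.fill_diagonal(corr, 1.0)

    rows = []
    if degenerate:
        for g in others:
            diff = float(data.groups[g].mean() - ref.mean())
            rows.append((g, diff, float("nan"), float("nan"),
                         float("nan"), float("nan")))
        table = pd.DataFrame(rows, columns=["group", "mean_diff", "t",
                                            "p_unadjusted", "p_adjusted",
                                            "p_mc_se"])
        return DunnettResult(table, df, mse, corr, seed, 0, degenerate=True)

    rng = np.random.default_rng(seed)
    max_abs = _mc_max_abs_t(lam, df, n_draws, rng)
    for g, lam_g in zip(others, lam):
        v = data.groups[g]
        diff = float(v.mean() - ref.mean())
        se = np.sqrt(mse * (1.0 / v.size + 1.0 / ref.size))
        t = diff / se
        p_un = float(2.0 * sps.t.sf(abs(t), df))
        p_mc = float(np.mean(max_abs >= abs(t)))
        p_se = float(np.sqrt(p_mc * (1.0 - p_mc) / n_draws))
        p_adj = min(max(p_mc, p_un), 1.0)
        rows.append((g, diff, t, p_un, p_adj, p_se))
    table = pd.DataFrame(rows, columns=["group", "mean_diff", "t",
                                        "p_unadjusted", "p_adjusted",
                                        "p_mc_se"])
    return DunnettResult(table, df, mse, corr, seed, n_draws)


def summarize_groups(data: GroupedMeasurements) -> pd.DataFrame:
    """Per-group mean, SEM, median and boxplot five-number summary."""
    rows = []
    for name, v in data.groups.items():
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        rows.append({
            "group": name,
            "n": v.size,
            "mean": float(v.mean()),
            "sem": float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else float("nan"),
            "median": float(med),
            "min": float(v.min()),
            "q1": float(q1),
            "q3": float(q3),
            "max": float(v.max()),
        })
    return pd.DataFrame(rows)
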