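"""Dual-luciferase normalization and relative transcriptional activity.

Firefly counts are normalized by the co-transfected Renilla counts per
replicate (transfection-efficiency control), then scaled by the mean
ratio of the empty-vector control condition so the control's mean
relative activity is 1 by construction. SATB2 is a transcriptional
repressor on its MAR reporter targets, so WT-like conditions sit well
below 1. Variant calls (reduced / retained / increased repression) come
from Dunnett-adjusted comparisons of replicate-level relative activities
against the wild-type condition.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from . import stats as _stats
from .synth import ReporterTable

__all__ = [
    "relative_activity",
    "repression_call",
    "REPRESSION_CALLS",
]

REPRESSION_CALLS = ("reduced_repression", "retained", "increased_repression")


def relative_activity(table: ReporterTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-replicate and per-condition relative luciferase activities.

    Ratio r = firefly/renilla per replicate; relative activity is r
    divided by the mean r of the control condition (unpaired, since
    conditions are independent transfections). Returns the replicate
    table (with ``ratio`` and ``relative_activity`` columns) and a
    per-condition summary with mean +/- SEM.
    """
    df = table.data.copy()
    if (df["renilla"] <= 0).any():
        raise ValueError("renilla counts must be strictly positive")
    if (df["firefly"] < 0).any():
        raise ValueError("firefly counts must be >= 0")
    df["ratio"] = df["firefly"] / df["renilla"]
    ctrl = df.loc[df["condition"] == table.control_label, "ratio"]
    if len(ctrl) < 2:
        raise ValueError("control condition needs >= 2 replicates")
    ctrl_mean = float(ctrl.mean())
    if ctrl_mean <= 0:
        raise ValueError("control condition has non-positive mean ratio")
    df["relative_activity"] = df["ratio"] / ctrl_mean

    rows = []
    for cond, sub in df.groupby("condition", sort=False):
        v = sub["relative_activity"].to_numpy()
        rows.append({
            "condition": cond,
            "n": v.size,
            "mean_relative_activity": float(v.mean()),
            "sem": float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1
                   else float("nan"),
            "percent_reduction": 100.0 * (1.0 - float(v.mean())),
        })
    return df, pd.DataFrame(rows)


def repression_call(table: ReporterTable, wt_label: str = "WT", *,
                    alpha: float = 0.05, n_draws: int = 100_000,
                    seed: int = 0) -> pd.DataFrame:
    """Classify each variant condition's transrepressive activity vs WT.

    Each non-control, non-WT condition is compared to the WT condition
    with Dunnett's test on replicate-level relative activities:
    significantly higher activity than WT -> ``reduced_repression``,
    significantly lower -> ``increased_repression``, otherwise
    ``retained``. Conditions with degenerate variance are flagged
    uncallable (NA). The empty-vector control is the normalizer, not a
    member of the comparison family.
    """
    reps, _ = relative_activity(table)
    if wt_label not in set(reps["condition"]):
        raise ValueError(f"WT condition {wt_label!r} missing")
    groups = {
        cond: sub["relative_activity"].to_numpy()
        for cond, sub in reps.groupby("condition", sort=False)
        if cond != table.control_label
    }
    if len(groups) < 2:
        raise ValueError("no variant conditions to compare against WT")
    for cond, v in groups.items():
        if v.size < 2:
            raise ValueError(f"condition {cond!r} needs >= 2 replicates")

    data = _stats.GroupedMeasurements(groups, reference=wt_label)
    res = _stats.dunnett_test(data, n_draws=n_draws, seed=seed)
    rows = []
    for _, row in res.table.iterrows():
        if res.degenerate or not np.isfinite(row["p_adjusted"]):
            call = "NA"
        elif row["p_adjusted"] < alpha:
            call = ("reduced_repression" if row["mean_diff"] > 0
                    else "increased_repression")
        else:
            call = "retained"
        rows.append({
            "condition": row["group"],
            "mean_diff_vs_wt": row["mean_diff"],
            "t": row["t"],
            "p_adjusted": row["p_adjusted"],
            "call": call,
        })
    out = pd.DataFrame(rows)
    out.attrs["alpha"] = alpha
    out.attrs["seed"] = seed
    out.attrs["n_draws"] = n_draws
    out.attrs["reference"] = wt_label
    return out
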