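"""Functional subgroup classification of SATB2 missense variants.

Combines the standardized per-variant readouts (nuclear aggregation,
DNA colocalization, nuclear fraction, transrepression on two MAR
reporters, and FRAP mobility) into functional subgroups:

* ``increased_function`` -- stronger colocalization with DNA together
  with maintained or increased transcriptional repression (reduced
  nuclear mobility supports the call but is not required);
* ``partial_LoF``        -- reduced repression on at least one reporter
  without increased DNA colocalization;
* ``condensate_class``   -- HOX-domain variants or variants forming
  abnormal nuclear condensates (treated apart from CUT-domain partial
  LoF even though their repression is also reduced);
* ``unclassified``       -- profiles matching none of the above.

The rule table operationalizes verbal criteria rather than a published
formal decision rule, so it is versioned and kept editable; alternative
operationalizations can be compared by swapping rule versions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from . import stats as _stats
from . import reporter as _reporter
from .synth import ReporterTable

__all__ = [
    "VariantProfile",
    "RULE_VERSION",
    "SUBGROUPS",
    "assign_subgroup",
    "build_profiles",
    "cohort_summary",
    "reference_cohort",
    "profiles_to_frame",
]

RULE_VERSION = "v1"
SUBGROUPS = ("increased_function", "partial_LoF", "condensate_class",
             "unclassified")
_CALLS = ("increased", "normal", "decreased", "NA")
_REP_CALLS = ("reduced_repression", "retained", "increased_repression", "NA")
_MOB_CALLS = ("reduced_mobility", "normal", "NA")


@dataclass
class VariantProfile:
    """Standardized assay outcomes for one variant (protein notation id).

    Every call derives from a Dunnett-adjusted comparison against WT at
    the configured alpha; NA marks readouts the variant was not assayed
    on. ``condensate_pattern`` flags the abnormal punctate localization
    seen for HOX-domain variants.
    """

    variant: str
    domain: str = "none"  # CUT1 | CUT2 | HOX | none
    aggregation_call: str = "NA"
    coloc_call: str = "NA"
    nuclear_fraction_call: str = "NA"
    repression_call_ctip2: str = "NA"
    repression_call_nr4a2: str = "NA"
    mobility_call: str = "NA"
    condensate_pattern: bool = False
    subgroup: Optional[str] = None

    def __post_init__(self) -> None:
        if self.domain not in ("CUT1", "CUT2", "HOX", "none"):
            raise ValueError(f"unknown domain {self.domain!r}")
        for name, allowed in (
                ("aggregation_call", _CALLS), ("coloc_call", _CALLS),
                ("nuclear_fraction_call", _CALLS),
                ("repression_call_ctip2", _REP_CALLS),
                ("repression_call_nr4a2", _REP_CALLS),
                ("mobility_call", _MOB_CALLS)):
            if getattr(self, name) not in allowed:
                raise ValueError(f"{name} must be one of {allowed}")

    @property
    def calls(self) -> dict[str, str]:
        return {
            "aggregation": self.aggregation_call,
            "coloc": self.coloc_call,
            "nuclear_fraction": self.nuclear_fraction_call,
            "repression_ctip2": self.repression_call_ctip2,
            "repression_nr4a2": self.repression_call_nr4a2,
            "mobility": self.mobility_call,
        }


def assign_subgroup(profile: VariantProfile,
                    rule_version: str = RULE_VERSION) -> str:
    """Pure function mapping a profile's call fields to a subgroup label.

    Rule v1 (in priority order): condensate_class for HOX-domain or
    condensate-pattern variants; increased_function when coloc is
    increased and no reporter shows reduced repression; partial_LoF when
    at least one reporter shows reduced repression and coloc is not
    increased; otherwise unclassified. A profile can never be both
    increased_function and partial_LoF.
    """
    if rule_version != RULE_VERSION:
        raise ValueError(f"unknown rule version {rule_version!r}")
    if all(c == "NA" for c in profile.calls.values()) and not profile.condensate_pattern:
        raise ValueError(f"profile {profile.variant!r} has no non-NA call")
    reps = (profile.repression_call_ctip2, profile.repression_call_nr4a2)
    any_reduced = "reduced_repression" in reps
    if profile.domain == "HOX" or profile.condensate_pattern:
        return "condensate_class"
    if profile.coloc_call == "increased" and not any_reduced:
        return "increased_function"
    if any_reduced and profile.coloc_call != "increased":
        return "partial_LoF"
    return "unclassified"


def _direction_call(row: Optional[pd.Series], alpha: float) -> str:
    if row is None or not np.isfinite(row["p_adjusted"]):
        return "NA"
    if row["p_adjusted"] >= alpha:
        return "normal"
    return "increased" if row["mean_diff"] > 0 else "decreased"


def _dunnett_calls(df: pd.DataFrame, value: str, wt_label: str,
                   alpha: float, n_draws: int, seed: int) -> dict[str, pd.Series]:
    groups = {v: sub[value].dropna().to_numpy()
              for v, sub in df.groupby("variant", sort=False)}
    groups = {v: x for v, x in groups.items() if x.size >= 2}
    if wt_label not in groups:
        raise ValueError(f"WT group missing or too small for {value!r}")
    if len(groups) < 2:
        return {}
    data = _stats.GroupedMeasurements(groups, reference=wt_label)
    res = _stats.dunnett_test(data, n_draws=n_draws, seed=seed)
    return {row["group"]: row for _, row in res.table.iterrows()}


def build_profiles(imaging: Optional[pd.DataFrame] = None,
                   frap_fits: Optional[pd.DataFrame] = None,
                   reporter_ctip2: Optional[ReporterTable] = None,
                   reporter_nr4a2: Optional[ReporterTable] = None,
                   *, wt_label: str = "WT", alpha: float = 0.05,
                   domains: Optional[Mapping[str, str]] = None,
                   n_draws: int = 100_000, seed: int = 0
                   ) -> list[VariantProfile]:
    """Join assay outputs keyed by variant into VariantProfiles.

    ``imaging`` is the per-image table from ``imgmetrics.batch_quantify``
    (column ``group`` is the variant); ``frap_fits`` needs columns
    ``variant`` and ``t_half``; the two reporters are ReporterTables
    whose condition labels are variant ids. WT must be present in every
    supplied table; variants found in no table are excluded with a
    warning. Every call is traceable to an adjusted p-value and effect
    direction.
    """
    if all(x is None for x in (imaging, frap_fits, reporter_ctip2,
                               reporter_nr4a2)):
        raise ValueError("at least one assay table is required")
    domains = dict(domains or {})
    calls: dict[str, dict[str, str]] = {}

    def record(variant: str, readout: str, call: str) -> None:
        calls.setdefault(variant, {})[readout] = call

    if imaging is not None:
        img = imaging.rename(columns={"group": "variant"})
        for metric, readout in (("aggregation_ratio", "aggregation"),
                                ("coloc_ratio", "coloc"),
                                ("nuclear_fraction", "nuclear_fraction")):
            if metric not in img:
                continue
            rows = _dunnett_calls(img, metric, wt_label, alpha, n_draws, seed)
            for variant in img["variant"].unique():
                if variant == wt_label:
                    record(variant, readout, "normal")
                else:
                    record(variant, readout,
                           _direction_call(rows.get(variant), alpha))
    if frap_fits is not None:
        rows = _dunnett_calls(frap_fits, "t_half", wt_label, alpha,
                              n_draws, seed)
        for variant in frap_fits["variant"].unique():
            if variant == wt_label:
                record(variant, "mobility", "normal")
            else:
                d = _direction_call(rows.get(variant), alpha)
                # longer half-time = slower recovery = reduced mobility
                record(variant, "mobility",
                       "reduced_mobility" if d == "increased"
                       else ("NA" if d == "NA" else "normal"))
    for tbl, readout in ((reporter_ctip2, "repression_ctip2"),
                         (reporter_nr4a2, "repression_nr4a2")):
        if tbl is None:
            continue
        res = _reporter.repression_call(tbl, wt_label, alpha=alpha,
                                        n_draws=n_draws, seed=seed)
        record(wt_label, readout, "retained")
        for _, row in res.iterrows():
            record(row["condition"], readout, row["call"])

    profiles = []
    for variant, c in calls.items():
        profiles.append(VariantProfile(
            variant=variant,
            domain=domains.get(variant, "none"),
            aggregation_call=c.get("aggregation", "NA"),
            coloc_call=c.get("coloc", "NA"),
            nuclear_fraction_call=c.get("nuclear_fraction", "NA"),
            repression_call_ctip2=c.get("repression_ctip2", "NA"),
            repression_call_nr4a2=c.get("repression_nr4a2", "NA"),
            mobility_call=c.get("mobility", "NA"),
        ))
    for p in profiles:
        p.subgroup = assign_subgroup(p)
    return profiles


def cohort_summary(profiles: Iterable[VariantProfile]) -> pd.DataFrame:
    """Subgroup counts and fractions of the total tested cohort."""
    profiles = list(profiles)
    if not profiles:
        raise ValueError("no profiles")
    labels = [p.subgroup or assign_subgroup(p) for p in profiles]
    total = len(labels)
    rows = []
    for sg in SUBGROUPS:
        n = labels.count(sg)
        rows.append({"subgroup": sg, "count": n, "fraction": n / total,
                     "percent": 100.0 * n / total})
    out = pd.DataFrame(rows)
    out.attrs["total"] = total
    return out


def profiles_to_frame(profiles: Iterable[VariantProfile]) -> pd.DataFrame:
    """Variant x readout call matrix (overview-figure style) as a table."""
    rows = []
    for p in profiles:
        row = {"variant": p.variant, "domain": p.domain}
        row.update(p.calls)
        row["condensate_pattern"] = p.condensate_pattern
        row["subgroup"] = p.subgroup or assign_subgroup(p)
        rows.append(row)
    return pd.DataFrame(rows)


def reference_cohort() -> list[VariantProfile]:
    """The 31-variant etiological cohort with its reported outcomes.

    Encodes, per variant, the functional outcome pattern reported for
    the etiological SATB2 missense screen: eight named variants with
    stronger DNA colocalization and maintained-or-increased repression
    (five of which also showed reduced FRAP mobility), three HOX-domain
    variants forming nuclear condensates with reduced repression, and
    twenty CUT-domain variants with partial loss of function. Variants
    whose individual outcome rows are not enumerated in the published
    text carry synthetic placeholder ids (``CUT?_unnamed_*``,
    ``HOX_unnamed_*``); their outcome pattern, and the 8/31 arithmetic,
    follow the reported totals.
    """
    profiles: list[VariantProfile] = []

    increased = {
        "p.Glu396Gln": ("CUT1", "reduced_mobility"),
        "p.Glu401Lys": ("CUT1", "NA"),
        "p.Glu402Lys": ("CUT1", "reduced_mobility"),
        "p.Gln409Arg": ("CUT1", "NA"),
        "p.Glu436Val": ("CUT1", "reduced_mobility"),
        "p.Gln514Arg": ("CUT2", "reduced_mobility"),
        "p.Gly515Ser": ("CUT2", "reduced_mobility"),
        "p.Glu566Lys": ("CUT2", "NA"),
    }
    for var, (domain, mob) in increased.items():
        profiles.append(VariantProfile(
            variant=var, domain=domain, aggregation_call="decreased",
            coloc_call="increased", repression_call_ctip2="retained",
            repression_call_nr4a2="increased_repression",
            mobility_call=mob))

    partial_lof_named = {
        "p.Ala386Val": "CUT1", "p.Arg389Cys": "CUT1", "p.Arg389Leu": "CUT1",
        "p.Thr390Ile": "CUT1", "p.Gln391Arg": "CUT1", "p.Gly392Arg": "CUT1",
        "p.Gly392Glu": "CUT1", "p.Gly392Val": "CUT1", "p.Arg399His": "CUT1",
        "p.Arg429Gln": "CUT1", "p.Cys518Trp": "CUT2", "p.Arg522Cys": "CUT2",
        "p.Leu545Pro": "CUT2",
    }
    lof_ids = list(partial_lof_named.items()) + [
        (f"CUT1_unnamed_{i}", "CUT1") for i in range(1, 5)
    ] + [(f"CUT2_unnamed_{i}", "CUT2") for i in range(1, 4)]
    for var, domain in lof_ids:
        profiles.append(VariantProfile(
            variant=var, domain=domain, aggregation_call="decreased",
            coloc_call="decreased",
            repression_call_ctip2="reduced_repression",
            repression_call_nr4a2="reduced_repression",
            mobility_call="normal"))

    for i in range(1, 4):
        profiles.append(VariantProfile(
            variant=f"HOX_unnamed_{i}", domain="HOX",
            aggregation_call="decreased", coloc_call="normal",
            repression_call_ctip2="reduced_repression",
            repression_call_nr4a2="reduced_repression",
            condensate_pattern=True))

    assert len(profiles) == 31
    for p in profiles:
        p.subgroup = assign_subgroup(p)
    return profiles
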