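"""Specificity, PAM-compatibility and mismatch-stratification summaries.

Specificity of a guide/variant is 1 - (corrected indel frequency at the
mismatched target / corrected frequency at the perfectly matched
target); relative activity is the complementary ratio off/on. Summaries
operate on filtered, background-corrected frequency tables joined to
library mismatch annotations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .library_model import GuideTargetPair

__all__ = [
    "specificity",
    "relative_activity",
    "specificity_table",
    "pam_profile",
    "positionwise_specificity",
    "stratify_by_mismatch",
    "tradeoff_summary",
    "select_comparable_guides",
    "annotation_frame",
]


class UndefinedSpecificity(ValueError):
    """On-target frequency is zero; the ratio is undefined."""


class SelectionError(ValueError):
    """No overlapping guides across variants."""


def specificity(on_pct: float, off_pct: float) -> float:
    """1 - off/on. Undefined (raises) when on_pct = 0."""
    if on_pct <= 0:
        raise UndefinedSpecificity("on-target frequency must be > 0")
    return 1.0 - off_pct / on_pct


def relative_activity(off_pct: float, on_pct: float) -> float:
    """off/on, the complement of specificity."""
    if on_pct <= 0:
        raise UndefinedSpecificity("on-target frequency must be > 0")
    return off_pct / on_pct


def annotation_frame(pairs: Sequence[GuideTargetPair]) -> pd.DataFrame:
    """Per-pair mismatch summary for joining onto frequency tables.

    guide_id is the pair_id prefix before the last underscore-delimited
    target token (the convention of the synthetic library builder).
    """
    rows = []
    for p in pairs:
        designed = [m for m in p.mismatches if not m.five_prime_g]
        rows.append(
            {
                "pair_id": p.pair_id,
                "guide_id": p.pair_id.rsplit("_", 1)[0],
                "is_matched": len(designed) == 0,
                "n_mismatch": len(designed),
                "mm_positions": ",".join(str(m.position_pam) for m in designed),
                "mm_classes": ",".join(m.mclass for m in designed),
                "pam": p.pam,
                "pam_class": p.pam_class,
                "pam4": p.pam4,
            }
        )
    return pd.DataFrame(rows)


def specificity_table(
    freq: pd.DataFrame, annotations: pd.DataFrame
) -> pd.DataFrame:
    """Join mismatched-target frequencies to their guide's matched
    target and compute specificity / relative activity per record.

    ``freq`` needs pair_id, variant, day, corrected_pct (filtered rows
    only). Records whose guide has no (passing) matched target, or a
    matched corrected frequency of 0, are dropped with a reason column
    in the returned attrs.
    """
    df = freq.merge(annotations, on="pair_id", how="inner")
    matched = (
        df[df["is_matched"]]
        .loc[:, ["guide_id", "variant", "day", "corrected_pct"]]
        .rename(columns={"corrected_pct": "on_pct"})
    )
    off = df[~df["is_matched"]].rename(columns={"corrected_pct": "off_pct"})
    out = off.merge(matched, on=["guide_id", "variant", "day"], how="inner")
    dropped_zero_on = int((out["on_pct"] <= 0).sum())
    out = out[out["on_pct"] > 0].copy()
    out["relative_activity"] = out["off_pct"] / out["on_pct"]
    out["specificity"] = 1.0 - out["relative_activity"]
    out.attrs["dropped_zero_on"] = dropped_zero_on
    return out


def pam_profile(
    freq: pd.DataFrame, annotations: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean corrected frequency per 4-nt PAM and per PAM class.

    Only filtered records should be passed. Returns (per_pam4,
    per_class) tables sorted by descending mean; empty groups simply do
    not appear.
    """
    df = freq.merge(annotations, on="pair_id", how="inner")
    per_pam4 = (
        df.groupby("pam4")["corrected_pct"]
        .agg(mean_pct="mean", n="size")
        .sort_values("mean_pct", ascending=False)
        .reset_index()
    )
    per_class = (
        df.groupby("pam_class")["corrected_pct"]
        .agg(mean_pct="mean", n="size")
        .sort_values("mean_pct", ascending=False)
        .reset_index()
    )
    return per_pam4, per_class


def positionwise_specificity(
    spec_table: pd.DataFrame, per_guide: bool = False
) -> pd.DataFrame:
    """Mean specificity per PAM-anchored position over single-mismatch
    records.

    ``per_guide=True`` averages within guide before averaging across
    guides; the default averages per record.
    """
    single = spec_table[spec_table["n_mismatch"] == 1].copy()
    single["position_pam"] = single["mm_positions"].astype(int)
    if per_guide:
        g = (
            single.groupby(["position_pam", "guide_id"])["specificity"]
            .mean()
            .reset_index()
        )
        prof = g.groupby("position_pam")["specificity"].agg(
            mean_specificity="mean", n="size"
        )
    else:
        prof = single.groupby("position_pam")["specificity"].agg(
            mean_specificity="mean", n="size"
        )
    return prof.reset_index()


def stratify_by_mismatch(spec_table: pd.DataFrame) -> pd.DataFrame:
    """Relative-activity distributions stratified by mismatch count and,
    for single mismatches, by base-pairing class."""
    rows = []
    for count, grp in spec_table.groupby("n_mismatch"):
        rows.append(
            {
                "stratum": f"{count}_mismatch",
                "n": len(grp),
                "median_relative_activity": float(grp["relative_activity"].median()),
                "median_specificity": float(grp["specificity"].median()),
            }
        )
    single = spec_table[spec_table["n_mismatch"] == 1]
    for mclass, grp in single.groupby("mm_classes"):
        rows.append(
            {
                "stratum": f"class_{mclass}",
                "n": len(grp),
                "median_relative_activity": float(grp["relative_activity"].median()),
                "median_specificity": float(grp["specificity"].median()),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class TradeoffPoint:
    variant: str
    general_activity: float  # median matched NGG corrected %
    general_specificity: float  # median single-mismatch specificity


def tradeoff_summary(
    freq: pd.DataFrame,
    spec_table: pd.DataFrame,
    annotations: pd.DataFrame,
    center=np.median,
) -> list[TradeoffPoint]:
    """One activity/specificity point per variant.

    General activity: median corrected frequency over matched NGG
    targets; general specificity: median specificity over
    single-mismatch records.
    """
    df = freq.merge(annotations, on="pair_id", how="inner")
    matched_ngg = df[df["is_matched"] & (df["pam_class"] == "NGG")]
    single = spec_table[spec_table["n_mismatch"] == 1]
    points = []
    for variant in sorted(df["variant"].unique()):
        act = matched_ngg.loc[matched_ngg["variant"] == variant, "corrected_pct"]
        spc = single.loc[single["variant"] == variant, "specificity"]
        if act.empty or spc.empty:
            continue
        points.append(
            TradeoffPoint(
                variant=variant,
                general_activity=float(center(act)),
                general_specificity=float(center(spc)),
            )
        )
    return points


def select_comparable_guides(
    on_target: pd.DataFrame, tolerance: float
) -> list[str]:
    """Guides whose matched-target corrected frequencies are comparable
    across variants: max - min range <= ``tolerance`` (absolute %) at
    day 4 or day 7.

    ``on_target`` needs guide_id, variant, day, corrected_pct (matched
    targets only).
    """
    if on_target.empty:
        raise SelectionError("no on-target records")
    n_variants = on_target["variant"].nunique()
    selected: set[str] = set()
    overlap = False
    for day, day_grp in on_target.groupby("day"):
        wide = day_grp.pivot_table(
            index="guide_id", columns="variant", values="corrected_pct"
        ).dropna()
        if wide.empty or wide.shape[1] < n_variants:
            continue
        overlap = True
        rng = wide.max(axis=1) - wide.min(axis=1)
        selected.update(rng.index[rng <= tolerance])
    if not overlap:
        raise SelectionError("no guide measured across all variants")
    return sorted(selected)
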