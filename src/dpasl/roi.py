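"""Regional aggregation, cohort assembly and age-group/sex summaries.

Age groups follow the study design: children-to-young-adulthood 8-35,
middle age 36-61, older age 62-92, encoded as half-open bins
[8, 36), [36, 62), [62, 93) so that every integer age 8..92 falls in exactly
one group.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DEFAULT_AGE_EDGES",
    "REGION_NAMES",
    "RoiSet",
    "extract_roi_means",
    "build_cohort_table",
    "group_summary",
    "sex_difference_percent",
    "round_half_away",
]

DEFAULT_AGE_EDGES = (8, 36, 62, 93)

#: the 14 subregions used in the regional trajectory analysis
REGION_NAMES = (
    "GM",
    "WM",
    "frontal",
    "temporal",
    "parietal",
    "ACC",
    "PCC",
    "precuneus",
    "caudate",
    "putamen",
    "amygdala",
    "hippocampus",
    "PHG",
    "MTL",
)

FEATURE_UNITS = {"kw": "min^-1", "cbf": "ml/100g/min", "att": "ms"}


@dataclasses.dataclass
class RoiSet:
    """Integer-labeled atlas volume plus a name -> label map."""

    atlas: np.ndarray
    labels: dict[str, int]

    def __post_init__(self) -> None:
        values = list(self.labels.values())
        if len(set(values)) != len(values):
            raise ValueError("duplicate atlas labels")
        if any(v <= 0 for v in values):
            raise ValueError("atlas labels must be positive")
        present = set(np.unique(self.atlas))
        empty = [n for n, v in self.labels.items() if v not in present]
        if empty:
            raise ValueError(f"empty regions: {empty}")


def extract_roi_means(map3d, roiset: RoiSet, weights=None) -> dict[str, float]:
    """(Weighted) mean of a parameter map over each named region.

    Only finite voxels contribute; a region with no finite voxel (or zero
    total weight) is reported as NaN.
    """
    m = np.asarray(map3d, dtype=float)
    if m.shape != roiset.atlas.shape:
        raise ValueError("map and atlas grids differ")
    if weights is not None:
        weights = np.asarray(weights, dtype=float)
        if weights.shape != m.shape:
            raise ValueError("weights and map grids differ")
    out: dict[str, float] = {}
    for name, label in roiset.labels.items():
        sel = (roiset.atlas == label) & np.isfinite(m)
        if weights is not None:
            w = weights[sel]
            tot = w.sum()
            out[name] = float((m[sel] * w).sum() / tot) if tot > 0 else float("nan")
        else:
            out[name] = float(m[sel].mean()) if sel.any() else float("nan")
    return out


def build_cohort_table(
    roi_values: pd.DataFrame,
    demographics: pd.DataFrame,
    units: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Strict join of per-subject regional values with demographics.

    Both tables must carry a ``subject_id`` column; unmatched ids on either
    side raise with the offending ids listed.  Feature units are recorded in
    ``df.attrs['units']``.
    """
    for df, name in ((roi_values, "roi_values"), (demographics, "demographics")):
        if "subject_id" not in df.columns:
            raise ValueError(f"{name} table lacks a subject_id column")
        if df["subject_id"].duplicated().any():
            raise ValueError(f"duplicate subject_id in {name}")
    left = set(demographics["subject_id"])
    right = set(roi_values["subject_id"])
    if left != right:
        raise ValueError(
            f"unmatched subjects: demographics-only={sorted(left - right)}, "
            f"roi-only={sorted(right - left)}"
        )
    merged = demographics.merge(roi_values, on="subject_id", validate="1:1")
    merged.attrs["units"] = dict(units or FEATURE_UNITS)
    return merged


def _age_groups(ages, edges=DEFAULT_AGE_EDGES) -> pd.Categorical:
    labels = [f"{lo}-{hi - 1}" for lo, hi in zip(edges[:-1], edges[1:])]
    return pd.cut(ages, bins=list(edges), right=False, labels=labels)


def group_summary(
    cohort: pd.DataFrame,
    features,
    age_edges=DEFAULT_AGE_EDGES,
) -> pd.DataFrame:
    """Per age-bin x sex mean/SD/count plus a cross-sex one-way ANOVA per bin.

    SD uses the n-1 denominator and is NaN for singleton cells.  The ANOVA F
    and p compare the sexes within each bin (F = 0 for identical groups).
    """
    if isinstance(features, str):
        features = [features]
    ages = np.asarray(cohort["age"], dtype=float)
    if ages.min() < age_edges[0] or ages.max() >= age_edges[-1]:
        raise ValueError("ages outside the configured bins")
    groups = _age_groups(ages, age_edges)
    rows = []
    for feat in features:
        for g in groups.categories:
            in_bin = np.asarray(groups == g)
            by_sex = {}
            for sex in ("M", "F"):
                sel = in_bin & np.asarray(cohort["sex"] == sex)
                vals = np.asarray(cohort.loc[sel, feat], dtype=float)
                vals = vals[np.isfinite(vals)]
                by_sex[sex] = vals
                rows.append(
                    {
                        "feature": feat,
                        "age_group": g,
                        "sex": sex,
                        "n": len(vals),
                        "mean": vals.mean() if len(vals) else np.nan,
                        "sd": vals.std(ddof=1) if len(vals) > 1 else np.nan,
                    }
                )
            m, f = by_sex["M"], by_sex["F"]
            if len(m) and len(f):
                if np.ptp(np.concatenate([m, f])) == 0:
                    fstat, p = 0.0, 1.0
                else:
                    fstat, p = stats.f_oneway(m, f)
            else:
                fstat, p = np.nan, np.nan
            for r in rows[-2:]:
                r["anova_F"] = fstat
                r["anova_p"] = p
    return pd.DataFrame(rows)


def round_half_away(x, decimals: int = 1):
    """Round half away from zero (the convention used for printed percents)."""
    factor = 10.0**decimals
    x = np.asarray(x, dtype=float)
    out = np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor
    return out if out.ndim else float(out)


def sex_difference_percent(summary: pd.DataFrame, feature: str) -> pd.Series:
    """Relative sex difference (F - M) / F * 100 per age bin, 1-decimal.

    Positive values mean the male mean is lower.  Rounding is half away from
    zero, matching the printed-group convention.
    """
    sub = summary[summary["feature"] == feature]
    piv = sub.pivot_table(index="age_group", columns="sex", values="mean", observed=False)
    diff = (piv["F"] - piv["M"]) / piv["F"] * 100.0
    return diff.apply(round_half_away)
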