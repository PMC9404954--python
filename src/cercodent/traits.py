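"""Dental trait computation from crown metrics.

Four traits are computed from mesiodistal length (L) and buccolingual
breadth (W) of the maxillary P4, M1, M2 and M3:

* 2D occlusal area of each molar: ``L * W`` (mm^2);
* MMC (molar module component): M3 length / M1 length;
* PMM (premolar-molar module): M2 length / P4 length;
* IC (inhibitory cascade trait): M3 area / M1 area.

Ratios are computed per specimen, requiring both component teeth on one
side. Left-side measurements are preferred; a trait falls back to the right
side only when any left tooth it needs is absent, and sides are never mixed
within one trait.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import IntegrityError

#: teeth whose mesiodistal lengths or areas enter each trait
TRAIT_TEETH = {
    "MMC": ["M1", "M3"],
    "PMM": ["P4", "M2"],
    "IC": ["M1", "M3"],
    "area_M1": ["M1"],
    "area_M2": ["M2"],
    "area_M3": ["M3"],
}


def crown_area(md_length: float, bl_breadth: float) -> float:
    """Two-dimensional occlusal area: mesiodistal length x buccolingual breadth."""
    if md_length <= 0 or bl_breadth <= 0:
        raise ValueError("crown_area requires strictly positive metrics")
    return md_length * bl_breadth


def _ratio(num, den) -> float:
    if num is None or den is None or np.isnan(num) or np.isnan(den):
        return np.nan
    if den == 0 or num <= 0 or den < 0:
        raise ValueError("ratio traits require positive metrics")
    return num / den


def compute_mmc(m1_length: float, m3_length: float) -> float:
    """M3 mesiodistal length over M1 mesiodistal length; NaN if either missing."""
    return _ratio(m3_length, m1_length)


def compute_pmm(p4_length: float, m2_length: float) -> float:
    """M2 mesiodistal length over P4 mesiodistal length; NaN if either missing."""
    return _ratio(m2_length, p4_length)


def compute_ic(area_m1: float, area_m3: float) -> float:
    """M3 occlusal area over M1 occlusal area; NaN if either missing."""
    return _ratio(area_m3, area_m1)


def _side_metrics(rows: pd.DataFrame, side: str) -> dict:
    """{tooth: (md, bl)} for one side of one specimen."""
    out = {}
    for _, r in rows[rows["side"] == side].iterrows():
        out[r["tooth"]] = (r["md_length"], r["bl_breadth"])
    return out


def resolve_side(rows: pd.DataFrame) -> dict:
    """Choose the side used for each trait of a single specimen.

    Returns ``{trait: (side, {tooth: (md, bl)})}`` with entries only for
    traits whose required teeth are complete on one side. Left side is
    preferred per trait; sides are never mixed within a trait.
    """
    if rows["specimen_id"].nunique() > 1:
        raise IntegrityError("resolve_side expects rows for a single specimen")
    by_side = {s: _side_metrics(rows, s) for s in ("L", "R")}

    def complete(side: str, trait: str) -> bool:
        m = by_side[side]
        for tooth in TRAIT_TEETH[trait]:
            if tooth not in m or np.isnan(m[tooth][0]):
                return False
            needs_breadth = trait == "IC" or trait.startswith("area")
            if needs_breadth and np.isnan(m[tooth][1]):
                return False
        return True

    chosen = {}
    for trait in TRAIT_TEETH:
        for side in ("L", "R"):
            if complete(side, trait):
                chosen[trait] = (side, by_side[side])
                break
    return chosen


def specimen_traits(table: pd.DataFrame) -> pd.DataFrame:
    """Per-specimen trait table with one row per specimen and side_used columns."""
    recs = []
    for spec_id, rows in table.groupby("specimen_id", sort=True):
        chosen = resolve_side(rows)
        rec = {
            "specimen_id": spec_id,
            "genus": rows["genus"].iloc[0],
            "species": rows["species"].iloc[0],
        }
        for trait in ("area_M1", "area_M2", "area_M3"):
            tooth = TRAIT_TEETH[trait][0]
            if trait in chosen:
                side, m = chosen[trait]
                rec[trait] = crown_area(*m[tooth])
                rec[f"side_{trait}"] = side
            else:
                rec[trait] = np.nan
                rec[f"side_{trait}"] = ""
        if "MMC" in chosen:
            side, m = chosen["MMC"]
            rec["MMC"] = compute_mmc(m["M1"][0], m["M3"][0])
            rec["side_MMC"] = side
        else:
            rec["MMC"], rec["side_MMC"] = np.nan, ""
        if "PMM" in chosen:
            side, m = chosen["PMM"]
            rec["PMM"] = compute_pmm(m["P4"][0], m["M2"][0])
            rec["side_PMM"] = side
        else:
            rec["PMM"], rec["side_PMM"] = np.nan, ""
        if "IC" in chosen:
            side, m = chosen["IC"]
            rec["IC"] = compute_ic(crown_area(*m["M1"]), crown_area(*m["M3"]))
            rec["side_IC"] = side
        else:
            rec["IC"], rec["side_IC"] = np.nan, ""
        recs.append(rec)
    return pd.DataFrame.from_records(recs)


def size_correct_areas(areas: pd.DataFrame) -> pd.DataFrame:
    """Geometric-mean size correction of the three molar areas, row-wise.

    Each area is divided by the geometric mean of the observation's three
    areas; rows with any missing area yield all-missing corrected values.
    The result is invariant to global rescaling of the input areas.
    """
    cols = ["area_M1", "area_M2", "area_M3"]
    a = areas[cols].to_numpy(dtype=float)
    gm = np.exp(np.log(a).mean(axis=1))  # NaN propagates through the log-mean
    out = areas.copy()
    out[cols] = a / gm[:, None]
    return out


TRAIT_COLUMNS = ["area_M1", "area_M2", "area_M3", "IC", "MMC", "PMM"]


@dataclass
class DescStats:
    """Univariate summary; kurtosis is the Pearson (non-excess) moment ratio."""

    n: int
    mean: float
    sd: float
    min: float
    max: float
    kurtosis: float


def descriptive_stats(values) -> DescStats:
    """n, mean, sample sd (n-1), min, max and Pearson kurtosis m4/m2^2.

    Kurtosis follows the moment convention (a large normal sample gives ~3);
    it is NaN for constant samples, where m2 = 0.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        raise ValueError("descriptive_stats requires at least one value")
    sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    if x.size > 1 and sd > 0:
        kurt = float(stats.kurtosis(x, fisher=False, bias=True))
    else:
        kurt = np.nan
    return DescStats(
        n=int(x.size), mean=float(np.mean(x)), sd=sd,
        min=float(np.min(x)), max=float(np.max(x)), kurtosis=kurt,
    )


def species_means(traits: pd.DataFrame) -> pd.DataFrame:
    """Unweighted specimen -> species means with per-trait specimen counts."""
    recs = []
    for (genus, species), grp in traits.groupby(["genus", "species"], sort=True):
        rec = {"genus": genus, "species": species}
        for col in TRAIT_COLUMNS:
            vals = grp[col].dropna()
            rec[col] = vals.mean() if len(vals) else np.nan
            rec[f"n_{col}"] = len(vals)
        recs.append(rec)
    return pd.DataFrame.from_records(recs)


def genus_summaries(traits: pd.DataFrame) -> pd.DataFrame:
    """Two-level aggregation: specimen -> species mean -> unweighted genus mean.

    Per-trait n at the genus level counts species with a non-missing value;
    a genus with no non-missing species values gets a missing trait value.
    """
    sp = species_means(traits)
    recs = []
    for genus, grp in sp.groupby("genus", sort=True):
        rec = {"genus": genus}
        for col in TRAIT_COLUMNS:
            vals = grp[col].dropna()
            rec[col] = vals.mean() if len(vals) else np.nan
            rec[f"n_{col}"] = len(vals)
        recs.append(rec)
    return pd.DataFrame.from_records(recs)
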