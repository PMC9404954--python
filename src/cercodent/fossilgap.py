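"""Quantify the gap between ancestral state estimates and fossil trait values.

Each pairing matches an internal node (or an extant tip) of the chronogram
with a fossil genus thought to be near that divergence in time and
position, for the MMC and PMM ratio traits. Two explicit subsets control
the aggregates: ``include_in_mean`` marks the internal-node pairings that
enter the per-trait mean absolute difference, and
``include_in_direction_count`` marks the pairings counted when asking how
often the reconstruction is at or above the fossil value. Ties
(ASR = fossil) count as "not lower".
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import load_fixture

TRAITS = ("MMC", "PMM")


def round_half_up(x: float, digits: int = 3) -> float:
    """Decimal rounding with ties away from zero, matching printed tables."""
    q = decimal.Decimal(10) ** -digits
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))


def pair_nodes(pairings: pd.DataFrame, asr_values: dict,
               fossil_means: pd.DataFrame) -> pd.DataFrame:
    """Expand a pairing spec to one row per (pairing, trait).

    ``pairings`` needs pairing_id, node_label, fossil_genus, node_age (Ma)
    and the two include flags, one row per pairing. ``asr_values`` maps
    (node_label, trait) -> reconstructed value. ``fossil_means`` is indexed
    by genus with one column per trait. A genus may appear in several
    pairings. Unresolvable genera or nodes raise with the offenders listed.
    """
    bad = []
    for genus in pairings["fossil_genus"].unique():
        if genus not in fossil_means.index:
            bad.append(f"fossil genus {genus!r} has no trait values")
    for label in pairings["node_label"].unique():
        if not any((label, t) in asr_values for t in TRAITS):
            bad.append(f"node {label!r} has no ASR value")
    if bad:
        raise KeyError("; ".join(bad))
    rows = []
    for _, p in pairings.iterrows():
        for trait in TRAITS:
            key = (p["node_label"], trait)
            if key not in asr_values:
                continue
            fossil = fossil_means.loc[p["fossil_genus"], trait]
            if np.isnan(fossil):
                continue
            asr = asr_values[key]
            rows.append({
                "pairing_id": p["pairing_id"],
                "node_label": p["node_label"],
                "trait": trait,
                "asr_value": asr,
                "fossil_value": float(fossil),
                "signed_diff": asr - float(fossil),
                "abs_diff": abs(asr - float(fossil)),
                "node_age": p.get("node_age", np.nan),
                "fossil_age_min": p.get("fossil_age_min", np.nan),
                "fossil_age_max": p.get("fossil_age_max", np.nan),
                "include_in_mean": bool(p["include_in_mean"]),
                "include_in_direction_count": bool(p["include_in_direction_count"]),
            })
    return pd.DataFrame(rows)


@dataclass
class GapReport:
    """Per-pairing differences plus the per-trait aggregates."""

    rows: pd.DataFrame
    mean_abs_diff: dict      # trait -> mean |ASR - fossil| over the mean-subset
    n_mean_subset: dict
    asr_ge_fossil: dict      # trait -> count of pairings with ASR >= fossil
    n_direction_subset: dict

    def mean_abs_diff_rounded(self, digits: int = 3) -> dict:
        return {t: round_half_up(v, digits) for t, v in self.mean_abs_diff.items()}

    def summary(self) -> str:
        lines = ["ASR vs fossil gap report"]
        for t in TRAITS:
            if t in self.mean_abs_diff:
                lines.append(
                    f"  {t}: mean |ASR - fossil| = {self.mean_abs_diff[t]:.6f} "
                    f"(~{self.mean_abs_diff_rounded()[t]:.3f}) over "
                    f"{self.n_mean_subset[t]} pairings; ASR >= fossil in "
                    f"{self.asr_ge_fossil[t]}/{self.n_direction_subset[t]} "
                    f"direction-subset pairings")
        return "\n".join(lines)


def gap_statistics(rows: pd.DataFrame) -> GapReport:
    """Aggregate pairing rows into the per-trait gap report."""
    mean_abs, n_mean, ge, n_dir = {}, {}, {}, {}
    for trait in TRAITS:
        sub = rows[rows["trait"] == trait]
        m = sub[sub["include_in_mean"]]
        if len(m) == 0:
            raise ValueError(f"empty mean-subset for trait {trait}")
        mean_abs[trait] = float(m["abs_diff"].mean())
        n_mean[trait] = int(len(m))
        d = sub[sub["include_in_direction_count"]]
        ge[trait] = int((d["signed_diff"] >= 0).sum())
        n_dir[trait] = int(len(d))
    return GapReport(rows=rows, mean_abs_diff=mean_abs, n_mean_subset=n_mean,
                     asr_ge_fossil=ge, n_direction_subset=n_dir)


def gap_from_fixture() -> GapReport:
    """Gap report computed from the packaged printed pairing table."""
    t8 = load_fixture("table8")
    rows = []
    for _, p in t8.iterrows():
        for trait in TRAITS:
            asr = p[f"asr_{trait.lower()}"]
            fossil = p[f"fossil_{trait.lower()}"]
            rows.append({
                "pairing_id": p["pairing_id"],
                "node_label": p["node_label"],
                "trait": trait,
                "asr_value": float(asr),
                "fossil_value": float(fossil),
                "signed_diff": float(asr) - float(fossil),
                "abs_diff": abs(float(asr) - float(fossil)),
                "node_age": float(p["divergence_ma"]),
                "fossil_age_min": float(p["fossil_age_min_ma"]),
                "fossil_age_max": float(p["fossil_age_max_ma"]),
                "include_in_mean": bool(p["include_in_mean"]),
                "include_in_direction_count": bool(p["include_in_direction_count"]),
            })
    return gap_statistics(pd.DataFrame(rows))


def gap_over_time(report: GapReport) -> pd.DataFrame:
    """Long-format (node_age, trait, abs_diff) rows over the mean-subset,
    with each trait's mean attached — the table behind an age-vs-gap scatter.
    Rows with missing node age are retained but flagged for plotting."""
    if len(report.rows) == 0:
        raise ValueError("empty gap report")
    sub = report.rows[report.rows["include_in_mean"]].copy()
    out = sub[["pairing_id", "node_age", "trait", "abs_diff"]].copy()
    out["trait_mean_abs_diff"] = [report.mean_abs_diff[t] for t in out["trait"]]
    out["plottable"] = out["node_age"].notna()
    return out.reset_index(drop=True)


def plot_gap_over_time(report: GapReport, path) -> None:
    """Scatter of |ASR - fossil| against node age with per-trait mean lines."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = gap_over_time(report)
    fig, ax = plt.subplots(figsize=(6, 4))
    markers = {"MMC": "o", "PMM": "^"}
    for trait, grp in table[table["plottable"]].groupby("trait"):
        ax.scatter(grp["node_age"], grp["abs_diff"], marker=markers[trait],
                   label=trait)
        ax.axhline(report.mean_abs_diff[trait], linestyle="--", linewidth=1)
    ax.set_xlabel("Node age (Ma)")
    ax.set_ylabel("|ASR - fossil|")
    ax.invert_xaxis()
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
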