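"""Maximum-likelihood ancestral state reconstruction under Brownian motion.

For each internal node the ML state equals the GLS estimate of the root
state after re-rooting the tree at that node:

    a_hat = (1' V^-1 1)^-1 1' V^-1 x,

where V is the BM tip covariance of the re-rooted tree. Re-rooting is done
implicitly through patristic distances: with the candidate root r,
V_r[i, j] = (d(r, i) + d(r, j) - d(i, j)) / 2. The estimate's variance is
sigma2_hat * (1' V^-1 1)^-1 with sigma2_hat the ML BM rate fitted once
from the tip data. Because the GLS weights are a convex combination of the
tips, every reconstructed state lies within the range of the observed tip
values — ancestral states can never exceed what the present shows.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .comparative import _values_vector, bm_rate
from .trees import Chronogram


class ASRResults:
    """Per-node ML estimates with variances and 95% CIs.

    ``table`` has one row per internal node: node_id, tip_set (sorted,
    ``|``-joined), age (Ma), estimate, variance, ci95_low, ci95_high.
    """

    def __init__(self, table: pd.DataFrame, sigma2_hat: float,
                 tree: Chronogram, tip_values: pd.Series):
        self.table = table
        self.sigma2_hat = sigma2_hat
        self.tree = tree
        self.tip_values = tip_values

    def estimate_for(self, tips) -> pd.Series:
        """Row for the MRCA of a tip-label set (or a single tip's own value)."""
        tips = [tips] if isinstance(tips, str) else list(tips)
        if len(tips) == 1:
            lab = tips[0]
            return pd.Series({
                "node_id": lab, "tip_set": lab, "age": 0.0,
                "estimate": float(self.tip_values.loc[lab]),
                "variance": 0.0,
                "ci95_low": float(self.tip_values.loc[lab]),
                "ci95_high": float(self.tip_values.loc[lab]),
            })
        node = self.tree.mrca(tips)
        tipset = "|".join(sorted(self.tree._leafset[node]))
        row = self.table[self.table["tip_set"] == tipset]
        return row.iloc[0]

    def annotated_newick(self, digits: int = 4) -> str:
        """Newick with internal-node labels set to the reconstructed states."""
        out = self.tree.copy()
        by_tipset = dict(zip(self.table["tip_set"], self.table["estimate"]))
        for node in out.tree.preorder_node_iter():
            if node.is_leaf():
                continue
            key = "|".join(sorted(out._leafset[node]))
            node.label = f"{by_tipset[key]:.{digits}f}"
        return out.tree.as_string(schema="newick", suppress_rooting=True,
                                  unquoted_underscores=True).strip()

    def summary(self) -> str:
        lines = [f"ML ancestral states under BM (sigma2_hat = {self.sigma2_hat:.6g})"]
        for _, r in self.table.iterrows():
            tips = r["tip_set"].split("|")
            shown = ",".join(tips[:3]) + (",..." if len(tips) > 3 else "")
            lines.append(
                f"  {r['node_id']}  age {r['age']:.2f} Ma  "
                f"{r['estimate']:.4f} [{r['ci95_low']:.4f}, {r['ci95_high']:.4f}]"
                f"  mrca({shown})")
        return "\n".join(lines)


class AncestralStateModel:
    """ML ancestral states for one continuous trait on a chronogram.

    Parameters
    ----------
    tree : Chronogram
    values : pd.Series or array
        Trait values for every tip (missing values are an error; prune or
        impute upstream).
    """

    def __init__(self, tree: Chronogram, values, rate_method: str = "ML"):
        if len(tree) < 3:
            raise ValueError("ASR requires at least 3 tips")
        self.tree = tree
        self.labels = tree.tip_labels
        self.rate_method = rate_method
        x = _values_vector(self.labels, values)
        if np.isnan(x).any():
            missing = [t for t, v in zip(self.labels, x) if np.isnan(v)]
            raise ValueError(f"missing tip values: {missing}")
        self.x = x

    def fit(self, ci: float = 0.95) -> ASRResults:
        tree = self.tree
        x = self.x
        sigma2 = bm_rate(tree, pd.Series(x, index=self.labels),
                         method=self.rate_method)
        nodes, labels, D_nt = tree.node_tip_distances()
        _, D_tt = tree.tip_distances()
        z = stats.norm.ppf(0.5 + ci / 2)
        rows = []
        for info, d_r in zip(nodes, D_nt):
            V = 0.5 * (d_r[:, None] + d_r[None, :] - D_tt)
            Vinv = np.linalg.pinv(V)
            one = np.ones(len(labels))
            denom = float(one @ Vinv @ one)
            est = float(one @ Vinv @ x) / denom
            var = sigma2 / denom
            rows.append({
                "node_id": info.node_id,
                "tip_set": "|".join(sorted(info.tips)),
                "age": info.age,
                "estimate": est,
                "variance": var,
                "ci95_low": est - z * np.sqrt(var),
                "ci95_high": est + z * np.sqrt(var),
            })
        table = pd.DataFrame(rows)
        return ASRResults(table, sigma2, tree,
                          pd.Series(x, index=self.labels))


def ml_asr(tree: Chronogram, values, rate_method: str = "ML") -> ASRResults:
    """Convenience wrapper: ``AncestralStateModel(tree, values).fit()``.

    ``rate_method`` selects the BM rate behind the node variances: "ML"
    (divide the contrast sum of squares by n) or "REML" (n - 1).
    """
    return AncestralStateModel(tree, values, rate_method=rate_method).fit()
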