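"""Comparative methods on a chronogram.

Brownian-motion (BM) simulation, Felsenstein's standardized independent
contrasts, Blomberg's K with a tip-shuffling randomization test, and a
simulation-null phylogenetic ANOVA comparing genera across species tips.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trees import Chronogram


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _values_vector(labels, values) -> np.ndarray:
    if isinstance(values, pd.Series):
        missing = [t for t in labels if t not in values.index]
        if missing:
            raise KeyError(f"tips without values: {missing}")
        return values.loc[labels].to_numpy(dtype=float)
    x = np.asarray(values, dtype=float)
    if x.size != len(labels):
        raise ValueError("value vector length does not match tip count")
    return x


class BMSimulator:
    """Reusable multivariate-normal sampler for BM tip values on a fixed tree."""

    def __init__(self, tree: Chronogram, sigma2: float = 1.0,
                 root_state: float = 0.0):
        if sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        self.labels, V = tree.bm_covariance()
        self.sigma2 = sigma2
        self.root_state = root_state
        # eigenfactor handles the singular V of zero-length branches
        d, U = np.linalg.eigh(V)
        d = np.clip(d, 0.0, None)
        self._L = U * np.sqrt(d)

    def draw(self, rng, size: int | None = None):
        rng = _as_rng(rng)
        n = len(self.labels)
        if size is None:
            z = rng.standard_normal(n)
            x = self.root_state + np.sqrt(self.sigma2) * (self._L @ z)
            return pd.Series(x, index=self.labels)
        z = rng.standard_normal((size, n))
        return self.root_state + np.sqrt(self.sigma2) * (z @ self._L.T)


def simulate_bm(tree: Chronogram, sigma2: float, root_state: float,
                seed) -> pd.Series:
    """One BM realization at the tips: MVN(root_state, sigma2 * bm_covariance)."""
    return BMSimulator(tree, sigma2, root_state).draw(_as_rng(seed))


# -- independent contrasts ----------------------------------------------

class _ContrastProgram:
    """Pre-compiled pruning schedule so contrasts are cheap under permutation.

    Polytomies are resolved with zero-length splits (which leaves the BM
    covariance unchanged); the branch-length extensions of the pruning
    algorithm depend only on the tree, so they are computed once.
    """

    def __init__(self, tree: Chronogram):
        work = tree.copy()
        work.tree.resolve_polytomies()
        self.labels = tree.tip_labels
        slot = {lab: i for i, lab in enumerate(self.labels)}
        n = len(self.labels)
        self.n_slots = 2 * n - 1 if n else 0
        ops = []
        node_slot: dict = {}
        node_v: dict = {}
        next_slot = n
        for node in work.tree.postorder_node_iter():
            edge = node.edge.length or 0.0
            if node.is_leaf():
                node_slot[node] = slot[node.taxon.label]
                node_v[node] = edge
                continue
            kids = node.child_nodes()
            if len(kids) != 2:  # pragma: no cover - resolve_polytomies guarantees 2
                raise ValueError("contrast pruning requires a bifurcating tree")
            a, b = kids
            va, vb = node_v[a], node_v[b]
            s = node_slot[node] = next_slot
            next_slot += 1
            ops.append((s, node_slot[a], node_slot[b], va, vb))
            node_v[node] = edge + (va * vb / (va + vb) if va + vb > 0 else 0.0)
        self.ops = ops

    def contrasts(self, x_tips: np.ndarray) -> np.ndarray:
        x = np.empty(self.n_slots)
        x[: x_tips.size] = x_tips
        out = np.empty(len(self.ops))
        for k, (s, a, b, va, vb) in enumerate(self.ops):
            tot = va + vb
            if tot > 0:
                out[k] = (x[a] - x[b]) / np.sqrt(tot)
                x[s] = (x[a] * vb + x[b] * va) / tot
            else:
                out[k] = 0.0 if x[a] == x[b] else np.inf
                x[s] = 0.5 * (x[a] + x[b])
        return out


def independent_contrasts(tree: Chronogram, values) -> np.ndarray:
    """n - 1 contrasts, each standardized by its expected BM standard deviation."""
    prog = _ContrastProgram(tree)
    return prog.contrasts(_values_vector(prog.labels, values))


def bm_rate(tree: Chronogram, values, method: str = "ML") -> float:
    """BM rate (trait variance per Ma) from standardized contrasts.

    The sum of squared standardized contrasts equals the GLS quadratic form
    about the phylogenetic mean; ML divides by n, REML by n - 1.
    """
    u = independent_contrasts(tree, values)
    q = float(np.sum(u**2))
    n = u.size + 1
    if method == "ML":
        return q / n
    if method == "REML":
        return q / (n - 1)
    raise ValueError("method must be 'ML' or 'REML'")


def phylogenetic_mean(tree: Chronogram, values) -> float:
    """GLS estimate of the root state: (1' V^-1 1)^-1 1' V^-1 x."""
    labels, V = tree.bm_covariance()
    x = _values_vector(labels, values)
    Vinv = np.linalg.pinv(V)
    one = np.ones(x.size)
    return float(one @ Vinv @ x) / float(one @ Vinv @ one)


# -- Blomberg's K --------------------------------------------------------

@dataclass
class BlombergResult:
    K: float
    p: float
    n_perm: int

    def summary(self) -> str:
        return (f"Blomberg's K = {self.K:.4f}, randomization p = {self.p:.4f} "
                f"({self.n_perm} permutations)")


def blomberg_k(tree: Chronogram, values) -> float:
    """Phylogenetic signal K of a continuous trait.

    K = (MSE0 / MSE) / E[MSE0 / MSE] with MSE0 the mean squared deviation of
    tip values about the phylogenetically corrected (GLS) mean, MSE the GLS
    mean squared error under the BM tip covariance V, and the expectation
    (tr V - n / sum(V^-1)) / (n - 1). K ~ 1 under BM; K < 1 indicates less
    signal than BM predicts.
    """
    labels, V = tree.bm_covariance()
    x = _values_vector(labels, values)
    n = x.size
    if n < 4:
        raise ValueError("blomberg_k requires at least 4 tips")
    if np.ptp(x) == 0:
        raise ValueError("blomberg_k undefined for constant values")
    Vinv = np.linalg.pinv(V)
    one = np.ones(n)
    denom = float(one @ Vinv @ one)
    ahat = float(one @ Vinv @ x) / denom
    dev = x - ahat
    mse0 = float(dev @ dev) / (n - 1)
    mse = float(dev @ Vinv @ dev) / (n - 1)
    expected = (float(np.trace(V)) - n / denom) / (n - 1)
    return (mse0 / mse) / expected


def phylosignal_test(tree: Chronogram, values, n_perm: int = 999,
                     seed=None) -> BlombergResult:
    """K with a randomization p-value from shuffling tip values.

    The test statistic is the variance of the standardized contrasts; lower
    observed contrast variance than in the shuffled data indicates signal.
    p = (1 + #{permutations with statistic <= observed}) / (1 + n_perm).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    rng = _as_rng(seed)
    prog = _ContrastProgram(tree)
    x = _values_vector(prog.labels, values)
    if np.ptp(x) == 0:
        raise ValueError("phylosignal undefined for constant values")
    K = blomberg_k(tree, pd.Series(x, index=prog.labels))

    def stat(v):
        # sample variance (not mean square): the mean square equals the GLS
        # quadratic form, which is permutation-invariant on a star tree
        u = prog.contrasts(v)
        return float(np.var(u, ddof=1)) if u.size > 1 else float(u[0] ** 2)

    obs = stat(x)
    hits = sum(
        stat(rng.permutation(x)) <= obs for _ in range(n_perm)
    )
    return BlombergResult(K=K, p=(1 + hits) / (1 + n_perm), n_perm=n_perm)


# -- phylogenetic ANOVA --------------------------------------------------

@dataclass
class PhyloAnovaResult:
    F: float
    p_phylo: float
    per_group_p: dict
    n_sim: int

    def summary(self) -> str:
        lines = [f"Phylogenetic ANOVA: F = {self.F:.4f}, "
                 f"simulation p = {self.p_phylo:.4f} ({self.n_sim} simulations)"]
        for g, p in sorted(self.per_group_p.items()):
            lines.append(f"  {g}: p = {p:.4f}")
        return "\n".join(lines)


def _anova_f(x: np.ndarray, gidx: np.ndarray, k: int):
    """One-way ANOVA F plus per-group deviations from the grand mean.

    Vectorized over rows when x is 2-D (simulations x tips).
    """
    x2d = np.atleast_2d(x)
    n = x2d.shape[1]
    counts = np.bincount(gidx, minlength=k).astype(float)
    sums = np.zeros((x2d.shape[0], k))
    np.add.at(sums.T, gidx, x2d.T)
    means = sums / counts
    grand = x2d.mean(axis=1, keepdims=True)
    ssb = ((means - grand) ** 2 * counts).sum(axis=1)
    sst = ((x2d - grand) ** 2).sum(axis=1)
    ssw = sst - ssb
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / (k - 1)) / (ssw / (n - k))
    F = np.where(ssb == 0, 0.0, np.where(ssw == 0, np.inf, F))
    dev = np.abs(means - grand)
    return F, dev


def phylo_anova(tree: Chronogram, groups, values, n_sim: int = 1000,
                seed=None) -> PhyloAnovaResult:
    """Simulation-null one-way ANOVA of tip values across groups.

    The observed F comes from an ordinary one-way ANOVA of tip (species)
    values by group (genus). The null distribution is built by simulating
    BM on the tree with the rate estimated from the data by ML contrasts,
    recomputing F for each simulation: p = (1 + #{F_sim >= F_obs}) /
    (1 + n_sim). Per-group p-values compare each group mean's absolute
    deviation from the grand mean with its simulated distribution
    (two-sided by construction). The result is invariant to affine
    transformation of the trait.
    """
    rng = _as_rng(seed)
    labels, _ = tree.bm_covariance()
    x = _values_vector(labels, values)
    g = (groups.loc[labels].to_numpy() if isinstance(groups, pd.Series)
         else np.asarray(groups))
    keep = ~np.isnan(x)
    dropped_groups = set(g[~keep]) - set(g[keep])
    if dropped_groups:
        warnings.warn(f"groups with no values dropped: {sorted(dropped_groups)}")
    work_tree = tree
    if not keep.all():
        for lab in np.asarray(labels)[~keep]:
            work_tree = work_tree.drop_tip(lab)
        labels = work_tree.tip_labels
        order = {lab: i for i, lab in enumerate(tree.tip_labels)}
        x = x[[order[lab] for lab in labels]]
        g = g[[order[lab] for lab in labels]]
    group_names = sorted(set(g))
    if len(group_names) < 2:
        raise ValueError("phylo_anova requires at least 2 groups with data")
    gidx = np.array([group_names.index(v) for v in g])
    k = len(group_names)

    F_obs, dev_obs = _anova_f(x, gidx, k)
    F_obs, dev_obs = float(F_obs[0]), dev_obs[0]
    if np.ptp(x) == 0:
        return PhyloAnovaResult(0.0, 1.0, {gname: 1.0 for gname in group_names},
                                n_sim)

    sigma2 = bm_rate(work_tree, pd.Series(x, index=labels), method="ML")
    sims = BMSimulator(work_tree, sigma2=max(sigma2, 1e-300)).draw(rng, size=n_sim)
    F_sim, dev_sim = _anova_f(sims, gidx, k)
    p_phylo = (1 + int(np.sum(F_sim >= F_obs))) / (1 + n_sim)
    per_group = {
        gname: (1 + int(np.sum(dev_sim[:, j] >= dev_obs[j]))) / (1 + n_sim)
        for j, gname in enumerate(group_names)
    }
    return PhyloAnovaResult(F=F_obs, p_phylo=p_phylo, per_group_p=per_group,
                            n_sim=n_sim)
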