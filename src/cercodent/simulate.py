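"""Synthetic data generators with the statistical structure the analyses assume.

Three generators cover the three kinds of input:

* a multi-generation captive pedigree with additive genetic trait
  covariance (Mendelian sampling recursion), sex and age fixed effects,
  and iid environmental noise;
* per-specimen crown measurements built from target trait ratios with
  lognormal measurement noise and configurable left/right missingness;
* continuous trait evolution on a chronogram under BM with the realization
  recorded at every node, plus noisy "fossil" observations at internal
  nodes with an optional directional trend per Ma.

Every generator is deterministic under a fixed seed, and its output passes
the same validators as real inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import _topological_order, validate_pedigree
from .trees import Chronogram


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# -- pedigree ------------------------------------------------------------

@dataclass
class PedigreeSimSpec:
    """Design of a simulated captive colony.

    Defaults emulate the structure of a large managed breeding colony:
    six non-overlapping generations, a roughly 1:2 male:female sex ratio,
    random mate assignment avoiding sibling matings, adult ages spanning
    8-32 years with the oldest generation oldest.
    """

    n_founders: int = 60
    n_generations: int = 6
    mean_offspring: float = 1.0   # expected offspring per member of a generation
    h2_true: float = 0.5
    sex_effect: float = 0.0       # additive male effect, in phenotypic SD units
    age_slope: float = 0.0        # per year, raw trait units
    sigma_P2_true: float = 1.0
    prob_male: float = 1.0 / 3.0
    seed: int | None = None

    def __post_init__(self):
        if not 0.0 <= self.h2_true <= 1.0:
            raise ValueError("h2_true must be in [0, 1]")
        if self.sigma_P2_true <= 0:
            raise ValueError("sigma_P2_true must be positive")

    def expected_size(self) -> float:
        """Branching-process expectation of the total pedigree size."""
        r, g = self.mean_offspring, self.n_generations
        if abs(r - 1.0) < 1e-12:
            return self.n_founders * g
        return self.n_founders * (r**g - 1.0) / (r - 1.0)


def simulate_pedigree(spec: PedigreeSimSpec, seed=None) -> pd.DataFrame:
    """Non-overlapping-generation pedigree with sibling matings avoided."""
    rng = _as_rng(spec.seed if seed is None else seed)
    rows = []
    generation: list[dict] = []
    for i in range(spec.n_founders):
        sex = "M" if rng.random() < spec.prob_male else "F"
        age = 8.0 + 4.0 * (spec.n_generations - 1) + rng.uniform(0.0, 4.0)
        rec = {"id": f"G0I{i}", "sire": np.nan, "dam": np.nan, "sex": sex,
               "age": round(min(age, 32.0), 1), "parents": (None, None)}
        rows.append(rec)
        generation.append(rec)

    for g in range(1, spec.n_generations):
        males = [r for r in generation if r["sex"] == "M"]
        females = [r for r in generation if r["sex"] == "F"]
        rng.shuffle(males)
        rng.shuffle(females)
        couples = []
        used_f: set[int] = set()
        for m in males:
            for j, f in enumerate(females):
                if j in used_f or f["parents"] == m["parents"] != (None, None):
                    continue  # avoid full-sibling matings
                couples.append((m, f))
                used_f.add(j)
                break
        if not couples:
            break
        lam = spec.mean_offspring * len(generation) / len(couples)
        new_gen = []
        k = 0
        for m, f in couples:
            for _ in range(rng.poisson(lam)):
                sex = "M" if rng.random() < spec.prob_male else "F"
                age = 8.0 + 4.0 * (spec.n_generations - 1 - g) + rng.uniform(0, 4)
                rec = {"id": f"G{g}I{k}", "sire": m["id"], "dam": f["id"],
                       "sex": sex, "age": round(min(age, 32.0), 1),
                       "parents": (m["id"], f["id"])}
                rows.append(rec)
                new_gen.append(rec)
                k += 1
        generation = new_gen
    ped = pd.DataFrame(rows).drop(columns="parents")
    validate_pedigree(ped)
    return ped


def _kinship_recursion(ped: pd.DataFrame):
    """Memoized pairwise kinship phi(a, b) without building the full matrix."""
    order = _topological_order(ped)
    rank = {v: k for k, v in enumerate(order)}
    parents = {
        r["id"]: tuple(p if isinstance(p, str) else None
                       for p in (r["sire"], r["dam"]))
        for _, r in ped.iterrows()
    }
    memo: dict = {}

    def phi(a, b):
        if a is None or b is None:
            return 0.0
        if rank[a] < rank[b]:
            a, b = b, a
        key = (a, b)
        if key in memo:
            return memo[key]
        s, d = parents[a]
        if a == b:
            val = 0.5 * (1.0 + phi(s, d))
        elif s is None and d is None:
            val = 0.0
        else:
            val = 0.5 * (phi(s, b) + phi(d, b))
        memo[key] = val
        return val

    return parents, order, phi


def simulate_pedigree_traits(ped: pd.DataFrame, spec: PedigreeSimSpec,
                             seed=None) -> pd.DataFrame:
    """Phenotypes y = Xb + g + e on a pedigree, with Cov(g) = h2 * sigma_P2 * A.

    Genetic values are generated founder-by-founder with the Mendelian
    sampling recursion g_i = (g_s + g_d)/2 + m_i,
    m_i ~ N(0, sigma_G2/2 * (1 - (F_s + F_d)/2)), with inbreeding
    coefficients F from a memoized pairwise-kinship recursion, so no
    full-matrix factorization is needed even for very large pedigrees;
    equivalence with the covariance route holds by construction of the
    additive model. Returns a frame indexed by id with columns y
    (phenotype) and g (true genetic value).
    """
    rng = _as_rng(spec.seed if seed is None else seed)
    sigma_G2 = spec.h2_true * spec.sigma_P2_true
    sigma_E2 = (1.0 - spec.h2_true) * spec.sigma_P2_true
    parents, order, phi = _kinship_recursion(ped)
    info = ped.set_index("id")

    g: dict[str, float] = {}
    for ind in order:
        s, d = parents[ind]
        if s is not None and d is not None:
            F_s, F_d = phi(*parents[s]), phi(*parents[d])
            msv = 0.5 * sigma_G2 * (1.0 - 0.5 * (F_s + F_d))
            g[ind] = 0.5 * (g[s] + g[d]) + rng.normal(0.0, np.sqrt(max(msv, 0.0)))
        else:
            g[ind] = rng.normal(0.0, np.sqrt(sigma_G2))

    ids = list(ped["id"])
    gv = np.array([g[i] for i in ids])
    sex = (info.loc[ids, "sex"] == "M").to_numpy(dtype=float)
    age = info.loc[ids, "age"].to_numpy(dtype=float)
    age = np.where(np.isnan(age), np.nanmean(age), age)
    e = rng.normal(0.0, np.sqrt(sigma_E2), size=len(ids))
    y = (spec.sex_effect * np.sqrt(spec.sigma_P2_true) * sex
         + spec.age_slope * (age - age.mean()) + gv + e)
    return pd.DataFrame({"y": y, "g": gv}, index=pd.Index(ids, name="id"))


# -- crown measurements --------------------------------------------------

def simulate_crown_measurements(taxa: pd.DataFrame, n_per_taxon: int,
                                cv: float, seed=None,
                                p_missing_left: float = 0.0,
                                p_missing_right: float = 0.0) -> pd.DataFrame:
    """Long-format crown metrics realizing target MMC/PMM/IC per taxon.

    ``taxa`` needs columns genus, species, mmc, pmm, ic, m1_length and
    optionally m1_breadth (default 0.85 * m1_length) and p4_length
    (default 0.72 * m1_length). Per specimen and side, M1 is drawn around
    the size target, M3 length is MMC times the realized M1 length, M2
    length is PMM times the realized P4 length, and M3 breadth is chosen
    so the area ratio realizes IC; every final metric carries multiplicative
    lognormal noise with coefficient of variation ``cv`` (median equal to
    its target, so cv = 0 recovers the targets exactly).
    """
    if cv < 0:
        raise ValueError("cv must be non-negative")
    rng = _as_rng(seed)
    sig = np.sqrt(np.log1p(cv**2))

    def noise(x):
        return x * np.exp(sig * rng.standard_normal()) if sig > 0 else x

    rows = []
    for _, t in taxa.iterrows():
        if min(t["mmc"], t["pmm"], t["ic"], t["m1_length"]) <= 0:
            raise ValueError("trait and size targets must be positive")
        m1w0 = t.get("m1_breadth", np.nan)
        m1w0 = t["m1_length"] * 0.85 if pd.isna(m1w0) else m1w0
        p4l0 = t.get("p4_length", np.nan)
        p4l0 = t["m1_length"] * 0.72 if pd.isna(p4l0) else p4l0
        for k in range(n_per_taxon):
            sid = f"{t['genus']}_{t['species']}_{k:03d}"
            for side, p_miss in (("L", p_missing_left), ("R", p_missing_right)):
                m1l, m1w = noise(t["m1_length"]), noise(m1w0)
                p4l = noise(p4l0)
                m3l = noise(t["mmc"] * m1l)
                m2l = noise(t["pmm"] * p4l)
                m3w = noise(t["ic"] * m1l * m1w / m3l)
                m2w = noise(1.05 * m1w)
                p4w = noise(0.9 * m1w)
                for tooth, (L, W) in {
                    "P4": (p4l, p4w), "M1": (m1l, m1w),
                    "M2": (m2l, m2w), "M3": (m3l, m3w),
                }.items():
                    if rng.random() < p_miss:
                        continue
                    rows.append({
                        "specimen_id": sid, "genus": t["genus"],
                        "species": t["species"], "side": side, "tooth": tooth,
                        "md_length": L, "bl_breadth": W,
                    })
    return pd.DataFrame(rows)


# -- clade / fossil ------------------------------------------------------

@dataclass
class CladeSimSpec:
    """BM trait evolution on a chronogram with fossil observations at nodes.

    Root values default to plausible cercopithecid means for the three
    ratio traits. ``trend_per_ma`` adds trend * node_age to each fossil
    observation: a positive value makes older fossils larger than the BM
    expectation, reproducing systematic ASR under-estimation of a trait
    that has declined toward the present.
    """

    tree: Chronogram = None
    sigma2_bm: dict = field(default_factory=lambda: {
        "MMC": 0.002, "PMM": 0.004, "IC": 0.004})
    root_values: dict = field(default_factory=lambda: {
        "MMC": 1.1, "PMM": 1.55, "IC": 1.2})
    fossil_noise_sd: float = 0.0
    trend_per_ma: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if self.fossil_noise_sd < 0:
            raise ValueError("noise parameters must be non-negative")


@dataclass
class CladeSimResult:
    tip_values: pd.DataFrame       # tips x traits
    node_states: pd.DataFrame      # node_id, tip_set, age, one column per trait
    fossil_observations: pd.DataFrame  # node_id, age, trait, value


def simulate_clade(spec: CladeSimSpec, seed=None) -> CladeSimResult:
    """One BM realization recorded at every node, with fossils at internal nodes."""
    rng = _as_rng(spec.seed if seed is None else seed)
    chron = spec.tree
    traits = sorted(spec.root_values)
    states: dict = {}
    for trait in traits:
        s2 = spec.sigma2_bm[trait] if isinstance(spec.sigma2_bm, dict) \
            else spec.sigma2_bm
        for node in chron.tree.preorder_node_iter():
            parent = node.parent_node
            if parent is None:
                states[(trait, node)] = spec.root_values[trait]
            else:
                t = node.edge.length or 0.0
                states[(trait, node)] = (states[(trait, parent)]
                                         + rng.normal(0.0, np.sqrt(s2 * t)))
    tip_rows = {}
    for leaf in chron.tree.leaf_node_iter():
        tip_rows[leaf.taxon.label] = {t: states[(t, leaf)] for t in traits}
    tip_values = pd.DataFrame.from_dict(tip_rows, orient="index").sort_index()

    node_rows, fossil_rows = [], []
    for node in chron.tree.preorder_node_iter():
        if node.is_leaf():
            continue
        tips = chron._leafset[node]
        from .trees import _node_id
        info_id = _node_id(tips)
        age = chron.node_age(node)
        rec = {"node_id": info_id, "tip_set": "|".join(sorted(tips)), "age": age}
        for t in traits:
            rec[t] = states[(t, node)]
        node_rows.append(rec)
        for t in traits:
            obs = (states[(t, node)]
                   + rng.normal(0.0, spec.fossil_noise_sd)
                   + spec.trend_per_ma * age)
            fossil_rows.append({"node_id": info_id, "age": age,
                                "trait": t, "value": obs})
    return CladeSimResult(
        tip_values=tip_values,
        node_states=pd.DataFrame(node_rows),
        fossil_observations=pd.DataFrame(fossil_rows),
    )
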