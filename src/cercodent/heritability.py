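"""Pedigree-based maximum-likelihood variance decomposition.

The phenotypic covariance among relatives is modelled as

    Cov(y) = sigma_G2 * A + sigma_E2 * I,

with A the additive relationship matrix. Narrow-sense heritability is
h2 = sigma_G2 / sigma_P2 with sigma_P2 = sigma_G2 + sigma_E2. The
likelihood is maximised by a one-time eigendecomposition of A and a 1-D
profile over h2 in [0, 1): for fixed h2 the weights h2*d_i + (1 - h2)
diagonalise the covariance, the mean coefficients are solved by weighted
least squares and the total variance is profiled out analytically. ML
(not REML) is used throughout so that nested models are comparable by
likelihood-ratio tests; sigma_G2 therefore carries the usual small-sample
downward bias.

Significance of h2 uses the boundary likelihood-ratio test: twice the
log-likelihood difference is referred to a 1/2:1/2 mixture of a point mass
at zero and chi-square with 1 df, i.e. the chi-square tail p is halved.
Covariate tests are ordinary (non-boundary) chi-square LRTs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import FitError
from .pedigree import kinship_matrix

_H2_EPS = 1e-9
_BOUNDARY_BAND = 0.02  # se flagged unreliable within this distance of 0 or 1


def inverse_normal(values) -> np.ndarray:
    """Rank-based inverse normal transform with Blom offsets.

    z_i = Phi^-1((r_i - 3/8) / (n + 1/4)), ties resolved by mid-ranks.
    Preserves rank order; for tie-free input the sample mean is 0 by the
    symmetry of the Blom scores.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("inverse_normal requires n >= 3")
    if np.isnan(x).any():
        raise ValueError("inverse_normal requires complete data")
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - 0.375) / (x.size + 0.25))


def lrt_pvalue(loglik_full: float, loglik_null: float, boundary: bool,
               df: int = 1, tol: float = 1e-6) -> float:
    """Likelihood-ratio p-value; halved chi-square tail for boundary tests."""
    lam = 2.0 * (loglik_full - loglik_null)
    if lam < -tol:
        raise FitError(
            f"likelihood ratio is negative ({lam:.3g}): optimisation failure"
        )
    lam = max(lam, 0.0)
    if boundary:
        return 0.5 * stats.chi2.sf(lam, 1)
    return stats.chi2.sf(lam, df)


def covariate_variance_proportion(var_raw: float, var_resid: float) -> float:
    """Fraction of raw phenotypic variance removed by the covariate model."""
    if var_raw <= 0:
        raise ValueError("var_raw must be positive")
    prop = 1.0 - var_resid / var_raw
    if prop < 0:
        warnings.warn("residual variance exceeds raw variance; clamping to 0")
        return 0.0
    return min(prop, 1.0)


@dataclass
class VarianceComponentsResults:
    """Fitted variance decomposition for one trait."""

    h2: float
    h2_se: float
    sigma_G2: float
    sigma_E2: float
    sigma_P2: float
    loglik: float
    loglik_null: float
    p_h2: float
    n_used: int
    beta: np.ndarray
    se_unreliable: bool
    unidentifiable: bool
    covariates_used: tuple = ()
    covariate_prop: float = np.nan
    covariate_pvalues: dict = field(default_factory=dict)
    trait: str = ""

    def summary(self) -> str:
        lines = [
            f"Variance decomposition{': ' + self.trait if self.trait else ''}",
            f"  n = {self.n_used}",
            f"  h2       = {self.h2:.4f}  (se {self.h2_se:.4f}"
            + (", unreliable near boundary)" if self.se_unreliable else ")"),
            f"  sigma_G2 = {self.sigma_G2:.4f}",
            f"  sigma_E2 = {self.sigma_E2:.4f}",
            f"  sigma_P2 = {self.sigma_P2:.4f}",
            f"  loglik   = {self.loglik:.4f}  (null {self.loglik_null:.4f})",
            f"  p(h2=0)  = {self.p_h2:.4g}  [boundary LRT, halved]",
        ]
        if self.covariates_used:
            lines.append(f"  covariates = {', '.join(self.covariates_used)}"
                         f"  (proportion of variance {self.covariate_prop:.3f})")
        if self.unidentifiable:
            lines.append("  WARNING: no family structure (A ~ I); h2 unidentifiable")
        return "\n".join(lines)


class VarianceComponentsModel:
    """ML variance decomposition of one trait on a pedigree.

    Parameters
    ----------
    y : array-like
        Phenotype values, aligned with the rows of ``A``.
    X : ndarray, optional
        Fixed-effect design; defaults to an intercept.
    A : ndarray, optional
        Additive relationship matrix. Exactly one of ``A`` / ``eig`` is
        required; pass ``eig=(d, U)`` to reuse an eigendecomposition across
        repeated fits on the same individuals.
    """

    def __init__(self, y, X=None, A=None, *, eig=None):
        self.y = np.asarray(y, dtype=float)
        n = self.y.size
        self.X = np.ones((n, 1)) if X is None else np.atleast_2d(np.asarray(X, float))
        if self.X.shape[0] != n:
            raise ValueError("X and y lengths differ")
        if eig is None:
            if A is None:
                raise ValueError("supply A or eig")
            A = np.asarray(A, dtype=float)
            d, U = np.linalg.eigh(A)
            if d[0] < -1e-8 * max(1.0, d[-1]):
                raise FitError("relationship matrix is not positive semidefinite")
            d = np.clip(d, 0.0, None)
            self._offdiag_max = float(np.abs(A - np.diag(np.diag(A))).max())
        else:
            d, U = eig
            self._offdiag_max = float(np.max(d) - np.min(d))
        self.d, self.U = d, U
        self.ty = U.T @ self.y
        self.tX = U.T @ self.X

    @classmethod
    def eigendecompose(cls, A: np.ndarray):
        """(d, U) of A for reuse across models on the same individuals."""
        d, U = np.linalg.eigh(np.asarray(A, dtype=float))
        return np.clip(d, 0.0, None), U

    # -- profile log-likelihood over h2 ---------------------------------
    def loglik(self, h2: float) -> float:
        n = self.ty.size
        w = h2 * self.d + (1.0 - h2)
        if np.any(w <= 0):
            return -np.inf
        sw = np.sqrt(w)
        Xw = self.tX / sw[:, None]
        yw = self.ty / sw
        beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
        rss = float(np.sum((yw - Xw @ beta) ** 2))
        sigma_P2 = rss / n
        if sigma_P2 <= 0:
            return -np.inf
        return -0.5 * (n * np.log(2 * np.pi * sigma_P2)
                       + float(np.sum(np.log(w))) + n)

    def _beta_sigma(self, h2: float):
        w = h2 * self.d + (1.0 - h2)
        sw = np.sqrt(w)
        Xw = self.tX / sw[:, None]
        yw = self.ty / sw
        beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
        sigma_P2 = float(np.sum((yw - Xw @ beta) ** 2)) / self.ty.size
        return beta, sigma_P2

    def fit(self) -> VarianceComponentsResults:
        unidentifiable = self._offdiag_max < 1e-10
        res = optimize.minimize_scalar(
            lambda h: -self.loglik(h), bounds=(0.0, 1.0 - _H2_EPS),
            method="bounded", options={"xatol": 1e-8},
        )
        # guard against a maximum pinned at either boundary
        candidates = [(self.loglik(0.0), 0.0), (-res.fun, float(res.x)),
                      (self.loglik(1.0 - _H2_EPS), 1.0 - _H2_EPS)]
        ll, h2 = max(candidates, key=lambda t: t[0])
        ll0 = self.loglik(0.0)
        p = lrt_pvalue(ll, ll0, boundary=True)
        beta, sigma_P2 = self._beta_sigma(h2)

        near_boundary = h2 < _BOUNDARY_BAND or h2 > 1.0 - _BOUNDARY_BAND
        se = np.nan
        if not unidentifiable:
            step = min(1e-3, max(h2, _H2_EPS), max(1.0 - _H2_EPS - h2, _H2_EPS))
            if step > 1e-7:
                curv = (self.loglik(h2 + step) - 2.0 * ll
                        + self.loglik(h2 - step)) / step**2
                if curv < 0:
                    se = float(np.sqrt(-1.0 / curv))
        return VarianceComponentsResults(
            h2=h2, h2_se=se, sigma_G2=h2 * sigma_P2,
            sigma_E2=(1.0 - h2) * sigma_P2, sigma_P2=sigma_P2,
            loglik=ll, loglik_null=ll0, p_h2=p, n_used=self.ty.size,
            beta=beta, se_unreliable=near_boundary or np.isnan(se),
            unidentifiable=unidentifiable,
        )


def screen_covariates(y, covars: pd.DataFrame, A=None, *, eig=None,
                      alpha: float = 0.05):
    """Retain covariates by LRT within the variance-decomposition likelihood.

    Candidates are first tested jointly (chi-square, df = number of
    candidates); if the joint test is significant at ``alpha``, each
    candidate is tested by a drop-one LRT and retained when p < alpha.
    Constant covariates are dropped with a warning before testing. Returns
    ``(retained, residuals, pvalues)`` where residuals come from the
    GLS fit of the retained-covariate mean model on the raw scale.
    """
    y = np.asarray(y, dtype=float)
    if np.nanstd(y) == 0:
        raise ValueError("trait is constant")
    names = []
    cols = []
    for name in covars.columns:
        col = np.asarray(covars[name], dtype=float)
        if np.std(col) == 0:
            warnings.warn(f"covariate {name!r} is constant; dropped")
            continue
        names.append(name)
        cols.append(col - col.mean())
    if eig is None:
        eig = VarianceComponentsModel.eigendecompose(A)

    def fit_with(idx):
        X = np.column_stack([np.ones_like(y)] + [cols[i] for i in idx]) \
            if idx else np.ones((y.size, 1))
        return VarianceComponentsModel(y, X, eig=eig).fit()

    pvalues: dict[str, float] = {}
    if not names:
        base = fit_with([])
        resid = y - base.beta[0]
        return [], resid, pvalues

    full = fit_with(list(range(len(names))))
    none = fit_with([])
    p_joint = lrt_pvalue(full.loglik, none.loglik, boundary=False, df=len(names))
    retained_idx: list[int] = []
    if p_joint < alpha:
        for i, name in enumerate(names):
            reduced = fit_with([j for j in range(len(names)) if j != i])
            pvalues[name] = lrt_pvalue(full.loglik, reduced.loglik,
                                       boundary=False, df=1)
            if pvalues[name] < alpha:
                retained_idx.append(i)
    else:
        pvalues = {name: p_joint for name in names}

    final = fit_with(retained_idx)
    X = np.column_stack([np.ones_like(y)] + [cols[i] for i in retained_idx]) \
        if retained_idx else np.ones((y.size, 1))
    resid = y - X @ final.beta
    return [names[i] for i in retained_idx], resid, pvalues


def heritability_analysis(
    trait_values: pd.Series,
    ped: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    *,
    alpha: float = 0.05,
    trait_name: str = "",
    kinship: tuple | None = None,
) -> VarianceComponentsResults:
    """Full single-trait workflow mirroring the heritability-table machinery.

    1. restrict the pedigree relationship matrix to phenotyped individuals;
    2. screen sex/age covariates by non-boundary LRT on the raw scale;
    3. form residuals from the retained-covariate GLS mean model and record
       the proportion of raw phenotypic variance they remove;
    4. inverse-normal transform the residuals;
    5. fit h2 on the transformed scale with a boundary LRT against h2 = 0.

    ``trait_values`` is indexed by pedigree id; missing phenotypes (or
    missing covariate values) drop the individual. ``kinship`` may carry a
    precomputed ``(ids, A)`` to avoid rebuilding it per trait.
    """
    ids_all, A_all = kinship_matrix(ped) if kinship is None else kinship
    pos = {v: i for i, v in enumerate(ids_all)}
    mask = trait_values.notna()
    if covariates is not None:
        covariates = covariates.reindex(trait_values.index)
        mask &= covariates.notna().all(axis=1)
    use = [i for i in trait_values.index[mask] if i in pos]
    if len(use) < 3:
        raise ValueError("fewer than 3 phenotyped pedigree members")
    sel = [pos[i] for i in use]
    A = A_all[np.ix_(sel, sel)]
    y = trait_values.loc[use].to_numpy(dtype=float)
    eig = VarianceComponentsModel.eigendecompose(A)

    if covariates is not None and covariates.shape[1]:
        retained, resid, pvals = screen_covariates(
            y, covariates.loc[use], eig=eig, alpha=alpha)
    else:
        retained, resid, pvals = [], y - y.mean(), {}
    prop = covariate_variance_proportion(
        float(np.var(y, ddof=1)), float(np.var(resid, ddof=1)))

    z = inverse_normal(resid)
    res = VarianceComponentsModel(z, eig=eig).fit()
    res.covariates_used = tuple(retained)
    res.covariate_prop = prop
    res.covariate_pvalues = pvals
    res.trait = trait_name
    return res


def heritability_report(results: dict[str, VarianceComponentsResults],
                        alpha: float = 0.05) -> pd.DataFrame:
    """One row per trait with h2, se, p, n, covariate burden and flags."""
    if not results:
        raise ValueError("no models supplied")
    rows = []
    for name, r in results.items():
        rows.append({
            "trait": name, "h2": r.h2, "h2_se": r.h2_se, "p_value": r.p_h2,
            "n_individuals": r.n_used, "covariate_prop": r.covariate_prop,
            "significant_covariates": ",".join(r.covariates_used),
            "h2_significant": bool(r.p_h2 < alpha),
        })
    return pd.DataFrame(rows)


def covariate_burden(table: pd.DataFrame, subset) -> float:
    """Mean covariate variance proportion over a named subset of report rows.

    ``subset`` is a boolean mask or an index/label list into ``table``.
    """
    sel = table.loc[subset] if not isinstance(subset, pd.Series) else table[subset]
    if len(sel) == 0:
        raise ValueError("empty subset")
    return float(sel["covariate_prop"].mean())
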