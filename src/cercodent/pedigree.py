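"""Pedigree relationship structure: the additive (numerator) relationship matrix.

The additive relationship A[i, j] is twice the kinship coefficient
Phi(i, j); its diagonal is 1 + F_i where F_i is the inbreeding coefficient.
A is built with the tabular (Henderson) recursion over a topological order
of the pedigree, with founders taken as unrelated and non-inbred.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import _topological_order, validate_pedigree


def kinship_matrix(ped: pd.DataFrame) -> tuple[list[str], np.ndarray]:
    """Additive relationship matrix over all pedigree members.

    Returns ``(ids, A)`` with ids in a parents-first (topological) order.
    Recursion: A[i,i] = 1 + A[s,d]/2 and A[i,j] = (A[j,s] + A[j,d])/2 for
    previously placed j, where an unknown parent contributes 0.
    """
    validate_pedigree(ped)
    order = _topological_order(ped)
    idx = {v: k for k, v in enumerate(order)}
    parents = {
        r["id"]: tuple(
            idx[p] if isinstance(p, str) else -1 for p in (r["sire"], r["dam"])
        )
        for _, r in ped.iterrows()
    }
    n = len(order)
    A = np.zeros((n, n))
    for i, ind in enumerate(order):
        s, d = parents[ind]
        A[i, i] = 1.0 + (0.5 * A[s, d] if s >= 0 and d >= 0 else 0.0)
        if i:
            row = np.zeros(i)
            if s >= 0:
                row += 0.5 * A[s, :i]
            if d >= 0:
                row += 0.5 * A[d, :i]
            A[i, :i] = row
            A[:i, i] = row
    return order, A


def inbreeding_coefficients(ped: pd.DataFrame) -> pd.Series:
    ids, A = kinship_matrix(ped)
    return pd.Series(np.diag(A) - 1.0, index=ids, name="F")
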