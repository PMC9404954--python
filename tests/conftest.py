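"""Shared fixtures: small trees, pedigrees and measurement tables.

Everything is generated programmatically; no data files are read beyond
the package's own printed-table fixtures.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cercodent import Chronogram

NINE_TIP_NEWICK = (
    "(((A:2,B:2):3,(C:1,D:1):4):5,((E:4,F:4):2,(G:3,(H:1,I:1):2):3):4);"
)
SEVEN_TIP_NEWICK = "(((A:2,B:2):3,(C:1,D:1):4):5,((E:4,F:4):2,G:6):4);"


@pytest.fixture
def nine_tip_tree() -> Chronogram:
    return Chronogram.from_newick(NINE_TIP_NEWICK)


@pytest.fixture
def seven_tip_tree() -> Chronogram:
    return Chronogram.from_newick(SEVEN_TIP_NEWICK)


@pytest.fixture
def trio_pedigree() -> pd.DataFrame:
    return pd.DataFrame({
        "id": ["father", "mother", "child"],
        "sire": [np.nan, np.nan, "father"],
        "dam": [np.nan, np.nan, "mother"],
        "sex": ["M", "F", "F"],
        "age": [20.0, 18.0, 2.0],
    })


@pytest.fixture
def inbred_pedigree() -> pd.DataFrame:
    """Founders, two full sibs, and an offspring of the full-sib mating."""
    return pd.DataFrame({
        "id": ["f", "m", "c1", "c2", "gc"],
        "sire": [np.nan, np.nan, "f", "f", "c1"],
        "dam": [np.nan, np.nan, "m", "m", "c2"],
        "sex": ["M", "F", "M", "F", "M"],
        "age": [20.0, 20.0, 10.0, 10.0, 2.0],
    })


def random_ultrametric_newick(rng: np.random.Generator, n_tips: int) -> str:
    """Coalescent-style random ultrametric tree with exponential waiting times."""
    frags = [(f"t{i}", 0.0) for i in range(n_tips)]
    height = 0.0
    while len(frags) > 1:
        height += rng.exponential(1.0)
        i, j = sorted(rng.choice(len(frags), size=2, replace=False))
        (fa, ha), (fb, hb) = frags[i], frags[j]
        merged = (f"({fa}:{height - ha:.6f},{fb}:{height - hb:.6f})", height)
        frags = [f for k, f in enumerate(frags) if k not in (i, j)] + [merged]
    return frags[0][0] + ";"


@pytest.fixture
def measurement_rows() -> pd.DataFrame:
    """Complete left+right crown metrics for two specimens of one species."""
    rows = []
    metrics = {"P4": (7.0, 6.3), "M1": (10.0, 8.5), "M2": (12.0, 9.0),
               "M3": (12.2, 8.8)}
    for sid in ("s1", "s2"):
        for side in ("L", "R"):
            for tooth, (md, bl) in metrics.items():
                rows.append({
                    "specimen_id": sid, "genus": "Papio", "species": "hamadryas",
                    "side": side, "tooth": tooth,
                    "md_length": md, "bl_breadth": bl,
                })
    return pd.DataFrame(rows)
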