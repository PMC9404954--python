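"""Readers and writers for the external table formats, plus packaged fixtures.

All tabular inputs are tidy CSV (RFC-4180 quoting). Missing values are empty
fields on write; ``NA`` and empty are both accepted on read. Pedigree founders
are marked with the literal token ``0`` or an empty field.
"""

from __future__ import annotations

import importlib.resources

import numpy as np
import pandas as pd

from .errors import CycleError, IntegrityError, SchemaError

MEASUREMENT_COLUMNS = [
    "specimen_id", "genus", "species", "side", "tooth", "md_length", "bl_breadth",
]
PEDIGREE_COLUMNS = ["id", "sire", "dam", "sex", "age"]
PAIRING_COLUMNS = [
    "pairing_id", "node_tips", "fossil_genus", "trait",
    "include_in_mean", "include_in_direction_count",
]

SIDES = {"L", "R"}
TEETH = {"P4", "M1", "M2", "M3"}
_NA_TOKENS = {"", "NA", "NaN", "nan"}

FIXTURE_NAMES = ("table1", "table2", "table3", "table5", "table8")


def _read_csv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, dtype=str, keep_default_na=False, **kwargs)


def _require_columns(df: pd.DataFrame, required, what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing columns {missing}")


def _to_float(s: str):
    if s is None or str(s).strip() in _NA_TOKENS:
        return np.nan
    return float(s)


def read_measurements(path) -> pd.DataFrame:
    """Read a long-format crown-metric table.

    One row per (specimen, side, tooth) with mesiodistal length and
    buccolingual breadth in mm. Non-numeric or non-positive metrics are
    rejected with a row-level diagnostic; breadth may be missing.
    """
    raw = _read_csv(path)
    _require_columns(raw, MEASUREMENT_COLUMNS, "measurement table")
    bad: list[str] = []
    md, bl = [], []
    for i, row in raw.iterrows():
        try:
            v = _to_float(row["md_length"])
        except ValueError:
            bad.append(f"row {i}: md_length {row['md_length']!r} not numeric")
            v = np.nan
        else:
            if np.isnan(v):
                bad.append(f"row {i}: md_length missing")
            elif v <= 0:
                bad.append(f"row {i}: md_length {v} not positive")
        md.append(v)
        try:
            w = _to_float(row["bl_breadth"])
        except ValueError:
            bad.append(f"row {i}: bl_breadth {row['bl_breadth']!r} not numeric")
            w = np.nan
        else:
            if not np.isnan(w) and w <= 0:
                bad.append(f"row {i}: bl_breadth {w} not positive")
        bl.append(w)
        if row["side"] not in SIDES:
            bad.append(f"row {i}: side {row['side']!r} not in {sorted(SIDES)}")
        if row["tooth"] not in TEETH:
            bad.append(f"row {i}: tooth {row['tooth']!r} not in {sorted(TEETH)}")
    if bad:
        raise IntegrityError("measurement table: " + "; ".join(bad))
    out = raw[["specimen_id", "genus", "species", "side", "tooth"]].copy()
    out["md_length"] = md
    out["bl_breadth"] = bl
    dup = out.duplicated(subset=["specimen_id", "side", "tooth"])
    if dup.any():
        rows = out.loc[dup, ["specimen_id", "side", "tooth"]].to_records(index=False)
        raise IntegrityError(f"duplicate (specimen, side, tooth) rows: {list(rows)}")
    return out.reset_index(drop=True)


def write_measurements(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, na_rep="")


def read_pedigree(path) -> pd.DataFrame:
    """Read a pedigree table and verify acyclicity and parent-sex consistency.

    Founders are rows whose sire/dam field is empty, ``0`` or ``NA``; they are
    represented as NaN in the returned frame.
    """
    raw = _read_csv(path)
    _require_columns(raw, PEDIGREE_COLUMNS, "pedigree table")
    ped = raw.copy()
    for col in ("sire", "dam"):
        ped[col] = [
            np.nan if str(v).strip() in (_NA_TOKENS | {"0"}) else str(v)
            for v in ped[col]
        ]
    ped["age"] = [_to_float(v) for v in ped["age"]]
    validate_pedigree(ped)
    return ped.reset_index(drop=True)


def validate_pedigree(ped: pd.DataFrame) -> None:
    ids = set(ped["id"])
    if len(ids) != len(ped):
        raise IntegrityError("pedigree: duplicate ids")
    sex = dict(zip(ped["id"], ped["sex"]))
    bad = []
    for col, want in (("sire", "M"), ("dam", "F")):
        for v in ped[col].dropna():
            if v not in ids:
                bad.append(f"{col} {v!r} not in pedigree")
            elif sex.get(v) != want:
                bad.append(f"{col} {v!r} has sex {sex.get(v)!r}, expected {want!r}")
    if bad:
        raise IntegrityError("pedigree: " + "; ".join(bad))
    if (ped["age"].dropna() < 0).any():
        raise IntegrityError("pedigree: negative age")
    _topological_order(ped)  # raises CycleError on a cycle


def _topological_order(ped: pd.DataFrame) -> list[str]:
    """Order ids so that parents precede offspring; raise CycleError otherwise."""
    parents = {
        r["id"]: [p for p in (r["sire"], r["dam"]) if isinstance(p, str)]
        for _, r in ped.iterrows()
    }
    order: list[str] = []
    state: dict[str, int] = {}  # 0 visiting, 1 done

    for start in parents:
        if start in state:
            continue
        stack = [(start, iter(parents[start]))]
        state[start] = 0
        while stack:
            node, it = stack[-1]
            advanced = False
            for p in it:
                if state.get(p) == 0:
                    raise CycleError(f"pedigree cycle involving {p!r}")
                if p not in state:
                    state[p] = 0
                    stack.append((p, iter(parents[p])))
                    advanced = True
                    break
            if not advanced:
                state[node] = 1
                order.append(node)
                stack.pop()
    return order


def write_pedigree(ped: pd.DataFrame, path) -> None:
    out = ped.copy()
    for col in ("sire", "dam"):
        out[col] = out[col].fillna("0")
    out.to_csv(path, index=False, na_rep="")


def read_pairings(path) -> pd.DataFrame:
    """Read a node-fossil pairing specification.

    ``node_tips`` is a ``|``-separated list of tip labels whose MRCA defines
    the node (a single label addresses a tip pairing). Flags must be explicit.
    """
    raw = _read_csv(path)
    _require_columns(raw, PAIRING_COLUMNS, "pairing table")
    out = raw.copy()
    for col in ("include_in_mean", "include_in_direction_count"):
        vals = []
        for v in out[col]:
            s = str(v).strip().lower()
            if s in {"true", "1", "yes"}:
                vals.append(True)
            elif s in {"false", "0", "no"}:
                vals.append(False)
            else:
                raise IntegrityError(f"pairing table: flag {col}={v!r} not explicit")
        out[col] = vals
    bad = set(out["trait"]) - {"MMC", "PMM"}
    if bad:
        raise IntegrityError(f"pairing table: unknown traits {sorted(bad)}")
    return out.reset_index(drop=True)


def write_pairings(pairings: pd.DataFrame, path) -> None:
    pairings.to_csv(path, index=False, na_rep="")


def load_fixture(name: str) -> pd.DataFrame:
    """Load one of the packaged printed tables: table1|table2|table3|table5|table8."""
    if name not in FIXTURE_NAMES:
        raise LookupError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")
    ref = importlib.resources.files("cercodent.fixtures").joinpath(f"{name}.csv")
    with importlib.resources.as_file(ref) as p:
        if name == "table3":
            df = pd.read_csv(p)
            # printed "<0.001" entries carry an upper bound; keep the printed
            # string and expose a numeric bound for significance logic
            df["p_value"] = [
                float(str(s).lstrip("<")) for s in df["p_printed"]
            ]
            return df
        if name == "table8":
            df = pd.read_csv(p)
            for col in ("include_in_mean", "include_in_direction_count"):
                df[col] = df[col].astype(bool)
            return df
        return pd.read_csv(p)
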