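"""Strain x lipid-class composition tables.

Two instruments see complementary parts of the hydrolysis-derived core lipid
pool: GC-FID/GC-MS quantifies mono- and diethers (including archaeol, AR)
while HPLC-MS quantifies AR and the tetraethers (GDGTs). Because AR is the
one compound measured by both, each dataset is normalized to its AR response
and the two are combined into a single percent distribution per strain.

Tables are pandas DataFrames with compounds as rows and strains as columns
(missing compounds are absent/NaN cells in raw tables and count as zero in
percent normalization). Percent columns sum to 100.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "merge_core_datasets",
    "gdgt_ar_ratio",
    "aggregate_ipl_areas",
    "read_abundance_tsv",
    "write_abundance_tsv",
]

AR = "AR"
GDGT_CLASSES = ("GDGT-0", "GDGT-1")


class ProfileError(ValueError):
    pass


def _check_ar(table: pd.DataFrame, which: str) -> pd.Series:
    if AR not in table.index:
        raise ProfileError(f"{which} table has no {AR} row")
    ar = table.loc[AR]
    bad = [c for c in table.columns if pd.isna(ar[c]) or ar[c] <= 0]
    if bad:
        raise ProfileError(f"{which} table has missing/zero {AR} for strains: {bad}")
    return ar


def _to_percent(table: pd.DataFrame) -> pd.DataFrame:
    filled = table.fillna(0.0)
    totals = filled.sum(axis=0)
    return filled.div(totals, axis=1) * 100.0


def merge_core_datasets(gc_table: pd.DataFrame,
                        hplc_table: pd.DataFrame) -> pd.DataFrame:
    """Combine GC-derived and HPLC-derived core lipid areas into one percent table.

    Each table is scaled per strain so AR = 1, the union of compounds is
    taken (AR counted once; for any other compound present in both the GC
    value wins), and the union is rescaled to percent of total per strain.
    """
    strains = [c for c in gc_table.columns if c in hplc_table.columns]
    if not strains:
        raise ProfileError("tables share no strain columns")
    gc = gc_table[strains].astype(float)
    hplc = hplc_table[strains].astype(float)
    gc_norm = gc.div(_check_ar(gc, "GC"), axis=1)
    hplc_norm = hplc.div(_check_ar(hplc, "HPLC"), axis=1)
    extra = hplc_norm.loc[[i for i in hplc_norm.index if i not in gc_norm.index]]
    combined = pd.concat([gc_norm, extra])
    return _to_percent(combined)


def gdgt_ar_ratio(percent_table: pd.DataFrame, strain: str) -> float:
    """(GDGT-0 + GDGT-1) / AR for one strain of a composition table.

    Absent GDGT rows count as zero; an absent or zero AR entry is an error.
    Returned at full precision; round for display.
    """
    if strain not in percent_table.columns:
        raise ProfileError(f"unknown strain: {strain!r}")
    col = percent_table[strain]
    ar = col.get(AR)
    if ar is None or pd.isna(ar) or ar <= 0:
        raise ProfileError(f"{AR} absent or zero for strain {strain!r}")
    gdgt = sum(float(col.get(g, 0.0) or 0.0) for g in GDGT_CLASSES
               if not pd.isna(col.get(g, 0.0)))
    return gdgt / float(ar)


def aggregate_ipl_areas(areas: pd.DataFrame, by: str = "head") -> pd.DataFrame:
    """Aggregate per-species IPL peak areas into class groups, percent per strain.

    ``areas`` is tidy with columns ``strain``, ``head``, ``core``, ``area``
    (areas non-negative). ``by`` selects the grouping key: "head", "core" or
    "both". An empty input yields an empty table.
    """
    if by not in ("head", "core", "both"):
        raise ProfileError(f"unknown grouping key: {by!r}")
    if len(areas) == 0:
        return pd.DataFrame()
    if (areas["area"] < 0).any():
        raise ProfileError("negative peak area")
    df = areas.copy()
    if by == "both":
        df["group"] = df["head"].astype(str) + "-" + df["core"].astype(str)
    else:
        df["group"] = df[by]
    table = df.pivot_table(index="group", columns="strain", values="area",
                           aggfunc="sum", fill_value=0.0)
    table.index.name = None
    table.columns.name = None
    return _to_percent(table)


def read_abundance_tsv(path) -> pd.DataFrame:
    """Read a compounds-as-rows, strains-as-columns TSV table."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_abundance_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t")
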