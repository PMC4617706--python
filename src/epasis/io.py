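"""Readers and writers for the pipeline's tabular formats.

Canonical on-disk format is TSV (CSV accepted on read; decimal point,
UTF-8).  The wide intensity table has the accession in the first column
and one column per (replicate, elution step) named
``<replicate>__<step>``; a MaxQuant-proteinGroups-style dialect selects
intensity columns by a configurable prefix instead.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .assign import Assignment
from .containers import ElutionProfileSet, IntensityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "read_intensity_table",
    "write_intensity_table",
    "read_modules",
    "write_profiles",
    "read_profiles",
    "write_assignment",
    "read_epd_table",
]

_SEP = "__"


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_intensity_table(
    path: str | Path, *, intensity_prefix: str | None = None
) -> IntensityMatrix:
    """Read a wide intensity table into an :class:`IntensityMatrix`.

    Columns after the accession column must be named
    ``<replicate>__<step>`` and cover the complete replicate x step
    grid.  With ``intensity_prefix`` (MaxQuant-style, e.g.
    ``"Intensity "``) only columns carrying the prefix are used, the
    prefix is stripped before parsing, and other columns are ignored.
    Step order is first-appearance order in the header (the elution
    sequence), never re-sorted.  Unparseable numeric cells become
    missing, with a logged count.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=str)
    if intensity_prefix is not None:
        cols = [c for c in df.columns if c.startswith(intensity_prefix)]
        if not cols:
            raise ValueError(f"no columns with prefix {intensity_prefix!r}")
        df = df[cols]
        df.columns = [c[len(intensity_prefix):] for c in cols]
    pairs = []
    for c in df.columns:
        if _SEP not in c:
            raise ValueError(f"column {c!r} is not of the form <replicate>__<step>")
        rep, step = c.split(_SEP, 1)
        pairs.append((rep, step))
    if len(set(pairs)) != len(pairs):
        dup = [c for c in df.columns if pairs.count(tuple(c.split(_SEP, 1))) > 1]
        raise ValueError(f"duplicated (replicate, step) columns: {dup}")
    replicates = list(dict.fromkeys(r for r, _ in pairs))
    steps = list(dict.fromkeys(s for _, s in pairs))
    missing_cols = [
        f"{r}{_SEP}{s}" for r in replicates for s in steps if (r, s) not in set(pairs)
    ]
    if missing_cols:
        raise ValueError(f"incomplete replicate x step grid; missing: {missing_cols}")

    def _cell(s):
        # Python float() is correctly rounded; pandas' fast parser is not
        if s is None or (isinstance(s, float) and np.isnan(s)) or s == "":
            return np.nan
        try:
            return float(s)
        except ValueError:
            return np.nan

    numeric = df.apply(lambda col: col.map(_cell))
    n_bad = int((numeric.isna() & df.notna() & (df != "")).sum().sum())
    if n_bad:
        logger.warning("%d unparseable cells in %s treated as missing", n_bad, path)
    numeric.columns = pd.MultiIndex.from_tuples(pairs, names=["replicate", "step"])
    return IntensityMatrix(numeric, replicates, steps)


def write_intensity_table(m: IntensityMatrix, path: str | Path) -> None:
    path = Path(path)
    flat = m.values.copy()
    flat.columns = [f"{r}{_SEP}{s}" for r, s in m.values.columns]
    flat.index.name = "accession"
    flat.to_csv(path, sep=_sep_for(path))


def read_modules(path: str | Path) -> dict[str, list[str]]:
    """Read a module-definition table: columns (module, accession[, source_reference])."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    for col in ("module", "accession"):
        if col not in df.columns:
            raise ValueError(f"module-definition file lacks a {col!r} column")
    out: dict[str, list[str]] = {}
    for _, row in df.iterrows():
        out.setdefault(row["module"], []).append(row["accession"])
    return out


def write_profiles(p: ElutionProfileSet, path: str | Path) -> None:
    path = Path(path)
    df = p.profiles.copy()
    df.index.name = "accession"
    df["n_replicates_used"] = p.n_replicates_used
    df.to_csv(path, sep=_sep_for(path))


def read_profiles(path: str | Path) -> ElutionProfileSet:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, float_precision="round_trip")
    n_used = None
    if "n_replicates_used" in df.columns:
        n_used = df.pop("n_replicates_used")
    return ElutionProfileSet(
        profiles=df.astype(float), steps=list(df.columns), n_replicates_used=n_used
    )


def write_assignment(a: Assignment, path: str | Path) -> None:
    path = Path(path)
    a.table.to_csv(path, sep=_sep_for(path))


def read_epd_table(path: str | Path) -> pd.DataFrame:
    """Read a precomputed EPD table (accession index, one column per module).

    Accepts the layout of published supplementary EPD tables exported to
    TSV/CSV; values must be nonnegative distances.
    """
    path = Path(path)
    df = pd.read_csv(
        path, sep=_sep_for(path), index_col=0, float_precision="round_trip"
    ).astype(float)
    if (df.to_numpy() < 0).any():
        raise ValueError("EPD values must be >= 0")
    return df
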