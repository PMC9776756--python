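"""Reading and writing of screen tables, annotations and result tables.

All tables are TSV (tab-separated, UTF-8, "." decimal), the dialect of
MaxQuant-style exports. Fractions are 1-based integers 1..25 throughout;
conditions are the labels ``CTRL`` and ``RNASE``.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ParseError
from .simulate import CONDITIONS, FRACTIONS

N_FRACTIONS = len(FRACTIONS)

LONG_COLUMNS = ["protein_id", "condition", "replicate", "fraction", "intensity"]
WIDE_META = ["protein_id", "condition", "replicate"]
WIDE_FRACTION_COLUMNS = [f"F{f}" for f in FRACTIONS]

ANNOTATION_COLUMNS = {
    "rbp2go_score": float,
    "rbp_listed": bool,
    "rbd_count": float,  # integer-valued but nullable
    "rbd_fraction": float,
    "idr_fraction": float,
    "pI": float,
    "monomeric_mw_kda": float,
}


class ScreenTable:
    """A validated long-format abundance table over the protein x
    condition x replicate x fraction grid.

    Missing fractions are explicit: profiles are only materialized for
    (protein, condition, replicate) channels present in the input, and
    completeness is reported rather than silently zero-filled.
    """

    def __init__(self, data: pd.DataFrame, min_replicates: int = 2, validate: bool = True):
        self.data = data.reset_index(drop=True)
        self.min_replicates = min_replicates
        if validate:
            self._validate()

    # -- validation --------------------------------------------------------
    def _validate(self) -> None:
        df = self.data
        missing = [c for c in LONG_COLUMNS if c not in df.columns]
        if missing:
            raise ParseError(f"screen table missing columns {missing}")
        bad_cond = df.loc[~df["condition"].isin(CONDITIONS)]
        if len(bad_cond):
            i = bad_cond.index[0]
            raise ParseError(
                f"row {i}: unknown condition {bad_cond['condition'].iloc[0]!r} "
                f"(expected one of {CONDITIONS})"
            )
        frac = df["fraction"]
        bad_frac = df.loc[(frac < 1) | (frac > N_FRACTIONS) | (frac != frac.astype(int))]
        if len(bad_frac):
            i = bad_frac.index[0]
            raise ParseError(f"row {i}: fraction {bad_frac['fraction'].iloc[0]} outside 1..{N_FRACTIONS}")
        bad_int = df.loc[df["intensity"] < 0]
        if len(bad_int):
            i = bad_int.index[0]
            raise ParseError(f"row {i}: negative intensity {bad_int['intensity'].iloc[0]}")
        dup = df.duplicated(subset=["protein_id", "condition", "replicate", "fraction"])
        if dup.any():
            i = int(np.flatnonzero(dup.to_numpy())[0])
            raise ParseError(f"row {i}: duplicate (protein, condition, replicate, fraction) entry")

    # -- accessors ---------------------------------------------------------
    @property
    def proteins(self) -> list[str]:
        return sorted(self.data["protein_id"].unique())

    @property
    def replicates(self) -> list[int]:
        return sorted(self.data["replicate"].unique())

    def __len__(self) -> int:
        return len(self.data)

    def profiles(self, protein_id: str, condition: str) -> pd.DataFrame:
        """Replicate x fraction abundance matrix for one protein/condition.

        Rows are the replicates that quantified the protein (complete
        channels only); columns the 25 fractions.
        """
        sub = self.data[
            (self.data["protein_id"] == protein_id) & (self.data["condition"] == condition)
        ]
        mat = sub.pivot(index="replicate", columns="fraction", values="intensity")
        mat = mat.dropna(axis=0)  # drop incomplete channels
        return mat.reindex(columns=FRACTIONS)

    def completeness(self) -> pd.DataFrame:
        """Per (protein, condition): number of complete replicate channels
        and whether the protein meets ``min_replicates``."""
        counts = (
            self.data.groupby(["protein_id", "condition", "replicate"])["fraction"]
            .nunique()
            .eq(N_FRACTIONS)
            .groupby(["protein_id", "condition"])
            .sum()
            .rename("n_complete_replicates")
            .reset_index()
        )
        counts["sufficient"] = counts["n_complete_replicates"] >= self.min_replicates
        return counts

    def insufficient_proteins(self) -> list[str]:
        """Proteins quantified in fewer than min_replicates complete
        channels in at least one condition, or missing a condition."""
        comp = self.completeness().pivot(
            index="protein_id", columns="condition", values="n_complete_replicates"
        )
        comp = comp.reindex(columns=list(CONDITIONS)).fillna(0)
        bad = comp[(comp < self.min_replicates).any(axis=1)]
        return sorted(bad.index)


def read_screen(path: str | Path, format: str = "long", min_replicates: int = 2) -> ScreenTable:
    """Read an abundance table (``long`` or ``wide`` dialect) and validate it."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t")
    if format == "long":
        return ScreenTable(df, min_replicates=min_replicates)
    if format == "wide":
        missing = [c for c in WIDE_META + WIDE_FRACTION_COLUMNS if c not in df.columns]
        if missing:
            raise ParseError(f"wide table missing columns {missing}")
        long = df.melt(
            id_vars=WIDE_META,
            value_vars=WIDE_FRACTION_COLUMNS,
            var_name="fraction",
            value_name="intensity",
        )
        long["fraction"] = long["fraction"].str.lstrip("F").astype(int)
        long = long.dropna(subset=["intensity"]).sort_values(
            ["protein_id", "condition", "replicate", "fraction"]
        )
        return ScreenTable(long.reset_index(drop=True), min_replicates=min_replicates)
    raise ParseError(f"unknown format {format!r}; expected 'long' or 'wide'")


def write_screen(table: ScreenTable | pd.DataFrame, path: str | Path, format: str = "long") -> None:
    df = table.data if isinstance(table, ScreenTable) else table
    path = Path(path)
    if format == "long":
        df.to_csv(path, sep="\t", index=False)
    elif format == "wide":
        wide = df.pivot_table(
            index=WIDE_META, columns="fraction", values="intensity", aggfunc="first"
        )
        wide.columns = [f"F{c}" for c in wide.columns]
        wide.reset_index().to_csv(path, sep="\t", index=False)
    else:
        raise ParseError(f"unknown format {format!r}")


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read a protein annotation table keyed by protein_id.

    Known columns (``rbp2go_score, rbp_listed, rbd_count, rbd_fraction,
    idr_fraction, pI, monomeric_mw_kda``) are type-checked and
    range-checked; unknown columns are preserved. Empty cells stay
    missing (NaN), never silently zero.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t")
    if "protein_id" not in df.columns:
        raise ParseError("annotation table missing 'protein_id' column")
    dup = df["protein_id"].duplicated()
    if dup.any():
        raise ParseError(f"duplicated protein_id {df.loc[dup, 'protein_id'].iloc[0]!r}")
    for col, typ in ANNOTATION_COLUMNS.items():
        if col not in df.columns:
            continue
        if typ is bool:
            df[col] = df[col].map(_parse_bool)
            continue
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise ParseError(f"non-numeric value in column {col!r}: {exc}") from None
    for col in ("rbd_fraction", "idr_fraction"):
        if col in df.columns:
            bad = df.loc[(df[col] < 0) | (df[col] > 1)]
            if len(bad):
                raise ParseError(
                    f"{col} = {bad[col].iloc[0]} for {bad['protein_id'].iloc[0]!r} outside [0,1]"
                )
    if "monomeric_mw_kda" in df.columns:
        bad = df.loc[df["monomeric_mw_kda"] <= 0]
        if len(bad):
            raise ParseError(f"non-positive monomeric_mw_kda for {bad['protein_id'].iloc[0]!r}")
    if "rbd_count" in df.columns:
        bad = df.loc[df["rbd_count"] < 0]
        if len(bad):
            raise ParseError(f"negative rbd_count for {bad['protein_id'].iloc[0]!r}")
    return df.set_index("protein_id", drop=False)


def _parse_bool(v):
    if pd.isna(v) or v == "":
        return np.nan
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    s = str(v).strip().lower()
    if s in ("true", "1", "yes", "t"):
        return True
    if s in ("false", "0", "no", "f"):
        return False
    raise ParseError(f"cannot parse boolean {v!r}")


RESULT_FILES = {
    "peaks": "peak_fits.tsv",
    "shifts": "shifts.tsv",
    "proteins": "proteins.tsv",
}


def write_results(results, outdir: str | Path) -> dict[str, Path]:
    """Write the three result tables of a fitted screen.

    ``results`` is a :class:`~rdeep.model.ScreenResults` (or any object
    with ``peak_table``, ``shift_table`` and ``protein_table`` DataFrame
    attributes). Emits ``peak_fits.tsv`` (one row per fitted Gaussian),
    ``shifts.tsv`` (one row per control/RNase peak pairing) and
    ``proteins.tsv`` (per-protein summary). Returns the written paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables = {
        "peaks": results.peak_table,
        "shifts": results.shift_table,
        "proteins": results.protein_table,
    }
    if all(len(t) == 0 for t in tables.values()):
        raise ParseError("refusing to write empty result set")
    paths = {}
    for key, df in tables.items():
        p = outdir / RESULT_FILES[key]
        df.to_csv(p, sep="\t", index=False, float_format="%.10g")
        paths[key] = p
    return paths
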