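"""Differential-expression gene tables (consumed, not recomputed).

The table carries the shape of a published DEG list: gene id, direction of
regulation, log fold-change and FDR.  Direction may be given explicitly or
inferred from the sign of the log fold-change.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

REQUIRED_COLUMNS = ("gene_id", "log_fc", "fdr")


@dataclass
class GeneTable:
    """Typed DEG rows: gene_id, direction ('up'/'down'), log_fc, fdr."""

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.rows
        for col in ("gene_id", "direction", "log_fc", "fdr"):
            if col not in df.columns:
                raise ValueError(f"gene table missing column {col!r}")
        bad_dir = set(df["direction"]) - {"up", "down"}
        if bad_dir:
            raise ValueError(f"invalid direction value(s): {sorted(bad_dir)}")
        if ((df["fdr"] < 0) | (df["fdr"] > 1)).any():
            raise ValueError("fdr values must lie in [0, 1]")
        for direction, sub in df.groupby("direction"):
            dup = sub["gene_id"][sub["gene_id"].duplicated()].unique()
            if len(dup):
                raise ValueError(
                    f"duplicate gene ids within direction {direction!r}: "
                    f"{sorted(dup)}"
                )

    def gene_set(self, direction: str) -> set[str]:
        sub = self.rows[self.rows["direction"] == direction]
        return set(sub["gene_id"])

    def __len__(self) -> int:
        return len(self.rows)


def read_gene_table(path) -> GeneTable:
    """Read a TSV gene table with header.

    Requires ``gene_id``, ``log_fc`` and ``fdr`` columns; an optional
    ``direction`` column overrides sign-based inference.  A zero log
    fold-change without an explicit direction is ambiguous and rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"gene table missing required column(s): {missing}")
    for col in ("log_fc", "fdr"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() & df[col].notna()] + 2  # 1-based + header
        if len(bad):
            raise ValueError(
                f"unparseable numeric value in column {col!r} at "
                f"line(s) {bad.tolist()}"
            )
        if vals.isna().any():
            raise ValueError(f"missing value in column {col!r}")
        df[col] = vals
    if "direction" not in df.columns:
        zero = df.index[df["log_fc"] == 0] + 2
        if len(zero):
            raise ValueError(
                "log_fc of exactly 0 with no direction column is ambiguous "
                f"(line(s) {zero.tolist()})"
            )
        df["direction"] = ["up" if v > 0 else "down" for v in df["log_fc"]]
    return GeneTable(rows=df[["gene_id", "direction", "log_fc", "fdr"]].copy())


def write_gene_table(table: GeneTable, path) -> None:
    table.rows.to_csv(path, sep="\t", index=False)
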