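"""Per-sample categorical metadata: stratifiers and tested characters.

A metadata table has one row per sample.  Ordinary columns are categorical
(string levels, empty cell = missing).  Declared *multi-label* columns hold a
set of levels per sample — a swab location can sit on several transit lines —
and are split from the raw TSV cell on a configurable delimiter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd


@dataclass
class SampleMetadata:
    """Categorical sample annotations.

    Parameters
    ----------
    table
        DataFrame indexed by sample id.  Multi-label columns contain
        ``frozenset`` of level strings; other columns contain strings or
        ``None`` for missing.
    multilabel
        Names of the multi-label columns.
    """

    table: pd.DataFrame
    multilabel: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            dups = self.table.index[self.table.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids in metadata: {dups}")
        unknown = self.multilabel - set(self.table.columns)
        if unknown:
            raise ValueError(f"multi-label columns not in table: {sorted(unknown)}")
        for col in self.table.columns:
            if not self.table[col].dropna().astype(bool).any():
                raise ValueError(f"metadata column {col!r} has no non-missing value")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def variables(self) -> list[str]:
        return list(self.table.columns)

    def levels(self, variable: str) -> list[str]:
        """Sorted distinct levels of a variable (union of sets if multi-label)."""
        col = self.table[variable]
        if variable in self.multilabel:
            out: set[str] = set()
            for cell in col.dropna():
                out |= set(cell)
            return sorted(out)
        return sorted({v for v in col.dropna() if v != ""})

    def level_mask(self, variable: str, level: str) -> dict[str, bool]:
        """Map sample id -> membership of ``level`` under ``variable``."""
        if variable not in self.table.columns:
            raise KeyError(f"unknown metadata variable {variable!r}")
        col = self.table[variable]
        if variable in self.multilabel:
            return {
                s: (cell is not None and level in cell)
                for s, cell in col.items()
            }
        return {s: (cell == level) for s, cell in col.items()}

    def states(self, variable: str) -> dict[str, str | None]:
        """Map sample id -> state string (None for missing); single-label only."""
        if variable in self.multilabel:
            raise ValueError(
                f"{variable!r} is multi-label and has no single state per sample"
            )
        col = self.table[variable]
        return {
            s: (None if (pd.isna(v) or v == "") else str(v)) for s, v in col.items()
        }

    def subset(self, sample_ids: list[str]) -> "SampleMetadata":
        sub = self.table.loc[sample_ids]
        return SampleMetadata(sub, set(self.multilabel))

    def write_tsv(self, path, delimiter: str = ";") -> None:
        out = self.table.copy()
        for col in self.multilabel:
            out[col] = out[col].map(
                lambda cell: "" if cell is None else delimiter.join(sorted(cell))
            )
        out.index.name = out.index.name or "sample"
        out.to_csv(path, sep="\t")


def read_metadata(
    path,
    multilabel: tuple[str, ...] | list[str] = (),
    delimiter: str = ";",
) -> SampleMetadata:
    """Read a sample metadata TSV (first column = sample id, header required).

    ``multilabel`` names columns whose cells are ``delimiter``-separated level
    lists; they are parsed into sets (empty cell -> empty set).
    """
    table = pd.read_csv(path, sep="\t", dtype=str, index_col=0)
    if table.index.size == 0:
        raise ValueError(f"metadata file {path} has no samples")
    table.index = table.index.astype(str)
    for col in multilabel:
        if col not in table.columns:
            raise ValueError(f"declared multi-label column {col!r} not in {path}")
        table[col] = table[col].map(
            lambda cell: frozenset()
            if pd.isna(cell) or cell == ""
            else frozenset(cell.split(delimiter))
        )
    return SampleMetadata(table, set(multilabel))
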