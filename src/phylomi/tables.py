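"""Species x trait tables with explicit missingness and per-column types."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["TraitTable"]

CONTINUOUS = "continuous"
CATEGORICAL = "categorical"


@dataclass
class TraitTable:
    """A species x trait matrix with a missingness mask.

    ``df`` holds one row per species (index = species label, sorted) and one
    column per trait.  Continuous traits are floats, stored on natural-log
    scale when flagged so by the generator; categorical traits are string
    levels.  Missing cells are NaN; ``mask`` is True where a value is absent.
    ``complete_columns`` flags traits that must never be masked.
    """

    df: pd.DataFrame
    column_types: dict[str, str]
    complete_columns: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        unknown = set(self.df.columns) - set(self.column_types)
        if unknown:
            raise ValueError(f"columns without a declared type: {sorted(unknown)}")
        self.df = self.df.sort_index()

    @property
    def species(self) -> list[str]:
        return list(self.df.index)

    @property
    def mask(self) -> pd.DataFrame:
        return self.df.isna()

    def missing_fraction(self, column: str | None = None) -> float:
        if column is not None:
            return float(self.df[column].isna().mean())
        return float(self.df.isna().to_numpy().mean())

    def continuous_columns(self) -> list[str]:
        return [c for c in self.df.columns if self.column_types[c] == CONTINUOUS]

    def categorical_columns(self) -> list[str]:
        return [c for c in self.df.columns if self.column_types[c] == CATEGORICAL]

    def levels(self, column: str) -> list[str]:
        if self.column_types[column] != CATEGORICAL:
            raise ValueError(f"{column!r} is not categorical")
        return sorted(self.df[column].dropna().astype(str).unique())

    def copy(self) -> "TraitTable":
        return TraitTable(self.df.copy(), dict(self.column_types), set(self.complete_columns))

    def to_csv(self, path) -> None:
        out = self.df.copy()
        out.index.name = "species"
        out.to_csv(path, na_rep="")

    @classmethod
    def from_csv(cls, path, column_types: dict[str, str] | None = None,
                 complete_columns: set[str] | None = None) -> "TraitTable":
        """Read a trait CSV (first column species, blank cells missing).

        Without an explicit ``column_types``, numeric columns are continuous
        and everything else categorical.
        """
        df = pd.read_csv(path, index_col=0)
        df.index = df.index.astype(str)
        if column_types is None:
            column_types = {}
            for c in df.columns:
                coerced = pd.to_numeric(df[c], errors="coerce")
                numeric = coerced.notna() | df[c].isna()
                column_types[c] = CONTINUOUS if numeric.all() else CATEGORICAL
        for c, t in column_types.items():
            if t == CONTINUOUS:
                df[c] = pd.to_numeric(df[c])
            else:
                df[c] = df[c].where(df[c].isna(), df[c].astype(str))
        if complete_columns is None:
            complete_columns = {c for c in df.columns if not df[c].isna().any()}
        return cls(df, column_types, set(complete_columns))

    def assert_species_match(self, tips: list[str]) -> None:
        extra = set(self.species) - set(tips)
        if extra:
            raise ValueError(f"species absent from the tree: {sorted(extra)}")
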