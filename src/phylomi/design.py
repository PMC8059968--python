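"""Model matrices with treatment coding and a minimal formula parser.

Categorical columns are expanded into indicator columns against a baseline
level (alphabetically first unless a reference level is given), labelled
``col[level]``.  Interaction terms ``a:b`` multiply every encoded column of
``a`` with every encoded column of ``b``.  Formulas are of the restricted
form ``response ~ term + term + a:b``; ``1`` denotes the intercept-only
model.  The intercept column is always included and labelled
``(Intercept)``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .tables import CATEGORICAL, TraitTable

__all__ = ["encode_column", "build_design", "parse_formula", "design_from_formula"]


def encode_column(table: TraitTable, df: pd.DataFrame, col: str,
                  reference_levels: dict[str, str] | None = None) -> pd.DataFrame:
    """Encode one column of ``df``: identity for continuous, dummies for
    categorical (baseline dropped). Level set is taken from ``table`` so the
    coding is stable even if a subset of rows lacks some level."""
    reference_levels = reference_levels or {}
    if table.column_types[col] == CATEGORICAL:
        levels = table.levels(col)
        base = reference_levels.get(col, levels[0])
        if base not in levels:
            raise ValueError(f"reference level {base!r} not a level of {col!r}")
        out = {}
        for lv in levels:
            if lv == base:
                continue
            out[f"{col}[{lv}]"] = (df[col].astype(object) == lv).astype(float)
        return pd.DataFrame(out, index=df.index)
    return pd.DataFrame({col: pd.to_numeric(df[col]).astype(float)}, index=df.index)


def build_design(table: TraitTable, terms: list[str],
                 reference_levels: dict[str, str] | None = None,
                 df: pd.DataFrame | None = None,
                 intercept: bool = True) -> pd.DataFrame:
    """Design matrix for ``terms`` over the rows of ``df`` (default: table).

    Terms are column names or ``a:b`` interactions.  Rows with missing
    values in any used column are the caller's responsibility.
    """
    if df is None:
        df = table.df
    parts = []
    if intercept:
        parts.append(pd.DataFrame({"(Intercept)": np.ones(len(df))}, index=df.index))
    for term in terms:
        if term in ("1", ""):
            continue
        if ":" in term:
            a, b = term.split(":", 1)
            ea = encode_column(table, df, a.strip(), reference_levels)
            eb = encode_column(table, df, b.strip(), reference_levels)
            inter = {}
            for ca in ea.columns:
                for cb in eb.columns:
                    inter[f"{ca}:{cb}"] = ea[ca] * eb[cb]
            parts.append(pd.DataFrame(inter, index=df.index))
        else:
            parts.append(encode_column(table, df, term.strip(), reference_levels))
    X = pd.concat(parts, axis=1)
    if X.columns.duplicated().any():
        X = X.loc[:, ~X.columns.duplicated()]
    return X


def parse_formula(formula: str) -> tuple[str, list[str]]:
    """Split ``"y ~ a + b + a:b"`` into (response, [terms])."""
    if "~" not in formula:
        raise ValueError(f"formula {formula!r} has no '~'")
    lhs, rhs = formula.split("~", 1)
    response = lhs.strip()
    terms = [t.strip() for t in rhs.split("+") if t.strip() and t.strip() != "1"]
    return response, terms


def design_from_formula(table: TraitTable, formula: str,
                        reference_levels: dict[str, str] | None = None,
                        df: pd.DataFrame | None = None):
    """(y, X) pair for a formula; rows with any NA in used columns dropped."""
    response, terms = parse_formula(formula)
    if df is None:
        df = table.df
    used = {response}
    for t in terms:
        used.update(p.strip() for p in t.split(":"))
    keep = df[sorted(used)].notna().all(axis=1)
    sub = df.loc[keep]
    y = pd.to_numeric(sub[response]).astype(float)
    X = build_design(table, terms, reference_levels, df=sub)
    return y, X
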