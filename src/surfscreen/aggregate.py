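"""Cross-disease aggregation of ranked surface-target tables.

Counts how many disease top-k lists share each gene (the cross-disease
frequency view that surfaces broadly expressed candidates such as MCAM or
GPC2), summarizes each list's T distribution for box-whisker display, and
optionally groups genes into user-supplied functional categories.

Gene identity across tables requires symbol normalization: published lists
mix forms such as "CD146/MCAM" and "LPPR3/PRG2".  An alias table maps such
forms to a canonical symbol; an unmapped slash-compound falls back to the
segment after the final "/", upper-cased.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .screen import TargetTable


def load_alias_map(path: str | Path) -> dict[str, str]:
    """Read an ``alias<TAB>canonical`` two-column TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = list(df.columns)
    if len(cols) < 2:
        raise ValueError("alias map needs two columns (alias, canonical)")
    return dict(zip(df[cols[0]], df[cols[1]]))


def load_category_map(path: str | Path) -> dict[str, str]:
    """Read a ``gene_symbol<TAB>category`` two-column TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = list(df.columns)
    if len(cols) < 2:
        raise ValueError("category map needs two columns (symbol, category)")
    return dict(zip(df[cols[0]], df[cols[1]]))


def normalize_symbol(raw: str, alias_map: Mapping[str, str] | None = None) -> str:
    """Resolve a raw symbol form to its canonical gene symbol.

    Lookup order: the raw form, then its upper-case; for an unmapped
    slash-compound, the segment after the final "/" (again looked up, then
    upper-cased); otherwise the upper-cased input unchanged.
    """
    if not raw or not raw.strip():
        raise ValueError("empty gene symbol")
    raw = raw.strip()
    alias_map = alias_map or {}
    for key in (raw, raw.upper()):
        if key in alias_map:
            return alias_map[key]
    if "/" in raw:
        tail = raw.rsplit("/", 1)[-1].strip()
        if not tail:
            raise ValueError(f"malformed slash-compound symbol {raw!r}")
        for key in (tail, tail.upper()):
            if key in alias_map:
                return alias_map[key]
        return tail.upper()
    return raw.upper()


def cross_disease_frequency(
    tables: Sequence[TargetTable],
    alias_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per canonical symbol, the set of diseases whose top-k table lists it.

    Each disease contributes at most once per symbol regardless of how many
    probes map to it; the result is sorted by count descending then symbol
    ascending.  Columns: gene_symbol, count, diseases (";"-joined).
    """
    seen_diseases: set[str] = set()
    membership: dict[str, set[str]] = {}
    for tt in tables:
        if tt.disease in seen_diseases:
            raise ValueError(f"disease {tt.disease!r} appears more than once")
        seen_diseases.add(tt.disease)
        for raw in tt.table["gene_symbol"]:
            symbol = normalize_symbol(raw, alias_map)
            membership.setdefault(symbol, set()).add(tt.disease)
    records = [
        {
            "gene_symbol": symbol,
            "count": len(diseases),
            "diseases": ";".join(sorted(diseases)),
        }
        for symbol, diseases in membership.items()
    ]
    out = pd.DataFrame(records, columns=["gene_symbol", "count", "diseases"])
    if len(out):
        out = out.sort_values(
            ["count", "gene_symbol"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)
    return out


@dataclass
class TSummary:
    """Five-number summary plus mean of a top-k list's T values."""

    disease: str
    min: float
    q1: float
    median: float
    q3: float
    max: float
    mean: float

    def present(self) -> dict[str, float]:
        """Values rounded for display: round-half-even to one decimal."""
        return {
            name: round_half_even(getattr(self, name), 1)
            for name in ("min", "q1", "median", "q3", "max", "mean")
        }


def round_half_even(value: float, decimals: int = 1) -> float:
    """Decimal round-half-even (banker's rounding) for presentation."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(str(value)).quantize(q, rounding=ROUND_HALF_EVEN))


def summarize_top_T(table: TargetTable) -> TSummary:
    """Box-whisker summary of a ranked table's T values.

    Quartiles use the linear-interpolation (type-7) convention; min, max and
    mean are convention-free.  Rounding happens only at presentation time.
    """
    t = table.table["T"].to_numpy(dtype=float)
    if t.size == 0:
        raise ValueError(f"{table.disease}: empty target table")
    q1, med, q3 = np.percentile(t, [25, 50, 75])
    return TSummary(
        disease=table.disease,
        min=float(t.min()),
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        max=float(t.max()),
        mean=float(t.mean()),
    )


def group_by_category(
    frequency: pd.DataFrame,
    category_map: Mapping[str, str] | None = None,
) -> dict[str, list[str]]:
    """Group frequency-record symbols into functional categories.

    The map may be partial; unmapped symbols land in "Uncharacterized".
    Each symbol appears in exactly one bucket.
    """
    category_map = category_map or {}
    buckets: dict[str, list[str]] = {}
    for symbol in frequency["gene_symbol"]:
        category = category_map.get(symbol, "Uncharacterized")
        buckets.setdefault(category, []).append(symbol)
    return buckets
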