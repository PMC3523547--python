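"""Per-probe differential expression screening against the normal panel.

For each tumor cohort, every probe is scored with a pooled-variance
(Student) two-sample t-statistic comparing the cohort's arrays (group 1,
size n1) with the pooled normal-tissue panel (group 2, size n2, 15 arrays by
default):

    T  = (mean(x) - mean(y)) / (s_p * sqrt(1/n1 + 1/n2))
    s_p^2 = ((n1-1) s1^2 + (n2-1) s2^2) / (n1 + n2 - 2)
    df = n1 + n2 - 2

with unbiased (n-1 denominator) sample variances.  T is positive when the
tumor mean exceeds the normal mean.  The two-sided p-value is the Student-t
tail probability, evaluated through the regularized incomplete beta function
so that values far below the double-precision 1-CDF cancellation floor
(~1e-16) remain exact.

Probes are ranked by descending T (ties broken by probe ID, ascending) so
the most tumor-over-expressed transcripts lead the table.  Hit counting uses
a strict one-sided threshold (T > tau, over-expression only); no
multiple-testing correction is applied — reported p-values are raw.
Zero-pooled-variance probes are excluded with a logged warning rather than
reported as infinite.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special

from .io import ExpressionMatrix, Role, SampleMetadata

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 10.0
DEFAULT_TOP_K = 25

#: Columns of a per-disease screen statistics frame, in output order.
STAT_COLUMNS = (
    "probe_id",
    "gene_symbol",
    "disease",
    "T",
    "df",
    "p",
    "tumor_mean",
    "normal_mean",
)


@dataclass
class TargetTable:
    """Ranked surface-target list for one disease.

    ``table`` has columns rank, probe_id, gene_symbol, T, p (ranks
    consecutive from 1, T non-increasing).
    """

    disease: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        n = len(self.table)
        if n:
            ranks = self.table["rank"].to_numpy()
            if not np.array_equal(ranks, np.arange(1, n + 1)):
                raise ValueError(f"{self.disease}: ranks not consecutive from 1")
            t = self.table["T"].to_numpy(dtype=float)
            if np.any(np.diff(t) > 1e-12):
                raise ValueError(f"{self.disease}: T increases down the table")

    def __len__(self) -> int:
        return len(self.table)


def pooled_t_statistic(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, int]:
    """Pooled two-sample t-statistic and its degrees of freedom.

    Raises ``ValueError`` when either group has fewer than two values or the
    pooled variance is zero (T undefined; callers exclude such probes).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValueError(f"both groups need >=2 values, got {n1} and {n2}")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / df
    if sp2 <= 0.0:
        raise ValueError("pooled variance is zero; t-statistic undefined")
    t = (x.mean() - y.mean()) / math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    return float(t), int(df)


def t_tail_probability(t: float, df: int) -> float:
    """Two-sided Student-t tail probability, 2*(1 - F(|T|; df)).

    Uses the incomplete-beta path (``scipy.special.stdtr``), which stays
    accurate for p-values down to the underflow limit instead of losing all
    precision to 1-CDF cancellation.
    """
    if df < 1:
        raise ValueError(f"degrees of freedom must be >= 1, got {df}")
    return float(2.0 * special.stdtr(df, -abs(t)))


def _pooled_t_matrix(
    x: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, int, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized pooled t over all probes at once.

    ``x`` is probes x n1 (tumor), ``y`` probes x n2 (normal).  Returns
    (T, df, tumor_mean, normal_mean, valid) where ``valid`` flags positive
    pooled variance; T is NaN where invalid.
    """
    n1, n2 = x.shape[1], y.shape[1]
    df = n1 + n2 - 2
    mx, my = x.mean(axis=1), y.mean(axis=1)
    vx, vy = x.var(axis=1, ddof=1), y.var(axis=1, ddof=1)
    sp2 = ((n1 - 1) * vx + (n2 - 1) * vy) / df
    valid = sp2 > 0.0
    se = np.sqrt(np.where(valid, sp2, np.nan) * (1.0 / n1 + 1.0 / n2))
    t = (mx - my) / se
    return t, df, mx, my, valid


def screen_disease(
    matrix: ExpressionMatrix,
    meta: SampleMetadata,
    disease: str,
    probe_to_gene: Mapping[str, str] | None = None,
    normal_mode: str = "pooled_samples",
) -> pd.DataFrame:
    """Screen one tumor cohort against the normal panel.

    Returns one row per probe with positive pooled variance, sorted by T
    descending (ties by probe_id ascending), with columns
    ``STAT_COLUMNS``.  ``normal_mode`` selects the comparator group:
    ``pooled_samples`` (default) uses every normal array as one observation;
    ``per_tissue_means`` first collapses each normal tissue to its mean — a
    sensitivity-analysis mode, equivalent when the panel has one array per
    tissue.
    """
    cohorts = meta.tumor_cohorts()
    if disease not in cohorts:
        raise ValueError(
            f"unknown disease {disease!r}; available cohorts: {cohorts}"
        )
    tumor_samples = meta.cohort_samples(disease)
    normal_samples = meta.samples_with_role(Role.NORMAL)
    x = matrix.data.loc[:, tumor_samples].to_numpy()
    if normal_mode == "pooled_samples":
        y = matrix.data.loc[:, normal_samples].to_numpy()
    elif normal_mode == "per_tissue_means":
        normal_meta = meta.table.loc[normal_samples]
        groups = [
            matrix.data.loc[:, list(ids)].to_numpy().mean(axis=1)
            for _, ids in normal_meta.groupby("cohort", sort=False).groups.items()
        ]
        y = np.column_stack(groups)
    else:
        raise ValueError(
            f"normal_mode must be 'pooled_samples' or 'per_tissue_means', "
            f"got {normal_mode!r}"
        )
    t, df, mx, my, valid = _pooled_t_matrix(x, y)
    n_dropped = int((~valid).sum())
    if n_dropped:
        logger.warning(
            "%s: %d probe(s) with zero pooled variance excluded from screen",
            disease,
            n_dropped,
        )
    probes = np.asarray(matrix.probe_ids)
    out = pd.DataFrame(
        {
            "probe_id": probes[valid],
            "gene_symbol": (
                [probe_to_gene.get(p, "") for p in probes[valid]]
                if probe_to_gene
                else ""
            ),
            "disease": disease,
            "T": t[valid],
            "df": df,
            "p": 2.0 * special.stdtr(df, -np.abs(t[valid])),
            "tumor_mean": mx[valid],
            "normal_mean": my[valid],
        },
        columns=list(STAT_COLUMNS),
    )
    out = out.sort_values(
        ["T", "probe_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return out


def count_hits(stats: pd.DataFrame, tau: float = DEFAULT_THRESHOLD) -> int:
    """Number of probes with T strictly above the hit threshold."""
    if len(stats) == 0:
        return 0
    return int((stats["T"] > tau).sum())


def top_k_surface_targets(
    stats: pd.DataFrame,
    surface_probes: Sequence[str],
    k: int = DEFAULT_TOP_K,
) -> TargetTable:
    """First ``k`` ranked statistics whose probe passed the surface filter.

    Fewer than ``k`` rows are returned when the surface pool is smaller.
    ``stats`` must be ranked as produced by :func:`screen_disease`.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    surface = set(surface_probes)
    hits = stats.loc[stats["probe_id"].isin(surface)].head(k).reset_index(drop=True)
    disease = hits["disease"].iloc[0] if len(hits) else (
        stats["disease"].iloc[0] if len(stats) else ""
    )
    table = hits[["probe_id", "gene_symbol", "T", "p"]].copy()
    table.insert(0, "rank", np.arange(1, len(table) + 1))
    return TargetTable(disease=disease, table=table)
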