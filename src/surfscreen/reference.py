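"""Packaged reference top-25 surface-target tables for 12 pediatric cancers.

A curated transcription of published per-disease ranked lists (rank, probe
ID, gene symbol, T, p) for twelve pediatric tumor cohorts screened against a
15-tissue normal panel, together with the cohort sample sizes and
above-threshold hit counts.  It ships inside the package with a SHA-256
checksum so that aggregation and consistency checks run offline and detect a
corrupted transcription.

Known transcription notes (carried as metadata flags):

``ASPS``
    The printed ASPS p-values are inconsistent with a pooled two-sample t at
    df = n1 + 15 - 2 = 20 (they imply df around 27-28); the source gives no
    explanation.  ASPS rows are excluded from p-consistency checks.
``OS``
    Row 11 (LRRC8E) prints p = 7.90E-01, an evident misprint for ~7.9E-10;
    transcribed as printed.
``STS``
    The printed rank column contains a duplicate "21" at list position 12;
    ranks are stored as consecutive positions 1-25.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .screen import TargetTable

#: Diseases screened, in published hit-count order.
REFERENCE_DISEASES: tuple[str, ...] = (
    "Pre-B_ALL",
    "ARMS",
    "ASPS",
    "GBM",
    "NBL-MYCNA",
    "STS",
    "OS",
    "HBL",
    "EWS",
    "ERMS",
    "NBL",
    "DSRCT",
)

#: Per-disease metadata flags for known transcription anomalies.
ANOMALY_NOTES: dict[str, str] = {
    "ASPS": (
        "printed p-values inconsistent with pooled-t df=20 (imply df~27-28); "
        "excluded from p-consistency checks"
    ),
    "OS": "row 11 (LRRC8E) p=7.90E-01 is an evident misprint for ~7.9E-10",
    "STS": "printed rank column duplicates '21' at position 12; stored ranks are positional",
}

_DATA_PACKAGE = "surfscreen.data"
_TARGETS_FILE = "reference_targets.tsv"
_CHECKSUM_FILE = "reference_targets.sha256"
_COHORTS_FILE = "reference_cohorts.tsv"
_ALIASES_FILE = "aliases.tsv"


@dataclass
class ReferenceTables:
    """The packaged reference screen results.

    ``tables`` maps disease -> :class:`~surfscreen.screen.TargetTable` (25
    rows each); ``cohort_sizes`` maps disease -> n1 (tumor group size);
    ``hit_counts`` maps disease -> published number of probes with T > 10;
    ``notes`` carries the anomaly flags.
    """

    tables: dict[str, TargetTable]
    cohort_sizes: dict[str, int]
    hit_counts: dict[str, int]
    notes: dict[str, str] = field(default_factory=dict)

    def degrees_of_freedom(self, disease: str, n_normal: int = 15) -> int:
        """Pooled-t df for a disease screen: n1 + n_normal - 2."""
        return self.cohort_sizes[disease] + n_normal - 2


def _read_packaged(name: str) -> bytes:
    return (resources.files(_DATA_PACKAGE) / name).read_bytes()


def load_reference_tables() -> ReferenceTables:
    """Load and checksum-verify the packaged reference tables."""
    raw = _read_packaged(_TARGETS_FILE)
    expected = _read_packaged(_CHECKSUM_FILE).decode().strip()
    actual = hashlib.sha256(raw).hexdigest()
    if actual != expected:
        raise ValueError(
            f"reference table checksum mismatch: expected {expected}, got {actual}"
        )
    import io as _io

    df = pd.read_csv(
        _io.BytesIO(raw),
        sep="\t",
        dtype={"disease": str, "rank": int, "probe_id": str, "gene_symbol": str},
    )
    df["T"] = df["t_value"].astype(float)
    df["p"] = df["p_value"].astype(float)
    tables: dict[str, TargetTable] = {}
    for disease in REFERENCE_DISEASES:
        sub = df.loc[df["disease"] == disease].reset_index(drop=True)
        if len(sub) != 25:
            raise ValueError(
                f"reference table for {disease} has {len(sub)} rows, expected 25"
            )
        tables[disease] = TargetTable(
            disease=disease,
            table=sub[["rank", "probe_id", "gene_symbol", "T", "p"]].copy(),
        )
    cohorts = pd.read_csv(
        _io.BytesIO(_read_packaged(_COHORTS_FILE)), sep="\t", dtype={"disease": str}
    )
    cohort_sizes = dict(zip(cohorts["disease"], cohorts["n_samples"].astype(int)))
    hit_counts = dict(zip(cohorts["disease"], cohorts["hits_above_10"].astype(int)))
    return ReferenceTables(
        tables=tables,
        cohort_sizes=cohort_sizes,
        hit_counts=hit_counts,
        notes=dict(ANOMALY_NOTES),
    )


def load_packaged_aliases() -> dict[str, str]:
    """The packaged gene-symbol alias table covering the reference lists'
    compound and legacy symbol forms."""
    import io as _io

    df = pd.read_csv(
        _io.BytesIO(_read_packaged(_ALIASES_FILE)),
        sep="\t",
        dtype=str,
        keep_default_na=False,
    )
    return dict(zip(df["alias"], df["canonical"]))
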