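"""Expression matrix and sample metadata I/O.

Expression values are treated as already-normalized summary intensities on
whatever scale the source database serves; no chip-level preprocessing is
performed.  An optional log2 transform is provided but is off by default,
because the screening t-statistic is computed on the stored scale.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: The 15-tissue normal comparator panel used as group 2 in every screen.
NORMAL_TISSUES: tuple[str, ...] = (
    "lung",
    "liver",
    "kidney",
    "heart",
    "adrenal",
    "cerebrum",
    "cerebellum",
    "uterus",
    "testes",
    "stomach",
    "spleen",
    "bladder",
    "skeletal muscle",
    "prostate",
    "ovary",
)

#: Tumor cohorts with fewer samples than this are excluded from screening
#: ("more than five samples" inclusion rule).
DEFAULT_MIN_GROUP_SIZE = 6


class Role(str, enum.Enum):
    """Whether a sample belongs to a tumor cohort or the normal panel."""

    TUMOR = "tumor"
    NORMAL = "normal"


class ExpressionMatrix:
    """Probe x sample grid of continuous expression intensities.

    Thin wrapper around a float64 :class:`pandas.DataFrame` (probes as rows,
    samples as columns) that enforces the container invariants: unique probe
    and sample identifiers, every cell finite, at least one probe and two
    samples.
    """

    def __init__(self, data: pd.DataFrame):
        if data.index.has_duplicates:
            dup = data.index[data.index.duplicated()][0]
            raise ValueError(f"duplicate probe ID: {dup!r}")
        if data.columns.has_duplicates:
            dup = data.columns[data.columns.duplicated()][0]
            raise ValueError(f"duplicate sample ID: {dup!r}")
        if data.shape[0] < 1 or data.shape[1] < 2:
            raise ValueError(
                f"matrix must have >=1 probe and >=2 samples, got {data.shape}"
            )
        values = data.to_numpy(dtype=np.float64, copy=False)
        if not np.isfinite(values).all():
            r, c = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite value at probe {data.index[r]!r}, "
                f"sample {data.columns[c]!r}"
            )
        self.data = data.astype(np.float64, copy=False)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        """Column subset preserving per-probe values bit-for-bit."""
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)])

    def write(self, path: str | Path, index_label: str = "probe_id") -> None:
        """Serialize to TSV at full precision (shortest round-tripping repr)."""
        self.data.to_csv(path, sep="\t", index_label=index_label)

    def __eq__(self, other) -> bool:  # pragma: no cover - convenience
        return isinstance(other, ExpressionMatrix) and self.data.equals(other.data)


@dataclass
class SampleMetadata:
    """Per-sample cohort assignment and tumor/normal role.

    ``table`` is indexed by sample_id with columns ``cohort`` and ``role``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            dup = self.table.index[self.table.index.duplicated()][0]
            raise ValueError(f"duplicate sample ID: {dup!r}")
        if (self.table["cohort"].astype(str).str.len() == 0).any():
            bad = self.table.index[self.table["cohort"].astype(str).str.len() == 0][0]
            raise ValueError(f"empty cohort for sample {bad!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def samples_with_role(self, role: Role) -> list[str]:
        return list(self.table.index[self.table["role"] == role])

    def tumor_cohorts(self) -> list[str]:
        """Tumor cohort names in first-appearance order."""
        mask = self.table["role"] == Role.TUMOR
        return list(dict.fromkeys(self.table.loc[mask, "cohort"]))

    def cohort_samples(self, cohort: str) -> list[str]:
        return list(self.table.index[self.table["cohort"] == cohort])

    def write(self, path: str | Path) -> None:
        out = self.table[["cohort"]]
        out.to_csv(path, sep="\t", index_label="sample_id")


@dataclass
class ValidationReport:
    """Outcome of dataset validation: who is screenable and who is not."""

    screenable_cohorts: list[str]
    excluded_cohorts: dict[str, int] = field(default_factory=dict)
    n_normal: int = 0
    n_probes: int = 0

    def __str__(self) -> str:
        lines = [
            f"probes: {self.n_probes}",
            f"normal panel size: {self.n_normal}",
            f"screenable tumor cohorts ({len(self.screenable_cohorts)}): "
            + ", ".join(self.screenable_cohorts),
        ]
        if self.excluded_cohorts:
            lines.append(
                "excluded (below minimum group size): "
                + ", ".join(f"{c} (n={n})" for c, n in self.excluded_cohorts.items())
            )
        return "\n".join(lines)


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a probe x sample TSV.

    First header cell is ignored; remaining header cells are sample IDs; each
    subsequent row is a probe ID followed by one numeric value per sample.
    Duplicate IDs and non-numeric or missing cells are hard errors naming the
    offending coordinates.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    samples = header[1:]
    seen: set[str] = set()
    for s in samples:
        if s in seen:
            raise ValueError(f"duplicate sample ID in header: {s!r}")
        seen.add(s)
    raw = pd.read_csv(
        path,
        sep="\t",
        index_col=0,
        header=0,
        names=["probe_id", *samples],
        float_precision="round_trip",
    )
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()][0]
        raise ValueError(f"duplicate probe ID: {dup!r}")
    for col in raw.columns:
        coerced = pd.to_numeric(raw[col], errors="coerce")
        bad = coerced.isna()
        if bad.any():
            probe = raw.index[bad][0]
            cell = raw.loc[probe, col]
            what = "missing" if pd.isna(cell) else f"non-numeric ({cell!r})"
            raise ValueError(f"{what} value at probe {probe!r}, sample {col!r}")
        raw[col] = coerced
    return ExpressionMatrix(raw)


def read_sample_metadata(
    path: str | Path, normal_panel: Iterable[str]
) -> SampleMetadata:
    """Read a ``sample_id<TAB>cohort`` TSV and assign tumor/normal roles.

    A sample's role is NORMAL iff its cohort is in ``normal_panel``.
    """
    normal = set(normal_panel)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"sample_id", "cohort"}
    if not required.issubset(df.columns):
        raise ValueError(f"metadata must have columns {sorted(required)}")
    df = df.set_index("sample_id")
    df["role"] = [
        Role.NORMAL if c in normal else Role.TUMOR for c in df["cohort"]
    ]
    return SampleMetadata(df)


def build_sample_metadata(
    sample_ids: Sequence[str], cohorts: Sequence[str], normal_panel: Iterable[str]
) -> SampleMetadata:
    """Construct metadata in memory (same role rule as the TSV reader)."""
    normal = set(normal_panel)
    df = pd.DataFrame(
        {
            "cohort": list(cohorts),
            "role": [Role.NORMAL if c in normal else Role.TUMOR for c in cohorts],
        },
        index=pd.Index(list(sample_ids), name="sample_id"),
    )
    return SampleMetadata(df)


def validate_dataset(
    matrix: ExpressionMatrix,
    meta: SampleMetadata,
    min_group_size: int = DEFAULT_MIN_GROUP_SIZE,
) -> ValidationReport:
    """Check matrix/metadata consistency and apply the cohort-size rule.

    Side-effect free and idempotent.  Tumor cohorts with fewer than
    ``min_group_size`` samples are listed as excluded from screening; a
    mismatch between metadata samples and matrix columns, or a normal panel
    with fewer than two arrays (pooled variance undefined), is a hard error.
    """
    matrix_samples = set(matrix.sample_ids)
    meta_samples = set(meta.sample_ids)
    if matrix_samples != meta_samples:
        only_matrix = sorted(matrix_samples - meta_samples)[:5]
        only_meta = sorted(meta_samples - matrix_samples)[:5]
        raise ValueError(
            "sample sets differ between matrix and metadata; "
            f"matrix-only: {only_matrix}, metadata-only: {only_meta}"
        )
    normals = meta.samples_with_role(Role.NORMAL)
    if len(normals) < 2:
        raise ValueError(
            f"normal panel has {len(normals)} samples; >=2 required "
            "(pooled variance undefined otherwise)"
        )
    screenable: list[str] = []
    excluded: dict[str, int] = {}
    for cohort in meta.tumor_cohorts():
        n = len(meta.cohort_samples(cohort))
        if n >= min_group_size:
            screenable.append(cohort)
        else:
            excluded[cohort] = n
    return ValidationReport(
        screenable_cohorts=screenable,
        excluded_cohorts=excluded,
        n_normal=len(normals),
        n_probes=matrix.shape[0],
    )


def log2_transform(matrix: ExpressionMatrix, offset: float = 1.0) -> ExpressionMatrix:
    """Return a new matrix with each value v replaced by log2(v + offset).

    Off by default in the pipeline; values must be non-negative.
    """
    values = matrix.data.to_numpy()
    if (values < 0).any():
        r, c = np.argwhere(values < 0)[0]
        raise ValueError(
            f"negative value at probe {matrix.probe_ids[r]!r}, "
            f"sample {matrix.sample_ids[c]!r}; log2 transform requires values >= 0"
        )
    return ExpressionMatrix(
        pd.DataFrame(
            np.log2(values + offset), index=matrix.data.index, columns=matrix.data.columns
        )
    )
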