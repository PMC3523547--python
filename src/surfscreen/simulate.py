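"""Seeded synthetic microarray datasets with planted surface targets.

The generator emulates the statistical structure the screen assumes: a
probe x sample intensity matrix over 12 tumor cohorts (default sizes match
the study design: 6-24 arrays each) and a 15-tissue normal panel with one
array per tissue.  Per probe g, a baseline b_g ~ Normal(mu_b, sigma_b^2) is
shared by every sample; each cell adds Normal(0, sigma^2) noise; probes
planted for a cohort add an over-expression shift delta (in noise-SD units
when sigma = 1) to that cohort's tumor samples only:

    value(g, s) = b_g + delta * [g planted for cohort(s), s tumor] + eps

Because the downstream consumer is a two-sample t-statistic, which sees only
group means and variances, this additive Gaussian model on the stored scale
is the simplest structure that exercises every pipeline contract.  A
fraction of probes is annotated with cell-surface compartment terms and
planted probes are drawn only from that surface-labeled pool, so
ground-truth recovery can be measured through the full filter + rank path.

All draws come from one ``numpy`` Generator seeded with ``config.seed``:
identical configs give bit-identical datasets.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import load_annotation_table
from .io import (
    NORMAL_TISSUES,
    ExpressionMatrix,
    SampleMetadata,
    build_sample_metadata,
    read_expression_matrix,
    read_sample_metadata,
)

#: Default tumor cohort sizes (study design: 12 cohorts, 6-24 arrays each).
DEFAULT_COHORT_SIZES: dict[str, int] = {
    "Pre-B_ALL": 9,
    "ARMS": 12,
    "ASPS": 7,
    "GBM": 7,
    "NBL-MYCNA": 24,
    "STS": 6,
    "OS": 17,
    "HBL": 7,
    "EWS": 19,
    "ERMS": 9,
    "NBL": 15,
    "DSRCT": 8,
}

_SURFACE_TERMS = ("plasma membrane", "cell surface")
_INTERNAL_TERMS = (
    "mitochondrial membrane",
    "golgi apparatus",
    "endoplasmic reticulum",
    "nuclear membrane",
)
_OTHER_TERMS = ("cytoplasm", "nucleus", "membrane")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic dataset.

    delta is the planted over-expression shift in intensity units (equal to
    noise-SD units at the default sigma = 1); mu_b / sigma_b set the probe
    baseline distribution on a log2-like intensity scale.
    """

    n_probes: int = 10_000
    cohort_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_COHORT_SIZES)
    )
    n_normal: int = 15
    surface_fraction: float = 0.15
    planted_per_disease: int = 25
    delta: float = 3.0
    sigma: float = 1.0
    mu_b: float = 8.0
    sigma_b: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_probes < 1:
            raise ValueError("n_probes must be >= 1")
        if not self.cohort_sizes:
            raise ValueError("cohort_sizes must be non-empty")
        for cohort, n in self.cohort_sizes.items():
            if n < 2:
                raise ValueError(f"cohort {cohort!r} size {n} < 2")
        if self.n_normal < 2:
            raise ValueError("n_normal must be >= 2")
        if not 0.0 <= self.surface_fraction <= 1.0:
            raise ValueError("surface_fraction must be in [0, 1]")
        n_surface = math.ceil(self.surface_fraction * self.n_probes)
        if self.planted_per_disease > n_surface:
            raise ValueError(
                f"planted_per_disease ({self.planted_per_disease}) exceeds the "
                f"surface pool ({n_surface})"
            )
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.sigma_b < 0:
            raise ValueError("sigma_b must be >= 0")


@dataclass
class GroundTruth:
    """What was planted: per disease, probe -> shift; plus surface labels."""

    planted: dict[str, dict[str, float]]
    surface_labels: dict[str, bool]

    def planted_probes(self, disease: str) -> set[str]:
        return set(self.planted.get(disease, {}))


@dataclass
class SyntheticDataset:
    matrix: ExpressionMatrix
    metadata: SampleMetadata
    evidence: pd.DataFrame
    probe_to_gene: dict[str, str]
    truth: GroundTruth
    config: SimulationConfig


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate a seeded dataset per the additive Gaussian model above.

    Draw order is fixed (baselines, noise, surface-label choice, per-disease
    planting, evidence term assignment), so identical configs are
    bit-identical and any config change before a draw leaves earlier draws
    untouched.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    probes = [f"SYN{i:06d}_at" for i in range(1, config.n_probes + 1)]
    genes = {p: f"GENE{i:06d}" for i, p in enumerate(probes, start=1)}

    tumor_ids: list[str] = []
    tumor_cohorts: list[str] = []
    for cohort, n in config.cohort_sizes.items():
        for j in range(1, n + 1):
            tumor_ids.append(f"{cohort}_{j:02d}")
            tumor_cohorts.append(cohort)
    tissues = [NORMAL_TISSUES[i % len(NORMAL_TISSUES)] for i in range(config.n_normal)]
    normal_ids = []
    counts: dict[str, int] = {}
    for tissue in tissues:
        counts[tissue] = counts.get(tissue, 0) + 1
        suffix = "" if counts[tissue] == 1 else f"_{counts[tissue]}"
        normal_ids.append("normal_" + tissue.replace(" ", "_") + suffix)
    sample_ids = tumor_ids + normal_ids
    cohorts = tumor_cohorts + tissues
    meta = build_sample_metadata(sample_ids, cohorts, normal_panel=set(tissues))

    baseline = rng.normal(config.mu_b, config.sigma_b, size=config.n_probes)
    noise = rng.normal(0.0, config.sigma, size=(config.n_probes, len(sample_ids)))
    values = baseline[:, None] + noise

    n_surface = math.ceil(config.surface_fraction * config.n_probes)
    surface_idx = rng.choice(config.n_probes, size=n_surface, replace=False)
    surface_set = {probes[i] for i in surface_idx}

    probe_pos = {p: i for i, p in enumerate(probes)}
    col_pos = {s: j for j, s in enumerate(sample_ids)}
    planted: dict[str, dict[str, float]] = {}
    for cohort in config.cohort_sizes:
        chosen = rng.choice(surface_idx, size=config.planted_per_disease, replace=False)
        planted[cohort] = {probes[i]: config.delta for i in chosen}
        cols = [col_pos[s] for s in meta.cohort_samples(cohort)]
        rows = [probe_pos[probes[i]] for i in chosen]
        values[np.ix_(rows, cols)] += config.delta

    evidence_rows: list[tuple[str, str, str]] = []
    # surface probes: a surface term; every 7th also carries an internal term
    # (surface + another compartment must still pass the filter)
    for k, i in enumerate(sorted(surface_idx)):
        p = probes[i]
        evidence_rows.append((p, _SURFACE_TERMS[k % len(_SURFACE_TERMS)], "GO"))
        if k % 7 == 0:
            evidence_rows.append((p, _INTERNAL_TERMS[k % len(_INTERNAL_TERMS)], "GO"))
    non_surface = [p for p in probes if p not in surface_set]
    term_choice = rng.integers(0, len(_INTERNAL_TERMS) + len(_OTHER_TERMS), size=len(non_surface))
    all_other = _INTERNAL_TERMS + _OTHER_TERMS
    for p, c in zip(non_surface, term_choice):
        evidence_rows.append((p, all_other[c], "CHIP_ANNOTATION"))
    evidence = pd.DataFrame(
        evidence_rows, columns=["subject", "compartment_term", "source"]
    )

    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=pd.Index(probes, name="probe_id"), columns=sample_ids)
    )
    truth = GroundTruth(
        planted=planted, surface_labels={p: p in surface_set for p in probes}
    )
    return SyntheticDataset(matrix, meta, evidence, genes, truth, config)


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Emit the TSV formats the readers consume, plus the ground truth.

    Returns the paths written.  Matrix values serialize at full precision so
    a write-then-read round trip is cell-for-cell identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": outdir / "matrix.tsv",
        "metadata": outdir / "metadata.tsv",
        "annotation": outdir / "annotation.tsv",
        "probe_to_gene": outdir / "probe_to_gene.tsv",
        "ground_truth": outdir / "ground_truth.json",
    }
    dataset.matrix.write(paths["matrix"])
    dataset.metadata.write(paths["metadata"])
    dataset.evidence.to_csv(paths["annotation"], sep="\t", index=False)
    pd.DataFrame(
        {
            "probe_id": list(dataset.probe_to_gene),
            "gene_symbol": list(dataset.probe_to_gene.values()),
        }
    ).to_csv(paths["probe_to_gene"], sep="\t", index=False)
    with open(paths["ground_truth"], "w", encoding="utf-8") as fh:
        json.dump(
            {
                "planted": dataset.truth.planted,
                "surface_labels": dataset.truth.surface_labels,
            },
            fh,
        )
    return paths


def read_dataset(
    outdir: str | Path,
) -> tuple[ExpressionMatrix, SampleMetadata, pd.DataFrame]:
    """Read back a written dataset's matrix, metadata and annotation."""
    outdir = Path(outdir)
    matrix = read_expression_matrix(outdir / "matrix.tsv")
    meta = read_sample_metadata(outdir / "metadata.tsv", normal_panel=set(NORMAL_TISSUES))
    evidence = load_annotation_table([outdir / "annotation.tsv"])
    return matrix, meta, evidence
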