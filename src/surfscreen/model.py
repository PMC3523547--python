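"""Model/results interface to the surface-target screen.

:class:`SurfaceTargetScreen` bundles the inputs (expression matrix, sample
metadata, localization evidence, probe-to-gene map) and screen settings;
``fit()`` runs validation, localization classification, the per-disease
pooled-t screen, surface filtering, top-k selection and cross-disease
aggregation, and returns a :class:`ScreenResults` carrying every table the
analysis produces plus diagnostics (excluded cohorts, zero-variance and
unannotated probe counts).
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from ._format import format_scientific
from .aggregate import TSummary, cross_disease_frequency, summarize_top_T
from .annotation import (
    Call,
    TermConfig,
    DEFAULT_TERM_CONFIG,
    classify_all,
    load_annotation_table,
    load_overrides,
    load_probe_to_gene,
    surface_probe_set,
)
from .io import (
    DEFAULT_MIN_GROUP_SIZE,
    NORMAL_TISSUES,
    ExpressionMatrix,
    SampleMetadata,
    ValidationReport,
    log2_transform,
    read_expression_matrix,
    read_sample_metadata,
    validate_dataset,
)
from .aggregate import load_alias_map
from .screen import (
    DEFAULT_THRESHOLD,
    DEFAULT_TOP_K,
    TargetTable,
    count_hits,
    screen_disease,
    top_k_surface_targets,
)


class SurfaceTargetScreen:
    """Differential cell-surface target screen over tumor cohorts.

    Parameters
    ----------
    matrix, metadata
        Expression intensities and per-sample cohort/role assignments.
    evidence
        Merged localization evidence (subject, compartment_term, source).
        When ``None``, no surface filter can be applied and top-k tables are
        empty.
    probe_to_gene
        Optional probe -> gene symbol map used for gene-level annotation
        lookup and report columns.
    threshold, top_k, min_group_size
        Screen settings: hit threshold on T (strict, one-sided), list
        length, and minimum tumor-cohort size.
    include_unknown_membrane
        Admit bare-"membrane" annotations into the surface set (the
        manual-review pool); off by default.
    log2
        Apply log2(v + 1) before screening; off by default because the
        screen operates on whatever scale the stored intensities use.
    normal_mode
        ``pooled_samples`` (default) treats every normal array as one
        observation; ``per_tissue_means`` collapses each tissue to its mean
        first (sensitivity mode).
    """

    def __init__(
        self,
        matrix: ExpressionMatrix,
        metadata: SampleMetadata,
        evidence: pd.DataFrame | None = None,
        probe_to_gene: Mapping[str, str] | None = None,
        *,
        overrides: Mapping[str, Call] | None = None,
        term_config: TermConfig = DEFAULT_TERM_CONFIG,
        alias_map: Mapping[str, str] | None = None,
        threshold: float = DEFAULT_THRESHOLD,
        top_k: int = DEFAULT_TOP_K,
        min_group_size: int = DEFAULT_MIN_GROUP_SIZE,
        include_unknown_membrane: bool = False,
        log2: bool = False,
        normal_mode: str = "pooled_samples",
    ):
        self.matrix = matrix
        self.metadata = metadata
        self.evidence = evidence
        self.probe_to_gene = dict(probe_to_gene) if probe_to_gene else None
        self.overrides = dict(overrides) if overrides else None
        self.term_config = term_config
        self.alias_map = dict(alias_map) if alias_map else None
        self.threshold = float(threshold)
        self.top_k = int(top_k)
        self.min_group_size = int(min_group_size)
        self.include_unknown_membrane = bool(include_unknown_membrane)
        self.log2 = bool(log2)
        self.normal_mode = normal_mode

    @classmethod
    def from_files(
        cls,
        matrix_path: str | Path,
        metadata_path: str | Path,
        annotation_paths: list[str | Path] | None = None,
        probe_to_gene_path: str | Path | None = None,
        overrides_path: str | Path | None = None,
        alias_path: str | Path | None = None,
        normal_panel: list[str] | None = None,
        **kwargs,
    ) -> "SurfaceTargetScreen":
        """Build the model from the TSV formats documented in the readers."""
        panel = normal_panel if normal_panel is not None else list(NORMAL_TISSUES)
        matrix = read_expression_matrix(matrix_path)
        metadata = read_sample_metadata(metadata_path, normal_panel=panel)
        evidence = (
            load_annotation_table(annotation_paths) if annotation_paths else None
        )
        probe_to_gene = (
            load_probe_to_gene(probe_to_gene_path) if probe_to_gene_path else None
        )
        overrides = load_overrides(overrides_path) if overrides_path else None
        alias_map = load_alias_map(alias_path) if alias_path else None
        return cls(
            matrix,
            metadata,
            evidence,
            probe_to_gene,
            overrides=overrides,
            alias_map=alias_map,
            **kwargs,
        )

    def fit(self) -> "ScreenResults":
        """Run the full screen and return its results."""
        validation = validate_dataset(
            self.matrix, self.metadata, min_group_size=self.min_group_size
        )
        matrix = log2_transform(self.matrix) if self.log2 else self.matrix

        if self.evidence is not None or self.overrides:
            evidence = (
                self.evidence
                if self.evidence is not None
                else pd.DataFrame(columns=["subject", "compartment_term", "source"])
            )
            calls = classify_all(evidence, self.term_config, self.overrides)
            surface_probes = surface_probe_set(
                matrix.probe_ids,
                self.probe_to_gene,
                calls,
                include_unknown=self.include_unknown_membrane,
            )
        else:
            calls = {}
            surface_probes = []

        statistics: dict[str, pd.DataFrame] = {}
        hit_counts: dict[str, int] = {}
        target_tables: dict[str, TargetTable] = {}
        t_summaries: dict[str, TSummary] = {}
        for disease in validation.screenable_cohorts:
            stats = screen_disease(
                matrix,
                self.metadata,
                disease,
                probe_to_gene=self.probe_to_gene,
                normal_mode=self.normal_mode,
            )
            statistics[disease] = stats
            hit_counts[disease] = count_hits(stats, self.threshold)
            table = top_k_surface_targets(stats, surface_probes, k=self.top_k)
            table.disease = disease
            target_tables[disease] = table
            if len(table):
                t_summaries[disease] = summarize_top_T(table)
        frequency = cross_disease_frequency(
            [t for t in target_tables.values() if len(t)], self.alias_map
        )
        return ScreenResults(
            model=self,
            validation=validation,
            localization_calls=calls,
            surface_probes=surface_probes,
            statistics=statistics,
            hit_counts=hit_counts,
            target_tables=target_tables,
            t_summaries=t_summaries,
            frequency=frequency,
        )


@dataclass
class ScreenResults:
    """Everything the screen computed, with serialization and display."""

    model: SurfaceTargetScreen
    validation: ValidationReport
    localization_calls: dict[str, Call]
    surface_probes: list[str]
    statistics: dict[str, pd.DataFrame]
    hit_counts: dict[str, int]
    target_tables: dict[str, TargetTable]
    t_summaries: dict[str, TSummary]
    frequency: pd.DataFrame
    warnings: list[str] = field(default_factory=list)

    @property
    def diseases(self) -> list[str]:
        return list(self.statistics)

    def summary(self) -> str:
        """Human-readable per-disease overview table."""
        lines = [
            "Surface-target screen results",
            "=" * 70,
            str(self.validation),
            f"surface probes passing filter: {len(self.surface_probes)}",
            f"hit threshold: T > {self.model.threshold:g}",
            "",
            f"{'disease':<14}{'n':>4}{'hits':>10}{'top-k':>8}{'T max':>9}{'T min':>9}",
            "-" * 70,
        ]
        for disease in self.diseases:
            n = len(self.model.metadata.cohort_samples(disease))
            table = self.target_tables[disease]
            if len(table):
                tmax = table.table["T"].iloc[0]
                tmin = table.table["T"].iloc[-1]
                tmax_s, tmin_s = f"{tmax:9.2f}", f"{tmin:9.2f}"
            else:
                tmax_s = tmin_s = f"{'-':>9}"
            lines.append(
                f"{disease:<14}{n:>4}{self.hit_counts[disease]:>10}"
                f"{len(table):>8}{tmax_s}{tmin_s}"
            )
        if len(self.frequency):
            shared = self.frequency.loc[self.frequency["count"] >= 3]
            lines += [
                "",
                f"genes in >=3 disease top-k lists: {len(shared)}",
            ]
        return "\n".join(lines)

    def save_reports(self, outdir: str | Path) -> dict[str, Path]:
        """Write the report bundle: per-disease full screen and top-k TSVs,
        hit counts, T summaries, cross-disease frequency, and a run log.

        Output is deterministic: identical inputs and settings produce
        byte-identical files.
        """
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written: dict[str, Path] = {}

        def _slug(disease: str) -> str:
            return disease.replace("/", "_").replace(" ", "_")

        for disease, stats in self.statistics.items():
            out = stats.copy()
            out.insert(0, "rank", np.arange(1, len(out) + 1))
            out["p"] = [format_scientific(min(p, 1.0)) if p > 0 else "0.00E+00" for p in out["p"]]
            path = outdir / f"screen_{_slug(disease)}.tsv"
            out[
                ["rank", "probe_id", "gene_symbol", "T", "p", "tumor_mean", "normal_mean"]
            ].to_csv(path, sep="\t", index=False)
            written[f"screen_{disease}"] = path
        for disease, table in self.target_tables.items():
            out = table.table.copy()
            if len(out):
                out["p"] = [format_scientific(min(p, 1.0)) if p > 0 else "0.00E+00" for p in out["p"]]
            path = outdir / f"top_{_slug(disease)}.tsv"
            out.to_csv(path, sep="\t", index=False)
            written[f"top_{disease}"] = path

        hits = pd.DataFrame(
            {"disease": list(self.hit_counts), "hits": list(self.hit_counts.values())}
        )
        written["hits"] = outdir / "hits.tsv"
        hits.to_csv(written["hits"], sep="\t", index=False)

        rows = []
        for disease, s in self.t_summaries.items():
            p = s.present()
            rows.append(
                {
                    "disease": disease,
                    "min": p["min"],
                    "q1": p["q1"],
                    "median": p["median"],
                    "q3": p["q3"],
                    "max": p["max"],
                    "mean": p["mean"],
                }
            )
        written["t_summary"] = outdir / "t_summary.tsv"
        pd.DataFrame(
            rows, columns=["disease", "min", "q1", "median", "q3", "max", "mean"]
        ).to_csv(written["t_summary"], sep="\t", index=False)

        written["frequency"] = outdir / "frequency.tsv"
        self.frequency.to_csv(written["frequency"], sep="\t", index=False)

        m = self.model
        log_lines = [
            f"surfscreen {__version__}",
            f"python {sys.version.split()[0]}",
            f"threshold={m.threshold:g} top_k={m.top_k} "
            f"min_group_size={m.min_group_size}",
            f"include_unknown_membrane={m.include_unknown_membrane} "
            f"log2={m.log2} normal_mode={m.normal_mode}",
            f"matrix: {m.matrix.shape[0]} probes x {m.matrix.shape[1]} samples",
            f"normal panel size: {self.validation.n_normal}",
            f"surface probes: {len(self.surface_probes)}",
        ]
        for cohort, n in self.validation.excluded_cohorts.items():
            log_lines.append(f"warning: cohort {cohort} excluded (n={n})")
        for w in self.warnings:
            log_lines.append(f"warning: {w}")
        written["run_log"] = outdir / "run_log.txt"
        written["run_log"].write_text("\n".join(log_lines) + "\n", encoding="utf-8")
        return written

    def plot_t_ranges(self, ax=None):
        """Box-whisker plot of each disease's top-k T values."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        diseases = [d for d in self.diseases if len(self.target_tables[d])]
        data = [self.target_tables[d].table["T"].to_numpy() for d in diseases]
        ax.boxplot(data, tick_labels=diseases, showmeans=True)
        ax.set_ylabel("T statistic")
        ax.set_xlabel("disease")
        ax.tick_params(axis="x", rotation=60)
        return ax
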