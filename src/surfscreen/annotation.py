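"""Membrane-localization evidence merging and cell-surface classification.

Immunotherapy constructs (CARs, therapeutic antibodies) can only reach
proteins exposed on the extracellular plasma membrane, so a screen for
candidate targets must separate genuinely surface-expressed proteins from
those confined to intracellular membranes (mitochondria, nuclear envelope,
Golgi, ER, sorting vesicles).  Proteins expressed both on the surface and in
another compartment are kept.

Hand curation is mechanized as (a) configurable compartment-term
vocabularies matched case-insensitively as substrings, and (b) a
curation-override table that fixes the call for a subject regardless of
evidence.  A bare "membrane" tag with no recognizable compartment resolves
to UNKNOWN_MEMBRANE — the pool a curator would review manually — and is
excluded from the surface set by default.
"""

from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Accepted evidence source labels, in decreasing curation weight.
EVIDENCE_SOURCES: tuple[str, ...] = (
    "CURATION_OVERRIDE",
    "LITERATURE",
    "PROTEIN_DB",
    "GO",
    "CHIP_ANNOTATION",
)

_MEMBRANE_TOKEN = re.compile(r"\bmembrane\b", re.IGNORECASE)


class Call(str, enum.Enum):
    """Resolved sub-cellular localization class for a probe or gene."""

    CELL_SURFACE = "CELL_SURFACE"
    INTERNAL_MEMBRANE_ONLY = "INTERNAL_MEMBRANE_ONLY"
    UNKNOWN_MEMBRANE = "UNKNOWN_MEMBRANE"
    NON_MEMBRANE = "NON_MEMBRANE"


@dataclass(frozen=True)
class TermConfig:
    """Compartment vocabularies; each entry is matched as a case-insensitive
    substring of an evidence term."""

    surface_terms: tuple[str, ...] = (
        "plasma membrane",
        "cell surface",
        "integral component of plasma membrane",
        "external side of plasma membrane",
    )
    internal_terms: tuple[str, ...] = (
        "mitochondrion",
        "mitochondrial",
        "nuclear membrane",
        "nuclear envelope",
        "golgi",
        "endoplasmic reticulum",
        "endosome",
        "lysosome",
        "vesicle",
    )


DEFAULT_TERM_CONFIG = TermConfig()


@dataclass
class LocalizationCall:
    subject: str
    call: Call
    supporting_terms: list[str] = field(default_factory=list)
    decided_by: str = "GO"


def load_annotation_table(paths: Sequence[str | Path]) -> pd.DataFrame:
    """Merge evidence TSVs (columns subject, compartment_term, source).

    Duplicate (subject, term, source) records are collapsed to one; an
    unrecognized source label is an error listing the accepted labels.
    """
    frames = []
    for path in paths:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        required = {"subject", "compartment_term", "source"}
        if not required.issubset(df.columns):
            raise ValueError(f"{path}: annotation TSV needs columns {sorted(required)}")
        frames.append(df[["subject", "compartment_term", "source"]])
    if not frames:
        return pd.DataFrame(columns=["subject", "compartment_term", "source"])
    merged = pd.concat(frames, ignore_index=True).drop_duplicates(ignore_index=True)
    unknown = set(merged["source"]) - set(EVIDENCE_SOURCES)
    if unknown:
        raise ValueError(
            f"unknown evidence source(s) {sorted(unknown)}; "
            f"accepted: {list(EVIDENCE_SOURCES)}"
        )
    if (merged["compartment_term"].str.len() == 0).any():
        raise ValueError("empty compartment_term in annotation table")
    return merged


def load_overrides(path: str | Path) -> dict[str, Call]:
    """Read a curation-override TSV (columns subject, call)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if not {"subject", "call"}.issubset(df.columns):
        raise ValueError("override TSV needs columns subject, call")
    out: dict[str, Call] = {}
    for subject, call in zip(df["subject"], df["call"]):
        try:
            out[subject] = Call(call)
        except ValueError as exc:
            raise ValueError(
                f"override for {subject!r} has unknown call {call!r}; "
                f"accepted: {[c.value for c in Call]}"
            ) from exc
    return out


def _matches_any(term: str, vocab: Iterable[str]) -> bool:
    low = term.lower()
    return any(entry.lower() in low for entry in vocab)


def classify_terms(
    terms: Sequence[str], term_config: TermConfig = DEFAULT_TERM_CONFIG
) -> Call:
    """Resolve an evidence term multiset to one call.

    Precedence (total and order-independent): any surface term wins even when
    internal terms are also present; otherwise any internal term; otherwise a
    bare "membrane" token; otherwise non-membrane.
    """
    if any(_matches_any(t, term_config.surface_terms) for t in terms):
        return Call.CELL_SURFACE
    if any(_matches_any(t, term_config.internal_terms) for t in terms):
        return Call.INTERNAL_MEMBRANE_ONLY
    if any(_MEMBRANE_TOKEN.search(t) for t in terms):
        return Call.UNKNOWN_MEMBRANE
    return Call.NON_MEMBRANE


def classify_localization(
    subject: str,
    evidence: pd.DataFrame,
    term_config: TermConfig = DEFAULT_TERM_CONFIG,
    overrides: Mapping[str, Call] | None = None,
) -> LocalizationCall:
    """Classify one subject from the merged evidence collection.

    An override, when present, fixes the call regardless of evidence.
    """
    if overrides and subject in overrides:
        return LocalizationCall(
            subject=subject,
            call=overrides[subject],
            supporting_terms=[],
            decided_by="CURATION_OVERRIDE",
        )
    rows = evidence.loc[evidence["subject"] == subject]
    terms = list(rows["compartment_term"])
    call = classify_terms(terms, term_config)
    relevant = {
        Call.CELL_SURFACE: term_config.surface_terms,
        Call.INTERNAL_MEMBRANE_ONLY: term_config.internal_terms,
    }.get(call)
    if relevant is not None:
        supporting = [t for t in terms if _matches_any(t, relevant)]
    elif call is Call.UNKNOWN_MEMBRANE:
        supporting = [t for t in terms if _MEMBRANE_TOKEN.search(t)]
    else:
        supporting = []
    decided_by = rows["source"].iloc[0] if len(rows) else "GO"
    return LocalizationCall(subject, call, supporting, decided_by)


def classify_all(
    evidence: pd.DataFrame,
    term_config: TermConfig = DEFAULT_TERM_CONFIG,
    overrides: Mapping[str, Call] | None = None,
) -> dict[str, Call]:
    """Vectorized classification of every subject appearing in the evidence
    (plus every overridden subject)."""
    calls: dict[str, Call] = {}
    if len(evidence):
        for subject, group in evidence.groupby("subject", sort=False):
            calls[subject] = classify_terms(
                list(group["compartment_term"]), term_config
            )
    if overrides:
        for subject, call in overrides.items():
            calls[subject] = call
    return calls


def surface_probe_set(
    matrix_probes: Sequence[str],
    probe_to_gene: Mapping[str, str] | None,
    calls: Mapping[str, Call],
    include_unknown: bool = False,
) -> list[str]:
    """Probes whose subject (the probe itself, or its mapped gene) is
    CELL_SURFACE — plus UNKNOWN_MEMBRANE subjects when ``include_unknown``
    is set, mirroring a manual-review pool.

    Probes with no annotation at all are treated as NON_MEMBRANE and counted
    in a single log message.  Input order is preserved.
    """
    wanted = {Call.CELL_SURFACE}
    if include_unknown:
        wanted.add(Call.UNKNOWN_MEMBRANE)
    selected: list[str] = []
    unannotated = 0
    for probe in matrix_probes:
        call = calls.get(probe)
        if call is None and probe_to_gene is not None:
            gene = probe_to_gene.get(probe)
            if gene is not None:
                call = calls.get(gene)
        if call is None:
            unannotated += 1
            continue
        if call in wanted:
            selected.append(probe)
    if unannotated:
        logger.warning(
            "%d probe(s) had no localization annotation; treated as NON_MEMBRANE",
            unannotated,
        )
    return selected


def load_probe_to_gene(path: str | Path) -> dict[str, str]:
    """Read a ``probe_id<TAB>gene_symbol`` map."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if not {"probe_id", "gene_symbol"}.issubset(df.columns):
        raise ValueError("probe-to-gene TSV needs columns probe_id, gene_symbol")
    if df["probe_id"].duplicated().any():
        dup = df.loc[df["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise ValueError(f"probe {dup!r} maps to more than one gene")
    return dict(zip(df["probe_id"], df["gene_symbol"]))
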