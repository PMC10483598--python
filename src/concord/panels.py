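"""Panel harmonization: comparable gene sets and alteration filtering.

Two sequencing panels (a tissue assay and a plasma ctDNA assay) report
alterations over different gene universes, and the ctDNA panel changed
composition over time.  Analyses must be restricted to genes sequenced by
*both* assays for the relevant test date.  This module resolves the
date-appropriate comparable gene set and restricts alteration lists to it.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from typing import Iterable, Mapping, Sequence

__all__ = [
    "AlterationKind",
    "Assay",
    "Alteration",
    "PanelDefinition",
    "ComparableGeneSet",
    "PanelConfigError",
    "ParseError",
    "normalize_gene_symbol",
    "normalize_locus",
    "load_panel_definitions",
    "resolve_comparable_set",
    "restrict_alterations",
    "filter_characterized",
]


class AlterationKind(str, Enum):
    POINT_MUTATION = "point_mutation"
    INDEL = "indel"
    AMPLIFICATION = "amplification"
    FUSION = "fusion"
    OTHER = "other"


class Assay(str, Enum):
    TISSUE = "tissue"
    CTDNA = "ctdna"


class ParseError(ValueError):
    """A record could not be parsed/validated; message names the record."""


class PanelConfigError(ValueError):
    """Panel era configuration does not cover a date, or covers it twice."""


def normalize_gene_symbol(raw: str, synonym_map: Mapping[str, str] | None = None) -> str:
    """Trim + uppercase a gene symbol and apply an optional synonym map.

    Idempotent: the synonym map is applied to the normalized symbol, and map
    values are themselves normalized before return.
    """
    if raw is None or not str(raw).strip():
        raise ParseError(f"empty gene symbol in record: {raw!r}")
    symbol = str(raw).strip().upper()
    if synonym_map:
        canon = {k.strip().upper(): v.strip().upper() for k, v in synonym_map.items()}
        symbol = canon.get(symbol, symbol)
    return symbol


def normalize_locus(raw: str | None) -> str:
    """Normalize a protein-change style locus descriptor.

    Strips an optional leading ``p.`` prefix, trims whitespace, uppercases.
    Empty/None becomes the empty string (the canonical locus of an
    amplification).
    """
    if raw is None:
        return ""
    locus = str(raw).strip()
    if locus.lower().startswith("p."):
        locus = locus[2:]
    return locus.upper()


@dataclass(frozen=True)
class Alteration:
    """One called genomic aberration in one assay for one patient."""

    patient_id: str
    gene: str
    kind: AlterationKind
    locus: str
    assay: Assay
    vaf_percent: float | None = None
    characterized: bool = True

    def __post_init__(self) -> None:
        if not self.gene:
            raise ParseError(f"alteration with empty gene (patient {self.patient_id})")
        if self.kind is AlterationKind.AMPLIFICATION and self.locus:
            raise ParseError(
                f"amplification must have empty locus, got {self.locus!r} "
                f"(patient {self.patient_id}, gene {self.gene})"
            )
        if self.vaf_percent is not None and not (0.0 <= self.vaf_percent <= 100.0):
            raise ParseError(
                f"vaf_percent {self.vaf_percent!r} outside [0, 100] "
                f"(patient {self.patient_id}, gene {self.gene})"
            )

    def normalized(self, synonym_map: Mapping[str, str] | None = None) -> "Alteration":
        return replace(
            self,
            gene=normalize_gene_symbol(self.gene, synonym_map),
            locus="" if self.kind is AlterationKind.AMPLIFICATION else normalize_locus(self.locus),
        )


@dataclass(frozen=True)
class PanelDefinition:
    """One era of the ctDNA panel: gene universe + amplification subset.

    ``effective_from``/``effective_to`` form a half-open interval
    [from, to): inclusive start, exclusive end.
    """

    name: str
    genes: frozenset[str]
    amp_genes: frozenset[str]
    effective_from: dt.date
    effective_to: dt.date

    def __post_init__(self) -> None:
        if not self.amp_genes <= self.genes:
            extra = sorted(self.amp_genes - self.genes)
            raise PanelConfigError(f"panel {self.name}: amp_genes not subset of genes: {extra}")
        if not self.effective_from < self.effective_to:
            raise PanelConfigError(
                f"panel {self.name}: effective_from must precede effective_to"
            )

    def covers(self, day: dt.date) -> bool:
        return self.effective_from <= day < self.effective_to


@dataclass(frozen=True)
class ComparableGeneSet:
    """Genes (and amp-eligible genes) sequenced by both assays for a date."""

    genes: frozenset[str]
    amp_genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.amp_genes <= self.genes:
            raise PanelConfigError("amp_genes must be a subset of genes")


def _parse_date(s: str) -> dt.date:
    return dt.date.fromisoformat(s)


def load_panel_definitions(path: str | None = None) -> list[PanelDefinition]:
    """Load panel era definitions from JSON (packaged fixture by default)."""
    if path is None:
        text = resources.files("concord.data").joinpath("panels.json").read_text()
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    raw = json.loads(text)
    panels = []
    for entry in raw["panels"]:
        panels.append(
            PanelDefinition(
                name=entry["name"],
                genes=frozenset(normalize_gene_symbol(g) for g in entry["genes"]),
                amp_genes=frozenset(normalize_gene_symbol(g) for g in entry["amp_genes"]),
                effective_from=_parse_date(entry["effective_from"]),
                effective_to=_parse_date(entry["effective_to"]),
            )
        )
    return panels


def resolve_comparable_set(
    sample_date: dt.date,
    panel_set: Sequence[PanelDefinition],
    tissue_genes: Iterable[str],
    tissue_amp_genes: Iterable[str] | None = None,
) -> ComparableGeneSet:
    """Intersect the tissue gene universe with the era-matched ctDNA panel.

    ``tissue_amp_genes`` defaults to the full tissue universe (the tissue
    assay reports copy number on all its genes), so the amplification-eligible
    subset is then driven by the ctDNA panel.
    """
    matching = [p for p in panel_set if p.covers(sample_date)]
    if len(matching) != 1:
        names = [p.name for p in matching]
        raise PanelConfigError(
            f"date {sample_date.isoformat()} covered by {len(matching)} panel eras {names}; "
            "exactly one required"
        )
    panel = matching[0]
    tissue = frozenset(tissue_genes)
    tissue_amp = tissue if tissue_amp_genes is None else frozenset(tissue_amp_genes)
    genes = tissue & panel.genes
    amp = tissue_amp & panel.amp_genes & genes
    return ComparableGeneSet(genes=genes, amp_genes=amp)


def restrict_alterations(
    alterations: Sequence[Alteration], cgs: ComparableGeneSet
) -> list[Alteration]:
    """Keep alterations in the comparable universe; order preserved.

    An amplification additionally requires its gene to be amp-eligible.
    """
    out = []
    for alt in alterations:
        if alt.gene not in cgs.genes:
            continue
        if alt.kind is AlterationKind.AMPLIFICATION and alt.gene not in cgs.amp_genes:
            continue
        out.append(alt)
    return out


def filter_characterized(alterations: Sequence[Alteration]) -> list[Alteration]:
    """Drop VUS / synonymous records, keeping only characterized alterations."""
    return [a for a in alterations if a.characterized]
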