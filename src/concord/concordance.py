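"""Per-patient and cohort-level concordance between paired assays.

Gene-level concordance: the same gene carries a characterized alteration in
both the tissue and the ctDNA assay (any locus).  Mutation-level concordance:
at least one alteration pair in the gene matches at the exact locus — the
same normalized protein-change descriptor for point mutations and indels, or
amplification called in both assays.  Fusions and uncategorized alterations
participate in gene-level matching only.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .panels import Alteration, AlterationKind, Assay, normalize_locus

__all__ = [
    "ConcordanceStatus",
    "ConcordanceProfile",
    "GeneConcordanceRow",
    "match_locus",
    "profile_patient",
    "cohort_gene_table",
    "conditional_mutation_frequency",
]

_LOCUS_KINDS = {AlterationKind.POINT_MUTATION, AlterationKind.INDEL}


class ConcordanceStatus(str, Enum):
    N_N = "N_N"  # no mutual gene
    Y_N = "Y_N"  # >=1 mutual gene, no mutual mutation
    Y_Y = "Y_Y"  # >=1 mutual gene and >=1 mutual mutation


@dataclass(frozen=True)
class ConcordanceProfile:
    patient_id: str
    mutual_genes: frozenset[str]
    mutual_mutation_genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.mutual_mutation_genes <= self.mutual_genes:
            raise ValueError(
                f"patient {self.patient_id}: mutation-level concordant genes "
                "must be a subset of gene-level concordant genes"
            )

    @property
    def mutual_gene_count(self) -> int:
        return len(self.mutual_genes)

    @property
    def mutual_mutation_count(self) -> int:
        return len(self.mutual_mutation_genes)

    @property
    def status(self) -> ConcordanceStatus:
        if self.mutual_gene_count == 0:
            return ConcordanceStatus.N_N
        if self.mutual_mutation_count == 0:
            return ConcordanceStatus.Y_N
        return ConcordanceStatus.Y_Y


@dataclass(frozen=True)
class GeneConcordanceRow:
    """Cohort-level counts for one gene (each tumor counted at most once)."""

    gene: str
    tissue_n: int
    ctdna_n: int
    mutual_gene_n: int
    mutual_mutation_n: int

    def __post_init__(self) -> None:
        if not (
            0
            <= self.mutual_mutation_n
            <= self.mutual_gene_n
            <= min(self.tissue_n, self.ctdna_n)
        ):
            raise ValueError(
                f"gene {self.gene}: inconsistent counts "
                f"({self.tissue_n}, {self.ctdna_n}, "
                f"{self.mutual_gene_n}, {self.mutual_mutation_n})"
            )


def match_locus(a: Alteration, b: Alteration) -> bool:
    """True iff the two alterations are the identical aberration.

    Requires the same gene and either amplification in both assays or an
    identical normalized locus descriptor for point mutations / indels.
    """
    if a.gene != b.gene:
        return False
    if a.kind is AlterationKind.AMPLIFICATION and b.kind is AlterationKind.AMPLIFICATION:
        return True
    if a.kind in _LOCUS_KINDS and b.kind in _LOCUS_KINDS:
        la, lb = normalize_locus(a.locus), normalize_locus(b.locus)
        return bool(la) and la == lb
    return False


def _check_single_patient(alts: Iterable[Alteration], assay: Assay) -> str | None:
    pids = {a.patient_id for a in alts}
    if len(pids) > 1:
        raise ValueError(f"{assay.value} list mixes patients: {sorted(pids)}")
    return next(iter(pids)) if pids else None


def profile_patient(
    tissue_alts: Sequence[Alteration], ctdna_alts: Sequence[Alteration]
) -> ConcordanceProfile:
    """Score one patient's gene-level and mutation-level concordance.

    Both lists must already be harmonized (same comparable gene set) and
    filtered to characterized alterations.
    """
    pid_t = _check_single_patient(tissue_alts, Assay.TISSUE)
    pid_c = _check_single_patient(ctdna_alts, Assay.CTDNA)
    if pid_t is not None and pid_c is not None and pid_t != pid_c:
        raise ValueError(f"patient_id mismatch: tissue={pid_t!r} ctdna={pid_c!r}")
    patient_id = pid_t or pid_c or ""

    tissue_by_gene: dict[str, list[Alteration]] = {}
    for a in tissue_alts:
        tissue_by_gene.setdefault(a.gene, []).append(a)
    ctdna_by_gene: dict[str, list[Alteration]] = {}
    for b in ctdna_alts:
        ctdna_by_gene.setdefault(b.gene, []).append(b)

    mutual = frozenset(tissue_by_gene) & frozenset(ctdna_by_gene)
    mutual_mut = frozenset(
        g
        for g in mutual
        if any(match_locus(a, b) for a in tissue_by_gene[g] for b in ctdna_by_gene[g])
    )
    return ConcordanceProfile(
        patient_id=patient_id, mutual_genes=mutual, mutual_mutation_genes=mutual_mut
    )


def cohort_gene_table(
    patient_alterations: Mapping[str, tuple[Sequence[Alteration], Sequence[Alteration]]],
) -> list[GeneConcordanceRow]:
    """Aggregate per-gene counts over a cohort.

    ``patient_alterations`` maps patient_id -> (tissue list, ctdna list),
    both harmonized and characterized.  Each tumor contributes at most one
    to each count per gene.  Rows are sorted by descending tissue_n, then
    gene symbol.
    """
    tissue_n: dict[str, int] = {}
    ctdna_n: dict[str, int] = {}
    mutual_n: dict[str, int] = {}
    mutation_n: dict[str, int] = {}

    for pid, (t_alts, c_alts) in patient_alterations.items():
        for g in {a.gene for a in t_alts}:
            tissue_n[g] = tissue_n.get(g, 0) + 1
        for g in {b.gene for b in c_alts}:
            ctdna_n[g] = ctdna_n.get(g, 0) + 1
        prof = profile_patient(t_alts, c_alts)
        for g in prof.mutual_genes:
            mutual_n[g] = mutual_n.get(g, 0) + 1
        for g in prof.mutual_mutation_genes:
            mutation_n[g] = mutation_n.get(g, 0) + 1

    genes = set(tissue_n) | set(ctdna_n)
    rows = [
        GeneConcordanceRow(
            gene=g,
            tissue_n=tissue_n.get(g, 0),
            ctdna_n=ctdna_n.get(g, 0),
            mutual_gene_n=mutual_n.get(g, 0),
            mutual_mutation_n=mutation_n.get(g, 0),
        )
        for g in genes
    ]
    rows.sort(key=lambda r: (-r.tissue_n, r.gene))
    return rows


def conditional_mutation_frequency(
    table: Sequence[GeneConcordanceRow], min_mutual: int = 5
) -> tuple[dict[str, float], float | None]:
    """Per-gene P(mutation-level | gene-level concordance), and the median.

    Only genes with at least ``min_mutual`` gene-level concordant tumors are
    retained.  Returns ``({gene: frequency}, median)``; the median is None
    for an empty retained set (never a silent NaN).
    """
    if min_mutual < 1:
        raise ValueError("min_mutual must be >= 1")
    freqs = {
        row.gene: row.mutual_mutation_n / row.mutual_gene_n
        for row in table
        if row.mutual_gene_n >= min_mutual
    }
    median = statistics.median(freqs.values()) if freqs else None
    return freqs, median
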