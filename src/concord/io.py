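"""Table readers/writers and run configuration.

All delimited output is tab-separated UTF-8 with a fixed column order and
6-significant-digit floats, so repeated runs diff cleanly.  Spreadsheet
(XLSX) input is supported through the same column adapters as delimited
text.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .concordance import GeneConcordanceRow
from .panels import Alteration, AlterationKind, Assay, ParseError, normalize_gene_symbol

__all__ = [
    "ALTERATION_COLUMNS",
    "AlterationRecord",
    "SchemaAdapter",
    "TableParseError",
    "RunConfig",
    "read_alteration_table",
    "write_alteration_table",
    "read_clinical_table",
    "read_survival_table",
    "load_reference_gene_table",
    "format_float",
]

ALTERATION_COLUMNS = [
    "patient_id", "assay", "gene", "kind", "locus",
    "vaf_percent", "characterized", "sample_date",
]

_TRUE = {"true", "t", "1", "yes", "y"}
_FALSE = {"false", "f", "0", "no", "n", ""}


class TableParseError(ValueError):
    """One or more rows failed to parse; message lists every failure."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__(
            f"{len(errors)} row error(s):\n" + "\n".join(errors[:50])
        )


@dataclass(frozen=True)
class SchemaAdapter:
    """Maps a source table layout onto the canonical alteration schema.

    ``column_map`` renames source columns to canonical names; ``kind_map``
    and ``assay_map`` translate source vocabulary for those enums.
    """

    column_map: dict[str, str] = field(default_factory=dict)
    kind_map: dict[str, str] = field(default_factory=dict)
    assay_map: dict[str, str] = field(default_factory=dict)
    characterized_map: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_json(cls, path: str | Path) -> "SchemaAdapter":
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        return cls(
            column_map=raw.get("column_map", {}),
            kind_map=raw.get("kind_map", {}),
            assay_map=raw.get("assay_map", {}),
            characterized_map=raw.get("characterized_map", {}),
        )


@dataclass(frozen=True)
class AlterationRecord:
    alteration: Alteration
    sample_date: dt.date | None
    row_number: int


def _parse_bool(raw, row: int) -> bool:
    s = str(raw).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ParseError(f"row {row}: cannot parse boolean {raw!r}")


def _read_frame(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() in {".xlsx", ".xls"}:
        return pd.read_excel(path, dtype=str)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def read_alteration_table(
    path: str | Path,
    adapter: SchemaAdapter | None = None,
    synonym_map: Mapping[str, str] | None = None,
) -> list[AlterationRecord]:
    """Parse an alteration table, collecting all row errors before failing."""
    return records_from_frame(_read_frame(path), adapter=adapter, synonym_map=synonym_map)


def records_from_frame(
    df: pd.DataFrame,
    adapter: SchemaAdapter | None = None,
    synonym_map: Mapping[str, str] | None = None,
) -> list[AlterationRecord]:
    """Validate an in-memory alteration table (same contract as the reader)."""
    adapter = adapter or SchemaAdapter()
    df = df.rename(columns=adapter.column_map)
    missing = [c for c in ALTERATION_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise TableParseError([f"header missing required columns {missing}"])

    records: list[AlterationRecord] = []
    errors: list[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        d = dict(zip(df.columns, row))
        try:
            kind_raw = str(d.get("kind", "")).strip().lower()
            kind_raw = adapter.kind_map.get(kind_raw, kind_raw)
            try:
                kind = AlterationKind(kind_raw)
            except ValueError:
                raise ParseError(f"row {i}: unknown kind {d.get('kind')!r}")
            assay_raw = str(d.get("assay", "")).strip().lower()
            assay_raw = adapter.assay_map.get(assay_raw, assay_raw)
            try:
                assay = Assay(assay_raw)
            except ValueError:
                raise ParseError(f"row {i}: unknown assay {d.get('assay')!r}")
            vaf_raw = str(d.get("vaf_percent", "")).strip()
            vaf = None
            if vaf_raw not in ("", "na", "nan", "none", "NA"):
                try:
                    vaf = float(vaf_raw)
                except ValueError:
                    raise ParseError(f"row {i}: malformed vaf_percent {vaf_raw!r}")
            date_raw = str(d.get("sample_date", "")).strip()
            sample_date = None
            if date_raw and date_raw.lower() not in ("na", "nan", "none"):
                try:
                    sample_date = dt.date.fromisoformat(date_raw[:10])
                except ValueError:
                    raise ParseError(f"row {i}: malformed sample_date {date_raw!r}")
            gene = normalize_gene_symbol(str(d.get("gene", "")), synonym_map)
            char_raw = str(d.get("characterized", "true")).strip().lower()
            char_raw = adapter.characterized_map.get(char_raw, char_raw)
            alt = Alteration(
                patient_id=str(d.get("patient_id", "")).strip(),
                gene=gene,
                kind=kind,
                locus="" if kind is AlterationKind.AMPLIFICATION
                else str(d.get("locus", "")).strip(),
                assay=assay,
                vaf_percent=vaf,
                characterized=_parse_bool(char_raw, i),
            ).normalized(synonym_map)
            records.append(AlterationRecord(alt, sample_date, i))
        except ParseError as exc:
            errors.append(str(exc))
    if errors:
        raise TableParseError(errors)
    return records


def write_alteration_table(records: Sequence[AlterationRecord], path: str | Path) -> None:
    rows = []
    for rec in records:
        a = rec.alteration
        rows.append(
            {
                "patient_id": a.patient_id,
                "assay": a.assay.value,
                "gene": a.gene,
                "kind": a.kind.value,
                "locus": a.locus,
                "vaf_percent": "" if a.vaf_percent is None else format_float(a.vaf_percent),
                "characterized": str(a.characterized).lower(),
                "sample_date": rec.sample_date.isoformat() if rec.sample_date else "",
            }
        )
    pd.DataFrame(rows, columns=ALTERATION_COLUMNS).to_csv(path, sep="\t", index=False)


def read_clinical_table(path: str | Path) -> pd.DataFrame:
    """Read the clinical table; derive gap_months from dates if absent."""
    df = _read_frame(path)
    required = {"patient_id", "age_at_diagnosis", "sex", "tumor_type"}
    missing = sorted(required - set(df.columns))
    if missing:
        raise TableParseError([f"clinical table missing columns {missing}"])
    out = df.copy()
    for col in ("age_at_diagnosis", "tmb", "pct_ctdna", "gap_months"):
        if col in out.columns:
            out[col] = pd.to_numeric(out[col], errors="coerce")
    if "gap_months" not in out.columns:
        if not {"tissue_date", "blood_date"} <= set(out.columns):
            raise TableParseError(
                ["clinical table needs gap_months or tissue_date+blood_date"]
            )
        t = pd.to_datetime(out["tissue_date"])
        b = pd.to_datetime(out["blood_date"])
        out["gap_months"] = (b - t).dt.days / 30.44
    return out


def read_survival_table(path: str | Path) -> pd.DataFrame:
    df = _read_frame(path)
    missing = sorted({"patient_id", "time_months", "event"} - set(df.columns))
    if missing:
        raise TableParseError([f"survival table missing columns {missing}"])
    out = df.copy()
    out["time_months"] = pd.to_numeric(out["time_months"], errors="coerce")
    out["event"] = [
        _parse_bool(v, i) for i, v in enumerate(out["event"], start=2)
    ]
    return out


def load_reference_gene_table(strict: bool = False) -> list[GeneConcordanceRow]:
    """Packaged published per-gene concordance counts.

    One published row (KIT) violates the count ordering invariant as
    printed; with ``strict=False`` such rows are dropped instead of raising.
    """
    from importlib import resources
    from io import StringIO

    text = resources.files("concord.data").joinpath("gene_table_reference.tsv").read_text()
    df = pd.read_csv(StringIO(text), sep="\t")
    rows = []
    for rec in df.itertuples(index=False):
        try:
            rows.append(
                GeneConcordanceRow(
                    gene=rec.gene,
                    tissue_n=int(rec.tissue_n),
                    ctdna_n=int(rec.ctdna_n),
                    mutual_gene_n=int(rec.mutual_gene_n),
                    mutual_mutation_n=int(rec.mutual_mutation_n),
                )
            )
        except ValueError:
            if strict:
                raise
    return rows


#: smallest double distinguishable from 0 by R's printing convention; text
#: output floors p-values here while JSON keeps the raw float
P_FLOOR = 2.2e-16


def format_p(p: float) -> str:
    return "< 2.2e-16" if p < P_FLOOR else f"{p:.6e}"


def format_float(x: float) -> str:
    """6 significant digits; integers render without an exponent tail."""
    if x != x:  # NaN
        return "nan"
    if float(x).is_integer() and abs(x) < 1e15:
        return str(int(x))
    return f"{x:.6g}"


@dataclass
class RunConfig:
    """End-to-end pipeline configuration; JSON round-trippable."""

    alterations_path: str
    clinical_path: str
    survival_path: str
    out_dir: str
    panels_path: str | None = None
    adapter_path: str | None = None
    synonym_map: dict[str, str] = field(default_factory=dict)
    chi_bin_edges: tuple[int, ...] = (0, 1, 2)
    covariates: tuple[str, ...] = (
        "age_at_diagnosis", "sex", "tumor_type", "gap_months", "pct_ctdna",
        "tissue_gene_count", "ctdna_gene_count", "tmb",
    )
    reference_levels: dict[str, str] = field(default_factory=dict)
    thresholds: tuple[int, ...] = (1, 2, 3)
    gap_filters: tuple[float, ...] = (6.0, 12.0, 24.0, 48.0)
    min_mutual: int = 5
    seed: int = 0

    def validate(self) -> None:
        for name in ("alterations_path", "clinical_path", "survival_path"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")
        for name in ("panels_path", "adapter_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        for key in ("chi_bin_edges", "covariates", "thresholds", "gap_filters"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)
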