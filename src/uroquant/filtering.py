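"""Differential-excretion filtering of protein quantitation tables.

A protein is called differentially excreted between microalbuminuric
(MA) and normoalbuminuric (NA) urine when it satisfies every evidence
and effect-size gate: P value below ``max_p``, error factor below
``max_ef``, at least ``min_unique_peptides`` unique peptides at the
confidence gate, and an MA:NA ratio outside the replicate-derived
fold-change band (above ``upper_cutoff`` or below ``lower_cutoff``).

Classification of survivors as up- or down-regulated is by ratio versus
1, not versus the cutoff band: published differential tables of this
design contain rows whose ratio sits inside the band, and only the
ratio-versus-1 reading yields a complete up/down partition. A validation
helper reports band membership as a warning-level finding instead.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Sequence

from .itraq import ProteinQuantRecord

__all__ = [
    "FilterCriteria",
    "DifferentialTable",
    "Exclusion",
    "apply_filter",
    "count_regulation",
    "read_quant_table",
    "write_quant_table",
    "load_reference_differential_table",
]

Regulation = Literal["up", "down"]


@dataclass(frozen=True)
class FilterCriteria:
    """Gates for calling a protein differentially excreted."""

    max_p: float = 0.05
    max_ef: float = 2.0
    min_unique_peptides: int = 2
    min_peptide_confidence: float = 95.0
    upper_cutoff: float = 1.25
    lower_cutoff: float = 0.80

    def __post_init__(self) -> None:
        if not 0.0 < self.max_p < 1.0:
            raise ValueError("max_p must lie in (0, 1)")
        if not self.lower_cutoff < 1.0 < self.upper_cutoff:
            raise ValueError("cutoffs must bracket 1 (lower < 1 < upper)")
        if self.min_unique_peptides < 1:
            raise ValueError("min_unique_peptides must be >= 1")

    def passes_evidence(self, record: ProteinQuantRecord) -> bool:
        """Evidence-only gates (peptide count and P value), used when
        selecting technical-replicate proteins for cutoff calibration."""
        return (
            record.n_unique_peptides >= self.min_unique_peptides
            and record.p_value is not None
            and record.p_value < self.max_p
        )


@dataclass(frozen=True)
class Exclusion:
    accession: str
    reason: str


@dataclass
class DifferentialTable:
    """Filter survivors, their regulation calls, and the exclusion log."""

    records: list[ProteinQuantRecord]
    regulation: list[Regulation]
    exclusions: list[Exclusion] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.records) != len(self.regulation):
            raise ValueError("records and regulation must be parallel lists")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(zip(self.records, self.regulation))


def _exclusion_reason(record: ProteinQuantRecord, criteria: FilterCriteria) -> str | None:
    if record.p_value is None or record.ef is None:
        return "undefined_statistics"
    if record.n_unique_peptides < criteria.min_unique_peptides:
        return "too_few_peptides"
    if not record.p_value < criteria.max_p:
        return "p_value"
    if not record.ef < criteria.max_ef:
        return "error_factor"
    if criteria.lower_cutoff <= record.ratio_ma_na <= criteria.upper_cutoff:
        return "inside_cutoff_band"
    return None


def apply_filter(
    table: Sequence[ProteinQuantRecord], criteria: FilterCriteria = FilterCriteria()
) -> DifferentialTable:
    """Apply all differential-excretion gates; order is preserved.

    Records with undefined p_value or ef (single-peptide quantitation)
    are excluded with reason ``undefined_statistics``. Every exclusion is
    logged with a reason code; nothing is silently dropped.
    """
    records: list[ProteinQuantRecord] = []
    regulation: list[Regulation] = []
    exclusions: list[Exclusion] = []
    for rec in table:
        reason = _exclusion_reason(rec, criteria)
        if reason is not None:
            exclusions.append(Exclusion(rec.accession, reason))
            continue
        records.append(rec)
        regulation.append("up" if rec.ratio_ma_na > 1.0 else "down")
    return DifferentialTable(records, regulation, exclusions)


def count_regulation(
    table: DifferentialTable | Sequence[ProteinQuantRecord],
) -> tuple[int, int, int]:
    """(n_total, n_up, n_down) with classification by ratio versus 1."""
    records = table.records if isinstance(table, DifferentialTable) else list(table)
    n_up = n_down = 0
    for rec in records:
        if rec.ratio_ma_na == 1.0:
            raise AssertionError(
                f"ratio exactly 1 for {rec.accession}: impossible after fold-change gating"
            )
        if rec.ratio_ma_na > 1.0:
            n_up += 1
        else:
            n_down += 1
    return n_up + n_down, n_up, n_down


_QUANT_COLUMNS = ["accession", "protein_name", "n_unique_peptides", "ratio_ma_na", "p_value", "ef"]


def read_quant_table(
    path: str | Path, *, allow_duplicate_accessions: bool = False
) -> list[ProteinQuantRecord]:
    """Read a tab-separated protein quantitation table.

    Malformed rows are reported with their line numbers. Duplicate
    accessions are rejected by default; published tables occasionally
    repeat an accession across database entries, so a permissive flag
    is available.
    """
    records: list[ProteinQuantRecord] = []
    seen: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != _QUANT_COLUMNS:
            raise ValueError(f"unexpected quant table header {header}; expected {_QUANT_COLUMNS}")
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(_QUANT_COLUMNS):
                raise ValueError(f"{path}, line {lineno}: expected {len(_QUANT_COLUMNS)} fields, got {len(row)}")
            acc, name, n_pep, ratio, p, ef = row
            if acc in seen and not allow_duplicate_accessions:
                raise ValueError(f"{path}, line {lineno}: duplicate accession {acc!r}")
            seen.add(acc)
            try:
                record = ProteinQuantRecord(
                    accession=acc,
                    protein_name=name,
                    n_unique_peptides=int(n_pep),
                    ratio_ma_na=float(ratio),
                    p_value=float(p) if p != "" else None,
                    ef=float(ef) if ef != "" else None,
                )
            except ValueError as exc:
                raise ValueError(f"{path}, line {lineno}: {exc}") from None
            records.append(record)
    return records


def write_quant_table(table: Iterable[ProteinQuantRecord], path: str | Path) -> None:
    """Write the tab-separated quantitation schema; None statistics are
    serialized as empty fields, numbers at shortest round-tripping
    precision."""

    def fmt(x: float | None) -> str:
        return "" if x is None else repr(float(x))

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_QUANT_COLUMNS)
        for rec in table:
            writer.writerow(
                [
                    rec.accession,
                    rec.protein_name,
                    rec.n_unique_peptides,
                    fmt(rec.ratio_ma_na),
                    fmt(rec.p_value),
                    fmt(rec.ef),
                ]
            )


def load_reference_differential_table() -> list[ProteinQuantRecord]:
    """The packaged 196-protein differential urinary proteome reference
    table (MA vs NA, type 2 diabetes), as printed in the source study.

    Contains a few repeated accessions (the same protein quantified under
    multiple database entries), hence the permissive duplicate flag.
    """
    ref = resources.files("uroquant.data") / "differential_urinary_proteome.tsv"
    with resources.as_file(ref) as path:
        return read_quant_table(path, allow_duplicate_accessions=True)
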