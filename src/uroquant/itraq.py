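"""Protein-level quantitation from 4-plex isobaric reporter intensities.

The quantitation atom is a peptide-spectrum match carrying four reporter
channel intensities (m/z 114-117). Two pooled samples (normoalbuminuric,
NA, and microalbuminuric, MA) are labeled on different channels, so the
per-spectrum channel ratio estimates the MA:NA abundance ratio of the
parent protein. This module turns those spectra into per-protein ratios
with a P value and an error factor (EF), after optional isotope-impurity
correction and median bias normalization.

Statistics are computed on log10 peptide ratios:

* protein ratio  = geometric mean of qualifying peptide ratios,
* P value        = two-sided one-sample t-test of the log ratios against 0,
* EF             = 10 ** (t_{0.975, n-1} * s / sqrt(n)),

so EF is the multiplicative half-width of the ratio's 95% confidence
interval; EF < 2 means the ratio is known to within a factor of two.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy import stats

from .masses import CANONICAL_RESIDUES

CHANNELS = (114, 115, 116, 117)

__all__ = [
    "CHANNELS",
    "ReporterRecord",
    "CorrectionMatrix",
    "ProteinQuantRecord",
    "QuantSummary",
    "CorrectionOutcome",
    "correct_isotope_impurities",
    "peptide_ratio",
    "bias_normalize",
    "summarize_protein",
    "labeling_efficiency",
    "quantify_proteins",
    "read_reporter_table",
    "write_reporter_table",
]


@dataclass(frozen=True)
class ReporterRecord:
    """One peptide-spectrum match with four reporter-channel intensities."""

    spectrum_id: str
    peptide_sequence: str
    protein_accession: str
    confidence_percent: float
    intensity_114: float
    intensity_115: float
    intensity_116: float
    intensity_117: float
    n_labeled_sites: int = 0
    n_possible_sites: int = 1

    def __post_init__(self) -> None:
        if not set(self.peptide_sequence) <= CANONICAL_RESIDUES:
            bad = set(self.peptide_sequence) - CANONICAL_RESIDUES
            raise ValueError(f"non-canonical residues {sorted(bad)} in {self.peptide_sequence!r}")
        if not 0.0 <= self.confidence_percent <= 100.0:
            raise ValueError(f"confidence_percent {self.confidence_percent} outside [0, 100]")
        for ch in CHANNELS:
            if self.intensity(ch) < 0:
                raise ValueError(f"negative intensity in channel {ch}")
        if self.n_possible_sites < 1:
            raise ValueError("n_possible_sites must be >= 1")
        if not 0 <= self.n_labeled_sites <= self.n_possible_sites:
            raise ValueError("n_labeled_sites must lie in [0, n_possible_sites]")

    def intensity(self, channel: int) -> float:
        if channel not in CHANNELS:
            raise ValueError(f"unknown reporter channel {channel}")
        return getattr(self, f"intensity_{channel}")

    def intensities(self) -> np.ndarray:
        return np.array([self.intensity(ch) for ch in CHANNELS], dtype=float)


@dataclass(frozen=True)
class CorrectionMatrix:
    """4x4 isotope-impurity matrix; entry (i, j) is the fraction of channel
    j's signal observed in channel i. Column sums may not exceed 1."""

    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.shape != (4, 4):
            raise ValueError("correction matrix must be 4x4")
        if np.any(arr < -1e-12):
            raise ValueError("correction matrix entries must be nonnegative")
        if np.any(arr.sum(axis=0) > 1.0 + 1e-9):
            raise ValueError("correction matrix column sums must be <= 1")
        for j in range(4):
            if arr[j, j] < np.max(np.delete(arr[:, j], j), initial=0.0):
                raise ValueError("correction matrix must be diagonally dominant")
        object.__setattr__(self, "values", arr)

    @classmethod
    def identity(cls) -> "CorrectionMatrix":
        return cls(np.eye(4))

    @classmethod
    def from_csv(cls, path: str | Path) -> "CorrectionMatrix":
        """Load a 4x4 matrix from a headerless CSV (manufacturer lot sheet)."""
        arr = np.loadtxt(path, delimiter=",", dtype=float)
        return cls(arr)


@dataclass(frozen=True)
class ProteinQuantRecord:
    """Per-protein MA:NA quantitation; p_value and ef are None for
    single-peptide proteins, where dispersion is unidentifiable."""

    accession: str
    protein_name: str
    n_unique_peptides: int
    ratio_ma_na: float
    p_value: float | None
    ef: float | None

    def __post_init__(self) -> None:
        if self.n_unique_peptides < 1:
            raise ValueError("n_unique_peptides must be >= 1")
        if not self.ratio_ma_na > 0:
            raise ValueError(f"ratio_ma_na must be > 0, got {self.ratio_ma_na}")
        if self.p_value is not None and not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")
        if self.ef is not None and self.ef < 1.0 - 1e-12:
            raise ValueError(f"ef must be >= 1, got {self.ef}")


class CorrectionOutcome(NamedTuple):
    records: list[ReporterRecord]
    n_clamped: int


class QuantSummary(NamedTuple):
    """Protein-level statistics from one set of peptide ratios."""

    ratio_ma_na: float
    p_value: float | None
    ef: float | None
    n_peptides: int


def correct_isotope_impurities(
    records: Iterable[ReporterRecord], matrix: CorrectionMatrix
) -> CorrectionOutcome:
    """Undo reporter-channel isotope crosstalk.

    Solves ``matrix @ corrected = observed`` per spectrum. Small negative
    solutions (noise near zero) are clamped to 0 and counted.
    """
    m = matrix.values
    if abs(np.linalg.det(m)) < 1e-12:
        raise ValueError("singular correction matrix")
    inv = np.linalg.inv(m)
    out: list[ReporterRecord] = []
    n_clamped = 0
    for rec in records:
        corrected = inv @ rec.intensities()
        if np.any(corrected < 0):
            n_clamped += 1
            corrected = np.clip(corrected, 0.0, None)
        out.append(
            replace(
                rec,
                intensity_114=corrected[0],
                intensity_115=corrected[1],
                intensity_116=corrected[2],
                intensity_117=corrected[3],
            )
        )
    if n_clamped:
        warnings.warn(f"{n_clamped} spectra had negative corrected intensities clamped to 0")
    return CorrectionOutcome(out, n_clamped)


def peptide_ratio(record: ReporterRecord, numerator_channel: int, denominator_channel: int) -> float:
    """Reporter-ion ratio for one spectrum, e.g. 115/114 (MA:NA).

    Raises
    ------
    ZeroDivisionError
        If the denominator intensity is 0; callers exclude and count
        such spectra.
    """
    den = record.intensity(denominator_channel)
    if den == 0:
        raise ZeroDivisionError(
            f"zero intensity in denominator channel {denominator_channel} "
            f"for spectrum {record.spectrum_id!r}"
        )
    return record.intensity(numerator_channel) / den


def bias_normalize(ratios: Sequence[float]) -> np.ndarray:
    """Divide every ratio by the median ratio, removing a constant
    labeling/mixing bias; the output median is 1."""
    arr = np.asarray(ratios, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot bias-normalize an empty ratio list")
    return arr / np.median(arr)


def summarize_protein(
    peptide_ratios: Sequence[float],
    confidence_percents: Sequence[float] | None = None,
    min_confidence: float = 95.0,
) -> QuantSummary:
    """Protein ratio, P value and error factor from peptide ratios.

    Only peptides at or above the confidence gate contribute. With a
    single qualifying peptide the dispersion statistics are undefined
    (None). With zero sample variance the t distribution degenerates:
    ef = 1 and the P value is taken as the continuous limit (0 when the
    mean log ratio is nonzero, 1 when it is zero).
    """
    ratios = np.asarray(peptide_ratios, dtype=float)
    if confidence_percents is not None:
        conf = np.asarray(confidence_percents, dtype=float)
        if conf.shape != ratios.shape:
            raise ValueError("confidence_percents length must match peptide_ratios")
        ratios = ratios[conf >= min_confidence]
    if ratios.size == 0:
        raise ValueError("no peptide ratios pass the confidence gate")
    if np.any(ratios <= 0):
        raise ValueError("peptide ratios must be positive")

    logs = np.log10(ratios)
    n = logs.size
    ratio = float(10.0 ** logs.mean())
    if n == 1:
        return QuantSummary(ratio, None, None, 1)

    s = float(logs.std(ddof=1))
    if s == 0.0:
        p_value = 1.0 if logs[0] == 0.0 else 0.0
        return QuantSummary(ratio, p_value, 1.0, n)

    t_crit = float(stats.t.ppf(0.975, n - 1))
    ef = float(10.0 ** (t_crit * s / math.sqrt(n)))
    with warnings.catch_warnings():
        # near-identical log ratios trip scipy's catastrophic-cancellation
        # notice; the zero-variance branch above handles the exact case
        warnings.simplefilter("ignore", RuntimeWarning)
        p_value = float(stats.ttest_1samp(logs, 0.0).pvalue)
    return QuantSummary(ratio, p_value, ef, n)


def labeling_efficiency(records: Iterable[ReporterRecord]) -> float:
    """Fraction of possible isobaric labeling sites actually labeled.

    Each peptide offers one N-terminal site plus one per lysine; a record
    whose declared site count disagrees with its sequence is a validation
    error. The study design requires this fraction to be near 1 for the
    reporter ratios to be interpretable.
    """
    total_possible = 0
    total_labeled = 0
    for rec in records:
        expected = 1 + rec.peptide_sequence.count("K")
        if rec.n_possible_sites != expected:
            raise ValueError(
                f"record {rec.spectrum_id!r}: n_possible_sites={rec.n_possible_sites} "
                f"inconsistent with sequence {rec.peptide_sequence!r} (expected {expected})"
            )
        total_possible += rec.n_possible_sites
        total_labeled += rec.n_labeled_sites
    if total_possible == 0:
        raise ValueError("no labeling sites in record set")
    return total_labeled / total_possible


def quantify_proteins(
    records: Sequence[ReporterRecord],
    numerator_channel: int,
    denominator_channel: int,
    *,
    min_confidence: float = 95.0,
    exclude_shared_peptides: bool = True,
    normalize_bias: bool = False,
) -> tuple[list[ProteinQuantRecord], dict[str, int]]:
    """Full rollup: spectra -> per-protein MA:NA quantitation table.

    Peptide sequences observed under more than one accession are excluded
    by default (shared peptides carry ambiguous evidence; the unique-
    peptide count is what downstream filters gate on). Spectra with a
    zero denominator are excluded and counted. ``normalize_bias`` applies
    median centering across all qualifying peptide ratios before the
    per-protein rollup.

    Returns the table (ordered by accession) and a counter dict with keys
    ``zero_denominator``, ``shared_peptides``, ``low_confidence``,
    ``unquantified_proteins``.
    """
    counters = {
        "zero_denominator": 0,
        "shared_peptides": 0,
        "low_confidence": 0,
        "unquantified_proteins": 0,
    }
    if exclude_shared_peptides:
        owners: dict[str, set[str]] = {}
        for rec in records:
            owners.setdefault(rec.peptide_sequence, set()).add(rec.protein_accession)
        shared = {seq for seq, accs in owners.items() if len(accs) > 1}
    else:
        shared = set()

    kept: list[tuple[str, str, float]] = []  # (accession, sequence, ratio)
    for rec in records:
        if rec.peptide_sequence in shared:
            counters["shared_peptides"] += 1
            continue
        if rec.confidence_percent < min_confidence:
            counters["low_confidence"] += 1
            continue
        try:
            r = peptide_ratio(rec, numerator_channel, denominator_channel)
        except ZeroDivisionError:
            counters["zero_denominator"] += 1
            continue
        if r <= 0:
            counters["zero_denominator"] += 1
            continue
        kept.append((rec.protein_accession, rec.peptide_sequence, r))

    if normalize_bias and kept:
        normed = bias_normalize([r for _, _, r in kept])
        kept = [(a, s, rn) for (a, s, _), rn in zip(kept, normed)]

    by_protein: dict[str, list[tuple[str, float]]] = {}
    for acc, seq, r in kept:
        by_protein.setdefault(acc, []).append((seq, r))

    table: list[ProteinQuantRecord] = []
    for acc in sorted(by_protein):
        peptides = by_protein[acc]
        summary = summarize_protein([r for _, r in peptides])
        n_unique = len({seq for seq, _ in peptides})
        table.append(
            ProteinQuantRecord(
                accession=acc,
                protein_name=acc,
                n_unique_peptides=n_unique,
                ratio_ma_na=summary.ratio_ma_na,
                p_value=summary.p_value,
                ef=summary.ef,
            )
        )
    all_accessions = {rec.protein_accession for rec in records}
    counters["unquantified_proteins"] = len(all_accessions) - len(table)
    return table, counters


_REPORTER_COLUMNS = [
    "spectrum_id",
    "peptide_sequence",
    "protein_accession",
    "confidence_percent",
    "intensity_114",
    "intensity_115",
    "intensity_116",
    "intensity_117",
    "n_labeled_sites",
    "n_possible_sites",
]


def read_reporter_table(path: str | Path) -> list[ReporterRecord]:
    """Read a tab-separated reporter-record table (fixed one-line header)."""
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames != _REPORTER_COLUMNS:
            raise ValueError(
                f"unexpected reporter table header {reader.fieldnames}; expected {_REPORTER_COLUMNS}"
            )
        for row in reader:
            records.append(
                ReporterRecord(
                    spectrum_id=row["spectrum_id"],
                    peptide_sequence=row["peptide_sequence"],
                    protein_accession=row["protein_accession"],
                    confidence_percent=float(row["confidence_percent"]),
                    intensity_114=float(row["intensity_114"]),
                    intensity_115=float(row["intensity_115"]),
                    intensity_116=float(row["intensity_116"]),
                    intensity_117=float(row["intensity_117"]),
                    n_labeled_sites=int(row["n_labeled_sites"]),
                    n_possible_sites=int(row["n_possible_sites"]),
                )
            )
    return records


def write_reporter_table(records: Iterable[ReporterRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_REPORTER_COLUMNS)
        for rec in records:
            writer.writerow(
                [
                    rec.spectrum_id,
                    rec.peptide_sequence,
                    rec.protein_accession,
                    repr(rec.confidence_percent),
                    repr(rec.intensity_114),
                    repr(rec.intensity_115),
                    repr(rec.intensity_116),
                    repr(rec.intensity_117),
                    rec.n_labeled_sites,
                    rec.n_possible_sites,
                ]
            )
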