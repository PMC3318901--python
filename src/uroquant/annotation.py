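"""Two-dimensional functional-category matrix over a differential table.

Each differentially excreted protein is assigned one "biological
process" subcategory (8 in the default vocabulary) and one "molecular
function" subcategory (13), following the protein-classification scheme
used for urinary proteome annotation. Crossing the two axes gives an
8 x 13 count matrix — the heatmap view — and collapsing along either
axis gives per-subcategory up/down regulation fractions.

The classification database itself is an external resource and is not
bundled; callers supply an accession -> (process, function) mapping.
Vocabularies are user-extensible: the defaults carry the subcategory
names reported for this study design, padded with standard names from
the same classification system's generation.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .filtering import DifferentialTable

__all__ = [
    "DEFAULT_BIOLOGICAL_PROCESSES",
    "DEFAULT_MOLECULAR_FUNCTIONS",
    "AnnotationMap",
    "CategoryMatrix",
    "build_category_matrix",
    "subcategory_regulation_fractions",
    "read_annotation_map",
    "plot_category_heatmap",
]

#: Default "biological process" vocabulary (8 subcategories).
DEFAULT_BIOLOGICAL_PROCESSES: tuple[str, ...] = (
    "immunity and defense",
    "protein metabolism",
    "carbohydrate metabolism",
    "lipid metabolism",
    "signal transduction",
    "transport",
    "cell adhesion",
    "developmental processes",
)

#: Default "molecular function" vocabulary (13 subcategories).
DEFAULT_MOLECULAR_FUNCTIONS: tuple[str, ...] = (
    "immunity protein",
    "receptor",
    "signaling molecule",
    "protease",
    "protease inhibitor",
    "transfer/carrier protein",
    "transporter",
    "cell adhesion molecule",
    "cytoskeletal protein",
    "extracellular matrix",
    "hydrolase",
    "oxidoreductase",
    "miscellaneous function",
)


@dataclass(frozen=True)
class AnnotationMap:
    """accession -> (biological-process, molecular-function) subcategories.

    Every annotated accession maps to exactly one subcategory per axis;
    accessions absent from the map are allowed and counted separately.
    """

    assignments: Mapping[str, tuple[str, str]]
    bp_vocabulary: tuple[str, ...] = DEFAULT_BIOLOGICAL_PROCESSES
    mf_vocabulary: tuple[str, ...] = DEFAULT_MOLECULAR_FUNCTIONS

    def __post_init__(self) -> None:
        bp, mf = set(self.bp_vocabulary), set(self.mf_vocabulary)
        if len(bp) != len(self.bp_vocabulary) or len(mf) != len(self.mf_vocabulary):
            raise ValueError("vocabulary subcategory names must be unique")
        for acc, (b, m) in self.assignments.items():
            if b not in bp:
                raise ValueError(f"{acc}: unknown biological-process subcategory {b!r}")
            if m not in mf:
                raise ValueError(f"{acc}: unknown molecular-function subcategory {m!r}")


@dataclass
class CategoryMatrix:
    """Process x function count matrix plus per-subcategory regulation."""

    bp_vocabulary: tuple[str, ...]
    mf_vocabulary: tuple[str, ...]
    counts: np.ndarray  # shape (n_bp, n_mf), ints
    cell_accessions: dict[tuple[str, str], list[str]]
    bp_regulation: dict[str, tuple[int, int]]  # subcategory -> (n_up, n_down)
    mf_regulation: dict[str, tuple[int, int]]
    unannotated: list[str] = field(default_factory=list)

    @property
    def n_annotated(self) -> int:
        return int(self.counts.sum())


def build_category_matrix(
    table: DifferentialTable, annotations: AnnotationMap
) -> CategoryMatrix:
    """Tally each annotated protein into exactly one matrix cell.

    Unannotated proteins are listed separately so that
    ``counts.sum() + len(unannotated) == len(table)`` always holds.
    Cell membership lists are kept in input order; duplicated accessions
    (the same protein under several database entries) each count once
    per row, mirroring how the published tables enumerate entries.
    """
    n_bp, n_mf = len(annotations.bp_vocabulary), len(annotations.mf_vocabulary)
    bp_index = {name: i for i, name in enumerate(annotations.bp_vocabulary)}
    mf_index = {name: j for j, name in enumerate(annotations.mf_vocabulary)}
    counts = np.zeros((n_bp, n_mf), dtype=int)
    cells: dict[tuple[str, str], list[str]] = {}
    bp_reg = {name: [0, 0] for name in annotations.bp_vocabulary}
    mf_reg = {name: [0, 0] for name in annotations.mf_vocabulary}
    unannotated: list[str] = []

    for record, regulation in table:
        pair = annotations.assignments.get(record.accession)
        if pair is None:
            unannotated.append(record.accession)
            continue
        bp, mf = pair
        counts[bp_index[bp], mf_index[mf]] += 1
        cells.setdefault((bp, mf), []).append(record.accession)
        k = 0 if regulation == "up" else 1
        bp_reg[bp][k] += 1
        mf_reg[mf][k] += 1

    return CategoryMatrix(
        bp_vocabulary=annotations.bp_vocabulary,
        mf_vocabulary=annotations.mf_vocabulary,
        counts=counts,
        cell_accessions=cells,
        bp_regulation={k: (v[0], v[1]) for k, v in bp_reg.items()},
        mf_regulation={k: (v[0], v[1]) for k, v in mf_reg.items()},
        unannotated=unannotated,
    )


def subcategory_regulation_fractions(
    matrix: CategoryMatrix, axis: str = "bp"
) -> dict[str, tuple[float, float]]:
    """Per-subcategory (percent_up, percent_down) for nonempty
    subcategories; the two percentages sum to 100. Empty subcategories
    are omitted (the fraction is undefined)."""
    if axis not in ("bp", "mf"):
        raise ValueError("axis must be 'bp' or 'mf'")
    reg = matrix.bp_regulation if axis == "bp" else matrix.mf_regulation
    out: dict[str, tuple[float, float]] = {}
    for name, (n_up, n_down) in reg.items():
        total = n_up + n_down
        if total == 0:
            continue
        pct_up = 100.0 * n_up / total
        out[name] = (pct_up, 100.0 - pct_up)
    return out


def plot_category_heatmap(matrix: CategoryMatrix, path: str | Path | None = None):
    """Heatmap view of the process x function count matrix.

    Returns the matplotlib Axes; saves to *path* when given. Import is
    deferred so headless pipelines never pay for a plotting backend.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(1.0 + 0.6 * len(matrix.mf_vocabulary), 1.0 + 0.5 * len(matrix.bp_vocabulary))
    )
    im = ax.imshow(matrix.counts, cmap="viridis", aspect="auto")
    ax.set_xticks(range(len(matrix.mf_vocabulary)), matrix.mf_vocabulary, rotation=60, ha="right")
    ax.set_yticks(range(len(matrix.bp_vocabulary)), matrix.bp_vocabulary)
    ax.set_xlabel("molecular function")
    ax.set_ylabel("biological process")
    fig.colorbar(im, ax=ax, label="proteins")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return ax


def read_annotation_map(
    path: str | Path,
    bp_vocabulary: Sequence[str] = DEFAULT_BIOLOGICAL_PROCESSES,
    mf_vocabulary: Sequence[str] = DEFAULT_MOLECULAR_FUNCTIONS,
) -> AnnotationMap:
    """Read a tab-separated (accession, bp_subcategory, mf_subcategory)
    mapping with a one-line header."""
    assignments: dict[str, tuple[str, str]] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != ["accession", "bp_subcategory", "mf_subcategory"]:
            raise ValueError(f"unexpected annotation header {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 3:
                raise ValueError(f"{path}, line {lineno}: expected 3 fields, got {len(row)}")
            acc, bp, mf = row
            if acc in assignments:
                raise ValueError(f"{path}, line {lineno}: duplicate accession {acc!r}")
            assignments[acc] = (bp, mf)
    return AnnotationMap(assignments, tuple(bp_vocabulary), tuple(mf_vocabulary))
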