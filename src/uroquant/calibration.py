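"""Fold-change cutoff calibration from technical replicates.

A technical replicate labels the same pooled sample with two different
reporter channels, so any deviation of the replicate ratio pair from
equality is pure measurement noise. The calibration matches proteins
quantified in both replicates, computes each pair's % variation

    100 * |r1 - r2| / ((r1 + r2) / 2),

and converts a chosen quantile q of that distribution (default the 90th
percentile) into a symmetric significance band: ratios above
``1 + q/100`` or below its reciprocal are larger than what measurement
noise alone produces. With a 90th percentile of 25% this yields the
familiar 1.25 / 0.80 band.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .filtering import FilterCriteria
from .itraq import ProteinQuantRecord

__all__ = [
    "ReplicatePair",
    "CutoffCalibration",
    "match_common_proteins",
    "percent_variation",
    "replicate_correlation",
    "derive_fold_change_cutoffs",
    "calibrate",
]


@dataclass(frozen=True)
class ReplicatePair:
    """One protein's MA:NA ratio measured in two technical replicates."""

    accession: str
    ratio_rep1: float
    ratio_rep2: float
    channel_label: str = ""

    def __post_init__(self) -> None:
        if not (self.ratio_rep1 > 0 and self.ratio_rep2 > 0):
            raise ValueError("replicate ratios must be > 0")


@dataclass(frozen=True)
class CutoffCalibration:
    """Result of a replicate calibration run."""

    percent_variations: tuple[float, ...]
    r_squared: float | None
    quantile: float
    upper_cutoff: float
    lower_cutoff: float

    def rounded_cutoffs(self) -> tuple[float, float]:
        """Cutoffs at the 2-decimal reporting precision."""
        return round(self.upper_cutoff, 2), round(self.lower_cutoff, 2)


def match_common_proteins(
    table1: Sequence[ProteinQuantRecord],
    table2: Sequence[ProteinQuantRecord],
    criteria: FilterCriteria = FilterCriteria(),
    channel_label: str = "",
) -> list[ReplicatePair]:
    """Pair proteins quantified in both replicate tables.

    Only proteins passing the evidence gates (unique-peptide count and
    P value) in *both* tables are selected; effect-size gates do not
    apply here, since the point is to measure noise around equality.
    Output is ordered by accession.
    """
    by_acc1: dict[str, ProteinQuantRecord] = {}
    for rec in table1:
        if rec.accession in by_acc1:
            raise ValueError(f"duplicate accession {rec.accession!r} in replicate table 1")
        by_acc1[rec.accession] = rec
    by_acc2: dict[str, ProteinQuantRecord] = {}
    for rec in table2:
        if rec.accession in by_acc2:
            raise ValueError(f"duplicate accession {rec.accession!r} in replicate table 2")
        by_acc2[rec.accession] = rec

    pairs: list[ReplicatePair] = []
    for acc in sorted(set(by_acc1) & set(by_acc2)):
        r1, r2 = by_acc1[acc], by_acc2[acc]
        if criteria.passes_evidence(r1) and criteria.passes_evidence(r2):
            pairs.append(ReplicatePair(acc, r1.ratio_ma_na, r2.ratio_ma_na, channel_label))
    return pairs


def percent_variation(pair: ReplicatePair) -> float:
    """Absolute replicate difference as a percentage of the pair mean."""
    r1, r2 = pair.ratio_rep1, pair.ratio_rep2
    return 100.0 * abs(r1 - r2) / ((r1 + r2) / 2.0)


def replicate_correlation(pairs: Sequence[ReplicatePair], log_space: bool = False) -> float:
    """Squared Pearson correlation r^2 between replicate ratios.

    Computed on raw ratios by default (replicate scatter plots in this
    design plot ratios, not logs); ``log_space`` switches to log10.
    Returns NaN, with a warning-free sentinel, when either coordinate is
    degenerate (zero variance) or fewer than 3 pairs are given.
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 replicate pairs for a correlation")
    x = np.array([p.ratio_rep1 for p in pairs], dtype=float)
    y = np.array([p.ratio_rep2 for p in pairs], dtype=float)
    if log_space:
        x, y = np.log10(x), np.log10(y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def derive_fold_change_cutoffs(
    percent_variations: Sequence[float], quantile: float = 0.90
) -> tuple[float, float]:
    """Convert a % variation distribution into (upper, lower) cutoffs.

    q = the empirical ``quantile`` of the variations (linear
    interpolation between order statistics, endpoints inclusive);
    upper = 1 + q/100 and lower = 1/upper exactly.
    """
    arr = np.asarray(percent_variations, dtype=float)
    if arr.size == 0:
        raise ValueError("empty % variation list")
    if not 0.0 < quantile <= 1.0:
        raise ValueError("quantile must lie in (0, 1]")
    if np.any(arr < 0):
        raise ValueError("% variations must be >= 0")
    q = float(np.quantile(arr, quantile, method="linear"))
    upper = 1.0 + q / 100.0
    return upper, 1.0 / upper


def calibrate(
    pairs: Sequence[ReplicatePair], quantile: float = 0.90
) -> CutoffCalibration:
    """Full calibration from matched replicate pairs."""
    variations = tuple(percent_variation(p) for p in pairs)
    upper, lower = derive_fold_change_cutoffs(variations, quantile)
    r2 = replicate_correlation(pairs) if len(pairs) >= 3 else None
    return CutoffCalibration(variations, r2, quantile, upper, lower)
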