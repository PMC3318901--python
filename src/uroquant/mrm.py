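"""MRM verification: transition m/z, normalization, ROC, marker panels.

Multiple reaction monitoring (MRM) verifies candidate biomarkers on a
triple quadrupole: each assay is a Q1 (precursor) -> Q3 (fragment)
transition for a proteotypic peptide. This module recomputes transition
m/z values from sequence (monoisotopic, label-free samples),

    precursor m/z = (sum residue masses + water + z * proton) / z,
    y_k m/z       = (sum of k C-terminal residue masses + water
                     + z_f * proton) / z_f,

normalizes transition peak areas to a spiked internal standard
(beta-galactosidase peptide, Q1/Q3 542.3/636.3 by convention in this
assay), and evaluates markers singly and in combination by ROC
analysis. The AUC is computed by trapezoidal integration over all
distinct score thresholds with ties contributing half, which equals the
normalized Mann-Whitney U statistic: the probability that a random
microalbuminuric (MA) sample outscores a random normoalbuminuric (NA)
one.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .masses import CANONICAL_RESIDUES, PROTON, WATER, residue_mass_sum

__all__ = [
    "INTERNAL_STANDARD_Q1",
    "INTERNAL_STANDARD_Q3",
    "Peptide",
    "Transition",
    "PeakAreaRecord",
    "RocResult",
    "PanelModel",
    "TransitionFinding",
    "precursor_mz",
    "y_ion_mz",
    "validate_transition_table",
    "normalize_area",
    "roc_curve",
    "marker_scores",
    "marker_roc",
    "panel_matrix",
    "fit_panel",
    "read_transition_table",
    "read_peak_area_table",
    "write_peak_area_table",
    "load_reference_transitions",
]

#: Spiked beta-galactosidase internal-standard transition (m/z), stored as
#: printed in the assay design; the peptide sequence behind it is not part
#: of the published design and is configurable where needed.
INTERNAL_STANDARD_Q1 = 542.3
INTERNAL_STANDARD_Q3 = 636.3


@dataclass(frozen=True)
class Peptide:
    sequence: str
    charge: int

    def __post_init__(self) -> None:
        if not self.sequence or not set(self.sequence) <= CANONICAL_RESIDUES:
            raise ValueError(f"invalid peptide sequence {self.sequence!r}")
        if self.charge not in (1, 2, 3, 4):
            raise ValueError(f"charge must be in 1..4, got {self.charge}")


@dataclass(frozen=True)
class Transition:
    """One Q1/Q3 MRM transition for a proteotypic peptide."""

    analyte_name: str
    peptide: Peptide
    q1_mz: float
    q3_mz: float
    fragment_label: str  # e.g. "y6"
    collision_energy: float

    def __post_init__(self) -> None:
        if not (self.q1_mz > 0 and self.q3_mz > 0):
            raise ValueError("q1_mz and q3_mz must be > 0")
        if not self.fragment_label.startswith("y"):
            raise ValueError(f"only y-type fragments are supported, got {self.fragment_label!r}")
        length = int(self.fragment_label[1:])
        if not 1 <= length < len(self.peptide.sequence):
            raise ValueError(
                f"fragment {self.fragment_label} out of range for {self.peptide.sequence!r}"
            )

    @property
    def fragment_length(self) -> int:
        return int(self.fragment_label[1:])


@dataclass(frozen=True)
class PeakAreaRecord:
    """One transition's integrated peak area in one sample."""

    sample_id: str
    group: str  # "NA" or "MA"
    analyte_name: str
    transition_id: str
    peak_area: float
    internal_standard_area: float

    def __post_init__(self) -> None:
        if self.group not in ("NA", "MA"):
            raise ValueError(f"group must be 'NA' or 'MA', got {self.group!r}")
        if self.peak_area < 0:
            raise ValueError("peak_area must be >= 0")
        if not self.internal_standard_area > 0:
            raise ValueError("internal_standard_area must be > 0")


def precursor_mz(peptide: Peptide) -> float:
    """Monoisotopic precursor m/z for a multiply protonated peptide."""
    return (residue_mass_sum(peptide.sequence) + WATER + peptide.charge * PROTON) / peptide.charge


def y_ion_mz(peptide: Peptide, y_length: int, fragment_charge: int = 1) -> float:
    """Monoisotopic m/z of the y_k fragment (k C-terminal residues)."""
    if not 1 <= y_length < len(peptide.sequence):
        raise ValueError(
            f"y_length must lie in [1, {len(peptide.sequence) - 1}], got {y_length}"
        )
    if fragment_charge < 1:
        raise ValueError("fragment_charge must be >= 1")
    tail = peptide.sequence[-y_length:]
    return (residue_mass_sum(tail) + WATER + fragment_charge * PROTON) / fragment_charge


@dataclass(frozen=True)
class TransitionFinding:
    """A printed-versus-computed m/z deviation; a finding, not a failure."""

    analyte_name: str
    sequence: str
    which: str  # "q1" or "q3"
    printed_mz: float
    computed_mz: float

    @property
    def deviation(self) -> float:
        return self.printed_mz - self.computed_mz


def validate_transition_table(
    transitions: Sequence[Transition], tolerance_mz: float = 0.25
) -> list[TransitionFinding]:
    """Recompute every Q1/Q3 from sequence; report rows deviating beyond
    ``tolerance_mz``. Discrepancies are findings about the printed table
    (typos, rounding, mislabeled fragments), never exceptions."""
    if not tolerance_mz > 0:
        raise ValueError("tolerance_mz must be > 0")
    findings: list[TransitionFinding] = []
    for tr in transitions:
        q1 = precursor_mz(tr.peptide)
        if abs(q1 - tr.q1_mz) > tolerance_mz:
            findings.append(
                TransitionFinding(tr.analyte_name, tr.peptide.sequence, "q1", tr.q1_mz, q1)
            )
        q3 = y_ion_mz(tr.peptide, tr.fragment_length)
        if abs(q3 - tr.q3_mz) > tolerance_mz:
            findings.append(
                TransitionFinding(tr.analyte_name, tr.peptide.sequence, "q3", tr.q3_mz, q3)
            )
    return findings


def normalize_area(record: PeakAreaRecord) -> float:
    """Peak area relative to the spiked internal standard."""
    return record.peak_area / record.internal_standard_area


@dataclass
class RocResult:
    """ROC curve of one score against the MA/NA grouping."""

    auc: float
    thresholds: np.ndarray
    sensitivity: np.ndarray  # fraction of MA above each threshold
    specificity: np.ndarray  # fraction of NA at or below each threshold
    optimal_cutoff: float
    sens_at_optimal: float  # percent
    spec_at_optimal: float  # percent
    n_positive: int
    n_negative: int
    degenerate: bool = False
    flipped: bool = False


def roc_curve(
    scores_positive: Sequence[float], scores_negative: Sequence[float]
) -> RocResult:
    """ROC analysis of positives (MA) against negatives (NA).

    A sample is called positive when its score exceeds the cutoff.
    The AUC is the trapezoidal area over all distinct thresholds; tied
    scores contribute half, so the value equals the tie-corrected
    Mann-Whitney statistic. The operating cutoff maximizes Youden's
    J = sensitivity + specificity - 1, ties broken toward higher
    specificity (the higher cutoff).
    """
    pos = np.asarray(scores_positive, dtype=float)
    neg = np.asarray(scores_negative, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both groups must be nonempty")

    thresholds = np.unique(np.concatenate([pos, neg]))[::-1]
    sens = np.array([(pos > t).mean() for t in thresholds])
    spec = np.array([(neg <= t).mean() for t in thresholds])
    fpr = 1.0 - spec

    # trapezoid over (0,0) .. curve points .. (1,1)
    xs = np.concatenate([[0.0], fpr, [1.0]])
    ys = np.concatenate([[0.0], sens, [1.0]])
    auc = float(np.trapezoid(ys, xs))

    degenerate = thresholds.size == 1
    j = sens + spec - 1.0
    best = int(np.argmax(j))  # first occurrence = highest threshold = highest specificity
    return RocResult(
        auc=auc,
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        optimal_cutoff=float(thresholds[best]),
        sens_at_optimal=float(100.0 * sens[best]),
        spec_at_optimal=float(100.0 * spec[best]),
        n_positive=int(pos.size),
        n_negative=int(neg.size),
        degenerate=degenerate,
    )


def marker_scores(
    records: Iterable[PeakAreaRecord], analyte_name: str
) -> tuple[pd.Series, pd.Series]:
    """Per-sample normalized score for one analyte, split by group.

    A sample's score is the mean internal-standard-normalized area over
    that analyte's transitions. Returns (ma_scores, na_scores) indexed
    by sample id.
    """
    rows = [
        (r.sample_id, r.group, normalize_area(r))
        for r in records
        if r.analyte_name == analyte_name
    ]
    if not rows:
        raise ValueError(f"no peak areas for analyte {analyte_name!r}")
    df = pd.DataFrame(rows, columns=["sample_id", "group", "normalized"])
    groups = df.groupby("sample_id")["group"].nunique()
    if (groups > 1).any():
        raise ValueError("a sample id appears under both group labels")
    per_sample = df.groupby(["group", "sample_id"])["normalized"].mean()
    ma = per_sample.get("MA", pd.Series(dtype=float))
    na = per_sample.get("NA", pd.Series(dtype=float))
    return ma, na


def marker_roc(
    records: Iterable[PeakAreaRecord], analyte_name: str, auto_flip: bool = True
) -> RocResult:
    """Single-marker ROC with MA as the positive class.

    Some markers are excreted less, not more, in MA urine; with
    ``auto_flip`` the score direction is inverted (negated) when the raw
    AUC falls below 0.5, and the result is marked ``flipped``.
    """
    ma, na = marker_scores(records, analyte_name)
    result = roc_curve(ma.to_numpy(), na.to_numpy())
    if auto_flip and result.auc < 0.5:
        result = roc_curve(-ma.to_numpy(), -na.to_numpy())
        result.flipped = True
    return result


@dataclass
class PanelModel:
    """Multi-marker panel: a logistic score over log normalized areas."""

    marker_names: list[str]
    method: str  # "logistic" or "rank_sum" (separation fallback)
    coefficients: dict[str, float] | None
    scores: pd.Series  # per-sample panel score
    labels: pd.Series  # per-sample group ("NA"/"MA")
    roc: RocResult
    n_dropped_samples: int = 0


def panel_matrix(
    records: Iterable[PeakAreaRecord], markers: Sequence[str]
) -> tuple[pd.DataFrame, pd.Series]:
    """Sample x marker matrix of normalized areas plus group labels.

    Samples missing any requested marker are dropped (complete-case
    rule); the count of dropped samples is reported by ``fit_panel``.
    """
    frames = {}
    labels: dict[str, str] = {}
    for m in markers:
        ma, na = marker_scores(records, m)
        frames[m] = pd.concat([ma, na])
        labels.update({s: "MA" for s in ma.index})
        labels.update({s: "NA" for s in na.index})
    X = pd.DataFrame(frames)
    y = pd.Series(labels, name="group").reindex(X.index)
    return X, y


def fit_panel(
    records: Iterable[PeakAreaRecord] | pd.DataFrame,
    markers: Sequence[str] | None = None,
    labels: pd.Series | None = None,
) -> PanelModel:
    """Combine markers into one panel score and evaluate it by ROC.

    Accepts either raw peak-area records plus marker names, or a
    prebuilt sample x marker matrix of normalized areas with labels.
    Areas are log10-transformed (zeros replaced by half the smallest
    positive value per marker) and combined by a maximum-likelihood
    logistic regression for MA membership; the fitted linear predictor
    is the panel score. Under complete separation the likelihood
    diverges, so the model falls back to a rank-sum score (sum of
    per-marker ranks, each oriented toward MA) with a warning.
    """
    if isinstance(records, pd.DataFrame):
        if labels is None:
            raise ValueError("labels are required with a prebuilt matrix")
        X, y = records.copy(), labels.reindex(records.index)
        markers = list(X.columns) if markers is None else list(markers)
        X = X[markers]
    else:
        if markers is None or len(markers) == 0:
            raise ValueError("marker names are required with raw records")
        records = list(records)
        X, y = panel_matrix(records, list(markers))
        markers = list(markers)
    if len(markers) < 2:
        raise ValueError("a panel needs at least 2 markers")

    complete = X.notna().all(axis=1) & y.notna()
    n_dropped = int((~complete).sum())
    X, y = X.loc[complete], y.loc[complete]
    if y.nunique() != 2:
        raise ValueError("panel fitting needs both NA and MA samples")

    logX = pd.DataFrame(index=X.index, columns=markers, dtype=float)
    for m in markers:
        col = X[m].to_numpy(dtype=float)
        positive = col[col > 0]
        if positive.size == 0:
            raise ValueError(f"marker {m!r} has no positive normalized areas")
        floor = positive.min() / 2.0
        logX[m] = np.log10(np.where(col > 0, col, floor))

    y01 = (y == "MA").astype(int)
    design = sm.add_constant(logX.to_numpy(), has_constant="add")

    coefficients: dict[str, float] | None = None
    method = "logistic"
    score_values: np.ndarray
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error")  # treat separation warnings as failures
            fit = sm.Logit(y01.to_numpy(), design).fit(disp=0, maxiter=200)
        if not np.all(np.isfinite(fit.params)) or np.max(np.abs(fit.params[1:])) > 1e3:
            raise ValueError("diverging coefficients (separation)")
        coefficients = {"intercept": float(fit.params[0])}
        coefficients.update({m: float(b) for m, b in zip(markers, fit.params[1:])})
        score_values = design @ fit.params
    except Exception:
        warnings.warn(
            "complete separation in logistic panel fit; falling back to rank-sum score",
            stacklevel=2,
        )
        method = "rank_sum"
        ranks = np.zeros(len(logX))
        for m in markers:
            col = stats.rankdata(logX[m].to_numpy())
            auc_m = roc_curve(logX.loc[y01 == 1, m], logX.loc[y01 == 0, m]).auc
            ranks += col if auc_m >= 0.5 else -col
        score_values = ranks

    scores = pd.Series(score_values, index=X.index, name="panel_score")
    roc = roc_curve(scores[y01 == 1].to_numpy(), scores[y01 == 0].to_numpy())
    return PanelModel(
        marker_names=markers,
        method=method,
        coefficients=coefficients,
        scores=scores,
        labels=y,
        roc=roc,
        n_dropped_samples=n_dropped,
    )


_TRANSITION_COLUMNS = ["protein", "q1_mz", "q3_mz", "sequence", "fragment", "charge", "collision_energy"]


def read_transition_table(path: str | Path) -> list[Transition]:
    """Read a tab-separated transition list (protein, q1, q3, sequence,
    fragment, charge, collision energy)."""
    out: list[Transition] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames != _TRANSITION_COLUMNS:
            raise ValueError(f"unexpected transition header {reader.fieldnames}")
        for row in reader:
            out.append(
                Transition(
                    analyte_name=row["protein"],
                    peptide=Peptide(row["sequence"], int(row["charge"])),
                    q1_mz=float(row["q1_mz"]),
                    q3_mz=float(row["q3_mz"]),
                    fragment_label=row["fragment"],
                    collision_energy=float(row["collision_energy"]),
                )
            )
    return out


def load_reference_transitions() -> list[Transition]:
    """The packaged 18-transition reference list for the seven verified
    urinary candidates (transferrin, ceruloplasmin, alpha-1-antitrypsin,
    haptoglobin, vitamin D-binding protein, alpha-1-acid glycoprotein 1,
    prostate stem cell antigen)."""
    ref = resources.files("uroquant.data") / "mrm_transitions.tsv"
    with resources.as_file(ref) as path:
        return read_transition_table(path)


_AREA_COLUMNS = ["sample_id", "group", "analyte", "transition", "peak_area", "internal_standard_area"]


def read_peak_area_table(path: str | Path) -> list[PeakAreaRecord]:
    out: list[PeakAreaRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames != _AREA_COLUMNS:
            raise ValueError(f"unexpected peak-area header {reader.fieldnames}")
        for row in reader:
            out.append(
                PeakAreaRecord(
                    sample_id=row["sample_id"],
                    group=row["group"],
                    analyte_name=row["analyte"],
                    transition_id=row["transition"],
                    peak_area=float(row["peak_area"]),
                    internal_standard_area=float(row["internal_standard_area"]),
                )
            )
    return out


def write_peak_area_table(records: Iterable[PeakAreaRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_AREA_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.sample_id,
                    r.group,
                    r.analyte_name,
                    r.transition_id,
                    repr(float(r.peak_area)),
                    repr(float(r.internal_standard_area)),
                ]
            )
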