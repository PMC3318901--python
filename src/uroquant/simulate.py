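"""Synthetic study generators with known ground truth.

Three generators emulate the data the pipeline consumes, each with the
statistical structure of its real counterpart:

* pooled NA/MA isobaric experiments — per-peptide reporter intensities
  with multiplicative log-normal noise around channel means set by each
  protein's true MA:NA fold change (114/116 carry the NA pool, 115/117
  the MA pool);
* technical replicate pairs — the same ratio table measured twice with
  independent log-normal noise, with the noise scale solved by bisection
  so the chosen quantile of the % variation distribution hits a
  requested target;
* two-group MRM cohorts — per-marker log normalized areas normal with
  group mean difference delta and unit variance, so the true AUC is the
  binormal value Phi(delta / sqrt(2)).

Every generator takes a mandatory seed and draws from its own
independent stream, so adding one generator call never perturbs
another's output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
from scipy import stats

from .itraq import ProteinQuantRecord, ReporterRecord
from .mrm import PeakAreaRecord

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "delta_for_auc",
    "simulate_itraq_experiment",
    "simulate_technical_replicates",
    "simulate_mrm_cohort",
]

# residues used to mint unique peptide sequences (no K/R: those are
# appended as the tryptic terminus so the labeling-site count is exact)
_SEQ_ALPHABET = "ACDEFGHILMNPQSTVWY"


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the generators.

    Defaults mirror the source study design: a pooled two-channel
    comparison with ~20% peptide-level CV, labeling efficiency above
    98% (failure rate 0.01), peptide confidence mostly above the 95%
    gate, a replicate calibration targeting 25% at the 90th percentile,
    and an MRM cohort of 9 NA vs 14 MA samples.
    """

    seed: int
    n_proteins: int = 100
    peptides_per_protein: float = 8.0  # mean of a (1 + Poisson) count
    true_fold_changes: Mapping[str, float] | None = None
    reporter_cv: float = 0.2
    labeling_failure_rate: float = 0.01
    high_confidence_fraction: float = 0.95
    replicate_target_percent: float = 25.0
    replicate_quantile: float = 0.90
    n_na: int = 9
    n_ma: int = 14
    marker_effect_sizes: Mapping[str, float] = field(
        default_factory=lambda: {"A1AT": 1.5, "AGP1": 1.6, "PSCA": 1.3}
    )
    upper_cutoff: float = 1.25
    lower_cutoff: float = 0.80

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if self.peptides_per_protein < 1:
            raise ValueError("peptides_per_protein must be >= 1")
        if not self.reporter_cv >= 0:
            raise ValueError("reporter_cv must be >= 0")
        if not 0.0 <= self.labeling_failure_rate <= 1.0:
            raise ValueError("labeling_failure_rate must lie in [0, 1]")
        if not 0.0 <= self.high_confidence_fraction <= 1.0:
            raise ValueError("high_confidence_fraction must lie in [0, 1]")
        if not 0.0 <= self.replicate_target_percent < 200.0:
            raise ValueError("replicate_target_percent must lie in [0, 200)")
        if not 0.0 < self.replicate_quantile <= 1.0:
            raise ValueError("replicate_quantile must lie in (0, 1]")
        if self.n_na < 1 or self.n_ma < 1:
            raise ValueError("cohort sizes must be >= 1")
        if self.true_fold_changes is not None and any(
            f <= 0 for f in self.true_fold_changes.values()
        ):
            raise ValueError("true fold changes must be > 0")
        for name, d in self.marker_effect_sizes.items():
            if not np.isfinite(d):
                raise ValueError(f"effect size for {name!r} must be finite")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator knows that the pipeline must recover."""

    fold_changes: dict[str, float]
    regulation: dict[str, Literal["up", "down", "none"]]
    marker_true_auc: dict[str, float]
    cutoff_target: tuple[float, float] | None = None


def delta_for_auc(auc: float) -> float:
    """Standardized group difference delta with binormal AUC = Phi(delta/sqrt 2)."""
    if not 0.0 < auc < 1.0:
        raise ValueError("auc must lie in (0, 1)")
    return math.sqrt(2.0) * float(stats.norm.ppf(auc))


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # independent stream per generator: same seed never couples generators
    return np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(stream,)))


def _regulation(f: float, upper: float, lower: float) -> Literal["up", "down", "none"]:
    if f > upper:
        return "up"
    if f < lower:
        return "down"
    return "none"


def _mint_sequence(rng: np.random.Generator, counter: int, body_length: int = 7) -> str:
    """Unique tryptic-looking sequence: random body + base-18 counter tail
    + K/R terminus. The counter digits guarantee global uniqueness."""
    body = "".join(rng.choice(list(_SEQ_ALPHABET), size=body_length))
    digits = []
    n = counter
    for _ in range(5):
        digits.append(_SEQ_ALPHABET[n % len(_SEQ_ALPHABET)])
        n //= len(_SEQ_ALPHABET)
    terminus = "K" if rng.random() < 0.5 else "R"
    return body + "".join(digits) + terminus


def simulate_itraq_experiment(
    config: SimulationConfig,
) -> tuple[list[ReporterRecord], GroundTruth]:
    """Pooled NA/MA reporter table with known per-protein fold changes.

    Channels 114/116 fluctuate log-normally around each protein's basal
    abundance, 115/117 around basal x fold-change, with the per-channel
    noise scaled so each peptide's MA:NA ratio (115/114 or 117/116) has
    multiplicative CV ``reporter_cv``. Labeled-site counts
    are binomial with rate 1 - labeling_failure_rate; peptide
    confidences exceed the 95% gate for ``high_confidence_fraction`` of
    spectra. In the reporter_cv -> 0 limit every peptide ratio equals
    its protein's true fold change exactly.
    """
    rng = _rng(config, stream=1)
    if config.true_fold_changes is not None:
        fold_changes = dict(config.true_fold_changes)
    else:
        # thirds: clearly up, clearly down, inside the null band
        fold_changes = {}
        for i in range(config.n_proteins):
            acc = f"SIM{i + 1:04d}"
            kind = i % 3
            if kind == 0:
                fold_changes[acc] = float(np.exp(rng.uniform(np.log(1.5), np.log(3.0))))
            elif kind == 1:
                fold_changes[acc] = float(np.exp(rng.uniform(np.log(1 / 3.0), np.log(1 / 1.5))))
            else:
                fold_changes[acc] = 1.0

    # reporter_cv is the multiplicative CV of a peptide's channel-pair
    # ratio; each channel carries sigma/sqrt(2) of log noise so the ratio
    # of two channels has log-sd sigma
    sigma = math.sqrt(math.log(1.0 + config.reporter_cv**2)) / math.sqrt(2.0)
    records: list[ReporterRecord] = []
    counter = 0
    for acc, f in fold_changes.items():
        basal = float(10.0 ** rng.uniform(3.0, 6.0))
        n_peptides = 1 + rng.poisson(config.peptides_per_protein - 1.0)
        for _ in range(n_peptides):
            seq = _mint_sequence(rng, counter)
            counter += 1
            n_possible = 1 + seq.count("K")
            noise = np.exp(rng.normal(0.0, sigma, size=4)) if sigma > 0 else np.ones(4)
            means = np.array([basal, basal * f, basal, basal * f])
            intensities = means * noise
            if rng.random() < config.high_confidence_fraction:
                conf = float(rng.uniform(95.0, 100.0))
            else:
                conf = float(rng.uniform(50.0, 95.0))
            records.append(
                ReporterRecord(
                    spectrum_id=f"sp{counter:06d}",
                    peptide_sequence=seq,
                    protein_accession=acc,
                    confidence_percent=conf,
                    intensity_114=float(intensities[0]),
                    intensity_115=float(intensities[1]),
                    intensity_116=float(intensities[2]),
                    intensity_117=float(intensities[3]),
                    n_labeled_sites=int(rng.binomial(n_possible, 1.0 - config.labeling_failure_rate)),
                    n_possible_sites=n_possible,
                )
            )

    truth = GroundTruth(
        fold_changes=fold_changes,
        regulation={
            acc: _regulation(f, config.upper_cutoff, config.lower_cutoff)
            for acc, f in fold_changes.items()
        },
        marker_true_auc={},
        cutoff_target=(config.upper_cutoff, config.lower_cutoff),
    )
    return records, truth


def _percent_variation_from_logdiff(d: np.ndarray) -> np.ndarray:
    # 200|r1-r2|/(r1+r2) depends on the pair only through d = log r1 - log r2
    return 200.0 * np.tanh(np.abs(d) / 2.0)


def simulate_technical_replicates(
    config: SimulationConfig,
) -> tuple[list[ProteinQuantRecord], list[ProteinQuantRecord]]:
    """Two quantitation tables of the same proteins differing only by noise.

    Both replicates observe the same true ratio per protein under
    independent multiplicative log-normal noise exp(sigma * z). The pair's
    % variation depends only on the log-ratio difference d through
    200 * tanh(|d| / 2), which is strictly increasing in sigma for fixed
    draws, so sigma is solved by bisection until the empirical
    ``replicate_quantile`` of the % variations equals
    ``replicate_target_percent``. A target of 0 returns noise-free
    replicates.
    """
    rng = _rng(config, stream=2)
    n = config.n_proteins
    accs = [f"SIM{i + 1:04d}" for i in range(n)]
    # spread of true ratios across proteins (log-e scale 0.5 ~ ratios 0.4-2.7,
    # the range real pooled replicate tables span); sets r-squared realism
    true_log = rng.normal(0.0, 0.5, size=n)
    z1 = rng.normal(size=n)
    z2 = rng.normal(size=n)
    target = config.replicate_target_percent
    q = config.replicate_quantile

    if target == 0.0:
        sigma = 0.0
    else:
        diff = z1 - z2
        if np.ptp(np.abs(diff)) == 0 and np.all(diff == 0):
            raise ValueError("degenerate noise draws; cannot attain a nonzero target")

        def quant_at(s: float) -> float:
            return float(np.quantile(_percent_variation_from_logdiff(s * diff), q))

        lo, hi = 0.0, 1.0
        while quant_at(hi) < target:
            hi *= 2.0
            if hi > 1e6:
                raise ValueError(f"% variation target {target} unattainable")
        for _ in range(200):
            mid = (lo + hi) / 2.0
            if quant_at(mid) < target:
                lo = mid
            else:
                hi = mid
        sigma = (lo + hi) / 2.0

    r1 = np.exp(true_log + sigma * z1)
    r2 = np.exp(true_log + sigma * z2)
    n_peptides = 2 + rng.poisson(3.0, size=n)

    def table(ratios: np.ndarray) -> list[ProteinQuantRecord]:
        return [
            ProteinQuantRecord(
                accession=acc,
                protein_name=acc,
                n_unique_peptides=int(k),
                ratio_ma_na=float(r),
                p_value=0.001,  # evidence gates are not under test here
                ef=1.1,
            )
            for acc, r, k in zip(accs, ratios, n_peptides)
        ]

    return table(r1), table(r2)


def simulate_mrm_cohort(config: SimulationConfig) -> tuple[list[PeakAreaRecord], GroundTruth]:
    """Two-group MRM peak-area cohort with known per-marker true AUCs.

    Per marker, log normalized areas are N(0, 1) for NA and
    N(delta, 1) for MA, so the true AUC is Phi(delta / sqrt 2).
    Internal-standard areas are drawn log-normally around 1e5 counts and
    peak areas are reconstructed as normalized x standard, so the
    pipeline's normalization step is genuinely exercised.
    """
    rng = _rng(config, stream=3)
    records: list[PeakAreaRecord] = []
    samples = [(f"NA{i + 1:03d}", "NA") for i in range(config.n_na)] + [
        (f"MA{i + 1:03d}", "MA") for i in range(config.n_ma)
    ]
    for marker, delta in config.marker_effect_sizes.items():
        for sample_id, group in samples:
            mean = delta if group == "MA" else 0.0
            log_norm = rng.normal(mean, 1.0)
            is_area = float(np.exp(rng.normal(np.log(1e5), 0.1)))
            records.append(
                PeakAreaRecord(
                    sample_id=sample_id,
                    group=group,
                    analyte_name=marker,
                    transition_id=f"{marker}_t1",
                    peak_area=float(np.exp(log_norm) * is_area),
                    internal_standard_area=is_area,
                )
            )
    truth = GroundTruth(
        fold_changes={},
        regulation={},
        marker_true_auc={
            m: float(stats.norm.cdf(d / math.sqrt(2.0)))
            for m, d in config.marker_effect_sizes.items()
        },
    )
    return records, truth
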