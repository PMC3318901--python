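# Methods

## Study design the package models

Two urine pools — normoalbuminuric (NA) and microalbuminuric (MA) type 2
diabetic patients — are digested, labeled with 4-plex isobaric reagents
(NA on reporter channels 114/116, MA on 115/117), and analyzed by MS/MS.
Each peptide-spectrum match contributes four reporter intensities; the
115/114 (or 117/116) ratio estimates the parent protein's MA:NA
abundance ratio. Candidate markers surviving a differential-excretion
filter are then verified label-free by MRM on individual urine samples
(the design cohort is 9 NA vs 14 MA) and ranked by ROC analysis.

## Protein-level quantitation

Peptide ratios are aggregated on log₁₀: the protein ratio is the
unweighted geometric mean of qualifying peptide ratios (peptides at
≥ 95% confidence; peptides shared between proteins excluded by default,
since shared spectra carry ambiguous evidence). The P value is the
two-sided one-sample t-test of the log ratios against 0, and the error
factor is EF = 10^(t₀.₉₇₅,ₙ₋₁ · s/√n), the multiplicative 95%-CI
half-width. The geometric mean was chosen over a weighted mean because
the weighting used by vendor quantitation software is undocumented; an
unweighted log-mean is reproducible and carries transparent error
propagation. Channel-swap symmetry is exact: inverting the ratio
direction inverts the protein ratio and preserves P and EF.

Degenerate inputs: with a single qualifying peptide, P and EF are
undefined (`None`) rather than guessed — such proteins are excluded by
the downstream ≥ 2-peptide gate. With zero sample variance (all peptide
ratios identical, e.g. in noise-free simulation), the t statistic is
undefined; the implementation takes the continuous limit, EF = 1 and
P = 0 for a nonzero mean log-ratio (P = 1 at mean zero). Without this
limit a noise-free dataset — where the evidence for differential
excretion is strongest — would paradoxically be unfilterable.

Isotope-impurity correction solves M·x = observed for the 4×4 channel
crosstalk matrix M; the default is the identity, since lot-specific
impurity factors must come from the manufacturer's certificate. Negative
solutions (inconsistent observations near zero) are clamped to 0 and
counted; the correct→forward round-trip identity is only claimed for
unclamped spectra. Median bias normalization (every ratio divided by the
median ratio) is an explicit optional stage, off by default, because it
is not documented whether published tables of this design are
bias-corrected.

Labeling-site accounting: each peptide offers 1 + (number of lysines)
labeling sites (N-terminus plus K side chains); the efficiency is total
labeled over total possible, and a record whose declared site count
disagrees with its sequence is rejected rather than trusted.

## Cutoff calibration

% variation per replicate pair is 100·|r₁−r₂|/pair mean, computed in
ratio space — the conventional reading, and the one that reproduces the
25% → 1.25/0.80 band self-consistently. The empirical quantile uses
linear interpolation between order statistics; with that convention the
fraction of pairs at or below the quantile value is guaranteed ≥ q − 1/n
(not ≥ q exactly, which would require the `higher` convention).
upper = 1 + q/100 and lower = 1/upper exactly, so the band is symmetric
on the ratio scale. Replicate correlation is reported as r² on raw
ratios (replicate scatter plots in this design are in ratio space); a
log-space option exists but is off by default. Replicate channels can be
calibrated independently; the final band is intended to come from the
pooled variations of both channels.

## Differential filter

Gates: P < max_p (0.05), EF < max_ef (2), unique peptides ≥ 2, ratio
outside (lower, upper). Survivor regulation is classified by ratio
versus 1, not versus the band: published tables of this design contain
rows inside the 0.80–1.25 band, and only the ratio-vs-1 reading yields a
complete up/down partition (the packaged 196-protein reference table
splits exactly 99 up / 97 down this way). Band membership of reference
rows is therefore a warning-level finding, not an error. The
"more than 2 unique peptides" criterion is implemented as ≥ 2 — the
reference table contains many 2-peptide rows — with the literal > 2
available through `min_unique_peptides=3`. Every exclusion carries a
reason code; undefined-statistics rows are excluded and counted, never
silently dropped.

## Category matrix

Each annotated protein occupies exactly one cell of the 8 (biological
process) × 13 (molecular function) matrix; unannotated proteins are
listed separately so the conservation identity
`counts.sum() + unannotated = table size` always holds. Per-subcategory
regulation percentages are over annotated, filtered proteins only and
sum to 100 for every nonempty subcategory. The classification database
is consumed as a mapping file: the 2006-era snapshot used for the
original annotation is unrecoverable, so exact subcategory counts are
annotation-version-dependent and deliberately not asserted anywhere.
The default vocabularies carry the subcategory names reported for this
study design, padded to 8/13 with standard names of the same scheme's
generation; both are constructor arguments.

## MRM

Masses are monoisotopic throughout (proton 1.00728 Da, water
18.01056 Da, standard residue masses in `masses.py`); MRM samples are
label-free so no tag masses enter. Recomputing the packaged 18-row
transition list from sequence confirms 16 printed values at a 0.25 m/z
tolerance and flags two: a y10 printed 0.64 low, and a transition
labeled y5 whose printed mass is the peptide's y4 — findings about the
printed table, reported rather than silently corrected.

ROC: thresholds are the distinct observed scores; sensitivity is the
fraction of MA above threshold, specificity the fraction of NA at or
below. The trapezoidal area with ties contributing half equals the
normalized Mann–Whitney U statistic; this equivalence is enforced by a
pair-counting oracle test. The operating point maximizes Youden's
J = sens + spec − 1, ties broken toward the higher threshold (higher
specificity). Markers whose raw AUC falls below 0.5 (excretion decreases
in MA) are auto-flipped and marked.

Panels: normalized areas (peak area / internal-standard area, averaged
over a marker's transitions per sample) are log₁₀-transformed — zeros
floored at half the marker's smallest positive value — and combined by
maximum-likelihood logistic regression; the fitted linear predictor is
the panel score, whose ROC is the "merged" curve. The combination method
behind merged ROC curves in clinical-statistics software is logistic
scoring, hence the default; it is isolated behind `PanelModel` so an
alternative combiner can be swapped in. Under complete separation
(common at 9-vs-14 cohort sizes with strong markers) the likelihood
diverges and the model falls back to a rank-sum score — the sum of each
marker's within-cohort ranks, oriented toward MA — with a warning. Note
the panel AUC is in-sample and optimistically biased; at these cohort
sizes a null panel averages above 0.5, which the tests account for by
averaging over label permutations.

## Synthetic data

The generators define the study conditions, not tuning knobs:

- **Pooled reporter experiment** — per-protein basal abundance uniform
  in log₁₀ over 10³–10⁶; channel intensities log-normal with the
  per-channel noise scaled so a peptide's channel-pair ratio has
  multiplicative CV `reporter_cv` (default 0.2); true fold changes by
  default a third up (1.5–3×), a third down, a third null; peptide
  counts 1 + Poisson(mean−1) with mean 8; labeling failure rate 0.01
  (efficiency ≈ 99%, matching a > 98% design requirement); 95% of
  spectra above the confidence gate. Peptide sequences embed a base-18
  counter so they are globally unique and their lysine counts are exact.
- **Technical replicates** — one true ratio table (log-sd 0.5 across
  proteins, the spread real pooled replicate tables span) observed twice
  with independent log-normal noise. A pair's % variation depends on the
  draws only through d = log r₁ − log r₂ via 200·tanh(|d|/2), strictly
  increasing in the noise scale, so the scale is solved by bisection
  until the chosen quantile of % variation equals the target (default
  25% at the 90th percentile, the band-defining condition).
- **MRM cohort** — per marker, log normalized areas N(0,1) for NA and
  N(δ,1) for MA, so the true AUC is the binormal Φ(δ/√2);
  `delta_for_auc` inverts this. Internal-standard areas are drawn
  log-normally around 10⁵ counts and peak areas reconstructed as
  normalized × standard, so the normalization step is genuinely
  exercised. Default cohort 9 NA / 14 MA; convergence checks use
  200/group, where the empirical AUC sits within ±0.05 of truth.

Determinism: every generator draws from its own child stream of the
config seed, so outputs are reproducible and mutually independent.
What the generators do **not** emulate: chromatographic effects,
fractionation, correlated peptide noise within a protein, missing
values beyond labeling failure, non-log-normal intensity tails, and
clinical covariates. Passing tests therefore demonstrate correctness of
the statistical machinery under the stated noise model, not performance
on real urine data.

## Problem sizes and numerical choices

The test and acceptance workloads use 100–200 proteins, 200 replicate
pairs, and 200 samples/group — sizes at which the binomial/binormal
sampling error of each recovered quantity is comfortably inside its
stated tolerance (e.g. AUC SE ≈ 0.02 at 200/group against a ±0.05
check). Bisection for the replicate noise scale runs 200 iterations
(interval < 10⁻⁵⁰, i.e. to machine precision); impurity matrices are
rejected as singular below |det| = 10⁻¹²; quantile interpolation is
`numpy`'s linear method; filter gates use strict inequalities exactly as
stated (P = 0.05 fails P < 0.05).

## Known limitations

- The original study's raw spectra, per-patient MRM areas, and
  replicate tables are not public, so its printed r² values, marker
  AUCs (0.762–0.873, merged 0.921), protein counts (710 identified) and
  subcategory percentages cannot be recomputed — the pipeline instead
  demonstrates recovery of such quantities from synthetic cohorts with
  planted truth.
- EF and P assume approximately log-normal peptide ratios; heavy-tailed
  contamination will widen EF but is not explicitly modeled.
- The panel AUC is apparent (in-sample); no cross-validation is built
  in, matching the verification-stage scope.
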