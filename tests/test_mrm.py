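"""Transition m/z computation, ROC analysis, and panel combination."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from pyteomics import mass as pyteomics_mass
from sklearn.metrics import roc_auc_score

from uroquant.masses import MONOISOTOPIC_RESIDUE_MASS, PROTON
from uroquant.mrm import (
    PeakAreaRecord,
    Peptide,
    Transition,
    fit_panel,
    load_reference_transitions,
    marker_roc,
    normalize_area,
    precursor_mz,
    roc_curve,
    validate_transition_table,
    y_ion_mz,
)


def area_record(sample, group, analyte, area, is_area=1e5, transition="t1"):
    return PeakAreaRecord(sample, group, analyte, transition, area, is_area)


class TestMassCalculator:
    @pytest.mark.parametrize(
        "sequence,charge,expected_q1,decimals",
        [("VVNPTQK", 2, 393.2, 1), ("LSITGTYDLK", 2, 555.81, 2), ("SDVVYTDWK", 2, 556.8, 1)],
    )
    def test_precursor_matches_printed_value(self, sequence, charge, expected_q1, decimals):
        assert round(precursor_mz(Peptide(sequence, charge)), decimals) == expected_q1

    @pytest.mark.parametrize(
        "sequence,y_length,expected_q3",
        [
            ("VVNPTQK", 5, 587.3),
            ("LSITGTYDLK", 9, 997.5),
            ("LSITGTYDLK", 7, 797.4),
            ("SDVVYTDWK", 6, 811.4),
        ],
    )
    def test_y_ion_matches_printed_value(self, sequence, y_length, expected_q3):
        assert round(y_ion_mz(Peptide(sequence, 2), y_length), 1) == expected_q3

    def test_charge_state_identity(self):
        p1 = precursor_mz(Peptide("VVNPTQK", 1))
        p2 = precursor_mz(Peptide("VVNPTQK", 2))
        assert p1 == pytest.approx(2 * p2 - PROTON, abs=1e-9)

    def test_agrees_with_pyteomics_over_reference_list(self):
        # independent mass oracle on every packaged transition
        for tr in load_reference_transitions():
            seq, z = tr.peptide.sequence, tr.peptide.charge
            assert precursor_mz(tr.peptide) == pytest.approx(
                pyteomics_mass.fast_mass(seq, charge=z), abs=2e-3
            )
            k = tr.fragment_length
            assert y_ion_mz(tr.peptide, k) == pytest.approx(
                pyteomics_mass.fast_mass(seq[-k:], ion_type="y", charge=1), abs=2e-3
            )

    def test_telescoping_identity_on_reference_peptides(self):
        # singly protonated peptide mass = y_(n-1) + first residue mass
        for tr in load_reference_transitions():
            seq = tr.peptide.sequence
            whole = precursor_mz(Peptide(seq, 1))
            tail = y_ion_mz(tr.peptide, len(seq) - 1)
            assert whole == pytest.approx(tail + MONOISOTOPIC_RESIDUE_MASS[seq[0]], abs=1e-9)

    def test_unknown_residue_rejected(self):
        with pytest.raises(ValueError):
            Peptide("AVGB", 2)

    def test_y_length_out_of_range(self):
        with pytest.raises(ValueError):
            y_ion_mz(Peptide("AVGK", 2), 4)


class TestValidateTransitionTable:
    def test_acceptance_rows_all_confirm(self):
        findings = validate_transition_table(load_reference_transitions())
        flagged = {(f.sequence, f.which, f.printed_mz) for f in findings}
        assert ("VVNPTQK", "q1", 393.2) not in flagged
        assert ("VVNPTQK", "q3", 587.3) not in flagged
        assert ("LSITGTYDLK", "q1", 555.81) not in flagged
        assert ("SDVVYTDWK", "q3", 811.4) not in flagged

    def test_known_printed_discrepancies_flagged(self):
        # two printed values disagree with the sequence-derived masses:
        # a ceruloplasmin y10 and a duplicated fragment label row
        findings = validate_transition_table(load_reference_transitions())
        flagged = {(f.sequence, f.which, f.printed_mz) for f in findings}
        assert ("GAYPLSIEPIGVR", "q3", 1080.0) in flagged
        assert ("VVNPTQK", "q3", 473.3) in flagged

    def test_empty_table_empty_report(self):
        assert validate_transition_table([]) == []

    def test_injected_error_flagged(self):
        tr = Transition("X", Peptide("LSITGTYDLK", 2), 555.81, 997.5 + 5.0, "y9", 29.0)
        findings = validate_transition_table([tr])
        assert len(findings) == 1 and findings[0].which == "q3"


class TestNormalizeArea:
    def test_unit_and_zero_cases(self):
        assert normalize_area(area_record("s", "NA", "A", 100.0, 100.0)) == 1.0
        assert normalize_area(area_record("s", "NA", "A", 0.0)) == 0.0

    def test_scale_invariance(self):
        a = normalize_area(area_record("s", "NA", "A", 120.0, 400.0))
        b = normalize_area(area_record("s", "NA", "A", 240.0, 800.0))
        assert a == pytest.approx(b)

    def test_zero_standard_rejected(self):
        with pytest.raises(ValueError):
            area_record("s", "NA", "A", 10.0, 0.0)


def pair_counting_auc(pos, neg):
    """Brute-force Mann-Whitney: wins + half-ties over all pairs."""
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocCurve:
    def test_perfect_separation(self):
        assert roc_curve([3.0, 4.0], [1.0, 2.0]).auc == 1.0

    def test_identical_distributions_give_half(self):
        r = roc_curve([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.auc == pytest.approx(0.5)

    def test_all_tied_scores_degenerate(self):
        r = roc_curve([1.0, 1.0], [1.0, 1.0, 1.0])
        assert r.auc == pytest.approx(0.5)
        assert r.degenerate

    def test_toy_vectors_match_pair_counting(self):
        pos = [5.1, 3.3, 4.0, 4.0, 2.2, 6.0]
        neg = [1.0, 4.0, 2.2, 3.0, 0.5]
        r = roc_curve(pos, neg)
        assert r.auc == pytest.approx(pair_counting_auc(pos, neg), abs=1e-12)

    def test_youden_cutoff_prefers_higher_specificity(self):
        # J is maximized at two cutoffs; the higher threshold must win
        pos, neg = [2.0, 3.0, 4.0], [0.0, 1.0]
        r = roc_curve(pos, neg)
        assert r.sens_at_optimal == pytest.approx(100.0)
        assert r.spec_at_optimal == pytest.approx(100.0)
        assert r.optimal_cutoff == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([], [1.0])

    @given(st.data())
    @settings(deadline=None, max_examples=300)
    def test_pair_counting_and_sklearn_equivalence(self, data):
        # ties forced via a small integer score range
        pos = data.draw(st.lists(st.integers(0, 8), min_size=1, max_size=20))
        neg = data.draw(st.lists(st.integers(0, 8), min_size=1, max_size=20))
        auc = roc_curve(pos, neg).auc
        assert auc == pytest.approx(pair_counting_auc(pos, neg), abs=1e-12)
        labels = [1] * len(pos) + [0] * len(neg)
        assert auc == pytest.approx(roc_auc_score(labels, pos + neg), abs=1e-12)

    @given(st.data())
    @settings(deadline=None, max_examples=200)
    def test_complement_and_monotone_invariance(self, data):
        pos = data.draw(st.lists(st.integers(0, 6), min_size=1, max_size=15))
        neg = data.draw(st.lists(st.integers(0, 6), min_size=1, max_size=15))
        auc = roc_curve(pos, neg).auc
        assert auc + roc_curve(neg, pos).auc == pytest.approx(1.0, abs=1e-12)
        # strictly monotone transform: x -> exp(0.7 x) + 3
        f = lambda xs: [float(np.exp(0.7 * x) + 3.0) for x in xs]
        assert roc_curve(f(pos), f(neg)).auc == pytest.approx(auc, abs=1e-12)


class TestMarkerRoc:
    def cohort(self, ma_shift):
        rng = np.random.default_rng(42)
        records = []
        for i in range(12):
            records.append(area_record(f"NA{i}", "NA", "M", float(np.exp(rng.normal(0, 1)) * 1e5)))
        for i in range(12):
            records.append(
                area_record(f"MA{i}", "MA", "M", float(np.exp(rng.normal(ma_shift, 1)) * 1e5))
            )
        return records

    def test_down_regulated_marker_auto_flips(self):
        r = marker_roc(self.cohort(-2.0), "M")
        assert r.flipped and r.auc > 0.5
        raw = marker_roc(self.cohort(-2.0), "M", auto_flip=False)
        assert raw.auc < 0.5
        assert r.auc == pytest.approx(1.0 - raw.auc, abs=1e-12)

    def test_multiple_transitions_averaged_per_sample(self):
        records = [
            area_record("s1", "MA", "M", 200.0, transition="t1"),
            area_record("s1", "MA", "M", 400.0, transition="t2"),
            area_record("s2", "NA", "M", 100.0, transition="t1"),
        ]
        r = marker_roc(records, "M")
        assert r.auc == 1.0  # mean MA score 3e-3 vs NA 1e-3

    def test_unknown_analyte_rejected(self):
        with pytest.raises(ValueError, match="no peak areas"):
            marker_roc([area_record("s", "NA", "M", 1.0)], "missing")


class TestFitPanel:
    def cohort(self, rng, deltas, n=60):
        records = []
        for marker, delta in deltas.items():
            for i in range(n):
                records.append(
                    area_record(f"NA{i}", "NA", marker, float(np.exp(rng.normal(0, 1)) * 1e5))
                )
            for i in range(n):
                records.append(
                    area_record(f"MA{i}", "MA", marker, float(np.exp(rng.normal(delta, 1)) * 1e5))
                )
        return records

    def test_informative_markers_combine_near_or_above_best(self, rng):
        records = self.cohort(rng, {"A": 1.2, "B": 1.4, "C": 1.0}, n=200)
        panel = fit_panel(records, ["A", "B", "C"])
        best = max(marker_roc(records, m).auc for m in "ABC")
        assert panel.method == "logistic"
        assert panel.roc.auc >= best - 0.02

    def test_permuted_labels_give_null_panel(self, rng):
        # the in-sample panel AUC is optimistically biased even under the
        # null, so average over permutations rather than trusting one draw
        records = self.cohort(rng, {"A": 1.2, "B": 1.4}, n=100)
        ids = sorted({r.sample_id for r in records})
        aucs = []
        for _ in range(10):
            perm = dict(
                zip(ids, rng.permutation([("NA" if i < 100 else "MA") for i in range(200)]))
            )
            shuffled = [
                PeakAreaRecord(
                    r.sample_id, perm[r.sample_id], r.analyte_name, r.transition_id,
                    r.peak_area, r.internal_standard_area,
                )
                for r in records
            ]
            aucs.append(fit_panel(shuffled, ["A", "B"]).roc.auc)
        assert abs(np.mean(aucs) - 0.5) <= 0.1

    def test_complete_separation_falls_back_to_rank_sum(self):
        records = []
        for i in range(5):
            records.append(area_record(f"NA{i}", "NA", "A", 100.0 + i))
            records.append(area_record(f"NA{i}", "NA", "B", 100.0 + i))
            records.append(area_record(f"MA{i}", "MA", "A", 900.0 + i))
            records.append(area_record(f"MA{i}", "MA", "B", 900.0 + i))
        with pytest.warns(UserWarning, match="separation"):
            panel = fit_panel(records, ["A", "B"])
        assert panel.method == "rank_sum"
        assert panel.roc.auc == 1.0

    def test_requires_two_markers(self):
        with pytest.raises(ValueError, match="at least 2"):
            fit_panel([area_record("s", "NA", "A", 1.0)], ["A"])
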