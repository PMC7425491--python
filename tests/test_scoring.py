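"""The immune score and its component terms."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spliceneo.scoring import (
    EpitopeLibrary,
    ScoreComponents,
    ScoredPeptide,
    gapless_alignment_score,
    hydrophobicity_score_H,
    immune_score,
    label_hin,
    logistic,
    predict_binding,
    recognition_probability_R,
)
from spliceneo.predictors import RecordedOutputPredictor

ALLELE = "HLA-A*02:01"


class TestLogistic:
    def test_midpoint_at_two(self):
        assert logistic(2.0) == 0.5

    def test_value_at_zero(self):
        assert logistic(0.0) == pytest.approx(1 / (1 + math.exp(-10)), rel=1e-12)

    def test_symmetry_about_two(self):
        for d in np.arange(0.1, 5.01, 0.1):
            assert logistic(2 - d) + logistic(2 + d) == pytest.approx(1.0, abs=1e-12)

    def test_strictly_decreasing(self):
        xs = np.linspace(-5, 10, 50)
        ys = [logistic(x) for x in xs]
        assert all(a > b for a, b in zip(ys, ys[1:]))


class TestImmuneScore:
    def test_worked_example(self):
        c = ScoreComponents(Rm=0.5, Rn=10.0, M=3, C=0.8, H=0.9, R=0.7)
        expected = 0.8 * logistic(0.5) * (1 - logistic(10.0) / 8) * 0.9 * 0.7
        assert immune_score(c) == pytest.approx(expected, rel=1e-12)
        assert round(immune_score(c), 5) == 0.50372

    def test_zero_processing_zeroes_score(self):
        c = ScoreComponents(Rm=0.5, Rn=10.0, M=3, C=0.0, H=0.9, R=0.7)
        assert immune_score(c) == 0.0

    def test_decreasing_in_rm_increasing_in_m(self):
        base = dict(Rn=1.0, C=0.8, H=0.9, R=0.7)
        assert immune_score(ScoreComponents(Rm=0.5, M=2, **base)) > immune_score(
            ScoreComponents(Rm=1.5, M=2, **base)
        )
        assert immune_score(ScoreComponents(Rm=0.5, M=3, **base)) > immune_score(
            ScoreComponents(Rm=0.5, M=2, **base)
        )

    def test_self_dissimilarity_factor_saturates(self):
        # (1 - L(Rn)/2^M) is in (0, 1] and -> 1 as M grows
        for rn in (0.1, 1.0, 5.0):
            vals = [1 - logistic(rn) / 2**m for m in range(1, 12)]
            assert all(0 < v <= 1 for v in vals)
            assert vals == sorted(vals)
            assert vals[-1] == pytest.approx(1.0, abs=1e-3)

    def test_dissimilar_strong_binder_normal_beats_near_self(self):
        base = dict(Rm=0.5, C=0.8, H=0.9, R=0.7)
        far = ScoreComponents(Rn=10.0, M=6, **base)
        near_self = ScoreComponents(Rn=0.2, M=1, **base)
        assert immune_score(far) > immune_score(near_self)

    def test_components_recompute_to_property(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            c = ScoreComponents(
                Rm=float(rng.uniform(0, 20)), Rn=float(rng.uniform(0, 50)),
                M=int(rng.integers(1, 10)), C=float(rng.uniform(0, 1)),
                H=float(rng.uniform(0, 1)), R=float(rng.uniform(0, 1)),
            )
            assert c.S == pytest.approx(immune_score(c), rel=1e-12)


class TestBindingRetention:
    def test_strict_threshold_at_two(self):
        table = {
            ("AAAAAAAAA", ALLELE): 2.0,
            ("CCCCCCCCC", ALLELE): 1.99,
            ("DDDDDDDDD", ALLELE): 30.0,
        }
        pred = RecordedOutputPredictor(table)
        peptides = [p for p, _ in table]
        results, retained = predict_binding(peptides, [ALLELE], pred)
        assert len(results) == 3
        assert [(r.peptide, r.percent_rank) for r in retained] == [("CCCCCCCCC", 1.99)]

    def test_retained_equals_brute_force_filter(self):
        rng = np.random.default_rng(1)
        peps = [f"{'ACDEFGHIKL'[i]}" * 9 for i in range(10)]
        table = {(p, ALLELE): float(rng.uniform(0, 10)) for p in peps}
        pred = RecordedOutputPredictor(table)
        results, retained = predict_binding(peps, [ALLELE], pred, rank_threshold=2.0)
        brute = {(p, a) for (p, a), r in table.items() if r < 2.0}
        assert {(r.peptide, r.hla_allele) for r in retained} == brute

    def test_invalid_allele_rejected(self):
        with pytest.raises(ValueError, match="allele"):
            predict_binding(["AAAAAAAAA"], ["A0201"], RecordedOutputPredictor({}))


class TestHydrophobicity:
    def test_hydrophobic_beats_charged(self):
        assert hydrophobicity_score_H("I" * 9) > hydrophobicity_score_H("R" * 9)

    def test_invariant_to_non_contact_positions(self):
        # positions 1, 2 and k (1-based) face the MHC groove, not the TCR
        assert hydrophobicity_score_H("AAIIIIIIA") == hydrophobicity_score_H("WWIIIIIIW")

    def test_all_alanine_calibration(self):
        assert hydrophobicity_score_H("A" * 9) == pytest.approx(0.73, abs=1e-9)

    def test_non_canonical_residue_rejected(self):
        with pytest.raises(ValueError):
            hydrophobicity_score_H("AAAAXAAAA")

    @settings(max_examples=200, derandomize=True)
    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=8, max_size=11))
    def test_score_always_in_unit_interval(self, peptide):
        assert 0.0 <= hydrophobicity_score_H(peptide) <= 1.0


class TestRecognition:
    def test_self_epitope_drives_r_to_one(self):
        pep = "SIINFEKLM"
        lib = EpitopeLibrary([("self", pep)])
        assert recognition_probability_R(pep, lib) > 0.999

    def test_unrelated_epitope_drives_r_to_zero(self):
        lib = EpitopeLibrary([("far", "DDDDDDDDD")])
        assert recognition_probability_R("KKKKKKKKK", lib) < 1e-6

    def test_three_epitope_library_matches_closed_form(self):
        pep = "SIINFEKLM"
        epis = [("e1", "SIINFEKLM"), ("e2", "SIINFEKLV"), ("e3", "QQQQQQQQQ")]
        lib = EpitopeLibrary(epis)
        a, k = 26.0, 4.87
        z = sum(
            math.exp(k * (gapless_alignment_score(pep, e) - a)) for _, e in epis
        )
        assert recognition_probability_R(pep, lib, a=a, k_steep=k) == pytest.approx(
            z / (1 + z), rel=1e-9
        )

    def test_unequal_lengths_slide_gaplessly(self):
        # best offset aligns the shared 9-mer; hand sum of BLOSUM62
        # diagonal entries for SIINFEKLM: 4+4+4+6+6+5+5+4+5 = 43
        assert gapless_alignment_score("SIINFEKLM", "AASIINFEKLMAA") == 43.0

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            EpitopeLibrary([])

    def test_library_from_fasta(self, fixture_dir):
        lib = EpitopeLibrary.from_fasta(fixture_dir / "epitopes.fa")
        assert len(lib.sequences) == 15
        assert all(set(s) <= set("ACDEFGHIKLMNPQRSTVWY") for s in lib.sequences)


class TestHinLabel:
    @staticmethod
    def _record(c):
        return ScoredPeptide("AAAAAAAAA", ALLELE, c, "AAAAAAAAC")

    def test_cutoff_is_strict(self):
        # choose components whose score lands exactly on the cutoff
        c_at = ScoreComponents(Rm=2.0, Rn=50.0, M=9, C=2e-8, H=1.0, R=1.0)
        assert immune_score(c_at) == pytest.approx(1e-8, rel=1e-9)
        (rec,) = label_hin([self._record(c_at)], hin_cutoff=immune_score(c_at))
        assert rec.hin is False

    def test_representative_magnitude_is_hin(self):
        c = ScoreComponents(Rm=1.0, Rn=50.0, M=9, C=1.92e-7, H=1.0, R=1.0)
        (rec,) = label_hin([self._record(c)])
        assert 1e-8 < rec.S < 1e-6
        assert rec.hin is True

    def test_all_zero_scores_give_zero_hin(self):
        recs = [
            self._record(ScoreComponents(Rm=5.0, Rn=5.0, M=1, C=0.0, H=0.5, R=0.5))
            for _ in range(3)
        ]
        assert sum(r.hin for r in label_hin(recs)) == 0
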