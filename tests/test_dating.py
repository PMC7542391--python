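"""Twin-LTR alignment, distance corrections, T = K/2r and the landscape."""

import math
import random

import numpy as np
import pytest

from ltrscape.core import GenomeSet, Interval, LtrElement
from ltrscape.dating import (
    ClockRate,
    SaturationError,
    Scoring,
    UndefinedDistanceError,
    align_twin_ltrs,
    alignment_score,
    build_landscape,
    date_elements,
    detect_ltr_pairs,
    insertion_age,
    jc_correction,
    k2p_correction,
    p_distance,
)
from ltrscape.simulate import ElementSpec, SimConfig, random_seq, simulate_genome

from oracles import (
    affine_dp_score,
    enumerate_alignments_score,
    jc_numerical_inverse,
    score_alignment_rows,
)

SPEC_SCORING = Scoring(match=1, mismatch=-1, gap_open=-2, gap_extend=-1)


class TestAlignment:
    def test_identity_alignment(self):
        rows = align_twin_ltrs("ACGT", "ACGT")
        assert rows == ("ACGT", "ACGT")

    def test_single_gap_example(self):
        """ACGT vs AGT at {+1,-1,-2,-1}: one gap column, optimal score 1."""
        assert alignment_score("ACGT", "AGT", SPEC_SCORING) == 1
        a, b = align_twin_ltrs("ACGT", "AGT", SPEC_SCORING)
        assert (a + b).count("-") == 1
        assert score_alignment_rows(a, b, 1, -1, -2, -1) == 1

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_twin_ltrs("", "ACGT")

    def test_dp_oracle_agrees_with_full_enumeration(self):
        """The three-state DP oracle itself is validated against exhaustive
        enumeration of every alignment at tiny lengths."""
        rng = random.Random(0)
        for _ in range(30):
            a = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 4)))
            b = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 4)))
            assert affine_dp_score(a, b, 1, -1, -4, -1) == pytest.approx(
                enumerate_alignments_score(a, b, 1, -1, -4, -1)
            )

    @pytest.mark.parametrize("scoring", [Scoring(), SPEC_SCORING])
    def test_score_matches_dp_oracle_random_pairs(self, scoring):
        rng = random.Random(42)
        for _ in range(100):
            a = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 12)))
            b = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 12)))
            expected = affine_dp_score(
                a, b, scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend
            )
            assert alignment_score(a, b, scoring) == pytest.approx(expected)
            rows = align_twin_ltrs(a, b, scoring)
            got = score_alignment_rows(
                *rows, scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend
            )
            assert got == pytest.approx(expected)


class TestPDistance:
    def test_identical_columns(self):
        assert p_distance(("A" * 100, "A" * 100)) == (0.0, 100)

    def test_gap_columns_excluded(self):
        # 10 columns, 1 mismatch, 2 gap columns -> p = 1/8 over 8 sites
        a = "ACGTACGT-A"
        b = "ACGAACGTT-"
        assert p_distance((a, b)) == (1 / 8, 8)

    def test_n_columns_excluded(self):
        assert p_distance(("ANA", "AAA")) == (0.0, 2)

    def test_all_gap_alignment_errors(self):
        with pytest.raises(UndefinedDistanceError):
            p_distance(("--", "AA"))


class TestCorrections:
    def test_jc_fixed_points(self):
        assert jc_correction(0.0) == 0.0
        assert jc_correction(0.05) == pytest.approx(0.0517447, abs=1e-6)
        assert jc_correction(0.74) == pytest.approx(3.23805, abs=1e-4)

    def test_jc_saturation(self):
        with pytest.raises(SaturationError):
            jc_correction(0.75)

    def test_jc_monotone_and_above_p(self):
        grid = np.linspace(0, 0.74, 200)
        K = [jc_correction(p) for p in grid]
        assert all(k2 > k1 for k1, k2 in zip(K, K[1:]))
        assert all(k >= p for k, p in zip(K, grid))

    def test_jc_matches_numerical_inversion(self):
        for p in np.linspace(0.0, 0.74, 149):
            assert jc_correction(p) == pytest.approx(
                jc_numerical_inverse(p), abs=1e-10
            )

    def test_k2p_identical_is_zero_and_dominates_p(self):
        assert k2p_correction(("ACGT", "ACGT")) == 0.0
        aln = ("A" * 10 + "C" * 90, "G" * 10 + "C" * 90)  # 10 transitions
        p, _ = p_distance(aln)
        assert k2p_correction(aln) >= p

    def test_insertion_age_formula(self):
        assert insertion_age(0.0) == 0.0
        assert insertion_age(0.0612, ClockRate(1.02e-9)) == pytest.approx(3.0e7)
        assert insertion_age(0.1, ClockRate(1.02e-9)) == pytest.approx(4.902e7, rel=1e-3)


class TestLandscape:
    def _element(self, eid, start, length, superfamily="Gypsy"):
        ltr5 = Interval("c", start, start + 100)
        ltr3 = Interval("c", start + length - 100, start + length)
        internal = Interval("c", ltr5.end, ltr3.start)
        return LtrElement(eid, ltr5, ltr3, internal, superfamily)

    def test_single_element_bin(self):
        from ltrscape.dating import AgeEstimate

        el = self._element("e1", 0, 6000)
        est = [AgeEstimate("e1", "Gypsy", 6000, 100, 0.03, 0.031, 1.5e7)]
        landscape = build_landscape(est, [el], 0.01)
        b = landscape.bins[3]
        assert (b.k_low, b.k_high) == (pytest.approx(0.03), pytest.approx(0.04))
        assert b.lengths == {"Gypsy": 6000}

    def test_empty_input(self):
        landscape = build_landscape([], [], 0.01)
        assert landscape.bins == [] and landscape.total_length == 0

    def test_conservation_with_undatable(self, small_sim):
        import copy

        genome, elements = small_sim.genome, copy.deepcopy(small_sim.elements)
        elements[0].complete = False  # force one skipped element
        estimates, skipped = date_elements(genome, elements)
        assert [s[0] for s in skipped] == [elements[0].element_id]
        landscape = build_landscape(estimates, elements, 0.01)
        assert landscape.total_length == sum(e.span.length for e in elements)
        assert landscape.undatable_length == elements[0].span.length

    def test_cohort_modal_bin(self):
        """Ages {10,30,30,50} My: the modal bin holds K = 2r*30My = 0.0612."""
        res = simulate_genome(
            SimConfig(
                seed=21, n_contigs=3, contig_length=120_000, n_genes=0,
                elements=[
                    ElementSpec("Gypsy", 800, 1000, 10e6, 8),
                    ElementSpec("Gypsy", 800, 1000, 30e6, 16),
                    ElementSpec("Gypsy", 800, 1000, 50e6, 8),
                ],
            )
        )
        estimates, _ = date_elements(res.genome, res.elements)
        landscape = build_landscape(estimates, res.elements, 0.01)
        modal = landscape.modal_bin()
        # K = 0.0612 sits near a bin edge; per-element noise (SE of p ~0.008
        # at L=800) puts the peak in the bin holding 2rT or its neighbour
        mid = (modal.k_low + modal.k_high) / 2
        assert abs(mid - 0.0612) <= 0.01


class TestDetectLtrPairs:
    def test_planted_identical_pair_recovered(self):
        res = simulate_genome(
            SimConfig(seed=31, n_contigs=1, contig_length=60_000, n_genes=0,
                      elements=[ElementSpec("Gypsy", 400, 2000, 0.0, 1)])
        )
        (truth,) = res.elements
        seq = res.genome.contigs[truth.contig]
        found = detect_ltr_pairs(seq, min_ltr_len=100, max_internal_len=5000,
                                 min_identity=0.9, contig=truth.contig)
        assert len(found) == 1
        slop = 25
        assert abs(found[0].ltr5.start - truth.ltr5.start) <= slop
        assert abs(found[0].ltr3.end - truth.ltr3.end) <= slop

    def test_random_background_no_false_positives(self):
        rng = np.random.default_rng(32)
        seq = random_seq(100_000, 0.5, rng)
        assert detect_ltr_pairs(seq) == []

    def test_two_disjoint_elements_recovered(self):
        res = simulate_genome(
            SimConfig(seed=33, n_contigs=1, contig_length=60_000, n_genes=0,
                      elements=[ElementSpec("Copia", 300, 1500, 0.0, 2)])
        )
        seq = res.genome.contigs["contig001"]
        found = detect_ltr_pairs(seq, min_ltr_len=100, max_internal_len=5000,
                                 min_identity=0.9)
        starts = sorted(e.span.start for e in found)
        truth = sorted(e.span.start for e in res.elements)
        assert len(found) == 2
        assert all(abs(a - b) <= 25 for a, b in zip(starts, truth))


def test_parameter_recovery_on_simulated_cohort():
    """>=100 elements, L = 1000, age 30 My: mean estimated age within 10%."""
    res = simulate_genome(
        SimConfig(seed=41, n_contigs=4, contig_length=200_000, n_genes=0,
                  elements=[ElementSpec("Gypsy", 1000, 500, 30e6, 100)])
    )
    estimates, skipped = date_elements(res.genome, res.elements)
    assert not skipped and len(estimates) == 100
    mean_age = float(np.mean([a.T for a in estimates]))
    assert abs(mean_age - 30e6) <= 0.1 * 30e6
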