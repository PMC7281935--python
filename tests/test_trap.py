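"""TRAP affinity model: energies, occupancy, deltas, information content."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nccmscan.trap import (
    PFMModel,
    affinity_delta,
    default_r0,
    matrix_position_conservation,
    pfm_to_energy,
    reverse_complement,
    trap_affinity,
)

# EMSA oligos: forward-strand wild-type and T>C variant at 0-based index 10
WT_F = "GCAACAGTGGTTTGCTCTGGAGAGGAAA"
MUT_F = "GCAACAGTGGCTTGCTCTGGAGAGGAAA"


def uniform_pfm(width=4, depth=40):
    return PFMModel("U", np.full((4, width), depth // 4))


def t_requiring_pfm():
    """Consensus TGGTTTGC with a near-invariant T at column 3."""
    counts = np.full((4, 8), 10)
    for j, b in enumerate("TGGTTTGC"):
        counts["ACGT".index(b), j] = 70
    counts[:, 3] = 1
    counts["ACGT".index("T"), 3] = 97
    return PFMModel("TREQ", counts)


class TestEnergy:
    def test_uniform_column_all_zero(self):
        e = pfm_to_energy(np.full((4, 5), 10))
        assert np.allclose(e, 0.0)

    def test_hand_computed_971(self):
        counts = np.zeros((4, 4))
        counts[:, :] = 10
        counts[:, 0] = [97, 1, 1, 1]
        e = pfm_to_energy(counts, pseudocount=1, lambda_param=0.7)
        expected = (1 / 0.7) * math.log(98 / 2)
        assert e[1, 0] == pytest.approx(expected)
        assert e[0, 0] == 0.0

    def test_consensus_energy_zero_everywhere(self):
        pfm = t_requiring_pfm()
        cons = pfm.consensus
        total = sum(pfm.energy["ACGT".index(b), j] for j, b in enumerate(cons))
        assert total == 0.0
        assert (pfm.energy >= 0).all()

    def test_all_zero_column_is_error(self):
        counts = np.full((4, 4), 5.0)
        counts[:, 2] = 0
        with pytest.raises(ValueError, match="all-zero"):
            pfm_to_energy(counts)


class TestAffinity:
    def test_single_site_consensus_value(self):
        pfm = t_requiring_pfm()
        a = trap_affinity(pfm.consensus, pfm)
        r0 = default_r0(8)
        # forward offset contributes exactly R0/(1+R0); reverse strand adds a
        # strictly smaller, non-negative term
        assert a >= r0 / (1 + r0)
        assert a == pytest.approx(r0 / (1 + r0), rel=0.5)

    def test_matches_brute_force_enumeration(self):
        pfm = uniform_pfm()
        rng = np.random.default_rng(3)
        pfm2 = PFMModel("R", rng.integers(1, 30, size=(4, 4)))
        for pfm_ in (pfm, pfm2):
            seq = "ACGTTGCAGT"  # 10 bp, W=4 -> 7 offsets per strand
            expected = 0.0
            for strand_seq in (seq, reverse_complement(seq)):
                for i in range(len(seq) - 4 + 1):
                    e = sum(
                        pfm_.energy["ACGT".index(strand_seq[i + j]), j]
                        for j in range(4)
                    )
                    x = pfm_.r0 * math.exp(-e)
                    expected += x / (1 + x)
            assert trap_affinity(seq, pfm_) == pytest.approx(expected)

    @given(st.text(alphabet="ACGT", min_size=8, max_size=30))
    @settings(derandomize=True, max_examples=60)
    def test_strand_symmetry(self, seq):
        pfm = t_requiring_pfm()
        assert trap_affinity(seq, pfm) == pytest.approx(
            trap_affinity(reverse_complement(seq), pfm)
        )

    def test_exhaustive_small_equivalence(self):
        """Brute-force equality over all 4-mers against a W=4 matrix."""
        from itertools import product

        rng = np.random.default_rng(9)
        pfm = PFMModel("X", rng.integers(1, 50, size=(4, 4)))
        for tup in product("ACGT", repeat=4):
            seq = "".join(tup)
            expected = 0.0
            for strand_seq in (seq, reverse_complement(seq)):
                e = sum(pfm.energy["ACGT".index(strand_seq[j]), j] for j in range(4))
                x = pfm.r0 * math.exp(-e)
                expected += x / (1 + x)
            assert trap_affinity(seq, pfm) == pytest.approx(expected)

    def test_n_base_uses_column_mean(self):
        pfm = t_requiring_pfm()
        a_n = trap_affinity("N" * 8, pfm)
        assert a_n > 0

    def test_short_sequence_is_error(self):
        with pytest.raises(ValueError, match="shorter"):
            trap_affinity("ACG", uniform_pfm())

    def test_higher_energy_base_does_not_increase_affinity(self):
        pfm = t_requiring_pfm()
        best = pfm.consensus
        worse = best[:3] + "C" + best[4:]  # invariant-T column -> high energy
        assert trap_affinity(worse, pfm) <= trap_affinity(best, pfm)


class TestDelta:
    def test_identical_windows_all_zero(self):
        pfms = [uniform_pfm(), t_requiring_pfm()]
        deltas = affinity_delta(WT_F, WT_F, pfms)
        assert all(d.delta == 0.0 for d in deltas)

    def test_printed_oligos_lose_affinity(self):
        """The T>C variant lowers affinity for the T-requiring factor."""
        d = affinity_delta(WT_F, MUT_F, [t_requiring_pfm()])[0]
        assert d.delta < 0
        assert d.affinity_mut < d.affinity_wt

    def test_ranking_matches_sorted_brute_force(self):
        rng = np.random.default_rng(11)
        pfms = [PFMModel(f"T{i}", rng.integers(1, 40, size=(4, int(rng.integers(4, 8)))))
                for i in range(5)]
        deltas = affinity_delta(WT_F, MUT_F, pfms)
        brute = sorted(
            ((trap_affinity(MUT_F, p) - trap_affinity(WT_F, p), p.tf_name) for p in pfms),
            key=lambda t: (-abs(t[0]), t[1]),
        )
        assert [d.tf_name for d in deltas] == [name for _, name in brute]
        for d, (delta, _) in zip(deltas, brute):
            assert d.delta == pytest.approx(delta)
        assert [d.rank for d in deltas] == [1, 2, 3, 4, 5]

    def test_top_k(self):
        pfms = [uniform_pfm(), t_requiring_pfm()]
        assert len(affinity_delta(WT_F, MUT_F, pfms, top=1)) == 1


class TestInformationContent:
    def test_uniform_column_zero_bits(self):
        assert matrix_position_conservation(uniform_pfm(), 0) == pytest.approx(0.0, abs=1e-9)

    def test_near_invariant_column_direct_formula(self):
        counts = np.zeros((4, 4))
        counts[:, :] = 10
        counts[:, 1] = [97, 1, 1, 1]
        pfm = PFMModel("Y", counts)
        p = (counts[:, 1] + 1) / (100 + 4)
        expected = 2 + sum(x * math.log2(x) for x in p)
        assert matrix_position_conservation(pfm, 1) == pytest.approx(expected)
        assert expected > 1.5

    def test_bounds(self):
        pfm = t_requiring_pfm()
        for j in range(pfm.width):
            assert 0.0 <= matrix_position_conservation(pfm, j) <= 2.0

    def test_invalid_index(self):
        with pytest.raises(IndexError):
            matrix_position_conservation(uniform_pfm(), 99)
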