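"""Model C: Boltzmann DP against brute-force Boltzmann sums."""

import random

import pytest

from rnadegree import (
    MoveSetId,
    compute_turner_tables,
    compute_uniform_tables,
    energy_of_structure,
    enumerate_structures,
    mccaskill_partition,
    multiloop_restricted_filter,
    neighbors,
    turner_Q,
    turner_expected_degree,
    zero_parameters,
)
from rnadegree.fixtures import random_sequences
from rnadegree.params import TurnerParameters
from rnadegree.structure import NucleotideSequence, loop_decomposition, parse_sequence
from rnadegree.turner import ArcCounts

#: sequences chosen to populate multiloops heavily
MULTILOOP_SEQS = [
    "GGGAAACCCGGGAAACCC",
    "GCGAAACGCGCGAAACGCAA",
    "ACGGAUCCGGAAUUCCGG",
    "GGCAUCCGGAUCCAAGG",
]


def _boltzmann_oracle(seq, params, ms, restricted=True):
    filt = multiloop_restricted_filter(seq) if restricted else None
    z = 0.0
    q = 0.0
    for s in enumerate_structures(seq):
        w = energy_of_structure(seq, s, params).boltzmann_factor(params.rt)
        if w == 0.0:
            continue
        z += w
        q += w * len(neighbors(seq, s, ms, move_filter=filt))
    return q, z


class TestPartitionFunction:
    def test_single_structure(self, minimal_params):
        z, _ = mccaskill_partition(parse_sequence("AAAA"), minimal_params)
        assert z == 1.0

    def test_zero_params_equal_counts(self, gggg, zero_params):
        z, _ = mccaskill_partition(gggg, zero_params)
        assert z == pytest.approx(8.0, abs=1e-12)

    def test_boltzmann_sum(self, minimal_params):
        """Z_{1,n} equals the enumerated Boltzmann sum on random 8..14-mers."""
        for seq in random_sequences(seed=31, count=25, min_len=8, max_len=14):
            z, _ = mccaskill_partition(seq, minimal_params)
            zo = sum(
                energy_of_structure(seq, s, minimal_params).boltzmann_factor(minimal_params.rt)
                for s in enumerate_structures(seq)
            )
            assert z == pytest.approx(zo, rel=1e-9)


class TestArcCounts:
    def test_no_pairable_positions(self):
        arcs = ArcCounts(parse_sequence("AAAAAAAA"))
        assert arcs.arc1a(1, 8) == 0

    def test_arc1b_worked_example(self, gggg):
        """(1, 7) on GGGGCCC can re-anchor to (1, 5) or (1, 6)."""
        arcs = ArcCounts(gggg)
        assert arcs.arc1b(1, 7) == 2

    def test_against_direct_enumeration(self):
        """Every accessor equals its defining set cardinality on a random
        sequence."""
        rng = random.Random(13)
        seq = NucleotideSequence("".join(rng.choice("ACGU") for _ in range(16)))
        arcs = ArcCounts(seq)
        th = 3

        def bp(x, y):
            return y - x > th and (seq.at(x), seq.at(y)) in {
                ("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")
            }

        n = seq.n
        for i in range(1, n):
            for j in range(i + th + 1, n + 1):
                assert arcs.arc1a(i, j) == sum(
                    1 for x in range(i, j) for y in range(x + th + 1, j + 1) if bp(x, y)
                )
                assert arcs.arc1b(i, j) == sum(1 for k in range(i + 1, j) if bp(i, k))
                assert arcs.arc1c(i, j) == sum(1 for k in range(i + 1, j) if bp(k, j))
                for l in range(i + 1, j):
                    for r in range(l + th + 1, j):
                        a2a = sum(
                            1
                            for x in range(i + 1, l)
                            for y in range(r + 1, j)
                            if bp(x, y)
                        )
                        assert arcs.arc2a(i, j, l, r) == a2a
                        assert arcs.arc3(i, j, l, r) == arcs.arc1a(i + 1, l - 1) + arcs.arc1a(
                            r + 1, j - 1
                        ) + arcs.arc2(i, j, l, r)
        for i in range(1, n):
            for j in range(i + 1, n):
                for k in range(j + 1, n + 1):
                    assert arcs.arc4(i, j, k) == sum(1 for x in range(j + 1, k + 1) if bp(i, x))
                    assert arcs.arc5(i, j, k) == sum(1 for x in range(j + 1, k + 1) if bp(j, x))


class TestDegreeDP:
    def test_unpairable_sequence(self, minimal_params):
        q, _ = turner_Q(parse_sequence("AAAAAAAAAA"), minimal_params, MoveSetId.MS2)
        assert q == 0.0

    def test_zero_params_worked_example(self, gggg, zero_params):
        """No structure of GGGGCCC contains a multiloop, so the restricted
        Boltzmann count at zero energies reproduces the uniform counts."""
        q, _ = turner_Q(gggg, zero_params, MoveSetId.MS2)
        assert q == pytest.approx(32.0, abs=1e-9)
        _, _, deg, _ = turner_expected_degree(gggg, zero_params, MoveSetId.MS2)
        assert deg == pytest.approx(4.0, abs=1e-12)
        _, _, deg1, _ = turner_expected_degree(gggg, zero_params, MoveSetId.MS1)
        assert deg1 == pytest.approx(2.0, abs=1e-12)

    @pytest.mark.parametrize("ms", [MoveSetId.MS1, MoveSetId.MS2], ids=lambda m: m.value)
    def test_restricted_oracle_random(self, minimal_params, ms):
        """DP Q equals the enumerated restricted Boltzmann count on seeded
        random 8..14-mers."""
        for seq in random_sequences(seed=47, count=20, min_len=8, max_len=14):
            qd, _ = turner_Q(seq, minimal_params, ms)
            qo, _ = _boltzmann_oracle(seq, minimal_params, ms)
            assert qd == pytest.approx(qo, rel=1e-9, abs=1e-9), seq.residues

    @pytest.mark.parametrize("ms", [MoveSetId.MS1, MoveSetId.MS2], ids=lambda m: m.value)
    def test_restricted_oracle_multiloop_rich(self, minimal_params, ms):
        """Same equivalence on sequences whose ensembles contain many
        multiloops (the restricted counter differs from the full one here)."""
        for text in MULTILOOP_SEQS:
            seq = parse_sequence(text)
            qd, _ = turner_Q(seq, minimal_params, ms)
            qo, _ = _boltzmann_oracle(seq, minimal_params, ms)
            assert qd == pytest.approx(qo, rel=1e-9), text
            if ms is MoveSetId.MS2:
                q_full, _ = _boltzmann_oracle(seq, minimal_params, ms, restricted=False)
                assert qd < q_full  # the exclusions remove real moves

    def test_zero_energy_reduction(self, zero_params):
        """With zero energies Q equals the model B count exactly on
        multiloop-free sequences and is never larger elsewhere."""
        for seq in random_sequences(seed=53, count=20, min_len=6, max_len=13):
            has_ml = any(
                any(l.kind == "multiloop" for l in loop_decomposition(s))
                for s in enumerate_structures(seq)
            )
            ub = compute_uniform_tables(seq)
            for ms in (MoveSetId.MS1, MoveSetId.MS2):
                qc, _ = turner_Q(seq, zero_params, ms)
                qb = ub.q(ms, 1, seq.n)
                if has_ml:
                    assert qc <= qb + 1e-9
                else:
                    assert qc == pytest.approx(qb, rel=1e-12), seq.residues

    def test_ms_consistency(self, minimal_params):
        for seq in random_sequences(seed=59, count=10, min_len=8, max_len=14):
            t = compute_turner_tables(seq, minimal_params)
            q2 = t.q(MoveSetId.MS2, 1, seq.n)
            q1 = t.q(MoveSetId.MS1, 1, seq.n)
            qs = t.q(MoveSetId.SHIFT_ONLY, 1, seq.n)
            assert q2 >= q1 >= 0.0
            assert qs == pytest.approx(q2 - q1)

    def test_high_temperature_limit(self, minimal_params):
        """As RT grows with energies fixed, the degree approaches the
        zero-parameter (uniform-restricted) value."""
        seq = parse_sequence("GGGAAACCCGGGAAACCC")
        hot = TurnerParameters.from_json(minimal_params.to_json())
        hot.temperature = 310.15 * 4000
        _, _, dhot, _ = turner_expected_degree(seq, hot, MoveSetId.MS2)
        _, _, dzero, _ = turner_expected_degree(seq, zero_parameters(), MoveSetId.MS2)
        assert dhot == pytest.approx(dzero, rel=2e-3)
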