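"""Degree distributions, contact order, native contacts, entropy."""

import math

import pytest

from rnadegree import (
    MoveSetId,
    RNA_RULE,
    SecondaryStructure,
    conformational_entropy,
    contact_order,
    degree_distribution,
    expected_native_contacts,
    metrics_table,
    structure_from_dot_bracket,
    turner_expected_degree,
    uniform_expected_degree,
    validate_structure,
)
from rnadegree.errors import EmptyStructure
from rnadegree.fixtures import random_sequences
from rnadegree.structure import parse_sequence


class TestDegreeDistribution:
    def test_uniform_means(self, gggg):
        d2 = degree_distribution(gggg, "B", ms=MoveSetId.MS2)
        assert d2.mean == pytest.approx(4.0, abs=1e-12)
        assert d2.coverage == 1.0
        d1 = degree_distribution(gggg, "B", ms=MoveSetId.MS1)
        assert d1.mean == pytest.approx(2.0, abs=1e-12)
        assert set(d1.histogram) <= set(range(1, 7))
        assert sum(d1.histogram.values()) == pytest.approx(1.0)

    def test_single_structure(self):
        d = degree_distribution(parse_sequence("AAAA"), "B")
        assert d.histogram == {0: 1.0}
        assert d.standard_deviation == 0.0

    def test_mean_matches_dp(self, minimal_params):
        """Full-enumeration mean equals the DP expected degree (model B
        exactly, model C with the restricted counter)."""
        for seq in random_sequences(seed=71, count=8, min_len=6, max_len=12):
            for ms in (MoveSetId.MS1, MoveSetId.MS2):
                db = degree_distribution(seq, "B", ms=ms)
                _, _, deg, _ = uniform_expected_degree(seq, ms)
                assert db.mean == pytest.approx(float(deg), abs=1e-12 * max(1, float(deg)))
                dc = degree_distribution(
                    seq, "C", minimal_params, ms, neighbor_counter="restricted"
                )
                _, _, degc, _ = turner_expected_degree(seq, minimal_params, ms)
                assert dc.mean == pytest.approx(degc, rel=1e-10)

    def test_coverage_monotone_in_cutoff(self, minimal_params):
        seq = parse_sequence("GGGAAACCCAUGC")
        covs = [
            degree_distribution(seq, "C", minimal_params, energy_cutoff=c).coverage
            for c in (1.0, 3.0, 8.0, 100.0)
        ]
        assert covs == sorted(covs)
        assert covs[-1] == pytest.approx(1.0)


class TestContactOrder:
    def test_direct_formula(self):
        s = SecondaryStructure(7, frozenset({(1, 7), (2, 6)}))
        r = contact_order(s)
        assert r.absolute == pytest.approx(5.0)
        assert r.relative == pytest.approx(5.0 / 7)

    def test_single_pair(self):
        s = SecondaryStructure(10, frozenset({(2, 9)}))
        assert contact_order(s).absolute == 7.0

    def test_empty_raises(self):
        with pytest.raises(EmptyStructure):
            contact_order(SecondaryStructure(5))

    def test_y_rna_golden(self, yrna, yrna_db):
        from rnadegree import parse_dot_bracket

        s = SecondaryStructure(yrna.n, parse_dot_bracket(yrna_db))
        r = contact_order(s)
        assert r.n_pairs == 23
        assert r.absolute == pytest.approx(1535 / 23)  # frozen from the 23 printed pairs
        assert r.relative == pytest.approx(1535 / 23 / 102)


class TestNativeContacts:
    def test_empty_reference(self, gggg):
        r = expected_native_contacts(gggg, SecondaryStructure(7))
        assert r.expected_native_contacts == 0.0

    def test_uniform_occupancy(self, gggg):
        """Each of (1,7), (2,6) occurs in 2 of the 8 structures."""
        s0 = validate_structure(gggg, {(1, 7), (2, 6)}, RNA_RULE)
        r = expected_native_contacts(gggg, s0, "B")
        assert r.pair_probabilities[(1, 7)] == pytest.approx(0.25)
        assert r.expected_native_contacts == pytest.approx(0.5)

    def test_zero_energy_model_c_matches_uniform(self, gggg, zero_params):
        s0 = validate_structure(gggg, {(1, 7), (2, 6)}, RNA_RULE)
        rb = expected_native_contacts(gggg, s0, "B")
        rc = expected_native_contacts(gggg, s0, "C", zero_params)
        assert rc.expected_native_contacts == pytest.approx(rb.expected_native_contacts)

    def test_bounded_by_reference_size(self, minimal_params):
        seq = parse_sequence("GGGAAACCCAU")
        s0 = structure_from_dot_bracket(seq, "(((...))).." )
        r = expected_native_contacts(seq, s0, "C", minimal_params)
        assert 0.0 <= r.expected_native_contacts <= len(s0)


class TestEntropy:
    def test_single_structure(self):
        assert conformational_entropy(parse_sequence("AAAA"), "B") == 0.0

    def test_uniform_is_log_count(self, gggg):
        assert conformational_entropy(gggg, "B") == pytest.approx(math.log(8))

    def test_boltzmann(self, gggg, minimal_params):
        """Matches -sum p ln p with enumerated Boltzmann probabilities."""
        from rnadegree import energy_of_structure, enumerate_structures

        ws = [
            energy_of_structure(gggg, s, minimal_params).boltzmann_factor(minimal_params.rt)
            for s in enumerate_structures(gggg)
        ]
        z = sum(ws)
        expect = -sum(w / z * math.log(w / z) for w in ws if w > 0)
        got = conformational_entropy(gggg, "C", minimal_params)
        assert got == pytest.approx(expect, rel=1e-12)
        assert got <= math.log(8)  # uniform maximizes entropy


class TestMetricsTable:
    def test_columns_and_values(self, gggg):
        s0 = validate_structure(gggg, {(1, 7), (2, 6)}, RNA_RULE)
        df = metrics_table([("toy", gggg, s0)])
        row = df.loc["toy"]
        assert row["degree_ms2"] == pytest.approx(4.0)
        assert row["degree_ms1"] == pytest.approx(2.0)
        assert row["entropy"] == pytest.approx(math.log(8))
        assert row["contact_order_abs"] == pytest.approx(5.0)
        assert row["native_contacts"] == pytest.approx(0.5)
        corr = df.corr()  # single row: degenerate but well-formed
        assert set(corr.columns) == set(df.columns)
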