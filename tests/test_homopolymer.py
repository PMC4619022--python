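"""Model A: homopolymer recursions against the exhaustive oracle."""

import pytest

from rnadegree import (
    MoveSetId,
    compute_homopolymer_tables,
    normalized_degree,
)
from rnadegree.errors import NegativeLength
from rnadegree.homopolymer import expected_degree, f_table, g_table
from rnadegree.network import enumerate_structures, neighbors
from rnadegree.structure import PairingMode, PairingRule, homopolymer

#: analytically proved large-n limit of Q_n/(n Z_n) for MS1 (theta = 3)
MS1_LIMIT = 0.4734176431521986


@pytest.fixture(scope="module", params=[1, 3], ids=["theta1", "theta3"])
def theta(request):
    return request.param


@pytest.fixture(scope="module")
def oracle(theta):
    """Exhaustive per-length Z, E, Q and visibility profiles for n <= 12."""
    rule = PairingRule(PairingMode.HOMOPOLYMER, theta=theta)
    out = {}
    for n in range(0, 13):
        if n == 0:
            out[n] = dict(Z=1, E=0, Q1=0, Q2=0, f={0: 1}, g={})
            continue
        seq = homopolymer(n)
        structs = list(enumerate_structures(seq, rule))
        E = sum(len(s.external_pairs()) for s in structs)
        q1 = sum(len(neighbors(seq, s, MoveSetId.MS1, rule)) for s in structs)
        q2 = sum(len(neighbors(seq, s, MoveSetId.MS2, rule)) for s in structs)
        f = {}
        g = {}
        for s in structs:
            vis = s.visible_positions()
            f[len(vis)] = f.get(len(vis), 0) + 1
            if not s.is_paired(n):
                x = sum(1 for k in vis if k <= n - theta - 1)
                g[x] = g.get(x, 0) + 1
        out[n] = dict(Z=len(structs), E=E, Q1=q1, Q2=q2, f=f, g=g)
    return out


class TestAgainstOracle:
    def test_counts_and_degrees(self, theta, oracle):
        """Z, E and Q (all move sets) equal exhaustive enumeration exactly."""
        t = compute_homopolymer_tables(12, theta=theta)
        qs = t.Q(MoveSetId.SHIFT_ONLY)
        for n in range(0, 13):
            o = oracle[n]
            assert t.Z[n] == o["Z"]
            assert t.E[n] == o["E"]
            assert t.Q_ms1[n] == o["Q1"]
            assert t.Q_ms2[n] == o["Q2"]
            assert qs[n] == o["Q2"] - o["Q1"]

    def test_visibility_profiles(self, theta, oracle):
        """f(n, x) and g(n, x) match the enumerated profiles; their row sums
        partition Z_n and Z_{n-1}."""
        f = f_table(12, theta)
        g = g_table(12, theta)
        t = compute_homopolymer_tables(12, theta=theta)
        for n in range(0, 13):
            o = oracle[n]
            for x in range(0, n + 2):
                assert f[n][x] == o["f"].get(x, 0), (n, x)
                if n > theta + 1:  # short lengths use the g = 0 convention
                    assert g[n][x] == o["g"].get(x, 0), (n, x)
            assert sum(f[n]) == t.Z[n]
            if n > theta + 1:
                assert sum(g[n]) == t.Z[n - 1]

    def test_moments_match_profiles(self, theta):
        t = compute_homopolymer_tables(12, theta=theta)
        f = f_table(12, theta)
        for n in range(13):
            assert t.F1[n] == sum(x * v for x, v in enumerate(f[n]))
            assert t.F2[n] == sum(x * (x - 1) * v for x, v in enumerate(f[n]))


class TestNormalizedDegree:
    def test_small_n_exact(self):
        t = compute_homopolymer_tables(4, theta=1)
        assert normalized_degree(t, MoveSetId.MS2, 3) == pytest.approx(2 / 6)
        assert expected_degree(t, MoveSetId.MS1, 4) == pytest.approx(6 / 4)

    def test_tables_attached_by_default(self):
        t = compute_homopolymer_tables(20, theta=1)
        assert t.f is not None and t.g is not None

    def test_negative_length(self):
        with pytest.raises(NegativeLength):
            compute_homopolymer_tables(-1)


class TestRepresentations:
    def test_exact_and_rescaled_agree_to_ten_digits(self):
        """Both representations give identical degree ratios (n <= 300)."""
        exact = compute_homopolymer_tables(300, theta=3, with_profiles=False)
        resc = compute_homopolymer_tables(300, theta=3, representation="rescaled_float")
        for n in (50, 150, 300):
            for ms in (MoveSetId.MS1, MoveSetId.MS2):
                a = normalized_degree(exact, ms, n)
                b = normalized_degree(resc, ms, n)
                assert abs(a - b) <= 1e-10 * abs(a)

    def test_ms1_convergence_toward_limit(self):
        """|Q_n/(n Z_n) - limit| decreases with n for MS1 (theta = 3)."""
        t = compute_homopolymer_tables(400, theta=3, representation="rescaled_float")
        devs = [abs(normalized_degree(t, MoveSetId.MS1, n) - MS1_LIMIT) for n in (100, 200, 400)]
        assert devs[0] > devs[1] > devs[2]

    def test_ms2_exceeds_three_times_ms1(self):
        t = compute_homopolymer_tables(400, theta=3, representation="rescaled_float")
        r = normalized_degree(t, MoveSetId.MS2, 400) / normalized_degree(t, MoveSetId.MS1, 400)
        assert r > 3.0
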