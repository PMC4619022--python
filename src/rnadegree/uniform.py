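"""Expected network degree under uniform probability (model B).

Every secondary structure of a real RNA sequence (Watson-Crick/wobble
pairing, theta = 3) has energy zero, so the probability of each structure is
1/Z and the expected network degree is the exact rational Q_{1,n} / Z_{1,n},
where Q_{1,n} = sum_s N(s) counts directed move-set edges.

The recursions decompose on the rightmost position j of the interval [i, j]
and need, besides the structure counts Z, five auxiliary families:

* ``EL[i][j][c]``  - total over structures of [i, j] of external pairs
  (x, y) whose left end can pair with nucleotide c (a shift (x, y) -> (x, j)
  exists for every such pair when j is unpaired);
* ``ER[i][j][c]``  - same with the right end pairable with c;
* ``ERp[i][j][c]`` - external pairs (x, y) with y <= j - theta - 1, j
  unpaired (a shift (x, y) -> (y, j) exists for every such pair);
* ``F[i][j][c][x]`` - structures with exactly x visible positions pairable
  with c;
* ``G[i][j][c][x]`` - structures with j unpaired and exactly x visible
  positions in [i, j - theta - 1] pairable with c (a pair (k, j) can shift
  to (k', j) for any ordered choice of two such positions k, k').

All arithmetic is exact (Python integers).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Dict, List, Optional, Tuple

from .network import MoveSetId
from .structure import NucleotideSequence, PairingRule, RNA_RULE

__all__ = ["UniformTables", "compute_uniform_tables", "uniform_Q", "uniform_expected_degree"]

_ACGU = "ACGU"


@dataclass
class UniformTables:
    """Triangular count tables for one sequence (1-based outer indices)."""

    seq: NucleotideSequence
    rule: PairingRule
    Z: List[List[int]]
    EL: List[List[List[int]]]
    ER: List[List[List[int]]]
    ERp: List[List[List[int]]]
    F: List[List[List[List[int]]]]
    G: List[List[List[List[int]]]]
    Q: Dict[MoveSetId, List[List[int]]]

    def z(self, i: int, j: int) -> int:
        """Z_{i,j}; 1 for empty or sub-theta intervals."""
        if j < i or j - i <= self.rule.theta:
            return 1
        return self.Z[i][j]

    def q(self, ms: MoveSetId, i: int, j: int) -> int:
        if j < i or j - i <= self.rule.theta:
            return 0
        return self.Q[ms][i][j]


def compute_uniform_tables(
    seq: NucleotideSequence, rule: PairingRule = RNA_RULE
) -> UniformTables:
    """Fill Z, EL, ER, ER', F, G and Q (all three move sets) for seq."""
    n = seq.n
    th = rule.theta

    def bp(i: int, j: int) -> bool:
        return j - i > th and rule.letters_pair(seq.at(i), seq.at(j))

    def bpc(k: int, c: str) -> bool:
        return rule.letters_pair(seq.at(k), c)

    # tables indexed [i][j]; i in 1..n, j in 0..n (j < i unused)
    mk = lambda fill: [[fill] * (n + 1) for _ in range(n + 2)]  # noqa: E731
    Z = mk(1)
    EL = [[[0] * 4 for _ in range(n + 1)] for _ in range(n + 2)]
    ER = [[[0] * 4 for _ in range(n + 1)] for _ in range(n + 2)]
    ERp = [[[0] * 4 for _ in range(n + 1)] for _ in range(n + 2)]
    # F/G: [i][j][ci] -> dense list over x
    F: List[List[Optional[List[List[int]]]]] = [[None] * (n + 1) for _ in range(n + 2)]
    G: List[List[Optional[List[List[int]]]]] = [[None] * (n + 1) for _ in range(n + 2)]
    Q = {ms: mk(0) for ms in MoveSetId}

    def zf(i, j):
        return 1 if (j < i or j - i <= th) else Z[i][j]

    def elf(tab, i, j, ci):
        return 0 if (j < i or j - i <= th) else tab[i][j][ci]

    def f_vec(i, j, ci) -> List[int]:
        """F_{i,j,c,.} as a dense list (length j - i + 2, zero padded)."""
        if j < i:
            return [1]
        if j - i <= th:
            # only the empty structure: x = number of c-pairable positions
            m = sum(1 for k in range(i, j + 1) if bpc(k, _ACGU[ci]))
            v = [0] * (j - i + 2)
            v[m] = 1
            return v
        return F[i][j][ci]

    def qf(ms, i, j):
        return 0 if (j < i or j - i <= th) else Q[ms][i][j]

    for d in range(th + 1, n):
        for i in range(1, n - d + 1):
            j = i + d
            aj = _ACGU.index(seq.at(j))
            # Z ---------------------------------------------------------
            z = zf(i, j - 1)
            for k in range(i, j - th):
                if bp(k, j):
                    z += zf(i, k - 1) * zf(k + 1, j - 1)
            Z[i][j] = z
            # EL / ER ---------------------------------------------------
            for ci in range(4):
                c = _ACGU[ci]
                el = elf(EL, i, j - 1, ci)
                er = elf(ER, i, j - 1, ci)
                if bp(i, j):
                    inner = zf(i + 1, j - 1)
                    if bpc(i, c):
                        el += inner
                    if bpc(j, c):
                        er += inner
                for k in range(i + 1, j - th):
                    if bp(k, j):
                        right = zf(k + 1, j - 1)
                        el += (elf(EL, i, k - 1, ci) + (zf(i, k - 1) if bpc(k, c) else 0)) * right
                        er += (elf(ER, i, k - 1, ci) + (zf(i, k - 1) if bpc(j, c) else 0)) * right
                EL[i][j][ci] = el
                ER[i][j][ci] = er
            # ER' -------------------------------------------------------
            for ci in range(4):
                erp = elf(ER, i, j - th - 1, ci)
                for u in range(1, th + 1):
                    p = j - th - 1 + u
                    for k in range(i + 1, p - th):
                        if bp(k, p):
                            erp += elf(ER, i, k - 1, ci) * zf(k + 1, p - 1)
                ERp[i][j][ci] = erp
            # F ---------------------------------------------------------
            F[i][j] = []
            for ci in range(4):
                c = _ACGU[ci]
                prev = f_vec(i, j - 1, ci)
                size = j - i + 2
                vec = [0] * size
                if bpc(j, c):
                    for x in range(1, size):
                        if x - 1 < len(prev):
                            vec[x] = prev[x - 1]
                else:
                    for x in range(min(size, len(prev))):
                        vec[x] = prev[x]
                if bp(i, j):
                    vec[0] += zf(i + 1, j - 1)
                for k in range(i + 1, j - th):
                    if bp(k, j):
                        right = zf(k + 1, j - 1)
                        sub = f_vec(i, k - 1, ci)
                        for x in range(min(len(sub), size)):
                            if sub[x]:
                                vec[x] += sub[x] * right
                F[i][j].append(vec)
            # G ---------------------------------------------------------
            G[i][j] = []
            for ci in range(4):
                size = j - i + 2
                vec = [0] * size
                base = f_vec(i, j - th - 1, ci)
                for x in range(min(len(base), size)):
                    vec[x] = base[x]
                for u in range(1, th + 1):
                    p = j - th - 1 + u
                    if p - i > th and bp(i, p):
                        vec[0] += zf(i + 1, p - 1)
                    for k in range(i + 1, p - th):
                        if bp(k, p):
                            right = zf(k + 1, p - 1)
                            sub = f_vec(i, k - 1, ci)
                            for x in range(min(len(sub), size)):
                                if sub[x]:
                                    vec[x] += sub[x] * right
                G[i][j].append(vec)
            # Q ---------------------------------------------------------
            add_remove = 0
            for k in range(i, j - th):
                if bp(k, j):
                    add_remove += zf(i, k - 1) * zf(k + 1, j - 1)
            gx = sum(x * (x - 1) * w for x, w in enumerate(G[i][j][aj]))
            shift_src = 2 * (elf(EL, i, j - 1, aj) + ERp[i][j][aj]) + gx
            for ms in MoveSetId:
                acc = qf(ms, i, j - 1)
                if ms is not MoveSetId.SHIFT_ONLY:
                    acc += 2 * add_remove
                if ms is not MoveSetId.MS1:
                    acc += shift_src
                for k in range(i, j - th):
                    if bp(k, j):
                        acc += qf(ms, i, k - 1) * zf(k + 1, j - 1)
                        acc += zf(i, k - 1) * qf(ms, k + 1, j - 1)
                Q[ms][i][j] = acc

    return UniformTables(seq, rule, Z, EL, ER, ERp, F, G, Q)


def uniform_Q(
    seq: NucleotideSequence,
    ms: MoveSetId,
    rule: PairingRule = RNA_RULE,
    tables: Optional[UniformTables] = None,
) -> int:
    """Q_{1,n} = sum_s N(s) for the chosen move set (exact integer)."""
    t = tables if tables is not None else compute_uniform_tables(seq, rule)
    return t.q(ms, 1, seq.n)


def uniform_expected_degree(
    seq: NucleotideSequence,
    ms: MoveSetId,
    rule: PairingRule = RNA_RULE,
    tables: Optional[UniformTables] = None,
) -> Tuple[int, int, Fraction, Fraction]:
    """(Q, Z, degree, normalized_degree); degree = Q/Z as exact Fraction."""
    t = tables if tables is not None else compute_uniform_tables(seq, rule)
    q = t.q(ms, 1, seq.n)
    z = t.z(1, seq.n)
    deg = Fraction(q, z)
    return q, z, deg, deg / seq.n
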