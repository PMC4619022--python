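"""Boltzmann-weighted expected network degree (model C).

The partition function Z_{1,n} = sum_s exp(-E(s)/RT) follows the McCaskill
interval decomposition (Z, ZB, ZM, ZM1), and Q_{1,n} = sum_s BF(s) N*(s) is
computed alongside it (Q, QB, QM, QM1) together with Boltzmann versions of
the exterior shift auxiliaries EL, ER, ER', F, G and the loop-interior move
counters arc1a..arc5.

N*(s) is the move count of s restricted the way the multiloop decomposition
demands: inside a multiloop, additions that would enclose a component, all
shifts of the closing pair into the loop, and all component shifts other
than right-gap extensions (plus the first component's left-gap re-anchoring)
cannot be attributed to any subproblem and are not counted.  On structures
without multiloops N*(s) = N(s) exactly.  The same restricted counter is
available for brute-force comparison via
:func:`rnadegree.network.multiloop_restricted_filter`.

Per-component multiloop costs (the b of the affine score) are carried inside
ZM1/QM1 so that every component pays its term exactly once; the closing
pair's b sits in the e^{-(a+b)/RT} factor of the ZB/QB multiloop case.

All tables are double precision with energies pre-divided by RT.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

from .energy import hairpin_energy, internal_energy
from .errors import DegreeOverflow
from .network import MoveSetId
from .params import TurnerParameters
from .structure import NucleotideSequence, PairingRule, RNA_RULE

__all__ = [
    "TurnerTables",
    "compute_turner_tables",
    "mccaskill_partition",
    "turner_Q",
    "turner_expected_degree",
    "ArcCounts",
]

_ACGU = "ACGU"


class ArcCounts:
    """O(1) counts of pairable positions and addable pairs from prefix sums.

    ``cnt(k, lo, hi)`` is the number of positions x in [lo, hi] that can
    pair with the nucleotide at position k; ``arc1a(i, j)`` the number of
    addable pairs inside [i, j]; the remaining accessors count the shift
    targets at hairpin/internal/multiloop boundaries.
    """

    def __init__(self, seq: NucleotideSequence, rule: PairingRule = RNA_RULE):
        self.seq = seq
        self.theta = rule.theta
        n = seq.n
        # prefix[c][k] = #{x <= k : letter x pairs with letter c}
        self._prefix = {}
        for c in _ACGU:
            row = [0] * (n + 1)
            for k in range(1, n + 1):
                row[k] = row[k - 1] + (1 if rule.letters_pair(seq.at(k), c) else 0)
            self._prefix[c] = row
        # arc1a table
        th = self.theta
        self._a1 = [[0] * (n + 2) for _ in range(n + 2)]
        for i in range(n, 0, -1):
            for j in range(i, n + 1):
                self._a1[i][j] = self._a1[i + 1][j] + self.cnt(i, i + th + 1, j)

    def cnt(self, k: int, lo: int, hi: int) -> int:
        if hi < lo:
            return 0
        lo = max(lo, 1)
        hi = min(hi, self.seq.n)
        if hi < lo:
            return 0
        row = self._prefix[self.seq.at(k)]
        return row[hi] - row[lo - 1]

    def arc1a(self, i: int, j: int) -> int:
        if j < i or j > self.seq.n or i < 1:
            return 0
        return self._a1[i][j]

    def arc1b(self, i: int, j: int) -> int:
        return self.cnt(i, i + self.theta + 1, j - 1)

    def arc1c(self, i: int, j: int) -> int:
        return self.cnt(j, i + 1, j - self.theta - 1)

    def arc2a(self, i: int, j: int, l: int, r: int) -> int:
        return sum(self.cnt(x, r + 1, j - 1) for x in range(i + 1, l))

    def arc2b(self, i: int, j: int, l: int, r: int) -> int:
        th = self.theta
        b1 = self.cnt(i, r + 1, j - 1) + self.cnt(i, i + th + 1, l - 1)
        b2 = self.cnt(l, r + 1, j - 1) + self.cnt(l, i + 1, l - th - 1)
        return b1 + b2

    def arc2c(self, i: int, j: int, l: int, r: int) -> int:
        th = self.theta
        c1 = self.cnt(j, i + 1, l - 1) + self.cnt(j, r + 1, j - th - 1)
        c2 = self.cnt(r, i + 1, l - 1) + self.cnt(r, r + th + 1, j - 1)
        return c1 + c2

    def arc2(self, i: int, j: int, l: int, r: int) -> int:
        return self.arc2a(i, j, l, r) + self.arc2b(i, j, l, r) + self.arc2c(i, j, l, r)

    def arc3(self, i: int, j: int, l: int, r: int) -> int:
        return self.arc1a(i + 1, l - 1) + self.arc1a(r + 1, j - 1) + self.arc2(i, j, l, r)

    def arc4(self, i: int, j: int, k: int) -> int:
        return self.cnt(i, max(j + 1, i + self.theta + 1), k)

    def arc5(self, i: int, j: int, k: int) -> int:
        return self.cnt(j, j + self.theta + 1, k)


@dataclass
class TurnerTables:
    seq: NucleotideSequence
    params: TurnerParameters
    rule: PairingRule
    arcs: ArcCounts
    Z: List[List[float]]
    ZB: List[List[float]]
    ZM: List[List[float]]
    ZM1: List[List[float]]
    EL: List[List[List[float]]]
    ER: List[List[List[float]]]
    ERp: List[List[List[float]]]
    F: List[List[Optional[List[List[float]]]]]
    G: List[List[Optional[List[List[float]]]]]
    Q: Dict[MoveSetId, List[List[float]]]  # MS1 and MS2
    QB: Dict[MoveSetId, List[List[float]]]

    def z(self, i: int, j: int) -> float:
        if j < i or j - i <= self.rule.theta:
            return 1.0
        return self.Z[i][j]

    def zb(self, i: int, j: int) -> float:
        if j < i or j - i <= self.rule.theta:
            return 0.0
        return self.ZB[i][j]

    def q(self, ms: MoveSetId, i: int, j: int) -> float:
        if ms is MoveSetId.SHIFT_ONLY:
            return self.q(MoveSetId.MS2, i, j) - self.q(MoveSetId.MS1, i, j)
        if j < i or j - i <= self.rule.theta:
            return 0.0
        return self.Q[ms][i][j]


def compute_turner_tables(
    seq: NucleotideSequence,
    params: TurnerParameters,
    rule: PairingRule = RNA_RULE,
) -> TurnerTables:
    """Fill all partition and degree tables (MS1 and MS2 in one pass)."""
    n = seq.n
    th = rule.theta
    rt = params.rt
    a_ml, b_ml, c_ml = params.multiloop_affine
    arcs = ArcCounts(seq, rule)

    def bp(i: int, j: int) -> bool:
        return j - i > th and rule.letters_pair(seq.at(i), seq.at(j))

    def bpc(k: int, c: str) -> bool:
        return rule.letters_pair(seq.at(k), c)

    def boltz(e: float) -> float:
        if e == math.inf:
            return 0.0
        w = math.exp(-e / rt)
        if math.isinf(w):
            raise DegreeOverflow(f"Boltzmann factor overflow for energy {e}")
        return w

    eb = boltz(b_ml)
    ec = boltz(c_ml)
    eab = boltz(a_ml + b_ml)

    mkf = lambda: [[0.0] * (n + 1) for _ in range(n + 2)]  # noqa: E731
    Z, ZB, ZM, ZM1 = mkf(), mkf(), mkf(), mkf()
    MS = (MoveSetId.MS1, MoveSetId.MS2)
    Q = {ms: mkf() for ms in MS}
    QB = {ms: mkf() for ms in MS}
    QM = {ms: mkf() for ms in MS}
    QM1 = {ms: mkf() for ms in MS}
    EL = [[[0.0] * 4 for _ in range(n + 1)] for _ in range(n + 2)]
    ER = [[[0.0] * 4 for _ in range(n + 1)] for _ in range(n + 2)]
    ERp = [[[0.0] * 4 for _ in range(n + 1)] for _ in range(n + 2)]
    F: List[List[Optional[List[List[float]]]]] = [[None] * (n + 1) for _ in range(n + 2)]
    G: List[List[Optional[List[List[float]]]]] = [[None] * (n + 1) for _ in range(n + 2)]

    def zf(i, j):
        return 1.0 if (j < i or j - i <= th) else Z[i][j]

    def zbf(i, j):
        return 0.0 if (j < i or j - i <= th) else ZB[i][j]

    def zmf(i, j):
        return 0.0 if (j < i or j - i <= th) else ZM[i][j]

    def zm1f(i, j):
        return 0.0 if (j < i or j - i <= th) else ZM1[i][j]

    def tabf(tab, i, j, default=0.0):
        return default if (j < i or j - i <= th) else tab[i][j]

    def elf(tab, i, j, ci):
        return 0.0 if (j < i or j - i <= th) else tab[i][j][ci]

    def f_vec(i, j, ci) -> List[float]:
        if j < i:
            return [1.0]
        if j - i <= th:
            m = sum(1 for k in range(i, j + 1) if bpc(k, _ACGU[ci]))
            v = [0.0] * (j - i + 2)
            v[m] = 1.0
            return v
        return F[i][j][ci]

    for d in range(th + 1, n):
        for i in range(1, n - d + 1):
            j = i + d
            aj = _ACGU.index(seq.at(j))
            # ZB / QB ---------------------------------------------------
            if bp(i, j):
                wh = boltz(hairpin_energy(params, seq, i, j))
                zb = wh
                qb = {
                    MoveSetId.MS1: wh * (1 + arcs.arc1a(i + 1, j - 1)),
                    MoveSetId.MS2: wh
                    * (1 + arcs.arc1a(i + 1, j - 1) + arcs.arc1b(i, j) + arcs.arc1c(i, j)),
                }
                cap = params.max_interior_unpaired
                lmax = j - th - 2 if cap is None else min(i + cap + 1, j - th - 2)
                for l in range(i + 1, lmax + 1):
                    left = l - i - 1
                    rmin = l + th + 1 if cap is None else max(l + th + 1, j - 1 - (cap - left))
                    for r in range(rmin, j):
                        w = boltz(internal_energy(params, seq, i, j, l, r))
                        if w == 0.0:
                            continue
                        zbin = zbf(l, r)
                        if zbin == 0.0 and tabf(QB[MoveSetId.MS2], l, r) == 0.0:
                            continue
                        zb += w * zbin
                        add1 = arcs.arc1a(i + 1, l - 1) + arcs.arc1a(r + 1, j - 1) + arcs.arc2a(i, j, l, r)
                        shifts = arcs.arc2b(i, j, l, r) + arcs.arc2c(i, j, l, r)
                        qb[MoveSetId.MS1] += w * (zbin * (1 + add1) + tabf(QB[MoveSetId.MS1], l, r))
                        qb[MoveSetId.MS2] += w * (
                            zbin * (1 + add1 + shifts) + tabf(QB[MoveSetId.MS2], l, r)
                        )
                for r in range(i + 2, j - 1):
                    zm_l = zmf(i + 1, r - 1)
                    zm1_r = zm1f(r, j - 1)
                    if zm_l == 0.0 and zm1_r == 0.0:
                        continue
                    zb += eab * zm_l * zm1_r
                    for ms in MS:
                        qb[ms] += eab * (
                            zm_l * zm1_r  # removal of (i, j) itself
                            + tabf(QM[ms], i + 1, r - 1) * zm1_r
                            + zm_l * tabf(QM1[ms], r, j - 1)
                        )
                ZB[i][j] = zb
                for ms in MS:
                    QB[ms][i][j] = qb[ms]
            # ZM1 / QM1 -------------------------------------------------
            zm1 = 0.0
            qm1 = {ms: 0.0 for ms in MS}
            for k in range(i + th + 1, j + 1):
                zbk = zbf(i, k)
                if zbk == 0.0 and tabf(QB[MoveSetId.MS2], i, k) == 0.0:
                    continue
                w = eb * ec ** (j - k)
                zm1 += w * zbk
                add1 = arcs.arc1a(k + 1, j)
                shifts = arcs.arc4(i, k, j) + arcs.arc5(i, k, j)
                qm1[MoveSetId.MS1] += w * (tabf(QB[MoveSetId.MS1], i, k) + zbk * add1)
                qm1[MoveSetId.MS2] += w * (
                    tabf(QB[MoveSetId.MS2], i, k) + zbk * (add1 + shifts)
                )
            ZM1[i][j] = zm1
            for ms in MS:
                QM1[ms][i][j] = qm1[ms]
            # ZM / QM ---------------------------------------------------
            zm = 0.0
            qm = {ms: 0.0 for ms in MS}
            for r in range(i, j - th):
                zm1_r = zm1f(r, j)
                qm1_r = {ms: tabf(QM1[ms], r, j) for ms in MS}
                if zm1_r == 0.0 and qm1_r[MoveSetId.MS2] == 0.0:
                    continue
                w = ec ** (r - i)
                zm += w * zm1_r
                add1 = arcs.arc1a(i, r - 1)
                for ms in MS:
                    extra = add1 + (arcs.arc1c(i - 1, r) if ms is MoveSetId.MS2 else 0)
                    qm[ms] += w * (qm1_r[ms] + zm1_r * extra)
                if r - 1 >= i + th + 1:
                    zm_l = zmf(i, r - 1)
                    zm += zm_l * zm1_r
                    for ms in MS:
                        qm[ms] += tabf(QM[ms], i, r - 1) * zm1_r + zm_l * qm1_r[ms]
            ZM[i][j] = zm
            for ms in MS:
                QM[ms][i][j] = qm[ms]
            # Z ---------------------------------------------------------
            z = zf(i, j - 1)
            for k in range(i, j - th):
                z += zf(i, k - 1) * zbf(k, j)
            Z[i][j] = z
            # EL / ER ---------------------------------------------------
            for ci in range(4):
                c = _ACGU[ci]
                el = elf(EL, i, j - 1, ci)
                er = elf(ER, i, j - 1, ci)
                if bp(i, j):
                    zbij = ZB[i][j]
                    if bpc(i, c):
                        el += zbij
                    if bpc(j, c):
                        er += zbij
                for k in range(i + 1, j - th):
                    zbk = zbf(k, j)
                    if zbk == 0.0:
                        continue
                    el += (elf(EL, i, k - 1, ci) + (zf(i, k - 1) if bpc(k, c) else 0.0)) * zbk
                    er += (elf(ER, i, k - 1, ci) + (zf(i, k - 1) if bpc(j, c) else 0.0)) * zbk
                EL[i][j][ci] = el
                ER[i][j][ci] = er
            # ER' -------------------------------------------------------
            for ci in range(4):
                erp = elf(ER, i, j - th - 1, ci)
                for u in range(1, th + 1):
                    p = j - th - 1 + u
                    for k in range(i + 1, p - th):
                        zbk = zbf(k, p)
                        if zbk:
                            erp += elf(ER, i, k - 1, ci) * zbk
                ERp[i][j][ci] = erp
            # F ---------------------------------------------------------
            F[i][j] = []
            for ci in range(4):
                c = _ACGU[ci]
                prev = f_vec(i, j - 1, ci)
                size = j - i + 2
                vec = [0.0] * size
                if bpc(j, c):
                    for x in range(1, size):
                        if x - 1 < len(prev):
                            vec[x] = prev[x - 1]
                else:
                    for x in range(min(size, len(prev))):
                        vec[x] = prev[x]
                if bp(i, j):
                    vec[0] += ZB[i][j]
                for k in range(i + 1, j - th):
                    zbk = zbf(k, j)
                    if zbk == 0.0:
                        continue
                    sub = f_vec(i, k - 1, ci)
                    for x in range(min(len(sub), size)):
                        if sub[x]:
                            vec[x] += sub[x] * zbk
                F[i][j].append(vec)
            # G ---------------------------------------------------------
            G[i][j] = []
            for ci in range(4):
                size = j - i + 2
                vec = [0.0] * size
                base = f_vec(i, j - th - 1, ci)
                for x in range(min(len(base), size)):
                    vec[x] = base[x]
                for u in range(1, th + 1):
                    p = j - th - 1 + u
                    if p - i > th:
                        zbp = zbf(i, p)
                        if zbp:
                            vec[0] += zbp
                    for k in range(i + 1, p - th):
                        zbk = zbf(k, p)
                        if zbk == 0.0:
                            continue
                        sub = f_vec(i, k - 1, ci)
                        for x in range(min(len(sub), size)):
                            if sub[x]:
                                vec[x] += sub[x] * zbk
                G[i][j].append(vec)
            # Q ---------------------------------------------------------
            shift_src = EL[i][j - 1][aj] if j - 1 - i > th else 0.0
            shift_src += ERp[i][j][aj]
            fg = 0.0
            for k in range(i, j - th):
                zbk = zbf(k, j)
                if zbk == 0.0:
                    continue
                fvec = f_vec(i, k - 1, aj)
                gvec = G[i][k][_ACGU.index(seq.at(k))] if (k - i > th) else None
                acc = 0.0
                for x in range(1, len(fvec)):
                    acc += x * fvec[x]
                if gvec is not None:
                    for x in range(1, len(gvec)):
                        acc += x * gvec[x]
                fg += acc * zbk
            for ms in MS:
                acc = tabf(Q[ms], i, j - 1)
                for k in range(i, j - th):
                    if bp(k, j):
                        acc += zf(i, k - 1) * zf(k + 1, j - 1)  # additions (k, j)
                    zbk = zbf(k, j)
                    if zbk:
                        acc += tabf(Q[ms], i, k - 1) * zbk
                    acc += zf(i, k - 1) * tabf(QB[ms], k, j)
                if ms is MoveSetId.MS2:
                    acc += shift_src + fg
                Q[ms][i][j] = acc

    return TurnerTables(seq, params, rule, arcs, Z, ZB, ZM, ZM1, EL, ER, ERp, F, G, Q, QB)


def mccaskill_partition(
    seq: NucleotideSequence,
    params: TurnerParameters,
    rule: PairingRule = RNA_RULE,
    tables: Optional[TurnerTables] = None,
) -> Tuple[float, TurnerTables]:
    """(Z_{1,n}, tables)."""
    t = tables if tables is not None else compute_turner_tables(seq, params, rule)
    return t.z(1, seq.n), t


def turner_Q(
    seq: NucleotideSequence,
    params: TurnerParameters,
    ms: MoveSetId,
    rule: PairingRule = RNA_RULE,
    tables: Optional[TurnerTables] = None,
) -> Tuple[float, TurnerTables]:
    """(Q_{1,n}, tables) for the requested move set."""
    t = tables if tables is not None else compute_turner_tables(seq, params, rule)
    return t.q(ms, 1, seq.n), t


def turner_expected_degree(
    seq: NucleotideSequence,
    params: TurnerParameters,
    ms: MoveSetId,
    rule: PairingRule = RNA_RULE,
    tables: Optional[TurnerTables] = None,
) -> Tuple[float, float, float, float]:
    """(Q, Z, degree, normalized_degree) with degree = Q_{1,n} / Z_{1,n}."""
    t = tables if tables is not None else compute_turner_tables(seq, params, rule)
    q = t.q(ms, 1, seq.n)
    z = t.z(1, seq.n)
    deg = q / z
    return q, z, deg, deg / seq.n
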