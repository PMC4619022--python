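"""Loop-based free energy of a secondary structure.

This evaluator decomposes a structure into its loops and scores each with
exactly the same H / IL / multiloop-affine terms that the Boltzmann
recursions use, making it the energy oracle for brute-force Boltzmann sums:
for any structure s, exp(-E(s)/RT) summed over enumerated structures must
reproduce the partition function table entry.

Conventions (shared with the DP, dangle-free throughout):

* exterior bases and pairs: 0;
* hairpin (i, j): length-dependent initiation (logarithmic extrapolation
  beyond table size), plus terminal mismatch if a mismatch table is loaded
  and the loop has size > 3, else the terminal-AU penalty;
* internal loops (i, j)-(l, r): stack term for size 0; bulges use the
  initiation ladder (size-1 bulges keep the stack term, larger ones pay
  terminal-AU on both closing pairs); proper internal loops pay initiation,
  Ninio asymmetry and either terminal mismatches (if loaded) or terminal-AU;
  loops with more than ``max_interior_unpaired`` unpaired bases are
  excluded from the ensemble (infinite energy);
* multiloop with N_b pairs (closing included) and N_u unpaired bases:
  a + b*N_b + c*N_u, with no sequence-dependent terms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Tuple

from .errors import UnclassifiableLoop
from .params import TurnerParameters, PAIR_TYPES
from .structure import (
    Loop,
    NucleotideSequence,
    Pair,
    SecondaryStructure,
    loop_decomposition,
)

INF = math.inf


def pair_type(seq: NucleotideSequence, i: int, j: int) -> Optional[str]:
    pt = seq.at(i) + seq.at(j)
    return pt if pt in PAIR_TYPES else None


def _init_energy(table: List[float], size: int, lxc: float) -> float:
    if size < len(table):
        return table[size]
    if not table:
        return 0.0
    base = table[-1]
    if base == INF:
        return INF
    return base + lxc * math.log(size / (len(table) - 1))


def _terminal_au(p: TurnerParameters, pt: str) -> float:
    return p.terminal_au if pt in ("AU", "UA", "GU", "UG") else 0.0


def hairpin_energy(p: TurnerParameters, seq: NucleotideSequence, i: int, j: int) -> float:
    """H(i, j): hairpin closed by (i, j) with j - i - 1 unpaired bases."""
    pt = pair_type(seq, i, j)
    if pt is None:
        return INF
    size = j - i - 1
    e = _init_energy(p.hairpin_init, size, p.lxc)
    if p.mismatch_hairpin is not None and size > 3:
        e += p.mismatch_hairpin[pt]["ACGU".index(seq.at(i + 1))]["ACGU".index(seq.at(j - 1))]
    else:
        e += _terminal_au(p, pt)
    return e


def internal_energy(
    p: TurnerParameters, seq: NucleotideSequence, i: int, j: int, l: int, r: int
) -> float:
    """IL(i, j, l, r): stack, bulge or internal loop between (i,j) and (l,r)."""
    pt_out = pair_type(seq, i, j)
    pt_in = pair_type(seq, l, r)
    if pt_out is None or pt_in is None:
        return INF
    n1 = l - i - 1
    n2 = j - r - 1
    total = n1 + n2
    if p.max_interior_unpaired is not None and total > p.max_interior_unpaired:
        return INF
    if total == 0:
        return p.stack[pt_out][pt_in]
    if n1 == 0 or n2 == 0:  # bulge
        e = _init_energy(p.bulge_init, total, p.lxc)
        if total == 1:
            e += p.stack[pt_out][pt_in]
        else:
            e += _terminal_au(p, pt_out) + _terminal_au(p, pt_in)
        return e
    e = _init_energy(p.internal_init, total, p.lxc)
    e += min(p.ninio_max, p.ninio_m * abs(n1 - n2))
    if p.mismatch_internal is not None:
        rev = seq.at(r) + seq.at(l)  # inner pair viewed from inside the loop
        if rev in PAIR_TYPES:
            e += p.mismatch_internal[pt_out]["ACGU".index(seq.at(i + 1))]["ACGU".index(seq.at(j - 1))]
            e += p.mismatch_internal[rev]["ACGU".index(seq.at(r + 1))]["ACGU".index(seq.at(l - 1))]
    else:
        e += _terminal_au(p, pt_out) + _terminal_au(p, pt_in)
    return e


def multiloop_energy(p: TurnerParameters, n_branches: int, n_unpaired: int) -> float:
    """Affine multiloop score; n_branches counts the closing pair too."""
    return p.ml_closing + p.ml_branch * n_branches + p.ml_unpaired * n_unpaired


@dataclass
class EnergyEvaluation:
    total: float  # kcal/mol; inf when the structure is excluded
    loop_decomposition: List[Tuple[str, Optional[Pair], float]]

    def boltzmann_factor(self, rt: float) -> float:
        return 0.0 if self.total == INF else math.exp(-self.total / rt)


def energy_of_structure(
    seq: NucleotideSequence, s: SecondaryStructure, p: TurnerParameters
) -> EnergyEvaluation:
    """Total loop-decomposed free energy of s under parameters p."""
    parts: List[Tuple[str, Optional[Pair], float]] = []
    total = 0.0
    for loop in loop_decomposition(s):
        if loop.kind == "exterior":
            e = 0.0
        elif loop.kind == "hairpin":
            i, j = loop.closing
            e = hairpin_energy(p, seq, i, j)
        elif loop.kind == "internal":
            i, j = loop.closing
            (l, r), = loop.children
            e = internal_energy(p, seq, i, j, l, r)
        elif loop.kind == "multiloop":
            e = multiloop_energy(p, len(loop.children) + 1, len(loop.unpaired))
        else:  # pragma: no cover
            raise UnclassifiableLoop(loop.kind)
        parts.append((loop.kind, loop.closing, e))
        if e == INF:
            total = INF
        elif total != INF:
            total += e
    return EnergyEvaluation(total, parts)
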