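"""Move sets, exhaustive enumeration and the brute-force network oracle.

The set of all secondary structures of a sequence forms a network in which
two structures are adjacent when one move transforms one into the other.
Move set MS1 contains base-pair additions and removals; MS2 additionally
contains shift moves, which re-anchor one endpoint of an existing pair;
SHIFT_ONLY is MS2 \\ MS1.

Everything here is exhaustive and therefore limited to short sequences; it
is the ground truth against which the dynamic-programming modules are
validated.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Callable, Iterator, List, Optional, Set, Tuple

import networkx as nx

from .errors import SequenceTooLong
from .structure import (
    NucleotideSequence,
    Pair,
    PairingRule,
    RNA_RULE,
    SecondaryStructure,
    enclosing_pair,
    loop_decomposition,
    write_dot_bracket,
)


class MoveSetId(enum.Enum):
    MS1 = "MS1"  # base-pair addition / removal
    MS2 = "MS2"  # MS1 plus shift moves
    SHIFT_ONLY = "SHIFT_ONLY"  # MS2 \ MS1


class MoveKind(enum.Enum):
    ADD = "add"
    REMOVE = "remove"
    SHIFT = "shift"


@dataclass(frozen=True)
class Move:
    kind: MoveKind
    removed_pair: Optional[Pair] = None
    added_pair: Optional[Pair] = None

    def __post_init__(self):
        if self.kind is MoveKind.ADD:
            assert self.added_pair and not self.removed_pair
        elif self.kind is MoveKind.REMOVE:
            assert self.removed_pair and not self.added_pair
        else:
            assert self.added_pair and self.removed_pair
            shared = set(self.added_pair) & set(self.removed_pair)
            assert len(shared) == 1, "a shift retains exactly one endpoint"

    @property
    def move_class(self) -> str:
        return "shift" if self.kind is MoveKind.SHIFT else "add_remove"


#: Default enumeration caps (structure counts grow roughly like 2.3^n).
ENUMERATION_CAP = 40
ENUMERATION_CAP_WITH_ENERGIES = 25


def _check_cap(n: int, cap: int, force: bool) -> None:
    if n > cap and not force:
        raise SequenceTooLong(
            f"exhaustive enumeration refused for n = {n} > cap = {cap}; "
            "pass force=True to override"
        )


def _candidate_pairs(seq: NucleotideSequence, rule: PairingRule) -> List[Pair]:
    n = seq.n
    return [
        (i, j)
        for i in range(1, n + 1)
        for j in range(i + rule.theta + 1, n + 1)
        if rule.letters_pair(seq.at(i), seq.at(j))
    ]


def _compatible(pairs: List[Pair], cand: Pair) -> bool:
    """cand can be added to the valid pair list without triple/pseudoknot."""
    i, j = cand
    for (x, y) in pairs:
        if i in (x, y) or j in (x, y):
            return False
        if x < i < y < j or i < x < j < y:
            return False
    return True


def enumerate_structures(
    seq: NucleotideSequence,
    rule: PairingRule = RNA_RULE,
    cap: int = ENUMERATION_CAP,
    force: bool = False,
) -> Iterator[SecondaryStructure]:
    """Yield every secondary structure of seq exactly once.

    Deterministic order: lexicographic on the sorted pair list (the empty
    structure first).
    """
    _check_cap(seq.n, cap, force)
    cands = sorted(_candidate_pairs(seq, rule))

    def rec(start: int, chosen: List[Pair]) -> Iterator[SecondaryStructure]:
        yield SecondaryStructure(seq.n, frozenset(chosen))
        for idx in range(start, len(cands)):
            p = cands[idx]
            if _compatible(chosen, p):
                chosen.append(p)
                yield from rec(idx + 1, chosen)
                chosen.pop()

    yield from rec(0, [])


def count_structures(seq: NucleotideSequence, rule: PairingRule = RNA_RULE, **kw) -> int:
    return sum(1 for _ in enumerate_structures(seq, rule, **kw))


def neighbors(
    seq: NucleotideSequence,
    s: SecondaryStructure,
    ms: MoveSetId,
    rule: PairingRule = RNA_RULE,
    move_filter: Optional[Callable[[SecondaryStructure, Move], bool]] = None,
) -> Set[Tuple[Move, SecondaryStructure]]:
    """All (move, structure) reachable from s by one move of the move set.

    Each neighboring structure corresponds to exactly one move, so the size
    of the returned set is the degree N(s).  ``move_filter`` may drop moves
    (used by the restricted multiloop comparator).
    """
    out: Set[Tuple[Move, SecondaryStructure]] = set()
    partner = s.partner()
    cands = _candidate_pairs(seq, rule)
    cand_set = set(cands)
    plist = list(s.sorted_pairs)

    def emit(move: Move, t: SecondaryStructure) -> None:
        if move_filter is None or move_filter(s, move):
            out.add((move, t))

    if ms in (MoveSetId.MS1, MoveSetId.MS2):
        for p in cands:
            if _compatible(plist, p):
                emit(
                    Move(MoveKind.ADD, added_pair=p),
                    s.with_pairs(add=[p]),
                )
        for p in plist:
            emit(
                Move(MoveKind.REMOVE, removed_pair=p),
                s.with_pairs(remove=[p]),
            )
    if ms in (MoveSetId.MS2, MoveSetId.SHIFT_ONLY):
        for (x, y) in plist:
            rest = [q for q in plist if q != (x, y)]
            for keep, drop in ((x, y), (y, x)):
                for w in range(1, seq.n + 1):
                    if w == keep or w == drop:
                        continue
                    new = (min(keep, w), max(keep, w))
                    if new == (x, y):
                        continue
                    if new not in cand_set:
                        continue
                    if partner[w] != 0:
                        continue
                    if _compatible(rest, new):
                        emit(
                            Move(MoveKind.SHIFT, removed_pair=(x, y), added_pair=new),
                            s.with_pairs(add=[new], remove=[(x, y)]),
                        )
    return out


@dataclass
class StructureNetwork:
    """The full move network of a sequence, wrapping a networkx graph."""

    seq: NucleotideSequence
    moveset: MoveSetId
    rule: PairingRule
    nodes: List[SecondaryStructure]
    graph: nx.Graph

    @property
    def undirected_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def directed_edge_count(self) -> int:
        return 2 * self.graph.number_of_edges()

    def degree_sequence(self) -> List[int]:
        return [self.graph.degree(k) for k in range(len(self.nodes))]

    def is_connected(self) -> bool:
        return nx.is_connected(self.graph) if len(self.nodes) else True

    def edge_table(self) -> List[Tuple[int, int, str]]:
        """Edge list rows (from_index, to_index, move_class)."""
        return sorted(
            (u, v, d["move_class"]) if u < v else (v, u, d["move_class"])
            for u, v, d in self.graph.edges(data=True)
        )

    def node_table(self) -> List[Tuple[int, str]]:
        return [(k, write_dot_bracket(s)) for k, s in enumerate(self.nodes)]


def build_network(
    seq: NucleotideSequence,
    ms: MoveSetId,
    rule: PairingRule = RNA_RULE,
    cap: int = ENUMERATION_CAP,
    force: bool = False,
) -> StructureNetwork:
    """Build the full (undirected) move network by brute force."""
    nodes = list(enumerate_structures(seq, rule, cap=cap, force=force))
    index = {s.pairs: k for k, s in enumerate(nodes)}
    g = nx.Graph()
    g.add_nodes_from(range(len(nodes)))
    for k, s in enumerate(nodes):
        for move, t in neighbors(seq, s, ms, rule):
            m = index[t.pairs]
            g.add_edge(k, m, move_class=move.move_class)
    return StructureNetwork(seq, ms, rule, nodes, g)


def brute_force_expected_degree(
    seq: NucleotideSequence,
    ms: MoveSetId,
    rule: PairingRule = RNA_RULE,
    energy_function: Optional[Callable[[SecondaryStructure], float]] = None,
    rt: float = 1.0,
    move_filter: Optional[Callable[[SecondaryStructure, Move], bool]] = None,
    cap: int = ENUMERATION_CAP,
    force: bool = False,
):
    """(Q, Z, degree) by exhaustive enumeration.

    Q = sum_s w(s) N(s), Z = sum_s w(s) with w(s) = exp(-E(s)/RT), or 1 when
    no energy function is given (uniform weights: Q and Z are then exact
    integers).
    """
    import math

    if energy_function is not None and not force:
        cap = min(cap, ENUMERATION_CAP_WITH_ENERGIES)
    Q = 0
    Z = 0
    for s in enumerate_structures(seq, rule, cap=cap, force=force):
        if energy_function is None:
            w = 1
        else:
            e = energy_function(s)
            if e == math.inf:
                continue
            w = math.exp(-e / rt)
        ns = len(neighbors(seq, s, ms, rule, move_filter=move_filter))
        Q += w * ns
        Z += w
    return Q, Z, (Q / Z if Z else 0.0)


# ---------------------------------------------------------------------------
# Restricted multiloop move classification
# ---------------------------------------------------------------------------


def multiloop_restricted_filter(
    seq: NucleotideSequence, rule: PairingRule = RNA_RULE
) -> Callable[[SecondaryStructure, Move], bool]:
    """Move filter reproducing the Boltzmann DP's multiloop conventions.

    The Boltzmann-weighted recursions decompose multiloops the McCaskill
    way, so a handful of geometrically valid moves inside multiloops cannot
    be attributed to any subproblem and are not counted.  The counted set,
    derived from the recursion structure and verified by exhaustive
    cross-checking, is:

    * removals: always counted;
    * additions (x, y): counted unless x and y lie in two different
      unpaired gaps of the same multiloop (the added pair would enclose
      one or more multiloop components);
    * shifts of pair P to a new pair with retained endpoint e and new
      (currently unpaired) endpoint w, where L is the loop of the gap
      containing w:

      - L exterior: counted;
      - L a hairpin or an internal loop (P is necessarily the closing or
        the inner pair): counted;
      - L a multiloop closed by C with components P_1 < ... < P_k:
        not counted when P = C; when P = P_t = (i_t, j_t), counted only if
        w lies in the gap immediately right of j_t and the new pair is
        (i_t, w) or (j_t, w), or if t = 1, w lies in the gap left of i_1
        and the new pair is (w, i_1).
    """

    def allowed(s: SecondaryStructure, move: Move) -> bool:
        if move.kind is MoveKind.REMOVE:
            return True
        if move.kind is MoveKind.ADD:
            x, y = move.added_pair
            enc = enclosing_pair(s, x)
            if enc is None:
                return True  # exterior additions always counted
            # loop under enc containing x (and necessarily y)
            loop = _loop_of(s, enc)
            if loop.kind != "multiloop":
                return True
            return not any(x < c0 and c1 < y for (c0, c1) in loop.children)
        # shift
        rx, ry = move.removed_pair
        ax, ay = move.added_pair
        (w,) = set((ax, ay)) - set((rx, ry))
        enc = enclosing_pair(s, w)
        if enc is None:
            return True
        loop = _loop_of(s, enc)
        if loop.kind in ("hairpin", "internal"):
            return True
        # multiloop
        if move.removed_pair == enc:
            return False  # shifting the closing pair into its own multiloop
        comps = loop.children
        try:
            t = comps.index(move.removed_pair)
        except ValueError:
            return False  # cannot occur for a valid shift
        it, jt = comps[t]
        right_limit = comps[t + 1][0] if t + 1 < len(comps) else (enc[1] if enc else s.n + 1)
        if jt < w < right_limit:
            # gap immediately right of the component
            return move.added_pair in ((it, w), (jt, w))
        if t == 0:
            left_limit = enc[0] if enc else 0
            if left_limit < w < it:
                return move.added_pair == (w, it)
        return False

    def _loop_of(s: SecondaryStructure, closing: Pair):
        for loop in loop_decomposition(s):
            if loop.closing == closing:
                return loop
        raise AssertionError("closing pair not found")  # pragma: no cover

    return allowed
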