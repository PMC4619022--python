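"""Sequences, pairing rules and secondary structures.

A secondary structure of a sequence a_1..a_n is a set of base pairs (i, j),
1 <= i < j <= n (1-based, inclusive), such that

1. a_i, a_j can pair under the active rule (Watson-Crick or wobble for real
   sequences; any two positions for the homopolymer model),
2. j - i > theta (steric constraint; theta = 3 for nucleotide sequences,
   theta = 1 for the homopolymer),
3. no position occurs in two pairs (no base triples),
4. no two pairs (i, j), (k, l) interleave with i < k < j < l (no pseudoknots).

All public coordinates are 1-based.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional, Tuple

from .errors import (
    BaseTriple,
    EmptyInput,
    IllegalSymbol,
    IndexOutOfRange,
    NotAPair,
    Pseudoknot,
    StericViolation,
    UnbalancedBrackets,
)

Pair = Tuple[int, int]

#: Watson-Crick plus wobble pairs.
WC_WOBBLE = frozenset(
    [("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")]
)

_VALID = frozenset("ACGU")


class PairingMode(enum.Enum):
    HOMOPOLYMER = "homopolymer"  # every position pair allowed
    WATSON_CRICK_WOBBLE = "watson_crick_wobble"


@dataclass(frozen=True)
class PairingRule:
    """Which (i, j) may pair: a minimum separation theta plus a letter rule."""

    mode: PairingMode = PairingMode.WATSON_CRICK_WOBBLE
    theta: int = None  # type: ignore[assignment]

    def __post_init__(self):
        if self.theta is None:
            default = 1 if self.mode is PairingMode.HOMOPOLYMER else 3
            object.__setattr__(self, "theta", default)
        if self.theta < 0:
            raise ValueError("theta must be non-negative")

    def letters_pair(self, a: str, b: str) -> bool:
        if self.mode is PairingMode.HOMOPOLYMER:
            return True
        return (a, b) in WC_WOBBLE


#: Convenience instances for the two models used throughout.
HOMOPOLYMER_RULE = PairingRule(PairingMode.HOMOPOLYMER)
RNA_RULE = PairingRule(PairingMode.WATSON_CRICK_WOBBLE)


@dataclass(frozen=True)
class NucleotideSequence:
    """An RNA sequence over {A, C, G, U}; indexable with 1-based positions."""

    residues: str

    def __post_init__(self):
        if not self.residues:
            raise EmptyInput("empty sequence")
        for k, ch in enumerate(self.residues, start=1):
            if ch not in _VALID:
                raise IllegalSymbol(ch, k)

    @property
    def n(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues

    def at(self, i: int) -> str:
        """Residue at 1-based position i."""
        if not 1 <= i <= self.n:
            raise IndexOutOfRange(f"position {i} outside [1, {self.n}]")
        return self.residues[i - 1]


def parse_sequence(text: str) -> NucleotideSequence:
    """Parse a raw string or single-record FASTA chunk into a sequence.

    Uppercases, maps T to U, skips FASTA header lines and whitespace.
    """
    lines = [ln.strip() for ln in text.splitlines()]
    body = "".join(ln for ln in lines if ln and not ln.startswith((">", ";")))
    body = body.upper().replace("T", "U")
    if not body:
        raise EmptyInput("no sequence data found")
    return NucleotideSequence(body)


def homopolymer(n: int) -> NucleotideSequence:
    """A length-n stand-in sequence for the homopolymer model (all A's)."""
    return NucleotideSequence("A" * n)


def can_pair(seq: NucleotideSequence, i: int, j: int, rule: PairingRule) -> bool:
    """True iff positions i < j of seq may form a base pair under the rule."""
    if not (1 <= i <= seq.n and 1 <= j <= seq.n and i < j):
        raise IndexOutOfRange(f"need 1 <= i < j <= {seq.n}, got ({i}, {j})")
    if j - i <= rule.theta:
        return False
    return rule.letters_pair(seq.at(i), seq.at(j))


@dataclass(frozen=True)
class SecondaryStructure:
    """An immutable set of base pairs on a length-n backbone."""

    n: int
    pairs: frozenset = field(default_factory=frozenset)

    @property
    def sorted_pairs(self) -> Tuple[Pair, ...]:
        return tuple(sorted(self.pairs))

    def __len__(self) -> int:
        return len(self.pairs)

    def partner(self) -> list:
        """0-index-unused array p with p[i] = partner of i, or 0 if unpaired."""
        p = [0] * (self.n + 1)
        for i, j in self.pairs:
            p[i] = j
            p[j] = i
        return p

    def is_paired(self, k: int) -> bool:
        return any(k == i or k == j for i, j in self.pairs)

    def external_pairs(self) -> frozenset:
        """Pairs not enclosed by any other pair of the structure."""
        out = []
        for (i, j) in self.pairs:
            if not any(x < i and j < y for (x, y) in self.pairs):
                out.append((i, j))
        return frozenset(out)

    def visible_positions(self) -> Tuple[int, ...]:
        """Positions k with no pair (i, j) such that i <= k <= j."""
        covered = [False] * (self.n + 1)
        for i, j in self.pairs:
            for k in range(i, j + 1):
                covered[k] = True
        return tuple(k for k in range(1, self.n + 1) if not covered[k])

    def with_pairs(self, add: Iterable[Pair] = (), remove: Iterable[Pair] = ()) -> "SecondaryStructure":
        return SecondaryStructure(self.n, frozenset(self.pairs - set(remove) | set(add)))


def validate_structure(
    seq: NucleotideSequence, pairs: Iterable[Pair], rule: PairingRule
) -> SecondaryStructure:
    """Check all four structure conditions; raise on the first violation.

    Violations are reported in the order: pairing rule, steric constraint,
    base triple, pseudoknot.
    """
    plist = sorted(tuple(p) for p in pairs)
    n = seq.n
    for (i, j) in plist:
        if not (1 <= i < j <= n):
            raise IndexOutOfRange(f"pair ({i}, {j}) outside 1..{n}")
        if not rule.letters_pair(seq.at(i), seq.at(j)):
            raise NotAPair(f"{seq.at(i)}{seq.at(j)} at ({i}, {j}) cannot pair")
        if j - i <= rule.theta:
            raise StericViolation(f"pair ({i}, {j}): j - i <= theta = {rule.theta}")
    seen: dict = {}
    for (i, j) in plist:
        for k in (i, j):
            if k in seen:
                raise BaseTriple(f"position {k} occurs in pairs {seen[k]} and ({i}, {j})")
        seen[i] = (i, j)
        seen[j] = (i, j)
    for a in range(len(plist)):
        i, j = plist[a]
        for b in range(a + 1, len(plist)):
            k, l = plist[b]
            if i < k < j < l:
                raise Pseudoknot(f"pairs ({i}, {j}) and ({k}, {l}) interleave")
    return SecondaryStructure(n, frozenset(plist))


def parse_dot_bracket(text: str) -> frozenset:
    """Matched-parenthesis pairs of a dot-bracket string, as 1-based pairs."""
    text = text.strip()
    stack = []
    pairs = []
    for k, ch in enumerate(text, start=1):
        if ch == "(":
            stack.append(k)
        elif ch == ")":
            if not stack:
                raise UnbalancedBrackets(k, "unmatched ')'")
            pairs.append((stack.pop(), k))
        elif ch != ".":
            raise UnbalancedBrackets(k, f"unexpected character {ch!r}")
    if stack:
        raise UnbalancedBrackets(stack[-1], "unmatched '('")
    return frozenset(pairs)


def write_dot_bracket(s: SecondaryStructure) -> str:
    """Dot-bracket string of a (pseudoknot-free) structure."""
    out = ["."] * s.n
    for i, j in s.pairs:
        out[i - 1] = "("
        out[j - 1] = ")"
    return "".join(out)


def structure_from_dot_bracket(
    seq: NucleotideSequence, text: str, rule: PairingRule = RNA_RULE
) -> SecondaryStructure:
    """Parse and validate a dot-bracket string against a sequence."""
    if len(text.strip()) != seq.n:
        raise UnbalancedBrackets(
            min(len(text.strip()), seq.n) + 1,
            f"dot-bracket length {len(text.strip())} != sequence length {seq.n}",
        )
    return validate_structure(seq, parse_dot_bracket(text), rule)


# ---------------------------------------------------------------------------
# Loop decomposition
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Loop:
    """One face of the structure's arc diagram.

    kind is one of "exterior", "hairpin", "internal" (stacked pairs and
    bulges included) or "multiloop".  ``closing`` is the enclosing pair
    (None for the exterior loop); ``children`` are the directly nested
    pairs, left to right; ``unpaired`` are the loop's unpaired positions.
    """

    kind: str
    closing: Optional[Pair]
    children: Tuple[Pair, ...]
    unpaired: Tuple[int, ...]


def loop_decomposition(s: SecondaryStructure) -> Tuple[Loop, ...]:
    """All loops of s, exterior loop first, then by closing pair order."""
    pairs = s.sorted_pairs
    partner = s.partner()

    def face(closing: Optional[Pair]) -> Loop:
        lo, hi = (closing[0] + 1, closing[1] - 1) if closing else (1, s.n)
        children = []
        unpaired = []
        k = lo
        while k <= hi:
            if partner[k] > k:
                children.append((k, partner[k]))
                k = partner[k] + 1
            elif partner[k] == 0:
                unpaired.append(k)
                k += 1
            else:  # partner[k] < k cannot happen scanning left-to-right
                k += 1
        if closing is None:
            kind = "exterior"
        elif not children:
            kind = "hairpin"
        elif len(children) == 1:
            kind = "internal"
        else:
            kind = "multiloop"
        return Loop(kind, closing, tuple(children), tuple(unpaired))

    loops = [face(None)]
    loops.extend(face(p) for p in pairs)
    return tuple(loops)


def enclosing_pair(s: SecondaryStructure, k: int) -> Optional[Pair]:
    """Innermost pair (i, j) of s with i <= k <= j, or None (exterior)."""
    best = None
    for (i, j) in s.pairs:
        if i <= k <= j:
            if best is None or (i > best[0]):
                best = (i, j)
    return best


def base_pair_distance(s: SecondaryStructure, t: SecondaryStructure) -> int:
    """Number of pairs in exactly one of s, t."""
    return len(s.pairs ^ t.pairs)
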