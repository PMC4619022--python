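"""Canonical worked examples and the seeded fixture generator."""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import List, Tuple

from .errors import BadRange
from .structure import NucleotideSequence

#: 7-mer whose full MS2 network has 8 nodes and 16 undirected edges.
TOY_GGGGCCC = "GGGGCCC"
#: 12-mer with 35 structures; 126 directed MS1 edges, 68 directed shifts.
TOY_ACGU12 = "ACGUACGUACGU"
#: 102-nt Y RNA (consensus secondary structure with one external pair (1, 98)).
Y_RNA_SEQUENCE = (
    "GGCUGGUCCGAGUGCAGUGGUGUUUACAACUAAUUGAUCACAGCCAGUUACAGAUUCCUUUGUUCCUUCUCUACUCCCACUGCUUCACUUGACUAGCCUUUU"
)
Y_RNA_DOT_BRACKET = (
    "((((((((.((..(((((((.(.....(((.((.........................)).)))...........))))))...))..))))))))))...."
)

CANONICAL: List[Tuple[str, str]] = [
    ("toy_GGGGCCC", TOY_GGGGCCC),
    ("toy_ACGUACGUACGU", TOY_ACGU12),
    ("yrna_102", Y_RNA_SEQUENCE),
]


@dataclass
class FixtureSet:
    seed: int
    sequences: List[Tuple[str, NucleotideSequence]]

    def to_fasta(self) -> str:
        out = []
        for sid, seq in self.sequences:
            out.append(f">{sid}\n{seq.residues}\n")
        return "".join(out)


def generate_fixtures(
    seed: int,
    count: int = 0,
    min_len: int = 8,
    max_len: int = 16,
    gc_bias: float = 0.5,
) -> FixtureSet:
    """Canonical sequences plus ``count`` reproducible random ones.

    ``gc_bias`` is the probability mass on {G, C} (split evenly); the
    remainder goes to {A, U}.  The same seed always yields byte-identical
    FASTA output.
    """
    if min_len > max_len or min_len < 1 or count < 0:
        raise BadRange(f"bad range: count={count}, len in [{min_len}, {max_len}]")
    if not 0.0 <= gc_bias <= 1.0:
        raise BadRange("gc_bias must be in [0, 1]")
    rng = random.Random(seed)
    seqs = [(sid, NucleotideSequence(s)) for sid, s in CANONICAL]
    weights = [
        (1 - gc_bias) / 2,  # A
        gc_bias / 2,  # C
        gc_bias / 2,  # G
        (1 - gc_bias) / 2,  # U
    ]
    for k in range(count):
        n = rng.randint(min_len, max_len)
        s = "".join(rng.choices("ACGU", weights=weights, k=n))
        seqs.append((f"rand_{seed}_{k:04d}", NucleotideSequence(s)))
    return FixtureSet(seed, seqs)


def random_sequences(seed: int, count: int, min_len: int, max_len: int) -> List[NucleotideSequence]:
    """Unbiased random sequences only (no canonical entries)."""
    rng = random.Random(seed)
    out = []
    for _ in range(count):
        n = rng.randint(min_len, max_len)
        out.append(NucleotideSequence("".join(rng.choice("ACGU") for _ in range(n))))
    return out
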