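"""Degree distributions and kinetic order parameters.

Everything here is enumeration-based and therefore intended for short
sequences (the same caps as the brute-force oracle): the degree
distribution N(s) over the full or energy-bounded ensemble, the 2D contact
order of a reference structure, the expected number of native contacts
sum_{(i,j) in s0} p_ij, and the conformational entropy -sum_s p(s) ln p(s)
(in units of k_B).

Distributions count full move-set neighbors N(s) on explicit structures
(not the multiloop-restricted N* used inside the Boltzmann DP); the report
records which counter was used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import pandas as pd

from .energy import energy_of_structure
from .errors import EmptyStructure, InvalidReference
from .network import (
    ENUMERATION_CAP,
    ENUMERATION_CAP_WITH_ENERGIES,
    MoveSetId,
    enumerate_structures,
    neighbors,
)
from .params import TurnerParameters
from .structure import (
    NucleotideSequence,
    PairingRule,
    RNA_RULE,
    SecondaryStructure,
    validate_structure,
)
from .uniform import uniform_expected_degree

__all__ = [
    "DegreeDistribution",
    "degree_distribution",
    "ContactOrderReport",
    "contact_order",
    "NativeContactReport",
    "expected_native_contacts",
    "conformational_entropy",
    "metrics_table",
]


def _weights(seq, structures, model, params):
    if model == "B":
        return [1.0] * len(structures), [0.0] * len(structures)
    energies = [energy_of_structure(seq, s, params).total for s in structures]
    rt = params.rt
    return [0.0 if e == math.inf else math.exp(-e / rt) for e in energies], energies


@dataclass
class DegreeDistribution:
    """Weighted histogram of neighbor counts N(s) over an ensemble."""

    histogram: Dict[int, float]  # degree -> normalized weight
    mean: float
    standard_deviation: float
    coverage: float  # Z*/Z; 1.0 for full enumeration
    normalization_constant: float  # Z*
    moveset: MoveSetId
    model: str
    neighbor_counter: str = "full"

    def as_rows(self) -> List[Tuple[int, float]]:
        return sorted(self.histogram.items())


def degree_distribution(
    seq: NucleotideSequence,
    model: str = "B",
    params: Optional[TurnerParameters] = None,
    ms: MoveSetId = MoveSetId.MS2,
    energy_cutoff: Optional[float] = None,
    rule: PairingRule = RNA_RULE,
    cap: int = ENUMERATION_CAP_WITH_ENERGIES,
    force: bool = False,
    neighbor_counter: str = "full",
) -> DegreeDistribution:
    """Enumerate the ensemble and histogram N(s).

    With ``energy_cutoff`` (model C only, kcal/mol above the minimum
    enumerated energy) only structures inside the band contribute; the
    reported ``coverage`` is Z*/Z.  ``neighbor_counter`` is "full" (every
    move of the move set) or "restricted" (the multiloop-restricted counter
    N* that the Boltzmann DP computes).
    """
    if model == "C" and params is None:
        raise ValueError("model C requires parameters")
    if neighbor_counter not in ("full", "restricted"):
        raise ValueError("neighbor_counter must be 'full' or 'restricted'")
    move_filter = None
    if neighbor_counter == "restricted":
        from .network import multiloop_restricted_filter

        move_filter = multiloop_restricted_filter(seq, rule)
    structures = list(enumerate_structures(seq, rule, cap=cap, force=force))
    w, energies = _weights(seq, structures, model, params)
    z_full = sum(w)
    keep = range(len(structures))
    if energy_cutoff is not None and model == "C":
        emin = min(energies)
        keep = [k for k in keep if energies[k] <= emin + energy_cutoff]
    hist: Dict[int, float] = {}
    z_star = 0.0
    m1 = 0.0
    m2 = 0.0
    for k in keep:
        if w[k] == 0.0:
            continue
        deg = len(neighbors(seq, structures[k], ms, rule, move_filter=move_filter))
        hist[deg] = hist.get(deg, 0.0) + w[k]
        z_star += w[k]
        m1 += w[k] * deg
        m2 += w[k] * deg * deg
    mean = m1 / z_star if z_star else 0.0
    var = max(0.0, m2 / z_star - mean * mean) if z_star else 0.0
    hist = {d: v / z_star for d, v in hist.items()} if z_star else {}
    return DegreeDistribution(
        histogram=hist,
        mean=mean,
        standard_deviation=math.sqrt(var),
        coverage=z_star / z_full if z_full else 0.0,
        normalization_constant=z_star,
        moveset=ms,
        model=model,
        neighbor_counter=neighbor_counter,
    )


@dataclass
class ContactOrderReport:
    absolute: float  # mean chain separation sum (j - i) / N
    relative: float  # absolute / n
    n_pairs: int


def contact_order(s: SecondaryStructure, n: Optional[int] = None) -> ContactOrderReport:
    """2D contact order of a structure: sum over pairs of (j - i) / N."""
    if not s.pairs:
        raise EmptyStructure("contact order undefined for the empty structure")
    length = n if n is not None else s.n
    total = sum(j - i for i, j in s.pairs)
    absolute = total / len(s.pairs)
    return ContactOrderReport(absolute, absolute / length, len(s.pairs))


@dataclass
class NativeContactReport:
    expected_native_contacts: float
    reference_structure: SecondaryStructure
    pair_probabilities: Dict[Tuple[int, int], float]


def expected_native_contacts(
    seq: NucleotideSequence,
    s0: SecondaryStructure,
    model: str = "B",
    params: Optional[TurnerParameters] = None,
    rule: PairingRule = RNA_RULE,
    cap: int = ENUMERATION_CAP_WITH_ENERGIES,
    force: bool = False,
) -> NativeContactReport:
    """sum_{(i,j) in s0} p_ij with pair probabilities from enumeration."""
    if s0.n != seq.n:
        raise InvalidReference("reference structure length mismatch")
    validate_structure(seq, s0.pairs, rule)
    structures = list(enumerate_structures(seq, rule, cap=cap, force=force))
    w, _ = _weights(seq, structures, model, params)
    z = sum(w)
    probs: Dict[Tuple[int, int], float] = {p: 0.0 for p in s0.sorted_pairs}
    for wk, s in zip(w, structures):
        if wk == 0.0:
            continue
        for p in s.pairs & s0.pairs:
            probs[p] += wk
    probs = {p: v / z for p, v in probs.items()}
    return NativeContactReport(sum(probs.values()), s0, probs)


def conformational_entropy(
    seq: NucleotideSequence,
    model: str = "B",
    params: Optional[TurnerParameters] = None,
    rule: PairingRule = RNA_RULE,
    cap: int = ENUMERATION_CAP_WITH_ENERGIES,
    force: bool = False,
) -> float:
    """-sum_s p(s) ln p(s) over the enumerated ensemble, in units of k_B."""
    structures = list(enumerate_structures(seq, rule, cap=cap, force=force))
    w, _ = _weights(seq, structures, model, params)
    z = sum(w)
    ent = 0.0
    for wk in w:
        if wk > 0.0:
            p = wk / z
            ent -= p * math.log(p)
    return ent


def metrics_table(
    rows: List[Tuple[str, NucleotideSequence, SecondaryStructure]],
    params: Optional[TurnerParameters] = None,
    rule: PairingRule = RNA_RULE,
    cap: int = ENUMERATION_CAP_WITH_ENERGIES,
    force: bool = False,
) -> pd.DataFrame:
    """Per-sequence order-parameter matrix for (id, sequence, structure) rows.

    Columns: uniform expected degree for MS1/MS2, conformational entropy,
    absolute/relative contact order of the supplied structure, and expected
    native contacts with the supplied structure as reference.  Use
    ``df.corr()`` for the Pearson correlation matrix.
    """
    recs = []
    for sid, seq, s0 in rows:
        _, _, d1, _ = uniform_expected_degree(seq, MoveSetId.MS1, rule)
        _, _, d2, _ = uniform_expected_degree(seq, MoveSetId.MS2, rule)
        model = "C" if params is not None else "B"
        co = contact_order(s0)
        nc = expected_native_contacts(seq, s0, model, params, rule, cap=cap, force=force)
        ent = conformational_entropy(seq, model, params, rule, cap=cap, force=force)
        recs.append(
            {
                "sequence_id": sid,
                "length": seq.n,
                "degree_ms1": float(d1),
                "degree_ms2": float(d2),
                "entropy": ent,
                "contact_order_abs": co.absolute,
                "contact_order_rel": co.relative,
                "native_contacts": nc.expected_native_contacts,
            }
        )
    return pd.DataFrame.from_records(recs).set_index("sequence_id")
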