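"""Nearest-neighbor energy parameters (dangle-free).

The Boltzmann model scores a structure as a sum of loop free energies:
hairpins H(i, j), internal loops IL(i, j, l, r) (stacked pairs and bulges
included) and an affine multiloop term a + b*N_b + c*N_u for a multiloop
with N_b base pairs (components plus the closing pair) and N_u unpaired
bases.  Exterior bases and pairs contribute nothing (no dangling ends, no
exterior terminal penalties), which is what makes the partition-function
recursions multiplicative across exterior segments.

Three sources of parameters are supported:

* ``zero``            - every term 0.0 (the uniform limit; no interior cap);
* ``builtin_minimal`` - a compact, self-contained nearest-neighbor set with
  realistic magnitudes (stacks, length-dependent loop initiations, Ninio
  asymmetry, terminal-AU penalty, multiloop affine coefficients);
* Vienna-dialect parameter files ("## RNAfold parameter file v2.0"), e.g.
  the Turner 1999 / Turner 2004 tables shipped with the Vienna RNA package.

Energies are kept in kcal/mol; R = 0.00198717 kcal/(mol K).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Tuple

from .errors import MissingTable, UnknownDialect

R_KCAL = 0.00198717
T37 = 310.15

#: canonical pair-type order used by stack/mismatch tables
PAIR_TYPES = ("CG", "GC", "GU", "UG", "AU", "UA")
_NT = "ACGU"
INF = math.inf


@dataclass
class TurnerParameters:
    parameter_set_id: str
    temperature: float = T37  # Kelvin
    max_interior_unpaired: Optional[int] = 30
    # loop tables (kcal/mol)
    stack: Dict[str, Dict[str, float]] = field(default_factory=dict)  # [pt1][pt2]
    hairpin_init: List[float] = field(default_factory=list)  # index = size
    bulge_init: List[float] = field(default_factory=list)
    internal_init: List[float] = field(default_factory=list)
    mismatch_hairpin: Optional[Dict[str, List[List[float]]]] = None  # [pt][5'][3']
    mismatch_internal: Optional[Dict[str, List[List[float]]]] = None
    terminal_au: float = 0.0
    ninio_m: float = 0.0
    ninio_max: float = 0.0
    ml_closing: float = 0.0  # a
    ml_branch: float = 0.0  # b
    ml_unpaired: float = 0.0  # c
    lxc: float = 1.07856  # loop-size extrapolation coefficient

    @property
    def rt(self) -> float:
        return R_KCAL * self.temperature

    @property
    def multiloop_affine(self) -> Tuple[float, float, float]:
        return (self.ml_closing, self.ml_branch, self.ml_unpaired)

    def is_zero(self) -> bool:
        return self.parameter_set_id == "zero"

    # -- serialization ---------------------------------------------------
    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TurnerParameters":
        return cls(**json.loads(text))


def zero_parameters(temperature: float = T37) -> TurnerParameters:
    """All-zero energies: Boltzmann weights collapse to uniform counting."""
    size31 = [0.0] * 31
    return TurnerParameters(
        parameter_set_id="zero",
        temperature=temperature,
        max_interior_unpaired=None,
        stack={p: {q: 0.0 for q in PAIR_TYPES} for p in PAIR_TYPES},
        hairpin_init=list(size31),
        bulge_init=list(size31),
        internal_init=list(size31),
        lxc=0.0,
    )


def builtin_minimal(temperature: float = T37) -> TurnerParameters:
    """Self-contained parameter set with Turner-like magnitudes."""
    stack_vals = {
        # symmetric-ish stabilities, kcal/mol, 5'->3' outer pair x inner pair
        "CG": {"CG": -2.4, "GC": -3.3, "GU": -2.1, "UG": -1.4, "AU": -2.1, "UA": -2.1},
        "GC": {"CG": -3.3, "GC": -3.4, "GU": -2.5, "UG": -1.5, "AU": -2.2, "UA": -2.4},
        "GU": {"CG": -2.1, "GC": -2.5, "GU": 1.3, "UG": -0.5, "AU": -1.4, "UA": -1.3},
        "UG": {"CG": -1.4, "GC": -1.5, "GU": -0.5, "UG": 0.3, "AU": -0.6, "UA": -1.0},
        "AU": {"CG": -2.1, "GC": -2.2, "GU": -1.4, "UG": -0.6, "AU": -1.1, "UA": -0.9},
        "UA": {"CG": -2.1, "GC": -2.4, "GU": -1.3, "UG": -1.0, "AU": -0.9, "UA": -1.3},
    }

    def ladder(first: float, last: float) -> List[float]:
        # smooth log-like interpolation from size 3 (bulge/internal: 1/2) to 30
        out = [INF] * 31
        for m in range(1, 31):
            out[m] = first + (last - first) * math.log(m) / math.log(30)
        return out

    hp = [INF] * 31
    for m in range(3, 31):
        hp[m] = 5.4 + 2.3 * math.log(m / 3.0)
    return TurnerParameters(
        parameter_set_id="builtin_minimal",
        temperature=temperature,
        stack=stack_vals,
        hairpin_init=hp,
        bulge_init=ladder(3.8, 6.1),
        internal_init=ladder(1.7, 6.5),
        terminal_au=0.5,
        ninio_m=0.6,
        ninio_max=3.0,
        ml_closing=3.4,
        ml_branch=0.4,
        ml_unpaired=0.0,
    )


# ---------------------------------------------------------------------------
# Vienna-dialect loader
# ---------------------------------------------------------------------------


def _strip_comments(line: str) -> str:
    out = line
    if "/*" in out:
        pre, _, rest = out.partition("/*")
        _, _, post = rest.partition("*/")
        out = pre + post
    return out.strip()


def _tokens(lines: List[str], start: int, count: int) -> Tuple[List[float], int]:
    vals: List[float] = []
    k = start
    while len(vals) < count and k < len(lines):
        ln = _strip_comments(lines[k])
        k += 1
        if not ln:
            continue
        if ln.startswith("#"):
            raise MissingTable(f"section ended early at line {k} while reading values")
        for tok in ln.split():
            if tok.upper().startswith("INF"):
                vals.append(INF)
            else:
                vals.append(int(tok) / 100.0)  # dal/mol -> kcal/mol
    if len(vals) < count:
        raise MissingTable(f"truncated table: expected {count} values")
    return vals[:count], k


def load_vienna_file(path: str, temperature: float = T37) -> TurnerParameters:
    """Read the subset of a Vienna 2.0 parameter file this model consumes.

    Sections used: stack, mismatch_hairpin, mismatch_internal, hairpin,
    bulge, internal, ML_params, NINIO, Misc.  Enthalpies, dangles (off by
    construction), coaxial terms and special loops are ignored.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or "RNAfold parameter file" not in lines[0]:
        raise UnknownDialect(f"{path}: not a Vienna 2.0 parameter file")

    sections: Dict[str, int] = {}
    for k, ln in enumerate(lines):
        if ln.startswith("# "):
            sections[ln[2:].strip()] = k + 1

    def have(name: str) -> bool:
        return name in sections

    def need(name: str) -> int:
        if name not in sections:
            raise MissingTable(f"{path}: missing section '{name}'")
        return sections[name]

    p = TurnerParameters(parameter_set_id=path, temperature=temperature)

    vals, _ = _tokens(lines, need("stack"), 49)
    p.stack = {
        pt1: {pt2: vals[a * 7 + b] for b, pt2 in enumerate(PAIR_TYPES)}
        for a, pt1 in enumerate(PAIR_TYPES)
    }
    vals, _ = _tokens(lines, need("hairpin"), 31)
    p.hairpin_init = vals
    vals, _ = _tokens(lines, need("bulge"), 31)
    p.bulge_init = vals
    vals, _ = _tokens(lines, need("internal"), 31)
    p.internal_init = vals

    def mismatch(name: str) -> Optional[Dict[str, List[List[float]]]]:
        if not have(name):
            return None
        vals, _ = _tokens(lines, sections[name], 7 * 5 * 5)
        out = {}
        for a, pt in enumerate(PAIR_TYPES):
            block = vals[a * 25 : (a + 1) * 25]
            # rows/cols ordered E,A,C,G,U; keep the 4x4 ACGU part
            out[pt] = [[block[(r + 1) * 5 + (c + 1)] for c in range(4)] for r in range(4)]
        return out

    p.mismatch_hairpin = mismatch("mismatch_hairpin")
    p.mismatch_internal = mismatch("mismatch_internal")

    vals, _ = _tokens(lines, need("ML_params"), 6)
    p.ml_unpaired, p.ml_closing, p.ml_branch = vals[0], vals[2], vals[4]
    if have("NINIO"):
        vals, _ = _tokens(lines, sections["NINIO"], 3)
        p.ninio_m, p.ninio_max = vals[0], vals[2]
    if have("Misc"):
        vals, _ = _tokens(lines, sections["Misc"], 4)
        p.terminal_au = vals[2]
    return p


def load_parameters(source: str, temperature: float = T37) -> TurnerParameters:
    """Builtin label ('zero', 'builtin_minimal') or Vienna parameter file."""
    if source == "zero":
        return zero_parameters(temperature)
    if source in ("builtin_minimal", "builtin"):
        return builtin_minimal(temperature)
    return load_vienna_file(source, temperature)
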