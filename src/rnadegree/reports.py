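"""Serializable degree reports."""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Optional

#: significant digits used when serializing floating-point results
SIG_DIGITS = 12


def _round(v):
    if isinstance(v, float):
        return float(f"{v:.{SIG_DIGITS}g}")
    return v


@dataclass
class DegreeReport:
    sequence_id: str
    sequence: str
    model: str  # A | B | C
    moveset: str
    theta: int
    Z: float
    Q: float
    expected_degree: float
    normalized_degree: float
    parameter_set_id: Optional[str] = None
    undirected_edges: Optional[int] = None  # oracle runs only
    directed_edge_count: Optional[int] = None

    def to_json(self) -> str:
        d = {k: _round(v) for k, v in asdict(self).items() if v is not None}
        return json.dumps(d, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "DegreeReport":
        return cls(**json.loads(text))
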