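"""Exception hierarchy for rnadegree.

All user-facing errors derive from :class:`RnaDegreeError` so callers (and the
command-line layer) can distinguish input problems (exit code 2) from usage
problems (exit code 1) and internal cross-check failures (exit code 3).
"""


class RnaDegreeError(Exception):
    """Base class for all errors raised by this package."""


class EmptyInput(RnaDegreeError):
    """A sequence string contained no residues."""


class IllegalSymbol(RnaDegreeError):
    """A sequence contained a character outside {A, C, G, U} (after T->U)."""

    def __init__(self, symbol: str, position: int):
        self.symbol = symbol
        self.position = position  # 1-based
        super().__init__(f"illegal symbol {symbol!r} at position {position}")


class IndexOutOfRange(RnaDegreeError):
    """A 1-based position lies outside the sequence."""


class StructureError(RnaDegreeError):
    """A pair set violates one of the secondary-structure conditions."""


class NotAPair(StructureError):
    """Positions cannot pair under the active pairing rule."""


class StericViolation(StructureError):
    """A pair (i, j) violates the minimum hairpin size j - i > theta."""


class BaseTriple(StructureError):
    """A position occurs in more than one base pair."""


class Pseudoknot(StructureError):
    """Two pairs (i, j), (k, l) interleave: i < k < j < l."""


class UnbalancedBrackets(RnaDegreeError):
    """Dot-bracket string with an unmatched parenthesis."""

    def __init__(self, position: int, message: str = "unbalanced bracket"):
        self.position = position  # 1-based, first offender
        super().__init__(f"{message} at position {position}")


class SequenceTooLong(RnaDegreeError):
    """Exhaustive enumeration refused beyond the configured cap."""


class NegativeLength(RnaDegreeError):
    """A homopolymer length below zero was requested."""


class UnknownDialect(RnaDegreeError):
    """An energy-parameter file was not recognized."""


class MissingTable(RnaDegreeError):
    """An energy-parameter file lacks a required section."""


class UnclassifiableLoop(RnaDegreeError):
    """Internal error: a loop of a valid structure could not be classified."""


class EmptyStructure(RnaDegreeError):
    """An operation (e.g. contact order) requires at least one base pair."""


class InvalidReference(RnaDegreeError):
    """A reference structure is not valid for the given sequence."""


class BadRange(RnaDegreeError):
    """Invalid fixture-generation range."""


class DegreeOverflow(RnaDegreeError):
    """A Boltzmann factor overflowed double precision."""
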