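"""Expected network degree of the RNA homopolymer (model A).

In the homopolymer model any two positions i < j may pair provided
j - i > theta (default theta = 1), every structure has energy zero, and all
quantities depend only on the interval length n.  The module computes, for
each n up to ``n_max``:

* ``Z[n]``   - the number of secondary structures of [1, n];
* ``E[n]``   - the total number of external base pairs over all structures;
* ``Q_ms1`` / ``Q_ms2`` - the total number of neighbors over all structures
  under MS1 (additions/removals) and MS2 (plus shifts);

together with the visible-position profiles f(n, x) (structures with exactly
x visible positions) and g(n, x) (structures with position n unpaired and x
visible positions in [1, n - theta - 1]).

The degree recursions only consume the first two moments of f and g, so the
large-n path tracks sum_x x * f(n, x) and sum_x x (x-1) * f(n, x) directly
(arrays F1, F2), bringing the whole computation to O(n^2) time and O(n)
space; the full profiles are materialized separately for moderate n where
they are cross-checked against exhaustive enumeration.

Counts overflow fixed-width floats near n ~ 370, so two representations are
offered: exact arbitrary-precision integers, and geometrically rescaled
floats that store X_n / s^n for a growth estimate s (only ratios such as
Q_n / (n Z_n) are ever materialized).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

from .errors import IndexOutOfRange, NegativeLength
from .network import MoveSetId

__all__ = [
    "HomopolymerTables",
    "compute_homopolymer_tables",
    "homopolymer_Q",
    "normalized_degree",
    "expected_degree",
    "f_table",
    "g_table",
]


@dataclass
class HomopolymerTables:
    """DP arrays for the length range 0..n_max (index = length)."""

    theta: int
    n_max: int
    representation: str  # "exact_integer" | "rescaled_float"
    Z: List
    E: List
    F1: List  # sum_x x f(n, x)
    F2: List  # sum_x x (x - 1) f(n, x)
    Q_ms1: List
    Q_ms2: List
    scale: Optional[float] = None  # rescaled_float: stored X_n = true X_n / scale^n
    f: Optional[List[List[int]]] = None  # full profile, exact mode on request
    g: Optional[List[List[int]]] = None

    def Q(self, ms: MoveSetId) -> List:
        if ms is MoveSetId.MS1:
            return self.Q_ms1
        if ms is MoveSetId.MS2:
            return self.Q_ms2
        return [a - b for a, b in zip(self.Q_ms2, self.Q_ms1)]


def _z_recursion(n_max: int, theta: int) -> List[int]:
    """Exact structure counts; with pair (r+1, n) the interval splits as
    [1, r] x [r+2, n-1], giving Z_n = Z_{n-1} + sum_r Z_r Z_{n-r-2} over
    r <= n - theta - 2."""
    Z = [1] * min(theta + 2, n_max + 1)
    for n in range(len(Z), n_max + 1):
        acc = Z[n - 1]
        for r in range(0, n - theta - 1):
            acc += Z[r] * Z[n - r - 2]
        Z.append(acc)
    return Z


def compute_homopolymer_tables(
    n_max: int,
    theta: int = 1,
    representation: str = "exact_integer",
    with_profiles: Optional[bool] = None,
) -> HomopolymerTables:
    """Fill all homopolymer arrays up to n_max.

    ``with_profiles`` additionally stores the full f and g tables (exact
    representation only; defaults to True for n_max <= 200).
    """
    if n_max < 0:
        raise NegativeLength(f"n_max = {n_max}")
    if representation not in ("exact_integer", "rescaled_float"):
        raise ValueError(f"unknown representation {representation!r}")

    scale = None
    if representation == "rescaled_float":
        scale = _estimate_growth(theta, n_max)
        si = 1.0 / scale
        one_at = lambda n: si ** n  # noqa: E731  true value 1 at length n
    else:
        si = None
        one_at = lambda n: 1  # noqa: E731

    # Z ------------------------------------------------------------------
    if representation == "exact_integer":
        Z = _z_recursion(n_max, theta)
    else:
        Z = [one_at(n) for n in range(min(theta + 2, n_max + 1))]
        for n in range(len(Z), n_max + 1):
            acc = Z[n - 1] * si
            for r in range(0, n - theta - 1):
                acc += Z[r] * Z[n - r - 2] * si * si
            Z.append(acc)
    del one_at

    zero = 0 if representation == "exact_integer" else 0.0
    mul2 = (lambda a, b: a * b) if si is None else (lambda a, b: a * b * si * si)
    step = (lambda a: a) if si is None else (lambda a: a * si)

    # E: external base pairs; pair (k, n) contributes E_{k-1} externals on
    # the left plus one for itself, times Z_{n-k-1} inner structures.
    E = [zero] * (n_max + 1)
    for n in range(theta + 2, n_max + 1):
        acc = step(E[n - 1])
        for k in range(1, n - theta):
            acc += mul2(E[k - 1] + Z[k - 1], Z[n - k - 1])
        E[n] = acc

    # First and second factorial moments of the visible-position profile f.
    F1 = [zero] * (n_max + 1)
    F2 = [zero] * (n_max + 1)
    for n in range(1, n_max + 1):
        a1 = step(F1[n - 1] + Z[n - 1])
        a2 = step(F2[n - 1] + 2 * F1[n - 1])
        for r in range(1, n - theta - 1):
            a1 += mul2(F1[r], Z[n - r - 2])
            a2 += mul2(F2[r], Z[n - r - 2])
        F1[n] = a1
        F2[n] = a2

    # Window sums: for p in the theta-window below n, pair (k, p) with the
    # rest of the window unpaired; left part contributes its own tally.
    def window_sum(arr, n):
        # sum over u=1..theta, p = n - theta - 1 + u, k = 2..p - theta - 1
        # of arr[k-1] * Z[p-k-1], scaled to length-n units.
        acc = zero
        for u in range(1, theta + 1):
            p = n - theta - 1 + u
            for k in range(2, p - theta):
                term = arr[k - 1] * Z[p - k - 1]
                if si is not None:
                    term *= si ** (n - (p - 2))
                acc += term
        return acc

    def tail(arr, n):
        # arr[n - theta - 1] rescaled from length n - theta - 1 to n units
        m = n - theta - 1
        if m < 0:
            return zero
        v = arr[m]
        if si is not None:
            v *= si ** (theta + 1)
        return v

    Q1 = [zero] * (n_max + 1)
    Q2 = [zero] * (n_max + 1)
    for n in range(theta + 2, n_max + 1):
        add_remove = zero
        for k in range(1, n - theta):
            add_remove += mul2(Z[k - 1], Z[n - k - 1])
        split1 = zero
        split2 = zero
        for k in range(1, n - theta):
            split1 += mul2(Z[k - 1], Q1[n - k - 1]) + mul2(Q1[k - 1], Z[n - k - 1])
            split2 += mul2(Z[k - 1], Q2[n - k - 1]) + mul2(Q2[k - 1], Z[n - k - 1])
        Q1[n] = step(Q1[n - 1]) + 2 * add_remove + split1
        # shift contributions: external-pair re-anchorings to the last
        # position (E terms) and re-pairings among visible positions (g
        # second moment).
        e_prime = tail(E, n) + window_sum(E, n)
        g2 = tail(F2, n) + window_sum(F2, n)
        Q2[n] = (
            step(Q2[n - 1])
            + 2 * add_remove
            + 2 * (step(E[n - 1]) + e_prime)
            + g2
            + split2
        )

    tables = HomopolymerTables(
        theta=theta,
        n_max=n_max,
        representation=representation,
        Z=Z,
        E=E,
        F1=F1,
        F2=F2,
        Q_ms1=Q1,
        Q_ms2=Q2,
        scale=scale,
    )
    if with_profiles is None:
        with_profiles = representation == "exact_integer" and n_max <= 200
    if with_profiles:
        if representation != "exact_integer":
            raise ValueError("full f/g profiles require the exact representation")
        tables.f = f_table(n_max, theta)
        tables.g = g_table(n_max, theta, tables.f)
    return tables


def _estimate_growth(theta: int, n_max: int) -> float:
    """Asymptotic per-step growth of Z, from a short exact run."""
    m = min(max(n_max, 10), 120)
    Z = _z_recursion(m, theta)
    lo = max(theta + 2, m - 10)
    if Z[lo] == 0 or m == lo:
        return 2.0
    return float((Z[m] / Z[lo]) ** (1.0 / (m - lo)))


def f_table(n_max: int, theta: int = 1) -> List[List[int]]:
    """f[n][x]: structures on [1, n] with exactly x visible positions."""
    Z = _z_recursion(n_max, theta)
    f = [[0] * (n_max + 2) for _ in range(n_max + 1)]
    f[0][0] = 1
    for n in range(1, n_max + 1):
        # pair (1, n) covers everything
        if n >= theta + 2:
            f[n][0] += Z[n - 2]
        for x in range(0, n + 1):
            if x > 0:
                f[n][x] += f[n - 1][x - 1]  # position n unpaired, visible
            for r in range(1, n - theta - 1):  # pair (r + 1, n)
                f[n][x] += f[r][x] * Z[n - r - 2]
    return f


def g_table(n_max: int, theta: int = 1, f: Optional[List[List[int]]] = None) -> List[List[int]]:
    """g[n][x]: structures with n unpaired and x visible positions in
    [1, n - theta - 1]."""
    Z = _z_recursion(n_max, theta)
    if f is None:
        f = f_table(n_max, theta)
    g = [[0] * (n_max + 2) for _ in range(n_max + 1)]
    for n in range(theta + 2, n_max + 1):
        for x in range(0, n + 1):
            g[n][x] += f[n - theta - 1][x]
            for u in range(1, theta + 1):
                p = n - theta - 1 + u
                if x == 0 and p - 1 > theta:
                    g[n][x] += Z[p - 2]  # pair (1, p) covers the window
                for k in range(2, p - theta):
                    g[n][x] += f[k - 1][x] * Z[p - k - 1]
    return g


def homopolymer_Q(tables: HomopolymerTables, ms: MoveSetId) -> List:
    """Q_n array for the requested move set."""
    return tables.Q(ms)


def expected_degree(tables: HomopolymerTables, ms: MoveSetId, n: int) -> float:
    """Q_n / Z_n."""
    if not 0 <= n <= tables.n_max:
        raise IndexOutOfRange(f"n = {n} outside [0, {tables.n_max}]")
    q = tables.Q(ms)[n]
    z = tables.Z[n]
    return q / z


def normalized_degree(tables: HomopolymerTables, ms: MoveSetId, n: int) -> float:
    """Q_n / (n Z_n), the length-normalized expected network degree."""
    if n <= 0:
        raise IndexOutOfRange("n must be positive")
    return expected_degree(tables, ms, n) / n
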