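# Methods

## The quantity

For an RNA sequence a = a_1..a_n, consider the network whose nodes are all
secondary structures of a (pseudoknot-free, triple-free pair sets with
j - i > theta) and whose directed edges s -> t are single moves of a
folding-kinetics move set: MS1 = base-pair additions and removals, MS2 =
MS1 plus shift moves that keep one endpoint of an existing pair and
re-anchor the other.  Stochastic folding simulators perform random walks on
exactly this network, so its expected out-degree

    <N> = Q_{1,n} / Z_{1,n},
    Q_{1,n} = sum_s BF(s) N(s),   Z_{1,n} = sum_s BF(s),
    BF(s) = exp(-E(s)/RT)

is an ensemble-level order parameter for folding kinetics: it measures how
many elementary conformational rearrangements are, on average, available at
equilibrium.  The package computes <N> by dynamic programming under three
energy models and cross-checks everything against exhaustive enumeration.

* **Model A (homopolymer)** — any two positions may pair (theta = 1 by
  default), E(s) = 0.  All quantities depend only on interval length, so
  the tables are one-dimensional and <N> can be pushed to n in the
  thousands.  O(n^2) time after reduction of the visible-position profile
  to its first two factorial moments (docs/recursion_notes.md).
* **Model B (uniform)** — Watson-Crick/wobble pairing, theta = 3, E(s) = 0:
  the probability of each structure is 1/Z and all tables are exact
  integers (arbitrary precision), so the toy-network results are
  bit-reproducible.  O(n^4) time / O(n^3) space, dominated by the
  visible-position tables F and G.
* **Model C (Boltzmann)** — dangle-free nearest-neighbor energies: hairpin
  and internal-loop tables, affine multiloops a + b N_b + c N_u, exterior
  contributions zero.  The partition function follows the McCaskill
  Z/ZB/ZM/ZM1 decomposition; the degree tables Q/QB/QM/QM1 ride along with
  loop-interior move counters (arc1a..arc5) answered in O(1) from
  nucleotide-class prefix sums.

## Move accounting in model C

The multiloop decomposition cannot attribute certain rare moves to any
subproblem: additions that would enclose a multiloop component, shifts of a
multiloop's closing pair into its own loop, and component shifts other than
an extension into the gap on the component's right (or the first
component's re-anchoring into the gap on its left).  Model C therefore
computes a restricted counter N*(s) <= N(s); the exact taxonomy is listed
in docs/recursion_notes.md and implemented independently as a move filter
for the brute-force comparator, which reproduces the DP to ~1e-15 relative
error on multiloop-rich test ensembles.  Because multiloops with room for
such moves are entropically penalized, their Boltzmann mass is small and
the omitted moves matter little in practice; on multiloop-free sequences
N* = N exactly.  Degree *distributions* (metrics module) always count full
N(s) on explicit structures unless the restricted counter is requested
(`neighbor_counter="restricted"`), and the report records which counter was
used.

## Energy parameters

Model C reads Vienna-dialect nearest-neighbor files (e.g. the Turner 1999 /
Turner 2004 sets shipped with ViennaRNA) and maps them onto the terms this
model uses: stacks, hairpin/bulge/internal initiation ladders, terminal
mismatches (hairpin and internal), Ninio asymmetry, terminal-AU penalty and
the multiloop affine coefficients.  Size-dependent terms beyond the table
extrapolate logarithmically (coefficient `lxc`).  Specialized corrections
the model does not represent (1x1/2x1/2x2 interior tables, special
hairpins, coaxial stacking, all dangle terms) are ignored, so absolute free
energies differ from full Turner implementations; this is irrelevant to the
package's internal consistency because the structure-energy evaluator and
the DP share one routine per loop type, making every DP/enumeration
comparison parameter-set-agnostic.  Two builtin sets avoid any file
dependency: `zero` (all terms 0, the uniform limit — interior-loop cap
disabled so the reduction to model B is exact at any length) and
`builtin_minimal`, a compact self-contained set with Turner-like magnitudes
(stacks -3.4..+1.3 kcal/mol, hairpin initiation 5.4 + 2.3 ln(m/3),
terminal-AU 0.5, Ninio 0.6/nt capped at 3.0, multiloop a = 3.4, b = 0.4,
c = 0).  R = 0.00198717 kcal/(mol K); default T = 310.15 K; interior loops
are capped at 30 unpaired bases (hairpins and multiloops are not).

## Homopolymer conditions

The published normalized-degree curve for the homopolymer is reproduced at
theta = 3: the MS1 value at n = 998 (0.472393, rescaled-float
representation) matches to all six printed decimals and approaches the
analytically proved MS1 constant 0.4734176431521986 from below
(|deviation| = 1.02e-3 at n = 998, decreasing in n).  theta remains a
parameter; theta = 1 gives 0.552038 (MS1) and 1.991415 (MS2) at n = 998.
For MS2 at theta = 3 this implementation obtains 1.549061 at n = 998,
about 1.2% above the published asymptote 1.530161.  The discrepancy is not
a tolerance issue: the recursions here agree bit-exactly with exhaustive
enumeration for every n <= 14 at theta in {1, 2, 3}, and no natural
sub-class omission reproduces the published figure, so the computed value
is reported as is and the corresponding six-decimal assertion in the test
suite documents the disagreement as a failure rather than masking it.

## Numerical representation

Model A offers exact arbitrary-precision integers and a rescaled-float
representation storing X_n / s^n with the growth estimate s read off a
short exact run (counts grow ~2.29^n at theta = 1 and overflow doubles near
n = 370).  Ratios such as Q_n/(n Z_n) are scale-free; the two
representations agree to >= 10 significant digits up to n = 300 (tested)
and the float path covers n = 2000 within double range even with a few
percent error in s.  Model B is exact integer throughout, converting to
rationals only in final ratios.  Model C uses doubles with energies
pre-divided by RT; per-loop Boltzmann-factor overflow raises an error
rather than saturating.

## Enumeration limits and what the tests show

The oracle (enumeration, neighbor generation, networks, distributions,
pair probabilities, entropy) is exponential and capped at 40 nt (25 with
energies), overridable with `force`.  Test problem sizes: oracle
equivalence sweeps use random sequences of length 5-16 (hundreds of
sequences, thousands of structures each at the top of the range), the toy
worked examples are 7 and 12 nt, and the homopolymer curve runs to n = 998
in about a second.  Random-sequence ensembles at these lengths exercise
every loop type including nested multiloops, but they cannot probe
behaviors that only appear in long natural RNAs (deep multiloop nesting,
long-range exterior structure, parameter-set detail); passing tests
establish the correctness of the recursions, not the biophysical fidelity
of `builtin_minimal`.

## Design choices

* Coordinates are 1-based everywhere in the public API.
* Edge counts are reported both ways (undirected edges, and directed
  edge count = sum_s N(s) = twice the undirected count) because "edges"
  is ambiguous between the two conventions; expected degree is always
  sum BF(s) N(s) / sum BF(s).
* Shift legality is decided purely by validating the resulting structure;
  no locality constraint beyond sharing one endpoint.
* Enumeration order is lexicographic on sorted pair lists, so exports and
  tests are byte-stable.
* Pair probabilities and entropy are enumeration-only by design (no
  outside/pair-probability recursions); they are short-sequence features.
* The benchmark-style correlation study is exposed as a utility
  (`metrics_table` + `DataFrame.corr()`) that consumes user-supplied
  (sequence, structure) tables; assembling structure databases is out of
  scope.
* The command line serializes numbers with 12 significant digits; exit
  codes are 0 (ok), 1 (usage), 2 (invalid input), 3 (DP/oracle mismatch in
  the `oracle` subcommand, which is the recursion-audit gate).
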