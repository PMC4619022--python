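# rnadegree

Expected degree of RNA secondary-structure move networks.

The secondary structures of an RNA sequence form a network: nodes are all
pseudoknot-free structures, and an edge joins two structures that differ by
one move of a folding-kinetics move set — a base-pair addition or removal
(move set **MS1**), or additionally a *shift* that re-anchors one endpoint
of an existing pair (**MS2**, the default move set of stochastic folding
simulators; shifts enable defect diffusion and helix slippage).  Folding
simulations are random walks on this network, so its **expected degree**

    <N> = Q / Z,   Q = Σ_s e^{-E(s)/RT} · N(s),   Z = Σ_s e^{-E(s)/RT}

(N(s) = number of neighbors of structure s) is an ensemble order parameter
for folding kinetics, alongside contact order, conformational entropy and
the expected number of native contacts.  Enumerating the ensemble is
exponential; this package computes <N> by dynamic programming in polynomial
time for three energy models:

| model | ensemble | pairing | arithmetic |
|---|---|---|---|
| A | homopolymer, E = 0 | any pair, θ = 1 (or any θ) | exact int / rescaled float, O(n²) |
| B | uniform, E = 0 | WC + wobble, θ = 3 | exact integers, O(n⁴) |
| C | Boltzmann, dangle-free nearest neighbor | WC + wobble, θ = 3 | double precision, O(n⁴) |

plus a brute-force oracle (exhaustive enumeration, neighbor generation,
network construction) against which every recursion is tested bit-for-bit,
degree-distribution estimation, and the kinetic order parameters used to
correlate <N> with folding-rate proxies.  It is intended for researchers in
RNA folding kinetics and ensemble-based structure analysis.

## Worked example

The 12-mer ACGUACGUACGU has 35 secondary structures.  Its MS1 network has
126 directed edges, its shift-only network 68, so under MS2:

    $ rnadegree degree --seq ACGUACGUACGU --model B --moveset MS2
    {
     "Q": 194.0,
     "Z": 35.0,
     "expected_degree": 5.54285714286,
     "model": "B",
     "moveset": "MS2",
     "normalized_degree": 0.461904761905,
     "sequence": "ACGUACGUACGU",
     "sequence_id": "ACGUACGUACGU",
     "theta": 3
    }

Q = 194 counts directed edges (Σ_s N(s)); the expected network degree is
194/35 ≈ 5.54 neighbors per structure, 3.6 of which are additions/removals
and 1.94 shifts.  The `oracle` subcommand recomputes the same numbers by
exhaustive enumeration and exits non-zero on any disagreement:

    $ rnadegree oracle --seq ACGUACGUACGU --moveset MS1
    { ... "Q_dp": 126.0, "Q_enumeration": 126.0, "status": "MATCH" ... }

With Turner 2004 energies (Boltzmann weighting, dangles off) the degree of
an 18-mer that folds into two competing hairpins:

    $ rnadegree degree --seq GGGAAACCCGGGAAACCC --model C \
          --params /opt/conda/envs/bio/share/ViennaRNA/rna_turner2004.par
    { ... "Z": 177.987560471, "expected_degree": 8.17954177562, ... }

i.e. at 37 °C the thermodynamic ensemble concentrates on structures with
about 8.2 available MS2 moves each.  (`--params builtin` uses a compact
self-contained parameter set; `--params zero` gives the uniform limit.)

The homopolymer curve: the length-normalized expected degree Q_n/(n·Z_n)
converges as n grows; at n = 998 with θ = 3,

    $ rnadegree homopolymer --n 998 --moveset MS1 --normalized
    0.472393

about 0.47 MS1-neighbors per nucleotide, within 1.1e-3 of the analytically
known MS1 limit 0.4734176431521986 (the MS2 value is 1.549061 — see
docs/methods.md for notes on this figure).

Other subcommands: `network` (TSV node/edge export), `distribution`
(degree histograms with optional energy band and ensemble coverage Z*/Z),
`metrics` (per-sequence table of degree, entropy, contact order, expected
native contacts, with Pearson correlations), `fixtures` (seeded FASTA
generation).  Everything is also available as a library
(`rnadegree.uniform_expected_degree`, `rnadegree.turner_expected_degree`,
`rnadegree.compute_homopolymer_tables`, ...).

## Documentation

* `docs/methods.md` — the models, the restricted multiloop move counter,
  parameter handling, numerical representations, limitations.
* `docs/recursion_notes.md` — the exact recurrences, base values fixed by
  the enumeration audit, and the multiloop move taxonomy.
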