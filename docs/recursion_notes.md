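# Recursion notes

This file records the recurrences the package actually implements, the base
values they use, and every place where a bound or base value was fixed by
requiring bit-exact agreement with exhaustive enumeration (the `core`
oracle).  Positions are 1-based; `theta` is the minimum number of unpaired
bases between paired positions; `bp(i, j)` is true iff `j - i > theta` and
the letters may pair (always true in homopolymer mode) — folding the steric
constraint into `bp` makes every summation bound below safe.

## Model A (homopolymer, default theta = 1)

Counts, with `Z_n = 1` for `n <= theta + 1`:

    Z_n  = Z_{n-1} + sum_{r=0}^{n-theta-2} Z_r * Z_{n-r-2}

The sum is over the split pair `(r+1, n)`.  Writing the bound as
`r = 0 .. n-theta-2` (rather than `1 .. n-2`) makes the recursion valid for
every theta; at theta = 1 the two formulations give identical totals because
the `r = 0` and `r = n-2` end terms have equal value.

External pairs (`E_n`), visible-position profile (`f`, `g`) and degree
totals (`Q_n`) use the base values

    E_0 = 0,   E_n = 0 for n <= theta + 1,
    Q_0 = 0,   Q_n = 0 for n <= theta + 1.

`E_0 = 0` and `Q_0 = 0` are forced by the oracle: with `E_0 = 1` the
recursion gives `E_3 = 2` at theta = 1, while enumeration of the two
structures of a 3-mer (empty and {(1,3)}) counts exactly one external pair;
with `Q_0 = 1` it gives `Q_3 = 3` instead of the enumerated 2.

The theta-window decompositions (the analogues of the interval functions
`ER'` and `G` of model B, specialized to the homopolymer) condition on the
largest paired position `p = n - theta - 1 + u`, `u = 1..theta`, below an
unpaired terminal position:

    e'(n)  = E_{n-theta-1}  + sum_u sum_{k=2}^{p-theta-1} E_{k-1}  * Z_{p-k-1}
    g2(n)  = F2_{n-theta-1} + sum_u sum_{k=2}^{p-theta-1} F2_{k-1} * Z_{p-k-1}

where `F1_n = sum_x x f(n,x)` and `F2_n = sum_x x(x-1) f(n,x)` obey

    F1_n = F1_{n-1} + Z_{n-1} + sum_{r=1}^{n-theta-2} F1_r * Z_{n-r-2}
    F2_n = F2_{n-1} + 2 F1_{n-1} + sum_{r=1}^{n-theta-2} F2_r * Z_{n-r-2}

(obtained by summing the `f` recursion against `x` and `x(x-1)`; the
pair-(1,n) and x = 0 source terms vanish under both weights).  Only these
two moments enter `Q`, which keeps the large-n path at O(n^2) time / O(n)
space.  Full `f`/`g` tables are materialized separately for moderate n and
compared entry-by-entry with enumeration.

Degree totals:

    Q^MS1_n = Q^MS1_{n-1} + 2 sum_k Z_{k-1} Z_{n-k-1}
              + sum_k (Z_{k-1} Q^MS1_{n-k-1} + Q^MS1_{k-1} Z_{n-k-1})
    Q^MS2_n = Q^MS2_{n-1} + 2 sum_k Z_{k-1} Z_{n-k-1}
              + 2 (E_{n-1} + e'(n)) + g2(n)
              + sum_k (Z_{k-1} Q^MS2_{n-k-1} + Q^MS2_{k-1} Z_{n-k-1})

with `k = 1 .. n-theta-1` throughout.  Verified bit-exact against the
oracle for all n <= 14 at theta in {1, 2, 3}.

`g(n, x)` is stored as 0 for `n <= theta + 1` (the semantic count of the
empty structure would be 1 at x = 0); `Q` consumes only `x >= 2` terms, so
the convention is immaterial and kept.

## Model B (uniform counting, theta = 3, WC + wobble)

Implemented exactly as the interval recursions for `Z`, `EL`, `ER`, `ER'`,
`F`, `G` and `Q` (MS1 / MS2 / shift-only), with two clarifications, both
validated by the oracle-equivalence suite:

* Summation bounds: every inner sum over a split point `k` runs over
  `k` with `bp(k, j) = 1`; since `bp` embeds the theta constraint, printed
  bounds that nominally admit `j - k <= theta` contribute zero.
* The `x > 0` branch of the `F` recursion needs the unpaired-j term for a
  terminal letter that cannot pair with `c`:

      F_{i,j,c,x} = [bp(j,c)] F_{i,j-1,c,x-1} + [not bp(j,c)] F_{i,j-1,c,x}
                    + sum_k bp(k,j) F_{i,k-1,c,x} Z_{k+1,j-1}

  Without the second term, structures whose terminal position is unpaired
  and non-pairable would be dropped; the partition identity
  `sum_x F_{i,j,c,x} = Z_{i,j}` then fails, and the oracle comparison
  localizes the defect immediately.
* The `ER'` window bound is `u = 1 .. theta` (not a literal 3), so theta
  stays a genuine parameter.

`F_{i,j,c,x}` for an empty interval (`j < i`) is 1 at x = 0; for
`j - i <= theta` the only structure is the open chain, so `F` is the point
mass at the number of c-pairable positions in `[i, j]`.

## Model C (Boltzmann, dangle-free nearest neighbor)

The McCaskill tables use the convention that each multiloop component's
per-branch term `b` is carried **inside** `ZM1`/`QM1`:

    ZM1_{i,j} = sum_{k=i+theta+1}^{j} ZB_{i,k} * e^{-(b + c (j-k))/RT}
    ZM_{i,j}  = sum_r e^{-c (r-i)/RT} ZM1_{r,j} + sum_r ZM_{i,r-1} ZM1_{r,j}
    ZB multiloop case:  e^{-(a+b)/RT} * sum_r ZM_{i+1,r-1} * ZM1_{r,j-1}

so a k-component multiloop pays `a + (k+1) b + c N_u` exactly once — the
closing pair's `b` in the `ZB` case, one `b` per component in `ZM1`.  A
formulation that leaves `b` outside `ZM1` must add it in *both* `ZM` sums
and in the `ZB` case; mixing the conventions drops one `b` per multiloop.
The brute-force Boltzmann comparison (shared loop-energy routine) pins the
implemented convention down.

The 30-nt interior-loop cap is enforced inside `IL` itself (infinite energy
above the cap) and mirrored by the `QB` case-B loop bounds as a *joint* cap
on `(l - i - 1) + (j - r - 1)`; because the structure-energy evaluator and
the DP share the same `IL`, capped loops are excluded consistently from
both the DP ensemble and the enumerated one.

### Moves counted by the Boltzmann recursions (multiloop taxonomy)

The degree recursions attribute every counted move to a unique subproblem.
The resulting per-structure counter N*(s), confirmed by exhaustive
comparison on multiloop-rich ensembles (relative error < 1e-15 observed):

* every removal;
* additions `(x, y)` with x, y unpaired in the same loop face, except when
  that face is a multiloop and one of its components lies strictly between
  x and y (the added pair would enclose a component);
* shifts, classified by the loop face that contains the *new* endpoint w:
  - exterior face: every flavor, any visible w (`EL`, `ER'`, and the
    x-weighted `F`/`G` sums);
  - hairpin or internal-loop face: every flavor of shifting either closing
    pair into the face (`arc1b/arc1c`, `arc2b/arc2c`);
  - multiloop face: only a component `(i_t, j_t)` extending into the gap
    immediately to its right — new pair `(i_t, w)` (`arc4`) or `(j_t, w)`
    (`arc5`) — plus, for the first component only, the re-anchoring
    `(w, i_1)` with w in the gap before it (`arc1c` term of `QM`);
    shifts of the multiloop's closing pair into the face are not counted.

On multiloop-free structures N*(s) equals the full move count N(s), which
is why the zero-energy model C totals reproduce the model B integers
exactly on multiloop-free sequences and are strictly smaller otherwise.

MS1 mode drops all shift sources (`EL`, `ER'`, `F`/`G`, `arc1b/1c`,
`arc2b/2c`, `arc4/5`) but keeps the addition counters (`arc1a`, `arc2a`),
so MS1 additions inside multiloops follow the same spanning exclusion.
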