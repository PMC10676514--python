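# Methods

## The energy model

modfold predicts RNA secondary structures under the nearest-neighbor
free-energy model: the free energy of a structure is the sum of
independent loop contributions — base-pair stacks, hairpin loops, bulges
and internal loops, multiloops (affine: closing + per-branch + per-unpaired
terms) and the exterior loop.  The parameter set is the Turner 2004
compilation of free energies (ΔG°₃₇, measured at 310.15 K and 1 M NaCl)
and enthalpies (ΔH°), including the dedicated 1×1, 2×1 and 2×2 internal
loop tables, tabulated stable tri-/tetra-/hexaloops, the Ninio asymmetry
term (capped), the non-GC helix-end penalty, and logarithmic loop-size
extrapolation `ΔG(s) = ΔG(30) + lxc·ln(s/30)` beyond the tabulated sizes.

Tables are read from plain-text files in the widely used "RNAfold
parameter file v2.0" format.  Shipping a private transcription of the full
compilation (including the large 2×2 interior tables) would duplicate
several hundred kilobytes of standard data, so the default loader locates
`rna_turner2004.par` in the ViennaRNA data directory of the host
environment; any v2.0 file can be supplied explicitly or through
`MODFOLD_PARAMS`.  The parser is implemented in this package.

Temperatures other than 37 °C rescale each entry through
`ΔG(T) = ΔH − T·(ΔH − ΔG₃₇)/310.15`; entries without an enthalpy are used
unchanged.  Rescaling is exact at the reference temperature by
construction.

Unpaired bases flanking helix ends contribute through the `d2` dangle
model (the RNAfold default): mismatch-style terms on both sides of every
helix end in multiloops and the exterior loop, with single-sided dangle
terms only at the sequence boundaries.  A `none` model is selectable.
Lonely (isolated) pairs are allowed; prohibiting them is not implemented.

All energies are integers in units of 0.01 kcal/mol internally.  This
makes the dynamic programming, the traceback and the independent
structure evaluator agree bit-for-bit; floats appear only at the API
boundary.

## Modified bases

A modified base is described by a sparse JSON record: one-letter code,
unmodified counterpart, a *fallback* base, the set of allowed pairing
partners, and energy tables for up to four loop classes — base-pair
stacks, helix ends, terminal mismatches, dangling ends (ΔG°₃₇ plus
optional ΔH°).  Six sets ship with the package (7-deaza-adenosine,
inosine, N6-methyladenosine, pseudouridine, nebularine, dihydrouridine),
transcribed from the cited experimental literature (the dihydrouridine
values derive from published molecular-simulation estimates).  A small
alias table maps tRNA-database codes without thermodynamic data to their
unmodified counterparts, and flags 1-methyladenosine and
N2,N2-dimethylguanosine as non-pairing.

The prediction algorithms never see the extended alphabet.  Each input is
split into a canonical *proxy* sequence (modified letters replaced by
their fallback base) plus two kinds of constraints:

* **hard constraints** — positions whose modification admits no pairing
  partner are forced unpaired; otherwise the partner set restricts which
  proxy letters the position may pair;
* **soft corrections** — for every loop *face* (a helix end with its
  local context) that touches a modified position and has a tabulated
  value, an additive correction
  `ΔΔG = ΔG(modified context) − ΔG(proxy context)` at the working
  temperature.  Faces without data contribute 0, which implements
  fallback substitution implicitly.

Corrections attach at loop granularity: the hairpin closing face, both
faces of every non-stack interior loop (helix-end class; mismatch class
additionally requires an unpaired base on each strand), stacks (the 0×0
interior case), and exterior-loop/multiloop helix ends (helix-end class
plus, under `d2`, mismatch or boundary-dangle classes).  The dedicated
1×1/2×1/2×2 tables have no modified variants, so such loops only receive
helix-end and mismatch face corrections.  Context keys are read in the
frame of the enclosing loop; stack and helix-end contexts with a single
modified slot also match the 180°-rotated (reversed) key.  When one face
joins two *distinct* modified bases, each modification type is evaluated
separately with the other type replaced by its fallback, and the
differences add — the sum-of-differences treatment of doubly modified
pairs.  Tabulated kcal/mol values are mapped to the integer grid by
truncation toward zero, the same conversion the reference parameter
readers apply, so corrections reproduce RNAfold's integer arithmetic
exactly.

This placement was validated against ViennaRNA 2.7.2: on hundreds of
random modified sequences (one or two modification types, 1–4 sites) the
MFE predictions agree bit-for-bit with `RNAfold`'s `sc_mod` machinery
(see `tests/test_reference_crosscheck.py`).  One deliberate difference:
this package enforces `pairing_partners` as hard constraints (a
pseudouridine restricted to partner A cannot wobble-pair G), whereas the
reference applies energy corrections only.  Cross-check tests therefore
disable the partner restriction.  Note also that the reference's
structure *evaluator* omits the exterior/multiloop corrections its
folding recursions apply; modfold's evaluator is self-consistent with its
own recursions, which the round-trip tests require.

## Algorithms

Folding uses the standard cubic-time recursions over an unambiguous
grammar (exterior `F`, paired `C`, multiloop `M`/`M1`), so that energy
minimisation, partition function and complete suboptimal enumeration all
share one decomposition:

* **MFE** — integer DP with deterministic traceback; ties prefer the
  pairing branch, then the smallest inner index.
* **Partition function** — the same recursions over Boltzmann weights
  `exp(−E/RT)` in linear space with a per-nucleotide scaling factor
  derived from the MFE (`exp(1.07·E_MFE/(n·RT))` per base), followed by
  an outside pass for base-pair probabilities.  Finite for sequences well
  beyond 250 nt; the multiloop outside step is quartic in the worst case,
  which is acceptable for the global, single-sequence scope of this
  package (typical inputs ≤ a few hundred nt).
* **Suboptimal structures** — complete enumeration of all structures
  within a user band of the MFE by branch-and-bound over the DP matrices;
  every structure appears exactly once (unambiguous grammar), each
  reported energy equals its independent loop-decomposition evaluation,
  and a configurable cap (default 100 000) guards against explosive
  bands.

Interior loops are capped at total size 30 (standard), with the
logarithmic extrapolation carrying larger bulges.  The hot loops are
compiled with numba; correctness does not depend on it (the kernels are
plain array arithmetic).

## Verification strategy

The primary oracle is exhaustive enumeration: for short sequences every
legal structure is generated and evaluated through the loop
decomposition, giving reference MFE, partition function, pair
probabilities and banded suboptimal sets.  The DP engine must match these
exactly (probabilities to 1e-6 relative).  ViennaRNA serves as an
additional, independent cross-check of the energy model and of the
modified-base semantics, never as part of the implementation.

## Synthetic data

`generate_fixture` produces seeded random sequences with a chosen number
of modified positions and, optionally, a planted complementary hairpin as
a reference structure.  `synthetic_cloverleaf` builds a 74-nt tRNA-like
sequence: four complementary arms (acceptor 7 bp, D 4 bp, anticodon 5 bp,
T 5 bp), two dihydrouridines in the D loop, the T-loop T-Ψ-C motif, a
non-pairing 1-methyladenosine in the T loop and a non-pairing
N2,N2-dimethylguanosine in the variable region, and a 3' ACCA tail.  Arm
sequences are drawn deterministically; the default seed is fixed such
that the unmodified proxy misfolds (the D-loop and T-loop sequences
support a competing fold) while the modification-aware prediction
recovers the cloverleaf.  This emulates the qualitative behaviour of
heavily modified tRNAs — it does not reproduce any natural tRNA's
identity elements, tertiary interactions, or measured modification
landscape, so passing tests demonstrate the mechanics of the constraint
layer, not accuracy on biological tRNA data.

## Knobs that matter

| parameter | default | meaning |
|---|---|---|
| temperature | 310.15 K | working temperature; tables rescaled via ΔH |
| dangle_model | `d2` | helix-end single-strand stacking treatment |
| min_hairpin | 3 | minimum unpaired span inside a hairpin |
| subopt cap | 100 000 | maximum structures returned per band |
| MAXLOOP | 30 | largest interior loop (n1+n2) |

## Known limitations

* Global, single-strand folding only: no sliding-window/local variants,
  no two-strand cofolding, no consensus folding, no pseudoknots, no
  coaxial stacking, fixed 1 M NaCl reference state.
* Modified-base data cover four loop classes; modifications inside
  1×1/2×1/2×2 loops fall back to the unmodified tables.
* Dangling-end entries only act in one-sided exterior contexts under
  `d2` (two-sided contexts are mismatch-class), matching the reference
  behaviour.
* Corrections are exact per modification type; interactions between two
  distinct modifications in one face are approximated by the
  sum-of-differences rule, as no measured parameters exist for them.
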