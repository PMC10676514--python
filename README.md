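# modfold

RNA secondary-structure prediction with support for post-transcriptionally
modified bases.

Many RNAs — tRNAs above all — carry chemical modifications (pseudouridine
Ψ, dihydrouridine D, N6-methyladenosine m⁶A, inosine, 1-methyladenosine
m¹A, …) that change which structures the molecule prefers; some tRNAs
need them to adopt the cloverleaf at all.  Standard thermodynamic folding
engines work on the four-letter ACGU alphabet and ignore this.  modfold
is for anyone who wants minimum-free-energy structures, base-pair
probabilities and suboptimal structures for sequences written in an
extended alphabet where each modified base has its own one-letter code.

## How it works

The core is a nearest-neighbor folding engine (Turner 2004 parameters,
`d2` dangle model, integer 0.01 kcal/mol arithmetic) computing

* the MFE structure, `min_S E(S)` with `E(S) = Σ_loops ΔG(loop)`,
* the partition function `Z = Σ_S exp(−E(S)/RT)`, the ensemble free
  energy `−RT ln Z` and all pair probabilities `p_ij`,
* the complete set of structures within a band of the MFE.

Modified bases never enter these recursions.  Each input sequence is
mapped to a canonical *proxy* (every modified letter replaced by its
fallback base), and the modification data — sparse JSON records with
stacking, helix-end, terminal-mismatch and dangling-end energies, plus
pairing rules — are converted into a constraint layer: hard constraints
remove forbidden pairings (m¹A and m²₂G cannot pair at all), and soft
per-loop corrections `ΔΔG = ΔG(modified) − ΔG(proxy)` adjust every loop
for which data exist.  Loops without data implicitly use the fallback
base — no complete modified parameter set is ever required.  Six
literature parameter sets ship with the package (Ψ, D, m⁶A, inosine,
7-deaza-adenosine, nebularine), plus a tRNA-database alias table.
Details: [docs/methods.md](docs/methods.md).

## Worked example

A 74-nt synthetic tRNA-like sequence with two dihydrouridines (D), the
T-loop T-Ψ-C motif (codes `T`, `P`, `C`) and non-pairing m¹A (`"`) and
m²₂G (`R`):

```sh
$ modfold fixture --cloverleaf > clover.fa      # sequence + reference
$ head -2 clover.fa > seq.fa
$ modfold fold -m --trnadb-aliases --ref '(((((((.((((........)))).(((((.......)))))....(((((.......))))))))))))....' seq.fa
>synthetic_cloverleaf
UGGCAAGUGGGUADAGGGDAACCCGCCCUAAUGCGCCUAGGGRAACAUUAUTPCA"AUAUAAUCUUGCCAACCA
((((((((((((........)))))(((((.......)))))....(((((.......)))))))))))).... ( -19.80)
 bp distance to reference = 1
 ensemble defect = 0.12
```

The prediction (MFE −19.80 kcal/mol) recovers the cloverleaf to within
one base pair, and only 12 % of nucleotides disagree with the reference
pairing across the whole thermodynamic ensemble.  Folding the same
sequence with all modified letters silently replaced by their unmodified
counterparts (drop `-m --trnadb-aliases` and substitute the letters)
yields a completely different structure — 28 base pairs away from the
cloverleaf with an ensemble defect of 0.47.  That contrast is the point
of the package.

Library use mirrors the CLI:

```python
import modfold

res = modfold.partition_function("GGGAPAAAAAAAUCCC")   # P = pseudouridine
print(res.mfe_structure.to_dotbracket(), res.mfe_energy)
print(res.ensemble_free_energy, res.bpp.max())
```

Additional parameter sets are plain JSON files (`modfold
validate-mod-file my_mod.json`, then `modfold fold --mod-file
my_mod.json ...`); the schema is documented in
`src/modfold/modbase.py` and `data/mod/`.

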