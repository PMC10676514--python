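"""Synthetic sequence fixtures: random modified sequences and a modified
cloverleaf test case.

Everything here is synthetic, generated deterministically from a seed; no
natural sequence data is embedded.  The cloverleaf constructor emulates
the situation in heavily modified tRNAs: the unmodified proxy sequence
prefers a non-cloverleaf fold, while dihydrouridine destabilisation,
pseudouridine stabilisation and the non-pairing modifications
(1-methyladenosine, N2,N2-dimethylguanosine) steer the prediction back to
the cloverleaf reference.
"""

from __future__ import annotations

import random

from .structures import SecondaryStructure

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

#: default one-letter codes drawn for random modified positions
DEFAULT_MOD_CODES = "PD769I"


def generate_fixture(n: int, n_mods: int, seed: int, codes: str = DEFAULT_MOD_CODES,
                     plant_hairpin: bool = False):
    """Seeded random sequence with ``n_mods`` modified positions.

    Returns ``(raw_sequence, reference)`` where ``reference`` is a planted
    hairpin :class:`SecondaryStructure` (or ``None``).  Deterministic per
    seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= n_mods <= n:
        raise ValueError("n_mods must be between 0 and n")
    rng = random.Random(seed)
    seq = [rng.choice("ACGU") for _ in range(n)]
    reference = None
    if plant_hairpin and n >= 11:
        stem = min((n - 3) // 2, 6)
        span = 2 * stem + 3
        off = rng.randrange(0, n - span + 1)
        pairs = []
        for t in range(stem):
            a, b = off + t, off + span - 1 - t
            seq[b] = _COMPLEMENT[seq[a]]
            pairs.append((a, b))
        reference = SecondaryStructure(n, frozenset(pairs))
    for pos in rng.sample(range(n), n_mods):
        seq[pos] = rng.choice(codes)
    return "".join(seq), reference


def synthetic_cloverleaf(seed: int = 27):
    """A synthetic modified cloverleaf sequence with its reference structure.

    Four helical arms (acceptor 7 bp, D 4 bp, anticodon 5 bp, T 5 bp) with
    tRNA-like loop content: two dihydrouridines (D) in the D loop, the
    T-loop motif T-P-C (5-methyluridine, pseudouridine, cytidine) followed
    by 1-methyladenosine ('"'), and N2,N2-dimethylguanosine (R) in the
    variable loop.  Arm sequences are drawn deterministically from
    ``seed``; the default seed is fixed so that the unmodified proxy
    misfolds while the modification-aware prediction recovers the
    cloverleaf, the situation this package exists to model.

    Returns ``(raw_sequence, reference)``; decoding the sequence requires
    the pseudouridine and dihydrouridine parameter sets plus the
    tRNA-database alias table.
    """
    rng = random.Random(seed)

    def helix(nbp: int):
        top = [rng.choice("ACGU") for _ in range(nbp)]
        return top, [_COMPLEMENT[c] for c in reversed(top)]

    acc_t, acc_b = helix(7)
    d_t, d_b = helix(4)
    ac_t, ac_b = helix(5)
    t_t, t_b = helix(5)
    d_loop = list("ADA" + rng.choice("ACGU") + "GGDA")
    ac_loop = [rng.choice("ACGU") for _ in range(7)]
    t_loop = list("TPC" + rng.choice("ACGU") + '"AU')
    j1 = [rng.choice("ACGU")]
    j2 = [rng.choice("ACGU")]
    var = ["R"] + [rng.choice("ACGU") for _ in range(3)]
    seq = (acc_t + j1 + d_t + d_loop + d_b + j2 + ac_t + ac_loop + ac_b
           + var + t_t + t_loop + t_b + acc_b + list("ACCA"))
    n = len(seq)
    pairs = []
    acc_b_start = n - 11
    for t in range(7):
        pairs.append((t, acc_b_start + 6 - t))
    o = 8
    for t in range(4):
        pairs.append((o + t, o + 15 - t))
    o2 = o + 17
    for t in range(5):
        pairs.append((o2 + t, o2 + 16 - t))
    o3 = o2 + 21
    for t in range(5):
        pairs.append((o3 + t, o3 + 16 - t))
    return "".join(seq), SecondaryStructure(n, frozenset(pairs))
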