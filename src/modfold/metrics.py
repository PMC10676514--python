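"""Structure comparison metrics: base-pair distance and ensemble defect."""

from __future__ import annotations

import numpy as np

from .structures import SecondaryStructure


def _as_structure(s) -> SecondaryStructure:
    if isinstance(s, str):
        return SecondaryStructure.from_dotbracket(s)
    return s


def base_pair_distance(a, b) -> int:
    """Cardinality of the symmetric difference of two pair sets.

    Both arguments may be :class:`SecondaryStructure` objects or
    dot-bracket strings of equal length.
    """
    a, b = _as_structure(a), _as_structure(b)
    if a.n != b.n:
        raise ValueError(f"structures differ in length ({a.n} vs {b.n})")
    return len(a.pairs ^ b.pairs)


def ensemble_defect(bpp: np.ndarray, reference, normalized: bool = True) -> float:
    """Expected disagreement between an ensemble and a reference structure.

    For a base-pair probability matrix ``p`` and a reference with pair set
    R, the defect is::

        n - sum_{(i,j) in R} 2 p_ij - sum_{i unpaired in R} q_i,
        q_i = 1 - sum_j p_ij

    i.e. the expected number of nucleotides whose pairing status disagrees
    with the reference.  With ``normalized=True`` (default) the count is
    divided by n, giving the fraction of nucleotides in [0, 1].
    """
    ref = _as_structure(reference)
    bpp = np.asarray(bpp, dtype=float)
    if bpp.ndim != 2 or bpp.shape[0] != bpp.shape[1] or bpp.shape[0] != ref.n:
        raise ValueError("probability matrix dimension does not match reference")
    n = ref.n
    paired_prob = bpp.sum(axis=1)
    agree = 0.0
    in_pair = set()
    for i, j in ref.pairs:
        agree += 2.0 * bpp[i, j]
        in_pair.update((i, j))
    for i in range(n):
        if i not in in_pair:
            agree += 1.0 - paired_prob[i]
    defect = n - agree
    return float(defect / n) if normalized else float(defect)
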