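"""Hard and soft constraints: the plug-in layer through which modified
bases reach the fold engine.

The dynamic-programming recursions only ever see the canonical proxy
sequence.  Everything a modification does is expressed here, in two forms:

* **hard constraints** remove structures: positions forced unpaired, or
  positions whose pairing partners are restricted;
* **soft corrections** shift loop energies: an additive dG correction per
  loop, nonzero only when a loop both touches a modified position and has
  tabulated parameters.

Corrections attach to loop *faces* (helix-end contexts), which is the
granularity of all four supported parameter classes (stacks, helix ends,
terminal mismatches, dangling ends).  :class:`LoopCorrections` stores the
sparse face tables and also implements the per-loop provider contract: it
is a pure, memoizable function of (descriptor, sequence, temperature), and
it returns 0 for any loop without modified positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import LoopDescriptor, ModelSettings


@dataclass(frozen=True)
class HardConstraintSet:
    """Per-position pairing restrictions (0-based positions)."""

    unpaired_only: frozenset[int] = frozenset()
    #: position -> set of canonical bases allowed as (proxy) partners
    allowed_partners: dict[int, frozenset[str]] = field(default_factory=dict)

    def permits(self, i: int, j: int, proxy: str) -> bool:
        if i in self.unpaired_only or j in self.unpaired_only:
            return False
        ap = self.allowed_partners.get(i)
        if ap is not None and proxy[j] not in ap:
            return False
        ap = self.allowed_partners.get(j)
        if ap is not None and proxy[i] not in ap:
            return False
        return True


def pair_allowed(i: int, j: int, hard: HardConstraintSet | None, seq_proxy: str,
                 settings: ModelSettings | None = None) -> bool:
    """May positions i and j (0-based, i < j) pair under the model rules?

    False when either position is forced unpaired, when the hairpin
    separation rule j - i - 1 >= min_hairpin is violated, when the proxy
    bases cannot form a canonical (Watson-Crick or wobble) pair, or when a
    partner restriction excludes the pairing.
    """
    settings = settings or ModelSettings()
    if not (0 <= i < j < len(seq_proxy)):
        raise IndexError(f"pair ({i},{j}) out of range")
    if j - i - 1 < settings.min_hairpin:
        return False
    from .model import pair_type_of
    if pair_type_of(seq_proxy[i], seq_proxy[j]) == 0:
        return False
    if hard is not None and not hard.permits(i, j, seq_proxy):
        return False
    return True


#: face-table names understood by the engine; values are dicts
#: (i, j) -> integer correction in 0.01 kcal/mol
FACE_KINDS = ("hairpin", "stack", "end_outer", "end_inner",
              "mm_outer", "mm_inner", "ext_stem", "ml_stem", "ml_close")


@dataclass
class LoopCorrections:
    """Sparse soft-correction provider over loop faces.

    ``faces[kind][(i, j)]`` is an integer dG correction (0.01 kcal/mol)
    for the face anchored at the (ordered, 0-based) pair ``(i, j)``:

    - ``hairpin``: whole hairpin loop closed by (i, j) (helix-end +
      terminal-mismatch corrections of the closing pair);
    - ``stack``: stack between (i, j) and (i+1, j-1);
    - ``end_outer`` / ``end_inner``: helix-end corrections applied when
      (i, j) is the closing / the enclosed pair of any interior loop of
      size > 0 (bulges included);
    - ``mm_outer`` / ``mm_inner``: terminal-mismatch corrections applied
      when (i, j) closes / is enclosed by an interior loop with at least
      one unpaired base on each strand;
    - ``ext_stem`` / ``ml_stem`` / ``ml_close``: helix-end plus
      mismatch-or-dangle corrections of a helix end facing the exterior
      loop or a multiloop (as branch or closing pair).
    """

    n: int
    positions: frozenset[int] = frozenset()
    faces: dict[str, dict[tuple[int, int], int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for kind in FACE_KINDS:
            self.faces.setdefault(kind, {})
        unknown = set(self.faces) - set(FACE_KINDS)
        if unknown:
            raise ValueError(f"unknown face kinds: {sorted(unknown)}")
        for kind, tab in self.faces.items():
            for key, v in tab.items():
                if not isinstance(v, int):
                    raise ValueError(
                        f"non-integer correction {v!r} for {kind}{key}; "
                        "corrections are integers in 0.01 kcal/mol")

    def face(self, kind: str, i: int, j: int) -> int:
        return self.faces[kind].get((i, j), 0)

    # -- the per-loop provider contract -----------------------------------
    def loop(self, descriptor: LoopDescriptor) -> float:
        """dG correction for one loop, kcal/mol (0 when nothing applies)."""
        return self.loop_int(descriptor) / 100.0

    __call__ = loop

    def loop_int(self, d: LoopDescriptor) -> int:
        if d.kind == "hairpin":
            return self.face("hairpin", d.i, d.j)
        if d.kind == "interior":
            n1 = d.k - d.i - 1
            n2 = d.j - d.l - 1
            if n1 == 0 and n2 == 0:
                return self.face("stack", d.i, d.j)
            v = self.face("end_outer", d.i, d.j) + self.face("end_inner", d.k, d.l)
            if n1 > 0 and n2 > 0:
                v += self.face("mm_outer", d.i, d.j) + self.face("mm_inner", d.k, d.l)
            return v
        if d.kind == "multiloop_part":
            return self.face("ml_close" if d.closing else "ml_stem", d.i, d.j)
        if d.kind == "exterior_part":
            return self.face("ext_stem", d.i, d.j)
        raise ValueError(f"unknown loop kind {d.kind!r}")


def zero_corrections(n: int) -> LoopCorrections:
    return LoopCorrections(n=n)


def combine(a: LoopCorrections, b: LoopCorrections) -> LoopCorrections:
    """Additive composition: the provider returning a(.) + b(.)."""
    if a.n != b.n:
        raise ValueError("cannot combine corrections for different lengths")
    faces: dict[str, dict[tuple[int, int], int]] = {}
    for kind in FACE_KINDS:
        merged = dict(a.faces[kind])
        for key, v in b.faces[kind].items():
            merged[key] = merged.get(key, 0) + v
        faces[kind] = merged
    return LoopCorrections(n=a.n, positions=a.positions | b.positions, faces=faces)


def loop_correction(descriptor: LoopDescriptor, provider: LoopCorrections | None) -> float:
    """Soft correction of one loop in kcal/mol (0 without a provider)."""
    if provider is None:
        return 0.0
    val = provider.loop(descriptor)
    if not isinstance(val, (int, float)) or val != val or val in (float("inf"), float("-inf")):
        raise ValueError("soft-correction provider returned a non-finite value")
    return val
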