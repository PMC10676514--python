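"""Secondary structures: non-crossing pair sets, dot-bracket, loop decomposition."""

from __future__ import annotations

from dataclasses import dataclass

from .model import LoopDescriptor


class StructureError(ValueError):
    pass


@dataclass(frozen=True)
class SecondaryStructure:
    """A set of mutually non-crossing base pairs over ``n`` positions (0-based)."""

    n: int
    pairs: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for i, j in self.pairs:
            if not (0 <= i < j < self.n):
                raise StructureError(f"pair ({i},{j}) out of range for n={self.n}")
            if j - i - 1 < 3:
                raise StructureError(f"pair ({i},{j}) closes a hairpin of size < 3")
            if i in seen or j in seen:
                raise StructureError(f"position in more than one pair near ({i},{j})")
            seen.add(i)
            seen.add(j)
        ordered = sorted(self.pairs)
        for a in range(len(ordered)):
            i, j = ordered[a]
            for b in range(a + 1, len(ordered)):
                k, l = ordered[b]
                if k > j:
                    break
                if not (i < k < l < j):
                    raise StructureError(
                        f"crossing pairs ({i},{j}) and ({k},{l})")

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_dotbracket(cls, db: str) -> "SecondaryStructure":
        stack: list[int] = []
        pairs = set()
        for pos, c in enumerate(db):
            if c == "(":
                stack.append(pos)
            elif c == ")":
                if not stack:
                    raise StructureError(f"unbalanced ')' at position {pos + 1}")
                pairs.add((stack.pop(), pos))
            elif c != ".":
                raise StructureError(f"unexpected character {c!r} at position {pos + 1}")
        if stack:
            raise StructureError(f"unbalanced '(' at position {stack[-1] + 1}")
        return cls(len(db), frozenset(pairs))

    def to_dotbracket(self) -> str:
        out = ["."] * self.n
        for i, j in self.pairs:
            out[i] = "("
            out[j] = ")"
        return "".join(out)

    # -- helpers -----------------------------------------------------------
    def pair_table(self) -> list[int]:
        """partner[i] = j (or -1 if unpaired)."""
        pt = [-1] * self.n
        for i, j in self.pairs:
            pt[i] = j
            pt[j] = i
        return pt

    def pairs_1based(self) -> set[tuple[int, int]]:
        return {(i + 1, j + 1) for i, j in self.pairs}

    def loops(self):
        """Yield the loop decomposition as :class:`LoopDescriptor` objects.

        Exterior helix ends come first (kind ``exterior_part``), then for
        every closing pair the loop it closes: a hairpin, an interior loop,
        or the parts of a multiloop (closing descriptor followed by one
        descriptor per branch).
        """
        pt = self.pair_table()
        n = self.n

        def children(i: int, j: int) -> list[tuple[int, int]]:
            out = []
            k = i + 1
            while k < j:
                if pt[k] > k:
                    out.append((k, pt[k]))
                    k = pt[k] + 1
                else:
                    k += 1
            return out

        # exterior
        k = 0
        ext: list[tuple[int, int]] = []
        while k < n:
            if pt[k] > k:
                ext.append((k, pt[k]))
                k = pt[k] + 1
            else:
                k += 1
        for i, j in ext:
            yield LoopDescriptor("exterior_part", i, j)

        todo = list(ext)
        while todo:
            i, j = todo.pop()
            ch = children(i, j)
            todo.extend(ch)
            if not ch:
                yield LoopDescriptor("hairpin", i, j)
            elif len(ch) == 1:
                k_, l_ = ch[0]
                yield LoopDescriptor("interior", i, j, k_, l_)
            else:
                yield LoopDescriptor("multiloop_part", i, j, closing=True)
                for k_, l_ in ch:
                    yield LoopDescriptor("multiloop_part", k_, l_)
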