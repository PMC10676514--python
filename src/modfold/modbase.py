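"""Modified-base parameter sets, the extended alphabet, and constraint building.

A modification is described by a small JSON document (see ``data/mod/`` for
the six built-in sets and the format reference below).  Each document names
a one-letter code, the unmodified counterpart, a *fallback* base whose
parameters stand in wherever no modified-base parameters exist, the allowed
pairing partners, and sparse energy tables for up to four loop classes:
base-pair stacks, helix ends, terminal mismatches and dangling ends.  Free
energies are dG37 in kcal/mol; optional enthalpies enable temperature
rescaling.

Context keys read 5'->3' on the top strand, then 3'->5' on the bottom
strand, with the modified code in place::

    stack     "APUA"  =  5'-A P-3' / 3'-U A-5'   (pairs A.U and P.A)
    terminal  "PA"    =  helix-end pair P.A (both orientations listed)
    mismatch  "C6G6"  =  closing pair C.G with 3' mismatch 6 / 5' mismatch 6
    dangle    "UA6"   =  pair U.A with the dangling base 6

:func:`build_constraints` turns a :class:`ModifiedSequence` into the
(hard, soft) constraint pair consumed by the fold engine: pairing-rule
changes become hard constraints, tabulated energies become per-face soft
corrections of the form (modified value) - (proxy value of the same face).
When one loop face joins two *distinct* modified bases the correction is
the sum of each base's individual difference to the unmodified case.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .constraints import HardConstraintSet, LoopCorrections
from .model import ModelSettings, ScaledTables
from .params import (BASE_INDEX, PAIR_TYPE, T37, EnergyEntry,
                     NNParameterSet, rescale)

CANONICAL = "ACGU"


class ModFileError(ValueError):
    """A modified-base parameter document failed validation."""


class AlphabetError(ValueError):
    """An input sequence character could not be resolved."""


@dataclass(frozen=True)
class ModifiedBaseParameterSet:
    """Sparse thermodynamic record for one modified base."""

    name: str
    one_letter_code: str
    unmodified: str
    fallback: str
    pairing_partners: frozenset[str]
    stacking: dict[str, EnergyEntry] = field(default_factory=dict)
    terminal: dict[str, EnergyEntry] = field(default_factory=dict)
    mismatch: dict[str, EnergyEntry] = field(default_factory=dict)
    dangle5: dict[str, EnergyEntry] = field(default_factory=dict)
    dangle3: dict[str, EnergyEntry] = field(default_factory=dict)
    sources: tuple = ()

    def __hash__(self):
        return hash(self.one_letter_code)


@dataclass(frozen=True)
class ModifiedSequence:
    """An extended-alphabet sequence and its canonical proxy."""

    raw: str
    proxy: str
    #: 0-based position -> parameter set
    mods: dict[int, ModifiedBaseParameterSet] = field(default_factory=dict)
    #: positions forced unpaired by pairing-rule aliases (m1A, m22G)
    forced_unpaired: frozenset[int] = frozenset()

    def __post_init__(self):
        if len(self.raw) != len(self.proxy):
            raise ValueError("raw and proxy sequences differ in length")

    def decode(self) -> str:
        return self.raw


# --------------------------------------------------------------------------
# JSON parsing / validation
# --------------------------------------------------------------------------

_KEY_LENGTH = {"stacking": 4, "terminal": 2, "mismatch": 4,
               "dangle5": 3, "dangle3": 3}
_KNOWN_KEYS = {"name", "sources", "one_letter_code", "unmodified", "fallback",
               "pairing_partners", "duplexes"}
for _cls in _KEY_LENGTH:
    _n = {"stacking": "stacking", "terminal": "terminal",
          "mismatch": "mismatch", "dangle5": "dangle5", "dangle3": "dangle3"}[_cls]
    _KNOWN_KEYS |= {f"{_n}_energies", f"{_n}_enthalpies"}


def parse_mod_json(document: str | dict) -> ModifiedBaseParameterSet:
    """Parse and validate a modified-base JSON document."""
    if isinstance(document, str):
        try:
            document = json.loads(document)
        except json.JSONDecodeError as exc:
            raise ModFileError(f"invalid JSON: {exc}") from exc
    if not isinstance(document, dict) or "modified_base" not in document:
        raise ModFileError("missing mandatory top-level object 'modified_base'")
    d = document["modified_base"]
    for key in ("name", "one_letter_code", "unmodified", "fallback",
                "pairing_partners"):
        if key not in d:
            raise ModFileError(f"missing mandatory key '{key}'")
    code = d["one_letter_code"]
    if not isinstance(code, str) or len(code) != 1:
        raise ModFileError("'one_letter_code' must be a single character")
    if code in CANONICAL:
        raise ModFileError("'one_letter_code' must not be one of A, C, G, U")
    for key in ("unmodified", "fallback"):
        if d[key] not in tuple(CANONICAL):
            raise ModFileError(f"'{key}' must be one of A, C, G, U")
    partners = d["pairing_partners"]
    if (not isinstance(partners, list)
            or any(p not in tuple(CANONICAL) for p in partners)):
        raise ModFileError("'pairing_partners' must be a list of A/C/G/U")

    unknown = set(d) - _KNOWN_KEYS
    if unknown:
        warnings.warn(f"ignoring unknown keys in modified-base file: "
                      f"{sorted(unknown)}", stacklevel=2)

    alphabet = set(CANONICAL) | {code}

    def table(cls: str) -> dict[str, EnergyEntry]:
        energies = d.get(f"{cls}_energies", {})
        enthalpies = d.get(f"{cls}_enthalpies", {})
        if not isinstance(energies, dict) or not isinstance(enthalpies, dict):
            raise ModFileError(f"'{cls}_energies' must be an object")
        out = {}
        for key, val in energies.items():
            if len(key) != _KEY_LENGTH[cls] or any(c not in alphabet for c in key):
                raise ModFileError(
                    f"bad context key {key!r} in '{cls}_energies' "
                    f"(expected {_KEY_LENGTH[cls]} characters over ACGU+{code})")
            if not isinstance(val, (int, float)):
                raise ModFileError(f"non-numeric energy for key {key!r}")
            dh = enthalpies.get(key)
            out[key] = EnergyEntry(float(val), None if dh is None else float(dh))
        for key in enthalpies:
            if key not in energies:
                raise ModFileError(
                    f"enthalpy for {key!r} in '{cls}_enthalpies' has no "
                    f"matching free energy")
        return out

    return ModifiedBaseParameterSet(
        name=str(d["name"]), one_letter_code=code, unmodified=d["unmodified"],
        fallback=d["fallback"], pairing_partners=frozenset(partners),
        stacking=table("stacking"), terminal=table("terminal"),
        mismatch=table("mismatch"), dangle5=table("dangle5"),
        dangle3=table("dangle3"),
        sources=tuple(map(str, d.get("sources", ()))))


def load_mod_file(path: str | Path) -> ModifiedBaseParameterSet:
    return parse_mod_json(Path(path).read_text())


# --------------------------------------------------------------------------
# built-in parameter sets and tRNA-database aliases
# --------------------------------------------------------------------------

_BUILTIN_FILES = {
    "7": "deaza7A.json", "I": "inosine.json", "6": "m6A.json",
    "P": "pseudouridine.json", "9": "purine.json", "D": "dihydrouridine.json",
}
_BUILTIN_NAMES = {
    "7da": "7", "7-deaza-adenosine": "7", "deaza": "7",
    "inosine": "I", "m6a": "6", "n6-methyladenosine": "6",
    "pseudouridine": "P", "psi": "P",
    "purine": "9", "nebularine": "9",
    "dihydrouridine": "D",
}
_builtin_cache: dict[str, ModifiedBaseParameterSet] = {}


def _data_text(name: str) -> str:
    return resources.files("modfold").joinpath(f"data/mod/{name}").read_text()


def load_builtin(code_or_name: str) -> ModifiedBaseParameterSet:
    """One of the six shipped parameter sets, by code or by name."""
    key = code_or_name if code_or_name in _BUILTIN_FILES else \
        _BUILTIN_NAMES.get(code_or_name.lower())
    if key is None:
        raise KeyError(
            f"unknown built-in modified base {code_or_name!r}; available: "
            f"{sorted(_BUILTIN_FILES)} "
            f"(names: {sorted(set(_BUILTIN_NAMES))}). Pairing-rule-only "
            "modifications such as m1A/m22G are provided through the "
            "tRNA-database alias table, not as energy parameter sets.")
    if key not in _builtin_cache:
        _builtin_cache[key] = parse_mod_json(_data_text(_BUILTIN_FILES[key]))
    return _builtin_cache[key]


def builtin_sets() -> tuple[ModifiedBaseParameterSet, ...]:
    return tuple(load_builtin(c) for c in _BUILTIN_FILES)


def trnadb_aliases() -> dict[str, dict]:
    """tRNA-database one-letter-code aliases (m1A, m22G, m5U/T, ...).

    Maps a code to ``{"fallback": base, "unpaired": bool, "name": str}``.
    Codes listed here take precedence over parameter-set codes when both
    are active (the tRNA database uses '7' for 7-methylguanosine)."""
    return json.loads(_data_text("trnadb_aliases.json"))


# --------------------------------------------------------------------------
# sequence encoding
# --------------------------------------------------------------------------

def encode_sequence(raw: str, sets=(), alias_map: dict | None = None
                    ) -> ModifiedSequence:
    """Resolve an extended-alphabet string into a :class:`ModifiedSequence`.

    Every non-ACGU character must resolve through ``sets`` (a collection of
    :class:`ModifiedBaseParameterSet`) or ``alias_map``; aliases win when
    both define a code.
    """
    by_code = {s.one_letter_code: s for s in sets}
    if len(by_code) != len(tuple(sets)):
        raise ModFileError("duplicate one-letter codes among parameter sets")
    proxy = []
    mods: dict[int, ModifiedBaseParameterSet] = {}
    forced: set[int] = set()
    for pos, c in enumerate(raw):
        if c in CANONICAL:
            proxy.append(c)
        elif alias_map is not None and c in alias_map:
            entry = alias_map[c]
            proxy.append(entry["fallback"])
            if entry.get("unpaired"):
                forced.add(pos)
        elif c in by_code:
            s = by_code[c]
            proxy.append(s.fallback)
            mods[pos] = s
        else:
            raise AlphabetError(
                f"unresolvable character {c!r} at position {pos + 1}; "
                "load a parameter set or alias that defines it")
    return ModifiedSequence(raw=raw, proxy="".join(proxy), mods=mods,
                            forced_unpaired=frozenset(forced))


# --------------------------------------------------------------------------
# constraint construction
# --------------------------------------------------------------------------

def build_constraints(modseq: ModifiedSequence,
                      settings: ModelSettings | None = None,
                      baseline: NNParameterSet | ScaledTables | None = None
                      ) -> tuple[HardConstraintSet, LoopCorrections]:
    """Hard constraints and per-face soft corrections for a sequence.

    ``baseline`` provides the unmodified tables the corrections subtract;
    both the modified entries and the baseline are rescaled to the working
    temperature before the difference is taken.
    """
    settings = settings or ModelSettings()
    if baseline is None:
        from .params import load_parameters
        baseline = load_parameters()
    tables = baseline if isinstance(baseline, ScaledTables) else \
        ScaledTables(baseline, settings)
    T = settings.temperature
    n = len(modseq.raw)
    raw, proxy = modseq.raw, modseq.proxy
    S = [BASE_INDEX[c] for c in proxy]
    d2 = settings.dangle_model == "d2"

    # ---- hard constraints -------------------------------------------------
    unpaired = set(modseq.forced_unpaired)
    partners: dict[int, frozenset[str]] = {}
    for pos, s in modseq.mods.items():
        if not s.pairing_partners:
            unpaired.add(pos)
        else:
            partners[pos] = s.pairing_partners
    hard = HardConstraintSet(unpaired_only=frozenset(unpaired),
                             allowed_partners=partners)

    # ---- soft corrections -------------------------------------------------
    ismod = [p in modseq.mods for p in range(n)]

    def vint(entry: EnergyEntry) -> int:
        # kcal/mol -> integer grid by truncation toward zero (the same
        # conversion the reference parameter reader applies), then
        # temperature rescaling on the integer grid
        g = int(100.0 * entry.dG37)
        if entry.dH is None or abs(T - T37) < 1e-9:
            return g
        h = int(100.0 * entry.dH)
        return int(round(h - (h - g) * T / T37))

    def groups(slot_positions):
        """Modified positions among the slots, grouped by parameter set."""
        by_set: dict[ModifiedBaseParameterSet, list[int]] = {}
        for idx, p in enumerate(slot_positions):
            if ismod[p]:
                by_set.setdefault(modseq.mods[p], []).append(idx)
        return by_set

    def type_key(slots, s):
        """Context key for one modification type: other types fall back."""
        return "".join(
            raw[q] if not ismod[q] or modseq.mods[q] is s else proxy[q]
            for q in slots)

    def delta_pairwise(cls: str, slots, base: int) -> int:
        """Stack / helix-end correction: per modification type, exact key
        lookup; contexts touching a single modified slot may also match
        through the 180-degree rotation of the context (the reversed key
        string).  Distinct types contribute their individual differences
        to the proxy baseline (sum-of-differences rule)."""
        acc = 0
        for s, idxs in groups(slots).items():
            tab = getattr(s, cls)
            key = type_key(slots, s)
            entry = tab.get(key)
            if entry is None and len(idxs) == 1:
                entry = tab.get(key[::-1])
            if entry is not None:
                acc += vint(entry) - base
        return acc

    def delta_mismatch(a: int, a1: int, b: int, b1: int) -> int:
        """Terminal-mismatch correction in the loop frame (a, b) with the
        3' neighbour a1 of a and the 5' neighbour b1 of b.

        The proxy baseline is the generic (multiloop/exterior) mismatch
        term; when the modification sits on the pair itself the context is
        read from the opposite strand, which reverses the pair type.
        Entries whose modified base is the bottom pair base of the frame
        belong to the opposite frame and never match here."""
        slots = (a, a1, b, b1)
        acc = 0
        for s, idxs in groups(slots).items():
            if 2 in idxs:
                continue
            entry = s.mismatch.get(type_key(slots, s))
            if entry is None:
                continue
            pt = int(PAIR_TYPE[S[a], S[b]])
            if 0 in idxs:
                base = int(tables.mm_multi[int(PAIR_TYPE[S[b], S[a]]),
                                           S[a1], S[b1]])
            else:
                base = int(tables.mm_multi[pt, S[b1], S[a1]])
            acc += vint(entry) - base
        return acc

    def delta_dangle(cls: str, a: int, b: int, d: int) -> int:
        """Dangling-end correction for a one-sided exterior helix end.

        The key reads the pair in the exterior-loop frame (a, b) followed
        by the dangling base; the baseline is the same dangle table on the
        proxy context."""
        slots = (a, b, d)
        base = int(getattr(tables, cls)[int(PAIR_TYPE[S[a], S[b]]), S[d]])
        acc = 0
        for s in groups(slots):
            entry = getattr(s, cls).get(type_key(slots, s))
            if entry is not None:
                acc += vint(entry) - base
        return acc

    def term_base(pt: int) -> int:
        return 0 if pt in (1, 2) else tables.terminal_au

    faces: dict[str, dict[tuple[int, int], int]] = {}

    def put(kind: str, i: int, j: int, v: int) -> None:
        if v:
            faces.setdefault(kind, {})[(i, j)] = v

    if modseq.mods:
        for i in range(n):
            for j in range(i + settings.min_hairpin + 1, n):
                pt = int(PAIR_TYPE[S[i], S[j]])
                if pt == 0:
                    continue
                near_pair = ismod[i] or ismod[j]
                near_in = near_pair or ismod[i + 1] or ismod[j - 1]
                near_out = near_pair or (i > 0 and ismod[i - 1]) or \
                    (j + 1 < n and ismod[j + 1])
                # stack between (i, j) and (i+1, j-1)
                if near_in and j - i - 1 >= 2:
                    pt2 = int(PAIR_TYPE[S[j - 1], S[i + 1]])
                    if pt2:
                        put("stack", i, j,
                            delta_pairwise("stacking", (i, i + 1, j, j - 1),
                                           int(tables.stack[pt, pt2])))
                # helix-end and mismatch faces in the closing frame
                if near_pair or near_in:
                    end = delta_pairwise("terminal", (i, j), term_base(pt)) \
                        if near_pair else 0
                    mm = delta_mismatch(i, i + 1, j, j - 1)
                    put("end_outer", i, j, end)
                    put("mm_outer", i, j, mm)
                    put("hairpin", i, j, end + mm)
                # the same pair as the enclosed pair of a loop (flipped frame)
                if i > 0 and j + 1 < n and (near_pair or near_out):
                    if near_pair:
                        put("end_inner", i, j,
                            delta_pairwise("terminal", (i, j), term_base(pt)))
                    put("mm_inner", i, j, delta_mismatch(j, j + 1, i, i - 1))
                # exterior-loop and multiloop helix ends
                if near_pair or near_in or near_out:
                    end = delta_pairwise("terminal", (i, j), term_base(pt)) \
                        if near_pair else 0
                    ext = ml_s = ml_c = end
                    if d2:
                        if i > 0 and j + 1 < n:
                            mm_out_frame = delta_mismatch(j, j + 1, i, i - 1)
                            ext += mm_out_frame
                            ml_s += mm_out_frame
                        elif j + 1 < n:
                            ext += delta_dangle("dangle3", j, i, j + 1)
                        elif i > 0:
                            ext += delta_dangle("dangle5", j, i, i - 1)
                        ml_c += delta_mismatch(i, i + 1, j, j - 1)
                    put("ext_stem", i, j, ext)
                    put("ml_stem", i, j, ml_s)
                    put("ml_close", i, j, ml_c)

    soft = LoopCorrections(
        n=n, positions=frozenset(modseq.mods) | modseq.forced_unpaired,
        faces=faces)
    return hard, soft
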