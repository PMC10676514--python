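"""Nearest-neighbor energy parameters for the canonical ACGU alphabet.

The free-energy model is the standard Turner model: stacks, hairpin /
bulge / internal loop length tables, terminal mismatches, dangling ends,
special small interior loop tables (1x1, 2x1, 2x2), tabulated stable
tri-/tetra-/hexaloops and an affine multiloop term.  All free energies are
Gibbs energies at 37 degC (310.15 K) and 1 M NaCl in kcal/mol; enthalpies,
where available, allow rescaling to other temperatures via
``dG(T) = dH - T * (dH - dG37) / 310.15``.

Tables are read from parameter files in the widely used ``RNAfold parameter
file v2.0`` plain-text format (sections introduced by ``# name``, integer
energies in units of 0.01 kcal/mol, ``INF`` for forbidden entries).  The
default table set is the Turner 2004 compilation, located at import time in
the ViennaRNA data directory of the host environment (see
:func:`default_parameter_file`).

Internally every energy is an integer in units of 0.01 kcal/mol; floats
appear only at the API boundary.
"""

from __future__ import annotations

import math
import os
import re
import shutil
from dataclasses import dataclass
from pathlib import Path

import numpy as np

#: gas constant in kcal/(mol K)
GAS_CONSTANT = 1.98717e-3
#: reference temperature of the tabulated free energies (37 degC), K
T37 = 310.15
#: "forbidden" energy sentinel, units of 0.01 kcal/mol
INF = 1 << 28
#: largest interior loop (n1 + n2) considered by the fold engine
MAXLOOP = 30

# base encoding: 0 is the wildcard/none slot used by the table layout
BASES = "NACGU"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

# pair-type encoding used by every table: CG GC GU UG AU UA, 7 = unknown/NN
PAIR_STRINGS = ("NN", "CG", "GC", "GU", "UG", "AU", "UA", "NN")
PAIR_TYPE = np.zeros((5, 5), dtype=np.int64)
for _t, _p in ((1, "CG"), (2, "GC"), (3, "GU"), (4, "UG"), (5, "AU"), (6, "UA")):
    PAIR_TYPE[BASE_INDEX[_p[0]], BASE_INDEX[_p[1]]] = _t


def encode(seq: str) -> np.ndarray:
    """Encode an ACGU string into the integer representation (A=1..U=4)."""
    try:
        return np.array([BASE_INDEX[c] for c in seq], dtype=np.int64)
    except KeyError as exc:  # pragma: no cover - guarded by callers
        raise ValueError(f"non-ACGU character {exc} in proxy sequence") from exc


@dataclass(frozen=True)
class EnergyEntry:
    """A single tabulated energy: dG at 37 degC and an optional enthalpy.

    Both values are in kcal/mol.  Entries without an enthalpy cannot be
    rescaled and are used unchanged at every temperature.
    """

    dG37: float
    dH: float | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.dG37):
            raise ValueError("dG37 must be finite")
        if self.dH is not None and not math.isfinite(self.dH):
            raise ValueError("dH must be finite when present")

    def at(self, temperature: float) -> float:
        """Free energy at ``temperature`` (K), kcal/mol."""
        return rescale(self, temperature)


def rescale(entry: EnergyEntry, temperature: float) -> float:
    """Rescale a tabulated dG37/dH pair to another temperature.

    Uses dS = (dH - dG37) / 310.15 so that the value at 310.15 K is exactly
    dG37.  Entries without an enthalpy are returned unchanged.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive (kelvin)")
    if entry.dH is None:
        return entry.dG37
    ds = (entry.dH - entry.dG37) / T37
    return entry.dH - temperature * ds


def _rescale_int(dg: np.ndarray, dh: np.ndarray, temperature: float) -> np.ndarray:
    """Vectorized integer rescaling; INF entries stay INF."""
    tf = temperature / T37
    out = np.rint(dh - (dh - dg) * tf).astype(np.int64)
    out[dg >= INF] = INF
    return out


# --------------------------------------------------------------------------
# parameter-file parsing
# --------------------------------------------------------------------------

_COMMENT = re.compile(r"/\*.*?\*/", re.S)


class ParameterFileError(ValueError):
    pass


def _split_sections(text: str) -> dict[str, str]:
    if not text.lstrip().startswith("## RNAfold parameter file v2.0"):
        raise ParameterFileError("not an 'RNAfold parameter file v2.0' header")
    sections: dict[str, str] = {}
    name = None
    buf: list[str] = []
    for line in text.splitlines():
        if line.startswith("#"):
            if name is not None:
                sections[name] = "\n".join(buf)
            name = line[1:].strip()
            buf = []
        elif name is not None:
            buf.append(line)
    if name is not None:
        sections[name] = "\n".join(buf)
    return sections


def _numbers(section: str) -> np.ndarray:
    toks = _COMMENT.sub(" ", section).split()
    vals = [INF if t.upper().startswith("INF") else int(t) for t in toks]
    return np.array(vals, dtype=np.int64)


def _table(sections: dict[str, str], name: str, shape: tuple[int, ...],
           required: bool = True) -> np.ndarray:
    if name not in sections:
        if required:
            raise ParameterFileError(f"missing section '# {name}'")
        return np.zeros(shape, dtype=np.int64)
    vals = _numbers(sections[name])
    if vals.size != np.prod(shape):
        raise ParameterFileError(
            f"section '# {name}': expected {np.prod(shape)} values, got {vals.size}")
    return vals.reshape(shape)


def _pad_pairs(arr: np.ndarray, ndim_pairs: int) -> np.ndarray:
    """Embed a table indexed by 7 pair types (CG..NN) into an 8-slot axis.

    Slot 0 is the 'no pair' type and is filled with INF so that illegal
    contexts evaluated through it are loudly forbidden rather than silent.
    """
    out = np.full((8,) * ndim_pairs + arr.shape[ndim_pairs:], INF, dtype=np.int64)
    idx = tuple(slice(1, 8) for _ in range(ndim_pairs))
    out[idx] = arr
    return out


class NNParameterSet:
    """Complete Turner-style nearest-neighbor table set (integer 0.01 kcal/mol).

    Every ``*_dH`` array carries the enthalpy twin used for temperature
    rescaling.  Pair axes are 8 wide (0 = no pair, 1..6 = CG GC GU UG AU UA,
    7 = NN wildcard), base axes are 5 wide (0 = N).
    """

    def __init__(self, sections: dict[str, str], source: str = "<memory>"):
        self.source = source
        g, h = self._pair_tables(sections, "stack", (7, 7))
        self.stack, self.stack_dH = _pad_pairs(g, 2), _pad_pairs(h, 2)

        for nm, attr in (("mismatch_hairpin", "mm_hairpin"),
                         ("mismatch_internal", "mm_interior"),
                         ("mismatch_internal_1n", "mm_interior_1n"),
                         ("mismatch_internal_23", "mm_interior_23"),
                         ("mismatch_multi", "mm_multi"),
                         ("mismatch_exterior", "mm_exterior")):
            g, h = self._pair_tables(sections, nm, (7, 5, 5))
            setattr(self, attr, _pad_pairs(g, 1))
            setattr(self, attr + "_dH", _pad_pairs(h, 1))

        for nm in ("dangle5", "dangle3"):
            g, h = self._pair_tables(sections, nm, (7, 5))
            setattr(self, nm, _pad_pairs(g, 1))
            setattr(self, nm + "_dH", _pad_pairs(h, 1))

        g, h = self._pair_tables(sections, "int11", (7, 7, 5, 5))
        self.int11, self.int11_dH = _pad_pairs(g, 2), _pad_pairs(h, 2)
        g, h = self._pair_tables(sections, "int21", (7, 7, 5, 5, 5))
        self.int21, self.int21_dH = _pad_pairs(g, 2), _pad_pairs(h, 2)
        g, h = self._pair_tables(sections, "int22", (6, 6, 4, 4, 4, 4))
        # int22 is stored without wildcard rows: pairs 1..6, bases 1..4
        full = np.full((8, 8, 5, 5, 5, 5), INF, dtype=np.int64)
        full_h = np.full_like(full, INF)
        full[1:7, 1:7, 1:, 1:, 1:, 1:] = g
        full_h[1:7, 1:7, 1:, 1:, 1:, 1:] = h
        self.int22, self.int22_dH = full, full_h

        self.hairpin = _table(sections, "hairpin", (31,))
        self.hairpin_dH = _table(sections, "hairpin_enthalpies", (31,))
        self.bulge = _table(sections, "bulge", (31,))
        self.bulge_dH = _table(sections, "bulge_enthalpies", (31,))
        self.internal = _table(sections, "internal", (31,))
        self.internal_dH = _table(sections, "internal_enthalpies", (31,))

        ml = _table(sections, "ML_params", (6,))
        self.ml_base, self.ml_base_dH = int(ml[0]), int(ml[1])
        self.ml_closing, self.ml_closing_dH = int(ml[2]), int(ml[3])
        self.ml_intern, self.ml_intern_dH = int(ml[4]), int(ml[5])

        ninio = _table(sections, "NINIO", (3,))
        self.ninio, self.ninio_dH, self.ninio_max = (int(x) for x in ninio)

        misc = _numbers(sections.get("Misc", ""))
        if misc.size < 4:
            raise ParameterFileError("section '# Misc' must list at least 4 values")
        self.duplex_init, self.duplex_init_dH = int(misc[0]), int(misc[1])
        self.terminal_au, self.terminal_au_dH = int(misc[2]), int(misc[3])

        # logarithmic loop-size extrapolation coefficient (0.01 kcal/mol);
        # 1.07856 kcal/mol is the standard value tied to the Jacobson-
        # Stockmayer entropy and scales linearly with temperature
        self.lxc37 = 107.856

        self.special_hairpins: dict[str, EnergyEntry] = {}
        for nm in ("Triloops", "Tetraloops", "Hexaloops"):
            for line in sections.get(nm, "").splitlines():
                toks = line.split()
                if len(toks) == 3:
                    self.special_hairpins[toks[0]] = EnergyEntry(
                        int(toks[1]) / 100.0, int(toks[2]) / 100.0)

    @staticmethod
    def _pair_tables(sections, name, shape):
        g = _table(sections, name, shape)
        h = _table(sections, name + "_enthalpies", shape)
        return g, h

    # -- public float views (kcal/mol) ------------------------------------
    def stack_entry(self, pair_outer: str, pair_inner: str) -> EnergyEntry:
        """Stacking entry for two pairs given as e.g. ("CG", "GC")."""
        t1 = PAIR_TYPE[BASE_INDEX[pair_outer[0]], BASE_INDEX[pair_outer[1]]]
        t2 = PAIR_TYPE[BASE_INDEX[pair_inner[0]], BASE_INDEX[pair_inner[1]]]
        return EnergyEntry(self.stack[t1, t2] / 100.0, self.stack_dH[t1, t2] / 100.0)

    def terminal_entry(self, pair: str) -> EnergyEntry:
        """Helix-end (non-GC terminal pair) penalty for a pair string."""
        t = PAIR_TYPE[BASE_INDEX[pair[0]], BASE_INDEX[pair[1]]]
        if t in (1, 2):
            return EnergyEntry(0.0, 0.0)
        return EnergyEntry(self.terminal_au / 100.0, self.terminal_au_dH / 100.0)


def default_parameter_file() -> Path:
    """Locate the Turner 2004 parameter file of the host environment.

    Search order: ``$MODFOLD_PARAMS``, the ``share/ViennaRNA`` directory next
    to an ``RNAfold`` executable on PATH, and ``<sys.prefix>/share/ViennaRNA``.
    """
    env = os.environ.get("MODFOLD_PARAMS")
    if env:
        p = Path(env)
        if p.is_file():
            return p
        raise FileNotFoundError(f"MODFOLD_PARAMS={env} does not exist")
    candidates = []
    rnafold = shutil.which("RNAfold")
    if rnafold:
        candidates.append(Path(rnafold).parent.parent / "share" / "ViennaRNA")
    import sys
    candidates.append(Path(sys.prefix) / "share" / "ViennaRNA")
    for d in candidates:
        p = d / "rna_turner2004.par"
        if p.is_file():
            return p
    raise FileNotFoundError(
        "could not locate rna_turner2004.par; set MODFOLD_PARAMS to a "
        "parameter file in 'RNAfold parameter file v2.0' format")


_cache: dict[str, NNParameterSet] = {}


def load_parameters(path: str | Path | None = None) -> NNParameterSet:
    """Load (and cache) a nearest-neighbor parameter file."""
    p = Path(path) if path is not None else default_parameter_file()
    key = str(p.resolve())
    if key not in _cache:
        _cache[key] = NNParameterSet(_split_sections(p.read_text()), source=key)
    return _cache[key]
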