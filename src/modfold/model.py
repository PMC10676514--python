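"""Model settings, loop descriptors and temperature-scaled tables.

The fold engine works on integer energies (units of 0.01 kcal/mol) taken
from a :class:`~modfold.params.NNParameterSet` rescaled once to the working
temperature.  :class:`ScaledTables` holds those integer arrays; the loop
evaluation functions in :mod:`modfold.fold` and the DP kernels both read
from it, which is what guarantees that a traceback structure re-evaluated
loop by loop reproduces the DP energy bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .params import (GAS_CONSTANT, INF, MAXLOOP, PAIR_TYPE, T37, EnergyEntry,
                     NNParameterSet, _rescale_int, encode)


@dataclass(frozen=True)
class ModelSettings:
    """Global knobs of the energy model.

    temperature is in kelvin; the tabulated parameters refer to 310.15 K
    and are rescaled through their enthalpies for other temperatures.
    ``dangle_model`` selects how unpaired bases next to helix ends
    contribute: ``"d2"`` (the default, mismatch-style terms on both sides
    of every helix end) or ``"none"``.
    """

    temperature: float = T37
    gas_constant: float = GAS_CONSTANT
    dangle_model: str = "d2"
    min_hairpin: int = 3
    allow_lonely_pairs: bool = True
    #: internal integer unit, kcal/mol
    energy_quantum: float = 0.01

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (kelvin)")
        if self.min_hairpin < 3:
            raise ValueError("min_hairpin must be >= 3")
        if self.dangle_model not in ("d2", "none"):
            raise ValueError("dangle_model must be 'd2' or 'none'")
        if not self.allow_lonely_pairs:
            raise ValueError("prohibiting lonely pairs is not supported")

    @property
    def rt(self) -> float:
        """R*T in kcal/mol."""
        return self.gas_constant * self.temperature


@dataclass(frozen=True)
class LoopDescriptor:
    """Identifies one loop (or loop face) of a secondary structure.

    Positions are 0-based.  ``kind`` is one of ``hairpin``, ``interior``,
    ``multiloop_part`` or ``exterior_part``.  For interior loops ``(i, j)``
    is the closing and ``(k, l)`` the enclosed pair (i < k < l < j).  For
    ``multiloop_part`` the descriptor names one helix end inside the loop:
    the closing pair when ``closing`` is true, a branch otherwise.
    """

    kind: str
    i: int
    j: int
    k: int | None = None
    l: int | None = None
    closing: bool = False

    def __post_init__(self) -> None:
        if self.i >= self.j:
            raise ValueError("loop descriptor requires i < j")
        if self.kind == "interior":
            if self.k is None or self.l is None or not (self.i < self.k < self.l < self.j):
                raise ValueError("interior loop requires i < k < l < j")
        elif self.kind not in ("hairpin", "multiloop_part", "exterior_part"):
            raise ValueError(f"unknown loop kind {self.kind!r}")


class ScaledTables:
    """All integer tables of a parameter set rescaled to one temperature."""

    def __init__(self, params: NNParameterSet, settings: ModelSettings):
        self.params = params
        self.settings = settings
        T = settings.temperature

        def rs(name: str) -> np.ndarray:
            return _rescale_int(getattr(params, name), getattr(params, name + "_dH"), T)

        self.stack = rs("stack")
        self.mm_hairpin = rs("mm_hairpin")
        self.mm_interior = rs("mm_interior")
        self.mm_interior_1n = rs("mm_interior_1n")
        self.mm_interior_23 = rs("mm_interior_23")
        self.mm_multi = rs("mm_multi")
        self.mm_exterior = rs("mm_exterior")
        self.dangle5 = rs("dangle5")
        self.dangle3 = rs("dangle3")
        self.int11 = rs("int11")
        self.int21 = rs("int21")
        self.int22 = rs("int22")
        self.hairpin = rs("hairpin")
        self.bulge = rs("bulge")
        self.internal = rs("internal")

        def rs1(g: int, h: int) -> int:
            return int(round(h - (h - g) * T / T37))

        self.ml_base = rs1(params.ml_base, params.ml_base_dH)
        self.ml_closing = rs1(params.ml_closing, params.ml_closing_dH)
        self.ml_intern = rs1(params.ml_intern, params.ml_intern_dH)
        self.ninio = rs1(params.ninio, params.ninio_dH)
        self.ninio_max = params.ninio_max
        self.terminal_au = rs1(params.terminal_au, params.terminal_au_dH)
        self.lxc = params.lxc37 * T / T37

        self.special_hairpins = {
            k: int(round(100.0 * e.at(T))) for k, e in params.special_hairpins.items()
        }

        # scalar block handed to the DP kernels
        self.scalars = np.array(
            [self.ml_base, self.ml_closing, self.ml_intern,
             self.ninio, self.ninio_max, self.terminal_au],
            dtype=np.int64)

    def length_tables(self, n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Loop length terms extended to size ``n`` by log extrapolation."""
        def extend(tab: np.ndarray) -> np.ndarray:
            out = np.full(max(n + 1, 31), INF, dtype=np.int64)
            out[:31] = tab
            for s in range(31, out.size):
                out[s] = tab[30] + int(self.lxc * math.log(s / 30.0))
            return out
        return extend(self.hairpin), extend(self.bulge), extend(self.internal)

    def terminal_penalty(self, pair_type: int) -> int:
        return 0 if pair_type in (1, 2) else self.terminal_au

    def mismatch_table(self, kind: str) -> np.ndarray:
        return {"hairpin": self.mm_hairpin, "interior": self.mm_interior,
                "multi": self.mm_multi, "exterior": self.mm_exterior}[kind]


def pair_type_of(a: str, b: str) -> int:
    """Pair-type code of two canonical bases (0 if not pairable)."""
    from .params import BASE_INDEX
    return int(PAIR_TYPE[BASE_INDEX[a], BASE_INDEX[b]])
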