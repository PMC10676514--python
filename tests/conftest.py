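"""Shared fixtures: parameter tables and the exhaustive-enumeration oracle.

The oracle enumerates every legal secondary structure of a (short)
sequence under the engine's pair rules and evaluates each one through the
loop-decomposition evaluator.  MFE, partition function, base-pair
probabilities and banded suboptimal lists derived from this enumeration
are the independent reference the DP recursions are tested against.
"""

from __future__ import annotations

import math
import random
from functools import lru_cache

import numpy as np
import pytest

from modfold import (EnergyModel, HardConstraintSet, ModelSettings,
                     ScaledTables, build_constraints, builtin_sets,
                     encode_sequence, load_parameters, trnadb_aliases)
from modfold._kernels import BIG


@pytest.fixture(scope="session")
def params():
    return load_parameters()


@pytest.fixture(scope="session")
def settings():
    return ModelSettings()


@pytest.fixture(scope="session")
def tables(params, settings):
    return ScaledTables(params, settings)


@pytest.fixture(scope="session")
def all_sets():
    return builtin_sets()


def make_model(raw, tables, settings=None, aliases=False, hard=None):
    """Encode an extended-alphabet sequence and build its EnergyModel."""
    settings = settings or tables.settings
    ms = encode_sequence(raw, builtin_sets(),
                         trnadb_aliases() if aliases else None)
    h, soft = build_constraints(ms, settings, tables)
    if hard is not None:
        h = hard
    return EnergyModel(ms.proxy, tables, settings, h, soft), ms


class Oracle:
    """Exhaustive enumeration over all hard-constraint-satisfying structures."""

    def __init__(self, model: EnergyModel):
        self.model = model
        n = model.n
        mh = model.settings.min_hairpin
        ptype = model.ptype

        @lru_cache(maxsize=None)
        def rec(i, j):
            if j - i < mh:
                return ((),)
            out = list(rec(i + 1, j))
            for k in range(i + mh + 1, j + 1):
                if ptype[i, k] > 0:
                    left = rec(i + 1, k - 1)
                    right = rec(k + 1, j) if k + 1 <= j else ((),)
                    for L in left:
                        for R in right:
                            out.append(((i, k),) + L + R)
            return tuple(out)

        self.structures = rec(0, n - 1) if n else ((),)
        self.energies = [model.eval_pairs(sorted(p)) for p in self.structures]

    def mfe(self) -> int:
        return min(self.energies)

    def boltzmann(self):
        """(ensemble free energy kcal/mol, bpp matrix) by direct summation."""
        m = self.model
        rt = m.settings.rt
        weights = [math.exp(-e / (rt * 100.0)) if e < BIG else 0.0
                   for e in self.energies]
        z = sum(weights)
        bpp = np.zeros((m.n, m.n))
        for pairs, w in zip(self.structures, weights):
            for i, j in pairs:
                bpp[i, j] += w / z
        return -rt * math.log(z), bpp

    def subopt(self, band: int):
        emin = self.mfe()
        out = [(frozenset(p), e) for p, e in zip(self.structures, self.energies)
               if e <= emin + band]
        return sorted(out, key=lambda t: (t[1], sorted(t[0])))


@pytest.fixture
def oracle_factory():
    return Oracle


def random_rna(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGU") for _ in range(n))
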