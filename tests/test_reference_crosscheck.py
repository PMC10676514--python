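"""Cross-checks against an independent reference implementation.

The ViennaRNA package (available in the environment, imported as ``RNA``)
implements the same thermodynamic model and the same modified-base
correction scheme.  It is used here purely as an independent oracle; the
exhaustive-enumeration tests elsewhere are the primary correctness
reference.  Modified-base comparisons pass an empty hard-constraint set
because the reference applies energy corrections only (it does not
restrict pairing partners), whereas this package enforces them.
"""

import random
import subprocess

import pytest

import RNA

from modfold import (EnergyModel, HardConstraintSet, build_constraints,
                     encode_sequence, load_builtin)
from conftest import random_rna

MD = RNA.md()
MD.dangles = 2

SC_HOOK = {"P": "sc_mod_pseudouridine", "D": "sc_mod_dihydrouridine",
           "7": "sc_mod_7DA", "6": "sc_mod_m6A", "9": "sc_mod_purine",
           "I": "sc_mod_inosine"}


class TestUnmodified:
    def test_structure_energies_match_reference_eval(self, tables):
        rng = random.Random(201)
        for _ in range(40):
            seq = random_rna(rng, rng.randint(10, 60))
            model = EnergyModel(seq, tables)
            _, struct = model.mfe()
            db = struct.to_dotbracket()
            ref = RNA.fold_compound(seq, MD).eval_structure(db)
            mine = model.eval_pairs(sorted(struct.pairs)) / 100.0
            assert mine == pytest.approx(ref, abs=1e-6)

    def test_mfe_matches_reference_fold(self, tables):
        rng = random.Random(202)
        for _ in range(40):
            seq = random_rna(rng, rng.randint(10, 70))
            e, _ = EnergyModel(seq, tables).mfe()
            _, e_ref = RNA.fold_compound(seq, MD).mfe()
            assert e / 100.0 == pytest.approx(e_ref, abs=1e-6)

    def test_subopt_band_matches_reference_tool(self, tables):
        rng = random.Random(203)
        for _ in range(6):
            seq = random_rna(rng, rng.randint(15, 35))
            mine = sorted((round(e / 100.0, 2), s.to_dotbracket())
                          for s, e in EnergyModel(seq, tables).subopt(200))
            out = subprocess.run(["RNAsubopt", "-d2", "-e", "2"], input=seq,
                                 capture_output=True, text=True).stdout
            ref = sorted((round(float(ln.split()[1]), 2), ln.split()[0])
                         for ln in out.splitlines()[1:] if ln.strip())
            assert mine == ref


class TestModified:
    def test_modified_mfe_matches_reference_fold(self, tables, settings):
        rng = random.Random(204)
        hits = 0
        for _ in range(60):
            n = rng.randint(15, 55)
            seq = [rng.choice("ACGU") for _ in range(n)]
            code = rng.choice("PD769I")
            pos = rng.sample(range(n), rng.randint(1, 3))
            for p in pos:
                seq[p] = code
            raw = "".join(seq)
            ms = encode_sequence(raw, [load_builtin(code)])
            _, soft = build_constraints(ms, settings, tables)
            model = EnergyModel(ms.proxy, tables, settings,
                                HardConstraintSet(), soft)
            e, _ = model.mfe()
            fc = RNA.fold_compound(ms.proxy, MD)
            getattr(fc, SC_HOOK[code])([p + 1 for p in pos])
            _, e_ref = fc.mfe()
            assert e / 100.0 == pytest.approx(e_ref, abs=1e-6)
            hits += 1
        assert hits == 60

    def test_two_distinct_modifications_match_reference_fold(self, tables, settings):
        rng = random.Random(205)
        for _ in range(25):
            n = rng.randint(20, 50)
            seq = [rng.choice("ACGU") for _ in range(n)]
            placed = {}
            for code in rng.sample("PD769I", 2):
                for p in rng.sample(range(n), 2):
                    if seq[p] in "ACGU":
                        seq[p] = code
                        placed.setdefault(code, []).append(p)
            raw = "".join(seq)
            ms = encode_sequence(raw, [load_builtin(c) for c in placed])
            _, soft = build_constraints(ms, settings, tables)
            model = EnergyModel(ms.proxy, tables, settings,
                                HardConstraintSet(), soft)
            e, _ = model.mfe()
            fc = RNA.fold_compound(ms.proxy, MD)
            for code, ps in placed.items():
                getattr(fc, SC_HOOK[code])([p + 1 for p in ps])
            _, e_ref = fc.mfe()
            assert e / 100.0 == pytest.approx(e_ref, abs=1e-6)

    def test_modified_ensemble_free_energy_close_to_reference(self, tables, settings):
        # the reference smooths Boltzmann factors; agreement is approximate
        rng = random.Random(206)
        for _ in range(10):
            n = rng.randint(15, 45)
            seq = [rng.choice("ACGU") for _ in range(n)]
            code = rng.choice("PD769I")
            pos = rng.sample(range(n), 2)
            for p in pos:
                seq[p] = code
            ms = encode_sequence("".join(seq), [load_builtin(code)])
            _, soft = build_constraints(ms, settings, tables)
            model = EnergyModel(ms.proxy, tables, settings,
                                HardConstraintSet(), soft)
            f, _ = model.partition()
            fc = RNA.fold_compound(ms.proxy, MD)
            getattr(fc, SC_HOOK[code])([p + 1 for p in pos])
            _, f_ref = fc.pf()
            assert f == pytest.approx(f_ref, abs=0.02)
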