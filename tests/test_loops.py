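"""Loop free-energy evaluation: hairpins, interior loops, multiloops."""

import math
import random

import pytest

from modfold import LoopDescriptor, ModelSettings
from modfold.fold import (EnergyModel, eval_hairpin, eval_interior,
                          eval_multiloop)


class TestHairpin:
    def test_minimal_gc_hairpin_is_pure_length_term(self, params):
        # GAAAC: closing G.C pair, size-3 loop -> length term only (5.40)
        assert eval_hairpin("GAAAC", 0, 4, params) == pytest.approx(5.40)

    def test_below_minimum_size_is_forbidden(self, params):
        assert eval_hairpin("GAAC", 0, 3, params) == math.inf

    def test_au_closing_pays_terminal_penalty(self, params):
        # AAAAU size-3: 5.40 + 0.50 terminal penalty
        assert eval_hairpin("AAAAU", 0, 4, params) == pytest.approx(5.90)

    def test_larger_loops_add_terminal_mismatch(self, params):
        # CAAAAAG size 5: hairpin[5] (5.70) + mismatch(CG, A, A) (-1.50)
        assert eval_hairpin("CAAAAAG", 0, 6, params) == pytest.approx(4.20)

    def test_special_loop_overrides_generic_rule(self, params):
        # tabulated stable tetraloop: the entry is the complete energy
        assert eval_hairpin("CCCAGG", 0, 5, params) == pytest.approx(3.40)

    def test_out_of_range_indices_raise(self, params):
        with pytest.raises(IndexError):
            eval_hairpin("GAAAC", 0, 9, params)


class TestInterior:
    def test_stack_is_the_size_zero_case(self, params):
        # 0x0 loop: 5'-CC-3'/3'-GG-5' == the published CG/GC stack entry
        seq = "CCAAAAGG"  # pairs (0,7) C.G and (1,6) C.G
        assert eval_interior(seq, 0, 7, 1, 6, params) == pytest.approx(-3.30)

    def test_stack_identity_under_reference_temperature_rescaling(self, params):
        seq = "CCAAAAGG"
        cold = eval_interior(seq, 0, 7, 1, 6, params,
                             ModelSettings(temperature=310.15))
        assert cold == pytest.approx(-3.30)

    def test_single_bulge_keeps_stack_term(self, params):
        # 1x0 bulge between two C.G pairs: bulge[1] (3.80) + CG/GC stack (-3.30)
        seq = "CACGAAAAGG"  # pairs (0,9) C.G, (2,8) C.G, bulge = position 1
        assert eval_interior(seq, 0, 9, 2, 8, params) == pytest.approx(0.50)

    def test_crossing_indices_rejected(self, params):
        with pytest.raises(IndexError):
            eval_interior("CGAAAACG", 1, 6, 0, 7, params)

    def test_large_loop_uses_length_asymmetry_and_mismatches(self, params, tables):
        # 3x5 interior loop: verify against a hand-sum of the table terms
        seq = "C" + "AAA" + "G" + "AAAA" + "C" + "AAAAA" + "G"
        i, j, k, l = 0, 15, 4, 9
        t = tables
        expected = (t.internal[8] + min(2 * t.ninio, t.ninio_max)
                    + t.mm_interior[1, 1, 1] + t.mm_interior[1, 1, 1])
        assert eval_interior(seq, i, j, k, l, params) == pytest.approx(expected / 100)


class TestMultiloop:
    def test_affine_formula_without_dangles(self, params):
        # 2 branches, 0 unpaired: closing + 3 * intern (+ terminal penalties)
        seq = "CGGGGAAAACCCCGGGGAAAACCCCG"
        no_d = ModelSettings(dangle_model="none")
        e = eval_multiloop(seq, (0, 25), [(1, 12), (13, 24)], params, no_d)
        assert e == pytest.approx((930 + 3 * -90) / 100.0)

    def test_each_unpaired_base_costs_the_linear_term(self, params, tables):
        seq = "CAGGGGAAAACCCCGGGGAAAACCCCG"
        no_d = ModelSettings(dangle_model="none")
        e = eval_multiloop(seq, (0, 26), [(2, 13), (14, 25)], params, no_d)
        base = eval_multiloop(seq, (0, 26), [(2, 13), (14, 25)], params, no_d,
                              unpaired_count=0)
        assert e - base == pytest.approx(tables.ml_base / 100.0)

    def test_requires_at_least_two_branches(self, params):
        with pytest.raises(Exception):
            eval_multiloop("CGGGGAAAACCCCG", (0, 13), [(1, 12)], params)

    def test_three_branch_junction_matches_hand_sum(self, params, tables):
        # cloverleaf-style junction, d2 terms included via the stem arrays
        seq = "CC" + "GGGGAAAACCCC" + "A" + "GGGGAAAACCCC" + "GGGGAAAACCCC" + "GG"
        model = EnergyModel(seq, tables)
        closing = (1, len(seq) - 2)
        branches = [(2, 13), (15, 26), (27, 38)]
        e = eval_multiloop(seq, closing, branches, params)
        scal = tables.scalars
        hand = (int(scal[1]) + 4 * int(scal[2]) + 1 * int(scal[0])
                + int(model.MLC[closing]) + sum(int(model.MLS[b]) for b in branches))
        assert e == pytest.approx(hand / 100.0)


class TestLoopDescriptor:
    def test_interior_ordering_enforced(self):
        with pytest.raises(ValueError):
            LoopDescriptor("interior", 5, 10, k=7, l=12)
        d = LoopDescriptor("interior", 2, 20, k=5, l=15)
        assert (d.i, d.k, d.l, d.j) == (2, 5, 15, 20)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            LoopDescriptor("bulge", 1, 5)


def test_structure_energy_equals_sum_over_loop_decomposition(tables):
    """Summing per-loop evaluations over the decomposition reproduces the
    whole-structure energy (and hence the DP energy, tested elsewhere)."""
    from modfold._kernels import S_MLBASE, S_MLCLOSING, S_MLINTERN
    rng = random.Random(4)
    for _ in range(25):
        n = rng.randint(10, 45)
        seq = "".join(rng.choice("ACGU") for _ in range(n))
        model = EnergyModel(seq, tables)
        _, struct = model.mfe()
        total = 0
        pt = struct.pair_table()
        for d in struct.loops():
            if d.kind == "hairpin":
                total += model.H[d.i, d.j]
            elif d.kind == "interior":
                total += model.interior_energy(d.i, d.j, d.k, d.l)
            elif d.kind == "exterior_part":
                total += model.EXT[d.i, d.j]
            elif d.closing:
                branches = [p for p in struct.pairs if d.i < p[0] < d.j]
                direct = [p for p in branches
                          if not any(q[0] < p[0] and p[1] < q[1] for q in branches)]
                unpaired = (d.j - d.i - 1) - sum(b - a + 1 for a, b in direct)
                total += (model.scal[S_MLCLOSING]
                          + model.scal[S_MLINTERN] * (len(direct) + 1)
                          + model.scal[S_MLBASE] * unpaired
                          + model.MLC[d.i, d.j])
            else:
                total += model.MLS[d.i, d.j]
        assert total == model.eval_pairs(sorted(struct.pairs))
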