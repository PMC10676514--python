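"""The DP core: MFE folding, partition function, suboptimal enumeration.

All recursions operate on the canonical proxy sequence; hard constraints
shrink the structure space through the pair-type matrix and soft
corrections shift loop energies through precomputed face arrays (see
:mod:`modfold.constraints`).  The recursions follow the unambiguous
F/C/M/M1 grammar so that complete suboptimal enumeration produces every
structure exactly once:

    F  -> . F | F' C(ext stem)            (exterior)
    C  -> hairpin | interior C | M M1     (loop closed by a pair)
    M  -> M . | ...C | M C                (>= 1 multiloop branch)
    M1 -> M1 . | C                        (exactly one branch at fixed 5')

Energies are integers in 0.01 kcal/mol internally; the public API speaks
kcal/mol floats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from ._kernels import BIG, INF
from .constraints import HardConstraintSet, LoopCorrections
from .model import LoopDescriptor, ModelSettings, ScaledTables
from .params import MAXLOOP, PAIR_TYPE, NNParameterSet, encode, load_parameters
from .structures import SecondaryStructure


class FoldInputError(ValueError):
    pass


class SuboptOverflowError(RuntimeError):
    def __init__(self, cap: int):
        super().__init__(f"suboptimal list exceeds the cap of {cap} structures")
        self.cap = cap


@dataclass
class FoldResult:
    """Container for prediction output (energies in kcal/mol)."""

    sequence: str
    proxy: str
    mfe_structure: SecondaryStructure | None = None
    mfe_energy: float | None = None
    ensemble_free_energy: float | None = None
    bpp: np.ndarray | None = None
    suboptimals: list[tuple[SecondaryStructure, float]] | None = None


class EnergyModel:
    """Precomputed, temperature-scaled view of one folding problem.

    Bundles the proxy sequence, the pair-type matrix (hard constraints
    included), the hairpin/helix-end arrays (soft corrections included)
    and the face-correction arrays consumed by the DP kernels.  Both the
    recursions and :meth:`eval_structure` read from the same arrays, which
    makes traceback energies exact by construction.
    """

    def __init__(self, proxy: str, tables: ScaledTables,
                 settings: ModelSettings | None = None,
                 hard: HardConstraintSet | None = None,
                 soft: LoopCorrections | None = None):
        if not proxy:
            raise FoldInputError("empty sequence")
        self.settings = settings or tables.settings
        self.tables = tables
        self.proxy = proxy
        self.S = encode(proxy)
        self.n = n = len(proxy)
        self.hard = hard
        self.soft = soft
        mh = self.settings.min_hairpin

        # pair types with hard constraints applied
        pt = PAIR_TYPE[self.S[:, None], self.S[None, :]].copy()
        ii, jj = np.indices((n, n))
        pt[jj - ii - 1 < mh] = 0
        if hard is not None:
            for p in hard.unpaired_only:
                pt[p, :] = 0
                pt[:, p] = 0
            for p, partners in hard.allowed_partners.items():
                for q in range(n):
                    if proxy[q] not in partners:
                        pt[p, q] = 0
                        pt[q, p] = 0
        self.ptype = np.ascontiguousarray(np.triu(pt), dtype=np.int64)

        # face-correction arrays
        def face_array(kind: str) -> np.ndarray:
            arr = np.zeros((n, n), dtype=np.int64)
            if soft is not None:
                for (a, b), v in soft.faces[kind].items():
                    if 0 <= a < b < n:
                        arr[a, b] = v
            return arr

        self.SC = face_array("stack")
        self.EO = face_array("end_outer")
        self.EI = face_array("end_inner")
        self.MO = face_array("mm_outer")
        self.MI = face_array("mm_inner")
        self._HC = face_array("hairpin")
        self._EC = face_array("ext_stem")
        self._MSC = face_array("ml_stem")
        self._MCC = face_array("ml_close")

        t = tables
        self.hp_len, self.bulge_len, self.internal_len = t.length_tables(n)
        self.scal = t.scalars
        self._build_face_energies()

    # -- construction of the loop-face energy arrays -----------------------
    def _build_face_energies(self) -> None:
        n, S, t = self.n, self.S, self.tables
        d2 = self.settings.dangle_model == "d2"
        H = np.full((n, n), INF, dtype=np.int64)
        EXT = np.zeros((n, n), dtype=np.int64)
        MLS = np.zeros((n, n), dtype=np.int64)
        MLC = np.zeros((n, n), dtype=np.int64)
        tAU = t.terminal_au
        for i in range(n):
            for j in range(i + self.settings.min_hairpin + 1, n):
                pt = self.ptype[i, j]
                if pt == 0:
                    continue
                size = j - i - 1
                # hairpin
                special = None
                if size in (3, 4, 6):
                    special = t.special_hairpins.get(self.proxy[i:j + 1])
                if special is not None:
                    e = special
                else:
                    e = self.hp_len[size]
                    if size == 3:
                        if pt > 2:
                            e += tAU
                    else:
                        e += t.mm_hairpin[pt, S[i + 1], S[j - 1]]
                H[i, j] = e + self._HC[i, j]
                # exterior stem
                e = tAU if pt > 2 else 0
                if d2:
                    if i > 0 and j < n - 1:
                        e += t.mm_exterior[pt, S[i - 1], S[j + 1]]
                    elif i > 0:
                        e += t.dangle5[pt, S[i - 1]]
                    elif j < n - 1:
                        e += t.dangle3[pt, S[j + 1]]
                EXT[i, j] = e + self._EC[i, j]
                # multiloop branch stem (neighbors always exist when used)
                e = tAU if pt > 2 else 0
                if d2 and 0 < i and j < n - 1:
                    e += t.mm_multi[pt, S[i - 1], S[j + 1]]
                MLS[i, j] = e + self._MSC[i, j]
                # multiloop closing stem (the pair seen from inside the loop)
                ptr = int(PAIR_TYPE[S[j], S[i]])
                e = tAU if ptr > 2 else 0
                if d2:
                    e += t.mm_multi[ptr, S[j - 1], S[i + 1]]
                MLC[i, j] = e + self._MCC[i, j]
        self.H, self.EXT, self.MLS, self.MLC = H, EXT, MLS, MLC

    # -- kernels interface -------------------------------------------------
    def _kernel_args(self):
        t = self.tables
        return (t.stack, t.int11, t.int21, t.int22, t.mm_interior,
                t.mm_interior_1n, t.mm_interior_23, self.bulge_len,
                self.internal_len, self.scal, self.SC, self.EO, self.EI,
                self.MO, self.MI, PAIR_TYPE)

    def interior_energy(self, i: int, j: int, k: int, l: int) -> int:
        """Integer energy of the interior loop closed by (i,j) / (k,l)."""
        if not (i < k < l < j):
            raise IndexError("interior loop requires i < k < l < j")
        if self.ptype[i, j] == 0 or self.ptype[k, l] == 0:
            return INF
        return int(_kernels.e_interior(i, j, k, l, self.S, *self._kernel_args()))

    def fill(self):
        if not hasattr(self, "_mats"):
            self._mats = _kernels.fill_mfe(
                self.S, self.ptype, self.H, self.EXT, self.MLS, self.MLC,
                *self._kernel_args(), MAXLOOP, self.settings.min_hairpin)
        return self._mats

    # -- structure evaluation ---------------------------------------------
    def eval_pairs(self, pairs) -> int:
        """Loop-decomposition energy of a structure, integer units.

        Returns INF when the structure violates a hard constraint or
        contains a non-pairable proxy pair.
        """
        n = self.n
        pt = [-1] * n
        for i, j in pairs:
            if self.ptype[i, j] == 0:
                return INF
            pt[i] = j
            pt[j] = i
        scal = self.scal
        total = 0

        def children(i: int, j: int):
            out = []
            k = i + 1
            while k < j:
                if pt[k] > k:
                    out.append((k, pt[k]))
                    k = pt[k] + 1
                else:
                    k += 1
            return out

        ext = children(-1, n)
        for i, j in ext:
            total += self.EXT[i, j]
        stack = list(ext)
        while stack:
            i, j = stack.pop()
            ch = children(i, j)
            stack.extend(ch)
            if not ch:
                total += self.H[i, j]
            elif len(ch) == 1:
                (k, l) = ch[0]
                e = self.interior_energy(i, j, k, l)
                if e >= BIG:
                    return INF
                total += e
            else:
                unpaired = (j - i - 1) - sum(l - k + 1 for k, l in ch)
                total += (scal[_kernels.S_MLCLOSING]
                          + scal[_kernels.S_MLINTERN] * (len(ch) + 1)
                          + scal[_kernels.S_MLBASE] * unpaired
                          + self.MLC[i, j]
                          + sum(self.MLS[k, l] for k, l in ch))
        return int(total)

    # -- MFE + traceback ----------------------------------------------------
    def mfe(self) -> tuple[int, SecondaryStructure]:
        C, M, M1, F = self.fill()
        n = self.n
        mh = self.settings.min_hairpin
        scal = self.scal
        mlb = int(scal[_kernels.S_MLBASE])
        mli = int(scal[_kernels.S_MLINTERN])
        mlc = int(scal[_kernels.S_MLCLOSING])
        pairs: list[tuple[int, int]] = []
        work: list[tuple] = [("F", n)]
        while work:
            seg = work.pop()
            if seg[0] == "F":
                j = seg[1]
                while j > 0:
                    target = F[j]
                    hit = None
                    for u in range(0, j - mh - 1):
                        if (self.ptype[u, j - 1] > 0 and C[u, j - 1] < BIG
                                and F[u] + C[u, j - 1] + self.EXT[u, j - 1] == target):
                            hit = u
                            break
                    if hit is not None:
                        pairs.append((hit, j - 1))
                        work.append(("C", hit, j - 1))
                        j = hit
                    else:
                        j -= 1
            elif seg[0] == "C":
                _, i, j = seg
                target = C[i, j]
                if target == self.H[i, j]:
                    continue
                kk, ll, ee = self._interior_candidates(i, j)
                done = False
                for k, l, e in zip(kk, ll, ee):
                    if C[k, l] < BIG and C[k, l] + e == target:
                        pairs.append((int(k), int(l)))
                        work.append(("C", int(k), int(l)))
                        done = True
                        break
                if done:
                    continue
                for u in range(i + 2, j - 1):
                    if (M[i + 1, u - 1] < BIG and M1[u, j - 1] < BIG and
                            M[i + 1, u - 1] + M1[u, j - 1] + mlc + mli
                            + self.MLC[i, j] == target):
                        work.append(("M", i + 1, u - 1))
                        work.append(("M1", u, j - 1))
                        done = True
                        break
                if not done:  # pragma: no cover - would be a DP defect
                    raise AssertionError("traceback failed in C")
            elif seg[0] == "M":
                _, i, j = seg
                while True:
                    target = M[i, j]
                    hit = None
                    for u in range(i, j - mh):
                        if self.ptype[u, j] > 0 and C[u, j] < BIG:
                            stemv = C[u, j] + mli + self.MLS[u, j]
                            if (u - i) * mlb + stemv == target:
                                hit = ("single", u)
                                break
                            if u > i and M[i, u - 1] < BIG and M[i, u - 1] + stemv == target:
                                hit = ("multi", u)
                                break
                    if hit is None:
                        j -= 1  # trailing unpaired base
                        continue
                    kind, u = hit
                    pairs.append((u, j))
                    work.append(("C", u, j))
                    if kind == "single":
                        break
                    j = u - 1
            else:  # M1
                _, i, j = seg
                while M1[i, j] != C[i, j] + mli + self.MLS[i, j] or self.ptype[i, j] == 0:
                    j -= 1
                pairs.append((i, j))
                work.append(("C", i, j))
        return int(F[n]), SecondaryStructure(n, frozenset(pairs))

    def _interior_candidates(self, i: int, j: int):
        """All (k, l, energy) interior-loop candidates below pair (i, j)."""
        mh = self.settings.min_hairpin
        ks, ls, es = [], [], []
        kmax = min(i + MAXLOOP + 1, j - mh - 2)
        for k in range(i + 1, kmax + 1):
            n1 = k - i - 1
            for l in range(max(k + mh + 1, j - 1 - (MAXLOOP - n1)), j):
                if self.ptype[k, l] > 0:
                    e = self.interior_energy(i, j, k, l)
                    if e < BIG:
                        ks.append(k)
                        ls.append(l)
                        es.append(e)
        return ks, ls, es

    # -- partition function -------------------------------------------------
    def partition(self) -> tuple[float, np.ndarray]:
        """Ensemble free energy (kcal/mol) and base-pair probability matrix."""
        mfe_int, _ = self.mfe()
        n = self.n
        rt = self.settings.rt
        kT = rt * 100.0
        u1 = math.exp(1.07 * mfe_int / (n * kT)) if mfe_int < 0 else 1.0
        QB, QM, QM1, Q, Qr = _kernels.fill_pf(
            self.S, self.ptype, self.H, self.EXT, self.MLS, self.MLC,
            *self._kernel_args(), MAXLOOP, self.settings.min_hairpin, kT, u1)
        if not np.isfinite(Q[n]) or Q[n] <= 0.0:  # pragma: no cover
            raise FloatingPointError("partition function over/underflow")
        f_ens = -rt * (math.log(Q[n]) - n * math.log(u1))
        P = _kernels.fill_outside(
            self.S, self.ptype, self.EXT, self.MLS, self.MLC,
            *self._kernel_args(), MAXLOOP, self.settings.min_hairpin, kT, u1,
            QB, QM, Q, Qr)
        P = np.maximum(P, P.T)  # symmetric view; computed upper-triangular
        return f_ens, P

    # -- complete suboptimal enumeration ------------------------------------
    def subopt(self, band_int: int, cap: int = 100_000):
        """All structures within ``band_int`` (0.01 kcal/mol) of the MFE."""
        if band_int < 0:
            raise FoldInputError("band must be >= 0")
        C, M, M1, F = self.fill()
        n = self.n
        mh = self.settings.min_hairpin
        scal = self.scal
        mlb = int(scal[_kernels.S_MLBASE])
        mli = int(scal[_kernels.S_MLINTERN])
        mlc = int(scal[_kernels.S_MLCLOSING])
        if F[n] >= BIG:  # no structure at all (cannot happen: open chain = 0)
            return []
        th = int(F[n]) + band_int

        def bound(seg) -> int:
            kind = seg[0]
            if kind == "F":
                return int(F[seg[1]])
            arr = {"C": C, "M": M, "M1": M1}[kind]
            return int(arr[seg[1], seg[2]])

        results: list[tuple[int, frozenset]] = []
        # state: (list of segments, pairs tuple, exact energy of decided part)
        stack = [((("F", n),), (), 0)]
        while stack:
            segs, pairs, eacc = stack.pop()
            if not segs:
                results.append((eacc, frozenset(pairs)))
                if len(results) > cap:
                    raise SuboptOverflowError(cap)
                continue
            seg, rest = segs[-1], segs[:-1]
            base = eacc + sum(bound(s) for s in rest)

            def push(de: int, new_segs, new_pairs=()):
                lb = base + de + sum(bound(s) for s in new_segs)
                if lb <= th:
                    stack.append((rest + tuple(new_segs), pairs + new_pairs,
                                  eacc + de))

            kind = seg[0]
            if kind == "F":
                j = seg[1]
                if j == 0:
                    push(0, ())
                    continue
                push(0, (("F", j - 1),))
                for u in range(0, j - mh - 1):
                    if self.ptype[u, j - 1] > 0 and C[u, j - 1] < BIG:
                        push(int(self.EXT[u, j - 1]),
                             (("F", u), ("C", u, j - 1)), ((u, j - 1),))
            elif kind == "C":
                _, i, j = seg
                if self.H[i, j] < BIG:
                    push(int(self.H[i, j]), ())
                kk, ll, ee = self._interior_candidates(i, j)
                for k, l, e in zip(kk, ll, ee):
                    if C[k, l] < BIG:
                        push(int(e), (("C", k, l),), ((k, l),))
                demlc = mlc + mli + int(self.MLC[i, j])
                for u in range(i + 2, j - 1):
                    if M[i + 1, u - 1] < BIG and M1[u, j - 1] < BIG:
                        push(demlc, (("M", i + 1, u - 1), ("M1", u, j - 1)))
            elif kind == "M":
                _, i, j = seg
                if j - 1 - i > mh and M[i, j - 1] < BIG:
                    push(mlb, (("M", i, j - 1),))
                for u in range(i, j - mh):
                    if self.ptype[u, j] > 0 and C[u, j] < BIG:
                        de = mli + int(self.MLS[u, j])
                        push(de + (u - i) * mlb, (("C", u, j),), ((u, j),))
                        if u > i and M[i, u - 1] < BIG:
                            push(de, (("M", i, u - 1), ("C", u, j)), ((u, j),))
            else:  # M1
                _, i, j = seg
                if j - 1 - i > mh and M1[i, j - 1] < BIG:
                    push(mlb, (("M1", i, j - 1),))
                if self.ptype[i, j] > 0 and C[i, j] < BIG:
                    push(mli + int(self.MLS[i, j]), (("C", i, j),), ((i, j),))

        out = [(SecondaryStructure(n, p), e) for e, p in results]
        out.sort(key=lambda t: (t[1], t[0].to_dotbracket()))
        return out


# --------------------------------------------------------------------------
# public API
# --------------------------------------------------------------------------

def _as_model(modseq, params, settings, constraints) -> tuple[EnergyModel, str]:
    from .modbase import ModifiedSequence, build_constraints

    settings = settings or ModelSettings()
    if isinstance(params, ScaledTables):
        tables = params
    else:
        if params is None:
            params = load_parameters()
        tables = ScaledTables(params, settings)
    if isinstance(modseq, str):
        from .modbase import encode_sequence
        modseq = encode_sequence(modseq, ())
    if not isinstance(modseq, ModifiedSequence):
        raise FoldInputError("expected a sequence string or ModifiedSequence")
    if len(modseq.raw) == 0:
        raise FoldInputError("empty sequence")
    if constraints is None:
        hard, soft = build_constraints(modseq, settings, tables)
    else:
        hard, soft = constraints
    model = EnergyModel(modseq.proxy, tables, settings, hard, soft)
    return model, modseq.raw


def mfe_fold(modseq, params=None, settings=None, constraints=None) -> FoldResult:
    """Minimum free energy structure under hard and soft constraints."""
    model, raw = _as_model(modseq, params, settings, constraints)
    e, struct = model.mfe()
    return FoldResult(sequence=raw, proxy=model.proxy,
                      mfe_structure=struct, mfe_energy=e / 100.0)


def partition_function(modseq, params=None, settings=None,
                       constraints=None) -> FoldResult:
    """Ensemble free energy and base-pair probabilities."""
    model, raw = _as_model(modseq, params, settings, constraints)
    e, struct = model.mfe()
    f_ens, bpp = model.partition()
    return FoldResult(sequence=raw, proxy=model.proxy, mfe_structure=struct,
                      mfe_energy=e / 100.0, ensemble_free_energy=f_ens,
                      bpp=bpp)


def subopt(modseq, band: float, params=None, settings=None, constraints=None,
           cap: int = 100_000):
    """Complete list of structures within ``band`` kcal/mol of the MFE,
    sorted by energy, then lexicographically by dot-bracket string."""
    model, _ = _as_model(modseq, params, settings, constraints)
    out = model.subopt(int(round(band * 100)), cap=cap)
    return [(s, e / 100.0) for s, e in out]


def eval_hairpin(seq: str, i: int, j: int, params=None, settings=None) -> float:
    """Energy of the hairpin loop closed by the pair (i, j), kcal/mol.

    Positions are 0-based; the sequence must be plain ACGU.  Returns
    ``inf`` when (i, j) cannot pair or the loop is below the minimum
    hairpin size."""
    model, _ = _as_model(seq, params, settings, (None, None))
    if not (0 <= i < j < model.n):
        raise IndexError(f"pair ({i},{j}) out of range")
    e = model.H[i, j]
    return math.inf if e >= BIG else e / 100.0


def eval_interior(seq: str, i: int, j: int, k: int, l: int, params=None,
                  settings=None) -> float:
    """Energy of the interior loop delimited by (i, j) and (k, l), kcal/mol.

    The 0x0 case is the stacking energy of the two pairs."""
    model, _ = _as_model(seq, params, settings, (None, None))
    e = model.interior_energy(i, j, k, l)
    return math.inf if e >= BIG else e / 100.0


def eval_multiloop(seq: str, closing: tuple[int, int], branches, params=None,
                   settings=None, unpaired_count: int | None = None) -> float:
    """Affine multiloop energy: closing term + per-branch and per-unpaired
    terms + helix-end contributions per the dangle model, kcal/mol."""
    if len(branches) < 2:
        raise FoldInputError("a multiloop requires at least 2 inner branches")
    model, _ = _as_model(seq, params, settings, (None, None))
    i, j = closing
    if unpaired_count is None:
        unpaired_count = (j - i - 1) - sum(l - k + 1 for k, l in branches)
    if unpaired_count < 0:
        raise FoldInputError("branches exceed the closing span")
    scal = model.scal
    e = (int(scal[_kernels.S_MLCLOSING])
         + int(scal[_kernels.S_MLINTERN]) * (len(branches) + 1)
         + int(scal[_kernels.S_MLBASE]) * unpaired_count
         + int(model.MLC[i, j])
         + sum(int(model.MLS[k, l]) for k, l in branches))
    return e / 100.0


def eval_structure(modseq, structure, params=None, settings=None,
                   constraints=None) -> float:
    """Loop-decomposition energy of a given structure, kcal/mol.

    Returns ``inf`` when the structure violates the hard constraints."""
    model, _ = _as_model(modseq, params, settings, constraints)
    if isinstance(structure, str):
        structure = SecondaryStructure.from_dotbracket(structure)
    if structure.n != model.n:
        raise FoldInputError("structure length does not match sequence")
    e = model.eval_pairs(sorted(structure.pairs))
    return math.inf if e >= BIG else e / 100.0
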