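"""Numba kernels for the fold engine.

Everything here operates on the canonical proxy sequence and on dense
integer tables prepared by :class:`modfold.fold.EnergyModel`; soft
corrections enter through the ``SC/IO/II/BO/BI`` face arrays and through
the precomputed ``H/EXT/MLS/MLC`` arrays, so the recursions themselves are
oblivious to modified bases.

Energies are int64 in units of 0.01 kcal/mol; ``INF`` marks forbidden
states and ``BIG`` is the guard threshold for additions.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

INF = 1 << 28
BIG = 1 << 27

# scalar block layout (see ScaledTables.scalars)
S_MLBASE, S_MLCLOSING, S_MLINTERN, S_NINIO, S_NINIOMAX, S_TERMAU = range(6)


@njit(cache=True)
def e_interior(i, j, k, l, S, stack, i11, i21, i22, mmi, mm1n, mm23,
               bulge_len, internal_len, scal, SC, EO, EI, MO, MI, PAIRT):
    """Energy of the interior loop delimited by pairs (i,j) and (k,l)."""
    pt1 = PAIRT[S[i], S[j]]
    pt2 = PAIRT[S[l], S[k]]  # enclosed pair seen from inside the loop
    n1 = k - i - 1
    n2 = j - l - 1
    if n1 == 0 and n2 == 0:
        return stack[pt1, pt2] + SC[i, j]
    # helix-end corrections apply to both delimiting pairs of every
    # non-stack interior loop; mismatch corrections additionally need one
    # unpaired base on each strand
    fc = EO[i, j] + EI[k, l]
    if n1 > 0 and n2 > 0:
        fc += MO[i, j] + MI[k, l]
    if n1 == 0 or n2 == 0:
        size = n1 + n2
        e = bulge_len[size]
        if size == 1:
            e += stack[pt1, pt2]
        else:
            if pt1 > 2:
                e += scal[S_TERMAU]
            if pt2 > 2:
                e += scal[S_TERMAU]
        return e + fc
    si1 = S[i + 1]
    sj1 = S[j - 1]
    sp1 = S[k - 1]
    sq1 = S[l + 1]
    if n1 == 1 and n2 == 1:
        return i11[pt1, pt2, si1, sj1] + fc
    if n1 == 1 and n2 == 2:
        return i21[pt1, pt2, si1, sq1, sj1] + fc
    if n1 == 2 and n2 == 1:
        return i21[pt2, pt1, sq1, si1, sp1] + fc
    if n1 == 2 and n2 == 2:
        return i22[pt1, pt2, si1, sp1, sq1, sj1] + fc
    nd = n1 - n2 if n1 > n2 else n2 - n1
    asym = nd * scal[S_NINIO]
    if asym > scal[S_NINIOMAX]:
        asym = scal[S_NINIOMAX]
    if (n1 == 2 and n2 == 3) or (n1 == 3 and n2 == 2):
        return (internal_len[5] + asym
                + mm23[pt1, si1, sj1] + mm23[pt2, sq1, sp1] + fc)
    if n1 == 1 or n2 == 1:
        return (internal_len[n1 + n2] + asym
                + mm1n[pt1, si1, sj1] + mm1n[pt2, sq1, sp1] + fc)
    return (internal_len[n1 + n2] + asym
            + mmi[pt1, si1, sj1] + mmi[pt2, sq1, sp1] + fc)


@njit(cache=True)
def fill_mfe(S, ptype, H, EXT, MLS, MLC, stack, i11, i21, i22, mmi, mm1n,
             mm23, bulge_len, internal_len, scal, SC, EO, EI, MO, MI, PAIRT,
             maxloop, min_hairpin):
    n = S.shape[0]
    C = np.full((n, n), INF, dtype=np.int64)
    M = np.full((n, n), INF, dtype=np.int64)
    M1 = np.full((n, n), INF, dtype=np.int64)
    F = np.zeros(n + 1, dtype=np.int64)
    mlb = scal[S_MLBASE]
    mli = scal[S_MLINTERN]
    mlc = scal[S_MLCLOSING]
    for j in range(n):
        for i in range(j - min_hairpin - 1, -1, -1):
            # --- C: (i, j) paired --------------------------------------
            if ptype[i, j] > 0:
                best = H[i, j]
                kmax = i + maxloop + 1
                if kmax > j - min_hairpin - 2:
                    kmax = j - min_hairpin - 2
                for k in range(i + 1, kmax + 1):
                    n1 = k - i - 1
                    lmin = j - 1 - (maxloop - n1)
                    if lmin < k + min_hairpin + 1:
                        lmin = k + min_hairpin + 1
                    for l in range(lmin, j):
                        if ptype[k, l] > 0 and C[k, l] < BIG:
                            e = C[k, l] + e_interior(
                                i, j, k, l, S, stack, i11, i21, i22, mmi,
                                mm1n, mm23, bulge_len, internal_len, scal,
                                SC, EO, EI, MO, MI, PAIRT)
                            if e < best:
                                best = e
                for u in range(i + 2, j - 1):
                    a = M[i + 1, u - 1]
                    b = M1[u, j - 1]
                    if a < BIG and b < BIG:
                        e = a + b + mlc + mli + MLC[i, j]
                        if e < best:
                            best = e
                C[i, j] = best
            # --- M1: exactly one branch starting at i ------------------
            best = INF
            if C[i, j] < BIG and ptype[i, j] > 0:
                best = C[i, j] + mli + MLS[i, j]
            if M1[i, j - 1] < BIG:
                e = M1[i, j - 1] + mlb
                if e < best:
                    best = e
            M1[i, j] = best
            # --- M: at least one branch --------------------------------
            best = INF
            if M[i, j - 1] < BIG:
                best = M[i, j - 1] + mlb
            for u in range(i, j - min_hairpin):
                if ptype[u, j] > 0 and C[u, j] < BIG:
                    stemv = C[u, j] + mli + MLS[u, j]
                    e = (u - i) * mlb + stemv
                    if e < best:
                        best = e
                    if u > i and M[i, u - 1] < BIG:
                        e = M[i, u - 1] + stemv
                        if e < best:
                            best = e
            M[i, j] = best
    # --- exterior ---------------------------------------------------------
    for j in range(1, n + 1):
        best = F[j - 1]
        for u in range(0, j - min_hairpin - 1):
            if ptype[u, j - 1] > 0 and C[u, j - 1] < BIG and F[u] < BIG:
                e = F[u] + C[u, j - 1] + EXT[u, j - 1]
                if e < best:
                    best = e
        F[j] = best
    return C, M, M1, F


@njit(cache=True)
def fill_pf(S, ptype, H, EXT, MLS, MLC, stack, i11, i21, i22, mmi, mm1n,
            mm23, bulge_len, internal_len, scal, SC, EO, EI, MO, MI, PAIRT,
            maxloop, min_hairpin, kT, u1):
    """Inside pass of the partition function.

    ``kT`` is R*T in units of 0.01 kcal/mol, ``u1`` the per-nucleotide
    scaling factor (stored arrays are true values times u1**length).
    """
    n = S.shape[0]
    QB = np.zeros((n, n))
    QM = np.zeros((n, n))
    QM1 = np.zeros((n, n))
    Q = np.zeros(n + 1)
    Qr = np.zeros(n + 1)
    mlb = scal[S_MLBASE]
    mli = scal[S_MLINTERN]
    mlc = scal[S_MLCLOSING]
    wb = math.exp(-mlb / kT) * u1
    for j in range(n):
        for i in range(j - min_hairpin - 1, -1, -1):
            if ptype[i, j] > 0:
                qb = 0.0
                if H[i, j] < BIG:
                    qb = math.exp(-H[i, j] / kT) * u1 ** (j - i + 1)
                kmax = i + maxloop + 1
                if kmax > j - min_hairpin - 2:
                    kmax = j - min_hairpin - 2
                for k in range(i + 1, kmax + 1):
                    n1 = k - i - 1
                    lmin = j - 1 - (maxloop - n1)
                    if lmin < k + min_hairpin + 1:
                        lmin = k + min_hairpin + 1
                    for l in range(lmin, j):
                        if ptype[k, l] > 0 and QB[k, l] > 0.0:
                            e = e_interior(
                                i, j, k, l, S, stack, i11, i21, i22, mmi,
                                mm1n, mm23, bulge_len, internal_len, scal,
                                SC, EO, EI, MO, MI, PAIRT)
                            if e < BIG:
                                qb += (QB[k, l] * math.exp(-e / kT)
                                       * u1 ** (n1 + (j - l - 1) + 2))
                wcl = math.exp(-(mlc + mli + MLC[i, j]) / kT) * u1 * u1
                acc = 0.0
                for u in range(i + 2, j - 1):
                    acc += QM[i + 1, u - 1] * QM1[u, j - 1]
                qb += acc * wcl
                QB[i, j] = qb
            # QM1
            v = QM1[i, j - 1] * wb if j - 1 >= 0 else 0.0
            if QB[i, j] > 0.0:
                v += QB[i, j] * math.exp(-(mli + MLS[i, j]) / kT)
            QM1[i, j] = v
            # QM
            v = QM[i, j - 1] * wb if j - 1 >= 0 else 0.0
            for u in range(i, j - min_hairpin):
                if QB[u, j] > 0.0:
                    stemw = QB[u, j] * math.exp(-(mli + MLS[u, j]) / kT)
                    v += wb ** (u - i) * stemw
                    if u > i:
                        v += QM[i, u - 1] * stemw
            QM[i, j] = v
    Q[0] = 1.0
    for j in range(1, n + 1):
        v = Q[j - 1] * u1
        for u in range(0, j - min_hairpin - 1):
            if QB[u, j - 1] > 0.0:
                v += Q[u] * QB[u, j - 1] * math.exp(-EXT[u, j - 1] / kT)
        Q[j] = v
    Qr[n] = 1.0
    for i in range(n - 1, -1, -1):
        v = Qr[i + 1] * u1
        for v2 in range(i + min_hairpin + 1, n):
            if QB[i, v2] > 0.0:
                v += QB[i, v2] * math.exp(-EXT[i, v2] / kT) * Qr[v2 + 1]
        Qr[i] = v
    return QB, QM, QM1, Q, Qr


@njit(cache=True)
def fill_outside(S, ptype, EXT, MLS, MLC, stack, i11, i21, i22, mmi, mm1n,
                 mm23, bulge_len, internal_len, scal, SC, EO, EI, MO, MI,
                 PAIRT, maxloop, min_hairpin, kT, u1, QB, QM, Q, Qr):
    """Outside pass: base-pair probabilities from the inside arrays."""
    n = S.shape[0]
    P = np.zeros((n, n))
    mlb = scal[S_MLBASE]
    mli = scal[S_MLINTERN]
    mlc = scal[S_MLCLOSING]
    wb = math.exp(-mlb / kT) * u1
    ztot = Q[n]
    # exterior contributions
    for i in range(n):
        for j in range(i + min_hairpin + 1, n):
            if QB[i, j] > 0.0:
                P[i, j] = (Q[i] * QB[i, j] * math.exp(-EXT[i, j] / kT)
                           * Qr[j + 1] / ztot)
    # propagate through interior loops and multiloops, long spans first
    for span in range(n - 1, min_hairpin, -1):
        for i in range(0, n - span):
            j = i + span
            if P[i, j] <= 0.0:
                continue
            pij = P[i, j] / QB[i, j]
            # interior loops
            kmax = i + maxloop + 1
            if kmax > j - min_hairpin - 2:
                kmax = j - min_hairpin - 2
            for k in range(i + 1, kmax + 1):
                n1 = k - i - 1
                lmin = j - 1 - (maxloop - n1)
                if lmin < k + min_hairpin + 1:
                    lmin = k + min_hairpin + 1
                for l in range(lmin, j):
                    if ptype[k, l] > 0 and QB[k, l] > 0.0:
                        e = e_interior(
                            i, j, k, l, S, stack, i11, i21, i22, mmi, mm1n,
                            mm23, bulge_len, internal_len, scal,
                            SC, EO, EI, MO, MI, PAIRT)
                        if e < BIG:
                            P[k, l] += (pij * math.exp(-e / kT) * QB[k, l]
                                        * u1 ** (n1 + (j - l - 1) + 2))
            # multiloops: (k, l) is a branch inside the loop closed by (i, j)
            wcl = pij * math.exp(-(mlc + mli + MLC[i, j]) / kT) * u1 * u1
            for k in range(i + 1, j - min_hairpin - 1):
                for l in range(k + min_hairpin + 1, j):
                    if ptype[k, l] == 0 or QB[k, l] <= 0.0:
                        continue
                    qml = QM[i + 1, k - 1] if k - 1 >= i + 1 else 0.0
                    qmr = QM[l + 1, j - 1] if j - 1 >= l + 1 else 0.0
                    rest = qml * qmr
                    rest += qml * wb ** (j - 1 - l)
                    rest += wb ** (k - i - 1) * qmr
                    if rest > 0.0:
                        P[k, l] += (wcl * rest * QB[k, l]
                                    * math.exp(-(mli + MLS[k, l]) / kT))
    return P
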