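"""Numba kernels for the folding engine.

Implements the Zuker-style minimum-free-energy recursions and the
McCaskill inside/outside partition-function recursions over the reduced
nearest-neighbor model defined in :mod:`splicefold.fold.energy`.  The
scalar model parameters arrive packed in a float array (see
``EnergyModel.params_array``): kT, hairpin_a, loop_log, bulge_a,
interior_a, ml_a, ml_b, ml_c, maxloop.

``max_dist <= 0`` means unconstrained pairing distance.  The partition
kernels carry a per-nucleotide scaling factor ``sc`` so long windows do
not overflow double precision; every stored segment quantity of length L
is multiplied by ``sc**L`` and the factors cancel exactly in the pair
probabilities.
"""

import math

import numpy as np
from numba import njit

INF = 1e30
_BIG = 1e29  # anything above this is treated as +infinity


@njit(cache=True, inline="always")
def _hairpin_e(size, ha, clog):
    if size < 3:
        return INF
    if size == 3:
        return ha
    return ha + clog * math.log(size / 3.0)


@njit(cache=True, inline="always")
def _interior_e(l1, l2, pt_out, pt_in, stack_tab, ba, ia, clog, maxloop):
    total = l1 + l2
    if total == 0:
        return stack_tab[pt_out, pt_in]
    if total > maxloop:
        return INF
    if l1 == 0 or l2 == 0:
        return ba + clog * math.log(float(total))
    return ia + clog * math.log(float(total))


@njit(cache=True)
def mfe_fill(codes, pe, ptab, stack_tab, params, max_dist):
    kT = params[0]
    ha = params[1]
    clog = params[2]
    ba = params[3]
    ia = params[4]
    ml_a = params[5]
    ml_b = params[6]
    ml_c = params[7]
    maxloop = int(params[8])
    n = codes.shape[0]
    V = np.full((n, n), INF)
    WM = np.full((n, n), INF)
    for d in range(1, n):
        for i in range(0, n - d):
            j = i + d
            if d >= 4 and (max_dist <= 0 or d <= max_dist):
                pt = ptab[codes[i], codes[j]]
                if pt >= 0:
                    best = _hairpin_e(d - 1, ha, clog)
                    kmax = i + maxloop + 1
                    if kmax > j - 4:
                        kmax = j - 4
                    for k in range(i + 1, kmax + 1):
                        l1 = k - i - 1
                        lmin = j - 1 - (maxloop - l1)
                        if lmin < k + 4:
                            lmin = k + 4
                        for l in range(j - 1, lmin - 1, -1):
                            if V[k, l] > _BIG:
                                continue
                            pt_in = ptab[codes[k], codes[l]]
                            e = (
                                _interior_e(l1, j - l - 1, pt, pt_in, stack_tab,
                                            ba, ia, clog, maxloop)
                                + V[k, l]
                            )
                            if e < best:
                                best = e
                    for k in range(i + 2, j - 1):
                        if WM[i + 1, k] < _BIG and WM[k + 1, j - 1] < _BIG:
                            e = ml_a + ml_b + WM[i + 1, k] + WM[k + 1, j - 1]
                            if e < best:
                                best = e
                    if best < _BIG:
                        V[i, j] = best + pe[i] + pe[j]
            # WM: segment of a multiloop containing at least one branch
            w = INF
            if V[i, j] < _BIG and V[i, j] + ml_b < w:
                w = V[i, j] + ml_b
            if WM[i + 1, j] < _BIG and WM[i + 1, j] + ml_c < w:
                w = WM[i + 1, j] + ml_c
            if WM[i, j - 1] < _BIG and WM[i, j - 1] + ml_c < w:
                w = WM[i, j - 1] + ml_c
            for k in range(i + 1, j):
                if WM[i, k - 1] < _BIG and WM[k, j] < _BIG:
                    e = WM[i, k - 1] + WM[k, j]
                    if e < w:
                        w = e
            WM[i, j] = w
    W = np.zeros(n + 1)
    for j in range(n):
        best = W[j]
        for i in range(0, j - 3):
            if V[i, j] < _BIG:
                e = W[i] + V[i, j]
                if e < best:
                    best = e
        W[j + 1] = best
    return V, WM, W


@njit(cache=True)
def mfe_traceback(codes, pe, ptab, stack_tab, params, max_dist, V, WM, W):
    """Recover one optimal structure; ties are resolved deterministically
    (pairing preferred, then smallest 5' index, then stacking before larger
    interior loops, then earliest multiloop split)."""
    ha = params[1]
    clog = params[2]
    ba = params[3]
    ia = params[4]
    ml_a = params[5]
    ml_b = params[6]
    ml_c = params[7]
    maxloop = int(params[8])
    n = codes.shape[0]
    eps = 1e-8
    partner = np.full(n, -1, np.int64)
    cap = 8 * n + 16
    sti = np.empty(cap, np.int64)
    stj = np.empty(cap, np.int64)
    stm = np.empty(cap, np.int64)  # 0 = V segment, 1 = WM segment
    top = 0
    # exterior loop
    j = n - 1
    while j >= 3:
        paired = False
        for i in range(0, j - 3):
            if V[i, j] < _BIG and abs(W[i] + V[i, j] - W[j + 1]) <= eps:
                partner[i] = j
                partner[j] = i
                sti[top] = i
                stj[top] = j
                stm[top] = 0
                top += 1
                j = i - 1
                paired = True
                break
        if not paired:
            j -= 1
    while top > 0:
        top -= 1
        i = sti[top]
        j = stj[top]
        mode = stm[top]
        if mode == 0:
            pt = ptab[codes[i], codes[j]]
            rest = V[i, j] - pe[i] - pe[j]
            if abs(rest - _hairpin_e(j - i - 1, ha, clog)) <= eps:
                continue
            found = False
            kmax = i + maxloop + 1
            if kmax > j - 4:
                kmax = j - 4
            for k in range(i + 1, kmax + 1):
                if found:
                    break
                l1 = k - i - 1
                lmin = j - 1 - (maxloop - l1)
                if lmin < k + 4:
                    lmin = k + 4
                for l in range(j - 1, lmin - 1, -1):
                    if V[k, l] > _BIG:
                        continue
                    pt_in = ptab[codes[k], codes[l]]
                    e = (
                        _interior_e(l1, j - l - 1, pt, pt_in, stack_tab,
                                    ba, ia, clog, maxloop)
                        + V[k, l]
                    )
                    if abs(e - rest) <= eps:
                        partner[k] = l
                        partner[l] = k
                        sti[top] = k
                        stj[top] = l
                        stm[top] = 0
                        top += 1
                        found = True
                        break
            if found:
                continue
            for k in range(i + 2, j - 1):
                if WM[i + 1, k] < _BIG and WM[k + 1, j - 1] < _BIG:
                    e = ml_a + ml_b + WM[i + 1, k] + WM[k + 1, j - 1]
                    if abs(e - rest) <= eps:
                        sti[top] = i + 1
                        stj[top] = k
                        stm[top] = 1
                        top += 1
                        sti[top] = k + 1
                        stj[top] = j - 1
                        stm[top] = 1
                        top += 1
                        break
        else:
            w = WM[i, j]
            if V[i, j] < _BIG and abs(V[i, j] + ml_b - w) <= eps:
                partner[i] = j
                partner[j] = i
                sti[top] = i
                stj[top] = j
                stm[top] = 0
                top += 1
                continue
            if i + 1 <= j and WM[i + 1, j] < _BIG and abs(WM[i + 1, j] + ml_c - w) <= eps:
                sti[top] = i + 1
                stj[top] = j
                stm[top] = 1
                top += 1
                continue
            if j - 1 >= i and WM[i, j - 1] < _BIG and abs(WM[i, j - 1] + ml_c - w) <= eps:
                sti[top] = i
                stj[top] = j - 1
                stm[top] = 1
                top += 1
                continue
            for k in range(i + 1, j):
                if WM[i, k - 1] < _BIG and WM[k, j] < _BIG:
                    if abs(WM[i, k - 1] + WM[k, j] - w) <= eps:
                        sti[top] = i
                        stj[top] = k - 1
                        stm[top] = 1
                        top += 1
                        sti[top] = k
                        stj[top] = j
                        stm[top] = 1
                        top += 1
                        break
    return partner


@njit(cache=True)
def partition_fill(codes, pe, ptab, stack_tab, params, max_dist, sc):
    kT = params[0]
    ha = params[1]
    clog = params[2]
    ba = params[3]
    ia = params[4]
    ml_a = params[5]
    ml_b = params[6]
    ml_c = params[7]
    maxloop = int(params[8])
    n = codes.shape[0]
    QB = np.zeros((n, n))
    QM = np.zeros((n, n))
    QM1 = np.zeros((n, n))
    expb = math.exp(-ml_b / kT)
    expc = math.exp(-ml_c / kT) * sc
    exp_close = math.exp(-(ml_a + ml_b) / kT) * sc * sc
    for d in range(4, n):
        for i in range(0, n - d):
            j = i + d
            pt = ptab[codes[i], codes[j]]
            if pt >= 0 and (max_dist <= 0 or d <= max_dist):
                s = math.exp(-_hairpin_e(d - 1, ha, clog) / kT) * sc ** (d + 1)
                kmax = i + maxloop + 1
                if kmax > j - 4:
                    kmax = j - 4
                for k in range(i + 1, kmax + 1):
                    l1 = k - i - 1
                    lmin = j - 1 - (maxloop - l1)
                    if lmin < k + 4:
                        lmin = k + 4
                    for l in range(j - 1, lmin - 1, -1):
                        if QB[k, l] <= 0.0:
                            continue
                        pt_in = ptab[codes[k], codes[l]]
                        e = _interior_e(l1, j - l - 1, pt, pt_in, stack_tab,
                                        ba, ia, clog, maxloop)
                        if e > _BIG:
                            continue
                        l2 = j - l - 1
                        s += math.exp(-e / kT) * QB[k, l] * sc ** (l1 + l2 + 2)
                mls = 0.0
                for k in range(i + 2, j - 1):
                    if QM[i + 1, k] > 0.0 and QM1[k + 1, j - 1] > 0.0:
                        mls += QM[i + 1, k] * QM1[k + 1, j - 1]
                s += mls * exp_close
                QB[i, j] = s * math.exp(-(pe[i] + pe[j]) / kT)
            # QM1: 5' end paired with some l, trailing bases unpaired
            s1 = 0.0
            for l in range(i + 4, j + 1):
                if QB[i, l] > 0.0:
                    s1 += QB[i, l] * expb * expc ** (j - l)
            QM1[i, j] = s1
            # QM: >= 1 branch; decomposition on the start of the last branch
            sm = 0.0
            for k in range(i, j + 1):
                q1 = QM1[k, j]
                if q1 <= 0.0:
                    continue
                sm += expc ** (k - i) * q1
                if k > i and QM[i, k - 1] > 0.0:
                    sm += QM[i, k - 1] * q1
            QM[i, j] = sm
    # exterior prefix / suffix partition functions
    Qp = np.ones(n + 1)
    for i in range(1, n + 1):
        s = Qp[i - 1] * sc
        for k in range(0, i - 4):
            if QB[k, i - 1] > 0.0:
                s += Qp[k] * QB[k, i - 1]
        Qp[i] = s
    Qs = np.ones(n + 1)
    for j in range(n - 1, -1, -1):
        s = Qs[j + 1] * sc
        for l in range(j + 4, n):
            if QB[j, l] > 0.0:
                s += QB[j, l] * Qs[l + 1]
        Qs[j] = s
    return QB, QM, QM1, Qp, Qs


@njit(cache=True)
def pair_probabilities_fill(codes, pe, ptab, stack_tab, params, max_dist, sc,
                            QB, QM, QM1, Qp, Qs):
    kT = params[0]
    clog = params[2]
    ba = params[3]
    ia = params[4]
    ml_a = params[5]
    ml_b = params[6]
    ml_c = params[7]
    maxloop = int(params[8])
    n = codes.shape[0]
    P = np.zeros((n, n))
    Qtot = Qp[n]
    expc = math.exp(-ml_c / kT) * sc
    exp_ml = math.exp(-(ml_a + 2.0 * ml_b) / kT) * sc * sc
    for d in range(n - 1, 3, -1):
        for i in range(0, n - d):
            j = i + d
            qb = QB[i, j]
            if qb <= 0.0:
                continue
            pt_in = ptab[codes[i], codes[j]]
            p = Qp[i] * qb * Qs[j + 1] / Qtot
            # (i,j) as the inner pair of a stack/bulge/interior loop
            kmin = i - maxloop - 1
            if kmin < 0:
                kmin = 0
            for k in range(kmin, i):
                l1 = i - k - 1
                lmax = j + 1 + (maxloop - l1)
                if lmax > n - 1:
                    lmax = n - 1
                for l in range(j + 1, lmax + 1):
                    if P[k, l] <= 0.0:
                        continue
                    pt_out = ptab[codes[k], codes[l]]
                    e = _interior_e(l1, l - j - 1, pt_out, pt_in, stack_tab,
                                    ba, ia, clog, maxloop)
                    if e > _BIG:
                        continue
                    l2 = l - j - 1
                    p += (
                        P[k, l] / QB[k, l]
                        * math.exp(-(e + pe[k] + pe[l]) / kT)
                        * qb
                        * sc ** (l1 + l2 + 2)
                    )
            # (i,j) as one branch of a multiloop closed by (k,l)
            for k in range(0, i):
                lstop = n - 1
                if max_dist > 0 and k + max_dist < lstop:
                    lstop = k + max_dist
                for l in range(j + 1, lstop + 1):
                    pkl = P[k, l]
                    if pkl <= 0.0:
                        continue
                    ul = expc ** (i - k - 1)
                    ur = expc ** (l - j - 1)
                    qml = QM[k + 1, i - 1] if i - 1 >= k + 1 else 0.0
                    qmr = QM[j + 1, l - 1] if l - 1 >= j + 1 else 0.0
                    inner = ul * qmr + qml * ur + qml * qmr
                    if inner <= 0.0:
                        continue
                    p += (
                        pkl / QB[k, l]
                        * math.exp(-(pe[k] + pe[l]) / kT)
                        * exp_ml
                        * inner
                        * qb
                    )
            P[i, j] = p
    return P
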