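"""Numba dynamic-programming kernels.

Two kernels live here: plain affine-gap Smith-Waterman and a spliced
(est-to-genome) variant with an additional intron state.  Both fill exact
DP recurrences with deterministic tie-breaking (first-found optimum on the
scan order, which for the intron state means the leftmost donor).

A gap of length L costs ``gap_open + L * gap_ext``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = np.int32(-(10 ** 9))

# pointer encodings (low 3 bits: H source; bits 3/4: E/F gap-open flags)
P_STOP, P_DIAG, P_E, P_F, P_INTRON = 0, 1, 2, 3, 4
FLAG_EOPEN, FLAG_FOPEN = 8, 16


@njit(cache=True)
def sw_kernel(a, b, sub, go, ge):
    """Affine-gap local alignment; returns (score, bi, bj, ptr).

    ptr is the packed traceback matrix; (bi, bj) the 1-based end cell of the
    best local alignment (first such cell in scan order on ties).
    """
    m, n = a.shape[0], b.shape[0]
    Hprev = np.zeros(n + 1, np.int32)
    Hcur = np.zeros(n + 1, np.int32)
    Fcol = np.full(n + 1, NEG, np.int32)   # gap in b (consumes a); per column j
    ptr = np.zeros((m + 1, n + 1), np.uint8)
    best = np.int32(0)
    bi = 0
    bj = 0
    goe = np.int32(go + ge)
    gei = np.int32(ge)
    for i in range(1, m + 1):
        srow = sub[a[i - 1]]
        ptri = ptr[i]
        e = NEG                    # E state along the row (gap consuming b)
        hdiag = Hprev[0]
        hleft = np.int32(0)
        Hcur[0] = 0
        for j in range(1, n + 1):
            hup = Hprev[j]
            flags = 0
            e_open = hleft - goe
            e_ext = e - gei
            if e_open >= e_ext:
                e = e_open
                flags = FLAG_EOPEN
            else:
                e = e_ext
            f_open = hup - goe
            f_ext = Fcol[j] - gei
            if f_open >= f_ext:
                f = f_open
                flags |= FLAG_FOPEN
            else:
                f = f_ext
            Fcol[j] = f
            d = hdiag + srow[b[j - 1]]
            h = np.int32(0)
            src = P_STOP
            if d > h:
                h = d
                src = P_DIAG
            if e > h:
                h = e
                src = P_E
            if f > h:
                h = f
                src = P_F
            ptri[j] = np.uint8(src | flags)
            Hcur[j] = h
            hdiag = hup
            hleft = h
            if h > best:
                best = h
                bi = i
                bj = j
        Hprev, Hcur = Hcur, Hprev
    return best, bi, bj, ptr


@njit(cache=True)
def spliced_kernel(est, gen, sub, go, ge, min_intron, ipen, extra,
                   donor_ok, acceptor_ok):
    """est2genome-style local DP with an intron state.

    An intron is a genome-only jump of length >= min_intron charging ``ipen``
    when its termini are GT..AG (donor_ok/acceptor_ok precomputed) and
    ``ipen + extra`` otherwise.  Returns (score, bi, bj, ptr, jsrc) where
    jsrc[i, j] holds the length of the intron ending at column j of row i
    (uint16, which bounds the genome window at 65535 nt; the wrapper
    enforces that).
    """
    m, n = est.shape[0], gen.shape[0]
    Hprev = np.zeros(n + 1, np.int32)
    Hcur = np.zeros(n + 1, np.int32)
    Ecol = np.full(n + 1, NEG, np.int32)   # gap consuming est (vertical)
    ptr = np.zeros((m + 1, n + 1), np.uint8)
    jsrc = np.zeros((m + 1, n + 1), np.uint16)
    best = np.int32(0)
    bi = 0
    bj = 0
    goe = np.int32(go + ge)
    gei = np.int32(ge)
    ipen_c = np.int32(ipen)
    ipen_nc = np.int32(ipen + extra)
    for i in range(1, m + 1):
        srow = sub[est[i - 1]]
        ptri = ptr[i]
        jsrci = jsrc[i]
        f = NEG                     # gap consuming genome (horizontal)
        bgt = NEG                   # best H[i, u] with GT donor, u <= j - min_intron
        ball = NEG                  # best H[i, u] overall,      u <= j - min_intron
        agt = 0
        aall = 0
        Hcur[0] = 0
        for j in range(1, n + 1):
            flags = 0
            # running maxima feeding the intron state (same row i)
            u = j - min_intron
            if u >= 0:
                v = Hcur[u]
                if v > ball:
                    ball = v
                    aall = u
                if donor_ok[u] and v > bgt:
                    bgt = v
                    agt = u
            e_open = Hprev[j] - goe
            e_ext = Ecol[j] - gei
            if e_open >= e_ext:
                e = e_open
                flags |= FLAG_EOPEN
            else:
                e = e_ext
            Ecol[j] = e
            f_open = Hcur[j - 1] - goe
            f_ext = f - gei
            if f_open >= f_ext:
                f = f_open
                flags |= FLAG_FOPEN
            else:
                f = f_ext
            jbest = NEG
            jarg = 0
            if acceptor_ok[j] and bgt > NEG:
                jbest = bgt - ipen_c
                jarg = agt
            if ball > NEG:
                cand = ball - ipen_nc
                if cand > jbest:
                    jbest = cand
                    jarg = aall
            d = Hprev[j - 1] + srow[gen[j - 1]]
            h = np.int32(0)
            src = P_STOP
            if d > h:
                h = d
                src = P_DIAG
            if e > h:
                h = e
                src = P_E
            if f > h:
                h = f
                src = P_F
            if jbest > h:
                h = jbest
                src = P_INTRON
                jsrci[j] = np.uint16(j - jarg)
            Hcur[j] = h
            ptri[j] = np.uint8(src | flags)
            if h > best:
                best = h
                bi = i
                bj = j
        Hprev, Hcur = Hcur, Hprev
    return best, bi, bj, ptr, jsrc
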