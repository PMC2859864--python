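"""Independent reference implementations used as test oracles.

These deliberately share no code with the package kernels: plain
full-matrix dynamic programs without rolling rows, running maxima or
pointer packing, plus interval-enumeration scoring for spliced alignment
on gap-free instances.
"""

from __future__ import annotations


def sw_score(a: str, b: str, match=1, mismatch=-3, gap_open=5, gap_extend=2):
    """Affine-gap Smith-Waterman score, textbook three-matrix form.

    A gap of length L costs gap_open + L * gap_extend.
    """
    NEG = -(10 ** 9)
    m, n = len(a), len(b)
    H = [[0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    best = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] - gap_open - gap_extend,
                          E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open - gap_extend,
                          F[i - 1][j] - gap_extend)
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i][j] = max(0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def spliced_score(est: str, gen: str, min_intron: int, intron_penalty: int,
                  noncanonical_extra: int, match=1, mismatch=-3,
                  gap_open=5, gap_extend=2) -> int:
    """Naive O(m n^2) spliced local score: the intron state is evaluated by
    direct scan over every admissible donor position."""
    NEG = -(10 ** 9)
    m, n = len(est), len(gen)
    H = [[0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    best = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] - gap_open - gap_extend,
                          E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open - gap_extend,
                          F[i - 1][j] - gap_extend)
            s = match if est[i - 1] == gen[j - 1] else mismatch
            cand = max(0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            acceptor = gen[j - 2:j] == "AG"
            for u in range(0, j - min_intron + 1):
                pen = intron_penalty
                if not (gen[u:u + 2] == "GT" and acceptor):
                    pen += noncanonical_extra
                cand = max(cand, H[i][u] - pen)
            H[i][j] = cand
            best = max(best, H[i][j])
    return best


def enumerate_single_intron_score(est: str, gen: str, min_intron: int,
                                  intron_penalty: int,
                                  noncanonical_extra: int, **sw_kw) -> int:
    """Max over {no intron} and every single intron placement [u, v):
    score the est against the reduced genome and charge the penalty."""
    best = sw_score(est, gen, **sw_kw)
    n = len(gen)
    for u in range(n):
        for v in range(u + min_intron, n + 1):
            pen = intron_penalty
            if not (gen[u:u + 2] == "GT" and gen[v - 2:v] == "AG"):
                pen += noncanonical_extra
            reduced = gen[:u] + gen[v:]
            if reduced:
                best = max(best, sw_score(est, reduced, **sw_kw) - pen)
    return best
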