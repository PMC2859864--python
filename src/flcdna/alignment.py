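"""Local alignment with Karlin-Altschul E-value calibration and batch search.

This is the pipeline's BLASTN/BLASTP stand-in: exact affine-gap
Smith-Waterman scores with E-values from ungapped Karlin-Altschul theory
(lambda solved to machine precision, K from the standard lattice series).
E-values are therefore comparable across searches but will not bit-match
NCBI BLAST; every threshold that consumes them is configurable.

``search`` scans a :class:`~flcdna.io_formats.ReferenceDb`.  On large
databases it first collects candidate subjects by exact k-mer seeding and
aligns only those; on small inputs (``mode="auto"``) it aligns every record,
so the DP itself is never approximated where exhaustive comparison is
feasible.  At the pipeline's operating thresholds (E < 1e-50 and tighter)
every qualifying hit necessarily shares long exact k-mers, so seeding does
not change decisions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from Bio.Align import substitution_matrices

from . import _seq
from ._kernels import (FLAG_EOPEN, FLAG_FOPEN, P_DIAG, P_E, P_F, sw_kernel)
from .io_formats import ReferenceDb

LN2 = math.log(2.0)
LN10 = math.log(10.0)


class CalibrationError(ValueError):
    pass


# Robinson & Robinson amino-acid background frequencies (standard ungapped
# BLASTP background), indexed by _seq.PROT_ORDER[:20].
_ROBINSON = {
    "A": 0.07805, "R": 0.05129, "N": 0.04487, "D": 0.05364, "C": 0.01925,
    "Q": 0.04264, "E": 0.06295, "G": 0.07377, "H": 0.02199, "I": 0.05142,
    "L": 0.09019, "K": 0.05744, "M": 0.02243, "F": 0.03856, "P": 0.05203,
    "S": 0.07120, "T": 0.05841, "W": 0.01330, "Y": 0.03216, "V": 0.06441,
}


@dataclass(frozen=True)
class ScoringScheme:
    """Scoring parameters for nucleotide or protein local alignment.

    Defaults are the classic BLASTN-like +1/-3 with gap open 5 / extend 2;
    ``protein_default()`` gives BLOSUM62 with 11/1 gaps.
    """

    match: int = 1
    mismatch: int = -3
    gap_open: int = 5
    gap_extend: int = 2
    alphabet: str = "nucleotide"
    matrix_name: str = "BLOSUM62"

    def __post_init__(self):
        if self.alphabet not in ("nucleotide", "protein"):
            raise ValueError(f"bad alphabet {self.alphabet!r}")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be non-negative")

    @classmethod
    def protein_default(cls) -> "ScoringScheme":
        return cls(gap_open=11, gap_extend=1, alphabet="protein")

    def substitution_matrix(self) -> np.ndarray:
        """Integer substitution matrix over the encoded alphabet."""
        if self.alphabet == "nucleotide":
            if self.match <= 0:
                raise ValueError("match reward must be positive")
            k = len(_seq.NUC_ORDER)
            sub = np.full((k, k), self.mismatch, dtype=np.int32)
            for i in range(4):
                sub[i, i] = self.match
            # N/X never reward
            sub[4:, :] = self.mismatch
            sub[:, 4:] = self.mismatch
            return sub
        blosum = substitution_matrices.load(self.matrix_name)
        k = len(_seq.PROT_ORDER)
        sub = np.zeros((k, k), dtype=np.int32)
        for i, a in enumerate(_seq.PROT_ORDER):
            for j, b in enumerate(_seq.PROT_ORDER):
                sub[i, j] = int(blosum[a][b])
        return sub

    def background(self) -> np.ndarray:
        """Default background letter frequencies for calibration."""
        if self.alphabet == "nucleotide":
            bg = np.zeros(len(_seq.NUC_ORDER))
            bg[:4] = 0.25
            return bg
        bg = np.zeros(len(_seq.PROT_ORDER))
        for a, p in _ROBINSON.items():
            bg[_seq.PROT_INDEX[a]] = p
        return bg / bg.sum()

    def encode(self, seq: str) -> np.ndarray:
        if self.alphabet == "nucleotide":
            return _seq.encode_nuc(seq)
        return _seq.encode_protein(seq)


def calibrate(scheme: ScoringScheme,
              background: np.ndarray | None = None) -> tuple[float, float]:
    """Karlin-Altschul (lambda, K) for an ungapped scoring scheme.

    lambda solves sum_ij p_i p_j exp(lambda s_ij) = 1 (residual < 1e-9 by
    bisection refinement of a Brent solve); K uses the lattice series
    K = d*lambda*exp(-2*sigma) / (H*(1-exp(-lambda*d))) with
    sigma = sum_k (1/k)[P(S_k >= 0) + E(exp(lambda S_k); S_k < 0)], truncated
    when the (geometrically decaying) terms fall below 1e-12.
    """
    bg = scheme.background() if background is None else np.asarray(background, float)
    bg = bg / bg.sum()
    sub = scheme.substitution_matrix()
    k = sub.shape[0]
    # score distribution over aligned background pairs
    probs: dict[int, float] = {}
    for i in range(k):
        if bg[i] == 0:
            continue
        for j in range(k):
            if bg[j] == 0:
                continue
            s = int(sub[i, j])
            probs[s] = probs.get(s, 0.0) + bg[i] * bg[j]
    scores = np.array(sorted(probs), dtype=np.int64)
    p = np.array([probs[int(s)] for s in scores])
    expected = float((p * scores).sum())
    if expected >= 0 or scores.max() <= 0:
        raise CalibrationError(
            "expected pair score must be negative with a positive maximum")

    def f(lam: float) -> float:
        return float((p * np.exp(lam * scores)).sum()) - 1.0

    hi = 0.5
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e4:  # pragma: no cover - defensive
            raise CalibrationError("failed to bracket lambda")
    lo = 1e-12
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
        if abs(f(mid)) < 1e-12:
            break
    lam = 0.5 * (lo + hi)

    d = int(np.gcd.reduce(np.abs(scores[scores != 0])))
    tilt = p * np.exp(lam * scores)
    H = lam * float((tilt * scores).sum())

    # convolution series for sigma
    lo_s, hi_s = int(scores.min()), int(scores.max())
    dist = np.zeros(hi_s - lo_s + 1)
    for s, pr in zip(scores, p):
        dist[int(s) - lo_s] = pr
    conv = dist.copy()
    off = lo_s  # conv[x] = P(S_k = off + x)
    sigma = 0.0
    for kk in range(1, 200):
        support = off + np.arange(conv.size)
        pos = float(conv[support >= 0].sum())
        neg_mask = support < 0
        neg = float((conv[neg_mask] * np.exp(lam * support[neg_mask])).sum())
        term = (pos + neg) / kk
        sigma += term
        if term < 1e-12 and kk > 5:
            break
        conv = np.convolve(conv, dist)
        off += lo_s
    K = d * lam * math.exp(-2.0 * sigma) / (H * (1.0 - math.exp(-lam * d)))
    return lam, K


_CALIBRATION_CACHE: dict[tuple, tuple[float, float]] = {}


def cached_calibration(scheme: ScoringScheme) -> tuple[float, float]:
    key = (scheme.match, scheme.mismatch, scheme.alphabet, scheme.matrix_name)
    if key not in _CALIBRATION_CACHE:
        _CALIBRATION_CACHE[key] = calibrate(scheme)
    return _CALIBRATION_CACHE[key]


@dataclass
class AlignmentHit:
    """Best local alignment of a query against one subject.

    ``identity`` is the fraction of aligned non-gap columns that match (the
    spec of the in-memory type); ``identity_blast`` is matches over all
    alignment columns including gaps, the convention BLAST tabular output
    prints and the one every curation threshold consumes.
    """

    query_id: str
    subject_id: str
    query_interval: tuple[int, int]
    subject_interval: tuple[int, int]
    strand: str
    score: int
    bit_score: float
    log10_evalue: float
    matches: int
    mismatches: int
    gap_columns: int
    subject_description: str = ""

    def __post_init__(self):
        if self.score < 0:
            raise ValueError("negative alignment score")

    @property
    def align_len(self) -> int:
        return self.matches + self.mismatches + self.gap_columns

    @property
    def identity(self) -> float:
        cols = self.matches + self.mismatches
        return self.matches / cols if cols else 0.0

    @property
    def identity_blast(self) -> float:
        return self.matches / self.align_len if self.align_len else 0.0

    @property
    def evalue(self) -> float:
        return 10.0 ** max(self.log10_evalue, -320.0) if self.log10_evalue > -320 else 0.0

    def query_coverage(self, qlen: int) -> float:
        return (self.query_interval[1] - self.query_interval[0]) / qlen

    def subject_coverage(self, slen: int) -> float:
        return (self.subject_interval[1] - self.subject_interval[0]) / slen


def _traceback_counts(a, b, ptr, bi, bj):
    """Walk the packed pointers from (bi, bj); return endpoints and counts."""
    i, j = bi, bj
    matches = mismatches = gaps = 0
    state = "H"
    while True:
        if state == "H":
            src = ptr[i, j] & 7
            if src == 0:
                break
            if src == P_DIAG:
                if a[i - 1] == b[j - 1]:
                    matches += 1
                else:
                    mismatches += 1
                i -= 1
                j -= 1
            elif src == P_E:
                state = "E"
            elif src == P_F:
                state = "F"
        elif state == "E":  # gap in a, consumes b
            gaps += 1
            opened = ptr[i, j] & FLAG_EOPEN
            j -= 1
            if opened:
                state = "H"
        else:               # gap in b, consumes a
            gaps += 1
            opened = ptr[i, j] & FLAG_FOPEN
            i -= 1
            if opened:
                state = "H"
    return i, j, matches, mismatches, gaps


def _evalue_log10(score: int, m: int, n: int, lam: float, K: float) -> float:
    # E = K * m * n * exp(-lambda * score); raw (unadjusted) lengths
    return math.log10(K * m * n) - lam * score / LN10


def local_align(query: str, subject: str, scheme: ScoringScheme | None = None,
                query_id: str = "query", subject_id: str = "subject",
                strands: str = "both",
                subject_description: str = "") -> AlignmentHit:
    """Best affine-gap local alignment (both strands for nucleotides).

    ``strands``: "both" (default), "+" or "-"; proteins always use "+".
    """
    if not query or not subject:
        raise ValueError("empty sequence")
    scheme = scheme or ScoringScheme()
    sub = scheme.substitution_matrix()
    qa = scheme.encode(query)
    lam, K = cached_calibration(scheme)

    def run(subj_seq: str, strand: str):
        sa = scheme.encode(subj_seq)
        score, bi, bj, ptr = sw_kernel(qa, sa, sub, scheme.gap_open,
                                       scheme.gap_extend)
        return score, bi, bj, ptr, subj_seq, strand

    if scheme.alphabet != "nucleotide":
        strands = "+"
    results = []
    if strands in ("both", "+"):
        results.append(run(subject, "+"))
    if strands in ("both", "-"):
        results.append(run(_seq.revcomp(subject), "-"))
    score, bi, bj, ptr, subj_seq, strand = max(
        results, key=lambda r: (r[0], r[5] == "+"))
    sa = scheme.encode(subj_seq)
    qi, qj, matches, mismatches, gaps = _traceback_counts(qa, sa, ptr, bi, bj)
    s_start, s_end = qj, bj
    if strand == "-":
        n = len(subject)
        s_start, s_end = n - bj, n - qj
    return AlignmentHit(
        query_id=query_id, subject_id=subject_id,
        query_interval=(qi, bi), subject_interval=(s_start, s_end),
        strand=strand, score=int(score),
        bit_score=(lam * score - math.log(K)) / LN2,
        log10_evalue=_evalue_log10(int(score), len(query), len(subject), lam, K),
        matches=matches, mismatches=mismatches, gap_columns=gaps,
        subject_description=subject_description)


# ---------------------------------------------------------------------------
# k-mer seeded candidate selection
# ---------------------------------------------------------------------------

def _low_complexity(kmer: str) -> bool:
    # near-homopolymer and two-letter-repeat k-mers (poly(A) tails, AT
    # microsatellites) seed unrelated sequences; keep them out of the index
    distinct = set(kmer)
    return (len(distinct) <= 2
            or max(kmer.count(c) for c in distinct) > 0.8 * len(kmer))


class KmerIndex:
    """Exact k-mer index over a database, for candidate prescreening.

    Low-complexity k-mers are excluded from the index: they connect
    unrelated sequences (every poly(A)-tailed cDNA shares them) without
    ever being the only evidence for a real hit at the pipeline thresholds.
    """

    def __init__(self, db: ReferenceDb, k: int):
        self.k = k
        # query k-mers are sampled at this stride so a single chance match
        # of ~k+stride nt cannot contribute several overlapping shared
        # k-mers; the index side stays exhaustive, so real matches always
        # seed regardless of phase
        self.stride = max(1, k // 3)
        self.index: dict[str, list[tuple[str, int]]] = {}
        for rid in db.ids():
            seq = db.seq(rid)
            for pos in range(0, len(seq) - k + 1):
                kmer = seq[pos:pos + k]
                if not _low_complexity(kmer):
                    self.index.setdefault(kmer, []).append((rid, pos))

    def candidates(self, query: str, min_shared: int = 2,
                   both_strands: bool = True
                   ) -> dict[str, tuple[int, int, str, int]]:
        """subject id -> (span_lo, span_hi, strand_hint, shared_count).

        The span is the subject region covered by shared k-mers; the hint is
        the strand with more shared k-mers ("both" on a tie).
        """
        counts: dict[str, list[int]] = {}
        span: dict[str, tuple[int, int]] = {}
        queries = [(query, 0)]
        if both_strands:
            queries.append((_seq.revcomp(query), 1))
        for q, sidx in queries:
            seen_kmers = set()
            for pos in range(0, len(q) - self.k + 1, self.stride):
                kmer = q[pos:pos + self.k]
                if kmer in seen_kmers or kmer not in self.index:
                    continue
                seen_kmers.add(kmer)
                for rid, spos in self.index[kmer]:
                    counts.setdefault(rid, [0, 0])[sidx] += 1
                    lo, hi = span.get(rid, (spos, spos + self.k))
                    span[rid] = (min(lo, spos), max(hi, spos + self.k))
        out = {}
        for rid, (fwd, rev) in counts.items():
            if fwd + rev < min_shared:
                continue
            hint = "+" if fwd > 2 * rev else "-" if rev > 2 * fwd else "both"
            out[rid] = (*span[rid], hint, fwd + rev)
        return out

    def seed_positions(self, query: str, both_strands: bool = True
                       ) -> dict[str, tuple[list[int], int, int]]:
        """subject id -> (sorted seed positions, fwd count, rev count)."""
        pos: dict[str, list[int]] = {}
        counts: dict[str, list[int]] = {}
        queries = [(query, 0)]
        if both_strands:
            queries.append((_seq.revcomp(query), 1))
        for q, sidx in queries:
            seen = set()
            for p in range(0, len(q) - self.k + 1, self.stride):
                kmer = q[p:p + self.k]
                if kmer in seen or kmer not in self.index:
                    continue
                seen.add(kmer)
                for rid, spos in self.index[kmer]:
                    pos.setdefault(rid, []).append(spos)
                    counts.setdefault(rid, [0, 0])[sidx] += 1
        return {rid: (sorted(ps), counts[rid][0], counts[rid][1])
                for rid, ps in pos.items()}


def db_index(db: ReferenceDb, k: int) -> KmerIndex:
    """Build (once) and memoize the k-mer index on the database object."""
    cache = getattr(db, "_kmer_indexes", None)
    if cache is None:
        cache = {}
        object.__setattr__(db, "_kmer_indexes", cache)
    if k not in cache:
        cache[k] = KmerIndex(db, k)
    return cache[k]


def search(query: str, db: ReferenceDb, scheme: ScoringScheme | None = None,
           max_evalue: float = 10.0, query_id: str = "query",
           exclude: set[str] | frozenset[str] | None = None,
           mode: str = "auto", seed_k: int | None = None,
           min_shared: int = 4, clip_margin: int | None = None
           ) -> list[AlignmentHit]:
    """Align a query against every (candidate) record of a database.

    Returns hits with E-value <= max_evalue sorted by (E-value, subject id).
    ``mode``: "full" aligns all records, "seeded" only k-mer candidates,
    "auto" picks "full" when the total DP work is small (< 5e7 cells).
    In seeded mode, ``clip_margin`` restricts the DP to the seed-covered
    subject region extended by that many nt (for long genome scaffolds);
    reported subject coordinates are always on the full record.
    """
    if len(db) == 0:
        raise ValueError(f"database {db.name!r} is empty")
    scheme = scheme or ScoringScheme()
    if max_evalue <= 0:
        return []
    exclude = exclude or set()
    if seed_k is None:
        seed_k = 12 if scheme.alphabet == "nucleotide" else 4
    total_cells = len(query) * sum(len(db.seq(r)) for r in db.ids())
    if mode == "auto":
        mode = "full" if total_cells < 5e7 else "seeded"
    if mode == "full":
        cand = {r: (0, len(db.seq(r)), "both", 0)
                for r in db.ids() if r not in exclude}
    else:
        idx = db_index(db, seed_k)
        both = scheme.alphabet == "nucleotide"
        cand = {r: v
                for r, v in idx.candidates(query, min_shared, both).items()
                if r not in exclude}
    log10_max = math.log10(max_evalue)
    hits = []
    for rid in sorted(cand):
        lo, hi, hint, _count = cand[rid]
        subj = db.seq(rid)
        off = 0
        if mode == "seeded" and clip_margin is not None:
            off = max(0, lo - clip_margin)
            subj = subj[off:min(len(subj), hi + clip_margin)]
        hit = local_align(query, subj, scheme, query_id=query_id,
                          subject_id=rid, strands=hint,
                          subject_description=db.desc(rid))
        if off:
            s, e = hit.subject_interval
            hit.subject_interval = (s + off, e + off)
        if hit.log10_evalue <= log10_max:
            hits.append(hit)
    hits.sort(key=lambda h: (h.log10_evalue, h.subject_id))
    return hits


def best_hit(query: str, db: ReferenceDb, scheme: ScoringScheme | None = None,
             max_evalue: float = 10.0, **kw) -> AlignmentHit | None:
    hits = search(query, db, scheme, max_evalue, **kw)
    return hits[0] if hits else None


def hits_to_table(hits: list[AlignmentHit]) -> list[dict]:
    """BLAST outfmt-6-style rows (1-based inclusive coordinates)."""
    rows = []
    for h in hits:
        qs, qe = h.query_interval
        ss, se = h.subject_interval
        if h.strand == "-":
            ss, se = se, ss  # BLAST convention: s.start > s.end on minus
            rows.append(dict(query=h.query_id, subject=h.subject_id,
                             pident=round(100 * h.identity_blast, 2),
                             align_len=h.align_len, mismatches=h.mismatches,
                             gaps=h.gap_columns, q_start=qs + 1, q_end=qe,
                             s_start=ss, s_end=se + 1,
                             evalue=h.evalue, bitscore=round(h.bit_score, 1)))
        else:
            rows.append(dict(query=h.query_id, subject=h.subject_id,
                             pident=round(100 * h.identity_blast, 2),
                             align_len=h.align_len, mismatches=h.mismatches,
                             gaps=h.gap_columns, q_start=qs + 1, q_end=qe,
                             s_start=ss + 1, s_end=se,
                             evalue=h.evalue, bitscore=round(h.bit_score, 1)))
    return rows
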