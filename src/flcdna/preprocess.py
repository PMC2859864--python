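"""Read trimming/filtering, EST clustering, 5'-most representative choice.

The original phrap/cross_match stage is replaced by explicit rules: vector
matches are clipped from the read ends, the longest window whose 20-nt
sliding mean Phred quality stays >= 30 is kept (edge bases below Q30 are
then polished off), reads shorter than 50 nt or dominated by a single-
nucleotide run are discarded, and clustering is greedy single linkage on
a >= 100 nt / >= 95% identity local-alignment rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import ScoringScheme, local_align
from .io_formats import CloneRead, ReferenceDb

QUALITY_WINDOW = 20
QUALITY_MIN = 30.0
MIN_READ_LEN = 50
HOMOPOLYMER_FRAC = 0.10
VECTOR_MIN_LEN = 15
VECTOR_MIN_IDENTITY = 0.90
LINK_MIN_LEN = 100
LINK_MIN_IDENTITY = 0.95


def trim_read(read: CloneRead, vector_db: ReferenceDb,
              scheme: ScoringScheme | None = None) -> CloneRead:
    """Clip terminal vector matches, then keep the best-quality window.

    Vector hits (identity >= 90%, length >= 15) are masked and terminal
    masked stretches removed; the remainder is cut to the longest contiguous
    window whose 20-nt sliding mean quality is >= 30, with edge bases below
    Q30 polished off.  Reads without qualities skip quality trimming.
    """
    if not read.sequence:
        raise ValueError("empty read")
    scheme = scheme or ScoringScheme()
    seq = read.sequence
    mask = np.zeros(len(seq), dtype=bool)
    for vid in vector_db.ids():
        hit = local_align(seq, vector_db.seq(vid), scheme,
                          query_id=read.id, subject_id=vid)
        span = hit.query_interval[1] - hit.query_interval[0]
        if span >= VECTOR_MIN_LEN and hit.identity_blast >= VECTOR_MIN_IDENTITY:
            mask[hit.query_interval[0]:hit.query_interval[1]] = True
    start, end = 0, len(seq)
    while start < end and mask[start]:
        start += 1
    while end > start and mask[end - 1]:
        end -= 1
    quals = read.qualities
    if quals is not None and end > start:
        q = np.asarray(quals[start:end], dtype=float)
        n = q.size
        w = min(QUALITY_WINDOW, n)
        means = np.convolve(q, np.ones(w) / w, mode="valid")
        valid = means >= QUALITY_MIN
        best_len, best_s = 0, 0
        run_s = None
        for i, v in enumerate(np.append(valid, False)):
            if v and run_s is None:
                run_s = i
            elif not v and run_s is not None:
                if i - run_s > best_len:
                    best_len, best_s = i - run_s, run_s
                run_s = None
        if best_len == 0:
            start = end = 0
        else:
            s, e = best_s, best_s + best_len - 1 + w
            # polish residual low-quality edge bases
            while s < e and q[s] < QUALITY_MIN:
                s += 1
            while e > s and q[e - 1] < QUALITY_MIN:
                e -= 1
            start, end = start + s, start + e
    return CloneRead(id=read.id, sequence=read.sequence[start:end],
                     library=read.library,
                     qualities=None if quals is None else quals[start:end])


def filter_read(read: CloneRead) -> tuple[bool, str]:
    """(keep, reason); reason is empty when kept."""
    from ._seq import longest_homopolymer
    n = len(read.sequence)
    if n < MIN_READ_LEN:
        return False, "length"
    if longest_homopolymer(read.sequence) > HOMOPOLYMER_FRAC * n:
        return False, "homopolymer"
    return True, ""


@dataclass
class Cluster:
    id: str
    members: list[str]
    representative: str = ""
    offsets: dict[str, int] = field(default_factory=dict)


def _link_candidates(reads: list[CloneRead], k: int = 14):
    """Candidate read pairs sharing k-mers (prescreen for the link test)."""
    from .alignment import _low_complexity
    index: dict[str, set[int]] = {}
    for i, r in enumerate(reads):
        s = r.sequence
        for p in range(0, len(s) - k + 1):
            kmer = s[p:p + k]
            if not _low_complexity(kmer):
                index.setdefault(kmer, set()).add(i)
    pairs: set[tuple[int, int]] = set()
    for ids in index.values():
        if 1 < len(ids) <= 200:
            ids = sorted(ids)
            for x in range(len(ids)):
                for y in range(x + 1, len(ids)):
                    pairs.add((ids[x], ids[y]))
    return sorted(pairs)


def cluster_ests(reads: list[CloneRead],
                 scheme: ScoringScheme | None = None,
                 min_len: int = LINK_MIN_LEN,
                 min_identity: float = LINK_MIN_IDENTITY) -> list[Cluster]:
    """Greedy single-linkage clustering of trimmed reads.

    Two reads link when they share a local alignment of >= min_len columns
    at >= min_identity; clusters are the connected components.  Cluster ids
    are deterministic (smallest member id), so the result is invariant to
    input order.
    """
    scheme = scheme or ScoringScheme()
    order = sorted(range(len(reads)), key=lambda i: reads[i].id)
    reads = [reads[i] for i in order]
    parent = list(range(len(reads)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in _link_candidates(reads):
        if find(i) == find(j):
            continue
        hit = local_align(reads[i].sequence, reads[j].sequence, scheme)
        if hit.align_len >= min_len and hit.identity_blast >= min_identity:
            parent[find(j)] = find(i)

    groups: dict[int, list[int]] = {}
    for i in range(len(reads)):
        groups.setdefault(find(i), []).append(i)
    clusters = []
    for idxs in groups.values():
        member_ids = sorted(reads[i].id for i in idxs)
        clusters.append(Cluster(id=f"cluster:{member_ids[0]}",
                                members=member_ids))
    clusters.sort(key=lambda c: c.id)
    read_map = {r.id: r for r in reads}
    for c in clusters:
        select_representative(c, read_map, scheme)
    return clusters


def select_representative(cluster: Cluster, reads: dict[str, CloneRead],
                          scheme: ScoringScheme | None = None) -> str:
    """Pick the member whose insert extends furthest in the 5' direction.

    Members are anchored pairwise to the lexicographically smallest member;
    the anchored 5'-end offset decides (ties: longest insert, then smallest
    id).  Unanchorable members stay in the cluster but never win.
    """
    if not cluster.members:
        raise ValueError("empty cluster")
    scheme = scheme or ScoringScheme()
    anchor_id = cluster.members[0]
    anchor = reads[anchor_id].sequence
    offsets: dict[str, int] = {anchor_id: 0}
    for mid in cluster.members[1:]:
        hit = local_align(reads[mid].sequence, anchor, scheme)
        if hit.score < 30 or hit.strand != "+":
            continue  # unanchorable; excluded from representative choice
        # anchor coordinate of the member's first base, extrapolated
        offsets[mid] = hit.subject_interval[0] - hit.query_interval[0]
    cluster.offsets = offsets
    best = min(offsets,
               key=lambda m: (offsets[m], -len(reads[m].sequence), m))
    cluster.representative = best
    return best


def clusters_to_rows(clusters: list[Cluster]) -> list[dict]:
    rows = []
    for c in clusters:
        for m in c.members:
            rows.append(dict(cluster_id=c.id, member_id=m,
                             offset=c.offsets.get(m, ""),
                             is_representative=int(m == c.representative)))
    return rows
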