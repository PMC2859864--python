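"""est2genome-style spliced alignment of a transcript against genomic DNA.

The DP extends affine-gap local alignment with an intron state: a
genome-only jump of length >= ``min_intron`` costing a flat penalty, reduced
for canonical GT..AG termini.  Both orientations are tried and the best
kept; splice dinucleotides are always reported in transcription sense.
Equal-score splice placements resolve to the leftmost donor.

With ``intron_penalty`` effectively infinite the model reduces exactly to
the plain local aligner (a tested invariant).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _seq
from ._kernels import (FLAG_EOPEN, FLAG_FOPEN, P_DIAG, P_E, P_F, P_INTRON,
                       spliced_kernel)
from .alignment import ScoringScheme

CANONICAL_DONOR = "GT"
CANONICAL_ACCEPTOR = "AG"


@dataclass(frozen=True)
class SplicedParams:
    """Tunables of the spliced aligner.

    min_intron: shortest genomic jump treated as an intron (nt).
    intron_penalty: flat score cost of a GT..AG intron.
    noncanonical_extra: additional cost for non-GT..AG termini.
    """

    min_intron: int = 60
    intron_penalty: int = 40
    noncanonical_extra: int = 20
    scheme: ScoringScheme = field(default_factory=ScoringScheme)

    def __post_init__(self):
        if self.min_intron < 20:
            raise ValueError("min_intron must be >= 20")


@dataclass
class Intron:
    genome_interval: tuple[int, int]
    donor: str
    acceptor: str

    @property
    def is_canonical(self) -> bool:
        return self.donor == CANONICAL_DONOR and self.acceptor == CANONICAL_ACCEPTOR

    @property
    def length(self) -> int:
        return self.genome_interval[1] - self.genome_interval[0]


@dataclass
class ExonBlock:
    est_interval: tuple[int, int]
    genome_interval: tuple[int, int]
    matches: int = 0
    mismatches: int = 0
    gap_columns: int = 0

    @property
    def columns(self) -> int:
        return self.matches + self.mismatches + self.gap_columns


@dataclass
class SplicedAlignment:
    """Exon/intron block structure of a transcript on a genomic sequence."""

    est_id: str
    genome_id: str
    strand: str
    exons: list[ExonBlock]
    introns: list[Intron]
    score: int
    est_length: int

    @property
    def matches(self) -> int:
        return sum(b.matches for b in self.exons)

    @property
    def exon_columns(self) -> int:
        return sum(b.columns for b in self.exons)

    @property
    def identity(self) -> float:
        """Matches over exon alignment columns (gap columns included)."""
        cols = self.exon_columns
        return self.matches / cols if cols else 0.0

    @property
    def est_coverage(self) -> float:
        covered = sum(b.est_interval[1] - b.est_interval[0] for b in self.exons)
        return covered / self.est_length if self.est_length else 0.0

    def validate(self) -> None:
        """Assert block ordering and intron/exon adjacency invariants."""
        prev = None
        for blk in self.exons:
            qs, qe = blk.est_interval
            gs, ge = blk.genome_interval
            assert qs < qe and gs < ge
            if prev is not None:
                assert qs >= prev.est_interval[1]
                if self.strand == "+":
                    assert gs >= prev.genome_interval[1]
                else:
                    assert ge <= prev.genome_interval[0]
            prev = blk
        assert len(self.introns) == max(0, len(self.exons) - 1)
        for left, intron, right in zip(self.exons, self.introns, self.exons[1:]):
            if self.strand == "+":
                assert intron.genome_interval == (left.genome_interval[1],
                                                  right.genome_interval[0])
            else:
                assert intron.genome_interval == (right.genome_interval[1],
                                                  left.genome_interval[0])


def _run_one(est_arr, gen_seq: str, params: SplicedParams):
    scheme = params.scheme
    sub = scheme.substitution_matrix()
    gen_arr = _seq.encode_nuc(gen_seq)
    n = gen_arr.shape[0]
    if n > 65535:
        raise ValueError("genome region exceeds the 65.5 kb spliced-DP "
                         "window; align a smaller region")
    donor_ok = np.zeros(n + 1, dtype=np.bool_)
    acceptor_ok = np.zeros(n + 1, dtype=np.bool_)
    if n >= 2:
        is_g = gen_arr == 2
        is_t = gen_arr == 3
        is_a = gen_arr == 0
        donor_ok[:n - 1] = is_g[:-1] & is_t[1:]
        acceptor_ok[2:] = is_a[:-1] & is_g[1:]
    return spliced_kernel(est_arr, gen_arr, sub, scheme.gap_open,
                          scheme.gap_extend, params.min_intron,
                          params.intron_penalty, params.noncanonical_extra,
                          donor_ok, acceptor_ok)


def _traceback_blocks(est_arr, gen_seq, ptr, jsrc, bi, bj):
    """Walk pointers; return ordered exon blocks and intron intervals."""
    i, j = bi, bj
    state = "H"
    # collect per-block stats walking backwards
    blocks: list[ExonBlock] = []
    introns: list[tuple[int, int]] = []
    cur = ExonBlock((i, bi), (j, bj))
    cur_qe, cur_ge = bi, bj
    gen_arr = _seq.encode_nuc(gen_seq)

    def close_block(qs, gs):
        if cur_qe - qs > 0 or cur_ge - gs > 0:
            cur.est_interval = (qs, cur_qe)
            cur.genome_interval = (gs, cur_ge)
            blocks.append(replace(cur))

    while True:
        if state == "H":
            src = ptr[i, j] & 7
            if src == 0:
                break
            if src == P_DIAG:
                if est_arr[i - 1] == gen_arr[j - 1]:
                    cur.matches += 1
                else:
                    cur.mismatches += 1
                i -= 1
                j -= 1
            elif src == P_E:
                state = "E"
            elif src == P_F:
                state = "F"
            elif src == P_INTRON:
                u = j - int(jsrc[i, j])
                close_block(i, j)
                introns.append((u, j))
                j = u
                cur = ExonBlock((i, i), (j, j))
                cur_qe, cur_ge = i, j
        elif state == "E":  # consumes est (gap in genome)
            cur.gap_columns += 1
            opened = ptr[i, j] & FLAG_EOPEN
            i -= 1
            if opened:
                state = "H"
        else:               # consumes genome (gap in est)
            cur.gap_columns += 1
            opened = ptr[i, j] & FLAG_FOPEN
            j -= 1
            if opened:
                state = "H"
    close_block(i, j)
    blocks.reverse()
    introns.reverse()
    return blocks, introns


def spliced_align(est: str, genome_region: str,
                  params: SplicedParams | None = None,
                  est_id: str = "est", genome_id: str = "genome",
                  strands: str = "both") -> SplicedAlignment:
    """Best spliced local alignment of ``est`` against ``genome_region``."""
    if not est or not genome_region:
        raise ValueError("empty sequence")
    params = params or SplicedParams()
    est_arr = _seq.encode_nuc(est)

    def run(gen_seq: str, strand: str):
        score, bi, bj, ptr, jsrc = _run_one(est_arr, gen_seq, params)
        return score, bi, bj, ptr, jsrc, gen_seq, strand

    results = []
    if strands in ("both", "+"):
        results.append(run(genome_region, "+"))
    if strands in ("both", "-"):
        results.append(run(_seq.revcomp(genome_region), "-"))
    score, bi, bj, ptr, jsrc, gen_seq, strand = max(
        results, key=lambda r: (r[0], r[6] == "+"))
    blocks, intron_ivals = _traceback_blocks(est_arr, gen_seq, ptr, jsrc, bi, bj)

    introns = [Intron((s, e), gen_seq[s:s + 2], gen_seq[e - 2:e])
               for s, e in intron_ivals]
    if strand == "-":
        # Blocks stay in transcript (est) order; genome intervals are mapped
        # back onto the forward axis, so they descend along the gene.  Splice
        # dinucleotides are kept as seen in the aligned (transcription-sense)
        # orientation.
        n = len(genome_region)
        for blk in blocks:
            gs, ge = blk.genome_interval
            blk.genome_interval = (n - ge, n - gs)
        for intr in introns:
            s, e = intr.genome_interval
            intr.genome_interval = (n - e, n - s)
    aln = SplicedAlignment(est_id=est_id, genome_id=genome_id, strand=strand,
                           exons=blocks, introns=introns, score=int(score),
                           est_length=len(est))
    return aln


def detect_intron_pairwise(seq_a: str, seq_b: str,
                           params: SplicedParams | None = None
                           ) -> tuple[list[Intron], list[Intron]]:
    """Bidirectional intron detection between two transcripts.

    Returns (introns in a relative to b, introns in b relative to a): each
    sequence takes the "genome" role in turn and any reported intron of
    length >= min_intron counts against it.
    """
    params = params or SplicedParams()
    in_a = spliced_align(seq_b, seq_a, params, est_id="b", genome_id="a").introns
    in_b = spliced_align(seq_a, seq_b, params, est_id="a", genome_id="b").introns
    return in_a, in_b
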