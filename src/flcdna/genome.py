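"""Transcript-to-genome mapping, gene-model statistics and SNP estimation.

A poly(A)-stripped cDNA is assigned to its best scaffold (seeded search,
E < 1e-50), spliced-aligned against the seed-covered region extended by a
12 kb margin, and accepted as full-length-mapped when identity and cDNA
coverage both reach 90% and both cDNA ends lie inside exon blocks.  Mapped
models feed exon typing (initial/internal/terminal/single), exon/intron/
gene length statistics, the placement of translation start/stop codons
relative to internal exons, alternative-splicing event classification and
the exon-restricted nucleotide-mismatch (SNP) rate against a second
genome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .alignment import db_index
from .io_formats import GffGene, ReferenceDb
from .spliced import SplicedParams, spliced_align

MAP_EVALUE = 1e-50
MAP_IDENTITY = 0.90
MAP_COVERAGE = 0.90
MAP_MARGIN = 12_000
END_ANCHOR = 20
SNP_IDENTITY_FLOOR = 0.995

EXON_TYPES = ("initial", "internal", "terminal", "single")
EVENT_TYPES = ("retained_intron", "alt_donor", "alt_acceptor", "exon_skip",
               "other")


@dataclass
class TypedExon:
    genome_interval: tuple[int, int]
    cdna_interval: tuple[int, int]
    type: str = ""

    @property
    def length(self) -> int:
        return self.genome_interval[1] - self.genome_interval[0]


@dataclass
class GeneModel:
    """A transcript mapped onto a scaffold, with typed exons."""

    cdna_id: str
    scaffold_id: str
    strand: str
    exons: list[TypedExon]                    # transcript order
    introns: list[tuple[int, int]]            # forward-axis intervals
    intron_sites: list[tuple[str, str]]       # donor/acceptor, sense
    identity: float
    coverage: float
    score: int
    exon_matches: int = 0
    exon_mismatches: int = 0
    exon_gap_columns: int = 0
    start_codon_exon_index: Optional[int] = None
    stop_codon_exon_index: Optional[int] = None

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def exon_lengths(self) -> list[int]:
        return [e.length for e in self.exons]

    def intron_lengths(self) -> list[int]:
        return [e - s for s, e in self.introns]

    @property
    def gene_span(self) -> tuple[int, int]:
        lo = min(e.genome_interval[0] for e in self.exons)
        hi = max(e.genome_interval[1] for e in self.exons)
        return lo, hi

    @property
    def gene_length(self) -> int:
        lo, hi = self.gene_span
        return hi - lo

    def validate(self) -> None:
        assert self.gene_length == (sum(self.exon_lengths())
                                    + sum(self.intron_lengths()))
        types = [e.type for e in self.exons]
        if len(types) == 1:
            assert types == ["single"]
        else:
            assert types[0] == "initial" and types[-1] == "terminal"
            assert all(t == "internal" for t in types[1:-1])

    def to_gff(self) -> GffGene:
        return GffGene(id=self.cdna_id, seqid=self.scaffold_id,
                       strand=self.strand,
                       exons=sorted(e.genome_interval for e in self.exons),
                       attributes={"exons": str(self.n_exons)})


@dataclass
class Unmapped:
    cdna_id: str
    reason: str     # no_hit | low_identity | low_coverage


MAX_DP_WINDOW = 60_000


def _pick_scaffold(body: str, scaffolds: ReferenceDb, seed_k: int = 14
                   ) -> Optional[tuple[str, int, int, str]]:
    """Best scaffold by shared-seed count, localized to the densest seed
    window (chance k-mer matches elsewhere on a scaffold must not inflate
    the DP region)."""
    idx = db_index(scaffolds, seed_k)
    seeds = idx.seed_positions(body)
    seeds = {r: v for r, v in seeds.items() if v[1] + v[2] >= 3}
    if not seeds:
        return None
    best_rid = max(sorted(seeds), key=lambda r: seeds[r][1] + seeds[r][2])
    pos, fwd, rev = seeds[best_rid]
    # densest window of bounded width (two pointers over sorted positions)
    best = (0, 0, 0)
    j = 0
    for i in range(len(pos)):
        while pos[i] - pos[j] > MAX_DP_WINDOW - idx.k:
            j += 1
        if i - j + 1 > best[0]:
            best = (i - j + 1, pos[j], pos[i] + idx.k)
    _n, lo, hi = best
    hint = "+" if fwd > 2 * rev else "-" if rev > 2 * fwd else "both"
    return best_rid, lo, hi, hint


def map_to_genome(cdna_id: str, body: str, scaffolds: ReferenceDb,
                  params: SplicedParams | None = None,
                  cds_interval: tuple[int, int] | None = None,
                  margin: int = MAP_MARGIN,
                  min_identity: float = MAP_IDENTITY,
                  min_coverage: float = MAP_COVERAGE) -> GeneModel | Unmapped:
    """Map a poly(A)-stripped cDNA onto genome scaffolds.

    Returns a typed :class:`GeneModel` when the spliced alignment reaches
    the full-length criteria (identity >= 90%, coverage >= 90%, first and
    last 20 nt inside exon blocks and hit E-value < 1e-50), otherwise
    :class:`Unmapped` with the failing reason.
    """
    params = params or SplicedParams()
    pick = _pick_scaffold(body, scaffolds)
    if pick is None:
        return Unmapped(cdna_id, "no_hit")
    rid, lo, hi, hint = pick
    scaffold = scaffolds.seq(rid)
    # the spliced DP window is capped at 65 kb (uint16 intron offsets);
    # shrink the margin symmetrically if the seed window is already wide
    margin = max(200, min(margin, (65_000 - (hi - lo)) // 2))
    assert (hi - lo) + 2 * margin <= 65_400
    off = max(0, lo - margin)
    region = scaffold[off:min(len(scaffold), hi + margin)]
    aln = spliced_align(body, region, params, est_id=cdna_id, genome_id=rid,
                        strands=hint)
    if aln.score <= 0 or not aln.exons:
        return Unmapped(cdna_id, "no_hit")
    from .alignment import cached_calibration
    lam, K = cached_calibration(params.scheme)
    log_e = (math.log10(K * len(body) * len(scaffold))
             - lam * aln.score / math.log(10))
    if log_e >= math.log10(MAP_EVALUE):
        return Unmapped(cdna_id, "no_hit")
    if aln.identity < min_identity:
        return Unmapped(cdna_id, "low_identity")
    covered = sorted(b.est_interval for b in aln.exons)
    anchored = (covered[0][0] <= END_ANCHOR
                and covered[-1][1] >= len(body) - END_ANCHOR)
    if aln.est_coverage < min_coverage or not anchored:
        return Unmapped(cdna_id, "low_coverage")
    exons = [TypedExon((b.genome_interval[0] + off, b.genome_interval[1] + off),
                       b.est_interval) for b in aln.exons]
    introns = [(i.genome_interval[0] + off, i.genome_interval[1] + off)
               for i in aln.introns]
    model = GeneModel(
        cdna_id=cdna_id, scaffold_id=rid, strand=aln.strand, exons=exons,
        introns=introns,
        intron_sites=[(i.donor, i.acceptor) for i in aln.introns],
        identity=aln.identity, coverage=aln.est_coverage, score=aln.score,
        exon_matches=aln.matches,
        exon_mismatches=sum(b.mismatches for b in aln.exons),
        exon_gap_columns=sum(b.gap_columns for b in aln.exons))
    classify_exons(model)
    if cds_interval is not None:
        model.start_codon_exon_index = _locate(model, cds_interval[0])
        model.stop_codon_exon_index = _locate(model, cds_interval[1] - 3)
    model.validate()
    return model


def _locate(model: GeneModel, cdna_pos: int) -> Optional[int]:
    for i, e in enumerate(model.exons):
        if e.cdna_interval[0] <= cdna_pos < e.cdna_interval[1]:
            return i
    return None


def classify_exons(model: GeneModel) -> GeneModel:
    """Assign initial/internal/terminal/single types in transcript sense."""
    n = len(model.exons)
    for i, e in enumerate(model.exons):
        if n == 1:
            e.type = "single"
        elif i == 0:
            e.type = "initial"
        elif i == n - 1:
            e.type = "terminal"
        else:
            e.type = "internal"
    return model


# ---------------------------------------------------------------------------
# statistics over mapped models
# ---------------------------------------------------------------------------

def exon_intron_stats(models: Sequence[GeneModel]) -> dict:
    """Exon-count, exon/intron/gene length summaries (+ per exon type)."""
    if not models:
        raise ValueError("no mapped models")
    exon_counts = [m.n_exons for m in models]
    exon_lens = [l for m in models for l in m.exon_lengths()]
    intron_lens = [l for m in models for l in m.intron_lengths()]
    gene_lens = [m.gene_length for m in models]
    by_type: dict[str, list[int]] = {t: [] for t in EXON_TYPES}
    for m in models:
        for e in m.exons:
            by_type[e.type].append(e.length)
    out = {
        "n_models": len(models),
        "exons_per_gene_mean": float(np.mean(exon_counts)),
        "exons_per_gene_median": float(np.median(exon_counts)),
        "exon_len_mean": float(np.mean(exon_lens)),
        "exon_len_median": float(np.median(exon_lens)),
        "gene_len_mean": float(np.mean(gene_lens)),
        "gene_len_median": float(np.median(gene_lens)),
        "n_exons": len(exon_lens),
        "n_introns": len(intron_lens),
    }
    if intron_lens:
        out["intron_len_mean"] = float(np.mean(intron_lens))
        out["intron_len_median"] = float(np.median(intron_lens))
    for t in EXON_TYPES:
        if by_type[t]:
            out[f"exon_{t}_median"] = float(np.median(by_type[t]))
            out[f"exon_{t}_n"] = len(by_type[t])
    return out


def utr_intron_occurrence(models: Sequence[GeneModel]) -> tuple[float, float]:
    """Fraction of models whose start / stop codon sits in an internal exon.

    Models must carry mapped translation sites; single- and two-exon models
    contribute to denominators but can never hit an internal exon.
    """
    usable = [m for m in models if m.start_codon_exon_index is not None
              and m.stop_codon_exon_index is not None]
    if not usable:
        raise ValueError("no models with mapped translation sites")
    start_in = sum(1 for m in usable
                   if m.exons[m.start_codon_exon_index].type == "internal")
    stop_in = sum(1 for m in usable
                  if m.exons[m.stop_codon_exon_index].type == "internal")
    return start_in / len(usable), stop_in / len(usable)


# ---------------------------------------------------------------------------
# alternative-splicing event classification
# ---------------------------------------------------------------------------

@dataclass
class SpliceEvent:
    pair: tuple[str, str]
    type: str
    locus: tuple[int, int]

    def __post_init__(self):
        assert self.type in EVENT_TYPES


def _sense_introns(model: GeneModel) -> list[tuple[int, int]]:
    return sorted(model.introns)


def classify_splice_events(model_a: GeneModel, model_b: GeneModel
                           ) -> list[SpliceEvent]:
    """Classify the structural differences between two overlapping models.

    Per difference: retained_intron when one model's exon fully spans the
    other's intron; alt_acceptor / alt_donor when an intron pair shares one
    boundary (donor = 5' end in transcription sense); exon_skip when an
    internal exon of one model has no overlapping exon in the other while
    its flanking exons are shared; anything else is ``other``.  One pair
    may yield several events.
    """
    if (model_a.scaffold_id != model_b.scaffold_id
            or model_a.strand != model_b.strand):
        return []
    span_a, span_b = model_a.gene_span, model_b.gene_span
    if min(span_a[1], span_b[1]) <= max(span_a[0], span_b[0]):
        return []
    pair = (model_a.cdna_id, model_b.cdna_id)
    strand = model_a.strand
    events: list[SpliceEvent] = []
    handled: set[tuple] = set()

    def exon_ivals(m):
        return sorted(e.genome_interval for e in m.exons)

    for first, second in ((model_a, model_b), (model_b, model_a)):
        ex_first = exon_ivals(first)
        ex_second = exon_ivals(second)
        introns_second = _sense_introns(second)
        bounds_first = {p for iv in ex_first for p in iv}
        bounds_second = {p for iv in ex_second for p in iv}
        # retained introns: an exon of `first` spans an intron of `second`
        for s, e in introns_second:
            key = ("ri", s, e)
            if key in handled:
                continue
            for xs, xe in ex_first:
                if xs < s and xe > e and s not in bounds_first \
                        and e not in bounds_first:
                    events.append(SpliceEvent(pair, "retained_intron", (s, e)))
                    handled.add(key)
                    break
        # alternative donors/acceptors: intron pairs sharing one boundary
        introns_first = _sense_introns(first)
        for s1, e1 in introns_first:
            for s2, e2 in introns_second:
                if (s1, e1) == (s2, e2):
                    continue
                if max(s1, s2) >= min(e1, e2):
                    continue
                key = ("alt", min(s1, s2), max(e1, e2))
                if key in handled:
                    continue
                shared_left = s1 == s2
                shared_right = e1 == e2
                if shared_left != shared_right:
                    if shared_left:
                        diff = (min(e1, e2), max(e1, e2))
                    else:
                        diff = (min(s1, s2), max(s1, s2))
                    # a whole exon inside the differing region means the
                    # introns differ by exon skipping, not by a shifted
                    # splice site
                    if any(diff[0] <= xs and xe <= diff[1]
                           for xs, xe in ex_first + ex_second):
                        continue
                    # left genome boundary is the donor on '+', acceptor on '-'
                    if shared_left:
                        etype = "alt_acceptor" if strand == "+" else "alt_donor"
                    else:
                        etype = "alt_donor" if strand == "+" else "alt_acceptor"
                    events.append(SpliceEvent(
                        pair, etype, (min(s1, s2), max(e1, e2))))
                    handled.add(key)
        # exon skipping: internal exon of `first` absent from `second`
        for i in range(1, len(ex_first) - 1):
            xs, xe = ex_first[i]
            key = ("skip", xs, xe)
            if key in handled:
                continue
            overlaps = any(max(xs, s) < min(xe, e) for s, e in ex_second)
            if overlaps:
                continue
            intron_cover = any(s < xs and e > xe for s, e in introns_second)
            flank_ok = (ex_first[i - 1][1] in bounds_second
                        and ex_first[i + 1][0] in bounds_second)
            if intron_cover and flank_ok:
                events.append(SpliceEvent(pair, "exon_skip", (xs, xe)))
                handled.add(key)
    # any residual structural difference beyond the recognized classes
    if not events:
        a_set = {e.genome_interval for e in model_a.exons}
        b_set = {e.genome_interval for e in model_b.exons}
        if a_set != b_set:
            lo = min(span_a[0], span_b[0])
            hi = max(span_a[1], span_b[1])
            events.append(SpliceEvent(pair, "other", (lo, hi)))
    return events


# ---------------------------------------------------------------------------
# SNP-rate estimation
# ---------------------------------------------------------------------------

@dataclass
class SnpEstimate:
    pairs_used: int
    mismatches: int
    aligned_exon_bases: int

    @property
    def rate(self) -> float:
        if self.aligned_exon_bases == 0:
            raise ZeroDivisionError("no aligned exon bases")
        return self.mismatches / self.aligned_exon_bases

    @property
    def rate_percent(self) -> float:
        return 100.0 * self.rate

    @property
    def nt_per_difference(self) -> float:
        if self.mismatches == 0:
            return math.inf
        return self.aligned_exon_bases / self.mismatches


def estimate_snp_rate(models: Sequence[GeneModel],
                      identity_floor: float = SNP_IDENTITY_FLOOR
                      ) -> SnpEstimate:
    """Exon-restricted substitution rate over mapped cDNA-scaffold pairs.

    Only pairs with overall exon identity >= ``identity_floor`` contribute;
    the numerator counts substitution columns inside exon blocks, the
    denominator aligned non-gap exon columns (indel columns excluded from
    both).
    """
    pairs = mism = bases = 0
    for m in models:
        ident_cols = m.exon_matches + m.exon_mismatches
        if ident_cols == 0:
            continue
        if m.exon_matches / ident_cols < identity_floor:
            continue
        pairs += 1
        mism += m.exon_mismatches
        bases += ident_cols
    if bases == 0:
        raise ZeroDivisionError("no qualifying pairs: SNP rate undefined")
    return SnpEstimate(pairs_used=pairs, mismatches=mism,
                       aligned_exon_bases=bases)


# ---------------------------------------------------------------------------
# truth-backed model construction (for generator-scale statistics)
# ---------------------------------------------------------------------------

def model_from_truth(gene, transcript=None) -> GeneModel:
    """Build a GeneModel directly from simulator truth coordinates."""
    exons_local = gene.exons_local if transcript is None \
        else transcript.exons_local
    ivs = [gene._to_scaffold(iv) for iv in exons_local]
    cum = 0
    exons = []
    for (ls, le), giv in zip(exons_local, ivs):
        exons.append(TypedExon(giv, (cum, cum + (le - ls))))
        cum += le - ls
    introns = []
    for left, right in zip(exons, exons[1:]):
        a = sorted([left.genome_interval, right.genome_interval])
        introns.append((a[0][1], a[1][0]))
    cds = (gene.utr5_len, gene.utr5_len + gene.cds_len) \
        if transcript is None or transcript.event is None else None
    model = GeneModel(
        cdna_id=(transcript.id if transcript is not None else gene.id),
        scaffold_id=gene.scaffold_id, strand=gene.strand, exons=exons,
        introns=introns, intron_sites=[("GT", "AG")] * len(introns),
        identity=1.0, coverage=1.0, score=cum,
        exon_matches=cum)
    classify_exons(model)
    if cds is not None:
        model.start_codon_exon_index = _locate(model, cds[0])
        model.stop_codon_exon_index = _locate(model, cds[1] - 3)
    model.validate()
    return model
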