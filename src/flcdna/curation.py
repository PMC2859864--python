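"""The non-redundant full-length cDNA filter cascade.

Finished cDNAs (HTCs) pass, in fixed order, through: redundancy collapse,
ncRNA filter, pathogen filter with host-rescue, chimeric-clone detection
and retained-intron flagging.  A sequence removed by an earlier stage is
never tested by later ones, and an audit ledger records in = kept + removed
for every stage.

Thresholds default to the study criteria they implement: redundancy pairs
need E < 1e-180, BLAST identity >= 97% and an alignment spanning >= 80% of
both sequences; ncRNA hits E <= 1e-180; pathogen hits E < 1e-30 unless a
host transcript matches with a strictly smaller E; chimera candidates need
two unigene hits (E < 1e-50) with different functional descriptions on
essentially disjoint query regions, confirmed by a two-scaffold match or a
BamHI/XhoI site between the matched regions; retained introns come from
bidirectional spliced alignment within E < 1e-50 similarity groups.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field

from .alignment import AlignmentHit, ScoringScheme, local_align, search
from .io_formats import ReferenceDb
from .spliced import SplicedParams, spliced_align

log = logging.getLogger(__name__)

FLAGS = ("redundant", "ncRNA", "pathogen", "chimera", "retained_intron",
         "no_cds", "partial_cds", "nrFLcDNA")

ENZYME_SITES = ("GGATCC", "CTCGAG")


@dataclass
class Htc:
    """A finished full-length cDNA with its curation audit trail."""

    id: str
    sequence: str
    flags: list[str] = field(default_factory=list)
    evidence: dict[str, object] = field(default_factory=dict)

    def flag(self, name: str, evidence=None) -> None:
        if name not in FLAGS:
            raise ValueError(f"unknown flag {name!r}")
        if name not in self.flags:
            self.flags.append(name)
        if evidence is not None:
            self.evidence[name] = evidence

    @property
    def disposition(self) -> str:
        return self.flags[-1] if self.flags else "unprocessed"

    def __len__(self):
        return len(self.sequence)


@dataclass
class CurationThresholds:
    redundancy_evalue: float = 1e-180
    redundancy_identity: float = 0.97
    redundancy_coverage: float = 0.80
    ncrna_evalue: float = 1e-180
    pathogen_evalue: float = 1e-30
    chimera_evalue: float = 1e-50
    group_evalue: float = 1e-50
    chimera_overlap_frac: float = 0.20
    max_group_members: int = 12


# ---------------------------------------------------------------------------
# redundancy
# ---------------------------------------------------------------------------

def _redundant_pair(hit: AlignmentHit, len_a: int, len_b: int,
                    thr: CurationThresholds) -> bool:
    span_q = hit.query_interval[1] - hit.query_interval[0]
    span_s = hit.subject_interval[1] - hit.subject_interval[0]
    return (hit.log10_evalue < math.log10(thr.redundancy_evalue)
            and hit.identity_blast >= thr.redundancy_identity
            and span_q / len_a >= thr.redundancy_coverage
            and span_s / len_b >= thr.redundancy_coverage)


def remove_redundant(htcs: list[Htc],
                     thr: CurationThresholds | None = None,
                     scheme: ScoringScheme | None = None
                     ) -> tuple[list[Htc], list[list[str]]]:
    """Collapse redundant HTC components; keep the longest member.

    Pairs meeting all three criteria (coverage tested against both lengths)
    link; connected components collapse to their longest member (smallest id
    on ties).  A post-condition re-check asserts no kept pair still links.
    """
    if not htcs:
        raise ValueError("no HTCs")
    thr = thr or CurationThresholds()
    scheme = scheme or ScoringScheme()
    htcs = sorted(htcs, key=lambda h: h.id)
    db = ReferenceDb("htc", "transcript",
                     {h.id: (h.sequence, "") for h in htcs})
    by_id = {h.id: h for h in htcs}
    parent = {h.id: h.id for h in htcs}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    # linking is symmetric and transitive: align each candidate pair at most
    # once, and skip pairs already joined through earlier links
    from .alignment import db_index, local_align as _local_align
    idx = db_index(db, 12)
    seen: set[str] = set()
    for h in htcs:
        seen.add(h.id)
        cands = idx.candidates(h.sequence, min_shared=4)
        for rid in sorted(cands):
            if rid in seen:
                continue
            other = by_id[rid]
            if find(h.id) == find(other.id):
                continue
            hint = cands[rid][2]
            hit = _local_align(h.sequence, other.sequence, scheme,
                               query_id=h.id, subject_id=rid, strands=hint)
            if _redundant_pair(hit, len(h), len(other), thr):
                parent[find(other.id)] = find(h.id)

    groups: dict[str, list[Htc]] = {}
    for h in htcs:
        groups.setdefault(find(h.id), []).append(h)
    kept: list[Htc] = []
    components: list[list[str]] = []
    for members in groups.values():
        members.sort(key=lambda h: (-len(h), h.id))
        keep = members[0]
        kept.append(keep)
        components.append([m.id for m in members])
        for m in members[1:]:
            m.flag("redundant", {"kept": keep.id})
    kept.sort(key=lambda h: h.id)
    # post-condition: no kept pair still meets the redundancy criteria
    kept_db = ReferenceDb("kept", "transcript",
                          {h.id: (h.sequence, "") for h in kept})
    kept_by_id = {h.id: h for h in kept}
    seen = set()
    for h in kept:
        seen.add(h.id)
        for hit in search(h.sequence, kept_db, scheme, max_evalue=1e-100,
                          query_id=h.id, exclude=seen):
            if _redundant_pair(hit, len(h), len(kept_by_id[hit.subject_id]),
                               thr):
                raise AssertionError(
                    f"redundancy re-check failed for {h.id}/{hit.subject_id}")
    return kept, components


# ---------------------------------------------------------------------------
# contaminant filters
# ---------------------------------------------------------------------------

def flag_ncrna(htc: Htc, ncrna_db: ReferenceDb,
               thr: CurationThresholds | None = None,
               scheme: ScoringScheme | None = None) -> bool:
    """True iff the best ncRNA hit has E <= the ncRNA threshold."""
    thr = thr or CurationThresholds()
    if len(ncrna_db) == 0:
        log.warning("empty ncRNA database; nothing flagged")
        return False
    hits = search(htc.sequence, ncrna_db, scheme,
                  max_evalue=thr.ncrna_evalue, query_id=htc.id)
    if hits:
        htc.flag("ncRNA", {"hit": hits[0].subject_id,
                           "log10_evalue": hits[0].log10_evalue})
        return True
    return False


def flag_pathogen(htc: Htc, pathogen_db: ReferenceDb, host_db: ReferenceDb,
                  thr: CurationThresholds | None = None,
                  scheme: ScoringScheme | None = None) -> bool:
    """Pathogen hit below threshold, unless rescued by a better host hit.

    A sequence matching a pathogen record at E < 1e-30 is still treated as
    host-derived when a host transcript matches with strictly smaller E.
    """
    thr = thr or CurationThresholds()
    p_hits = search(htc.sequence, pathogen_db, scheme,
                    max_evalue=thr.pathogen_evalue, query_id=htc.id)
    p_hits = [h for h in p_hits
              if h.log10_evalue < math.log10(thr.pathogen_evalue)]
    if not p_hits:
        return False
    h_hits = search(htc.sequence, host_db, scheme, max_evalue=10.0,
                    query_id=htc.id)
    if h_hits and h_hits[0].log10_evalue <= p_hits[0].log10_evalue:
        return False  # rescued: host explains the sequence at least as well
    htc.flag("pathogen", {"hit": p_hits[0].subject_id,
                          "log10_evalue": p_hits[0].log10_evalue})
    return True


# ---------------------------------------------------------------------------
# chimera detection
# ---------------------------------------------------------------------------

_DESC_DROP = {"putative", "predicted", "like", "family", "protein"}


def _normalize_description(desc: str) -> frozenset[str]:
    tokens = re.sub(r"[^\w\s]", " ", desc.casefold()).split()
    return frozenset(t for t in tokens if t not in _DESC_DROP)


def descriptions_differ(a: str, b: str) -> bool:
    """Different iff neither normalized token set contains the other."""
    ta, tb = _normalize_description(a), _normalize_description(b)
    return not (ta <= tb or tb <= ta)


def _disjoint(iv_a, iv_b, max_overlap_frac: float) -> bool:
    ov = max(0, min(iv_a[1], iv_b[1]) - max(iv_a[0], iv_b[0]))
    shorter = min(iv_a[1] - iv_a[0], iv_b[1] - iv_b[0])
    return shorter > 0 and ov < max_overlap_frac * shorter


def flag_chimera(htc: Htc, unigene_db: ReferenceDb, genome_db: ReferenceDb,
                 thr: CurationThresholds | None = None,
                 scheme: ScoringScheme | None = None,
                 enzyme_sites=ENZYME_SITES) -> tuple[bool, str]:
    """Detect cloning chimeras; returns (is_chimera, rule_fired).

    Candidate: two or more unigene hits with different functional
    descriptions whose query regions are essentially disjoint.  Confirmed
    when the two regions match distinct genome scaffolds, or a BamHI/XhoI
    site lies strictly between them.  rule_fired is scaffold | enzyme_site
    | none.
    """
    thr = thr or CurationThresholds()
    hits = search(htc.sequence, unigene_db, scheme,
                  max_evalue=thr.chimera_evalue, query_id=htc.id)
    if hits and not any(h.subject_description for h in hits):
        log.warning("unigene db lacks descriptions; chimera candidates "
                    "cannot form")
    pair = None
    for i in range(len(hits)):
        for j in range(i + 1, len(hits)):
            a, b = hits[i], hits[j]
            if (descriptions_differ(a.subject_description,
                                    b.subject_description)
                    and _disjoint(a.query_interval, b.query_interval,
                                  thr.chimera_overlap_frac)):
                pair = (a, b) if a.query_interval <= b.query_interval else (b, a)
                break
        if pair:
            break
    if pair is None:
        return False, "none"
    left, right = pair
    # rule 1: the two halves land on distinct scaffolds
    scaffolds: dict[str, str] = {}
    for part, iv in (("left", left.query_interval),
                     ("right", right.query_interval)):
        sub = htc.sequence[iv[0]:iv[1]]
        g_hits = search(sub, genome_db, scheme, max_evalue=thr.chimera_evalue,
                        query_id=f"{htc.id}:{part}", clip_margin=2000)
        if g_hits:
            scaffolds[part] = g_hits[0].subject_id
    if len(scaffolds) == 2 and scaffolds["left"] != scaffolds["right"]:
        htc.flag("chimera", {"rule": "scaffold", "scaffolds": scaffolds,
                             "unigenes": (left.subject_id, right.subject_id)})
        return True, "scaffold"
    # rule 2: a ligation site between the matched regions; the window is
    # padded a few nt because alignment ends can absorb part of the site
    lo, hi = left.query_interval[1], right.query_interval[0]
    if lo < hi:
        between = htc.sequence[max(0, lo - 5):hi + 5]
        for site in enzyme_sites:
            if site in between:
                htc.flag("chimera", {"rule": "enzyme_site", "site": site,
                                     "unigenes": (left.subject_id,
                                                  right.subject_id)})
                return True, "enzyme_site"
    return False, "none"


# ---------------------------------------------------------------------------
# retained introns
# ---------------------------------------------------------------------------

def flag_retained_intron(htc: Htc, companion_db: ReferenceDb,
                         thr: CurationThresholds | None = None,
                         params: SplicedParams | None = None) -> bool:
    """True iff any similar companion reveals an intron inside the HTC.

    Companions (E < 1e-50 similarity group) take the "est" role and the
    candidate the "genome" role; a reported intron of length >= min_intron
    flags the candidate.  Singleton groups are never flagged.
    """
    thr = thr or CurationThresholds()
    params = params or SplicedParams()
    hits = search(htc.sequence, companion_db, params.scheme,
                  max_evalue=thr.group_evalue, query_id=htc.id,
                  exclude={htc.id})
    for hit in hits[:thr.max_group_members]:
        member_seq = companion_db.seq(hit.subject_id)
        if member_seq == htc.sequence:
            continue
        aln = spliced_align(member_seq, htc.sequence, params,
                            est_id=hit.subject_id, genome_id=htc.id,
                            strands=hit.strand)
        # only canonical GT..AG introns count: a skipped exon in the
        # companion also shows up as a genomic insertion in the candidate,
        # but without spliceosomal termini
        introns = [i for i in aln.introns
                   if i.length >= params.min_intron and i.is_canonical]
        if introns:
            htc.flag("retained_intron",
                     {"companion": hit.subject_id,
                      "introns": [i.genome_interval for i in introns]})
            return True
    return False


# ---------------------------------------------------------------------------
# the cascade
# ---------------------------------------------------------------------------

@dataclass
class LedgerRow:
    stage: str
    n_in: int
    n_removed: int
    n_kept: int

    def check(self) -> None:
        assert self.n_in == self.n_removed + self.n_kept, self


@dataclass
class CurationResult:
    kept: list[Htc]
    all_htcs: list[Htc]
    ledger: list[LedgerRow]
    redundancy_groups: list[list[str]]

    def dispositions(self) -> dict[str, str]:
        return {h.id: h.disposition for h in self.all_htcs}


def run_curation(htcs: list[Htc], *, ncrna_db: ReferenceDb,
                 pathogen_db: ReferenceDb, host_db: ReferenceDb,
                 unigene_db: ReferenceDb, genome_db: ReferenceDb,
                 thresholds: CurationThresholds | None = None,
                 scheme: ScoringScheme | None = None,
                 spliced_params: SplicedParams | None = None
                 ) -> CurationResult:
    """Apply the full filter cascade in fixed order with ledger accounting.

    Order: redundancy -> ncRNA -> pathogen -> chimera -> retained intron.
    Survivors are flagged nrFLcDNA candidates (the CDS check is a separate
    stage); every stage satisfies in = kept + removed exactly.
    """
    thr = thresholds or CurationThresholds()
    ledger: list[LedgerRow] = []
    if not htcs:
        return CurationResult([], [], ledger, [])
    all_htcs = list(htcs)

    kept, groups = remove_redundant(htcs, thr, scheme)
    ledger.append(LedgerRow("redundancy", len(htcs),
                            len(htcs) - len(kept), len(kept)))

    survivors = []
    removed = 0
    for h in kept:
        if flag_ncrna(h, ncrna_db, thr, scheme):
            removed += 1
        else:
            survivors.append(h)
    ledger.append(LedgerRow("ncRNA", len(kept), removed, len(survivors)))
    kept = survivors

    survivors, removed = [], 0
    for h in kept:
        if flag_pathogen(h, pathogen_db, host_db, thr, scheme):
            removed += 1
        else:
            survivors.append(h)
    ledger.append(LedgerRow("pathogen", len(kept), removed, len(survivors)))
    kept = survivors

    survivors, removed = [], 0
    for h in kept:
        is_chim, _rule = flag_chimera(h, unigene_db, genome_db, thr, scheme)
        if is_chim:
            removed += 1
        else:
            survivors.append(h)
    ledger.append(LedgerRow("chimera", len(kept), removed, len(survivors)))
    kept = survivors

    companion = ReferenceDb(
        "companion", "transcript",
        {**{h.id: (h.sequence, "") for h in kept},
         **{rid: unigene_db.records[rid] for rid in unigene_db.ids()}})
    survivors, removed = [], 0
    for h in kept:
        if flag_retained_intron(h, companion, thr, spliced_params):
            removed += 1
        else:
            survivors.append(h)
    ledger.append(LedgerRow("retained_intron", len(kept), removed,
                            len(survivors)))
    for h in survivors:
        h.flag("nrFLcDNA")
    for row in ledger:
        row.check()
    return CurationResult(survivors, all_htcs, ledger, groups)
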