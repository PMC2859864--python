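"""ORF enumeration, homology-guided CDS selection, UTR and composition.

CDS prediction follows a two-step cascade: enumerate every sense-strand ORF
(ATG..in-frame-stop complete ORFs plus end-open partials), then rank
candidates by protein homology (E < 1e-10 against a protein database),
preferring the best-E candidate whose protein is full length; without any
hit the longest ORF wins.  Proteins shorter than 10 aa are never selected.
The stop codon is counted inside the CDS interval; the protein excludes it
(so a 938 bp mean CDS corresponds to a 313 aa mean polypeptide, stop
included in the nucleotide length only).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from ._seq import STOP_CODONS, translate
from .alignment import ScoringScheme, search
from .io_formats import ReferenceDb

MIN_PROTEIN_AA = 10
PROTEIN_EVALUE = 1e-10
MAX_CANDIDATES = 20
POLYA_MIN_LEN = 10
POLYA_MIN_FRAC = 0.90


def strip_polya(seq: str) -> tuple[str, tuple[int, int]]:
    """Remove the poly(A) tail; returns (body, tail interval).

    The tail is the longest suffix of length >= 10 that starts with A and is
    >= 90% A; the empty interval (n, n) means no tail qualified.
    """
    n = len(seq)
    best = 0
    a_count = 0
    for k in range(1, n + 1):
        if seq[n - k] == "A":
            a_count += 1
            if k >= POLYA_MIN_LEN and a_count >= POLYA_MIN_FRAC * k:
                best = k
    return seq[:n - best], (n - best, n)


@dataclass
class OrfCandidate:
    interval: tuple[int, int]   # 0-based half-open on the cDNA body
    frame: int                  # 0-2
    has_start: bool
    has_stop: bool
    protein: str

    @property
    def aa_len(self) -> int:
        return len(self.protein)


def find_orfs(seq: str, include_partial: bool = True) -> list[OrfCandidate]:
    """Enumerate sense-strand ORFs in all three frames.

    Complete ORFs run ATG..stop (every ATG starts its own candidate,
    nested ones included).  With ``include_partial``, frames also yield
    end-open candidates (ATG without a downstream stop, or a stop-bounded
    5'-open segment), which is how 5'/3'-truncated CDSs surface.  Sorted by
    protein length descending (ties: leftmost, then frame).
    """
    orfs: list[OrfCandidate] = []
    n = len(seq)
    for frame in range(3):
        stops = [p for p in range(frame, n - 2, 3)
                 if seq[p:p + 3] in STOP_CODONS]
        seg_start = frame
        bounds = [(s, True) for s in stops] + [(n - (n - frame) % 3, False)]
        prev = frame
        for stop_pos, is_stop in bounds:
            seg_end = stop_pos + 3 if is_stop else stop_pos
            atgs = [p for p in range(prev, stop_pos, 3)
                    if seq[p:p + 3] == "ATG"]
            for a in atgs:
                prot = translate(seq[a:seg_end])
                orfs.append(OrfCandidate((a, seg_end), frame,
                                         True, is_stop, prot))
            if (include_partial and not atgs and prev == frame
                    and prev < stop_pos):
                # 5'-open leading segment: CDS truncated upstream of the ATG
                prot = translate(seq[prev:seg_end])
                if prot:
                    orfs.append(OrfCandidate((prev, seg_end), frame,
                                             False, is_stop, prot))
            prev = stop_pos + 3
    if not include_partial:
        orfs = [o for o in orfs if o.has_start and o.has_stop]
    orfs.sort(key=lambda o: (-o.aa_len, not (o.has_start and o.has_stop),
                             not o.has_start, o.interval[0], o.frame))
    return orfs


@dataclass
class CdsAnnotation:
    cdna_id: str
    cds_interval: Optional[tuple[int, int]]
    frame: Optional[int]
    protein: str
    has_start: bool
    has_stop: bool
    completeness: str            # full_length | partial | none
    selection_basis: str         # homology | longest_orf | none
    best_log10_evalue: Optional[float] = None

    def validate(self, body: str) -> None:
        if self.cds_interval is None:
            assert self.completeness == "none"
            return
        s, e = self.cds_interval
        cds = body[s:e]
        if self.has_stop:
            assert (e - s) % 3 == 0
            assert cds[-3:] in STOP_CODONS
        assert self.has_start == cds.startswith("ATG")
        assert translate(cds) == self.protein
        assert (self.completeness == "full_length") == (
            self.has_start and self.has_stop)


def select_cds(cdna_id: str, body: str, orfs: list[OrfCandidate],
               protein_db: ReferenceDb | None,
               scheme: ScoringScheme | None = None) -> CdsAnnotation:
    """Homology-ranked CDS choice among enumerated ORFs.

    Candidates (longest 20, proteins >= 10 aa) are searched against the
    protein database at E < 1e-10.  The full-length candidate with the
    smallest E wins; if the best-E candidate is not full length the
    E-ranked order falls through to the first full-length one (none
    full-length: the best-E candidate itself).  No hits, an all-tie, or an
    empty database fall back to the longest ORF.
    """
    scheme = scheme or ScoringScheme.protein_default()
    cands = [o for o in orfs if o.aa_len >= MIN_PROTEIN_AA][:MAX_CANDIDATES]
    if not cands:
        return CdsAnnotation(cdna_id, None, None, "", False, False,
                             "none", "none")

    def annotate(o: OrfCandidate, basis: str, log_e=None) -> CdsAnnotation:
        return CdsAnnotation(
            cdna_id, o.interval, o.frame, o.protein, o.has_start, o.has_stop,
            ("full_length" if o.has_start and o.has_stop
             else "partial"), basis, log_e)

    ranked: list[tuple[float, int, OrfCandidate]] = []
    if protein_db is not None and len(protein_db) > 0:
        for idx, o in enumerate(cands):
            # seeded mode: candidate proteins without any shared peptide
            # 4-mers cannot reach E < 1e-10 against ~full-length proteins
            hits = search(o.protein, protein_db, scheme,
                          max_evalue=PROTEIN_EVALUE,
                          query_id=f"{cdna_id}|orf{idx}", mode="seeded")
            if hits:
                ranked.append((hits[0].log10_evalue, idx, o))
    if ranked:
        ranked.sort(key=lambda t: (t[0], t[1]))
        tied = {round(e, 6) for e, _, _ in ranked}
        if len(tied) == 1 and len(ranked) > 1:
            # all candidate E-values equal: take the longest of the tied set
            o = max((o for _, _, o in ranked),
                    key=lambda o: (o.aa_len, -o.interval[0]))
            return annotate(o, "homology", ranked[0][0])
        for log_e, _, o in ranked:
            if o.has_start and o.has_stop:
                return annotate(o, "homology", log_e)
        log_e, _, o = ranked[0]
        return annotate(o, "homology", log_e)
    # no informative homology: longest complete ORF; end-open partial
    # candidates are a last resort (a frame with no stop codon almost always
    # out-lengths the real CDS by a few residues and would shadow it)
    complete = [o for o in cands if o.has_start and o.has_stop]
    return annotate((complete or cands)[0], "longest_orf")


def classify_completeness(ann: CdsAnnotation) -> str:
    if ann.cds_interval is None:
        return "none"
    return "full_length" if ann.has_start and ann.has_stop else "partial"


@dataclass
class UtrAnnotation:
    utr5_interval: tuple[int, int]
    utr3_interval: tuple[int, int]
    polya_interval: tuple[int, int]

    @property
    def utr5_len(self) -> int:
        return self.utr5_interval[1] - self.utr5_interval[0]

    @property
    def utr3_len(self) -> int:
        return self.utr3_interval[1] - self.utr3_interval[0]

    @property
    def polya_len(self) -> int:
        return self.polya_interval[1] - self.polya_interval[0]


def extract_utrs(cdna: str, ann: CdsAnnotation,
                 polya_interval: tuple[int, int] | None = None
                 ) -> UtrAnnotation:
    """UTRs from a full-length CDS: 5'-UTR before ATG, 3'-UTR after the
    stop up to the poly(A) tail.  utr5+cds+utr3+polyA partition the cDNA."""
    if ann.completeness != "full_length":
        raise ValueError("UTRs are defined only for full-length CDSs")
    if polya_interval is None:
        _, polya_interval = strip_polya(cdna)
    s, e = ann.cds_interval
    utr = UtrAnnotation(utr5_interval=(0, s),
                        utr3_interval=(e, polya_interval[0]),
                        polya_interval=polya_interval)
    total = (utr.utr5_len + (e - s) + utr.utr3_len + utr.polya_len)
    assert total == len(cdna), "partition identity violated"
    return utr


# ---------------------------------------------------------------------------
# composition and summary statistics
# ---------------------------------------------------------------------------

def composition(regions: Sequence[str]) -> dict[str, float]:
    """A/T/G/C percentages over a set of region strings.

    N and X are tallied separately and excluded from the four-way
    denominator; the four percentages sum to 100 up to rounding.
    """
    counts = {c: 0 for c in "ATGCNX"}
    for seq in regions:
        for c in "ATGCNX":
            counts[c] += seq.count(c)
    denom = sum(counts[c] for c in "ATGC")
    out = {c: (100.0 * counts[c] / denom if denom else 0.0) for c in "ATGC"}
    out["N"] = counts["N"]
    out["X"] = counts["X"]
    return out


def stop_codon_usage(stop_codons: Sequence[str]) -> dict[str, float]:
    """Percentage usage of TGA/TAA/TAG among full-length CDSs."""
    n = len(stop_codons)
    if n == 0:
        return {c: 0.0 for c in STOP_CODONS}
    bad = set(stop_codons) - set(STOP_CODONS)
    if bad:
        raise ValueError(f"not stop codons: {sorted(bad)}")
    return {c: 100.0 * sum(1 for s in stop_codons if s == c) / n
            for c in STOP_CODONS}


def length_summary(values: Sequence[float]) -> tuple[float, float]:
    """(mean, median); median averages the two central values for even n."""
    if len(values) == 0:
        raise ValueError("no values")
    arr = np.asarray(values, dtype=float)
    return float(arr.mean()), float(np.median(arr))


@dataclass
class CdsUtrResult:
    cdna_id: str
    body: str
    polya_interval: tuple[int, int]
    annotation: CdsAnnotation
    utrs: Optional[UtrAnnotation]

    @property
    def stop_codon(self) -> Optional[str]:
        if self.annotation.cds_interval and self.annotation.has_stop:
            s, e = self.annotation.cds_interval
            return self.body[e - 3:e]
        return None


def annotate_cdna(cdna_id: str, sequence: str,
                  protein_db: ReferenceDb | None = None,
                  scheme: ScoringScheme | None = None) -> CdsUtrResult:
    """Full per-cDNA annotation: poly(A) strip, ORF cascade, UTRs."""
    body, polya = strip_polya(sequence)
    orfs = find_orfs(body)
    ann = select_cds(cdna_id, body, orfs, protein_db, scheme)
    ann.validate(body)
    utrs = None
    if ann.completeness == "full_length":
        utrs = extract_utrs(sequence, ann, polya)
    return CdsUtrResult(cdna_id, body, polya, ann, utrs)
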