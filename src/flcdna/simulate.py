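"""Seeded generator of a toy genome, transcript isoforms and clone libraries.

The generator emulates the data a full-length cDNA sequencing study curates:
multi-exon GT..AG gene models with UTRs and complete CDSs, poly(A)-tailed
transcripts, 5'-truncated redundant clones, retained-intron / alternative
donor / alternative acceptor / exon-skip isoforms, chimeric clones joined at
BamHI/XhoI sites, ncRNA and pathogen contaminants, vector flanks with
low-quality read tails, and a second "cultivar" genome differing by a
configurable substitution rate.  Every emitted sequence carries a
machine-readable truth record so each downstream stage can be verified.

Length distributions are log-normal parameterised by (mean, median) summary
statistics; a hard minimum is applied by clamping (not resampling), which
leaves medians untouched.  One scaffold holds 20 genes separated by 2 kb
spacers.  The full seed determines every output byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._seq import STOP_CODONS, random_seq, revcomp, translate
from .io_formats import CloneRead, FastaRecord, ReferenceDb

EVENT_TYPES = ("retained_intron", "alt_donor", "alt_acceptor", "exon_skip")
ENZYME_SITES = ("GGATCC", "CTCGAG")  # BamHI, XhoI
_FUNCTION_WORDS = ("kinase", "transporter", "synthase", "reductase",
                   "hydrolase", "ligase", "phosphatase", "receptor",
                   "oxidase", "isomerase")

# Interior events keep this many matched nucleotides on either side so the
# spliced aligner always anchors the altered block inside the optimal
# alignment (the block must out-score its flat intron/gap cost).
EVENT_EDGE_MARGIN = 60


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class LengthDist:
    """Log-normal length distribution pinned to a target mean and median.

    sigma = sqrt(2 ln(mean/median)), mu = ln(median).  Draws below
    ``minimum`` are clamped up (clamping below the median does not move it).
    """

    mean: float
    median: float
    minimum: int = 1

    def __post_init__(self):
        if not (0 < self.median <= self.mean):
            raise ConfigurationError(
                f"need 0 < median <= mean, got ({self.mean}, {self.median})")
        if self.minimum <= 0:
            raise ConfigurationError("minimum must be positive")

    @property
    def sigma(self) -> float:
        return math.sqrt(max(2.0 * math.log(self.mean / self.median), 0.0))

    def sample(self, rng: np.random.Generator, size: int | None = None):
        draws = rng.lognormal(math.log(self.median), self.sigma, size=size)
        return np.maximum(np.rint(draws).astype(int), self.minimum)


@dataclass(frozen=True)
class ExonCountDist:
    """1 + Poisson(mean - 1): mean 4.9 exons/gene gives median 4."""

    mean: float = 4.9

    def __post_init__(self):
        if self.mean < 1:
            raise ConfigurationError("exon count mean must be >= 1")

    def sample(self, rng: np.random.Generator) -> int:
        return 1 + int(rng.poisson(self.mean - 1.0))


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 1
    n_genes: int = 200
    exon_count_dist: ExonCountDist = field(default_factory=ExonCountDist)
    exon_len_dist: LengthDist = field(
        default_factory=lambda: LengthDist(274, 154, minimum=60))
    intron_len_dist: LengthDist = field(
        default_factory=lambda: LengthDist(594, 264, minimum=70))
    utr5_len_dist: LengthDist = field(
        default_factory=lambda: LengthDist(175, 106, minimum=12))
    utr3_len_dist: LengthDist = field(
        default_factory=lambda: LengthDist(257, 220, minimum=20))
    cds_len_dist: LengthDist = field(  # in codons, stop excluded
        default_factory=lambda: LengthDist(312, 292, minimum=30))
    gc_content: float = 0.403
    stop_usage: tuple[float, float, float] = (0.406, 0.356, 0.238)  # TGA/TAA/TAG
    isoform_rates: dict = field(default_factory=lambda: {
        "retained_intron": 0.55, "alt_donor": 0.16,
        "alt_acceptor": 0.20, "exon_skip": 0.05})
    chimera_rate: float = 0.02
    ncrna_rate: float = 0.01
    pathogen_rate: float = 0.01
    redundancy_mean: float = 2.0
    trunc5_mean: float = 60.0
    snp_rate: float = 0.00061
    vector_seq: str = (
        "GACGGCCAGTGAATTGTAATACGACTCACTATAGGGCGAATTGGAGCTCCACCGCGGTGG"
        "CGGCCGCTCTAGAACTAGTGGATCCCCCGGGCTGCAGGAATTCGAT")
    quality_profile: str = "noisy"  # or "two_level"
    genes_per_scaffold: int = 20
    intergenic_len: int = 2000
    polya_range: tuple[int, int] = (15, 40)

    def __post_init__(self):
        for name in ("chimera_rate", "ncrna_rate", "pathogen_rate", "snp_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        for v in self.isoform_rates.values():
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError("isoform rates must be in [0, 1]")
        if set(self.isoform_rates) - set(EVENT_TYPES):
            raise ConfigurationError("unknown isoform event type")
        if not (0.0 < self.gc_content < 1.0):
            raise ConfigurationError("gc_content outside (0, 1)")
        if self.snp_rate >= 0.1:
            raise ConfigurationError("snp_rate must be < 0.1")
        if self.n_genes < 0:
            raise ConfigurationError("n_genes must be >= 0")
        if self.quality_profile not in ("noisy", "two_level"):
            raise ConfigurationError("quality_profile must be noisy|two_level")


# ---------------------------------------------------------------------------
# truth records
# ---------------------------------------------------------------------------

@dataclass
class GeneTruth:
    id: str
    scaffold_id: str
    strand: str
    offset: int                       # gene-region start on the scaffold
    region_len: int
    # transcription-sense structure, in gene-region local coordinates:
    exons_local: list[tuple[int, int]]
    introns_local: list[tuple[int, int]]
    utr5_len: int
    cds_len: int                      # includes stop codon
    utr3_len: int
    transcript: str                   # spliced body, no poly(A)
    protein: str
    stop_codon: str
    description: str
    intron_seqs: list[str] = field(default_factory=list)

    @property
    def n_exons(self) -> int:
        return len(self.exons_local)

    def exon_lengths(self) -> list[int]:
        return [e - s for s, e in self.exons_local]

    def intron_lengths(self) -> list[int]:
        return [e - s for s, e in self.introns_local]

    def _to_scaffold(self, iv: tuple[int, int]) -> tuple[int, int]:
        s, e = iv
        if self.strand == "+":
            return (self.offset + s, self.offset + e)
        return (self.offset + self.region_len - e,
                self.offset + self.region_len - s)

    def exons_genome(self) -> list[tuple[int, int]]:
        """Exon intervals on the scaffold forward axis, ascending."""
        ivs = [self._to_scaffold(iv) for iv in self.exons_local]
        return sorted(ivs)

    def introns_genome(self) -> list[tuple[int, int]]:
        return sorted(self._to_scaffold(iv) for iv in self.introns_local)


@dataclass
class TranscriptTruth:
    id: str
    gene_id: str
    event: Optional[str]              # None for the reference isoform
    body: str                         # sequence without poly(A)
    polya_len: int
    # closed-form geometry relative to the reference isoform:
    ins_blocks: list[tuple[int, int, int]]  # (intron_idx, lo, hi) intron-local
    del_exons: list[int]
    event_info: dict = field(default_factory=dict)
    # exon structure in gene-region local coordinates (transcription sense)
    exons_local: list[tuple[int, int]] = field(default_factory=list)
    # reference-transcript coordinate where the altered block begins
    event_ref_pos: Optional[int] = None

    @property
    def sequence(self) -> str:
        return self.body + "A" * self.polya_len

    def __len__(self) -> int:
        return len(self.body) + self.polya_len


@dataclass
class CloneTruth:
    id: str
    clone_class: str                  # normal|redundant|chimera|ncRNA|pathogen
    insert: str                       # finished (error-free) insert sequence
    source_tid: Optional[str] = None
    trunc5: int = 0
    chimera_parents: tuple[str, str] | None = None
    chimera_junction: int | None = None   # insert coord where the site starts
    enzyme_site: str | None = None
    pool_id: str | None = None


@dataclass
class TruthTables:
    gene_models: list[GeneTruth] = field(default_factory=list)
    transcripts: list[TranscriptTruth] = field(default_factory=list)
    clones: list[CloneTruth] = field(default_factory=list)
    snp_positions: list[tuple[str, int, str, str]] = field(default_factory=list)
    skipped_events: list[tuple[str, str, str]] = field(default_factory=list)

    def gene(self, gid: str) -> GeneTruth:
        return self._gene_index()[gid]

    def transcript(self, tid: str) -> TranscriptTruth:
        return self._tx_index()[tid]

    def _gene_index(self):
        if not hasattr(self, "_gidx") or len(self._gidx) != len(self.gene_models):
            self._gidx = {g.id: g for g in self.gene_models}
        return self._gidx

    def _tx_index(self):
        if not hasattr(self, "_tidx") or len(self._tidx) != len(self.transcripts):
            self._tidx = {t.id: t for t in self.transcripts}
        return self._tidx

    @property
    def transcript_isoforms(self) -> dict[str, str]:
        return {t.id: t.event or "reference" for t in self.transcripts}

    @property
    def clone_classes(self) -> dict[str, str]:
        return {c.id: c.clone_class for c in self.clones}


# ---------------------------------------------------------------------------
# gene construction
# ---------------------------------------------------------------------------

def _sample_cds(rng, n_codons: int, gc: float, stop_usage) -> str:
    codons = []
    while len(codons) < n_codons - 1:
        c = random_seq(rng, 3, gc)
        if c not in STOP_CODONS:
            codons.append(c)
    stop = STOP_CODONS[rng.choice(3, p=np.asarray(stop_usage) / sum(stop_usage))]
    return "ATG" + "".join(codons) + stop


def _partition_exons(rng, total: int, n_exons: int, dist: LengthDist) -> list[int]:
    """Split ``total`` nt into n exon lengths following ``dist`` shape."""
    n_exons = max(1, min(n_exons, total // dist.minimum))
    if n_exons == 1:
        return [total]
    raw = dist.sample(rng, n_exons).astype(float)
    lens = np.maximum((raw * total / raw.sum()).astype(int), dist.minimum)
    # settle the rounding surplus/deficit onto the largest exons
    diff = total - int(lens.sum())
    order = list(np.argsort(-lens))
    i = 0
    while diff != 0 and i < 100 * n_exons:
        idx = order[i % n_exons]
        if diff > 0:
            lens[idx] += 1
            diff -= 1
        elif lens[idx] > dist.minimum:
            lens[idx] -= 1
            diff += 1
        i += 1
    if lens.sum() != total or lens.min() < dist.minimum:
        base = total // n_exons
        lens = np.full(n_exons, base, dtype=int)
        lens[-1] += total - int(lens.sum())
        if lens.min() < dist.minimum:
            return [total]
    return [int(x) for x in lens]


def _splice(region: str, donor: int, acceptor: int) -> str:
    return region[:donor] + region[acceptor:]


def _junction_ambiguous(region: str, donor: int, acceptor: int,
                        window: int = 12) -> bool:
    """True if the intron (donor, acceptor) admits an equal-score canonical
    slide: removing a shifted interval yields the same spliced string with
    GT..AG termini."""
    target = _splice(region, donor, acceptor)
    for k in range(-window, window + 1):
        if k == 0:
            continue
        d, a = donor + k, acceptor + k
        if d < 0 or a > len(region):
            continue
        if (region[d:d + 2] == "GT" and region[a - 2:a] == "AG"
                and _splice(region, d, a) == target):
            return True
    return False


def _build_gene(rng, cfg: SimulationConfig, gid: str) -> GeneTruth:
    # the exon count is drawn once, outside the retry loop: retries resample
    # sequence content and lengths only, so the planting guards cannot bias
    # the exon-count distribution
    n_ex = cfg.exon_count_dist.sample(rng)
    for _attempt in range(50):
        utr5 = int(cfg.utr5_len_dist.sample(rng))
        utr3 = int(cfg.utr3_len_dist.sample(rng))
        codons = int(cfg.cds_len_dist.sample(rng))
        cds_len = 3 * codons + 3
        cds = _sample_cds(rng, codons, cfg.gc_content, cfg.stop_usage)
        assert len(cds) == cds_len
        utr5_seq = random_seq(rng, utr5, cfg.gc_content)
        utr3_seq = (random_seq(rng, utr3 - 8, cfg.gc_content)
                    + "".join("CGT"[i] for i in rng.choice(3, 8)))
        transcript = utr5_seq + cds + utr3_seq
        total = len(transcript)
        exon_lens = _partition_exons(rng, total, n_ex, cfg.exon_len_dist)
        intron_lens = cfg.intron_len_dist.sample(rng, len(exon_lens) - 1) \
            if len(exon_lens) > 1 else np.array([], dtype=int)
        # assemble gene region, tracking local coordinates
        parts = []
        exons_local: list[tuple[int, int]] = []
        introns_local: list[tuple[int, int]] = []
        intron_seqs: list[str] = []
        pos = 0
        tpos = 0
        ok = True
        for i, elen in enumerate(exon_lens):
            parts.append(transcript[tpos:tpos + elen])
            exons_local.append((pos, pos + elen))
            pos += elen
            tpos += elen
            if i < len(exon_lens) - 1:
                ilen = int(intron_lens[i])
                interior = list(random_seq(rng, ilen - 4, cfg.gc_content))
                # plant one alternative donor GT and acceptor AG inside the
                # intron so alternative-splice isoforms always have a site
                max_d = min(28, ilen - 70)
                if max_d >= 9:
                    dd = int(rng.integers(9, max_d + 1))
                    interior[dd - 2:dd] = ["G", "T"]
                    da = int(rng.integers(9, max_d + 1))
                    interior[ilen - 4 - da:ilen - 2 - da] = ["A", "G"]
                iseq = "GT" + "".join(interior) + "AG"
                parts.append(iseq)
                intron_seqs.append(iseq)
                introns_local.append((pos, pos + ilen))
                pos += ilen
        region = "".join(parts)
        for ds, de in introns_local:
            if _junction_ambiguous(region, ds, de):
                ok = False
                break
        if ok and len(exon_lens) >= 3:
            # guarantee at least one internal exon whose removal cannot be
            # misread as a canonical intron (so exon-skip isoforms are
            # always plantable on multi-exon genes)
            tpos2 = 0
            safe = False
            for k, elen in enumerate(exon_lens):
                if 0 < k < len(exon_lens) - 1 and _skip_block_safe(
                        transcript, tpos2, tpos2 + elen):
                    safe = True
                    break
                tpos2 += elen
            ok = safe
        if not ok:
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        desc = (f"{_FUNCTION_WORDS[int(rng.integers(len(_FUNCTION_WORDS)))]}"
                f" {gid}")
        return GeneTruth(
            id=gid, scaffold_id="", strand=strand, offset=0,
            region_len=len(region), exons_local=exons_local,
            introns_local=introns_local, utr5_len=utr5, cds_len=cds_len,
            utr3_len=utr3, transcript=transcript,
            protein=translate(cds), stop_codon=cds[-3:], description=desc,
            intron_seqs=intron_seqs)
    raise RuntimeError(f"could not build an unambiguous gene for {gid}")


def simulate_genome(config: SimulationConfig
                    ) -> tuple[list[FastaRecord], TruthTables]:
    """Generate scaffolds and gene-model truth.

    Genes never overlap; every intron starts GT and ends AG; every CDS runs
    ATG..stop.  Identical configs give byte-identical output.
    """
    rng = np.random.default_rng(config.seed)
    truth = TruthTables()
    scaffolds: list[FastaRecord] = []
    genes: list[GeneTruth] = []
    for i in range(config.n_genes):
        genes.append(_build_gene(rng, config, f"g{i:05d}"))
    per = config.genes_per_scaffold
    for s_idx in range(0, max((config.n_genes + per - 1) // per, 0)):
        sid = f"scf{s_idx:03d}"
        chunk = genes[s_idx * per:(s_idx + 1) * per]
        parts = []
        pos = 0
        for g in chunk:
            spacer = random_seq(rng, config.intergenic_len, config.gc_content)
            parts.append(spacer)
            pos += len(spacer)
            g.scaffold_id = sid
            g.offset = pos
            region = _gene_region_sequence(g)
            parts.append(region if g.strand == "+" else revcomp(region))
            pos += g.region_len
        parts.append(random_seq(rng, config.intergenic_len, config.gc_content))
        scaffolds.append(FastaRecord(sid, "".join(parts)))
    truth.gene_models = genes
    return scaffolds, truth


def _gene_region_sequence(g: GeneTruth) -> str:
    """Rebuild the transcription-sense gene region from truth coordinates."""
    parts = []
    tpos = 0
    for i, (s, e) in enumerate(g.exons_local):
        parts.append(g.transcript[tpos:tpos + (e - s)])
        tpos += e - s
        if i < len(g.introns_local):
            parts.append(g.intron_seqs[i])
    return "".join(parts)


def simulate_variant_genome(genome: list[FastaRecord], snp_rate: float,
                            seed: int
                            ) -> tuple[list[FastaRecord],
                                       list[tuple[str, int, str, str]]]:
    """Substitution-only variant of a genome (a second cultivar).

    Each base independently mutates with probability ``snp_rate``; positions
    and alleles are recorded.  No indels.
    """
    if not (0.0 <= snp_rate < 0.1):
        raise ConfigurationError(f"snp_rate={snp_rate} outside [0, 0.1)")
    rng = np.random.default_rng(seed)
    out = []
    positions: list[tuple[str, int, str, str]] = []
    for rec in genome:
        arr = np.frombuffer(rec.sequence.encode(), dtype=np.uint8).copy()
        hit = np.nonzero(rng.random(arr.size) < snp_rate)[0]
        bases = b"ACGT"
        for p in hit:
            ref = chr(arr[p])
            if ref not in "ACGT":
                continue
            alts = [b for b in "ACGT" if b != ref]
            alt = alts[int(rng.integers(3))]
            arr[p] = ord(alt)
            positions.append((rec.id, int(p), ref, alt))
        out.append(FastaRecord(rec.id, arr.tobytes().decode(),
                               rec.description))
    return out, positions


# ---------------------------------------------------------------------------
# transcript isoforms
# ---------------------------------------------------------------------------

def _isoform_exons(g: GeneTruth, event: str, info: dict
                   ) -> list[tuple[int, int]]:
    ex = list(g.exons_local)
    if event == "retained_intron":
        i = info["intron_idx"]
        merged = (ex[i][0], ex[i + 1][1])
        return ex[:i] + [merged] + ex[i + 2:]
    if event == "alt_donor":
        i, d = info["intron_idx"], info["delta"]
        ex[i] = (ex[i][0], ex[i][1] + d)
        return ex
    if event == "alt_acceptor":
        i, d = info["intron_idx"], info["delta"]
        ex[i + 1] = (ex[i + 1][0] - d, ex[i + 1][1])
        return ex
    if event == "exon_skip":
        k = info["exon_idx"]
        return ex[:k] + ex[k + 1:]
    raise ValueError(event)


def _exons_to_body(g: GeneTruth, exons_local) -> str:
    region = _gene_region_sequence(g)
    return "".join(region[s:e] for s, e in exons_local)


def _transcript_prefix_len(g: GeneTruth, upto_local: int) -> int:
    """Transcript length contributed by exon bases before local coord."""
    n = 0
    for s, e in g.exons_local:
        n += max(0, min(e, upto_local) - s)
    return n


def _event_margins_ok(g: GeneTruth, lo_local: int, hi_local: int) -> bool:
    """Events keep matched anchor sequence on both sides of the block."""
    up = _transcript_prefix_len(g, lo_local)
    down = len(g.transcript) - _transcript_prefix_len(g, hi_local)
    return up >= EVENT_EDGE_MARGIN and down >= EVENT_EDGE_MARGIN


def _global_score(x: str, y: str, match=1, mismatch=-3,
                  gap_open=5, gap_extend=2) -> int:
    """Tiny affine-gap global alignment score for planting guards."""
    NEG = -(10 ** 9)
    m, n = len(x), len(y)
    H = [NEG] * (n + 1)
    E = [NEG] * (n + 1)
    H[0] = 0
    for j in range(1, n + 1):
        H[j] = -(gap_open + gap_extend * j)
        E[j] = H[j]
    for i in range(1, m + 1):
        diag = H[0]
        H[0] = -(gap_open + gap_extend * i)
        f = NEG
        for j in range(1, n + 1):
            E[j] = max(H[j] - gap_open - gap_extend, E[j] - gap_extend)
            f = max(H[j - 1] - gap_open - gap_extend, f - gap_extend)
            s = match if x[i - 1] == y[j - 1] else mismatch
            best = max(diag + s, E[j], f)
            diag = H[j]
            H[j] = best
    return H[n]


def _skip_block_safe(body: str, s: int, e: int, window: int = 20,
                     margin: int = 21) -> bool:
    """Can the removed block [s, e) of ``body`` be mistaken for a canonical
    intron?  Scans nearby GT..AG placements and rejects the exon when one
    reconciles with the planted removal at a cost below ``margin`` (the
    non-canonical penalty plus slack)."""
    skipped = body[:s] + body[e:]
    for p in range(max(0, s - window), s + window + 1):
        if body[p:p + 2] != "GT":
            continue
        for q in range(max(p + 60, e - window), min(len(body), e + window) + 1):
            if body[q - 2:q] != "AG":
                continue
            alt = body[:p] + body[q:]
            lo = max(0, min(p, s) - 4)
            hi_alt = len(alt) - (len(body) - max(q, e)) + 4
            hi_sk = len(skipped) - (len(body) - max(q, e)) + 4
            mid_alt = alt[lo:hi_alt]
            mid_sk = skipped[lo:hi_sk]
            cost = len(mid_sk) - _global_score(mid_alt, mid_sk)
            if cost < margin:
                return False
    return True


def _try_event(rng, g: GeneTruth, region: str, event: str,
               used_introns: set[int]) -> Optional[dict]:
    n_int = len(g.introns_local)
    if event in ("retained_intron", "alt_donor", "alt_acceptor"):
        if n_int == 0:
            return None
        order = list(rng.permutation(n_int))
        for i in order:
            if i in used_introns:
                continue
            s, e = g.introns_local[i]
            ilen = e - s
            if event == "retained_intron":
                if _event_margins_ok(g, s, e):
                    used_introns.add(i)
                    return {"intron_idx": int(i)}
                continue
            # deltas are capped at 28 nt: a larger shifted block is cheaper
            # for the aligner to model as a (partial) retained intron than
            # as an affine gap, which would make the planted event class
            # ambiguous by construction
            max_d = min(28, ilen - 70)
            if max_d < 9:
                continue
            deltas = list(rng.permutation(np.arange(9, max_d + 1)))
            for d in deltas:
                d = int(d)
                if event == "alt_donor":
                    # new donor must be GT at intron offset d
                    if region[s + d:s + d + 2] != "GT":
                        continue
                    nd, na = s + d, e
                else:
                    # new acceptor must be AG ending at intron offset len-d
                    if region[e - d - 2:e - d] != "AG":
                        continue
                    nd, na = s, e - d
                if _junction_ambiguous(region, nd, na):
                    continue
                if not _event_margins_ok(g, s, e):
                    break
                used_introns.add(i)
                return {"intron_idx": int(i), "delta": d}
        return None
    if event == "exon_skip":
        if g.n_exons < 3:
            return None
        order = list(rng.permutation(np.arange(1, g.n_exons - 1)))
        for k in order:
            k = int(k)
            # merged intron junction must be unambiguous
            nd = g.introns_local[k - 1][0]
            na = g.introns_local[k][1]
            if _junction_ambiguous(region, nd, na):
                continue
            if not _event_margins_ok(g, nd, na):
                continue
            ts = _transcript_prefix_len(g, g.exons_local[k][0])
            te = ts + (g.exons_local[k][1] - g.exons_local[k][0])
            if not _skip_block_safe(g.transcript, ts, te):
                continue
            return {"exon_idx": k}
        return None
    raise ValueError(event)


_EVENT_SUFFIX = {"retained_intron": "ri", "alt_donor": "ad",
                 "alt_acceptor": "aa", "exon_skip": "es"}


def simulate_transcripts(truth: TruthTables, isoform_rates: dict, seed: int,
                         config: SimulationConfig | None = None
                         ) -> list[TranscriptTruth]:
    """Reference isoform per gene plus per-event alternative isoforms.

    Alternative events are planted at existing GT/AG sites 9-60 nt away from
    the reference boundary; each structural element hosts at most one event
    so isoform pairs have well-separated differences.  Events impossible on
    a gene (single exon, no eligible site) are skipped and logged.
    """
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    lo, hi = cfg.polya_range
    out: list[TranscriptTruth] = []
    for g in truth.gene_models:
        region = _gene_region_sequence(g)
        ref = TranscriptTruth(
            id=f"{g.id}.t1", gene_id=g.id, event=None, body=g.transcript,
            polya_len=int(rng.integers(lo, hi + 1)), ins_blocks=[],
            del_exons=[], exons_local=list(g.exons_local))
        out.append(ref)
        used: set[int] = set()
        # draw event requests first, then attempt in random order so no
        # class is systematically starved of eligible introns
        requested = [ev for ev in EVENT_TYPES
                     if isoform_rates.get(ev, 0.0) > 0
                     and rng.random() < isoform_rates[ev]]
        for idx in rng.permutation(len(requested)):
            event = requested[int(idx)]
            info = _try_event(rng, g, region, event, used)
            if info is None:
                truth.skipped_events.append((g.id, event, "no eligible site"))
                continue
            exons = _isoform_exons(g, event, info)
            body = _exons_to_body(g, exons)
            pre = np.concatenate([[0], np.cumsum(g.exon_lengths())])
            ins: list[tuple[int, int, int]] = []
            dels: list[int] = []
            if event == "retained_intron":
                i = info["intron_idx"]
                ilen = g.intron_lengths()[i]
                ins = [(i, 0, ilen)]
            elif event == "alt_donor":
                ins = [(info["intron_idx"], 0, info["delta"])]
            elif event == "alt_acceptor":
                i = info["intron_idx"]
                ilen = g.intron_lengths()[i]
                ins = [(i, ilen - info["delta"], ilen)]
            else:
                dels = [info["exon_idx"]]
            if ins:
                ref_pos = int(pre[ins[0][0] + 1])
            else:
                ref_pos = int(pre[dels[0]])
            out.append(TranscriptTruth(
                id=f"{g.id}.{_EVENT_SUFFIX[event]}1", gene_id=g.id,
                event=event, body=body,
                polya_len=int(rng.integers(lo, hi + 1)),
                ins_blocks=ins, del_exons=dels, event_info=info,
                exons_local=exons, event_ref_pos=ref_pos))
    truth.transcripts = out
    return out


# ---------------------------------------------------------------------------
# clone library
# ---------------------------------------------------------------------------

@dataclass
class CloneLibrary:
    reads: list[CloneRead]
    clones: list[CloneTruth]
    trim_truth: dict[str, tuple[int, int]]   # read id -> clean window
    ncrna_pool: list[FastaRecord]
    pathogen_pool: list[FastaRecord]


def _quality_array(rng, cfg: SimulationConfig, clean_len: int,
                   tail_len: int) -> np.ndarray:
    total = clean_len + tail_len
    if cfg.quality_profile == "two_level":
        q = np.full(total, 40, dtype=int)
        q[clean_len:] = 10
        return q
    q = rng.normal(38.0, 4.0, size=total)
    pos = np.arange(total)
    q = q - np.maximum(pos - 500, 0) * 0.08      # linear decay after 500
    q[clean_len:] = rng.normal(12.0, 4.0, size=tail_len)
    return np.clip(np.rint(q), 2, 60).astype(int)


def simulate_clone_library(transcripts: list[TranscriptTruth],
                           config: SimulationConfig, seed: int,
                           truth: TruthTables | None = None) -> CloneLibrary:
    """Clone inserts plus artifact-bearing 5'-end reads.

    Per transcript: one full-length clone and Poisson(redundancy_mean - 1)
    5'-truncated redundant copies.  Chimeras join two gene bodies with a
    BamHI/XhoI site; ncRNA/pathogen contaminants copy records from separate
    pools.  Reads carry a vector flank and a degraded 3' tail with emitted
    Phred strings; finished inserts are error-free.
    """
    if not transcripts:
        raise ConfigurationError("no transcripts to clone")
    rng = np.random.default_rng(seed)
    clones: list[CloneTruth] = []
    counter = 0

    def next_id():
        nonlocal counter
        cid = f"cl{counter:06d}"
        counter += 1
        return cid

    # truncations must stay upstream of every planted event block of the
    # gene so that pairwise alignment geometry is derivable from truth
    first_event: dict[str, int] = {}
    for t in transcripts:
        if t.event_ref_pos is not None:
            first_event[t.gene_id] = min(
                first_event.get(t.gene_id, 10 ** 9), t.event_ref_pos)
    for t in transcripts:
        clones.append(CloneTruth(next_id(), "normal", t.sequence,
                                 source_tid=t.id))
        n_extra = int(rng.poisson(max(config.redundancy_mean - 1.0, 0.0)))
        for _ in range(n_extra):
            cap = min(150, int(0.15 * len(t.sequence)),
                      first_event.get(t.gene_id, 10 ** 9) - 10)
            trunc = int(np.clip(rng.exponential(config.trunc5_mean), 10, cap)) \
                if cap >= 10 else 0
            clones.append(CloneTruth(next_id(), "redundant",
                                     t.sequence[trunc:], source_tid=t.id,
                                     trunc5=trunc))

    refs = [t for t in transcripts if t.event is None and len(t.body) >= 600]
    n_chim = round(config.chimera_rate * len(transcripts))
    for i in range(n_chim if len(refs) >= 2 else 0):
        a, b = (refs[int(k)] for k in
                rng.choice(len(refs), size=2, replace=False))
        fx = 0.35 + 0.3 * rng.random()
        fy = 0.35 + 0.3 * rng.random()
        x = int(fx * len(a.body))
        y = int(fy * len(b.body))
        site = ENZYME_SITES[int(rng.integers(2))]
        insert = a.body[:x] + site + b.sequence[len(b.sequence) - y:]
        clones.append(CloneTruth(next_id(), "chimera", insert,
                                 chimera_parents=(a.id, b.id),
                                 chimera_junction=x, enzyme_site=site))

    def make_pool(prefix, n):
        return [FastaRecord(f"{prefix}{j:04d}",
                            random_seq(rng, int(rng.integers(400, 901)),
                                       config.gc_content),
                            f"synthetic {prefix} record {j}")
                for j in range(n)]

    n_nc = round(config.ncrna_rate * len(transcripts))
    n_pa = round(config.pathogen_rate * len(transcripts))
    ncrna_pool = make_pool("ncRNA", max(n_nc, 5))
    pathogen_pool = make_pool("path", max(n_pa, 5))
    for j in range(n_nc):
        clones.append(CloneTruth(next_id(), "ncRNA", ncrna_pool[j].sequence,
                                 pool_id=ncrna_pool[j].id))
    for j in range(n_pa):
        clones.append(CloneTruth(next_id(), "pathogen",
                                 pathogen_pool[j].sequence,
                                 pool_id=pathogen_pool[j].id))

    reads: list[CloneRead] = []
    trim_truth: dict[str, tuple[int, int]] = {}
    libs = ("LEFL1", "FC", "LEFL2", "LEFL3")
    for c in clones:
        v5 = int(rng.integers(25, 36))
        vec = config.vector_seq[:v5]
        rl = max(int(rng.normal(650.0, 60.0)), 120)
        portion = c.insert[:rl]
        tail_len = int(rng.integers(40, 81))
        tail = random_seq(rng, tail_len, config.gc_content)
        seq = vec + portion + tail
        q = _quality_array(rng, config, v5 + len(portion), tail_len)
        reads.append(CloneRead(id=c.id, sequence=seq,
                               library=libs[int(rng.integers(4))],
                               qualities=[int(x) for x in q]))
        trim_truth[c.id] = (v5, v5 + len(portion))
    if truth is not None:
        truth.clones = clones
    return CloneLibrary(reads=reads, clones=clones, trim_truth=trim_truth,
                        ncrna_pool=ncrna_pool, pathogen_pool=pathogen_pool)


# ---------------------------------------------------------------------------
# study bundle and closed-form expected dispositions
# ---------------------------------------------------------------------------

@dataclass
class SimStudy:
    config: SimulationConfig
    genome: list[FastaRecord]
    variant_genome: list[FastaRecord]
    truth: TruthTables
    library: CloneLibrary
    genome_db: ReferenceDb
    variant_db: ReferenceDb
    unigene_db: ReferenceDb
    protein_db: ReferenceDb
    ncrna_db: ReferenceDb
    pathogen_db: ReferenceDb
    vector_db: ReferenceDb


def simulate_study(config: SimulationConfig) -> SimStudy:
    """Run every generator stage under one seed and bundle the outputs."""
    genome, truth = simulate_genome(config)
    seq = np.random.SeedSequence(config.seed)
    s_tx, s_lib, s_var = (int(s.generate_state(1)[0] % (2 ** 31))
                          for s in seq.spawn(3))
    transcripts = simulate_transcripts(truth, config.isoform_rates, s_tx,
                                       config)
    library = simulate_clone_library(transcripts, config, s_lib, truth)
    variant, snps = simulate_variant_genome(genome, config.snp_rate, s_var)
    truth.snp_positions = snps
    unigene = ReferenceDb(
        "unigene", "transcript",
        {f"U_{g.id}": (g.transcript, g.description)
         for g in truth.gene_models})
    protein = ReferenceDb(
        "proteins", "protein",
        {f"P_{g.id}": (g.protein, g.description) for g in truth.gene_models})
    return SimStudy(
        config=config, genome=genome, variant_genome=variant, truth=truth,
        library=library,
        genome_db=ReferenceDb.from_records(genome, "genome", "genome"),
        variant_db=ReferenceDb.from_records(variant, "variant", "genome"),
        unigene_db=unigene, protein_db=protein,
        ncrna_db=ReferenceDb.from_records(library.ncrna_pool, "ncrna", "ncrna"),
        pathogen_db=ReferenceDb.from_records(library.pathogen_pool,
                                             "pathogen", "pathogen"),
        vector_db=ReferenceDb("vector", "vector",
                              {"vec1": (config.vector_seq, "cloning vector")}))


def _pair_geometry(truth: TruthTables, ca: CloneTruth, cb: CloneTruth,
                   gap_open: int = 5, gap_extend: int = 2):
    """Closed-form best-local-alignment stats for clones of one gene.

    The two inserts are exact copies of the reference backbone apart from
    planted indel blocks (each on a distinct intron/exon by construction),
    5' truncations and poly(A)-tail length.  The optimal local alignment is
    therefore a contiguous run of matched segments, each gap either bridged
    (affine cost) or the alignment truncated; the best run is enumerated
    exactly.  Returns (matches, columns, cov_a, cov_b, score).
    """
    ta = truth.transcript(ca.source_tid)
    tb = truth.transcript(cb.source_tid)
    g = truth.gene(ta.gene_id)
    exon_lens = g.exon_lengths()
    pre = np.concatenate([[0], np.cumsum(exon_lens)])

    def event_set(t: TranscriptTruth):
        ev = {(int(pre[i + 1]), "ins", hi - lo) for i, lo, hi in t.ins_blocks}
        ev |= {(int(pre[k]), "del", exon_lens[k]) for k in t.del_exons}
        return ev

    ea, eb = event_set(ta), event_set(tb)
    events = sorted(
        [(pos, kind, ln, "a") for pos, kind, ln in ea - eb]
        + [(pos, kind, ln, "b") for pos, kind, ln in eb - ea]
        + [(pos, kind, ln, "both") for pos, kind, ln in ea & eb],
        # at a shared position the inserted block precedes the deleted one
        # in sequence order (an insertion attaches before the block that
        # starts there)
        key=lambda e: (e[0], e[1] != "ins"))
    tail = min(ta.polya_len, tb.polya_len)
    t_lead = max(ca.trunc5, cb.trunc5)
    segs: list[int] = []          # matched segment lengths
    gaps: list[tuple[int, str]] = []  # (len, side holding the extra bases)
    cur = t_lead
    mlen = 0
    for pos, kind, ln, side in events:
        mlen += pos - cur
        cur = pos
        if side == "both":      # block present in both inserts: matched
            if kind == "ins":
                mlen += ln
            else:
                cur = pos + ln
            continue
        segs.append(mlen)
        mlen = 0
        if kind == "ins":
            gaps.append((ln, side))
        else:
            gaps.append((ln, "b" if side == "a" else "a"))
            cur = pos + ln
    mlen += len(g.transcript) - cur + tail
    segs.append(mlen)
    assert all(s >= 0 for s in segs), (ca.id, cb.id, segs)
    # adjacent indel blocks (zero matched nt between) merge into one affine
    # run, exactly as the aligner scores them; by construction the merged
    # bases always sit on the same sequence
    i = 0
    while i < len(gaps) - 1:
        if segs[i + 1] == 0:
            assert gaps[i][1] == gaps[i + 1][1]
            gaps[i:i + 2] = [(gaps[i][0] + gaps[i + 1][0], gaps[i][1])]
            del segs[i + 1]
        else:
            i += 1

    best = (-1, 0, 0, 0, 0)  # score, matches, cols, span_a, span_b
    for i in range(len(segs)):
        for j in range(i, len(segs)):
            m = sum(segs[i:j + 1])
            run = gaps[i:j]
            score = m - sum(gap_open + gap_extend * gl for gl, _ in run)
            cols = m + sum(gl for gl, _ in run)
            span_a = m + sum(gl for gl, sd in run if sd == "a")
            span_b = m + sum(gl for gl, sd in run if sd == "b")
            if score > best[0]:
                best = (score, m, cols, span_a, span_b)
    score, matches, cols, span_a, span_b = best
    la, lb = len(ca.insert), len(cb.insert)
    return matches, cols, span_a / la, span_b / lb, score


def expected_dispositions(study: SimStudy, *, evalue_thr: float = 1e-180,
                          identity_thr: float = 0.97,
                          coverage_thr: float = 0.80,
                          scheme=None) -> dict[str, str]:
    """Terminal curation disposition each clone should receive.

    Derived purely from planted truth geometry with the study's stated
    redundancy criteria (E-value, BLAST-style identity, mutual coverage) in
    closed form -- fully independent of the aligner.  Dispositions:
    redundant | ncRNA | pathogen | chimera | retained_intron | nrFLcDNA.
    """
    from .alignment import ScoringScheme, cached_calibration
    scheme = scheme or ScoringScheme()
    lam, K = cached_calibration(scheme)
    truth = study.truth
    clones = truth.clones
    by_gene: dict[str, list[CloneTruth]] = {}
    for c in clones:
        if c.source_tid is not None:
            by_gene.setdefault(truth.transcript(c.source_tid).gene_id,
                               []).append(c)
    parent = {c.id: c.id for c in clones}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[ry] = rx

    log_thr = math.log10(evalue_thr)
    for members in by_gene.values():
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                ca, cb = members[i], members[j]
                m, cols, cov_a, cov_b, score = _pair_geometry(
                    truth, ca, cb, scheme.gap_open, scheme.gap_extend)
                ident = m / cols if cols else 0.0
                if score <= 0:
                    continue
                log_e = (math.log10(K * len(ca.insert) * len(cb.insert))
                         - lam * score / math.log(10))
                if (ident >= identity_thr and cov_a >= coverage_thr
                        and cov_b >= coverage_thr and log_e <= log_thr):
                    union(ca.id, cb.id)

    comp: dict[str, list[CloneTruth]] = {}
    for c in clones:
        comp.setdefault(find(c.id), []).append(c)
    out: dict[str, str] = {}
    for members in comp.values():
        kept = sorted(members, key=lambda c: (-len(c.insert), c.id))[0]
        for c in members:
            if c is not kept:
                out[c.id] = "redundant"
        if kept.clone_class in ("ncRNA", "pathogen", "chimera"):
            out[kept.id] = kept.clone_class
        elif (kept.source_tid is not None
              and truth.transcript(kept.source_tid).event == "retained_intron"):
            out[kept.id] = "retained_intron"
        else:
            out[kept.id] = "nrFLcDNA"
    return out
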