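"""Readers and writers for the plain-text formats the pipeline exchanges.

Supported formats: FASTA (nucleotide and protein), FASTA-style ``.qual``
files with space-separated Phred integers, a GFF3 subset
(gene/mRNA/exon/CDS features) and TSV tables.  Parsing is strict: illegal
characters, empty sequences and malformed headers raise :class:`ParseError`
naming the offending line.  All in-memory coordinates are 0-based half-open;
GFF3 emission/consumption converts to/from 1-based inclusive in exactly one
place (this module).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from ._seq import NUC_ALPHABET, PROT_ALPHABET


class ParseError(ValueError):
    pass


class ValidationError(ValueError):
    pass


LIBRARIES = ("LEFL1", "FC", "LEFL2", "LEFL3", "synthetic")


@dataclass
class CloneRead:
    """A single (5'-end) clone read with optional Phred qualities."""

    id: str
    sequence: str
    library: str = "synthetic"
    qualities: list[int] | None = None

    def __post_init__(self):
        if self.library not in LIBRARIES:
            raise ValidationError(f"unknown library {self.library!r}")
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValidationError(
                f"{self.id}: {len(self.qualities)} qualities for "
                f"{len(self.sequence)} bases"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class FastaRecord:
    id: str
    sequence: str
    description: str = ""


DB_KINDS = ("transcript", "ncrna", "pathogen", "protein", "genome", "vector")


@dataclass
class ReferenceDb:
    """A named FASTA database: id -> (sequence, description)."""

    name: str
    kind: str
    records: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in DB_KINDS:
            raise ValidationError(f"unknown db kind {self.kind!r}")
        for rid in self.records:
            if not rid:
                raise ValidationError("empty record id")

    @classmethod
    def from_fasta(cls, path, name: str, kind: str) -> "ReferenceDb":
        alphabet = "protein" if kind == "protein" else "nucleotide"
        recs = read_fasta(path, alphabet=alphabet)
        return cls(name=name, kind=kind,
                   records={r.id: (r.sequence, r.description) for r in recs})

    @classmethod
    def from_records(cls, records: Iterable[FastaRecord], name: str, kind: str):
        return cls(name=name, kind=kind,
                   records={r.id: (r.sequence, r.description) for r in records})

    def ids(self) -> list[str]:
        return list(self.records)

    def seq(self, rid: str) -> str:
        return self.records[rid][0]

    def desc(self, rid: str) -> str:
        return self.records[rid][1]

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, rid) -> bool:
        return rid in self.records


def read_fasta(path, alphabet: str = "nucleotide") -> list[FastaRecord]:
    """Strict FASTA reader.

    Uppercases sequences, preserves record order and description lines,
    rejects characters outside the chosen alphabet and duplicated/missing
    ids; errors carry the 1-based line number.
    """
    legal = NUC_ALPHABET if alphabet == "nucleotide" else PROT_ALPHABET
    records: list[FastaRecord] = []
    seen: set[str] = set()
    cur_id = None
    cur_desc = ""
    cur_seq: list[str] = []
    header_line = 0

    def flush():
        if cur_id is None:
            return
        seq = "".join(cur_seq)
        if not seq:
            raise ParseError(f"{path}:{header_line}: record {cur_id!r} has an "
                             "empty sequence")
        records.append(FastaRecord(cur_id, seq, cur_desc))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                flush()
                parts = line[1:].split(None, 1)
                if not parts:
                    raise ParseError(f"{path}:{lineno}: empty FASTA header")
                cur_id = parts[0]
                if cur_id in seen:
                    raise ParseError(f"{path}:{lineno}: duplicate id {cur_id!r}")
                seen.add(cur_id)
                cur_desc = parts[1].strip() if len(parts) > 1 else ""
                cur_seq = []
                header_line = lineno
            else:
                if cur_id is None:
                    raise ParseError(f"{path}:{lineno}: sequence before header")
                chunk = line.strip().upper()
                bad = set(chunk) - legal
                if bad:
                    raise ParseError(
                        f"{path}:{lineno}: illegal {alphabet} character(s) "
                        f"{sorted(bad)}")
                cur_seq.append(chunk)
    flush()
    return records


def write_fasta(records: Iterable, path, width: int = 60) -> None:
    """Write records (anything with .id/.sequence, and optional .description)."""
    with open(path, "w") as fh:
        for rec in records:
            desc = getattr(rec, "description", "")
            header = f">{rec.id}" + (f" {desc}" if desc else "")
            fh.write(header + "\n")
            seq = rec.sequence
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_db_fasta(db: ReferenceDb, path, width: int = 60) -> None:
    write_fasta(
        [FastaRecord(rid, s, d) for rid, (s, d) in db.records.items()],
        path, width=width)


def read_qual(path) -> dict[str, list[int]]:
    """Read a FASTA-style .qual file: id -> list of Phred integers."""
    quals: dict[str, list[int]] = {}
    cur: list[int] | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                rid = line[1:].split(None, 1)[0]
                if not rid:
                    raise ParseError(f"{path}:{lineno}: empty header")
                if rid in quals:
                    raise ParseError(f"{path}:{lineno}: duplicate id {rid!r}")
                cur = quals.setdefault(rid, [])
            else:
                if cur is None:
                    raise ParseError(f"{path}:{lineno}: values before header")
                try:
                    cur.extend(int(tok) for tok in line.split())
                except ValueError:
                    raise ParseError(
                        f"{path}:{lineno}: non-integer quality value") from None
    return quals


def write_qual(quals: dict[str, Sequence[int]], path, per_line: int = 20) -> None:
    with open(path, "w") as fh:
        for rid, vals in quals.items():
            fh.write(f">{rid}\n")
            for i in range(0, len(vals), per_line):
                fh.write(" ".join(str(v) for v in vals[i:i + per_line]) + "\n")


def attach_qualities(reads: list[CloneRead], quals: dict[str, list[int]]) -> None:
    """Attach a .qual table to reads, validating length agreement."""
    for read in reads:
        if read.id in quals:
            q = quals[read.id]
            if len(q) != len(read.sequence):
                raise ValidationError(
                    f"{read.id}: {len(q)} qualities for "
                    f"{len(read.sequence)} bases")
            read.qualities = list(q)


# ---------------------------------------------------------------------------
# GFF3 (gene / mRNA / exon / CDS subset)
# ---------------------------------------------------------------------------

@dataclass
class GffGene:
    """A transcript-backed gene model for GFF3 round-tripping.

    ``exons``/``cds`` hold 0-based half-open genome intervals, ascending.
    """

    id: str
    seqid: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]] = field(default_factory=list)
    attributes: dict[str, str] = field(default_factory=dict)

    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


def _validate_gene(g: GffGene) -> None:
    if g.strand not in "+-":
        raise ValidationError(f"{g.id}: bad strand {g.strand!r}")
    if not g.exons:
        raise ValidationError(f"{g.id}: no exons")
    prev_end = -1
    for s, e in g.exons:
        if not (0 <= s < e):
            raise ValidationError(f"{g.id}: bad exon interval ({s},{e})")
        if s < prev_end:
            raise ValidationError(f"{g.id}: overlapping/unsorted exons")
        prev_end = e


def write_gff3(genes: Iterable[GffGene], path) -> None:
    """Emit validated models as GFF3 (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            _validate_gene(g)
            s, e = g.span()
            extra = "".join(f";{k}={v}" for k, v in sorted(g.attributes.items()))
            fh.write(f"{g.seqid}\tflcdna\tgene\t{s + 1}\t{e}\t.\t{g.strand}\t."
                     f"\tID=gene:{g.id}{extra}\n")
            fh.write(f"{g.seqid}\tflcdna\tmRNA\t{s + 1}\t{e}\t.\t{g.strand}\t."
                     f"\tID=mRNA:{g.id};Parent=gene:{g.id}\n")
            for i, (xs, xe) in enumerate(g.exons, start=1):
                fh.write(f"{g.seqid}\tflcdna\texon\t{xs + 1}\t{xe}\t.\t"
                         f"{g.strand}\t.\tID=exon:{g.id}.{i};Parent=mRNA:{g.id}\n")
            for i, (cs, ce) in enumerate(g.cds, start=1):
                fh.write(f"{g.seqid}\tflcdna\tCDS\t{cs + 1}\t{ce}\t.\t"
                         f"{g.strand}\t0\tID=cds:{g.id}.{i};Parent=mRNA:{g.id}\n")


_ATTR_RE = re.compile(r"([^;=]+)=([^;]*)")


def read_gff3(path) -> list[GffGene]:
    genes: dict[str, GffGene] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 columns")
            seqid, _src, ftype, start, end, _score, strand, _frame, attrs = cols
            s, e = int(start) - 1, int(end)
            adict = dict(_ATTR_RE.findall(attrs))
            if ftype == "gene":
                gid = adict["ID"].removeprefix("gene:")
                extra = {k: v for k, v in adict.items() if k != "ID"}
                genes[gid] = GffGene(gid, seqid, strand, exons=[],
                                     attributes=extra)
                order.append(gid)
            elif ftype == "exon":
                gid = adict["Parent"].removeprefix("mRNA:")
                genes[gid].exons.append((s, e))
            elif ftype == "CDS":
                gid = adict["Parent"].removeprefix("mRNA:")
                genes[gid].cds.append((s, e))
    for g in genes.values():
        g.exons.sort()
        g.cds.sort()
        _validate_gene(g)
    return [genes[gid] for gid in order]


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def write_table(rows: Iterable[dict] | pd.DataFrame, path) -> None:
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
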