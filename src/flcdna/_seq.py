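"""Low-level sequence helpers shared across modules.

All sequences are plain upper-case Python strings; alignment kernels work on
uint8 index arrays produced by :func:`encode_nuc` / :func:`encode_protein`.
Internal coordinates are 0-based half-open throughout the package; files are
written 1-based inclusive at the IO boundary only.
"""

from __future__ import annotations

import numpy as np
from Bio.Seq import Seq

NUC_ORDER = "ACGTNX"
NUC_INDEX = {c: i for i, c in enumerate(NUC_ORDER)}
NUC_ALPHABET = set(NUC_ORDER)

# 20 amino acids + ambiguity/stop; order fixed for the substitution matrix.
PROT_ORDER = "ARNDCQEGHILKMFPSTWYVBZX*"
PROT_INDEX = {c: i for i, c in enumerate(PROT_ORDER)}
PROT_ALPHABET = set(PROT_ORDER)

_COMP = str.maketrans("ACGTNX", "TGCANX")

STOP_CODONS = ("TGA", "TAA", "TAG")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def translate(cds: str) -> str:
    """Translate a CDS (stop codon, if present, is dropped from the protein)."""
    prot = str(Seq(cds[: len(cds) - len(cds) % 3]).translate())
    return prot[:-1] if prot.endswith("*") else prot


_NUC_LUT = np.full(256, 255, dtype=np.uint8)
for _c, _i in NUC_INDEX.items():
    _NUC_LUT[ord(_c)] = _i

_PROT_LUT = np.full(256, 255, dtype=np.uint8)
for _c, _i in PROT_INDEX.items():
    _PROT_LUT[ord(_c)] = _i
# tolerate selenocysteine/unknowns by mapping to X
for _c in "UOJ":
    _PROT_LUT[ord(_c)] = PROT_INDEX["X"]


def encode_nuc(seq: str) -> np.ndarray:
    arr = _NUC_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if arr.size and arr.max() == 255:
        bad = seq[int(np.argmax(arr == 255))]
        raise ValueError(f"illegal nucleotide character {bad!r}")
    return arr


def encode_protein(seq: str) -> np.ndarray:
    arr = _PROT_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if arr.size and arr.max() == 255:
        bad = seq[int(np.argmax(arr == 255))]
        raise ValueError(f"illegal amino-acid character {bad!r}")
    return arr


def random_seq(rng: np.random.Generator, length: int, gc: float = 0.4) -> str:
    """Random nucleotide string with the given expected GC fraction."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return "".join("ACGT"[i] for i in idx)


def longest_homopolymer(seq: str) -> int:
    if not seq:
        return 0
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        if run > best:
            best = run
    return best
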