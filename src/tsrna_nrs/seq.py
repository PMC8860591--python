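"""Sequence primitives shared across the pipeline.

Everything internal runs on the DNA alphabet {A,C,G,T}; RNA input (U) is
mapped to T on entry so tsRNAs, tRNA references and genomic sequence live
in one coordinate system.
"""

from __future__ import annotations

from typing import Iterable, Iterator, TextIO

import numpy as np

DNA = "ACGT"
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")
_U2T = str.maketrans("Uu", "Tt")

# integer encoding used by the vectorised aligner/scanner
BASE_INDEX = {b: i for i, b in enumerate(DNA)}


def normalize(seq: str) -> str:
    """Uppercase and map U->T. Raises on characters outside {A,C,G,T,U}."""
    s = seq.translate(_U2T).upper()
    if s.strip("ACGT"):
        bad = sorted(set(s) - set(DNA))
        raise ValueError(f"non-ACGT(U) characters in sequence: {bad}")
    return s


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode an ACGT string as uint8 indices."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.empty(arr.size, dtype=np.uint8)
    for base, idx in BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(DNA[i] for i in rng.integers(0, 4, size=length))


def write_fasta(records: Iterable[tuple[str, str]], handle: TextIO, width: int = 70) -> None:
    for name, seq in records:
        handle.write(f">{name}\n")
        for i in range(0, len(seq), width):
            handle.write(seq[i : i + width] + "\n")


def write_fastq(records: Iterable[tuple[str, str]], handle: TextIO, quality_char: str = "I") -> None:
    for name, seq in records:
        handle.write(f"@{name}\n{seq}\n+\n{quality_char * len(seq)}\n")


def read_seqs(path: str) -> Iterator[str]:
    """Yield normalized sequences from a FASTA or FASTQ file (by extension)."""
    from Bio import SeqIO

    fmt = "fastq" if str(path).endswith(("fastq", "fq")) else "fasta"
    for rec in SeqIO.parse(str(path), fmt):
        yield normalize(str(rec.seq))
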