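"""Gene models: ordered exons/introns on a genome with sequence access.

Coordinates are 0-based half-open internally; the GTF-like interchange
format is 1-based inclusive (columns: seqname, source, feature in
{gene, exon}, start, end, score, strand, frame, attributes with a
``gene_id`` key).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional

from .seq import revcomp


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    #: genomic exon intervals, 0-based half-open, ascending
    exons: list[tuple[int, int]]
    utr3: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        self.exons = sorted(tuple(e) for e in self.exons)
        for (s0, e0), (s1, e1) in zip(self.exons, self.exons[1:]):
            if e0 >= s1:
                raise ValueError(f"{self.gene_id}: exons overlap or touch")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Genomic intron intervals, ascending."""
        return [(e0, s1) for (_, e0), (s1, _) in zip(self.exons, self.exons[1:])]

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1

    def introns_transcription_order(self) -> list[tuple[int, int]]:
        ivs = self.introns
        return ivs if self.strand == "+" else ivs[::-1]

    def body_sequence(self, genome: Mapping[str, str]) -> str:
        """Unspliced sense-transcript sequence of the full gene body."""
        raw = genome[self.chrom][self.start : self.end]
        return raw if self.strand == "+" else revcomp(raw)

    def body_to_genomic(self, start: int, end: int) -> tuple[int, int]:
        """Map a body-coordinate interval (sense, 0-based half-open) to genomic."""
        if self.strand == "+":
            return self.start + start, self.start + end
        return self.end - end, self.end - start


def write_gene_models(models: list[GeneModel], path: str | Path, source: str = "sim") -> None:
    with open(path, "w") as fh:
        for m in models:
            attrs = f'gene_id "{m.gene_id}";'
            fh.write(
                f"{m.chrom}\t{source}\tgene\t{m.start + 1}\t{m.end}\t.\t{m.strand}\t.\t{attrs}\n"
            )
            for s, e in m.exons:
                fh.write(f"{m.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t{attrs}\n")


def read_gene_models(path: str | Path) -> list[GeneModel]:
    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str]] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, _, feature, start, end, _, strand, _, attrs = line.rstrip("\n").split("\t")
            gene_id = None
            for part in attrs.split(";"):
                part = part.strip()
                if part.startswith("gene_id"):
                    gene_id = part.split(None, 1)[1].strip('"')
            if gene_id is None:
                raise ValueError(f"missing gene_id attribute: {line!r}")
            if gene_id not in meta:
                meta[gene_id] = (chrom, strand)
                order.append(gene_id)
            if feature == "exon":
                exons.setdefault(gene_id, []).append((int(start) - 1, int(end)))
    return [
        GeneModel(gene_id=g, chrom=meta[g][0], strand=meta[g][1], exons=exons[g]) for g in order
    ]
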