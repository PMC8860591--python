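"""tRNA reference model.

Each tRNA gene is represented by four sequence *forms* that a small-RNA
fragment may derive from:

* ``mature``      — the spliced mature tRNA body,
* ``mature_cca``  — mature body with the post-transcriptional 3' CCA,
* ``pre``         — 5' leader + unspliced body (intron retained) + 3' trailer,
* ``flanked``     — the pre-tRNA with +/-7 nt of genomic context.

Coordinates of the optional intron are 0-based half-open on the unspliced
(mature-with-intron) body.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

import pandas as pd

from .seq import normalize, write_fasta

FORMS = ("mature", "mature_cca", "pre", "flanked")

#: width of the genomic context added on each side of the pre-tRNA
FLANK = 7


@dataclass(frozen=True)
class TRNAEntry:
    id: str
    isotype: str
    anticodon: str
    mature_seq: str
    leader_seq: str
    trailer_seq: str
    #: (insertion point in mature coordinates, intron sequence); None if intronless
    intron: Optional[tuple[int, str]] = None
    flank5: str = ""
    flank3: str = ""

    @property
    def mature_with_intron(self) -> str:
        if self.intron is None:
            return self.mature_seq
        pos, iseq = self.intron
        return self.mature_seq[:pos] + iseq + self.mature_seq[pos:]

    @property
    def intron_interval(self) -> Optional[tuple[int, int]]:
        """Intron location on the unspliced body, 0-based half-open."""
        if self.intron is None:
            return None
        pos, iseq = self.intron
        return (pos, pos + len(iseq))

    def form_seq(self, form: str) -> str:
        if form == "mature":
            return self.mature_seq
        if form == "mature_cca":
            return self.mature_seq + "CCA"
        if form == "pre":
            return self.leader_seq + self.mature_with_intron + self.trailer_seq
        if form == "flanked":
            return self.flank5 + self.leader_seq + self.mature_with_intron + self.trailer_seq + self.flank3
        raise KeyError(f"unknown tRNA form: {form!r}")


@dataclass
class TRNAReference:
    entries: list[TRNAEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._by_id = {e.id: e for e in self.entries}
        if len(self._by_id) != len(self.entries):
            raise ValueError("duplicate tRNA entry ids")

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, entry_id: str) -> TRNAEntry:
        return self._by_id[entry_id]

    def __contains__(self, entry_id: str) -> bool:
        return entry_id in self._by_id

    def iter_forms(self) -> Iterator[tuple[str, str, str]]:
        """Yield (entry_id, form, sequence) over all entries and forms."""
        for e in self.entries:
            for form in FORMS:
                yield e.id, form, e.form_seq(form)

    # ------------------------------------------------------------------ I/O

    def write(self, outdir: str | Path, prefix: str = "trna") -> dict[str, Path]:
        """Write one FASTA per form plus the sidecar annotation table.

        Returns the mapping of artifact name -> path.
        """
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        for form in FORMS:
            p = outdir / f"{prefix}_{form}.fa"
            with open(p, "w") as fh:
                write_fasta(((e.id, e.form_seq(form)) for e in self.entries), fh)
            paths[form] = p
        table = pd.DataFrame(
            {
                "id": [e.id for e in self.entries],
                "isotype": [e.isotype for e in self.entries],
                "anticodon": [e.anticodon for e in self.entries],
                "leader": [e.leader_seq for e in self.entries],
                "trailer": [e.trailer_seq for e in self.entries],
                "intron_start": [e.intron_interval[0] if e.intron else -1 for e in self.entries],
                "intron_end": [e.intron_interval[1] if e.intron else -1 for e in self.entries],
                "flank5": [e.flank5 for e in self.entries],
                "flank3": [e.flank3 for e in self.entries],
            }
        )
        tp = outdir / f"{prefix}_annotation.tsv"
        table.to_csv(tp, sep="\t", index=False)
        paths["annotation"] = tp
        return paths

    @classmethod
    def load(cls, mature_fasta: str | Path, annotation_tsv: str | Path) -> "TRNAReference":
        """Rebuild a reference from the mature FASTA plus the sidecar table."""
        from Bio import SeqIO

        mature = {rec.id: normalize(str(rec.seq)) for rec in SeqIO.parse(str(mature_fasta), "fasta")}
        table = pd.read_csv(annotation_tsv, sep="\t", keep_default_na=False)
        entries = []
        for row in table.itertuples(index=False):
            m = mature[row.id]
            intron = None
            if int(row.intron_start) >= 0:
                # sidecar stores unspliced coordinates; recover the intron seq
                # is not possible from the spliced FASTA alone, so the sidecar
                # must carry it when present
                raise ValueError(
                    "intron-bearing references must be reloaded via the pre-tRNA FASTA; "
                    "use TRNAReference.load_full"
                )
            entries.append(
                TRNAEntry(
                    id=row.id,
                    isotype=row.isotype,
                    anticodon=row.anticodon,
                    mature_seq=m,
                    leader_seq=normalize(row.leader) if row.leader else "",
                    trailer_seq=normalize(row.trailer) if row.trailer else "",
                    intron=intron,
                    flank5=normalize(row.flank5) if row.flank5 else "",
                    flank3=normalize(row.flank3) if row.flank3 else "",
                )
            )
        return cls(entries)

    @classmethod
    def load_full(cls, pre_fasta: str | Path, annotation_tsv: str | Path) -> "TRNAReference":
        """Rebuild a reference (introns included) from the pre-tRNA FASTA."""
        from Bio import SeqIO

        pre = {rec.id: normalize(str(rec.seq)) for rec in SeqIO.parse(str(pre_fasta), "fasta")}
        table = pd.read_csv(annotation_tsv, sep="\t", keep_default_na=False)
        entries = []
        for row in table.itertuples(index=False):
            leader = normalize(row.leader) if row.leader else ""
            trailer = normalize(row.trailer) if row.trailer else ""
            body = pre[row.id][len(leader) : len(pre[row.id]) - len(trailer) or None]
            intron = None
            if int(row.intron_start) >= 0:
                s, e = int(row.intron_start), int(row.intron_end)
                intron = (s, body[s:e])
                body = body[:s] + body[e:]
            entries.append(
                TRNAEntry(
                    id=row.id,
                    isotype=row.isotype,
                    anticodon=row.anticodon,
                    mature_seq=body,
                    leader_seq=leader,
                    trailer_seq=trailer,
                    intron=intron,
                    flank5=normalize(row.flank5) if row.flank5 else "",
                    flank3=normalize(row.flank3) if row.flank3 else "",
                )
            )
        return cls(entries)
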