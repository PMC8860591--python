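"""PAR-CLIP tsRNA selection.

PAR-CLIP reads carry crosslink-induced T->C conversions; before counting,
each aligned read is *equalized to its genomic sequence* (every mismatching
position replaced by the reference base). Sequences are then length- and
occurrence-filtered per protein set (Ago1-4 and three Dicer replicates),
grouped into near-identical clusters (one terminal nucleotide of length
difference per edge), and intersected with Dicer dependence from the
small-RNA-seq differential results.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .annotate import ReadAlignment
from .reference import TRNAReference

logger = logging.getLogger(__name__)

AGO_SETS = ("Ago1", "Ago2", "Ago3", "Ago4")
DICER_SETS = ("Dicer_rep1", "Dicer_rep2", "Dicer_rep3")


@dataclass(frozen=True)
class ParclipThresholds:
    length_min: int = 18
    length_max: int = 22
    ago_min_occurrence: int = 25
    dicer_rep_min: tuple[int, int, int] = (323, 41, 19)

    def __post_init__(self) -> None:
        if self.length_min > self.length_max:
            raise ValueError("length_min > length_max")
        if self.ago_min_occurrence <= 0 or any(t <= 0 for t in self.dicer_rep_min):
            raise ValueError("occurrence thresholds must be positive")


@dataclass
class TsRNACandidate:
    sequence: str
    occurrences: dict[str, int] = field(default_factory=dict)
    cluster_id: int | None = None
    ago_bound: bool = False
    dicer_bound: bool = False
    dicer_dependent: bool = False
    log2fc: float | None = None
    de_missing: bool = False

    @property
    def total_occurrence(self) -> int:
        return sum(self.occurrences.values())


def equalize_to_genome(alignment: ReadAlignment, ref: TRNAReference) -> str:
    """Replace every mismatching read position with the reference base.

    Returns the reference substring [start, end) of the aligned form, which
    reverts T->C conversions and sequencing errors alike.
    """
    form_seq = ref[alignment.reference_id].form_seq(alignment.form)
    if alignment.start < 0 or alignment.end > len(form_seq):
        raise ValueError("alignment coordinates outside the reference form")
    return form_seq[alignment.start : alignment.end]


def filter_parclip(
    readsets: Mapping[str, Mapping[str, int]],
    thr: ParclipThresholds = ParclipThresholds(),
    ago_mode: str = "each_set",
) -> list[TsRNACandidate]:
    """Length- and occurrence-filter PAR-CLIP sequences into candidates.

    A sequence is retained when 18 <= length <= 22 (per ``thr``), it passes
    the Ago rule — occurrence >= 25 in *every* Ago set (``each_set``) or
    summed across Ago sets (``combined``) — and it passes the Dicer rule in
    at least one replicate at that replicate's threshold.
    """
    if ago_mode not in ("each_set", "combined"):
        raise ValueError(f"unknown ago_mode {ago_mode!r}")
    known = set(AGO_SETS) | set(DICER_SETS)
    unknown = set(readsets) - known
    if unknown:
        raise KeyError(f"unknown protein set(s): {sorted(unknown)}")

    all_seqs: set[str] = set()
    for occs in readsets.values():
        all_seqs.update(occs)

    out: list[TsRNACandidate] = []
    for seq in sorted(all_seqs):
        if not thr.length_min <= len(seq) <= thr.length_max:
            continue
        occ = {p: int(readsets.get(p, {}).get(seq, 0)) for p in (*AGO_SETS, *DICER_SETS)}
        if ago_mode == "each_set":
            ago_ok = all(occ[p] >= thr.ago_min_occurrence for p in AGO_SETS)
        else:
            ago_ok = sum(occ[p] for p in AGO_SETS) >= thr.ago_min_occurrence
        dicer_ok = any(occ[p] >= t for p, t in zip(DICER_SETS, thr.dicer_rep_min))
        if ago_ok and dicer_ok:
            out.append(TsRNACandidate(seq, occ, ago_bound=ago_ok, dicer_bound=dicer_ok))
    return out


def _one_nt_longer(longer: str, shorter: str) -> bool:
    """True when ``longer`` equals ``shorter`` plus one terminal nucleotide."""
    return len(longer) == len(shorter) + 1 and (
        longer[:-1] == shorter or longer[1:] == shorter
    )


def group_near_identical(
    seqs: Iterable[str],
    abundance: Mapping[str, int] | None = None,
) -> tuple[dict[str, int], dict[int, str]]:
    """Cluster sequences by the transitive closure of one-terminal-nt
    extension.

    Returns ``(assignment, representatives)``: sequence -> cluster id and
    cluster id -> representative (most abundant member; ties broken by
    shortest, then lexicographic order). Cluster ids are dense integers
    ordered by their representative.
    """
    seqs = sorted(set(seqs))
    index = {s: i for i, s in enumerate(seqs)}
    parent = list(range(len(seqs)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    pool = set(seqs)
    for s in seqs:
        for shorter in (s[:-1], s[1:]):
            if shorter in pool:
                union(index[s], index[shorter])

    members: dict[int, list[str]] = {}
    for s in seqs:
        members.setdefault(find(index[s]), []).append(s)

    def rep_key(s: str) -> tuple:
        a = abundance.get(s, 0) if abundance else 0
        return (-a, len(s), s)

    reps = sorted(min(group, key=rep_key) for group in members.values())
    rep_to_id = {r: i for i, r in enumerate(reps)}
    assignment = {}
    for root, group in members.items():
        rep = min(group, key=rep_key)
        for s in group:
            assignment[s] = rep_to_id[rep]
    return assignment, {i: r for r, i in rep_to_id.items()}


def select_dicer_dependent(
    candidates: Sequence[TsRNACandidate],
    de: Mapping[str, float],
    threshold: float = 1.0,
    mode: str = "absolute",
) -> list[TsRNACandidate]:
    """Keep candidates whose sRNA-seq log2 fold change marks Dicer dependence.

    ``absolute`` mode keeps |log2FC| > threshold (the printed rule);
    ``negative`` keeps log2FC < -threshold (depletion upon Dicer loss).
    Candidates missing from ``de`` are flagged (``de_missing``), not
    silently dropped from the input collection, but are never selected.
    """
    if mode not in ("absolute", "negative"):
        raise ValueError(f"unknown mode {mode!r}")
    kept: list[TsRNACandidate] = []
    for cand in candidates:
        if cand.sequence not in de:
            cand.de_missing = True
            logger.warning("candidate %s absent from sRNA DE results", cand.sequence)
            continue
        lfc = float(de[cand.sequence])
        cand.log2fc = lfc
        ok = abs(lfc) > threshold if mode == "absolute" else lfc < -threshold
        if ok:
            cand.dicer_dependent = True
            kept.append(cand)
    return kept
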