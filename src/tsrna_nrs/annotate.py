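"""Mismatch-tolerant mapping of unique sequences to tRNA forms and
hierarchical origin classification.

Mapping is an ungapped scan of every offset of every reference form on the
sense strand, keeping all alignments in the *best stratum* (the minimum
mismatch count achieved by the query), none beyond ``max_mismatch`` — the
behaviour of ``bowtie -v3 --all --best --strata`` restricted to the tRNA
reference space.

Categories, in priority order:

1. ``tRNA_CCA_end`` — alignment on the CCA form ending at its 3' terminus;
2. ``tRNA_3p_end``  — alignment on the mature form ending at its 3' terminus;
3. ``tRNA_5p_end``  — alignment starting at mature position 0;
4. ``pre_tRNA``     — best alignment on the pre/flanked form covering at
   least one nucleotide of leader, trailer or intron (3'-end reads are
   captured by rule 2 first and never reach this rule);
5. ``tRNA_other``   — internal mature-body alignments;
6. ``unannotated``  — no alignment at all.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .reference import FORMS, TRNAReference
from .seq import encode

CATEGORIES = ("tRNA_5p_end", "tRNA_3p_end", "tRNA_CCA_end", "pre_tRNA", "tRNA_other", "unannotated")


@dataclass(frozen=True)
class ReadAlignment:
    query: str
    reference_id: str
    form: str
    start: int
    end: int
    mismatch_positions: tuple[int, ...]

    @property
    def mismatch_count(self) -> int:
        return len(self.mismatch_positions)


def align_to_reference(
    seqs: Iterable[str],
    ref: TRNAReference,
    max_mismatch: int = 3,
) -> dict[str, list[ReadAlignment]]:
    """Best-stratum ungapped alignments for each query sequence.

    Returns a mapping query -> alignments (empty list when the query has no
    alignment within ``max_mismatch``). Alignments are ordered by
    (reference id, form, start) for reproducibility.
    """
    if len(ref) == 0:
        raise ValueError("empty tRNA reference")
    queries = sorted(set(seqs))
    forms = [(eid, form, s, encode(s)) for eid, form, s in ref.iter_forms()]
    form_order = {f: i for i, f in enumerate(FORMS)}

    by_len: dict[int, list[str]] = {}
    for q in queries:
        by_len.setdefault(len(q), []).append(q)

    result: dict[str, list[ReadAlignment]] = {q: [] for q in queries}
    best: dict[str, int] = {q: max_mismatch + 1 for q in queries}
    for L, group in sorted(by_len.items()):
        qmat = np.stack([encode(q) for q in group])  # (k, L)
        for eid, form, fseq, farr in forms:
            if farr.size < L:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(farr, L)  # (n_off, L)
            # (k, n_off) mismatch counts
            mism = (windows[None, :, :] != qmat[:, None, :]).sum(axis=2)
            hit_q, hit_o = np.nonzero(mism <= max_mismatch)
            for qi, off in zip(hit_q.tolist(), hit_o.tolist()):
                q = group[qi]
                m = int(mism[qi, off])
                if m > best[q]:
                    continue
                if m < best[q]:
                    best[q] = m
                    result[q] = []
                positions = tuple(np.nonzero(windows[off] != qmat[qi])[0].tolist())
                result[q].append(ReadAlignment(q, eid, form, off, off + L, positions))
    for q in queries:
        result[q].sort(key=lambda a: (a.reference_id, form_order[a.form], a.start))
    return result


def _covers_non_mature(aln: ReadAlignment, ref: TRNAReference) -> bool:
    """Does a pre/flanked alignment touch leader, trailer, intron or flank?"""
    entry = ref[aln.reference_id]
    start, end = aln.start, aln.end
    if aln.form == "flanked":
        f5 = len(entry.flank5)
        if start < f5 or end > f5 + len(entry.form_seq("pre")):
            return True  # covers the genomic flank itself
        start -= f5
        end -= f5
    leader = len(entry.leader_seq)
    body_end = leader + len(entry.mature_with_intron)
    if start < leader or end > body_end:
        return True
    iv = entry.intron_interval
    if iv is not None:
        i0, i1 = leader + iv[0], leader + iv[1]
        if start < i1 and end > i0:
            return True
    return False


def annotate_tsrna(
    alignments: Sequence[ReadAlignment],
    ref: TRNAReference,
    end_slack: int = 0,
) -> str:
    """Resolve one query's best-stratum alignments to a single category.

    ``end_slack`` relaxes the terminal-boundary rules by that many
    nucleotides (default 0: exact boundaries required).
    """
    if not alignments:
        return "unannotated"
    for a in alignments:
        if a.reference_id not in ref:
            raise KeyError(f"alignment references unknown entry {a.reference_id!r}")
    for a in alignments:
        if a.form == "mature_cca" and a.end >= len(ref[a.reference_id].mature_seq) + 3 - end_slack:
            return "tRNA_CCA_end"
    for a in alignments:
        if a.form == "mature" and a.end >= len(ref[a.reference_id].mature_seq) - end_slack:
            return "tRNA_3p_end"
    for a in alignments:
        if a.form == "mature" and a.start <= end_slack:
            return "tRNA_5p_end"
    for a in alignments:
        if a.form in ("pre", "flanked") and _covers_non_mature(a, ref):
            return "pre_tRNA"
    return "tRNA_other"


def annotate_collection(
    collapsed: pd.DataFrame,
    ref: TRNAReference,
    max_mismatch: int = 3,
    end_slack: int = 0,
) -> pd.DataFrame:
    """Annotate a collapsed unique-sequence table (adds category columns).

    Returns a DataFrame with ``sequence``, ``category``, ``best_reference``,
    ``isotype``, ``length`` and the count columns carried over.
    """
    seqs = collapsed["sequence"].tolist()
    alns = align_to_reference(seqs, ref, max_mismatch=max_mismatch)
    cats, refs, isos = [], [], []
    for s in seqs:
        a = alns[s]
        cats.append(annotate_tsrna(a, ref, end_slack=end_slack))
        refs.append(a[0].reference_id if a else "")
        isos.append(ref[a[0].reference_id].isotype if a else "")
    out = collapsed.copy()
    out["category"] = cats
    out["best_reference"] = refs
    out["isotype"] = isos
    out["length"] = out["sequence"].str.len()
    return out


def length_distribution(
    annotated: pd.DataFrame,
    count_col: str = "total",
) -> tuple[pd.DataFrame, pd.Series]:
    """Count-weighted length histograms per category plus the cumulative
    fraction F(L) of weight at lengths <= L (over all categories).

    Returns ``(histogram, cumulative)``; both empty when the input is empty
    (F is undefined in that case).
    """
    if annotated.empty:
        return pd.DataFrame(), pd.Series(dtype=float)
    hist = (
        annotated.pivot_table(
            index="length", columns="category", values=count_col, aggfunc="sum", fill_value=0
        )
        .sort_index()
    )
    weights = annotated.groupby("length")[count_col].sum().sort_index()
    cumulative = weights.cumsum() / weights.sum()
    cumulative.name = "cumulative_fraction"
    return hist, cumulative
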