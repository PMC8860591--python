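"""miRanda-style tsRNA target scanning.

A tsRNA binds a transcript antiparallel, so the reversed tsRNA is locally
aligned against the gene sequence under *complementarity* scoring: A-T and
G-C columns are matches, G-T is the RNA wobble, anything else a mismatch.
Column scores for tsRNA positions 2-8 from the 5' end (the seed) are
multiplied by ``seed_scale``; gap penalties are affine and not seed-scaled.
A reported site must reach the alignment score threshold (-sc) and, unless
running in relaxed mode, a nearest-neighbor duplex free energy at or below
the energy threshold (-en).

The per-gene scan is an exact column-vectorised Smith-Waterman/Gotoh: the
vertical affine-gap recurrence is resolved with a prefix-scan, which is
exact because gap_open < gap_extend (a gap continued from a gap-derived
cell can never beat extending the existing gap).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .genemodel import GeneModel
from .seq import encode, normalize

NEG = -1e9


@dataclass(frozen=True)
class ScoringParams:
    match: float = 5.0
    gu_wobble: float = 1.0
    mismatch: float = -3.0
    gap_open: float = -9.0
    gap_extend: float = -4.0
    #: seed positions on the tsRNA, 1-based inclusive from the 5' end
    seed_start: int = 2
    seed_end: int = 8
    seed_scale: float = 4.0
    score_threshold: float = 150.0
    energy_threshold: float = -30.0

    def __post_init__(self) -> None:
        if self.score_threshold <= 0:
            raise ValueError("score_threshold must be positive")
        if self.energy_threshold > 0:
            raise ValueError("energy threshold must be <= 0")


#: relaxed parameters of the cross-species (mouse homolog) run:
#: alignment score threshold 140, no energy filter
RELAXED_SCORE_THRESHOLD = 140.0


def pair_matrix(params: ScoringParams) -> np.ndarray:
    """5x5 complementarity score matrix (A,C,G,T + padding row/col)."""
    S = np.full((5, 5), params.mismatch)
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    for a, b in (("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")):
        S[idx[a], idx[b]] = params.match
    for a, b in (("G", "T"), ("T", "G")):
        S[idx[a], idx[b]] = params.gu_wobble
    S[4, :] = NEG
    S[:, 4] = NEG
    return S


def seed_weights(length: int, params: ScoringParams) -> np.ndarray:
    """Per-position column weights for the *reversed* tsRNA."""
    pos1 = length - np.arange(length)  # 1-based tsRNA position of reversed index
    return np.where((pos1 >= params.seed_start) & (pos1 <= params.seed_end), params.seed_scale, 1.0)


@dataclass(frozen=True)
class AlignmentTrace:
    """A tsRNA/target duplex alignment.

    ``query_aligned`` reads tsRNA 5'->3'; ``target_aligned`` is the aligned
    target segment written antiparallel (3'->5') so columns pair up.
    ``target_start``/``target_end`` are 0-based half-open on the scanned
    sequence; ``query_start``/``query_end`` likewise on the tsRNA.
    """

    query_aligned: str
    pair_string: str
    target_aligned: str
    query_start: int
    query_end: int
    target_start: int
    target_end: int


def _gotoh_matrices(qr: np.ndarray, w: np.ndarray, t: np.ndarray, S: np.ndarray, params: ScoringParams):
    """Full Smith-Waterman/Gotoh DP of reversed query vs target segment."""
    m, n = qr.size, t.size
    go, ge = params.gap_open, params.gap_extend
    H = np.zeros((m + 1, n + 1))
    E = np.full((m + 1, n + 1), NEG)  # gap in target direction (consumes target)
    F = np.full((m + 1, n + 1), NEG)  # gap consuming query
    for i in range(1, m + 1):
        sub_row = S[qr[i - 1], t] * w[i - 1]
        for j in range(1, n + 1):
            E[i, j] = max(H[i, j - 1] + go, E[i, j - 1] + ge)
            F[i, j] = max(H[i - 1, j] + go, F[i - 1, j] + ge)
            H[i, j] = max(0.0, H[i - 1, j - 1] + sub_row[j - 1], E[i, j], F[i, j])
    return H, E, F


def _traceback(qr_s: str, t_s: str, H, E, F, i: int, j: int, w: np.ndarray, S: np.ndarray, params: ScoringParams):
    """Recover the alignment ending at cell (i, j); returns column lists."""
    go, ge = params.gap_open, params.gap_extend
    qcols: list[str] = []
    tcols: list[str] = []
    qi = {"A": 0, "C": 1, "G": 2, "T": 3}
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            if H[i, j] == 0.0:
                break
            sub = S[qi[qr_s[i - 1]], qi[t_s[j - 1]]] * w[i - 1]
            if H[i, j] == H[i - 1, j - 1] + sub:
                qcols.append(qr_s[i - 1])
                tcols.append(t_s[j - 1])
                i, j = i - 1, j - 1
            elif H[i, j] == E[i, j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            qcols.append("-")
            tcols.append(t_s[j - 1])
            if E[i, j] == H[i, j - 1] + go:
                state = "H"
            j -= 1
        else:  # F
            qcols.append(qr_s[i - 1])
            tcols.append("-")
            if F[i, j] == H[i - 1, j] + go:
                state = "H"
            i -= 1
    return qcols[::-1], tcols[::-1], i, j


_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "T"), ("T", "G")}


def _pair_char(q: str, t: str) -> str:
    if (q, t) in _PAIRS:
        return "|"
    if (q, t) in _WOBBLE:
        return ":"
    return " "


def score_site(
    tsrna: str,
    window: str,
    params: ScoringParams = ScoringParams(),
) -> tuple[float, Optional[AlignmentTrace]]:
    """Best local duplex alignment of a tsRNA against a sequence window.

    Returns ``(score, trace)``; the trace is None when the best score is 0
    (no complementary pairing at all).
    """
    tsrna = normalize(tsrna)
    window = normalize(window)
    if not 16 <= len(tsrna) <= 30:
        raise ValueError("tsRNA length must lie in [16, 30]")
    if len(window) < 8:
        raise ValueError("window shorter than 8 nt")
    qr_s = tsrna[::-1]
    qr = encode(qr_s)
    w = seed_weights(len(tsrna), params)
    t = encode(window)
    S = pair_matrix(params)
    H, E, F = _gotoh_matrices(qr, w, t, S, params)
    score = float(H.max())
    if score <= 0.0:
        return 0.0, None
    i, j = np.unravel_index(int(H.argmax()), H.shape)
    return score, _build_trace(qr_s, window, H, E, F, int(i), int(j), w, S, params, len(tsrna))


def _build_trace(qr_s, window, H, E, F, i, j, w, S, params, m) -> AlignmentTrace:
    qcols, tcols, i0, j0 = _traceback(qr_s, window, H, E, F, i, j, w, S, params)
    # flip to tsRNA 5'->3' orientation: reversed-query indices [i0, i) map to
    # tsRNA positions [m - i, m - i0)
    q_aln = "".join(qcols)[::-1]
    t_aln = "".join(tcols)[::-1]
    pair = "".join(
        _pair_char(q, t) if q != "-" and t != "-" else " " for q, t in zip(q_aln, t_aln)
    )
    return AlignmentTrace(
        query_aligned=q_aln,
        pair_string=pair,
        target_aligned=t_aln,
        query_start=m - i,
        query_end=m - i0,
        target_start=j0,
        target_end=j,
    )


# --------------------------------------------------------------- gene scan


def scan_candidates(
    tsrnas: Sequence[str],
    target: str,
    params: ScoringParams,
    threshold: float,
) -> list[list[tuple[float, int]]]:
    """Exact vectorised scan of many tsRNAs over one target sequence.

    Returns, per tsRNA, the list of ``(score, end)`` cells (end exclusive,
    target coordinates) whose best-in-column alignment score reaches
    ``threshold``.
    """
    nq = len(tsrnas)
    if nq == 0 or not target:
        return [[] for _ in range(nq)]
    m_max = max(len(q) for q in tsrnas)
    Q = np.full((nq, m_max), 4, dtype=np.uint8)
    W = np.ones((nq, m_max))  # pad weight 1 so padded columns keep NEG scores
    for k, q in enumerate(tsrnas):
        Q[k, : len(q)] = encode(q[::-1])
        W[k, : len(q)] = seed_weights(len(q), params)
    t = encode(target)
    S = pair_matrix(params)
    go, ge = params.gap_open, params.gap_extend
    # rows r = 0..m_max-1 represent query index i = r+1
    H_prev = np.zeros((nq, m_max))
    E_prev = np.full((nq, m_max), NEG)
    rows = np.arange(m_max)
    bound = go + rows * ge  # vertical gap opened from the zero row
    out: list[list[tuple[float, int]]] = [[] for _ in range(nq)]
    sub_all = S[Q]  # (nq, m_max, 4)
    for j in range(t.size):
        sub = sub_all[:, :, t[j]] * W
        E = np.maximum(H_prev + go, E_prev + ge)
        Hdiag = np.concatenate([np.zeros((nq, 1)), H_prev[:, :-1]], axis=1)
        Ht = np.maximum(np.maximum(Hdiag + sub, E), 0.0)
        # lazy-F prefix scan (exact: gap_open < gap_extend)
        B = np.maximum.accumulate(Ht - rows * ge, axis=1)
        Fv = np.full((nq, m_max), NEG)
        Fv[:, 1:] = B[:, :-1] + go + (rows[1:] - 1) * ge
        Fv = np.maximum(Fv, bound)
        H = np.maximum(Ht, Fv)
        best = H.max(axis=1)
        hits = np.nonzero(best >= threshold)[0]
        for k in hits.tolist():
            out[k].append((float(best[k]), j + 1))
        H_prev, E_prev = H, E
    return out


def align_ending_at(
    tsrna: str,
    target: str,
    end: int,
    expected_score: float,
    params: ScoringParams,
) -> tuple[float, AlignmentTrace]:
    """Recover the best alignment ending exactly at ``end`` (exclusive).

    Recomputes the DP on a window left of ``end``, widening until the score
    matches the scan value.
    """
    tsrna = normalize(tsrna)
    m = len(tsrna)
    qr_s = tsrna[::-1]
    qr = encode(qr_s)
    w = seed_weights(m, params)
    S = pair_matrix(params)
    width = 4 * m + 16
    while True:
        ws = max(0, end - width)
        seg = target[ws:end]
        H, E, F = _gotoh_matrices(qr, w, encode(seg), S, params)
        i = int(H[:, -1].argmax())
        score = float(H[i, -1])
        if abs(score - expected_score) < 1e-6 or ws == 0:
            trace = _build_trace(qr_s, seg, H, E, F, i, H.shape[1] - 1, w, S, params, m)
            trace = replace(
                trace, target_start=trace.target_start + ws, target_end=trace.target_end + ws
            )
            return score, trace
        width *= 2


# ------------------------------------------------------------ duplex energy


@dataclass(frozen=True)
class NearestNeighborTable:
    """Simplified nearest-neighbor duplex free energies (kcal/mol).

    Watson-Crick stacks are keyed by the tsRNA-strand dinucleotide read
    5'->3'; stacks involving a G:T wobble pair collapse onto one flat value.
    Gaps and mismatches interrupt stacking. Terminal A:T or G:T pairs pay a
    closure penalty, duplex formation an initiation penalty.
    """

    stacks: Mapping[str, float] = field(
        default_factory=lambda: {
            "AA": -0.93, "AC": -2.24, "AG": -2.08, "AT": -1.10,
            "CA": -2.11, "CC": -3.26, "CG": -2.36, "CT": -2.08,
            "GA": -2.35, "GC": -3.42, "GG": -3.26, "GT": -2.24,
            "TA": -1.33, "TC": -2.35, "TG": -2.11, "TT": -0.93,
        }
    )
    wobble_stack: float = -1.0
    initiation: float = 4.09
    terminal_au: float = 0.45

    def __post_init__(self) -> None:
        if any(v >= 0 for v in self.stacks.values()):
            raise ValueError("stack energies must be negative")
        if self.initiation <= 0:
            raise ValueError("initiation penalty must be positive")


def duplex_energy(
    trace: AlignmentTrace,
    table: NearestNeighborTable = NearestNeighborTable(),
) -> float:
    """Free energy of the aligned duplex.

    Initiation + sum of stack energies over adjacent paired columns +
    terminal closure penalties for weak (A:T / G:T) end pairs. Mismatched
    or gapped columns break stacks.
    """
    q, t = trace.query_aligned, trace.target_aligned
    paired = [
        q[k] != "-" and t[k] != "-" and ((q[k], t[k]) in _PAIRS or (q[k], t[k]) in _WOBBLE)
        for k in range(len(q))
    ]
    if not any(paired):
        raise ValueError("trace contains no base pair")
    dg = table.initiation
    for k in range(len(q) - 1):
        if paired[k] and paired[k + 1]:
            wob = (q[k], t[k]) in _WOBBLE or (q[k + 1], t[k + 1]) in _WOBBLE
            dg += table.wobble_stack if wob else table.stacks[q[k] + q[k + 1]]
    ends = [k for k in range(len(q)) if paired[k]]
    for k in {ends[0], ends[-1]}:
        if {q[k], t[k]} != {"G", "C"}:  # weak closing pair: A:T or G:T
            dg += table.terminal_au
    return dg


# ------------------------------------------------------------- target sites


@dataclass
class TargetSite:
    tsrna_id: str
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    score: float
    energy: Optional[float]
    region: str = ""
    intron_ordinal: Optional[int] = None
    within_intron_offset: Optional[float] = None
    trace: Optional[AlignmentTrace] = None


def classify_site_region(site: TargetSite, gene: GeneModel) -> TargetSite:
    """Label a site by the gene region containing its midpoint.

    Intronic sites get the transcription-order intron ordinal (0-based) and
    the relative offset within that intron (transcription direction).
    """
    if site.start < gene.start or site.end > gene.end:
        raise ValueError(f"site outside gene body of {gene.gene_id}")
    mid = (site.start + site.end) // 2
    if gene.utr3 is not None and gene.utr3[0] <= mid < gene.utr3[1]:
        site.region = "utr3"
        return site
    for ordinal, (s, e) in enumerate(gene.introns_transcription_order()):
        if s <= mid < e:
            site.region = f"intron({ordinal})"
            site.intron_ordinal = ordinal
            if gene.strand == "+":
                site.within_intron_offset = (mid - s) / (e - s)
            else:
                site.within_intron_offset = (e - 1 - mid) / (e - s)
            return site
    site.region = "exon"
    return site


def predict_targets(
    tsrnas: Mapping[str, str],
    genes: Sequence[GeneModel],
    genome: Mapping[str, str],
    params: ScoringParams = ScoringParams(),
    relaxed: bool = False,
    energy_table: NearestNeighborTable = NearestNeighborTable(),
) -> list[TargetSite]:
    """Scan tsRNAs over full unspliced gene bodies and report target sites.

    Default mode reports non-overlapping local optima (greedy by descending
    score, per tsRNA/gene pair) with score >= ``params.score_threshold``
    and duplex energy <= ``params.energy_threshold``. Relaxed mode (the
    cross-species run) lowers the score threshold to 140 and drops the
    energy filter.
    """
    threshold = RELAXED_SCORE_THRESHOLD if relaxed else params.score_threshold
    ids = sorted(tsrnas)
    seqs = [normalize(tsrnas[i]) for i in ids]
    sites: list[TargetSite] = []
    for gene in genes:
        if gene.chrom not in genome:
            raise KeyError(f"no sequence for gene {gene.gene_id} (chrom {gene.chrom})")
        body = gene.body_sequence(genome)
        cands = scan_candidates(seqs, body, params, threshold)
        for tid, seq, cand in zip(ids, seqs, cands):
            cand.sort(key=lambda t: (-t[0], t[1]))
            accepted: list[tuple[int, int]] = []
            for cscore, cend in cand:
                if any(s < cend <= e for s, e in accepted):
                    continue
                score, trace = align_ending_at(seq, body, cend, cscore, params)
                iv = (trace.target_start, trace.target_end)
                if any(iv[0] < e and s < iv[1] for s, e in accepted):
                    continue
                energy = duplex_energy(trace, energy_table)
                if not relaxed and energy > params.energy_threshold:
                    continue
                accepted.append(iv)
                g0, g1 = gene.body_to_genomic(*iv)
                site = TargetSite(
                    tsrna_id=tid,
                    gene_id=gene.gene_id,
                    chrom=gene.chrom,
                    start=g0,
                    end=g1,
                    strand=gene.strand,
                    score=score,
                    energy=energy,
                    trace=trace,
                )
                sites.append(classify_site_region(site, gene))
    sites.sort(key=lambda s: (s.gene_id, s.start, s.tsrna_id))
    return sites
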