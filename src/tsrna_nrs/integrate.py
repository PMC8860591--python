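"""Downstream integration of differential expression and target prediction.

Covers the Venn intersection of knockdown-upregulated gene sets, the
intron/exon partition of target genes, the intronic metagene profile, the
conservation comparison between Dicer-dependent and other target sites, the
cross-species conservation-fraction statistic, gene-disease Fisher
enrichment and the tRNA-expression/tsRNA-abundance correlation.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genemodel import GeneModel
from .targets import TargetSite

logger = logging.getLogger(__name__)


# ------------------------------------------------------------------- Venn


def intersect_upregulated(
    dicer_up: set[str],
    ago2_up: set[str],
    drosha_up: set[str],
    exclude_drosha: bool = True,
) -> tuple[dict[str, int], set[str]]:
    """Seven-region Venn counts plus the working target-gene universe.

    Region keys are ``dicer``/``ago2``/``drosha`` membership patterns such
    as ``"110"`` (in Dicer and Ago2 but not Drosha). The universe is
    ``dicer_up & ago2_up``, minus ``drosha_up`` when ``exclude_drosha``.
    """
    venn: dict[str, int] = {}
    everything = dicer_up | ago2_up | drosha_up
    for d, a, r in itertools.product((1, 0), repeat=3):
        if (d, a, r) == (0, 0, 0):
            continue
        exact = {
            g
            for g in everything
            if (g in dicer_up) == bool(d) and (g in ago2_up) == bool(a) and (g in drosha_up) == bool(r)
        }
        venn[f"{d}{a}{r}"] = len(exact)
    universe = dicer_up & ago2_up
    if exclude_drosha:
        universe -= drosha_up
    return venn, universe


# -------------------------------------------------------------- partition


def partition_target_genes(
    sites: Sequence[TargetSite],
    universe: set[str],
) -> dict[str, set[str]]:
    """Partition the gene universe by where its target sites fall.

    ``intronic_or_both``: at least one intronic site; ``exon_only``: sites
    but none intronic; ``untargeted``: no sites. The three sets partition
    the universe exactly.
    """
    intronic: set[str] = set()
    targeted: set[str] = set()
    for s in sites:
        if s.gene_id not in universe:
            raise ValueError(f"site for gene {s.gene_id} outside the universe")
        targeted.add(s.gene_id)
        if s.intron_ordinal is not None:
            intronic.add(s.gene_id)
    return {
        "intronic_or_both": intronic,
        "exon_only": targeted - intronic,
        "untargeted": universe - targeted,
    }


# --------------------------------------------------------------- metagene


@dataclass(frozen=True)
class MetageneProfile:
    bin_edges: np.ndarray
    density: np.ndarray  # probability per bin; sums to 1 when n_sites > 0
    counts: np.ndarray
    n_sites: int


def intron_metagene(
    sites: Sequence[TargetSite],
    models: Mapping[str, GeneModel],
    n_bins: int = 20,
    coord: str = "ordinal",
) -> MetageneProfile:
    """Histogram of intronic site positions across the gene's intron space.

    ``ordinal`` coordinate: x = (i + p) / N for intron ordinal i (0-based,
    transcription order), within-intron offset p in [0,1) and N introns —
    the reading under which "early introns" is expressible. ``within``:
    x = p alone.
    """
    if coord not in ("ordinal", "within"):
        raise ValueError(f"unknown coord {coord!r}")
    xs: list[float] = []
    for s in sites:
        if s.intron_ordinal is None or s.within_intron_offset is None:
            raise ValueError(f"site {s.tsrna_id}->{s.gene_id} lacks intron coordinates")
        if coord == "within":
            xs.append(s.within_intron_offset)
        else:
            n = models[s.gene_id].n_introns
            xs.append((s.intron_ordinal + s.within_intron_offset) / n)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(xs, bins=edges)
    density = counts / counts.sum() if counts.sum() else counts.astype(float)
    return MetageneProfile(bin_edges=edges, density=density, counts=counts, n_sites=len(xs))


# ----------------------------------------------------------- conservation


class ConservationTrack:
    """Per-base conservation scores from bedGraph-like rows
    (chrom, start, end, score; 0-based half-open)."""

    def __init__(self, rows: pd.DataFrame):
        self._chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, sub in rows.groupby("chrom"):
            sub = sub.sort_values("start")
            self._chrom[str(chrom)] = (
                sub["start"].to_numpy(int),
                sub["end"].to_numpy(int),
                sub["score"].to_numpy(float),
            )

    def site_mean(self, chrom: str, start: int, end: int) -> float | None:
        """Overlap-weighted mean score over [start, end); None if uncovered."""
        if chrom not in self._chrom:
            return None
        starts, ends, scores = self._chrom[chrom]
        lo = np.searchsorted(ends, start, side="right")
        hi = np.searchsorted(starts, end, side="left")
        if hi <= lo:
            return None
        ov = np.minimum(ends[lo:hi], end) - np.maximum(starts[lo:hi], start)
        ov = np.clip(ov, 0, None)
        total = ov.sum()
        if total == 0:
            return None
        return float((scores[lo:hi] * ov).sum() / total)


def site_conservation_scores(
    sites: Sequence[TargetSite],
    track: ConservationTrack,
) -> list[float]:
    """Mean per-base conservation per site; unresolvable sites are dropped."""
    out = []
    for s in sites:
        v = track.site_mean(s.chrom, s.start, s.end)
        if v is None:
            logger.warning("site %s:%d-%d not resolvable on the track; discarded", s.chrom, s.start, s.end)
            continue
        out.append(v)
    return out


@dataclass(frozen=True)
class RankSumResult:
    statistic: float
    pvalue: float
    median_a: float
    median_b: float


def compare_site_conservation(
    scores_dependent: Sequence[float],
    scores_other: Sequence[float],
) -> RankSumResult:
    """Two-sided Mann-Whitney rank-sum comparison of per-site conservation."""
    a, b = list(scores_dependent), list(scores_other)
    if not a or not b:
        raise ValueError("both score groups must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return RankSumResult(
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
    )


@dataclass(frozen=True)
class ConservationPair:
    human_gene_id: str
    mouse_gene_id: str
    k: int
    shared_count: int

    @property
    def fraction(self) -> float:
        return self.shared_count / self.k


def conservation_fraction(
    human_targets: Mapping[str, set[str]],
    homolog_map: Mapping[str, str],
    mouse_sites: Sequence[TargetSite],
    threshold: float = 0.9,
) -> tuple[list[ConservationPair], int]:
    """Fraction of each human gene's tsRNAs that also hit its mouse homolog.

    ``mouse_sites`` come from the relaxed-parameter cross-species run.
    Genes without a homolog in the map are dropped (and logged). Returns
    the per-pair fractions and the count of pairs at fraction >= threshold.
    """
    mouse_hits: dict[str, set[str]] = {}
    for s in mouse_sites:
        mouse_hits.setdefault(s.gene_id, set()).add(s.tsrna_id)
    pairs: list[ConservationPair] = []
    for hg in sorted(human_targets):
        tset = human_targets[hg]
        if not tset:
            continue
        if hg not in homolog_map:
            logger.warning("no mouse homolog for %s; discarded from conservation analysis", hg)
            continue
        mg = homolog_map[hg]
        shared = len(tset & mouse_hits.get(mg, set()))
        pairs.append(ConservationPair(hg, mg, k=len(tset), shared_count=shared))
    conserved = sum(1 for p in pairs if p.fraction >= threshold)
    return pairs, conserved


# ------------------------------------------------------------- enrichment


@dataclass(frozen=True)
class ContingencyTable2x2:
    a: int  # target gene, disease-associated
    b: int  # target gene, no disease
    c: int  # non-target, disease-associated
    d: int  # non-target, no disease

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def odds_ratio(self) -> float:
        if self.b * self.c == 0:
            return math.inf if self.a * self.d > 0 else math.nan
        return (self.a * self.d) / (self.b * self.c)


def fisher_one_sided(table: ContingencyTable2x2) -> float:
    """One-sided (enrichment) Fisher exact p as an exact hypergeometric
    upper-tail sum, evaluated in integer arithmetic."""
    a, b, c, d = table.a, table.b, table.c, table.d
    n, row1, col1 = table.n, a + b, a + c
    denom = math.comb(n, col1)
    tail = Fraction(0)
    for x in range(a, min(row1, col1) + 1):
        tail += Fraction(math.comb(row1, x) * math.comb(n - row1, col1 - x), denom)
    return float(min(tail, Fraction(1)))


def disease_enrichment(
    target_genes: set[str],
    association_table: pd.DataFrame,
    ncbi_symbols: set[str],
    ensembl_symbols: set[str],
    synonyms: Mapping[str, str] | None = None,
) -> tuple[ContingencyTable2x2, float, pd.DataFrame]:
    """Fisher enrichment of disease association among target genes.

    The gene universe is the intersection of the NCBI and Ensembl symbol
    sets after synonym resolution; the association table's symbols are
    resolved the same way and restricted to the universe. Also returns the
    binary gene x disease matrix with columns (genes) ordered by column
    sum, then rows (diseases) by row sum, both descending.
    """
    syn = dict(synonyms or {})

    def resolve(symbol: str) -> str:
        return syn.get(symbol, symbol)

    universe = {resolve(s) for s in ncbi_symbols} & {resolve(s) for s in ensembl_symbols}
    if not universe:
        raise ValueError("empty gene universe")
    assoc = association_table.copy()
    assoc["gene_symbol"] = assoc["gene_symbol"].map(resolve)
    assoc = assoc[assoc["gene_symbol"].isin(universe)]
    targets = {resolve(g) for g in target_genes} & universe
    disease_genes = set(assoc["gene_symbol"])
    a = len(targets & disease_genes)
    b = len(targets - disease_genes)
    c = len(disease_genes - targets)
    d = len(universe) - a - b - c
    table = ContingencyTable2x2(a, b, c, d)
    p = fisher_one_sided(table)

    sub = assoc[assoc["gene_symbol"].isin(targets)]
    if sub.empty:
        matrix = pd.DataFrame()
    else:
        matrix = (
            sub.assign(v=1)
            .pivot_table(index="disease_id", columns="gene_symbol", values="v", fill_value=0)
            .astype(int)
        )
        matrix = matrix.loc[:, matrix.sum(axis=0).sort_values(ascending=False, kind="mergesort").index]
        matrix = matrix.loc[matrix.sum(axis=1).sort_values(ascending=False, kind="mergesort").index, :]
    return table, p, matrix


# ------------------------------------------------------------ correlation


def expression_abundance_correlation(
    trna_expression: Mapping[str, float],
    tsrna_abundance: Mapping[str, float],
) -> tuple[float, float]:
    """Spearman correlation between tRNA expression and tsRNA abundance.

    Mid-rank ties; exact permutation p (two-sided) for n <= 9, t
    approximation otherwise. Requires >= 3 shared ids.
    """
    shared = sorted(set(trna_expression) & set(tsrna_abundance))
    n = len(shared)
    if n < 3:
        raise ValueError("need at least 3 shared ids")
    x = np.array([trna_expression[i] for i in shared], dtype=float)
    y = np.array([tsrna_abundance[i] for i in shared], dtype=float)
    rho, p_t = stats.spearmanr(x, y)
    rho = float(rho)
    if n > 9:
        return rho, float(p_t)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    norm = np.sqrt((rxc**2).sum() * (ryc**2).sum())
    if norm == 0:
        return rho, 1.0
    perms = np.array(list(itertools.permutations(range(n))))
    rho_all = (ryc[perms] @ rxc) / norm
    p = float(np.mean(np.abs(rho_all) >= abs(rho) - 1e-12))
    return rho, p
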