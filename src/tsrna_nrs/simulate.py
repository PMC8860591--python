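"""Synthetic pipeline inputs with planted, recorded ground truth.

Emulates the full input surface of the tsRNA/nascent-RNA-silencing study:
a tRNA reference with leaders, trailers, introns and CCA forms; small-RNA
reads from fragment classes of those tRNAs under a control-vs-Dicer
knockdown design; PAR-CLIP occurrence sets for Ago1-4 and three Dicer
replicates (with crosslink-style T->C conversions); gene models on a
synthetic genome with target sites planted into introns; chromatin-RNA
count matrices with knockdown effects; mouse homologs that conserve or
scramble the planted sites; a per-base conservation track; and a
gene-disease association table with a controlled enrichment odds ratio.

Everything is driven by a single integer seed; identical arguments yield
byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .genemodel import GeneModel
from .reference import FLANK, TRNAEntry, TRNAReference
from .seq import normalize, random_seq, revcomp
from .targets import (
    NearestNeighborTable,
    ScoringParams,
    duplex_energy,
    score_site,
)

#: NEB small-RNA 3' adapter, the library chemistry the reads emulate
DEFAULT_ADAPTER = "AGATCGGAAGAGCACACGTCT"

ISOTYPES = [
    ("Ala", "AGC"), ("Arg", "ACG"), ("Asn", "GTT"), ("Asp", "GTC"),
    ("Cys", "GCA"), ("Gln", "CTG"), ("Glu", "CTC"), ("Gly", "GCC"),
    ("His", "GTG"), ("Ile", "AAT"), ("Leu", "AAG"), ("Lys", "CTT"),
    ("Met", "CAT"), ("Phe", "GAA"), ("Pro", "AGG"), ("Ser", "AGA"),
    ("Thr", "AGT"), ("Trp", "CCA"), ("Tyr", "GTA"), ("Val", "AAC"),
]


@dataclass
class SimulationTruth:
    """Ground truth recorded while generating fixtures."""

    rng_seed: int
    #: fragment id -> true log2 fold change, restricted to |lfc| > 1
    dicer_dependent_tsrna_ids: dict[str, float] = field(default_factory=dict)
    #: (tsrna_id, gene_id, intron_index, (chrom, start, end))
    planted_target_sites: list[tuple] = field(default_factory=list)
    planted_nondependent_sites: list[tuple] = field(default_factory=list)
    upregulated_genes_by_condition: dict[str, dict[str, float]] = field(default_factory=dict)
    conserved_homolog_pairs: list[tuple[str, str]] = field(default_factory=list)
    enriched_disease_genes: set[str] = field(default_factory=set)
    #: all fragment effects as assigned (sequence-keyed)
    effects: dict[str, float] = field(default_factory=dict)
    tsrna_sequences: dict[str, str] = field(default_factory=dict)
    trna_expression: dict[str, float] = field(default_factory=dict)

    def planted_genes(self) -> set[str]:
        return {g for _, g, _, _ in self.planted_target_sites}

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["enriched_disease_genes"] = sorted(self.enriched_disease_genes)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationTruth":
        with open(path) as fh:
            payload = json.load(fh)
        payload["enriched_disease_genes"] = set(payload["enriched_disease_genes"])
        payload["planted_target_sites"] = [tuple(t[:3]) + (tuple(t[3]),) for t in payload["planted_target_sites"]]
        payload["planted_nondependent_sites"] = [
            tuple(t[:3]) + (tuple(t[3]),) for t in payload["planted_nondependent_sites"]
        ]
        payload["conserved_homolog_pairs"] = [tuple(t) for t in payload["conserved_homolog_pairs"]]
        return cls(**payload)


# ----------------------------------------------------------- tRNA reference


def generate_trna_reference(n_genes: int, seed: int) -> TRNAReference:
    """Random tRNA reference with realistic structural proportions.

    Mature bodies are 60-90 nt with the anticodon placed around position
    34; leaders and trailers are 5-20 nt; about a quarter of the genes
    carry a 10-30 nt intron inserted just 3' of the anticodon loop, the
    canonical position of tRNA introns.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    entries = []
    for i in range(n_genes):
        isotype, anticodon = ISOTYPES[int(rng.integers(0, len(ISOTYPES)))]
        m_len = int(rng.integers(60, 91))
        body = list(random_seq(rng, m_len))
        ac_pos = min(33, m_len - 3)
        body[ac_pos : ac_pos + 3] = anticodon
        mature = "".join(body)
        intron = None
        if rng.random() < 0.25:
            ins = min(ac_pos + 5, m_len - 1)
            intron = (ins, random_seq(rng, int(rng.integers(10, 31))))
        entries.append(
            TRNAEntry(
                id=f"tRNA-{isotype}-{anticodon}-{i + 1}",
                isotype=isotype,
                anticodon=anticodon,
                mature_seq=mature,
                leader_seq=random_seq(rng, int(rng.integers(5, 21))),
                trailer_seq=random_seq(rng, int(rng.integers(5, 21))),
                intron=intron,
                flank5=random_seq(rng, FLANK),
                flank3=random_seq(rng, FLANK),
            )
        )
    return TRNAReference(entries)


# ------------------------------------------------------- fragment catalogue

#: fragment classes with (count per tRNA, length range, abundance weight).
#: tRNA halves (angiogenin-type products, 30-40 nt) dominate the library
#: and are Dicer-independent; they anchor median-of-ratios normalisation
#: the way the unchanged bulk of a real sRNA library does.
_FRAG_CLASSES = (
    ("cca_end", 2, (18, 22), 3.0),
    ("three_p", 1, (18, 24), 1.5),
    ("five_p", 1, (26, 32), 1.0),
    ("five_half", 1, (31, 38), 4.0),
    ("three_half", 1, (30, 36), 3.0),
    ("internal", 2, (23, 30), 0.8),
    ("trailer", 1, (18, 22), 0.6),
    ("leader_junction", 1, (19, 24), 0.5),
)


@dataclass
class FragmentCatalogue:
    """Realized tsRNA fragment universe for read simulation."""

    table: pd.DataFrame  # fragment_id, entry_id, frag_class, form, start, end, sequence, abundance
    expression: dict[str, float]  # tRNA entry id -> expression level

    def sequences(self) -> dict[str, str]:
        return dict(zip(self.table["fragment_id"], self.table["sequence"]))


def fragment_catalogue(ref: TRNAReference, seed: int) -> FragmentCatalogue:
    """Draw a deterministic fragment universe from the reference.

    Fragment abundance couples to the source tRNA's expression level with
    lognormal noise, so expression and summed fragment abundance correlate
    positively but imperfectly (as observed for real tsRNAs).
    """
    rng = np.random.default_rng(seed)
    rows = []
    expression: dict[str, float] = {}
    seen: set[str] = set()
    for entry in ref.entries:
        expr = float(rng.lognormal(np.log(50.0), 1.0))
        expression[entry.id] = expr
        # per-tRNA processing efficiency decouples fragment yield from
        # expression, leaving only a moderate positive correlation
        processing = float(rng.lognormal(0.0, 1.2))
        mature = entry.mature_seq
        cca = entry.form_seq("mature_cca")
        pre = entry.form_seq("pre")
        leader = len(entry.leader_seq)
        body_len = len(entry.mature_with_intron)
        for frag_class, count, (lo, hi), weight in _FRAG_CLASSES:
            for k in range(count):
                L = int(rng.integers(lo, hi + 1))
                if frag_class == "cca_end":
                    form, start, end = "mature_cca", len(cca) - L, len(cca)
                elif frag_class in ("three_p", "three_half"):
                    form, start, end = "mature", len(mature) - L, len(mature)
                elif frag_class in ("five_p", "five_half"):
                    form, start, end = "mature", 0, min(L, len(mature))
                elif frag_class == "internal":
                    start = int(rng.integers(5, max(6, len(mature) - L - 5)))
                    form, end = "mature", min(start + L, len(mature))
                elif frag_class == "trailer":
                    start = leader + body_len - int(rng.integers(2, 6))
                    form, end = "pre", min(start + L, len(pre))
                else:  # leader_junction
                    start = max(0, leader - int(rng.integers(5, 12)))
                    form, end = "pre", min(start + L, len(pre))
                seq = ref[entry.id].form_seq(form)[start:end]
                if len(seq) < 16 or seq in seen:
                    continue
                seen.add(seq)
                rows.append(
                    {
                        "fragment_id": f"{entry.id}|{frag_class}{k + 1}",
                        "entry_id": entry.id,
                        "frag_class": frag_class,
                        "form": form,
                        "start": start,
                        "end": end,
                        "sequence": seq,
                        "abundance": expr * processing * weight * float(rng.lognormal(0.0, 0.6)),
                    }
                )
    return FragmentCatalogue(table=pd.DataFrame(rows), expression=expression)


# ------------------------------------------------------------- sRNA reads


def _nb_draw(rng: np.random.Generator, mean: float, alpha: float) -> int:
    if mean <= 0:
        return 0
    n = 1.0 / alpha
    return int(rng.negative_binomial(n, n / (n + mean)))


@dataclass
class SRNASimResult:
    reads: dict[str, list[str]]  # sample -> raw reads (insert + adapter portion)
    catalogue: FragmentCatalogue
    condition_of: dict[str, str]
    effects: dict[str, float]  # fragment sequence -> true log2FC

    def write_fastq(self, outdir: str | Path) -> dict[str, Path]:
        from .seq import write_fastq

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for sample, reads in self.reads.items():
            p = outdir / f"{sample}.fastq"
            with open(p, "w") as fh:
                write_fastq(((f"{sample}.{i}", r) for i, r in enumerate(reads)), fh)
            paths[sample] = p
        return paths


def simulate_srna_reads(
    ref: TRNAReference,
    design: Mapping[str, int],
    effects: Mapping[str, float],
    dispersion: float = 0.1,
    depth: int = 20000,
    seed: int = 0,
    reference_condition: str = "control",
    adapter: str = DEFAULT_ADAPTER,
    adapter_fraction: float = 0.80,
    partial_adapter_fraction: float = 0.15,
    error_rate: float = 0.005,
    catalogue: Optional[FragmentCatalogue] = None,
) -> SRNASimResult:
    """Simulate small-RNA-seq reads from tRNA fragments.

    ``design`` maps condition -> replicate count (>= 2 each); ``effects``
    maps fragment *sequences* to true log2 fold changes applied in every
    non-reference condition. Counts are negative binomial with variance
    mu + dispersion*mu^2; a fraction of reads carry the full or partial 3'
    adapter and substitution errors at ``error_rate`` per base (capped at
    3 per read).
    """
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    if depth < 0:
        raise ValueError("depth must be non-negative")
    for cond, nrep in design.items():
        if nrep < 2:
            raise ValueError(f"condition {cond!r} needs >= 2 replicates")
    rng = np.random.default_rng(seed)
    if catalogue is None:
        catalogue = fragment_catalogue(ref, seed)
    forms = [s for _, _, s in ref.iter_forms()]
    for seq in effects:
        s = normalize(seq)
        if not any(s in f for f in forms):
            raise ValueError(f"effect assigned to sequence absent from the reference: {seq}")
    effects = {normalize(k): float(v) for k, v in effects.items()}

    tab = catalogue.table
    rel = tab["abundance"].to_numpy() / tab["abundance"].sum()
    adapter = normalize(adapter)
    reads: dict[str, list[str]] = {}
    condition_of: dict[str, str] = {}
    for cond in design:
        scale = np.array(
            [2.0 ** effects.get(s, 0.0) if cond != reference_condition else 1.0 for s in tab["sequence"]]
        )
        means = rel * depth * scale
        for rep in range(design[cond]):
            sample = f"{cond}_rep{rep + 1}"
            condition_of[sample] = cond
            sample_reads: list[str] = []
            for seq, mu in zip(tab["sequence"], means):
                count = _nb_draw(rng, mu, dispersion)
                for _ in range(count):
                    insert = seq
                    n_err = min(int(rng.binomial(len(insert), error_rate)), 3)
                    if n_err:
                        pos = rng.choice(len(insert), size=n_err, replace=False)
                        chars = list(insert)
                        for p_ in pos:
                            chars[p_] = "ACGT"[(("ACGT".index(chars[p_])) + int(rng.integers(1, 4))) % 4]
                        insert = "".join(chars)
                    u = rng.random()
                    if u < adapter_fraction:
                        read = insert + adapter
                    elif u < adapter_fraction + partial_adapter_fraction:
                        read = insert + adapter[: int(rng.integers(3, len(adapter)))]
                    else:
                        read = insert
                    sample_reads.append(read)
            reads[sample] = sample_reads
    return SRNASimResult(reads=reads, catalogue=catalogue, condition_of=condition_of, effects=dict(effects))


# -------------------------------------------------------------- PAR-CLIP


def simulate_parclip_sets(
    catalogue: FragmentCatalogue,
    ref: TRNAReference,
    dependent_sequences: Sequence[str],
    nondependent_sequences: Sequence[str] = (),
    seed: int = 0,
    tc_conversion_fraction: float = 0.3,
    n_low_occurrence_decoys: int = 6,
    n_random_decoys: int = 4,
) -> dict[str, dict[str, int]]:
    """Per-protein (sequence -> occurrence) PAR-CLIP sets.

    Dependent and non-dependent candidate sequences receive occurrences
    above every threshold (25 per Ago set; 323/41/19 for the Dicer
    replicates); decoys fall below them or fail the length window. A
    fraction of candidate occurrence mass is emitted as a T->C conversion
    variant (the PAR-CLIP crosslink signature), and the first candidates
    also appear as one-terminal-nt extensions to exercise grouping.
    """
    rng = np.random.default_rng(seed)
    proteins = ("Ago1", "Ago2", "Ago3", "Ago4", "Dicer_rep1", "Dicer_rep2", "Dicer_rep3")
    sets: dict[str, dict[str, int]] = {p: {} for p in proteins}
    tab = catalogue.table.set_index("sequence")

    def add(seq: str, occ: Mapping[str, int]) -> None:
        for p, v in occ.items():
            if v > 0:
                sets[p][seq] = sets[p].get(seq, 0) + int(v)

    def passing_occ() -> dict[str, int]:
        return {
            "Ago1": int(rng.integers(30, 150)),
            "Ago2": int(rng.integers(40, 250)),
            "Ago3": int(rng.integers(28, 120)),
            "Ago4": int(rng.integers(27, 100)),
            "Dicer_rep1": int(rng.integers(350, 900)),
            "Dicer_rep2": int(rng.integers(50, 160)),
            "Dicer_rep3": int(rng.integers(25, 90)),
        }

    candidates = [(s, True) for s in dependent_sequences] + [(s, False) for s in nondependent_sequences]
    for idx, (seq, _dep) in enumerate(candidates):
        occ = passing_occ()
        main = dict(occ)
        if tc_conversion_fraction > 0 and "T" in seq:
            tpos = [i for i, b in enumerate(seq) if b == "T"]
            p_ = int(rng.choice(tpos))
            variant = seq[:p_] + "C" + seq[p_ + 1 :]
            var_occ = {k: int(v * tc_conversion_fraction) for k, v in occ.items()}
            main = {k: v - var_occ[k] for k, v in occ.items()}
            add(variant, var_occ)
        add(seq, main)
        if idx < 2 and seq in tab.index:
            # genomic one-nt 3' extension of the fragment: same cluster later
            row = tab.loc[seq]
            form_seq = ref[row["entry_id"]].form_seq(row["form"])
            if int(row["end"]) < len(form_seq):
                add(form_seq[int(row["start"]) : int(row["end"]) + 1], passing_occ())

    pool = [
        s
        for s in catalogue.table["sequence"]
        if 18 <= len(s) <= 22 and s not in {c for c, _ in candidates}
    ]
    rng.shuffle(pool)
    for seq in pool[:n_low_occurrence_decoys]:
        add(
            seq,
            {
                "Ago1": int(rng.integers(1, 20)),
                "Ago2": int(rng.integers(1, 20)),
                "Ago3": int(rng.integers(1, 20)),
                "Ago4": int(rng.integers(1, 20)),
                "Dicer_rep1": int(rng.integers(1, 300)),
                "Dicer_rep2": int(rng.integers(1, 40)),
                "Dicer_rep3": int(rng.integers(1, 18)),
            },
        )
    long_pool = [s for s in catalogue.table["sequence"] if len(s) > 22]
    for seq in long_pool[:4]:
        add(seq, passing_occ())  # length filter must remove these
    for _ in range(n_random_decoys):
        add(random_seq(rng, 20), passing_occ())  # not tRNA-derived; unmapped
    return sets


def write_parclip_sets(sets: Mapping[str, Mapping[str, int]], outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for protein in sorted(sets):
        p = outdir / f"parclip_{protein}.tsv"
        df = pd.DataFrame(sorted(sets[protein].items()), columns=["sequence", "occurrence"])
        df.to_csv(p, sep="\t", index=False)
        paths[protein] = p
    return paths


def read_parclip_sets(paths: Mapping[str, str | Path]) -> dict[str, dict[str, int]]:
    return {
        protein: dict(
            zip(
                (df := pd.read_csv(path, sep="\t"))["sequence"],
                df["occurrence"].astype(int),
            )
        )
        for protein, path in paths.items()
    }


# ------------------------------------------------- conservation fixture


@dataclass
class ConservationFixture:
    """Orthologous site loci for conservation-fraction recovery.

    One human gene per pair, each targeted by one tsRNA; the mouse
    "homolog" is the orthologous locus (planted site +/- flank), copied
    verbatim for exactly round(conservation_fraction * n_pairs) pairs and
    scrambled otherwise. Short loci keep relaxed-mode chance hits
    negligible, so the recovered fraction reflects the parameter.
    """

    human_targets: dict[str, set[str]]
    tsrna_sequences: dict[str, str]
    homolog_map: dict[str, str]
    mouse_models: list[GeneModel]
    mouse_genome: dict[str, str]
    conserved_pairs: set[tuple[str, str]]


def simulate_conservation_fixture(
    tsrnas: Mapping[str, str],
    n_pairs: int,
    conservation_fraction: float,
    seed: int,
    flank: int = 150,
) -> ConservationFixture:
    if not 0.0 <= conservation_fraction <= 1.0:
        raise ValueError("conservation_fraction must lie in [0, 1]")
    if not tsrnas:
        raise ValueError("tsRNA list empty")
    rng = np.random.default_rng(seed)
    ids = sorted(tsrnas)
    n_cons = int(round(conservation_fraction * n_pairs))
    order = list(range(n_pairs))
    rng.shuffle(order)
    conserved_idx = set(order[:n_cons])

    human_targets: dict[str, set[str]] = {}
    homolog_map: dict[str, str] = {}
    mouse_models: list[GeneModel] = []
    mouse_genome: dict[str, str] = {}
    conserved_pairs: set[tuple[str, str]] = set()
    for i in range(n_pairs):
        hg = f"H{i + 1:04d}"
        mg = f"m{hg}"
        tid = ids[i % len(ids)]
        tseq = normalize(tsrnas[tid])
        site = revcomp(tseq)
        locus = random_seq(rng, flank) + site + random_seq(rng, flank)
        if i in conserved_idx:
            conserved_pairs.add((hg, mg))
        else:
            # scramble and verify by scanning: the locus of an unconserved
            # pair must not reach the relaxed threshold by chance, the
            # mirror image of the positive-site verification at planting
            from .targets import RELAXED_SCORE_THRESHOLD, ScoringParams, scan_candidates

            params = ScoringParams()
            while True:
                locus = random_seq(rng, 2 * flank + len(site))
                hits = scan_candidates([tseq], locus, params, RELAXED_SCORE_THRESHOLD)
                if not hits[0]:
                    break
        chrom = f"mchr_{hg}"
        mouse_genome[chrom] = locus
        mouse_models.append(
            GeneModel(gene_id=mg, chrom=chrom, strand="+", exons=[(0, len(locus))])
        )
        human_targets[hg] = {tid}
        homolog_map[hg] = mg
    return ConservationFixture(
        human_targets=human_targets,
        tsrna_sequences={k: normalize(v) for k, v in tsrnas.items()},
        homolog_map=homolog_map,
        mouse_models=mouse_models,
        mouse_genome=mouse_genome,
        conserved_pairs=conserved_pairs,
    )


# --------------------------------------------------------------- gene set


@dataclass
class GeneSetBundle:
    models: list[GeneModel]
    genome: dict[str, str]
    counts: pd.DataFrame  # genes x samples
    condition_of: dict[str, str]
    homolog_map: dict[str, str]
    mouse_models: list[GeneModel]
    mouse_genome: dict[str, str]
    conservation: pd.DataFrame  # chrom, start, end, score
    disease: pd.DataFrame  # gene_symbol, disease_id, disease_class
    ncbi_symbols: set[str]
    ensembl_symbols: set[str]
    synonyms: dict[str, str]
    truth: SimulationTruth


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    chars = list(seq)
    n = rng.binomial(len(chars), rate)
    for p in rng.choice(len(chars), size=int(n), replace=False):
        chars[p] = "ACGT"[(("ACGT".index(chars[p])) + int(rng.integers(1, 4))) % 4]
    return "".join(chars)


def simulate_gene_set(
    tsrnas: Mapping[str, str],
    n_genes: int,
    planted_fraction: float,
    conservation_fraction: float,
    disease_enrichment_odds: float,
    seed: int,
    dependent_ids: Optional[set[str]] = None,
    n_replicates: int = 3,
    dispersion: float = 0.1,
    effect_range: tuple[float, float] = (1.5, 2.5),
    params: ScoringParams = ScoringParams(),
    energy_table: NearestNeighborTable = NearestNeighborTable(),
) -> GeneSetBundle:
    """Synthetic gene space with planted tsRNA target sites.

    Planted genes carry, in an (early-biased) intron, the reverse
    complement of an assigned tsRNA — verified at generation time to clear
    the default score and energy thresholds — and receive positive
    chromatin-RNA effects under Dicer and Ago2 knockdown but not Drosha.
    Mouse homologs copy the human target regions verbatim for exactly
    round(conservation_fraction * n_mapped) planted genes and scramble
    them otherwise. Disease labels follow the requested enrichment odds.
    """
    if not 0.0 <= planted_fraction <= 1.0 or not 0.0 <= conservation_fraction <= 1.0:
        raise ValueError("fractions must lie in [0, 1]")
    if disease_enrichment_odds <= 0:
        raise ValueError("disease_enrichment_odds must be positive")
    if planted_fraction > 0 and not tsrnas:
        raise ValueError("tsRNA list empty while planted_fraction > 0")
    rng = np.random.default_rng(seed)
    truth = SimulationTruth(rng_seed=int(seed), tsrna_sequences={k: normalize(v) for k, v in tsrnas.items()})

    dep_ids = sorted(dependent_ids if dependent_ids is not None else tsrnas)
    nondep_ids = sorted(set(tsrnas) - set(dep_ids))

    # --- gene models and genome -------------------------------------------
    models: list[GeneModel] = []
    genome: dict[str, str] = {}
    margin = 100
    for g in range(n_genes):
        gene_id = f"G{g + 1:04d}"
        chrom = f"chr_{gene_id}"
        n_exons = int(rng.integers(3, 9))
        exon_lens = rng.integers(80, 301, size=n_exons)
        intron_lens = [int(rng.integers(800, 2001))] + [
            int(rng.integers(200, 1201)) for _ in range(n_exons - 2)
        ]
        pos = margin
        exons = []
        for i, el in enumerate(exon_lens):
            exons.append((pos, pos + int(el)))
            pos += int(el)
            if i < n_exons - 1:
                pos += intron_lens[i]
        genome[chrom] = random_seq(rng, pos + margin)
        models.append(GeneModel(gene_id=gene_id, chrom=chrom, strand="+", exons=exons))

    # --- plant target sites ------------------------------------------------
    n_planted = int(round(planted_fraction * n_genes))
    planted_idx = sorted(rng.choice(n_genes, size=n_planted, replace=False).tolist())

    used_intervals: dict[str, list[tuple[int, int]]] = {}

    def plant_site(gene: GeneModel, tsrna_id: str, check_energy: bool) -> Optional[tuple]:
        seq = truth.tsrna_sequences[tsrna_id]
        introns = gene.introns_transcription_order()
        order = list(range(len(introns)))
        # early-intron bias: try intron 0/1 first, then the rest shuffled
        tail = order[2:]
        rng.shuffle(tail)
        for oi in order[:2] + tail:
            s, e = introns[oi]
            if e - s < len(seq) + 20:
                continue
            off = int(rng.integers(s + 10, e - len(seq) - 10))
            iv = (off - 30, off + len(seq) + 30)
            if any(a < iv[1] and iv[0] < b for a, b in used_intervals.get(gene.chrom, [])):
                continue
            site = revcomp(seq)
            chrom_seq = genome[gene.chrom]
            new_seq = chrom_seq[:off] + site + chrom_seq[off + len(site) :]
            window = new_seq[max(0, off - 25) : off + len(site) + 25]
            score, trace = score_site(seq, window, params)
            if score < params.score_threshold or trace is None:
                continue
            if check_energy and duplex_energy(trace, energy_table) > params.energy_threshold:
                return None  # energy is a property of the tsRNA itself; try another
            genome[gene.chrom] = new_seq
            used_intervals.setdefault(gene.chrom, []).append(iv)
            return (tsrna_id, gene.gene_id, oi, (gene.chrom, off, off + len(site)))
        return None

    dep_cycle = 0
    nondep_cycle = 0
    for gi in planted_idx:
        gene = models[gi]
        n_sites = int(rng.integers(1, 3))
        planted_here = 0
        attempts = 0
        while planted_here < n_sites and attempts < 4 * max(1, len(dep_ids)):
            tsrna_id = dep_ids[dep_cycle % len(dep_ids)]
            dep_cycle += 1
            attempts += 1
            rec = plant_site(gene, tsrna_id, check_energy=True)
            if rec is not None:
                truth.planted_target_sites.append(rec)
                planted_here += 1
        if nondep_ids and rng.random() < 0.5:
            tsrna_id = nondep_ids[nondep_cycle % len(nondep_ids)]
            nondep_cycle += 1
            rec = plant_site(gene, tsrna_id, check_energy=True)
            if rec is not None:
                truth.planted_nondependent_sites.append(rec)

    planted_genes = truth.planted_genes()

    # --- chromatin-RNA counts ----------------------------------------------
    conditions = ["control", "shDicer", "shAgo2", "shDrosha"]
    gene_ids = [m.gene_id for m in models]
    base = rng.lognormal(np.log(300.0), 0.7, size=n_genes)
    effects_by_cond: dict[str, dict[str, float]] = {c: {} for c in conditions[1:]}
    for gi in planted_idx:
        if models[gi].gene_id not in planted_genes:
            continue
        lfc = float(rng.uniform(*effect_range))
        effects_by_cond["shDicer"][models[gi].gene_id] = lfc
        effects_by_cond["shAgo2"][models[gi].gene_id] = lfc
    unplanted = [g for g in range(n_genes) if models[g].gene_id not in planted_genes]
    rng.shuffle(unplanted)
    if planted_genes:  # a null scenario carries no condition effects at all
        for g in unplanted[:2]:  # miRNA-like: up in every knockdown, excluded by Venn
            for cond in ("shDicer", "shAgo2", "shDrosha"):
                effects_by_cond[cond][models[g].gene_id] = 2.0
        for g in unplanted[2:4]:  # Drosha-only responders
            effects_by_cond["shDrosha"][models[g].gene_id] = 2.0
    truth.upregulated_genes_by_condition = effects_by_cond

    cols: dict[str, np.ndarray] = {}
    condition_of: dict[str, str] = {}
    for cond in conditions:
        scale = np.array([2.0 ** effects_by_cond.get(cond, {}).get(g, 0.0) for g in gene_ids])
        for rep in range(n_replicates):
            sample = f"{cond}_rep{rep + 1}"
            condition_of[sample] = cond
            mu = base * scale
            nconv = 1.0 / dispersion
            cols[sample] = rng.negative_binomial(nconv, nconv / (nconv + mu))
    counts = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id"))

    # --- mouse homologs -----------------------------------------------------
    mapped = [models[gi].gene_id for gi in planted_idx if models[gi].gene_id in planted_genes]
    dropped_from_map = mapped[-1] if len(mapped) > 1 else None
    homolog_map = {g: f"m{g}" for g in mapped if g != dropped_from_map}
    for g in unplanted[4:7]:
        homolog_map[models[g].gene_id] = f"m{models[g].gene_id}"

    mapped_planted = [g for g in mapped if g in homolog_map]
    n_cons = int(round(conservation_fraction * len(mapped_planted)))
    shuffled = list(mapped_planted)
    rng.shuffle(shuffled)
    conserved = set(shuffled[:n_cons])
    truth.conserved_homolog_pairs = sorted((g, homolog_map[g]) for g in conserved)

    sites_by_gene: dict[str, list[tuple]] = {}
    for rec in truth.planted_target_sites + truth.planted_nondependent_sites:
        sites_by_gene.setdefault(rec[1], []).append(rec)

    mouse_models: list[GeneModel] = []
    mouse_genome: dict[str, str] = {}
    by_id = {m.gene_id: m for m in models}
    for hg, mg in sorted(homolog_map.items()):
        gene = by_id[hg]
        mchrom = f"m{gene.chrom}"
        mseq = _mutate(rng, genome[gene.chrom], 0.05)
        for rec in sites_by_gene.get(hg, []):
            _, _, _, (chrom, s, e) = rec
            if hg in conserved:
                mseq = mseq[:s] + genome[chrom][s:e] + mseq[e:]
            else:
                mseq = mseq[:s] + random_seq(rng, e - s) + mseq[e:]
        mouse_genome[mchrom] = mseq
        mouse_models.append(GeneModel(gene_id=mg, chrom=mchrom, strand="+", exons=list(gene.exons)))

    # --- conservation track -------------------------------------------------
    cons_rows = []
    dep_sites = {(c, s, e) for _, _, _, (c, s, e) in truth.planted_target_sites}
    for m in models:
        chrom = m.chrom
        L = len(genome[chrom])
        arr = np.empty(L)
        edges = np.arange(0, L + 25, 25)
        for b0, b1 in zip(edges[:-1], edges[1:]):
            arr[b0:b1] = round(float(rng.uniform(0.05, 0.45)), 3)
        for c, s, e in sorted(dep_sites):
            if c == chrom:
                arr[s:e] = round(float(rng.uniform(0.75, 0.98)), 3)
        breaks = np.nonzero(np.diff(arr))[0] + 1
        bounds = np.concatenate([[0], breaks, [L]])
        for b0, b1 in zip(bounds[:-1], bounds[1:]):
            cons_rows.append((chrom, int(b0), int(b1), float(arr[b0])))
    conservation = pd.DataFrame(cons_rows, columns=["chrom", "start", "end", "score"])

    # --- disease associations ----------------------------------------------
    classes = ["neoplasm", "metabolic", "neurological", "cardiovascular"]
    diseases = [(f"D{i + 1:03d}", classes[i % len(classes)]) for i in range(12)]
    p0 = 0.25
    odds = disease_enrichment_odds
    p1 = odds * p0 / (1.0 - p0 + odds * p0)
    dis_rows = []
    for m in models:
        p_assoc = p1 if m.gene_id in planted_genes else p0
        if rng.random() < p_assoc:
            if m.gene_id in planted_genes:
                truth.enriched_disease_genes.add(m.gene_id)
            k = int(rng.integers(1, 4))
            for di in rng.choice(len(diseases), size=k, replace=False):
                did, dclass = diseases[int(di)]
                dis_rows.append((m.gene_id, did, dclass))
    disease = pd.DataFrame(sorted(dis_rows), columns=["gene_symbol", "disease_id", "disease_class"])

    ncbi_symbols = {m.gene_id for m in models}
    ensembl = sorted(ncbi_symbols)
    rng.shuffle(ensembl)
    # Ensembl lacks a couple of (unplanted) symbols so the universe is a
    # strict intersection
    ensembl_symbols = set(ensembl) - set([g for g in ensembl if g not in planted_genes][:2])
    synonyms: dict[str, str] = {}
    aliased = [g for g in sorted(ncbi_symbols & ensembl_symbols) if g not in planted_genes][:2]
    for g in aliased:
        alias = f"{g}~1"
        synonyms[alias] = g
        disease.loc[disease["gene_symbol"] == g, "gene_symbol"] = alias

    return GeneSetBundle(
        models=models,
        genome=genome,
        counts=counts,
        condition_of=condition_of,
        homolog_map=homolog_map,
        mouse_models=mouse_models,
        mouse_genome=mouse_genome,
        conservation=conservation,
        disease=disease,
        ncbi_symbols=ncbi_symbols,
        ensembl_symbols=ensembl_symbols,
        synonyms=synonyms,
        truth=truth,
    )
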