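"""End-to-end orchestration of the synthetic tsRNA/NRS study.

``run_pipeline`` chains every stage — simulation, read preprocessing, tRNA
annotation, small-RNA differential abundance, PAR-CLIP candidate
selection, chromatin-RNA differential expression, Venn integration, target
prediction and the downstream statistics — writing per-stage TSVs, a JSON
report and a provenance log. Stage functions are importable on their own;
running them separately composes to the same result as the single call.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from . import __version__
from .annotate import annotate_collection, align_to_reference, length_distribution
from .diffexpr import classify_de, nb_test, size_factors
from .genemodel import GeneModel, write_gene_models
from .integrate import (
    ConservationTrack,
    compare_site_conservation,
    conservation_fraction,
    disease_enrichment,
    expression_abundance_correlation,
    intersect_upregulated,
    intron_metagene,
    partition_target_genes,
    site_conservation_scores,
)
from .parclip import (
    ParclipThresholds,
    TsRNACandidate,
    equalize_to_genome,
    filter_parclip,
    group_near_identical,
    select_dicer_dependent,
)
from .preprocess import collapse_reads, trim_adapters
from .reference import TRNAReference
from .seq import write_fasta
from .simulate import (
    DEFAULT_ADAPTER,
    GeneSetBundle,
    SimulationTruth,
    SRNASimResult,
    fragment_catalogue,
    generate_trna_reference,
    simulate_gene_set,
    simulate_parclip_sets,
    simulate_srna_reads,
    write_parclip_sets,
)
from .targets import ScoringParams, TargetSite, predict_targets

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage parameters; defaults are the study's printed thresholds."""

    seed: int = 42
    outdir: str = "results/pipeline"
    # synthetic scenario
    n_trna: int = 20
    n_genes: int = 40
    planted_fraction: float = 0.25
    conservation_fraction: float = 0.7
    disease_enrichment_odds: float = 4.0
    srna_depth: int = 20000
    srna_replicates: int = 3
    chr_replicates: int = 5
    dispersion: float = 0.1
    # preprocessing
    adapter: str = DEFAULT_ADAPTER
    min_length: int = 18
    min_partial_overlap: int = 3
    # annotation
    max_mismatch: int = 3
    # PAR-CLIP selection
    length_min: int = 18
    length_max: int = 22
    ago_min_occurrence: int = 25
    dicer_rep_min: tuple[int, int, int] = (323, 41, 19)
    ago_mode: str = "each_set"
    dicer_dep_threshold: float = 1.0
    dicer_dep_mode: str = "absolute"
    # differential expression thresholds
    mrna_alpha: float = 0.001
    chr_alpha_dicer: float = 0.005
    chr_alpha_ago2: float = 0.005
    chr_alpha_drosha: float = 0.05
    exclude_drosha: bool = True
    # target prediction
    score_threshold: float = 150.0
    energy_threshold: float = -30.0
    # downstream
    metagene_bins: int = 20
    conservation_threshold: float = 0.9

    def thresholds(self) -> ParclipThresholds:
        return ParclipThresholds(
            length_min=self.length_min,
            length_max=self.length_max,
            ago_min_occurrence=self.ago_min_occurrence,
            dicer_rep_min=tuple(self.dicer_rep_min),
        )

    def scoring(self) -> ScoringParams:
        return ScoringParams(
            score_threshold=self.score_threshold, energy_threshold=self.energy_threshold
        )

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Flat ``key = value`` configuration dialect; CLI flags override."""
        values: dict = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        defaults = cls()
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, raw = line.partition("=")
                key, raw = key.strip(), raw.strip().strip('"')
                if key not in types:
                    raise KeyError(f"unknown configuration key {key!r}")
                current = getattr(defaults, key)
                if isinstance(current, bool):
                    values[key] = raw.lower() in ("1", "true", "yes")
                elif isinstance(current, int):
                    values[key] = int(raw)
                elif isinstance(current, float):
                    values[key] = float(raw)
                elif isinstance(current, tuple):
                    values[key] = tuple(int(x) for x in raw.split(","))
                else:
                    values[key] = raw
        values.update(overrides)
        return cls(**values)


@dataclass
class SimBundle:
    """All synthetic inputs of one scenario plus the merged ground truth."""

    ref: TRNAReference
    srna: SRNASimResult
    parclip_sets: dict[str, dict[str, int]]
    genes: GeneSetBundle
    truth: SimulationTruth
    dependent_sequences: list[str]
    nondependent_sequences: list[str]


def stage_simulate(cfg: PipelineConfig) -> SimBundle:
    """Generate every pipeline input with planted truth.

    Dicer-dependent fragment classes (CCA ends, 3' ends, trailers) receive
    strong negative sRNA effects; a few 18-22 nt fragments stay flat and
    serve as Dicer-*independent* PAR-CLIP candidates.
    """
    seed = cfg.seed
    ref = generate_trna_reference(cfg.n_trna, seed)
    cat = fragment_catalogue(ref, seed + 1)
    rng = np.random.default_rng(seed + 2)

    effects: dict[str, float] = {}
    for row in cat.table.itertuples(index=False):
        if row.frag_class in ("cca_end", "three_p", "trailer"):
            effects[row.sequence] = float(rng.uniform(-3.5, -2.0))
        else:
            effects[row.sequence] = 0.0
    # candidate tsRNAs must be measurable in the sRNA library: expected
    # control coverage high enough that the |log2FC| > 1 rule can fire
    rel = cat.table["abundance"] / cat.table["abundance"].sum()
    expected = dict(zip(cat.table["sequence"], rel * cfg.srna_depth))
    in_window = [
        s for s in cat.table["sequence"] if cfg.length_min <= len(s) <= cfg.length_max
    ]
    dependent = [s for s in in_window if abs(effects[s]) > 1 and expected[s] >= 15]
    if len(dependent) < 5:  # degenerate draw: fall back to the most abundant
        dependent = sorted(
            (s for s in in_window if abs(effects[s]) > 1),
            key=lambda s: -expected[s],
        )[:5]
    flat = [s for s in in_window if effects[s] == 0.0 and expected[s] >= 15]
    nondependent = flat[:4]

    srna = simulate_srna_reads(
        ref,
        design={"control": cfg.srna_replicates, "shDicer": cfg.srna_replicates},
        effects=effects,
        dispersion=cfg.dispersion,
        depth=cfg.srna_depth,
        seed=seed + 3,
        catalogue=cat,
    )
    parclip_sets = simulate_parclip_sets(
        cat, ref, dependent, nondependent, seed=seed + 4
    )

    id_of = {row.sequence: row.fragment_id for row in cat.table.itertuples(index=False)}
    tsrna_map = {id_of[s]: s for s in dependent + nondependent}
    genes = simulate_gene_set(
        tsrna_map,
        n_genes=cfg.n_genes,
        planted_fraction=cfg.planted_fraction,
        conservation_fraction=cfg.conservation_fraction,
        disease_enrichment_odds=cfg.disease_enrichment_odds,
        seed=seed + 5,
        dependent_ids={id_of[s] for s in dependent},
        n_replicates=cfg.chr_replicates,
        dispersion=cfg.dispersion,
        effect_range=(3.0, 4.0),
        params=cfg.scoring(),
    )
    truth = genes.truth
    truth.rng_seed = seed
    truth.effects = dict(srna.effects)
    truth.dicer_dependent_tsrna_ids = {
        id_of[s]: lfc for s, lfc in srna.effects.items() if abs(lfc) > 1 and s in id_of
    }
    truth.trna_expression = dict(cat.expression)
    return SimBundle(
        ref=ref,
        srna=srna,
        parclip_sets=parclip_sets,
        genes=genes,
        truth=truth,
        dependent_sequences=dependent,
        nondependent_sequences=nondependent,
    )


def stage_preprocess(reads: Mapping[str, list[str]], cfg: PipelineConfig) -> pd.DataFrame:
    trimmed = {
        sample: trim_adapters(rs, cfg.adapter, cfg.min_length, cfg.min_partial_overlap)
        for sample, rs in reads.items()
    }
    return collapse_reads(trimmed)


def stage_annotate(collapsed: pd.DataFrame, ref: TRNAReference, cfg: PipelineConfig) -> pd.DataFrame:
    """Annotate supported features (total count > 1) against the reference."""
    supported = collapsed[collapsed["feature_flag"]].reset_index(drop=True)
    return annotate_collection(supported, ref, max_mismatch=cfg.max_mismatch)


def stage_srna_de(collapsed: pd.DataFrame, cfg: PipelineConfig) -> pd.DataFrame:
    """NB test on supported unique-sequence features, knockdown vs control."""
    supported = collapsed[collapsed["feature_flag"]]
    samples = [c for c in collapsed.columns if c not in ("sequence", "total", "feature_flag")]
    counts = supported.set_index("sequence")[samples]
    labels = [s.rsplit("_rep", 1)[0] for s in samples]
    return nb_test(counts, labels, reference="control")


def stage_parclip(
    parclip_sets: Mapping[str, Mapping[str, int]],
    ref: TRNAReference,
    srna_de: pd.DataFrame,
    cfg: PipelineConfig,
    collapsed: Optional[pd.DataFrame] = None,
) -> tuple[list[TsRNACandidate], list[TsRNACandidate], list[TsRNACandidate]]:
    """Equalize, threshold, cluster and select Dicer-dependent candidates.

    Near-identical cluster members are one tsRNA species, so Dicer
    dependence is assessed on the cluster: with the collapsed count table
    available, the log2 fold change is recomputed on summed member counts;
    otherwise the representative falls back to the DE value of its most
    abundant member.

    Returns ``(all_candidates, cluster_representatives,
    dicer_dependent_representatives)``.
    """
    all_seqs = sorted({s for occs in parclip_sets.values() for s in occs})
    alns = align_to_reference(all_seqs, ref, max_mismatch=cfg.max_mismatch)
    equalized: dict[str, dict[str, int]] = {p: {} for p in parclip_sets}
    for protein, occs in parclip_sets.items():
        for s, occ in occs.items():
            hits = alns.get(s, [])
            if not hits:
                continue  # not tRNA-derived
            eq = equalize_to_genome(hits[0], ref)
            equalized[protein][eq] = equalized[protein].get(eq, 0) + int(occ)
    candidates = filter_parclip(equalized, cfg.thresholds(), ago_mode=cfg.ago_mode)

    abundance = {c.sequence: c.total_occurrence for c in candidates}
    assignment, reps = group_near_identical(list(abundance), abundance)
    for c in candidates:
        c.cluster_id = assignment[c.sequence]
    rep_candidates = [c for c in candidates if reps[c.cluster_id] == c.sequence]

    de_map = dict(zip(srna_de.index, srna_de["log2FoldChange"]))
    members: dict[int, list[TsRNACandidate]] = {}
    for c in candidates:
        members.setdefault(c.cluster_id, []).append(c)
    rep_de: dict[str, float] = {}
    if collapsed is not None:
        supported = collapsed[collapsed["feature_flag"]]
        samples = [
            c for c in collapsed.columns if c not in ("sequence", "total", "feature_flag")
        ]
        counts = supported.set_index("sequence")[samples]
        sf = size_factors(counts)
        norm = counts / sf
        ctrl = [s for s in samples if s.startswith("control")]
        kd = [s for s in samples if not s.startswith("control")]
        for c in rep_candidates:
            seqs = [m.sequence for m in members[c.cluster_id] if m.sequence in norm.index]
            if not seqs:
                continue
            pooled = norm.loc[seqs].sum(axis=0)
            m_a, m_b = pooled[ctrl].mean(), pooled[kd].mean()
            rep_de[c.sequence] = float(np.log2(m_b + 0.5) - np.log2(m_a + 0.5))
    else:
        # fall back to the DE value of the most abundant member
        for c in rep_candidates:
            for m in sorted(members[c.cluster_id], key=lambda x: (-x.total_occurrence, x.sequence)):
                if m.sequence in de_map:
                    rep_de[c.sequence] = de_map[m.sequence]
                    break
    dependent = select_dicer_dependent(
        rep_candidates, rep_de, threshold=cfg.dicer_dep_threshold, mode=cfg.dicer_dep_mode
    )
    for c in dependent:  # propagate the cluster-level call to members
        for m in members[c.cluster_id]:
            m.dicer_dependent = True
    return candidates, rep_candidates, dependent


def stage_chr_de(
    counts: pd.DataFrame,
    condition_of: Mapping[str, str],
    cfg: PipelineConfig,
) -> tuple[dict[str, pd.DataFrame], dict[str, set[str]]]:
    """Per-knockdown NB tests vs control and upregulated gene sets."""
    alphas = {
        "shDicer": cfg.chr_alpha_dicer,
        "shAgo2": cfg.chr_alpha_ago2,
        "shDrosha": cfg.chr_alpha_drosha,
    }
    tables: dict[str, pd.DataFrame] = {}
    up: dict[str, set[str]] = {}
    control = [s for s, c in condition_of.items() if c == "control"]
    for cond, alpha in alphas.items():
        cond_samples = [s for s, c in condition_of.items() if c == cond]
        sub = counts[control + cond_samples]
        res = nb_test(sub, ["control"] * len(control) + [cond] * len(cond_samples), reference="control")
        tables[cond] = res
        up[cond] = classify_de(res, alpha, "up")
    return tables, up


def stage_predict(
    candidates: list[TsRNACandidate],
    universe: set[str],
    models: list[GeneModel],
    genome: Mapping[str, str],
    cfg: PipelineConfig,
) -> list[TargetSite]:
    """Scan all candidate tsRNAs against the universe genes (strict mode)."""
    tsrnas = {c.sequence: c.sequence for c in candidates}
    genes = [m for m in models if m.gene_id in universe]
    return predict_targets(tsrnas, genes, genome, params=cfg.scoring())


@dataclass
class PipelineResult:
    config: PipelineConfig
    report: dict
    truth: SimulationTruth
    sites: list[TargetSite]
    outdir: Path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_inputs(bundle: SimBundle, outdir: Path) -> list[Path]:
    inputs = outdir / "inputs"
    inputs.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    paths += bundle.ref.write(inputs).values()
    paths += bundle.srna.write_fastq(inputs / "srna").values()
    paths += write_parclip_sets(bundle.parclip_sets, inputs / "parclip").values()
    g = bundle.genes
    write_gene_models(g.models, inputs / "genes.gtf")
    write_gene_models(g.mouse_models, inputs / "mouse_genes.gtf")
    with open(inputs / "genome.fa", "w") as fh:
        write_fasta(sorted(g.genome.items()), fh)
    with open(inputs / "mouse_genome.fa", "w") as fh:
        write_fasta(sorted(g.mouse_genome.items()), fh)
    g.counts.to_csv(inputs / "chr_counts.tsv", sep="\t")
    g.conservation.to_csv(inputs / "conservation.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(g.homolog_map.items()), columns=["human_gene_id", "mouse_gene_id"]
    ).to_csv(inputs / "homologs.tsv", sep="\t", index=False)
    g.disease.to_csv(inputs / "disease.tsv", sep="\t", index=False)
    pd.DataFrame({"symbol": sorted(g.ncbi_symbols)}).to_csv(inputs / "ncbi_symbols.tsv", sep="\t", index=False)
    pd.DataFrame({"symbol": sorted(g.ensembl_symbols)}).to_csv(inputs / "ensembl_symbols.tsv", sep="\t", index=False)
    pd.DataFrame(sorted(g.synonyms.items()), columns=["alias", "symbol"]).to_csv(
        inputs / "synonyms.tsv", sep="\t", index=False
    )
    bundle.truth.to_json(inputs / "truth.json")
    paths += [
        inputs / "genes.gtf", inputs / "mouse_genes.gtf", inputs / "genome.fa",
        inputs / "mouse_genome.fa", inputs / "chr_counts.tsv", inputs / "conservation.tsv",
        inputs / "homologs.tsv", inputs / "disease.tsv", inputs / "truth.json",
    ]
    return sorted(paths)


def _sites_frame(sites: list[TargetSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "tsrna_id": s.tsrna_id,
                "gene_id": s.gene_id,
                "chrom": s.chrom,
                "start": s.start,
                "end": s.end,
                "strand": s.strand,
                "score": s.score,
                "energy": "" if s.energy is None else round(s.energy, 3),
                "region": s.region,
                "intron_ordinal": "" if s.intron_ordinal is None else s.intron_ordinal,
                "within_intron_offset": ""
                if s.within_intron_offset is None
                else round(s.within_intron_offset, 5),
            }
            for s in sites
        ],
        columns=[
            "tsrna_id", "gene_id", "chrom", "start", "end", "strand",
            "score", "energy", "region", "intron_ordinal", "within_intron_offset",
        ],
    )


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute the full synthetic study and write the report bundle."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = stage_simulate(cfg)
    input_paths = _write_inputs(bundle, outdir)
    truth = bundle.truth

    collapsed = stage_preprocess(bundle.srna.reads, cfg)
    collapsed.to_csv(outdir / "collapsed.tsv", sep="\t", index=False)

    annotated = stage_annotate(collapsed, bundle.ref, cfg)
    annotated.to_csv(outdir / "annotated.tsv", sep="\t", index=False)
    hist, cumulative = length_distribution(annotated)
    hist.to_csv(outdir / "length_histogram.tsv", sep="\t")

    srna_de = stage_srna_de(collapsed, cfg)
    srna_de.to_csv(outdir / "srna_de.tsv", sep="\t")

    candidates, rep_candidates, dependent = stage_parclip(
        bundle.parclip_sets, bundle.ref, srna_de, cfg, collapsed=collapsed
    )
    pd.DataFrame(
        [
            {
                "sequence": c.sequence,
                "cluster_id": c.cluster_id,
                "ago_bound": c.ago_bound,
                "dicer_bound": c.dicer_bound,
                "dicer_dependent": c.dicer_dependent,
                "log2fc": "" if c.log2fc is None else round(c.log2fc, 4),
            }
            for c in candidates
        ]
    ).to_csv(outdir / "parclip_candidates.tsv", sep="\t", index=False)

    chr_tables, chr_up = stage_chr_de(bundle.genes.counts, bundle.genes.condition_of, cfg)
    for cond, tab in chr_tables.items():
        tab.to_csv(outdir / f"chr_de_{cond}.tsv", sep="\t")
    venn, universe = intersect_upregulated(
        chr_up["shDicer"], chr_up["shAgo2"], chr_up["shDrosha"], exclude_drosha=cfg.exclude_drosha
    )

    sites = stage_predict(rep_candidates, universe, bundle.genes.models, bundle.genes.genome, cfg)
    _sites_frame(sites).to_csv(outdir / "target_sites.tsv", sep="\t", index=False)

    dependent_seqs = {c.sequence for c in dependent}
    dependent_cluster_seqs = {c.sequence for c in candidates if c.dicer_dependent}
    dep_sites = [s for s in sites if s.tsrna_id in dependent_seqs]
    other_sites = [s for s in sites if s.tsrna_id not in dependent_seqs]

    partition = partition_target_genes(dep_sites, universe)
    models_by_id = {m.gene_id: m for m in bundle.genes.models}
    intronic = [s for s in dep_sites if s.intron_ordinal is not None]
    metagene = intron_metagene(intronic, models_by_id, n_bins=cfg.metagene_bins) if intronic else None

    track = ConservationTrack(bundle.genes.conservation)
    cons_dep = site_conservation_scores(dep_sites, track)
    cons_other = site_conservation_scores(other_sites, track)
    conservation_test = (
        compare_site_conservation(cons_dep, cons_other) if cons_dep and cons_other else None
    )

    # cross-species run: each human target gene's own tsRNAs vs its homolog
    human_targets: dict[str, set[str]] = {}
    for s in dep_sites:
        human_targets.setdefault(s.gene_id, set()).add(s.tsrna_id)
    mouse_by_id = {m.gene_id: m for m in bundle.genes.mouse_models}
    mouse_sites: list[TargetSite] = []
    for hg in sorted(human_targets):
        mg = bundle.genes.homolog_map.get(hg)
        if mg is None or mg not in mouse_by_id:
            continue
        mouse_sites += predict_targets(
            {t: t for t in human_targets[hg]},
            [mouse_by_id[mg]],
            bundle.genes.mouse_genome,
            params=cfg.scoring(),
            relaxed=True,
        )
    _sites_frame(mouse_sites).to_csv(outdir / "mouse_sites.tsv", sep="\t", index=False)
    pairs, conserved_count = conservation_fraction(
        human_targets, bundle.genes.homolog_map, mouse_sites, threshold=cfg.conservation_threshold
    )

    targeted = partition["intronic_or_both"] | partition["exon_only"]
    table, fisher_p, matrix = disease_enrichment(
        targeted,
        bundle.genes.disease,
        bundle.genes.ncbi_symbols,
        bundle.genes.ensembl_symbols,
        bundle.genes.synonyms,
    )
    matrix.to_csv(outdir / "disease_matrix.tsv", sep="\t")

    abundance = (
        annotated[annotated["best_reference"] != ""]
        .groupby("best_reference")[[c for c in annotated.columns if c.startswith("control_")]]
        .sum()
        .sum(axis=1)
    )
    rho, rho_p = expression_abundance_correlation(
        truth.trna_expression, dict(abundance)
    )

    # ---- evaluation against the planted truth -----------------------------
    planted = truth.planted_genes()
    seq_of = truth.tsrna_sequences
    planted_dep_seqs = {seq_of[t] for t, _, _, _ in truth.planted_target_sites}
    recovered = partition["intronic_or_both"]
    unplanted_n = cfg.n_genes - len(planted)
    evaluation = {
        "planted_genes": len(planted),
        "planted_recall": (len(planted & recovered) / len(planted)) if planted else None,
        "false_inclusion_rate": (len(recovered - planted) / unplanted_n) if unplanted_n else 0.0,
        "dependent_tsrna_recall": (
            len(planted_dep_seqs & dependent_cluster_seqs) / len(planted_dep_seqs)
            if planted_dep_seqs
            else None
        ),
        "dependent_tsrna_false": sorted(
            s
            for s in dependent_cluster_seqs
            if abs(truth.effects.get(s, 0.0)) <= 1 and s in truth.effects
        ),
        "conservation_fraction_recovered": (
            conserved_count / len(pairs) if pairs else None
        ),
    }

    report = {
        "package_version": __version__,
        "seed": cfg.seed,
        "parameters": dataclasses.asdict(cfg),
        "n_unique_sequences": int(len(collapsed)),
        "n_supported_features": int(collapsed["feature_flag"].sum()),
        "cumulative_length_fraction": {
            str(L): round(float(cumulative.loc[:L].iloc[-1]), 4) for L in (22, 25) if len(cumulative)
        },
        "n_parclip_candidates": len(candidates),
        "n_parclip_clusters": len({c.cluster_id for c in candidates}),
        "n_dicer_dependent": len(dependent),
        "venn": venn,
        "universe_size": len(universe),
        "n_target_sites": len(sites),
        "n_target_genes": len(targeted),
        "partition": {k: sorted(v) for k, v in partition.items()},
        "partition_counts": {k: len(v) for k, v in partition.items()},
        "metagene_density": [round(float(d), 6) for d in metagene.density] if metagene else [],
        "metagene_n_sites": metagene.n_sites if metagene else 0,
        "conservation_comparison": (
            {
                "statistic": conservation_test.statistic,
                "pvalue": conservation_test.pvalue,
                "median_dependent": conservation_test.median_a,
                "median_other": conservation_test.median_b,
            }
            if conservation_test
            else None
        ),
        "conservation_pairs": len(pairs),
        "conserved_homologs": conserved_count,
        "disease_table": {"a": table.a, "b": table.b, "c": table.c, "d": table.d},
        "disease_fisher_p": fisher_p,
        "expression_abundance_spearman": {"rho": rho, "pvalue": rho_p},
        "evaluation": evaluation,
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")

    with open(outdir / "run_log.txt", "w") as fh:
        fh.write(f"tsrna-nrs {__version__}\nseed: {cfg.seed}\n")
        for f in dataclasses.fields(cfg):
            fh.write(f"param {f.name} = {getattr(cfg, f.name)}\n")
        for p in input_paths:
            fh.write(f"input {p.name} sha256 {_sha256(p)}\n")

    return PipelineResult(config=cfg, report=report, truth=truth, sites=sites, outdir=outdir)
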