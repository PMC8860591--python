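"""Synthetic-data generator: determinism, planted effects and truth closure."""

import numpy as np
import pytest

from tsrna_nrs.simulate import (
    fragment_catalogue,
    generate_trna_reference,
    simulate_conservation_fixture,
    simulate_gene_set,
    simulate_parclip_sets,
    simulate_srna_reads,
)
from tsrna_nrs.targets import predict_targets


@pytest.fixture(scope="module")
def ref():
    return generate_trna_reference(10, seed=31)


@pytest.fixture(scope="module")
def catalogue(ref):
    return fragment_catalogue(ref, seed=32)


def _tsrnas(catalogue, n=6):
    seqs = [s for s in catalogue.table["sequence"] if 18 <= len(s) <= 22]
    return {f"t{i}": s for i, s in enumerate(seqs[:n])}


class TestSRNAReads:
    def test_null_design_centres_on_unity_ratio(self, ref, catalogue):
        sim = simulate_srna_reads(
            ref, {"control": 2, "shDicer": 2}, effects={}, depth=5000, seed=1,
            catalogue=catalogue, adapter_fraction=0.0, partial_adapter_fraction=0.0,
            error_rate=0.0,
        )
        from collections import Counter

        ctrl = Counter(sim.reads["control_rep1"]) + Counter(sim.reads["control_rep2"])
        kd = Counter(sim.reads["shDicer_rep1"]) + Counter(sim.reads["shDicer_rep2"])
        shared = [s for s in ctrl if ctrl[s] >= 20 and s in kd]
        lfcs = [np.log2(kd[s] / ctrl[s]) for s in shared]
        assert abs(float(np.mean(lfcs))) < 0.25

    def test_planted_depletion_recovers_ratio(self, ref, catalogue):
        """Monte-Carlo over many fragments: knockdown/control mean-count
        ratio of fragments with log2FC -2 centres on 2^-2."""
        from collections import Counter

        top = catalogue.table.nlargest(50, "abundance")["sequence"].tolist()
        sim = simulate_srna_reads(
            ref, {"control": 3, "shDicer": 3}, effects={s: -2.0 for s in top},
            depth=60000, seed=2, catalogue=catalogue, adapter_fraction=0.0,
            partial_adapter_fraction=0.0, error_rate=0.0,
        )
        ctrl = Counter()
        kd = Counter()
        for i in (1, 2, 3):
            ctrl.update(sim.reads[f"control_rep{i}"])
            kd.update(sim.reads[f"shDicer_rep{i}"])
        ratios = [np.log2(kd[s] / ctrl[s]) for s in top if ctrl[s] >= 30 and kd[s] > 0]
        assert len(ratios) >= 30
        assert float(np.mean(ratios)) == pytest.approx(-2.0, abs=0.3)

    def test_zero_depth_is_valid_and_empty(self, ref, catalogue):
        sim = simulate_srna_reads(
            ref, {"control": 2, "shDicer": 2}, effects={}, depth=0, seed=3,
            catalogue=catalogue,
        )
        assert all(len(r) == 0 for r in sim.reads.values())
        assert sim.effects == {}

    def test_effect_on_unknown_sequence_rejected(self, ref, catalogue):
        with pytest.raises(ValueError):
            simulate_srna_reads(
                ref, {"control": 2, "shDicer": 2}, effects={"ACGT" * 5: -1.0},
                depth=100, seed=4, catalogue=catalogue,
            )

    def test_reads_are_reference_fragments_plus_adapter(self, ref, catalogue):
        sim = simulate_srna_reads(
            ref, {"control": 2, "shDicer": 2}, effects={}, depth=500, seed=5,
            catalogue=catalogue, error_rate=0.0,
        )
        forms = [s for _, _, s in ref.iter_forms()]
        frags = set(catalogue.table["sequence"])
        for read in sim.reads["control_rep1"][:50]:
            insert = next((f for f in frags if read.startswith(f)), None)
            assert insert is not None
            assert any(insert in f for f in forms)


class TestParclipSets:
    def test_candidates_pass_and_decoys_fail_thresholds(self, ref, catalogue):
        ts = _tsrnas(catalogue)
        sets = simulate_parclip_sets(
            catalogue, ref, list(ts.values())[:4], list(ts.values())[4:6], seed=6,
            tc_conversion_fraction=0.0,
        )
        from tsrna_nrs.parclip import filter_parclip

        kept = {c.sequence for c in filter_parclip(sets)}
        assert set(list(ts.values())[:4]) <= kept
        long_seqs = {s for s in catalogue.table["sequence"] if len(s) > 22}
        assert not kept & long_seqs

    def test_tc_conversion_mass_restores_after_equalization(self, ref, catalogue):
        ts = _tsrnas(catalogue, 2)
        sets = simulate_parclip_sets(
            catalogue, ref, list(ts.values()), [], seed=7, tc_conversion_fraction=0.3,
            n_low_occurrence_decoys=0, n_random_decoys=0,
        )
        for seq in ts.values():
            variants = [s for s in sets["Ago1"] if s != seq and len(s) == len(seq)]
            if variants:  # a T->C variant was emitted; mass was split
                assert sets["Ago1"][seq] < sum(sets["Ago1"].values())


class TestGeneSet:
    def test_no_planting_when_fraction_zero(self, catalogue):
        bundle = simulate_gene_set(
            _tsrnas(catalogue), n_genes=8, planted_fraction=0.0,
            conservation_fraction=0.5, disease_enrichment_odds=2.0, seed=8,
        )
        assert bundle.truth.planted_target_sites == []
        assert all(not v for v in bundle.truth.upregulated_genes_by_condition.values())

    def test_planted_sites_lie_in_annotated_introns(self, catalogue):
        bundle = simulate_gene_set(
            _tsrnas(catalogue), n_genes=10, planted_fraction=0.4,
            conservation_fraction=1.0, disease_enrichment_odds=2.0, seed=9,
        )
        models = {m.gene_id: m for m in bundle.models}
        assert bundle.truth.planted_target_sites
        for tsid, gid, ordinal, (chrom, s, e) in bundle.truth.planted_target_sites:
            gene = models[gid]
            iv = gene.introns_transcription_order()[ordinal]
            assert iv[0] <= s < e <= iv[1]
            assert tsid in bundle.truth.tsrna_sequences

    def test_planted_sites_rescore_above_threshold(self, catalogue):
        """Generator self-consistency: the scanner finds every planted site."""
        bundle = simulate_gene_set(
            _tsrnas(catalogue), n_genes=10, planted_fraction=0.4,
            conservation_fraction=1.0, disease_enrichment_odds=2.0, seed=10,
        )
        models = {m.gene_id: m for m in bundle.models}
        ts = {t: bundle.truth.tsrna_sequences[t] for t, _, _, _ in bundle.truth.planted_target_sites}
        for tsid, gid, _, (chrom, s, e) in bundle.truth.planted_target_sites:
            sites = predict_targets({tsid: ts[tsid]}, [models[gid]], bundle.genome)
            assert any(x.start == s and x.end == e and x.score >= 150 for x in sites)

    def test_full_conservation_copies_regions_verbatim(self, catalogue):
        bundle = simulate_gene_set(
            _tsrnas(catalogue), n_genes=10, planted_fraction=0.4,
            conservation_fraction=1.0, disease_enrichment_odds=2.0, seed=11,
        )
        for _, gid, _, (chrom, s, e) in bundle.truth.planted_target_sites:
            if gid not in bundle.homolog_map:
                continue
            human_region = bundle.genome[chrom][s:e]
            assert bundle.mouse_genome[f"m{chrom}"][s:e] == human_region

    def test_unit_odds_ratio_is_null(self, catalogue):
        """Pooled over many seeds, odds ratio 1 gives an empirical odds
        ratio near 1 between planted and unplanted genes."""
        ts = _tsrnas(catalogue, 3)
        cells = np.zeros(4)
        for seed in range(100):
            b = simulate_gene_set(
                ts, n_genes=12, planted_fraction=0.25, conservation_fraction=0.0,
                disease_enrichment_odds=1.0, seed=1000 + seed,
            )
            planted = b.truth.planted_genes()
            diseased = set(
                b.disease["gene_symbol"].map(lambda s: b.synonyms.get(s, s))
            )
            for m in b.models:
                i = 2 * (m.gene_id not in planted) + (m.gene_id not in diseased)
                cells[i] += 1
        a, bb, c, d = cells
        odds = (a * d) / (bb * c)
        assert 0.7 < odds < 1.4

    def test_empty_tsrnas_with_planting_rejected(self):
        with pytest.raises(ValueError):
            simulate_gene_set({}, 5, 0.5, 0.5, 2.0, seed=12)

    def test_truth_closure(self, catalogue):
        bundle = simulate_gene_set(
            _tsrnas(catalogue), n_genes=10, planted_fraction=0.3,
            conservation_fraction=0.5, disease_enrichment_odds=2.0, seed=13,
        )
        genes = {m.gene_id for m in bundle.models}
        t = bundle.truth
        for _, gid, _, _ in t.planted_target_sites:
            assert gid in genes
        for cond, eff in t.upregulated_genes_by_condition.items():
            assert set(eff) <= genes
        for hg, mg in t.conserved_homolog_pairs:
            assert bundle.homolog_map.get(hg) == mg
            assert any(m.gene_id == mg for m in bundle.mouse_models)
        assert t.enriched_disease_genes <= genes

    def test_determinism_across_repeat_calls(self, catalogue):
        a = simulate_gene_set(_tsrnas(catalogue), 8, 0.25, 0.5, 2.0, seed=14)
        b = simulate_gene_set(_tsrnas(catalogue), 8, 0.25, 0.5, 2.0, seed=14)
        assert a.genome == b.genome
        assert a.counts.equals(b.counts)
        assert a.disease.equals(b.disease)
        assert a.conservation.equals(b.conservation)


class TestConservationFixture:
    def test_conserved_loci_verbatim_scrambled_loci_clean(self, catalogue):
        ts = _tsrnas(catalogue, 5)
        fx = simulate_conservation_fixture(ts, 20, 0.5, seed=15)
        from tsrna_nrs.seq import revcomp

        assert len(fx.conserved_pairs) == 10
        for i, hg in enumerate(sorted(fx.human_targets)):
            (tid,) = fx.human_targets[hg]
            locus = fx.mouse_genome[f"mchr_{hg}"]
            site = revcomp(fx.tsrna_sequences[tid])
            conserved = (hg, fx.homolog_map[hg]) in fx.conserved_pairs
            assert (site in locus) == conserved
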