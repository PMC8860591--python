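"""Venn integration, partitions, metagene, conservation and enrichment."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oracles import fisher_greater_scipy
from tsrna_nrs.genemodel import GeneModel
from tsrna_nrs.integrate import (
    ConservationTrack,
    ContingencyTable2x2,
    compare_site_conservation,
    conservation_fraction,
    disease_enrichment,
    expression_abundance_correlation,
    fisher_one_sided,
    intersect_upregulated,
    intron_metagene,
    partition_target_genes,
)
from tsrna_nrs.targets import TargetSite


def _site(gene, tsrna="t", ordinal=None, offset=None, chrom="c", start=0, end=20):
    s = TargetSite(tsrna, gene, chrom, start, end, "+", 160.0, -31.0)
    s.intron_ordinal = ordinal
    s.within_intron_offset = offset
    s.region = "exon" if ordinal is None else f"intron({ordinal})"
    return s


class TestVenn:
    def test_exclusion_example(self):
        venn, uni = intersect_upregulated({"g1", "g2", "g3"}, {"g2", "g3"}, {"g3"}, True)
        assert uni == {"g2"}
        assert venn["111"] == 1 and venn["110"] == 1 and venn["100"] == 1

    def test_disjoint_sets_empty_universe(self):
        _, uni = intersect_upregulated({"a"}, {"b"}, set(), True)
        assert uni == set()

    def test_counts_match_membership_enumeration(self):
        rng = np.random.default_rng(21)
        genes = [f"g{i}" for i in range(60)]
        A = {g for g in genes if rng.random() < 0.4}
        B = {g for g in genes if rng.random() < 0.4}
        C = {g for g in genes if rng.random() < 0.3}
        venn, uni = intersect_upregulated(A, B, C, exclude_drosha=True)
        for pat in venn:
            d, a, r = (bool(int(x)) for x in pat)
            expect = sum(
                1
                for g in genes
                if (g in A) == d and (g in B) == a and (g in C) == r and (d or a or r)
            )
            assert venn[pat] == expect
        assert uni == (A & B) - C
        _, uni2 = intersect_upregulated(A, B, C, exclude_drosha=False)
        assert uni2 == A & B


class TestPartition:
    def test_mixed_sites_classify_as_intronic_or_both(self):
        uni = {"g1", "g2", "g3"}
        sites = [_site("g1", ordinal=0, offset=0.5), _site("g1"), _site("g2")]
        part = partition_target_genes(sites, uni)
        assert part["intronic_or_both"] == {"g1"}
        assert part["exon_only"] == {"g2"}
        assert part["untargeted"] == {"g3"}

    def test_partition_covers_universe(self):
        rng = np.random.default_rng(22)
        uni = {f"g{i}" for i in range(30)}
        sites = []
        for g in sorted(uni)[:18]:
            ordinal = int(rng.integers(0, 3)) if rng.random() < 0.6 else None
            sites.append(_site(g, ordinal=ordinal, offset=0.1 if ordinal is not None else None))
        part = partition_target_genes(sites, uni)
        groups = list(part.values())
        assert set.union(*groups) == uni
        assert sum(len(g) for g in groups) == len(uni)

    def test_site_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            partition_target_genes([_site("gX")], {"g1"})


class TestMetagene:
    models = {
        "g": GeneModel(
            gene_id="g", chrom="c", strand="+",
            exons=[(0, 100), (200, 300), (400, 500), (600, 700), (800, 900)],
        )
    }  # 4 introns

    def test_coordinate_formula(self):
        prof = intron_metagene([_site("g", ordinal=0, offset=0.0)], self.models, n_bins=20)
        assert prof.counts[0] == 1 and prof.n_sites == 1
        prof2 = intron_metagene([_site("g", ordinal=1, offset=0.5)], self.models, n_bins=20)
        # x = (1 + 0.5)/4 = 0.375 -> bin 7 of 20
        assert prof2.counts[7] == 1

    def test_density_sums_to_one(self):
        rng = np.random.default_rng(23)
        sites = [
            _site("g", ordinal=int(rng.integers(0, 4)), offset=float(rng.random()))
            for _ in range(100)
        ]
        prof = intron_metagene(sites, self.models)
        assert prof.density.sum() == pytest.approx(1.0)
        assert (prof.density >= 0).all()

    def test_uniform_placement_is_flat(self):
        rng = np.random.default_rng(24)
        sites = [
            _site("g", ordinal=int(rng.integers(0, 4)), offset=float(rng.random()))
            for _ in range(2000)
        ]
        prof = intron_metagene(sites, self.models, n_bins=20)
        chi2 = ((prof.counts - 100.0) ** 2 / 100.0).sum()
        assert stats.chi2.sf(chi2, df=19) > 0.01

    def test_missing_intron_coordinates_rejected(self):
        with pytest.raises(ValueError):
            intron_metagene([_site("g")], self.models)


class TestConservationComparison:
    def test_identical_groups_not_significant(self):
        x = list(np.linspace(0.1, 0.9, 30))
        res = compare_site_conservation(x, x)
        assert res.pvalue > 0.9
        assert res.median_a == res.median_b

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(25)
        a = rng.uniform(0.3, 0.7, 200) + 0.3
        b = rng.uniform(0.3, 0.7, 200)
        res = compare_site_conservation(a, b)
        assert res.pvalue < 0.01
        assert res.median_a > res.median_b

    def test_single_elements_exact_enumeration(self):
        # two observations, all 2 orderings equally likely: two-sided p = 1
        res = compare_site_conservation([0.9], [0.1])
        assert res.pvalue == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_site_conservation([], [0.5])


class TestConservationTrack:
    def test_site_mean_is_overlap_weighted(self):
        rows = pd.DataFrame(
            {"chrom": ["c", "c"], "start": [0, 10], "end": [10, 20], "score": [0.2, 0.8]}
        )
        track = ConservationTrack(rows)
        assert track.site_mean("c", 5, 15) == pytest.approx(0.5)
        assert track.site_mean("c", 0, 10) == pytest.approx(0.2)
        assert track.site_mean("x", 0, 10) is None
        assert track.site_mean("c", 30, 40) is None


class TestConservationFraction:
    def test_nine_of_ten_counts_as_conserved(self):
        human = {"h": {f"t{i}" for i in range(10)}}
        sites = [_site("m", tsrna=f"t{i}") for i in range(9)]
        pairs, conserved = conservation_fraction(human, {"h": "m"}, sites, threshold=0.9)
        assert pairs[0].fraction == pytest.approx(0.9)
        assert conserved == 1

    def test_no_mouse_hits_gives_zero_fraction(self):
        pairs, conserved = conservation_fraction({"h": {"t"}}, {"h": "m"}, [], 0.9)
        assert pairs[0].fraction == 0.0 and conserved == 0

    def test_missing_homolog_dropped(self):
        pairs, _ = conservation_fraction({"h1": {"t"}, "h2": {"t"}}, {"h1": "m1"}, [], 0.9)
        assert [p.human_gene_id for p in pairs] == ["h1"]


class TestFisher:
    def test_extreme_table_closed_form(self):
        p = fisher_one_sided(ContingencyTable2x2(10, 0, 0, 10))
        assert p == pytest.approx(1.0 / math.comb(20, 10), rel=1e-12)

    def test_balanced_table_not_significant(self):
        assert fisher_one_sided(ContingencyTable2x2(5, 5, 5, 5)) > 0.5

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(26)
        for _ in range(300):
            a, b, c, d = (int(x) for x in rng.integers(0, 30, 4))
            ours = fisher_one_sided(ContingencyTable2x2(a, b, c, d))
            assert ours == pytest.approx(fisher_greater_scipy(a, b, c, d), abs=1e-12)

    def test_null_pvalues_are_uniformish(self):
        """Independent target/disease labels (odds ratio 1): the one-sided p
        is stochastically no smaller than uniform."""
        rng = np.random.default_rng(27)
        ps = []
        for _ in range(200):
            target = rng.random(400) < 0.3
            disease = rng.random(400) < 0.4
            a = int((target & disease).sum())
            b = int((target & ~disease).sum())
            c = int((~target & disease).sum())
            d = int((~target & ~disease).sum())
            ps.append(fisher_one_sided(ContingencyTable2x2(a, b, c, d)))
        ps = np.array(ps)
        for alpha in (0.05, 0.1, 0.25):
            assert (ps <= alpha).mean() <= alpha + 0.05


class TestDiseaseEnrichment:
    def _fixture(self):
        genes = [f"g{i}" for i in range(20)]
        assoc = pd.DataFrame(
            {
                "gene_symbol": ["g0", "g0", "g1", "g2", "g10", "ALIAS11"],
                "disease_id": ["D1", "D2", "D1", "D2", "D3", "D1"],
                "disease_class": ["x", "y", "x", "y", "z", "x"],
            }
        )
        return genes, assoc

    def test_universe_intersection_and_synonyms(self):
        genes, assoc = self._fixture()
        table, p, matrix = disease_enrichment(
            {"g0", "g1", "g2"},
            assoc,
            ncbi_symbols=set(genes),
            ensembl_symbols=set(genes) - {"g19"},
            synonyms={"ALIAS11": "g11"},
        )
        assert table.n == 19
        assert table.a == 3  # g0, g1, g2 all associated
        assert table.c == 2  # g10 and (resolved) g11
        assert p == pytest.approx(fisher_greater_scipy(table.a, table.b, table.c, table.d), abs=1e-12)

    def test_matrix_ordering_descending(self):
        genes, assoc = self._fixture()
        _, _, matrix = disease_enrichment(
            {"g0", "g1", "g2"}, assoc, set(genes), set(genes), None
        )
        colsums = matrix.sum(axis=0).to_numpy()
        rowsums = matrix.sum(axis=1).to_numpy()
        assert (np.diff(colsums) <= 0).all()
        assert (np.diff(rowsums) <= 0).all()

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            disease_enrichment(set(), pd.DataFrame(columns=["gene_symbol", "disease_id", "disease_class"]), {"a"}, {"b"}, None)


class TestSpearman:
    def test_monotone_extremes(self):
        x = {f"i{k}": float(k) for k in range(10)}
        y_up = {f"i{k}": float(k * k) for k in range(10)}
        y_dn = {f"i{k}": float(-k) for k in range(10)}
        rho, _ = expression_abundance_correlation(x, y_up)
        assert rho == pytest.approx(1.0)
        rho2, _ = expression_abundance_correlation(x, y_dn)
        assert rho2 == pytest.approx(-1.0)

    def test_exact_permutation_p_matches_enumeration(self):
        rng = np.random.default_rng(28)
        x = {f"i{k}": float(v) for k, v in enumerate(rng.random(8))}
        y = {f"i{k}": float(v) for k, v in enumerate(rng.random(8))}
        rho, p = expression_abundance_correlation(x, y)
        xr = stats.rankdata([x[f"i{k}"] for k in range(8)])
        yr = stats.rankdata([y[f"i{k}"] for k in range(8)])
        count = 0
        total = 0
        for perm in itertools.permutations(range(8)):
            r = np.corrcoef(xr, yr[list(perm)])[0, 1]
            count += abs(r) >= abs(rho) - 1e-12
            total += 1
        assert p == pytest.approx(count / total)

    def test_too_few_shared_ids_rejected(self):
        with pytest.raises(ValueError):
            expression_abundance_correlation({"a": 1.0, "b": 2.0}, {"a": 1.0, "b": 2.0})
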