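"""Enrichment battery against brute-force and exhaustive-enumeration oracles."""

import itertools
import math

import numpy as np
import pytest

from eqtlenrich.datamodel import DeRecord, GeneRecord, GeneSet
from eqtlenrich.enrichment import (
    RankedGenes,
    enrichment_suite,
    fisher_threshold_enrichment,
    gsea_preranked,
    ks_enrichment,
    map_snps_to_genes,
    rank_genes,
    report_table,
    select_targets,
)
from eqtlenrich.enrichment import _running_sum_extremum

from conftest import make_gwas


# ---------------------------------------------------------------------------
# target selection
# ---------------------------------------------------------------------------

class TestSelectTargets:
    @pytest.mark.parametrize(
        "rec,expected",
        [
            (DeRecord("g", 2.5, 0.05), True),
            (DeRecord("g", -2.5, 0.05), True),   # sign-symmetric
            (DeRecord("g", 3.0, 0.1), False),    # fdr boundary is strict
            (DeRecord("g", 2.0, 0.05), False),   # fold boundary is strict
            (DeRecord("g", 1.5, 0.01), False),
        ],
    )
    def test_filter_boundaries(self, rec, expected):
        got = "g" in select_targets([rec, DeRecord("pad", 1.0, 1.0)]).gene_ids
        assert got is expected

    def test_exclusion_list_applied(self):
        de = [DeRecord("driver", 8.0, 0.001), DeRecord("t1", 3.0, 0.01)]
        assert select_targets(de, exclude={"driver"}).gene_ids == {"t1"}

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            select_targets([])


# ---------------------------------------------------------------------------
# SNP-to-gene mapping
# ---------------------------------------------------------------------------

class TestMapSnpsToGenes:
    GENE = [GeneRecord("G", "chr1", 100_000, 105_000)]

    def test_flank_boundary_inclusion(self):
        snps = make_gwas([0.5], positions=[60_001])  # pos0 = 60,000
        a = map_snps_to_genes(snps, self.GENE, flank=50_000)
        assert a.snp_to_genes == {"g1": {"G"}}

    def test_flank_boundary_exclusion(self):
        snps = make_gwas([0.5], positions=[50_000])  # pos0 = 49,999 < start - flank
        a = map_snps_to_genes(snps, self.GENE, flank=50_000)
        assert a.snp_to_genes == {}

    def test_right_edge_half_open(self):
        inside = make_gwas([0.5], positions=[155_000])   # pos0 = 154,999 < end + flank
        outside = make_gwas([0.5], positions=[155_001])  # pos0 = 155,000
        assert map_snps_to_genes(inside, self.GENE, flank=50_000).snp_to_genes
        assert not map_snps_to_genes(outside, self.GENE, flank=50_000).snp_to_genes

    def test_low_maf_snps_dropped(self):
        snps = make_gwas([0.5], positions=[102_000], maf=0.01)  # == maf_min: dropped
        assert not map_snps_to_genes(snps, self.GENE, flank=0).snp_to_genes

    def test_matches_brute_force_double_loop(self, rng):
        genes = []
        for i in range(50):
            start = int(rng.integers(0, 5_000_000))
            genes.append(GeneRecord(f"G{i}", "chr1", start, start + int(rng.integers(1000, 80_000))))
        positions = sorted(int(v) for v in rng.choice(np.arange(1, 5_200_000), 500, replace=False))
        snps = make_gwas(rng.uniform(size=500), positions=positions)
        flank = 25_000
        got = map_snps_to_genes(snps, genes, flank=flank)
        expected: dict[str, set[str]] = {}
        for s in snps:
            hits = {
                g.gene_id
                for g in genes
                if g.start - flank <= s.meta.pos0 < g.end + flank
            }
            if hits:
                expected[s.meta.snp_id] = hits
        assert got.snp_to_genes == expected

    def test_monotone_in_flank(self, rng):
        genes = [GeneRecord(f"G{i}", "chr1", i * 200_000, i * 200_000 + 30_000) for i in range(10)]
        snps = make_gwas(
            rng.uniform(size=200),
            positions=sorted(int(v) for v in rng.choice(np.arange(1, 2_000_000), 200, replace=False)),
        )
        small = map_snps_to_genes(snps, genes, flank=10_000)
        large = map_snps_to_genes(snps, genes, flank=60_000)
        for snp_id, gids in small.snp_to_genes.items():
            assert gids <= large.snp_to_genes.get(snp_id, set())

    def test_order_invariance(self, rng):
        genes = [GeneRecord(f"G{i}", "chr1", i * 100_000, i * 100_000 + 40_000) for i in range(5)]
        snps = make_gwas(
            rng.uniform(size=100),
            positions=sorted(int(v) for v in rng.choice(np.arange(1, 600_000), 100, replace=False)),
        )
        fwd = map_snps_to_genes(snps, genes, flank=20_000)
        rev = map_snps_to_genes(snps[::-1], genes[::-1], flank=20_000)
        assert fwd.snp_to_genes == rev.snp_to_genes


# ---------------------------------------------------------------------------
# K-S enrichment
# ---------------------------------------------------------------------------

def assignment_from_samples(a_pvals, b_pvals):
    """Assignment with disjoint target/background SNP groups."""
    snp_to_genes, pvals = {}, {}
    for i, p in enumerate(a_pvals):
        snp_to_genes[f"t{i}"] = {"T"}
        pvals[f"t{i}"] = float(p)
    for i, p in enumerate(b_pvals):
        snp_to_genes[f"b{i}"] = {"B"}
        pvals[f"b{i}"] = float(p)
    gene_to_snps = {"T": {s for s in snp_to_genes if s.startswith("t")},
                    "B": {s for s in snp_to_genes if s.startswith("b")}}
    from eqtlenrich.enrichment import SnpAssignment
    return SnpAssignment(50_000, snp_to_genes, gene_to_snps, pvals)


class TestKsEnrichment:
    TARGETS = GeneSet("t", {"T"})

    def test_disjoint_supports_give_d_one(self):
        a = assignment_from_samples([0.1, 0.2, 0.3], [0.6, 0.7, 0.8])
        d, p = ks_enrichment(a, self.TARGETS)
        assert d == pytest.approx(1.0)

    def test_matches_ecdf_grid_oracle(self, rng):
        xs, ys = rng.uniform(size=50), rng.uniform(size=50) ** 2
        a = assignment_from_samples(xs, ys)
        d, _ = ks_enrichment(a, self.TARGETS)
        grid = np.concatenate([xs, ys])
        ecdf_a = np.array([(xs <= v).mean() for v in grid])
        ecdf_b = np.array([(ys <= v).mean() for v in grid])
        assert d == pytest.approx(np.max(np.abs(ecdf_a - ecdf_b)), abs=1e-12)

    def test_empty_sample_error_names_side(self):
        a = assignment_from_samples([], [0.5])
        with pytest.raises(ValueError, match="target"):
            ks_enrichment(a, self.TARGETS)
        b = assignment_from_samples([0.5], [])
        with pytest.raises(ValueError, match="background"):
            ks_enrichment(b, self.TARGETS)

    def test_shared_snps_counted_as_target_by_default(self):
        from eqtlenrich.enrichment import SnpAssignment
        a = SnpAssignment(
            0,
            {"s1": {"T", "B"}, "s2": {"B"}, "s3": {"T"}},
            {"T": {"s1", "s3"}, "B": {"s1", "s2"}},
            {"s1": 0.1, "s2": 0.9, "s3": 0.2},
        )
        d_tp, _ = ks_enrichment(a, self.TARGETS, overlap_policy="target-priority")
        assert d_tp == pytest.approx(1.0)  # targets {0.1, 0.2} vs background {0.9}


# ---------------------------------------------------------------------------
# Fisher threshold enrichment
# ---------------------------------------------------------------------------

def fisher_two_sided_oracle(table):
    """Exhaustive hypergeometric enumeration of the two-tailed p."""
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d

    def prob(x):
        return (
            math.comb(col1, x)
            * math.comb(n - col1, row1 - x)
            / math.comb(n, row1)
        )

    p_obs = prob(a)
    return sum(
        prob(x)
        for x in range(max(0, row1 + col1 - n), min(row1, col1) + 1)
        if prob(x) <= p_obs * (1 + 1e-9)
    )


class TestFisher:
    def run_one(self, a_pvals, b_pvals, threshold=0.05):
        assignment = assignment_from_samples(a_pvals, b_pvals)
        return fisher_threshold_enrichment(
            assignment, GeneSet("t", {"T"}), thresholds=(threshold,)
        )[0]

    def test_worked_example_3113(self):
        # table [[3,1],[1,3]]: two-tailed p = 34/70
        res = self.run_one([0.01, 0.02, 0.03, 0.5], [0.01, 0.6, 0.7, 0.8])
        assert res.table == ((3, 1), (1, 3))
        assert res.p_value == pytest.approx(0.4857142857, abs=1e-9)

    def test_matches_enumeration_oracle_on_random_tables(self, rng):
        for _ in range(25):
            a = rng.uniform(size=int(rng.integers(3, 12)))
            b = rng.uniform(size=int(rng.integers(3, 12)))
            t = float(rng.uniform(0.05, 0.95))
            res = self.run_one(a, b, threshold=t)
            if res.no_snps:
                continue
            assert res.p_value == pytest.approx(fisher_two_sided_oracle(res.table), rel=1e-9)

    def test_no_effect_large_counts(self):
        a = [0.01] * 50 + [0.9] * 50
        b = [0.01] * 50 + [0.9] * 50
        res = self.run_one(a, b)
        assert res.p_value > 0.5

    def test_group_label_symmetry(self, rng):
        a, b = rng.uniform(size=20), rng.uniform(size=30)
        assert self.run_one(a, b).p_value == pytest.approx(self.run_one(b, a).p_value)

    def test_no_qualifying_snps_flagged(self):
        res = self.run_one([0.5, 0.6], [0.7, 0.8], threshold=1e-6)
        assert res.no_snps and res.p_value == 1.0

    def test_haldane_corrected_odds_ratio_on_zero_cell(self):
        res = self.run_one([0.01, 0.02], [0.9, 0.8])
        (a, b), (c, d) = res.table
        assert c == 0
        expected = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
        assert res.odds_ratio == pytest.approx(expected)


# ---------------------------------------------------------------------------
# gene ranking
# ---------------------------------------------------------------------------

class TestRankGenes:
    def test_min_p_rule(self):
        a = assignment_from_samples([0.5, 1e-6], [0.3])
        ranked = rank_genes(a)
        assert ranked.gene_ids[0] == "T"
        assert ranked.scores[0] == pytest.approx(6.0)

    def test_shared_snp_ties_broken_lexicographically(self):
        from eqtlenrich.enrichment import SnpAssignment
        a = SnpAssignment(
            0,
            {"s1": {"GB", "GA"}},
            {"GA": {"s1"}, "GB": {"s1"}},
            {"s1": 0.01},
        )
        ranked = rank_genes(a)
        assert ranked.gene_ids == ["GA", "GB"]
        assert ranked.scores[0] == ranked.scores[1]

    def test_matches_brute_force_on_random_fixture(self, rng):
        genes = [GeneRecord(f"G{i:03d}", "chr1", i * 50_000, i * 50_000 + 20_000) for i in range(100)]
        positions = sorted(int(v) for v in rng.choice(np.arange(1, 5_100_000), 2000, replace=False))
        snps = make_gwas(rng.uniform(size=2000), positions=positions)
        assignment = map_snps_to_genes(snps, genes, flank=50_000)
        ranked = rank_genes(assignment)
        p_of = {s.meta.snp_id: s.p_value for s in snps}
        brute = {}
        for s in snps:
            for g in genes:
                if g.start - 50_000 <= s.meta.pos0 < g.end + 50_000:
                    brute[g.gene_id] = min(brute.get(g.gene_id, 1.0), p_of[s.meta.snp_id])
        expected = sorted(((-np.log10(p), g) for g, p in brute.items()), key=lambda t: (-t[0], t[1]))
        assert ranked.gene_ids == [g for _, g in expected]
        np.testing.assert_allclose(ranked.scores, [s for s, _ in expected], atol=1e-12)


# ---------------------------------------------------------------------------
# preranked GSEA
# ---------------------------------------------------------------------------

class TestGsea:
    def ranked(self, scores, ids=None):
        ids = ids or [f"g{i}" for i in range(len(scores))]
        return RankedGenes(ids, np.asarray(scores, float))

    def test_top_concentration_gives_es_one(self):
        ranked = self.ranked([5.0, 4.0, 3.0, 2.0, 1.0, 0.5])
        res = gsea_preranked(ranked, GeneSet("t", {"g0", "g1"}), n_perm=100, seed=1)
        assert res.es == pytest.approx(1.0)

    def test_bottom_concentration_gives_negative_es(self):
        ranked = self.ranked([5.0, 4.0, 3.0, 2.0, 1.0, 0.5])
        res = gsea_preranked(ranked, GeneSet("t", {"g4", "g5"}), n_perm=100, seed=1)
        assert res.es < 0

    def test_p_never_zero(self):
        ranked = self.ranked(np.linspace(10, 0.1, 50))
        res = gsea_preranked(ranked, GeneSet("t", {"g0", "g1", "g2"}), n_perm=99, seed=0)
        assert res.p_value >= 1 / 100

    def test_permutation_p_matches_exhaustive_null(self):
        """C(6,2)=15 placements enumerated exactly vs the permutation estimate."""
        scores = np.array([3.0, 2.5, 2.0, 1.5, 1.0, 0.5])
        ranked = self.ranked(scores)
        targets = GeneSet("t", {"g0", "g2"})
        res = gsea_preranked(ranked, targets, n_perm=100_000, seed=42)
        null = [
            _running_sum_extremum(np.array(idx), scores[list(idx)], 6)
            for idx in itertools.combinations(range(6), 2)
        ]
        exact = np.mean([e >= res.es - 1e-12 for e in null])
        assert res.p_value == pytest.approx(exact, abs=0.02)

    def test_exponent_zero_invariant_to_monotone_transform(self):
        scores = np.array([9.0, 5.0, 3.0, 2.0, 1.0, 0.5, 0.2, 0.1])
        targets = GeneSet("t", {"g1", "g4", "g6"})
        a = gsea_preranked(self.ranked(scores), targets, n_perm=50, weight_exponent=0.0, seed=3)
        b = gsea_preranked(self.ranked(np.log1p(scores)), targets, n_perm=50, weight_exponent=0.0, seed=3)
        assert a.es == pytest.approx(b.es, abs=1e-12)

    def test_exponent_one_invariant_to_positive_rescaling(self):
        scores = np.array([9.0, 5.0, 3.0, 2.0, 1.0, 0.5, 0.2, 0.1])
        targets = GeneSet("t", {"g0", "g3", "g5"})
        a = gsea_preranked(self.ranked(scores), targets, n_perm=50, seed=3)
        b = gsea_preranked(self.ranked(scores * 7.3), targets, n_perm=50, seed=3)
        assert a.es == pytest.approx(b.es, abs=1e-12)

    def test_empty_intersection_errors(self):
        with pytest.raises(ValueError, match="intersect"):
            gsea_preranked(self.ranked([1.0, 0.5]), GeneSet("t", {"zz"}), n_perm=10)

    def test_deterministic_given_seed(self):
        ranked = self.ranked(np.linspace(5, 0.1, 40))
        t = GeneSet("t", {"g1", "g5", "g9"})
        a = gsea_preranked(ranked, t, n_perm=500, seed=9)
        b = gsea_preranked(ranked, t, n_perm=500, seed=9)
        assert (a.es, a.p_value) == (b.es, b.p_value)


# ---------------------------------------------------------------------------
# the full battery
# ---------------------------------------------------------------------------

class TestSuite:
    def test_table_shape_contract(self, rng):
        genes = [GeneRecord(f"G{i}", "chr1", i * 150_000, i * 150_000 + 20_000) for i in range(40)]
        positions = sorted(int(v) for v in rng.choice(np.arange(1, 6_000_000), 3000, replace=False))
        snps = make_gwas(rng.uniform(size=3000), positions=positions)
        targets = GeneSet("t", {g.gene_id for g in genes[::4]})
        flanks = (10_000, 25_000, 50_000, 100_000)
        reports = enrichment_suite(snps, genes, targets, flanks=flanks, n_perm=50, seed=0)
        table = report_table(reports)
        assert len(table) == len(flanks)
        assert list(table["flank_kb"]) == [f / 1000 for f in flanks]
        # GSEA only at the 50-kb flank
        assert table["gsea_p"].notna().tolist() == [f == 50_000 for f in flanks]
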