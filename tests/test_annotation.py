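import numpy as np
import pandas as pd
import pytest
from scipy import stats

from segdup.annotation import classify_genes, genes_in_sds, go_enrichment
from segdup.sdmap import SDRecord

from _dp_oracle import hypergeom_tail
from test_sdmap import make_pair


def gene_frame(rows):
    return pd.DataFrame(rows, columns=["seqid", "start", "end", "strand", "gene_id"])


class TestGenesInSDs:
    def test_overlapping_gene_included(self):
        genes = gene_frame([("c", 100, 200, "+", "g1")])
        ids, frac = genes_in_sds(genes, {"c": [(150, 1000)]})
        assert ids == ["g1"] and frac == 1.0

    def test_adjacent_gene_excluded(self):
        genes = gene_frame([("c", 100, 150, "+", "g1")])
        ids, frac = genes_in_sds(genes, {"c": [(150, 1000)]})
        assert ids == [] and frac == 0.0

    def test_duplicate_gene_ids_error(self):
        genes = gene_frame([("c", 0, 10, "+", "g1"), ("c", 20, 30, "+", "g1")])
        with pytest.raises(ValueError):
            genes_in_sds(genes, {"c": [(0, 100)]})

    def test_monotone_in_union_size(self):
        rng = np.random.default_rng(0)
        genes = gene_frame(
            [("c", int(s), int(s) + 500, "+", f"g{i}")
             for i, s in enumerate(rng.integers(0, 90_000, size=60))]
        )
        small, _ = genes_in_sds(genes, {"c": [(10_000, 20_000)]})
        large, _ = genes_in_sds(genes, {"c": [(10_000, 40_000)]})
        assert set(small) <= set(large)

    def test_truth_planted_genes_recovered(self, small_scenario):
        from segdup.io import read_gff_genes, write_gff_genes

        sc = small_scenario
        sp = sc.species[0]
        slots = []
        for e in sc.truth.events_for(sp):
            slots += [e.source, e.copy_intervals[sp]]
        genes = gene_frame([("chr1", s, e, "+", g) for g, s, e in sc.truth.genes])
        ids, _ = genes_in_sds(genes, {"chr1": slots})
        assert sorted(ids) == sorted(sc.truth.sd_genes[sp])


class TestClassifyGenes:
    def _records(self):
        shared = SDRecord(make_pair(sa=0, sb=50_000), ">=90", "shared")
        unique = SDRecord(make_pair(sa=1000, sb=80_000), ">=90", "unique")
        return [shared, unique]

    def test_shared_precedence_over_unique(self):
        genes = gene_frame([("c", 1200, 1400, "+", "g1")])  # overlaps both
        status = classify_genes(genes, self._records(), ["g1"])
        assert status == {"g1": "shared"}

    def test_gene_in_unique_only(self):
        genes = gene_frame([("c", 80_100, 80_300, "+", "g1")])
        status = classify_genes(genes, self._records(), ["g1"])
        assert status == {"g1": "unique"}

    def test_non_sd_genes_ignored(self):
        genes = gene_frame([("c", 200_000, 200_400, "+", "g1")])
        assert classify_genes(genes, self._records(), []) == {}


class TestGoEnrichment:
    def test_matches_hypergeometric_oracle_small_tables(self):
        # the documented example: 5/5 in-set vs 5/85 out-of-set
        bg = [f"g{i}" for i in range(100)]
        sd = bg[:10]
        go_map = {g: ["T"] for g in bg[:5] + bg[10:15]}
        (res,) = go_enrichment(sd, bg, go_map)
        want = float(hypergeom_tail(5, 10, 10, 100))
        assert res.p_value == pytest.approx(want, rel=1e-9)
        assert res.observed == 5
        assert res.expected == pytest.approx(10 * 10 / 100)

    def test_exhaustive_oracle_on_moderate_margins(self):
        # all 2x2 tables with set size and term size up to 12 in N=24
        N = 24
        bg = [f"g{i}" for i in range(N)]
        for n_set in range(1, 13, 3):
            for K in range(1, 13, 3):
                for k in range(0, min(n_set, K) + 1):
                    sd = bg[:n_set]
                    with_term = bg[:k] + bg[n_set : n_set + (K - k)]
                    go_map = {g: ["T"] for g in with_term}
                    (res,) = go_enrichment(sd, bg, go_map)
                    want = float(hypergeom_tail(k, K, n_set, N))
                    assert res.p_value == pytest.approx(want, rel=1e-9), (n_set, K, k)

    def test_proportional_term_not_enriched(self):
        bg = [f"g{i}" for i in range(100)]
        sd = bg[:20]
        go_map = {g: ["T"] for g in bg[:10] + bg[20:60]}  # 50% in and out
        (res,) = go_enrichment(sd, bg, go_map)
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p_value >= 0.5

    def test_planted_overrepresentation_flagged(self):
        rng = np.random.default_rng(1)
        bg = [f"g{i}" for i in range(500)]
        sd = bg[:50]
        go_map = {}
        for g in bg:
            terms = []
            rate = 0.5 if g in sd[:50] else 0.05  # 10x over-representation
            if rng.random() < rate:
                terms.append("HOT")
            if rng.random() < 0.2:
                terms.append("COLD")
            go_map[g] = terms
        results = {r.term: r for r in go_enrichment(sd, bg, go_map)}
        assert results["HOT"].significant
        assert not results["COLD"].significant

    def test_expected_counts_sum_to_mean_terms_per_gene(self):
        rng = np.random.default_rng(2)
        bg = [f"g{i}" for i in range(80)]
        go_map = {g: [f"T{j}" for j in range(5) if rng.random() < 0.3] for g in bg}
        sd = bg[:16]
        results = go_enrichment(sd, bg, go_map)
        total_expected = sum(r.expected for r in results)
        mean_terms = np.mean([len(go_map[g]) for g in bg])
        assert total_expected == pytest.approx(len(sd) * mean_terms)

    def test_sd_gene_missing_from_background_errors(self):
        with pytest.raises(ValueError):
            go_enrichment(["gX"], ["g1"], {})

    def test_bh_flag_reduces_significant_calls(self):
        rng = np.random.default_rng(3)
        bg = [f"g{i}" for i in range(300)]
        sd = bg[:30]
        go_map = {g: [f"T{j}" for j in range(30) if rng.random() < 0.1] for g in bg}
        raw = go_enrichment(sd, bg, go_map, bh_correct=False)
        bh = go_enrichment(sd, bg, go_map, bh_correct=True)
        assert sum(r.significant for r in bh) <= sum(r.significant for r in raw)
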