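import numpy as np
import pytest

from segdup.intervals import merge_intervals, subtract, total_length
from segdup.masking import RepeatAnnotation
from segdup.te import (
    enrichment,
    enrichment_significance,
    flanks,
    region_content,
    te_content_table,
)


def rep(s, e, cls="DNA", seq="c"):
    return RepeatAnnotation(seq, s, e, cls)


class TestRegionContent:
    def test_simple_fraction(self):
        out = region_content({"c": [(0, 1000)]}, [rep(100, 300)])
        assert out["DNA"] == (200, 0.2)

    def test_straddling_repeat_clipped(self):
        out = region_content({"c": [(0, 1000)]}, [rep(900, 1200)])
        assert out["DNA"] == (100, 0.1)

    def test_genome_fraction_matches_planted_density(self):
        from segdup.simulate import SimulationConfig, simulate_scenario

        cfg = SimulationConfig(
            newick="(A);", genome_length=300_000, n_ancestral=0, n_clade_shared=0,
            n_lineage_unique=15, te_sd_bias=1.0, n_genes=0, seed=21,
        )
        sc = simulate_scenario(cfg)
        out = region_content({"chr1": [(0, cfg.genome_length)]}, sc.repeats["A"])
        for cls, dens in cfg.te_density.items():
            assert out[cls][1] == pytest.approx(dens, abs=0.01)


class TestFlanks:
    def test_both_sides(self):
        fl = flanks({"c": [(10_000, 12_000)]}, {"c": 1_000_000})
        assert fl["c"] == [(7_500, 10_000), (12_000, 14_500)]

    def test_clipped_at_sequence_start(self):
        fl = flanks({"c": [(1000, 3000)]}, {"c": 1_000_000})
        assert fl["c"][0] == (0, 1000)

    def test_inter_sd_bases_counted_once_and_sd_excluded(self):
        union = {"c": [(10_000, 12_000), (15_000, 17_000)]}
        fl = flanks(union, {"c": 1_000_000})
        # the 3 kb between the two SDs is covered once, SD bases excluded
        manual = subtract(
            merge_intervals(
                [(7_500, 10_000), (12_000, 14_500), (12_500, 15_000), (17_000, 19_500)]
            ),
            union["c"],
        )
        assert fl["c"] == manual
        assert total_length(fl["c"]) == 2500 + 3000 + 2500


class TestEnrichment:
    def test_ratio(self):
        assert enrichment(0.10, 0.05) == pytest.approx(2.0)

    def test_equal_fractions_unity(self):
        assert enrichment(0.037, 0.037) == pytest.approx(1.0)

    def test_zero_reference_not_applicable(self):
        assert enrichment(0.1, 0.0) is None

    def test_published_ltr_ratio(self):
        # printed diamondback-moth LTR fractions: 0.043% in SDs, 0.006% genome
        ratio = enrichment(0.043, 0.006)
        assert ratio == pytest.approx(7.173, rel=0.02)


class TestSignificance:
    def _uniform_setup(self, rng, G=200_000, n_rep=120, te_len=400):
        starts = rng.choice(G - te_len, size=n_rep, replace=False)
        reps = [rep(int(s), int(s) + te_len, "DNA") for s in starts]
        return reps

    def test_no_enrichment_gives_middling_p(self):
        rng = np.random.default_rng(0)
        reps = self._uniform_setup(rng)
        union = {"c": [(i * 20_000, i * 20_000 + 3000) for i in range(8)]}
        p = enrichment_significance(
            union, reps, "DNA", {"c": 200_000}, n_samples=1000,
            rng=np.random.default_rng(1),
        )
        assert 0.2 <= p <= 0.8

    def test_planted_bias_detected(self):
        rng = np.random.default_rng(2)
        G = 200_000
        union = {"c": [(i * 20_000, i * 20_000 + 3000) for i in range(8)]}
        inside = []
        for s, e in union["c"]:
            inside += [rep(s + 200, s + 600), rep(s + 1000, s + 1400)]  # 4x density
        outside = self._uniform_setup(rng, G=G, n_rep=40)
        p = enrichment_significance(
            union, inside + outside, "DNA", {"c": G}, n_samples=1000,
            rng=np.random.default_rng(3),
        )
        assert p <= 0.05

    def test_absent_class_p_one(self):
        union = {"c": [(0, 5000)]}
        p = enrichment_significance(union, [], "LTR", {"c": 100_000}, n_samples=200)
        assert p == 1.0

    def test_type_one_error_calibrated(self):
        # uniform repeats, random SD placement: rejection rate ~ alpha
        rng = np.random.default_rng(4)
        rejections = 0
        reps_n = 150
        for i in range(reps_n):
            G = 60_000
            te = [
                rep(int(s), int(s) + 300, "DNA")
                for s in rng.choice(G - 300, size=30, replace=False)
            ]
            sd_starts = rng.choice(G - 2000, size=5, replace=False)
            union = {"c": merge_intervals([(int(s), int(s) + 2000) for s in sd_starts])}
            p = enrichment_significance(
                union, te, "DNA", {"c": G}, n_samples=300,
                rng=np.random.default_rng(1000 + i),
            )
            rejections += p <= 0.05
        assert 0.01 <= rejections / reps_n <= 0.10

    def test_small_n_samples_rejected(self):
        with pytest.raises(ValueError):
            enrichment_significance({"c": [(0, 100)]}, [], "DNA", {"c": 1000}, n_samples=10)


class TestTable:
    def test_conservation_and_columns(self, small_scenario):
        sc = small_scenario
        sp = sc.species[0]
        G = sc.config.genome_length
        union = {"chr1": merge_intervals(
            [e.source for e in sc.truth.events_for(sp)]
            + [e.copy_intervals[sp] for e in sc.truth.events_for(sp)]
        )}
        tbl = te_content_table(
            union, sc.repeats[sp], {"chr1": G}, n_samples=200,
            rng=np.random.default_rng(5),
        )
        assert set(tbl["class"]) == {"DNA", "SINE", "LTR", "LINE"}
        assert (tbl["p_value"] > 0).all() and (tbl["p_value"] <= 1).all()
        # genome bp per class equals the truth's planted bp per class
        for cls in ("DNA", "SINE", "LTR", "LINE"):
            planted = sum(e - s for s, e, c in sc.truth.tes[sp] if c == cls)
            got = int(tbl.loc[tbl["class"] == cls, "genome_bp"].iloc[0])
            assert got == planted
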