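import numpy as np
import pytest

from segdup.align import AlignmentPair
from segdup.sdmap import build_union, filter_sds
from segdup.simulate import (
    ConfigError,
    SimulationConfig,
    TruthSet,
    score_recovery,
    shared_species_sets,
    simulate_scenario,
    parse_tree,
)


def test_empty_config_gives_clean_random_genome():
    cfg = SimulationConfig(
        newick="(A);", genome_length=5000, n_ancestral=0, n_clade_shared=0,
        n_lineage_unique=0, te_density={}, n_genes=0, seed=3,
    )
    sc = simulate_scenario(cfg)
    assert sc.truth.events == []
    assert sc.truth.tes["A"] == []
    assert set(sc.genomes["A"]["chr1"]) <= set("ACGT")
    assert len(sc.genomes["A"]["chr1"]) == 5000


def test_determinism_byte_identical(tmp_path):
    cfg = SimulationConfig(genome_length=60_000, n_ancestral=2, n_clade_shared=3,
                           n_lineage_unique=2, n_genes=40, seed=9)
    d1, d2 = tmp_path / "a", tmp_path / "b"
    simulate_scenario(cfg).write(str(d1))
    simulate_scenario(cfg).write(str(d2))
    files = sorted(p.name for p in d1.iterdir())
    assert files == sorted(p.name for p in d2.iterdir())
    for name in files:
        assert (d1 / name).read_bytes() == (d2 / name).read_bytes(), name


def test_planted_mismatch_count_matches_emitted_sequences():
    cfg = SimulationConfig(
        newick="(A);", genome_length=30_000, n_ancestral=0, n_clade_shared=0,
        n_lineage_unique=1, dup_length_range=(2000, 2000),
        dup_divergence_range=(0.05, 0.05), te_density={}, n_genes=0, seed=1,
    )
    sc = simulate_scenario(cfg)
    (ev,) = sc.truth.events
    g = sc.genomes["A"]["chr1"]
    src = g[ev.source[0]:ev.source[1]]
    cp_iv = ev.copy_intervals["A"]
    cp = g[cp_iv[0]:cp_iv[1]]
    mm = sum(a != b for a, b in zip(src, cp))
    assert mm == ev.realized_mismatches["A"]
    assert 50 <= mm <= 160  # ~100 expected at rate 0.05 over 2 kb


def test_divergence_calibration_over_many_events():
    cfg = SimulationConfig(
        newick="(A);", genome_length=900_000, n_ancestral=0, n_clade_shared=0,
        n_lineage_unique=60, dup_length_range=(1500, 3000),
        dup_divergence_range=(0.08, 0.08), te_density={}, n_genes=0, seed=2,
    )
    sc = simulate_scenario(cfg)
    g = sc.genomes["A"]["chr1"]
    fracs = []
    for ev in sc.truth.events:
        src = g[ev.source[0]:ev.source[1]]
        s, e = ev.copy_intervals["A"]
        cp = g[s:e]
        fracs.append(sum(a != b for a, b in zip(src, cp)) / len(src))
    assert abs(np.mean(fracs) - 0.08) < 0.01


def test_ancestral_event_present_in_all_species(five_species_scenario):
    sc = five_species_scenario
    for ev in sc.truth.events:
        if ev.category == "ancestral":
            assert set(ev.species) == set(sc.species)
        if ev.category == "lineage_unique":
            assert len(ev.species) == 1
        # every planted set is a union of clades (by construction candidates)
        assert ev.copy_intervals.keys() == set(ev.species)


def test_clade_candidates_are_clade_unions():
    tree = parse_tree("(Pxyl,((Dple,Hmel),(Msex,Bmor)));")
    cands = shared_species_sets(tree)
    assert ("Dple", "Hmel") in cands
    assert ("Msex", "Bmor") in cands
    assert ("Pxyl", "Dple", "Hmel") in cands  # complement of the moth pair
    assert ("Pxyl", "Msex", "Bmor") in cands


def test_requested_duplication_bp_exceeding_genome_errors():
    cfg = SimulationConfig(genome_length=10_000, n_ancestral=10, n_clade_shared=0,
                           n_lineage_unique=0, dup_length_range=(2000, 2000))
    with pytest.raises(ConfigError):
        simulate_scenario(cfg)


def test_invalid_divergence_range_rejected():
    with pytest.raises(ConfigError):
        SimulationConfig(dup_divergence_range=(0.0, 0.4)).validate()


def test_indel_mode_changes_copy_length():
    cfg = SimulationConfig(
        newick="(A);", genome_length=120_000, n_ancestral=0, n_clade_shared=0,
        n_lineage_unique=8, dup_length_range=(3000, 4000),
        dup_divergence_range=(0.02, 0.05), indels=True, indel_rate=0.003,
        te_density={}, n_genes=0, seed=4,
    )
    sc = simulate_scenario(cfg)
    lens = [
        (e.copy_intervals["A"][1] - e.copy_intervals["A"][0]) - (e.source[1] - e.source[0])
        for e in sc.truth.events
    ]
    assert any(d != 0 for d in lens)


def test_expression_truth_plants_suppression(five_species_scenario):
    sc = five_species_scenario
    sp = sc.species[0]
    sd = set(sc.truth.sd_genes[sp])
    if len(sd) < 5:
        pytest.skip("too few SD genes in this compact scenario")
    expr = sc.expression[sp]
    logv = np.log10(expr["rpkm"] + 0.01)
    in_sd = expr["gene_id"].isin(sd)
    assert logv[in_sd].mean() < logv[~in_sd].mean()


def test_truthset_json_round_trip(tmp_path, five_species_scenario):
    path = tmp_path / "truth.json"
    five_species_scenario.truth.to_json(str(path))
    back = TruthSet.from_json(str(path))
    assert back.species == five_species_scenario.truth.species
    assert len(back.events) == len(five_species_scenario.truth.events)
    e0, e1 = five_species_scenario.truth.events[0], back.events[0]
    assert (e0.source, e0.copy, e0.species) == (e1.source, e1.copy, e1.species)
    assert back.sd_genes == five_species_scenario.truth.sd_genes


class TestScoreRecovery:
    def _map_from_pairs(self, truth, species, pairs):
        recs = filter_sds(pairs)
        return build_union(recs, {"chr1": truth.genome_length}, species=species)

    def _perfect_pairs(self, truth, species):
        out = []
        for ev in truth.events_for(species):
            s0, s1 = ev.source
            c0, c1 = ev.copy_intervals[species]
            n = min(s1 - s0, c1 - c0)
            out.append(
                AlignmentPair("chr1", s0, s1, "chr1", c0, c1, "+", n, 0, 0, n)
            )
        return out

    def test_empty_truth_and_calls_not_applicable(self):
        truth = TruthSet(["A"], 1000, [], {"A": []}, [], {"A": []})
        m = self._map_from_pairs(truth, "A", [])
        r = score_recovery(truth, m)
        assert r.sensitivity is None and r.precision is None

    def test_perfect_calls_give_unit_scores(self, small_scenario):
        sp = small_scenario.species[0]
        truth = small_scenario.truth
        m = self._map_from_pairs(truth, sp, self._perfect_pairs(truth, sp))
        r = score_recovery(truth, m)
        assert r.sensitivity == 1.0 and r.precision == 1.0
        assert r.max_boundary_error == 0

    def test_half_kb_shift_on_2kb_event_not_recovered(self):
        ev_src, ev_cp = (10_000, 12_000), (50_000, 52_000)
        truth = TruthSet(
            ["A"], 100_000,
            [__import__("segdup.simulate", fromlist=["DupEvent"]).DupEvent(
                "e", "lineage_unique", ("A",), ev_src, ev_cp, 0.0,
                {"A": 0}, {"A": ev_cp},
            )],
            {"A": []}, [], {"A": []},
        )
        shifted = AlignmentPair(
            "chr1", 10_500, 12_500, "chr1", 50_500, 52_500, "+", 2000, 0, 0, 2000
        )
        m = self._map_from_pairs(truth, "A", [shifted])
        r = score_recovery(truth, m)  # 75% reciprocal overlap < 80% rule
        assert r.n_recovered == 0 and r.precision == 0.0

    def test_species_mismatch_errors(self, small_scenario):
        truth = small_scenario.truth
        m = self._map_from_pairs(truth, truth.species[0], [])
        m.species = "nonexistent"
        with pytest.raises(ValueError):
            score_recovery(truth, m)
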