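import numpy as np
import pytest
from scipy import stats

from segdup.align import KmerIndex
from segdup.comparative import (
    HitParams,
    PresenceVector,
    assign_groups,
    classify_shared,
    contrast_identity,
    contrast_variance,
    default_pattern_table,
)
from segdup.masking import fuguize, select_repeats
from segdup.align import discard_self, refine, reinsert, self_align
from segdup.sdmap import SDRecord, build_union, filter_sds
from segdup.intervals import reciprocal_overlap

TREE = "(Pxyl,((Dple,Hmel),(Msex,Bmor)));"
SPECIES = ["Pxyl", "Dple", "Hmel", "Msex", "Bmor"]


def vec(present):
    return PresenceVector(0, "Pxyl", {sp: sp in present for sp in SPECIES})


class TestAssignGroups:
    def test_all_present_is_ancestral_group(self):
        assert assign_groups([vec(SPECIES)], TREE) == ["A"]

    def test_loss_of_moth_pair_is_group_b(self):
        assert assign_groups([vec(["Pxyl", "Dple", "Hmel"])], TREE) == ["B"]

    def test_loss_of_butterfly_pair_is_group_e(self):
        assert assign_groups([vec(["Pxyl", "Msex", "Bmor"])], TREE) == ["E"]

    def test_single_losses_within_clades(self):
        assert assign_groups([vec(["Pxyl", "Dple", "Hmel", "Msex"])], TREE) == ["C"]
        assert assign_groups([vec(["Pxyl", "Dple", "Msex", "Bmor"])], TREE) == ["D"]

    def test_focal_only_is_unique(self):
        assert assign_groups([vec(["Pxyl"])], TREE) == ["unique"]

    def test_unmatched_multi_species_is_other(self):
        assert assign_groups([vec(["Pxyl", "Bmor"])], TREE) == ["other"]

    def test_duplicate_pattern_in_table_rejected(self):
        table = default_pattern_table(TREE)

        class DupKeys(dict):
            def keys(self):
                return list(super().keys()) + [frozenset()]

        with pytest.raises(ValueError):
            assign_groups([vec(SPECIES)], TREE, DupKeys(table))


class TestClassifyShared:
    def test_planted_events_recovered_with_truth_labels(self, five_species_scenario):
        sc = five_species_scenario
        cfg = sc.config
        maps = {}
        for sp in sc.species:
            g = sc.genomes[sp]
            fugu, cmap = fuguize(g, select_repeats(sc.repeats[sp]))
            pairs = refine(reinsert(discard_self(self_align(fugu)), cmap), g)
            maps[sp] = build_union(
                filter_sds(pairs), {"chr1": len(g["chr1"])}, species=sp
            )
        indexes = {sp: KmerIndex(sc.genomes[sp]) for sp in sc.species}
        agree = tot = status_agree = 0
        for sp in sc.species:
            others = {o: sc.genomes[o] for o in sc.species if o != sp}
            vectors = classify_shared(
                maps[sp], others, sc.genomes[sp], HitParams(), indexes=indexes,
                focal_repeats=sc.repeats[sp],
            )
            labels = assign_groups(vectors, cfg.newick)
            for v, rec in zip(vectors, maps[sp].records):
                p = rec.pair
                truth_ev = None
                for e in sc.truth.events_for(sp):
                    cp = e.copy_intervals[sp]
                    for x, y in (
                        (((p.start_a, p.end_a)), (p.start_b, p.end_b)),
                        (((p.start_b, p.end_b)), (p.start_a, p.end_a)),
                    ):
                        if (
                            reciprocal_overlap(x, e.source) >= 0.8
                            and reciprocal_overlap(y, cp) >= 0.8
                        ):
                            truth_ev = e
                            break
                    if truth_ev:
                        break
                if truth_ev is None:
                    continue
                tv = PresenceVector(0, sp, {s: s in truth_ev.species for s in sc.species})
                tot += 1
                agree += assign_groups([tv], cfg.newick)[0] == v.group
                # shared/unique must match the planted species set
                want = "shared" if len(truth_ev.species) > 1 else "unique"
                status_agree += rec.shared_status == want
        assert tot > 10
        assert agree / tot >= 0.95
        assert status_agree / tot >= 0.95

    def test_missing_genome_errors(self, five_species_scenario):
        sc = five_species_scenario
        m = build_union([], {"chr1": sc.truth.genome_length}, species="Pxyl")
        with pytest.raises(ValueError, match="Dple"):
            classify_shared(m, {"Dple": {}}, sc.genomes["Pxyl"])


def _recs(values):
    from test_sdmap import make_pair

    return [
        SDRecord(make_pair(len_a=2000, identity=v, sa=i * 3000, sb=i * 3000 + 500_000),
                 ">=90")
        for i, v in enumerate(values)
    ]


class TestContrasts:
    def test_identical_distributions_high_p(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(90, 2, size=200).clip(75, 100)
        r = contrast_identity(_recs(vals), _recs(vals))
        assert abs(r.statistic) < 1e-9 and r.p_value > 0.99

    def test_planted_difference_detected(self):
        rng = np.random.default_rng(1)
        shared = rng.normal(95, 2, size=200).clip(75, 100)
        unique = rng.normal(85, 2, size=200).clip(75, 100)
        r = contrast_identity(_recs(shared), _recs(unique))
        assert r.direction == "shared_higher"
        assert r.p_value < 0.01

    def test_t_statistic_matches_closed_form_on_toy_vectors(self):
        x = np.array([90.0, 92.0, 94.0, 96.0])
        y = np.array([85.0, 87.0, 89.0, 91.0])
        r = contrast_identity(_recs(x), _recs(y), welch=False)
        # pooled-variance two-sample t computed by hand
        sp2 = (x.var(ddof=1) * 3 + y.var(ddof=1) * 3) / 6
        t_hand = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / 4 + 1 / 4))
        assert r.statistic == pytest.approx(t_hand)

    def test_degenerate_equal_constant_groups(self):
        r = contrast_identity(_recs([90, 90, 90]), _recs([90, 90, 90]))
        assert r.p_value == 1.0

    def test_variance_identical_samples_p_one(self):
        vals = [88.0, 91.0, 95.0, 99.0]
        r = contrast_variance(_recs(vals), _recs(vals))
        assert r.p_value == pytest.approx(1.0)

    def test_variance_4x_difference_detected(self):
        rng = np.random.default_rng(2)
        a = rng.normal(90, 4, size=200).clip(75, 100)
        b = rng.normal(90, 2, size=200).clip(75, 100)
        r = contrast_variance(_recs(a), _recs(b))
        assert r.p_value < 0.01

    def test_variance_test_calibrated_under_null(self):
        rng = np.random.default_rng(3)
        rejections = 0
        reps = 200
        for _ in range(reps):
            a = rng.normal(90, 2, size=50)
            b = rng.normal(90, 2, size=50)
            f = a.var(ddof=1) / b.var(ddof=1)
            cdf = stats.f.cdf(f, 49, 49)
            p = 2 * min(cdf, 1 - cdf)
            rejections += p < 0.05
        assert 0.02 <= rejections / reps <= 0.09
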