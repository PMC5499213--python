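"""Shared/unique classification and phylogenetic grouping of SDs.

An SD is *shared* when the duplication it describes exists in at least one
other species, *unique* otherwise.  Because every locus has an alignable
ortholog in closely related genomes, presence of the duplication (not mere
presence of homologous sequence) is what is scored: the SD's sequence must
hit at least two distinct loci in the other genome — its ancestral locus
plus a duplicate copy.  Both sides of the SD are used as queries and their
qualifying hits are merged; two or more disjoint hit loci count as
presence.

Presence/absence patterns across the species set are then mapped to
phylogenetic groups: all-present patterns are potential ancestral events
(group A), specific loss patterns get configurable labels (B..E), and
everything seen in a single species is "unique".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .align import KmerIndex, search_sequence
from .intervals import merge_intervals
from .masking import RepeatAnnotation
from .sdmap import SDMap, SDRecord
from .simulate import parse_tree, tree_clades, tree_leaves


def _mask_query(seq: str, start: int, masked: Sequence[Tuple[int, int]]) -> str:
    """Hard-mask repeat intervals (genome coordinates) inside a query slice.

    Repeat sequence inside an SD would otherwise seed hits at every other
    copy of the same repeat family and fake a second locus; presence must
    rest on the SD's unique sequence, mirroring the masked self-alignment.
    """
    out = list(seq)
    n = len(seq)
    for ms, me in masked:
        lo = max(0, ms - start)
        hi = min(n, me - start)
        for i in range(lo, hi):
            out[i] = "N"
    return "".join(out)


@dataclass
class PresenceVector:
    """Per-SD presence/absence across the species set."""

    record_index: int
    focal: str
    presence: Dict[str, bool]
    group: str = ""

    @property
    def present_set(self) -> FrozenSet[str]:
        return frozenset(sp for sp, p in self.presence.items() if p)


@dataclass(frozen=True)
class HitParams:
    min_identity: float = 75.0
    min_len: int = 1000
    min_loci: int = 2  # distinct loci required for the duplication to exist
    k: int = 14
    max_gap: int = 1000  # cluster tolerance when joining hit components
    chain_gap: int = 200  # within-component chaining gap
    component_min_score: int = 50
    max_occ: int = 64


def _qualifying_loci(
    queries: Sequence[str], index: KmerIndex, params: HitParams
) -> List[Tuple[str, int, int]]:
    """Distinct target loci hit by the queries at the identity/length floor.

    Hits are found with a tight chaining gap so homology segments separated
    by (excluded) repeat sequence surface as separate components; components
    at >= ``min_identity`` are clustered when within ``max_gap`` bp of each
    other, and a cluster qualifies as a locus when its repeat-inclusive
    span reaches ``min_len`` bp and at least half of ``min_len`` is
    actually aligned.  (SD lengths are repeat-inclusive after reinsertion,
    so the presence floor measures loci the same way.)  An isolated
    sub-``min_len`` hit is therefore never a locus, while an SD-scale
    homology interrupted by a repeat insertion is one.
    """
    ivs = []
    for q in queries:
        for h in search_sequence(
            q, index, max_gap=params.chain_gap,
            min_score=max(1, params.component_min_score), max_occ=params.max_occ,
        ):
            if h.identity >= params.min_identity:
                ivs.append((h.seq, h.start, h.end))
    by_seq: Dict[str, List[Tuple[int, int]]] = {}
    for seq, s, e in ivs:
        by_seq.setdefault(seq, []).append((s, e))
    out: List[Tuple[str, int, int]] = []
    for seq in sorted(by_seq):
        merged = merge_intervals(by_seq[seq])
        cluster: List[Tuple[int, int]] = []
        for iv in merged + [(None, None)]:
            if cluster and (iv[0] is None or iv[0] - cluster[-1][1] > params.max_gap):
                aligned_bp = sum(e - s for s, e in cluster)
                span = cluster[-1][1] - cluster[0][0]
                if span >= params.min_len and 2 * aligned_bp >= params.min_len:
                    out.append((seq, cluster[0][0], cluster[-1][1]))
                cluster = []
            if iv[0] is not None:
                cluster.append(iv)
    return out


def classify_shared(
    sd_map: SDMap,
    genomes: Mapping[str, Mapping[str, str]],
    focal_genome: Mapping[str, str],
    params: HitParams = HitParams(),
    indexes: Optional[Mapping[str, KmerIndex]] = None,
    focal_repeats: Optional[Sequence[RepeatAnnotation]] = None,
) -> List[PresenceVector]:
    """Set ``shared_status`` on every record of ``sd_map`` and return the
    presence vectors.

    ``genomes`` maps the *other* species to their (unmasked) genome dicts;
    ``indexes`` may carry prebuilt :class:`KmerIndex` objects to reuse
    across maps.  ``focal_repeats`` (the focal species' repeat annotation)
    is hard-masked out of the query sequences.  Presence in another
    species means >= ``params.min_loci`` distinct qualifying hit loci
    there (see module docstring).
    """
    others = sorted(genomes.keys())
    for sp in others:
        if not genomes[sp]:
            raise ValueError(f"missing genome for species {sp!r}")
    if indexes is None:
        indexes = {}
    built = dict(indexes)
    for sp in others:
        if sp not in built:
            built[sp] = KmerIndex(dict(genomes[sp]), k=params.k, max_gap=params.max_gap)
    masked_by_seq: Dict[str, List[Tuple[int, int]]] = {}
    if focal_repeats:
        for r in focal_repeats:
            masked_by_seq.setdefault(r.seq_id, []).append((r.start, r.end))
        masked_by_seq = {s: merge_intervals(v) for s, v in masked_by_seq.items()}
    vectors: List[PresenceVector] = []
    for idx_rec, rec in enumerate(sd_map.records):
        p = rec.pair
        qa = _mask_query(
            focal_genome[p.seq_a][p.start_a:p.end_a], p.start_a,
            masked_by_seq.get(p.seq_a, ()),
        )
        qb = _mask_query(
            focal_genome[p.seq_b][p.start_b:p.end_b], p.start_b,
            masked_by_seq.get(p.seq_b, ()),
        )
        presence = {sd_map.species: True}
        for sp in others:
            loci = _qualifying_loci((qa, qb), built[sp], params)
            presence[sp] = len(loci) >= params.min_loci
        rec.shared_status = (
            "shared" if any(presence[sp] for sp in others) else "unique"
        )
        vectors.append(PresenceVector(idx_rec, sd_map.species, presence))
    return vectors


def default_pattern_table(newick: str) -> Dict[FrozenSet[str], str]:
    """Loss-pattern -> group-label table derived from the tree.

    Keyed by the *absent* species set: nothing absent is group A (potential
    ancestral events); both species of the deeper ingroup clade absent is
    B; single losses within that clade are C; single losses within the
    shallower (sister) clade are D; the full sister clade absent is E.
    With the default five-species tree this reproduces the classical
    layout: B = lost in the moth pair, E = lost in the butterfly pair.
    """
    tree = parse_tree(newick)
    leaves = tree_leaves(tree)
    clades = [c for c in tree_clades(tree) if len(c) == 2]
    table: Dict[FrozenSet[str], str] = {frozenset(): "A"}
    # order clades deterministically by leaf order of their first member
    order = {sp: i for i, sp in enumerate(leaves)}
    clades.sort(key=lambda c: min(order[s] for s in c), reverse=True)
    labels_pair = ["B", "E"]
    labels_single = ["C", "D"]
    for i, clade in enumerate(clades[:2]):
        table[frozenset(clade)] = labels_pair[i]
        for sp in sorted(clade, key=order.get):
            table[frozenset({sp})] = labels_single[i]
    return table


def assign_groups(
    vectors: Sequence[PresenceVector],
    newick: str,
    pattern_table: Optional[Mapping[FrozenSet[str], str]] = None,
) -> List[str]:
    """Label each presence vector with its phylogenetic group.

    Single-species patterns are "unique"; multi-species patterns not in the
    table are "other".  A table covering the same pattern twice is a
    configuration error.
    """
    if pattern_table is None:
        pattern_table = default_pattern_table(newick)
    keys = list(pattern_table.keys())
    if len(set(keys)) != len(keys):
        raise ValueError("pattern table covers the same pattern twice")
    species = set(tree_leaves(parse_tree(newick)))
    labels = []
    for v in vectors:
        present = v.present_set
        if len(present) <= 1:
            label = "unique"
        else:
            absent = frozenset(species - present)
            label = pattern_table.get(absent, "other")
        v.group = label
        labels.append(label)
    return labels


@dataclass
class ContrastResult:
    statistic: float
    p_value: float
    mean_shared: float
    mean_unique: float
    n_shared: int
    n_unique: int
    direction: str


def contrast_identity(
    shared: Sequence[SDRecord], unique: Sequence[SDRecord], welch: bool = True
) -> ContrastResult:
    """Two-sample t-test on identity of shared vs unique SDs (Welch default)."""
    x = np.array([r.identity for r in shared], dtype=float)
    y = np.array([r.identity for r in unique], dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least two records per group")
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0 and x.mean() == y.mean():
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_ind(x, y, equal_var=not welch)
    direction = "shared_higher" if x.mean() > y.mean() else (
        "unique_higher" if y.mean() > x.mean() else "equal"
    )
    return ContrastResult(float(t), float(p), float(x.mean()), float(y.mean()),
                          len(x), len(y), direction)


def contrast_variance(
    shared: Sequence[SDRecord], unique: Sequence[SDRecord]
) -> ContrastResult:
    """Two-sided variance-ratio (F) test on identity of shared vs unique SDs."""
    x = np.array([r.identity for r in shared], dtype=float)
    y = np.array([r.identity for r in unique], dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least two records per group")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        f, p = 1.0, 1.0
    else:
        if vy == 0:
            f, p = float("inf"), 0.0
        else:
            f = vx / vy
            cdf = stats.f.cdf(f, len(x) - 1, len(y) - 1)
            p = float(2 * min(cdf, 1 - cdf))
            p = min(1.0, p)
    direction = "shared_more_variable" if vx > vy else (
        "unique_more_variable" if vy > vx else "equal"
    )
    return ContrastResult(float(f), float(p), float(vx), float(vy),
                          len(x), len(y), direction)
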