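"""Synthetic multi-species genomes with planted duplication truth.

The generator emulates the statistical structure the downstream analyses
assume: five genomes related by a known phylogeny, planted duplication
pairs of controlled length (>= 1 kb) and divergence (substitutions at a
configurable per-base rate, optional small indels), interspersed
transposable elements of four classes with a density bias near
duplications, gene intervals (a fraction forced inside duplications), and
per-gene expression with a multiplicative suppression of duplicated genes.

Homologous positions across species are realised by simulating one
ancestral sequence and applying substitutions along each tree branch
(default 0.5% per branch), which keeps cross-species searches well above
the 75% identity floor.  Duplication copies are planted per species after
branching, so lineage-specific events exist in exactly their clade.

Everything is driven by one ``numpy`` Generator seeded from the config:
identical configs give byte-identical output files.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import dendropy
import numpy as np
import pandas as pd

from . import io as sdio
from .intervals import Interval, merge_intervals, reciprocal_overlap, subtract
from .masking import RepeatAnnotation

DEFAULT_TREE = "(Pxyl,((Dple,Hmel),(Msex,Bmor)));"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

TE_CLASSES = ("DNA", "SINE", "LTR", "LINE")
_TE_LENGTHS = {"DNA": 600, "SINE": 300, "LTR": 900, "LINE": 1200}


class ConfigError(ValueError):
    pass


@dataclass
class SimulationConfig:
    newick: str = DEFAULT_TREE
    genome_length: int = 1_000_000
    n_ancestral: int = 20
    n_clade_shared: int = 40
    n_lineage_unique: int = 40
    dup_length_range: Tuple[int, int] = (1000, 5000)
    dup_divergence_range: Tuple[float, float] = (0.0, 0.15)
    branch_sub_rate: float = 0.005
    te_density: Dict[str, float] = field(
        default_factory=lambda: {"DNA": 0.02, "SINE": 0.01, "LTR": 0.01, "LINE": 0.02}
    )
    te_sd_bias: float = 3.0
    te_mutation_rate: float = 0.10
    n_genes: int = 300
    gene_length_range: Tuple[int, int] = (300, 1500)
    frac_genes_in_sds: float = 0.2
    expr_sd_effect: float = 0.5
    n_conditions: int = 6
    expr_log10_mean: float = 1.0
    expr_log10_sd: float = 0.5
    expr_noise_sd: float = 0.3
    indels: bool = False
    indel_rate: float = 0.002
    indel_mean: float = 2.0
    min_gap: int = 300
    flank_width: int = 2500
    seed: int = 0

    def validate(self) -> None:
        if self.genome_length <= 0:
            raise ConfigError("genome_length must be positive")
        lo, hi = self.dup_divergence_range
        if not (0.0 <= lo <= hi <= 0.25):
            raise ConfigError("dup_divergence_range must lie within [0, 0.25]")
        if self.dup_length_range[0] < 1 or self.dup_length_range[0] > self.dup_length_range[1]:
            raise ConfigError("invalid dup_length_range")
        if not 0 <= self.frac_genes_in_sds <= 1:
            raise ConfigError("frac_genes_in_sds must be in [0,1]")


@dataclass
class DupEvent:
    event_id: str
    category: str  # ancestral | clade_shared | lineage_unique
    species: Tuple[str, ...]
    source: Interval
    copy: Interval
    divergence: float
    realized_mismatches: Dict[str, int] = field(default_factory=dict)
    copy_intervals: Dict[str, Interval] = field(default_factory=dict)


@dataclass
class TruthSet:
    """Planted events emitted by the simulator, for recovery scoring."""

    species: List[str]
    genome_length: int
    events: List[DupEvent]
    tes: Dict[str, List[Tuple[int, int, str]]]
    genes: List[Tuple[str, int, int]]  # (gene_id, start, end), shared coords
    sd_genes: Dict[str, List[str]]

    def events_for(self, species: str) -> List[DupEvent]:
        if species not in self.species:
            raise ValueError(f"unknown species {species!r}")
        return [e for e in self.events if species in e.species]

    def te_bp_for(self, species: str) -> int:
        return sum(e - s for s, e, _ in self.tes[species])

    def to_json(self, path: str) -> None:
        obj = {
            "species": self.species,
            "genome_length": self.genome_length,
            "events": [
                {
                    "event_id": e.event_id,
                    "category": e.category,
                    "species": list(e.species),
                    "source": list(e.source),
                    "copy": list(e.copy),
                    "divergence": e.divergence,
                    "realized_mismatches": e.realized_mismatches,
                    "copy_intervals": {s: list(v) for s, v in e.copy_intervals.items()},
                }
                for e in self.events
            ],
            "tes": self.tes,
            "genes": self.genes,
            "sd_genes": self.sd_genes,
        }
        sdio.write_json(obj, path)

    @classmethod
    def from_json(cls, path: str) -> "TruthSet":
        with open(path) as fh:
            obj = json.load(fh)
        events = [
            DupEvent(
                d["event_id"], d["category"], tuple(d["species"]),
                tuple(d["source"]), tuple(d["copy"]), d["divergence"],
                d["realized_mismatches"],
                {s: tuple(v) for s, v in d["copy_intervals"].items()},
            )
            for d in obj["events"]
        ]
        return cls(
            obj["species"], obj["genome_length"], events,
            {s: [tuple(t) for t in v] for s, v in obj["tes"].items()},
            [tuple(g) for g in obj["genes"]],
            obj["sd_genes"],
        )


@dataclass
class Scenario:
    """In-memory result of :func:`simulate_scenario`."""

    config: SimulationConfig
    species: List[str]
    genomes: Dict[str, Dict[str, str]]
    repeats: Dict[str, List[RepeatAnnotation]]
    genes: List[Tuple[str, int, int]]
    expression: Dict[str, pd.DataFrame]
    methylation: Dict[str, pd.DataFrame]
    truth: TruthSet

    def write(self, outdir: str) -> Dict[str, Dict[str, str]]:
        """Write one file set per species; returns {species: {kind: path}}."""
        os.makedirs(outdir, exist_ok=True)
        paths: Dict[str, Dict[str, str]] = {}
        for sp in self.species:
            d: Dict[str, str] = {}
            d["fasta"] = os.path.join(outdir, f"{sp}.fa")
            sdio.write_fasta(self.genomes[sp], d["fasta"])
            d["repeats"] = os.path.join(outdir, f"{sp}.repeats.bed")
            sdio.write_repeat_bed(self.repeats[sp], d["repeats"])
            d["gff"] = os.path.join(outdir, f"{sp}.genes.gff3")
            sdio.write_gff_genes(
                [("chr1", s, e, g) for g, s, e in self.genes], d["gff"]
            )
            d["expression"] = os.path.join(outdir, f"{sp}.expression.tsv")
            sdio.write_tsv(self.expression[sp], d["expression"])
            d["methylation"] = os.path.join(outdir, f"{sp}.methylation.tsv")
            sdio.write_tsv(self.methylation[sp], d["methylation"])
            paths[sp] = d
        tpath = os.path.join(outdir, "truth.json")
        self.truth.to_json(tpath)
        paths["truth"] = {"json": tpath}
        with open(os.path.join(outdir, "tree.nwk"), "w") as fh:
            fh.write(self.config.newick + "\n")
        return paths


def parse_tree(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick")


def tree_leaves(tree: dendropy.Tree) -> List[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def tree_clades(tree: dendropy.Tree) -> List[FrozenSet[str]]:
    """Leaf sets of all internal nodes (including the root)."""
    out = []
    for node in tree.preorder_node_iter():
        if not node.is_leaf():
            out.append(frozenset(lf.taxon.label for lf in node.leaf_iter()))
    return out


def shared_species_sets(tree: dendropy.Tree) -> List[Tuple[str, ...]]:
    """Candidate species sets for clade-shared events.

    Proper clades of size >= 2, plus complements of clades (loss patterns)
    of size >= 2 — unions of tree clades, as planted truth requires.
    """
    leaves = tree_leaves(tree)
    all_set = frozenset(leaves)
    cands: List[FrozenSet[str]] = []
    for c in tree_clades(tree):
        if 2 <= len(c) < len(all_set) and c not in cands:
            cands.append(c)
        comp = all_set - c
        if 2 <= len(comp) < len(all_set) and comp not in cands:
            cands.append(comp)
    order = {sp: i for i, sp in enumerate(leaves)}
    return [
        tuple(sorted(c, key=order.get))
        for c in sorted(cands, key=lambda c: (len(c), sorted(c)))
    ]


def _rand_codes(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, size=n, dtype=np.uint8)


def mutate_codes(rng: np.random.Generator, codes: np.ndarray, rate: float) -> Tuple[np.ndarray, int]:
    """Substitute each base independently at ``rate``; returns (copy, count)."""
    out = codes.copy()
    if rate <= 0:
        return out, 0
    hit = np.nonzero(rng.random(len(codes)) < rate)[0]
    if len(hit):
        out[hit] = (out[hit] + rng.integers(1, 4, size=len(hit))) % 4
    return out, len(hit)


def _apply_indels(rng: np.random.Generator, codes: np.ndarray, rate: float,
                  mean_len: float) -> np.ndarray:
    """Small insertions/deletions at ``rate`` per base, geometric lengths."""
    if rate <= 0:
        return codes
    n_events = rng.binomial(len(codes), rate)
    if n_events == 0:
        return codes
    sites = np.sort(rng.choice(len(codes), size=n_events, replace=False))
    p = 1.0 / mean_len
    pieces = []
    prev = 0
    for s in sites:
        ln = int(rng.geometric(p))
        pieces.append(codes[prev:s])
        if rng.random() < 0.5:  # insertion
            pieces.append(_rand_codes(rng, ln))
            prev = s
        else:  # deletion
            prev = min(len(codes), s + ln)
    pieces.append(codes[prev:])
    return np.concatenate(pieces)


def _codes_to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def _place_in_regions(rng: np.random.Generator, regions: List[Interval], length: int,
                      occupied: List[Interval], attempts: int = 40) -> Optional[Interval]:
    """Uniformly place an interval of ``length`` fully inside ``regions``,
    avoiding ``occupied`` (sorted merged list, updated in place)."""
    fitting = [(s, e) for s, e in regions if e - s >= length]
    if not fitting:
        return None
    weights = np.array([e - s - length + 1 for s, e in fitting], dtype=float)
    weights /= weights.sum()
    for _ in range(attempts):
        ridx = rng.choice(len(fitting), p=weights)
        s0, e0 = fitting[ridx]
        start = int(rng.integers(s0, e0 - length + 1))
        iv = (start, start + length)
        lo = np.searchsorted([o[1] for o in occupied], iv[0], side="right")
        if lo < len(occupied) and occupied[lo][0] < iv[1]:
            continue
        occupied.insert(lo, iv)
        return iv
    return None


def simulate_scenario(config: SimulationConfig) -> Scenario:
    """Generate the full multi-species scenario with planted truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    tree = parse_tree(config.newick)
    species = tree_leaves(tree)
    G = config.genome_length

    # --- event layout (ancestral coordinates) -------------------------------
    n_events = config.n_ancestral + config.n_clade_shared + config.n_lineage_unique
    lengths = rng.integers(
        config.dup_length_range[0], config.dup_length_range[1] + 1, size=n_events
    )
    divs = rng.uniform(*config.dup_divergence_range, size=n_events)
    slack = 64 if config.indels else 0
    slot_lens: List[int] = []
    for ln in lengths:
        slot_lens.extend([int(ln), int(ln) + slack])  # source, copy
    need = sum(slot_lens) + config.min_gap * (len(slot_lens) + 1)
    if need > G:
        raise ConfigError(
            f"requested duplication bp ({need}) exceeds genome_length ({G})"
        )
    order = rng.permutation(len(slot_lens))
    extra = G - need
    gap_extra = rng.multinomial(extra, np.full(len(slot_lens) + 1, 1.0 / (len(slot_lens) + 1)))
    slot_pos: Dict[int, Interval] = {}
    cursor = 0
    for gi, si in enumerate(order):
        cursor += config.min_gap + int(gap_extra[gi])
        slot_pos[si] = (cursor, cursor + slot_lens[si])
        cursor += slot_lens[si]

    cands = shared_species_sets(tree)
    events: List[DupEvent] = []
    for i in range(n_events):
        if i < config.n_ancestral:
            cat, spset = "ancestral", tuple(species)
        elif i < config.n_ancestral + config.n_clade_shared:
            j = i - config.n_ancestral
            cat, spset = "clade_shared", cands[j % len(cands)] if cands else tuple(species)
        else:
            j = i - config.n_ancestral - config.n_clade_shared
            cat, spset = "lineage_unique", (species[j % len(species)],)
        src = slot_pos[2 * i]
        cp_slot = slot_pos[2 * i + 1]
        events.append(
            DupEvent(f"dup{i:04d}", cat, spset, src, cp_slot, float(divs[i]))
        )

    # --- ancestral sequence and TEs -----------------------------------------
    ancestor = _rand_codes(rng, G)
    motifs = {cls: _rand_codes(rng, _TE_LENGTHS[cls]) for cls in TE_CLASSES}

    source_regions = [e.source for e in events]
    copy_slots = [e.copy for e in events]
    all_slots = merge_intervals(source_regions + copy_slots)
    gaps = subtract([(0, G)], all_slots)
    flank_raw = []
    for s, e in all_slots:
        flank_raw.append((max(0, s - config.flank_width), s))
        flank_raw.append((e, min(G, e + config.flank_width)))
    flanks = subtract(merge_intervals(flank_raw), all_slots)
    background = subtract(gaps, flanks)

    occupied: List[Interval] = []
    anc_tes: List[Tuple[int, int, str]] = []

    def _fill(regions: List[Interval], density_scale: float) -> None:
        region_bp = sum(e - s for s, e in regions)
        for cls in TE_CLASSES:
            te_len = _TE_LENGTHS[cls]
            n_te = int(round(config.te_density.get(cls, 0.0) * density_scale * region_bp / te_len))
            for _ in range(n_te):
                iv = _place_in_regions(rng, regions, te_len, occupied)
                if iv is None:
                    continue
                inst, _ = mutate_codes(rng, motifs[cls], config.te_mutation_rate)
                ancestor[iv[0]:iv[1]] = inst
                anc_tes.append((iv[0], iv[1], cls))

    _fill(background, 1.0)
    _fill(flanks, config.te_sd_bias)
    _fill([e.source for e in events], 1.0)  # TEs interior to duplications
    anc_tes.sort()

    # --- species sequences along the tree -----------------------------------
    seqs: Dict[str, np.ndarray] = {}

    def _descend(node, parent_codes):
        for child in node.child_nodes():
            br = child.edge.length if child.edge.length is not None else 1.0
            child_codes, _ = mutate_codes(rng, parent_codes, config.branch_sub_rate * br)
            if child.is_leaf():
                seqs[child.taxon.label] = child_codes
            else:
                _descend(child, child_codes)

    root = tree.seed_node
    if root.is_leaf():  # degenerate single-leaf tree
        seqs[root.taxon.label] = ancestor.copy()
    _descend(root, ancestor)

    # --- plant duplications per species -------------------------------------
    tes: Dict[str, List[Tuple[int, int, str]]] = {sp: list(anc_tes) for sp in species}
    for ev in events:
        s0, s1 = ev.source
        c0, c1 = ev.copy
        src_tes = [(ts, te, cls) for ts, te, cls in anc_tes if ts >= s0 and te <= s1]
        for sp in ev.species:
            src = seqs[sp][s0:s1]
            cp, n_mm = mutate_codes(rng, src, ev.divergence)
            if config.indels:
                cp = _apply_indels(rng, cp, config.indel_rate, config.indel_mean)
                cp = cp[: c1 - c0]
            seqs[sp][c0 : c0 + len(cp)] = cp
            ev.realized_mismatches[sp] = n_mm
            ev.copy_intervals[sp] = (c0, c0 + len(cp))
            for ts, te, cls in src_tes:
                off = ts - s0
                if off + (te - ts) <= len(cp):
                    tes[sp].append((c0 + off, c0 + off + (te - ts), cls))
    for sp in species:
        tes[sp].sort()

    # --- genes ----------------------------------------------------------------
    n_sd_genes = int(round(config.frac_genes_in_sds * config.n_genes))
    gene_ivs: List[Interval] = []
    gene_occ: List[Interval] = []
    slot_cycle = [iv for ev in events for iv in (ev.source, ev.copy)]
    gi = 0
    while len(gene_ivs) < n_sd_genes and slot_cycle:
        slot = slot_cycle[gi % len(slot_cycle)]
        gi += 1
        glen = int(rng.integers(*config.gene_length_range))
        glen = min(glen, slot[1] - slot[0])
        iv = _place_in_regions(rng, [slot], glen, gene_occ, attempts=20)
        if iv is not None:
            gene_ivs.append(iv)
        if gi > 20 * max(1, n_sd_genes):
            break
    fails = 0
    while len(gene_ivs) < config.n_genes and fails < 50:
        glen = int(rng.integers(*config.gene_length_range))
        iv = _place_in_regions(rng, gaps, glen, gene_occ, attempts=12)
        if iv is None:
            fails += 1  # genome crowded; emit what fits
            continue
        fails = 0
        gene_ivs.append(iv)
    gene_ivs.sort()
    genes = [(f"g{i:05d}", s, e) for i, (s, e) in enumerate(gene_ivs)]

    sd_genes: Dict[str, List[str]] = {}
    for sp in species:
        slots = merge_intervals(
            [ev.source for ev in events if sp in ev.species]
            + [ev.copy_intervals.get(sp, ev.copy) for ev in events if sp in ev.species]
        )
        inside = []
        for g, s, e in genes:
            for ss, se in slots:
                if s < se and e > ss:
                    inside.append(g)
                    break
        sd_genes[sp] = inside

    # --- expression and methylation ------------------------------------------
    base_mu = rng.normal(config.expr_log10_mean, config.expr_log10_sd, size=len(genes))
    conditions = [f"cond{i + 1}" for i in range(config.n_conditions)]
    shift = math.log10(config.expr_sd_effect) if config.expr_sd_effect > 0 else -4.0
    expression: Dict[str, pd.DataFrame] = {}
    methylation: Dict[str, pd.DataFrame] = {}
    for sp in species:
        in_sd = np.array([g in set(sd_genes[sp]) for g, _, _ in genes], dtype=bool)
        rows = []
        for ci, cond in enumerate(conditions):
            noise = rng.normal(0.0, config.expr_noise_sd, size=len(genes))
            logv = base_mu + shift * in_sd + noise
            for (g, _, _), lv in zip(genes, logv):
                rows.append((g, cond, round(10.0 ** lv, 4)))
        expression[sp] = pd.DataFrame(rows, columns=["gene_id", "condition", "rpkm"])
        meth = np.round(rng.beta(2.0, 18.0, size=len(genes)), 5)
        meth[in_sd] = 0.0
        methylation[sp] = pd.DataFrame(
            {"gene_id": [g for g, _, _ in genes], "level": meth}
        )

    genomes = {sp: {"chr1": _codes_to_str(seqs[sp])} for sp in species}
    repeats = {
        sp: [RepeatAnnotation("chr1", s, e, cls) for s, e, cls in tes[sp]]
        for sp in species
    }
    truth = TruthSet(species, G, events, tes, genes, sd_genes)
    return Scenario(config, species, genomes, repeats, genes, expression, methylation, truth)


@dataclass
class RecoveryResult:
    n_planted: int
    n_calls: int
    n_recovered: int
    n_matching_calls: int
    boundary_errors: List[int]

    @property
    def sensitivity(self) -> Optional[float]:
        return self.n_recovered / self.n_planted if self.n_planted else None

    @property
    def precision(self) -> Optional[float]:
        return self.n_matching_calls / self.n_calls if self.n_calls else None

    @property
    def max_boundary_error(self) -> Optional[int]:
        return max(self.boundary_errors) if self.boundary_errors else None

    @property
    def mean_boundary_error(self) -> Optional[float]:
        return float(np.mean(self.boundary_errors)) if self.boundary_errors else None


def score_recovery(truth: TruthSet, called, min_reciprocal: float = 0.8) -> RecoveryResult:
    """Score called SDs against planted events.

    An event is recovered when some call reciprocally overlaps both its
    source and copy intervals by at least ``min_reciprocal`` (either side
    assignment); a call matches when it recovers any event.  The called
    :class:`~segdup.sdmap.SDMap` must be for a species present in the truth.
    """
    sp = called.species
    if sp not in truth.species:
        raise ValueError(f"called map species {sp!r} not in truth {truth.species}")
    events = truth.events_for(sp)
    recovered = set()
    matching_calls = 0
    boundary: List[int] = []
    for rec in called.records:
        p = rec.pair
        a = (p.start_a, p.end_a)
        b = (p.start_b, p.end_b)
        hit = False
        for ev in events:
            src = ev.source
            cp = ev.copy_intervals.get(sp, ev.copy)
            for x, y in ((a, b), (b, a)):
                if (
                    reciprocal_overlap(x, src) >= min_reciprocal
                    and reciprocal_overlap(y, cp) >= min_reciprocal
                ):
                    hit = True
                    if ev.event_id not in recovered:
                        recovered.add(ev.event_id)
                        boundary.append(
                            max(
                                abs(x[0] - src[0]), abs(x[1] - src[1]),
                                abs(y[0] - cp[0]), abs(y[1] - cp[1]),
                            )
                        )
                    break
            if hit:
                break
        if hit:
            matching_calls += 1
    return RecoveryResult(
        n_planted=len(events),
        n_calls=len(called.records),
        n_recovered=len(recovered),
        n_matching_calls=matching_calls,
        boundary_errors=boundary,
    )
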