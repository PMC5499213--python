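"""End-to-end driver: masking -> self-alignment -> SD calling -> analyses.

Chains every stage over one or more species and writes all module outputs
under one output directory.  Fully deterministic under a fixed config:
one base seed feeds per-stage substreams, no timestamps enter report
files, and every table carries the tool version and a config hash in a
comment header.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from . import io as sdio
from .align import KmerIndex, discard_self, refine, reinsert, self_align
from .annotation import classify_genes, enrichment_table, genes_in_sds, go_enrichment
from .comparative import (
    HitParams,
    assign_groups,
    classify_shared,
    contrast_identity,
    contrast_variance,
)
from .expression import contrast_expression, contrast_methylation
from .masking import fuguize, load_repeats, select_repeats
from .sdmap import SDMap, build_union, filter_sds, length_histogram, percent_high_identity
from .te import te_content_table

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """All inputs and parameters of one pipeline run."""

    species: List[str]
    genome_paths: Dict[str, str]
    repeat_paths: Dict[str, List[str]] = field(default_factory=dict)
    gff_paths: Dict[str, str] = field(default_factory=dict)
    go_paths: Dict[str, str] = field(default_factory=dict)
    expression_paths: Dict[str, str] = field(default_factory=dict)
    methylation_paths: Dict[str, str] = field(default_factory=dict)
    newick: Optional[str] = None
    outdir: str = "results/pipeline"
    # masking
    max_divergence_pct: float = 15.0
    # self-alignment
    k: int = 14
    max_gap: int = 1000
    min_score: int = 250
    refine_band: int = 32
    # SD filter
    min_len: int = 1000
    min_identity: float = 75.0
    # comparative / TE / expression
    flank_width: int = 2500
    n_samples: int = 1000
    pseudocount: float = 0.01
    alpha: float = 0.05
    seed: int = 0
    run_comparative: bool = True

    def validate(self) -> None:
        for sp in self.species:
            if sp not in self.genome_paths:
                raise ValueError(f"no genome path for species {sp!r}")
        for mapping in (
            self.genome_paths, self.gff_paths, self.go_paths,
            self.expression_paths, self.methylation_paths,
        ):
            for sp, p in mapping.items():
                if not os.path.exists(p):
                    raise FileNotFoundError(f"{sp}: missing input file {p}")
        for sp, paths in self.repeat_paths.items():
            for p in paths:
                if not os.path.exists(p):
                    raise FileNotFoundError(f"{sp}: missing repeat file {p}")

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        d.pop("outdir", None)  # hash covers inputs and parameters only
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _header(config: RunConfig) -> str:
    return f"segdup v{__version__} config={config.config_hash()}"


def call_sds(config: RunConfig, species: str, genome: Mapping[str, str]) -> SDMap:
    """Masking through SD calling for one species."""
    repeats = []
    for path in config.repeat_paths.get(species, []):
        repeats.extend(load_repeats(path))
    selected = select_repeats(repeats, config.max_divergence_pct)
    fugu, cmap = fuguize(dict(genome), selected)
    pairs = self_align(
        fugu, k=config.k, max_gap=config.max_gap, min_score=config.min_score
    )
    pairs = discard_self(pairs)
    pairs = reinsert(pairs, cmap)
    pairs = refine(pairs, dict(genome), band=config.refine_band)
    records = filter_sds(pairs, min_len=config.min_len, min_identity=config.min_identity)
    lengths = {seq: len(s) for seq, s in genome.items()}
    return build_union(records, lengths, species=species)


def pairs_table(sd_map: SDMap) -> pd.DataFrame:
    rows = []
    for r in sd_map.records:
        p = r.pair
        rows.append(
            {
                "seq_a": p.seq_a, "start_a": p.start_a, "end_a": p.end_a,
                "seq_b": p.seq_b, "start_b": p.start_b, "end_b": p.end_b,
                "strand": p.strand, "identity": round(p.identity, 3),
                "aligned_columns": p.aligned_columns, "matches": p.matches,
                "gap_columns": p.gap_columns, "score": p.score,
                "identity_bin": r.identity_bin, "shared_status": r.shared_status,
            }
        )
    return pd.DataFrame(rows)


def census_row(sd_map: SDMap) -> Dict[str, object]:
    counts = sd_map.bin_counts
    return {
        "species": sd_map.species,
        "total_sds": sd_map.n_records,
        "n_ge90": counts[">=90"],
        "n_80_90": counts["80-90"],
        "n_75_80": counts["75-80"],
        "pct_ge90": percent_high_identity(sd_map),
        "union_bp": sd_map.union_bp,
        "summed_pair_bp": sd_map.summed_pair_bp,
        "pct_genome": round(100 * sd_map.fraction_of_genome, 3),
    }


def run_pipeline(config: RunConfig) -> Dict[str, object]:
    """Execute the full analysis; returns the in-memory result bundle.

    Writes per-species SD pair tables, union BED, census summary, length
    histograms, presence/group tables, GO enrichment, TE content tables
    and expression/methylation contrasts under ``config.outdir``.
    """
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    hdr = _header(config)
    with open(os.path.join(config.outdir, "run_config.json"), "w") as fh:
        json.dump(dataclasses.asdict(config), fh, indent=1, sort_keys=True)
        fh.write("\n")
    results: Dict[str, object] = {"maps": {}, "census": None}
    genomes: Dict[str, Dict[str, str]] = {}
    t_stage = time.time()
    for sp in config.species:
        try:
            genomes[sp] = sdio.read_fasta(config.genome_paths[sp])
            results["maps"][sp] = call_sds(config, sp, genomes[sp])
        except Exception as exc:  # noqa: BLE001 - abort names the stage
            raise StageError(f"callsd:{sp}", exc) from exc
        log.info("stage callsd:%s done in %.1fs", sp, time.time() - t_stage)
        t_stage = time.time()

    # comparative
    if config.run_comparative and len(config.species) > 1:
        try:
            indexes = {
                sp: KmerIndex(genomes[sp], k=config.k, max_gap=config.max_gap)
                for sp in config.species
            }
            hp = HitParams(
                min_identity=config.min_identity, min_len=config.min_len,
                k=config.k, max_gap=config.max_gap,
            )
            newick = config.newick or "(" + ",".join(config.species) + ");"
            results["presence"] = {}
            results["contrasts"] = {}
            for sp in config.species:
                others = {o: genomes[o] for o in config.species if o != sp}
                focal_repeats = []
                for path in config.repeat_paths.get(sp, []):
                    focal_repeats.extend(load_repeats(path))
                vectors = classify_shared(
                    results["maps"][sp], others, genomes[sp], hp,
                    indexes={o: indexes[o] for o in others},
                    focal_repeats=focal_repeats,
                )
                assign_groups(vectors, newick)
                results["presence"][sp] = vectors
                shared = [r for r in results["maps"][sp].records if r.shared_status == "shared"]
                unique = [r for r in results["maps"][sp].records if r.shared_status == "unique"]
                if len(shared) >= 2 and len(unique) >= 2:
                    results["contrasts"][sp] = {
                        "identity": contrast_identity(shared, unique),
                        "variance": contrast_variance(shared, unique),
                    }
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise StageError("compare", exc) from exc
        log.info("stage compare done in %.1fs", time.time() - t_stage)
        t_stage = time.time()

    # annotation, TE, expression per species
    results["genes"] = {}
    results["go"] = {}
    results["te"] = {}
    results["expression"] = {}
    results["methylation"] = {}
    for si, sp in enumerate(config.species):
        sd_map: SDMap = results["maps"][sp]
        if sp in config.gff_paths:
            try:
                genes = sdio.read_gff_genes(config.gff_paths[sp])
                sd_gene_ids, frac = genes_in_sds(genes, sd_map.union)
                gene_status = classify_genes(genes, sd_map.records, sd_gene_ids)
                results["genes"][sp] = {
                    "sd_gene_ids": sd_gene_ids,
                    "frac_sd_intervals_with_gene": frac,
                    "status": gene_status,
                    "n_genes": len(genes),
                }
                if sp in config.go_paths:
                    go_map = sdio.read_go_map(config.go_paths[sp])
                    results["go"][sp] = go_enrichment(
                        sd_gene_ids, list(genes["gene_id"]), go_map, alpha=config.alpha
                    )
            except Exception as exc:  # noqa: BLE001
                raise StageError(f"annotate:{sp}", exc) from exc
        try:
            repeats = []
            for path in config.repeat_paths.get(sp, []):
                repeats.extend(load_repeats(path))
            rng = np.random.default_rng([config.seed % (2**31), 1000 + si])
            results["te"][sp] = te_content_table(
                sd_map.union, repeats, sd_map.genome_lengths,
                flank_width=config.flank_width, n_samples=config.n_samples, rng=rng,
            )
        except Exception as exc:  # noqa: BLE001
            raise StageError(f"te:{sp}", exc) from exc
        if sp in config.expression_paths:
            try:
                table = sdio.read_expression(config.expression_paths[sp])
                sd_gene_ids = results["genes"].get(sp, {}).get("sd_gene_ids", [])
                results["expression"][sp] = contrast_expression(
                    table, sd_gene_ids, pseudocount=config.pseudocount,
                    alpha=config.alpha,
                )
            except Exception as exc:  # noqa: BLE001
                raise StageError(f"express:{sp}", exc) from exc
        if sp in config.methylation_paths:
            try:
                meth = sdio.read_methylation(config.methylation_paths[sp])
                sd_gene_ids = results["genes"].get(sp, {}).get("sd_gene_ids", [])
                results["methylation"][sp] = contrast_methylation(meth, sd_gene_ids)
            except Exception as exc:  # noqa: BLE001
                raise StageError(f"methylation:{sp}", exc) from exc

    _write_outputs(config, results, hdr)
    return results


def _write_outputs(config: RunConfig, results: Dict[str, object], hdr: str) -> None:
    out = config.outdir
    census_rows = []
    for sp in config.species:
        sd_map: SDMap = results["maps"][sp]
        sdio.write_tsv(pairs_table(sd_map), os.path.join(out, f"{sp}.sd_pairs.tsv"), hdr)
        with open(os.path.join(out, f"{sp}.sd_union.bed"), "w") as fh:
            fh.write(f"# {hdr}\n")
            for seq in sorted(sd_map.union):
                for s, e in sd_map.union[seq]:
                    fh.write(f"{seq}\t{s}\t{e}\n")
        hist = length_histogram(sd_map.records)
        sdio.write_tsv(
            pd.DataFrame(hist, columns=["len_lo", "len_hi", "count"]),
            os.path.join(out, f"{sp}.length_hist.tsv"), hdr,
        )
        row = census_row(sd_map)
        if sp in results["genes"]:
            row["n_sd_genes"] = len(results["genes"][sp]["sd_gene_ids"])
            row["pct_genes"] = round(
                100 * row["n_sd_genes"] / max(1, results["genes"][sp]["n_genes"]), 3
            )
            row["frac_sd_intervals_with_gene"] = round(
                results["genes"][sp]["frac_sd_intervals_with_gene"], 4
            )
        census_rows.append(row)
        if "presence" in results and sp in results["presence"]:
            pres_rows = []
            for v in results["presence"][sp]:
                r = {"record": v.record_index, "group": v.group}
                r.update({s: "+" if p else "-" for s, p in sorted(v.presence.items())})
                pres_rows.append(r)
            sdio.write_tsv(
                pd.DataFrame(pres_rows), os.path.join(out, f"{sp}.presence.tsv"), hdr
            )
        if sp in results["go"]:
            sdio.write_tsv(
                enrichment_table(results["go"][sp]),
                os.path.join(out, f"{sp}.go_enrichment.tsv"), hdr,
            )
        if sp in results["te"]:
            sdio.write_tsv(
                results["te"][sp], os.path.join(out, f"{sp}.te_content.tsv"), hdr
            )
        if sp in results.get("expression", {}):
            df = pd.DataFrame([dataclasses.asdict(c) for c in results["expression"][sp]])
            sdio.write_tsv(df, os.path.join(out, f"{sp}.expression_contrast.tsv"), hdr)
        if sp in results.get("methylation", {}):
            m = results["methylation"][sp]
            sdio.write_tsv(
                pd.DataFrame([dataclasses.asdict(m)]),
                os.path.join(out, f"{sp}.methylation_contrast.tsv"), hdr,
            )
        if sp in results.get("contrasts", {}):
            rows = []
            for kind, c in results["contrasts"][sp].items():
                d = dataclasses.asdict(c)
                d["contrast"] = kind
                rows.append(d)
            sdio.write_tsv(
                pd.DataFrame(rows), os.path.join(out, f"{sp}.shared_unique_contrasts.tsv"),
                hdr,
            )
    census = pd.DataFrame(census_rows)
    sdio.write_tsv(census, os.path.join(out, "census.tsv"), hdr)
    results["census"] = census


def load_sd_map(tsv_path: str, genome_lengths: Dict[str, int], species: str) -> SDMap:
    """Rebuild an :class:`SDMap` from a written ``*.sd_pairs.tsv`` table."""
    from .align import AlignmentPair
    from .sdmap import SDRecord, identity_bin

    df = pd.read_csv(tsv_path, sep="\t", comment="#")
    records = []
    for row in df.itertuples(index=False):
        mismatches = row.aligned_columns - row.matches - row.gap_columns
        pair = AlignmentPair(
            row.seq_a, int(row.start_a), int(row.end_a),
            row.seq_b, int(row.start_b), int(row.end_b),
            row.strand, int(row.matches), int(mismatches), int(row.gap_columns),
            int(row.score),
        )
        records.append(SDRecord(pair, identity_bin(pair.identity), row.shared_status))
    return build_union(records, genome_lengths, species=species)


def published_census() -> pd.DataFrame:
    """The published five-species SD census shipped with the package."""
    path = os.path.join(os.path.dirname(__file__), "data", "lepidoptera_sd_census.tsv")
    return pd.read_csv(path, sep="\t", comment="#")
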