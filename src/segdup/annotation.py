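"""Gene content of SD regions and GO-term enrichment.

Genes are assigned to the SD set when their body overlaps the SD union
(>= 1 bp by default).  Enrichment of GO (slim) terms among SD genes versus
the whole annotated gene background uses a one-sided Fisher's exact test
(over-representation); no multiple-testing correction by default, with
Benjamini-Hochberg available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import Interval
from .sdmap import SDRecord


def genes_in_sds(
    genes: pd.DataFrame,
    sd_union: Mapping[str, Sequence[Interval]],
    min_overlap_bp: int = 1,
) -> Tuple[List[str], float]:
    """Gene ids overlapping the SD union, and the fraction of SD intervals
    containing at least one gene.

    ``genes`` is the frame from :func:`segdup.io.read_gff_genes`
    (0-based half-open).  Overlap rule: at least ``min_overlap_bp`` of the
    gene body inside the union.
    """
    if genes["gene_id"].duplicated().any():
        raise ValueError("duplicate gene ids in annotation")
    hit_ids: List[str] = []
    union_flat: List[Tuple[str, int, int]] = [
        (seq, s, e) for seq, ivs in sd_union.items() for s, e in ivs
    ]
    for row in genes.itertuples(index=False):
        ov = 0
        for seq, s, e in union_flat:
            if seq == row.seqid and row.start < e and row.end > s:
                ov += min(row.end, e) - max(row.start, s)
        if ov >= min_overlap_bp:
            hit_ids.append(row.gene_id)
    n_with_gene = 0
    for seq, s, e in union_flat:
        sub = genes[genes["seqid"] == seq]
        if ((sub["start"] < e) & (sub["end"] > s)).any():
            n_with_gene += 1
    frac = n_with_gene / len(union_flat) if union_flat else 0.0
    return hit_ids, frac


def classify_genes(
    genes: pd.DataFrame,
    records: Sequence[SDRecord],
    sd_gene_ids: Iterable[str],
) -> Dict[str, str]:
    """Label SD genes "shared" or "unique" by the SDs they overlap.

    A gene touching any shared SD is "shared" (shared takes precedence
    over unique when a gene overlaps both).
    """
    shared_ivs: List[Tuple[str, int, int]] = []
    unique_ivs: List[Tuple[str, int, int]] = []
    for r in records:
        target = shared_ivs if r.shared_status == "shared" else unique_ivs
        target.append(r.pair.interval_a())
        target.append(r.pair.interval_b())
    sd_ids = set(sd_gene_ids)
    out: Dict[str, str] = {}
    for row in genes.itertuples(index=False):
        if row.gene_id not in sd_ids:
            continue
        in_shared = any(
            seq == row.seqid and row.start < e and row.end > s
            for seq, s, e in shared_ivs
        )
        out[row.gene_id] = "shared" if in_shared else "unique"
    return out


@dataclass
class EnrichmentResult:
    term: str
    observed: int
    expected: float
    odds_ratio: float
    p_value: float
    significant: bool
    n_set: int
    n_background: int
    term_total: int


def go_enrichment(
    sd_genes: Iterable[str],
    background_genes: Iterable[str],
    go_map: Mapping[str, Sequence[str]],
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> List[EnrichmentResult]:
    """Per-term over-representation of GO terms among SD genes.

    For each term a 2x2 table (in-set/out-of-set x has-term/lacks-term) is
    tested with a one-sided (greater) Fisher's exact test.  Expected count
    is ``|set| * term_genes / |background|``.  Terms with no genes in the
    background are skipped.  ``bh_correct`` switches the significance flag
    (not the reported p) to Benjamini-Hochberg adjusted values.
    """
    bg = list(dict.fromkeys(background_genes))
    sd = set(sd_genes)
    missing = sd - set(bg)
    if missing:
        raise ValueError(f"SD genes not in background: {sorted(missing)[:5]}")
    n_bg = len(bg)
    n_set = len(sd)
    terms: Dict[str, Set[str]] = {}
    for g in bg:
        for t in go_map.get(g, ()):
            terms.setdefault(t, set()).add(g)
    results: List[EnrichmentResult] = []
    for term in sorted(terms):
        genes_with = terms[term]
        k = len(genes_with & sd)
        K = len(genes_with)
        table = [[k, n_set - k], [K - k, n_bg - n_set - (K - k)]]
        odds, p = stats.fisher_exact(table, alternative="greater")
        results.append(
            EnrichmentResult(
                term=term,
                observed=k,
                expected=n_set * K / n_bg,
                odds_ratio=float(odds),
                p_value=float(p),
                significant=False,
                n_set=n_set,
                n_background=n_bg,
                term_total=K,
            )
        )
    if bh_correct and results:
        ps = np.array([r.p_value for r in results])
        order = np.argsort(ps)
        n = len(ps)
        adj = np.empty(n)
        running = 1.0
        for rank_pos in range(n - 1, -1, -1):
            i = order[rank_pos]
            running = min(running, ps[i] * n / (rank_pos + 1))
            adj[i] = running
        for r, a in zip(results, adj):
            r.significant = a < alpha
    else:
        for r in results:
            r.significant = r.p_value < alpha
    return results


def enrichment_table(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Results as a frame mirroring a term / p-value / protein-count table."""
    return pd.DataFrame(
        {
            "term": [r.term for r in results],
            "p_value": [r.p_value for r in results],
            "n_proteins": [r.observed for r in results],
            "expected": [r.expected for r in results],
            "odds_ratio": [r.odds_ratio for r in results],
            "significant": [r.significant for r in results],
        }
    )
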