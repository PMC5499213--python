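#!/usr/bin/env python
"""Gene content of SDs and GO-term over-representation.

Intersects the gene models with each species' SD union, labels SD genes
shared/unique, builds a deterministic synthetic gene-to-GO map in which
one term is strongly over-represented among duplicated genes, and runs
the Fisher's-exact enrichment against the whole-genome background.
"""

import argparse
import os

import numpy as np
import pandas as pd

from segdup.annotation import classify_genes, enrichment_table, genes_in_sds, go_enrichment
from segdup.io import read_fasta, read_gff_genes
from segdup.pipeline import load_sd_map


def synthetic_go_map(genes, sd_gene_ids, rng, n_terms=20, enriched_term="GO:HI0001"):
    """Gene->terms map with ``enriched_term`` planted at ~10x frequency
    among SD genes (synthetic stand-in for a curated annotation)."""
    sd = set(sd_gene_ids)
    go_map = {}
    terms = [f"GO:{i:07d}" for i in range(n_terms)]
    for g in genes["gene_id"]:
        mine = [t for t in terms if rng.random() < 0.08]
        base = 0.5 if g in sd else 0.05
        if rng.random() < base:
            mine.append(enriched_term)
        go_map[g] = mine
    return go_map


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--simdir", default="results/sim")
    ap.add_argument("--sddir", default="results/comparative")
    ap.add_argument("--outdir", default="results/gene_content")
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    os.makedirs(args.outdir, exist_ok=True)

    species = sorted(fn[:-3] for fn in os.listdir(args.simdir) if fn.endswith(".fa"))
    for si, sp in enumerate(species):
        genome = read_fasta(os.path.join(args.simdir, f"{sp}.fa"))
        lengths = {seq: len(s) for seq, s in genome.items()}
        sd_map = load_sd_map(
            os.path.join(args.sddir, f"{sp}.sd_pairs.classified.tsv"), lengths, sp
        )
        genes = read_gff_genes(os.path.join(args.simdir, f"{sp}.genes.gff3"))
        sd_gene_ids, frac = genes_in_sds(genes, sd_map.union)
        status = classify_genes(genes, sd_map.records, sd_gene_ids)
        n_shared = sum(1 for v in status.values() if v == "shared")
        print(f"{sp}: {len(sd_gene_ids)}/{len(genes)} genes in SDs "
              f"({100 * len(sd_gene_ids) / len(genes):.1f}%); "
              f"{100 * frac:.0f}% of SD intervals contain a gene; "
              f"{n_shared} shared / {len(status) - n_shared} unique SD genes")
        rng = np.random.default_rng([args.seed, si])
        go_map = synthetic_go_map(genes, sd_gene_ids, rng)
        results = go_enrichment(sd_gene_ids, list(genes["gene_id"]), go_map)
        tbl = enrichment_table(results).sort_values("p_value")
        tbl.to_csv(os.path.join(args.outdir, f"{sp}.go_enrichment.tsv"),
                   sep="\t", index=False)
        top = tbl.iloc[0]
        print(f"   top term {top['term']} p={top['p_value']:.3g} "
              f"({top['n_proteins']} proteins, expected {top['expected']:.1f})")
        pd.DataFrame(
            [{"gene_id": g, "status": s} for g, s in sorted(status.items())]
        ).to_csv(os.path.join(args.outdir, f"{sp}.sd_genes.tsv"), sep="\t", index=False)


if __name__ == "__main__":
    main()
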