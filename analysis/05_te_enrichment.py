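#!/usr/bin/env python
"""Transposable-element content of SDs, 2.5 kb flanks, and the genome.

Builds the census-style TE table per species (masked bp and fraction per
class and region, enrichment ratios against the genome average and the
non-duplicated remainder) and assesses significance with the
interval-placement permutation null.
"""

import argparse
import os

import numpy as np

from segdup.io import read_fasta
from segdup.masking import load_repeats
from segdup.pipeline import load_sd_map
from segdup.te import te_content_table


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--simdir", default="results/sim")
    ap.add_argument("--sddir", default="results/pipeline")
    ap.add_argument("--outdir", default="results/te")
    ap.add_argument("--n-samples", type=int, default=1000)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    os.makedirs(args.outdir, exist_ok=True)

    species = sorted(fn[:-3] for fn in os.listdir(args.simdir) if fn.endswith(".fa"))
    for si, sp in enumerate(species):
        genome = read_fasta(os.path.join(args.simdir, f"{sp}.fa"))
        lengths = {seq: len(s) for seq, s in genome.items()}
        sd_map = load_sd_map(os.path.join(args.sddir, f"{sp}.sd_pairs.tsv"), lengths, sp)
        repeats = load_repeats(os.path.join(args.simdir, f"{sp}.repeats.bed"))
        rng = np.random.default_rng([args.seed, si])
        tbl = te_content_table(
            sd_map.union, repeats, lengths, n_samples=args.n_samples, rng=rng
        )
        tbl.to_csv(os.path.join(args.outdir, f"{sp}.te_content.tsv"), sep="\t", index=False)
        print(f"{sp}:")
        for row in tbl.itertuples(index=False):
            enr = row.enrichment_sd_vs_genome
            print(f"   {row._0 if hasattr(row, '_0') else row[0]:>4}: SD {row.sd_pct:.2f}% "
                  f"flank {row.flank_pct:.2f}% genome {row.genome_pct:.2f}% "
                  f"enrichment {enr:.2f} (p={row.p_value:.3g})")


if __name__ == "__main__":
    main()
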