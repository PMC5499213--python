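#!/usr/bin/env python
"""Shared/unique classification and phylogenetic grouping of the SD maps.

Searches every SD of every species against the other four genomes,
classifies each as shared or unique (a duplication must exist — at least
two distinct hit loci — in another genome to count as present there),
assigns presence patterns to phylogenetic groups, and contrasts identity
and variance between shared and unique SDs.
"""

import argparse
import os
from collections import Counter

import pandas as pd

from segdup.align import KmerIndex
from segdup.comparative import (
    HitParams, assign_groups, classify_shared, contrast_identity, contrast_variance,
)
from segdup.io import read_fasta
from segdup.masking import load_repeats
from segdup.pipeline import load_sd_map, pairs_table


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--simdir", default="results/sim")
    ap.add_argument("--sddir", default="results/pipeline")
    ap.add_argument("--outdir", default="results/comparative")
    args = ap.parse_args()
    os.makedirs(args.outdir, exist_ok=True)

    with open(os.path.join(args.simdir, "tree.nwk")) as fh:
        newick = fh.read().strip()
    genomes = {}
    species = []
    for fn in sorted(os.listdir(args.simdir)):
        if fn.endswith(".fa"):
            sp = fn[:-3]
            species.append(sp)
            genomes[sp] = read_fasta(os.path.join(args.simdir, fn))
    indexes = {sp: KmerIndex(genomes[sp]) for sp in species}
    hp = HitParams()
    contrast_rows = []
    for sp in species:
        lengths = {seq: len(s) for seq, s in genomes[sp].items()}
        sd_map = load_sd_map(os.path.join(args.sddir, f"{sp}.sd_pairs.tsv"), lengths, sp)
        others = {o: genomes[o] for o in species if o != sp}
        vectors = classify_shared(
            sd_map, others, genomes[sp], hp,
            indexes={o: indexes[o] for o in others},
            focal_repeats=load_repeats(os.path.join(args.simdir, f"{sp}.repeats.bed")),
        )
        labels = assign_groups(vectors, newick)
        counts = Counter(labels)
        n_shared = sum(1 for r in sd_map.records if r.shared_status == "shared")
        print(f"{sp}: {n_shared}/{sd_map.n_records} shared; groups {dict(counts)}")
        pairs_table(sd_map).to_csv(
            os.path.join(args.outdir, f"{sp}.sd_pairs.classified.tsv"),
            sep="\t", index=False,
        )
        pres = pd.DataFrame(
            [
                {"record": v.record_index, "group": v.group,
                 **{s: "+" if p else "-" for s, p in sorted(v.presence.items())}}
                for v in vectors
            ]
        )
        pres.to_csv(os.path.join(args.outdir, f"{sp}.presence.tsv"), sep="\t", index=False)
        shared = [r for r in sd_map.records if r.shared_status == "shared"]
        unique = [r for r in sd_map.records if r.shared_status == "unique"]
        if len(shared) >= 2 and len(unique) >= 2:
            ci = contrast_identity(shared, unique)
            cv = contrast_variance(shared, unique)
            contrast_rows.append(
                {"species": sp, "t": round(ci.statistic, 3), "t_p": ci.p_value,
                 "mean_shared": round(ci.mean_shared, 2),
                 "mean_unique": round(ci.mean_unique, 2), "direction": ci.direction,
                 "F": round(cv.statistic, 3), "F_p": cv.p_value}
            )
            print(f"   identity shared {ci.mean_shared:.1f} vs unique "
                  f"{ci.mean_unique:.1f} (p={ci.p_value:.2g}); variance F p={cv.p_value:.2g}")
    if contrast_rows:
        pd.DataFrame(contrast_rows).to_csv(
            os.path.join(args.outdir, "shared_unique_contrasts.tsv"), sep="\t", index=False
        )


if __name__ == "__main__":
    main()
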