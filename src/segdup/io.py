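"""File-format boundary: FASTA, BED, GFF3, TSV tables.

Internal coordinates are 0-based half-open everywhere; GFF3 (1-based
closed) and BED (0-based half-open) are converted here on read/write.
"""

from __future__ import annotations

import json
import math
import os
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .masking import RepeatAnnotation


def read_fasta(path: str) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(genome: Dict[str, str], path: str, width: int = 80) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in genome.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def write_repeat_bed(repeats: Sequence[RepeatAnnotation], path: str) -> None:
    """BED6 dialect: name = repeat class, score column = divergence (0 if unknown)."""
    with open(path, "w") as fh:
        for r in sorted(repeats, key=lambda r: (r.seq_id, r.start, r.end)):
            div = 0.0 if math.isnan(r.divergence) else r.divergence
            fh.write(f"{r.seq_id}\t{r.start}\t{r.end}\t{r.repeat_class}\t{div:g}\t+\n")


GFF_COLUMNS = ["seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes"]


def read_gff_genes(path: str) -> pd.DataFrame:
    """Gene features as a DataFrame with 0-based half-open ``start``/``end``.

    Duplicate gene IDs raise ``ValueError``.
    """
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=GFF_COLUMNS,
        dtype={"seqid": str, "attributes": str},
    )
    genes = df[df["type"] == "gene"].copy()
    genes["gene_id"] = genes["attributes"].str.extract(r"ID=([^;]+)")[0]
    if genes["gene_id"].isna().any():
        raise ValueError(f"{path}: gene feature without ID attribute")
    if genes["gene_id"].duplicated().any():
        dup = genes.loc[genes["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"{path}: duplicate gene id {dup!r}")
    genes["start"] = genes["start"].astype(int) - 1  # GFF3 is 1-based closed
    genes["end"] = genes["end"].astype(int)
    return genes[["seqid", "start", "end", "strand", "gene_id"]].reset_index(drop=True)


def write_gff_genes(genes: Iterable[Tuple[str, int, int, str]], path: str,
                    source: str = "segdup-sim") -> None:
    """Write (seqid, start0, end, gene_id) gene features as GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for seqid, start, end, gene_id in genes:
            fh.write(
                f"{seqid}\t{source}\tgene\t{start + 1}\t{end}\t.\t+\t.\tID={gene_id}\n"
            )


def read_expression(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene_id", "condition", "rpkm"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expression table needs columns {sorted(required)}")
    return df


def read_methylation(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"gene_id", "level"}.issubset(df.columns):
        raise ValueError(f"{path}: methylation table needs columns gene_id, level")
    return df


def read_go_map(path: str) -> Dict[str, List[str]]:
    """Two-column TSV gene_id <tab> term; genes may map to several terms."""
    out: Dict[str, List[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            gene, term = line.split("\t")[:2]
            out.setdefault(gene, []).append(term)
    return out


def write_tsv(df: pd.DataFrame, path: str, header_comment: Optional[str] = None) -> None:
    os.makedirs(os.path.dirname(path) or ".", exist_ok=True)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def write_json(obj, path: str) -> None:
    os.makedirs(os.path.dirname(path) or ".", exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")
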