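"""Transposable-element content of SDs, their flanks, and the genome.

For each repeat class the masked bp and fraction of three region sets are
compared: the SD union, 2.5 kb flanking regions (excluding SD bases), and
the genome.  Enrichment is the repeat-content fraction of the duplicated
sequence divided by the repeat-content fraction of a reference region —
either the non-duplicated ("unique") remainder of the genome or the
genome average; both denominators are computed.  Significance comes from a
placement-permutation null: length-matched random intervals are drawn
uniformly on the genome and the class fraction recomputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .intervals import (
    CoverageIndex,
    Interval,
    intersect_length,
    merge_intervals,
    subtract,
    total_length,
)
from .masking import RepeatAnnotation

TE_CLASSES = ("DNA", "SINE", "LTR", "LINE")


def _class_intervals(
    repeats: Iterable[RepeatAnnotation], classes: Sequence[str]
) -> Dict[str, Dict[str, List[Interval]]]:
    out: Dict[str, Dict[str, List[Interval]]] = {c: {} for c in classes}
    for r in repeats:
        if r.repeat_class in out:
            out[r.repeat_class].setdefault(r.seq_id, []).append((r.start, r.end))
    return {
        c: {seq: merge_intervals(ivs) for seq, ivs in per.items()}
        for c, per in out.items()
    }


def region_content(
    regions: Mapping[str, Sequence[Interval]],
    repeats: Iterable[RepeatAnnotation],
    classes: Sequence[str] = TE_CLASSES,
) -> Dict[str, Tuple[int, float]]:
    """Per repeat class: (masked bp inside regions, fraction of region bp)."""
    merged = {seq: merge_intervals(ivs) for seq, ivs in regions.items()}
    region_bp = sum(total_length(ivs) for ivs in merged.values())
    per_class = _class_intervals(repeats, classes)
    out: Dict[str, Tuple[int, float]] = {}
    for c in classes:
        bp = 0
        for seq, ivs in merged.items():
            bp += intersect_length(ivs, per_class[c].get(seq, []))
        out[c] = (bp, bp / region_bp if region_bp else 0.0)
    return out


def flanks(
    sd_union: Mapping[str, Sequence[Interval]],
    genome_lengths: Mapping[str, int],
    width: int = 2500,
) -> Dict[str, List[Interval]]:
    """``width`` bp on each side of every SD interval, clipped to sequence
    bounds, excluding bases inside any SD, merged."""
    out: Dict[str, List[Interval]] = {}
    for seq, ivs in sd_union.items():
        L = genome_lengths[seq]
        raw = []
        for s, e in ivs:
            raw.append((max(0, s - width), s))
            raw.append((e, min(L, e + width)))
        out[seq] = subtract(merge_intervals(raw), ivs)
    return out


def enrichment(dup_fraction: float, ref_fraction: float) -> Optional[float]:
    """Content ratio; None (not applicable) when the reference is zero."""
    if ref_fraction == 0:
        return None
    return dup_fraction / ref_fraction


def enrichment_significance(
    sd_union: Mapping[str, Sequence[Interval]],
    repeats: Iterable[RepeatAnnotation],
    repeat_class: str,
    genome_lengths: Mapping[str, int],
    n_samples: int = 1000,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Empirical p for over-representation of one class inside the SD union.

    The null re-places length-matched intervals uniformly (per sequence,
    chosen proportional to length) ``n_samples`` times; p = (1 + #{null >=
    observed}) / (n_samples + 1).  A class absent genome-wide gives p = 1.
    """
    if n_samples < 100:
        raise ValueError("n_samples must be >= 100")
    if rng is None:
        rng = np.random.default_rng(0)
    per_class = _class_intervals(repeats, (repeat_class,))[repeat_class]
    seqs = sorted(genome_lengths)
    cov = {
        seq: CoverageIndex(per_class.get(seq, []), genome_lengths[seq]) for seq in seqs
    }
    lengths: List[int] = []
    obs_bp = 0
    for seq, ivs in sd_union.items():
        for s, e in merge_intervals(ivs):
            if e - s > genome_lengths[seq]:
                raise ValueError("SD interval longer than its sequence")
            lengths.append(e - s)
            obs_bp += int(cov[seq].covered_bp([s], [e])[0])
    if not lengths:
        return 1.0
    total_class_bp = sum(
        total_length(per_class.get(seq, [])) for seq in seqs
    )
    if total_class_bp == 0:
        return 1.0
    total_sd = sum(lengths)
    obs_frac = obs_bp / total_sd
    seq_lens = np.array([genome_lengths[s] for s in seqs], dtype=float)
    weights = seq_lens / seq_lens.sum()
    lengths_arr = np.array(lengths, dtype=np.int64)
    null_frac = np.empty(n_samples)
    for it in range(n_samples):
        seq_choice = rng.choice(len(seqs), size=len(lengths_arr), p=weights)
        bp = 0
        for si in range(len(seqs)):
            mask = seq_choice == si
            if not mask.any():
                continue
            ls = lengths_arr[mask]
            max_start = genome_lengths[seqs[si]] - ls
            ok = max_start >= 0
            ls = ls[ok]
            if len(ls) == 0:
                continue
            starts = (rng.random(len(ls)) * (max_start[ok] + 1)).astype(np.int64)
            bp += int(cov[seqs[si]].covered_bp(starts, starts + ls).sum())
        null_frac[it] = bp / total_sd
    p = (1 + int((null_frac >= obs_frac).sum())) / (n_samples + 1)
    return float(p)


def te_content_table(
    sd_union: Mapping[str, Sequence[Interval]],
    repeats: Sequence[RepeatAnnotation],
    genome_lengths: Mapping[str, int],
    flank_width: int = 2500,
    n_samples: int = 1000,
    rng: Optional[np.random.Generator] = None,
    classes: Sequence[str] = TE_CLASSES,
) -> pd.DataFrame:
    """Census-style TE table: per class, content of SDs / flanks / genome,
    enrichment against both the genome average and the unique (non-SD)
    remainder, and the permutation p for the SD region."""
    fl = flanks(sd_union, genome_lengths, flank_width)
    genome_regions = {seq: [(0, L)] for seq, L in genome_lengths.items()}
    unique_regions = {
        seq: subtract([(0, genome_lengths[seq])], sd_union.get(seq, []))
        for seq in genome_lengths
    }
    sd_c = region_content(sd_union, repeats, classes)
    fl_c = region_content(fl, repeats, classes)
    g_c = region_content(genome_regions, repeats, classes)
    u_c = region_content(unique_regions, repeats, classes)
    rows = []
    for c in classes:
        p = enrichment_significance(
            sd_union, repeats, c, genome_lengths, n_samples=n_samples, rng=rng
        )
        rows.append(
            {
                "class": c,
                "sd_bp": sd_c[c][0],
                "sd_pct": 100 * sd_c[c][1],
                "flank_bp": fl_c[c][0],
                "flank_pct": 100 * fl_c[c][1],
                "genome_bp": g_c[c][0],
                "genome_pct": 100 * g_c[c][1],
                "enrichment_sd_vs_genome": enrichment(sd_c[c][1], g_c[c][1]),
                "enrichment_sd_vs_unique": enrichment(sd_c[c][1], u_c[c][1]),
                "enrichment_flank_vs_genome": enrichment(fl_c[c][1], g_c[c][1]),
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)
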