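"""SD calling: filter refined alignments, bin identities, build the map.

A segmental duplication is a refined alignment pair longer than 1 kb
(strict, on the shorter side) with identity of at least 75%.  Identity bins
follow the conventional census layout: >=90, 80-90 (lower edge closed),
75-80 (lower edge closed).  The per-genome map carries the non-redundant
union of all SD sides and census-style summary statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .align import AlignmentPair
from .intervals import Interval, merge_by_seq, total_length

IDENTITY_BINS = (">=90", "80-90", "75-80")


def identity_bin(identity: float) -> str:
    if identity >= 90.0:
        return ">=90"
    if identity >= 80.0:
        return "80-90"
    return "75-80"


@dataclass
class SDRecord:
    """A filtered alignment pair qualifying as a segmental duplication."""

    pair: AlignmentPair
    identity_bin: str
    shared_status: str = "unknown"  # unknown | shared | unique

    @property
    def identity(self) -> float:
        return self.pair.identity

    @property
    def length(self) -> int:
        """Aligned length (columns, terminal-trimmed)."""
        return self.pair.aligned_columns


def filter_sds(
    pairs: Iterable[AlignmentPair],
    min_len: int = 1000,
    min_identity: float = 75.0,
) -> List[SDRecord]:
    """Keep pairs with both sides strictly longer than ``min_len`` bp and
    identity >= ``min_identity``; assign identity bins."""
    out: List[SDRecord] = []
    for p in pairs:
        if p.stale:
            raise ValueError("filter_sds requires refined (non-stale) pairs")
        if min(p.len_a, p.len_b) <= min_len:
            continue
        if p.identity < min_identity:
            continue
        out.append(SDRecord(p, identity_bin(p.identity)))
    return out


@dataclass
class SDMap:
    """All SD records of one genome plus the union interval set."""

    species: str
    records: List[SDRecord]
    union: Dict[str, List[Interval]]
    genome_lengths: Dict[str, int]

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def bin_counts(self) -> Dict[str, int]:
        counts = {b: 0 for b in IDENTITY_BINS}
        for r in self.records:
            counts[r.identity_bin] += 1
        return counts

    @property
    def union_bp(self) -> int:
        return sum(total_length(ivs) for ivs in self.union.values())

    @property
    def genome_bp(self) -> int:
        return sum(self.genome_lengths.values())

    @property
    def fraction_of_genome(self) -> float:
        return self.union_bp / self.genome_bp if self.genome_bp else 0.0

    @property
    def summed_pair_bp(self) -> int:
        """Alternative total: summed side lengths, bases counted per record."""
        return sum(r.pair.len_a + r.pair.len_b for r in self.records)


def build_union(
    records: Sequence[SDRecord],
    genome_lengths: Dict[str, int],
    species: str = "",
) -> SDMap:
    """Merge all record sides into a sorted disjoint union and summarise."""
    triples = []
    for r in records:
        for seq, s, e in (r.pair.interval_a(), r.pair.interval_b()):
            if seq not in genome_lengths:
                raise ValueError(f"record on unknown sequence {seq!r}")
            if e > genome_lengths[seq]:
                raise ValueError(
                    f"interval {seq}:{s}-{e} exceeds sequence length {genome_lengths[seq]}"
                )
            triples.append((seq, s, e))
    union = merge_by_seq(triples)
    return SDMap(species, list(records), union, dict(genome_lengths))


def length_histogram(
    records: Sequence[SDRecord], bin_width: int = 500, start: int = 1000
) -> List[Tuple[int, int, int]]:
    """Counts of records per aligned-length bin: [(lo, hi, count), ...].

    Bins start at ``start`` bp; records shorter than ``start`` (none under
    default filtering) land in the first bin.
    """
    if not records:
        return []
    top = max(r.length for r in records)
    nbins = max(1, (max(top, start) - start) // bin_width + 1)
    counts = [0] * nbins
    for r in records:
        b = max(0, (r.length - start) // bin_width)
        counts[b] += 1
    return [
        (start + i * bin_width, start + (i + 1) * bin_width, c)
        for i, c in enumerate(counts)
    ]


def percent_high_identity(sd_map_or_counts) -> Optional[int]:
    """Percent of SD records in the >=90 identity bin, to the nearest integer.

    Accepts an :class:`SDMap` or a ``(n_ge90, n_total)`` tuple; returns
    ``None`` (not applicable) for an empty map.
    """
    if isinstance(sd_map_or_counts, SDMap):
        n = sd_map_or_counts.n_records
        n90 = sd_map_or_counts.bin_counts[">=90"]
    else:
        n90, n = sd_map_or_counts
    if n == 0:
        return None
    return int(round(100.0 * n90 / n))
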