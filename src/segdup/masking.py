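"""Repeat masking and "fuguization".

Before self-alignment the genome is stripped of annotated repeats (and long
N runs): every masked interval is excised and the remaining blocks are
concatenated into a compact "fugu" sequence.  A :class:`CoordinateMap`
records the kept blocks so alignment coordinates found in fugu space can be
lifted back to the original assembly, re-including any excised repeat bases
interior to an alignment.

Coordinates are 0-based half-open throughout; GFF3/BED conversion happens at
the file boundary (:mod:`segdup.io`).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .intervals import Interval, merge_intervals

REPEAT_CLASSES = ("DNA", "SINE", "LTR", "LINE", "SSR", "other")

# leading tokens of RepeatMasker class/family strings -> five-way scheme
_CLASS_MAP = {
    "DNA": "DNA",
    "RC": "DNA",  # rolling-circle (Helitron) transposons are DNA transposons
    "SINE": "SINE",
    "LTR": "LTR",
    "LINE": "LINE",
    "SSR": "SSR",
    "SIMPLE_REPEAT": "SSR",
    "SATELLITE": "SSR",
    "LOW_COMPLEXITY": "SSR",
}


def normalize_class(label: str) -> str:
    token = label.split("/")[0].strip().upper().replace("-", "_")
    token = token.rstrip("?")
    return _CLASS_MAP.get(token, "other")


@dataclass(frozen=True)
class RepeatAnnotation:
    """One annotated repeat interval.

    ``divergence`` is percent divergence from the repeat consensus
    (RepeatMasker "div" column); NaN when the source annotation (e.g. a
    plain BED) does not carry it.
    """

    seq_id: str
    start: int
    end: int
    repeat_class: str = "other"
    divergence: float = math.nan

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"empty repeat interval {self.seq_id}:{self.start}-{self.end}")


def load_repeats(path: str, format: str = "auto") -> List[RepeatAnnotation]:
    """Parse repeat annotations from BED6 or RepeatMasker ``.out``.

    ``format``: "bed", "rmout", or "auto" (sniff: a ``.out`` header or a
    first field that is not a sequence name followed by two ints).
    Malformed lines raise ``ValueError`` naming the line number.
    """
    with open(path) as fh:
        lines = fh.readlines()
    if format == "auto":
        format = "rmout" if _looks_like_rmout(lines) else "bed"
    out: List[RepeatAnnotation] = []
    if format == "bed":
        for ln, line in enumerate(lines, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                parts = line.split()
            try:
                seq, start, end = parts[0], int(parts[1]), int(parts[2])
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}: malformed BED line {ln}: {line!r}") from exc
            name = parts[3] if len(parts) > 3 else "other"
            # divergence may ride in the score column of our own BED dialect
            div = math.nan
            if len(parts) > 4:
                try:
                    div = float(parts[4])
                except ValueError:
                    div = math.nan
            out.append(RepeatAnnotation(seq, start, end, normalize_class(name), div))
    elif format == "rmout":
        for ln, line in enumerate(lines, 1):
            parts = line.split()
            if not parts or not parts[0].lstrip("-").isdigit():
                continue  # header / blank
            try:
                div = float(parts[1])
                seq = parts[4]
                start = int(parts[5]) - 1  # .out is 1-based closed
                end = int(parts[6])
                cls = normalize_class(parts[10])
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}: malformed RepeatMasker line {ln}: {line!r}") from exc
            out.append(RepeatAnnotation(seq, start, end, cls, div))
    else:
        raise ValueError(f"unknown repeat format {format!r}")
    return out


def _looks_like_rmout(lines: Sequence[str]) -> bool:
    for line in lines[:5]:
        if re.match(r"\s*SW\s+perc", line) or re.match(r"\s*score\s+div", line):
            return True
        parts = line.split()
        if len(parts) >= 11 and parts[0].isdigit():
            try:
                float(parts[1])
                int(parts[5])
                return True
            except ValueError:
                return False
    return False


def select_repeats(
    repeats: Iterable[RepeatAnnotation], max_divergence_pct: float = 15.0
) -> List[RepeatAnnotation]:
    """Keep repeats at or below the divergence cutoff and union-merge them.

    Records with unknown (NaN) divergence are kept: masking is conservative.
    Merged intervals keep their class when uniform, else "other".
    Idempotent: the output (divergence NaN) passes through unchanged.
    """
    by_seq: Dict[str, List[Tuple[int, int, str]]] = {}
    for r in repeats:
        if not math.isnan(r.divergence) and r.divergence > max_divergence_pct:
            continue
        by_seq.setdefault(r.seq_id, []).append((r.start, r.end, r.repeat_class))
    out: List[RepeatAnnotation] = []
    for seq in sorted(by_seq):
        ivs = sorted(by_seq[seq])
        i = 0
        while i < len(ivs):
            s, e, cls = ivs[i]
            classes = {cls}
            j = i + 1
            while j < len(ivs) and ivs[j][0] <= e:
                e = max(e, ivs[j][1])
                classes.add(ivs[j][2])
                j += 1
            out.append(RepeatAnnotation(seq, s, e, cls if len(classes) == 1 else "other"))
            i = j
    return out


@dataclass
class CoordinateMap:
    """Invertible fugu <-> original coordinate map for one genome.

    Per sequence, ``blocks[seq]`` is an ``(n, 3)`` int array of
    ``(fugu_start, orig_start, length)`` rows: the kept (non-excised)
    blocks, sorted, with fugu blocks contiguous from 0.
    """

    blocks: Dict[str, np.ndarray] = field(default_factory=dict)
    orig_lengths: Dict[str, int] = field(default_factory=dict)

    def fugu_length(self, seq: str) -> int:
        b = self.blocks[seq]
        return int(b[:, 2].sum()) if len(b) else 0

    def lift(self, seq: str, interval: Interval, direction: str) -> List[Interval]:
        """Lift an interval between coordinate spaces.

        ``direction`` is ``"fugu->orig"`` or ``"orig->fugu"``.  A fugu
        interval spanning an excision lifts to the single original interval
        spanning the reinserted repeat; an original interval lying entirely
        in excised sequence lifts to an empty list.
        """
        s, e = int(interval[0]), int(interval[1])
        if e <= s:
            raise ValueError(f"empty interval {interval}")
        b = self.blocks.get(seq)
        if b is None or len(b) == 0:
            raise KeyError(f"no kept blocks for sequence {seq!r}")
        if direction == "fugu->orig":
            flen = self.fugu_length(seq)
            if s < 0 or e > flen:
                raise ValueError(f"fugu interval {interval} outside [0,{flen})")
            os = self._fugu_pos_to_orig(b, s)
            oe = self._fugu_pos_to_orig(b, e - 1) + 1
            return [(os, oe)]
        if direction == "orig->fugu":
            olen = self.orig_lengths[seq]
            if s < 0 or e > olen:
                raise ValueError(f"orig interval {interval} outside [0,{olen})")
            pieces: List[Interval] = []
            for fs, osrt, ln in b:
                lo = max(s, osrt)
                hi = min(e, osrt + ln)
                if hi > lo:
                    pieces.append((int(fs + lo - osrt), int(fs + hi - osrt)))
            return merge_intervals(pieces)
        raise ValueError(f"unknown lift direction {direction!r}")

    @staticmethod
    def _fugu_pos_to_orig(b: np.ndarray, pos: int) -> int:
        idx = int(np.searchsorted(b[:, 0], pos, side="right")) - 1
        fs, osrt, ln = b[idx]
        off = pos - fs
        if off < 0 or off >= ln:
            raise ValueError(f"fugu position {pos} not covered by map")
        return int(osrt + off)

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("#seq\tfugu_start\torig_start\tlength\n")
            for seq in sorted(self.blocks):
                fh.write(f"##orig_length\t{seq}\t{self.orig_lengths[seq]}\n")
                for fs, osrt, ln in self.blocks[seq]:
                    fh.write(f"{seq}\t{fs}\t{osrt}\t{ln}\n")

    @classmethod
    def from_tsv(cls, path: str) -> "CoordinateMap":
        blocks: Dict[str, List[Tuple[int, int, int]]] = {}
        lengths: Dict[str, int] = {}
        with open(path) as fh:
            for line in fh:
                if line.startswith("##orig_length"):
                    _, seq, ln = line.strip().split("\t")
                    lengths[seq] = int(ln)
                    continue
                if line.startswith("#") or not line.strip():
                    continue
                seq, fs, osrt, ln = line.strip().split("\t")
                blocks.setdefault(seq, []).append((int(fs), int(osrt), int(ln)))
        return cls(
            blocks={s: np.array(v, dtype=np.int64).reshape(-1, 3) for s, v in blocks.items()},
            orig_lengths=lengths,
        )


def n_run_intervals(seq: str, min_run: int = 20) -> List[Interval]:
    """Runs of N (case-insensitive) of at least ``min_run`` bp."""
    return [
        (m.start(), m.end())
        for m in re.finditer(r"[Nn]{%d,}" % min_run, seq)
    ]


def fuguize(
    genome: Dict[str, str],
    repeats: Sequence[RepeatAnnotation],
    mask_n_runs: int = 20,
) -> Tuple[Dict[str, str], CoordinateMap]:
    """Excise masked intervals, returning the fugu genome and its map.

    Repeat intervals (plus N runs of >= ``mask_n_runs`` bp, set 0 to
    disable) are removed from each sequence and the kept blocks are
    concatenated.  ``len(fugu) + excised bp == len(genome)`` always holds.
    """
    fugu: Dict[str, str] = {}
    cmap = CoordinateMap()
    by_seq: Dict[str, List[Interval]] = {seq: [] for seq in genome}
    for r in repeats:
        if r.seq_id not in genome:
            continue
        if r.start < 0 or r.end > len(genome[r.seq_id]):
            raise ValueError(
                f"repeat {r.seq_id}:{r.start}-{r.end} outside sequence "
                f"of length {len(genome[r.seq_id])}"
            )
        by_seq[r.seq_id].append((r.start, r.end))
    for seq, s in genome.items():
        masked = list(by_seq.get(seq, []))
        if mask_n_runs:
            masked.extend(n_run_intervals(s, mask_n_runs))
        masked = merge_intervals(masked)
        blocks: List[Tuple[int, int, int]] = []
        parts: List[str] = []
        fpos = 0
        prev = 0
        for ms, me in masked + [(len(s), len(s))]:
            if ms > prev:
                blocks.append((fpos, prev, ms - prev))
                parts.append(s[prev:ms])
                fpos += ms - prev
            prev = max(prev, me)
        fugu[seq] = "".join(parts)
        cmap.blocks[seq] = np.array(blocks, dtype=np.int64).reshape(-1, 3)
        cmap.orig_lengths[seq] = len(s)
    return fugu, cmap
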