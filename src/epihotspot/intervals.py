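"""Native genomic-interval engine.

Coordinates are 0-based half-open (BED convention) everywhere. One-based
inputs are converted at the I/O boundary by callers. All operations are
strand-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional, Tuple

import numpy as np

__all__ = [
    "GenomicInterval",
    "IntervalTrack",
    "intersect",
    "intersect_count",
    "subtract",
    "closest",
    "merge_within",
    "read_bed",
    "write_bed",
    "read_chrom_sizes",
    "UNREACHABLE",
]

#: Sentinel distance for a-intervals whose chromosome is absent from b.
UNREACHABLE = -1


@dataclass(frozen=True)
class GenomicInterval:
    """A genomic interval in 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    name: Optional[str] = None
    score: Optional[float] = None
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def distance_to(self, other: "GenomicInterval") -> int:
        """Gap in bp between two intervals on the same chrom; 0 if they
        overlap or are bookended."""
        if self.chrom != other.chrom:
            raise ValueError("distance undefined across chromosomes")
        return max(other.start - self.end, self.start - other.end, 0)


class _ChromIndex:
    """Per-chromosome start/end arrays, sorted by (start, end)."""

    __slots__ = ("starts", "ends", "max_end_prefix", "intervals")

    def __init__(self, intervals: List[GenomicInterval]):
        self.intervals = intervals
        self.starts = np.array([iv.start for iv in intervals], dtype=np.int64)
        self.ends = np.array([iv.end for iv in intervals], dtype=np.int64)
        self.max_end_prefix = np.maximum.accumulate(self.ends) if len(intervals) else self.ends


class IntervalTrack:
    """A named, sorted collection of :class:`GenomicInterval`.

    Intervals are kept sorted by (chrom, start, end). Overlapping intervals
    are allowed and are never merged implicitly.
    """

    def __init__(
        self,
        intervals: Iterable[GenomicInterval] = (),
        name: str = "",
        genome: Optional[Dict[str, int]] = None,
    ):
        self.name = name
        self.genome = dict(genome) if genome else None
        self._intervals: List[GenomicInterval] = sorted(
            intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)
        )
        by_chrom: Dict[str, List[GenomicInterval]] = {}
        for iv in self._intervals:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        self._index: Dict[str, _ChromIndex] = {
            chrom: _ChromIndex(ivs) for chrom, ivs in by_chrom.items()
        }

    def __len__(self) -> int:
        return len(self._intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self._intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self._intervals[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalTrack):
            return NotImplemented
        return [(iv.chrom, iv.start, iv.end) for iv in self] == [
            (iv.chrom, iv.start, iv.end) for iv in other
        ]

    def __repr__(self) -> str:
        return f"IntervalTrack({self.name!r}, n={len(self)})"

    def chroms(self) -> List[str]:
        return sorted(self._index)

    def total_bases(self) -> int:
        """Sum of interval lengths (overlaps counted multiply)."""
        return sum(iv.length for iv in self._intervals)

    def covered_bases(self) -> int:
        """Number of distinct bases covered by the track."""
        return merge_within(self, 0).total_bases()

    def overlapping(self, chrom: str, start: int, end: int) -> List[GenomicInterval]:
        """All intervals overlapping [start, end) on chrom, in sorted order."""
        idx = self._index.get(chrom)
        if idx is None:
            return []
        hi = int(np.searchsorted(idx.starts, end, side="left"))
        if hi == 0:
            return []
        hits = np.nonzero(idx.ends[:hi] > start)[0]
        return [idx.intervals[i] for i in hits]

    def any_overlap(self, chrom: str, start: int, end: int) -> bool:
        idx = self._index.get(chrom)
        if idx is None:
            return False
        hi = int(np.searchsorted(idx.starts, end, side="left"))
        return hi > 0 and bool(idx.max_end_prefix[hi - 1] > start)


def intersect(a: IntervalTrack, b: IntervalTrack) -> IntervalTrack:
    """Sub-intervals of *a* overlapping >= 1 bp of some interval in *b*.

    Reports each a-interval truncated to every overlap (one record per
    overlapping (a, b) pair), mirroring default ``bedtools intersect``
    output. The number of distinct contributing a-intervals is available
    via :func:`intersect_count`.
    """
    out: List[GenomicInterval] = []
    for iv in a:
        for hit in b.overlapping(iv.chrom, iv.start, iv.end):
            out.append(
                replace(iv, start=max(iv.start, hit.start), end=min(iv.end, hit.end))
            )
    return IntervalTrack(out, name=a.name)


def intersect_count(a: IntervalTrack, b: IntervalTrack) -> int:
    """Number of distinct a-intervals with >= 1 bp overlap in b
    (``bedtools intersect -u`` style counting)."""
    return sum(1 for iv in a if b.any_overlap(iv.chrom, iv.start, iv.end))


def subtract(a: IntervalTrack, b: IntervalTrack) -> IntervalTrack:
    """Portions of each a-interval not covered by any b-interval."""
    out: List[GenomicInterval] = []
    for iv in a:
        pieces: List[Tuple[int, int]] = [(iv.start, iv.end)]
        for hit in b.overlapping(iv.chrom, iv.start, iv.end):
            nxt: List[Tuple[int, int]] = []
            for s, e in pieces:
                if hit.end <= s or hit.start >= e:
                    nxt.append((s, e))
                    continue
                if hit.start > s:
                    nxt.append((s, hit.start))
                if hit.end < e:
                    nxt.append((hit.end, e))
            pieces = nxt
            if not pieces:
                break
        for s, e in pieces:
            out.append(replace(iv, start=s, end=e))
    return IntervalTrack(out, name=a.name)


def closest(
    a: IntervalTrack, b: IntervalTrack
) -> List[Tuple[GenomicInterval, Optional[GenomicInterval], int]]:
    """For each a-interval, the nearest b-interval and the gap in bp.

    Distance is 0 when the intervals overlap or are bookended. Ties are
    broken toward the b-interval with the smaller start. a-intervals on
    chromosomes absent from b yield ``(iv, None, UNREACHABLE)``.
    """
    results: List[Tuple[GenomicInterval, Optional[GenomicInterval], int]] = []
    for iv in a:
        idx = b._index.get(iv.chrom)
        if idx is None:
            results.append((iv, None, UNREACHABLE))
            continue
        d = np.maximum(
            np.maximum(idx.starts - iv.end, iv.start - idx.ends), 0
        )
        # first minimum = smallest start among ties (arrays sorted by start)
        i = int(np.argmin(d))
        results.append((iv, idx.intervals[i], int(d[i])))
    return results


def merge_within(a: IntervalTrack, gap: int) -> IntervalTrack:
    """Union intervals whose gap is <= ``gap`` bp into single intervals.

    ``gap=0`` merges only overlapping or bookended intervals. Output is
    sorted and non-overlapping; names/scores are dropped.
    """
    if gap < 0:
        raise ValueError("gap must be non-negative")
    out: List[GenomicInterval] = []
    cur: Optional[Tuple[str, int, int]] = None
    for iv in a:
        if cur is not None and iv.chrom == cur[0] and iv.start - cur[2] <= gap:
            cur = (cur[0], cur[1], max(cur[2], iv.end))
        else:
            if cur is not None:
                out.append(GenomicInterval(cur[0], cur[1], cur[2]))
            cur = (iv.chrom, iv.start, iv.end)
    if cur is not None:
        out.append(GenomicInterval(cur[0], cur[1], cur[2]))
    return IntervalTrack(out, name=a.name)


# ---------------------------------------------------------------------------
# BED I/O


def read_bed(path, name: str = "", genome: Optional[Dict[str, int]] = None) -> IntervalTrack:
    """Read BED3/BED6 (tab-separated, no header; ``track``/``browser``/``#``
    lines skipped). Zero-length records are rejected at parse time."""
    intervals: List[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            chrom, start_s, end_s = fields[0], fields[1], fields[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end <= start:
                raise ValueError(
                    f"{path}:{lineno}: zero-length or inverted interval "
                    f"{chrom}:{start}-{end}"
                )
            nm = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                score = float(fields[4])
            strand = fields[5] if len(fields) > 5 else "."
            intervals.append(GenomicInterval(chrom, start, end, nm, score, strand))
    track_name = name or Path(path).stem
    return IntervalTrack(intervals, name=track_name, genome=genome)


def write_bed(track: IntervalTrack, path) -> None:
    with open(path, "w") as fh:
        for iv in track:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None or iv.strand != ".":
                fields.append(iv.name if iv.name is not None else ".")
                fields.append(format(iv.score, "g") if iv.score is not None else ".")
                fields.append(iv.strand)
            fh.write("\t".join(fields) + "\n")


def read_chrom_sizes(path) -> Dict[str, int]:
    """Read a chrom<TAB>length TSV."""
    sizes: Dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected chrom<TAB>length")
            sizes[parts[0]] = int(parts[1])
    return sizes
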