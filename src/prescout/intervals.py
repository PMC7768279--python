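"""Genomic interval arithmetic and BED I/O.

All coordinates are 0-based half-open (BED convention).  Intervals are the
currency of every peak post-processing step: merging nearby peaks, taking the
base-level intersection of replicates, forming TF-binding-site unions, and
flagging evidence overlap.  Operations are deliberately strand-unaware —
histone-modification peaks have no strand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence


class IntervalError(ValueError):
    """Raised when an interval or interval file fails validation."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic span [start, end) on a chromosome.

    Parameters
    ----------
    chrom : str
        Chromosome name (non-empty).
    start, end : int
        0-based inclusive start and exclusive end; ``end > start >= 0``.
    name : str, optional
        Free-text label (BED column 4).
    score : float, optional
        Numeric score (BED column 5); peaks carry -log10(q) here.
    """

    chrom: str
    start: int
    end: int
    name: str | None = field(default=None, compare=False)
    score: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise IntervalError(f"empty chromosome name in {self!r}")
        if self.start < 0:
            raise IntervalError(f"negative start in {self!r}")
        if self.end <= self.start:
            raise IntervalError(f"end must exceed start in {self!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two spans share at least one base (half-open)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


class IntervalSet:
    """An ordered collection of :class:`GenomicInterval`.

    Kept sorted by (chrom, start, end).  A set produced by a merging
    operation is flagged ``merged``; a merged set has no two intervals on
    the same chromosome that overlap or touch.
    """

    def __init__(
        self,
        intervals: Iterable[GenomicInterval] = (),
        genome: Mapping[str, int] | None = None,
        merged: bool = False,
    ) -> None:
        self.intervals: list[GenomicInterval] = sorted(intervals)
        self.genome = dict(genome) if genome is not None else None
        self.merged = merged

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i):
        return self.intervals[i]

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return [(iv.chrom, iv.start, iv.end) for iv in self] == [
            (iv.chrom, iv.start, iv.end) for iv in other
        ]

    def __repr__(self) -> str:
        return f"IntervalSet({len(self)} intervals, merged={self.merged})"

    def total_bases(self) -> int:
        """Sum of span lengths (double counts overlapping bases if unmerged)."""
        return sum(len(iv) for iv in self)

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out


def merge_within(intervals: IntervalSet, max_gap: int = 0) -> IntervalSet:
    """Coalesce intervals on the same chromosome separated by <= ``max_gap`` bp.

    The gap between consecutive sorted intervals is ``next.start - prev.end``;
    touching intervals (gap 0) merge at any ``max_gap >= 0``, and merging is
    transitive.  Scores and names are dropped on coalesced spans except where
    a span is a single untouched input interval.
    """
    if max_gap < 0:
        raise ValueError(f"max_gap must be non-negative, got {max_gap}")
    merged: list[GenomicInterval] = []
    for chrom, ivs in sorted(intervals.by_chrom().items()):
        cur_start, cur_end = ivs[0].start, ivs[0].end
        members = [ivs[0]]
        for iv in ivs[1:]:
            if iv.start - cur_end <= max_gap:
                cur_end = max(cur_end, iv.end)
                members.append(iv)
            else:
                merged.append(_coalesce(chrom, cur_start, cur_end, members))
                cur_start, cur_end, members = iv.start, iv.end, [iv]
        merged.append(_coalesce(chrom, cur_start, cur_end, members))
    return IntervalSet(merged, genome=intervals.genome, merged=True)


def _coalesce(chrom: str, start: int, end: int, members: Sequence[GenomicInterval]) -> GenomicInterval:
    if len(members) == 1:
        m = members[0]
        return GenomicInterval(chrom, start, end, m.name, m.score)
    scores = [m.score for m in members if m.score is not None]
    return GenomicInterval(chrom, start, end, None, max(scores) if scores else None)


def intersect(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Base-level intersection: maximal spans covered by both sets."""
    am, bm = merge_within(a, 0), merge_within(b, 0)
    out: list[GenomicInterval] = []
    b_chrom = bm.by_chrom()
    for chrom, a_ivs in am.by_chrom().items():
        b_ivs = b_chrom.get(chrom, [])
        i = j = 0
        while i < len(a_ivs) and j < len(b_ivs):
            lo = max(a_ivs[i].start, b_ivs[j].start)
            hi = min(a_ivs[i].end, b_ivs[j].end)
            if lo < hi:
                out.append(GenomicInterval(chrom, lo, hi))
            if a_ivs[i].end < b_ivs[j].end:
                i += 1
            else:
                j += 1
    return IntervalSet(out, genome=a.genome or b.genome, merged=True)


def union(sets: Sequence[IntervalSet]) -> IntervalSet:
    """Base-level union of any number of sets; merged output."""
    if not sets:
        return IntervalSet([], merged=True)
    all_ivs = [iv for s in sets for iv in s]
    genome = next((s.genome for s in sets if s.genome is not None), None)
    return merge_within(IntervalSet(all_ivs, genome=genome), 0)


def subtract(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Bases of ``a`` not covered by ``b`` (used to keep peak classes disjoint)."""
    am, bm = merge_within(a, 0), merge_within(b, 0)
    out: list[GenomicInterval] = []
    b_chrom = bm.by_chrom()
    for chrom, a_ivs in am.by_chrom().items():
        b_ivs = b_chrom.get(chrom, [])
        for aiv in a_ivs:
            cursor = aiv.start
            for biv in b_ivs:
                if biv.end <= cursor:
                    continue
                if biv.start >= aiv.end:
                    break
                if biv.start > cursor:
                    out.append(GenomicInterval(chrom, cursor, biv.start, aiv.name, aiv.score))
                cursor = max(cursor, biv.end)
            if cursor < aiv.end:
                out.append(GenomicInterval(chrom, cursor, aiv.end, aiv.name, aiv.score))
    return IntervalSet(out, genome=a.genome, merged=True)


def overlaps_any(query: IntervalSet, evidence: IntervalSet) -> list[bool]:
    """Per-query flag: does the query interval share >= 1 bp with any evidence
    interval?  Touching intervals ([0,100) vs [100,200)) do not overlap."""
    ev = merge_within(evidence, 0).by_chrom()
    flags: list[bool] = []
    for iv in query:
        ivs = ev.get(iv.chrom, [])
        # binary search would be fine; evidence sets are small at desk scale
        flags.append(any(iv.start < e.end and e.start < iv.end for e in ivs))
    return flags


def coverage_fraction(query: IntervalSet, cover: IntervalSet) -> list[float]:
    """Per-query fraction of bases covered by ``cover`` (merged)."""
    cov = merge_within(cover, 0).by_chrom()
    fracs = []
    for iv in query:
        covered = sum(iv.overlap_length(c) for c in cov.get(iv.chrom, []))
        fracs.append(covered / len(iv))
    return fracs


# ---------------------------------------------------------------------------
# BED I/O
# ---------------------------------------------------------------------------

def read_bed(path) -> IntervalSet:
    """Read a BED3+ file (tab-separated; optional name and score columns).

    Track definition, browser and ``#`` comment lines are skipped with a
    warning.  A malformed record raises :class:`IntervalError` naming the
    line number.
    """
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("track", "browser", "#")):
                warnings.warn(f"{path}:{lineno}: skipping header line", stacklevel=2)
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise IntervalError(f"{path}:{lineno}: expected >=3 columns, got {len(fields)}")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise IntervalError(f"{path}:{lineno}: non-integer coordinate") from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] != ".":
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise IntervalError(f"{path}:{lineno}: non-numeric score") from exc
            try:
                intervals.append(GenomicInterval(chrom, start, end, name, score))
            except IntervalError as exc:
                raise IntervalError(f"{path}:{lineno}: {exc}") from exc
    return IntervalSet(intervals)


def write_bed(intervals: IntervalSet, path) -> None:
    """Write BED3/BED6 (name/score columns emitted when any record has them)."""
    has_name = any(iv.name is not None for iv in intervals)
    has_score = any(iv.score is not None for iv in intervals)
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if has_name or has_score:
                fields.append(iv.name if iv.name is not None else ".")
            if has_score:
                fields.append(f"{iv.score:.10g}" if iv.score is not None else ".")
            fh.write("\t".join(fields) + "\n")


def read_chrom_sizes(path) -> dict[str, int]:
    """Read a two-column chrom\tlength file."""
    genome: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 2:
                raise IntervalError(f"{path}:{lineno}: expected chrom and length")
            genome[fields[0]] = int(fields[1])
    return genome
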