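"""Genomic interval algebra on 0-based half-open coordinates.

:class:`IntervalSet` is the common currency of the whole screen: alignment
chain gaps, per-species conserved elements, per-base quorum masks and final
candidate intervals are all sorted, disjoint interval sets on one named
reference sequence.  All set operations are exact on base positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "Interval",
    "IntervalSet",
    "coverage_threshold",
    "find_assembly_gaps",
]


@dataclass(frozen=True, order=True)
class Interval:
    """A 0-based half-open interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class IntervalSet:
    """Sorted, disjoint, non-abutting intervals on a single chromosome.

    Stored as parallel int64 arrays of starts and ends.  Construction
    normalizes the input: intervals are sorted and any overlapping or
    abutting pair is unioned, so ``total_coverage`` always equals the sum
    of member lengths.
    """

    __slots__ = ("chrom", "starts", "ends")

    def __init__(
        self,
        chrom: str,
        starts: Sequence[int] | np.ndarray = (),
        ends: Sequence[int] | np.ndarray = (),
        *,
        _normalized: bool = False,
    ) -> None:
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        if starts.shape != ends.shape or starts.ndim != 1:
            raise ValueError("starts/ends must be 1-D arrays of equal length")
        if starts.size and (np.any(starts < 0) or np.any(ends <= starts)):
            raise ValueError("every interval needs 0 <= start < end")
        if not _normalized and starts.size:
            order = np.argsort(starts, kind="stable")
            starts, ends = starts[order], ends[order]
            starts, ends = _merge_sorted(starts, ends, 0)
        self.chrom = chrom
        self.starts = starts
        self.ends = ends

    # -- construction helpers ------------------------------------------------

    @classmethod
    def from_intervals(cls, intervals: Iterable[Interval]) -> "IntervalSet":
        ivs = list(intervals)
        if not ivs:
            raise ValueError("cannot infer chrom from an empty iterable; "
                             "use IntervalSet(chrom) instead")
        chroms = {iv.chrom for iv in ivs}
        if len(chroms) > 1:
            raise ValueError(f"intervals span multiple chroms: {sorted(chroms)}")
        return cls(ivs[0].chrom,
                   [iv.start for iv in ivs],
                   [iv.end for iv in ivs])

    @classmethod
    def from_pairs(cls, chrom: str,
                   pairs: Iterable[tuple[int, int]]) -> "IntervalSet":
        pairs = list(pairs)
        return cls(chrom, [p[0] for p in pairs], [p[1] for p in pairs])

    # -- basic protocol ------------------------------------------------------

    def __len__(self) -> int:
        return int(self.starts.size)

    def __iter__(self) -> Iterator[Interval]:
        for s, e in zip(self.starts.tolist(), self.ends.tolist()):
            yield Interval(self.chrom, s, e)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return (self.chrom == other.chrom
                and np.array_equal(self.starts, other.starts)
                and np.array_equal(self.ends, other.ends))

    def __repr__(self) -> str:
        items = ", ".join(f"[{s},{e})" for s, e in
                          zip(self.starts[:4].tolist(), self.ends[:4].tolist()))
        more = "" if len(self) <= 4 else f", ... {len(self)} total"
        return f"IntervalSet({self.chrom!r}: {items}{more})"

    @property
    def total_coverage(self) -> int:
        return int(np.sum(self.ends - self.starts))

    def is_empty(self) -> bool:
        return self.starts.size == 0

    # -- set algebra ---------------------------------------------------------

    def _check_chrom(self, other: "IntervalSet") -> None:
        if self.chrom != other.chrom:
            raise ValueError(
                f"chrom mismatch: {self.chrom!r} vs {other.chrom!r}")

    def union(self, other: "IntervalSet") -> "IntervalSet":
        self._check_chrom(other)
        return IntervalSet(self.chrom,
                           np.concatenate([self.starts, other.starts]),
                           np.concatenate([self.ends, other.ends]))

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        self._check_chrom(other)
        return _sweep(self.chrom, [self, other], lambda c: c == 2)

    def subtract(self, other: "IntervalSet") -> "IntervalSet":
        """Bases of ``self`` not covered by ``other``."""
        self._check_chrom(other)
        # with weights (+1, -1) only self-only bases run at count 1
        return _sweep(self.chrom, [self, other], lambda c: c == 1,
                      weights=[1, -1])

    def merge_within(self, distance: int) -> "IntervalSet":
        """Union any two intervals separated by ``<= distance`` bases.

        Idempotent; ``distance=0`` merges only overlapping/abutting
        intervals, which normalization has already done.
        """
        if distance < 0:
            raise ValueError("distance must be >= 0")
        if self.is_empty():
            return self
        s, e = _merge_sorted(self.starts, self.ends, distance)
        return IntervalSet(self.chrom, s, e, _normalized=True)

    def clip(self, start: int, end: int) -> "IntervalSet":
        """Restrict to the window ``[start, end)``."""
        if self.is_empty() or start >= end:
            return IntervalSet(self.chrom)
        keep = (self.ends > start) & (self.starts < end)
        s = np.clip(self.starts[keep], start, None)
        e = np.clip(self.ends[keep], None, end)
        return IntervalSet(self.chrom, s, e, _normalized=True)

    def overlaps_interval(self, start: int, end: int) -> bool:
        i = int(np.searchsorted(self.starts, end, side="left"))
        return i > 0 and int(self.ends[i - 1]) > start

    def contains_interval(self, start: int, end: int) -> bool:
        """True iff some single member interval covers ``[start, end)``."""
        i = int(np.searchsorted(self.starts, start, side="right"))
        return i > 0 and int(self.ends[i - 1]) >= end

    def expand(self, pad: int, *, lo: int = 0,
               hi: int | None = None) -> "IntervalSet":
        """Pad every interval by ``pad`` on each side, clamped to [lo, hi]."""
        if self.is_empty():
            return self
        s = np.maximum(self.starts - pad, lo)
        e = self.ends + pad if hi is None else np.minimum(self.ends + pad, hi)
        return IntervalSet(self.chrom, s, e)


def _merge_sorted(starts: np.ndarray, ends: np.ndarray,
                  distance: int) -> tuple[np.ndarray, np.ndarray]:
    """Merge start-sorted intervals whose separation is <= distance."""
    if starts.size == 0:
        return starts, ends
    # running maximum of ends handles contained intervals
    run_ends = np.maximum.accumulate(ends)
    new_group = np.empty(starts.size, dtype=bool)
    new_group[0] = True
    new_group[1:] = starts[1:] - run_ends[:-1] > distance
    group = np.cumsum(new_group) - 1
    n = int(group[-1]) + 1
    out_s = starts[new_group]
    out_e = np.full(n, -1, dtype=np.int64)
    np.maximum.at(out_e, group, ends)
    return out_s, out_e


def _sweep(chrom: str, sets: Sequence[IntervalSet],
           keep, weights: Sequence[int] | None = None) -> IntervalSet:
    """Boundary sweep over normalized sets; keep runs where keep(count)."""
    if weights is None:
        weights = [1] * len(sets)
    pos_parts, delta_parts = [], []
    for st, w in zip(sets, weights):
        if st.starts.size:
            pos_parts.append(st.starts)
            delta_parts.append(np.full(st.starts.size, w, dtype=np.int64))
            pos_parts.append(st.ends)
            delta_parts.append(np.full(st.ends.size, -w, dtype=np.int64))
    if not pos_parts:
        return IntervalSet(chrom)
    pos = np.concatenate(pos_parts)
    delta = np.concatenate(delta_parts)
    order = np.argsort(pos, kind="stable")
    pos, delta = pos[order], delta[order]
    # collapse equal positions
    uniq, idx = np.unique(pos, return_index=True)
    counts = np.add.reduceat(delta, idx)
    running = np.cumsum(counts)
    good = keep(running)
    good[-1] = False  # final boundary closes at count 0 by construction
    # runs [uniq[i], uniq[i+1]) where good[i]
    prev = np.concatenate([[False], good[:-1]])
    run_start = good & ~prev
    run_end = ~good & prev
    starts = uniq[run_start]
    ends = uniq[run_end]
    return IntervalSet(chrom, starts, ends, _normalized=True)


def coverage_threshold(sets: Sequence[IntervalSet],
                       min_count: int,
                       chrom: str | None = None) -> IntervalSet:
    """Bases covered by at least ``min_count`` of the given sets.

    Each input set contributes at most 1 per base (they are normalized).
    With ``min_count=1`` this is the n-way union; with ``min_count=len(sets)``
    the n-way intersection.
    """
    if chrom is None:
        if not sets:
            raise ValueError("need chrom when sets is empty")
        chrom = sets[0].chrom
    for st in sets:
        if st.chrom != chrom:
            raise ValueError(f"chrom mismatch: {st.chrom!r} vs {chrom!r}")
    if min_count <= 0:
        raise ValueError("min_count must be >= 1")
    if len(sets) < min_count:
        return IntervalSet(chrom)
    return _sweep(chrom, sets, lambda c: c >= min_count)


_VALID_BASES = frozenset(b"ACGTNacgtn")


def find_assembly_gaps(seq: str | bytes, min_run: int = 6,
                       chrom: str = "") -> IntervalSet:
    """Maximal runs of N (case-insensitive) of length >= ``min_run``.

    The default of 6 treats a run *longer than* 5 undetermined bases as an
    assembly gap; shorter N runs are tolerated as ordinary ambiguity.
    """
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    arr = np.frombuffer(seq, dtype=np.uint8)
    if arr.size:
        bad = ~np.isin(arr, np.frombuffer(b"ACGTNacgtn", dtype=np.uint8))
        if bad.any():
            pos = int(np.argmax(bad))
            raise ValueError(
                f"non-nucleotide character {chr(arr[pos])!r} at position {pos}")
    is_n = (arr == ord("N")) | (arr == ord("n"))
    if not is_n.any():
        return IntervalSet(chrom)
    padded = np.concatenate([[False], is_n, [False]])
    diffs = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diffs == 1)
    ends = np.flatnonzero(diffs == -1)
    keep = (ends - starts) >= min_run
    return IntervalSet(chrom, starts[keep], ends[keep], _normalized=True)
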