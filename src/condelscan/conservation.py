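"""Per-species conserved elements from sliding-window percent identity.

For every ungapped block of a species' orthologous chains, percent identity
to the reference is computed in sliding windows of 10, 25, 50 and 100 bp
(step 1 by default; windows never span a block boundary).  All windows of
all sizes are pooled and ranked by identity; the top-ranked windows are
accumulated until their merged, flattened footprint covers 5% of the
reference, every remaining window tied with the stopping window's identity
is added, and the selected windows — flattened and merged within 20 bp —
are that species' conserved elements.

Identity is exact base matching, case-insensitive; an N on either side
never matches.  The denominator is the window size (blocks are gapless, so
no gap-column policy is needed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chain import Chain
from .intervals import IntervalSet

__all__ = ["ConservationConfig", "WindowSet", "window_identity",
           "select_conserved_elements", "match_columns"]

_COMPLEMENT = bytes.maketrans(b"ACGTNacgtn", b"TGCANtgcan")


@dataclass(frozen=True)
class ConservationConfig:
    """window_sizes in bases; coverage_fraction of the reference to fill."""

    window_sizes: tuple[int, ...] = (10, 25, 50, 100)
    step: int = 1
    coverage_fraction: float = 0.05
    merge_distance: int = 20

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.window_sizes):
            raise ValueError("window sizes must be positive")
        if not (0 < self.coverage_fraction <= 1):
            raise ValueError("coverage_fraction must be in (0, 1]")
        if self.step < 1:
            raise ValueError("step must be >= 1")


@dataclass
class WindowSet:
    """Scored windows on one chromosome, stored columnar.

    ``starts[i]`` is the reference start of a window of ``sizes[i]`` bases
    whose exact-match fraction is ``identities[i]``.
    """

    chrom: str
    starts: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=np.int64))
    sizes: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=np.int64))
    identities: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=np.float64))

    def __len__(self) -> int:
        return int(self.starts.size)

    @classmethod
    def concat(cls, chrom: str, parts: list["WindowSet"]) -> "WindowSet":
        if not parts:
            return cls(chrom)
        return cls(chrom,
                   np.concatenate([p.starts for p in parts]),
                   np.concatenate([p.sizes for p in parts]),
                   np.concatenate([p.identities for p in parts]))


def _to_upper_bytes(seq: str | bytes) -> np.ndarray:
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    arr = np.frombuffer(seq.upper(), dtype=np.uint8)
    return arr


def match_columns(chain: Chain, ref_seq: str | bytes,
                  query_seq: str | bytes) -> tuple[np.ndarray, np.ndarray]:
    """Per-aligned-column match flags and their reference positions.

    ``query_seq`` is the query chromosome on its plus strand; minus-strand
    chains are compared against its reverse complement, which is the
    coordinate system chain query coordinates use.
    Returns ``(ref_positions, is_match)`` over all ungapped blocks.
    """
    ref = _to_upper_bytes(ref_seq)
    if isinstance(query_seq, str):
        query_seq = query_seq.encode("ascii")
    if chain.q_strand == "-":
        query_seq = query_seq.translate(_COMPLEMENT)[::-1]
    qry = _to_upper_bytes(query_seq)
    if chain.t_end > ref.size:
        raise ValueError(
            f"reference sequence length {ref.size} < chain t_end "
            f"{chain.t_end}")
    if chain.q_end > qry.size:
        raise ValueError(
            f"query sequence length {qry.size} < chain q_end {chain.q_end}")
    pos_parts, match_parts = [], []
    for ts, te, qs, qe in chain.block_coords():
        r = ref[ts:te]
        q = qry[qs:qe]
        m = (r == q) & (r != ord("N"))
        pos_parts.append(np.arange(ts, te, dtype=np.int64))
        match_parts.append(m)
    if not pos_parts:
        return (np.empty(0, dtype=np.int64), np.empty(0, dtype=bool))
    return np.concatenate(pos_parts), np.concatenate(match_parts)


def window_identity(chain: Chain, ref_seq: str | bytes,
                    query_seq: str | bytes,
                    config: ConservationConfig = ConservationConfig()
                    ) -> WindowSet:
    """Sliding-window identities over every ungapped block of one chain."""
    ref = _to_upper_bytes(ref_seq)
    if isinstance(query_seq, str):
        query_seq = query_seq.encode("ascii")
    if chain.q_strand == "-":
        query_seq = query_seq.translate(_COMPLEMENT)[::-1]
    qry = _to_upper_bytes(query_seq)
    if chain.t_end > ref.size:
        raise ValueError(
            f"reference sequence length {ref.size} < chain t_end "
            f"{chain.t_end}")
    if chain.q_end > qry.size:
        raise ValueError(
            f"query sequence length {qry.size} < chain q_end {chain.q_end}")
    starts_parts, sizes_parts, id_parts = [], [], []
    for ts, te, qs, qe in chain.block_coords():
        r = ref[ts:te]
        q = qry[qs:qe]
        m = ((r == q) & (r != ord("N"))).astype(np.int64)
        block_len = te - ts
        csum = np.concatenate([[0], np.cumsum(m)])
        for w in config.window_sizes:
            if w > block_len:
                continue
            offsets = np.arange(0, block_len - w + 1, config.step,
                                dtype=np.int64)
            matches = csum[offsets + w] - csum[offsets]
            starts_parts.append(ts + offsets)
            sizes_parts.append(np.full(offsets.size, w, dtype=np.int64))
            id_parts.append(matches / float(w))
    if not starts_parts:
        return WindowSet(chain.t_name)
    return WindowSet(chain.t_name,
                     np.concatenate(starts_parts),
                     np.concatenate(sizes_parts),
                     np.concatenate(id_parts))


def _coverage_mask(windows: WindowSet, threshold: float,
                   length: int) -> np.ndarray:
    """Boolean per-base mask of bases under any window with id >= threshold."""
    keep = windows.identities >= threshold
    if not keep.any():
        return np.zeros(length, dtype=bool)
    s = windows.starts[keep]
    e = s + windows.sizes[keep]
    diff = (np.bincount(s, minlength=length + 1)
            - np.bincount(e, minlength=length + 1))
    return np.cumsum(diff[:-1]) > 0


def _mask_to_set(mask: np.ndarray, chrom: str) -> IntervalSet:
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(np.int8))
    return IntervalSet(chrom, np.flatnonzero(d == 1), np.flatnonzero(d == -1),
                       _normalized=True)


def select_conserved_elements(
    windows: WindowSet | list[WindowSet],
    reference_total_bases: int,
    config: ConservationConfig = ConservationConfig(),
) -> IntervalSet:
    """Quota selection of top-identity windows into conserved elements.

    Windows (all sizes pooled) are conceptually accumulated in descending
    identity order, tracking merged-flattened coverage, stopping at the
    first window whose inclusion reaches ``coverage_fraction *
    reference_total_bases``; every window tied with the stopping window's
    identity is also included.  Because whole tie cohorts are taken, the
    selected set equals *all windows with identity >= theta*, where theta
    is the lowest identity level still needed to reach the quota — found
    here by bisection over the distinct identity levels.  If the supply
    never reaches the quota, every window is selected.  The result is
    order-independent by construction.
    """
    if isinstance(windows, list):
        if not windows:
            raise ValueError("no window sets given")
        windows = WindowSet.concat(windows[0].chrom, windows)
    chrom = windows.chrom
    if len(windows) == 0:
        return IntervalSet(chrom)
    quota = config.coverage_fraction * reference_total_bases
    length = int(np.max(windows.starts + windows.sizes))
    levels = np.unique(windows.identities)  # ascending
    # find the largest level theta with coverage(>= theta) >= quota;
    # coverage is non-increasing in theta
    lo, hi = 0, levels.size - 1  # candidate index range into levels
    if _coverage_mask(windows, levels[0], length).sum() < quota:
        theta = levels[0]  # even taking everything misses the quota
    else:
        while lo < hi:
            mid = (lo + hi + 1) // 2
            if _coverage_mask(windows, levels[mid], length).sum() >= quota:
                lo = mid
            else:
                hi = mid - 1
        theta = levels[lo]
    mask = _coverage_mask(windows, theta, length)
    return _mask_to_set(mask, chrom).merge_within(config.merge_distance)


def element_scores(elements: IntervalSet, windows: WindowSet) -> np.ndarray:
    """Max window identity under each element (for BED score columns)."""
    scores = np.zeros(len(elements), dtype=np.float64)
    if len(elements) == 0 or len(windows) == 0:
        return scores
    idx = np.searchsorted(elements.starts, windows.starts, side="right") - 1
    ok = (idx >= 0) & (windows.starts < elements.ends[np.clip(idx, 0, None)])
    np.maximum.at(scores, idx[ok], windows.identities[ok])
    return scores
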