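"""Per-species chain-gap calling: deletions relative to the reference.

Inter-block separators of an orthologous chain with ``dt > 0`` mark
reference bases missing (or unalignably diverged) in the query genome.  A
gap is *single-sided* when the query has nothing at the breakpoint
(``dq = 0``) and *double-sided* when unaligned query sequence sits between
the flanking blocks (``dq > 0``).  Gaps whose query-side context lies near
an assembly-gap N-run are discarded as likely sequencing/assembly artifacts
rather than biological deletions; surviving gaps are merged per chain and
unioned across a species' accepted chains.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .chain import Chain, query_interval_on_plus
from .intervals import Interval, IntervalSet

__all__ = ["GapCall", "GapCallerConfig", "raw_gaps",
           "mask_by_assembly_gaps", "species_gap_set"]


@dataclass(frozen=True)
class GapCallerConfig:
    """Thresholds for gap calling.

    assembly_gap_min_run: minimal N-run length treated as an assembly gap
        (6, i.e. "longer than 5" undetermined bases).
    proximity: a chain gap within this many query bases of an N-run is
        dropped (inclusive distance).
    merge_distance: per-chain merge radius for retained gap intervals.
    """

    assembly_gap_min_run: int = 6
    proximity: int = 100
    merge_distance: int = 20

    def __post_init__(self) -> None:
        if min(self.assembly_gap_min_run, self.proximity,
               self.merge_distance) < 0:
            raise ValueError("all GapCallerConfig fields must be >= 0")


@dataclass(frozen=True)
class GapCall:
    """One chain gap: reference footprint plus query-side context.

    ``q_context`` is the (possibly zero-length) plus-strand query interval
    between the flanking blocks, as a bare coordinate pair.
    """

    interval: Interval
    side: str  # 'single' | 'double'
    q_context: tuple[int, int]
    chain_id: int


def raw_gaps(chain: Chain) -> list[GapCall]:
    """One GapCall per inter-block separator with ``dt > 0``."""
    out: list[GapCall] = []
    t, q = chain.t_start, chain.q_start
    for size, dt, dq in chain.blocks:
        t_gap_start = t + size
        q_gap_start = q + size
        if dt > 0:
            out.append(GapCall(
                interval=Interval(chain.t_name, t_gap_start, t_gap_start + dt),
                side="double" if dq > 0 else "single",
                q_context=query_interval_on_plus(
                    chain, q_gap_start, q_gap_start + dq),
                chain_id=chain.chain_id,
            ))
        t += size + dt
        q += size + dq
    return out


def mask_by_assembly_gaps(
    gaps: Iterable[GapCall],
    query_n_runs: IntervalSet,
    config: GapCallerConfig = GapCallerConfig(),
    q_size: int | None = None,
) -> list[GapCall]:
    """Drop gaps whose query context lies within ``proximity`` of an N-run.

    The query context is extended by ``proximity`` bases on both sides
    (clamped to the sequence) and the gap is dropped iff the extension
    intersects any N-run.  Distances are measured from the context's edges,
    in query plus-strand coordinates.
    """
    kept = []
    for gap in gaps:
        s, e = gap.q_context
        # inclusive distance: an N-run exactly `proximity` bases from the
        # context edge still drops the gap, hence the +1 under half-open
        # overlap semantics
        lo = max(0, s - config.proximity - 1)
        hi = e + config.proximity + 1 if q_size is None \
            else min(q_size, e + config.proximity + 1)
        if hi > lo and query_n_runs.overlaps_interval(lo, hi):
            continue
        kept.append(gap)
    return kept


def species_gap_set(
    chains_for_species: Sequence[Chain],
    query_n_runs: IntervalSet | dict[str, IntervalSet],
    config: GapCallerConfig = GapCallerConfig(),
    chrom: str | None = None,
) -> IntervalSet:
    """Reference-coordinate gap set for one species on one chromosome.

    Per chain: raw gaps -> assembly-gap masking -> merge within
    ``merge_distance``; then union across chains.  Merging is per chain, so
    gaps on different chains never merge even when closer than the radius.
    ``query_n_runs`` may be a dict keyed by query sequence name.
    """
    if chrom is None:
        if not chains_for_species:
            raise ValueError("need chrom when no chains are given")
        chrom = chains_for_species[0].t_name
    result = IntervalSet(chrom)
    for chain in chains_for_species:
        if chain.t_name != chrom:
            continue
        n_runs = query_n_runs.get(chain.q_name, IntervalSet(chain.q_name)) \
            if isinstance(query_n_runs, dict) else query_n_runs
        kept = mask_by_assembly_gaps(raw_gaps(chain), n_runs, config,
                                     q_size=chain.q_size)
        if not kept:
            continue
        per_chain = IntervalSet(
            chrom,
            [g.interval.start for g in kept],
            [g.interval.end for g in kept],
        ).merge_within(config.merge_distance)
        result = result.union(per_chain)
    return result
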