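"""The gene-centric genotype-phenotype scan producing CONDEL candidates.

For every reference gene mapped confidently to enough outgroup and target
species, a window of 200 kb on each side of the canonical-isoform TSS
(400,001 bp unclipped) is scanned for bases that are

* deleted (covered by a valid chain gap) in at least two thirds of the
  mapped members of *every* screened target clade, and
* covered by conserved elements of at least 17 outgroup species
  (the reference assembly itself never counts).

Intersections of the two masks spanning at least 20 bp are raw candidates;
those are merged within 20 bp and kept when at least 50 bp long and showing
a gap in at most one *scorable* outgroup (an outgroup whose orthologous
chain's reference span fully contains the candidate — an outgroup whose
chain does not span it can neither support nor violate).  A candidate can
be called by several genes; overlapping per-gene records are unified and
each record is classified as coding-exon, genic non-coding, or intergenic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .chain import Chain
from .genes import GeneModel
from .intervals import Interval, IntervalSet, coverage_threshold
from .orthology import OrthologyCall
from .phenotypes import PhenotypeMatrix

__all__ = ["ScreenConfig", "CondelCandidate", "clade_quorum", "scan_gene",
           "merge_candidates_across_genes", "annotate_context"]


@dataclass(frozen=True)
class ScreenConfig:
    min_outgroup_mappings: int = 17
    min_target_mappings: int = 5
    flank: int = 200_000
    clade_fraction: float = 2.0 / 3.0
    min_conserved_support: int = 17
    min_intersection: int = 20
    merge_distance: int = 20
    min_candidate: int = 50
    max_outgroup_violations: int = 1
    screened_clades: tuple[str, ...] | None = None  # None = clades with >= 2

    def __post_init__(self) -> None:
        if not (0 < self.clade_fraction <= 1):
            raise ValueError("clade_fraction must be in (0, 1]")
        for name in ("min_outgroup_mappings", "min_target_mappings", "flank",
                     "min_conserved_support", "min_intersection",
                     "merge_distance", "min_candidate",
                     "max_outgroup_violations"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class CondelCandidate:
    interval: Interval
    linked_genes: tuple[str, ...]
    target_support: dict[str, int]          # screened clade -> species count
    target_species: tuple[str, ...]         # gap-bearing targets (all clades)
    outgroup_conserved_support: int         # min per-base support count
    outgroup_violations: int
    violating_species: tuple[str, ...]
    context: str = ""                       # set by annotate_context


def clade_quorum(clade_size: int, clade_fraction: float = 2.0 / 3.0) -> int:
    """Species required for a per-base deletion quorum: ceil(f * size)."""
    if clade_size < 1:
        raise ValueError("clade_size must be >= 1")
    return math.ceil(clade_fraction * clade_size)


def scan_window(tss: int, flank: int, chrom_length: int | None = None
                ) -> tuple[int, int]:
    """Scan window around a TSS: ``[tss - flank, tss + flank + 1)``.

    The +1 includes the TSS base itself symmetrically (flank bases each
    side plus the TSS: 400,001 bp at the default 200 kb flank), clipped to
    the chromosome.
    """
    lo = max(0, tss - flank)
    hi = tss + flank + 1
    if chrom_length is not None:
        hi = min(hi, chrom_length)
    return lo, hi


def scan_gene(
    gene: GeneModel,
    orthology_calls: Mapping[str, OrthologyCall],
    chains_by_id: Mapping[str, Mapping[int, Chain]],
    gap_sets: Mapping[str, IntervalSet],
    conserved_sets: Mapping[str, IntervalSet],
    phenotypes: PhenotypeMatrix,
    config: ScreenConfig = ScreenConfig(),
    chrom_length: int | None = None,
) -> list[CondelCandidate]:
    """Scan one gene's TSS window; returns candidates (possibly empty).

    ``orthology_calls``: species -> accepted call for *this* gene.
    ``chains_by_id``: species -> chain_id -> Chain (for scorability).
    ``gap_sets`` / ``conserved_sets``: species -> genome-wide sets on the
    gene's chromosome.
    """
    chrom = gene.chrom
    mapped_outgroups = [sp for sp in phenotypes.outgroups
                        if sp in orthology_calls]
    mapped_targets = [sp for sp in phenotypes.targets
                      if sp in orthology_calls]
    if len(mapped_outgroups) < config.min_outgroup_mappings:
        return []
    if len(mapped_targets) < config.min_target_mappings:
        return []

    w_lo, w_hi = scan_window(gene.tss, config.flank, chrom_length)

    screened = (config.screened_clades
                if config.screened_clades is not None
                else phenotypes.screened_clades())
    if not screened:
        return []

    # per-base deletion quorum in EVERY screened clade
    clade_masks: list[IntervalSet] = []
    quorums: dict[str, int] = {}
    for clade in screened:
        members = [sp for sp in phenotypes.clade_members(clade)
                   if sp in orthology_calls]
        if not members:
            return []
        q = clade_quorum(len(members), config.clade_fraction)
        quorums[clade] = q
        member_gaps = [gap_sets.get(sp, IntervalSet(chrom)).clip(w_lo, w_hi)
                       for sp in members]
        clade_masks.append(coverage_threshold(member_gaps, q, chrom=chrom))
    target_mask = clade_masks[0]
    for m in clade_masks[1:]:
        target_mask = target_mask.intersect(m)
    if target_mask.is_empty():
        return []

    # conserved in >= min_conserved_support outgroups (reference excluded)
    outgroup_cons = [
        conserved_sets.get(sp, IntervalSet(chrom)).clip(w_lo, w_hi)
        for sp in phenotypes.outgroups]
    conserved_mask = coverage_threshold(
        outgroup_cons, config.min_conserved_support, chrom=chrom)
    if conserved_mask.is_empty():
        return []

    raw = target_mask.intersect(conserved_mask)
    lengths = raw.ends - raw.starts
    raw = IntervalSet(chrom, raw.starts[lengths >= config.min_intersection],
                      raw.ends[lengths >= config.min_intersection],
                      _normalized=True)
    merged = raw.merge_within(config.merge_distance)

    candidates: list[CondelCandidate] = []
    for iv in merged:
        if len(iv) < config.min_candidate:
            continue
        violators = []
        for sp in mapped_outgroups:
            call = orthology_calls[sp]
            chain = chains_by_id[sp][call.chain_id]
            scorable = (chain.t_name == chrom
                        and chain.t_start <= iv.start
                        and chain.t_end >= iv.end)
            if not scorable:
                continue
            if gap_sets.get(sp, IntervalSet(chrom)).overlaps_interval(
                    iv.start, iv.end):
                violators.append(sp)
        if len(violators) > config.max_outgroup_violations:
            continue
        # support is reported over the bases that passed the conserved
        # mask (merging may bridge sub-threshold gaps <= merge_distance)
        support = _min_cover_count(outgroup_cons,
                                   raw.clip(iv.start, iv.end))
        clade_support = {
            clade: _species_with_gap(
                [sp for sp in phenotypes.clade_members(clade)
                 if sp in orthology_calls], gap_sets, iv)
            for clade in screened}
        gap_targets = tuple(
            sp for sp in mapped_targets
            if gap_sets.get(sp, IntervalSet(chrom)).overlaps_interval(
                iv.start, iv.end))
        candidates.append(CondelCandidate(
            interval=iv,
            linked_genes=(gene.gene_id,),
            target_support={c: len(s) for c, s in clade_support.items()},
            target_species=gap_targets,
            outgroup_conserved_support=support,
            outgroup_violations=len(violators),
            violating_species=tuple(violators),
        ))
    return candidates


def _species_with_gap(species: Sequence[str],
                      gap_sets: Mapping[str, IntervalSet],
                      iv: Interval) -> list[str]:
    return [sp for sp in species
            if sp in gap_sets
            and gap_sets[sp].overlaps_interval(iv.start, iv.end)]


def _min_cover_count(sets: Sequence[IntervalSet],
                     region: IntervalSet) -> int:
    """Minimum per-base cover count of ``sets`` over ``region``."""
    if region.is_empty():
        return 0
    n = len(sets)
    # binary search the largest k covering all of region at threshold k
    lo, hi = 0, n
    while lo < hi:
        mid = (lo + hi + 1) // 2
        cover = coverage_threshold(sets, mid, chrom=region.chrom)
        if all(cover.contains_interval(s, e)
               for s, e in zip(region.starts.tolist(),
                               region.ends.tolist())):
            lo = mid
        else:
            hi = mid - 1
    return lo


def merge_candidates_across_genes(
    per_gene_candidates: Sequence[CondelCandidate],
) -> list[CondelCandidate]:
    """Unify overlapping per-gene records into unique CONDELs.

    Records overlapping by >= 1 base merge into one whose interval is the
    union span and whose linked genes are the union; supports take the
    minimum and violations the maximum over members (identical in practice
    since all per-gene masks derive from the same genome-wide sets).
    """
    by_chrom: dict[str, list[CondelCandidate]] = {}
    for c in per_gene_candidates:
        by_chrom.setdefault(c.interval.chrom, []).append(c)
    out: list[CondelCandidate] = []
    for chrom in sorted(by_chrom):
        cands = sorted(by_chrom[chrom], key=lambda c: (c.interval.start,
                                                       c.interval.end))
        group: list[CondelCandidate] = []
        group_end = -1
        for c in cands:
            if group and c.interval.start >= group_end:
                out.append(_fuse(group))
                group = []
            group.append(c)
            group_end = max(group_end, c.interval.end)
        if group:
            out.append(_fuse(group))
    return out


def _fuse(group: list[CondelCandidate]) -> CondelCandidate:
    if len(group) == 1:
        return group[0]
    chrom = group[0].interval.chrom
    iv = Interval(chrom,
                  min(c.interval.start for c in group),
                  max(c.interval.end for c in group))
    genes = tuple(sorted({g for c in group for g in c.linked_genes}))
    clades = sorted({k for c in group for k in c.target_support})
    support = {k: min(c.target_support[k] for c in group
                      if k in c.target_support) for k in clades}
    violators = tuple(sorted({sp for c in group for sp in c.violating_species}))
    return CondelCandidate(
        interval=iv,
        linked_genes=genes,
        target_support=support,
        target_species=tuple(sorted({sp for c in group
                                     for sp in c.target_species})),
        outgroup_conserved_support=min(c.outgroup_conserved_support
                                       for c in group),
        outgroup_violations=max(c.outgroup_violations for c in group),
        violating_species=violators,
    )


def annotate_context(candidate: CondelCandidate,
                     gene_models: Sequence[GeneModel]) -> str:
    """Classify a candidate: coding-exon > genic-noncoding > intergenic."""
    iv = candidate.interval
    in_span = False
    for g in gene_models:
        if g.chrom != iv.chrom:
            continue
        for t in g.transcripts:
            if t.span.start < iv.end and iv.start < t.span.end:
                in_span = True
                if t.exons.overlaps_interval(iv.start, iv.end):
                    return "coding-exon"
    return "genic-noncoding" if in_span else "intergenic"
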