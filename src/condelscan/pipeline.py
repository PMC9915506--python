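"""End-to-end screen: orthology -> gap calling -> conservation -> scan.

Consumes the on-disk bundle formats (reference FASTA, BED12 gene models,
per-species chain files and query FASTAs, phenotype TSV) and produces the
unique CONDEL candidate table.  Every stage is the public function of its
module; this file only routes data between them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO

from .chain import Chain, parse_chain_file
from .conservation import (ConservationConfig, WindowSet,
                           select_conserved_elements, window_identity)
from .gaps import GapCallerConfig, species_gap_set
from .genes import GeneModel, read_gene_models
from .intervals import IntervalSet, find_assembly_gaps
from .orthology import OrthologyCall, map_gene_to_chain
from .phenotypes import PhenotypeMatrix, read_phenotypes
from .screen import (CondelCandidate, ScreenConfig, annotate_context,
                     merge_candidates_across_genes, scan_gene)

__all__ = ["ScreenInputs", "ScreenState", "ScreenResult", "load_inputs",
           "prepare_screen_state", "run_scan", "run_screen",
           "candidates_to_frame"]


@dataclass
class ScreenInputs:
    reference: dict[str, str]                 # chrom -> sequence
    genes: list[GeneModel]
    phenotypes: PhenotypeMatrix
    chains: dict[str, list[Chain]]            # species -> chains
    query_seqs: dict[str, dict[str, str]]     # species -> scaffold -> seq


@dataclass
class ScreenState:
    """Threshold-independent intermediates: orthology calls, gap sets and
    conserved elements.  Lets the scan stage re-run cheaply under
    different :class:`ScreenConfig` settings."""

    accepted: dict[str, dict[str, OrthologyCall]]
    chains_by_id: dict[str, dict[int, Chain]]
    gap_sets: dict[str, dict[str, IntervalSet]]
    conserved_sets: dict[str, dict[str, IntervalSet]]
    orthology: pd.DataFrame
    chrom_lengths: dict[str, int]


@dataclass
class ScreenResult:
    candidates: list[CondelCandidate]
    orthology: pd.DataFrame
    gap_sets: dict[str, dict[str, IntervalSet]]
    conserved_sets: dict[str, dict[str, IntervalSet]]
    eligible_genes: list[str]

    def to_frame(self) -> pd.DataFrame:
        return candidates_to_frame(self.candidates)


def _read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq)
            for rec in SeqIO.parse(str(path), "fasta")}


def load_inputs(bundle_dir) -> ScreenInputs:
    """Load a study bundle directory laid out like the simulator's output."""
    root = Path(bundle_dir)
    phenotypes = read_phenotypes(root / "phenotypes.tsv")
    chains: dict[str, list[Chain]] = {}
    query_seqs: dict[str, dict[str, str]] = {}
    for sp in (*phenotypes.outgroups, *phenotypes.targets):
        chains[sp] = parse_chain_file(root / "species" / f"{sp}.chain")
        query_seqs[sp] = _read_fasta(root / "species" / f"{sp}.fa")
    return ScreenInputs(
        reference=_read_fasta(root / "reference.fa"),
        genes=read_gene_models(root / "genes.bed"),
        phenotypes=phenotypes,
        chains=chains,
        query_seqs=query_seqs,
    )


def prepare_screen_state(
    inputs: ScreenInputs,
    conservation_config: ConservationConfig = ConservationConfig(),
    gap_config: GapCallerConfig = GapCallerConfig(),
    orthology_ratio_threshold: float = 10.0,
    orthology_synteny_threshold: float = 10.0,
) -> ScreenState:
    phen = inputs.phenotypes
    chrom_lengths = {c: len(s) for c, s in inputs.reference.items()}

    # ---- orthology: one accepted chain per (species, gene) ---------------
    accepted: dict[str, dict[str, OrthologyCall]] = {}
    chains_by_id: dict[str, dict[int, Chain]] = {}
    ortho_rows = []
    for sp in (*phen.outgroups, *phen.targets):
        sp_chains = inputs.chains[sp]
        chains_by_id[sp] = {c.chain_id: c for c in sp_chains}
        accepted[sp] = {}
        for gene in inputs.genes:
            call = map_gene_to_chain(
                gene, sp_chains, species_id=sp,
                ratio_threshold=0.0, synteny_threshold=0.0)
            if call is None:
                continue
            ok = (call.ratio_second >= orthology_ratio_threshold
                  and call.ratio_synteny >= orthology_synteny_threshold)
            if ok:
                accepted[sp][gene.gene_id] = call
            ortho_rows.append({
                "species_id": sp, "gene_id": gene.gene_id,
                "chain_id": call.chain_id,
                "in_gene_aligned": call.in_gene_aligned,
                "second_in_gene_aligned": call.second_in_gene_aligned,
                "total_aligned": call.total_aligned,
                "ratio_second": call.ratio_second,
                "ratio_synteny": call.ratio_synteny,
                "accepted": ok,
            })
    orthology = pd.DataFrame(ortho_rows)

    # ---- per-species accepted chains, N-runs, gap sets -------------------
    gap_sets: dict[str, dict[str, IntervalSet]] = {}
    accepted_chains: dict[str, list[Chain]] = {}
    for sp in (*phen.outgroups, *phen.targets):
        ids = sorted({call.chain_id for call in accepted[sp].values()})
        sp_accepted = [chains_by_id[sp][i] for i in ids]
        accepted_chains[sp] = sp_accepted
        n_runs = {
            name: find_assembly_gaps(seq, gap_config.assembly_gap_min_run,
                                     chrom=name)
            for name, seq in inputs.query_seqs[sp].items()}
        gap_sets[sp] = {
            chrom: species_gap_set(
                [c for c in sp_accepted if c.t_name == chrom],
                n_runs, gap_config, chrom=chrom)
            for chrom in chrom_lengths}

    # ---- per-outgroup conserved elements ---------------------------------
    non_n_total = sum(
        len(s) - s.upper().count("N") for s in inputs.reference.values())
    conserved_sets: dict[str, dict[str, IntervalSet]] = {}
    for sp in phen.outgroups:
        per_chrom: dict[str, list[WindowSet]] = {c: []
                                                 for c in chrom_lengths}
        for chain in accepted_chains[sp]:
            ws = window_identity(
                chain, inputs.reference[chain.t_name],
                inputs.query_seqs[sp][chain.q_name], conservation_config)
            per_chrom[chain.t_name].append(ws)
        pooled = {c: WindowSet.concat(c, parts)
                  for c, parts in per_chrom.items()}
        # the quota ranks one species-wide pool; per-chrom selection uses
        # the species-wide identity threshold
        all_ws = list(pooled.values())
        flat = WindowSet.concat("__pool__", all_ws) if len(all_ws) > 1 \
            else all_ws[0]
        conserved_sets[sp] = _select_per_chrom(
            pooled, flat, non_n_total, conservation_config)

    return ScreenState(accepted=accepted, chains_by_id=chains_by_id,
                       gap_sets=gap_sets, conserved_sets=conserved_sets,
                       orthology=orthology, chrom_lengths=chrom_lengths)


def run_scan(
    inputs: ScreenInputs,
    state: ScreenState,
    screen_config: ScreenConfig = ScreenConfig(),
) -> ScreenResult:
    """The gene-centric scan over precomputed gap/conservation state."""
    phen = inputs.phenotypes
    per_gene: list[CondelCandidate] = []
    eligible: list[str] = []
    for gene in inputs.genes:
        calls = {sp: state.accepted[sp][gene.gene_id]
                 for sp in state.accepted
                 if gene.gene_id in state.accepted[sp]}
        sp_gaps = {sp: state.gap_sets[sp][gene.chrom]
                   for sp in state.gap_sets}
        sp_cons = {sp: state.conserved_sets[sp][gene.chrom]
                   for sp in state.conserved_sets}
        found = scan_gene(gene, calls, state.chains_by_id, sp_gaps,
                          sp_cons, phen, screen_config,
                          chrom_length=state.chrom_lengths[gene.chrom])
        n_out = sum(1 for sp in phen.outgroups if sp in calls)
        n_tgt = sum(1 for sp in phen.targets if sp in calls)
        if (n_out >= screen_config.min_outgroup_mappings
                and n_tgt >= screen_config.min_target_mappings):
            eligible.append(gene.gene_id)
        per_gene.extend(found)

    merged = merge_candidates_across_genes(per_gene)
    for cand in merged:
        cand.context = annotate_context(cand, inputs.genes)
    return ScreenResult(candidates=merged, orthology=state.orthology,
                        gap_sets=state.gap_sets,
                        conserved_sets=state.conserved_sets,
                        eligible_genes=eligible)


def run_screen(
    inputs: ScreenInputs,
    screen_config: ScreenConfig = ScreenConfig(),
    conservation_config: ConservationConfig = ConservationConfig(),
    gap_config: GapCallerConfig = GapCallerConfig(),
    orthology_ratio_threshold: float = 10.0,
    orthology_synteny_threshold: float = 10.0,
) -> ScreenResult:
    """Full pipeline: orthology -> gaps -> conservation -> scan."""
    state = prepare_screen_state(
        inputs, conservation_config, gap_config,
        orthology_ratio_threshold, orthology_synteny_threshold)
    return run_scan(inputs, state, screen_config)


def _select_per_chrom(pooled: dict[str, WindowSet], flat: WindowSet,
                      reference_total_bases: int,
                      config: ConservationConfig
                      ) -> dict[str, IntervalSet]:
    """Species-wide quota selection applied chromosome by chromosome.

    The identity threshold is determined on the pooled windows (the quota
    is a fraction of the whole reference); each chromosome then keeps its
    windows at or above that species-wide threshold.
    """
    import numpy as np

    from .conservation import _coverage_mask, _mask_to_set

    if len(flat) == 0:
        return {c: IntervalSet(c) for c in pooled}
    quota = config.coverage_fraction * reference_total_bases
    levels = np.unique(flat.identities)

    def coverage_at(theta: float) -> int:
        total = 0
        for chrom, ws in pooled.items():
            if len(ws) == 0:
                continue
            length = int(np.max(ws.starts + ws.sizes))
            total += int(_coverage_mask(ws, theta, length).sum())
        return total

    if coverage_at(levels[0]) < quota:
        theta = float(levels[0])
    else:
        lo, hi = 0, levels.size - 1
        while lo < hi:
            mid = (lo + hi + 1) // 2
            if coverage_at(levels[mid]) >= quota:
                lo = mid
            else:
                hi = mid - 1
        theta = float(levels[lo])
    out: dict[str, IntervalSet] = {}
    for chrom, ws in pooled.items():
        if len(ws) == 0:
            out[chrom] = IntervalSet(chrom)
            continue
        length = int(np.max(ws.starts + ws.sizes))
        mask = _coverage_mask(ws, theta, length)
        out[chrom] = _mask_to_set(mask, chrom).merge_within(
            config.merge_distance)
    return out


def candidates_to_frame(candidates: list[CondelCandidate]) -> pd.DataFrame:
    rows = []
    for i, c in enumerate(candidates, start=1):
        rows.append({
            "condel_id": f"CONDEL.{i}",
            "chrom": c.interval.chrom,
            "start": c.interval.start,
            "end": c.interval.end,
            "length": len(c.interval),
            "linked_genes": ",".join(c.linked_genes),
            "target_support": ";".join(
                f"{k}={v}" for k, v in sorted(c.target_support.items())),
            "target_species": ",".join(c.target_species),
            "conserved_support": c.outgroup_conserved_support,
            "violations": c.outgroup_violations,
            "violating_species": ",".join(c.violating_species),
            "context": c.context,
        })
    cols = ["condel_id", "chrom", "start", "end", "length", "linked_genes",
            "target_support", "target_species", "conserved_support",
            "violations", "violating_species", "context"]
    return pd.DataFrame(rows, columns=cols)
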