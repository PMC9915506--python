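"""Synthetic miniature study generator with a known truth set.

Emulates the input of a multi-species deletion screen — a reference genome
with gene models, one edited genome per species, pairwise alignment chains,
and a phenotype table — entirely from a known per-species edit script, so
every downstream stage can be validated against engineered truth.

Per species the edit script contains: point substitutions at a role-specific
rate, deletions at truth intervals for quorum-satisfying subsets of the
target clades (with outward per-species breakpoint jitter), decoy edits per
decoy class, background indels, and injected assembly-gap N-runs.  Chains
are derived analytically from the script (no aligner): a deletion of L
reference bases yields a separator with ``dt = L`` and ``dq = 0``
(single-sided) or ``dq > 0`` when a query insertion is co-placed
(double-sided).  An identical seed yields a byte-identical bundle.

Decoy classes, each violating exactly one screen criterion:

* ``decoy_single_clade`` — deletion quorum in only one screened clade;
* ``decoy_low_conservation`` — deleted in both clades but hyper-diverged
  in every outgroup, so the interval is not conserved;
* ``decoy_assembly_gap`` — deleted in both clades, but every deleting
  species carries an N-run next to the breakpoint, so the gaps are masked
  as assembly artifacts;
* ``decoy_outgroup_violation`` — deleted in both clades and in two
  outgroups, exceeding the one-violation allowance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .chain import Chain, write_chain_file
from .genes import GeneModel, Transcript, write_bed12_text
from .intervals import Interval, IntervalSet
from .phenotypes import PhenotypeMatrix, write_phenotypes_text
from .screen import CondelCandidate, clade_quorum

__all__ = ["SimulationConfig", "TruthRecord", "StudyBundle",
           "simulate_study", "evaluate_recovery", "GenerationError"]

TRUE_CONDEL = "true_condel"
DECOY_CLASSES = ("decoy_single_clade", "decoy_low_conservation",
                 "decoy_assembly_gap", "decoy_outgroup_violation")

_COMPLEMENT = bytes.maketrans(b"ACGTN", b"TGCAN")
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class GenerationError(RuntimeError):
    """Raised when interval placement cannot satisfy its constraints."""


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    reference_length: int = 1_000_000
    n_genes: int = 40
    n_outgroups: int = 20
    target_clades: tuple[int, ...] = (4, 3)
    extra_single_targets: int = 2
    outgroup_substitution_rate: float = 0.02
    target_substitution_rate: float = 0.05
    n_true_condels: int = 8
    true_condel_length: tuple[int, int] = (60, 300)
    n_decoys: int = 4                  # per decoy class
    n_run_injections: int = 4          # benign N-runs away from any gap
    breakpoint_jitter: int = 30        # outward extension per side, truths
    background_indels: int = 12        # neutral indels per species
    double_sided_fraction: float = 0.3  # truth deletions with co-insertion
    min_truth_separation: int = 1000
    n_chromosomes: int = 1

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1:
            raise ValueError("need at least one chromosome")
        if self.true_condel_length[0] > self.true_condel_length[1]:
            raise ValueError("bad true_condel_length range")
        if self.breakpoint_jitter < 0:
            raise ValueError("breakpoint_jitter must be >= 0")


@dataclass(frozen=True)
class TruthRecord:
    interval: Interval
    truth_class: str
    expected_detected: bool
    name: str


@dataclass
class StudyBundle:
    """File paths plus in-memory copies of everything the screen consumes."""

    root: Path
    config: SimulationConfig
    reference: dict[str, bytes]
    genes: list[GeneModel]
    phenotypes: PhenotypeMatrix
    chains: dict[str, list[Chain]]          # species -> chains
    query_fastas: dict[str, Path]
    truth: list[TruthRecord]

    @property
    def reference_fasta(self) -> Path:
        return self.root / "reference.fa"

    @property
    def genes_bed(self) -> Path:
        return self.root / "genes.bed"

    @property
    def phenotypes_tsv(self) -> Path:
        return self.root / "phenotypes.tsv"


# --------------------------------------------------------------------------
# events
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class _Event:
    """One edit on one chromosome: deletion [ref_start, ref_end) plus an
    optional insertion of ins_len query bases at the breakpoint."""

    chrom: str
    ref_start: int
    ref_end: int
    ins_len: int

    @property
    def is_indel(self) -> bool:
        return self.ref_end > self.ref_start or self.ins_len > 0


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _place_intervals(
    rng: np.random.Generator,
    n: int,
    lengths: Sequence[int],
    chrom_lengths: dict[str, int],
    forbidden: dict[str, IntervalSet],
    near_tss: dict[str, np.ndarray],
    flank: int,
    separation: int,
    what: str,
    max_tries: int = 2000,
) -> list[Interval]:
    """Place n intervals respecting exon avoidance, TSS proximity and
    pairwise separation."""
    placed: list[Interval] = []
    chroms = sorted(chrom_lengths)
    for i in range(n):
        length = int(lengths[i])
        for _ in range(max_tries):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            climit = chrom_lengths[chrom] - length - separation
            if climit <= separation:
                continue
            start = int(rng.integers(separation, climit))
            end = start + length
            tss = near_tss[chrom]
            if tss.size == 0 or not np.any(
                    np.abs(tss - start) < flank - length):
                continue
            if forbidden[chrom].overlaps_interval(start - separation,
                                                  end + separation):
                continue
            if any(p.chrom == chrom
                   and p.start - separation < end
                   and start < p.end + separation for p in placed):
                continue
            placed.append(Interval(chrom, start, end))
            break
        else:
            raise GenerationError(
                f"could not place {what} interval {i}: constraints "
                "(TSS proximity / exon avoidance / separation) unsatisfiable")
    return placed


# --------------------------------------------------------------------------
# main generator
# --------------------------------------------------------------------------

def simulate_study(config: SimulationConfig, out_dir) -> StudyBundle:
    """Generate the full study bundle under ``out_dir``."""
    rng = np.random.default_rng(config.seed)
    root = Path(out_dir)
    (root / "species").mkdir(parents=True, exist_ok=True)

    # --- reference genome -------------------------------------------------
    per_chrom = config.reference_length // config.n_chromosomes
    chrom_lengths = {f"chr{i+1}": per_chrom
                     for i in range(config.n_chromosomes)}
    reference = {c: _random_seq(rng, ln)
                 for c, ln in chrom_lengths.items()}

    # --- gene models ------------------------------------------------------
    genes = _make_genes(rng, config, chrom_lengths)
    exon_sets = {c: IntervalSet(c) for c in chrom_lengths}
    for g in genes:
        exon_sets[g.chrom] = exon_sets[g.chrom].union(g.exon_set())
    tss_by_chrom = {
        c: np.array(sorted(g.tss for g in genes if g.chrom == c),
                    dtype=np.int64)
        for c in chrom_lengths}

    # --- truth and decoy intervals ----------------------------------------
    n_sites = config.n_true_condels + config.n_decoys * len(DECOY_CLASSES)
    lo, hi = config.true_condel_length
    lengths = rng.integers(lo, hi + 1, size=n_sites)
    sites = _place_intervals(
        rng, n_sites, lengths, chrom_lengths, exon_sets, tss_by_chrom,
        flank=200_000, separation=config.min_truth_separation,
        what="truth/decoy")
    truth: list[TruthRecord] = []
    classes = ([TRUE_CONDEL] * config.n_true_condels
               + [cls for cls in DECOY_CLASSES
                  for _ in range(config.n_decoys)])
    counters: dict[str, int] = {}
    for iv, cls in zip(sites, classes):
        counters[cls] = counters.get(cls, 0) + 1
        truth.append(TruthRecord(iv, cls, cls == TRUE_CONDEL,
                                 f"{cls}.{counters[cls]}"))

    # --- species roster ---------------------------------------------------
    outgroups = tuple(f"og{i+1:02d}" for i in range(config.n_outgroups))
    clade_names = tuple(chr(ord("A") + i)
                        for i in range(len(config.target_clades)))
    clade_members = {
        name: tuple(f"tg{name}{j+1}" for j in range(size))
        for name, size in zip(clade_names, config.target_clades)}
    singles = tuple(f"sg{i+1}" for i in range(config.extra_single_targets))
    targets = tuple(sp for name in clade_names
                    for sp in clade_members[name]) + singles
    clade_of = {sp: name for name in clade_names
                for sp in clade_members[name]}
    clade_of.update({sp: f"single{i+1}" for i, sp in enumerate(singles)})
    phenotypes = PhenotypeMatrix("ref", outgroups, targets, clade_of)

    # --- deletion assignments (drawn in fixed truth order) ----------------
    deleters: dict[str, list[TruthRecord]] = {sp: [] for sp in
                                              outgroups + targets}
    nrun_beside: dict[str, list[TruthRecord]] = {sp: [] for sp in targets}
    for rec in truth:
        cls = rec.truth_class
        if cls == "decoy_single_clade":
            active = [clade_names[0]] if len(clade_names) else []
        else:
            active = list(clade_names)
        for name in active:
            members = clade_members[name]
            q = clade_quorum(len(members))
            k = int(rng.integers(q, len(members) + 1))
            chosen = rng.choice(len(members), size=k, replace=False)
            for j in sorted(chosen.tolist()):
                deleters[members[j]].append(rec)
                if cls == "decoy_assembly_gap":
                    nrun_beside[members[j]].append(rec)
        if cls == TRUE_CONDEL:
            for sp in singles:
                if rng.random() < 0.5:
                    deleters[sp].append(rec)
        if cls == "decoy_outgroup_violation":
            n_viol = 2  # one more than the default violation allowance
            chosen = rng.choice(len(outgroups), size=n_viol, replace=False)
            for j in sorted(chosen.tolist()):
                deleters[outgroups[j]].append(rec)

    low_cons = [rec.interval for rec in truth
                if rec.truth_class == "decoy_low_conservation"]

    # --- per-species genomes and chains -----------------------------------
    chains: dict[str, list[Chain]] = {}
    query_fastas: dict[str, Path] = {}
    species_order = list(outgroups + targets)
    for idx, sp in enumerate(species_order):
        role = "outgroup" if sp in outgroups else "target"
        rate = (config.outgroup_substitution_rate if role == "outgroup"
                else config.target_substitution_rate)
        minus = idx % 5 == 3  # a deterministic sprinkling of '-' assemblies
        sp_chains, q_records = _build_species(
            rng, config, sp, idx, role, rate, minus, reference,
            chrom_lengths, deleters[sp],
            nrun_beside.get(sp, []), low_cons,
            avoid=[rec.interval for rec in truth])
        chains[sp] = sp_chains
        fasta_path = root / "species" / f"{sp}.fa"
        _write_fasta(fasta_path, q_records)
        write_chain_file(root / "species" / f"{sp}.chain", sp_chains)
        query_fastas[sp] = fasta_path

    # --- emit shared files -------------------------------------------------
    _write_fasta(root / "reference.fa",
                 [(c, reference[c].tobytes()) for c in sorted(reference)])
    (root / "genes.bed").write_text(write_bed12_text(genes))
    (root / "phenotypes.tsv").write_text(write_phenotypes_text(phenotypes))
    _write_truth_bed(root / "truth.bed", truth)
    _write_manifest(root, config)

    return StudyBundle(root=root, config=config, reference=
                       {c: reference[c].tobytes() for c in reference},
                       genes=genes, phenotypes=phenotypes, chains=chains,
                       query_fastas=query_fastas, truth=truth)


def _make_genes(rng: np.random.Generator, config: SimulationConfig,
                chrom_lengths: dict[str, int]) -> list[GeneModel]:
    genes: list[GeneModel] = []
    chroms = sorted(chrom_lengths)
    per = [config.n_genes // len(chroms)] * len(chroms)
    for i in range(config.n_genes - sum(per)):
        per[i] += 1
    gid = 0
    for chrom, n_chrom in zip(chroms, per):
        if n_chrom == 0:
            continue
        slot = chrom_lengths[chrom] // n_chrom
        for j in range(n_chrom):
            gid += 1
            span_len = int(rng.integers(3000, min(8000, slot - 200)))
            start = j * slot + int(rng.integers(100,
                                                slot - span_len - 100))
            end = start + span_len
            strand = "+" if rng.random() < 0.5 else "-"
            gene_id = f"gene{gid:03d}"
            transcripts = [_make_transcript(rng, chrom, f"{gene_id}.t1",
                                            start, end)]
            if rng.random() < 0.4:  # a shorter second isoform
                sub = int(rng.integers(span_len // 2, span_len - 100))
                off = int(rng.integers(0, span_len - sub))
                transcripts.append(_make_transcript(
                    rng, chrom, f"{gene_id}.t2", start + off,
                    start + off + sub))
            genes.append(GeneModel(gene_id, chrom, strand,
                                   tuple(transcripts)))
    return genes


def _make_transcript(rng: np.random.Generator, chrom: str, tx_id: str,
                     start: int, end: int) -> Transcript:
    n_exons = int(rng.integers(2, 5))
    length = end - start
    cuts = np.sort(rng.choice(np.arange(1, length),
                              size=2 * n_exons - 2, replace=False))
    bounds = [0, *cuts.tolist(), length]
    exon_starts = [start + bounds[i] for i in range(0, len(bounds), 2)]
    exon_ends = [start + bounds[i + 1] for i in range(0, len(bounds), 2)]
    return Transcript(tx_id, Interval(chrom, start, end),
                      IntervalSet(chrom, exon_starts, exon_ends))


def _build_species(
    rng: np.random.Generator,
    config: SimulationConfig,
    sp: str,
    sp_index: int,
    role: str,
    sub_rate: float,
    minus: bool,
    reference: dict[str, np.ndarray],
    chrom_lengths: dict[str, int],
    deleted: list[TruthRecord],
    nrun_recs: list[TruthRecord],
    low_cons: list[Interval],
    avoid: list[Interval] = (),
) -> tuple[list[Chain], list[tuple[str, bytes]]]:
    """Edit script -> mutated query genome + analytically derived chains."""
    events: dict[str, list[_Event]] = {c: [] for c in chrom_lengths}
    nrun_events: dict[str, set[tuple[int, int]]] = {c: set()
                                                    for c in chrom_lengths}
    for rec in deleted:
        iv = rec.interval
        if rec.truth_class == TRUE_CONDEL and role == "target":
            pad_l = int(rng.integers(0, config.breakpoint_jitter + 1))
            pad_r = int(rng.integers(0, config.breakpoint_jitter + 1))
        else:
            pad_l = pad_r = 0
        ins = 0
        if (rec.truth_class == TRUE_CONDEL
                and rng.random() < config.double_sided_fraction):
            ins = int(rng.integers(1, 11))
        ev = _Event(iv.chrom, iv.start - pad_l, iv.end + pad_r, ins)
        events[iv.chrom].append(ev)
        if rec in nrun_recs:
            nrun_events[iv.chrom].add((ev.ref_start, ev.ref_end))

    # background indels, kept clear of truth/decoy neighborhoods
    chroms = sorted(chrom_lengths)
    clearance = 600
    for _ in range(config.background_indels):
        for _try in range(200):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            if rng.random() < 2 / 3:
                dlen, ilen = int(rng.integers(1, 41)), 0
            else:
                dlen, ilen = 0, int(rng.integers(1, 16))
            pos = int(rng.integers(clearance,
                                   chrom_lengths[chrom] - clearance - dlen))
            ok = all(pos - clearance >= e.ref_end
                     or pos + dlen + clearance <= e.ref_start
                     for e in events[chrom])
            # keep neutral indels clear of every truth/decoy site in every
            # species, so they can never fake or break a genotype call
            ok = ok and all(iv.chrom != chrom
                            or pos - clearance >= iv.end
                            or pos + dlen + clearance <= iv.start
                            for iv in avoid)
            if ok:
                events[chrom].append(_Event(chrom, pos, pos + dlen, ilen))
                break
    # (silently placing fewer than requested is impossible at default scale;
    # the retry bound only guards degenerate configs)

    chains: list[Chain] = []
    records: list[tuple[str, bytes]] = []
    for ci, chrom in enumerate(chroms):
        evs = sorted(events[chrom], key=lambda e: (e.ref_start, e.ref_end))
        ref = reference[chrom]
        ref_len = ref.size
        mutated = ref.copy()
        # point substitutions outside 5-base breakpoint buffers
        if sub_rate > 0:
            eligible = np.ones(ref_len, dtype=bool)
            for e in evs:
                eligible[max(0, e.ref_start - 5):e.ref_end + 5] = False
            hits = np.flatnonzero((rng.random(ref_len) < sub_rate)
                                  & eligible)
            if hits.size:
                mutated[hits] = _substitute(rng, mutated[hits])
        else:
            rng.random(ref_len)  # keep the draw order role-independent
        if role == "outgroup":
            for iv in low_cons:
                if iv.chrom != chrom:
                    continue
                dense = np.arange(iv.start + 2, iv.end, 5)
                mutated[dense] = _substitute(rng, mutated[dense])

        pieces: list[np.ndarray] = []
        blocks: list[tuple[int, int, int]] = []
        q_pos = 0
        prev = 0
        nrun_targets = []  # query positions to overwrite with N
        for e in evs:
            size = e.ref_start - prev
            pieces.append(mutated[prev:e.ref_start])
            q_pos += size
            dt = e.ref_end - e.ref_start
            dq = e.ins_len
            blocks.append((size, dt, dq))
            if (e.ref_start, e.ref_end) in nrun_events[chrom]:
                nrun_targets.append(q_pos + dq + 40)
            if dq:
                pieces.append(_random_seq(rng, dq))
                q_pos += dq
            prev = e.ref_end
        pieces.append(mutated[prev:ref_len])
        blocks.append((ref_len - prev, 0, 0))
        query = np.concatenate(pieces) if pieces else mutated

        # assembly-gap N-runs beside decoy deletions
        for qp in nrun_targets:
            query[qp:qp + 8] = ord("N")
        # benign N-runs far from any separator, target species only
        if role == "target":
            seps = [0, query.size]
            qp = 0
            for size, _dt, dq in blocks:
                qp += size
                seps.append(qp)
                qp += dq
            for k in range(config.n_run_injections):
                for _try in range(200):
                    pos = int(rng.integers(1000, query.size - 1000))
                    if all(abs(pos - s) > 1000 and abs(pos + 8 - s) > 1000
                           for s in seps):
                        query[pos:pos + 8] = ord("N")
                        break

        q_name = f"{sp}_scf{ci+1}"
        q_len = int(query.size)
        chain = Chain(
            score=1000 + sp_index,
            t_name=chrom, t_size=ref_len, t_strand="+",
            t_start=0, t_end=ref_len,
            q_name=q_name, q_size=q_len,
            q_strand="-" if minus else "+",
            q_start=0, q_end=q_len,
            chain_id=ci + 1,
            blocks=tuple(blocks),
        )
        chains.append(chain)
        emitted = query.tobytes()
        if minus:
            emitted = emitted.translate(_COMPLEMENT)[::-1]
        records.append((q_name, emitted))
    return chains, records


def _substitute(rng: np.random.Generator, bases: np.ndarray) -> np.ndarray:
    """Replace each base by a different one, uniformly over the other 3."""
    idx = np.searchsorted(_BASES, bases)  # _BASES sorted: A<C<G<T
    # _BASES is b"ACGT" which is already sorted by byte value
    shift = rng.integers(1, 4, size=bases.size)
    return _BASES[(idx + shift) % 4]


# --------------------------------------------------------------------------
# output files
# --------------------------------------------------------------------------

def _write_fasta(path: Path, records: list[tuple[str, bytes]],
                 width: int = 60) -> None:
    with open(path, "w", encoding="ascii") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width].decode("ascii"))
                fh.write("\n")


def _write_truth_bed(path: Path, truth: list[TruthRecord]) -> None:
    lines = []
    for rec in sorted(truth, key=lambda r: (r.interval.chrom,
                                            r.interval.start)):
        lines.append("\t".join(map(str, [
            rec.interval.chrom, rec.interval.start, rec.interval.end,
            rec.name, int(rec.expected_detected),
            rec.truth_class])))
    path.write_text("\n".join(lines) + "\n")


def read_truth_bed(path) -> list[TruthRecord]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        chrom, start, end, name, flag, cls = line.split("\t")
        out.append(TruthRecord(Interval(chrom, int(start), int(end)),
                               cls, bool(int(flag)), name))
    return out


def _write_manifest(root: Path, config: SimulationConfig) -> None:
    files = sorted(p for p in root.rglob("*")
                   if p.is_file() and p.name != "manifest.json")
    checksums = {
        str(p.relative_to(root)):
            hashlib.sha256(p.read_bytes()).hexdigest()
        for p in files}
    manifest = {"config": asdict(config), "checksums": checksums}
    (root / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")


# --------------------------------------------------------------------------
# truth-set evaluation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RecoveryReport:
    recall: float
    precision: float
    zero_candidates: bool
    table: pd.DataFrame


def evaluate_recovery(
    candidates: Sequence[CondelCandidate] | Sequence[Interval],
    truth: Sequence[TruthRecord],
    min_overlap_fraction: float = 0.5,
) -> RecoveryReport:
    """Recall over engineered true intervals; precision over candidates.

    A truth record is recovered when some candidate overlaps at least
    ``min_overlap_fraction`` of it.  With zero candidates precision is
    reported as 1.0 and flagged (``zero_candidates``).
    """
    cand_ivs = [c.interval if isinstance(c, CondelCandidate) else c
                for c in candidates]
    rows = []
    recovered = 0
    n_true = 0
    for rec in truth:
        iv = rec.interval
        best = 0
        for c in cand_ivs:
            if c.chrom != iv.chrom:
                continue
            ov = min(c.end, iv.end) - max(c.start, iv.start)
            best = max(best, ov)
        frac = best / len(iv)
        hit = frac >= min_overlap_fraction
        if rec.truth_class == TRUE_CONDEL:
            n_true += 1
            recovered += int(hit)
        rows.append({"name": rec.name, "class": rec.truth_class,
                     "chrom": iv.chrom, "start": iv.start, "end": iv.end,
                     "best_overlap_fraction": frac, "recovered": hit})
    tp = sum(
        1 for c in cand_ivs
        if any(rec.truth_class == TRUE_CONDEL
               and rec.interval.chrom == c.chrom
               and min(c.end, rec.interval.end)
               > max(c.start, rec.interval.start)
               for rec in truth))
    recall = recovered / n_true if n_true else 1.0
    precision = tp / len(cand_ivs) if cand_ivs else 1.0
    return RecoveryReport(recall=recall, precision=precision,
                          zero_candidates=not cand_ivs,
                          table=pd.DataFrame(rows))
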