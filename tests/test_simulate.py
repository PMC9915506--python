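"""Synthetic study generator: determinism, construction guarantees,
recovery metrics, decoy semantics."""

import hashlib
import json
from pathlib import Path

import pytest

from condelscan.chain import parse_chain_file
from condelscan.intervals import Interval
from condelscan.screen import clade_quorum
from condelscan.simulate import (DECOY_CLASSES, SimulationConfig,
                                 TruthRecord, evaluate_recovery,
                                 read_truth_bed, simulate_study)


def digest_dir(root: Path) -> dict[str, str]:
    return {str(p.relative_to(root)): hashlib.sha256(
        p.read_bytes()).hexdigest()
        for p in sorted(root.rglob("*")) if p.is_file()}


SMALL = SimulationConfig(seed=5, reference_length=120_000, n_genes=5,
                         n_true_condels=2, n_decoys=1,
                         background_indels=5, n_run_injections=1)


class TestDeterminism:
    def test_identical_seed_byte_identical_bundle(self, tmp_path):
        simulate_study(SMALL, tmp_path / "a")
        simulate_study(SMALL, tmp_path / "b")
        assert digest_dir(tmp_path / "a") == digest_dir(tmp_path / "b")

    def test_different_seed_differs(self, tmp_path):
        simulate_study(SMALL, tmp_path / "a")
        simulate_study(SimulationConfig(**{**SMALL.__dict__, "seed": 6}),
                       tmp_path / "b")
        assert digest_dir(tmp_path / "a") != digest_dir(tmp_path / "b")

    def test_manifest_checksums_match_files(self, tmp_path):
        simulate_study(SMALL, tmp_path)
        manifest = json.loads((tmp_path / "manifest.json").read_text())
        for rel, digest in manifest["checksums"].items():
            assert hashlib.sha256(
                (tmp_path / rel).read_bytes()).hexdigest() == digest


class TestConstruction:
    def test_zero_divergence_zero_deletion_single_block_chains(
            self, tmp_path):
        cfg = SimulationConfig(
            seed=1, reference_length=50_000, n_genes=3,
            outgroup_substitution_rate=0.0, target_substitution_rate=0.0,
            n_true_condels=0, n_decoys=0, background_indels=0,
            n_run_injections=0)
        bundle = simulate_study(cfg, tmp_path)
        for sp, chains in bundle.chains.items():
            for c in chains:
                assert c.blocks == ((50_000, 0, 0),)

    def test_chain_files_reparse_and_satisfy_invariants(self, tmp_path):
        bundle = simulate_study(SMALL, tmp_path)
        for sp in bundle.chains:
            reparsed = parse_chain_file(tmp_path / "species" / f"{sp}.chain")
            assert reparsed == bundle.chains[sp]

    def test_truth_intervals_separated_and_off_exon(self, tmp_path):
        bundle = simulate_study(SMALL, tmp_path)
        ivs = [r.interval for r in bundle.truth]
        for i, a in enumerate(ivs):
            for b in ivs[i + 1:]:
                if a.chrom == b.chrom:
                    gap = max(a.start, b.start) - min(a.end, b.end)
                    assert gap >= SMALL.min_truth_separation
        exons = {}
        for g in bundle.genes:
            exons.setdefault(g.chrom, []).append(g.exon_set())
        for r in bundle.truth:
            for es in exons.get(r.interval.chrom, []):
                assert not es.overlaps_interval(r.interval.start,
                                                r.interval.end)

    def test_truth_bed_round_trip(self, tmp_path):
        bundle = simulate_study(SMALL, tmp_path)
        loaded = read_truth_bed(tmp_path / "truth.bed")
        assert sorted(loaded, key=lambda r: r.name) == \
            sorted(bundle.truth, key=lambda r: r.name)

    def test_expected_detected_flag_follows_class(self, tmp_path):
        bundle = simulate_study(SMALL, tmp_path)
        for rec in bundle.truth:
            assert rec.expected_detected == (rec.truth_class ==
                                             "true_condel")
        classes = {r.truth_class for r in bundle.truth}
        assert classes == {"true_condel", *DECOY_CLASSES}

    def test_multi_chromosome_mode(self, tmp_path):
        cfg = SimulationConfig(seed=2, reference_length=200_000,
                               n_chromosomes=2, n_genes=6,
                               n_true_condels=2, n_decoys=0,
                               background_indels=3)
        bundle = simulate_study(cfg, tmp_path)
        assert set(bundle.reference) == {"chr1", "chr2"}
        chroms_used = {c.t_name for chains in bundle.chains.values()
                       for c in chains}
        assert chroms_used == {"chr1", "chr2"}

    def test_infeasible_placement_raises(self, tmp_path):
        cfg = SimulationConfig(seed=3, reference_length=30_000, n_genes=2,
                               n_true_condels=40)
        with pytest.raises(Exception, match="constraint"):
            simulate_study(cfg, tmp_path)


class TestDecoySemantics:
    """Each decoy class must be rejected by exactly the criterion it was
    built to violate (checked mechanistically on the small bundle)."""

    def test_single_clade_decoys_spare_the_second_clade(self,
                                                        small_prepared):
        bundle = small_prepared.bundle
        state = small_prepared.state
        phen = bundle.phenotypes
        clade_b = phen.clade_members("B")
        for rec in bundle.truth:
            if rec.truth_class != "decoy_single_clade":
                continue
            hit = [sp for sp in clade_b
                   if state.gap_sets[sp][rec.interval.chrom]
                   .overlaps_interval(rec.interval.start,
                                      rec.interval.end)]
            assert hit == []

    def test_assembly_gap_decoys_leave_no_gap_calls(self, small_prepared):
        bundle = small_prepared.bundle
        state = small_prepared.state
        for rec in bundle.truth:
            if rec.truth_class != "decoy_assembly_gap":
                continue
            for sp in bundle.phenotypes.targets:
                assert not state.gap_sets[sp][rec.interval.chrom] \
                    .overlaps_interval(rec.interval.start, rec.interval.end)

    def test_low_conservation_decoys_lack_conserved_support(
            self, small_prepared):
        bundle = small_prepared.bundle
        state = small_prepared.state
        for rec in bundle.truth:
            if rec.truth_class != "decoy_low_conservation":
                continue
            mid = (rec.interval.start + rec.interval.end) // 2
            support = sum(
                1 for sp in bundle.phenotypes.outgroups
                if state.conserved_sets[sp][rec.interval.chrom]
                .overlaps_interval(mid, mid + 1))
            assert support < 17

    def test_violation_decoys_gapped_in_two_outgroups(self,
                                                      small_prepared):
        bundle = small_prepared.bundle
        state = small_prepared.state
        for rec in bundle.truth:
            if rec.truth_class != "decoy_outgroup_violation":
                continue
            violators = [
                sp for sp in bundle.phenotypes.outgroups
                if state.gap_sets[sp][rec.interval.chrom]
                .overlaps_interval(rec.interval.start, rec.interval.end)]
            assert len(violators) == 2

    def test_true_condel_deleters_meet_quorum_per_clade(self,
                                                        small_prepared):
        bundle = small_prepared.bundle
        state = small_prepared.state
        phen = bundle.phenotypes
        for rec in bundle.truth:
            if rec.truth_class != "true_condel":
                continue
            for clade in phen.screened_clades():
                members = phen.clade_members(clade)
                n_gap = sum(
                    1 for sp in members
                    if state.gap_sets[sp][rec.interval.chrom]
                    .contains_interval(rec.interval.start,
                                       rec.interval.end))
                assert n_gap >= clade_quorum(len(members))


class TestEvaluateRecovery:
    def _truth(self):
        return [TruthRecord(Interval("chr1", 100, 200), "true_condel",
                            True, "t1"),
                TruthRecord(Interval("chr1", 1000, 1100),
                            "decoy_single_clade", False, "d1")]

    def test_identical_candidates_perfect_scores(self):
        rep = evaluate_recovery([Interval("chr1", 100, 200)], self._truth())
        assert rep.recall == 1.0 and rep.precision == 1.0

    def test_empty_candidates_flagged(self):
        rep = evaluate_recovery([], self._truth())
        assert rep.recall == 0.0
        assert rep.precision == 1.0
        assert rep.zero_candidates

    def test_forty_percent_overlap_not_recovered(self):
        rep = evaluate_recovery([Interval("chr1", 100, 140)], self._truth())
        assert rep.recall == 0.0
        row = rep.table.set_index("name").loc["t1"]
        assert row.best_overlap_fraction == pytest.approx(0.4)
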