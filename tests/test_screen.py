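"""Gene-centric scan on constructed fixtures with a per-base oracle."""

import pytest

from condelscan.chain import Chain
from condelscan.genes import GeneModel, Transcript
from condelscan.intervals import Interval, IntervalSet
from condelscan.orthology import OrthologyCall
from condelscan.phenotypes import PhenotypeMatrix
from condelscan.screen import (CondelCandidate, ScreenConfig,
                               annotate_context, clade_quorum,
                               merge_candidates_across_genes, scan_gene,
                               scan_window)

CHROM_LEN = 1_000_000


class TestQuorumAndWindow:
    @pytest.mark.parametrize("size,expected", [(4, 3), (3, 2), (1, 1),
                                               (6, 4), (9, 6)])
    def test_two_thirds_quorum(self, size, expected):
        assert clade_quorum(size) == expected

    def test_window_is_400001_bases_unclipped(self):
        lo, hi = scan_window(tss=500_000, flank=200_000)
        assert hi - lo == 400_001

    def test_window_clipped_at_chrom_edges(self):
        lo, hi = scan_window(tss=100, flank=200_000, chrom_length=300_000)
        assert (lo, hi) == (0, 200_101)


def full_chain(sp_idx, chrom="chr1"):
    return Chain(100 + sp_idx, chrom, CHROM_LEN, "+", 0, CHROM_LEN,
                 f"q{sp_idx}", CHROM_LEN, "+", 0, CHROM_LEN, 1,
                 ((CHROM_LEN, 0, 0),))


class Fixture:
    """18 outgroups, clades of 4 and 3, one engineered 120 bp deletion.

    The deletion at [500200, 500320) is within the TSS window of a gene at
    500000, conserved in all outgroups, gapped in 3/4 of clade A and 2/3
    of clade B, with zero outgroup gaps.
    """

    def __init__(self, n_outgroups=18, conserved_in=None,
                 deletion=(500_200, 500_320)):
        chrom = "chr1"
        self.gene = GeneModel("geneX", chrom, "+", (
            Transcript("t1", Interval(chrom, 500_000, 505_000),
                       IntervalSet(chrom, [500_000, 504_000],
                                   [500_500, 505_000])),))
        self.outgroups = tuple(f"og{i}" for i in range(n_outgroups))
        cladeA = tuple(f"tgA{i}" for i in range(4))
        cladeB = tuple(f"tgB{i}" for i in range(3))
        self.targets = cladeA + cladeB
        clade_of = {sp: "A" for sp in cladeA} | {sp: "B" for sp in cladeB}
        self.phen = PhenotypeMatrix("ref", self.outgroups, self.targets,
                                    clade_of)
        self.calls = {}
        self.chains = {}
        for i, sp in enumerate(self.outgroups + self.targets):
            self.calls[sp] = OrthologyCall(sp, "geneX", 1, 5000, 0,
                                           CHROM_LEN)
            self.chains[sp] = {1: full_chain(i)}
        d = Interval(chrom, *deletion)
        gap_bearing = cladeA[:3] + cladeB[:2]
        self.gap_sets = {
            sp: (IntervalSet.from_pairs(chrom, [(d.start, d.end)])
                 if sp in gap_bearing else IntervalSet(chrom))
            for sp in self.outgroups + self.targets}
        conserved_in = self.outgroups if conserved_in is None \
            else conserved_in
        self.conserved_sets = {
            sp: (IntervalSet.from_pairs(chrom, [(400_000, 600_000)])
                 if sp in conserved_in else IntervalSet(chrom))
            for sp in self.outgroups}
        self.deletion = d

    def scan(self, config=ScreenConfig()):
        return scan_gene(self.gene, self.calls, self.chains,
                         self.gap_sets, self.conserved_sets, self.phen,
                         config, chrom_length=CHROM_LEN)


class TestScanGene:
    def test_engineered_deletion_yields_one_candidate(self):
        fx = Fixture()
        (cand,) = fx.scan()
        assert cand.interval == fx.deletion
        assert cand.outgroup_violations == 0
        assert cand.outgroup_conserved_support == 18
        assert cand.target_support == {"A": 3, "B": 2}
        assert cand.linked_genes == ("geneX",)

    def test_per_base_masks_match_brute_force(self):
        fx = Fixture()
        (cand,) = fx.scan()
        # brute-force per-base recount over the deletion neighborhood
        for pos in range(fx.deletion.start - 50, fx.deletion.end + 50):
            gap_cnt_a = sum(
                1 for sp in ("tgA0", "tgA1", "tgA2", "tgA3")
                if fx.gap_sets[sp].overlaps_interval(pos, pos + 1))
            gap_cnt_b = sum(
                1 for sp in ("tgB0", "tgB1", "tgB2")
                if fx.gap_sets[sp].overlaps_interval(pos, pos + 1))
            cons = sum(
                1 for sp in fx.outgroups
                if fx.conserved_sets[sp].overlaps_interval(pos, pos + 1))
            in_candidate = cand.interval.start <= pos < cand.interval.end
            passes = gap_cnt_a >= 3 and gap_cnt_b >= 2 and cons >= 17
            assert in_candidate == passes

    def test_sixteen_conserved_outgroups_is_not_enough(self):
        fx = Fixture(conserved_in=tuple(f"og{i}" for i in range(16)))
        assert fx.scan() == []

    def test_seventeen_conserved_outgroups_suffices(self):
        fx = Fixture(conserved_in=tuple(f"og{i}" for i in range(17)))
        (cand,) = fx.scan()
        assert cand.outgroup_conserved_support == 17

    def test_too_few_outgroup_mappings_makes_gene_ineligible(self):
        fx = Fixture(n_outgroups=16)
        assert fx.scan() == []

    def test_quorum_failure_in_one_clade_kills_candidate(self):
        fx = Fixture()
        fx.gap_sets["tgB1"] = IntervalSet("chr1")  # clade B down to 1/3
        assert fx.scan() == []

    def test_two_violating_outgroups_rejected_one_tolerated(self):
        fx = Fixture()
        d = fx.deletion
        fx.gap_sets["og0"] = IntervalSet.from_pairs(
            "chr1", [(d.start, d.end)])
        (cand,) = fx.scan()
        assert cand.outgroup_violations == 1
        assert cand.violating_species == ("og0",)
        fx.gap_sets["og1"] = IntervalSet.from_pairs(
            "chr1", [(d.start, d.end)])
        assert fx.scan() == []

    def test_non_spanning_outgroup_chain_is_not_scorable(self):
        fx = Fixture()
        d = fx.deletion
        for sp in ("og0", "og1"):
            fx.gap_sets[sp] = IntervalSet.from_pairs(
                "chr1", [(d.start, d.end)])
            # chain stops short of the candidate: neither support nor
            # violation
            fx.chains[sp] = {1: Chain(
                100, "chr1", CHROM_LEN, "+", 0, 450_000, f"q_{sp}",
                CHROM_LEN, "+", 0, 450_000, 1, ((450_000, 0, 0),))}
        (cand,) = fx.scan()
        assert cand.outgroup_violations == 0

    def test_short_deletion_below_min_candidate_dropped(self):
        fx = Fixture(deletion=(500_200, 500_245))  # 45 bp < 50
        assert fx.scan() == []

    def test_deletion_outside_window_not_seen(self):
        fx = Fixture(deletion=(800_000, 800_120))  # > 200 kb from TSS
        assert fx.scan() == []

    def test_raising_any_threshold_never_adds_candidates(self):
        fx = Fixture()
        base = len(fx.scan())
        stricter = [
            ScreenConfig(min_outgroup_mappings=19),
            ScreenConfig(min_target_mappings=8),
            ScreenConfig(clade_fraction=1.0),
            ScreenConfig(min_conserved_support=19),
            ScreenConfig(min_intersection=200),
            ScreenConfig(min_candidate=200),
            ScreenConfig(max_outgroup_violations=0),
            ScreenConfig(flank=100),
        ]
        for cfg in stricter:
            assert len(fx.scan(cfg)) <= base


class TestMergeAcrossGenes:
    def _cand(self, start, end, gene):
        return CondelCandidate(Interval("chr1", start, end), (gene,),
                               {"A": 3}, ("tgA0",), 18, 0, ())

    def test_same_interval_called_by_two_genes(self):
        merged = merge_candidates_across_genes(
            [self._cand(100, 220, "geneA"), self._cand(100, 220, "geneB")])
        assert len(merged) == 1
        assert merged[0].linked_genes == ("geneA", "geneB")

    def test_disjoint_intervals_pass_through(self):
        merged = merge_candidates_across_genes(
            [self._cand(100, 220, "geneA"), self._cand(500, 620, "geneB")])
        assert len(merged) == 2

    def test_unique_count_bounded_by_input_count(self):
        cands = [self._cand(100 + 10 * i, 200 + 10 * i, f"g{i}")
                 for i in range(5)]
        assert len(merge_candidates_across_genes(cands)) <= len(cands)


class TestContext:
    def _gene(self):
        return GeneModel("g", "chr1", "+", (
            Transcript("t1", Interval("chr1", 1000, 5000),
                       IntervalSet("chr1", [1000, 4000], [1500, 5000])),))

    def _cand(self, start, end):
        return CondelCandidate(Interval("chr1", start, end), ("g",),
                               {}, (), 18, 0, ())

    def test_exon_overlap_is_coding(self):
        assert annotate_context(self._cand(1200, 1300),
                                [self._gene()]) == "coding-exon"

    def test_intron_is_genic_noncoding(self):
        assert annotate_context(self._cand(2000, 2100),
                                [self._gene()]) == "genic-noncoding"

    def test_far_from_genes_is_intergenic(self):
        assert annotate_context(self._cand(50_000, 50_100),
                                [self._gene()]) == "intergenic"

    def test_exon_precedence_over_span(self):
        # overlaps both an exon and intronic sequence: coding wins
        assert annotate_context(self._cand(1400, 1600),
                                [self._gene()]) == "coding-exon"
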