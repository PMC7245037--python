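import math

import numpy as np
import pytest

from symbiocheck.census import (CensusParams, GeneQuery, GeneStatus,
                                VariantSite, detect_low_complexity,
                                locate_gene, run_census)
from symbiocheck.community import (BUCHNERA, TG_CONTAMINANT, CommunityConfig,
                                   generate_genomes, simulate_reads)
from symbiocheck.io import SequenceRecord
from symbiocheck.mapping import CompetitiveMapper, variant_fraction

CP = CensusParams(contaminants=(TG_CONTAMINANT,))


class TestStatusRecovery:
    def test_all_planted_statuses_recovered(self, community1, reports1):
        for sym, pg in community1.truth.genes.items():
            assert reports1[sym].status is pg.status, sym

    def test_disruption_positions_within_2bp(self, community1, reports1):
        for sym, pg in community1.truth.genes.items():
            detected = [
                (d.kind, d.position) for d in reports1[sym].disruptions
            ]
            for pos, kind in pg.disruptions:
                assert any(
                    k == kind and abs(p - pos) <= 2 for k, p in detected
                ), (sym, kind, pos, detected)

    def test_intact_gene_reports_full_coverage(self, community1, reports1):
        rep = reports1["trpA"]
        assert rep.status is GeneStatus.INTACT
        assert rep.query_coverage >= 0.95 and not rep.disruptions

    def test_absent_gene_has_no_span(self, reports1):
        rep = reports1["pgm"]
        assert rep.status is GeneStatus.ABSENT and rep.scaffold_id is None

    def test_binned_away_gene_found_via_fallback(self, community1, reports1):
        """A gene on a scaffold whose best hits belong to another organism
        is recovered from the full scaffold set with a bin-escape flag."""
        rep = reports1["trpE"]
        assert rep.bin_escape and rep.status is GeneStatus.INTACT
        assert community1.truth.scaffold_organism[rep.scaffold_id] == "wolbachia"

    def test_contaminant_gene_resolves_after_excision(self, reports1):
        for sym in ("lipA", "pgi"):
            rep = reports1[sym]
            assert rep.status is GeneStatus.CONTAMINANT_INSERTION
            assert rep.post_excision_status is GeneStatus.INTACT
            assert rep.contaminant_position is not None

    def test_premature_stop_recorded_for_trpG(self, community1, reports1):
        rep = reports1["trpG"]
        kinds = {d.kind for d in rep.disruptions}
        assert "premature_stop" in kinds and rep.status is GeneStatus.FRAMESHIFT_LC

    def test_reports_locate_genes_at_planted_spans(self, community1, reports1):
        for sym, pg in community1.truth.genes.items():
            if pg.scaffold_id is None:
                continue
            rep = reports1[sym]
            assert rep.scaffold_id == pg.scaffold_id
            assert rep.strand == pg.strand
            # located span covers the planted gene (local alignments may
            # wander a little into flanking sequence)
            overlap = min(rep.end, pg.end) - max(rep.start, pg.start)
            assert overlap >= 0.9 * (pg.end - pg.start), sym


class TestLocateGene:
    def test_unplanted_query_has_no_locus(self, community1, binned1):
        q = GeneQuery(symbol="ghost", aa_seq="MKWQERTYIPASDFGHKLCVNM" * 8)
        locus = locate_gene(q, binned1["bins"]["buchnera"], binned1["kept"], CP)
        assert locus is None


class TestLowComplexity:
    @pytest.mark.parametrize(
        "window,expected",
        [
            ("AAAAAAA", True),                     # homopolymer run >= 6
            ("ATATATATATAT", True),                # 6 AT units
            ("ACGTACGGTCAGTCAGGTCAA", False),
            ("CCGGTTAAACCGGTTAAACCG", False),      # runs of 3 only
        ],
    )
    def test_examples(self, window, expected):
        assert detect_low_complexity(window, CP) is expected

    def test_random_windows_rarely_flagged(self):
        """>=99% of random GC=0.5 21-mers are not low-complexity."""
        rng = np.random.default_rng(17)
        flagged = sum(
            detect_low_complexity("".join(rng.choice(list("ACGT"), 21)), CP)
            for _ in range(1000)
        )
        assert flagged <= 10


class TestVariantFraction:
    def _pileup(self, n_alt, n_ref, n_other=0):
        """Build a pileup through the mapper: reads spanning one codon."""
        template = (
            "ACCAGTTACGGACTTCAGGATACCATTGGACTT"
            "TAG"
            "CCATTGAGGTACCAGTTACGGACTTCAGGA"
        )
        site = 33
        reads = []
        specs = [("TAG", n_ref), ("CAG", n_alt), ("TGG", n_other)]
        i = 0
        for codon, count in specs:
            for _ in range(count):
                start = i % 20  # stagger read starts; all span the codon
                seq = template[start:site] + codon + template[site + 3 : start + 70]
                reads.append(SequenceRecord(id=f"r{i}", seq=seq))
                i += 1
        mapper = CompetitiveMapper({"t": template}, {})
        res = mapper.map_reads(reads)
        return variant_fraction(res, reads, "t", site, "TAG", "CAG")

    def test_fraction_arithmetic(self):
        vs = self._pileup(n_alt=134, n_ref=866)
        assert vs.alt_count == 134 and vs.ref_count == 866
        assert vs.alt_fraction == pytest.approx(0.134)

    def test_zero_alt(self):
        vs = self._pileup(n_alt=0, n_ref=50)
        assert vs.alt_fraction == 0.0

    def test_other_codons_counted_separately(self):
        vs = self._pileup(n_alt=10, n_ref=80, n_other=10)
        assert vs.other_count == 10
        assert vs.alt_fraction == pytest.approx(0.10)
        assert vs.alt_fraction_refalt == pytest.approx(10 / 90)

    def test_low_depth_flagged(self):
        vs = self._pileup(n_alt=1, n_ref=5)
        assert vs.low_confidence


class TestCompetitiveMapping:
    def test_depth_recovered_within_30_percent(self, community1):
        """A 20x Buchnera-only library maps back to ~20x on every gene."""
        r1, r2 = simulate_reads(community1, "cov20", depths={BUCHNERA: 20.0})
        genes = {
            pg.symbol: pg.nt_seq
            for pg in community1.truth.genes.values()
            if pg.nt_seq and pg.organism == BUCHNERA and not pg.bin_escape
        }
        mapper = CompetitiveMapper(genes, {})
        res = mapper.map_reads(r1 + r2)
        for g, seq in genes.items():
            depth = res.depth(g, len(seq))
            assert 14.0 <= depth <= 26.0, (g, depth)

    def test_decoys_absorb_ortholog_reads(self):
        """With a closely related ortholog (5% aa divergence — a deliberately
        hard case), Wolbachia-origin reads cross-map onto the gene targets
        unless the Wolbachia scaffolds compete as decoys; with decoys the
        same reads are absorbed and gene depths match the no-Wolbachia
        control within sampling noise."""
        com = generate_genomes(CommunityConfig(seed=6, aa_divergence=0.05))
        genes = {
            pg.symbol: pg.nt_seq
            for pg in com.truth.genes.values()
            if pg.nt_seq and pg.organism == BUCHNERA and not pg.bin_escape
        }
        decoys = {
            sc.id: sc.seq for sc in com.scaffolds
            if com.truth.scaffold_organism[sc.id] == "wolbachia"
        }
        r1, r2 = simulate_reads(
            com, "mix", depths={BUCHNERA: 20.0, "wolbachia": 120.0}
        )
        reads = r1 + r2

        def cross_mapped(mapper):
            res = mapper.map_reads(reads)
            return res, sum(
                1 for p, r in zip(res.placements, reads)
                if p.status == "mapped" and p.target in genes
                and com.truth.read_origin[r.id] == "wolbachia"
            )

        res_naked, cross_naked = cross_mapped(CompetitiveMapper(genes, {}))
        res_decoy, cross_decoy = cross_mapped(CompetitiveMapper(genes, decoys))
        assert cross_naked > 50  # the confounder is real without decoys
        assert cross_decoy <= 0.02 * cross_naked
        # and with decoys the depths agree with a Buchnera-only control
        rb1, rb2 = simulate_reads(com, "ctrl", depths={BUCHNERA: 20.0})
        res_ctrl = CompetitiveMapper(genes, decoys).map_reads(rb1 + rb2)
        for g, seq in genes.items():
            d0 = res_ctrl.depth(g, len(seq))
            d1 = res_decoy.depth(g, len(seq))
            assert abs(d1 - d0) <= 6 * math.sqrt(max(d0, 1.0)), (g, d0, d1)

    def test_empty_library(self):
        mapper = CompetitiveMapper({"g": "ACGT" * 50}, {})
        res = mapper.map_reads([])
        assert res.n_reads == 0 and res.depth("g", 200) == 0.0

    def test_fate_counts_conserved(self, community1):
        r1, r2 = simulate_reads(community1, "cons", depths={BUCHNERA: 5.0, "host": 5.0})
        genes = {
            pg.symbol: pg.nt_seq
            for pg in community1.truth.genes.values()
            if pg.nt_seq and pg.organism == BUCHNERA
        }
        mapper = CompetitiveMapper(genes, {})
        res = mapper.map_reads(r1 + r2)
        assert res.n_mapped + res.n_unmapped + res.n_ambiguous == len(r1) + len(r2)
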