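import random
from importlib import resources

import pytest

from symbiocheck.align import revcomp
from symbiocheck.primers import (AmplificationParams, PrimerPair,
                                 design_matching_pair, predict_amplification,
                                 read_primer_tsv, render_alignment,
                                 scan_primer)

from .oracles import primer_best_site_bruteforce

TEMPLATE = (
    "ATGGCTAAAGTTCTGGCAGATTACGGTCCTTGGAACCAGATTGCTGAACGTATCGCTGACCTG"
    "AAAGAAGCTGGTGTTACCGCTCTGGAAGCTCTGGAAAAAGCTCTGGCTGAACATCCGGAAGTT"
    "CTGGCTAACGCTATGGCTGAA"
)


class TestScanPrimer:
    def test_exact_substring_zero_mismatches(self):
        primer = TEMPLATE[30:50]
        hit = scan_primer(primer, TEMPLATE)
        assert hit.position == 30 and hit.strand == "+" and hit.mismatches == 0

    def test_reverse_complement_found_on_minus_strand(self):
        primer = revcomp(TEMPLATE[60:80])
        hit = scan_primer(primer, TEMPLATE)
        assert hit.strand == "-" and hit.position == 60 and hit.mismatches == 0
        assert hit.five_prime == 79

    def test_iupac_codes_match_compatible_bases(self):
        primer = "ATGGCTAARGTNCTGGCAGA"  # R~A, N~any
        hit = scan_primer(primer, TEMPLATE)
        assert hit.position == 0 and hit.mismatches == 0

    def test_3prime_tail_mismatches_counted(self):
        primer = TEMPLATE[30:50]
        primer = primer[:-1] + ("A" if primer[-1] != "A" else "C")
        hit = scan_primer(primer, TEMPLATE)
        assert hit.terminal_mismatch and hit.mismatches_3p5 == 1

    def test_random_primers_mismatch_heavily(self):
        """A random 20-mer vs a random 1 kb template: best site has >=5
        mismatches in >=95% of seeded trials (exhaustive-scan oracle)."""
        rng = random.Random(99)
        bad = 0
        trials = 200
        for _ in range(trials):
            template = "".join(rng.choice("ACGT") for _ in range(1000))
            primer = "".join(rng.choice("ACGT") for _ in range(20))
            hit = scan_primer(primer, template)
            assert hit.mismatches == primer_best_site_bruteforce(primer, template)
            if hit.mismatches < 5:
                bad += 1
        assert bad / trials <= 0.05


class TestPredictAmplification:
    def _pair(self, fwd, rev, name="p"):
        return PrimerPair(name=name, forward=fwd, reverse=rev)

    def test_perfect_convergent_pair_amplifies(self):
        pair = self._pair(TEMPLATE[:20], revcomp(TEMPLATE[120:140]))
        v = predict_amplification(pair, TEMPLATE)
        assert v.verdict == "amplifies"
        # 5'-to-5' inclusive convention
        assert v.amplicon_length == 140

    def test_terminal_mismatch_always_fails(self):
        fwd = TEMPLATE[:20]
        fwd = fwd[:-1] + ("A" if fwd[-1] != "A" else "C")
        v = predict_amplification(
            self._pair(fwd, revcomp(TEMPLATE[120:140])), TEMPLATE
        )
        assert v.verdict == "fails"
        assert any("3'-terminal" in r for r in v.reasons)

    def test_divergent_orientation_fails(self):
        pair = self._pair(revcomp(TEMPLATE[:20]), TEMPLATE[120:140])
        v = predict_amplification(pair, TEMPLATE)
        assert v.verdict == "fails"

    def test_one_marginal_criterion_is_unlikely(self):
        fwd = list(TEMPLATE[:20])
        # 4 internal mismatches (max_total_mm + 1), 3' tail intact
        for i in (2, 5, 8, 11):
            fwd[i] = "A" if fwd[i] != "A" else "C"
        v = predict_amplification(
            self._pair("".join(fwd), revcomp(TEMPLATE[120:140])), TEMPLATE
        )
        assert v.verdict == "unlikely"

    def test_two_marginal_criteria_fail(self):
        def degrade(seq):
            out = list(seq)
            for i in (2, 5, 8, 11):
                out[i] = "A" if out[i] != "A" else "C"
            return "".join(out)

        v = predict_amplification(
            self._pair(degrade(TEMPLATE[:20]), revcomp(degrade(TEMPLATE[120:140]))),
            TEMPLATE,
        )
        assert v.verdict == "fails"

    def test_swap_and_revcomp_symmetry(self):
        """Swapping primers (each reverse-complemented) on the
        reverse-complemented template yields the identical verdict."""
        rng = random.Random(5)
        for _ in range(20):
            template = "".join(rng.choice("ACGT") for _ in range(300))
            fwd = template[10:30]
            rev = revcomp(template[200:220])
            if rng.random() < 0.5:  # sometimes degrade a primer
                pos = rng.randrange(20)
                fwd = fwd[:pos] + rng.choice("ACGT") + fwd[pos + 1 :]
            v1 = predict_amplification(PrimerPair("a", fwd, rev), template)
            v2 = predict_amplification(
                PrimerPair("b", rev, fwd), revcomp(template)
            )
            assert v1.verdict == v2.verdict
            assert v1.amplicon_length == v2.amplicon_length


class TestPrimerIO:
    def test_length_validation(self):
        with pytest.raises(ValueError, match="length"):
            PrimerPair(name="short", forward="ACGT", reverse="ACGTACGTACGTACGTACGT")

    def test_alphabet_validation(self):
        with pytest.raises(ValueError, match="non-IUPAC"):
            PrimerPair(name="bad", forward="ACGTACGTACGTACGTACGZ",
                       reverse="ACGTACGTACGTACGTACGT")

    def test_fixture_file_parses(self):
        path = resources.files("symbiocheck") / "data" / "primers_demo.tsv"
        pairs = read_primer_tsv(str(path))
        assert [p.name for p in pairs] == ["demo_good", "demo_tail_mm", "demo_foreign"]

    def test_render_alignment_marks_mismatches(self):
        primer = TEMPLATE[30:50]
        hit = scan_primer(primer, TEMPLATE)
        text = render_alignment(primer, TEMPLATE, hit)
        assert "|" * 20 in text


class TestCommunityPrimers:
    def test_self_primers_amplify_ortholog_primers_fail(self, community1):
        """Primers designed on the recovered gene amplify; primers designed
        on the divergent ortholog do not — mismatches, not absence, explain
        the PCR failure."""
        import numpy as np

        from symbiocheck.community import _codon_weights, reverse_translate

        pg = community1.truth.genes["trpD"]
        good = design_matching_pair(pg.nt_seq, "self", "trpD")
        assert predict_amplification(good, pg.nt_seq).verdict == "amplifies"

        hom = next(
            s for pid, s in zip(
                community1.protein_db.ids, community1.protein_db.seqs
            ) if pid == "trpG_w"
        )
        rng = np.random.default_rng(0)
        hom_nt = reverse_translate(rng, hom, _codon_weights(0.35))
        foreign = design_matching_pair(hom_nt, "ortholog", "trpG")
        target = community1.truth.genes["trpG"].nt_seq
        assert predict_amplification(foreign, target).verdict == "fails"
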