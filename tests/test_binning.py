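import math
import random
import shutil
import subprocess

import pytest

from symbiocheck import binning
from symbiocheck.binning import (BinningParams, ProteinDB, assign_bins,
                                 filter_scaffolds, finalize_bins,
                                 parse_tabular_hits, translated_search)
from symbiocheck.io import Scaffold, write_fasta, SequenceRecord

AA = "ACDEFGHIKLMNPQRSTVWY"


def _sc(length, cov, sid=None, seq=None):
    seq = seq or "ACGT" * (length // 4) + "A" * (length % 4)
    return Scaffold(id=sid or f"s_{length}_{cov}", seq=seq, kmer_cov=cov)


class TestFilterScaffolds:
    @pytest.mark.parametrize(
        "length,cov,kept",
        [
            (199, 50.0, False),   # shorter than 200 -> dropped
            (200, 3.0, True),     # both boundaries inclusive
            (200, 2.99, False),   # coverage strictly below 3 -> dropped
            (5000, 2.9, False),
            (199, 3.0, False),
            (5000, 50.0, True),
        ],
    )
    def test_boundaries_exact(self, length, cov, kept):
        params = BinningParams()
        k, d = filter_scaffolds([_sc(length, cov)], params)
        assert (len(k) == 1) is kept
        assert len(k) + len(d) == 1

    def test_missing_coverage_errors(self):
        sc = Scaffold(id="x", seq="A" * 300, kmer_cov=None)
        with pytest.raises(ValueError, match="coverage"):
            filter_scaffolds([sc], BinningParams())


class TestTranslatedSearch:
    def test_embedded_protein_segment_is_found(self, community1):
        params = BinningParams()
        pg = community1.truth.genes["trpA"]
        sc = next(s for s in community1.scaffolds if s.id == pg.scaffold_id)
        hits = translated_search(sc, community1.protein_db, params)
        own = [h for h in hits if h.protein_id == "trpA"]
        assert own and min(h.evalue for h in own) < 1e-20
        best = min(own, key=lambda h: h.evalue)
        assert best.organism_label == "buchnera"
        assert best.query_start >= pg.start - 3 and best.query_end <= pg.end + 3

    def test_random_scaffolds_yield_no_hits(self, community1):
        """Random 300 bp sequences vs an unrelated database: <=5% spurious
        hit rate at e-value 1e-3 (seeding + Karlin-Altschul statistics)."""
        rng = random.Random(123)
        params = BinningParams()
        spurious = 0
        trials = 100
        for t in range(trials):
            seq = "".join(rng.choice("ACGT") for _ in range(300))
            sc = Scaffold(id=f"NODE_{t}_length_300_cov_50.0", seq=seq, kmer_cov=50.0)
            if translated_search(sc, community1.protein_db, params):
                spurious += 1
        assert spurious / trials <= 0.05

    def test_empty_db_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ProteinDB([], [], [])


class TestAssignBins:
    def _hit(self, sid, org, bits, pid="p", ev=None, span=(0, 300)):
        return binning.TranslatedHit(
            scaffold_id=sid, protein_id=pid, organism_label=org, frame=1,
            raw_score=bits, bitscore=bits, evalue=ev if ev is not None else 10 ** -bits,
            query_start=span[0], query_end=span[1], subject_start=0, subject_end=100,
        )

    def test_best_hit_and_margin(self):
        sc = _sc(300, 50.0, sid="s1")
        hits = [self._hit("s1", "orgA", 120), self._hit("s1", "orgB", 80)]
        (a,) = assign_bins(hits, [sc])
        assert a.organism_label == "orgA" and a.margin_bits == pytest.approx(40)

    def test_no_hits_unassigned(self):
        (a,) = assign_bins([], [_sc(300, 50.0, sid="s1")])
        assert a.organism_label == binning.UNASSIGNED and a.best_hit is None

    def test_tie_flagged_ambiguous_with_deterministic_winner(self):
        sc = _sc(300, 50.0, sid="s1")
        hits = [
            self._hit("s1", "orgB", 100, pid="zzz", ev=1e-30),
            self._hit("s1", "orgA", 100, pid="aaa", ev=1e-30),
        ]
        (a,) = assign_bins(hits, [sc])
        assert a.ambiguous and a.organism_label == "orgA"  # lexicographic pid

    def test_partition_property(self, community1, binned1):
        """Kept scaffolds are partitioned into bins plus UNASSIGNED."""
        kept_ids = {sc.id for sc in binned1["kept"]}
        assigned_ids = [a.scaffold_id for a in binned1["assignments"]]
        assert sorted(assigned_ids) == sorted(kept_ids)
        binned_ids = [sc.id for members in binned1["bins"].values() for sc in members]
        assert len(binned_ids) == len(set(binned_ids))
        assert set(binned_ids) <= kept_ids


class TestFinalizeBins:
    def _assignments(self, scaffolds, label):
        return [
            binning.BinAssignment(sc.id, label, None, math.inf) for sc in scaffolds
        ]

    def test_low_coverage_bacterial_scaffold_removed(self):
        scs = [_sc(1000, 9.9, sid="a"), _sc(1000, 50.0, sid="b")]
        bins, summaries = finalize_bins(
            self._assignments(scs, "buchnera"), scs, BinningParams()
        )
        assert [sc.id for sc in bins["buchnera"]] == ["b"]

    def test_non_bacterial_bins_keep_low_coverage(self):
        scs = [_sc(1000, 5.0, sid="a")]
        bins, _ = finalize_bins(self._assignments(scs, "host"), scs, BinningParams())
        assert len(bins["host"]) == 1

    def test_mean_coverages(self):
        scs = [
            _sc(1000, 100.0, sid="a"),
            _sc(3000, 120.0, sid="b"),
        ]
        _, summaries = finalize_bins(
            self._assignments(scs, "buchnera"), scs, BinningParams()
        )
        s = summaries["buchnera"]
        assert s.mean_kmer_cov == pytest.approx(110.0)
        assert s.weighted_mean_kmer_cov == pytest.approx(115.0)
        assert s.total_bp == 4000

    def test_raising_min_bin_cov_never_grows_bins(self):
        scs = [_sc(1000, c, sid=f"s{c}") for c in (10.0, 25.0, 80.0, 200.0)]
        assignments = self._assignments(scs, "wolbachia")
        sizes = []
        for cov in (10, 30, 100, 500):
            params = BinningParams(min_bin_cov=cov)
            bins, _ = finalize_bins(assignments, scs, params)
            sizes.append(len(bins.get("wolbachia", [])))
        assert sizes == sorted(sizes, reverse=True)


class TestTabularEngine:
    def test_parse_and_assign_matches_internal(self, tmp_path, community1, binned1):
        """External tabular hits flow through the same assignment semantics."""
        lines = []
        for h in binned1["hits"]:
            if h.frame > 0:
                qs, qe = h.query_start + 1, h.query_end
            else:
                qs, qe = h.query_end, h.query_start + 1
            lines.append(
                "\t".join(
                    map(str, [
                        h.scaffold_id, h.protein_id, 100.0,
                        h.subject_end - h.subject_start, 0, 0, qs, qe,
                        h.subject_start + 1, h.subject_end,
                        h.evalue, round(h.bitscore, 3),
                    ])
                )
            )
        path = tmp_path / "hits.tsv"
        path.write_text("\n".join(lines) + "\n")
        manifest = dict(zip(community1.protein_db.ids, community1.protein_db.organisms))
        hits = parse_tabular_hits(path, manifest)
        got = {
            a.scaffold_id: a.organism_label
            for a in assign_bins(hits, binned1["kept"])
        }
        expected = {
            a.scaffold_id: a.organism_label for a in binned1["assignments"]
        }
        assert got == expected

    def test_unparseable_line_reports_number(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("only\tthree\tcols\n")
        with pytest.raises(ValueError, match="line 1"):
            parse_tabular_hits(path, {})


def test_assignments_agree_with_ncbi_blastx(tmp_path, community1, binned1):
    """Independent oracle: NCBI blastx best-hit binning on the same scaffolds
    and database reproduces the internal engine's organism assignments."""
    db_fasta = tmp_path / "db.faa"
    write_fasta(
        (
            SequenceRecord(id=pid, seq=seq)
            for pid, seq in zip(community1.protein_db.ids, community1.protein_db.seqs)
        ),
        db_fasta,
    )
    query = tmp_path / "scaffolds.fna"
    write_fasta(
        (SequenceRecord(id=sc.id, seq=sc.seq) for sc in binned1["kept"]), query
    )
    subprocess.run(
        ["makeblastdb", "-in", str(db_fasta), "-dbtype", "prot"],
        check=True, capture_output=True,
    )
    out = tmp_path / "hits.tsv"
    subprocess.run(
        [
            "blastx", "-query", str(query), "-db", str(db_fasta),
            "-evalue", "1e-3", "-outfmt", "6", "-out", str(out),
            "-max_target_seqs", "500",
        ],
        check=True, capture_output=True,
    )
    org_of = dict(zip(community1.protein_db.ids, community1.protein_db.organisms))
    best: dict[str, tuple[float, str]] = {}
    for line in out.read_text().splitlines():
        parts = line.split("\t")
        sid, pid, bits = parts[0], parts[1], float(parts[11])
        if sid not in best or bits > best[sid][0]:
            best[sid] = (bits, org_of[pid])
    internal = {a.scaffold_id: a.organism_label for a in binned1["assignments"]}
    for sid, label in internal.items():
        assert best.get(sid, (0, binning.UNASSIGNED))[1] == label
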