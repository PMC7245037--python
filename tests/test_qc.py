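import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from symbiocheck.community import (DEFAULT_ADAPTERS, TG_CONTAMINANT,
                                   CommunityConfig, generate_genomes,
                                   simulate_reads)
from symbiocheck.io import SequenceRecord
from symbiocheck.qc import QcParams, clip_adapter, filter_pairs, qc_pipeline, quality_trim

from .oracles import best_adapter_clip_bruteforce


def _read(seq, qual=40, rid="r"):
    return SequenceRecord(id=rid, seq=seq, qual=[qual] * len(seq))


PARAMS = QcParams(adapters=(TG_CONTAMINANT,))


class TestClipAdapter:
    def test_full_contaminant_clipped_to_insert(self):
        # insert chosen not to alias the periodic T+G adapter
        insert = "CCAACCAACCAACCAACCAACCAACCAA"
        read = _read(insert + TG_CONTAMINANT + "CCAACC")
        assert clip_adapter(read, PARAMS).seq == insert

    def test_adapter_free_read_unchanged(self):
        read = _read("ACGAACCTTGGCATCAGATTACAGATTACA")
        assert clip_adapter(read, PARAMS).seq == read.seq

    def test_terminal_prefix_with_one_mismatch(self):
        # read ends in the adapter's first 10 bp carrying 1 mismatch
        insert = "ACGAACCTTGGCATCAGATTACA"
        tail = TG_CONTAMINANT[:10]
        tail = tail[:4] + "A" + tail[5:]
        read = _read(insert + tail)
        assert clip_adapter(read, PARAMS).seq == insert

    def test_qualities_truncated_in_lockstep(self):
        read = _read("CCAACCAACCAACCAACCAA" + TG_CONTAMINANT)
        out = clip_adapter(read, PARAMS)
        assert len(out.qual) == len(out.seq) == 20

    def test_matches_sliding_window_oracle(self):
        rng = np.random.default_rng(11)
        params = QcParams(adapters=DEFAULT_ADAPTERS)
        for _ in range(60):
            L = int(rng.integers(30, 120))
            seq = "".join(rng.choice(list("ACGT"), L))
            if rng.random() < 0.5:
                cut = int(rng.integers(0, L))
                adapter = DEFAULT_ADAPTERS[int(rng.integers(len(DEFAULT_ADAPTERS)))]
                seq = (seq[:cut] + adapter + seq[cut:])[:L]
            expected = best_adapter_clip_bruteforce(
                seq, params.adapters, params.min_adapter_overlap,
                params.max_adapter_mismatch_rate,
            )
            got = clip_adapter(_read(seq), params)
            assert len(got.seq) == expected


class TestQualityTrim:
    def test_high_quality_read_unchanged(self):
        read = _read("A" * 100, qual=40)
        assert quality_trim(read, PARAMS).seq == read.seq

    def test_survivor_below_min_length_dropped(self):
        read = SequenceRecord(id="r", seq="A" * 60, qual=[40] * 45 + [2] * 15)
        assert quality_trim(read, PARAMS) is None

    def test_scan_stops_at_first_passing_base(self):
        params = QcParams(adapters=(), min_length=1)
        read = SequenceRecord(id="r", seq="ACGTAC", qual=[40, 40, 19, 40, 19, 19])
        out = quality_trim(read, params)
        assert out.seq == "ACGT" and out.qual == [40, 40, 19, 40]


class TestFilterPairs:
    def test_clean_pair_kept(self):
        kept, singles, dropped = filter_pairs([(_read("ACGT"), _read("TTGG"))], PARAMS)
        assert len(kept) == 1 and not singles and dropped == 0

    def test_n_in_one_mate_orphans_other(self):
        kept, singles, dropped = filter_pairs([(_read("ACNT"), _read("TTGG"))], PARAMS)
        assert not kept and len(singles) == 1 and dropped == 1
        assert singles[0].seq == "TTGG"

    def test_both_mates_failing_drop_both(self):
        kept, singles, dropped = filter_pairs([(_read("NNNN"), _read("ANGG"))], PARAMS)
        assert not kept and not singles and dropped == 2

    def test_unsynchronised_ids_rejected(self):
        with pytest.raises(ValueError, match="unsynchronised"):
            filter_pairs([(_read("ACGT", rid="a/1"), _read("TTGG", rid="b/2"))], PARAMS)


@given(
    st.lists(
        st.tuples(
            st.text(alphabet="ACGTN", min_size=1, max_size=120),
            st.text(alphabet="ACGTN", min_size=1, max_size=120),
            st.lists(st.integers(0, 41), min_size=1, max_size=4),
        ),
        min_size=0,
        max_size=20,
    )
)
def test_read_count_conservation_fuzz(payload):
    """2*kept_pairs + singletons + dropped == input reads, on any input."""
    r1, r2 = [], []
    for i, (s1, s2, quals) in enumerate(payload):
        q1 = [quals[j % len(quals)] for j in range(len(s1))]
        q2 = [quals[j % len(quals)] for j in range(len(s2))]
        r1.append(SequenceRecord(id=f"p{i}", seq=s1, qual=q1))
        r2.append(SequenceRecord(id=f"p{i}", seq=s2, qual=q2))
    params = QcParams(adapters=(TG_CONTAMINANT,), min_length=5)
    kept, singles, summary = qc_pipeline(r1, r2, params)
    assert 2 * summary.kept_pairs + summary.singletons + summary.dropped == 2 * len(payload)
    assert summary.kept_pairs == len(kept) and summary.singletons == len(singles)


def test_qc_idempotent_on_simulated_reads(community1):
    """Running QC on its own kept output changes nothing."""
    r1, r2 = simulate_reads(community1, "idem", depths={"buchnera": 4.0})
    params = QcParams(adapters=DEFAULT_ADAPTERS)
    kept, _, _ = qc_pipeline(r1, r2, params)
    again, singles2, summary2 = qc_pipeline(
        [p[0] for p in kept], [p[1] for p in kept], params
    )
    assert summary2.dropped == 0 and not singles2
    assert [(a.seq, b.seq) for a, b in again] == [(a.seq, b.seq) for a, b in kept]


def test_readthrough_reads_clip_at_insert_boundary():
    """With read-through probability 1 and a fixed 80 bp insert, >=99% of
    reads are clipped at the true insert boundary (+/- 1 bp)."""
    config = CommunityConfig(
        seed=5, adapter_readthrough_prob=1.0, short_insert_fraction=1.0,
        short_insert_min=80, short_insert_max=80, error_rate=0.002, n_rate=0.0,
    )
    com = generate_genomes(config)
    r1, r2 = simulate_reads(com, "clip", depths={"buchnera": 10.0})
    params = QcParams(adapters=config.adapters)
    at_boundary = total = 0
    for read in r1 + r2:
        clipped = len(clip_adapter(read, params).seq)
        total += 1
        if abs(clipped - 80) <= 1:
            at_boundary += 1
    assert total > 500
    assert at_boundary / total >= 0.99


def test_fixed_insert_readthrough_places_adapter_at_insert_length():
    """Insert 80, read length 100, read-through probability 1: every read
    carries an adapter prefix starting at position 80."""
    config = CommunityConfig(
        seed=2, adapter_readthrough_prob=1.0, short_insert_fraction=1.0,
        short_insert_min=80, short_insert_max=80, error_rate=0.0, n_rate=0.0,
    )
    com = generate_genomes(config)
    r1, r2 = simulate_reads(com, "adapt", depths={"mitochondrion": 5.0})
    assert r1
    for read in r1 + r2:
        tail = read.seq[80:]
        assert any(a.startswith(tail[:15]) for a in config.adapters)
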