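"""Read QC: adapter clipping, right-tail quality trimming, pair hygiene.

The recipe reproduces a fastx-toolkit-style workflow: ungapped adapter
clipping at the leftmost occurrence (full internal matches plus 3'-terminal
adapter prefixes of at least ``min_adapter_overlap`` bases, each tolerating
a per-window mismatch-rate ceiling), right-tail quality trimming that scans
from the 3' end and stops at the first base at or above the threshold
(default Q20), a minimum surviving length of 50 bp, removal of reads
containing undefined nucleotides, and separation of mates orphaned by any
of the above.

Matching is ungapped by design — proportionate to the source tools; when
several adapters match, the leftmost occurrence wins and ties at the same
position go to the longest match.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .io import SequenceRecord

_DEFINED = frozenset("ACGTacgt")


@dataclass
class QcParams:
    adapters: tuple[str, ...] = ()
    quality_threshold: int = 20
    min_length: int = 50
    max_adapter_mismatch_rate: float = 0.1
    min_adapter_overlap: int = 8

    def __post_init__(self) -> None:
        if self.quality_threshold <= 0 or self.min_length <= 0:
            raise ValueError("thresholds must be positive")
        if not (0 <= self.max_adapter_mismatch_rate < 0.5):
            raise ValueError("max_adapter_mismatch_rate must be in [0, 0.5)")
        self.adapters = tuple(a.upper() for a in self.adapters)


@dataclass
class QcSummary:
    input_reads: int = 0
    kept_pairs: int = 0
    singletons: int = 0
    dropped: int = 0
    clipped: int = 0
    quality_trimmed: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _seq_matrix(seqs: Sequence[str]) -> np.ndarray:
    joined = "".join(seqs).encode("ascii")
    return np.frombuffer(joined, dtype=np.uint8).reshape(len(seqs), -1)


def _clip_positions(seqs: Sequence[str], params: QcParams) -> np.ndarray:
    """Leftmost adapter-match position per read (len(read) when none).

    All reads must share one length; vectorised over the read batch.
    Ties at the same position resolve to the longest compared window, which
    only matters for bookkeeping — the clip point is identical.
    """
    n = len(seqs)
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    L = len(seqs[0])
    mat = _seq_matrix(seqs)
    best = np.full(n, L, dtype=np.int64)
    rate = params.max_adapter_mismatch_rate
    for adapter in params.adapters:
        a = np.frombuffer(adapter.encode("ascii"), dtype=np.uint8)
        alen = len(a)
        for off in range(0, L - params.min_adapter_overlap + 1):
            comp = min(alen, L - off)
            budget = int(rate * comp)
            mm = (mat[:, off : off + comp] != a[:comp]).sum(axis=1)
            hit = mm <= budget
            np.minimum.at(best, np.nonzero(hit)[0], off)
    return best


def clip_adapter(read: SequenceRecord, params: QcParams) -> SequenceRecord:
    """Truncate a read at the leftmost adapter occurrence (no-op if none)."""
    if read.qual is None:
        raise ValueError(f"read {read.id!r} has no qualities")
    pos = _clip_to_fixpoint(read.seq.upper(), params)
    if pos >= len(read.seq):
        return read
    return SequenceRecord(
        id=read.id,
        seq=read.seq[:pos],
        description=read.description,
        qual=read.qual[:pos],
    )


def _clip_to_fixpoint(seq: str, params: QcParams) -> int:
    """Iterate clipping until stable: truncation can expose a 3'-terminal
    partial adapter prefix that a full-length window had out-voted, so a
    single pass is not idempotent."""
    pos = len(seq)
    while True:
        if pos < params.min_adapter_overlap:
            return pos
        new = int(_clip_positions([seq[:pos]], params)[0])
        if new >= pos:
            return pos
        pos = new


def quality_trim(read: SequenceRecord, params: QcParams) -> Optional[SequenceRecord]:
    """Right-tail trim below the quality threshold; drop short survivors.

    Scans right-to-left and stops at the first base whose quality meets the
    threshold (fastx semantics, not a running-sum rule). Returns None when
    the survivor is shorter than ``min_length``.
    """
    if read.qual is None:
        raise ValueError(f"read {read.id!r} has no qualities")
    end = len(read.qual)
    while end > 0 and read.qual[end - 1] < params.quality_threshold:
        end -= 1
    if end < params.min_length:
        return None
    if end == len(read.seq):
        return read
    return SequenceRecord(
        id=read.id, seq=read.seq[:end], description=read.description,
        qual=read.qual[:end],
    )


def _has_undefined(read: SequenceRecord) -> bool:
    return any(c not in _DEFINED for c in read.seq)


def _pair_key(read_id: str) -> str:
    for suffix in ("/1", "/2", ".1", ".2"):
        if read_id.endswith(suffix):
            return read_id[: -len(suffix)]
    return read_id


def filter_pairs(
    pairs: Iterable[tuple[Optional[SequenceRecord], Optional[SequenceRecord]]],
    params: QcParams,
) -> tuple[list[tuple[SequenceRecord, SequenceRecord]], list[SequenceRecord], int]:
    """Drop reads with undefined nucleotides; orphan mates become singletons.

    Accepts pairs where one mate may already be None (failed earlier QC).
    Conservation holds on every input:
    ``2 * kept_pairs + singletons + dropped == input reads``.
    """
    kept: list[tuple[SequenceRecord, SequenceRecord]] = []
    singletons: list[SequenceRecord] = []
    dropped = 0
    for r1, r2 in pairs:
        if r1 is not None and r2 is not None:
            if _pair_key(r1.id) != _pair_key(r2.id):
                raise ValueError(
                    f"unsynchronised mate ids: {r1.id!r} vs {r2.id!r}"
                )
        ok1 = r1 is not None and not _has_undefined(r1)
        ok2 = r2 is not None and not _has_undefined(r2)
        n_failed_now = (r1 is not None and not ok1) + (r2 is not None and not ok2)
        dropped += n_failed_now
        if ok1 and ok2:
            kept.append((r1, r2))
        elif ok1:
            singletons.append(r1)
        elif ok2:
            singletons.append(r2)
    return kept, singletons, dropped


def qc_pipeline(
    reads1: Sequence[SequenceRecord],
    reads2: Sequence[SequenceRecord],
    params: QcParams,
) -> tuple[list[tuple[SequenceRecord, SequenceRecord]], list[SequenceRecord], QcSummary]:
    """Full QC: clip -> quality-trim -> undefined-base/pair filtering.

    Returns (kept pairs, singletons, summary). Read-count conservation:
    ``2*kept_pairs + singletons + dropped == input reads``.
    """
    if len(reads1) != len(reads2):
        raise ValueError("R1 and R2 streams differ in length")
    summary = QcSummary(input_reads=2 * len(reads1))

    def clip_trim_fixpoint(
        reads: Sequence[SequenceRecord],
    ) -> list[Optional[SequenceRecord]]:
        """Batched clip + right-tail trim, iterated jointly to a fixpoint:
        trimming can expose a 3'-terminal partial adapter match (and vice
        versa), so one pass of each is not idempotent."""
        out: list[Optional[SequenceRecord]] = list(reads)
        active = list(range(len(reads)))
        first_round = True
        while active:
            changed: set[int] = set()
            by_len: dict[int, list[int]] = {}
            for i in active:
                by_len.setdefault(len(out[i].seq), []).append(i)
            for L, idxs in by_len.items():
                if L == 0:
                    continue
                pos = _clip_positions([out[i].seq.upper() for i in idxs], params)
                for i, p in zip(idxs, pos):
                    r = out[i]
                    if p < len(r.seq):
                        if first_round:
                            summary.clipped += 1
                        out[i] = SequenceRecord(
                            id=r.id, seq=r.seq[: int(p)],
                            description=r.description, qual=r.qual[: int(p)],
                        )
                        changed.add(i)
            for i in active:
                r = out[i]
                if r is None:
                    continue
                t = quality_trim(r, params)
                if t is None:
                    out[i] = None
                elif len(t) < len(r):
                    if first_round:
                        summary.quality_trimmed += 1
                    out[i] = t
                    changed.add(i)
            active = [i for i in sorted(changed) if out[i] is not None]
            first_round = False
        return out

    pairs = list(zip(clip_trim_fixpoint(reads1), clip_trim_fixpoint(reads2)))
    # quality-dropped reads count as dropped; mates flow into filter_pairs
    pre_dropped = sum((r1 is None) + (r2 is None) for r1, r2 in pairs)
    kept, singles, dropped = filter_pairs(pairs, params)
    summary.kept_pairs = len(kept)
    summary.singletons = len(singles)
    summary.dropped = dropped + pre_dropped
    return kept, singles, summary
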