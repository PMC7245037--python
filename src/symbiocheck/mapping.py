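"""Competitive read mapping with decoy sequences.

A minimal seed-and-verify mapper whose contract is *best single placement
among genes plus decoys*: every read is assigned to the single
highest-scoring ungapped placement across all targets, ties are declared
ambiguous, and reads below the score floor stay unmapped. Including the
competing organism's scaffolds as decoys prevents cross-mapping of reads
from orthologous genes — the property gene-level depth estimates rely on.

Scoring is end-to-end over the read/target overlap: score = matching bases;
placements with more than ``max_mismatch_frac`` mismatches in the overlap,
or an overlap shorter than ``min_overlap``, are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .align import revcomp
from .census import VariantSite
from .io import SequenceRecord


@dataclass
class ReadPlacement:
    read_id: str
    status: str  # mapped | unmapped | ambiguous
    target: Optional[str] = None
    pos: Optional[int] = None  # target coordinate of read base 0 (may be <0)
    strand: Optional[str] = None
    mismatches: int = 0
    overlap: int = 0


@dataclass
class MappingResult:
    placements: list[ReadPlacement]
    n_reads: int
    n_mapped: int
    n_unmapped: int
    n_ambiguous: int
    aligned_bases: dict[str, int]  # per target

    def depth(self, target: str, length: int) -> float:
        return self.aligned_bases.get(target, 0) / length if length else 0.0


class CompetitiveMapper:
    def __init__(
        self,
        targets: dict[str, str],
        decoys: Optional[dict[str, str]] = None,
        k: int = 15,
        seed_step: int = 20,
        max_mismatch_frac: float = 0.10,
        min_overlap: int = 30,
    ):
        self.k = k
        self.seed_step = seed_step
        self.max_mismatch_frac = max_mismatch_frac
        self.min_overlap = min_overlap
        self.targets = dict(targets)
        self.decoy_names = set(decoys or ())
        if decoys:
            self.targets.update(decoys)
        self._index: dict[str, list[tuple[str, int]]] = {}
        for name, seq in self.targets.items():
            for pos in range(len(seq) - k + 1):
                self._index.setdefault(seq[pos : pos + k], []).append((name, pos))

    def _candidates(self, seq: str):
        cands = set()
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            offsets = list(range(0, max(1, len(s) - self.k + 1), self.seed_step))
            last = len(s) - self.k
            if last > 0 and last not in offsets:
                offsets.append(last)
            for off in offsets:
                for name, tpos in self._index.get(s[off : off + self.k], ()):
                    cands.add((name, tpos - off, strand))
        return cands

    def _score(self, seq: str, name: str, pos: int):
        t = self.targets[name]
        t_lo, t_hi = max(0, pos), min(len(t), pos + len(seq))
        overlap = t_hi - t_lo
        if overlap < self.min_overlap:
            return None
        r_lo = t_lo - pos
        mm = sum(
            1
            for a, b in zip(seq[r_lo : r_lo + overlap], t[t_lo:t_hi])
            if a != b
        )
        if mm > self.max_mismatch_frac * overlap:
            return None
        return overlap - mm, mm, overlap

    def map_read(self, read: SequenceRecord) -> ReadPlacement:
        best = None
        best_score = -1
        tied = False
        for name, pos, strand in self._candidates(read.seq):
            seq = read.seq if strand == "+" else revcomp(read.seq)
            scored = self._score(seq, name, pos)
            if scored is None:
                continue
            score, mm, overlap = scored
            if score > best_score:
                best_score = score
                best = (name, pos, strand, mm, overlap)
                tied = False
            elif score == best_score and best is not None:
                if (name, pos, strand) != best[:3]:
                    tied = True
        if best is None:
            return ReadPlacement(read.id, "unmapped")
        if tied:
            return ReadPlacement(read.id, "ambiguous")
        name, pos, strand, mm, overlap = best
        return ReadPlacement(read.id, "mapped", name, pos, strand, mm, overlap)

    def map_reads(self, reads: Iterable[SequenceRecord]) -> MappingResult:
        placements = []
        aligned: dict[str, int] = {}
        n_m = n_u = n_a = 0
        for read in reads:
            p = self.map_read(read)
            placements.append(p)
            if p.status == "mapped":
                n_m += 1
                aligned[p.target] = aligned.get(p.target, 0) + p.overlap
            elif p.status == "ambiguous":
                n_a += 1
            else:
                n_u += 1
        return MappingResult(
            placements=placements,
            n_reads=len(placements),
            n_mapped=n_m,
            n_unmapped=n_u,
            n_ambiguous=n_a,
            aligned_bases=aligned,
        )


def gene_read_coverage(
    genes: dict[str, str],
    decoys: dict[str, str],
    reads_by_library: dict[str, list[SequenceRecord]],
) -> tuple[dict[str, dict[str, float]], dict[str, MappingResult]]:
    """Per-gene per-library mean read depth via competitive mapping.

    Returns (depth[gene][library], mapping result per library). Depth is
    aligned bases over gene length; the mapping results carry the per-fate
    read counts (conserved: mapped + unmapped + ambiguous == library size).
    """
    mapper = CompetitiveMapper(genes, decoys)
    depths: dict[str, dict[str, float]] = {g: {} for g in genes}
    results = {}
    for lib, reads in reads_by_library.items():
        res = mapper.map_reads(reads)
        results[lib] = res
        for g, seq in genes.items():
            depths[g][lib] = res.depth(g, len(seq))
    return depths, results


def variant_fraction(
    result: MappingResult,
    reads: Iterable[SequenceRecord],
    target: str,
    site_pos: int,
    ref_codon: str,
    alt_codon: str,
    min_depth: int = 10,
) -> VariantSite:
    """Count ref/alt/other codons among uniquely-placed reads spanning the
    full codon at ``site_pos`` on ``target``.

    ``reads`` must be the same sequence, in the same order, that produced
    ``result`` (placements pair with reads by position).
    """
    n_ref = n_alt = n_other = 0
    for p, read in zip(result.placements, reads):
        if p.status != "mapped" or p.target != target:
            continue
        seq = read.seq if p.strand == "+" else revcomp(read.seq)
        off = site_pos - p.pos
        if off < 0 or off + 3 > len(seq):
            continue
        codon = seq[off : off + 3]
        if codon == ref_codon:
            n_ref += 1
        elif codon == alt_codon:
            n_alt += 1
        else:
            n_other += 1
    total = n_ref + n_alt + n_other
    return VariantSite(
        position=site_pos,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        alt_count=n_alt,
        ref_count=n_ref,
        other_count=n_other,
        low_confidence=total < min_depth,
    )
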