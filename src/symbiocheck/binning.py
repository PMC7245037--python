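"""Scaffold binning by best translated hit.

The workflow mirrors the standard curated-database approach for separating
endosymbiont, organelle and host scaffolds in a pooled assembly:

1. drop scaffolds shorter than ``min_scaffold_len`` or with k-mer coverage
   below ``min_scaffold_cov`` (strict inequalities: boundary values kept);
2. translated search (six-frame) of each kept scaffold against curated
   per-organism protein sets, e-value cutoff 1e-3;
3. assign each scaffold to the organism of its single best hit (by bit
   score), reporting the margin to the best hit of any other organism;
4. filter bacterial bins at a minimum k-mer coverage of 10 and summarise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

from . import align
from .io import Scaffold

UNASSIGNED = "UNASSIGNED"


@dataclass
class BinningParams:
    min_scaffold_len: int = 200
    min_scaffold_cov: float = 3.0
    min_bin_cov: float = 10.0
    evalue_max: float = 1e-3
    engine: str = "internal"  # or "external-tabular"
    bacterial_labels: tuple[str, ...] = ("buchnera", "wolbachia")

    def __post_init__(self) -> None:
        if min(self.min_scaffold_len, self.min_scaffold_cov, self.min_bin_cov) <= 0:
            raise ValueError("all thresholds must be positive")
        if not (0 < self.evalue_max <= 1):
            raise ValueError("evalue_max must be in (0, 1]")


@dataclass
class TranslatedHit:
    """One scored translated-alignment hit (nt query vs aa subject)."""

    scaffold_id: str
    protein_id: str
    organism_label: str
    frame: int  # -3..-1, +1..+3
    raw_score: float
    bitscore: float
    evalue: float
    query_start: int  # bp on scaffold forward strand, 0-based half-open
    query_end: int
    subject_start: int  # aa on protein
    subject_end: int


@dataclass
class BinAssignment:
    scaffold_id: str
    organism_label: str  # or UNASSIGNED
    best_hit: Optional[TranslatedHit]
    margin_bits: float  # best bitscore minus best other-organism bitscore
    ambiguous: bool = False


@dataclass
class BinSummary:
    organism: str
    n_scaffolds: int
    total_bp: int
    mean_kmer_cov: float  # unweighted; NaN when empty
    weighted_mean_kmer_cov: float  # length-weighted; NaN when empty


class ProteinDB:
    """Curated amino-acid database with per-protein organism labels.

    Built from parallel lists or from a multi-FASTA plus a manifest TSV
    (``protein_id<TAB>organism``). The word index used for seeding is
    built lazily and cached.
    """

    def __init__(self, ids: list[str], organisms: list[str], seqs: list[str]):
        if not ids:
            raise ValueError("empty protein database")
        if not (len(ids) == len(organisms) == len(seqs)):
            raise ValueError("ids, organisms and seqs must be parallel")
        self.ids = list(ids)
        self.organisms = list(organisms)
        self.seqs = [s.upper() for s in seqs]
        self.total_aa = sum(len(s) for s in self.seqs)
        self._index = None

    @classmethod
    def from_fasta(cls, fasta_path, manifest_path) -> "ProteinDB":
        from .io import read_fasta

        labels: dict[str, str] = {}
        with open(manifest_path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ValueError(
                        f"{manifest_path}: line {lineno}: expected "
                        "'protein_id<TAB>organism'"
                    )
                labels[parts[0]] = parts[1]
        ids, orgs, seqs = [], [], []
        for rec in read_fasta(fasta_path):
            if rec.id not in labels:
                raise ValueError(f"protein {rec.id!r} missing from manifest")
            ids.append(rec.id)
            orgs.append(labels[rec.id])
            seqs.append(rec.seq)
        return cls(ids, orgs, seqs)

    @property
    def word_index(self):
        if self._index is None:
            self._index = align.build_word_index(self.seqs)
        return self._index


def filter_scaffolds(
    scaffolds: Iterable[Scaffold], params: BinningParams
) -> tuple[list[Scaffold], list[tuple[Scaffold, str]]]:
    """Length/coverage pre-filter. Returns (kept, [(dropped, reason)])."""
    kept, dropped = [], []
    for sc in scaffolds:
        if sc.kmer_cov is None:
            raise ValueError(
                f"scaffold {sc.id!r} has no coverage; supply a sidecar "
                "coverage table (id<TAB>kmer_cov)"
            )
        if sc.length < params.min_scaffold_len:
            dropped.append((sc, f"length {sc.length} < {params.min_scaffold_len}"))
        elif sc.kmer_cov < params.min_scaffold_cov:
            dropped.append((sc, f"coverage {sc.kmer_cov} < {params.min_scaffold_cov}"))
        else:
            kept.append(sc)
    return kept, dropped


def translated_search(
    scaffold: Scaffold, db: ProteinDB, params: BinningParams
) -> list[TranslatedHit]:
    """Six-frame translated search of one scaffold against the database.

    For each (frame, protein) pair that passes two-hit seeding, the exact
    optimal local alignment is computed; hits above the e-value cutoff are
    discarded. One HSP (the optimal one) is reported per (frame, protein).
    """
    hits: list[TranslatedHit] = []
    frames = align.six_frame_translate(scaffold.seq)
    for frame, aa in frames.items():
        if len(aa) < align.WORD_SIZE:
            continue
        for pi in align.seeded_pairs(aa, db.word_index):
            prot = db.seqs[pi]
            score, qs, qe, ss, se = align.local_align(aa, prot)
            if score <= 0:
                continue
            ev = align.evalue(score, len(aa), db.total_aa)
            if ev > params.evalue_max:
                continue
            nt_start, nt_end = align.frame_to_nt_span(frame, qs, qe, scaffold.length)
            hits.append(
                TranslatedHit(
                    scaffold_id=scaffold.id,
                    protein_id=db.ids[pi],
                    organism_label=db.organisms[pi],
                    frame=frame,
                    raw_score=score,
                    bitscore=align.bitscore(score),
                    evalue=ev,
                    query_start=nt_start,
                    query_end=nt_end,
                    subject_start=ss,
                    subject_end=se,
                )
            )
    return hits


def parse_tabular_hits(path, manifest: dict[str, str]) -> list[TranslatedHit]:
    """Parse BLAST-style 12-column tabular hits (blastx conventions).

    ``manifest`` maps subject protein ids to organism labels. Query
    coordinates are converted from 1-based inclusive (possibly reversed for
    minus-frame hits) to 0-based half-open forward-strand spans.
    """
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise ValueError(
                    f"{path}: line {lineno}: expected >=12 tab-separated columns"
                )
            try:
                (qseqid, sseqid, _pident, _length, _mm, _go,
                 qstart, qend, sstart, send, ev, bits) = parts[:12]
                qstart, qend = int(qstart), int(qend)
                sstart, send = int(sstart), int(send)
                ev, bits = float(ev), float(bits)
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
            if sseqid not in manifest:
                raise ValueError(
                    f"{path}: line {lineno}: subject {sseqid!r} not in manifest"
                )
            if qstart <= qend:
                frame = qstart % 3 or 3
                q0, q1 = qstart - 1, qend
            else:
                frame = -((qend - 1) % 3 + 1)
                q0, q1 = qend - 1, qstart
            hits.append(
                TranslatedHit(
                    scaffold_id=qseqid,
                    protein_id=sseqid,
                    organism_label=manifest[sseqid],
                    frame=frame,
                    raw_score=(bits * align.LN2 + math.log(align.KA_K)) / align.KA_LAMBDA,
                    bitscore=bits,
                    evalue=ev,
                    query_start=q0,
                    query_end=q1,
                    subject_start=sstart - 1,
                    subject_end=send,
                )
            )
    return hits


def _hit_rank_key(h: TranslatedHit):
    # higher bitscore first; ties by lower e-value, longer query span,
    # lexicographic protein id
    return (-h.bitscore, h.evalue, -(h.query_end - h.query_start), h.protein_id)


def assign_bins(
    hits: Iterable[TranslatedHit], scaffolds: Iterable[Scaffold]
) -> list[BinAssignment]:
    """One assignment per scaffold: organism of the single best hit."""
    by_scaffold: dict[str, list[TranslatedHit]] = {}
    for h in hits:
        by_scaffold.setdefault(h.scaffold_id, []).append(h)
    out = []
    for sc in scaffolds:
        shits = sorted(by_scaffold.get(sc.id, []), key=_hit_rank_key)
        if not shits:
            out.append(BinAssignment(sc.id, UNASSIGNED, None, math.nan))
            continue
        best = shits[0]
        ambiguous = (
            len(shits) > 1
            and shits[1].organism_label != best.organism_label
            and shits[1].bitscore == best.bitscore
        )
        other = [h for h in shits if h.organism_label != best.organism_label]
        margin = best.bitscore - other[0].bitscore if other else math.inf
        out.append(
            BinAssignment(sc.id, best.organism_label, best, margin, ambiguous)
        )
    return out


def finalize_bins(
    assignments: Iterable[BinAssignment],
    scaffolds: Iterable[Scaffold],
    params: BinningParams,
) -> tuple[dict[str, list[Scaffold]], dict[str, BinSummary]]:
    """Group scaffolds into bins, apply the bacterial bin-coverage filter,
    and summarise each bin (unweighted and length-weighted mean coverage)."""
    sc_by_id = {sc.id: sc for sc in scaffolds}
    bins: dict[str, list[Scaffold]] = {}
    for a in assignments:
        sc = sc_by_id[a.scaffold_id]
        if (
            a.organism_label in params.bacterial_labels
            and sc.kmer_cov < params.min_bin_cov
        ):
            continue
        bins.setdefault(a.organism_label, []).append(sc)
    summaries = {}
    for org, members in bins.items():
        n = len(members)
        total_bp = sum(sc.length for sc in members)
        if n == 0:
            summaries[org] = BinSummary(org, 0, 0, math.nan, math.nan)
            continue
        mean_cov = sum(sc.kmer_cov for sc in members) / n
        wmean = sum(sc.kmer_cov * sc.length for sc in members) / total_bp
        summaries[org] = BinSummary(org, n, total_bp, mean_cov, wmean)
    return bins, summaries
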