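"""Synthetic four-organism holobiont community with planted ground truth.

Emulates the sequencing data of a banana-aphid whole-body extraction: an
A+T-rich primary endosymbiont (Buchnera-like) at high coverage, a
facultative intracellular bacterium (Wolbachia-like) at very high coverage,
the host nuclear background at low coverage, and the mitochondrion.
Coverages default to the bin coverages such datasets show (110x and 396x
for the two bacteria). Reads carry TruSeq index adapters plus a T+G-rich
contaminant on short-insert read-through, substitution errors, occasional
undefined bases, and 3'-decaying qualities.

Planted truth covers every downstream stage:

* scaffold -> organism labels (plus deliberately junk scaffolds below the
  length/coverage pre-filters);
* a nutritional gene panel embedded in the Buchnera-like genome with
  statuses INTACT, FRAMESHIFT_LC (single indels inside forced homopolymer
  runs), FRAMESHIFT_OTHER (indel in a high-entropy context),
  TRUNCATED, ABSENT, CONTAMINANT_INSERTION (the T+G contaminant spliced
  into the gene at a fixed position, as assembled read-through produces);
* a two-allele premature-stop site (TAG consensus / CAG variant at a
  configured fraction, default 13.4%);
* one intact gene placed on a scaffold whose best translated hits belong
  to the Wolbachia-like organism, so bin-escape rescue is exercised;
* divergent Wolbachia-like homologs of several genes (default 40% amino
  acid divergence) that make best-hit binning well-posed and provide
  cross-mapping decoys.

Everything is a deterministic function of the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from Bio.Data import CodonTable

from .align import revcomp, translate_nt
from .binning import ProteinDB
from .census import GeneQuery, GeneStatus
from .io import Scaffold, SequenceRecord

#: the T+G-rich adapter contaminant observed in the emulated libraries
TG_CONTAMINANT = "TGTGTTGGGTGTGTTGGGTGTGTTGGGTGTGTTGGGTGTGTTGGGTGTGT"

_TRUSEQ_CORE = "GATCGGAAGAGCACACGTCTGAACTCCAGTCAC"
_TRUSEQ_TAIL = "ATCTCGTATGCCGTCTTCTGCTTG"
TRUSEQ_ADAPTERS = (
    _TRUSEQ_CORE + "TGACCA" + _TRUSEQ_TAIL,  # index 4
    _TRUSEQ_CORE + "ACAGTG" + _TRUSEQ_TAIL,  # index 5
    _TRUSEQ_CORE + "GCCAAT" + _TRUSEQ_TAIL,  # index 6
)

DEFAULT_ADAPTERS = TRUSEQ_ADAPTERS + (TG_CONTAMINANT,)

BUCHNERA = "buchnera"
WOLBACHIA = "wolbachia"
HOST = "host"
MITO = "mitochondrion"
ORGANISMS = (BUCHNERA, WOLBACHIA, HOST, MITO)

#: nutritional gene panel (essential amino acids, B vitamins, co-factors)
#: plus two non-nutritional controls (mutS, recA) that small A+T-rich
#: endosymbiont genomes routinely erode
PANEL_GENES = (
    "trpA", "trpB", "trpC", "trpD", "trpE", "trpG",
    "ilvC", "ilvD", "metE",
    "fabB", "bioA", "bioB", "bioD",
    "ribA", "ribD", "ribE", "ribH",
    "lipA", "lipB",
    "pgi", "pgm",
    "mutS", "recA",
)

#: genes with a divergent Wolbachia-like homolog (cross-mapping decoys)
WOLBACHIA_HOMOLOGS = ("trpG", "bioA", "lipA", "fabB", "ribD", "metE")
WOLBACHIA_MARKERS = ("groLw", "wspA", "ftsZw", "dnaAw", "secAw", "virB4")
HOST_GENES = ("actB", "ef1a", "rpL7", "gapdh", "tubA")
MITO_GENES = ("cox1", "cox2", "cob", "nad1")


@dataclass
class CommunityConfig:
    seed: int = 0
    read_length: int = 100
    insert_mean: float = 350.0
    insert_sd: float = 50.0
    error_rate: float = 0.002
    n_rate: float = 0.0005  # per-base chance of an undefined call
    adapters: tuple[str, ...] = DEFAULT_ADAPTERS
    adapter_readthrough_prob: float = 1.0
    short_insert_fraction: float = 0.10
    short_insert_min: int = 55
    short_insert_max: Optional[int] = None  # default: read_length - 1
    gc: dict = field(
        default_factory=lambda: {BUCHNERA: 0.25, WOLBACHIA: 0.35, HOST: 0.32, MITO: 0.20}
    )
    kmer_cov: dict = field(
        default_factory=lambda: {BUCHNERA: 110.0, WOLBACHIA: 396.0, HOST: 10.0, MITO: 60.0}
    )
    n_scaffolds: dict = field(
        default_factory=lambda: {BUCHNERA: 4, WOLBACHIA: 3, HOST: 3, MITO: 1}
    )
    #: per-library per-organism read depth (fold coverage); the three
    #: libraries echo the strong between-library imbalance of the emulated
    #: dataset (endosymbiont-poor, -rich, intermediate)
    libraries: dict = field(
        default_factory=lambda: {
            "lib1": {BUCHNERA: 3.0, WOLBACHIA: 200.0, HOST: 60.0, MITO: 30.0},
            "lib2": {BUCHNERA: 110.0, WOLBACHIA: 150.0, HOST: 60.0, MITO: 20.0},
            "lib3": {BUCHNERA: 12.0, WOLBACHIA: 96.0, HOST: 60.0, MITO: 10.0},
        }
    )
    aa_divergence: float = 0.40
    gene_len_range: tuple[int, int] = (160, 260)
    spacer_range: tuple[int, int] = (70, 140)
    minus_strand_prob: float = 0.35
    frameshift_run_length: int = 7
    stop_variant_fraction: float = 0.134
    drop_genes: tuple[str, ...] = ()  # planted genes to leave out entirely
    plant_binescape: bool = True
    include_junk_scaffolds: bool = True

    def __post_init__(self) -> None:
        for org, g in self.gc.items():
            if not 0 < g < 1:
                raise ValueError(f"GC for {org} must be in (0,1)")
        for lib, d in self.libraries.items():
            for org, depth in d.items():
                if depth < 0:
                    raise ValueError(f"negative depth for {org} in {lib}")
        if not 0 <= self.stop_variant_fraction <= 1:
            raise ValueError("stop_variant_fraction must be in [0,1]")


#: default plant plan: gene -> (status, details)
DEFAULT_PLANTS = {
    "bioA": (GeneStatus.FRAMESHIFT_LC, {"base": "A", "indel": +1}),
    "fabB": (GeneStatus.FRAMESHIFT_LC, {"base": "T", "indel": -1}),
    "trpG": (GeneStatus.FRAMESHIFT_LC, {"base": "A", "indel": +1, "stop": True}),
    "mutS": (GeneStatus.FRAMESHIFT_OTHER, {"indel": -1}),
    "recA": (GeneStatus.TRUNCATED, {"keep_frac": 0.65}),
    "lipA": (GeneStatus.CONTAMINANT_INSERTION, {"at_frac": 0.5}),
    "pgi": (GeneStatus.CONTAMINANT_INSERTION, {"at_frac": 0.4}),
    "pgm": (GeneStatus.ABSENT, {}),
}

BIN_ESCAPE_GENE = "trpE"


@dataclass
class PlantedGene:
    symbol: str
    organism: str
    status: GeneStatus
    scaffold_id: Optional[str] = None
    start: Optional[int] = None
    end: Optional[int] = None
    strand: Optional[str] = None
    disruptions: list = field(default_factory=list)  # (scaffold_pos, kind)
    bin_escape: bool = False
    nt_seq: str = ""  # final genomic sequence, gene-forward


@dataclass
class VariantTruth:
    scaffold_id: str
    position: int  # codon start, scaffold coordinates
    gene: str
    ref_codon: str
    alt_codon: str
    fraction: float


@dataclass
class TruthSet:
    scaffold_organism: dict = field(default_factory=dict)
    expected_filtered: set = field(default_factory=set)
    genes: dict = field(default_factory=dict)  # symbol -> PlantedGene
    variant: Optional[VariantTruth] = None
    read_origin: dict = field(default_factory=dict)  # read id -> organism


@dataclass
class Community:
    config: CommunityConfig
    scaffolds: list  # list[Scaffold]
    truth: TruthSet
    panel: list  # list[GeneQuery] — the census query panel
    protein_db: ProteinDB  # curated binning database


# ---------------------------------------------------------------------------
# sequence construction helpers

_AA20 = "ACDEFGHIKLMNPQRSTVWY"
_table11 = CodonTable.unambiguous_dna_by_id[11]
_CODONS_BY_AA: dict[str, list[str]] = {}
for _codon, _aa in _table11.forward_table.items():
    _CODONS_BY_AA.setdefault(_aa, []).append(_codon)
for _aa in _CODONS_BY_AA:
    _CODONS_BY_AA[_aa].sort()


def _codon_weights(gc: float) -> dict[str, np.ndarray]:
    p = {"G": gc / 2, "C": gc / 2, "A": (1 - gc) / 2, "T": (1 - gc) / 2}
    out = {}
    for aa, codons in _CODONS_BY_AA.items():
        w = np.array([p[c[0]] * p[c[1]] * p[c[2]] for c in codons])
        out[aa] = w / w.sum()
    return out


def random_nt(rng: np.random.Generator, length: int, gc: float) -> str:
    bases = np.array(list("ACGT"))
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(bases, size=length, p=p))


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_AA20), size=length))


def reverse_translate(
    rng: np.random.Generator, aa_seq: str, weights: dict[str, np.ndarray]
) -> str:
    parts = []
    for aa in aa_seq:
        codons = _CODONS_BY_AA[aa]
        parts.append(codons[rng.choice(len(codons), p=weights[aa])])
    return "".join(parts)


def _diverge_protein(rng: np.random.Generator, aa_seq: str, divergence: float) -> str:
    out = list(aa_seq)
    for i in range(len(out)):
        if rng.random() < divergence:
            choices = _AA20.replace(out[i], "")
            out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


_STOPS = ("TAA", "TAG", "TGA")


def _nt_rate_for_aa_divergence(aa_divergence: float) -> float:
    """Invert the (approximate) relation between per-base substitution rate
    and amino-acid divergence: aa_div ~ 0.75 * (1 - (1-r)^3)."""
    target = min(0.99, aa_divergence / 0.75)
    return 1.0 - (1.0 - target) ** (1.0 / 3.0)


def _diverge_nt(rng: np.random.Generator, nt: str, rate: float) -> str:
    """Ortholog CDS by per-base substitution of the reference CDS (keeps
    codon structure; no stop codons introduced)."""
    out = list(nt)
    for i in range(len(out)):
        if rng.random() < rate:
            choices = "ACGT".replace(out[i], "")
            out[i] = choices[rng.integers(3)]
    # repair any codon that became a stop
    for c0 in range(0, len(out) - 2, 3):
        codon = "".join(out[c0 : c0 + 3])
        while codon in _STOPS:
            out[c0 + 2] = "ACGT"[rng.integers(4)]
            codon = "".join(out[c0 : c0 + 3])
    return "".join(out)


def _force_homopolymer(nt: str, codon_idx: int, base: str, run: int) -> str:
    """Overwrite codons from ``codon_idx`` with a ``run``-long homopolymer
    padded to a codon boundary, avoiding stop codons."""
    pad_base = {"A": "T", "T": "G", "C": "A", "G": "A"}[base]
    total = 3 * math.ceil((run + 1) / 3)
    block = (base * run + pad_base * (total - run))
    # guard against creating a stop codon (TAA/TAG/TGA)
    codons = [block[i : i + 3] for i in range(0, total, 3)]
    for k, c in enumerate(codons):
        if c in ("TAA", "TAG", "TGA"):
            codons[k] = c[:2] + "C"
    block = "".join(codons)
    p0 = 3 * codon_idx
    return nt[:p0] + block + nt[p0 + total :]


def _search_plant_site(
    symbol: str,
    protein: str,
    nt: str,
    n_aa: int,
    edit,
    shift: int,
    require_high_entropy: bool,
    centre: Optional[int] = None,
):
    """Pick a codon index for a disruptive edit whose neighbourhood makes the
    planted position recoverable at codon resolution.

    ``edit(c)`` applies the edit at codon boundary 3c; ``shift`` is the net
    length change. The chosen site guarantees that around the junction the
    correct reading frame matches the reference protein on exactly one side:
    residues just upstream must not match by chance in the *downstream*
    frame and vice versa — otherwise the disruption's codon-level position
    is genuinely ambiguous and no detector could recover it.
    """
    from .census import CensusParams, detect_low_complexity

    cp = CensusParams()
    if centre is None:
        centre = n_aa // 2
    for delta in range(n_aa // 2):
        for c in (centre + delta, centre - delta):
            if not 12 < c < n_aa - 12:
                continue
            trial = edit(c)
            p = 3 * c
            if require_high_entropy:
                window = trial[max(0, p - 10) : p + 11]
                if detect_low_complexity(window, cp):
                    continue
            ok = True
            # downstream-frame readings of upstream residues must mismatch
            for i in range(c - 6, c):
                codon = trial[3 * i + shift : 3 * i + shift + 3]
                if len(codon) == 3 and translate_nt(codon) == protein[i]:
                    ok = False
                    break
            if not ok:
                continue
            # upstream-frame readings of the junction and downstream
            # residues must mismatch
            for i in range(c, c + 7):
                codon = trial[3 * i : 3 * i + 3]
                if len(codon) == 3 and translate_nt(codon) == protein[i]:
                    ok = False
                    break
            if not ok:
                continue
            # downstream-frame reading of the junction residue itself:
            # for insertions it is structurally intact (the shifted original
            # codon); for deletions require a mismatch so the tie plateau is
            # exactly {c, c+1}
            if shift < 0:
                codon = trial[3 * c + shift : 3 * c + shift + 3]
                if len(codon) == 3 and translate_nt(codon) == protein[c]:
                    continue
            return c, trial
    raise ValueError(f"no clean plant site found in {symbol}")


# ---------------------------------------------------------------------------
# genome generation


def _build_gene(
    rng: np.random.Generator,
    symbol: str,
    config: CommunityConfig,
    weights,
    plant: Optional[tuple[GeneStatus, dict]],
    n_aa_override: Optional[int] = None,
):
    """Build one Buchnera-like gene: reference protein, genomic nt sequence,
    and gene-local truth annotations.

    Returns (protein, nt_genome, status, disruptions, stop_site) where
    disruptions are (gene-forward position, kind) and stop_site is the
    gene-forward codon start of a planted premature stop (or None).
    """
    lo, hi = config.gene_len_range
    n_aa = n_aa_override if n_aa_override is not None else int(rng.integers(lo, hi + 1))
    aa0 = random_protein(rng, n_aa)
    nt = reverse_translate(rng, aa0, weights)

    status = GeneStatus.INTACT
    details: dict = {}
    if plant is not None:
        status, details = plant

    disruptions: list[tuple[int, str]] = []
    stop_site = None

    if status in (GeneStatus.FRAMESHIFT_LC,):
        run = config.frameshift_run_length
        c0 = n_aa // 3
        nt = _force_homopolymer(nt, c0, details["base"], run)
    protein = translate_nt(nt)
    assert "*" not in protein
    nt_ref = nt  # reference CDS before any disruptive edit

    if status is GeneStatus.FRAMESHIFT_LC:
        base = details["base"]
        indel = details["indel"]
        p0 = 3 * (n_aa // 3)
        if details.get("stop"):
            k = int(n_aa * 0.6)
            nt = nt[: 3 * k] + "TAG" + nt[3 * k + 3 :]
            stop_site = 3 * k
        if indel > 0:
            nt = nt[: p0 + 1] + base * indel + nt[p0 + 1 :]
        else:
            nt = nt[:p0] + nt[p0 - indel :]
        if stop_site is not None and stop_site > p0:
            stop_site += indel
            disruptions.append((stop_site, "premature_stop"))
        # truth position: centre of the (post-indel) run containing p0 —
        # the indel's phase inside a homopolymer is intrinsically ambiguous
        rs = p0
        while rs > 0 and nt[rs - 1] == base:
            rs -= 1
        re_ = p0
        while re_ < len(nt) and nt[re_] == base:
            re_ += 1
        disruptions.insert(0, (rs + (re_ - rs) // 2, "insertion" if indel > 0 else "deletion"))
    elif status is GeneStatus.FRAMESHIFT_OTHER:
        indel = details["indel"]
        if indel >= 0:
            raise ValueError("FRAMESHIFT_OTHER plant expects a deletion")
        chosen = _search_plant_site(
            symbol, protein, nt, n_aa,
            lambda c: nt[: 3 * c] + nt[3 * c - indel :],
            shift=indel, require_high_entropy=True,
        )
        c, nt = chosen
        disruptions.append((3 * c, "deletion"))
    elif status is GeneStatus.TRUNCATED:
        keep = 3 * int(n_aa * details["keep_frac"])
        nt = nt[:keep]
    elif status is GeneStatus.CONTAMINANT_INSERTION:
        c0 = int(n_aa * details["at_frac"])
        chosen = _search_plant_site(
            symbol, protein, nt, n_aa,
            lambda c: nt[: 3 * c] + TG_CONTAMINANT + nt[3 * c :],
            shift=len(TG_CONTAMINANT), require_high_entropy=False, centre=c0,
        )
        c, nt = chosen
        disruptions.append((3 * c, "insertion"))

    return protein, nt, nt_ref, status, disruptions, stop_site


def generate_genomes(config: CommunityConfig) -> Community:
    """Generate the four-organism scaffold set with full planted truth."""
    rng = np.random.default_rng(config.seed)
    weights = {org: _codon_weights(config.gc[org]) for org in ORGANISMS}
    truth = TruthSet()

    # --- Buchnera-like panel
    panel: list[GeneQuery] = []
    buch_genes: dict[str, dict] = {}  # symbol -> build info
    for symbol in PANEL_GENES:
        plant = DEFAULT_PLANTS.get(symbol)
        # the bin-escape gene is kept at the panel-minimum length so the
        # long Wolbachia anchor gene on its scaffold always wins the
        # best-hit contest (the misassignment is *by construction*)
        override = (
            config.gene_len_range[0]
            if symbol == BIN_ESCAPE_GENE and config.plant_binescape
            else None
        )
        protein, nt, nt_ref, status, disr, stop_site = _build_gene(
            rng, symbol, config, weights[BUCHNERA], plant, n_aa_override=override
        )
        panel.append(GeneQuery(symbol=symbol, aa_seq=protein, source_tag="ref"))
        if status is GeneStatus.ABSENT or symbol in config.drop_genes:
            truth.genes[symbol] = PlantedGene(
                symbol=symbol, organism=BUCHNERA, status=GeneStatus.ABSENT
            )
            continue
        buch_genes[symbol] = dict(
            nt=nt, nt_ref=nt_ref, status=status, disruptions=disr,
            stop_site=stop_site,
        )

    # --- other organisms' proteins
    db_ids: list[str] = [q.symbol for q in panel]
    db_orgs: list[str] = [BUCHNERA] * len(panel)
    db_seqs: list[str] = [q.aa_seq for q in panel]

    other_genes: dict[str, dict[str, str]] = {WOLBACHIA: {}, HOST: {}, MITO: {}}
    nt_rate = _nt_rate_for_aa_divergence(config.aa_divergence)
    for symbol in WOLBACHIA_HOMOLOGS:
        if symbol not in buch_genes:
            continue  # dropped/absent genes have no ortholog to derive
        hom_nt = _diverge_nt(rng, buch_genes[symbol]["nt_ref"], nt_rate)
        hom = translate_nt(hom_nt)
        other_genes[WOLBACHIA][symbol + "_w"] = hom_nt
        db_ids.append(symbol + "_w")
        db_orgs.append(WOLBACHIA)
        db_seqs.append(hom)
    for org, symbols in ((WOLBACHIA, WOLBACHIA_MARKERS), (HOST, HOST_GENES), (MITO, MITO_GENES)):
        for symbol in symbols:
            if symbol == "groLw":
                n_aa = int(rng.integers(340, 381))  # bin-escape anchor
            elif org == WOLBACHIA:
                n_aa = int(rng.integers(220, 320))
            else:
                n_aa = int(rng.integers(*config.gene_len_range))
            aa = random_protein(rng, n_aa)
            other_genes[org][symbol] = reverse_translate(rng, aa, weights[org])
            db_ids.append(symbol)
            db_orgs.append(org)
            db_seqs.append(aa)

    # --- lay genes onto scaffolds
    node_counter = [0]
    scaffolds: list[Scaffold] = []

    def cov_jitter(n: int) -> list[float]:
        pattern = [-4.0, 4.0, -2.0, 2.0, -1.0, 1.0]
        j = pattern[: n - n % 2]
        if n % 2:
            j = j + [0.0]
        return j

    def emit_scaffold(org: str, parts: list, cov: float) -> str:
        """parts: ('spacer', nt) or ('gene', symbol, nt, strand, disr, stop)"""
        seq_parts = []
        offset = 0
        gene_info = []
        for part in parts:
            if part[0] == "spacer":
                seq_parts.append(part[1])
                offset += len(part[1])
            else:
                _tag, symbol, nt, strand, disr, stop_site = part
                placed = nt if strand == "+" else revcomp(nt)
                gene_info.append((symbol, offset, len(nt), strand, disr, stop_site))
                seq_parts.append(placed)
                offset += len(placed)
        seq = "".join(seq_parts)
        node_counter[0] += 1
        sid = f"NODE_{node_counter[0]}_length_{len(seq)}_cov_{cov:.1f}"
        scaffolds.append(Scaffold(id=sid, seq=seq, kmer_cov=cov))
        truth.scaffold_organism[sid] = org
        L = len(seq)
        for symbol, g_start, g_len, strand, disr, stop_site in gene_info:
            if strand == "+":
                conv = lambda p: g_start + p
                span = (g_start, g_start + g_len)
            else:
                conv = lambda p: g_start + g_len - 1 - p
                span = (g_start, g_start + g_len)
            if symbol in truth.genes:  # placed Buchnera gene
                pg = truth.genes[symbol]
                pg.scaffold_id = sid
                pg.start, pg.end = span
                pg.strand = strand
                pg.disruptions = [(conv(p), kind) for p, kind in disr]
                if stop_site is not None and pg.symbol == "trpG":
                    truth.variant = VariantTruth(
                        scaffold_id=sid,
                        position=conv(stop_site) - (2 if strand == "-" else 0),
                        gene=symbol,
                        ref_codon="TAG" if strand == "+" else revcomp("TAG"),
                        alt_codon="CAG" if strand == "+" else revcomp("CAG"),
                        fraction=config.stop_variant_fraction,
                    )
        return sid

    def spacer(org: str) -> tuple:
        lo, hi = config.spacer_range
        return ("spacer", random_nt(rng, int(rng.integers(lo, hi + 1)), config.gc[org]))

    def edge_spacer(org: str) -> tuple:
        # insert-sized terminal spacers keep genes clear of the paired-end
        # coverage ramp at scaffold ends (real contigs dwarf the insert size)
        span = int(config.insert_mean + 2 * config.insert_sd)
        return ("spacer", random_nt(rng, span, config.gc[org]))

    # Buchnera scaffolds: round-robin panel genes (disrupted genes on '+'
    # so planted coordinates are straightforward to audit)
    placed_symbols = [s for s in buch_genes]
    bin_escape_symbol = BIN_ESCAPE_GENE if config.plant_binescape else None
    if bin_escape_symbol in placed_symbols:
        placed_symbols.remove(bin_escape_symbol)
    n_b = config.n_scaffolds[BUCHNERA]
    groups: list[list[str]] = [placed_symbols[i::n_b] for i in range(n_b)]
    for symbol in placed_symbols:
        info = buch_genes[symbol]
        has_plant = symbol in DEFAULT_PLANTS
        strand = "+" if has_plant else ("-" if rng.random() < config.minus_strand_prob else "+")
        info["strand"] = strand
        truth.genes[symbol] = PlantedGene(
            symbol=symbol, organism=BUCHNERA, status=info["status"]
        )
    jit = cov_jitter(n_b)
    for gi, group in enumerate(groups):
        parts: list = [edge_spacer(BUCHNERA)]
        for symbol in group:
            info = buch_genes[symbol]
            parts.append(
                ("gene", symbol, info["nt"], info["strand"], info["disruptions"], info["stop_site"])
            )
            parts.append(spacer(BUCHNERA))
        parts.append(edge_spacer(BUCHNERA))
        emit_scaffold(BUCHNERA, parts, config.kmer_cov[BUCHNERA] + jit[gi])

    # Wolbachia scaffolds; the first carries the bin-escape Buchnera gene
    w_items = list(other_genes[WOLBACHIA].items())
    n_w = config.n_scaffolds[WOLBACHIA]
    w_groups = [w_items[i::n_w] for i in range(n_w)]
    jit = cov_jitter(n_w)
    for gi, group in enumerate(w_groups):
        parts = [edge_spacer(WOLBACHIA)]
        for name, nt in group:
            strand = "-" if rng.random() < config.minus_strand_prob else "+"
            parts.append(("gene", name, nt, strand, [], None))
            parts.append(spacer(WOLBACHIA))
        if gi == 0 and bin_escape_symbol and bin_escape_symbol in buch_genes:
            info = buch_genes[bin_escape_symbol]
            truth.genes[bin_escape_symbol] = PlantedGene(
                symbol=bin_escape_symbol,
                organism=BUCHNERA,
                status=info["status"],
                bin_escape=True,
            )
            parts.append(("gene", bin_escape_symbol, info["nt"], "+", [], None))
            parts.append(spacer(WOLBACHIA))
        parts.append(edge_spacer(WOLBACHIA))
        emit_scaffold(WOLBACHIA, parts, config.kmer_cov[WOLBACHIA] + jit[gi])

    # host and mitochondrion
    for org in (HOST, MITO):
        items = list(other_genes[org].items())
        n_s = config.n_scaffolds[org]
        o_groups = [items[i::n_s] for i in range(n_s)]
        jit = cov_jitter(n_s)
        for gi, group in enumerate(o_groups):
            parts = [edge_spacer(org)]
            for name, nt in group:
                strand = "-" if rng.random() < config.minus_strand_prob else "+"
                parts.append(("gene", name, nt, strand, [], None))
                parts.append(spacer(org))
            parts.append(edge_spacer(org))
            emit_scaffold(org, parts, config.kmer_cov[org] + jit[gi])

    # junk scaffolds: below the length / coverage pre-filters
    if config.include_junk_scaffolds:
        for length, cov in ((150, 50.0), (400, 2.5)):
            node_counter[0] += 1
            sid = f"NODE_{node_counter[0]}_length_{length}_cov_{cov:.1f}"
            scaffolds.append(
                Scaffold(id=sid, seq=random_nt(rng, length, config.gc[HOST]), kmer_cov=cov)
            )
            truth.scaffold_organism[sid] = HOST
            truth.expected_filtered.add(sid)

    # record the final genomic gene sequences for read-mapping targets
    sc_by_id = {sc.id: sc for sc in scaffolds}
    for pg in truth.genes.values():
        if pg.scaffold_id is None:
            continue
        seq = sc_by_id[pg.scaffold_id].seq[pg.start : pg.end]
        pg.nt_seq = seq if pg.strand == "+" else revcomp(seq)

    db = ProteinDB(db_ids, db_orgs, db_seqs)
    return Community(config=config, scaffolds=scaffolds, truth=truth, panel=panel, protein_db=db)


# ---------------------------------------------------------------------------
# read simulation


def simulate_reads(
    community: Community,
    library: str,
    depths: Optional[dict[str, float]] = None,
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Simulate one paired-end library from the community scaffolds.

    Reads are drawn uniformly per organism at its configured fold depth;
    substitution errors, rare undefined bases, 3'-decaying qualities and
    adapter read-through on short inserts are applied. Fragments spanning
    the planted stop-variant site carry the alternative codon with the
    configured probability (both mates agree). Updates
    ``community.truth.read_origin``.
    """
    config = community.config
    if depths is None:
        depths = config.libraries[library]
    rl = config.read_length
    lib_tag = sum(ord(c) * 31**i for i, c in enumerate(library)) % (2**31)
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed % (2**31), lib_tag])
    )
    org_scaffolds: dict[str, list[Scaffold]] = {}
    for sc in community.scaffolds:
        if sc.id in community.truth.expected_filtered:
            continue
        org_scaffolds.setdefault(
            community.truth.scaffold_organism[sc.id], []
        ).append(sc)
    for org, scs in org_scaffolds.items():
        if depths.get(org, 0) > 0 and min(len(sc.seq) for sc in scs) < rl:
            raise ValueError(
                f"read length {rl} exceeds the shortest {org} scaffold"
            )

    variant = community.truth.variant
    short_max = (config.short_insert_max or rl - 1)
    reads1: list[SequenceRecord] = []
    reads2: list[SequenceRecord] = []
    serial = 0
    qpos = np.arange(rl)
    decay = 20.0 * (qpos / rl) ** 1.7

    for org in ORGANISMS:
        depth = depths.get(org, 0.0)
        if depth <= 0 or org not in org_scaffolds:
            continue
        for sc in org_scaffolds[org]:
            L = len(sc.seq)
            n_pairs = int(round(L * depth / (2 * rl)))
            if n_pairs == 0:
                continue
            short = rng.random(n_pairs) < config.short_insert_fraction
            inserts = np.clip(
                rng.normal(config.insert_mean, config.insert_sd, n_pairs), rl, L
            ).astype(np.int64)
            if short_max >= config.short_insert_min:
                inserts[short] = rng.integers(
                    config.short_insert_min, short_max + 1, int(short.sum())
                )
            starts = rng.integers(0, L - inserts + 1)
            with_adapter = rng.random(n_pairs) < config.adapter_readthrough_prob
            adapter_idx = rng.integers(0, len(config.adapters), n_pairs)
            alt_draw = rng.random(n_pairs)
            base_q = rng.normal(37.0, 1.5, (n_pairs, 2))
            noise = rng.normal(0.0, 1.5, (n_pairs, 2, rl))
            nerr = rng.binomial(rl, config.error_rate, (n_pairs, 2))
            n_undef = rng.binomial(rl, config.n_rate, (n_pairs, 2))

            for i in range(n_pairs):
                ins = int(inserts[i])
                s0 = int(starts[i])
                frag = sc.seq[s0 : s0 + ins]
                if (
                    variant is not None
                    and sc.id == variant.scaffold_id
                    and s0 <= variant.position
                    and variant.position + 3 <= s0 + ins
                    and alt_draw[i] < variant.fraction
                ):
                    off = variant.position - s0
                    frag = frag[:off] + variant.alt_codon + frag[off + 3 :]
                mates = []
                for mate, template in ((0, frag), (1, revcomp(frag))):
                    seq = template[:rl]
                    if len(seq) < rl:
                        if with_adapter[i]:
                            fill = config.adapters[int(adapter_idx[i])]
                        else:
                            fill = ""
                        need = rl - len(seq)
                        if len(fill) < need:
                            fill = fill + random_nt(rng, need - len(fill), 0.5)
                        seq = seq + fill[:need]
                    seq = list(seq)
                    for _ in range(int(nerr[i, mate])):
                        p = int(rng.integers(rl))
                        cur = seq[p]
                        alt = "ACGT".replace(cur if cur in "ACGT" else "A", "")
                        seq[p] = alt[int(rng.integers(3))]
                    for _ in range(int(n_undef[i, mate])):
                        seq[int(rng.integers(rl))] = "N"
                    q = np.clip(
                        base_q[i, mate] - decay + noise[i, mate], 2, 40
                    ).astype(int)
                    mates.append(("".join(seq), q.tolist()))
                rid = f"{library}.{serial}"
                serial += 1
                community.truth.read_origin[rid] = org
                reads1.append(SequenceRecord(id=rid, seq=mates[0][0], qual=mates[0][1]))
                reads2.append(SequenceRecord(id=rid, seq=mates[1][0], qual=mates[1][1]))
    return reads1, reads2


def default_community(seed: int = 0, **overrides) -> Community:
    return generate_genomes(CommunityConfig(seed=seed, **overrides))
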