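# Methods

This note documents the models and procedures implemented in
`symbiocheck`, the parameters that matter, what the synthetic community
does and does not emulate, and the numerical choices a maintainer would
want stated.

## Read QC

Adapter clipping is ungapped and fastx-clipper-like: for each adapter, a
read is scanned at every offset; full internal windows and 3'-terminal
adapter prefixes of at least `min_adapter_overlap` (8) bases match when
their mismatch count is at most `max_adapter_mismatch_rate` (0.10,
floored) times the compared length. The leftmost match wins; ties at one
position go to the longest window. Clipping and right-tail quality
trimming are iterated jointly to a fixpoint, because trimming a noisy tail
can expose a terminal partial adapter match that the first pass out-voted
(and truncation can expose new terminal prefixes). Without the fixpoint,
QC is not idempotent; with it, `qc(qc(x)) == qc(x)` holds and is tested.

Quality trimming scans right-to-left and stops at the first base at or
above Q20 (fastx semantics — deliberately not a BWA-style running sum, so
an interior low-quality base behind a good base survives). Survivors
shorter than 50 bp are dropped; reads containing undefined nucleotides are
removed and their mates routed to a singleton stream. The identity
`2*kept_pairs + singletons + dropped == input reads` holds on every input
and is fuzz-tested.

Gapped adapter alignment was rejected as out of proportion to the
source-tool behaviour being modelled. A caveat of the mismatch-tolerant
rule worth knowing: a periodic adapter (the T+G contaminant has period 9)
can match one period early when the preceding bases are similar enough;
this is a property of the rule, not a bug, and the clip point is still
inside the contamination.

## Translated search engine

The engine is a deliberately small BLASTX/TBLASTN analogue:

* six-frame conceptual translation, NCBI table 11, stops rendered `*`,
  ambiguity codes to `X`, trailing partial codons dropped;
* seeding with exact amino-acid words of size 4, requiring two
  non-overlapping hits on the same diagonal within 64 residues; query
  positions inside low-entropy windows (Shannon entropy < 2.2 bits over
  15-residue windows) are excluded from seeding only — a coarse SEG
  stand-in that stops the T+G contaminant's translations from seeding
  while never hiding residues from extension;
* exact affine-gap Smith-Waterman on every seeded (frame, protein) pair —
  full dynamic programme, not banded, so seeds decide *which* pairs are
  aligned, never the optimal score. BLOSUM62; a gap of length k costs
  11 + k (NCBI convention). Alignment spans are recovered with a second,
  reversed DP pass. The row-wise vectorised recurrence uses the standard
  lazy-F prefix-scan simplification, exact when gap-open >= gap-extend;
* bit scores and e-values from Karlin-Altschul statistics with the gapped
  BLOSUM62(11,1) constants lambda = 0.267, K = 0.041; the search space is
  query length x total database residues. Hits above e = 1e-3 are
  discarded.

The engine's optimal scores are tested equal to an independent brute-force
full-matrix DP on random and planted pairs, and its best-hit bin
assignments are tested equal to NCBI blastx run on the same scaffolds and
database. One HSP is reported per (frame, protein): sufficient for
frameshift stitching, since a frameshift necessarily moves the alignment
to another frame. Two co-linear segments in the *same* frame (e.g. either
side of a long in-frame insertion) would be merged or lost; this is a
known limitation.

An external-engine path parses 12-column BLAST tabular hits with identical
downstream semantics, so a production BLAST run can replace the internal
engine without changing any later stage.

## Binning

Scaffolds shorter than 200 bp or with assembler k-mer coverage below 3 are
dropped (strict inequalities; 200 bp / cov 3.0 survive). Each kept
scaffold is assigned to the organism of its single highest-bitscore hit —
best-hit, not LCA or margin voting, because that is the procedure under
evaluation; the margin to the best other-organism hit is reported so
fragile assignments are visible. Ties are broken by e-value, span length,
then protein id, and flagged ambiguous. Bacterial bins are then filtered
at k-mer coverage >= 10. Bin summaries report both the unweighted and the
length-weighted mean of scaffold coverage, since "average bin coverage" is
ambiguous between the two.

## Gene census

Each query gene (amino acids, from reference strains) is located in the
endosymbiont bin; if absent there, the full filtered scaffold set is
searched and the locus flagged `bin_escape` — the rescue path for genes
sitting on mis-binned scaffolds. The fallback is deliberately permissive:
it will also find a divergent ortholog on another organism's scaffold if
the true gene is genuinely absent, which mirrors how translated-search
censuses behave on real data; bin-escape loci deserve the same manual
scrutiny they get in practice.

HSPs are merged greedily by score, kept only if they contribute >= 10 (or
a quarter of their length) previously unexplained query residues —
pairwise-overlap pruning is wrong here because a cross-frame extension can
wander deep into a neighbouring segment's query range. Between adjacent
HSPs the implied nucleotide indel is measured between the HSPs' *outer*
anchors, `(gf_end2 - gf_start1) - 3*(q_end2 - q_start1)`, which is immune
to alignment gaps drifting into the junction. An indel not divisible by
three is a frameshift. The exact frame-change point is refined by scanning
split positions j and counting residues that translate correctly under
"frame A before j, frame B from j" (ties to the smallest j); sub-codon
position is unrecoverable from a protein query, so reported positions are
codon-resolution, within the +/-2 bp the coordinate convention allows.

Low complexity is formalised (the literature leaves it qualitative) as a
homopolymer run >= 6 or a perfect dinucleotide tandem >= 5 units within a
21 bp window centred on the disruption; all three thresholds are
config-exposed. A frameshift in such context is `FRAMESHIFT_LC`
("present-disrupted-rescuable" downstream — ribosomal slippage plausibly
restores expression in A+T-rich endosymbiont genomes); inside a
homopolymer the indel's phase is intrinsically ambiguous, so the reported
position snaps to the centre of the run spanned by the refinement's tie
plateau. In-frame premature stops are recorded as disruptions; stops
within 30 bp of a frameshift junction are suppressed as alignment-overhang
artifacts. Query coverage below 0.8 without a frame change is `TRUNCATED`.
A contaminant match (the full sequence, its reverse complement, or any
20-mer of either) inside the gene region yields `CONTAMINANT_INSERTION`;
the longest matching stretch is excised from a local copy and the gene
re-censused, and the post-excision status is what pathway inference
scores (a gene interrupted only by an assembled adapter is not a
pseudogene). The status vocabulary has no stop-only class: a gene with a
premature stop but no frameshift stays `INTACT` with the stop recorded as
a disruption.

## Competitive read mapping and variant fractions

The mapper is a minimal seed-and-verify aligner, not a Bowtie2
reimplementation: 15-mer seeds at fixed offsets on both strands, ungapped
end-to-end verification over the read/target overlap (>= 30 bp overlap,
<= 10% mismatches), best single placement across genes *plus decoys*,
score ties declared ambiguous. Including the co-resident bacterium's
scaffolds as decoys is what prevents ortholog reads from inflating gene
depth — tested with a deliberately hard 5% divergent ortholog, where
cross-mapping is >50 reads without decoys and ~0 with them. Every read
gets exactly one fate (mapped / unmapped / ambiguous); the count identity
is asserted. Depth is aligned bases over gene length.

Variant fractions count codons from uniquely placed reads spanning the
full codon; the primary denominator is ref+alt+other, with the
ref+alt-only convention also exposed (`alt_fraction_refalt`) since both
are defensible. Sites under 10 spanning reads carry a low-confidence flag.
The estimator is binomial-unbiased and is tested to recover a planted
13.4% variant within 3 binomial SD at depth 1000 and to be mean-unbiased
over 200 replicates at f in {0.05, 0.134, 0.5} (tolerance 3 standard
errors of the mean; a 1-SE band would reject an exact estimator on a
third of seeds).

## Pathway inference

Census statuses map to matrix cells: INTACT -> present; FRAMESHIFT_LC ->
present-disrupted-rescuable; contaminant insertions by their
post-excision status; everything else absent. A compound is complete when
every non-optional gene is present or rescuable (rescuable counts by
default; `--strict` disables that). `needs_partner` is true iff some
compound is incomplete in the focal strain while complete in the
mono-symbiotic reference — so losses shared with the reference (e.g. pgm,
absent in all sequenced *Buchnera*) carry no signal. The shipped
`pathways.yaml` covers the genes the synthetic panel exercises (Trp,
Ile/Val, Met, biotin, riboflavin, lipoate, hexose-phosphate
interconversion, with pgm optional); it is a starting point to be curated
per clade, not a reference reconstruction.

## Primer evaluation

Ungapped, IUPAC-aware scan of both strands; the best site has fewest total
mismatches, then fewest in the 3'-terminal 5 nt, then leftmost. A pair
amplifies when the sites are convergent, the amplicon (5' end to 5' end,
inclusive — the wet-lab convention) is <= 5 kb, each primer has <= 3 total
mismatches, a perfect 3'-terminal base, and <= 1 mismatch in the terminal
5 nt. Exactly one marginal failure (one extra mismatch, a terminal-5 count
of 2, or an amplicon within 1.5x the cap) downgrades to "unlikely";
3'-terminal-base mismatches and non-convergent layouts always fail. The
thresholds are decisions, not literature constants — no quantitative
mismatch rule exists for "primers did not match" — and are parameters of
`AmplificationParams`. Thermodynamic (Tm/dG) modelling is deliberately out
of scope: the argument being reproduced is mismatch-counting.

## The synthetic community

The generator emulates a pooled whole-aphid extract: Buchnera-like
(GC 0.25, k-mer coverage 110), Wolbachia-like (GC 0.35, coverage 396),
host background (GC 0.32, coverage 10), mitochondrion (GC 0.20, coverage
60). Genome sizes are desk-scale (roughly 12-20 kb per organism, 160-260
aa genes with intergenic spacers) — large enough that every stage has
realistic structure, small enough that 20-seed recovery studies run in
minutes. Three libraries echo the strong between-library imbalance of
real pooled datasets: an endosymbiont-poor library (~1% of read bases from
Buchnera genes), a rich one (~30%), and an intermediate one. Reads are
100 bp pairs, insert 350 +/- 50, substitution rate 0.002, rare undefined
bases, qualities decaying toward the 3' end so trimming has real work;
10% of fragments are short inserts that read through into a TruSeq index
adapter (indexes 4, 5, 6) or the T+G-rich contaminant.

Planted truth: per-scaffold organism labels plus two junk scaffolds below
the pre-filters; one gene per status class (bioA/fabB/trpG with single
indels in forced homopolymer runs of 7; mutS with a deletion in a
high-entropy context; recA truncated to 65%; lipA and pgi with the T+G
contaminant spliced at a fixed in-gene position, as assembled
read-through contamination presents; pgm absent). The two statuses that
imply genuine loss (frameshift-other, truncated) sit on non-pathway
control genes — biologically apt choices, as DNA-repair genes are
routinely eroded in these genomes — so the default community represents
the intact-nutritional-repertoire case and the verdict experiment stays
clean. trpG additionally carries an in-frame TAG whose CAG variant is
planted in 13.4% of site-spanning fragments (both mates agree, as a
collapsed tandem-repeat assembly would produce). One intact gene (trpE,
built at panel-minimum length) is placed on a Wolbachia scaffold that also
carries a long anchor gene, guaranteeing by construction that best-hit
binning sends the scaffold to Wolbachia and the census must rescue the
gene via fallback.

Ortholog decoys for six genes are derived by per-base substitution of the
reference CDS (stop codons repaired), at a rate inverted from the
configured amino-acid divergence via `aa_div ~ 0.75*(1-(1-r)^3)` — an
approximation; realised divergence scatters a few points around the
nominal 0.40. Deriving orthologs at the nucleotide level (rather than
re-reverse-translating a mutated protein) is essential: codon wobble would
otherwise erase the nucleotide identity that makes cross-mapping a real
confounder.

Two generator choices exist purely to make planted truth well-defined:
point indels are placed at codon boundaries, at sites where the +/-6-codon
junction neighbourhood is frame-unambiguous (otherwise no method could
recover the position at codon resolution — the ambiguity would be in the
data, not the detector); scaffolds get insert-sized terminal spacers so
gene depths are not confounded by the paired-end coverage ramp at contig
ends (real contigs dwarf the insert size). Not emulated: assembler
behaviour (contig fragmentation, collapsed repeats beyond the planted
variant), PCR duplicates, indel sequencing errors, quality-dependent
substitution profiles. Passing tests therefore demonstrate correctness of
the pipeline's logic under controlled conditions, not robustness to every
artifact of real assemblies.

## Determinism and coordinates

Every stochastic stage takes a seed; communities, reads and whole report
bundles are byte-identical under a fixed seed (tested by checksum). All
internal coordinates are 0-based half-open; conversion to 1-based happens
only at report boundaries (GFF3, BLAST tabular).

## Known limitations

* Single best HSP per (frame, protein): same-frame co-linear segment
  pairs are not stitched.
* The word seeder uses exact 4-mers (no neighbourhood words); sensitivity
  below ~40% amino-acid identity is not characterised.
* The mapper is ungapped; reads spanning indels relative to their target
  mis-pair at the tail (irrelevant here, since mapping targets are the
  genomic gene sequences themselves).
* The e-value calibration uses fixed Karlin-Altschul constants; it is
  accurate enough for a 1e-3 cutoff against curated databases, not for
  nr-scale searches.
* The fallback census path can report a divergent ortholog from another
  organism as a bin-escape locus when the true gene is absent; such loci
  are flagged and deserve verification.
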