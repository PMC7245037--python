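# symbiocheck

Genome-based testing of claimed co-obligate endosymbioses from holobiont
shotgun sequencing data.

Aphids almost universally host *Buchnera aphidicola*, a bacteriome-confined
endosymbiont that supplies essential amino acids (EAAs) and B vitamins
missing from phloem sap. A co-obligate symbiosis — where a second bacterium
such as *Wolbachia* is also required — is only supported when *Buchnera*
has genuinely lost biosynthetic genes that mono-symbiotic relatives retain.
Testing that claim from a pooled whole-insect assembly requires a careful
chain of steps, each of which can silently fabricate "missing" genes:
read QC (including removal of unusual adapter contaminants that can end up
*inside* assembled genes), conservative scaffold binning against a curated
database of expected organisms, translated-homology gene census that
recognises pseudogene-like states (frameshifts in homopolymeric runs are
often rescued by ribosomal slippage in A+T-rich genomes and do not imply
gene loss), decoy-aware read mapping so *Wolbachia* orthologs do not
inflate *Buchnera* gene coverage, and in-silico primer checks (a PCR that
fails because primers mismatch a divergent strain is not evidence of
absence).

`symbiocheck` implements that chain as a tested pipeline:

| stage | module | what it does |
| --- | --- | --- |
| read QC | `symbiocheck.qc` | adapter clipping (mismatch-tolerant, leftmost, iterated to a fixpoint), right-tail Q20 trimming, min length 50, undefined-base removal, orphan separation |
| binning | `symbiocheck.binning` | scaffold pre-filters (>=200 bp, k-mer cov >=3), six-frame translated search (word-seeded Smith-Waterman, BLOSUM62 11/1, Karlin-Altschul e-values, e <= 1e-3), best-hit assignment, bacterial bin coverage filter (>=10) |
| gene census | `symbiocheck.census` | TBLASTN-style gene location with bin-escape fallback, HSP stitching, frameshift calls classified by low-complexity context, premature stops, contaminant-insertion detection with excision re-census |
| read coverage | `symbiocheck.mapping` | competitive best-single-placement mapper over genes + decoy scaffolds; per-gene per-library depth; codon-level variant fractions |
| pathway inference | `symbiocheck.pathways` | presence matrix vs a mono-symbiotic reference; per-compound completeness; co-obligacy verdict |
| primer check | `symbiocheck.primers` | IUPAC-aware ungapped primer scan, 3'-mismatch rule table, amplification verdicts |
| synthetic community | `symbiocheck.community` | four-organism mock holobiont (Buchnera-like 110x, Wolbachia-like 396x, host, mitochondrion) with planted truth for every stage |

The synthetic community is first-class: it plants bin labels, gene statuses
(intact, frameshift-in-low-complexity, frameshift-elsewhere, truncated,
absent, contaminant-insertion), a two-allele stop-codon site (TAG consensus
with a CAG variant at 13.4%), a deliberately mis-binned gene, and divergent
ortholog decoys — so every stage's output can be checked against known
truth.

## Worked example

```bash
symbiocheck demo --seed 42 --out-dir results/demo
```

prints (abridged; numbers from this exact command):

```
Biosynthetic completeness for focal:
  Trp                                      complete-with-rescue   (reference: complete)
  Ile/Val                                  complete               (reference: complete)
  Met                                      complete               (reference: complete)
  biotin                                   complete-with-rescue   (reference: complete)
  riboflavin                               complete               (reference: complete)
  lipoate                                  complete               (reference: complete)
  glucose-phosphate interconversion        complete               (reference: complete)
VERDICT: no co-obligate partner required — the focal strain retains every
pathway its mono-symbiotic reference completes.
trpG stop-codon variant in lib2: 10.20% (10/98)
```

"complete-with-rescue" marks pathways whose only disruptions are
frameshifts inside homopolymer runs (plausibly rescued by ribosomal
slippage): Trp because of the planted trpG frameshift, biotin because of
bioA/fabB. The trpG line reports the fraction of endosymbiont-rich-library
reads carrying CAG instead of the consensus TAG stop at the planted site
(13.4% planted; a ~100-read pileup gives estimates like 10-15%). The
verdict flips to "partner REQUIRED" if a non-optional pathway gene (e.g.
the riboflavin gene ribE) is deleted from the community.

The same pipeline runs stepwise as numbered scripts:

```bash
python analysis/01_simulate_community.py
python analysis/02_read_qc.py
python analysis/03_bin_scaffolds.py
python analysis/04_gene_census.py
python analysis/05_pathway_verdict.py
python analysis/06_primer_check.py
```

Each writes its tables under `results/analysis/` and prints what it found.
For user data, the `symbiocheck qc / bin / census / pathways / primers`
subcommands accept FASTQ/FASTA/TSV inputs; scaffold coverage is read from
SPAdes-style headers (`NODE_n_length_L_cov_C`) or a sidecar table.

## Layout

```
src/symbiocheck/    library (all computation lives here)
analysis/           numbered narrative drivers over the library
tests/              pytest suite incl. brute-force oracles and an
                    NCBI blastx cross-check of the internal engine
scripts/            acceptance.py
docs/methods.md     models, parameters, design decisions, limitations
```
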