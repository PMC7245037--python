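#!/usr/bin/env python
"""Census the nutritional-gene panel in the endosymbiont bin.

Locates each panel gene by translated search (falling back to the full
filtered scaffold set when a gene's scaffold was binned elsewhere),
classifies disruptions, maps the QC'd libraries competitively against the
gene sequences with the Wolbachia scaffolds as decoys, and measures the
trpG stop-codon variant fraction per library."""

from pathlib import Path

import pandas as pd

from symbiocheck.binning import BinningParams, filter_scaffolds
from symbiocheck.census import CensusParams, run_census
from symbiocheck.community import (BUCHNERA, TG_CONTAMINANT, WOLBACHIA,
                                   CommunityConfig, generate_genomes)
from symbiocheck.io import load_scaffolds, read_fastq
from symbiocheck.mapping import CompetitiveMapper, variant_fraction
from symbiocheck.pipeline import _reports_to_frame, write_gff3

SEED = 42
COMMUNITY = Path("results/analysis/community")
QC = Path("results/analysis/qc")
BINS = Path("results/analysis/bins")
OUT = Path("results/analysis/census")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    com = generate_genomes(CommunityConfig(seed=SEED))
    scaffolds = load_scaffolds(COMMUNITY / "scaffolds.fasta")
    kept, _ = filter_scaffolds(scaffolds, BinningParams())
    labels = pd.read_csv(BINS / "assignments.tsv", sep="\t").set_index(
        "scaffold_id"
    )["organism"]
    bin_sc = [sc for sc in kept if labels.get(sc.id) == BUCHNERA]
    params = CensusParams(contaminants=(TG_CONTAMINANT,))
    reports = run_census(com.panel, bin_sc, kept, params)
    for rep in reports.values():
        flags = " (bin-escape)" if rep.bin_escape else ""
        print(f"  {rep.gene:6s} {rep.status.value:22s}{flags}")

    genes = {
        pg.symbol: pg.nt_seq for pg in com.truth.genes.values()
        if pg.nt_seq and pg.organism == BUCHNERA
    }
    decoys = {sc.id: sc.seq for sc in kept if labels.get(sc.id) == WOLBACHIA}
    mapper = CompetitiveMapper(genes, decoys)
    vt = com.truth.variant
    pg = com.truth.genes[vt.gene]
    for r1_path in sorted(QC.glob("*_R1.fastq")):
        lib = r1_path.name.replace("_R1.fastq", "")
        reads = list(read_fastq(r1_path)) + list(read_fastq(QC / f"{lib}_R2.fastq"))
        reads += list(read_fastq(QC / f"{lib}_singletons.fastq"))
        res = mapper.map_reads(reads)
        for g, seq in genes.items():
            if g in reports:
                reports[g].per_library_depth[lib] = res.depth(g, len(seq))
        vs = variant_fraction(
            res, reads, vt.gene, vt.position - pg.start, vt.ref_codon, vt.alt_codon
        )
        conf = " (low confidence)" if vs.low_confidence else ""
        print(f"  {lib}: trpG TAG->CAG variant {vs.alt_fraction * 100:.2f}% "
              f"({vs.alt_count}/{vs.total}){conf}")
    _reports_to_frame(reports).to_csv(OUT / "gene_reports.tsv", sep="\t", index=False)
    write_gff3(reports, OUT / "genes.gff3")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
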