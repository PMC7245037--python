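#!/usr/bin/env python
"""Generate the synthetic holobiont community the rest of the analysis runs on.

Writes scaffolds, three paired-end libraries and the planted truth tables to
results/analysis/community/. The community mimics a whole-aphid DNA extract:
a high-coverage A+T-rich primary endosymbiont (110x), a very-high-coverage
Wolbachia-like bacterium (396x), host background and mitochondrion, with
adapter read-through, a T+G-rich contaminant and a planted 13.4% stop-codon
variant in trpG.
"""

from pathlib import Path

from symbiocheck.community import CommunityConfig, generate_genomes, simulate_reads
from symbiocheck.io import SequenceRecord, write_fasta, write_fastq
from symbiocheck.pipeline import _write_truth_tables

SEED = 42
OUT = Path("results/analysis/community")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    com = generate_genomes(CommunityConfig(seed=SEED))
    write_fasta(
        (SequenceRecord(id=sc.id, seq=sc.seq) for sc in com.scaffolds),
        OUT / "scaffolds.fasta",
    )
    _write_truth_tables(com, OUT)
    print(f"community: {len(com.scaffolds)} scaffolds, "
          f"{len(com.truth.genes)} panel genes")
    for lib in com.config.libraries:
        r1, r2 = simulate_reads(com, lib)
        write_fastq(r1, OUT / f"{lib}_R1.fastq")
        write_fastq(r2, OUT / f"{lib}_R2.fastq")
        print(f"  {lib}: {len(r1)} read pairs")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
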