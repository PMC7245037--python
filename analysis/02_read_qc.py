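#!/usr/bin/env python
"""Clean the simulated libraries: adapter clipping (TruSeq indexes plus the
T+G-rich contaminant), right-tail Q20 trimming, minimum length 50, removal
of reads with undefined bases, and orphan separation."""

import json
from pathlib import Path

from symbiocheck.community import DEFAULT_ADAPTERS
from symbiocheck.io import read_fastq, write_fastq
from symbiocheck.qc import QcParams, qc_pipeline

IN = Path("results/analysis/community")
OUT = Path("results/analysis/qc")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    params = QcParams(adapters=DEFAULT_ADAPTERS)
    summaries = {}
    for r1_path in sorted(IN.glob("*_R1.fastq")):
        lib = r1_path.name.replace("_R1.fastq", "")
        r1 = list(read_fastq(r1_path))
        r2 = list(read_fastq(IN / f"{lib}_R2.fastq"))
        kept, singles, summary = qc_pipeline(r1, r2, params)
        write_fastq([p[0] for p in kept], OUT / f"{lib}_R1.fastq")
        write_fastq([p[1] for p in kept], OUT / f"{lib}_R2.fastq")
        write_fastq(singles, OUT / f"{lib}_singletons.fastq")
        summaries[lib] = summary.as_dict()
        print(f"{lib}: {summary.kept_pairs} pairs kept, "
              f"{summary.singletons} singletons, {summary.dropped} dropped "
              f"({summary.clipped} adapter-clipped)")
    with open(OUT / "qc_summary.json", "w") as fh:
        json.dump(summaries, fh, indent=2)
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
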