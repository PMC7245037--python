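#!/usr/bin/env python
"""Build the presence/absence matrix, score pathway completeness against the
mono-symbiotic reference, and print the co-obligacy verdict."""

import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from symbiocheck.census import GeneReport, GeneStatus
from symbiocheck.pathways import (assess_completeness, build_presence_matrix,
                                  load_pathways, verdict_text)

CENSUS = Path("results/analysis/census")
OUT = Path("results/analysis/pathways")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    df = pd.read_csv(CENSUS / "gene_reports.tsv", sep="\t")
    reports = {}
    for _, row in df.iterrows():
        post = row.get("post_excision_status")
        reports[row["gene"]] = GeneReport(
            gene=row["gene"],
            status=GeneStatus(row["status"]),
            post_excision_status=(
                GeneStatus(post) if isinstance(post, str) and post else None
            ),
        )
    pset = load_pathways()
    matrix = build_presence_matrix(reports, pset)
    verdict = assess_completeness(matrix, pset)
    matrix.to_csv(OUT / "presence_matrix.tsv", sep="\t")
    (OUT / "verdict.txt").write_text(verdict_text(verdict) + "\n")
    with open(OUT / "verdict.json", "w") as fh:
        json.dump(asdict(verdict), fh, indent=2)
    print(verdict_text(verdict))
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
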