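"""End-to-end orchestration: QC -> binning -> census -> pathways -> primers.

``run_demo`` exercises the whole pipeline on the synthetic community (the
package's test bench); the stage functions it strings together are the same
ones the CLI subcommands expose for user data. Every run writes a
provenance JSON (package version, parameters, input checksums) and a fixed
output layout::

    outdir/
      community/   scaffolds.fasta, truth_*.tsv, <lib>_R{1,2}.fastq
      qc/          kept/singleton FASTQs + qc_summary.json
      bins/        assignments.tsv, bin_summaries.tsv
      census/      gene_reports.tsv, gene_reports.json, genes.gff3
      pathways/    presence_matrix.tsv, verdict.txt, verdict.json
      primers/     primer_verdicts.tsv
      provenance.json
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .binning import (BinningParams, assign_bins, filter_scaffolds,
                      finalize_bins, translated_search)
from .census import CensusParams, GeneStatus, run_census
from .community import (BUCHNERA, TG_CONTAMINANT, WOLBACHIA, Community,
                        CommunityConfig, generate_genomes, simulate_reads)
from .io import write_fasta, write_fastq, SequenceRecord
from .mapping import CompetitiveMapper, variant_fraction
from .pathways import (assess_completeness, build_presence_matrix,
                       load_pathways, verdict_text)
from .primers import design_matching_pair, predict_amplification
from .qc import QcParams, qc_pipeline


@dataclass
class DemoResult:
    community: Community
    qc_summaries: dict
    bin_summaries: dict
    bin_assignments: list
    reports: dict
    matrix: object
    verdict: object
    variant_sites: dict  # library -> VariantSite
    mapping_counts: dict  # library -> dict of read fates
    depths: dict  # gene -> library -> depth
    primer_verdicts: list


def _write_truth_tables(community: Community, outdir: Path) -> None:
    truth = community.truth
    rows = [
        {"scaffold_id": sid, "organism": org,
         "expected_filtered": sid in truth.expected_filtered}
        for sid, org in truth.scaffold_organism.items()
    ]
    pd.DataFrame(rows).to_csv(outdir / "truth_scaffolds.tsv", sep="\t", index=False)
    rows = [
        {"gene": pg.symbol, "organism": pg.organism, "status": pg.status.value,
         "scaffold_id": pg.scaffold_id, "start": pg.start, "end": pg.end,
         "strand": pg.strand, "bin_escape": pg.bin_escape,
         "disruptions": ";".join(f"{p}:{k}" for p, k in pg.disruptions)}
        for pg in truth.genes.values()
    ]
    pd.DataFrame(rows).to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)


def _reports_to_frame(reports: dict) -> pd.DataFrame:
    rows = []
    for rep in reports.values():
        rows.append({
            "gene": rep.gene, "status": rep.status.value,
            "scaffold_id": rep.scaffold_id, "start": rep.start, "end": rep.end,
            "strand": rep.strand, "query_coverage": round(rep.query_coverage, 4),
            "bin_escape": rep.bin_escape,
            "post_excision_status": (
                rep.post_excision_status.value if rep.post_excision_status else ""
            ),
            "disruptions": ";".join(
                f"{d.position}:{d.kind}" for d in rep.disruptions
            ),
            **{f"depth_{lib}": round(v, 2) for lib, v in rep.per_library_depth.items()},
        })
    return pd.DataFrame(rows)


def write_gff3(reports: dict, path: Path) -> None:
    """Located gene spans as GFF3 (coordinates converted to 1-based)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rep in reports.values():
            if rep.scaffold_id is None:
                continue
            fh.write(
                "\t".join([
                    rep.scaffold_id, "symbiocheck", "gene",
                    str(rep.start + 1), str(rep.end),
                    ".", rep.strand or ".", ".",
                    f"ID={rep.gene};status={rep.status.value}",
                ]) + "\n"
            )


def run_demo(
    seed: int = 0,
    outdir: Optional[Path] = None,
    config: Optional[CommunityConfig] = None,
    libraries: Optional[list[str]] = None,
) -> DemoResult:
    """Full pipeline on the synthetic community, with planted ground truth.

    Deterministic in ``seed``; writes the report bundle when ``outdir`` is
    given, otherwise stays in memory.
    """
    if config is None:
        config = CommunityConfig(seed=seed)
    community = generate_genomes(config)
    if libraries is None:
        libraries = list(config.libraries)
    if outdir is not None:
        outdir = Path(outdir)
        for sub in ("community", "qc", "bins", "census", "pathways", "primers"):
            (outdir / sub).mkdir(parents=True, exist_ok=True)
        write_fasta(
            (SequenceRecord(id=sc.id, seq=sc.seq) for sc in community.scaffolds),
            outdir / "community" / "scaffolds.fasta",
        )
        _write_truth_tables(community, outdir / "community")

    # --- reads + QC
    qc_params = QcParams(adapters=config.adapters)
    qc_summaries = {}
    reads_by_library = {}
    for lib in libraries:
        r1, r2 = simulate_reads(community, lib)
        if outdir is not None:
            write_fastq(r1, outdir / "community" / f"{lib}_R1.fastq")
            write_fastq(r2, outdir / "community" / f"{lib}_R2.fastq")
        kept, singles, summary = qc_pipeline(r1, r2, qc_params)
        qc_summaries[lib] = summary.as_dict()
        reads_by_library[lib] = [r for pair in kept for r in pair] + singles
        if outdir is not None:
            write_fastq([p[0] for p in kept], outdir / "qc" / f"{lib}_R1.fastq")
            write_fastq([p[1] for p in kept], outdir / "qc" / f"{lib}_R2.fastq")
            write_fastq(singles, outdir / "qc" / f"{lib}_singletons.fastq")

    # --- binning
    bin_params = BinningParams()
    kept_sc, _dropped = filter_scaffolds(community.scaffolds, bin_params)
    hits = []
    for sc in kept_sc:
        hits.extend(translated_search(sc, community.protein_db, bin_params))
    assignments = assign_bins(hits, kept_sc)
    bins, summaries = finalize_bins(assignments, kept_sc, bin_params)

    # --- census
    census_params = CensusParams(contaminants=(TG_CONTAMINANT,))
    reports = run_census(
        community.panel, bins.get(BUCHNERA, []), kept_sc, census_params
    )

    # --- per-gene read coverage with decoy-aware competitive mapping
    genes_nt = {
        pg.symbol: pg.nt_seq
        for pg in community.truth.genes.values()
        if pg.nt_seq and pg.organism == BUCHNERA
    }
    decoys = {sc.id: sc.seq for sc in bins.get(WOLBACHIA, [])}
    mapper = CompetitiveMapper(genes_nt, decoys)
    variant_sites = {}
    mapping_counts = {}
    depths: dict[str, dict[str, float]] = {g: {} for g in genes_nt}
    vt = community.truth.variant
    for lib, reads in reads_by_library.items():
        res = mapper.map_reads(reads)
        mapping_counts[lib] = {
            "n_reads": res.n_reads, "mapped": res.n_mapped,
            "unmapped": res.n_unmapped, "ambiguous": res.n_ambiguous,
        }
        for g, seq in genes_nt.items():
            depths[g][lib] = res.depth(g, len(seq))
            if g in reports:
                reports[g].per_library_depth[lib] = depths[g][lib]
        if vt is not None and vt.gene in genes_nt:
            pg = community.truth.genes[vt.gene]
            site_in_gene = (
                vt.position - pg.start if pg.strand == "+"
                else pg.end - (vt.position + 3)
            )
            ref, alt = (
                (vt.ref_codon, vt.alt_codon) if pg.strand == "+"
                else (vt.ref_codon, vt.alt_codon)
            )
            vs = variant_fraction(
                res, reads, vt.gene, site_in_gene, ref, alt,
                min_depth=census_params.min_variant_depth,
            )
            variant_sites[lib] = vs
            reports[vt.gene].variant_sites.append(vs)

    # --- pathways
    pathway_set = load_pathways()
    matrix = build_presence_matrix(reports, pathway_set, focal_strain="focal")
    verdict = assess_completeness(matrix, pathway_set, focal_strain="focal")

    # --- primers: pairs designed on the recovered genes amplify; pairs
    # designed on the divergent ortholog do not (the mismatched-primer
    # explanation for PCR failure)
    primer_verdicts = []
    for sym in ("trpD", "ribA"):
        pg = community.truth.genes.get(sym)
        if pg is None or not pg.nt_seq:
            continue
        good = design_matching_pair(pg.nt_seq, f"{sym}_self", sym)
        primer_verdicts.append(predict_amplification(good, pg.nt_seq))
    for sym in ("trpG", "bioA"):
        pg = community.truth.genes.get(sym)
        hom = next(
            (s for pid, org, s in zip(
                community.protein_db.ids,
                community.protein_db.organisms,
                community.protein_db.seqs,
            ) if pid == sym + "_w"),
            None,
        )
        if pg is None or not pg.nt_seq or hom is None:
            continue
        # primers designed on the diverged ortholog's coding sequence
        from .community import _codon_weights, reverse_translate
        import numpy as np
        rng = np.random.default_rng(config.seed % (2**31) + 7)
        hom_nt = reverse_translate(rng, hom, _codon_weights(0.35))
        foreign = design_matching_pair(hom_nt, f"{sym}_ortholog", sym)
        primer_verdicts.append(predict_amplification(foreign, pg.nt_seq))

    result = DemoResult(
        community=community,
        qc_summaries=qc_summaries,
        bin_summaries=summaries,
        bin_assignments=assignments,
        reports=reports,
        matrix=matrix,
        verdict=verdict,
        variant_sites=variant_sites,
        mapping_counts=mapping_counts,
        depths=depths,
        primer_verdicts=primer_verdicts,
    )

    if outdir is not None:
        _write_bundle(result, outdir, seed)
    return result


def _write_bundle(result: DemoResult, outdir: Path, seed: int) -> None:
    with open(outdir / "qc" / "qc_summary.json", "w") as fh:
        json.dump(result.qc_summaries, fh, indent=2)
    pd.DataFrame(
        [
            {"scaffold_id": a.scaffold_id, "organism": a.organism_label,
             "margin_bits": a.margin_bits, "ambiguous": a.ambiguous}
            for a in result.bin_assignments
        ]
    ).to_csv(outdir / "bins" / "assignments.tsv", sep="\t", index=False)
    pd.DataFrame(
        [dataclasses.asdict(s) for s in result.bin_summaries.values()]
    ).to_csv(outdir / "bins" / "bin_summaries.tsv", sep="\t", index=False)
    _reports_to_frame(result.reports).to_csv(
        outdir / "census" / "gene_reports.tsv", sep="\t", index=False
    )
    with open(outdir / "census" / "gene_reports.json", "w") as fh:
        json.dump(
            {g: dataclasses.asdict(r) for g, r in result.reports.items()},
            fh, indent=2, default=str,
        )
    write_gff3(result.reports, outdir / "census" / "genes.gff3")
    result.matrix.to_csv(outdir / "pathways" / "presence_matrix.tsv", sep="\t")
    with open(outdir / "pathways" / "verdict.txt", "w") as fh:
        fh.write(verdict_text(result.verdict) + "\n")
    with open(outdir / "pathways" / "verdict.json", "w") as fh:
        json.dump(dataclasses.asdict(result.verdict), fh, indent=2)
    pd.DataFrame(
        [
            {"pair": v.pair.name, "target": v.pair.target_gene,
             "verdict": v.verdict, "amplicon": v.amplicon_length,
             "fwd_mm": v.fwd_hit.mismatches, "rev_mm": v.rev_hit.mismatches,
             "reasons": "; ".join(v.reasons)}
            for v in result.primer_verdicts
        ]
    ).to_csv(outdir / "primers" / "primer_verdicts.tsv", sep="\t", index=False)
    provenance = {
        "package": "symbiocheck",
        "version": __version__,
        "seed": seed,
        "config": dataclasses.asdict(result.community.config),
        "scaffold_checksum": hashlib.sha256(
            "".join(sc.seq for sc in result.community.scaffolds).encode()
        ).hexdigest(),
    }
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, default=str)
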