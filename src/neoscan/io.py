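"""Readers/writers for the plain-text formats the pipeline exchanges.

FASTA/FASTQ go through Biopython, SAM through pysam, tables through pandas
(tab-separated with headers). Coordinates are 1-based only inside SAM/GFF
records, 0-based half-open everywhere else (BED included).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .junction_caller import JunctionCall, JunctionSpanningCounts
from .locus_sim import ConcatemerMolecule, LocusModel, ReadSet
from .neo_finder import NeoGeneModel
from .repeat_counter import RepeatCountResult


def write_locus(locus: LocusModel, outdir, prefix: str | None = None) -> dict:
    """Write a locus as FASTA (ncRNA + cDNA unit), BED annotations and JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prefix = prefix or locus.locus_id
    paths = {
        "fasta": outdir / f"{prefix}.fasta",
        "bed": outdir / f"{prefix}.bed",
        "json": outdir / f"{prefix}.json",
    }
    SeqIO.write(
        [
            SeqRecord(Seq(locus.ncrna_seq), id=locus.locus_id, description="ncRNA"),
            SeqRecord(
                Seq(locus.unit),
                id=f"{locus.locus_id}_unit",
                description="single-repeat cDNA (cDNA sense)",
            ),
        ],
        str(paths["fasta"]),
        "fasta",
    )
    with open(paths["bed"], "w") as fh:
        feats = [
            ("template", *locus.template_interval),
            ("ACA-1", *locus.aca1_interval),
            ("ACA-2", *locus.aca2_interval),
        ] + [(label, s, e) for label, s, e in locus.stem_loops]
        for name, s, e in feats:
            fh.write(f"{locus.locus_id}\t{s}\t{e}\t{name}\t0\t+\n")
    locus.to_json(paths["json"])
    return paths


def write_molecules_fasta(molecules: list[ConcatemerMolecule], path) -> None:
    SeqIO.write(
        [
            SeqRecord(
                Seq(m.seq),
                id=m.molecule_id,
                description=f"n_repeats={m.n_repeats} strand_state={m.strand_state}",
            )
            for m in molecules
        ],
        str(path),
        "fasta",
    )


def write_readset(readset: ReadSet, fastq_path, truth_path) -> None:
    SeqIO.write(readset.reads, str(fastq_path), "fastq")
    readset.truth.to_csv(truth_path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_sam(alignments, path) -> None:
    alignments = list(alignments)
    if not alignments:
        raise ValueError("no alignments to write")
    with pysam.AlignmentFile(
        str(path), "w", header=alignments[0].header
    ) as fh:
        for a in alignments:
            fh.write(a)


def write_junction_calls(calls: list[JunctionCall], path) -> None:
    pd.DataFrame(
        [
            {
                "junction_ref_pos": c.junction_ref_pos,
                "remap_offset": c.remap_offset,
                "inserted_nt": c.inserted_nt,
                "expected": c.expected,
                "support": c.support,
                "strand": c.strand,
                "ambiguous": c.ambiguous,
            }
            for c in calls
        ]
    ).to_csv(path, sep="\t", index=False)


def write_strand_counts(counts: JunctionSpanningCounts, path) -> None:
    pd.DataFrame(
        [
            {"strand": "cDNA-sense", "count": counts.cdna_sense,
             "cpm": counts.cpm_cdna_sense},
            {"strand": "ncRNA-sense", "count": counts.ncrna_sense,
             "cpm": counts.cpm_ncrna_sense},
        ]
    ).to_csv(path, sep="\t", index=False)


def write_coverage_bedgraph(alignments, ref_name: str, ref_len: int, path) -> None:
    """Aligned-base coverage (soft clips excluded) as bedGraph."""
    import numpy as np

    cov = np.zeros(ref_len + 1, dtype=int)
    for a in alignments:
        if a.is_unmapped:
            continue
        cov[a.reference_start] += 1
        cov[a.reference_end] -= 1
    cov = np.cumsum(cov[:-1])
    with open(path, "w") as fh:
        start = 0
        for i in range(1, ref_len + 1):
            if i == ref_len or cov[i] != cov[start]:
                if cov[start]:
                    fh.write(f"{ref_name}\t{start}\t{i}\t{cov[start]}\n")
                start = i


def write_repeat_results(results: list[RepeatCountResult], path) -> None:
    pd.DataFrame(
        [
            {
                "read_id": r.read_id,
                "n_units": r.n_units,
                "orientation": r.orientation,
                "mean_identity": r.mean_identity,
                "terminal_partial_fraction": r.terminal_partial_fraction,
            }
            for r in results
        ]
    ).to_csv(path, sep="\t", index=False)


def write_neo_gff(model: NeoGeneModel, path, n_repeats: int = 3) -> None:
    """NeoGeneModel as GFF3 gene/CDS on the n-repeat concatemer (1-based)."""
    L = model.period * n_repeats
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        seqid = f"{model.locus_id}_concatemer_x{n_repeats}"
        fh.write(
            f"{seqid}\tneoscan\tgene\t1\t{L}\t.\t+\t.\t"
            f"ID=neo;Name=neo;stop_free_frames="
            f"{','.join(map(str, sorted(model.stop_free_frames)))}\n"
        )
        if model.start_offset is not None:
            fh.write(
                f"{seqid}\tneoscan\tCDS\t{model.start_offset + 1}\t{L}\t.\t+\t0\t"
                f"ID=neo_cds;Parent=neo;start_codon={model.start_codon};"
                f"rbs_score={model.rbs_score}\n"
            )


def write_protein_fasta(name: str, aa: str, path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(aa), id=name, description="Neo repeat protein")],
        str(path),
        "fasta",
    )
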