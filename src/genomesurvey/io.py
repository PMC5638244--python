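"""Readers and writers for the package's file surface.

FASTA/FASTQ go through Biopython; GFF3 is written 1-based inclusive with
``gene`` features carrying ``ID=`` attributes; count matrices are TSV with
a header row of stage labels and the gene id in the first column. Every
generator's ground truth (variants, planted clusters, planted folds,
seeds) serializes to a JSON sidecar so simulated datasets re-parse into
objects equal to the in-memory originals.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .synthetic_data import AnnotationSet, CountMatrix, DiploidGenome, ReadSet

__all__ = [
    "write_fasta",
    "read_fasta",
    "write_fastq",
    "read_fastq",
    "write_gff3",
    "read_gff3",
    "write_annotation",
    "read_annotation",
    "write_counts",
    "read_counts",
    "write_diploid",
    "read_diploid",
]


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(reads: ReadSet, path) -> None:
    """Plain four-line-per-read FASTQ with Sanger+33 qualities."""
    with open(path, "w") as fh:
        for rid, seq, qual in reads.reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def read_fastq(path) -> ReadSet:
    records = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(
            chr(q + 33) for q in rec.letter_annotations["phred_quality"]
        )
        records.append((rec.id, str(rec.seq), qual))
    return ReadSet.from_records(records)


# ---------------------------------------------------------------------------
# diploid genomes (two-record FASTA + JSON variant sidecar)
# ---------------------------------------------------------------------------


def write_diploid(dg: DiploidGenome, out_dir, stem: str = "diploid") -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fasta = out_dir / f"{stem}.fa"
    sidecar = out_dir / f"{stem}.truth.json"
    write_fasta({"reference": dg.reference, "alt_haplotype": dg.alt_haplotype}, fasta)
    with open(sidecar, "w") as fh:
        json.dump(
            {
                "true_het_rate": dg.true_het_rate,
                "seed": dg.seed,
                "variant_positions": [list(v) for v in dg.variant_positions],
            },
            fh,
        )
    return {"fasta": fasta, "truth": sidecar}


def read_diploid(out_dir, stem: str = "diploid") -> DiploidGenome:
    out_dir = Path(out_dir)
    seqs = read_fasta(out_dir / f"{stem}.fa")
    with open(out_dir / f"{stem}.truth.json") as fh:
        truth = json.load(fh)
    return DiploidGenome(
        reference=seqs["reference"],
        alt_haplotype=seqs["alt_haplotype"],
        variant_positions=[tuple(v) for v in truth["variant_positions"]],
        true_het_rate=truth["true_het_rate"],
        seed=truth["seed"],
    )


# ---------------------------------------------------------------------------
# annotations (GFF3 + protein FASTA + JSON cluster sidecar)
# ---------------------------------------------------------------------------


def write_gff3(annotation: AnnotationSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene_id, scaffold, start, end, strand in annotation.genes:
            fh.write(
                f"{scaffold}\tgenomesurvey\tgene\t{start}\t{end}\t.\t{strand}\t.\t"
                f"ID={gene_id}\n"
            )


def read_gff3(path) -> list[tuple[str, str, int, int, str]]:
    """Parse ``gene`` features of a GFF3 file into annotation rows."""
    genes = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9 or fields[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
            )
            genes.append(
                (attrs["ID"], fields[0], int(fields[3]), int(fields[4]), fields[6])
            )
    return genes


def write_annotation(annotation: AnnotationSet, out_dir, stem: str = "genes") -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    gff = out_dir / f"{stem}.gff3"
    prot = out_dir / f"{stem}.prot.fa"
    sidecar = out_dir / f"{stem}.truth.json"
    write_gff3(annotation, gff)
    write_fasta(annotation.proteins, prot)
    with open(sidecar, "w") as fh:
        json.dump({"planted_clusters": annotation.planted_clusters}, fh)
    return {"gff3": gff, "proteins": prot, "truth": sidecar}


def read_annotation(gff3_path, protein_path, truth_path=None) -> AnnotationSet:
    genes = read_gff3(gff3_path)
    proteins = read_fasta(protein_path)
    planted: list[list[str]] = []
    if truth_path is not None and Path(truth_path).exists():
        with open(truth_path) as fh:
            planted = json.load(fh).get("planted_clusters", [])
    return AnnotationSet(genes=genes, proteins=proteins, planted_clusters=planted)


# ---------------------------------------------------------------------------
# count matrices (TSV + JSON sidecar)
# ---------------------------------------------------------------------------


def write_counts(cm: CountMatrix, out_dir, stem: str = "counts") -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tsv = out_dir / f"{stem}.tsv"
    lengths = out_dir / f"{stem}.lengths.tsv"
    sidecar = out_dir / f"{stem}.truth.json"
    cm.counts.to_csv(tsv, sep="\t", index_label="gene")
    cm.gene_lengths.to_csv(lengths, sep="\t", index_label="gene", header=["length"])
    with open(sidecar, "w") as fh:
        json.dump({"planted": cm.planted, "seed": cm.seed}, fh)
    return {"counts": tsv, "lengths": lengths, "truth": sidecar}


def read_counts(out_dir, stem: str = "counts") -> CountMatrix:
    out_dir = Path(out_dir)
    counts = pd.read_csv(out_dir / f"{stem}.tsv", sep="\t", index_col="gene")
    lengths = pd.read_csv(out_dir / f"{stem}.lengths.tsv", sep="\t", index_col="gene")[
        "length"
    ]
    with open(out_dir / f"{stem}.truth.json") as fh:
        truth = json.load(fh)
    return CountMatrix(
        counts=counts,
        gene_lengths=lengths,
        library_sizes=counts.sum(axis=0),
        planted=truth["planted"],
        seed=truth["seed"],
    )


def read_expression_tsv(path) -> pd.DataFrame:
    """Plain genes x stages matrix (first column gene id, header stages)."""
    return pd.read_csv(path, sep="\t", index_col=0)
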