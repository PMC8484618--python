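"""Readers and writers for the plain-text bundle formats.

The on-disk bundle mirrors the field's standard formats: peaks as BED6 with
a summit-offset column, gene annotation as BED12, count matrices and
sample sheets as TSV, the peptide table as long-format TSV, footprint
calls as BED6 plus motif/state/bound columns, interaction edges as a
two-column TSV and the planted truth as JSON.  All writers are
deterministic (fixed ordering and float formatting) so that a fixed config
and seed reproduce the bundle byte-for-byte.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .genomic_model import GeneModel, GenomicInterval, Peak, ContactDomain
from .synthetic_cohort import Annotation, OmicsCohort, PlantedTruth

__all__ = [
    "FLOAT_FORMAT",
    "write_matrix",
    "read_matrix",
    "write_peaks_bed",
    "read_peaks_bed",
    "write_genes_bed12",
    "read_genes_bed12",
    "read_domains_bed",
    "write_bundle",
    "read_bundle",
]

FLOAT_FORMAT = "%.6g"


def write_matrix(df: pd.DataFrame, path, index_label: str = "feature_id") -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index_label=index_label)


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_peaks_bed(peaks, path) -> None:
    """BED6 + summit-offset column (summit position minus interval start)."""
    rows = [
        (
            p.interval.chrom,
            p.interval.start,
            p.interval.end,
            p.peak_id,
            0,
            ".",
            p.summit - p.interval.start,
        )
        for p in peaks
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_peaks_bed(path) -> list[Peak]:
    df = pd.read_csv(path, sep="\t", header=None)
    peaks = []
    for rec in df.itertuples(index=False):
        chrom, start, end, name = rec[0], int(rec[1]), int(rec[2]), str(rec[3])
        offset = int(rec[6]) if len(rec) > 6 else (end - start) // 2
        peaks.append(
            Peak(name, GenomicInterval(chrom, start, end), summit=start + offset)
        )
    return peaks


def write_genes_bed12(genes, path) -> None:
    rows = []
    for g in genes:
        sizes = ",".join(str(e.length) for e in g.exons) + ","
        starts = ",".join(str(e.start - g.body.start) for e in g.exons) + ","
        rows.append(
            (
                g.chrom,
                g.body.start,
                g.body.end,
                g.gene_id,
                0,
                g.strand,
                g.body.start,
                g.body.end,
                0,
                len(g.exons),
                sizes,
                starts,
            )
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_genes_bed12(path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", header=None)
    genes = []
    for rec in df.itertuples(index=False):
        chrom, start, end, name, strand = rec[0], int(rec[1]), int(rec[2]), str(rec[3]), str(rec[5])
        sizes = [int(x) for x in str(rec[10]).rstrip(",").split(",") if x]
        offsets = [int(x) for x in str(rec[11]).rstrip(",").split(",") if x]
        exons = tuple(
            GenomicInterval(chrom, start + o, start + o + s)
            for o, s in zip(offsets, sizes)
        )
        genes.append(
            GeneModel(name, GenomicInterval(chrom, start, end), strand=strand, exons=exons)
        )
    return genes


def read_domains_bed(path) -> list[ContactDomain]:
    df = pd.read_csv(path, sep="\t", header=None)
    return [
        ContactDomain(GenomicInterval(str(r[0]), int(r[1]), int(r[2])))
        for r in df.itertuples(index=False)
    ]


def write_bundle(
    outdir,
    annotation: Annotation,
    cohort: OmicsCohort,
    truth: PlantedTruth,
    footprints: pd.DataFrame,
    edges: pd.DataFrame,
) -> Path:
    """Write the full synthetic bundle to a directory; returns its path."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    pd.Series(annotation.chrom_sizes, name="size").rename_axis("chrom").to_csv(
        out / "chrom_sizes.tsv", sep="\t"
    )
    write_genes_bed12(annotation.genes, out / "genes.bed12")
    write_peaks_bed(cohort.peaks, out / "peaks.bed")
    cohort.sample_sheet.to_csv(out / "samples.tsv", sep="\t", index=False)
    cohort.atac_sample_sheet.to_csv(out / "atac_samples.tsv", sep="\t", index=False)
    write_matrix(cohort.atac_counts, out / "atac_counts.tsv", "peak_id")
    write_matrix(cohort.genebody_counts, out / "genebody_counts.tsv", "gene_id")
    write_matrix(cohort.rna_counts, out / "rna_counts.tsv", "gene_id")
    cohort.peptides.to_csv(
        out / "peptides.tsv", sep="\t", index=False, float_format=FLOAT_FORMAT
    )
    fp = footprints[["chrom", "start", "end", "motif_id", "gene_id", "state", "bound"]]
    fp.to_csv(out / "footprints.tsv", sep="\t", index=False)
    edges.to_csv(out / "edges.tsv", sep="\t", index=False)
    (out / "truth.json").write_text(truth.to_json())
    return out


def read_bundle(indir):
    """Read a bundle directory back into in-memory objects."""
    d = Path(indir)
    chrom_sizes = (
        pd.read_csv(d / "chrom_sizes.tsv", sep="\t", index_col=0)["size"].to_dict()
    )
    annotation = Annotation(
        genes=read_genes_bed12(d / "genes.bed12"), chrom_sizes=chrom_sizes
    )
    peptides = pd.read_csv(
        d / "peptides.tsv", sep="\t", keep_default_na=False, na_values=[""]
    )
    peptides["sample_id"] = peptides["sample_id"].fillna("")
    peptides["is_reference"] = peptides["is_reference"].astype(bool)
    cohort = OmicsCohort(
        sample_sheet=pd.read_csv(d / "samples.tsv", sep="\t"),
        atac_sample_sheet=pd.read_csv(d / "atac_samples.tsv", sep="\t"),
        peaks=read_peaks_bed(d / "peaks.bed"),
        atac_counts=read_matrix(d / "atac_counts.tsv"),
        genebody_counts=read_matrix(d / "genebody_counts.tsv"),
        rna_counts=read_matrix(d / "rna_counts.tsv"),
        peptides=peptides,
    )
    truth = PlantedTruth.from_json((d / "truth.json").read_text())
    footprints = pd.read_csv(d / "footprints.tsv", sep="\t")
    edges = pd.read_csv(d / "edges.tsv", sep="\t")
    return annotation, cohort, truth, footprints, edges
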