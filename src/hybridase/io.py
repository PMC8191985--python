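"""Readers and writers for the standard formats the pipeline touches.

All coordinates are normalised to 1-based inclusive on the way in: VCF and
GFF3 are already 1-based; BED intervals (0-based half-open) are converted
at this boundary. Strand is carried through but ignored by all downstream
computations, which operate on unstranded allele counts.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Iterable, Optional, Union

import gffutils
import pandas as pd
from Bio import SeqIO
from cyvcf2 import VCF

from .types import (
    AlleleCountRecord,
    GeneModel,
    ReferenceGenome,
    ValidationError,
    VariantSite,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

ASE_COLUMNS = [
    "contig",
    "position",
    "refAllele",
    "altAllele",
    "refCount",
    "altCount",
    "totalCount",
]


def read_vcf(path: PathLike) -> list[VariantSite]:
    """Read a VCF v4.x into a list of :class:`VariantSite`.

    Positions stay 1-based; multi-allelic records keep all ALTs; samples
    follow header order. Genotypes of ``./.`` are recorded as missing.
    """
    path = str(path)
    try:
        vcf = VCF(path)
    except Exception as exc:  # cyvcf2 raises bare Exception on bad headers
        raise ValidationError(f"{path}: malformed VCF header ({exc})") from exc
    samples = list(vcf.samples)
    sites: list[VariantSite] = []
    for i, rec in enumerate(vcf, start=1):
        genotypes = []
        for gt in rec.genotypes:
            a, b = gt[0], gt[1]
            if a < 0 or b < 0:
                genotypes.append(None)
            else:
                genotypes.append((int(a), int(b)))
        try:
            sites.append(
                VariantSite(
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    ref=rec.REF,
                    alts=list(rec.ALT),
                    genotypes=genotypes,
                    sample_ids=samples,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: record {i}: {exc}") from exc
    return sites


def write_vcf(
    sites: Iterable[VariantSite], sample_ids: list[str], path: PathLike
) -> None:
    """Write a minimal multi-sample VCF v4.2 with GT-only FORMAT fields."""
    sites = list(sites)
    contigs = dict.fromkeys(s.chrom for s in sites)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for contig in contigs:
            fh.write(f"##contig=<ID={contig}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_ids)
            + "\n"
        )
        for site in sites:
            gts = []
            for gt in site.genotypes:
                gts.append("./." if gt is None else f"{gt[0]}/{gt[1]}")
            fh.write(
                f"{site.chrom}\t{site.pos}\t.\t{site.ref}\t"
                f"{','.join(site.alts)}\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def read_fasta(path: PathLike) -> ReferenceGenome:
    """Read a FASTA file; sequences are uppercased and alphabet-checked."""
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise ValidationError(f"{path}: duplicate sequence name {rec.id!r}")
        sequences[rec.id] = str(rec.seq)
    return ReferenceGenome(sequences=sequences)


def write_fasta(
    genome: ReferenceGenome, path: PathLike, line_width: int = 60
) -> None:
    """Write a genome as FASTA with fixed line wrapping."""
    if line_width < 1:
        raise ValidationError("line_width must be >= 1")
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width] + "\n")


def _genes_from_gff3(path: str) -> list[GeneModel]:
    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    seen: set[str] = set()
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        if feat.end < feat.start:
            raise ValidationError(f"{path}: gene {feat.id}: end < start")
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        if gene_id in seen:
            raise ValidationError(f"{path}: duplicate gene id {gene_id!r}")
        seen.add(gene_id)
        # exonic length = length of the union of exon intervals
        exons = sorted(
            (e.start, e.end)
            for e in db.children(feat, featuretype="exon")
        )
        exonic = 0
        cur_start, cur_end = None, None
        for s, e in exons:
            if e < s:
                raise ValidationError(f"{path}: exon of {gene_id}: end < start")
            if cur_end is None:
                cur_start, cur_end = s, e
            elif s <= cur_end + 1:
                cur_end = max(cur_end, e)
            else:
                exonic += cur_end - cur_start + 1
                cur_start, cur_end = s, e
        if cur_end is not None:
            exonic += cur_end - cur_start + 1
        genes.append(
            GeneModel(
                gene_id=gene_id,
                chrom=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand if feat.strand in "+-" else ".",
                exonic_length=exonic,  # 0 -> span fallback in GeneModel
            )
        )
    return genes


def _genes_from_bed(path: str) -> list[GeneModel]:
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValidationError(
                    f"{path}: line {line_no}: BED needs >= 4 columns"
                )
            chrom, start0, end0, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            if end0 < start0:
                raise ValidationError(f"{path}: line {line_no}: end < start")
            if name in seen:
                raise ValidationError(f"{path}: duplicate gene id {name!r}")
            seen.add(name)
            strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "."
            exonic = 0
            if len(fields) >= 12:  # BED12 block structure
                sizes = [int(x) for x in fields[10].rstrip(",").split(",") if x]
                exonic = sum(sizes)
            genes.append(
                GeneModel(
                    gene_id=name,
                    chrom=chrom,
                    start=start0 + 1,  # 0-based half-open -> 1-based inclusive
                    end=end0,
                    strand=strand,
                    exonic_length=exonic,
                )
            )
    return genes


def read_gene_annotation(path: PathLike, format: str = "gff3") -> list[GeneModel]:
    """Read gene models from GFF3 or BED (4+ columns, BED12 for exons)."""
    if format == "gff3":
        return _genes_from_gff3(str(path))
    if format == "bed12":
        return _genes_from_bed(str(path))
    raise ValidationError(f"unknown annotation format {format!r}")


def write_gene_annotation_bed(genes: Iterable[GeneModel], path: PathLike) -> None:
    """Write gene spans as 6-column BED (converting back to 0-based)."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


def read_ase_table(
    path: PathLike,
    sample_id: str = "",
    cross: str = "",
    dataset: str = "",
) -> list[AlleleCountRecord]:
    """Read an ASEReadCounter-style TSV of per-SNP allele counts.

    The file must carry exactly the columns contig, position, refAllele,
    altAllele, refCount, altCount, totalCount. ``totalCount`` may exceed
    refCount + altCount (other bases), but never be smaller; the stored
    total is re-derived as refCount + altCount.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ASE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    records: list[AlleleCountRecord] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            ref_count = int(row.refCount)
            alt_count = int(row.altCount)
            total = int(row.totalCount)
            if total < ref_count + alt_count:
                raise ValidationError(
                    f"totalCount {total} < refCount+altCount "
                    f"{ref_count + alt_count}"
                )
            records.append(
                AlleleCountRecord(
                    chrom=str(row.contig),
                    pos=int(row.position),
                    ref_base=str(row.refAllele).upper(),
                    alt_base=str(row.altAllele).upper(),
                    ref_count=ref_count,
                    alt_count=alt_count,
                    sample_id=sample_id,
                    cross=cross,
                    dataset=dataset,
                )
            )
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"{path}: line {row_no}: {exc}") from exc
    return records


def write_ase_table(records: Iterable[AlleleCountRecord], path: PathLike) -> None:
    """Write allele-count records in ASEReadCounter column layout."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(ASE_COLUMNS)
        for r in records:
            writer.writerow(
                [r.chrom, r.pos, r.ref_base, r.alt_base, r.ref_count,
                 r.alt_count, r.total_count]
            )


def read_counts_matrix(path: PathLike) -> pd.DataFrame:
    """Read a featureCounts-style TSV (gene_id + one column per sample)."""
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "gene_id":
        raise ValidationError(f"{path}: first column must be 'gene_id'")
    df = df.set_index("gene_id")
    if (df.values < 0).any():
        raise ValidationError(f"{path}: negative counts")
    return df


def write_counts_matrix(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_fixed_diff_tsv(path: PathLike):
    """Read a fixed-difference TSV (chrom, pos, ref, alt) written by the CLI."""
    from .types import FixedDifferenceSet

    entries: dict[tuple[str, int], tuple[str, str]] = {}
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    for row in df.itertuples(index=False):
        key = (str(row.chrom), int(row.pos))
        if key in entries:
            raise ValidationError(f"{path}: duplicate site {key}")
        entries[key] = (str(row.ref), str(row.alt))
    return FixedDifferenceSet(entries=entries)


def write_fixed_diff_tsv(diffs, path: PathLike) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["chrom", "pos", "ref", "alt"])
        for chrom, pos, ref, alt in diffs.sorted_entries():
            writer.writerow([chrom, pos, ref, alt])
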