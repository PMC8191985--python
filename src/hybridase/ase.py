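"""Per-SNP allele-count filtering and per-gene aggregation.

The analysis keeps only *informative* SNPs — fixed-difference sites with
allele-consistent counts and read depth at or above a threshold — assigns
them to genes by position, and pools counts over SNPs and replicates
within each cross direction. A gene is testable only when it has at least
``min_snps_per_gene`` informative SNPs in *both* reciprocal hybrids.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .types import (
    AlleleCountRecord,
    AseFilterConfig,
    CROSS_GV,
    CROSS_VG,
    FixedDifferenceSet,
    GeneAseSummary,
    GeneModel,
    PooledCounts,
    ValidationError,
)

logger = logging.getLogger(__name__)


def restrict_to_fixed_sites(
    records: Iterable[AlleleCountRecord], diffs: FixedDifferenceSet
) -> list[AlleleCountRecord]:
    """Keep only records at fixed-difference positions with matching alleles.

    Records at a fixed-difference position whose (ref, alt) disagree with
    the recorded diff are dropped and counted separately — they signal an
    annotation or genotyping inconsistency rather than a mere non-diff site.
    """
    kept: list[AlleleCountRecord] = []
    n_offsite = 0
    n_allele_mismatch = 0
    for rec in records:
        alleles = diffs.entries.get((rec.chrom, rec.pos))
        if alleles is None:
            n_offsite += 1
            continue
        if (rec.ref_base, rec.alt_base) != alleles:
            n_allele_mismatch += 1
            continue
        kept.append(rec)
    logger.info(
        "fixed-site restriction: kept %d, dropped %d off-site, "
        "%d allele-mismatched",
        len(kept), n_offsite, n_allele_mismatch,
    )
    return kept


def filter_by_depth(
    records: Iterable[AlleleCountRecord], config: AseFilterConfig
) -> list[AlleleCountRecord]:
    """Keep records with total depth >= min_site_depth (boundary inclusive)."""
    kept = [r for r in records if r.total_count >= config.min_site_depth]
    return kept


@dataclass
class GeneAssignment:
    """SNP records grouped by gene, with multi-gene ambiguity flags."""

    by_gene: dict[str, list[AlleleCountRecord]] = field(default_factory=dict)
    ambiguous_genes: set[str] = field(default_factory=set)
    n_unassigned: int = 0


def assign_snps_to_genes(
    records: Iterable[AlleleCountRecord],
    genes: Sequence[GeneModel],
    strict: bool = False,
) -> GeneAssignment:
    """Assign each record to every gene whose span contains its position.

    Records overlapping no gene are discarded; records inside k > 1
    overlapping genes appear under all k, and each such gene is flagged
    ambiguous. With ``strict=True`` multi-gene records are discarded
    instead.
    """
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        # IntervalTree is half-open; genes are 1-based inclusive
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end + 1, g.gene_id)
    out = GeneAssignment()
    for rec in records:
        tree = trees.get(rec.chrom)
        hits = sorted(iv.data for iv in tree[rec.pos]) if tree is not None else []
        if not hits:
            out.n_unassigned += 1
            continue
        if len(hits) > 1:
            out.ambiguous_genes.update(hits)
            if strict:
                continue
        for gid in hits:
            out.by_gene.setdefault(gid, []).append(rec)
    return out


def pool_replicates(
    records: Sequence[AlleleCountRecord], cross: str
) -> PooledCounts:
    """Pool counts over SNPs and replicates of one cross direction.

    Counts are summed; ``n_snps`` is the number of distinct (chrom, pos)
    observed; ``mean_site_depth`` averages total depth over SNP x replicate
    observations. Order of records and replicates does not matter.
    """
    if cross not in (CROSS_VG, CROSS_GV):
        raise ValidationError(f"unknown cross {cross!r}")
    subset = [r for r in records if r.cross == cross]
    if not subset:
        return PooledCounts()
    positions = {(r.chrom, r.pos) for r in subset}
    sum_ref = sum(r.ref_count for r in subset)
    sum_alt = sum(r.alt_count for r in subset)
    mean_depth = sum(r.total_count for r in subset) / len(subset)
    return PooledCounts(
        n_snps=len(positions),
        sum_ref=sum_ref,
        sum_alt=sum_alt,
        mean_site_depth=mean_depth,
    )


def aggregate_gene_ase(
    records: Iterable[AlleleCountRecord],
    diffs: FixedDifferenceSet,
    genes: Sequence[GeneModel],
    config: AseFilterConfig = AseFilterConfig(),
    strict_ambiguous: bool = False,
) -> list[GeneAseSummary]:
    """Run the full filter -> intersect -> pool chain for one dataset.

    Returns one :class:`GeneAseSummary` per gene with at least one
    surviving record; ``testable`` requires >= ``min_snps_per_gene``
    informative SNPs in both crosses.
    """
    records = restrict_to_fixed_sites(records, diffs)
    records = filter_by_depth(records, config)
    assignment = assign_snps_to_genes(records, genes, strict=strict_ambiguous)
    summaries: list[GeneAseSummary] = []
    for gene_id in sorted(assignment.by_gene):
        recs = assignment.by_gene[gene_id]
        vg = pool_replicates(recs, CROSS_VG)
        gv = pool_replicates(recs, CROSS_GV)
        testable = (
            vg.n_snps >= config.min_snps_per_gene
            and gv.n_snps >= config.min_snps_per_gene
        )
        summaries.append(
            GeneAseSummary(
                gene_id=gene_id,
                vg=vg,
                gv=gv,
                testable=testable,
                ambiguous=gene_id in assignment.ambiguous_genes,
            )
        )
    logger.info(
        "aggregated %d genes (%d testable)",
        len(summaries),
        sum(s.testable for s in summaries),
    )
    return summaries
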