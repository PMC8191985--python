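"""Fixed-difference SNP classification between two inbred parental groups.

A site is *fixed and different* when it is a biallelic single-base SNP,
homozygous for the reference allele in every group-A sample and homozygous
for the (single) alternate allele in every group-B sample. Because the
parental lines are fully inbred, heterozygous or missing calls indicate
either genotyping noise or residual polymorphism and disqualify the site.
"""

from __future__ import annotations

import enum
import logging
from collections import Counter
from typing import Iterable, Sequence

from .types import (
    FixedDifferenceSet,
    ValidationError,
    VariantSite,
    VALID_BASES,
)

logger = logging.getLogger(__name__)


class SiteClass(str, enum.Enum):
    FIXED_DIFFERENT = "fixed_different"
    NOT_FIXED = "not_fixed"
    NOT_BIALLELIC_SNP = "not_biallelic_snp"


def classify_site(
    site: VariantSite,
    group_a: Sequence[str],
    group_b: Sequence[str],
) -> SiteClass:
    """Classify one jointly genotyped site against the fixed-difference rule.

    ``group_a`` carries the reference line's replicates, ``group_b`` the
    alternate line's. Any missing or heterozygous genotype, and any
    multi-allelic or indel record, disqualifies the site.
    """
    if not group_a or not group_b:
        raise ValidationError("both sample groups must be non-empty")
    if set(group_a) & set(group_b):
        raise ValidationError("sample groups must be disjoint")
    for sample in (*group_a, *group_b):
        if sample not in site.sample_ids:
            raise ValidationError(f"unknown sample id {sample!r}")

    if (
        len(site.alts) != 1
        or len(site.ref) != 1
        or len(site.alts[0]) != 1
        or site.ref.upper() not in VALID_BASES
        or site.alts[0].upper() not in VALID_BASES
    ):
        return SiteClass.NOT_BIALLELIC_SNP

    for sample in group_a:
        gt = site.genotype_of(sample)
        if gt is None or gt != (0, 0):
            return SiteClass.NOT_FIXED
    for sample in group_b:
        gt = site.genotype_of(sample)
        if gt is None or set(gt) != {1}:
            return SiteClass.NOT_FIXED
    return SiteClass.FIXED_DIFFERENT


def build_fixed_difference_set(
    sites: Iterable[VariantSite],
    group_a: Sequence[str],
    group_b: Sequence[str],
    provenance: tuple[str, str] = ("groupA", "groupB"),
) -> FixedDifferenceSet:
    """Collect every fixed-and-different site into a :class:`FixedDifferenceSet`.

    The result is independent of the input order of sites. Duplicate
    (chrom, pos) entries with conflicting alleles raise; identical
    duplicates are collapsed. Exclusion reasons are tallied in
    ``excluded_counts`` and logged.
    """
    entries: dict[tuple[str, int], tuple[str, str]] = {}
    tally: Counter[str] = Counter()
    for site in sites:
        cls = classify_site(site, group_a, group_b)
        tally[cls.value] += 1
        if cls is not SiteClass.FIXED_DIFFERENT:
            continue
        key = (site.chrom, site.pos)
        alleles = (site.ref.upper(), site.alts[0].upper())
        if key in entries and entries[key] != alleles:
            raise ValidationError(
                f"{site.chrom}:{site.pos}: conflicting alleles "
                f"{entries[key]} vs {alleles}"
            )
        entries[key] = alleles
    logger.info(
        "fixed-difference scan: %d fixed_different, %d not_fixed, "
        "%d not_biallelic_snp",
        tally["fixed_different"],
        tally["not_fixed"],
        tally["not_biallelic_snp"],
    )
    return FixedDifferenceSet(
        entries=entries, provenance=provenance, excluded_counts=dict(tally)
    )
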