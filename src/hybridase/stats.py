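"""Reciprocal-hybrid allelic-bias testing and gene categorisation.

The primary test compares, per gene, the pooled (reference-line vs
alternate-line) allele counts between the two reciprocal hybrids with a
two-sided Fisher's exact test; Benjamini-Hochberg controls the FDR across
the testable gene set. Significant genes are then classified by which side
of 0.5 the reference-line allele fraction falls in each hybrid:

* fractions on opposite sides of 0.5 with the *paternal* allele favoured in
  both crosses -> paternal imprinting signal (and mirrored for maternal);
* fractions on the same side of 0.5 -> a species/line-of-origin (cis)
  effect toward whichever allele is favoured.

A per-hybrid exact binomial test against a 0.5 fraction is provided as a
reported diagnostic; it never gates calls.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional, Sequence

from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .ase import aggregate_gene_ase, restrict_to_fixed_sites
from .types import (
    AlleleCountRecord,
    AseCategory,
    AseFilterConfig,
    CrossDesign,
    DESIGN_GV,
    DESIGN_VG,
    FixedDifferenceSet,
    GeneAseSummary,
    GeneModel,
    ImprintCallConfig,
    NotTestable,
    ValidationError,
)

logger = logging.getLogger(__name__)


def fisher_exact_two_sided(
    a: int, b: int, c: int, d: int
) -> Optional[float]:
    """Two-sided Fisher's exact p for the 2x2 table [[a, b], [c, d]].

    Rows are alleles (reference-line / alternate-line), columns are the
    two cross directions. Returns None when any margin is zero (the table
    carries no information about allelic bias).
    """
    if min(a, b, c, d) < 0:
        raise ValidationError("negative cell in contingency table")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        return None
    _, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(min(p, 1.0))


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p_list = list(p_values)
    if not p_list:
        return []
    for p in p_list:
        if not 0 <= p <= 1:
            raise ValidationError(f"p-value {p} outside [0, 1]")
    _, q, _, _ = multipletests(p_list, method="fdr_bh")
    return [float(x) for x in q]


def per_hybrid_bias_test(sum_ref: int, sum_alt: int) -> float:
    """Exact two-sided binomial p for H0: reference-allele fraction = 0.5."""
    if sum_ref < 0 or sum_alt < 0:
        raise ValidationError("negative allele count")
    total = sum_ref + sum_alt
    if total == 0:
        raise NotTestable("zero total count")
    return float(sps.binomtest(sum_ref, total, 0.5, alternative="two-sided").pvalue)


def classify_gene(
    summary: GeneAseSummary,
    design_vg: CrossDesign = DESIGN_VG,
    design_gv: CrossDesign = DESIGN_GV,
    config: ImprintCallConfig = ImprintCallConfig(),
) -> AseCategory:
    """Assign an imprinting / cis category from fractions and the q-value.

    Requires ``summary.q_value``; not-testable summaries pass through as
    NOT_TESTABLE. A fraction exactly at 0.5 carries no direction: the call
    falls to the cis side indicated by the other fraction, or to
    NO_DIFFERENCE when both are tied.
    """
    if not summary.testable:
        return AseCategory.NOT_TESTABLE
    if summary.q_value is None:
        raise ValidationError(f"gene {summary.gene_id}: no q-value")
    if summary.q_value > config.alpha:
        return AseCategory.NO_DIFFERENCE
    f_vg = summary.nv_fraction_vg
    f_gv = summary.nv_fraction_gv
    # in VG the reference line is the mother (standard design), so a
    # reference-allele deficit there means the paternal allele is favoured
    if not design_vg.ref_is_maternal or design_gv.ref_is_maternal:
        raise ValidationError(
            "designs must be reciprocal with the reference line maternal in VG"
        )
    if f_vg < 0.5 and f_gv > 0.5:
        return AseCategory.PATERNAL_BIAS
    if f_vg > 0.5 and f_gv < 0.5:
        return AseCategory.MATERNAL_BIAS
    if f_vg > 0.5 and f_gv > 0.5:
        return AseCategory.CIS_REF_PARENT
    if f_vg < 0.5 and f_gv < 0.5:
        return AseCategory.CIS_ALT_PARENT
    # at least one fraction exactly 0.5: no parent-of-origin direction
    other = f_gv if f_vg == 0.5 else f_vg
    if other > 0.5:
        return AseCategory.CIS_REF_PARENT
    if other < 0.5:
        return AseCategory.CIS_ALT_PARENT
    return AseCategory.NO_DIFFERENCE


def run_imprinting_analysis(
    summaries: Iterable[GeneAseSummary],
    config: ImprintCallConfig = ImprintCallConfig(),
    design_vg: CrossDesign = DESIGN_VG,
    design_gv: CrossDesign = DESIGN_GV,
) -> list[GeneAseSummary]:
    """Fisher-test every testable gene, BH-adjust within the testable set,
    classify, and return summaries sorted by (q, gene_id).

    Not-testable genes pass through unchanged (category NOT_TESTABLE) and
    sort after tested genes.
    """
    summaries = list(summaries)
    testable: list[GeneAseSummary] = []
    for s in summaries:
        if not s.testable:
            s.category = AseCategory.NOT_TESTABLE
            continue
        p = fisher_exact_two_sided(s.vg.sum_ref, s.gv.sum_ref,
                                   s.vg.sum_alt, s.gv.sum_alt)
        if p is None:
            s.testable = False
            s.category = AseCategory.NOT_TESTABLE
            continue
        s.p_value = p
        testable.append(s)
    qs = bh_adjust([s.p_value for s in testable])
    for s, q in zip(testable, qs):
        s.q_value = q
        s.category = classify_gene(s, design_vg, design_gv, config)
    logger.info(
        "imprinting analysis: %d testable genes, %d below FDR %g",
        len(testable),
        sum(s.q_value <= config.alpha for s in testable),
        config.alpha,
    )

    def sort_key(s: GeneAseSummary):
        return (s.q_value is None, s.q_value if s.q_value is not None else 0.0,
                s.gene_id)

    return sorted(summaries, key=sort_key)


def intersect_fixed_differences(
    diffs_a: FixedDifferenceSet, diffs_b: FixedDifferenceSet
) -> FixedDifferenceSet:
    """Sites fixed and different in both datasets with identical alleles.

    Shared positions whose alleles disagree between the datasets are
    dropped and logged — they cannot be interpreted consistently.
    """
    entries: dict[tuple[str, int], tuple[str, str]] = {}
    n_conflict = 0
    for key, alleles in diffs_a.entries.items():
        other = diffs_b.entries.get(key)
        if other is None:
            continue
        if other != alleles:
            n_conflict += 1
            continue
        entries[key] = alleles
    if n_conflict:
        logger.warning(
            "%d shared positions dropped for allele disagreement", n_conflict
        )
    return FixedDifferenceSet(
        entries=entries,
        provenance=(
            f"{diffs_a.provenance[0]}&{diffs_b.provenance[0]}",
            f"{diffs_a.provenance[1]}&{diffs_b.provenance[1]}",
        ),
    )


def combine_datasets(
    records_a: Iterable[AlleleCountRecord],
    records_b: Iterable[AlleleCountRecord],
    diffs_a: FixedDifferenceSet,
    diffs_b: FixedDifferenceSet,
    genes: Sequence[GeneModel],
    filter_config: AseFilterConfig = AseFilterConfig(),
    call_config: ImprintCallConfig = ImprintCallConfig(),
) -> list[GeneAseSummary]:
    """Combined-dataset analysis restricted to shared fixed-difference sites.

    Both record sets are restricted to the allele-consistent intersection
    of the two fixed-difference sets, pooled per gene and cross across
    datasets, and the imprinting analysis is rerun with its own BH family.
    """
    shared = intersect_fixed_differences(diffs_a, diffs_b)
    pooled = restrict_to_fixed_sites(list(records_a), shared) + \
        restrict_to_fixed_sites(list(records_b), shared)
    summaries = aggregate_gene_ase(pooled, shared, genes, filter_config)
    return run_imprinting_analysis(summaries, call_config)
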