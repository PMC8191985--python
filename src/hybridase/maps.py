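"""Genetic-map coordinate conversion, introgression scanning, and
locus/gene-set overlap utilities.

Two linkage maps of the same chromosomes generally disagree in total cM
length; conversion between them uses per-interval piecewise-linear scaling
anchored at markers placed on both maps (with two anchors this reduces to
a single conversion ratio). The introgression scan looks for array markers
at which a test strain retains the donor-line allele after repeated
backcrossing, requiring the marker to type correctly in both parental
controls and consistently across test samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from scipy.stats import hypergeom

from .types import (
    GeneModel,
    GeneticMapAnchor,
    IntervalLocus,
    MarkerGenotypeMatrix,
    ValidationError,
)

logger = logging.getLogger(__name__)


def _chrom_anchors(
    anchors: Iterable[GeneticMapAnchor], chrom: str
) -> list[GeneticMapAnchor]:
    subset = sorted(
        (a for a in anchors if a.chrom == chrom), key=lambda a: a.cm_map_a
    )
    if len(subset) < 2:
        raise ValidationError(f"chromosome {chrom}: need >= 2 anchors")
    return subset


def _interpolate(x: float, xs: list[float], ys: list[float]) -> float:
    """Piecewise-linear interpolation; terminal-segment extrapolation."""
    if x <= xs[0]:
        lo, hi = 0, 1
    elif x >= xs[-1]:
        lo, hi = len(xs) - 2, len(xs) - 1
    else:
        hi = next(i for i, v in enumerate(xs) if v >= x)
        lo = hi - 1
    x0, x1 = xs[lo], xs[hi]
    y0, y1 = ys[lo], ys[hi]
    if x1 == x0:
        return y0
    return y0 + (x - x0) * (y1 - y0) / (x1 - x0)


def convert_map_position(
    pos_cm_map_a: float, chrom: str, anchors: Iterable[GeneticMapAnchor]
) -> float:
    """Convert a cM position from map A to map B by piecewise-linear
    scaling between flanking anchors; queries outside the anchor range
    extrapolate with the terminal segment's ratio."""
    subset = _chrom_anchors(anchors, chrom)
    xs = [a.cm_map_a for a in subset]
    ys = [a.cm_map_b for a in subset]
    return _interpolate(pos_cm_map_a, xs, ys)


def map_to_physical(
    cm_map_b: float, chrom: str, anchors: Iterable[GeneticMapAnchor]
) -> float:
    """Interpolate a map-B cM position to a physical bp coordinate using
    anchors that carry physical positions."""
    subset = [a for a in anchors if a.chrom == chrom and a.phys_bp is not None]
    subset.sort(key=lambda a: a.cm_map_b)
    if len(subset) < 2:
        raise ValidationError(f"chromosome {chrom}: need >= 2 physical anchors")
    for prev, cur in zip(subset, subset[1:]):
        if cur.phys_bp < prev.phys_bp:
            raise ValidationError(
                f"non-monotone physical anchors {prev.marker_id} "
                f"({prev.phys_bp}) -> {cur.marker_id} ({cur.phys_bp})"
            )
    xs = [a.cm_map_b for a in subset]
    ys = [float(a.phys_bp) for a in subset]
    return _interpolate(cm_map_b, xs, ys)


@dataclass
class IntrogressionScan:
    loci: list[IntervalLocus] = field(default_factory=list)
    flagged_markers: list[str] = field(default_factory=list)
    usable_markers: list[str] = field(default_factory=list)


def scan_introgression(
    matrix: MarkerGenotypeMatrix,
    chrom_lengths: Optional[dict[str, int]] = None,
    source: str = "r16a_locus",
) -> IntrogressionScan:
    """Scan array genotypes for markers where the test strain retains the
    reference-line (V) allele.

    A marker is *usable* when every control_V sample calls V, every
    control_G sample calls G, and no control call is missing. A usable
    marker is *flagged* when every test sample calls V with none missing.
    Each maximal run of adjacent flagged markers yields one locus spanning
    the interval strictly between the nearest usable non-flagged markers
    on either side (extending to the chromosome end — or the outermost
    marker when no length is known — if there is none).
    """
    tests = matrix.samples_with_role("test")
    ctrl_v = matrix.samples_with_role("control_V")
    ctrl_g = matrix.samples_with_role("control_G")
    if not tests or not ctrl_v or not ctrl_g:
        raise ValidationError("scan needs test, control_V and control_G samples")

    out = IntrogressionScan()
    by_chrom: dict[str, list[str]] = {}
    for m in matrix.marker_ids:
        by_chrom.setdefault(matrix.marker_chrom[m], []).append(m)

    locus_no = 0
    for chrom in sorted(by_chrom):
        markers = sorted(by_chrom[chrom], key=lambda m: matrix.marker_pos[m])
        usable: list[str] = []
        for m in markers:
            calls = matrix.calls[m]
            if all(calls.get(s) == "V" for s in ctrl_v) and all(
                calls.get(s) == "G" for s in ctrl_g
            ):
                usable.append(m)
        if not usable:
            logger.warning("chromosome %s: no usable markers, skipped", chrom)
            continue
        out.usable_markers.extend(usable)
        flagged = [
            m
            for m in usable
            if all(matrix.calls[m].get(s) == "V" for s in tests)
        ]
        out.flagged_markers.extend(flagged)
        flagged_set = set(flagged)
        # merge runs of adjacent flagged markers (adjacency among usable)
        i = 0
        while i < len(usable):
            if usable[i] not in flagged_set:
                i += 1
                continue
            j = i
            while j + 1 < len(usable) and usable[j + 1] in flagged_set:
                j += 1
            left = usable[i - 1] if i > 0 else None
            right = usable[j + 1] if j + 1 < len(usable) else None
            start = matrix.marker_pos[left] + 1 if left else 1
            if right:
                end = matrix.marker_pos[right] - 1
            elif chrom_lengths and chrom in chrom_lengths:
                end = chrom_lengths[chrom]
            else:
                end = matrix.marker_pos[usable[j]]
            locus_no += 1
            out.loci.append(
                IntervalLocus(
                    label=f"locus_{locus_no}",
                    chrom=chrom,
                    start=start,
                    end=end,
                    source=source,
                )
            )
            i = j + 1
    return out


def genes_in_locus(
    locus: IntervalLocus, genes: Sequence[GeneModel]
) -> list[GeneModel]:
    """Genes whose span overlaps the locus by at least 1 bp."""
    return [g for g in genes if g.overlaps(locus.chrom, locus.start, locus.end)]


@dataclass
class OverlapResult:
    intersection: set[str]
    union_fraction: float
    fraction_of_a: float
    fraction_of_b: float


def gene_set_overlap(set_a: Iterable[str], set_b: Iterable[str]) -> OverlapResult:
    """Intersection size and overlap proportions of two gene-id sets."""
    a, b = set(set_a), set(set_b)
    inter = a & b
    union = a | b
    return OverlapResult(
        intersection=inter,
        union_fraction=len(inter) / len(union) if union else 0.0,
        fraction_of_a=len(inter) / len(a) if a else 0.0,
        fraction_of_b=len(inter) / len(b) if b else 0.0,
    )


def locus_enrichment(
    hit_genes: Iterable[str],
    locus_genes: Iterable[str],
    universe: Iterable[str],
) -> tuple[int, float]:
    """One-sided upper-tail hypergeometric enrichment of hits in a locus.

    Returns (overlap size, P[X >= overlap]) drawing \\|hits\\| genes from a
    universe containing \\|locus_genes\\| successes.
    """
    uni = set(universe)
    if not uni:
        raise ValidationError("empty universe")
    hits = set(hit_genes)
    locus = set(locus_genes)
    if not hits <= uni:
        raise ValidationError("hit genes outside the universe")
    if not locus <= uni:
        raise ValidationError("locus genes outside the universe")
    k = len(hits & locus)
    p = float(hypergeom.sf(k - 1, len(uni), len(locus), len(hits)))
    return k, min(p, 1.0)
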