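"""Shared domain types for the reciprocal-hybrid ASE pipeline.

Coordinate convention: all positions are 1-based inclusive (VCF-native).
BED input is converted at the boundary by :mod:`hybridase.io`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

VALID_BASES = frozenset("ACGT")
VALID_GENOME_BASES = frozenset("ACGTN")

#: The two reciprocal cross directions. VG = reference-line mother,
#: GV = alternate-line mother.
CROSS_VG = "VG"
CROSS_GV = "GV"
CROSSES = (CROSS_VG, CROSS_GV)


class HybridaseError(Exception):
    """Base class for all pipeline errors."""


class ValidationError(HybridaseError):
    """Input violates a type invariant or file-format contract."""


class NotTestable(HybridaseError):
    """A statistic was requested for data that cannot support it."""


@dataclass
class ReferenceGenome:
    """A genome assembly as an ordered mapping of sequence name -> bases.

    Invariants: names unique and non-empty; every base in {A,C,G,T,N}
    (normalised to upper case on construction).
    """

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        clean: dict[str, str] = {}
        for name, seq in self.sequences.items():
            if not name:
                raise ValidationError("empty sequence name")
            seq = seq.upper()
            bad = set(seq) - VALID_GENOME_BASES
            if bad:
                raise ValidationError(
                    f"sequence {name!r} contains illegal characters: {sorted(bad)}"
                )
            clean[name] = seq
        self.sequences = clean

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReferenceGenome):
            return NotImplemented
        return self.sequences == other.sequences

    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}


@dataclass(frozen=True)
class GeneModel:
    """One annotated gene: 1-based inclusive span plus exonic length in bp."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."
    exonic_length: int = 0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"gene {self.gene_id}: end {self.end} < start {self.start}"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValidationError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if self.exonic_length == 0:
            # span-length fallback for annotations without exon features
            object.__setattr__(self, "exonic_length", self.end - self.start + 1)
        if self.exonic_length < 1:
            raise ValidationError(f"gene {self.gene_id}: exonic_length < 1")

    @property
    def span_length(self) -> int:
        return self.end - self.start + 1

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return chrom == self.chrom and self.start <= end and start <= self.end


#: A diploid genotype as an unordered pair of allele indexes, or None if
#: the call is missing. Index 0 is REF, 1.. are ALTs.
Genotype = Optional[tuple[int, int]]


@dataclass
class VariantSite:
    """One jointly genotyped site with per-sample diploid genotype calls."""

    chrom: str
    pos: int
    ref: str
    alts: list[str]
    genotypes: list[Genotype]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"{self.chrom}:{self.pos}: position < 1")
        if not self.alts:
            raise ValidationError(f"{self.chrom}:{self.pos}: no ALT alleles")
        if len(self.genotypes) != len(self.sample_ids):
            raise ValidationError(
                f"{self.chrom}:{self.pos}: {len(self.genotypes)} genotypes for "
                f"{len(self.sample_ids)} samples"
            )
        n_alleles = len(self.alts)
        for sample, gt in zip(self.sample_ids, self.genotypes):
            if gt is None:
                continue
            if not all(0 <= a <= n_alleles for a in gt):
                raise ValidationError(
                    f"{self.chrom}:{self.pos}: sample {sample} genotype {gt} "
                    f"out of range for {n_alleles} ALT allele(s)"
                )

    def genotype_of(self, sample_id: str) -> Genotype:
        try:
            return self.genotypes[self.sample_ids.index(sample_id)]
        except ValueError:
            raise ValidationError(f"unknown sample id {sample_id!r}") from None


@dataclass
class FixedDifferenceSet:
    """Biallelic SNPs homozygous-REF in every group-A sample and
    homozygous-ALT in every group-B sample.

    ``entries`` maps (chrom, pos) -> (ref_base, alt_base); uniqueness of
    (chrom, pos) is structural. ``provenance`` records the group labels.
    """

    entries: dict[tuple[str, int], tuple[str, str]] = field(default_factory=dict)
    provenance: tuple[str, str] = ("groupA", "groupB")
    excluded_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (chrom, pos), (ref, alt) in self.entries.items():
            if ref == alt:
                raise ValidationError(f"{chrom}:{pos}: ref == alt ({ref})")
            if ref not in VALID_BASES or alt not in VALID_BASES:
                raise ValidationError(f"{chrom}:{pos}: non-SNP alleles {ref}>{alt}")

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, key: tuple[str, int]) -> bool:
        return key in self.entries

    def sorted_entries(self) -> list[tuple[str, int, str, str]]:
        return [
            (c, p, r, a)
            for (c, p), (r, a) in sorted(self.entries.items())
        ]

    def swapped(self) -> "FixedDifferenceSet":
        """The same sites with REF and ALT roles exchanged."""
        return FixedDifferenceSet(
            entries={k: (a, r) for k, (r, a) in self.entries.items()},
            provenance=(self.provenance[1], self.provenance[0]),
        )


@dataclass
class AlleleCountRecord:
    """Per-SNP, per-sample allele counts (one ASEReadCounter-style row).

    ``ref_count`` counts reads carrying the reference-line allele,
    ``alt_count`` the alternate-line allele; ``total_count`` is re-derived
    as their sum on ingestion (other bases are ignored).
    """

    chrom: str
    pos: int
    ref_base: str
    alt_base: str
    ref_count: int
    alt_count: int
    sample_id: str = ""
    cross: str = ""
    dataset: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"{self.chrom}:{self.pos}: position < 1")
        if self.ref_count < 0 or self.alt_count < 0:
            raise ValidationError(f"{self.chrom}:{self.pos}: negative count")
        if self.ref_base not in VALID_BASES or self.alt_base not in VALID_BASES:
            raise ValidationError(
                f"{self.chrom}:{self.pos}: bad alleles "
                f"{self.ref_base!r}>{self.alt_base!r}"
            )
        if self.cross and self.cross not in CROSSES:
            raise ValidationError(f"unknown cross label {self.cross!r}")

    @property
    def total_count(self) -> int:
        return self.ref_count + self.alt_count


@dataclass(frozen=True)
class CrossDesign:
    """One direction of the reciprocal cross.

    ``ref_parent`` names the line whose allele is the reference allele at
    fixed-difference sites (the line the reads were genotyped against).
    """

    maternal_line: str
    paternal_line: str
    ref_parent: str

    def __post_init__(self) -> None:
        if self.maternal_line == self.paternal_line:
            raise ValidationError("maternal and paternal lines must differ")
        if self.ref_parent not in (self.maternal_line, self.paternal_line):
            raise ValidationError(
                f"ref_parent {self.ref_parent!r} is neither parent"
            )

    @property
    def ref_is_maternal(self) -> bool:
        return self.ref_parent == self.maternal_line


#: Standard designs for crosses between a reference line V and an
#: alternate line G: VG has a V mother, GV has a G mother.
DESIGN_VG = CrossDesign(maternal_line="V", paternal_line="G", ref_parent="V")
DESIGN_GV = CrossDesign(maternal_line="G", paternal_line="V", ref_parent="V")


@dataclass(frozen=True)
class AseFilterConfig:
    """Site- and gene-level informativeness filters for the ASE analysis."""

    min_site_depth: int = 30
    min_snps_per_gene: int = 2
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.min_site_depth < 1:
            raise ValidationError("min_site_depth must be >= 1")
        if self.min_snps_per_gene < 1:
            raise ValidationError("min_snps_per_gene must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")


class AseCategory(str, enum.Enum):
    """Per-gene call from the reciprocal-hybrid comparison."""

    PATERNAL_BIAS = "paternal_bias"
    MATERNAL_BIAS = "maternal_bias"
    CIS_REF_PARENT = "cis_ref_parent"
    CIS_ALT_PARENT = "cis_alt_parent"
    NO_DIFFERENCE = "no_difference"
    NOT_TESTABLE = "not_testable"


@dataclass
class PooledCounts:
    """Replicate-pooled per-gene counts for one cross direction."""

    n_snps: int = 0
    sum_ref: int = 0
    sum_alt: int = 0
    mean_site_depth: float = float("nan")

    @property
    def total(self) -> int:
        return self.sum_ref + self.sum_alt

    @property
    def ref_fraction(self) -> float:
        if self.total == 0:
            return float("nan")
        return self.sum_ref / self.total


@dataclass
class GeneAseSummary:
    """Per-gene pooled counts, allelic fractions, test results and category."""

    gene_id: str
    vg: PooledCounts = field(default_factory=PooledCounts)
    gv: PooledCounts = field(default_factory=PooledCounts)
    testable: bool = False
    ambiguous: bool = False
    p_value: Optional[float] = None
    q_value: Optional[float] = None
    category: AseCategory = AseCategory.NOT_TESTABLE

    @property
    def nv_fraction_vg(self) -> float:
        """Reference-parent allele fraction in the VG hybrid."""
        return self.vg.ref_fraction

    @property
    def nv_fraction_gv(self) -> float:
        return self.gv.ref_fraction


@dataclass(frozen=True)
class ImprintCallConfig:
    """FDR level and tie handling for gene categorisation."""

    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")


@dataclass(frozen=True)
class GeneticMapAnchor:
    """A marker placed on two genetic maps (and optionally the assembly)."""

    marker_id: str
    chrom: str
    cm_map_a: float
    cm_map_b: float
    phys_bp: Optional[int] = None

    def __post_init__(self) -> None:
        if self.cm_map_a < 0 or self.cm_map_b < 0:
            raise ValidationError(f"marker {self.marker_id}: negative cM")


@dataclass(frozen=True)
class IntervalLocus:
    """A labelled physical interval (1-based inclusive)."""

    label: str
    chrom: str
    start: int
    end: int
    source: str = "custom"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"locus {self.label}: start > end")


@dataclass
class MarkerGenotypeMatrix:
    """Genotyping-array calls (V / G / missing) for markers x samples.

    ``roles`` assigns each sample to test, control_V or control_G.
    ``calls[marker_id][sample_id]`` is "V", "G" or None.
    """

    marker_ids: list[str]
    marker_chrom: dict[str, str]
    marker_pos: dict[str, int]
    sample_ids: list[str]
    roles: dict[str, str]
    calls: dict[str, dict[str, Optional[str]]]

    def __post_init__(self) -> None:
        for m in self.marker_ids:
            if m not in self.marker_chrom or m not in self.marker_pos:
                raise ValidationError(f"marker {m} lacks a position")
        for s in self.sample_ids:
            role = self.roles.get(s)
            if role not in {"test", "control_V", "control_G"}:
                raise ValidationError(f"sample {s}: bad role {role!r}")

    def samples_with_role(self, role: str) -> list[str]:
        return [s for s in self.sample_ids if self.roles[s] == role]
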