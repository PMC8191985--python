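"""Pseudo-reference construction: substitute the alternate allele at every
fixed-difference SNP so that reads from either parental line face the same
number of mismatches when mapped, removing reference mapping bias.

Substitutions are SNP-only, so sequence lengths — and therefore the shared
gene annotation — remain valid on both references.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .types import FixedDifferenceSet, ReferenceGenome, ValidationError


def build_pseudo_reference(
    genome: ReferenceGenome, diffs: FixedDifferenceSet
) -> ReferenceGenome:
    """Return a copy of ``genome`` with the ALT base substituted at every
    fixed-difference position.

    The base found in the genome must equal the recorded REF base at every
    position (case-insensitive); a mismatch indicates assembly/VCF version
    skew and raises naming the offending chrom:pos.
    """
    edited = {name: bytearray(seq, "ascii") for name, seq in genome.sequences.items()}
    for chrom, pos, ref_base, alt_base in diffs.sorted_entries():
        if chrom not in edited:
            raise ValidationError(f"{chrom}:{pos}: chrom not in genome")
        seq = edited[chrom]
        if not 1 <= pos <= len(seq):
            raise ValidationError(
                f"{chrom}:{pos}: position outside sequence of length {len(seq)}"
            )
        found = chr(seq[pos - 1]).upper()
        if found != ref_base.upper():
            raise ValidationError(
                f"{chrom}:{pos}: genome has {found!r}, expected REF "
                f"{ref_base!r} (assembly/VCF mismatch?)"
            )
        seq[pos - 1] = ord(alt_base.upper())
    return ReferenceGenome(
        sequences={name: seq.decode("ascii") for name, seq in edited.items()}
    )


@dataclass
class PseudoRefReport:
    """Result of checking a pseudo-reference against its fixed-difference set."""

    unexpected_edits: list[tuple[str, int, str, str]] = field(default_factory=list)
    unrealized_diffs: list[tuple[str, int, str, str]] = field(default_factory=list)

    @property
    def clean(self) -> bool:
        return not self.unexpected_edits and not self.unrealized_diffs


def verify_pseudo_reference(
    original: ReferenceGenome,
    pseudo: ReferenceGenome,
    diffs: FixedDifferenceSet,
) -> PseudoRefReport:
    """Recompute per-position differences between the two genomes and check
    they are exactly the fixed-difference set."""
    if set(original.sequences) != set(pseudo.sequences):
        raise ValidationError("sequence name sets differ")
    report = PseudoRefReport()
    for name, orig_seq in original.sequences.items():
        pseudo_seq = pseudo.sequences[name]
        if len(orig_seq) != len(pseudo_seq):
            raise ValidationError(
                f"{name}: length mismatch {len(orig_seq)} vs {len(pseudo_seq)}"
            )
        for i, (a, b) in enumerate(zip(orig_seq, pseudo_seq)):
            if a != b:
                key = (name, i + 1)
                expected = diffs.entries.get(key)
                if expected is None or expected != (a, b):
                    report.unexpected_edits.append((name, i + 1, a, b))
    for (chrom, pos), (ref_base, alt_base) in diffs.entries.items():
        if pseudo.sequences[chrom][pos - 1] != alt_base:
            report.unrealized_diffs.append((chrom, pos, ref_base, alt_base))
    return report
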