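"""Synthetic reciprocal-cross experiments with known ground truth.

The generator emits everything the pipeline consumes downstream of read
alignment and variant calling — a reference genome, a jointly genotyped
parental VCF, a gene annotation, per-replicate hybrid allele-count tables,
dual-reference gene count matrices, and a genotyping-array marker panel —
plus the truth needed to verify every stage.

Counts are simulated at the allele-counter output level (the pipeline's
actual input boundary): per-SNP total depth is negative-binomial, and the
reference-line allele count is binomial (or beta-binomial when an
overdispersion rho > 0 is configured) around the gene's true allelic
fraction for that cross. Gene classes:

* ``null``              — fraction 0.5 in both hybrids;
* ``cis``               — fraction = effect_ratio toward the reference line
                          in both hybrids (species-of-origin effect);
* ``paternal_imprint``  — paternal allele at effect_ratio in both hybrids;
* ``maternal_imprint``  — maternal allele at effect_ratio in both hybrids.

All randomness flows from one seed through named substreams, so enlarging
one component (say, adding genes) does not perturb the draws of another
(say, the marker panel).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import io as hio
from .pseudoref import build_pseudo_reference
from .types import (
    AlleleCountRecord,
    CROSS_GV,
    CROSS_VG,
    FixedDifferenceSet,
    GeneModel,
    MarkerGenotypeMatrix,
    ReferenceGenome,
    ValidationError,
    VariantSite,
)

GENE_CLASSES = ("null", "cis", "paternal_imprint", "maternal_imprint")


@dataclass
class SimConfig:
    """Study-condition parameters for one synthetic experiment."""

    seed: int = 0
    n_chrom: int = 2
    chrom_length_bp: int = 50_000
    n_genes: int = 40
    gene_length_bp: int = 1_000
    snp_density: float = 5.0  # fixed differences per kb of gene
    parental_replicates: int = 3
    hybrid_replicates: int = 3
    class_proportions: dict[str, float] = field(
        default_factory=lambda: {
            "null": 0.94,
            "cis": 0.02,
            "paternal_imprint": 0.02,
            "maternal_imprint": 0.02,
        }
    )
    effect_ratio: float = 0.8
    depth_mean: float = 100.0
    depth_dispersion: float = 10.0  # negative-binomial size parameter
    overdispersion_rho: float = 0.0
    genotype_error_rate: float = 0.0
    n_markers_per_chrom: int = 30
    marker_blocks: list[tuple[str, int, int]] = field(default_factory=list)
    marker_missingness: float = 0.0
    marker_test_samples: int = 2
    marker_control_samples: int = 2

    def __post_init__(self) -> None:
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError("class proportions must sum to 1")
        if set(self.class_proportions) - set(GENE_CLASSES):
            raise ValidationError(f"unknown gene class in {self.class_proportions}")
        if not 0.5 < self.effect_ratio < 1.0:
            raise ValidationError("effect_ratio must be in (0.5, 1)")
        if not 0 <= self.overdispersion_rho < 1:
            raise ValidationError("overdispersion_rho must be in [0, 1)")
        if min(self.n_chrom, self.n_genes, self.gene_length_bp,
               self.chrom_length_bp) < 1:
            raise ValidationError("counts and lengths must be positive")


@dataclass
class SimTruth:
    """Ground truth for one simulated experiment."""

    gene_class: dict[str, str]
    gene_fraction: dict[str, dict[str, float]]  # gene -> cross -> ref fraction
    snp_positions: dict[str, list[tuple[str, int]]]
    fixed_sites: dict[tuple[str, int], tuple[str, str]]
    marker_truth: set[str]  # markers planted V in the test strain

    def to_json(self, path) -> None:
        obj = {
            "gene_class": self.gene_class,
            "gene_fraction": self.gene_fraction,
            "snp_positions": {
                g: [[c, p] for c, p in v] for g, v in self.snp_positions.items()
            },
            "fixed_sites": [
                [c, p, r, a] for (c, p), (r, a) in sorted(self.fixed_sites.items())
            ],
            "marker_truth": sorted(self.marker_truth),
        }
        Path(path).write_text(json.dumps(obj, indent=1))


@dataclass
class SimBundle:
    """In-memory handles plus (optionally) on-disk paths of one experiment."""

    genome: ReferenceGenome
    pseudo_genome: ReferenceGenome
    sites: list[VariantSite]
    sample_ids: list[str]
    group_a: list[str]
    group_b: list[str]
    genes: list[GeneModel]
    ase_records: list[AlleleCountRecord]
    counts_ref: "object"
    counts_pseudo: "object"
    markers: MarkerGenotypeMatrix
    truth: SimTruth
    out_dir: Optional[Path] = None


def _rng(seed: int, name: str) -> np.random.Generator:
    """Named substream: a child generator keyed on (seed, name)."""
    digest = hashlib.sha256(name.encode()).digest()
    child = int.from_bytes(digest[:4], "big") % (2**31 - 1)
    return np.random.default_rng(np.random.SeedSequence([seed, child]))


def draw_site_counts(
    rng: np.random.Generator, total_depth: int, gene_fraction: float, rho: float
) -> tuple[int, int]:
    """Draw (refCount, altCount) summing to total_depth.

    Binomial when rho = 0; beta-binomial with mean ``gene_fraction`` and
    intra-class correlation ``rho`` otherwise.
    """
    if total_depth < 0:
        raise ValidationError("negative depth")
    if not 0 < gene_fraction < 1:
        raise ValidationError("fraction must be in (0, 1)")
    if total_depth == 0:
        return 0, 0
    if rho == 0:
        ref = int(rng.binomial(total_depth, gene_fraction))
    else:
        a = gene_fraction * (1 - rho) / rho
        b = (1 - gene_fraction) * (1 - rho) / rho
        p = rng.beta(a, b)
        ref = int(rng.binomial(total_depth, p))
    return ref, total_depth - ref


def _nb_depth(rng: np.random.Generator, mean: float, size: float) -> int:
    p = size / (size + mean)
    return int(rng.negative_binomial(size, p))


_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _simulate_genome(config: SimConfig) -> ReferenceGenome:
    rng = _rng(config.seed, "genome")
    seqs = {}
    for i in range(config.n_chrom):
        arr = _BASES[rng.integers(0, 4, size=config.chrom_length_bp)]
        seqs[f"chr{i + 1}"] = arr.tobytes().decode("ascii")
    return ReferenceGenome(sequences=seqs)


def _place_genes(config: SimConfig) -> list[GeneModel]:
    per_chrom = -(-config.n_genes // config.n_chrom)  # ceil
    slot = config.chrom_length_bp // per_chrom
    if slot < config.gene_length_bp + 2:
        raise ValidationError(
            f"{config.n_genes} genes of {config.gene_length_bp} bp do not fit "
            f"on {config.n_chrom} x {config.chrom_length_bp} bp chromosomes"
        )
    genes = []
    for g in range(config.n_genes):
        chrom = f"chr{g % config.n_chrom + 1}"
        rank = g // config.n_chrom
        start = rank * slot + 1
        genes.append(
            GeneModel(
                gene_id=f"gene{g + 1:04d}",
                chrom=chrom,
                start=start,
                end=start + config.gene_length_bp - 1,
                strand="+",
            )
        )
    return genes


def _plant_snps(
    config: SimConfig, genome: ReferenceGenome, genes: list[GeneModel]
) -> tuple[dict[tuple[str, int], tuple[str, str]], dict[str, list[tuple[str, int]]]]:
    rng = _rng(config.seed, "snps")
    fixed: dict[tuple[str, int], tuple[str, str]] = {}
    per_gene: dict[str, list[tuple[str, int]]] = {}
    n_per_gene = max(1, round(config.snp_density * config.gene_length_bp / 1000))
    for gene in genes:
        offsets = rng.choice(gene.span_length, size=n_per_gene, replace=False)
        positions = sorted(int(gene.start + o) for o in offsets)
        sites = []
        for pos in positions:
            ref = genome.sequences[gene.chrom][pos - 1]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            fixed[(gene.chrom, pos)] = (ref, alt)
            sites.append((gene.chrom, pos))
        per_gene[gene.gene_id] = sites
    return fixed, per_gene


def _simulate_vcf(
    config: SimConfig, fixed: dict[tuple[str, int], tuple[str, str]]
) -> tuple[list[VariantSite], list[str], list[str], list[str]]:
    rng = _rng(config.seed, "vcf")
    group_a = [f"VV{i + 1}" for i in range(config.parental_replicates)]
    group_b = [f"GG{i + 1}" for i in range(config.parental_replicates)]
    samples = group_a + group_b
    sites = []
    for (chrom, pos), (ref, alt) in sorted(fixed.items()):
        genotypes = []
        for sample in samples:
            hom = (0, 0) if sample.startswith("VV") else (1, 1)
            # genotyping error: spurious heterozygous call in an inbred line
            if config.genotype_error_rate > 0 and rng.random() < config.genotype_error_rate:
                hom = (0, 1)
            genotypes.append(hom)
        sites.append(
            VariantSite(
                chrom=chrom, pos=pos, ref=ref, alts=[alt],
                genotypes=genotypes, sample_ids=samples,
            )
        )
    return sites, samples, group_a, group_b


def _assign_classes(
    config: SimConfig, genes: list[GeneModel]
) -> tuple[dict[str, str], dict[str, dict[str, float]]]:
    rng = _rng(config.seed, "classes")
    labels = list(config.class_proportions)
    probs = [config.class_proportions[k] for k in labels]
    e = config.effect_ratio
    fractions = {
        "null": {CROSS_VG: 0.5, CROSS_GV: 0.5},
        # cis effects are same-side but unequal between hybrids (the
        # between-hybrid test cannot see a perfectly symmetric bias)
        "cis": {CROSS_VG: e, CROSS_GV: (0.5 + e) / 2},
        # paternal allele favoured: in VG the father is the alt line
        "paternal_imprint": {CROSS_VG: 1 - e, CROSS_GV: e},
        "maternal_imprint": {CROSS_VG: e, CROSS_GV: 1 - e},
    }
    gene_class, gene_fraction = {}, {}
    for gene in genes:
        cls = str(rng.choice(labels, p=probs))
        gene_class[gene.gene_id] = cls
        gene_fraction[gene.gene_id] = dict(fractions[cls])
    return gene_class, gene_fraction


def _simulate_ase(
    config: SimConfig,
    snp_positions: dict[str, list[tuple[str, int]]],
    fixed: dict[tuple[str, int], tuple[str, str]],
    gene_fraction: dict[str, dict[str, float]],
) -> list[AlleleCountRecord]:
    rng = _rng(config.seed, "ase")
    records = []
    for cross in (CROSS_VG, CROSS_GV):
        for rep in range(1, config.hybrid_replicates + 1):
            sample = f"{cross}{rep}"
            for gene_id in sorted(snp_positions):
                f = gene_fraction[gene_id][cross]
                for chrom, pos in snp_positions[gene_id]:
                    ref_base, alt_base = fixed[(chrom, pos)]
                    depth = _nb_depth(rng, config.depth_mean,
                                      config.depth_dispersion)
                    if depth == 0:
                        continue
                    ref, alt = draw_site_counts(
                        rng, depth, f, config.overdispersion_rho
                    )
                    records.append(
                        AlleleCountRecord(
                            chrom=chrom, pos=pos, ref_base=ref_base,
                            alt_base=alt_base, ref_count=ref, alt_count=alt,
                            sample_id=sample, cross=cross, dataset="sim",
                        )
                    )
    return records


def _simulate_counts(config: SimConfig, genes: list[GeneModel]):
    import pandas as pd

    from .exprqc import CountsMatrix, GROUPS

    rng = _rng(config.seed, "counts")
    samples, groups = [], {}
    for grp in GROUPS:
        for rep in range(1, config.hybrid_replicates + 1):
            s = f"{grp}_{rep}"
            samples.append(s)
            groups[s] = grp
    base = rng.lognormal(mean=5.0, sigma=1.0, size=len(genes))
    mats = []
    for _ in range(2):  # one matrix per reference
        values = np.empty((len(genes), len(samples)))
        for j in range(len(samples)):
            values[:, j] = [
                _nb_depth(rng, m, config.depth_dispersion) for m in base
            ]
        mats.append(
            CountsMatrix(
                values=pd.DataFrame(
                    values, index=[g.gene_id for g in genes], columns=samples
                ),
                groups=dict(groups),
            )
        )
    return mats[0], mats[1]


def plant_marker_blocks(
    config: SimConfig,
) -> tuple[MarkerGenotypeMatrix, set[str]]:
    """Build a genotyping-array panel with planted non-introgressed blocks.

    Control samples carry their own line's allele at every marker; test
    samples carry V inside planted blocks and G elsewhere, with optional
    missingness in test calls. Overlapping blocks are merged.
    """
    rng = _rng(config.seed, "markers")
    marker_ids, chrom_of, pos_of = [], {}, {}
    spacing = config.chrom_length_bp // (config.n_markers_per_chrom + 1)
    if spacing < 1:
        raise ValidationError("too many markers for chromosome length")
    for i in range(config.n_chrom):
        chrom = f"chr{i + 1}"
        for k in range(config.n_markers_per_chrom):
            m = f"mk_{chrom}_{k + 1:03d}"
            marker_ids.append(m)
            chrom_of[m] = chrom
            pos_of[m] = (k + 1) * spacing
    for chrom, start, end in config.marker_blocks:
        if end < start:
            raise ValidationError(f"block on {chrom}: end < start")

    ctrl_v = [f"Vctl{i + 1}" for i in range(config.marker_control_samples)]
    ctrl_g = [f"Gctl{i + 1}" for i in range(config.marker_control_samples)]
    tests = [f"R{i + 1}" for i in range(config.marker_test_samples)]
    roles = {**{s: "control_V" for s in ctrl_v},
             **{s: "control_G" for s in ctrl_g},
             **{s: "test" for s in tests}}

    truth: set[str] = set()
    calls: dict[str, dict[str, Optional[str]]] = {}
    for m in marker_ids:
        in_block = any(
            chrom_of[m] == c and s <= pos_of[m] <= e
            for c, s, e in config.marker_blocks
        )
        if in_block:
            truth.add(m)
        row: dict[str, Optional[str]] = {}
        for s in ctrl_v:
            row[s] = "V"
        for s in ctrl_g:
            row[s] = "G"
        for s in tests:
            if config.marker_missingness > 0 and rng.random() < config.marker_missingness:
                row[s] = None
            else:
                row[s] = "V" if in_block else "G"
        calls[m] = row
    matrix = MarkerGenotypeMatrix(
        marker_ids=marker_ids,
        marker_chrom=chrom_of,
        marker_pos=pos_of,
        sample_ids=ctrl_v + ctrl_g + tests,
        roles=roles,
        calls=calls,
    )
    return matrix, truth


def write_marker_csv(matrix: MarkerGenotypeMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("marker_id,chrom,pos," + ",".join(matrix.sample_ids) + "\n")
        for m in matrix.marker_ids:
            cells = [
                matrix.calls[m].get(s) or "NA" for s in matrix.sample_ids
            ]
            fh.write(
                f"{m},{matrix.marker_chrom[m]},{matrix.marker_pos[m]},"
                + ",".join(cells) + "\n"
            )


def read_marker_csv(path, roles: dict[str, str]) -> MarkerGenotypeMatrix:
    import csv as _csv

    with open(path) as fh:
        reader = _csv.reader(fh)
        header = next(reader)
        samples = header[3:]
        marker_ids, chrom_of, pos_of, calls = [], {}, {}, {}
        for row in reader:
            m = row[0]
            marker_ids.append(m)
            chrom_of[m] = row[1]
            pos_of[m] = int(row[2])
            calls[m] = {
                s: (None if v in {"NA", ""} else v)
                for s, v in zip(samples, row[3:])
            }
    return MarkerGenotypeMatrix(
        marker_ids=marker_ids, marker_chrom=chrom_of, marker_pos=pos_of,
        sample_ids=samples, roles=roles, calls=calls,
    )


def _write_gff3(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tsim\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            fh.write(
                f"{g.chrom}\tsim\texon\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}.e1;Parent={g.gene_id}\n"
            )


def simulate_experiment(
    config: SimConfig, out_dir: Optional[Path] = None
) -> SimBundle:
    """Generate a complete synthetic experiment (optionally written to disk).

    The same seed yields a byte-identical bundle. Emitted files: reference
    FASTA, truth pseudo-reference FASTA, parental multi-sample VCF, GFF3
    annotation, per-replicate hybrid ASE TSVs, dual-reference count TSVs,
    marker CSV, and truth JSON.
    """
    genome = _simulate_genome(config)
    genes = _place_genes(config)
    fixed, per_gene = _plant_snps(config, genome, genes)
    sites, samples, group_a, group_b = _simulate_vcf(config, fixed)
    gene_class, gene_fraction = _assign_classes(config, genes)
    ase_records = _simulate_ase(config, per_gene, fixed, gene_fraction)
    counts_ref, counts_pseudo = _simulate_counts(config, genes)
    markers, marker_truth = plant_marker_blocks(config)
    pseudo = build_pseudo_reference(
        genome, FixedDifferenceSet(entries=dict(fixed))
    )
    truth = SimTruth(
        gene_class=gene_class,
        gene_fraction=gene_fraction,
        snp_positions=per_gene,
        fixed_sites=fixed,
        marker_truth=marker_truth,
    )
    bundle = SimBundle(
        genome=genome, pseudo_genome=pseudo, sites=sites, sample_ids=samples,
        group_a=group_a, group_b=group_b, genes=genes,
        ase_records=ase_records, counts_ref=counts_ref,
        counts_pseudo=counts_pseudo, markers=markers, truth=truth,
        out_dir=out_dir,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        hio.write_fasta(genome, out_dir / "reference.fa")
        hio.write_fasta(pseudo, out_dir / "pseudo_reference_truth.fa")
        hio.write_vcf(sites, samples, out_dir / "parental.vcf")
        _write_gff3(genes, out_dir / "genes.gff3")
        ase_dir = out_dir / "ase"
        ase_dir.mkdir(exist_ok=True)
        by_sample: dict[str, list[AlleleCountRecord]] = {}
        for r in ase_records:
            by_sample.setdefault(r.sample_id, []).append(r)
        for sample, recs in sorted(by_sample.items()):
            hio.write_ase_table(recs, ase_dir / f"ase_{sample}.tsv")
        hio.write_counts_matrix(counts_ref.values, out_dir / "counts_ref.tsv")
        hio.write_counts_matrix(
            counts_pseudo.values, out_dir / "counts_pseudo.tsv"
        )
        write_marker_csv(markers, out_dir / "markers.csv")
        roles_yaml = "\n".join(
            f"{s}: {markers.roles[s]}" for s in markers.sample_ids
        )
        (out_dir / "roles.yaml").write_text(roles_yaml + "\n")
        truth.to_json(out_dir / "truth.json")
    return bundle
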