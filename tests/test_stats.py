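"""Imprinting statistics against independent oracles: exhaustive
hypergeometric enumeration for Fisher's test, the step-up definition for
BH, closed-form/enumerated binomial tails, and the published worked
examples for gene categorisation."""

import numpy as np
import pytest
from scipy.stats import binom, hypergeom

from hybridase.ase import aggregate_gene_ase
from hybridase.stats import (
    bh_adjust,
    classify_gene,
    combine_datasets,
    fisher_exact_two_sided,
    intersect_fixed_differences,
    per_hybrid_bias_test,
    run_imprinting_analysis,
)
from hybridase.types import (
    AlleleCountRecord,
    AseCategory,
    FixedDifferenceSet,
    GeneAseSummary,
    GeneModel,
    ImprintCallConfig,
    NotTestable,
    PooledCounts,
    ValidationError,
)

# ---------------------------------------------------------------- oracles


def oracle_fisher(a, b, c, d):
    """Two-sided Fisher p by summing hypergeometric probabilities no
    larger than the observed table's (relative tie slack 1e-7)."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    ks = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    pmf = hypergeom.pmf(ks, n, r1, c1)
    p_obs = hypergeom.pmf(a, n, r1, c1)
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-7)].sum()))


def oracle_bh(ps):
    """Step-up definition: q_(i) = min_{j >= i} p_(j) * m / j, clipped."""
    m = len(ps)
    order = np.argsort(ps, kind="mergesort")
    q_sorted = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, ps[order[rank - 1]] * m / rank)
        q_sorted[rank - 1] = min(1.0, running)
    out = np.empty(m)
    out[order] = q_sorted
    return out


def oracle_binom_two_sided(k, n):
    pmf = binom.pmf(np.arange(n + 1), n, 0.5)
    return float(min(1.0, pmf[pmf <= pmf[k] * (1 + 1e-7)].sum()))


def summary(gene_id, vg_ref, vg_alt, gv_ref, gv_alt, n_snps=2):
    return GeneAseSummary(
        gene_id=gene_id,
        vg=PooledCounts(n_snps, vg_ref, vg_alt, 100.0),
        gv=PooledCounts(n_snps, gv_ref, gv_alt, 100.0),
        testable=True,
    )


# ---------------------------------------------------------------- Fisher


class TestFisher:
    def test_balanced_table_p_is_one(self):
        assert fisher_exact_two_sided(10, 10, 10, 10) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 20, size=4)
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            got = fisher_exact_two_sided(int(a), int(b), int(c), int(d))
            assert got == pytest.approx(oracle_fisher(a, b, c, d), abs=1e-9)

    def test_transposition_symmetry(self):
        assert fisher_exact_two_sided(3, 11, 9, 2) == pytest.approx(
            fisher_exact_two_sided(3, 9, 11, 2)
        )

    def test_zero_margin_signals_not_testable(self):
        assert fisher_exact_two_sided(0, 0, 5, 5) is None
        assert fisher_exact_two_sided(5, 0, 5, 0) is None

    def test_negative_cell_rejected(self):
        with pytest.raises(ValidationError):
            fisher_exact_two_sided(-1, 2, 3, 4)


# -------------------------------------------------------------------- BH


class TestBh:
    def test_hand_worked_example(self):
        assert bh_adjust([0.01, 0.02, 0.04]) == pytest.approx([0.03, 0.03, 0.04])

    def test_all_equal_ps_stay_equal(self):
        assert bh_adjust([0.2, 0.2, 0.2, 0.2]) == pytest.approx([0.2] * 4)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.31]) == [pytest.approx(0.31)]

    def test_input_order_preserved_vs_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            ps = rng.uniform(size=int(rng.integers(1, 40)))
            assert bh_adjust(list(ps)) == pytest.approx(oracle_bh(ps))

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])

    def test_empty_input(self):
        assert bh_adjust([]) == []


# -------------------------------------------------------- binomial test


class TestPerHybridBias:
    def test_balanced_counts_p_is_one(self):
        assert per_hybrid_bias_test(10, 10) == pytest.approx(1.0)

    def test_extreme_count_closed_form(self):
        # all 30 reads on one allele: p = 2 * 0.5^30
        assert per_hybrid_bias_test(30, 0) == pytest.approx(2 * 0.5**30)

    @pytest.mark.parametrize("total", [1, 2, 7, 20, 50])
    def test_matches_enumeration_for_small_totals(self, total):
        for k in range(total + 1):
            assert per_hybrid_bias_test(k, total - k) == pytest.approx(
                oracle_binom_two_sided(k, total), abs=1e-12
            )

    def test_zero_total_not_testable(self):
        with pytest.raises(NotTestable):
            per_hybrid_bias_test(0, 0)


# -------------------------------------------------------- classification


class TestClassifyGene:
    def classify(self, f_vg, f_gv, q=0.001):
        n = 1000
        s = summary("g", round(f_vg * n), n - round(f_vg * n),
                    round(f_gv * n), n - round(f_gv * n))
        s.q_value = q
        return classify_gene(s)

    def test_paternal_bias_worked_example(self):
        # cuticular-protein gene: VG favours the paternal (alternate-line)
        # allele at 65.3%, GV favours the paternal (reference-line) allele
        assert self.classify(1 - 0.653, 0.62) is AseCategory.PATERNAL_BIAS

    def test_maternal_bias_is_the_mirror(self):
        assert self.classify(0.653, 1 - 0.62) is AseCategory.MATERNAL_BIAS

    def test_cis_reference_line_worked_example(self):
        # nasonin-3-like case: reference-line allele at 93% and 61%
        assert self.classify(0.93, 0.61) is AseCategory.CIS_REF_PARENT

    def test_cis_alternate_line(self):
        assert self.classify(0.1, 0.35) is AseCategory.CIS_ALT_PARENT

    def test_non_significant_q_is_no_difference(self):
        assert self.classify(0.93, 0.05, q=0.5) is AseCategory.NO_DIFFERENCE

    def test_tie_falls_to_cis_side_of_other_fraction(self):
        assert self.classify(0.5, 0.8) is AseCategory.CIS_REF_PARENT
        assert self.classify(0.2, 0.5) is AseCategory.CIS_ALT_PARENT

    def test_not_testable_passes_through(self):
        s = GeneAseSummary(gene_id="g")
        assert classify_gene(s) is AseCategory.NOT_TESTABLE


# ------------------------------------------------- analysis end-to-end


class TestRunImprintingAnalysis:
    def test_empty_input(self):
        assert run_imprinting_analysis([]) == []

    def test_null_genes_yield_no_calls(self):
        rng = np.random.default_rng(0)
        summaries = []
        for i in range(300):
            tot = 1500
            summaries.append(
                summary(f"g{i}", rng.binomial(tot, 0.5), 0, rng.binomial(tot, 0.5), 0)
            )
            summaries[-1].vg.sum_alt = tot - summaries[-1].vg.sum_ref
            summaries[-1].gv.sum_alt = tot - summaries[-1].gv.sum_ref
        out = run_imprinting_analysis(summaries)
        calls = [s for s in out if s.category not in
                 (AseCategory.NO_DIFFERENCE, AseCategory.NOT_TESTABLE)]
        assert len(calls) <= 2  # BH at 0.05 on a pure null set

    def test_planted_paternal_genes_recovered(self):
        rng = np.random.default_rng(1)
        summaries = []
        truth = {}
        for i in range(100):
            tot = 1500
            if i < 10:
                f_vg, f_gv = 0.2, 0.8
                truth[f"g{i}"] = AseCategory.PATERNAL_BIAS
            else:
                f_vg = f_gv = 0.5
            a = rng.binomial(tot, f_vg)
            c = rng.binomial(tot, f_gv)
            summaries.append(summary(f"g{i}", a, tot - a, c, tot - c))
        out = {s.gene_id: s.category for s in run_imprinting_analysis(summaries)}
        assert all(out[g] is cat for g, cat in truth.items())

    def test_output_sorted_by_q_then_gene(self):
        rng = np.random.default_rng(2)
        summaries = [
            summary(f"g{i}", rng.integers(400, 1100), 750,
                    rng.integers(400, 1100), 750)
            for i in range(20)
        ]
        out = run_imprinting_analysis(summaries)
        keys = [(s.q_value, s.gene_id) for s in out if s.q_value is not None]
        assert keys == sorted(keys)


# ------------------------------------------------------------- combine


GENES = [GeneModel("g1", "chr1", 100, 300)]
DIFFS = FixedDifferenceSet(entries={("chr1", 150): ("C", "T"),
                                    ("chr1", 200): ("A", "G")})


def records_for(dataset):
    out = []
    for cross, f in (("VG", 0.3), ("GV", 0.7)):
        for pos, (rb, ab) in (
            (150, ("C", "T")), (200, ("A", "G")),
        ):
            ref = round(100 * f)
            out.append(
                AlleleCountRecord(
                    chrom="chr1", pos=pos, ref_base=rb, alt_base=ab,
                    ref_count=ref, alt_count=100 - ref,
                    sample_id=f"{cross}1", cross=cross, dataset=dataset,
                )
            )
    return out


class TestCombine:
    def test_disjoint_diff_sets_leave_nothing_testable(self):
        other = FixedDifferenceSet(entries={("chr2", 5): ("A", "C")})
        out = combine_datasets(records_for("a"), records_for("b"),
                               DIFFS, other, GENES)
        assert all(not s.testable for s in out)

    def test_identical_datasets_equal_doubled_counts(self):
        combined = combine_datasets(records_for("a"), records_for("a"),
                                    DIFFS, DIFFS, GENES)
        single = run_imprinting_analysis(
            aggregate_gene_ase(records_for("a"), DIFFS, GENES)
        )
        (c,), (s,) = combined, single
        assert c.vg.sum_ref == 2 * s.vg.sum_ref
        assert c.gv.sum_alt == 2 * s.gv.sum_alt
        assert c.category is s.category

    def test_allele_disagreement_dropped_from_intersection(self):
        flipped = FixedDifferenceSet(entries={("chr1", 150): ("T", "C"),
                                              ("chr1", 200): ("A", "G")})
        shared = intersect_fixed_differences(DIFFS, flipped)
        assert set(shared.entries) == {("chr1", 200)}
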