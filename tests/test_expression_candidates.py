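"""Differential-expression filter (with an exact enumeration oracle for the
rank-sum level), qPCR quantification, eQTL orchestration and candidate
intersection."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from xcrossqtl import (
    ExpressionMatrix,
    GeneAnnotation,
    ValidationError,
    classify_cis,
    compile_report,
    delta_delta_ct,
    eqtl_scan_all,
    intersect_candidates,
    make_marker_map,
    np_scan,
    simulate_backcross,
    simulate_expression_traits,
    simulate_strain_expression,
    strain_differential_expression,
)
from xcrossqtl.expression_candidates import passing_genes
from xcrossqtl.genoprob import conditional_genotype_probs
from xcrossqtl.synthetic_data import ExpressionTraitSpec


def matrix_from(genes: dict, n_per_strain=5, strains=("NZO", "C3H", "129P2")):
    samples, labels = [], {}
    for s in strains:
        for i in range(n_per_strain):
            name = f"{s}_{i + 1}"
            samples.append(name)
            labels[name] = s
    values = pd.DataFrame(genes, index=samples).T
    values.columns = samples
    return ExpressionMatrix(values, labels)


class TestDifferentialExpression:
    def test_identical_groups_ratio_one_no_pass(self):
        m = matrix_from({"g": list(range(1, 6)) * 3})
        rec = strain_differential_expression(m).iloc[0]
        assert rec["ratio_C3H"] == 1.0 and rec["ratio_129P2"] == 1.0
        assert not rec["passed"]

    def test_absent_strain_rejected(self):
        m = matrix_from({"g": [1.0] * 10}, strains=("NZO", "C3H"))
        with pytest.raises(ValidationError, match="129P2"):
            strain_differential_expression(m)

    def test_per_comparison_level_matches_enumeration_oracle(self):
        """The attainable level of the exact two-sided rank-sum test at
        n=5 vs 5 is discrete; enumerate all C(10,5) rank splits to get it,
        then check the null rejection rate of the filter against it."""
        level = 0.0
        ranks = np.arange(1.0, 11.0)
        count = 0
        for comb in itertools.combinations(range(10), 5):
            x = ranks[list(comb)]
            y = np.delete(ranks, list(comb))
            if stats.mannwhitneyu(x, y, alternative="two-sided").pvalue < 0.05:
                count += 1
        level = count / math.comb(10, 5)
        assert level == pytest.approx(8 / 252, abs=1e-12)

        m = simulate_strain_expression(1500, 5, {}, seed=19)
        rec = strain_differential_expression(m)
        for col in ("p_C3H", "p_129P2"):
            rate = (rec[col] < 0.05).mean()
            tol = 3.5 * math.sqrt(level * (1 - level) / 1500)
            assert abs(rate - level) < tol
        # joint pass requires both comparisons plus direction agreement:
        # far rarer than a single rejection
        assert rec["passed"].mean() < level / 2

    def test_pass_flags_match_naive_reimplementation(self):
        rng = np.random.default_rng(31)
        m = simulate_strain_expression(
            120, 5, {f"g{i:04d}": s for i, s in [(1, 2.0), (2, -2.0), (3, 0.4)]},
            seed=29,
        )
        rec = strain_differential_expression(m, alpha=0.05).set_index("gene")
        vals = m.values
        for gene in vals.index:
            x = vals.loc[gene, m.samples_of("NZO")].to_numpy()
            flags, sides = [], []
            for other in ("C3H", "129P2"):
                y = vals.loc[gene, m.samples_of(other)].to_numpy()
                p = stats.mannwhitneyu(x, y, alternative="two-sided").pvalue
                flags.append(p < 0.05)
                sides.append(x.mean() / y.mean() > 1)
            expected = all(flags) and len(set(sides)) == 1
            assert bool(rec.loc[gene, "passed"]) == expected

    def test_planted_two_fold_shift_power_consistent(self):
        # power at a 2-fold focal-only shift, estimated from two independent
        # simulated batches, must agree to binomial error
        rates = []
        for seed in (101, 202):
            planted = {f"g{i + 1:04d}": 1.0 if i % 2 else -1.0 for i in range(150)}
            m = simulate_strain_expression(150, 5, planted, seed=seed)
            rec = strain_differential_expression(m)
            rates.append(rec["passed"].mean())
        assert min(rates) > 0.3
        tol = 4 * math.sqrt(0.5 * 0.5 / 150) * math.sqrt(2)
        assert abs(rates[0] - rates[1]) < tol

    def test_direction_labels(self):
        m = matrix_from({
            "up": [10, 11, 12, 13, 14] + [1, 2, 3, 4, 5] + [2, 3, 4, 5, 6],
            "down": [1, 2, 3, 4, 5] + [10, 11, 12, 13, 14] + [11, 12, 13, 14, 15],
        })
        rec = strain_differential_expression(m).set_index("gene")
        assert rec.loc["up", "direction"] == "up-in-focal"
        assert rec.loc["up", "passed"]
        assert rec.loc["down", "direction"] == "down-in-focal"
        assert rec.loc["down", "passed"]


class TestDeltaDeltaCt:
    def test_all_equal_gives_unity(self):
        ddct, fold = delta_delta_ct(20.0, 20.0, 20.0, 20.0)
        assert ddct == 0.0 and fold == 1.0

    def test_negative_ddct_amplifies(self):
        ddct, fold = delta_delta_ct(18.0, 20.0, 20.6, 18.0)
        assert ddct == pytest.approx(-4.6)
        assert fold == pytest.approx(24.25, abs=0.01)  # 2^4.6

    def test_positive_unit_halves(self):
        assert delta_delta_ct(21.0, 20.0, 20.0, 20.0)[1] == 0.5

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            delta_delta_ct(math.nan, 20.0, 20.0, 20.0)


class TestClassifyCis:
    def test_other_chromosome_is_trans(self):
        assert classify_cis("2", 30.0, "14", 60.0) == "trans"

    def test_within_window_is_cis(self):
        assert classify_cis("14", 60.0, "14", 63.5, window_mbp=20.0) == "cis"
        assert classify_cis("14", 20.0, "14", 63.5, window_mbp=20.0) == "trans"

    def test_missing_gene_location_rejected(self):
        with pytest.raises(ValidationError):
            classify_cis("14", 60.0, None, math.nan)


@pytest.fixture(scope="module")
def eqtl_setup():
    gmap = make_marker_map([100.0, 100.0], chrom_names=["1", "2"])
    cross = simulate_backcross(gmap, 250, seed=41, cross_label="eqtl")
    specs = [
        ExpressionTraitSpec("cisgene", "1", 30.0, dct_shift=2.0),
        ExpressionTraitSpec("transgene", "2", 20.0, dct_shift=1.2),
        ExpressionTraitSpec("nullgene", "1", 40.0, dct_shift=0.0),
    ]
    cross = simulate_expression_traits(cross, specs, seed=43)
    genes = GeneAnnotation(pd.DataFrame(
        {
            "chrom": ["1", "1", "1"],
            # cisgene sits at its own locus (30 cM = 60 Mbp); transgene's
            # coding location is far from its chromosome-2 regulator
            "start": [59_900_000, 10_000_000, 79_900_000],
            "end": [60_100_000, 10_200_000, 80_100_000],
            "name": ["cisgene", "transgene", "nullgene"],
        }
    ))
    return cross, genes


class TestEqtlScanAll:
    def test_planted_architectures_classified(self, eqtl_setup):
        cross, genes = eqtl_setup
        records = {r.gene: r for r in eqtl_scan_all(
            cross, genes, n_perm=100, seed=7
        )}
        assert records["cisgene"].significant
        assert records["cisgene"].regulation == "cis"
        assert records["cisgene"].peak_chrom == "1"
        assert abs(records["cisgene"].peak_cm - 30.0) < 10.0

        assert records["transgene"].significant
        assert records["transgene"].regulation == "trans"
        assert records["transgene"].peak_chrom == "2"

        assert not records["nullgene"].significant
        assert records["nullgene"].regulation is None

    def test_scan_invariant_under_monotone_rescaling(self, eqtl_setup):
        cross, _ = eqtl_setup
        probs = conditional_genotype_probs(cross)
        expr = cross.phenotypes["cisgene"]
        lod_expr = np_scan(probs, expr).lod
        lod_dct = np_scan(probs, -np.log2(expr)).lod  # back to the dCt scale
        np.testing.assert_allclose(lod_expr, lod_dct, atol=1e-12)

    def test_all_missing_trait_skipped(self, eqtl_setup):
        cross, genes = eqtl_setup
        pheno = cross.phenotypes.copy()
        pheno["cisgene"] = np.nan
        from xcrossqtl import CrossPopulation

        broken = CrossPopulation(cross.gmap, cross.genotypes, pheno)
        records = eqtl_scan_all(broken, genes, n_perm=100, seed=7)
        assert "cisgene" not in {r.gene for r in records}


class TestCandidates:
    def test_disjoint_sets_empty(self):
        report = intersect_candidates({"a", "b"}, ["c", "d"])
        assert report.intersection == []
        assert report.venn["overlap"] == 0

    def test_identical_sets(self):
        report = intersect_candidates({"a", "b"}, ["b", "a"])
        assert report.intersection == ["a", "b"]

    def test_intersection_uses_passing_genes_only(self):
        rec = pd.DataFrame({"gene": ["a", "b"], "passed": [True, False]})
        report = intersect_candidates({"a", "b"}, rec)
        assert report.intersection == ["a"]
        assert passing_genes(rec) == {"a"}

    def test_order_independent_and_idempotent(self):
        r1 = intersect_candidates(["b", "a", "a"], ["a", "c"])
        r2 = intersect_candidates(["a", "b"], ["c", "a"])
        assert r1.intersection == r2.intersection == ["a"]

    def test_compile_report_requires_all_stages(self, eqtl_setup):
        with pytest.raises(ValidationError, match="haplotype_windows"):
            compile_report([], None, pd.DataFrame(), pd.DataFrame(), [], set())
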