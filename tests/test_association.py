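from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from recwas.association import (DegenerateInput, code_genotype, filter_variants,
                                fisher_fallback, fit_association, run_phewas)
from recwas.io import GenotypeMatrix, PipelineConfig, VariantRecord
from recwas.simulate import (CohortSpec, InheritanceScenario, VariantSpec,
                             simulate_genotypes, simulate_phenotype)


def fisher_enum_oracle(a, b, c, d):
    """Brute-force two-sided Fisher P by exact-integer hypergeometric enumeration."""
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    probs = [comb(r1, x) * comb(r2, c1 - x) for x in range(lo, hi + 1)]
    pobs = probs[a - lo]
    return sum(p for p in probs if p <= pobs) / sum(probs)


class TestCodeGenotype:
    def test_recessive(self):
        np.testing.assert_array_equal(
            code_genotype(np.array([0, 1, 2, 2, 1]), "recessive"), [0, 0, 1, 1, 0])

    def test_additive_identity(self):
        np.testing.assert_array_equal(
            code_genotype(np.array([0, 1, 2]), "additive"), [0, 1, 2])

    def test_recessive_all_het_degenerate(self):
        coded = code_genotype(np.ones(10, dtype=int), "recessive")
        assert (coded == 0).all()

    def test_missing_preserved(self):
        g = np.array([0.0, 1.0, np.nan, 2.0])
        coded = code_genotype(g, "recessive")
        assert np.isnan(coded[2]) and coded[3] == 1

    def test_unknown_model(self):
        with pytest.raises(ValueError):
            code_genotype(np.array([0]), "dominant")


def _geno_with_hom_counts(counts, chrom="1", start_pos=1000):
    """One variant per requested hom count, n=20 individuals."""
    variants, cols = [], []
    for i, k in enumerate(counts):
        variants.append(VariantRecord(chrom, start_pos + i, "A", "C"))
        h = np.zeros((20, 2), dtype=np.int8)
        h[:k] = 1
        cols.append(h)
    return GenotypeMatrix(variants=variants, haplotypes=np.stack(cols, axis=1),
                         phased=np.ones(20, dtype=bool),
                         sample_ids=[f"S{i}" for i in range(20)])


class TestFilterVariants:
    def test_min_hom_boundary(self):
        geno = _geno_with_hom_counts([5, 4])
        kept, log = filter_variants(geno, min_hom=5)
        assert kept == [0]
        assert log[0]["reason"] == "n_hom=4<5"

    def test_hla_mask(self):
        geno = _geno_with_hom_counts([10], chrom="6", start_pos=30_000_000)
        kept, log = filter_variants(geno)
        assert kept == []
        assert "excluded_region" in log[0]["reason"]

    def test_hla_boundaries_half_open(self):
        geno = _geno_with_hom_counts([10, 10, 10], chrom="6", start_pos=1000)
        geno.variants[0].pos = 24_999_999
        geno.variants[1].pos = 25_000_000
        geno.variants[2].pos = 35_000_000
        kept, _ = filter_variants(geno)
        assert kept == [0, 2]

    def test_empty(self):
        geno = GenotypeMatrix(variants=[], haplotypes=np.zeros((3, 0, 2), dtype=np.int8),
                              phased=np.ones(3, dtype=bool), sample_ids=["a", "b", "c"])
        kept, log = filter_variants(geno)
        assert kept == [] and log == []


class TestFitAssociation:
    def test_constant_x_degenerate(self):
        y = np.array([0.0, 1.0] * 10)
        with pytest.raises(DegenerateInput, match="genotype"):
            fit_association(y, np.ones(20))

    def test_constant_y_degenerate(self):
        with pytest.raises(DegenerateInput, match="outcome"):
            fit_association(np.ones(20), np.arange(20) % 2)

    def test_2x2_score_equals_chisquare_oracle(self):
        # 40 individuals: exposed 12/20 cases, unexposed 4/20 cases
        y = np.array([1.0] * 12 + [0.0] * 8 + [1.0] * 4 + [0.0] * 16)
        x = np.array([1.0] * 20 + [0.0] * 20)
        res = fit_association(y, x)
        obs = np.array([[12, 8], [4, 16]])
        exp = obs.sum(1)[:, None] * obs.sum(0)[None, :] / obs.sum()
        p_oracle = stats.chi2.sf(((obs - exp) ** 2 / exp).sum(), 1)
        assert res.p == pytest.approx(p_oracle, abs=1e-6)
        assert res.method == "logistic_score"

    def test_null_calibration(self):
        """Under b=0 the score P is uniform; tail rate at 1e-3 within 3 SE."""
        from recwas.power_sim import run_simulation_cell

        scen = InheritanceScenario(5, 0.0, 0.0, baseline_logit=np.log(0.3 / 0.7))
        r = run_simulation_cell(scen, q=0.3, or_hom=1.0, n=10_000, reps=10_000, seed=99)
        for p in (r.p_add, r.p_rec):
            assert stats.kstest(p, "uniform").pvalue > 0.01
            rate = (p < 1e-3).mean()
            assert abs(rate - 1e-3) < 3 * np.sqrt(1e-3 * 0.999 / 10_000)

    def test_missing_dropped_complete_case(self):
        rng = np.random.default_rng(0)
        x = rng.binomial(2, 0.3, 200).astype(float)
        y = rng.binomial(1, 0.4, 200).astype(float)
        x_miss = x.copy()
        x_miss[:50] = np.nan
        res_miss = fit_association(y, x_miss)
        res_sub = fit_association(y[50:], x[50:])
        assert res_miss.p == pytest.approx(res_sub.p, rel=1e-12)
        assert res_miss.n_cases == res_sub.n_cases

    def test_covariate_adjustment_changes_test(self):
        rng = np.random.default_rng(1)
        n = 500
        c = rng.standard_normal(n)
        x = rng.binomial(2, 0.3, n) + (c > 1)  # confounded
        x = np.clip(x, 0, 2).astype(float)
        y = (rng.random(n) < 1 / (1 + np.exp(-(-1 + c)))).astype(float)
        p_raw = fit_association(y, x).p
        p_adj = fit_association(y, x, C=c[:, None]).p
        assert p_raw != pytest.approx(p_adj, rel=1e-3)

    def test_zero_cell_triggers_fisher(self):
        # all 5 homozygotes are cases: the documented non-convergence situation
        y = np.array([1.0] * 5 + [1.0] * 15 + [0.0] * 30)
        x = np.array([1.0] * 5 + [0.0] * 45)  # recessive-coded
        d = np.array([2.0] * 5 + [0.0] * 45)
        res = fit_association(y, x, dosage=d, model="recessive")
        assert res.method == "fisher_exact"
        assert np.isfinite(res.p) and 0 < res.p <= 1
        assert res.or_ci is not None

    def test_firth_finite_under_separation_path(self):
        rng = np.random.default_rng(3)
        x = rng.binomial(2, 0.2, 300).astype(float)
        y = (rng.random(300) < 1 / (1 + np.exp(-(-2 + 1.2 * x)))).astype(float)
        res = fit_association(y, x)
        assert np.isfinite(res.beta) and np.isfinite(res.se)


class TestFisherFallback:
    def test_enumeration_example(self):
        p, _, _ = fisher_fallback(np.array([[3, 7], [12, 2]]))
        assert p == pytest.approx(fisher_enum_oracle(3, 7, 12, 2), rel=1e-10)

    def test_proportional_table(self):
        p, or_est, _ = fisher_fallback(np.array([[5, 5], [5, 5]]))
        assert p == 1.0
        assert or_est == pytest.approx(1.0)

    def test_zero_cell_finite(self):
        p, or_est, (lo, hi) = fisher_fallback(np.array([[6, 0], [10, 40]]))
        assert np.isfinite(p) and 0 < p <= 1
        assert or_est == np.inf and np.isfinite(lo)

    def test_matches_scipy(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            t = rng.integers(0, 25, (2, 2))
            p, _, _ = fisher_fallback(t, ci=False)
            assert p == pytest.approx(stats.fisher_exact(t)[1], rel=1e-10)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            fisher_fallback(np.array([[-1, 2], [3, 4]]))

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            fisher_fallback(np.array([[1.5, 2.0], [3.0, 4.0]]))

    @given(st.lists(st.integers(0, 15), min_size=4, max_size=4))
    @settings(max_examples=100, deadline=None)
    def test_property_equals_enumeration(self, cells):
        a, b, c, d = cells
        if (a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0):
            return
        p, _, _ = fisher_fallback(np.array([[a, b], [c, d]]), ci=False)
        assert p == pytest.approx(fisher_enum_oracle(a, b, c, d), rel=1e-9)


class TestRunPhewas:
    def _setup(self, n=400, seed=21):
        spec = CohortSpec(n_individuals=n,
                          variants=[VariantSpec(maf=0.3, pos=1_000_000),
                                    VariantSpec(maf=0.25, pos=2_000_000),
                                    VariantSpec(maf=0.35, pos=3_000_000)],
                          seed=seed)
        geno = simulate_genotypes(spec)
        rng = np.random.default_rng(seed)
        ph = simulate_phenotype(geno, InheritanceScenario(3, 0.25, 0.5), rng=rng)
        ph.endpoints["D2"] = (np.random.default_rng(seed + 1).random(n) < 0.3).astype(int)
        return geno, ph

    def test_result_count(self):
        geno, ph = self._setup()
        results = run_phewas(geno, ph, models=["additive", "recessive"])
        # 3 variants x 2 endpoints x 2 models (all hom counts >= 5 at these MAFs)
        assert len(results) == 12

    def test_self_consistency_with_direct_call(self):
        geno, ph = self._setup()
        results = run_phewas(geno, ph, models=["additive"])
        r = next(x for x in results if x.variant_key == geno.variants[1].key
                 and x.phenotype == "D1")
        g = geno.dosage(1).astype(float)
        direct = fit_association(ph.endpoint("D1"), code_genotype(g, "additive"),
                                 C=ph.covariates.to_numpy(dtype=float), dosage=g,
                                 variant_key=r.variant_key, phenotype="D1",
                                 model="additive")
        assert r.p == direct.p and r.beta == direct.beta

    def test_zero_case_endpoint_skipped(self):
        geno, ph = self._setup()
        ph.endpoints["D3"] = 0
        results = run_phewas(geno, ph, models=["additive"])
        assert not any(r.phenotype == "D3" for r in results)

    def test_id_mismatch(self):
        geno, ph = self._setup()
        geno.sample_ids[0] = "STRANGER"
        with pytest.raises(ValueError, match="mismatch"):
            run_phewas(geno, ph)

    def test_recessive_filter_applied(self):
        geno, ph = self._setup()
        cfg = PipelineConfig(min_hom=10_000)  # nothing is eligible
        results = run_phewas(geno, ph, models=["recessive"], config=cfg)
        assert results == []
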