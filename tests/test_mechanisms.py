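"""Mechanism probes: HWE exact test, F_ST, haplotype and ancestry tests,
interaction regressions, parental-ancestry check."""

import math
from fractions import Fraction

import numpy as np
import pytest
from scipy import stats

from vqtlscan import (
    ancestry_probes,
    categorical_interaction_test,
    fst_hudson,
    haplotype_variance_tests,
    hwe_exact,
    interaction_test,
    inverse_normal_transform,
    parental_ancestry_check,
)


def hwe_enumeration(n_hom_major, n_het, n_hom_minor):
    """Independent oracle: exact rational enumeration of the conditional
    heterozygote-count distribution."""
    n = n_hom_major + n_het + n_hom_minor
    rare = 2 * min(n_hom_major, n_hom_minor) + n_het
    if rare == 0:
        return 1.0
    total_alleles = 2 * n
    fact = math.factorial

    def prob(h):
        n_aa = (rare - h) // 2
        n_AA = n - h - n_aa
        return (
            Fraction(fact(n), fact(n_AA) * fact(h) * fact(n_aa))
            * Fraction(2) ** h
            * Fraction(fact(rare) * fact(total_alleles - rare),
                       fact(total_alleles))
        )

    hs = range(rare % 2, min(rare, total_alleles - rare) + 1, 2)
    probs = {h: prob(h) for h in hs}
    p_obs = probs[n_het]
    return float(sum(p for p in probs.values() if p <= p_obs))


class TestHweExact:
    def test_perfect_proportions_are_modal(self):
        assert hwe_exact(25, 50, 25) == 1.0

    def test_monomorphic_is_certain(self):
        assert hwe_exact(100, 0, 0) == 1.0
        assert hwe_exact(0, 0, 7) == 1.0

    def test_matches_exact_enumeration(self):
        cases = [(57, 13, 2), (10, 1, 10), (0, 20, 0), (3, 4, 5),
                 (40, 20, 40), (68, 28, 4), (1, 1, 1)]
        for counts in cases:
            assert hwe_exact(*counts) == pytest.approx(
                hwe_enumeration(*counts), abs=1e-12)

    def test_symmetric_in_homozygote_labels(self):
        assert hwe_exact(57, 13, 2) == hwe_exact(2, 13, 57)

    def test_rejects_bad_counts(self):
        with pytest.raises(ValueError):
            hwe_exact(-1, 0, 1)
        with pytest.raises(ValueError):
            hwe_exact(0, 0, 0)


class TestFstHudson:
    @pytest.mark.parametrize("p1, p2, expected", [
        (0.313, 0.161, 0.0619),
        (0.225, 0.585, 0.2370),
    ])
    def test_published_frequency_pairs(self, p1, p2, expected):
        assert fst_hudson(p1, p2) == pytest.approx(expected, abs=5e-4)

    def test_equal_frequencies_give_zero(self):
        assert fst_hudson(0.3, 0.3) == pytest.approx(0.0, abs=1e-12)

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p1, p2 = rng.uniform(0.01, 0.99, 2)
            n1, n2 = rng.integers(10, 500, 2)
            assert fst_hudson(p1, p2, n1, n2) == pytest.approx(
                fst_hudson(p2, p1, n2, n1), abs=1e-12)
            assert fst_hudson(p1, p2) <= 1.0

    def test_finite_sample_correction_shrinks_estimate(self):
        assert fst_hudson(0.3, 0.6, 50, 50) < fst_hudson(0.3, 0.6)

    def test_undefined_when_both_fixed_same_allele(self):
        assert np.isnan(fst_hudson(0.0, 0.0))

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            fst_hudson(1.2, 0.5)


def _two_hap_locus(n, rng, k=4):
    """Locus with exactly two segregating haplotypes in perfect LD."""
    carrier = rng.binomial(1, 0.3, size=(n, 2))
    haps = np.repeat(carrier[:, :, None], k, axis=2).astype(np.int8)
    return haps, carrier.sum(axis=1)


class TestHaplotypeTests:
    def test_two_haplotypes_make_tests_identical(self):
        rng = np.random.default_rng(1)
        n = 600
        haps, dose = _two_hap_locus(n, rng)
        resid = rng.normal(size=n) * (1.0 + 0.3 * dose)
        res = haplotype_variance_tests(haps, resid)
        assert res.two_group.statistic == pytest.approx(
            res.all_group.statistic, abs=1e-10)
        assert res.difference_p == 1.0

    def test_perfect_ld_equals_single_marker_test(self):
        from vqtlscan import fligner_killeen
        rng = np.random.default_rng(2)
        n = 600
        haps, dose = _two_hap_locus(n, rng)
        resid = rng.normal(size=n) * (1.0 + 0.3 * dose)
        res = haplotype_variance_tests(haps, resid)
        single = fligner_killeen(resid, dose)
        assert res.two_group.statistic == pytest.approx(single.statistic,
                                                        abs=1e-10)

    def test_third_haplotype_with_variance_effect_is_detected(self):
        rng = np.random.default_rng(3)
        hits = 0
        for rep in range(5):
            n = 3000
            haps = np.zeros((n, 2, 3), dtype=np.int8)
            # haplotype pool: 000 (60%), 111 (30%), 110 (10%, the culprit)
            draws = rng.choice(3, size=(n, 2), p=[0.6, 0.3, 0.1])
            haps[draws == 1] = [1, 1, 1]
            haps[draws == 2] = [1, 1, 0]
            n_culprit = (draws == 2).sum(axis=1)
            resid = rng.normal(size=n) * (1.0 + 0.8 * n_culprit)
            res = haplotype_variance_tests(haps, resid, rare_collapse=0.01)
            if res.difference_p < 0.05:
                hits += 1
        assert hits >= 4

    def test_unphased_input_rejected(self):
        with pytest.raises(ValueError, match="phased"):
            haplotype_variance_tests(np.zeros((10, 3)), np.zeros(10))


class TestAncestryProbes:
    def test_signal_fraction_from_published_values(self):
        # r2_adj 0.00128 genome-wide vs 0.0006 within the homozygous stratum
        # implies ~53% of the signal is attributable to admixture
        frac = 1.0 - 0.0006 / 0.00128
        assert frac == pytest.approx(0.53, abs=0.01)

    def test_ancestry_scale_mechanism_detected(self):
        from vqtlscan import CohortConfig, VqtlMechanism, inject_phenotype, simulate_cohort
        hits = 0
        for rep in range(5):
            cohort = simulate_cohort(CohortConfig(
                n_individuals=5000, n_markers=10, admixture_mean=0.8,
                seed=400 + rep))
            cohort = inject_phenotype(
                cohort, [VqtlMechanism("ancestry_scale", 0,
                                       ancestry_sd_ratio=0.7)],
                covariate_effects={"age": 0, "sex": 0, "env": 0},
                seed=500 + rep)
            study_idx = cohort.covariates["study"].str.removeprefix("study").astype(int) - 1
            resid = cohort.phenotype - cohort.study_intercepts[study_idx.to_numpy()]
            res = ancestry_probes(resid, cohort.ancestry_calls[:, 0],
                                  cohort.dosages[:, 0])
            if res.ancestry_fk.p < 5e-4:
                hits += 1
        assert hits >= 4

    def test_no_ancestry_variation_degenerates_gracefully(self):
        rng = np.random.default_rng(4)
        n = 400
        g = rng.binomial(2, 0.4, n)
        resid = rng.normal(size=n)
        res = ancestry_probes(resid, np.zeros(n, dtype=int), g)
        assert not res.ancestry_fk.defined
        assert res.stratified_fk.statistic == pytest.approx(
            res.full_fk.statistic)
        assert res.signal_fraction == pytest.approx(0.0, abs=1e-12)


class TestInteractionTest:
    def test_null_interaction_calibrated(self):
        rng = np.random.default_rng(5)
        rejections = 0
        n_reps = 300
        for _ in range(n_reps):
            n = 300
            g = rng.binomial(2, 0.3, n).astype(float)
            x = rng.normal(size=n)
            y = 0.2 * g + 0.3 * x + rng.normal(size=n)
            res = interaction_test(y, g, x)
            rejections += res.p_interaction < 0.05
        rate = rejections / n_reps
        lo, hi = stats.binom.interval(0.999, n_reps, 0.05)
        assert lo / n_reps <= rate <= hi / n_reps

    def test_recovers_interaction_beta(self):
        rng = np.random.default_rng(6)
        estimates = []
        for _ in range(20):
            n = 3000
            g = rng.binomial(2, 0.3, n).astype(float)
            x = rng.normal(size=n)
            y = 0.1 * g + 0.2 * x + 0.3 * g * x + rng.normal(size=n)
            estimates.append(interaction_test(y, g, x).beta_interaction)
        assert np.mean(estimates) == pytest.approx(0.3, abs=0.03)

    def test_invariant_to_affine_coding_of_partner(self):
        rng = np.random.default_rng(7)
        n = 500
        g = rng.binomial(2, 0.3, n).astype(float)
        x01 = rng.binomial(1, 0.5, n).astype(float)
        y = 0.2 * g + 0.1 * x01 + 0.25 * g * x01 + rng.normal(size=n)
        p1 = interaction_test(y, g, x01).p_interaction
        p2 = interaction_test(y, g, x01 + 1.0).p_interaction
        assert p1 == pytest.approx(p2, rel=1e-9)

    def test_signal_fractions_follow_partial_r2(self):
        rng = np.random.default_rng(8)
        n = 2000
        g = rng.binomial(2, 0.3, n).astype(float)
        x = rng.normal(size=n)
        y = 0.3 * g * x + rng.normal(size=n)
        res = interaction_test(y, g, x, r2adj_g1=0.01, r2adj_x2=0.02)
        assert res.signal_fraction_g1 == pytest.approx(res.partial_r2adj / 0.01)
        assert res.signal_fraction_x2 == pytest.approx(res.partial_r2adj / 0.02)

    def test_rejects_constant_inputs(self):
        with pytest.raises(ValueError):
            interaction_test(np.ones(20), np.ones(20), np.arange(20.0))


class TestCategoricalInteraction:
    def test_single_level_undefined(self):
        rng = np.random.default_rng(9)
        p = categorical_interaction_test(
            rng.normal(size=50), rng.binomial(2, 0.5, 50),
            np.repeat("a", 50))
        assert np.isnan(p)

    def test_equal_slopes_null_calibrated(self):
        rng = np.random.default_rng(10)
        ps = []
        for _ in range(150):
            n = 400
            g = rng.binomial(2, 0.3, n).astype(float)
            lab = np.repeat([f"s{i}" for i in range(8)], n // 8)
            y = 0.2 * g + rng.normal(size=n)
            ps.append(categorical_interaction_test(y, g, lab))
        assert stats.kstest(np.array(ps), "uniform").pvalue > 0.01

    def test_sex_specific_slope_detected(self):
        rng = np.random.default_rng(11)
        hits = 0
        for _ in range(5):
            n = 5000
            g = rng.binomial(2, 0.3, n).astype(float)
            sex = rng.binomial(1, 0.5, n)
            y = 0.1 * g + 0.4 * g * sex + rng.normal(size=n)
            if categorical_interaction_test(y, g, sex.astype(str)) < 0.05:
                hits += 1
        assert hits >= 4


class TestParentalAncestryCheck:
    def test_null_never_false_positives(self):
        """Because both vectors are inverse-normal transformed to the same
        marginal before pairing, the signed-rank differences are close to
        antisymmetric and the probe is conservative: under independence it
        essentially never rejects (it is a guard against gross asymmetric
        confounding, not a calibrated association test)."""
        rng = np.random.default_rng(12)
        calls = rng.integers(0, 3, size=(300, 150))
        ps = []
        for _ in range(100):
            resid = rng.normal(size=300)
            _, p = parental_ancestry_check(resid, calls)
            ps.append(p)
        ps = np.array(ps)
        assert np.all((ps >= 0) & (ps <= 1))
        assert (ps < 0.05).mean() <= 0.05

    def test_transform_moments(self):
        rng = np.random.default_rng(13)
        z = inverse_normal_transform(rng.exponential(size=5000))
        assert abs(z.mean()) < 1e-6
        assert z.std(ddof=1) == pytest.approx(1.0, rel=0.02)

    def test_perfect_monotone_dependence_is_flagged_as_tied(self):
        """An exactly monotone outcome has identical ranks to the ancestry
        proportion, so every transformed difference is zero: the probe flags
        this as undefined (NaN) rather than fabricating a p-value."""
        rng = np.random.default_rng(14)
        calls = rng.integers(0, 3, size=(500, 150))
        prop = (calls == 0).mean(axis=1)
        _, p = parental_ancestry_check(2.0 * prop + 1.0, calls)
        assert np.isnan(p)
        # noisy monotone dependence still yields a defined, valid p
        _, p2 = parental_ancestry_check(
            np.exp(3 * prop) + rng.normal(0, 0.01, 500), calls)
        assert 0.0 <= p2 <= 1.0

    def test_requires_enough_markers(self):
        with pytest.raises(ValueError, match="100"):
            parental_ancestry_check(np.zeros(10), np.zeros((10, 5)))
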