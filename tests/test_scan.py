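"""Variance-QTL scan, variance-explained conversion, loci, replication."""

import numpy as np
import pandas as pd
import pytest

from vqtlscan import (
    CohortConfig,
    Locus,
    VqtlMechanism,
    VqtlScanner,
    define_loci,
    inject_phenotype,
    p_to_r2adj,
    replicate,
    simulate_cohort,
    vqtl_scan,
)
from vqtlscan.scan import SCAN_COLUMNS

import reference_values as ref


class TestVarianceExplainedConversion:
    @pytest.mark.parametrize(
        "p, n, expected",
        [(3.68e-8, ref.N_DISCOVERY, 1.28e-3),
         (0.01431195, ref.N_REPLICATION, 8.33e-4)],
    )
    def test_published_worked_examples(self, p, n, expected):
        out = p_to_r2adj(p, n)
        assert out.r2_adj == pytest.approx(expected, rel=5e-3)

    def test_null_point(self):
        out = p_to_r2adj(1.0, 100)
        assert out.t == 0.0
        assert out.r == 0.0
        assert out.r2_adj == pytest.approx(-1.0 / 98)

    def test_rejects_degenerate_inputs(self):
        with pytest.raises(ValueError):
            p_to_r2adj(0.0, 100)
        with pytest.raises(ValueError):
            p_to_r2adj(0.5, 3)
        with pytest.raises(ValueError):
            p_to_r2adj(1.5, 100)

    def test_monotone_decreasing_in_p(self):
        ps = np.logspace(-10, 0, 40)
        vals = [p_to_r2adj(p, 5000).r2_adj for p in ps]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_round_trips_through_inverse_chain(self):
        from scipy import stats
        n = 6002
        for p in (1e-9, 1e-4, 0.03, 0.7):
            out = p_to_r2adj(p, n)
            # invert: r2_adj -> r2 -> t -> p
            r2 = (out.r2_adj + 1.0 / (n - 2)) / (1.0 + 1.0 / (n - 2))
            t = np.sqrt(r2 * (n - 2) / (1.0 - r2))
            p_back = 2.0 * stats.t.sf(t, n - 2)
            assert p_back == pytest.approx(p, rel=1e-10)

    def test_near_one_p_gives_negative_r2adj(self):
        assert p_to_r2adj(0.99, 6002).r2_adj < 0


def _null_cohort(n=1000, m=400, seed=21):
    cohort = simulate_cohort(CohortConfig(n_individuals=n, n_markers=m,
                                          seed=seed))
    return inject_phenotype(cohort, [], covariate_effects={"age": 0, "sex": 0, "env": 0},
                            noise_sd=1.0, seed=seed + 1)


class TestScan:
    def test_null_scan_p_values_are_uniform(self):
        from scipy import stats
        cohort = _null_cohort()
        study_idx = cohort.covariates["study"].str.removeprefix("study").astype(int) - 1
        resid = cohort.phenotype - cohort.study_intercepts[study_idx.to_numpy()]
        results = vqtl_scan(cohort.to_genotype_set(), resid)
        ps = results["fk_p"].dropna().to_numpy()
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_scan_output_schema_and_counts(self, small_cohort):
        resid = small_cohort.phenotype - small_cohort.phenotype.mean()
        results = vqtl_scan(small_cohort.to_genotype_set(), resid)
        assert list(results.columns) == SCAN_COLUMNS
        counts = results[["n0", "n1", "n2"]].sum(axis=1)
        assert (counts == small_cohort.ids.size).all()
        assert results["fk_df"].isin([1, 2]).all()

    def test_scan_invariant_to_individual_ordering(self, small_cohort):
        gs = small_cohort.to_genotype_set()
        resid = small_cohort.phenotype - small_cohort.phenotype.mean()
        base = vqtl_scan(gs, resid)
        perm = np.random.default_rng(0).permutation(gs.n_individuals)
        shuffled = gs.take_individuals(perm)
        again = vqtl_scan(shuffled, resid[perm])
        pd.testing.assert_frame_equal(base, again)

    def test_injected_vqtl_is_top_hit(self):
        hits = 0
        for rep in range(5):
            cohort = simulate_cohort(CohortConfig(
                n_individuals=4000, n_markers=60, seed=100 + rep))
            cohort = inject_phenotype(
                cohort, [VqtlMechanism("gxe", 30, beta_interaction=0.35)],
                covariate_effects={"age": 0, "sex": 0, "env": 0},
                seed=200 + rep,
            )
            study_idx = cohort.covariates["study"].str.removeprefix("study").astype(int) - 1
            resid = cohort.phenotype - cohort.study_intercepts[study_idx.to_numpy()]
            results = vqtl_scan(cohort.to_genotype_set(), resid)
            if results["fk_p"].idxmin() == 30:
                hits += 1
        assert hits >= 4

    def test_permuted_residuals_are_null(self, small_cohort):
        from scipy import stats
        gs = small_cohort.to_genotype_set().take_sites([0])
        rng = np.random.default_rng(5)
        resid = small_cohort.phenotype
        ps = [
            vqtl_scan(gs, rng.permutation(resid))["fk_p"].iloc[0]
            for _ in range(120)
        ]
        assert stats.kstest(np.array(ps), "uniform").pvalue > 0.01

    def test_scan_requires_aligned_residuals(self, small_cohort):
        with pytest.raises(ValueError, match="align"):
            VqtlScanner().fit(small_cohort.to_genotype_set(), np.ones(3))


class TestLoci:
    def _results(self, chrom, pos, p, dosages=None):
        df = pd.DataFrame({
            "site_id": [f"{c}:{q}:A:G" for c, q in zip(chrom, pos)],
            "chrom": chrom, "pos": pos, "fk_p": p,
        })
        return df

    def test_no_significant_sites_gives_empty_list(self):
        res = self._results(["1"], [100], [0.5])
        assert define_loci(res) == []

    def test_ld_clump_mirrors_tightly_linked_cluster(self):
        # 4 markers in perfect LD within 50 kb + 1 independent far marker
        rng = np.random.default_rng(8)
        g = rng.binomial(2, 0.3, 500).astype(float)
        other = rng.binomial(2, 0.3, 500).astype(float)
        dosages = np.column_stack([g, g, g, g, other])
        res = self._results(
            ["2"] * 4 + ["7"],
            [164_648_055, 164_655_284, 164_668_241, 164_687_940, 76_211_003],
            [3.68e-8, 2.56e-8, 1.73e-8, 1.26e-8, 2.46e-8],
        )
        loci = define_loci(res, dosages=dosages)
        sizes = sorted(lo.n_markers for lo in loci)
        assert sizes == [1, 4]
        lead = next(lo for lo in loci if lo.n_markers == 4)
        assert lead.lead == "2:164687940:A:G"  # smallest p leads

    def test_distant_markers_split_into_two_loci(self):
        res = self._results(["1", "1"], [1_000_000, 11_000_000], [1e-9, 1e-9])
        assert len(define_loci(res)) == 2


class TestReplication:
    @staticmethod
    def _published_loci():
        return [Locus(lead=lead, members=members,
                      chrom=dict((r[0], r[1]) for r in ref.TABLE)[lead])
                for lead, members in ref.LOCI.items()]

    @staticmethod
    def _published_replication():
        return pd.DataFrame({
            "site_id": [r[0] for r in ref.TABLE],
            "fk_p": [r[4] for r in ref.TABLE],
        })

    def test_published_replication_outcome(self):
        report = replicate(self._published_loci(), self._published_replication(),
                           alpha_rep=0.05)
        assert int(report["replicated"].sum()) == 6
        rep_loci = report.loc[report["locus_replicated"], "locus_lead"].unique()
        chroms = {report.loc[report["locus_lead"] == lead, "chrom"].iloc[0]
                  for lead in rep_loci}
        assert chroms == {"2", "6", "7"}
        assert len(rep_loci) == 3

    def test_alpha_extremes(self):
        loci = self._published_loci()
        rep = self._published_replication()
        assert int(replicate(loci, rep, alpha_rep=0.0)["replicated"].sum()) == 0
        assert int(replicate(loci, rep, alpha_rep=1.0)["replicated"].sum()) == 15

    def test_unmatched_markers_logged_not_fatal(self):
        loci = [Locus(lead="chrX:1:A:G", members=["chrX:1:A:G"], chrom="X")]
        report = replicate(loci, self._published_replication())
        assert not report["matched"].iloc[0]
        assert not report["replicated"].iloc[0]
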