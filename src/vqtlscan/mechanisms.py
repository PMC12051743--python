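"""Probes for candidate explanations of a variance-QTL.

A marker at which phenotypic variance differs by genotype can arise from
several distinct mechanisms: natural selection (visible as departure from
Hardy-Weinberg equilibrium), multiple causal haplotypes, locus-specific
ancestry in an admixed cohort, an unmodelled gene x gene interaction, or an
unmodelled gene x covariate interaction.  Each probe here tests one of these
explanations on the residual outcome and, where applicable, quantifies the
fraction of the variance-explained signal attributable to the mechanism via
ratios of adjusted variance-explained (``r2_adj``) estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .effectsize import p_to_r2adj, r2adj_from_t
from .fk import FkResult, drop_sparse_classes, fligner_killeen

__all__ = [
    "hwe_exact",
    "fst_hudson",
    "haplotype_variance_tests",
    "ancestry_probes",
    "interaction_test",
    "categorical_interaction_test",
    "parental_ancestry_check",
    "inverse_normal_transform",
    "HaplotypeTestResult",
    "AncestryProbeResult",
    "InteractionResult",
]


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def _hwe_distribution(n: int, rare: int) -> tuple[np.ndarray, np.ndarray]:
    """Conditional distribution of the heterozygote count given ``n``
    genotypes and ``rare`` minor alleles, by the stable two-step recurrence

        Pr(h + 2) / Pr(h) = 4 n_AA(h) n_aa(h) / ((h + 2)(h + 1)).

    Returns the feasible heterozygote counts (parity of ``rare``) and their
    probabilities.
    """
    h_min = rare % 2
    h_max = min(rare, 2 * n - rare)
    hs = np.arange(h_min, h_max + 1, 2)
    probs = np.empty(hs.size)
    # anchor at the modal heterozygote count to keep the recurrence in range
    h_mode = int(round(rare * (2 * n - rare) / (2.0 * n)))
    h_mode += (h_mode - h_min) % 2
    h_mode = min(max(h_mode, h_min), h_max)
    i_mode = (h_mode - h_min) // 2
    probs[i_mode] = 1.0
    for i in range(i_mode, hs.size - 1):        # upward in h
        h = hs[i]
        n_aa = (rare - h) // 2
        n_AA = n - h - n_aa
        probs[i + 1] = probs[i] * (4.0 * n_AA * n_aa) / ((h + 2.0) * (h + 1.0))
    for i in range(i_mode, 0, -1):              # downward in h
        h = hs[i]
        n_aa = (rare - h) // 2
        n_AA = n - h - n_aa
        probs[i - 1] = probs[i] * (h * (h - 1.0)) / (4.0 * (n_AA + 1.0) * (n_aa + 1.0))
    probs /= probs.sum()
    return hs, probs


def hwe_exact(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Exact conditional test of Hardy-Weinberg equilibrium.

    Conditions on the allele counts and sums, over all heterozygote counts
    ``h`` compatible with them, the probabilities of configurations no more
    probable than the observed one:

        p = sum_{h : Pr(h) <= Pr(h_obs)} Pr(h)

    with Pr(h) the hypergeometric-type probability of ``h`` heterozygotes
    given the minor-allele count.  Probabilities are built by the stable
    two-step recurrence

        Pr(h + 2) / Pr(h) = 4 n_AA(h) n_aa(h) / ((h + 2)(h + 1))

    starting from the smallest feasible ``h`` (0 or 1 by parity).

    Parameters are the three genotype counts (major homozygote,
    heterozygote, minor homozygote); the labelling of which homozygote is
    "major" does not affect the result.
    """
    counts = (int(n_hom_major), int(n_het), int(n_hom_minor))
    if any(c < 0 for c in counts):
        raise ValueError("genotype counts must be non-negative")
    n = sum(counts)
    if n < 1:
        raise ValueError("total genotype count must be >= 1")
    n_hom_major, n_het, n_hom_minor = counts

    # minor allele count (conditioning statistic); symmetric in the two alleles
    rare = 2 * min(n_hom_major, n_hom_minor) + n_het
    if rare == 0:
        return 1.0  # monomorphic: single possible configuration

    hs, probs = _hwe_distribution(n, rare)
    p_obs = probs[(hs == n_het).nonzero()[0][0]]
    # tolerance guards against float ties being split by rounding error
    return float(min(1.0, probs[probs <= p_obs * (1.0 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# Hudson F_ST
# ---------------------------------------------------------------------------

def fst_hudson(p1: float, p2: float, n1: float = np.inf, n2: float = np.inf) -> float:
    """Hudson's estimator of allele-frequency differentiation between two
    populations.

    numerator   = (p1 - p2)^2 - p1 (1 - p1)/(n1 - 1) - p2 (1 - p2)/(n2 - 1)
    denominator = p1 (1 - p2) + p2 (1 - p1)

    The sampling-correction terms vanish for infinite sample sizes (i.e. when
    the inputs are treated as population frequencies).  When both populations
    are fixed for the same allele the denominator is zero and NaN is returned
    (flagged-undefined rather than raised).
    """
    for p in (p1, p2):
        if not 0.0 <= p <= 1.0:
            raise ValueError("allele frequencies must lie in [0, 1]")
    c1 = 0.0 if np.isinf(n1) else p1 * (1.0 - p1) / (n1 - 1.0)
    c2 = 0.0 if np.isinf(n2) else p2 * (1.0 - p2) / (n2 - 1.0)
    num = (p1 - p2) ** 2 - c1 - c2
    den = p1 * (1.0 - p2) + p2 * (1.0 - p1)
    if den == 0.0:
        return float("nan")
    return num / den


# ---------------------------------------------------------------------------
# haplotype tests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HaplotypeTestResult:
    two_group: FkResult
    all_group: FkResult
    difference_p: float
    haplotype_freqs: dict


def haplotype_variance_tests(
    haplotypes: np.ndarray,
    residuals: np.ndarray,
    rare_collapse: float = 0.01,
    min_class_count: int = 2,
) -> HaplotypeTestResult:
    """Variance-homogeneity tests on haplotypes at a multi-marker locus.

    Distinguishes a single causal haplotype from multiple causal haplotypes:

    * two-group test: individuals grouped by their count (0/1/2) of the
      second-most-frequent haplotype, mirroring a biallelic genotype test;
    * all-group test: individuals grouped by unordered diplotype, with
      haplotypes rarer than ``rare_collapse`` pooled into one class;
    * difference test: the extra heterogeneity captured by the finer grouping,
      evaluated as an upper-tail chi-square of ``stat_all - stat_two`` on
      ``df_all - df_two`` degrees of freedom.

    Parameters
    ----------
    haplotypes : int array of shape (n_individuals, 2, n_markers)
        Phased alleles (0/1) at the locus markers.
    residuals : float array of shape (n_individuals,)
    """
    haplotypes = np.asarray(haplotypes)
    if haplotypes.ndim != 3 or haplotypes.shape[1] != 2:
        raise ValueError("haplotypes must be phased, shape (n, 2, n_markers)")
    residuals = np.asarray(residuals, dtype=float)
    n = residuals.size

    flat = haplotypes.reshape(2 * n, -1)
    labels = np.array(["".join(map(str, row)) for row in flat])
    uniq, counts = np.unique(labels, return_counts=True)
    order = np.argsort(-counts, kind="stable")
    uniq, counts = uniq[order], counts[order]
    freqs = {u: c / (2.0 * n) for u, c in zip(uniq, counts)}

    lab = labels.reshape(n, 2)
    if uniq.size < 2:
        undef = fligner_killeen(residuals, np.zeros(n))
        return HaplotypeTestResult(undef, undef, np.nan, freqs)

    second = uniq[1]
    dose_second = (lab == second).sum(axis=1)
    v2, g2, _ = drop_sparse_classes(residuals, dose_second, min_class_count)
    two_group = fligner_killeen(v2, g2)

    collapsed = np.where(
        np.isin(lab, [u for u in uniq if freqs[u] >= rare_collapse]), lab, "rare"
    )
    diplo = np.array(["/".join(sorted(pair)) for pair in collapsed])
    va, ga, _ = drop_sparse_classes(residuals, diplo, min_class_count)
    all_group = fligner_killeen(va, ga)

    if not (two_group.defined and all_group.defined):
        diff_p = np.nan
    elif all_group.df <= two_group.df:
        diff_p = 1.0
    else:
        delta = max(all_group.statistic - two_group.statistic, 0.0)
        diff_p = float(stats.chi2.sf(delta, all_group.df - two_group.df))
    return HaplotypeTestResult(two_group, all_group, diff_p, freqs)


# ---------------------------------------------------------------------------
# locus-specific ancestry probes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AncestryProbeResult:
    ancestry_fk: FkResult
    full_fk: FkResult
    stratified_fk: FkResult
    r2adj_full: float
    r2adj_stratified: float
    signal_fraction_raw: float
    signal_fraction: float
    n_stratum: int


def ancestry_probes(
    residuals: np.ndarray,
    ancestry_calls: np.ndarray,
    genotypes: np.ndarray,
    min_class_count: int = 2,
) -> AncestryProbeResult:
    """Test whether admixture explains a vQTL at one marker.

    Three measurements:

    (a) variance of the residual outcome across locus-specific ancestry
        strata (0/1/2 chromosomes from the non-reference background B);
    (b) the genotype test repeated inside the stratum homozygous for
        background A, which removes any ancestry-driven component;
    (c) ``signal_fraction = 1 - r2_adj(stratified) / r2_adj(full)``,
        reported raw and clipped to [0, 1].
    """
    residuals = np.asarray(residuals, dtype=float)
    ancestry_calls = np.asarray(ancestry_calls)
    genotypes = np.asarray(genotypes)

    va, ga, _ = drop_sparse_classes(residuals, ancestry_calls, min_class_count)
    ancestry_fk = fligner_killeen(va, ga)

    vf, gf, _ = drop_sparse_classes(residuals, genotypes, min_class_count)
    full_fk = fligner_killeen(vf, gf)

    stratum = ancestry_calls == 0
    vs, gs, _ = drop_sparse_classes(
        residuals[stratum], genotypes[stratum], min_class_count
    )
    stratified_fk = fligner_killeen(vs, gs)

    def _r2(fk: FkResult, n: int) -> float:
        if not fk.defined or n <= 3:
            return np.nan
        return p_to_r2adj(max(fk.p, np.finfo(float).tiny), n).r2_adj

    r2_full = _r2(full_fk, len(vf))
    if not stratified_fk.defined and np.unique(ancestry_calls).size == 1:
        # no ancestry variation: stratified test degenerates to the full test
        stratified_fk = full_fk
        r2_strat = r2_full
    else:
        r2_strat = _r2(stratified_fk, len(vs))
    raw = 1.0 - r2_strat / r2_full if (np.isfinite(r2_full) and r2_full != 0) else np.nan
    clipped = float(np.clip(raw, 0.0, 1.0)) if np.isfinite(raw) else np.nan
    return AncestryProbeResult(
        ancestry_fk, full_fk, stratified_fk, r2_full, r2_strat, raw, clipped,
        int(stratum.sum()),
    )


# ---------------------------------------------------------------------------
# interaction probes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InteractionResult:
    beta_main: float
    p_main: float
    beta_partner: float
    p_partner: float
    beta_interaction: float
    se_interaction: float
    p_interaction: float
    partial_r2adj: float
    signal_fraction_g1: float
    signal_fraction_x2: float
    n: int


def interaction_test(
    residuals: np.ndarray,
    g1: np.ndarray,
    x2: np.ndarray,
    r2adj_g1: float = np.nan,
    r2adj_x2: float = np.nan,
) -> InteractionResult:
    """Gene x gene or gene x covariate interaction regression.

    Fits ``y ~ g1 + x2 + g1*x2`` by OLS and tests the product term.  The
    partial variance explained by the interaction is derived from its
    t-statistic on the residual df; dividing by a vQTL's own ``r2_adj``
    (``r2adj_g1`` / ``r2adj_x2``, when supplied) gives the fraction of each
    side's signal attributable to the interaction.
    """
    y = np.asarray(residuals, dtype=float)
    g1 = np.asarray(g1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    ok = np.isfinite(y) & np.isfinite(g1) & np.isfinite(x2)
    y, g1, x2 = y[ok], g1[ok], x2[ok]
    n = y.size
    if n < 10:
        raise ValueError("need at least 10 complete cases")
    if np.ptp(g1) == 0 or np.ptp(x2) == 0:
        raise ValueError("g1 and x2 must each be non-constant")

    import statsmodels.api as sm

    X = sm.add_constant(np.column_stack([g1, x2, g1 * x2]))
    fit = sm.OLS(y, X).fit()
    t_int = fit.tvalues[3]
    df_resid = int(fit.df_resid)
    partial = r2adj_from_t(t_int, df_resid).r2_adj
    return InteractionResult(
        beta_main=float(fit.params[1]),
        p_main=float(fit.pvalues[1]),
        beta_partner=float(fit.params[2]),
        p_partner=float(fit.pvalues[2]),
        beta_interaction=float(fit.params[3]),
        se_interaction=float(fit.bse[3]),
        p_interaction=float(fit.pvalues[3]),
        partial_r2adj=float(partial),
        signal_fraction_g1=float(partial / r2adj_g1) if np.isfinite(r2adj_g1) else np.nan,
        signal_fraction_x2=float(partial / r2adj_x2) if np.isfinite(r2adj_x2) else np.nan,
        n=n,
    )


def categorical_interaction_test(
    residuals: np.ndarray,
    g: np.ndarray,
    labels: np.ndarray,
) -> float:
    """F-test for genotype-slope heterogeneity across categorical strata
    (sex, study, genotyping array).

    Compares ``y ~ g + labels`` against ``y ~ g + labels + g:labels`` with
    dummy-coded labels.  Levels with fewer than 2 observations are dropped
    with a warning; with a single usable level the test is undefined and NaN
    is returned.
    """
    y = np.asarray(residuals, dtype=float)
    g = np.asarray(g, dtype=float)
    labels = np.asarray(labels)
    ok = np.isfinite(y) & np.isfinite(g)
    y, g, labels = y[ok], g[ok], labels[ok]

    uniq, counts = np.unique(labels, return_counts=True)
    thin = uniq[counts < 2]
    if thin.size:
        warnings.warn(f"dropping {thin.size} stratum level(s) with < 2 observations")
        keep = ~np.isin(labels, thin)
        y, g, labels = y[keep], g[keep], labels[keep]
        uniq = np.unique(labels)
    if uniq.size < 2:
        return float("nan")

    import statsmodels.api as sm

    dummies = (labels[:, None] == uniq[None, 1:]).astype(float)
    X0 = sm.add_constant(np.column_stack([g, dummies]))
    X1 = np.column_stack([X0, g[:, None] * dummies])
    fit0 = sm.OLS(y, X0).fit()
    fit1 = sm.OLS(y, X1).fit()
    f, p, _ = fit1.compare_f_test(fit0)
    return float(p)


# ---------------------------------------------------------------------------
# parental-ancestry (non-additive stratification) check
# ---------------------------------------------------------------------------

def inverse_normal_transform(x: np.ndarray, offset: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse-normal transform with Blom's offset.

    Ties receive average ranks; transformed values are
    ``Phi^{-1}((rank - c) / (n - 2c + 1))`` with ``c = 3/8``.
    """
    x = np.asarray(x, dtype=float)
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - offset) / (x.size - 2.0 * offset + 1.0))


def parental_ancestry_check(
    residuals: np.ndarray,
    ancestry_calls: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Probe for confounding by variation in parental ancestry.

    Controlling the global ancestry proportion (PC1) removes stratification
    from loci acting additively; non-additively acting loci additionally
    require the genome-wide proportion homozygous for the major background.
    This check compares that proportion with the residual outcome: both
    vectors are rank-inverse-normal transformed and a Wilcoxon signed-rank
    test is applied to the paired differences.  A non-significant p indicates
    no residual confounding of this form.

    Note that because both vectors are transformed to the same marginal
    before pairing, the paired differences are nearly symmetric even under
    monotone dependence: the probe is deliberately conservative and only
    fires on gross asymmetric discrepancies between the two rank structures.
    An exactly monotone relationship makes every difference zero, which is
    flagged as undefined (NaN).

    Parameters
    ----------
    residuals : (n,) float array
    ancestry_calls : (n, m) int array
        Per-individual, per-marker count of chromosomes from background B;
        0 means homozygous for background A.  Needs m >= 100 markers for a
        stable proportion.

    Returns
    -------
    (proportions, p) : per-individual proportion of the genome homozygous for
        background A, and the Wilcoxon signed-rank p (NaN if all paired
        differences are ties).
    """
    residuals = np.asarray(residuals, dtype=float)
    calls = np.asarray(ancestry_calls)
    if calls.ndim != 2 or calls.shape[1] < 100:
        raise ValueError("ancestry calls must cover >= 100 markers")
    prop_hom_a = (calls == 0).mean(axis=1)

    z_res = inverse_normal_transform(residuals)
    z_prop = inverse_normal_transform(prop_hom_a)
    diffs = z_res - z_prop
    if np.allclose(diffs, 0.0):
        return prop_hom_a, float("nan")
    _, p = stats.wilcoxon(z_res, z_prop)
    return prop_hom_a, float(p)
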