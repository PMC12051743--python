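"""Genetic relatedness, principal components, and mixed-model
residualization of the trait.

Before scanning for variance effects, the trait is cleaned of mean structure:
fixed covariates (age, sex, study/array, ancestry PCs) and a polygenic random
effect whose covariance is the genetic relatedness matrix (GRM).  Scanning
the residuals instead of the raw trait prevents mean-model misspecification
and family structure from masquerading as variance heterogeneity.

The model is the standard single-random-effect animal model

    y = X beta + g + e,   g ~ N(0, sigma2_g G),   e ~ N(0, sigma2_e I)

fitted by REML.  Because G enters through a single variance ratio, one
eigendecomposition ``G = U D U'`` reduces every REML evaluation to O(n p^2):
in the rotated basis the covariance is diagonal, and the profile restricted
likelihood is optimized over ``delta = sigma2_g / sigma2_e`` by a log-spaced
grid followed by Brent refinement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from sklearn.base import BaseEstimator

from .genotype_io import GenotypeSet

__all__ = ["GRM", "LmmFit", "LinearMixedModel", "compute_grm", "top_pcs", "fit_lmm"]


@dataclass
class GRM:
    """Genetic relatedness matrix over individuals.

    ``matrix[i, j] = (1/M_ij) sum_m (x_im - 2 p_m)(x_jm - 2 p_m) /
    (2 p_m (1 - p_m))`` with ``p_m`` the sample alt-allele frequency and
    ``M_ij`` the number of markers non-missing in both individuals.  Under
    Hardy-Weinberg equilibrium the diagonal averages 1 for unrelated
    individuals.
    """

    matrix: np.ndarray
    n_markers: int

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("GRM must be square")


def compute_grm(gs: GenotypeSet, min_maf: float = 0.01) -> GRM:
    """Estimate the GRM from standardized dosages.

    Markers with MAF below ``min_maf`` are excluded (near-monomorphic sites
    destabilize the 1/(2p(1-p)) standardization and the leading PCs).
    Missing genotypes contribute zero to the sum and are excluded from the
    per-pair marker count.
    """
    p = gs.alt_freq()
    with np.errstate(invalid="ignore"):
        poly = (np.minimum(p, 1 - p) >= min_maf) & (p > 0) & (p < 1)
    if poly.sum() < 2:
        raise ValueError("need at least 2 polymorphic sites for a GRM")
    X = gs.dosages[:, poly]
    p = p[poly]

    Z = (X - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    obs = np.isfinite(Z)
    Z = np.where(obs, Z, 0.0)
    pair_m = obs.astype(float) @ obs.astype(float).T
    with np.errstate(divide="ignore", invalid="ignore"):
        G = (Z @ Z.T) / pair_m
    G[pair_m == 0] = 0.0
    return GRM((G + G.T) / 2.0, int(poly.sum()))


def top_pcs(grm: GRM, k: int) -> np.ndarray:
    """Unit-norm eigenvectors of the GRM for its k largest eigenvalues."""
    if not np.all(np.isfinite(grm.matrix)):
        raise ValueError("GRM contains non-finite entries")
    n = grm.matrix.shape[0]
    if not 0 < k < n:
        raise ValueError("k must satisfy 0 < k < n")
    vals, vecs = np.linalg.eigh(grm.matrix)
    order = np.argsort(vals)[::-1][:k]
    pcs = vecs[:, order]
    # sign convention: largest-magnitude loading positive, for reproducibility
    for j in range(k):
        i = np.argmax(np.abs(pcs[:, j]))
        if pcs[i, j] < 0:
            pcs[:, j] = -pcs[:, j]
    return pcs


@dataclass
class LmmFit:
    """REML fit summary: fixed effects, variance components, residuals."""

    beta: np.ndarray
    sigma2_g: float
    sigma2_e: float
    loglik: float
    residuals: np.ndarray
    heritability: float


class LinearMixedModel(BaseEstimator):
    """REML linear mixed model with one GRM-structured random effect.

    Parameters
    ----------
    residual_type : {'conditional', 'marginal'}
        'conditional' residuals subtract the BLUP of the polygenic effect as
        well as the fixed effects (``y - X beta - g_hat``), making
        observations approximately exchangeable within genotype groups as the
        downstream rank test assumes; 'marginal' subtracts fixed effects
        only.
    n_grid : int
        Points of the log-spaced grid over the variance ratio searched before
        Brent refinement.
    tol : float
        Brent tolerance on log10(delta).

    Attributes (after fit)
    ----------------------
    beta_ : fixed-effect estimates (intercept prepended when add_intercept)
    sigma2_g_, sigma2_e_ : variance components (non-negative)
    heritability_ : sigma2_g_ / (sigma2_g_ + sigma2_e_)
    loglik_ : restricted log-likelihood at the optimum (up to a constant)
    residuals_ : residual vector per `residual_type`
    blup_ : best linear unbiased predictor of the random effect
    """

    def __init__(self, residual_type: str = "conditional", n_grid: int = 41,
                 tol: float = 1e-8, add_intercept: bool = True):
        self.residual_type = residual_type
        self.n_grid = n_grid
        self.tol = tol
        self.add_intercept = add_intercept

    # restricted log-likelihood, up to an additive constant, at arbitrary
    # non-negative variance components; reused by tests of optimality
    def reml_loglik(self, sigma2_g: float, sigma2_e: float) -> float:
        d, yt, Xt = self._eig_d, self._yt, self._Xt
        n, p = Xt.shape
        v = sigma2_g * d + sigma2_e
        if np.any(v <= 0):
            return -np.inf
        w = 1.0 / v
        XtWX = Xt.T @ (w[:, None] * Xt)
        XtWy = Xt.T @ (w * yt)
        beta = np.linalg.solve(XtWX, XtWy)
        r = yt - Xt @ beta
        quad = float(r @ (w * r))
        sign, logdet = np.linalg.slogdet(XtWX)
        return -0.5 * (np.sum(np.log(v)) + logdet + quad)

    def fit(self, X, y, grm: GRM):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y, dtype=float)
        n = y.size
        if self.add_intercept:
            X = np.column_stack([np.ones(n), X])
        p = X.shape[1]
        if n < p + 2:
            raise ValueError("need at least n_fixed_effects + 2 complete cases")
        if self.residual_type not in ("conditional", "marginal"):
            raise ValueError("residual_type must be 'conditional' or 'marginal'")

        d, U = np.linalg.eigh(grm.matrix)
        if d.min() < -1e-8 * max(1.0, d.max()):
            warnings.warn("GRM is not PSD; clipping negative eigenvalues at 0")
        d = np.clip(d, 0.0, None)
        self._eig_d, self._eig_U = d, U
        self._yt, self._Xt = U.T @ y, U.T @ X

        # profile REML over delta = sigma2_g / sigma2_e
        def neg_profile(log10_delta: float) -> float:
            delta = 10.0 ** log10_delta
            return -self._profile_loglik(delta)[0]

        grid = np.linspace(-6.0, 6.0, self.n_grid)
        vals = np.array([neg_profile(g) for g in grid])
        i = int(np.argmin(vals))
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, grid.size - 1)]
        best = optimize.minimize_scalar(
            neg_profile, bounds=(lo, hi), method="bounded",
            options={"xatol": self.tol},
        )
        delta = 10.0 ** best.x
        ll_delta, s2e, beta = self._profile_loglik(delta)
        # boundary: compare against the no-genetic-variance model
        ll0, s2e0, beta0 = self._profile_loglik(0.0)
        if ll0 >= ll_delta:
            delta, s2e, beta, ll = 0.0, s2e0, beta0, ll0
        else:
            ll = ll_delta

        self.beta_ = beta
        self.sigma2_e_ = s2e
        self.sigma2_g_ = delta * s2e
        self.heritability_ = (
            self.sigma2_g_ / (self.sigma2_g_ + self.sigma2_e_)
            if self.sigma2_g_ + self.sigma2_e_ > 0 else 0.0
        )
        self.loglik_ = ll

        w = 1.0 / (delta * d + 1.0)
        r_rot = self._yt - self._Xt @ beta
        marginal = U @ r_rot
        conditional = U @ (w * r_rot)
        self.blup_ = marginal - conditional
        self.residuals_ = (
            conditional if self.residual_type == "conditional" else marginal
        )
        self._X_fit = X
        return self

    def _profile_loglik(self, delta: float) -> tuple[float, float, np.ndarray]:
        """Profile restricted loglik at a variance ratio, with the GLS beta
        and the REML estimate of sigma2_e profiled out."""
        d, yt, Xt = self._eig_d, self._yt, self._Xt
        n, p = Xt.shape
        v = delta * d + 1.0
        w = 1.0 / v
        XtWX = Xt.T @ (w[:, None] * Xt)
        XtWy = Xt.T @ (w * yt)
        beta = np.linalg.solve(XtWX, XtWy)
        r = yt - Xt @ beta
        quad = float(r @ (w * r))
        s2e = quad / (n - p)
        sign, logdet = np.linalg.slogdet(XtWX)
        ll = -0.5 * ((n - p) * np.log(s2e) + np.sum(np.log(v)) + logdet + (n - p))
        return ll, s2e, beta

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if self.add_intercept:
            X = np.column_stack([np.ones(X.shape[0]), X])
        return X @ self.beta_


def fit_lmm(trait, covariates, grm: GRM,
            residual_type: str = "conditional") -> LmmFit:
    """Functional wrapper: fit the mixed model and return a summary.

    ``covariates`` is an (n, p) design without intercept (one is added);
    rows with any non-finite entry in trait or covariates are dropped, and
    the GRM is subset to the complete cases.
    """
    y = np.asarray(trait, dtype=float)
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    ok = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    if not ok.all():
        y, X = y[ok], X[ok]
        grm = GRM(grm.matrix[np.ix_(ok, ok)], grm.n_markers)
    model = LinearMixedModel(residual_type=residual_type).fit(X, y, grm)
    return LmmFit(
        beta=model.beta_,
        sigma2_g=model.sigma2_g_,
        sigma2_e=model.sigma2_e_,
        loglik=model.loglik_,
        residuals=model.residuals_,
        heritability=model.heritability_,
    )
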