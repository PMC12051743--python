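"""Synthetic two-way admixed cohorts with known variance-QTL mechanisms.

The generator emulates the structure of an admixed study population (e.g.
African Americans, ~80% ancestry from a sub-Saharan African background A and
~20% from a European background B): each individual draws a global ancestry
proportion from a Beta distribution, each haplotype is a Markov mosaic of
ancestry tracts along the marker index, and the allele at a site is drawn
from that tract's background-specific frequency.  Sib pairs share parental
haplotypes, giving the GRM random effect real structure to absorb.

Phenotypes are injected separately so a single genotype realization can host
different mechanisms: gene x environment or gene x gene interactions (which
inflate variance quadratically in genotype), ancestry-dependent residual
scale, or a pure main effect (``none``).  The injected truth is carried on
the cohort for downstream power and calibration checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genotype_io import SITE_COLUMNS, GenotypeSet

__all__ = [
    "CovariateModel",
    "CohortConfig",
    "VqtlMechanism",
    "SimulatedCohort",
    "simulate_cohort",
    "inject_phenotype",
    "write_cohort",
]

MECHANISM_KINDS = ("gxg", "gxe", "ancestry_scale", "none")


@dataclass(frozen=True)
class CovariateModel:
    """Distributional parameters of the non-genetic covariates.

    ``env`` is a continuous blood-pressure-like exposure used by the
    gene x covariate machinery; ``n_studies`` partitions individuals into
    contiguous blocks with block-specific intercepts, mimicking a multi-study
    discovery design.
    """

    age_mean: float = 45.0
    age_sd: float = 12.0
    sex_prob: float = 0.5
    n_studies: int = 8
    study_effect_sd: float = 0.5
    env_mean: float = 0.0
    env_sd: float = 1.0


@dataclass(frozen=True)
class CohortConfig:
    """Design of a simulated two-way admixed cohort.

    ``admixture_mean`` / ``admixture_concentration`` parameterize the Beta
    distribution of individual ancestry-A proportions as
    ``Beta(mean * c, (1 - mean) * c)``; the default mean of 0.8 matches the
    typical African-ancestry fraction of African Americans, and c = 10 gives
    a realistic spread (sd ~ 0.12).  ``allele_freq_A`` / ``allele_freq_B``
    are per-marker alt-allele frequencies in each ancestral background (drawn
    uniformly on (0.05, 0.95) when omitted).  ``tract_switch_prob`` is the
    per-inter-marker probability scale of the ancestry tract process.
    """

    n_individuals: int
    n_markers: int
    admixture_mean: float = 0.8
    admixture_concentration: float = 10.0
    allele_freq_A: np.ndarray | None = None
    allele_freq_B: np.ndarray | None = None
    n_sib_pairs: int = 0
    tract_switch_prob: float = 0.01
    covariates: CovariateModel = field(default_factory=CovariateModel)
    chrom: str = "1"
    marker_spacing_bp: int = 100_000
    seed: int = 0

    def __post_init__(self):
        if self.n_individuals < 1 or self.n_markers < 1:
            raise ValueError("cohort and marker counts must be positive")
        if not np.isfinite(self.admixture_mean) or not 0.0 <= self.admixture_mean <= 1.0:
            raise ValueError("admixture_mean must lie in [0, 1]")
        if not np.isfinite(self.admixture_concentration) or self.admixture_concentration <= 0:
            raise ValueError("admixture_concentration must be positive")
        if not 0.0 <= self.tract_switch_prob <= 1.0:
            raise ValueError("tract_switch_prob must lie in [0, 1]")
        if 2 * self.n_sib_pairs > self.n_individuals:
            raise ValueError("n_sib_pairs * 2 must not exceed n_individuals")
        for name in ("allele_freq_A", "allele_freq_B"):
            f = getattr(self, name)
            if f is not None:
                f = np.asarray(f, dtype=float)
                if f.shape != (self.n_markers,):
                    raise ValueError(f"{name} must have length n_markers")
                if np.any(~np.isfinite(f)) or np.any(f <= 0) or np.any(f >= 1):
                    raise ValueError(f"{name} must lie strictly inside (0, 1)")
                object.__setattr__(self, name, f)


@dataclass(frozen=True)
class VqtlMechanism:
    """One injected source of genotype-dependent phenotypic variance.

    kind='gxe'   : y += beta_main*g + beta_interaction*g*E, so
                   Var(y|g) = noise^2 + (beta_interaction*g)^2 Var(E).
    kind='gxg'   : same with the partner marker's genotype in place of E.
    kind='ancestry_scale' : residual sd multiplied by
                   ancestry_sd_ratio ** (copies of background B at the
                   target), plus the beta_main main effect.
    kind='none'  : main effect only (beta_interaction forced to 0).
    """

    kind: str
    target_marker: int
    partner: int | str | None = None
    beta_main: float = 0.0
    beta_interaction: float = 0.0
    ancestry_sd_ratio: float = 1.0

    def __post_init__(self):
        if self.kind not in MECHANISM_KINDS:
            raise ValueError(f"unknown mechanism kind {self.kind!r}")
        if self.kind == "none" and self.beta_interaction != 0.0:
            raise ValueError("kind='none' forces beta_interaction = 0")
        if self.kind == "gxg" and not isinstance(self.partner, (int, np.integer)):
            raise ValueError("gxg mechanism needs a partner marker index")
        if self.ancestry_sd_ratio <= 0:
            raise ValueError("ancestry_sd_ratio must be positive")


@dataclass
class SimulatedCohort:
    """Genotypes, phased haplotypes, local-ancestry truth, covariates, and
    (after injection) phenotypes for a simulated admixed cohort.

    ``haplotypes[i, h, j]`` is the 0/1 allele of haplotype h of individual i
    at marker j; ``hap_ancestry`` the matching tract state (0 = background A,
    1 = background B); ``ancestry_calls`` the per-site count of background-B
    chromosomes; dosage equals the haplotype allele sum by construction.
    """

    ids: np.ndarray
    sites: pd.DataFrame
    haplotypes: np.ndarray
    hap_ancestry: np.ndarray
    covariates: pd.DataFrame
    study_intercepts: np.ndarray
    global_ancestry: np.ndarray
    sib_pairs: list
    config: CohortConfig
    phenotype: np.ndarray | None = None
    mechanisms: list = field(default_factory=list)
    noise_sd: float | None = None

    @property
    def dosages(self) -> np.ndarray:
        return self.haplotypes.sum(axis=1).astype(float)

    @property
    def ancestry_calls(self) -> np.ndarray:
        return self.hap_ancestry.sum(axis=1)

    def to_genotype_set(self) -> GenotypeSet:
        return GenotypeSet(self.ids.copy(), self.sites.copy(), self.dosages)


def _sample_haplotypes(alphas: np.ndarray, cfg: CohortConfig, rng) -> tuple[np.ndarray, np.ndarray]:
    """Tract states and alleles for one haplotype per row of ``alphas``.

    The tract process is a two-state Markov chain along the marker index
    whose stationary distribution puts mass ``alpha`` on background A:
    switch probabilities t*(1-alpha) out of A and t*alpha out of B.
    """
    H = alphas.size
    m = cfg.n_markers
    states = np.empty((H, m), dtype=np.int8)
    states[:, 0] = rng.random(H) >= alphas
    t = cfg.tract_switch_prob
    for j in range(1, m):
        prev = states[:, j - 1]
        p_switch = np.where(prev == 0, t * (1.0 - alphas), t * alphas)
        flip = rng.random(H) < p_switch
        states[:, j] = np.where(flip, 1 - prev, prev)
    freq = np.where(states == 0, cfg.allele_freq_A[None, :], cfg.allele_freq_B[None, :])
    alleles = (rng.random((H, m)) < freq).astype(np.int8)
    return states, alleles


def simulate_cohort(config: CohortConfig) -> SimulatedCohort:
    """Draw genotypes, haplotypes, local-ancestry truth and covariates.

    Sib pairs are built by simulating two parents and transmitting one
    haplotype (with its ancestry tracts) from each parent to each sib; the
    remaining individuals are unrelated.  Phenotypes are added separately by
    :func:`inject_phenotype`.
    """
    rng = np.random.default_rng(config.seed)
    cfg = config
    if cfg.allele_freq_A is None or cfg.allele_freq_B is None:
        fA = cfg.allele_freq_A
        fB = cfg.allele_freq_B
        if fA is None:
            fA = rng.uniform(0.05, 0.95, cfg.n_markers)
        if fB is None:
            fB = rng.uniform(0.05, 0.95, cfg.n_markers)
        cfg = replace(cfg, allele_freq_A=fA, allele_freq_B=fB)

    n = cfg.n_individuals
    m = cfg.n_markers
    a = cfg.admixture_mean * cfg.admixture_concentration
    b = (1.0 - cfg.admixture_mean) * cfg.admixture_concentration

    haplotypes = np.empty((n, 2, m), dtype=np.int8)
    hap_anc = np.empty((n, 2, m), dtype=np.int8)
    global_anc = np.empty(n)
    sib_pairs = []

    # degenerate Beta endpoints (pure ancestry) handled explicitly
    def draw_alpha(size):
        if cfg.admixture_mean in (0.0, 1.0):
            return np.full(size, cfg.admixture_mean)
        return rng.beta(a, b, size)

    i = 0
    for _ in range(cfg.n_sib_pairs):
        parent_alpha = draw_alpha(2)
        p_states, p_alleles = _sample_haplotypes(
            np.repeat(parent_alpha, 2), cfg, rng
        )  # rows: mother hap0, hap1, father hap0, hap1
        for child in range(2):
            pick = rng.integers(0, 2, size=2)  # which haplotype from each parent
            rows = [pick[0], 2 + pick[1]]
            haplotypes[i, 0], haplotypes[i, 1] = p_alleles[rows[0]], p_alleles[rows[1]]
            hap_anc[i, 0], hap_anc[i, 1] = p_states[rows[0]], p_states[rows[1]]
            global_anc[i] = 1.0 - hap_anc[i].mean()
            i += 1
        sib_pairs.append((i - 2, i - 1))

    n_unrel = n - i
    if n_unrel:
        alphas = draw_alpha(n_unrel)
        states, alleles = _sample_haplotypes(np.repeat(alphas, 2), cfg, rng)
        haplotypes[i:] = alleles.reshape(n_unrel, 2, m)
        hap_anc[i:] = states.reshape(n_unrel, 2, m)
        global_anc[i:] = 1.0 - hap_anc[i:].mean(axis=(1, 2))

    cov = cfg.covariates
    ids = np.array([f"ind{k:06d}" for k in range(n)], dtype=object)
    study = np.array(
        [f"study{(k * cov.n_studies) // n + 1}" for k in range(n)], dtype=object
    )
    covariates = pd.DataFrame({
        "id": ids,
        "age": rng.normal(cov.age_mean, cov.age_sd, n),
        "sex": rng.binomial(1, cov.sex_prob, n),
        "study": study,
        "E": rng.normal(cov.env_mean, cov.env_sd, n),
    })
    study_intercepts = rng.normal(0.0, cov.study_effect_sd, cov.n_studies)

    pos = (np.arange(m) + 1) * cfg.marker_spacing_bp
    sites = pd.DataFrame({
        "chrom": cfg.chrom, "pos": pos, "ref": "A", "alt": "G", "rsq": 1.0,
    })[SITE_COLUMNS]

    return SimulatedCohort(
        ids=ids, sites=sites, haplotypes=haplotypes, hap_ancestry=hap_anc,
        covariates=covariates, study_intercepts=study_intercepts,
        global_ancestry=global_anc, sib_pairs=sib_pairs, config=cfg,
    )


def inject_phenotype(
    cohort: SimulatedCohort,
    mechanisms: list[VqtlMechanism],
    noise_sd: float = 1.0,
    covariate_effects: dict | None = None,
    seed: int = 0,
) -> SimulatedCohort:
    """Attach a phenotype with the given variance mechanisms.

    y_i = study intercept + beta_age (age_i - mean age) + beta_sex sex_i
          + beta_env E_i + sum of mechanism contributions + eps_i,

    eps_i ~ N(0, sd_i) with sd_i = noise_sd scaled per ancestry_scale
    mechanism by ``ancestry_sd_ratio ** (copies of background B)`` at the
    target marker.  Returns a new cohort; the input is unchanged.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    effects = {"age": 0.02, "sex": 0.5, "env": 0.3}
    if covariate_effects:
        unknown = set(covariate_effects) - set(effects)
        if unknown:
            raise ValueError(f"unknown covariate effects: {sorted(unknown)}")
        effects.update(covariate_effects)

    rng = np.random.default_rng(seed)
    n = cohort.ids.size
    cov = cohort.covariates
    cfg = cohort.config.covariates
    study_idx = cov["study"].str.removeprefix("study").astype(int).to_numpy() - 1

    y = cohort.study_intercepts[study_idx].copy()
    y += effects["age"] * (cov["age"].to_numpy() - cfg.age_mean)
    y += effects["sex"] * cov["sex"].to_numpy()
    y += effects["env"] * cov["E"].to_numpy()

    dosages = cohort.dosages
    calls = cohort.ancestry_calls
    sd = np.full(n, float(noise_sd))
    for mech in mechanisms:
        if not 0 <= mech.target_marker < dosages.shape[1]:
            raise ValueError(f"target marker {mech.target_marker} out of range")
        g = dosages[:, mech.target_marker]
        y += mech.beta_main * g
        if mech.kind == "gxe":
            partner = mech.partner if isinstance(mech.partner, str) else "E"
            x = cov[partner].to_numpy(dtype=float)
            y += mech.beta_interaction * g * x
        elif mech.kind == "gxg":
            g2 = dosages[:, mech.partner]
            y += mech.beta_interaction * g * g2
        elif mech.kind == "ancestry_scale":
            sd = sd * mech.ancestry_sd_ratio ** calls[:, mech.target_marker]
        # kind == 'none': main effect only

    y += rng.normal(0.0, 1.0, n) * sd
    return replace(
        cohort, phenotype=y, mechanisms=list(mechanisms), noise_sd=float(noise_sd)
    )


def write_cohort(cohort: SimulatedCohort, out_dir) -> dict[str, Path]:
    """Serialize a cohort: dosage VCF, phenotype TSV, local-ancestry TSV,
    and a truth YAML recording the injected mechanisms.

    The VCF carries phased GT plus DS (the haplotype allele sum) and
    INFO R2=1 (simulated genotypes are treated as perfectly imputed); it
    round-trips losslessly through :func:`vqtlscan.genotype_io.read_vcf`.
    """
    if cohort.phenotype is None:
        raise ValueError("inject a phenotype before writing the cohort")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "genotypes.vcf",
        "phenotypes": out / "phenotypes.tsv",
        "ancestry": out / "ancestry.tsv",
        "truth": out / "truth.yaml",
    }

    with open(paths["vcf"], "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=R2,Number=1,Type=Float,Description="Imputation quality">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alt dosage">\n')
        fh.write(f"##contig=<ID={cohort.config.chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(cohort.ids) + "\n")
        sites = cohort.sites
        hap = cohort.haplotypes
        for j in range(len(sites)):
            s = sites.iloc[j]
            fields = [
                f"{hap[i, 0, j]}|{hap[i, 1, j]}:{hap[i, 0, j] + hap[i, 1, j]}"
                for i in range(cohort.ids.size)
            ]
            fh.write(
                f"{s['chrom']}\t{s['pos']}\t.\t{s['ref']}\t{s['alt']}\t.\tPASS\t"
                f"R2={s['rsq']:g}\tGT:DS\t" + "\t".join(fields) + "\n"
            )

    pheno = cohort.covariates.copy()
    pheno.insert(1, "trait", cohort.phenotype)
    # round-trip float precision so re-running a stage from serialized inputs
    # reproduces in-memory results exactly
    pheno.to_csv(paths["phenotypes"], sep="\t", index=False, float_format="%.17g")

    calls = cohort.ancestry_calls
    site_ids = cohort.to_genotype_set().site_ids()
    long = pd.DataFrame({
        "id": np.repeat(cohort.ids, calls.shape[1]),
        "marker": np.tile(site_ids, calls.shape[0]),
        "n_copies_B": calls.reshape(-1),
    })
    long.to_csv(paths["ancestry"], sep="\t", index=False)

    truth = {
        "seed": int(cohort.config.seed),
        "noise_sd": float(cohort.noise_sd),
        "n_individuals": int(cohort.config.n_individuals),
        "n_markers": int(cohort.config.n_markers),
        "admixture_mean": float(cohort.config.admixture_mean),
        "sib_pairs": [list(map(int, p)) for p in cohort.sib_pairs],
        "mechanisms": [
            {
                "kind": m.kind,
                "target_marker": int(m.target_marker),
                "partner": (int(m.partner) if isinstance(m.partner, (int, np.integer))
                            else m.partner),
                "beta_main": float(m.beta_main),
                "beta_interaction": float(m.beta_interaction),
                "ancestry_sd_ratio": float(m.ancestry_sd_ratio),
            }
            for m in cohort.mechanisms
        ],
    }
    with open(paths["truth"], "w") as fh:
        yaml.safe_dump(truth, fh, sort_keys=True)
    return paths
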