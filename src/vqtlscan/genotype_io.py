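"""Genotype containers, VCF input, and site/individual quality-control
filters for imputed dosage data.

The central container is :class:`GenotypeSet`: an individuals x sites dosage
matrix (real-valued in [0, 2], NaN for missing) with per-site metadata
(chromosome, 1-based position, ref/alt alleles, imputation quality r^2).
Site identity throughout the package is the full ``chrom:pos:ref:alt`` tuple.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mechanisms import hwe_exact

__all__ = [
    "GenotypeSet",
    "SiteFilterConfig",
    "FilterLog",
    "read_vcf",
    "read_phenotypes",
    "read_ancestry",
    "most_probable_genotype",
    "apply_filters",
    "merge_sets",
]

SITE_COLUMNS = ["chrom", "pos", "ref", "alt", "rsq"]

_AMBIGUOUS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass
class GenotypeSet:
    """Dosage matrix plus site and individual metadata.

    Attributes
    ----------
    ids : array of str, shape (n_individuals,)
    sites : DataFrame with columns chrom, pos, ref, alt, rsq
        Positions are 1-based and non-decreasing within chromosome.
    dosages : float array, shape (n_individuals, n_sites)
        Alt-allele dosages in [0, 2]; NaN marks missing calls.
    """

    ids: np.ndarray
    sites: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self):
        self.ids = np.asarray(self.ids, dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.ids), len(self.sites)):
            raise ValueError("dosage matrix shape does not match ids x sites")
        with np.errstate(invalid="ignore"):
            bad = (self.dosages < 0) | (self.dosages > 2)
        if bad.any():
            raise ValueError("dosages must lie in [0, 2] or be NaN")

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def site_ids(self) -> np.ndarray:
        s = self.sites
        return (
            s["chrom"].astype(str) + ":" + s["pos"].astype(str)
            + ":" + s["ref"] + ":" + s["alt"]
        ).to_numpy()

    def alt_freq(self) -> np.ndarray:
        """Per-site alt-allele frequency from the non-missing dosages."""
        return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    def site_call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosages).mean(axis=0)

    def individual_call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosages).mean(axis=1)

    def take_sites(self, index) -> "GenotypeSet":
        return GenotypeSet(
            self.ids,
            self.sites.iloc[index].reset_index(drop=True),
            self.dosages[:, index],
        )

    def take_individuals(self, index) -> "GenotypeSet":
        return GenotypeSet(self.ids[index], self.sites.copy(), self.dosages[index])


@dataclass(frozen=True)
class SiteFilterConfig:
    """Thresholds for the standard pre-scan QC pass.

    Defaults correspond to common practice for array + imputed data:
    individuals with < 90% calls and markers with < 95% calls removed,
    extreme Hardy-Weinberg departure (p < 1e-10) removed, imputation
    r^2 >= 0.3, MAF >= 0.5%, and monomorphic or strand-ambiguous (A/T, C/G)
    markers dropped.
    """

    min_individual_call_rate: float = 0.90
    min_marker_call_rate: float = 0.95
    min_hwe_p: float = 1e-10
    min_rsq: float = 0.3
    min_maf: float = 0.005
    drop_strand_ambiguous: bool = True
    drop_monomorphic: bool = True

    def __post_init__(self):
        for name in ("min_individual_call_rate", "min_marker_call_rate",
                     "min_hwe_p", "min_rsq", "min_maf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class FilterLog:
    """Per-rule removal counts and a site-level table of removal reasons."""

    individuals_removed: list = field(default_factory=list)
    removed_sites: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["site_id", "reason"])
    )

    def counts(self) -> dict:
        out = dict(self.removed_sites["reason"].value_counts())
        out["individual_call_rate"] = len(self.individuals_removed)
        return {k: int(v) for k, v in out.items()}

    def to_tsv(self, path) -> None:
        self.removed_sites.to_csv(path, sep="\t", index=False)


def read_vcf(path) -> GenotypeSet:
    """Load a VCF into a :class:`GenotypeSet`.

    Dosages come from the FORMAT DS field when present, otherwise from GT
    (alt-allele count).  Imputation quality is taken from INFO R2 (1.0 when
    absent, i.e. genotyped).  Multi-allelic records are rejected; split them
    upstream (e.g. ``bcftools norm -m-``).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = np.array(vcf.samples, dtype=object)
    rows, dosage_cols = [], []
    for variant in vcf:
        if len(variant.ALT) != 1:
            raise ValueError(
                f"multi-allelic record at {variant.CHROM}:{variant.POS}; "
                "split to biallelics first"
            )
        ds = variant.format("DS")
        if ds is not None:
            d = np.asarray(ds, dtype=float).reshape(-1)
            d = np.where((d < 0) | (d > 2), np.nan, d)
        else:
            gt = np.asarray(variant.genotype.array())
            if gt.size == 0:
                raise ValueError(
                    f"record at {variant.CHROM}:{variant.POS} has neither DS nor GT"
                )
            alleles = gt[:, :2]
            d = np.where((alleles < 0).any(axis=1), np.nan,
                         alleles.clip(min=0).sum(axis=1)).astype(float)
        rsq = variant.INFO.get("R2")
        rows.append((variant.CHROM, variant.POS, variant.REF, variant.ALT[0],
                     float(rsq) if rsq is not None else 1.0))
        dosage_cols.append(d)
    sites = pd.DataFrame(rows, columns=SITE_COLUMNS)
    dosages = (np.array(dosage_cols).T if dosage_cols
               else np.empty((len(ids), 0)))
    return GenotypeSet(ids, sites, dosages)


def read_phenotypes(path) -> pd.DataFrame:
    """Read the phenotype/covariate table (TSV with at least id and trait)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"id": str},
                     float_precision="round_trip")
    if "id" not in df.columns:
        raise ValueError("phenotype table must have an 'id' column")
    return df


def read_ancestry(path) -> pd.DataFrame:
    """Read long-format local-ancestry calls (id, marker, n_copies_B) into a
    wide individuals x markers frame."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"id": str})
    wide = df.pivot(index="id", columns="marker", values="n_copies_B")
    return wide


def most_probable_genotype(dosage) -> np.ndarray:
    """Nearest-integer genotype for a dosage in [0, 2].

    Ties at .5 round up (0.5 -> 1, 1.5 -> 2); missing dosages propagate as
    NaN.  Accepts scalars or arrays.
    """
    d = np.asarray(dosage, dtype=float)
    out = np.floor(d + 0.5)
    out = np.clip(out, 0, 2)
    out = np.where(np.isnan(d), np.nan, out)
    return out if out.ndim else out[()]


def _hwe_p_per_site(gs: GenotypeSet) -> np.ndarray:
    mpg = most_probable_genotype(gs.dosages)
    out = np.ones(gs.n_sites)
    for j in range(gs.n_sites):
        col = mpg[:, j]
        col = col[~np.isnan(col)]
        if col.size == 0:
            continue
        n2 = int((col == 2).sum())
        n1 = int((col == 1).sum())
        n0 = int((col == 0).sum())
        out[j] = hwe_exact(n0, n1, n2)
    return out


def apply_filters(
    gs: GenotypeSet, cfg: SiteFilterConfig | None = None
) -> tuple[GenotypeSet, FilterLog]:
    """Apply individual then site QC filters, logging removals per rule.

    Order: individuals below the call-rate threshold are removed first (so
    site statistics are computed on the retained individuals), then sites are
    screened for call rate, monomorphism, strand ambiguity, imputation
    quality, MAF and Hardy-Weinberg departure.  The first failing rule, in
    that order, is recorded as the site's removal reason.  An empty result is
    allowed (with a warning), never an exception.
    """
    cfg = cfg or SiteFilterConfig()
    log = FilterLog()

    ind_ok = gs.individual_call_rate() >= cfg.min_individual_call_rate
    log.individuals_removed = list(gs.ids[~ind_ok])
    gs = gs.take_individuals(ind_ok)

    site_ids = gs.site_ids()
    reasons: dict[int, str] = {}

    call = gs.site_call_rate()
    for j in np.nonzero(call < cfg.min_marker_call_rate)[0]:
        reasons.setdefault(j, "marker_call_rate")

    if cfg.drop_monomorphic:
        maf = gs.maf()
        with np.errstate(invalid="ignore"):
            mono = (maf <= 0) | np.isnan(maf)
        for j in np.nonzero(mono)[0]:
            reasons.setdefault(j, "monomorphic")

    if cfg.drop_strand_ambiguous:
        amb = [
            j for j, (r, a) in enumerate(zip(gs.sites["ref"], gs.sites["alt"]))
            if (r, a) in _AMBIGUOUS
        ]
        for j in amb:
            reasons.setdefault(j, "strand_ambiguous")

    for j in np.nonzero(gs.sites["rsq"].to_numpy() < cfg.min_rsq)[0]:
        reasons.setdefault(j, "imputation_rsq")

    with np.errstate(invalid="ignore"):
        low_maf = gs.maf() < cfg.min_maf
    for j in np.nonzero(low_maf)[0]:
        reasons.setdefault(j, "maf")

    if cfg.min_hwe_p > 0:
        remaining = [j for j in range(gs.n_sites) if j not in reasons]
        if remaining:
            hwe = _hwe_p_per_site(gs.take_sites(remaining))
            for j, p in zip(remaining, hwe):
                if p < cfg.min_hwe_p:
                    reasons.setdefault(j, "hwe")

    removed = sorted(reasons)
    log.removed_sites = pd.DataFrame(
        {"site_id": [site_ids[j] for j in removed],
         "reason": [reasons[j] for j in removed]}
    )
    keep = np.setdiff1d(np.arange(gs.n_sites), removed)
    out = gs.take_sites(keep)
    if out.n_sites == 0 or out.n_individuals == 0:
        warnings.warn("all sites or individuals removed by QC filters")
    return out, log


def merge_sets(sets: list[GenotypeSet]) -> GenotypeSet:
    """Merge cohorts with disjoint individuals on the intersection of sites.

    Sites are matched on (chrom, pos, ref, alt); a site present with swapped
    ref/alt in a later set is harmonized by flipping its dosages to ``2 - d``.
    Conflicting alleles at a shared position drop the site from the
    intersection.  Duplicate individual ids raise.
    """
    if not sets:
        raise ValueError("nothing to merge")
    if len(sets) == 1:
        return sets[0]

    all_ids = np.concatenate([s.ids for s in sets])
    if len(set(all_ids)) != len(all_ids):
        raise ValueError("individual ids must be disjoint across sets")

    def keyed(s: GenotypeSet) -> dict:
        return {
            (c, int(p), r, a): j
            for j, (c, p, r, a) in enumerate(
                zip(s.sites["chrom"], s.sites["pos"], s.sites["ref"], s.sites["alt"])
            )
        }

    base = sets[0]
    base_keys = keyed(base)
    shared: list[tuple] = list(base_keys)
    for s in sets[1:]:
        k = keyed(s)
        shared = [
            key for key in shared
            if key in k or (key[0], key[1], key[3], key[2]) in k
        ]
    if not shared:
        raise ValueError("no shared sites across sets")

    blocks = []
    for s in sets:
        k = keyed(s)
        cols = np.empty((s.n_individuals, len(shared)))
        for out_j, key in enumerate(shared):
            if key in k:
                cols[:, out_j] = s.dosages[:, k[key]]
            else:
                flipped = (key[0], key[1], key[3], key[2])
                cols[:, out_j] = 2.0 - s.dosages[:, k[flipped]]
        blocks.append(cols)

    sites = base.sites.iloc[[base_keys[key] for key in shared]].reset_index(drop=True)
    order = np.lexsort((sites["pos"].to_numpy(), sites["chrom"].to_numpy()))
    sites = sites.iloc[order].reset_index(drop=True)
    dosages = np.vstack(blocks)[:, order]
    return GenotypeSet(all_ids, sites, dosages)
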