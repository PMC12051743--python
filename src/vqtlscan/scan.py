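"""Genome-wide variance-QTL scan, locus definition, and replication.

Each marker's imputed dosages are collapsed to most-probable genotypes, and
the residual trait is tested for variance homogeneity across the genotype
classes with the Fligner-Killeen test.  Alongside the variance test the scan
records the conventional additive-model p (OLS of residual on dosage), the
exact Hardy-Weinberg p, the minor-allele frequency, the genotype class
counts, and the adjusted variance explained implied by the variance-test p.

Significant markers are grouped into loci by greedy distance + LD clumping,
and replication is assessed per marker (p below ``alpha_rep`` in the
replication cohort) and per locus (any member replicates).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .effectsize import p_to_r2adj, r2adj_from_t  # re-exported  # noqa: F401
from .fk import drop_sparse_classes, fligner_killeen
from .genotype_io import GenotypeSet, most_probable_genotype
from .mechanisms import hwe_exact

__all__ = [
    "VqtlScanner",
    "Locus",
    "vqtl_scan",
    "p_to_r2adj",
    "define_loci",
    "replicate",
    "SCAN_COLUMNS",
]

SCAN_COLUMNS = [
    "site_id", "chrom", "pos", "ref", "alt", "maf",
    "n0", "n1", "n2", "fk_stat", "fk_df", "fk_p",
    "additive_p", "hwe_p", "r2_adj", "n_used",
]


@dataclass
class Locus:
    """A clump of significant markers around a lead variant."""

    lead: str
    members: list = field(default_factory=list)
    chrom: str = ""
    span: tuple = (0, 0)

    @property
    def n_markers(self) -> int:
        return len(self.members)


class VqtlScanner(BaseEstimator):
    """Per-marker variance-QTL scan on a residualized trait.

    Parameters
    ----------
    min_class_count : int
        Genotype classes smaller than this are dropped before the variance
        test (their spread is unestimable); the dropped classes still appear
        in the class counts.
    p_threshold : float
        Genome-wide significance threshold used by :meth:`loci`.
    window_bp : int
        Clumping window around a lead variant.
    ld_r2_min : float
        Minimum squared dosage correlation with the lead for clump
        membership.

    Attributes (after fit)
    ----------------------
    results_ : DataFrame with one row per scanned marker (``SCAN_COLUMNS``).
    """

    def __init__(self, min_class_count: int = 2, p_threshold: float = 5e-8,
                 window_bp: int = 1_000_000, ld_r2_min: float = 0.2):
        self.min_class_count = min_class_count
        self.p_threshold = p_threshold
        self.window_bp = window_bp
        self.ld_r2_min = ld_r2_min

    def fit(self, genotypes: GenotypeSet, residuals):
        residuals = np.asarray(residuals, dtype=float)
        if residuals.size != genotypes.n_individuals:
            raise ValueError("residuals must align with genotype individuals")

        rows = []
        site_ids = genotypes.site_ids()
        mafs = genotypes.maf()
        for j in range(genotypes.n_sites):
            d = genotypes.dosages[:, j]
            ok = np.isfinite(d) & np.isfinite(residuals)
            d, y = d[ok], residuals[ok]
            g = most_probable_genotype(d)
            counts = [int((g == k).sum()) for k in (0, 1, 2)]

            vals, grp, _ = drop_sparse_classes(y, g, self.min_class_count)
            fk = fligner_killeen(vals, grp)
            n_used = int(vals.size)
            if fk.defined and n_used > 3:
                r2_adj = p_to_r2adj(max(fk.p, np.finfo(float).tiny), n_used).r2_adj
            else:
                r2_adj = np.nan

            if np.ptp(d) > 0 and d.size > 2:
                additive_p = float(stats.linregress(d, y).pvalue)
            else:
                additive_p = np.nan
            hwe_p = hwe_exact(counts[0], counts[1], counts[2])

            s = genotypes.sites.iloc[j]
            rows.append((
                site_ids[j], s["chrom"], int(s["pos"]), s["ref"], s["alt"],
                float(mafs[j]), *counts, fk.statistic, fk.df, fk.p,
                additive_p, hwe_p, r2_adj, n_used,
            ))
        self.results_ = pd.DataFrame(rows, columns=SCAN_COLUMNS)
        self._dosages = genotypes.dosages
        return self

    def loci(self) -> list[Locus]:
        return define_loci(
            self.results_, self.p_threshold, self.window_bp,
            self.ld_r2_min, dosages=self._dosages,
        )


def vqtl_scan(
    genotypes: GenotypeSet, residuals, min_class_count: int = 2
) -> pd.DataFrame:
    """Functional wrapper over :class:`VqtlScanner`; returns ``results_``."""
    return VqtlScanner(min_class_count=min_class_count).fit(
        genotypes, residuals
    ).results_


def _ld_r2(a: np.ndarray, b: np.ndarray) -> float:
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3 or np.ptp(a[ok]) == 0 or np.ptp(b[ok]) == 0:
        return 0.0
    return float(np.corrcoef(a[ok], b[ok])[0, 1] ** 2)


def define_loci(
    results: pd.DataFrame,
    p_threshold: float = 5e-8,
    window_bp: int = 1_000_000,
    ld_r2_min: float = 0.2,
    dosages: np.ndarray | None = None,
) -> list[Locus]:
    """Greedy clumping of significant markers into loci.

    Repeatedly takes the most significant unassigned marker below
    ``p_threshold`` as a lead, then assigns every unassigned significant
    marker on the same chromosome within ``window_bp`` whose squared dosage
    correlation with the lead is at least ``ld_r2_min`` (distance-only when
    no dosages are supplied).  A chromosome can host several loci.
    """
    sig = results.index[results["fk_p"] < p_threshold].to_numpy()
    unassigned = set(sig.tolist())
    loci: list[Locus] = []
    while unassigned:
        lead = min(unassigned, key=lambda i: results.at[i, "fk_p"])
        chrom = results.at[lead, "chrom"]
        pos = results.at[lead, "pos"]
        members = [lead]
        for i in sorted(unassigned - {lead}):
            if results.at[i, "chrom"] != chrom:
                continue
            if abs(results.at[i, "pos"] - pos) > window_bp:
                continue
            if dosages is not None:
                if _ld_r2(dosages[:, lead], dosages[:, i]) < ld_r2_min:
                    continue
            members.append(i)
        unassigned -= set(members)
        positions = [int(results.at[i, "pos"]) for i in members]
        loci.append(Locus(
            lead=results.at[lead, "site_id"],
            members=[results.at[i, "site_id"] for i in members],
            chrom=str(chrom),
            span=(min(positions), max(positions)),
        ))
    return loci


def replicate(
    discovery_loci: list[Locus],
    replication_results: pd.DataFrame,
    alpha_rep: float = 0.05,
    p_column: str = "fk_p",
) -> pd.DataFrame:
    """Marker- and locus-level replication report.

    A discovery marker replicates when its p-value in the replication cohort
    (matched on the full chrom:pos:ref:alt site id) is below ``alpha_rep``;
    a locus replicates when at least one member marker does.  Markers absent
    from the replication results are recorded as unmatched, not fatal.
    """
    rep_p = dict(zip(replication_results["site_id"], replication_results[p_column]))
    rows = []
    for locus in discovery_loci:
        member_flags = []
        for sid in locus.members:
            p = rep_p.get(sid, np.nan)
            matched = sid in rep_p
            flag = bool(matched and np.isfinite(p) and p < alpha_rep)
            member_flags.append(flag)
            rows.append({
                "locus_lead": locus.lead, "site_id": sid, "chrom": locus.chrom,
                "matched": matched, "replication_p": p, "replicated": flag,
            })
        locus_flag = any(member_flags)
        for row in rows[-len(locus.members):]:
            row["locus_replicated"] = locus_flag
    return pd.DataFrame(rows)
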