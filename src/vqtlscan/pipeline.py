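"""End-to-end orchestration: simulate or load a cohort, run QC, residualize,
scan, replicate, and probe mechanisms, with deterministic seeded outputs.

Stages mirror a two-cohort vQTL study: a discovery pass (QC filters -> GRM ->
PCs -> mixed-model residuals -> Fligner-Killeen scan -> locus clumping), a
replication pass restricted to the discovery loci, and a mechanism-probe pass
over replicated loci.  Every output file carries a header comment with the
config hash and seed so reruns are verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import genotype_io, mechanisms as mech, residualize, scan as scan_mod
from .fk import SimSpec, validate_test
from .genotype_io import GenotypeSet, SiteFilterConfig, most_probable_genotype
from .simulate import CohortConfig, CovariateModel, VqtlMechanism, inject_phenotype, simulate_cohort

logger = logging.getLogger("vqtlscan")

__all__ = [
    "PipelineConfig",
    "CohortData",
    "load_cohort",
    "residualize_cohort",
    "run_discovery",
    "run_replication",
    "run_explain",
    "run_validate_fk",
]


@dataclass
class PipelineConfig:
    """Single-YAML configuration for the pipeline stages.

    Exactly one of ``paths`` (vcf/phenotypes/ancestry files) or ``simulate``
    (a :class:`CohortConfig`-shaped mapping plus mechanisms) must be given
    per cohort.
    """

    cohort: dict
    filters: dict = field(default_factory=dict)
    n_pcs: int = 1
    scan: dict = field(default_factory=dict)
    alpha_rep: float = 0.05
    probes: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        has_paths = "paths" in self.cohort
        has_sim = "simulate" in self.cohort
        if has_paths == has_sim:
            raise ValueError(
                "exactly one of cohort.paths or cohort.simulate must be set"
            )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "cohort": self.cohort, "filters": self.filters, "n_pcs": self.n_pcs,
            "scan": self.scan, "alpha_rep": self.alpha_rep,
            "probes": self.probes, "seed": self.seed,
        }

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class CohortData:
    """In-memory bundle of everything the stages consume."""

    genotypes: GenotypeSet
    phenotypes: pd.DataFrame
    ancestry_calls: np.ndarray | None = None     # individuals x sites
    haplotypes: np.ndarray | None = None         # individuals x 2 x sites
    hap_ancestry: np.ndarray | None = None


def load_cohort(config: PipelineConfig) -> CohortData:
    """Materialize the cohort from files or from the simulator."""
    c = config.cohort
    if "simulate" in c:
        sim_kwargs = dict(c["simulate"])
        sim_kwargs.setdefault("seed", config.seed)
        if "covariates" in sim_kwargs:
            sim_kwargs["covariates"] = CovariateModel(**sim_kwargs["covariates"])
        cohort = simulate_cohort(CohortConfig(**sim_kwargs))
        mechs = [VqtlMechanism(**m) for m in c.get("mechanisms", [])]
        cohort = inject_phenotype(
            cohort, mechs,
            noise_sd=c.get("noise_sd", 1.0),
            covariate_effects=c.get("covariate_effects"),
            seed=sim_kwargs["seed"] + 1,
        )
        pheno = cohort.covariates.copy()
        pheno.insert(1, "trait", cohort.phenotype)
        return CohortData(
            genotypes=cohort.to_genotype_set(), phenotypes=pheno,
            ancestry_calls=cohort.ancestry_calls,
            haplotypes=cohort.haplotypes, hap_ancestry=cohort.hap_ancestry,
        )
    paths = c["paths"]
    gs = genotype_io.read_vcf(paths["vcf"])
    pheno = genotype_io.read_phenotypes(paths["phenotypes"])
    anc = None
    if paths.get("ancestry"):
        wide = genotype_io.read_ancestry(paths["ancestry"])
        wide = wide.reindex(index=gs.ids, columns=gs.site_ids())
        anc = wide.to_numpy()
    return CohortData(genotypes=gs, phenotypes=pheno, ancestry_calls=anc)


def _design_matrix(pheno: pd.DataFrame, pcs: np.ndarray) -> np.ndarray:
    cols = [pheno["age"].to_numpy(dtype=float), pheno["sex"].to_numpy(dtype=float)]
    study = pheno["study"].astype(str).to_numpy()
    levels = np.unique(study)
    for lev in levels[1:]:
        cols.append((study == lev).astype(float))
    X = np.column_stack(cols)
    if pcs.size:
        X = np.column_stack([X, pcs])
    return X


def residualize_cohort(
    data: CohortData,
    filter_cfg: SiteFilterConfig | None = None,
    n_pcs: int = 1,
):
    """QC filter, build GRM + PCs, fit the LMM, and return aligned residuals.

    Returns ``(filtered GenotypeSet, residuals, filter log, LmmFit, kept
    individual mask)``; residuals align with the filtered set's individuals.
    """
    gs, log = genotype_io.apply_filters(data.genotypes, filter_cfg)
    if gs.n_sites == 0 or gs.n_individuals == 0:
        raise RuntimeError("no data left after QC filters")
    pheno = data.phenotypes.set_index("id").loc[list(gs.ids)].reset_index()

    grm = residualize.compute_grm(gs)
    pcs = residualize.top_pcs(grm, n_pcs) if n_pcs > 0 else np.empty((gs.n_individuals, 0))
    X = _design_matrix(pheno, pcs)
    y = pheno["trait"].to_numpy(dtype=float)

    ok = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    gs2 = gs.take_individuals(ok)
    grm2 = residualize.GRM(grm.matrix[np.ix_(ok, ok)], grm.n_markers)
    fit = residualize.fit_lmm(y[ok], X[ok], grm2)
    logger.info(
        "residualized %d individuals (h2=%.3f) over %d GRM markers",
        ok.sum(), fit.heritability, grm.n_markers,
    )
    return gs2, fit.residuals, log, fit, ok


def _header(config: PipelineConfig) -> str:
    return f"# vqtlscan config_hash={config.hash()} seed={config.seed}\n"


def _write_tsv(df: pd.DataFrame, path: Path, config: PipelineConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_header(config))
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def run_discovery(config: PipelineConfig, out_dir) -> dict:
    """Discovery pass: filters -> GRM -> PCs -> LMM residuals -> scan -> loci."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data = load_cohort(config)
    try:
        gs, resid, flog, fit, _ = residualize_cohort(
            data, SiteFilterConfig(**config.filters), config.n_pcs
        )
        scanner = scan_mod.VqtlScanner(**config.scan).fit(gs, resid)
    except Exception as e:
        raise RuntimeError(f"discovery stage failed: {e}") from e
    results = scanner.results_
    loci = scanner.loci()

    _write_tsv(results, out / "scan.tsv", config)
    loci_df = pd.DataFrame([
        {"lead": lo.lead, "chrom": lo.chrom, "span_start": lo.span[0],
         "span_end": lo.span[1], "n_markers": lo.n_markers,
         "members": ",".join(lo.members)}
        for lo in loci
    ], columns=["lead", "chrom", "span_start", "span_end", "n_markers", "members"])
    _write_tsv(loci_df, out / "loci.tsv", config)
    manhattan = pd.DataFrame({
        "pos_index": np.arange(len(results)),
        "neg_log10_p": -np.log10(results["fk_p"].clip(lower=np.finfo(float).tiny)),
    })
    _write_tsv(manhattan, out / "manhattan.tsv", config)
    flog.to_tsv(out / "filter_log.tsv")
    return {"results": results, "loci": loci, "lmm": fit, "genotypes": gs,
            "residuals": resid, "data": data}


def run_replication(
    config: PipelineConfig, discovery_loci: list, out_dir
) -> pd.DataFrame:
    """Replication pass restricted to the discovery loci's markers."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    wanted = {sid for lo in discovery_loci for sid in lo.members}
    if not wanted:
        report = pd.DataFrame(columns=[
            "locus_lead", "site_id", "chrom", "matched", "replication_p",
            "replicated", "locus_replicated",
        ])
        _write_tsv(report, out / "replication.tsv", config)
        return report

    data = load_cohort(config)
    gs, resid, _, _, _ = residualize_cohort(
        data, SiteFilterConfig(**config.filters), config.n_pcs
    )
    keep = np.isin(gs.site_ids(), sorted(wanted))
    if not keep.any():
        raise RuntimeError("no discovery markers present in the replication cohort")
    sub = gs.take_sites(np.nonzero(keep)[0])
    results = scan_mod.vqtl_scan(
        sub, resid, min_class_count=config.scan.get("min_class_count", 2)
    )
    report = scan_mod.replicate(discovery_loci, results, config.alpha_rep)
    _write_tsv(report, out / "replication.tsv", config)
    return report


_DEFAULT_PROBES = {
    "hwe": True, "haplotype": True, "ancestry": True, "gxg": True,
    "gxe": True, "categorical": True, "fst": True, "parental": True,
}


def _background_freqs(data: CohortData, site_index: int) -> tuple[float, float] | None:
    """Alt-allele frequency in each ancestral background from ancestry-labelled
    haplotypes (simulator truth or supplied calls)."""
    if data.haplotypes is None or data.hap_ancestry is None:
        return None
    alleles = data.haplotypes[:, :, site_index].reshape(-1)
    states = data.hap_ancestry[:, :, site_index].reshape(-1)
    in_a, in_b = states == 0, states == 1
    if not in_a.any() or not in_b.any():
        return None
    return float(alleles[in_a].mean()), float(alleles[in_b].mean())


def run_explain(
    config: PipelineConfig, loci: list, out_dir, min_class_count: int = 2
) -> list[dict]:
    """Run the enabled mechanism probes on each locus and serialize reports.

    Probe failures are logged and recorded in the report; the remaining
    probes still run.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    probes = {**_DEFAULT_PROBES, **config.probes}
    reports: list[dict] = []
    flat_rows: list[dict] = []
    if not loci:
        _write_tsv(pd.DataFrame(columns=["locus", "probe", "quantity", "value"]),
                   out / "mechanisms.tsv", config)
        return reports

    data = load_cohort(config)
    gs, resid, _, _, kept = residualize_cohort(
        data, SiteFilterConfig(**config.filters), config.n_pcs
    )
    site_index = {sid: j for j, sid in enumerate(gs.site_ids())}
    anc = data.ancestry_calls[kept] if data.ancestry_calls is not None else None
    haps = data.haplotypes[kept] if data.haplotypes is not None else None
    hap_anc = data.hap_ancestry[kept] if data.hap_ancestry is not None else None
    pheno = data.phenotypes.set_index("id").loc[list(gs.ids)].reset_index()
    sub = CohortData(gs, pheno, anc, haps, hap_anc)

    lead_info = {}
    for locus in loci:
        j = site_index.get(locus.lead)
        if j is None:
            logger.warning("locus lead %s absent post-QC; skipped", locus.lead)
            continue
        g = most_probable_genotype(gs.dosages[:, j])
        from .fk import drop_sparse_classes, fligner_killeen
        v, grp, _ = drop_sparse_classes(resid, g, min_class_count)
        fk = fligner_killeen(v, grp)
        r2 = (scan_mod.p_to_r2adj(max(fk.p, np.finfo(float).tiny), v.size).r2_adj
              if fk.defined else np.nan)
        lead_info[locus.lead] = (j, g, r2)

    for locus in loci:
        if locus.lead not in lead_info:
            continue
        j, g_lead, r2_lead = lead_info[locus.lead]
        report: dict = {"locus": locus.lead, "chrom": locus.chrom,
                        "members": list(locus.members), "probes": {}}

        def record(probe: str, payload):
            report["probes"][probe] = payload
            if isinstance(payload, dict):
                for k, v in payload.items():
                    if isinstance(v, (int, float, np.floating)):
                        flat_rows.append({"locus": locus.lead, "probe": probe,
                                          "quantity": k, "value": float(v)})
            elif isinstance(payload, (int, float, np.floating)):
                flat_rows.append({"locus": locus.lead, "probe": probe,
                                  "quantity": "p", "value": float(payload)})

        def run_probe(name, fn):
            if not probes.get(name, True):
                return
            try:
                record(name, fn())
            except Exception as e:  # probe failures must not kill the stage
                logger.warning("probe %s failed at %s: %s", name, locus.lead, e)
                report["probes"][name] = {"error": str(e)}

        def _hwe():
            out = {}
            for sid in locus.members:
                jj = site_index.get(sid)
                if jj is None:
                    continue
                gm = most_probable_genotype(gs.dosages[:, jj])
                gm = gm[np.isfinite(gm)]
                out[sid] = mech.hwe_exact(
                    int((gm == 0).sum()), int((gm == 1).sum()), int((gm == 2).sum())
                )
            return out

        run_probe("hwe", _hwe)

        if sub.haplotypes is not None:
            def _hap():
                cols = [site_index[s] for s in locus.members if s in site_index]
                res = mech.haplotype_variance_tests(
                    sub.haplotypes[:, :, cols], resid,
                    min_class_count=min_class_count,
                )
                return {"two_group_p": res.two_group.p,
                        "all_group_p": res.all_group.p,
                        "difference_p": res.difference_p}
            run_probe("haplotype", _hap)

        if anc is not None:
            def _anc():
                res = mech.ancestry_probes(
                    resid, anc[:, j], g_lead, min_class_count
                )
                return {"ancestry_fk_p": res.ancestry_fk.p,
                        "stratified_fk_p": res.stratified_fk.p,
                        "signal_fraction_raw": res.signal_fraction_raw,
                        "signal_fraction": res.signal_fraction}
            run_probe("ancestry", _anc)

            def _parental():
                _, p = mech.parental_ancestry_check(resid, anc)
                return {"wilcoxon_p": p}
            if anc.shape[1] >= 100:
                run_probe("parental", _parental)

        def _gxg():
            out = {}
            for other in loci:
                if other.lead == locus.lead or other.lead not in lead_info:
                    continue
                j2, g2, r2_2 = lead_info[other.lead]
                res = mech.interaction_test(resid, g_lead, g2, r2_lead, r2_2)
                out[other.lead] = {
                    "beta_interaction": res.beta_interaction,
                    "p_interaction": res.p_interaction,
                    "signal_fraction_here": res.signal_fraction_g1,
                    "signal_fraction_there": res.signal_fraction_x2,
                }
            return {f"{k}:{q}": v for k, d in out.items() for q, v in d.items()}

        if len(lead_info) > 1:
            run_probe("gxg", _gxg)

        def _gxe():
            res = mech.interaction_test(
                resid, g_lead, pheno["E"].to_numpy(dtype=float), r2adj_g1=r2_lead
            )
            return {"beta_main_p": res.p_main,
                    "beta_interaction": res.beta_interaction,
                    "p_interaction": res.p_interaction,
                    "signal_fraction": res.signal_fraction_g1}

        if "E" in pheno.columns:
            run_probe("gxe", _gxe)

        def _categorical():
            return {
                "gene_x_sex_p": mech.categorical_interaction_test(
                    resid, g_lead, pheno["sex"].to_numpy()),
                "gene_x_study_p": mech.categorical_interaction_test(
                    resid, g_lead, pheno["study"].to_numpy()),
            }

        run_probe("categorical", _categorical)

        def _fst():
            out = {}
            for sid in locus.members:
                jj = site_index.get(sid)
                if jj is None:
                    continue
                freqs = _background_freqs(sub, jj)
                if freqs is not None:
                    out[sid] = mech.fst_hudson(freqs[0], freqs[1])
            return out

        run_probe("fst", _fst)

        reports.append(report)
        safe = locus.lead.replace(":", "_")
        with open(out / f"mechanisms_{safe}.yaml", "w") as fh:
            fh.write(_header(config))
            yaml.safe_dump(_to_plain(report), fh, sort_keys=True)

    _write_tsv(pd.DataFrame(flat_rows, columns=["locus", "probe", "quantity", "value"]),
               out / "mechanisms.tsv", config)
    return reports


def _to_plain(obj):
    if isinstance(obj, dict):
        return {str(k): _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def run_validate_fk(specs: list[SimSpec], out_path, config: PipelineConfig | None = None) -> pd.DataFrame:
    """Run the size/power simulation study and write its TSV summary."""
    rows = [validate_test(s) for s in specs]
    df = pd.DataFrame(rows)
    with open(out_path, "w") as fh:
        if config is not None:
            fh.write(_header(config))
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")
    return df
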