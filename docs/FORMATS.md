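# File formats

All pipeline outputs are TSV or YAML. Every file written by a pipeline stage
begins with a header comment line:

```
# vqtlscan config_hash=<12-hex-digit sha256 prefix of the config> seed=<int>
```

## Inputs

### Genotype VCF
VCF 4.2, biallelic records only (split multi-allelics upstream).
- `FORMAT/DS` — alt-allele dosage in [0, 2]; preferred when present.
- `FORMAT/GT` — fallback; dosage = alt-allele count, missing alleles → NaN.
- `INFO/R2` — imputation quality; absent ⇒ 1.0 (genotyped).

### Phenotype/covariate TSV
Columns (tab-separated, header required): `id`, `trait`, `age`, `sex`
(0/1), `study` (string label), `E` (continuous exposure). Extra columns are
carried but unused.

### Local-ancestry TSV (long format)
Columns: `id`, `marker` (site id `chrom:pos:ref:alt`), `n_copies_B`
(0/1/2 chromosomes from the minority ancestral background).

### Truth YAML (simulator output)
Keys: `seed`, `noise_sd`, `n_individuals`, `n_markers`, `admixture_mean`,
`sib_pairs` (list of index pairs), `mechanisms` (list with `kind`,
`target_marker`, `partner`, `beta_main`, `beta_interaction`,
`ancestry_sd_ratio`).

## Outputs

### scan.tsv — one row per scanned marker
`site_id  chrom  pos  ref  alt  maf  n0  n1  n2  fk_stat  fk_df  fk_p
additive_p  hwe_p  r2_adj  n_used`
- `n0/n1/n2` — most-probable-genotype class counts (before sparse-class
  dropping).
- `fk_*` — Fligner–Killeen statistic / df / p on the retained classes.
- `additive_p` — OLS slope test of residual on dosage.
- `r2_adj` — adjusted variance explained implied by `fk_p` at `n_used`.

### loci.tsv — one row per clumped locus
`lead  chrom  span_start  span_end  n_markers  members` (members
comma-separated site ids). The CLI additionally writes `loci.pkl`, the
pickled `Locus` list consumed by `replicate`/`explain`.

### manhattan.tsv
`pos_index  neg_log10_p` — plot-ready two-column summary in scan order.

### filter_log.tsv
`site_id  reason` — one row per removed site; reasons:
`marker_call_rate`, `monomorphic`, `strand_ambiguous`, `imputation_rsq`,
`maf`, `hwe`.

### replication.tsv — one row per discovery-locus member marker
`locus_lead  site_id  chrom  matched  replication_p  replicated
locus_replicated`

### mechanisms.tsv / mechanisms_<locus>.yaml
Flat TSV: `locus  probe  quantity  value` (one row per numeric probe
output). The YAML per locus holds the full nested report: probes `hwe`
(p per member marker), `haplotype` (`two_group_p`, `all_group_p`,
`difference_p`), `ancestry` (`ancestry_fk_p`, `stratified_fk_p`,
`signal_fraction_raw`, `signal_fraction`), `parental` (`wilcoxon_p`),
`gxg` (per partner lead: `beta_interaction`, `p_interaction`, signal
fractions both sides), `gxe` (`beta_main_p`, `beta_interaction`,
`p_interaction`, `signal_fraction`), `categorical` (`gene_x_sex_p`,
`gene_x_study_p`), `fst` (per member marker).

### validate-fk TSV
`dist_a  dist_b  n_per_group  n_reps  alpha  rejection_rate  skew_a  kurt_a
skew_b  kurt_b` — one row per simulation spec.

## Pipeline config YAML

```yaml
seed: 1
cohort:
  # exactly one of:
  simulate: {n_individuals: 5000, n_markers: 500, admixture_mean: 0.8,
             n_sib_pairs: 100}
  mechanisms: [{kind: gxe, target_marker: 10, beta_interaction: 0.4}]
  noise_sd: 1.0
  # paths: {vcf: g.vcf, phenotypes: p.tsv, ancestry: a.tsv}
filters: {min_maf: 0.005, min_rsq: 0.3}     # SiteFilterConfig fields
n_pcs: 1                                     # 1 discovery-like, 2 replication-like
scan: {min_class_count: 2, p_threshold: 5.0e-8, window_bp: 1000000,
       ld_r2_min: 0.2}
alpha_rep: 0.05
probes: {hwe: true, haplotype: true, ancestry: true, gxg: true, gxe: true,
         categorical: true, fst: true, parental: true}
```
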