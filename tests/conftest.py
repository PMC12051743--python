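import numpy as np
import pandas as pd
import pytest

from vqtlscan import CohortConfig, GenotypeSet, inject_phenotype, simulate_cohort


def make_genotype_set(dosages, chrom="1", pos=None, ref="A", alt="G", rsq=1.0,
                      ids=None):
    """Build a GenotypeSet from a raw (individuals x sites) dosage array."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    if ids is None:
        ids = np.array([f"i{k}" for k in range(n)], dtype=object)
    if pos is None:
        pos = np.arange(1, m + 1) * 1000
    def _col(v):
        return list(v) if isinstance(v, (list, tuple, np.ndarray)) else [v] * m
    sites = pd.DataFrame({
        "chrom": _col(chrom), "pos": pos, "ref": _col(ref),
        "alt": _col(alt), "rsq": _col(rsq),
    })
    return GenotypeSet(np.asarray(ids, dtype=object), sites, dosages)


@pytest.fixture(scope="session")
def small_cohort():
    """A modest admixed cohort with sib pairs and no phenotype mechanisms."""
    cfg = CohortConfig(n_individuals=400, n_markers=60, n_sib_pairs=20, seed=11)
    cohort = simulate_cohort(cfg)
    return inject_phenotype(cohort, [], noise_sd=1.0, seed=12)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2026)
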