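import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

from sirefert import GenotypeMatrix, SimConfig, simulate_population

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_genotypes(dosage, chrom=None, pos=None, counted="A", other="B", ids=None):
    """Build a GenotypeMatrix from a plain dosage array."""
    dosage = np.asarray(dosage, dtype=float)
    n, p = dosage.shape
    snps = pd.DataFrame(
        {
            "chrom": chrom if chrom is not None else ["1"] * p,
            "pos": pos if pos is not None else np.arange(1, p + 1) * 1000,
            "counted_allele": counted if not isinstance(counted, str) else [counted] * p,
            "other_allele": other if not isinstance(other, str) else [other] * p,
        },
        index=pd.Index([f"snp{j + 1}" for j in range(p)], name="snp_id"),
    )
    if ids is None:
        ids = [f"ind{i + 1}" for i in range(n)]
    return GenotypeMatrix(dosage=dosage, individual_ids=ids, snps=snps)


def polygenic_config(**kwargs) -> SimConfig:
    """SimConfig with no major loci, overridable."""
    base = dict(n_major_loci=0, major_recessive_allele_freqs=[], major_effect_sizes=[])
    base.update(kwargs)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def small_population():
    """Cohort with the full generative structure: polygenic + 2 recessive loci."""
    return simulate_population(SimConfig(n_individuals=200, n_snps=400, seed=42))


@pytest.fixture(scope="session")
def polygenic_population():
    """Pure polygenic cohort (no major loci) for model-fitting tests."""
    return simulate_population(
        polygenic_config(n_individuals=120, n_snps=500, seed=7)
    )
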