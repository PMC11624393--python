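"""Synthetic sire-fertility populations for testing the prediction pipeline.

The generator emulates the statistical structure the analysis assumes for a
progeny-tested dairy-bull cohort: HD SNP genotypes in Hardy–Weinberg
proportions, a polygenic additive background acting through standardized
dosages, a small number of large-effect *purely recessive* loci, and a
conception-rate phenotype expressed as a percent deviation from a zero
population mean whose residual precision is driven by the number of
breedings behind each record (reliability r = n / (n + k)).

Defaults mirror a Brown Swiss service-sire cohort: 1,102 bulls, 29
autosomes, breedings between 50 and 8,110, and two recessive subfertility
loci with recessive-allele frequencies 0.29 and 0.31.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

__all__ = [
    "SimConfig",
    "SimulatedPopulation",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_population",
]


@dataclass
class SimConfig:
    """Configuration of the synthetic population.

    Parameters
    ----------
    n_individuals, n_snps, n_chromosomes : int
        Cohort and panel dimensions; SNPs are assigned round-robin to
        chromosomes with increasing positions.
    maf_range : (float, float)
        Counted-allele frequencies are drawn uniformly on this interval
        (each endpoint in (0, 0.5]); genotypes are Binomial(2, p) per SNP.
    heritability : float
        Narrow-sense h² of the polygenic background, in [0, 1]; splits
        ``phenotypic_var`` into genetic and residual components.
    phenotypic_var : float
        Baseline phenotypic variance (percentage points squared) at
        reliability 1; default 25 makes cohort-scale phenotypes span
        roughly −22 to +10.
    n_major_loci : int
        Number of planted large-effect recessive loci.
    major_recessive_allele_freqs, major_effect_sizes : list of float
        Per-locus recessive-allele frequency and phenotype deviation added
        to recessive homozygotes only (negative = subfertility).
    breedings_range : (int, int)
        Per-record breedings drawn uniformly (inclusive) on this range.
    reliability_shape : float
        k in the reliability mapping r = n_breedings / (n_breedings + k).
    missing_rate : float
        Fraction of genotype calls masked as missing.
    seed : int
        Seed for all randomness in the generator.
    """

    n_individuals: int = 1102
    n_snps: int = 5000
    n_chromosomes: int = 29
    maf_range: tuple[float, float] = (0.05, 0.5)
    heritability: float = 0.35
    phenotypic_var: float = 25.0
    n_major_loci: int = 2
    major_recessive_allele_freqs: list[float] = field(default_factory=lambda: [0.29, 0.31])
    major_effect_sizes: list[float] = field(default_factory=lambda: [-8.0, -8.0])
    breedings_range: tuple[int, int] = (50, 8110)
    reliability_shape: float = 200.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1 or self.n_snps < 1 or self.n_chromosomes < 1:
            raise ValueError("population dimensions must be positive")
        if self.n_snps < self.n_major_loci:
            raise ValueError(
                f"n_snps={self.n_snps} cannot hold {self.n_major_loci} major loci"
            )
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range endpoints must satisfy 0 < lo <= hi <= 0.5")
        if not 0.0 <= self.heritability <= 1.0:
            raise ValueError("heritability must lie in [0, 1]")
        if self.phenotypic_var <= 0:
            raise ValueError("phenotypic_var must be positive")
        if len(self.major_recessive_allele_freqs) != self.n_major_loci:
            raise ValueError(
                "major_recessive_allele_freqs length must equal n_major_loci"
            )
        if len(self.major_effect_sizes) != self.n_major_loci:
            raise ValueError("major_effect_sizes length must equal n_major_loci")
        if any(not (0.0 < f <= 0.5) for f in self.major_recessive_allele_freqs):
            raise ValueError("recessive allele frequencies must lie in (0, 0.5]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.reliability_shape <= 0:
            raise ValueError("reliability_shape must be positive")
        if self.breedings_range[0] < 1 or self.breedings_range[0] > self.breedings_range[1]:
            raise ValueError("breedings_range must be an increasing pair of positive ints")

    @property
    def sigma_g2(self) -> float:
        """Polygenic variance implied by heritability."""
        return self.heritability * self.phenotypic_var

    @property
    def sigma_e2(self) -> float:
        """Baseline residual variance (at reliability 1)."""
        return (1.0 - self.heritability) * self.phenotypic_var

    def major_locus_ids(self) -> list[str]:
        """SNP ids of the planted major loci (evenly spaced across the panel)."""
        return [f"snp{j + 1}" for j in self._major_indices()]

    def _major_indices(self) -> np.ndarray:
        if self.n_major_loci == 0:
            return np.array([], dtype=int)
        return np.unique(
            np.linspace(0, self.n_snps - 1, self.n_major_loci + 2)[1:-1].astype(int)
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["maf_range"] = list(self.maf_range)
        d["breedings_range"] = list(self.breedings_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        for key in ("maf_range", "breedings_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SimulatedPopulation:
    """Genotypes, phenotypes, and the generating truth of one simulation."""

    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame
    true_polygenic_values: np.ndarray
    true_major_indicator: np.ndarray
    true_variance_components: tuple[float, float]
    major_locus_ids: list[str]
    config: SimConfig

    def truth_table(self) -> pd.DataFrame:
        """Per-individual generating truth, for use as a test oracle."""
        cols = {
            "id": self.genotypes.individual_ids,
            "polygenic_value": self.true_polygenic_values,
        }
        for j, sid in enumerate(self.major_locus_ids):
            cols[f"homozygous_{sid}"] = self.true_major_indicator[:, j].astype(int)
        return pd.DataFrame(cols)


def _rngs(config: SimConfig) -> tuple[np.random.Generator, np.random.Generator]:
    ss = np.random.SeedSequence(config.seed)
    child_g, child_p = ss.spawn(2)
    return np.random.default_rng(child_g), np.random.default_rng(child_p)


def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Draw SNP dosages under Hardy–Weinberg equilibrium.

    Per SNP the counted-allele frequency is uniform on ``maf_range`` and
    dosages are Binomial(2, p).  Planted major loci get their configured
    recessive-allele frequency as the counted-allele frequency, so their
    counted allele *is* the recessive (minor) allele.  SNPs go round-robin
    onto chromosomes with increasing positions; calls are masked missing at
    ``missing_rate``.  Fully reproducible from ``config.seed``.
    """
    rng, _ = _rngs(config)
    n, p = config.n_individuals, config.n_snps

    freqs = rng.uniform(config.maf_range[0], config.maf_range[1], size=p)
    major_idx = config._major_indices()
    freqs[major_idx] = np.asarray(config.major_recessive_allele_freqs, dtype=float)[
        : len(major_idx)
    ]

    dosage = rng.binomial(2, freqs, size=(n, p)).astype(float)
    if config.missing_rate > 0:
        mask = rng.random((n, p)) < config.missing_rate
        dosage[mask] = np.nan

    snp_ids = pd.Index([f"snp{j + 1}" for j in range(p)], name="snp_id")
    chrom = np.array([str(j % config.n_chromosomes + 1) for j in range(p)])
    pos = np.array([10_000 * (j // config.n_chromosomes + 1) for j in range(p)])
    snps = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "counted_allele": "A",
            "other_allele": "B",
        },
        index=snp_ids,
    )
    ids = [f"bull{i + 1}" for i in range(n)]
    return GenotypeMatrix(dosage=dosage, individual_ids=ids, snps=snps)


def simulate_phenotypes(
    genotypes: GenotypeMatrix, config: SimConfig
) -> SimulatedPopulation:
    """Layer a phenotype over simulated genotypes.

    The polygenic value is u = S β with β i.i.d. normal over centered,
    standardized dosages, rescaled so the realized var(u) equals σg².
    Recessive homozygotes at each major locus receive that locus's effect;
    carriers and non-carriers receive exactly nothing.  Residuals are
    heteroscedastic, e_i ~ N(0, σe² / r_i) with r_i = n_i / (n_i + k) and
    n_i the record's breedings.  The finished phenotype is centered to a
    zero population mean, the scale on which conception-rate deviations
    are expressed.
    """
    _, rng = _rngs(config)
    n = genotypes.n_individuals
    dosage = genotypes.dosage

    with np.errstate(invalid="ignore"):
        freq = np.nanmean(dosage, axis=0) / 2.0
    freq = np.clip(freq, 1e-12, 1 - 1e-12)
    center = 2.0 * freq
    scale = np.sqrt(2.0 * freq * (1.0 - freq))
    filled = np.where(np.isnan(dosage), center, dosage)
    S = (filled - center) / scale

    sigma_g2, sigma_e2 = config.sigma_g2, config.sigma_e2

    beta = rng.standard_normal(genotypes.n_snps)
    u = S @ beta
    if sigma_g2 > 0 and n > 1 and u.std() > 0:
        u *= np.sqrt(sigma_g2) / u.std()
    else:
        u = np.zeros(n)

    major_ids = config.major_locus_ids()
    major_cols = genotypes.snps.index.get_indexer(major_ids)
    if (major_cols < 0).any():
        raise ValueError("major locus ids missing from the genotype matrix")
    indicator = np.zeros((n, len(major_ids)))
    for j, col in enumerate(major_cols):
        d = dosage[:, col]
        indicator[:, j] = (d == 2.0).astype(float)  # missing -> not homozygous
    major_term = indicator @ np.asarray(config.major_effect_sizes, dtype=float)

    breedings = rng.integers(
        config.breedings_range[0], config.breedings_range[1] + 1, size=n
    )
    reliability = breedings / (breedings + config.reliability_shape)
    e = rng.standard_normal(n) * np.sqrt(sigma_e2 / reliability)

    y = u + major_term + e
    y = y - y.mean()  # deviations from a zero population mean

    phenotypes = pd.DataFrame(
        {
            "id": genotypes.individual_ids,
            "scr": y,
            "n_breedings": breedings,
            "reliability": reliability,
        }
    )
    return SimulatedPopulation(
        genotypes=genotypes,
        phenotypes=phenotypes,
        true_polygenic_values=u,
        true_major_indicator=indicator,
        true_variance_components=(sigma_g2, sigma_e2),
        major_locus_ids=major_ids,
        config=config,
    )


def simulate_population(config: SimConfig) -> SimulatedPopulation:
    """Genotypes and phenotypes in one call."""
    return simulate_phenotypes(simulate_genotypes(config), config)
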