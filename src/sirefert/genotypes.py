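"""SNP genotype container, quality control, and the linear (GBLUP) kernel.

The central objects are :class:`GenotypeMatrix` — an individuals × SNPs
allele-dosage matrix with per-SNP metadata — and the pipeline

    qc_filter  →  standardize  →  build_linear_kernel

that turns raw dosages into the genomic relationship matrix
``K = S S' / p`` of VanRaden type, where ``S`` holds centered and
standardized dosages.  ``code_recessive`` produces the 0/1 design columns
used to fit large-effect recessive loci as fixed covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "QCReport",
    "StandardizedGenotypes",
    "LinearKernel",
    "EmptyAfterQCError",
    "qc_filter",
    "allele_frequencies",
    "standardize",
    "build_linear_kernel",
    "code_recessive",
]


class EmptyAfterQCError(ValueError):
    """All SNPs or all individuals were removed by quality control."""


@dataclass
class GenotypeMatrix:
    """Allele-dosage matrix (individuals × SNPs) with SNP metadata.

    Parameters
    ----------
    dosage : ndarray, shape (n, p), float
        Count of the *counted* allele per genotype, in {0, 1, 2}; missing
        calls are ``NaN``.
    individual_ids : sequence of str
        Unique identifiers, one per row.
    snps : pandas.DataFrame
        Indexed by SNP id, with columns ``chrom`` (str), ``pos`` (int,
        1-based), ``counted_allele`` and ``other_allele`` (str).
    """

    dosage: np.ndarray
    individual_ids: pd.Index
    snps: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        self.individual_ids = pd.Index(self.individual_ids, dtype=str)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be 2-dimensional (individuals x SNPs)")
        n, p = self.dosage.shape
        if len(self.individual_ids) != n:
            raise ValueError(
                f"{len(self.individual_ids)} individual ids for {n} dosage rows"
            )
        if len(self.snps) != p:
            raise ValueError(f"{len(self.snps)} SNP records for {p} dosage columns")
        if self.individual_ids.has_duplicates:
            raise ValueError("duplicate individual identifiers")
        if self.snps.index.has_duplicates:
            raise ValueError("duplicate SNP identifiers")
        ok = np.isnan(self.dosage) | np.isin(self.dosage, (0.0, 1.0, 2.0))
        if not ok.all():
            bad = np.argwhere(~ok)[0]
            raise ValueError(
                f"dosage entries must be 0, 1, 2 or missing; found "
                f"{self.dosage[bad[0], bad[1]]!r} at row {bad[0]}, column {bad[1]}"
            )

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    @property
    def snp_ids(self) -> pd.Index:
        return self.snps.index

    def subset(self, individuals=None, snps=None) -> "GenotypeMatrix":
        """Return a copy restricted to the given individual / SNP ids."""
        rows = slice(None) if individuals is None else self.individual_ids.get_indexer(individuals)
        cols = slice(None) if snps is None else self.snps.index.get_indexer(snps)
        if individuals is not None and (np.asarray(rows) < 0).any():
            missing = [i for i, r in zip(individuals, rows) if r < 0]
            raise KeyError(f"unknown individual ids: {missing}")
        if snps is not None and (np.asarray(cols) < 0).any():
            missing = [s for s, c in zip(snps, cols) if c < 0]
            raise KeyError(f"unknown SNP ids: {missing}")
        return GenotypeMatrix(
            dosage=self.dosage[rows][:, cols].copy(),
            individual_ids=self.individual_ids[rows],
            snps=self.snps.iloc[cols].copy() if snps is not None else self.snps.copy(),
        )


@dataclass
class QCReport:
    """Record of every removal made by :func:`qc_filter`, with reasons."""

    n_individuals_in: int
    n_individuals_out: int
    n_snps_in: int
    n_snps_out: int
    removed_individual_callrate: list = field(default_factory=list)
    removed_monomorphic: list = field(default_factory=list)
    removed_maf: list = field(default_factory=list)
    removed_snp_callrate: list = field(default_factory=list)
    thresholds: dict = field(default_factory=dict)

    @property
    def n_snps_removed(self) -> int:
        return (
            len(self.removed_monomorphic)
            + len(self.removed_maf)
            + len(self.removed_snp_callrate)
        )

    def to_dict(self) -> dict:
        return {
            "n_individuals_in": self.n_individuals_in,
            "n_individuals_out": self.n_individuals_out,
            "n_snps_in": self.n_snps_in,
            "n_snps_out": self.n_snps_out,
            "removed_individual_callrate": list(self.removed_individual_callrate),
            "removed_monomorphic": list(self.removed_monomorphic),
            "removed_maf": list(self.removed_maf),
            "removed_snp_callrate": list(self.removed_snp_callrate),
            "thresholds": dict(self.thresholds),
        }

    def __str__(self) -> str:  # human-readable QC summary
        lines = [
            "Genotype QC report",
            f"  individuals: {self.n_individuals_in} -> {self.n_individuals_out}"
            f" ({len(self.removed_individual_callrate)} removed, call rate)",
            f"  SNPs:        {self.n_snps_in} -> {self.n_snps_out}",
            f"    monomorphic:     {len(self.removed_monomorphic)}",
            f"    MAF below {self.thresholds.get('maf_min', '?')}:  {len(self.removed_maf)}",
            f"    call rate below {self.thresholds.get('snp_callrate_min', '?')}: "
            f"{len(self.removed_snp_callrate)}",
        ]
        return "\n".join(lines)


@dataclass
class StandardizedGenotypes:
    """Centered, standardized genotype matrix S with the frequencies used."""

    matrix: np.ndarray
    allele_freqs: np.ndarray
    snp_ids: pd.Index
    individual_ids: pd.Index
    imputation_policy: str = "column-mean"


@dataclass
class LinearKernel:
    """Genomic relationship matrix K = S S' / p (symmetric, PSD)."""

    K: np.ndarray
    individual_ids: pd.Index
    p_used: int

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K, dtype=float)
        self.individual_ids = pd.Index(self.individual_ids, dtype=str)

    @property
    def n(self) -> int:
        return self.K.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.K, index=self.individual_ids, columns=self.individual_ids)


def allele_frequencies(g: GenotypeMatrix) -> np.ndarray:
    """Observed counted-allele frequency per SNP among non-missing calls.

    SNPs with no non-missing calls get frequency NaN.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        return np.nanmean(g.dosage, axis=0) / 2.0


def qc_filter(
    g: GenotypeMatrix,
    maf_min: float = 0.01,
    snp_callrate_min: float = 0.99,
    ind_callrate_min: float = 0.95,
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the standard genotype quality-control filters.

    Individuals with call rate below ``ind_callrate_min`` are removed first,
    so that SNP statistics reflect the retained animals.  SNPs are then
    removed, in order and each listed once under its first failing rule, if
    they are monomorphic, have minor allele frequency strictly below
    ``maf_min``, or have call rate below ``snp_callrate_min``.

    Returns the filtered matrix and a :class:`QCReport`.  Raises
    :class:`EmptyAfterQCError` if nothing survives.
    """
    if g.n_snps == 0 or g.n_individuals == 0:
        raise ValueError("empty genotype matrix")

    missing = np.isnan(g.dosage)
    ind_callrate = 1.0 - missing.mean(axis=1)
    keep_ind = ind_callrate >= ind_callrate_min
    removed_ind = list(g.individual_ids[~keep_ind])
    if not keep_ind.any():
        raise EmptyAfterQCError("all individuals removed by call-rate filter")

    dosage = g.dosage[keep_ind]
    missing = missing[keep_ind]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        freq = np.nanmean(dosage, axis=0) / 2.0
    n_called = (~missing).sum(axis=0)
    snp_callrate = n_called / dosage.shape[0]

    monomorphic = np.isnan(freq) | (freq == 0.0) | (freq == 1.0)
    maf = np.minimum(freq, 1.0 - freq)
    low_maf = ~monomorphic & (maf < maf_min)
    low_callrate = ~monomorphic & ~low_maf & (snp_callrate < snp_callrate_min)

    keep_snp = ~(monomorphic | low_maf | low_callrate)
    if not keep_snp.any():
        raise EmptyAfterQCError("all SNPs removed by quality control")

    report = QCReport(
        n_individuals_in=g.n_individuals,
        n_individuals_out=int(keep_ind.sum()),
        n_snps_in=g.n_snps,
        n_snps_out=int(keep_snp.sum()),
        removed_individual_callrate=removed_ind,
        removed_monomorphic=list(g.snp_ids[monomorphic]),
        removed_maf=list(g.snp_ids[low_maf]),
        removed_snp_callrate=list(g.snp_ids[low_callrate]),
        thresholds={
            "maf_min": maf_min,
            "snp_callrate_min": snp_callrate_min,
            "ind_callrate_min": ind_callrate_min,
        },
    )
    out = GenotypeMatrix(
        dosage=dosage[:, keep_snp].copy(),
        individual_ids=g.individual_ids[keep_ind],
        snps=g.snps.loc[keep_snp].copy(),
    )
    return out, report


def standardize(g: GenotypeMatrix) -> StandardizedGenotypes:
    """Center and standardize dosages: s_ij = (g_ij − 2p_j) / √(2p_j(1−p_j)).

    ``p_j`` is the observed counted-allele frequency among non-missing
    calls.  Missing dosages are imputed to the column mean ``2p_j`` first,
    so they standardize to exactly 0.  Monomorphic columns (frequency 0 or
    1) are rejected: run :func:`qc_filter` first.
    """
    freq = allele_frequencies(g)
    mono = np.isnan(freq) | (freq == 0.0) | (freq == 1.0)
    if mono.any():
        bad = g.snp_ids[mono][0]
        raise ValueError(
            f"monomorphic SNP {bad!r} cannot be standardized; apply qc_filter first"
        )
    dosage = g.dosage.copy()
    center = 2.0 * freq
    scale = np.sqrt(2.0 * freq * (1.0 - freq))
    nan_mask = np.isnan(dosage)
    if nan_mask.any():
        dosage[nan_mask] = np.broadcast_to(center, dosage.shape)[nan_mask]
    S = (dosage - center) / scale
    return StandardizedGenotypes(
        matrix=S,
        allele_freqs=freq,
        snp_ids=g.snp_ids,
        individual_ids=g.individual_ids,
    )


def build_linear_kernel(s: StandardizedGenotypes) -> LinearKernel:
    """Linear kernel K = S S' / p, the additive genomic relationship matrix."""
    S = s.matrix
    p = S.shape[1]
    if p < 1:
        raise ValueError("need at least one SNP to build a kernel")
    K = S @ S.T / p
    K = (K + K.T) / 2.0  # enforce exact symmetry against round-off
    return LinearKernel(K=K, individual_ids=s.individual_ids, p_used=p)


def code_recessive(
    g: GenotypeMatrix,
    major_snp_ids,
    recessive_alleles: dict | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Code designated major-effect SNPs as recessive 0/1 indicators.

    Each output column is 1 only for individuals carrying two copies of the
    designated recessive allele of that SNP, 0 otherwise — the coding used
    to fit recessive loci as fixed effects.  By default the recessive
    allele is the minor allele observed in the cohort; ``recessive_alleles``
    maps a SNP id to an allele label to override this.

    Missing genotypes at a major SNP code to 0 with a warning.  Returns the
    (n × len(major_snp_ids)) indicator matrix, columns in input order, and a
    DataFrame (indexed by SNP id) with the recessive allele label and the
    homozygote count per SNP.
    """
    major_snp_ids = list(major_snp_ids)
    recessive_alleles = recessive_alleles or {}
    idx = g.snps.index.get_indexer(major_snp_ids)
    if (idx < 0).any():
        missing = [s for s, i in zip(major_snp_ids, idx) if i < 0]
        raise KeyError(f"major SNP ids not found in genotypes: {missing}")

    freq = allele_frequencies(g)
    n = g.n_individuals
    Z = np.zeros((n, len(major_snp_ids)))
    info = []
    for col, (snp_id, j) in enumerate(zip(major_snp_ids, idx)):
        counted = g.snps["counted_allele"].iloc[j]
        other = g.snps["other_allele"].iloc[j]
        if snp_id in recessive_alleles:
            rec = str(recessive_alleles[snp_id])
            if rec not in (counted, other):
                raise ValueError(
                    f"recessive allele {rec!r} for {snp_id} is neither "
                    f"{counted!r} nor {other!r}"
                )
        else:
            # default: minor allele in this cohort (ties -> counted allele)
            rec = counted if freq[j] <= 0.5 else other
        target = 2.0 if rec == counted else 0.0
        dos = g.dosage[:, j]
        miss = np.isnan(dos)
        if miss.any():
            warnings.warn(
                f"{int(miss.sum())} missing genotype(s) at major SNP {snp_id}; "
                "coded as non-homozygous (0)",
                stacklevel=2,
            )
        ind = (dos == target).astype(float)
        n_hom = int(ind.sum())
        if n_hom == 0:
            warnings.warn(
                f"major SNP {snp_id} has no recessive homozygotes in the cohort; "
                "its fixed effect is inestimable",
                stacklevel=2,
            )
        Z[:, col] = ind
        info.append({"snp_id": snp_id, "recessive_allele": rec, "n_homozygotes": n_hom})
    info_df = pd.DataFrame(info).set_index("snp_id")
    return Z, info_df
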