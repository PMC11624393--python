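"""Repeated k-fold cross-validation of the kernel prediction models.

Compares the whole-genome "Polygenic" model against the
"Polygenic+MajorMarkers" variant, which adds the recessive 0/1 indicators
of designated large-effect SNPs as fixed covariates.  Predictive ability
is scored, per repetition, over the pooled out-of-fold predictions by the
Pearson correlation with the observed records and by the mean squared
error of prediction (MSEP).  Both variants see identical fold assignments
within a repetition, so their comparison is paired.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from .genotypes import GenotypeMatrix, standardize, build_linear_kernel, code_recessive
from .kernel_model import KernelBLUP, McmcConfig, build_design

__all__ = [
    "POLYGENIC",
    "POLYGENIC_MAJORS",
    "FoldAssignment",
    "CVResult",
    "UndefinedCorrelationError",
    "make_folds",
    "pearson",
    "msep",
    "cross_validate",
]

POLYGENIC = "Polygenic"
POLYGENIC_MAJORS = "Polygenic+MajorMarkers"


class UndefinedCorrelationError(ValueError):
    """Pearson correlation requested for a constant vector."""


@dataclass
class FoldAssignment:
    """Balanced random partition of individuals into k folds (1-based)."""

    repetition: int
    fold_of_individual: dict
    k: int
    seed: int

    def test_ids(self, fold: int) -> list:
        return [i for i, f in self.fold_of_individual.items() if f == fold]


@dataclass
class CVResult:
    """Per-repetition predictive correlation and MSEP for one model variant."""

    model_label: str
    correlations: np.ndarray   # one per repetition; NaN if undefined
    mseps: np.ndarray
    k: int
    n_repetitions: int
    fold_details: pd.DataFrame | None = None

    @property
    def mean_correlation(self) -> float:
        return float(np.nanmean(self.correlations))

    @property
    def sd_correlation(self) -> float:
        return float(np.nanstd(self.correlations, ddof=1))

    @property
    def mean_msep(self) -> float:
        return float(np.mean(self.mseps))

    @property
    def sd_msep(self) -> float:
        return float(np.std(self.mseps, ddof=1))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model": self.model_label,
                "repetition": np.arange(1, self.n_repetitions + 1),
                "correlation": self.correlations,
                "msep": self.mseps,
            }
        )


def make_folds(ids, k: int = 5, repetition_seeds=None) -> list[FoldAssignment]:
    """Uniformly random balanced k-fold partitions, one per repetition seed."""
    ids = list(ids)
    if k > len(ids):
        raise ValueError(f"k={k} exceeds the number of individuals ({len(ids)})")
    if k < 2:
        raise ValueError("k must be at least 2")
    if repetition_seeds is None:
        repetition_seeds = [0]
    assignments = []
    for rep, seed in enumerate(repetition_seeds, start=1):
        kf = KFold(n_splits=k, shuffle=True, random_state=int(seed) % (2**31))
        fold_of = {}
        for fold_idx, (_, test_idx) in enumerate(kf.split(ids), start=1):
            for i in test_idx:
                fold_of[ids[i]] = fold_idx
        assignments.append(
            FoldAssignment(repetition=rep, fold_of_individual=fold_of, k=k, seed=int(seed))
        )
    return assignments


def pearson(obs, pred) -> float:
    """Pearson product-moment correlation between observed and predicted."""
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("obs and pred must have equal length")
    if len(obs) < 3:
        raise ValueError("need at least 3 pairs for a correlation")
    if np.ptp(obs) == 0 or np.ptp(pred) == 0:
        raise UndefinedCorrelationError(
            "correlation is undefined for a constant vector"
        )
    o = obs - obs.mean()
    p = pred - pred.mean()
    return float(o @ p / np.sqrt((o @ o) * (p @ p)))


def msep(obs, pred) -> float:
    """Mean squared error of prediction."""
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("obs and pred must have equal length")
    if len(obs) == 0:
        raise ValueError("need at least one pair")
    return float(np.mean((obs - pred) ** 2))


def _weighted_pearson(obs, pred, w):
    w = w / w.sum()
    om, pm = w @ obs, w @ pred
    o, p = obs - om, pred - pm
    return float((w * o) @ p / np.sqrt(((w * o) @ o) * ((w * p) @ p)))


def cross_validate(
    genotypes: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    major_snp_ids=None,
    variants=(POLYGENIC, POLYGENIC_MAJORS),
    k: int = 5,
    repetitions: int = 10,
    seed: int = 0,
    mcmc: McmcConfig | None = None,
    exclude_majors_from_kernel: bool = False,
    weighted_metrics: bool = False,
) -> dict[str, CVResult]:
    """Repeated k-fold cross-validation of the requested model variants.

    ``genotypes`` must already have passed QC (no monomorphic SNPs).  The
    kernel is built once from all individuals; per fold, test phenotypes
    are masked out of the likelihood and predicted through the kernel.
    If a training fold carries no recessive homozygote for a major SNP,
    that indicator column is dropped for the fold with a warning.

    Returns ``{model_label: CVResult}``.
    """
    if mcmc is None:
        mcmc = McmcConfig()
    pheno = phenotypes.set_index("id").loc[genotypes.individual_ids]
    y = pheno["scr"].to_numpy(dtype=float)
    w = pheno["reliability"].to_numpy(dtype=float)
    ids = list(genotypes.individual_ids)
    n = len(ids)

    major_snp_ids = list(major_snp_ids or [])
    if POLYGENIC_MAJORS in variants and not major_snp_ids:
        raise ValueError(f"{POLYGENIC_MAJORS!r} variant requires major_snp_ids")

    kernel_g = genotypes
    if exclude_majors_from_kernel and major_snp_ids:
        keep = [s for s in genotypes.snp_ids if s not in set(major_snp_ids)]
        kernel_g = genotypes.subset(snps=keep)
    kernel = build_linear_kernel(standardize(kernel_g))

    Z = None
    if major_snp_ids:
        Z, _ = code_recessive(genotypes, major_snp_ids)

    ss = np.random.SeedSequence(seed)
    rep_seeds = [int(s) % (2**31) for s in ss.generate_state(repetitions)]
    folds = make_folds(ids, k=k, repetition_seeds=rep_seeds)
    fit_seed_pool = iter(
        int(s) % (2**31)
        for s in np.random.SeedSequence((seed, 1)).generate_state(
            repetitions * k * len(variants)
        )
    )

    corr = {v: np.full(repetitions, np.nan) for v in variants}
    mse = {v: np.zeros(repetitions) for v in variants}
    detail_rows = []

    for rep_idx, fa in enumerate(folds):
        fold_index = np.array([fa.fold_of_individual[i] for i in ids])
        pooled_pred = {v: np.full(n, np.nan) for v in variants}
        for fold in range(1, k + 1):
            test = fold_index == fold
            if test.sum() < 2:
                raise ValueError(
                    f"fold {fold} of repetition {fa.repetition} has fewer than "
                    "2 test records"
                )
            train_mask = ~test
            for variant in variants:
                if variant == POLYGENIC:
                    X, names = build_design(n)
                elif variant == POLYGENIC_MAJORS:
                    cols, labels = [], []
                    for j, sid in enumerate(major_snp_ids):
                        if Z[train_mask, j].sum() > 0:
                            cols.append(Z[:, j])
                            labels.append(f"rec({sid})")
                        else:
                            warnings.warn(
                                f"repetition {fa.repetition} fold {fold}: no "
                                f"recessive homozygote for {sid} in training; "
                                "column dropped",
                                stacklevel=2,
                            )
                    cov = np.column_stack(cols) if cols else None
                    X, names = build_design(n, cov, labels)
                else:
                    raise ValueError(f"unknown model variant {variant!r}")
                model = KernelBLUP(
                    y,
                    kernel,
                    exog=X,
                    exog_names=names,
                    weights=w,
                    train_mask=train_mask,
                    ids=ids,
                )
                res = model.fit(mcmc, seed=next(fit_seed_pool))
                pooled_pred[variant][test] = res.fittedvalues[test]

        for variant in variants:
            pred = pooled_pred[variant]
            assert not np.isnan(pred).any(), "out-of-fold coverage incomplete"
            mse[variant][rep_idx] = (
                float(np.average((y - pred) ** 2, weights=w))
                if weighted_metrics
                else msep(y, pred)
            )
            try:
                corr[variant][rep_idx] = (
                    _weighted_pearson(y, pred, w)
                    if weighted_metrics
                    else pearson(y, pred)
                )
            except UndefinedCorrelationError:
                warnings.warn(
                    f"repetition {fa.repetition}, {variant}: constant "
                    "predictions; correlation undefined",
                    stacklevel=2,
                )
            detail_rows.append(
                {
                    "model": variant,
                    "repetition": fa.repetition,
                    "correlation": corr[variant][rep_idx],
                    "msep": mse[variant][rep_idx],
                }
            )

    details = pd.DataFrame(detail_rows)
    return {
        v: CVResult(
            model_label=v,
            correlations=corr[v],
            mseps=mse[v],
            k=k,
            n_repetitions=repetitions,
            fold_details=details[details["model"] == v].reset_index(drop=True),
        )
        for v in variants
    }
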