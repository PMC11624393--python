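"""Bayesian kernel (GBLUP-equivalent) regression with reliability weights.

The model is

    y = X b + g + e,      g ~ N(0, K sigma_g^2),    e ~ N(0, R^-1 sigma_e^2)

with K an n x n genomic kernel (here the linear kernel S S'/p, making the
model equivalent to GBLUP), X a fixed-effects design whose first column is
the intercept, and R = diag(r_i) the record reliabilities, so a record
backed by more breedings has residual variance sigma_e^2 / r_i.  The
shrinkage this induces on the kernel coefficients is governed by
lambda = sigma_e^2 / sigma_g^2.

:class:`KernelBLUP` is the model object (statsmodels style); ``fit()``
runs a Gibbs sampler over (b, g, sigma_g^2, sigma_e^2) and ``fit_blup()``
solves the weighted mixed-model equations in closed form for known
variance components — the two agree when the sampler's variances are held
fixed, which is the package's primary internal consistency check.  Both
return a :class:`KernelBLUPResults`.

Sampling uses the spectral reparameterization g = U diag(sqrt(d)) z with
K = U diag(d) U' (eigenvalues below ``eigen_tol * max(d)`` dropped; a
column-centered kernel always carries an exact zero eigenvalue), which
avoids the K^-1 that the prior notation alpha ~ N(0, K^-1 sigma_g^2)
would otherwise require.  Records outside ``train_mask`` contribute no
likelihood but their genetic values are still drawn through K — the
missing-phenotype convention used for cross-validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

from .genotypes import LinearKernel

__all__ = [
    "McmcConfig",
    "KernelBLUP",
    "KernelBLUPResults",
    "blup_closed_form",
    "build_design",
]


@dataclass
class McmcConfig:
    """Gibbs-chain settings.

    Defaults (30,000 iterations, 5,000 burn-in, thin 5, scaled-inverse-
    chi-square priors with 5 degrees of freedom and "auto" scales placing
    the prior mode at half the phenotypic variance for each component)
    follow common practice for Bayesian whole-genome regression software.
    """

    n_iter: int = 30_000
    burn_in: int = 5_000
    thin: int = 5
    seed: int = 0
    prior_df_g: float = 5.0
    prior_df_e: float = 5.0
    prior_scale_g: float | str = "auto"
    prior_scale_e: float | str = "auto"

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


def build_design(n: int, covariates: np.ndarray | None = None, labels=None):
    """Fixed-effects design with a leading intercept column.

    ``covariates`` (n x q0) are appended after the intercept.  Returns
    (X, column_labels).
    """
    cols = [np.ones((n, 1))]
    names = ["intercept"]
    if covariates is not None:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != n:
            raise ValueError("covariate rows do not match n")
        cols.append(covariates)
        if labels is None:
            labels = [f"x{j + 1}" for j in range(covariates.shape[1])]
        names.extend(labels)
    return np.hstack(cols), names


def _check_full_rank(X: np.ndarray, labels) -> None:
    _, R, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    bad = [labels[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
    if bad:
        raise np.linalg.LinAlgError(
            f"fixed-effects design is rank deficient; collinear columns: {bad}"
        )


class KernelBLUP:
    """Kernel regression model for reliability-weighted phenotypes.

    Parameters
    ----------
    endog : array-like, shape (n,)
        Phenotypic records (conception-rate deviations, percent scale).
    kernel : LinearKernel or ndarray (n, n)
        Genomic similarity matrix; must be symmetric PSD up to tolerance.
    exog : ndarray (n, q), optional
        Fixed-effects design.  The first column must be the intercept;
        defaults to intercept only.  Use :func:`build_design` to append
        recessive major-marker indicator columns.
    weights : array-like (n,), optional
        Record reliabilities in (0, 1], the diagonal of R.  Default 1.
    train_mask : bool array (n,), optional
        Records contributing to the likelihood; others are predicted
        through the kernel only.  Default all True.
    """

    def __init__(
        self,
        endog,
        kernel,
        exog=None,
        weights=None,
        train_mask=None,
        ids=None,
        exog_names=None,
        eigen_tol: float = 1e-8,
    ) -> None:
        if isinstance(kernel, LinearKernel):
            K = kernel.K
            if ids is None:
                ids = kernel.individual_ids
        else:
            K = np.asarray(kernel, dtype=float)
        n = K.shape[0]
        if K.shape != (n, n):
            raise ValueError("kernel must be square")
        if not np.allclose(K, K.T, atol=1e-10):
            raise ValueError("kernel must be symmetric")

        self.endog = np.asarray(endog, dtype=float)
        if self.endog.shape != (n,):
            raise ValueError(f"endog length {self.endog.shape} != kernel size {n}")
        if exog is None:
            self.exog, self.exog_names = build_design(n)
        else:
            self.exog = np.asarray(exog, dtype=float)
            if self.exog.ndim == 1:
                self.exog = self.exog[:, None]
            if self.exog.shape[0] != n:
                raise ValueError("exog rows do not match kernel size")
            if not np.all(self.exog[:, 0] == 1.0):
                raise ValueError("first exog column must be the intercept (all ones)")
            self.exog_names = list(
                exog_names
                if exog_names is not None
                else ["intercept"] + [f"x{j}" for j in range(1, self.exog.shape[1])]
            )
        _check_full_rank(self.exog, self.exog_names)

        self.weights = (
            np.ones(n) if weights is None else np.asarray(weights, dtype=float)
        )
        if self.weights.shape != (n,) or (self.weights <= 0).any() or (
            self.weights > 1
        ).any():
            raise ValueError("weights must be reliabilities in (0, 1], one per record")
        self.train_mask = (
            np.ones(n, dtype=bool)
            if train_mask is None
            else np.asarray(train_mask, dtype=bool)
        )
        if self.train_mask.shape != (n,):
            raise ValueError("train_mask length mismatch")
        if self.train_mask.sum() < self.exog.shape[1] + 2:
            raise ValueError(
                "need at least q + 2 training records to fit the model"
            )
        self.ids = pd.Index(ids if ids is not None else range(n)).astype(str)
        self.K = K
        self.nobs = n
        self.eigen_tol = eigen_tol
        self._eig = None  # cached (U_kept, d_kept, n_dropped)

    # -- spectral decomposition -------------------------------------------
    def _eigen(self):
        if self._eig is None:
            d, U = np.linalg.eigh(self.K)
            dmax = d.max() if d.size else 0.0
            if dmax <= 0:
                raise np.linalg.LinAlgError("kernel has no positive eigenvalues")
            if d.min() < -1e-6 * dmax:
                raise np.linalg.LinAlgError(
                    f"kernel is not PSD: min eigenvalue {d.min():.3e} "
                    f"(max {dmax:.3e})"
                )
            keep = d > self.eigen_tol * dmax
            self._eig = (U[:, keep], d[keep], int((~keep).sum()))
        return self._eig

    # -- closed-form weighted BLUP ----------------------------------------
    def fit_blup(self, sigma_g2: float, sigma_e2: float) -> "KernelBLUPResults":
        """Solve the weighted mixed-model equations for known variances.

        Training records enter with residual precision r_i / sigma_e^2;
        masked individuals are predicted through the kernel cross-block
        (equivalently, through the retained eigenspace of K).
        """
        if sigma_g2 < 0 or sigma_e2 <= 0:
            raise ValueError("variance components must be positive (sigma_g2 >= 0)")
        U, d, n_dropped = self._eigen()
        W = U * np.sqrt(d)  # n x m
        t = self.train_mask
        Xt, yt, rt = self.exog[t], self.endog[t], self.weights[t]
        Wt = W[t]
        q, m = Xt.shape[1], W.shape[1]

        if sigma_g2 == 0.0:
            XtRX = Xt.T @ (rt[:, None] * Xt)
            b = np.linalg.solve(XtRX, Xt.T @ (rt * yt))
            g = np.zeros(self.nobs)
            cov_b = sigma_e2 * np.linalg.inv(XtRX)
        else:
            P = rt / sigma_e2
            C = np.zeros((q + m, q + m))
            C[:q, :q] = Xt.T @ (P[:, None] * Xt)
            C[:q, q:] = Xt.T @ (P[:, None] * Wt)
            C[q:, :q] = C[:q, q:].T
            C[q:, q:] = Wt.T @ (P[:, None] * Wt) + np.eye(m) / sigma_g2
            rhs = np.concatenate([Xt.T @ (P * yt), Wt.T @ (P * yt)])
            cf = scipy.linalg.cho_factor(C)
            sol = scipy.linalg.cho_solve(cf, rhs)
            b, u = sol[:q], sol[q:]
            g = W @ u
            Cinv_qq = scipy.linalg.cho_solve(cf, np.eye(q + m)[:, :q])[:q]
            cov_b = Cinv_qq

        fitted = self.exog @ b + g
        return KernelBLUPResults(
            model=self,
            method="blup",
            params=b,
            bse=np.sqrt(np.diag(cov_b)),
            genetic_values=g,
            genetic_values_sd=np.full(self.nobs, np.nan),
            sigma_g2=float(sigma_g2),
            sigma_e2=float(sigma_e2),
            sigma_g2_sd=0.0,
            sigma_e2_sd=0.0,
            lambda_=float(sigma_e2 / sigma_g2) if sigma_g2 > 0 else np.inf,
            n_draws=0,
            n_eigen_dropped=n_dropped,
            fittedvalues=fitted,
        )

    # -- Gibbs sampler ------------------------------------------------------
    def fit(
        self,
        config: McmcConfig | None = None,
        fixed_variances: tuple[float, float] | None = None,
        store_draws: bool = False,
        **kwargs,
    ) -> "KernelBLUPResults":
        """Fit by Gibbs sampling.

        Keyword arguments override fields of ``config`` (e.g. ``n_iter=,
        seed=``).  ``fixed_variances=(sigma_g2, sigma_e2)`` disables
        variance-component sampling — the no-uncertainty limit used to
        check the sampler against :meth:`fit_blup`.

        Draw order per sweep, from a single seeded generator: kernel
        coordinates z, fixed effects b, residual variance, genetic
        variance.
        """
        if config is None:
            config = McmcConfig()
        if kwargs:
            config = McmcConfig(**{**config.__dict__, **kwargs})

        U, d, n_dropped = self._eigen()
        W = U * np.sqrt(d)
        t = self.train_mask
        Xt, yt, rt = self.exog[t], self.endog[t], self.weights[t]
        n_train = int(t.sum())
        q, m = Xt.shape[1], W.shape[1]
        if m == 0:
            raise np.linalg.LinAlgError("kernel degenerate: no retained eigenvalues")

        # rotate kernel coordinates so their full-conditional precision is
        # diagonal: A = W_t' R W_t = V diag(lam) V' is fixed across sweeps
        A = (W[t].T * rt) @ W[t]
        lam, V = np.linalg.eigh(A)
        lam = np.clip(lam, 0.0, None)
        G_all = W @ V            # zeta -> g for every individual
        G_t = G_all[t]
        a_y = G_t.T @ (rt * yt)          # m
        A_X = G_t.T @ (rt[:, None] * Xt)  # m x q

        XtRX = Xt.T @ (rt[:, None] * Xt)
        Lx = np.linalg.cholesky(XtRX)
        XtRX_inv = np.linalg.inv(XtRX)

        vy = float(np.var(yt))
        df_g, df_e = config.prior_df_g, config.prior_df_e
        S_g = (
            0.5 * vy * (df_g + 2.0) / df_g
            if config.prior_scale_g == "auto"
            else float(config.prior_scale_g)
        )
        S_e = (
            0.5 * vy * (df_e + 2.0) / df_e
            if config.prior_scale_e == "auto"
            else float(config.prior_scale_e)
        )

        rng = np.random.default_rng(config.seed)
        if fixed_variances is not None:
            sigma_g2, sigma_e2 = map(float, fixed_variances)
            # sigma_g2 == 0 is the degenerate no-signal override: g pinned at 0
            if sigma_g2 < 0 or sigma_e2 <= 0:
                raise ValueError("fixed variance components must be positive")
        else:
            sigma_g2 = sigma_e2 = 0.5 * vy

        b = np.linalg.solve(XtRX, Xt.T @ (rt * yt))
        zeta = np.zeros(m)

        kept = range(config.burn_in, config.n_iter, config.thin)
        n_kept = len(kept)
        sum_b = np.zeros(q)
        sumsq_b = np.zeros(q)
        sum_g = np.zeros(self.nobs)
        sumsq_g = np.zeros(self.nobs)
        sums = {"sg2": 0.0, "se2": 0.0, "lam": 0.0, "sg2_sq": 0.0, "se2_sq": 0.0}
        traces = (
            {"b": [], "g": [], "sigma_g2": [], "sigma_e2": []} if store_draws else None
        )

        next_keep = iter(kept)
        keep_at = next(next_keep, None)
        for it in range(config.n_iter):
            # z | rest — diagonal full conditional in rotated coordinates
            prec = lam / sigma_e2 + (np.inf if sigma_g2 == 0.0 else 1.0 / sigma_g2)
            mean = (a_y - A_X @ b) / sigma_e2 / prec
            zeta = mean + rng.standard_normal(m) / np.sqrt(prec)
            g_train = G_t @ zeta

            # b | rest — multivariate normal, flat prior
            resid = yt - g_train
            b_mean = XtRX_inv @ (Xt.T @ (rt * resid))
            b = b_mean + np.sqrt(sigma_e2) * scipy.linalg.solve_triangular(
                Lx.T, rng.standard_normal(q), lower=False
            )

            if fixed_variances is None:
                eps = resid - Xt @ b
                sse = float(np.sum(rt * eps * eps))
                sigma_e2 = (df_e * S_e + sse) / rng.chisquare(df_e + n_train)
                sigma_g2 = (df_g * S_g + float(zeta @ zeta)) / rng.chisquare(df_g + m)

            if keep_at is not None and it == keep_at:
                g_full = G_all @ zeta
                sum_b += b
                sumsq_b += b * b
                sum_g += g_full
                sumsq_g += g_full * g_full
                sums["sg2"] += sigma_g2
                sums["se2"] += sigma_e2
                sums["sg2_sq"] += sigma_g2**2
                sums["se2_sq"] += sigma_e2**2
                sums["lam"] += sigma_e2 / sigma_g2 if sigma_g2 > 0 else np.inf
                if store_draws:
                    traces["b"].append(b.copy())
                    traces["g"].append(g_full)
                    traces["sigma_g2"].append(sigma_g2)
                    traces["sigma_e2"].append(sigma_e2)
                keep_at = next(next_keep, None)

        def _sd(s, ss, n):
            v = ss / n - (s / n) ** 2
            return np.sqrt(np.clip(v, 0.0, None))

        b_mean = sum_b / n_kept
        g_mean = sum_g / n_kept
        res = KernelBLUPResults(
            model=self,
            method="gibbs",
            params=b_mean,
            bse=_sd(sum_b, sumsq_b, n_kept),
            genetic_values=g_mean,
            genetic_values_sd=_sd(sum_g, sumsq_g, n_kept),
            sigma_g2=sums["sg2"] / n_kept,
            sigma_e2=sums["se2"] / n_kept,
            sigma_g2_sd=float(_sd(sums["sg2"], sums["sg2_sq"], n_kept)),
            sigma_e2_sd=float(_sd(sums["se2"], sums["se2_sq"], n_kept)),
            lambda_=sums["lam"] / n_kept,
            n_draws=n_kept,
            n_eigen_dropped=n_dropped,
            fittedvalues=self.exog @ b_mean + g_mean,
            mcmc_config=config,
        )
        if store_draws:
            res.draws = {k: np.asarray(v) for k, v in traces.items()}
        return res


@dataclass
class KernelBLUPResults:
    """Posterior summary (Gibbs) or point solution (closed-form BLUP)."""

    model: KernelBLUP
    method: str
    params: np.ndarray          # fixed effects b (posterior mean / BLUE)
    bse: np.ndarray             # posterior sd / sampling sd of b
    genetic_values: np.ndarray  # g for every kernel individual
    genetic_values_sd: np.ndarray
    sigma_g2: float
    sigma_e2: float
    sigma_g2_sd: float
    sigma_e2_sd: float
    lambda_: float              # posterior mean of sigma_e2 / sigma_g2 per draw
    n_draws: int
    n_eigen_dropped: int
    fittedvalues: np.ndarray
    mcmc_config: McmcConfig | None = None
    draws: dict | None = None

    @property
    def param_names(self):
        return self.model.exog_names

    def predict(self) -> pd.DataFrame:
        """Predicted phenotype X b + g for every individual.

        ``is_test`` flags individuals outside the training mask (their
        records contributed no likelihood).
        """
        return pd.DataFrame(
            {
                "id": self.model.ids,
                "prediction": self.fittedvalues,
                "is_test": ~self.model.train_mask,
            }
        )

    def summary(self) -> str:
        lines = [
            "Weighted kernel regression (GBLUP)"
            + (" — Gibbs posterior summary" if self.method == "gibbs" else " — closed-form BLUP"),
            "=" * 64,
            f"No. individuals: {self.model.nobs:>6}    "
            f"training records: {int(self.model.train_mask.sum())}",
            f"kernel rank used: {self.model.nobs - self.n_eigen_dropped:>5}    "
            f"eigenvalues dropped: {self.n_eigen_dropped}",
        ]
        if self.method == "gibbs":
            lines.append(f"posterior draws retained: {self.n_draws}")
        lines += [
            "-" * 64,
            f"{'fixed effect':<24}{'estimate':>12}{'sd':>12}",
        ]
        for name, est, sd in zip(self.param_names, self.params, self.bse):
            lines.append(f"{name:<24}{est:>12.4f}{sd:>12.4f}")
        lines += [
            "-" * 64,
            f"sigma_g^2 (genetic):  {self.sigma_g2:>10.4f}  (sd {self.sigma_g2_sd:.4f})",
            f"sigma_e^2 (residual): {self.sigma_e2:>10.4f}  (sd {self.sigma_e2_sd:.4f})",
            f"lambda = sigma_e^2/sigma_g^2: {self.lambda_:>8.4f}",
            "=" * 64,
        ]
        return "\n".join(lines)


def blup_closed_form(
    y,
    kernel,
    sigma_g2: float,
    sigma_e2: float,
    exog=None,
    weights=None,
    train_mask=None,
    **model_kwargs,
) -> tuple[np.ndarray, np.ndarray]:
    """Convenience wrapper: weighted BLUP (b_hat, g_hat) for known variances."""
    model = KernelBLUP(
        y, kernel, exog=exog, weights=weights, train_mask=train_mask, **model_kwargs
    )
    res = model.fit_blup(sigma_g2, sigma_e2)
    return res.params, res.genetic_values
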