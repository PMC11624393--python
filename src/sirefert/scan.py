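"""Single-marker genome scan for recessive effects on the phenotype.

For each SNP the scan fits the weighted least-squares contrast

    y_i = mu + delta * 1[individual i is homozygous for the minor allele] + e_i

with record reliabilities as weights (var(e_i) = sigma^2 / r_i), and
reports the recessive-effect estimate delta-hat, its standard error and a
two-sided t-test p-value.  SNPs with fewer recessive homozygotes than
``min_homozygotes`` are skipped with a reason.  This is a deliberately
simple marginal scan — no polygenic-background adjustment — intended to
(re)discover large recessive loci in a cohort; a Bonferroni threshold
over the tested SNPs is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix, allele_frequencies

__all__ = ["ScanResult", "scan_recessive", "manhattan_table"]


@dataclass
class ScanResult:
    """Per-SNP recessive-contrast results plus the Bonferroni threshold."""

    table: pd.DataFrame          # one row per input SNP, skips included
    n_tested: int
    alpha: float
    bonferroni_threshold: float  # alpha / n_tested

    def top_hits(self, n: int = 10) -> pd.DataFrame:
        tested = self.table[self.table["tested"]]
        return tested.nsmallest(n, "p_value")


def scan_recessive(
    g: GenotypeMatrix,
    y,
    weights=None,
    min_homozygotes: int = 5,
    alpha: float = 0.05,
) -> ScanResult:
    """Weighted recessive-contrast scan over every SNP.

    ``y`` and ``weights`` (reliabilities; default 1) align with
    ``g.individual_ids``.  Missing genotypes at a SNP drop that individual
    from that SNP's test.  The output table has one row per input SNP in
    input order; untested SNPs carry ``tested=False`` and a skip reason.
    """
    y = np.asarray(y, dtype=float)
    n, p = g.n_individuals, g.n_snps
    if y.shape != (n,):
        raise ValueError(f"phenotype length {y.shape} does not match {n} individuals")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (n,):
        raise ValueError("weights length does not match individuals")

    freq = allele_frequencies(g)
    dosage = g.dosage
    called = ~np.isnan(dosage)
    # recessive homozygote = two copies of the cohort-minor allele
    minor_is_counted = freq <= 0.5
    hom = np.where(
        minor_is_counted[None, :], dosage == 2.0, dosage == 0.0
    ) & called

    rows = []
    for j in range(p):
        sid = g.snp_ids[j]
        meta = {
            "snp_id": sid,
            "chrom": g.snps["chrom"].iloc[j],
            "pos": int(g.snps["pos"].iloc[j]),
        }
        use = called[:, j]
        z = hom[use, j]
        n_hom = int(z.sum())
        n_other = int((~z).sum())
        base = {
            **meta,
            "n_recessive_homozygotes": n_hom,
            "effect_estimate": np.nan,
            "standard_error": np.nan,
            "p_value": np.nan,
            "tested": False,
            "skip_reason": "",
        }
        if n_hom == 0:
            base["skip_reason"] = "no recessive homozygotes"
            rows.append(base)
            continue
        if n_hom < min_homozygotes:
            base["skip_reason"] = (
                f"fewer than {min_homozygotes} recessive homozygotes"
            )
            rows.append(base)
            continue
        if n_other < 2 or use.sum() < 4:
            base["skip_reason"] = "too few non-homozygous records"
            rows.append(base)
            continue

        yy, ww = y[use], w[use]
        sw1, sw0 = float(ww[z].sum()), float(ww[~z].sum())
        m1 = float(ww[z] @ yy[z]) / sw1
        m0 = float(ww[~z] @ yy[~z]) / sw0
        delta = m1 - m0
        rss = float(ww[z] @ (yy[z] - m1) ** 2 + ww[~z] @ (yy[~z] - m0) ** 2)
        dof = use.sum() - 2
        s2 = rss / dof
        se = np.sqrt(s2 * (1.0 / sw1 + 1.0 / sw0))
        if se == 0.0:
            tval, pval = np.inf, np.nextafter(0, 1)
        else:
            tval = delta / se
            pval = 2.0 * stats.t.sf(abs(tval), dof)
        base.update(
            effect_estimate=delta,
            standard_error=se,
            p_value=max(pval, np.nextafter(0, 1)),
            tested=True,
        )
        rows.append(base)

    table = pd.DataFrame(rows)
    n_tested = int(table["tested"].sum())
    return ScanResult(
        table=table,
        n_tested=n_tested,
        alpha=alpha,
        bonferroni_threshold=alpha / n_tested if n_tested else np.nan,
    )


def manhattan_table(result: ScanResult) -> pd.DataFrame:
    """Manhattan-plot-ready table: chromosome, cumulative position, −log10 p.

    Chromosomes are laid end to end in numeric-then-lexical order.
    """
    t = result.table.copy()

    def chrom_key(c):
        return (0, int(c)) if str(c).isdigit() else (1, str(c))

    offsets, cum = {}, 0
    for c in sorted(t["chrom"].unique(), key=chrom_key):
        offsets[c] = cum
        cum += int(t.loc[t["chrom"] == c, "pos"].max()) + 1
    t["cumulative_pos"] = t["pos"] + t["chrom"].map(offsets)
    t["neg_log10_p"] = -np.log10(t["p_value"])
    return t[
        ["snp_id", "chrom", "pos", "cumulative_pos", "neg_log10_p", "tested"]
    ]
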