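"""CES detection from population allele counts via the gamma-Poisson model.

Under recurrent mutation and strong heterozygous selection s, the population
frequency of a LoF allele follows (Nei's approximation) a Gamma distribution
with shape 4Nₑμ and scale 1/(4Nₑs); a sample of n chromosomes then yields a
Poisson count k around n·p.  Decomposing the across-site variance,

    Var(k) = Var_sampling + Var_seg + Var_mu
           = k̄ + k̄·n/(4Nₑs) + (nκ/s)²·Var(μ),

separates Poisson sampling noise, drift-induced segregation variance and
mutation-rate heterogeneity.  Two estimators of inverse selection follow:

* mean-based (CES-sensitive):      κ/s = k̄/(n·μ̄)
* variance-based (CES-insensitive): n/(4Nₑs) = Var_seg/k̄

A clonal-expansion factor κ > 1 inflates the first but not the second, so in
a log-log regression of the mean-based estimate on the variance-based one
CES genes stand out as positive residuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError
from .mutmodel import QUALITY_PASS

__all__ = [
    "GenePopStats",
    "CESRegressionResult",
    "filter_popgen_genes",
    "gene_popstats",
    "ces_residuals",
    "af_vs_mu_binned",
]

#: Minimum qualifying LoF sites for a gene to enter the analysis.
MIN_SITES = 10
#: Unscaled-rate threshold for a qualifying (CpG-like) site; strict.
MU_QUALIFYING = 1.0
#: Drift-ratio level beyond which the gamma-Poisson regime is doubtful.
DRIFT_RATIO_FLAG = 10.0


def filter_popgen_genes(sites: pd.DataFrame, min_sites: int = MIN_SITES,
                        mu_threshold: float = MU_QUALIFYING) -> dict[str, pd.Index]:
    """Genes with at least ``min_sites`` quality-passing sites of unscaled
    rate strictly above ``mu_threshold``; returns gene -> qualifying index."""
    for col in ("gene_id", "mu", "quality"):
        if col not in sites.columns:
            raise DataError(f"population site table missing column {col!r}")
    ok = sites["quality"].isin(QUALITY_PASS) & (sites["mu"] > mu_threshold)
    out: dict[str, pd.Index] = {}
    for gid, sub in sites.loc[ok].groupby("gene_id", sort=True):
        if len(sub) >= min_sites:
            out[str(gid)] = sub.index
    return out


@dataclass
class GenePopStats:
    gene_id: str
    n_sites: int
    k_bar: float
    mu_bar: float            # mean per-generation rate
    var_k: float
    slope_b: float           # Poisson regression of k on mu through the origin
    var_mu_term: float       # b^2 * Var(mu)
    var_sampling: float      # = k_bar
    var_seg: float           # Var(k) - var_mu_term - k_bar
    inv_s_mean: float        # kappa/s estimate from the mean
    drift_ratio: float       # n/(4 Ne s) estimate from the variance (nan if k_bar = 0)
    out_of_regime: bool

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        return d


def gene_popstats(sites: pd.DataFrame, n_chrom: int,
                  drift_ratio_flag: float = DRIFT_RATIO_FLAG) -> GenePopStats:
    """Variance decomposition and selection estimators for one gene.

    ``sites`` needs columns ``mu_gen`` (per-generation rate) and ``k``
    (sampled allele count).  The regression of k on μ through the origin with
    Poisson error has the closed-form MLE b̂ = Σk/Σμ; its square times the
    sample variance of μ estimates the mutation-heterogeneity term.
    ``var_seg`` may come out negative by sampling noise — it is reported
    as-is with the ``out_of_regime`` flag set.
    """
    for col in ("mu_gen", "k"):
        if col not in sites.columns:
            raise DataError(f"population site table missing column {col!r}")
    if n_chrom <= 0:
        raise DataError("n_chrom must be positive")
    mu = sites["mu_gen"].to_numpy(dtype=float)
    k = sites["k"].to_numpy(dtype=float)
    if mu.size < 2:
        raise DataError("need at least 2 sites per gene")
    if np.any(mu <= 0) or np.any(k < 0):
        raise DataError("rates must be positive and counts non-negative")
    gid = str(sites["gene_id"].iloc[0]) if "gene_id" in sites.columns else ""
    k_bar = float(k.mean())
    mu_bar = float(mu.mean())
    var_k = float(k.var(ddof=1))
    slope = float(k.sum() / mu.sum())
    var_mu_term = slope ** 2 * float(mu.var(ddof=1))
    var_seg = var_k - var_mu_term - k_bar
    inv_s_mean = k_bar / (n_chrom * mu_bar)
    drift_ratio = var_seg / k_bar if k_bar > 0 else float("nan")
    out = (k_bar == 0.0) or (var_seg <= 0.0) or (
        np.isfinite(drift_ratio) and drift_ratio > drift_ratio_flag)
    return GenePopStats(
        gene_id=gid, n_sites=int(mu.size), k_bar=k_bar, mu_bar=mu_bar,
        var_k=var_k, slope_b=slope, var_mu_term=var_mu_term,
        var_sampling=k_bar, var_seg=var_seg, inv_s_mean=inv_s_mean,
        drift_ratio=drift_ratio, out_of_regime=bool(out),
    )


@dataclass
class CESRegressionResult:
    slope: float
    intercept: float
    residuals: pd.Series   # per gene, natural-log scale
    n_genes: int
    n_excluded: int

    def to_dict(self) -> dict:
        return {"slope": self.slope, "intercept": self.intercept,
                "n_genes": self.n_genes, "n_excluded": self.n_excluded,
                "residuals": self.residuals.to_dict()}


def ces_residuals(stats_list: list[GenePopStats],
                  min_genes: int = 10) -> CESRegressionResult:
    """OLS of log(κ/s estimate) on log(drift-ratio estimate) across genes.

    Genes with non-positive ``var_seg`` or zero mean count cannot enter the
    log-log regression and are excluded (counted in ``n_excluded``).  Genes
    whose mutation rate is inflated by clonal expansion (κ > 1) appear as
    positive residuals.
    """
    usable = [s for s in stats_list
              if s.k_bar > 0 and s.var_seg > 0 and s.inv_s_mean > 0
              and np.isfinite(s.drift_ratio) and s.drift_ratio > 0]
    n_excluded = len(stats_list) - len(usable)
    if len(usable) < min_genes:
        raise DataError(
            f"need >= {min_genes} genes with valid positive drift ratio, "
            f"got {len(usable)}")
    x = np.log([s.drift_ratio for s in usable])
    y = np.log([s.inv_s_mean for s in usable])
    design = np.column_stack([x, np.ones_like(x)])
    (slope, intercept), *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - (slope * x + intercept)
    residuals = pd.Series(resid, index=[s.gene_id for s in usable], name="residual")
    return CESRegressionResult(float(slope), float(intercept), residuals,
                               len(usable), n_excluded)


def af_vs_mu_binned(sites: pd.DataFrame, n_chrom: int,
                    min_per_bin: int = 10, n_bins: int = 10) -> dict:
    """Binned allele frequency vs mutation rate for one gene.

    Sites are cut into up-to-``n_bins`` quantile bins of μ; bins with fewer
    than ``min_per_bin`` sites are merged with the next-highest bin (the top
    bin merges downward).  Under a purely linear (possibly CES-inflated)
    relation the through-origin Poisson regression slope of k on μ_gen
    estimates n·κ/s.
    """
    if len(sites) < min_per_bin:
        raise DataError(f"need at least {min_per_bin} sites, got {len(sites)}")
    mu = sites["mu_gen"].to_numpy(dtype=float)
    k = sites["k"].to_numpy(dtype=float)
    order = np.argsort(mu, kind="stable")
    mu, k = mu[order], k[order]
    # quantile bin edges on ranks, then merge undersized bins upward
    n_bins = max(1, min(n_bins, len(mu) // min_per_bin))
    raw_bins = np.array_split(np.arange(len(mu)), n_bins)
    merged: list[np.ndarray] = []
    carry = np.array([], dtype=int)
    for b in raw_bins:
        b = np.concatenate([carry, b])
        if len(b) < min_per_bin:
            carry = b
        else:
            merged.append(b)
            carry = np.array([], dtype=int)
    if len(carry):
        if merged:
            merged[-1] = np.concatenate([merged[-1], carry])
        else:
            merged.append(carry)
    rows = [{"mean_mu_gen": float(mu[b].mean()),
             "mean_freq": float(k[b].mean() / n_chrom),
             "n_sites": int(len(b))} for b in merged]
    slope = float(k.sum() / mu.sum())  # through-origin Poisson MLE, = n*kappa/s
    return {"bins": pd.DataFrame(rows), "slope": slope,
            "slope_per_chrom": slope / n_chrom}
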