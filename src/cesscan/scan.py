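"""Ascertainment-bounded scans for drivers of clonal expansions in spermatogonia.

In a cohort ascertained for a disease D, the observed/expected enrichment of
any de novo variant is bounded by the inverse prevalence:

    obs/exp = P(D|V)/P(D) <= 1/P(D).

Testing observed counts against λ/P*(D), with P* a conservative lower bound
on prevalence, therefore yields a scan that no degree of disease
ascertainment can defeat: a significant excess implies inflation of the
mutation rate itself, the signature of clonal expansion in spermatogonia
(CES).

Three test families are provided:

* ``gof_scan`` — per-variant negative-binomial test of missense hotspots
  against λ_v/P* with overdispersion γ (gain-of-function drivers);
* ``lof1_scan`` — per-gene Poisson test of aggregated LoF counts against
  λ_g/P* (LoF drivers that exceed the ascertainment bound);
* ``lof_excess_scan`` — per-gene Poisson test against λ_g itself (no
  ascertainment divisor); combined with a LOEUF threshold via
  ``lof2_select`` this identifies high-polymorphism excess genes (LoF-2).

``cohort_compare_binomial`` contrasts LoF counts between a trio cohort and a
sperm-sequencing dataset, and ``set_enrichment`` pools observed/expected
ratios over a gene or site set with gamma-conjugate Poisson intervals.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import ScanConfig
from .errors import ConfigError, DataError
from .mutmodel import GeneModel, obs_exp_ratio_ci

__all__ = [
    "nb_tail_p",
    "poisson_tail_p",
    "gof_scan",
    "lof1_scan",
    "lof_excess_scan",
    "lof2_select",
    "cohort_compare_binomial",
    "set_enrichment",
]


def poisson_tail_p(n_obs, lam) -> np.ndarray:
    """Upper-tail Poisson p-value P(N >= n_obs | lam); p = 1 at n_obs = 0."""
    n = np.atleast_1d(np.asarray(n_obs, dtype=float))
    lam = np.broadcast_to(np.asarray(lam, dtype=float), n.shape)
    if np.any(n < 0):
        raise DataError("negative observed counts")
    if np.any(lam <= 0):
        raise DataError("expected counts must be positive")
    p = np.ones_like(n, dtype=float)
    nz = n > 0
    if np.any(nz):
        p[nz] = stats.poisson.sf(n[nz] - 1.0, lam[nz])
    return p


def nb_tail_p(n_obs, lam, gamma: float) -> np.ndarray:
    """Upper-tail p-value under NB(mean lam, variance lam(1+gamma)).

    With r = lam/γ and success probability 1/(1+γ) the mean is lam; γ = 0
    reduces exactly to the Poisson tail.
    """
    if gamma < 0:
        raise ConfigError("gamma must be >= 0")
    if gamma == 0:
        return poisson_tail_p(n_obs, lam)
    n = np.atleast_1d(np.asarray(n_obs, dtype=float))
    lam = np.broadcast_to(np.asarray(lam, dtype=float), n.shape)
    if np.any(n < 0):
        raise DataError("negative observed counts")
    if np.any(lam <= 0):
        raise DataError("expected counts must be positive")
    p = np.ones_like(n, dtype=float)
    nz = n > 0
    if np.any(nz):
        r = lam[nz] / gamma
        p[nz] = stats.nbinom.sf(n[nz] - 1.0, r, 1.0 / (1.0 + gamma))
    return p


def _adjust(frame: pd.DataFrame, n_bonferroni: int | None, fdr: float,
            alpha: float) -> pd.DataFrame:
    """Attach Bonferroni-adjusted p, BH q and significance flags."""
    m = n_bonferroni if n_bonferroni else len(frame)
    if m < len(frame):
        raise ConfigError(
            f"Bonferroni factor {m} smaller than the number of tests {len(frame)}")
    frame = frame.copy()
    frame["p_bonferroni"] = np.minimum(frame["p_value"] * m, 1.0)
    frame["sig_bonferroni"] = frame["p_bonferroni"] < alpha
    if len(frame):
        reject, qvals, *_ = multipletests(frame["p_value"].to_numpy(),
                                          alpha=fdr, method="fdr_bh")
        frame["q_value"] = qvals
        frame["sig_fdr"] = reject
    else:
        frame["q_value"] = np.nan
        frame["sig_fdr"] = False
    return frame


def _scan_frame(index, n_obs, lam_base, divisor: float) -> pd.DataFrame:
    lam_base = np.asarray(lam_base, dtype=float)
    n_obs = np.asarray(n_obs, dtype=float)
    if np.any(lam_base <= 0) and np.any(n_obs[lam_base <= 0] > 0):
        raise DataError("observed counts at sites/genes with zero expectation "
                        "(annotation inconsistency)")
    if np.any(lam_base <= 0):
        raise DataError("expected counts must be positive")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = n_obs / lam_base
    return pd.DataFrame({
        "n_obs": n_obs.astype(int),
        "lambda_base": lam_base,
        "lambda_asc": lam_base / divisor,
        "ratio": ratio,
    }, index=index)


def gof_scan(variant_counts: pd.Series, lambda_v: pd.Series,
             config: ScanConfig) -> pd.DataFrame:
    """Per-variant negative-binomial scan of missense counts against the
    ascertainment-capped expectation λ_v/P*(D).

    ``variant_counts`` and ``lambda_v`` must share an index (one entry per
    admissible missense variant).  Returns one row per variant with raw,
    Bonferroni-adjusted and BH-adjusted significance at ``config.fdr_gof``.
    """
    config.validate()
    lam = lambda_v.reindex(variant_counts.index)
    if lam.isna().any():
        raise DataError("variants missing from the expectation table")
    frame = _scan_frame(variant_counts.index, variant_counts.to_numpy(),
                        lam.to_numpy(), config.prevalence_lower_bound)
    frame["p_value"] = nb_tail_p(frame["n_obs"].to_numpy(),
                                 frame["lambda_asc"].to_numpy(), config.gamma)
    return _adjust(frame, config.bonferroni_n_variants, config.fdr_gof,
                   config.alpha_bonferroni)


def lof1_scan(gene_lof_counts: pd.Series, lambda_g: pd.Series,
              config: ScanConfig) -> pd.DataFrame:
    """Per-gene Poisson scan of LoF counts against λ_g/P*(D).

    Bonferroni adjustment uses ``config.bonferroni_n_genes``; the BH flag at
    ``config.fdr_lof`` is reported alongside (the published LoF-1 set is the
    Bonferroni one, with one extra FDR-only gene)."""
    config.validate()
    lam = lambda_g.reindex(gene_lof_counts.index)
    if lam.isna().any():
        missing = gene_lof_counts.index[lam.isna()].tolist()
        raise DataError(f"genes missing LoF expectations: {missing[:5]}")
    frame = _scan_frame(gene_lof_counts.index, gene_lof_counts.to_numpy(),
                        lam.to_numpy(), config.prevalence_lower_bound)
    frame["p_value"] = poisson_tail_p(frame["n_obs"].to_numpy(),
                                      frame["lambda_asc"].to_numpy())
    return _adjust(frame, config.bonferroni_n_genes, config.fdr_lof,
                   config.alpha_bonferroni)


def lof_excess_scan(gene_lof_counts: pd.Series, lambda_g: pd.Series,
                    config: ScanConfig | None = None) -> pd.DataFrame:
    """Per-gene Poisson scan for any excess of LoF de novo counts over λ_g
    (no ascertainment divisor)."""
    config = config or ScanConfig()
    config.validate()
    lam = lambda_g.reindex(gene_lof_counts.index)
    if lam.isna().any():
        missing = gene_lof_counts.index[lam.isna()].tolist()
        raise DataError(f"genes missing LoF expectations: {missing[:5]}")
    frame = _scan_frame(gene_lof_counts.index, gene_lof_counts.to_numpy(),
                        lam.to_numpy(), 1.0)
    frame["p_value"] = poisson_tail_p(frame["n_obs"].to_numpy(),
                                      frame["lambda_base"].to_numpy())
    return _adjust(frame, config.bonferroni_n_genes, config.fdr_lof,
                   config.alpha_bonferroni)


def lof2_select(excess_results: pd.DataFrame, gene_models: list[GeneModel],
                config: ScanConfig | None = None) -> dict:
    """Select the LoF-2 set: FDR < threshold AND LOEUF strictly > threshold,
    minus blocklisted genes.

    Flagged (blocklisted) genes and genes without a LOEUF value are reported
    separately rather than silently dropped.
    """
    config = config or ScanConfig()
    config.validate()
    loeuf = {g.gene_id: g.loeuf for g in gene_models}
    blocked: set[str] = set()
    for genes in dict(config.blocklists).values():
        blocked.update(genes)
    significant = excess_results.index[excess_results["sig_fdr"]]
    selected, flagged, missing_loeuf = [], [], []
    for gid in significant:
        value = loeuf.get(gid)
        if value is None or (isinstance(value, float) and np.isnan(value)):
            missing_loeuf.append(gid)
            continue
        if value > config.loeuf_threshold:  # strict: 0.5 exactly is excluded
            if gid in blocked:
                flagged.append(gid)
            else:
                selected.append(gid)
    return {
        "lof2": sorted(selected),
        "flagged": sorted(flagged),
        "missing_loeuf": sorted(missing_loeuf),
        "n_significant": int(len(significant)),
    }


def cohort_compare_binomial(n_g: int, m_g: int, lambda_trio: float,
                            lambda_sperm_g: float) -> dict:
    """Binomial comparison of per-gene LoF counts between a trio cohort
    (observed n_g, expected lambda_trio) and a sperm dataset (observed m_g,
    expected lambda_sperm_g).

    The null success probability for a sperm-derived LoF is
    p0 = λ_sperm/(λ_sperm + λ_trio) with n_g + m_g trials.  One-sided
    p-values are returned for each direction: excess in the trio cohort
    (P[trio count >= n_g]) and excess in sperm (P[sperm count >= m_g]).
    Only genes with at least one LoF in both datasets are meant to be tested;
    the caller enforces that selection rule.
    """
    if n_g < 0 or m_g < 0:
        raise DataError("counts must be non-negative")
    if n_g + m_g < 1:
        raise DataError("need at least one observed LoF variant")
    if lambda_trio <= 0 and lambda_sperm_g <= 0:
        raise DataError("both expectations are zero")
    total = n_g + m_g
    p0_sperm = lambda_sperm_g / (lambda_sperm_g + lambda_trio)
    p_trio = float(stats.binom.sf(n_g - 1, total, 1.0 - p0_sperm))
    p_sperm = float(stats.binom.sf(m_g - 1, total, p0_sperm))
    return {
        "n_trio": int(n_g),
        "n_sperm": int(m_g),
        "p0_sperm": float(p0_sperm),
        "p_excess_trio": p_trio,
        "p_excess_sperm": p_sperm,
    }


def set_enrichment(counts, lambdas, level: float = 0.95) -> dict:
    """Pooled observed/expected ratio over a gene or site set with a
    gamma-conjugate Poisson confidence interval."""
    n = np.asarray(counts, dtype=float)
    lam = np.asarray(lambdas, dtype=float)
    if n.size == 0:
        raise DataError("empty set")
    total_lam = float(lam.sum())
    if total_lam <= 0:
        raise DataError("total expectation is zero")
    total_n = int(round(float(n.sum())))
    ratio, lo, hi = obs_exp_ratio_ci(total_n, total_lam, level)
    return {"n_obs": total_n, "lambda": total_lam,
            "ratio": ratio, "ci_low": lo, "ci_high": hi}
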