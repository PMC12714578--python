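"""Binned site-frequency-spectrum model and per-gene s_het re-estimation.

Sampled allele counts K are binned (boundaries below, half-open, with counts
at or above the last boundary clipped into the final bin).  Within each
mutation-rate bin the neutral SFS is a saturated multinomial expressed as
log-odds against the monomorphic class:

    log P(K = i | μ) / P(K = 0 | μ) = β_i^μ .

Selection shifts every polymorphic class down in proportion to √s_het:

    log P(K = i | μ) / P(K = 0 | μ) = β_i^μ - β_i^s √s_het ,

with β^μ fitted on synonymous sites, β^s fitted on all LoF sites by maximum
likelihood (L-BFGS-B) using per-gene prior s_het values as covariates, and a
per-gene s_het then re-estimated on that gene's LoF sites by bounded maximum
likelihood on [0, 1].

Because clonal expansion in spermatogonia (CES) inflates the realised
mutation rate, fitting a CES-unaware model to κ > 1 genes biases ŝ_het
downward — the diagnostic direction exploited to corroborate CES candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import ConfigError, ConvergenceError, DataError

__all__ = [
    "SFSBinning",
    "SFSModel",
    "SHetEstimate",
    "bin_allele_count",
    "fit_neutral_sfs",
    "fit_selection_model",
    "estimate_shet",
]

#: Allele-count bin boundaries; bin j is [b_j, b_{j+1}), k >= 100 joins the last bin.
COUNT_BIN_BOUNDARIES = (0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 16, 24, 36, 100)

#: Pseudo-count for empty non-reference bins in the saturated neutral fit.
EPSILON = 0.5

BETA_S_BOUNDS = (-50.0, 50.0)


@dataclass
class SFSBinning:
    count_bin_boundaries: tuple[int, ...] = COUNT_BIN_BOUNDARIES
    mu_bin_edges: np.ndarray | None = None  # default: deciles of the fitting set

    def __post_init__(self) -> None:
        b = self.count_bin_boundaries
        if any(b[i] >= b[i + 1] for i in range(len(b) - 1)):
            raise ConfigError("count bin boundaries must be strictly increasing")
        if b[0] != 0:
            raise ConfigError("first count bin boundary must be 0 (monomorphic class)")

    @property
    def n_count_bins(self) -> int:
        return len(self.count_bin_boundaries) - 1


def bin_allele_count(k, binning: SFSBinning | None = None) -> np.ndarray:
    """Map allele counts to bin indices (half-open bins, overflow clipped)."""
    binning = binning or SFSBinning()
    karr = np.atleast_1d(np.asarray(k))
    if np.any(karr < 0):
        raise DataError("negative allele count")
    bounds = np.asarray(binning.count_bin_boundaries)
    idx = np.searchsorted(bounds, karr, side="right") - 1
    return np.minimum(idx, binning.n_count_bins - 1)


def _mu_bin_edges(mu: np.ndarray, n_bins: int = 10) -> np.ndarray:
    qs = np.quantile(mu, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(qs)
    if edges.size < 2:
        edges = np.array([mu.min(), mu.max() + 1.0])
    return edges


def _assign_mu_bin(mu: np.ndarray, edges: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(edges, mu, side="right") - 1
    return np.clip(idx, 0, edges.size - 2)


@dataclass
class SFSModel:
    """Fitted SFS coefficients: neutral log-odds per (count-bin, μ-bin) and
    selection coefficients of √s_het per count-bin (reference bin fixed 0)."""

    binning: SFSBinning
    mu_edges: np.ndarray
    beta_mu: np.ndarray              # (n_mu_bins, n_count_bins), [:,0] == 0
    beta_s: np.ndarray | None = None  # (n_count_bins,), [0] == 0
    shet_exponent: float = 0.5        # sensitivity knob; 0.5 is the model

    def logits(self, mu_bin: np.ndarray, s_het: float | np.ndarray) -> np.ndarray:
        if self.beta_s is None:
            raise ConfigError("selection coefficients not fitted")
        s = np.atleast_1d(np.asarray(s_het, dtype=float))
        return self.beta_mu[mu_bin] - np.power(s, self.shet_exponent)[:, None] * self.beta_s

    def log_probs(self, mu_bin: np.ndarray, s_het: float | np.ndarray) -> np.ndarray:
        z = self.logits(mu_bin, s_het)
        z = z - z.max(axis=1, keepdims=True)
        return z - np.log(np.exp(z).sum(axis=1, keepdims=True))


def fit_neutral_sfs(sites: pd.DataFrame, binning: SFSBinning | None = None,
                    n_mu_bins: int = 10, epsilon: float = EPSILON) -> SFSModel:
    """Saturated multinomial fit of the neutral SFS per mutation-rate bin.

    ``sites`` needs columns ``mu`` and ``k``.  β_i^μ = log(c_i/c_0) with a
    pseudo-count for empty non-reference bins; an empty reference (k = 0)
    class in any μ-bin is an error.
    """
    binning = binning or SFSBinning()
    for col in ("mu", "k"):
        if col not in sites.columns:
            raise DataError(f"site table missing column {col!r}")
    mu = sites["mu"].to_numpy(dtype=float)
    k = sites["k"].to_numpy()
    edges = (binning.mu_bin_edges if binning.mu_bin_edges is not None
             else _mu_bin_edges(mu, n_mu_bins))
    edges = np.asarray(edges, dtype=float)
    mu_bin = _assign_mu_bin(mu, edges)
    kbin = bin_allele_count(k, binning)
    B, I = edges.size - 1, binning.n_count_bins
    counts = np.zeros((B, I))
    np.add.at(counts, (mu_bin, kbin), 1.0)
    if np.any(counts[:, 0] == 0):
        empty = np.nonzero(counts[:, 0] == 0)[0]
        raise DataError(f"empty reference (k=0) class in mu-bins {empty.tolist()}")
    padded = np.where(counts == 0, epsilon, counts)
    beta_mu = np.log(padded / padded[:, [0]])
    beta_mu[:, 0] = 0.0
    return SFSModel(binning=binning, mu_edges=edges, beta_mu=beta_mu)


def _aggregate(sites: pd.DataFrame, model: SFSModel,
               shet: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Collapse sites into unique (mu_bin, s_het) cells with count matrices."""
    mu = sites["mu"].to_numpy(dtype=float)
    k = sites["k"].to_numpy()
    mu_bin = _assign_mu_bin(mu, model.mu_edges)
    kbin = bin_allele_count(k, model.binning)
    key = pd.MultiIndex.from_arrays([mu_bin, np.round(shet, 12)])
    codes, uniques = pd.factorize(key)
    I = model.binning.n_count_bins
    cells = np.zeros((len(uniques), I))
    np.add.at(cells, (codes, kbin), 1.0)
    cell_mu = np.fromiter((u[0] for u in uniques), dtype=int, count=len(uniques))
    cell_s = np.fromiter((u[1] for u in uniques), dtype=float, count=len(uniques))
    return cells, cell_mu, cell_s


def _model_loglik(model: SFSModel, cells: np.ndarray, cell_mu: np.ndarray,
                  cell_s: np.ndarray, beta_s: np.ndarray) -> tuple[float, np.ndarray]:
    """Log-likelihood and gradient w.r.t. beta_s[1:] on aggregated cells."""
    root_s = np.power(cell_s, model.shet_exponent)
    z = model.beta_mu[cell_mu] - root_s[:, None] * beta_s[None, :]
    zmax = z.max(axis=1, keepdims=True)
    logZ = zmax[:, 0] + np.log(np.exp(z - zmax).sum(axis=1))
    tot = cells.sum(axis=1)
    ll = float(np.sum(cells * z) - np.sum(tot * logZ))
    probs = np.exp(z - logZ[:, None])
    # d ll / d beta_s_i = sum_cells root_s * (tot * P_i - c_i)
    grad = np.sum(root_s[:, None] * (tot[:, None] * probs - cells), axis=0)
    return ll, grad[1:]


def fit_selection_model(lof_sites: pd.DataFrame, prior_shet: pd.Series,
                        neutral: SFSModel) -> SFSModel:
    """Fit the β^s coefficients on LoF sites using per-gene prior s_het.

    ``lof_sites`` needs columns ``gene_id``, ``mu``, ``k``; ``prior_shet``
    maps gene_id -> prior mean s_het.  All-identical priors leave β^s
    unidentifiable and raise.
    """
    for col in ("gene_id", "mu", "k"):
        if col not in lof_sites.columns:
            raise DataError(f"LoF site table missing column {col!r}")
    prior = prior_shet.reindex(lof_sites["gene_id"])
    if prior.isna().any():
        missing = sorted(set(lof_sites.loc[prior.isna().to_numpy(), "gene_id"]))
        raise DataError(f"genes without prior s_het: {missing[:5]}")
    shet = prior.to_numpy(dtype=float)
    if np.any(shet < 0) or np.any(shet > 1):
        raise DataError("prior s_het must lie in [0, 1]")
    if np.allclose(shet, shet[0]):
        raise DataError("all prior s_het identical: selection coefficients "
                        "are unidentifiable")
    cells, cell_mu, cell_s = _aggregate(lof_sites, neutral, shet)
    I = neutral.binning.n_count_bins

    def objective(bs_free: np.ndarray) -> tuple[float, np.ndarray]:
        beta_s = np.concatenate([[0.0], bs_free])
        ll, grad = _model_loglik(neutral, cells, cell_mu, cell_s, beta_s)
        return -ll, -grad

    x0 = np.zeros(I - 1)
    res = optimize.minimize(objective, x0, jac=True, method="L-BFGS-B",
                            bounds=[BETA_S_BOUNDS] * (I - 1))
    if not res.success:
        raise ConvergenceError(f"beta_s fit failed: {res.message}")
    beta_s = np.concatenate([[0.0], res.x])
    return SFSModel(binning=neutral.binning, mu_edges=neutral.mu_edges,
                    beta_mu=neutral.beta_mu, beta_s=beta_s,
                    shet_exponent=neutral.shet_exponent)


@dataclass
class SHetEstimate:
    gene_id: str
    s_het: float
    logL: float
    at_boundary: bool
    n_sites: int = 0

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _gene_loglik(model: SFSModel, cell_counts: np.ndarray, cell_mu: np.ndarray,
                 s: float) -> float:
    beta_s = model.beta_s
    z = model.beta_mu[cell_mu] - (s ** model.shet_exponent) * beta_s[None, :]
    zmax = z.max(axis=1, keepdims=True)
    logZ = zmax[:, 0] + np.log(np.exp(z - zmax).sum(axis=1))
    return float(np.sum(cell_counts * z) - np.sum(cell_counts.sum(axis=1) * logZ))


def estimate_shet(gene_sites: pd.DataFrame, model: SFSModel,
                  tol: float = 1e-6) -> SHetEstimate:
    """Per-gene maximum-likelihood s_het bounded to [0, 1].

    Bounded scalar maximisation with explicit endpoint evaluation, so
    boundary optima (monomorphic genes pushing s_het to 1, polymorphism-rich
    genes pushing it to 0) are reported with ``at_boundary`` set.
    """
    if model.beta_s is None:
        raise ConfigError("model has no fitted selection coefficients")
    if len(gene_sites) == 0:
        raise DataError("no sites for gene")
    gid = str(gene_sites["gene_id"].iloc[0]) if "gene_id" in gene_sites.columns else ""
    mu = gene_sites["mu"].to_numpy(dtype=float)
    kbin = bin_allele_count(gene_sites["k"].to_numpy(), model.binning)
    mu_bin = _assign_mu_bin(mu, model.mu_edges)
    I = model.binning.n_count_bins
    B = model.mu_edges.size - 1
    counts = np.zeros((B, I))
    np.add.at(counts, (mu_bin, kbin), 1.0)
    used = counts.sum(axis=1) > 0
    cell_counts, cell_mu = counts[used], np.nonzero(used)[0]

    res = optimize.minimize_scalar(
        lambda s: -_gene_loglik(model, cell_counts, cell_mu, s),
        bounds=(0.0, 1.0), method="bounded", options={"xatol": tol})
    candidates = [(float(res.x), -float(res.fun))] + [
        (s, _gene_loglik(model, cell_counts, cell_mu, s)) for s in (0.0, 1.0)]
    s_hat, ll = max(candidates, key=lambda t: t[1])
    at_boundary = s_hat <= tol or s_hat >= 1.0 - tol
    return SHetEstimate(gene_id=gid, s_het=float(np.clip(s_hat, 0.0, 1.0)),
                        logL=ll, at_boundary=bool(at_boundary),
                        n_sites=int(len(gene_sites)))
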