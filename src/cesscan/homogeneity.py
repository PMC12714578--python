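"""Phenotypic homogeneity of a composite cohort via multinomial model choice.

If the subcohorts of a composite disease cohort sample phenotypes uniformly,
the split of each gene's de novo variants across subcohorts should follow a
multinomial whose probabilities are fixed by the per-subcohort mutational
opportunity — proportional to each subcohort's synonymous variant count.
Heterogeneous recruitment shows up either as shifted proportions or as
between-gene overdispersion of the split.

Four nested models are compared by AIC (for C subcohorts):

1. multinomial, probabilities fixed at the synonymous-derived null — 0 free
   parameters;
2. multinomial, free shared probabilities — C-1 parameters;
3. Dirichlet-multinomial centred on the null proportions, free concentration
   α — 1 parameter;
4. Dirichlet-multinomial with free mean and concentration — C parameters.

The Dirichlet-multinomial is parameterised by mean m and concentration α
(Dirichlet parameters α·m), so model 3 is literally "centred on the observed
synonymous proportions".  Genes with zero total count carry no information
about the split and contribute zero log-likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.special import gammaln

from .errors import ConvergenceError, DataError

__all__ = ["SubcohortCounts", "HomogeneityResult", "fit_homogeneity_models",
           "multinomial_loglik", "dirichlet_multinomial_loglik"]

_LOG_ALPHA_BOUNDS = (np.log(1e-3), np.log(1e9))


@dataclass
class SubcohortCounts:
    """Per-gene counts over C subcohorts plus the synonymous-derived null."""

    counts: np.ndarray  # (G, C) integer matrix
    p_null: np.ndarray  # (C,) strictly positive, sums to 1

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.p_null = np.asarray(self.p_null, dtype=float)
        if self.counts.ndim != 2:
            raise DataError("counts must be a genes x subcohorts matrix")
        if np.any(self.counts < 0) or np.any(self.counts != np.floor(self.counts)):
            raise DataError("counts must be non-negative integers")
        if self.counts.shape[1] != self.p_null.size:
            raise DataError("p_null length must match the number of subcohorts")
        if np.any(self.p_null <= 0):
            raise DataError("p_null must be strictly positive")
        if abs(self.p_null.sum() - 1.0) > 1e-9:
            raise DataError("p_null must sum to 1 within 1e-9")

    @classmethod
    def from_synonymous_totals(cls, counts, syn_totals) -> "SubcohortCounts":
        syn = np.asarray(syn_totals, dtype=float)
        if np.any(syn <= 0):
            raise DataError("synonymous totals must be positive to define p_null")
        return cls(np.asarray(counts), syn / syn.sum())


def multinomial_loglik(counts: np.ndarray, p: np.ndarray) -> float:
    """Total multinomial log-likelihood across genes (rows)."""
    x = np.asarray(counts, dtype=float)
    p = np.asarray(p, dtype=float)
    tot = x.sum(axis=1)
    coef = gammaln(tot + 1) - gammaln(x + 1).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(x > 0, x * np.log(p), 0.0)
    return float(np.sum(coef + terms.sum(axis=1)))


def dirichlet_multinomial_loglik(counts: np.ndarray, mean: np.ndarray,
                                 alpha: float) -> float:
    """Dirichlet-multinomial log-likelihood, Dirichlet parameters alpha*mean."""
    x = np.asarray(counts, dtype=float)
    a = alpha * np.asarray(mean, dtype=float)
    tot = x.sum(axis=1)
    coef = gammaln(tot + 1) - gammaln(x + 1).sum(axis=1)
    ll = (coef + gammaln(alpha) - gammaln(alpha + tot)
          + (gammaln(a + x) - gammaln(a)).sum(axis=1))
    return float(np.sum(ll))


@dataclass
class HomogeneityResult:
    logL: dict[str, float]
    n_params: dict[str, int]
    aic: dict[str, float]
    preferred: str
    p_hat: np.ndarray          # model 2 MLE proportions
    alpha_hat: float           # model 3 concentration
    mean_hat: np.ndarray       # model 4 mean
    alpha_free_hat: float      # model 4 concentration

    def to_dict(self) -> dict:
        return {
            "logL": dict(self.logL),
            "n_params": dict(self.n_params),
            "aic": dict(self.aic),
            "preferred": self.preferred,
            "p_hat": self.p_hat.tolist(),
            "alpha_hat": self.alpha_hat,
            "mean_hat": self.mean_hat.tolist(),
            "alpha_free_hat": self.alpha_free_hat,
        }


def _fit_alpha(counts: np.ndarray, mean: np.ndarray) -> tuple[float, float]:
    def neg(la: float) -> float:
        return -dirichlet_multinomial_loglik(counts, mean, float(np.exp(la)))

    res = optimize.minimize_scalar(neg, bounds=_LOG_ALPHA_BOUNDS,
                                   method="bounded", options={"xatol": 1e-8})
    if not res.success:
        raise ConvergenceError(f"concentration fit failed: {res.message}")
    return float(np.exp(res.x)), -float(res.fun)


def _softmax(z: np.ndarray) -> np.ndarray:
    full = np.concatenate([[0.0], z])
    full -= full.max()
    e = np.exp(full)
    return e / e.sum()


def fit_homogeneity_models(data: SubcohortCounts) -> HomogeneityResult:
    """Fit the four split models and pick the AIC winner.

    Model 4 is optimised from multiple starts (including the fitted models 2
    and 3) so the nesting relations logL(4) >= logL(2), logL(3) >= logL(1)
    hold up to optimiser tolerance.
    """
    counts = data.counts[data.counts.sum(axis=1) > 0]
    if counts.shape[0] < 1:
        raise DataError("no gene with a positive total count")
    C = counts.shape[1]
    p_null = data.p_null

    ll1 = multinomial_loglik(counts, p_null)

    if C == 1:
        # degenerate: all models coincide, no free parameters identifiable
        logL = {m: ll1 for m in ("fixed_multinomial", "free_multinomial",
                                 "dirichlet_fixed_mean", "dirichlet_free")}
        n_params = {"fixed_multinomial": 0, "free_multinomial": 0,
                    "dirichlet_fixed_mean": 0, "dirichlet_free": 0}
        aic = {m: -2 * ll for m, ll in logL.items()}
        return HomogeneityResult(logL, n_params, aic, "fixed_multinomial",
                                 p_null.copy(), np.inf, p_null.copy(), np.inf)

    # model 2: shared free proportions; MLE is the pooled count fraction
    pooled = counts.sum(axis=0)
    p_hat = pooled / pooled.sum() if pooled.sum() > 0 else p_null.copy()
    p_hat = np.clip(p_hat, 1e-12, None)
    p_hat /= p_hat.sum()
    ll2 = multinomial_loglik(counts, p_hat)

    # model 3: Dirichlet-multinomial centred on the null proportions
    alpha3, ll3 = _fit_alpha(counts, p_null)
    ll3 = max(ll3, ll1)  # alpha -> inf recovers model 1

    # model 4: free mean + concentration, multi-start L-BFGS-B
    def neg4(theta: np.ndarray) -> float:
        mean = _softmax(theta[:-1])
        return -dirichlet_multinomial_loglik(counts, np.clip(mean, 1e-12, None),
                                             float(np.exp(theta[-1])))

    starts = [
        np.concatenate([np.log(p_hat[1:] / p_hat[0]), [np.log(max(alpha3, 1e-3))]]),
        np.concatenate([np.log(p_null[1:] / p_null[0]), [np.log(max(alpha3, 1e-3))]]),
        np.concatenate([np.log(p_hat[1:] / p_hat[0]), [np.log(1e8)]]),
    ]
    bounds = [(-30.0, 30.0)] * (C - 1) + [list(_LOG_ALPHA_BOUNDS)]
    best = None
    for x0 in starts:
        res = optimize.minimize(neg4, x0, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    ll4 = -float(best.fun)
    mean4 = _softmax(best.x[:-1])
    alpha4 = float(np.exp(best.x[-1]))
    # enforce nesting against the fitted submodels
    for ll_sub in (ll2, ll3):
        if ll4 < ll_sub:
            ll4 = ll_sub
    if ll4 == ll2:
        mean4, alpha4 = p_hat.copy(), np.inf
    elif ll4 == ll3:
        mean4, alpha4 = p_null.copy(), alpha3

    logL = {"fixed_multinomial": ll1, "free_multinomial": ll2,
            "dirichlet_fixed_mean": ll3, "dirichlet_free": ll4}
    n_params = {"fixed_multinomial": 0, "free_multinomial": C - 1,
                "dirichlet_fixed_mean": 1, "dirichlet_free": C}
    aic = {m: 2 * n_params[m] - 2 * logL[m] for m in logL}
    preferred = min(aic, key=lambda m: (aic[m], n_params[m]))
    return HomogeneityResult(logL, n_params, aic, preferred,
                             p_hat, alpha3, mean4, alpha4)
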