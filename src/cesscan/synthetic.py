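"""Synthetic cohort generator with known ground truth.

Every input the pipeline consumes can be generated here: a rate table of
possible SNVs grouped into genes, de novo counts for ascertained and control
trio cohorts, subcohort splits, gamma-Poisson population allele counts and
sperm (duplex-sequencing-like) counts.  The generative models mirror the
statistical assumptions of the analysis:

* de novo counts at site v are negative binomial with mean

      N_probands · c · μ_v · κ_v · A_v

  and variance inflation γ, where c converts unscaled rate units to a
  per-generation probability, κ_v ≥ 1 is the clonal-expansion factor and
  A_v the ascertainment factor — P(D|V)/P(D), capped at 1/P(D), in a
  disease-ascertained cohort, and (1-P(D|V))/(1-P(D)) (≈ 1) in controls;
* population allele frequencies follow the gamma-Poisson (Nei) model:
  p ~ Gamma(4Nₑκμ_gen, 1/(4Nₑs)), k ~ Poisson(n_chrom·p), valid only under
  strong selection s > 1/(4Nₑ);
* sperm counts are Poisson with mean depth·μ_gen·κ and no ascertainment.

Synonymous sites always carry κ = 1 and A = 1: they define the neutral
normalisation the analysis relies on.  A gene absent from the penetrance map
confers background risk, P(D|V) = P(D), so its ascertainment factor is 1.
All generators are deterministic given the config seed.
"""

from __future__ import annotations

import zlib

import numpy as np
import pandas as pd

from .config import SyntheticConfig
from .errors import ConfigError
from .homogeneity import SubcohortCounts

__all__ = [
    "simulate_rate_table",
    "simulate_denovo_cohort",
    "simulate_subcohort_split",
    "simulate_population",
    "simulate_sperm_counts",
    "gene_ids",
]

_BASES = np.array(["A", "C", "G", "T"], dtype=object)
_LOF_KINDS = ("stop_gained", "splice_donor", "splice_acceptor")


def gene_ids(config: SyntheticConfig) -> list[str]:
    return [f"G{i:04d}" for i in range(config.n_genes)]


def _rng(config: SyntheticConfig, stream: str) -> np.random.Generator:
    # independent, reproducible stream per generator (crc32 is stable,
    # unlike Python's randomised str hash)
    key = zlib.crc32(stream.encode())
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(config.seed), spawn_key=(key,)))


def simulate_rate_table(config: SyntheticConfig) -> pd.DataFrame:
    """Generate the site (rate) table: one row per possible SNV.

    Unscaled rates come from the two-component mixture in
    ``config.rate_model``: a low-rate body (all ≤ 1) and a "CpG-like" spike
    whose sites all exceed 1.  Columns follow the canonical site schema plus
    ``mu_gen`` (per-generation probability = mu · mu_scale).
    """
    config.validate()
    rng = _rng(config, "rates")
    rm = config.rate_model
    n = config.n_genes * config.sites_per_gene
    genes = np.repeat(np.array(gene_ids(config), dtype=object),
                      config.sites_per_gene)

    spike = rng.random(n) < rm.spike_weight
    mu = np.exp(rng.uniform(np.log(rm.low_lo), np.log(rm.low_hi), size=n))
    n_spike = int(spike.sum())
    if n_spike:
        mu[spike] = np.exp(rng.normal(rm.spike_log_mean, rm.spike_log_sd,
                                      size=n_spike))

    fracs = np.array([config.frac_synonymous, config.frac_missense,
                      config.frac_lof])
    fracs = np.append(fracs, max(0.0, 1.0 - fracs.sum()))
    cons_groups = np.searchsorted(np.cumsum(fracs / fracs.sum()), rng.random(n),
                                  side="right")
    is_lof_group = cons_groups == 2
    lof_kind = np.searchsorted(np.cumsum([0.6, 0.2, 0.2]), rng.random(n),
                               side="right")
    cons_code = np.where(is_lof_group, 3 + np.minimum(lof_kind, 2),
                         np.array([0, 1, 0, 2])[np.minimum(cons_groups, 3)])
    labels = np.array(["synonymous", "missense", "other",
                       "stop_gained", "splice_donor", "splice_acceptor"],
                      dtype=object)
    consequence = labels[cons_code]

    conf_labels = np.array(["none", "low", "high"], dtype=object)
    lof_confidence = conf_labels[np.where(
        is_lof_group, np.where(rng.random(n) < 0.9, 2, 1), 0)]
    qual_code = np.searchsorted(np.cumsum([0.90, 0.05, 0.05]), rng.random(n),
                                side="right")
    quality = np.array(["high", "TFBS", "low"],
                       dtype=object)[np.minimum(qual_code, 2)]
    am_score = np.full(n, np.nan)
    mis = consequence == "missense"
    am_score[mis] = rng.random(int(mis.sum()))

    chrom = (np.arange(config.n_genes) % 22 + 1).astype(str).astype(object)
    within = np.arange(n) % config.sites_per_gene
    gene_idx = np.arange(n) // config.sites_per_gene
    pos = within + 1 + gene_idx * (config.sites_per_gene + 1000)
    ref_idx = rng.integers(0, 4, size=n)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4

    return pd.DataFrame({
        "chrom": np.repeat(chrom, config.sites_per_gene),
        "pos": pos,
        "ref": _BASES[ref_idx],
        "alt": _BASES[alt_idx],
        "gene_id": genes,
        "consequence": consequence,
        "lof_confidence": lof_confidence,
        "quality": quality,
        "mu": mu,
        "am_score": am_score,
        "mu_gen": mu * rm.mu_scale,
    })


def _gene_map(sites: pd.DataFrame, mapping, default: float) -> np.ndarray:
    vals = sites["gene_id"].map(dict(mapping))
    return vals.fillna(default).to_numpy(dtype=float)


def _per_site_kappa(sites: pd.DataFrame, config: SyntheticConfig) -> np.ndarray:
    """Gene-level κ applies to that gene's LoF sites; per-site overrides apply
    anywhere; synonymous sites always have κ = 1."""
    kappa = np.ones(len(sites))
    gene_kappa = _gene_map(sites, config.kappa, config.kappa_default)
    is_lof = sites["consequence"].isin(_LOF_KINDS).to_numpy()
    kappa[is_lof] = gene_kappa[is_lof]
    if dict(config.kappa_sites):
        loc = sites.index.get_indexer(list(config.kappa_sites.keys()))
        if np.any(loc < 0):
            raise ConfigError("kappa_sites refers to unknown site indices")
        kappa[loc] = list(config.kappa_sites.values())
    kappa[sites["consequence"].eq("synonymous").to_numpy()] = 1.0
    return kappa


def _penetrance(sites: pd.DataFrame, config: SyntheticConfig) -> np.ndarray:
    """P(D|V) per site; genes absent from the map get the default, and a
    default of None means background risk P(D) (no disease effect)."""
    default = (config.prevalence if config.penetrance_default is None
               else config.penetrance_default)
    pen = _gene_map(sites, config.penetrance, default)
    if np.any(pen < 0.0) or np.any(pen > 1.0):
        raise ConfigError("penetrance must lie in [0, 1]")
    # synonymous variants never alter disease risk
    return np.where(sites["consequence"].eq("synonymous").to_numpy(),
                    config.prevalence, pen)


def _ascertainment(sites: pd.DataFrame, config: SyntheticConfig,
                   ascertained: bool) -> np.ndarray:
    pen = _penetrance(sites, config)
    P = config.prevalence
    if ascertained:
        return np.minimum(pen / P, 1.0 / P)
    return (1.0 - pen) / (1.0 - P)


def simulate_denovo_cohort(sites: pd.DataFrame, config: SyntheticConfig,
                           ascertained: bool = False,
                           n_probands: int | None = None,
                           stream: str = "denovo") -> pd.Series:
    """Draw per-site de novo counts for one cohort.

    Counts are negative binomial with mean
    N · μ_gen,v · κ_v · A_v · embryonic_survival and variance m(1+γ)
    (Poisson when γ = 0).  Returns an integer Series aligned to ``sites``.
    """
    config.validate()
    rng = _rng(config, stream)
    N = n_probands if n_probands is not None else config.n_probands
    kappa = _per_site_kappa(sites, config)
    A = _ascertainment(sites, config, ascertained)
    surv = np.where(sites["consequence"].eq("synonymous").to_numpy(),
                    1.0, config.embryonic_survival)
    mean = N * sites["mu_gen"].to_numpy(dtype=float) * kappa * A * surv
    counts = np.zeros(len(sites), dtype=np.int64)
    pos = mean > 0
    if config.gamma > 0:
        r = mean[pos] / config.gamma
        counts[pos] = rng.negative_binomial(r, 1.0 / (1.0 + config.gamma))
    else:
        counts[pos] = rng.poisson(mean[pos])
    return pd.Series(counts, index=sites.index, name="n")


def simulate_subcohort_split(gene_totals: pd.Series, config: SyntheticConfig,
                             n_synonymous_total: int = 10_000,
                             stream: str = "split") -> tuple[SubcohortCounts, np.ndarray]:
    """Split per-gene counts across subcohorts under the configured model.

    Returns the SubcohortCounts container (per-gene split matrix plus the
    synonymous-derived null proportions) and the simulated per-subcohort
    synonymous totals that define those proportions.  With a single
    subcohort the split is the identity.
    """
    config.validate()
    spec = config.subcohort
    rng = _rng(config, stream)
    p = np.asarray(spec.proportions, dtype=float)
    C = p.size
    totals = gene_totals.to_numpy(dtype=int)
    if C == 1:
        syn = np.array([n_synonymous_total])
        return SubcohortCounts(totals[:, None], np.array([1.0])), syn

    syn_totals = np.maximum(rng.multinomial(n_synonymous_total, p), 1)

    draw_p = p
    if spec.model in ("free-multinomial", "dirichlet-free"):
        draw_p = np.asarray(
            spec.shifted_proportions if spec.shifted_proportions is not None
            else np.roll(p, 1), dtype=float)
    G = totals.size
    if spec.model in ("fixed-multinomial", "free-multinomial"):
        counts = rng.multinomial(totals, np.tile(draw_p, (G, 1)))
    else:
        q = rng.dirichlet(spec.concentration * draw_p, size=G)
        counts = np.array([rng.multinomial(t, qi) for t, qi in zip(totals, q)])
    return SubcohortCounts.from_synonymous_totals(counts, syn_totals), syn_totals


def simulate_population(sites: pd.DataFrame, config: SyntheticConfig,
                        stream: str = "popgen") -> pd.DataFrame:
    """Gamma-Poisson population allele counts at the given sites.

    Per site: p ~ Gamma(shape 4Nₑκμ_gen, scale 1/(4Nₑs)), k ~ Poisson(n·p).
    Refuses the weak-selection regime s ≤ 1/(4Nₑ) where the approximation
    breaks down.
    """
    config.validate()
    rng = _rng(config, stream)
    pg = config.popgen
    if isinstance(pg.s, dict) or hasattr(pg.s, "get"):
        s = _gene_map(sites, pg.s, 0.05)
    else:
        s = np.full(len(sites), float(pg.s))
    if np.any(s <= 0):
        raise ConfigError("selection coefficient s <= 0: outside gamma-Poisson validity")
    if np.any(s <= 1.0 / (4.0 * pg.Ne)):
        raise ConfigError(
            "weak-selection regime s <= 1/(4 Ne): outside gamma-Poisson validity")
    kappa = _per_site_kappa(sites, config)
    shape = 4.0 * pg.Ne * kappa * sites["mu_gen"].to_numpy(dtype=float)
    scale = 1.0 / (4.0 * pg.Ne * s)
    freq = rng.gamma(shape, scale)
    k = (rng.poisson(pg.n_chrom * freq) if pg.n_chrom > 0
         else np.zeros(len(sites), dtype=np.int64))
    out = sites[["chrom", "pos", "ref", "alt", "gene_id", "quality",
                 "mu", "mu_gen"]].copy()
    out["k"] = k
    out["n_chrom"] = pg.n_chrom
    return out


def simulate_sperm_counts(sites: pd.DataFrame, config: SyntheticConfig,
                          stream: str = "sperm") -> pd.Series:
    """Poisson counts with mean depth · μ_gen · κ; no ascertainment factor."""
    config.validate()
    rng = _rng(config, stream)
    kappa = _per_site_kappa(sites, config)
    mean = config.sperm.depth * sites["mu_gen"].to_numpy(dtype=float) * kappa
    return pd.Series(rng.poisson(mean), index=sites.index, name="n")
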