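"""Generator contracts: determinism, mixture structure, ascertainment bound,
subcohort splits, gamma-Poisson moments and sperm counts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cesscan.config import (PopgenSpec, RateMixture, SpermSpec, SubcohortSpec,
                            SyntheticConfig)
from cesscan.errors import ConfigError
from cesscan.mutmodel import filter_sites
from cesscan.synthetic import (simulate_denovo_cohort, simulate_population,
                               simulate_rate_table, simulate_sperm_counts,
                               simulate_subcohort_split)


def base_config(**kw):
    defaults = dict(seed=5, n_genes=25, sites_per_gene=1500)
    defaults.update(kw)
    return SyntheticConfig(**defaults)


class TestRateTable:
    def test_same_seed_gives_identical_tables(self):
        cfg = base_config()
        a = simulate_rate_table(cfg)
        b = simulate_rate_table(base_config())
        pd.testing.assert_frame_equal(a, b)

    def test_different_seed_differs(self):
        a = simulate_rate_table(base_config())
        b = simulate_rate_table(base_config(seed=6))
        assert not a["mu"].equals(b["mu"])

    def test_zero_spike_weight_keeps_all_rates_at_most_one(self):
        cfg = base_config(rate_model=RateMixture(spike_weight=0.0))
        sites = simulate_rate_table(cfg)
        assert (sites["mu"] <= 1.0).all()

    def test_spike_fraction_within_binomial_bounds(self):
        cfg = base_config(rate_model=RateMixture(spike_weight=0.2),
                          n_genes=10, sites_per_gene=1000)
        sites = simulate_rate_table(cfg)
        n = len(sites)
        observed = int((sites["mu"] > 1.0).sum())
        lo, hi = stats.binom.ppf([0.005, 0.995], n, 0.2)
        assert lo <= observed <= hi

    def test_invalid_mixture_weight_rejected(self):
        with pytest.raises(ConfigError):
            base_config(rate_model=RateMixture(spike_weight=1.5)).validate()

    def test_mean_per_generation_rate_near_target(self):
        sites = simulate_rate_table(base_config(n_genes=40))
        assert sites["mu_gen"].mean() == pytest.approx(1.2e-8, rel=0.15)


class TestDeNovoCohort:
    def test_unascertained_neutral_cohort_pooled_ratio_is_one(self):
        # kappa = 1, no disease effect: observed/expected -> 1 over replicates
        cfg = base_config(n_probands=200_000)
        sites = simulate_rate_table(cfg)
        mu = sites["mu_gen"].to_numpy()
        expected = cfg.n_probands * mu.sum()
        ratios = []
        for rep in range(25):
            cfg.seed = 1000 + rep
            counts = simulate_denovo_cohort(sites, cfg, ascertained=False)
            ratios.append(counts.sum() / expected)
        se = np.std(ratios, ddof=1) / np.sqrt(len(ratios))
        assert abs(np.mean(ratios) - 1.0) < 3 * se + 1e-3

    def test_full_penetrance_ascertainment_gives_inverse_prevalence(self):
        cfg = base_config(prevalence=0.01,
                          penetrance={f"G{i:04d}": 1.0 for i in range(25)},
                          n_probands=100_000)
        sites = simulate_rate_table(cfg)
        lof = filter_sites(sites, "lof")
        mu = sites.loc[lof.index, "mu_gen"].to_numpy()
        ratios = []
        for rep in range(10):
            cfg.seed = 2000 + rep
            counts = simulate_denovo_cohort(sites, cfg, ascertained=True)
            ratios.append(counts.loc[lof.index].sum() / (cfg.n_probands * mu.sum()))
        assert np.mean(ratios) == pytest.approx(100.0, rel=0.05)

    def test_kappa_inflates_one_genes_lof_ratio(self):
        cfg = base_config(kappa={"G0001": 20.0}, n_probands=3_000_000)
        sites = simulate_rate_table(cfg)
        lof = filter_sites(sites, "lof")
        g1 = lof[lof["gene_id"] == "G0001"]
        mu = sites.loc[g1.index, "mu_gen"].to_numpy()
        ratios = []
        for rep in range(10):
            cfg.seed = 3000 + rep
            counts = simulate_denovo_cohort(sites, cfg, ascertained=False)
            ratios.append(counts.loc[g1.index].sum() / (cfg.n_probands * mu.sum()))
        assert np.mean(ratios) == pytest.approx(20.0, rel=0.15)

    def test_synonymous_sites_ignore_kappa_and_ascertainment(self):
        cfg = base_config(kappa={f"G{i:04d}": 50.0 for i in range(25)},
                          penetrance={f"G{i:04d}": 1.0 for i in range(25)},
                          n_probands=300_000)
        sites = simulate_rate_table(cfg)
        syn = filter_sites(sites, "synonymous")
        mu = sites.loc[syn.index, "mu_gen"].to_numpy()
        ratios = []
        for rep in range(10):
            cfg.seed = 4000 + rep
            counts = simulate_denovo_cohort(sites, cfg, ascertained=True)
            ratios.append(counts.loc[syn.index].sum() / (cfg.n_probands * mu.sum()))
        assert np.mean(ratios) == pytest.approx(1.0, rel=0.05)

    def test_ascertainment_bound_holds_for_any_penetrance(self):
        # pooled ascertained/baseline ratio <= 1/P(D) when kappa = 1
        rng = np.random.default_rng(0)
        pen = {f"G{i:04d}": float(rng.uniform(0, 1)) for i in range(25)}
        cfg = base_config(penetrance=pen, prevalence=0.01, n_probands=100_000)
        sites = simulate_rate_table(cfg)
        functional = sites[~sites["consequence"].isin(("synonymous", "other"))]
        mu = functional["mu_gen"].to_numpy()
        ratios = []
        for rep in range(50):
            cfg.seed = 5000 + rep
            counts = simulate_denovo_cohort(sites, cfg, ascertained=True)
            ratios.append(counts.loc[functional.index].sum()
                          / (cfg.n_probands * mu.sum()))
        se = np.std(ratios, ddof=1) / np.sqrt(len(ratios))
        assert np.mean(ratios) <= 100.0 + 3 * se

    def test_invalid_penetrance_rejected(self):
        cfg = base_config(penetrance={"G0000": 1.2})
        with pytest.raises(ConfigError):
            cfg.validate()

    def test_variance_inflation_matches_gamma(self):
        cfg = base_config(n_genes=1, sites_per_gene=200_000, gamma=1.0,
                          n_probands=500_000)
        sites = simulate_rate_table(cfg)
        counts = simulate_denovo_cohort(sites, cfg, ascertained=False)
        mean = cfg.n_probands * sites["mu_gen"].to_numpy()
        z = counts.to_numpy() - mean
        # Var = m(1+gamma): compare pooled variance with the prediction
        assert z.var() == pytest.approx((mean * (1 + cfg.gamma)).mean(), rel=0.05)


class TestSubcohortSplit:
    def test_single_subcohort_is_identity(self):
        cfg = base_config(subcohort=SubcohortSpec(proportions=(1.0,)))
        totals = pd.Series([3, 0, 7])
        split, _ = simulate_subcohort_split(totals, cfg)
        assert split.counts.shape == (3, 1)
        assert np.array_equal(split.counts[:, 0], totals.to_numpy())

    def test_proportions_must_sum_to_one(self):
        with pytest.raises(ConfigError):
            base_config(subcohort=SubcohortSpec(
                proportions=(0.5, 0.3, 0.1))).validate()

    def test_fixed_multinomial_totals_within_bounds(self):
        cfg = base_config(subcohort=SubcohortSpec(
            model="fixed-multinomial", proportions=(0.5, 0.3, 0.2)))
        totals = pd.Series(np.full(100, 100))
        split, _ = simulate_subcohort_split(totals, cfg)
        pooled = split.counts.sum(axis=0)
        n = int(pooled.sum())
        for c, p in zip(pooled, (0.5, 0.3, 0.2)):
            lo, hi = stats.binom.ppf([0.005, 0.995], n, p)
            assert lo <= c <= hi

    def test_tiny_concentration_overdisperses_fractions(self):
        totals = pd.Series(np.full(300, 60))
        cfg_m = base_config(subcohort=SubcohortSpec(model="fixed-multinomial"))
        cfg_d = base_config(subcohort=SubcohortSpec(
            model="dirichlet-fixed-mean", concentration=1.0))
        split_m, _ = simulate_subcohort_split(totals, cfg_m)
        split_d, _ = simulate_subcohort_split(totals, cfg_d, stream="split-d")
        var_m = (split_m.counts[:, 0] / 60).var()
        var_d = (split_d.counts[:, 0] / 60).var()
        assert var_d / var_m > 1.5

    def test_split_preserves_totals(self):
        cfg = base_config()
        totals = pd.Series([5, 11, 0, 2])
        split, _ = simulate_subcohort_split(totals, cfg)
        assert np.array_equal(split.counts.sum(axis=1), totals.to_numpy())


class TestPopulationAndSperm:
    def test_zero_chromosomes_give_zero_counts(self):
        cfg = base_config(popgen=PopgenSpec(n_chrom=0))
        sites = simulate_rate_table(cfg)
        pop = simulate_population(sites.head(100), cfg)
        assert (pop["k"] == 0).all()

    def test_mean_allele_count_tracks_inverse_selection(self):
        s = 0.05
        cfg = base_config(n_genes=1, sites_per_gene=10_000,
                          rate_model=RateMixture(spike_weight=1.0),
                          frac_synonymous=0, frac_missense=0, frac_lof=1.0,
                          popgen=PopgenSpec(Ne=1e4, s=s, n_chrom=1_000_000))
        sites = simulate_rate_table(cfg)
        pop = simulate_population(sites, cfg)
        expected = pop["mu_gen"].mean() * 1_000_000 / s
        assert pop["k"].mean() == pytest.approx(expected, rel=0.1)

    def test_gamma_poisson_moments_match_theory(self):
        s, Ne, n = 0.1, 1e4, 1_000_000
        cfg = base_config(n_genes=1, sites_per_gene=10_000,
                          rate_model=RateMixture(spike_weight=1.0),
                          frac_synonymous=0, frac_missense=0, frac_lof=1.0,
                          popgen=PopgenSpec(Ne=Ne, s=s, n_chrom=n))
        pop = simulate_population(simulate_rate_table(cfg), cfg)
        mu = pop["mu_gen"].to_numpy()
        kbar = n * mu.mean() / s
        var_theory = (kbar * (1 + n / (4 * Ne * s))
                      + (n / s) ** 2 * mu.var(ddof=1))
        assert pop["k"].mean() == pytest.approx(kbar, rel=0.1)
        assert pop["k"].var(ddof=1) == pytest.approx(var_theory, rel=0.25)

    def test_nonpositive_selection_rejected(self):
        cfg = base_config(popgen=PopgenSpec(s=0.0))
        sites = simulate_rate_table(cfg).head(10)
        with pytest.raises(ConfigError, match="gamma-Poisson"):
            simulate_population(sites, cfg)

    def test_sperm_null_ratio_is_one(self):
        cfg = base_config(sperm=SpermSpec(depth=1e6))
        sites = simulate_rate_table(cfg)
        counts = simulate_sperm_counts(sites, cfg)
        expected = 1e6 * sites["mu_gen"].sum()
        assert counts.sum() / expected == pytest.approx(1.0, rel=0.02)

    def test_sperm_kappa_500_on_gof_sites(self):
        cfg = base_config(sperm=SpermSpec(depth=2.1e4))
        sites = simulate_rate_table(cfg)
        mis = filter_sites(sites, "missense")
        gof_sites = mis.index[:5]
        cfg.kappa_sites = {int(i): 500.0 for i in gof_sites}
        ratios = []
        for rep in range(20):
            cfg.seed = 6000 + rep
            counts = simulate_sperm_counts(sites, cfg)
            expected = 2.1e4 * sites.loc[gof_sites, "mu_gen"].sum()
            ratios.append(counts.loc[gof_sites].sum() / expected)
        assert np.mean(ratios) == pytest.approx(500.0, rel=0.1)

    def test_zero_depth_gives_all_zero(self):
        cfg = base_config(sperm=SpermSpec(depth=0.0))
        sites = simulate_rate_table(cfg)
        assert (simulate_sperm_counts(sites, cfg) == 0).all()
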