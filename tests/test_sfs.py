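"""Binned SFS model: count binning, neutral fit, selection fit, s_het MLE."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cesscan.config import PopgenSpec, RateMixture, SyntheticConfig
from cesscan.errors import DataError
from cesscan.sfs import (SFSBinning, bin_allele_count, estimate_shet,
                         fit_neutral_sfs, fit_selection_model)
from cesscan.synthetic import simulate_population, simulate_rate_table

N_CHROM = 1_600_000
NE = 1.0e4


def make_pop(s, seed, n_genes=40, sites_per_gene=400, spike=0.5, kappa=None):
    cfg = SyntheticConfig(
        seed=seed, n_genes=n_genes, sites_per_gene=sites_per_gene,
        rate_model=RateMixture(spike_weight=spike),
        frac_synonymous=0.0, frac_missense=0.0, frac_lof=1.0,
        kappa=kappa or {},
        popgen=PopgenSpec(Ne=NE, s=s, n_chrom=N_CHROM))
    return simulate_population(simulate_rate_table(cfg), cfg)


@pytest.fixture(scope="module")
def neutral_pop():
    return make_pop(s=0.001, seed=60, n_genes=30, sites_per_gene=2000, spike=0.3)


class TestBinning:
    def test_published_boundary_mapping(self):
        binning = SFSBinning()
        assert bin_allele_count(0, binning)[0] == 0
        assert bin_allele_count(1, binning)[0] == 1
        assert bin_allele_count(10, binning)[0] == 10
        # k = 12 falls in the [11, 16) bin
        assert bin_allele_count(12, binning)[0] == 11
        # k = 36 opens the [36, 100) bin
        assert bin_allele_count(36, binning)[0] == 14
        # overflow clips into the final bin
        assert bin_allele_count(5000, binning)[0] == 14

    def test_bins_partition_counts(self):
        binning = SFSBinning()
        ks = np.arange(0, 300)
        bins = bin_allele_count(ks, binning)
        assert bins.min() == 0 and bins.max() == binning.n_count_bins - 1
        assert (np.diff(bins) >= 0).all()

    def test_negative_count_rejected(self):
        with pytest.raises(DataError):
            bin_allele_count(-1)


class TestNeutralFit:
    def test_equal_bin_counts_give_zero_log_odds(self):
        binning = SFSBinning(count_bin_boundaries=(0, 1, 2, 3))
        sites = pd.DataFrame({"mu": 1.0, "k": [0, 1, 2] * 50})
        model = fit_neutral_sfs(sites, binning, n_mu_bins=1)
        assert np.allclose(model.beta_mu, 0.0)

    def test_empty_bin_gets_pseudocount(self):
        binning = SFSBinning(count_bin_boundaries=(0, 1, 2, 3))
        sites = pd.DataFrame({"mu": 1.0, "k": [0] * 10 + [1] * 5})
        model = fit_neutral_sfs(sites, binning, n_mu_bins=1)
        assert model.beta_mu[0, 2] == pytest.approx(np.log(0.5 / 10))

    def test_empty_reference_bin_is_an_error(self):
        binning = SFSBinning(count_bin_boundaries=(0, 1, 2, 3))
        sites = pd.DataFrame({"mu": 1.0, "k": [1, 2] * 5})
        with pytest.raises(DataError):
            fit_neutral_sfs(sites, binning, n_mu_bins=1)

    def test_recovers_known_log_odds(self, rng):
        # simulate directly from a known per-bin multinomial
        binning = SFSBinning(count_bin_boundaries=(0, 1, 2, 3))
        beta = np.array([0.0, -0.7, -1.6])
        p = np.exp(beta) / np.exp(beta).sum()
        ks = rng.choice(3, size=100_000, p=p)
        model = fit_neutral_sfs(pd.DataFrame({"mu": 1.0, "k": ks}), binning,
                                n_mu_bins=1)
        assert np.allclose(model.beta_mu[0], beta, atol=0.1)


@pytest.fixture(scope="module")
def fitted(neutral_pop):
    rng = np.random.default_rng(61)
    s_map = {f"G{i:04d}": float(x) for i, x in enumerate(
        np.exp(rng.uniform(np.log(0.005), np.log(0.5), 40)))}
    lof_pop = make_pop(s=s_map, seed=62)
    neutral = fit_neutral_sfs(neutral_pop)
    model = fit_selection_model(lof_pop, pd.Series(s_map), neutral)
    return model, lof_pop, s_map, neutral


class TestSelectionFit:

    def test_fitted_loglik_not_below_neutral(self, fitted):
        model, lof_pop, s_map, neutral = fitted
        # beta_s = 0 recovers the neutral model, so the fit can only improve
        from cesscan.sfs import _aggregate, _model_loglik
        shet = pd.Series(s_map).reindex(lof_pop["gene_id"]).to_numpy()
        cells, cmu, cs = _aggregate(lof_pop, neutral, shet)
        ll_fit, _ = _model_loglik(neutral, cells, cmu, cs, model.beta_s)
        ll_neutral, _ = _model_loglik(neutral, cells, cmu, cs,
                                      np.zeros_like(model.beta_s))
        assert ll_fit >= ll_neutral - 1e-6

    def test_zero_shet_reduces_to_neutral_probabilities(self, fitted):
        model, *_ = fitted
        mu_bins = np.arange(model.mu_edges.size - 1)
        lp = model.log_probs(mu_bins, np.zeros(mu_bins.size))
        neutral_lp = model.beta_mu - np.log(
            np.exp(model.beta_mu).sum(axis=1, keepdims=True))
        assert np.allclose(lp, neutral_lp, atol=1e-10)

    def test_identical_priors_unidentifiable(self, neutral_pop):
        lof_pop = make_pop(s=0.05, seed=63, n_genes=5)
        prior = pd.Series(0.05, index=[f"G{i:04d}" for i in range(5)])
        with pytest.raises(DataError):
            fit_selection_model(lof_pop, prior,
                                fit_neutral_sfs(neutral_pop))

    def test_polymorphic_mass_decreases_with_shet(self, fitted):
        model, *_ = fitted
        mu_bin = np.array([model.mu_edges.size - 2])  # most informative bin
        masses = []
        for s in (0.001, 0.01, 0.1, 0.5):
            lp = model.log_probs(mu_bin, np.array([s]))
            masses.append(1.0 - np.exp(lp[0, 0]))  # P(K > 0)
        assert all(a >= b - 1e-9 for a, b in zip(masses, masses[1:]))


class TestSHetEstimation:
    def test_rank_recovery_across_genes(self, neutral_pop):
        rng = np.random.default_rng(64)
        s_map = {f"G{i:04d}": float(x) for i, x in enumerate(
            np.exp(rng.uniform(np.log(0.005), np.log(0.5), 60)))}
        lof_pop = make_pop(s=s_map, seed=65, n_genes=60, sites_per_gene=600)
        model = fit_selection_model(lof_pop, pd.Series(s_map),
                                    fit_neutral_sfs(neutral_pop))
        ests = {g: estimate_shet(sub, model).s_het
                for g, sub in lof_pop.groupby("gene_id")}
        true = np.array([s_map[g] for g in ests])
        est = np.array(list(ests.values()))
        assert stats.spearmanr(true, est).statistic > 0.75

    def test_monomorphic_gene_pushed_to_upper_boundary(self, neutral_pop):
        # with non-negative selection coefficients the all-monomorphic
        # likelihood is monotone increasing in s_het, so the MLE sits at 1
        model = fit_neutral_sfs(neutral_pop)
        model.beta_s = np.linspace(0.0, 3.0, model.binning.n_count_bins)
        gene = pd.DataFrame({"gene_id": "G", "mu": 30.0, "k": [0] * 50})
        est = estimate_shet(gene, model)
        assert est.s_het == pytest.approx(1.0, abs=1e-3) and est.at_boundary

    def test_abundant_polymorphism_pushes_estimate_down(self, neutral_pop):
        rng = np.random.default_rng(68)
        s_map = {f"G{i:04d}": float(x) for i, x in enumerate(
            np.exp(rng.uniform(np.log(0.005), np.log(0.5), 20)))}
        lof_pop = make_pop(s=s_map, seed=69, n_genes=20)
        model = fit_selection_model(lof_pop, pd.Series(s_map),
                                    fit_neutral_sfs(neutral_pop))
        nearly_neutral = make_pop(s=0.0005, seed=70, n_genes=1,
                                  sites_per_gene=800)
        est = estimate_shet(nearly_neutral, model)
        assert est.s_het < 0.01

    def test_kappa_unaware_fit_biases_estimates_down(self, neutral_pop):
        rng = np.random.default_rng(71)
        s_map = {f"G{i:04d}": float(x) for i, x in enumerate(
            np.exp(rng.uniform(np.log(0.01), np.log(0.3), 30)))}
        lof_null = make_pop(s=s_map, seed=72, n_genes=30)
        model = fit_selection_model(lof_null, pd.Series(s_map),
                                    fit_neutral_sfs(neutral_pop))
        lof_ces = make_pop(s=s_map, seed=73, n_genes=30,
                           kappa={g: 10.0 for g in s_map})
        ests = {g: estimate_shet(sub, model).s_het
                for g, sub in lof_ces.groupby("gene_id")}
        n_down = sum(ests[g] < s_map[g] for g in ests)
        p = stats.binomtest(n_down, len(ests), 0.5, alternative="greater").pvalue
        assert p < 0.01

    def test_empty_gene_rejected(self, neutral_pop):
        model = fit_neutral_sfs(neutral_pop)
        model.beta_s = np.zeros(model.binning.n_count_bins)
        with pytest.raises(DataError):
            estimate_shet(pd.DataFrame(columns=["gene_id", "mu", "k"]), model)
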