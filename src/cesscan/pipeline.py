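"""End-to-end pipeline driver.

Executes the stages on the configured inputs (simulating any that are
absent when a synthetic config is supplied): mutational expectations →
overdispersion diagnostics → CES scans (gain-of-function, LoF-1, LoF
excess/LoF-2) → subcohort homogeneity → population-genetics decomposition →
SFS selection re-estimation → sperm comparison.  Writes per-stage TSVs plus
a machine-readable JSON summary and logs the package version and seed.
Any stage failure aborts with an error naming the stage.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as cio
from .config import PipelineConfig
from .dispersion import fit_overdispersion, gene_dispersion_chi2
from .errors import CesScanError, DataError
from .homogeneity import SubcohortCounts, fit_homogeneity_models
from .mutmodel import compute_expectations, filter_sites
from .popgen import ces_residuals, filter_popgen_genes, gene_popstats
from .scan import (cohort_compare_binomial, gof_scan, lof1_scan,
                   lof2_select, lof_excess_scan, set_enrichment)
from .sfs import estimate_shet, fit_neutral_sfs, fit_selection_model
from .synthetic import (simulate_denovo_cohort, simulate_population,
                        simulate_rate_table, simulate_subcohort_split,
                        simulate_sperm_counts)

log = logging.getLogger(__name__)

_SITE_KEY = ["chrom", "pos", "ref", "alt"]


def counts_for_sites(sites: pd.DataFrame, denovo: pd.DataFrame) -> pd.Series:
    """Align a (chrom, pos, ref, alt, n) count table to a site table."""
    if len(denovo) == 0:
        return pd.Series(0, index=sites.index, name="n")
    merged = sites[_SITE_KEY].merge(
        denovo, on=_SITE_KEY, how="left", validate="one_to_one")
    return pd.Series(merged["n"].fillna(0).astype(int).to_numpy(),
                     index=sites.index, name="n")


class _Stage:
    """Context manager that renames any failure after its stage."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        log.info("stage %s", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None and not isinstance(exc, CesScanError):
            raise CesScanError(f"stage {self.name} failed: {exc}") from exc
        if isinstance(exc, CesScanError):
            raise CesScanError(f"stage {self.name} failed: {exc}") from exc
        return False


def run_pipeline(config: PipelineConfig) -> dict:
    config.scan.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "seed": config.seed}
    synth = config.synthetic
    if synth is not None:
        synth.seed = config.seed
        synth.validate()

    with _Stage("load_sites"):
        if config.sites:
            sites = cio.read_sites(config.sites)
        elif synth is not None:
            sites = simulate_rate_table(synth)
        else:
            raise DataError("no site table: provide `sites` or a synthetic config")
        if sites["mu_gen"].isna().all() and synth is not None:
            sites["mu_gen"] = sites["mu"] * synth.rate_model.mu_scale

    with _Stage("load_denovo"):
        if config.denovo:
            counts = counts_for_sites(sites, cio.read_denovo(config.denovo))
        elif synth is not None:
            counts = simulate_denovo_cohort(sites, synth, ascertained=True)
        else:
            raise DataError("no de novo counts: provide `denovo` or a synthetic config")

    with _Stage("expectations"):
        syn_sites = filter_sites(sites, "synonymous")
        n_syn = int(counts.loc[syn_sites.index].sum())
        expect = compute_expectations(sites, n_syn)
        report["expectations"] = {"n_syn": n_syn,
                                  "syn_mu_total": expect.syn_mu_total}

    with _Stage("dispersion"):
        syn_counts = counts.loc[syn_sites.index]
        syn_lam = expect.lambda_v.loc[syn_sites.index]
        fit = fit_overdispersion(syn_counts, syn_lam)
        lam_syn_gene = expect.lambda_gene("synonymous")
        n_syn_gene = syn_counts.groupby(syn_sites["gene_id"]).sum().reindex(
            lam_syn_gene.index).fillna(0)
        gene_test = gene_dispersion_chi2(n_syn_gene, lam_syn_gene)
        report["dispersion"] = {"site_fit": fit.to_dict(),
                                "gene_chi2": gene_test.to_dict()}
        gamma = fit.gamma_hat if fit.aic_preferred == "negbin" else config.scan.gamma

    with _Stage("scan_gof"):
        mis = filter_sites(sites, "missense")
        scan_cfg = config.scan
        if scan_cfg.bonferroni_n_variants is None or \
                scan_cfg.bonferroni_n_variants < len(mis):
            scan_cfg.bonferroni_n_variants = len(mis)
        gof = gof_scan(counts.loc[mis.index], expect.lambda_v, scan_cfg)
        gof.insert(0, "gene_id", mis["gene_id"])
        cio.write_results(gof[gof["n_obs"] > 0], outdir / "gof_scan.tsv")
        report["gof"] = {
            "n_tested": int(len(gof)),
            "bonferroni_hits": sorted(set(gof.loc[gof["sig_bonferroni"], "gene_id"])),
            "fdr_hits": sorted(set(gof.loc[gof["sig_fdr"], "gene_id"])),
        }

    with _Stage("scan_lof"):
        lof = filter_sites(sites, "lof")
        lam_lof = expect.lambda_gene("lof")
        n_lof = counts.loc[lof.index].groupby(lof["gene_id"]).sum().reindex(
            lam_lof.index).fillna(0).astype(int)
        if scan_cfg.bonferroni_n_genes is None or \
                scan_cfg.bonferroni_n_genes < len(n_lof):
            scan_cfg.bonferroni_n_genes = len(n_lof)
        lof1 = lof1_scan(n_lof, lam_lof, scan_cfg)
        excess = lof_excess_scan(n_lof, lam_lof, scan_cfg)
        lof1.index.name = excess.index.name = "gene_id"
        cio.write_results(lof1, outdir / "lof1_scan.tsv")
        cio.write_results(excess, outdir / "lof_excess_scan.tsv")
        report["lof1"] = {
            "bonferroni_hits": sorted(lof1.index[lof1["sig_bonferroni"]]),
            "fdr_hits": sorted(lof1.index[lof1["sig_fdr"]]),
        }

    with _Stage("scan_lof2"):
        gene_models = []
        if config.genes_bed:
            gene_models = cio.read_genes_bed(config.genes_bed)
        if config.loeuf:
            loeuf = cio.read_loeuf(config.loeuf)
            known = {g.gene_id for g in gene_models}
            from .mutmodel import GeneModel
            for gid, value in loeuf.items():
                if gid in known:
                    for g in gene_models:
                        if g.gene_id == gid:
                            g.loeuf = float(value)
                else:
                    gene_models.append(GeneModel(
                        gene_id=str(gid),
                        cds_intervals=[("1", 0, 1)], loeuf=float(value)))
            report["lof2"] = lof2_select(excess, gene_models, scan_cfg)
        else:
            report["lof2"] = {"skipped": "no LOEUF input"}

    with _Stage("homogeneity"):
        if config.subcohort_counts:
            counts_mat, syn_totals = cio.read_subcohort_counts(config.subcohort_counts)
            data = SubcohortCounts.from_synonymous_totals(
                counts_mat.to_numpy(), syn_totals)
            report["homogeneity"] = fit_homogeneity_models(data).to_dict()
        elif synth is not None:
            split, _ = simulate_subcohort_split(n_lof, synth)
            report["homogeneity"] = fit_homogeneity_models(split).to_dict()

    with _Stage("popgen"):
        pop = syn_pop = None
        if config.popcounts:
            allpop = cio.join_popcounts(cio.read_popcounts(config.popcounts), sites)
            pop = allpop[allpop["lof_confidence"].eq("high")
                         & allpop["consequence"].isin(
                             ("stop_gained", "splice_donor", "splice_acceptor"))]
            syn_pop = allpop[allpop["consequence"].eq("synonymous")]
        elif synth is not None:
            pop = simulate_population(lof, synth)
            syn_pop = simulate_population(syn_sites, synth, stream="popgen-syn")
        if pop is not None and len(pop):
            qualifying = filter_popgen_genes(pop)
            stats_list = [gene_popstats(pop.loc[idx], int(pop["n_chrom"].iloc[0]))
                          for idx in qualifying.values()]
            if stats_list:
                rows = pd.DataFrame([s.to_dict() for s in stats_list])
                cio.write_results(rows, outdir / "popgen_stats.tsv")
            try:
                reg = ces_residuals(stats_list)
                report["popgen"] = {"n_genes": reg.n_genes,
                                    "slope": reg.slope,
                                    "intercept": reg.intercept}
                cio.write_results(reg.residuals.to_frame(),
                                  outdir / "popgen_residuals.tsv")
            except DataError as exc:
                report["popgen"] = {"skipped": str(exc)}

    with _Stage("sfs"):
        if pop is not None and syn_pop is not None and config.shet_prior:
            prior = cio.read_shet_prior(config.shet_prior)
            neutral = fit_neutral_sfs(syn_pop)
            model = fit_selection_model(pop, prior, neutral)
            rows = []
            for gid, sub in pop.groupby("gene_id"):
                rows.append(estimate_shet(sub, model).to_dict())
            shet_frame = pd.DataFrame(rows)
            cio.write_results(shet_frame, outdir / "shet_estimates.tsv")
            report["sfs"] = {"n_genes": int(len(shet_frame)),
                             "beta_s": model.beta_s.tolist()}

    with _Stage("sperm_compare"):
        sperm = None
        if config.sperm_counts:
            sperm = counts_for_sites(sites, cio.read_denovo(config.sperm_counts))
        elif synth is not None and synth.sperm.depth > 0:
            sperm = simulate_sperm_counts(sites, synth)
        if sperm is not None:
            lam_sperm_gene = (sites.loc[lof.index, "mu_gen"]
                              .groupby(lof["gene_id"]).sum()
                              * (synth.sperm.depth if synth else 1.0))
            m_lof = sperm.loc[lof.index].groupby(lof["gene_id"]).sum()
            both = (n_lof > 0) & (m_lof.reindex(n_lof.index).fillna(0) > 0)
            compared = {}
            for gid in n_lof.index[both]:
                compared[gid] = cohort_compare_binomial(
                    int(n_lof[gid]), int(m_lof[gid]),
                    float(lam_lof[gid]), float(lam_sperm_gene[gid]))
            report["sperm_compare"] = {"n_tested": len(compared),
                                       "results": compared}
            pooled = set_enrichment(m_lof, lam_sperm_gene.reindex(m_lof.index))
            report["sperm_lof_enrichment"] = pooled

    with _Stage("write_summary"):
        cio.write_results(report, outdir / "summary.json")
    return report


def load_report(outdir) -> dict:
    with open(Path(outdir) / "summary.json") as fh:
        return json.load(fh)
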