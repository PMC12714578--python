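"""Gene/variant filtering and synonymous-scaled mutational expectations.

The baseline mutation-rate model supplies an *unscaled* relative rate μ_v per
possible SNV.  Expected de novo counts in a cohort are obtained by anchoring
to the observed number of synonymous de novo mutations N_S:

    λ_v = N_S · μ_v / Σ_{v∈S} μ_v,        λ_A = Σ_{v∈A} λ_v,

where S is the set of admissible synonymous sites.  This absorbs
cohort-specific factors (parental age, coverage) into a single empirical
normalisation, so that Σ_{v∈S} λ_v = N_S exactly.

Variant classes follow strict annotation rules: sites must carry a 'high' or
'TFBS' quality label; LoF requires a high-confidence annotation and a
stop-gained or splice-donor/acceptor consequence; synonymous requires a pure
synonymous consequence; missense requires a pathogenicity score strictly
greater than 0.1.

Gene models with overlapping coding sequence are resolved exactly: the
retained subset of genes is the maximum-total-CDS-length independent set of
the CDS-overlap graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataError

__all__ = [
    "GeneModel",
    "ExpectationTable",
    "SITE_COLUMNS",
    "QUALITY_PASS",
    "LOF_CONSEQUENCES",
    "AUTOSOMES",
    "resolve_gene_overlaps",
    "filter_sites",
    "compute_expectations",
    "obs_exp_ratio_ci",
    "poisson_ci",
]

#: Canonical column schema of a site table (one row per possible SNV).
SITE_COLUMNS = [
    "chrom", "pos", "ref", "alt", "gene_id",
    "consequence", "lof_confidence", "quality", "mu", "am_score",
]

QUALITY_PASS = frozenset({"high", "TFBS"})
LOF_CONSEQUENCES = frozenset({"stop_gained", "splice_donor", "splice_acceptor"})
AUTOSOMES = frozenset(str(i) for i in range(1, 23))

#: Components larger than this abort overlap resolution (they indicate
#: malformed annotation rather than genuine gene clusters).
MAX_COMPONENT = 25


@dataclass
class GeneModel:
    """A gene's coding intervals (0-based half-open BED) plus annotations."""

    gene_id: str
    cds_intervals: list[tuple[str, int, int]]
    loeuf: float | None = None
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in self.cds_intervals:
            if start < 0 or end <= start:
                raise DataError(
                    f"gene {self.gene_id}: malformed interval ({chrom}, {start}, {end})")
            by_chrom.setdefault(str(chrom), []).append((start, end))
        for chrom, ivals in by_chrom.items():
            ivals.sort()
            for (s0, e0), (s1, e1) in zip(ivals, ivals[1:]):
                if s1 < e0:
                    raise DataError(
                        f"gene {self.gene_id}: overlapping own intervals on {chrom}")
        self.cds_intervals = sorted(
            (str(c), int(s), int(e)) for c, s, e in self.cds_intervals)

    @property
    def cds_length(self) -> int:
        return sum(e - s for _, s, e in self.cds_intervals)


def _overlap_graph(genes: list[GeneModel]) -> nx.Graph:
    graph = nx.Graph()
    graph.add_nodes_from(g.gene_id for g in genes)
    events: dict[str, list[tuple[int, int, str]]] = {}
    for g in genes:
        for chrom, start, end in g.cds_intervals:
            events.setdefault(chrom, []).append((start, end, g.gene_id))
    for ivals in events.values():
        ivals.sort()
        active: list[tuple[int, str]] = []  # (end, gene_id)
        for start, end, gid in ivals:
            active = [(e, og) for e, og in active if e > start]
            for _, og in active:
                if og != gid:
                    graph.add_edge(gid, og)
            active.append((end, gid))
    return graph


def resolve_gene_overlaps(genes: list[GeneModel]) -> set[str]:
    """Return the retained gene set: no two genes share a CDS base and the
    total retained CDS length is maximal among all such subsets.

    Each connected component of the overlap graph is solved exactly as a
    maximum-weight independent set (via a maximum-weight clique on the
    complement graph).  Ties in total length are broken deterministically in
    favour of lexicographically smaller gene ids.  Components with more than
    ``MAX_COMPONENT`` genes raise :class:`DataError`.
    """
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        raise DataError("duplicate gene_id in gene models")
    lengths = {g.gene_id: g.cds_length for g in genes}
    graph = _overlap_graph(genes)
    retained: set[str] = set()
    for comp in nx.connected_components(graph):
        comp = sorted(comp)
        if len(comp) == 1:
            retained.update(comp)
            continue
        if len(comp) > MAX_COMPONENT:
            raise DataError(
                f"overlap component with {len(comp)} genes exceeds cap {MAX_COMPONENT}")
        # Exact max-weight independent set == max-weight clique on complement.
        # Integer weights encode CDS length in the high bits and a
        # lexicographic tie-break bonus in the low bits.
        m = len(comp)
        sub = graph.subgraph(comp)
        comp_graph = nx.complement(sub)
        for rank, gid in enumerate(comp):
            comp_graph.nodes[gid]["w"] = (lengths[gid] << m) | (1 << (m - 1 - rank))
        clique, _ = nx.max_weight_clique(comp_graph, weight="w")
        retained.update(clique)
    return retained


def _require_columns(sites: pd.DataFrame, cols: list[str]) -> None:
    missing = [c for c in cols if c not in sites.columns]
    if missing:
        raise DataError(f"site table missing required columns: {missing}")


def filter_sites(sites: pd.DataFrame, cls: str, autosomes_only: bool = False) -> pd.DataFrame:
    """Return the sites belonging to annotation class ``cls``.

    ``cls`` is one of ``"synonymous"``, ``"missense"``, ``"lof"``.  All
    classes require a passing quality label; the class rules are conjunctions,
    and a site can belong to at most one class.
    """
    _require_columns(sites, ["consequence", "lof_confidence", "quality", "mu"])
    mask = sites["quality"].isin(QUALITY_PASS)
    if autosomes_only:
        chrom = sites["chrom"].astype(str).str.removeprefix("chr")
        mask &= chrom.isin(AUTOSOMES)
    if cls == "synonymous":
        mask &= sites["consequence"].eq("synonymous")
    elif cls == "missense":
        am = pd.to_numeric(sites["am_score"], errors="coerce")
        mask &= sites["consequence"].eq("missense") & (am > 0.1)
    elif cls == "lof":
        mask &= sites["lof_confidence"].eq("high") & sites["consequence"].isin(LOF_CONSEQUENCES)
    else:
        raise ConfigError(f"unknown site class {cls!r}")
    return sites.loc[mask]


@dataclass
class ExpectationTable:
    """Synonymous-scaled expected de novo counts.

    ``lambda_v`` is indexed like the input site table (quality-passing sites
    only); ``by_gene_class`` aggregates λ over (gene_id, class) for the three
    admissible classes.  The normalisation guarantees that the synonymous
    λ sum equals ``n_syn`` exactly.
    """

    n_syn: int
    lambda_v: pd.Series
    by_gene_class: pd.DataFrame
    syn_mu_total: float

    def lambda_gene(self, cls: str) -> pd.Series:
        sub = self.by_gene_class[self.by_gene_class["class"] == cls]
        return sub.set_index("gene_id")["lam"]


def compute_expectations(sites: pd.DataFrame, n_syn_observed: int) -> ExpectationTable:
    """Scale per-site rates so the admissible synonymous λ total is N_S."""
    if n_syn_observed < 0:
        raise DataError("n_syn_observed must be non-negative")
    syn = filter_sites(sites, "synonymous")
    if syn.empty:
        raise DataError("empty admissible synonymous set; cannot normalise expectations")
    syn_mu_total = float(syn["mu"].sum())
    if syn_mu_total <= 0:
        raise DataError("total synonymous rate is not positive")
    passing = sites.loc[sites["quality"].isin(QUALITY_PASS)]
    lambda_v = passing["mu"] * (n_syn_observed / syn_mu_total)
    lambda_v.name = "lam"
    rows = []
    for cls in ("synonymous", "missense", "lof"):
        members = filter_sites(sites, cls)
        if members.empty:
            continue
        agg = lambda_v.loc[members.index].groupby(members["gene_id"]).sum()
        rows.append(pd.DataFrame({"gene_id": agg.index, "class": cls, "lam": agg.values}))
    by_gene_class = (
        pd.concat(rows, ignore_index=True)
        if rows else pd.DataFrame(columns=["gene_id", "class", "lam"])
    )
    return ExpectationTable(
        n_syn=int(n_syn_observed),
        lambda_v=lambda_v,
        by_gene_class=by_gene_class,
        syn_mu_total=syn_mu_total,
    )


def poisson_ci(n_obs: int, level: float = 0.95) -> tuple[float, float]:
    """Gamma-conjugate (Garwood) confidence bounds for a Poisson mean.

    Lower bound is the Gamma(n, 1) quantile at (1-level)/2 (zero when n = 0);
    upper is the Gamma(n+1, 1) quantile at (1+level)/2.  Equivalent to the
    chi-square formulation χ²(2n)/2, χ²(2n+2)/2.
    """
    if not 0.0 < level < 1.0:
        raise ConfigError(f"level must be in (0, 1), got {level}")
    if n_obs < 0:
        raise DataError("n_obs must be non-negative")
    alpha = 1.0 - level
    lo = 0.0 if n_obs == 0 else float(stats.gamma.ppf(alpha / 2, n_obs))
    hi = float(stats.gamma.ppf(1 - alpha / 2, n_obs + 1))
    return lo, hi


def obs_exp_ratio_ci(n_obs: int, lam: float, level: float = 0.95) -> tuple[float, float, float]:
    """Observed/expected ratio with a Poisson-conjugate (gamma) CI."""
    if lam <= 0:
        raise DataError(f"expected count must be positive, got {lam}")
    lo, hi = poisson_ci(n_obs, level)
    return n_obs / lam, lo / lam, hi / lam
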