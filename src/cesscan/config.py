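"""Configuration objects for the simulator, the scans and the pipeline.

All knobs that the statistical machinery depends on live here, with the
defaults used throughout the package:

* ``prevalence`` — the disease prevalence P(D) entering the ascertainment
  bound; the scans use a conservative lower bound ``prevalence_lower_bound``
  (default 0.01, i.e. a maximal 100-fold ascertainment effect).
* ``kappa`` — the multiplicative clonal-expansion (CES) factor κ ≥ 1 on the
  per-site mutation rate.
* ``gamma`` — per-site overdispersion of de novo counts; counts are negative
  binomial with mean m and variance m(1+γ).
* ``popgen`` — gamma-Poisson (Nei) segregation parameters: diploid effective
  size Nₑ, per-gene heterozygous selection s, and sampled chromosomes n.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import yaml

from .errors import ConfigError

__all__ = [
    "RateMixture",
    "SubcohortSpec",
    "PopgenSpec",
    "SpermSpec",
    "SyntheticConfig",
    "ScanConfig",
    "PipelineConfig",
]


@dataclass
class RateMixture:
    """Two-component model of unscaled per-site rates.

    A low-rate body (log-uniform on (``low_lo``, ``low_hi``], all ≤ 1) plus a
    high-rate "CpG-like" spike (log-normal, essentially all > 1).  ``mu_scale``
    maps unscaled rate units to a per-generation per-site probability; the
    default is chosen so the default mixture's mean per-generation rate is
    ≈ 1.2e-8, the genome-wide average de novo SNV rate per site.
    """

    spike_weight: float = 0.02
    low_lo: float = 0.02
    low_hi: float = 1.0
    spike_log_mean: float = 3.4012  # ln 30: CpG transitions ~30x the average
    spike_log_sd: float = 0.3
    mu_scale: float = 1.4e-8

    def validate(self) -> None:
        if not 0.0 <= self.spike_weight <= 1.0:
            raise ConfigError(f"spike_weight must be in [0, 1], got {self.spike_weight}")
        if not 0.0 < self.low_lo < self.low_hi <= 1.0:
            raise ConfigError("low-rate component must satisfy 0 < low_lo < low_hi <= 1")
        if self.mu_scale <= 0 or self.spike_log_sd <= 0:
            raise ConfigError("mu_scale and spike_log_sd must be positive")


@dataclass
class SubcohortSpec:
    """How per-gene counts are split across recruiting subcohorts.

    ``model`` is one of ``fixed-multinomial`` (proportions follow the
    synonymous-derived null), ``free-multinomial`` (shifted proportions),
    ``dirichlet-fixed-mean`` and ``dirichlet-free`` (per-gene proportions
    drawn from a Dirichlet with the given ``concentration``).
    """

    model: str = "fixed-multinomial"
    proportions: tuple[float, ...] = (0.43, 0.50, 0.07)
    shifted_proportions: tuple[float, ...] | None = None
    concentration: float = 50.0

    MODELS = ("fixed-multinomial", "free-multinomial", "dirichlet-fixed-mean", "dirichlet-free")

    def validate(self) -> None:
        if self.model not in self.MODELS:
            raise ConfigError(f"unknown subcohort model {self.model!r}; choose from {self.MODELS}")
        for name, p in (("proportions", self.proportions), ("shifted_proportions", self.shifted_proportions)):
            if p is None:
                continue
            if abs(sum(p) - 1.0) > 1e-9:
                raise ConfigError(f"{name} must sum to 1 within 1e-9, got sum {sum(p)!r}")
            if any(x <= 0 for x in p):
                raise ConfigError(f"{name} must be strictly positive")
        if self.concentration <= 0:
            raise ConfigError("concentration must be positive")


@dataclass
class PopgenSpec:
    """Gamma-Poisson segregation model parameters.

    ``s`` is the per-gene heterozygous selection coefficient; a mapping
    overrides the scalar default per gene.  The strong-selection regime
    s > 1/(4Nₑ) is required for the Nei approximation to hold.
    """

    Ne: float = 1.0e4
    s: float | Mapping[str, float] = 0.05
    n_chrom: int = 1_600_000

    def s_for(self, gene_id: str) -> float:
        if isinstance(self.s, Mapping):
            return float(self.s.get(gene_id, 0.05))
        return float(self.s)

    def validate(self) -> None:
        if self.Ne <= 0:
            raise ConfigError("Ne must be positive")
        if self.n_chrom < 0:
            raise ConfigError("n_chrom must be non-negative")


@dataclass
class SpermSpec:
    """Effective per-site duplex depth of a sperm sequencing experiment."""

    depth: float = 2.1e4

    def validate(self) -> None:
        if self.depth < 0:
            raise ConfigError("sperm depth must be non-negative")


@dataclass
class SyntheticConfig:
    """Ground-truth parameters for the synthetic cohort generator.

    ``penetrance`` maps gene → P(D|V) for functional (LoF/missense) variants;
    genes absent from the map get ``penetrance_default``.  ``kappa`` maps
    gene → κ applied to that gene's LoF sites; ``kappa_sites`` overrides κ at
    individual site indices (used for gain-of-function hotspots).  The seed
    fully determines every generated table.
    """

    seed: int = 0
    n_genes: int = 100
    sites_per_gene: int = 18_000
    rate_model: RateMixture = field(default_factory=RateMixture)
    gamma: float = 0.004
    n_probands: int = 31_058
    prevalence: float = 0.01
    penetrance: Mapping[str, float] = field(default_factory=dict)
    penetrance_default: float | None = None  # None: background risk P(D)
    kappa: Mapping[str, float] = field(default_factory=dict)
    kappa_default: float = 1.0
    kappa_sites: Mapping[int, float] = field(default_factory=dict)
    subcohort: SubcohortSpec = field(default_factory=SubcohortSpec)
    popgen: PopgenSpec = field(default_factory=PopgenSpec)
    sperm: SpermSpec = field(default_factory=SpermSpec)
    # consequence composition of the site table
    frac_synonymous: float = 0.25
    frac_missense: float = 0.65
    frac_lof: float = 0.07
    # optional multiplicative embryonic-survival factor < 1 (uncalibrated knob)
    embryonic_survival: float = 1.0

    def validate(self) -> None:
        if self.n_genes <= 0 or self.sites_per_gene <= 0:
            raise ConfigError("n_genes and sites_per_gene must be positive")
        if not 0.0 < self.prevalence < 1.0:
            raise ConfigError(f"prevalence must be in (0, 1), got {self.prevalence}")
        for g, p in dict(self.penetrance).items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"penetrance for {g} must be in [0, 1], got {p}")
        if self.penetrance_default is not None and not 0.0 <= self.penetrance_default <= 1.0:
            raise ConfigError("penetrance_default must be in [0, 1]")
        for g, k in dict(self.kappa).items():
            if k < 1.0:
                raise ConfigError(f"kappa for {g} must be >= 1, got {k}")
        if self.kappa_default < 1.0:
            raise ConfigError("kappa_default must be >= 1")
        for v, k in dict(self.kappa_sites).items():
            if k < 1.0:
                raise ConfigError(f"kappa_sites[{v}] must be >= 1, got {k}")
        if self.gamma < 0:
            raise ConfigError("gamma must be >= 0")
        if self.n_probands <= 0:
            raise ConfigError("n_probands must be positive")
        fracs = (self.frac_synonymous, self.frac_missense, self.frac_lof)
        if any(f < 0 for f in fracs) or sum(fracs) > 1.0 + 1e-12:
            raise ConfigError("consequence fractions must be non-negative and sum to <= 1")
        if not 0.0 < self.embryonic_survival <= 1.0:
            raise ConfigError("embryonic_survival must be in (0, 1]")
        self.rate_model.validate()
        self.subcohort.validate()
        self.popgen.validate()
        self.sperm.validate()

    def penetrance_for(self, gene_id: str) -> float:
        default = self.prevalence if self.penetrance_default is None else self.penetrance_default
        return float(dict(self.penetrance).get(gene_id, default))

    def kappa_for(self, gene_id: str) -> float:
        return float(dict(self.kappa).get(gene_id, self.kappa_default))


@dataclass
class ScanConfig:
    """Thresholds and correction factors for the CES driver scans.

    Defaults follow the published analysis: a 1% lower bound on disease
    prevalence (100-fold maximal ascertainment), per-site overdispersion
    γ = 0.004, FDR 0.20 for the per-variant gain-of-function scan, FDR 0.10
    for the per-gene LoF scans, a LOEUF threshold of 0.5 for the LoF-2 set,
    and Bonferroni factors of 49,686,008 missense variants and 17,791
    autosomal genes (both depend on the annotation inputs and are therefore
    configurable).
    """

    prevalence_lower_bound: float = 0.01
    gamma: float = 0.004
    fdr_gof: float = 0.20
    fdr_lof: float = 0.10
    loeuf_threshold: float = 0.5
    alpha_bonferroni: float = 0.05
    bonferroni_n_variants: int | None = 49_686_008
    bonferroni_n_genes: int | None = 17_791
    blocklists: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    gof_expectation_scaled: bool = True  # use synonymous-scaled rates (vs raw)

    def validate(self) -> None:
        if not 0.0 < self.prevalence_lower_bound <= 1.0:
            raise ConfigError("prevalence_lower_bound must be in (0, 1]")
        for name in ("fdr_gof", "fdr_lof", "alpha_bonferroni"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigError(f"{name} must be in (0, 1), got {v}")
        if self.gamma < 0:
            raise ConfigError("gamma must be >= 0")


@dataclass
class PipelineConfig:
    """End-to-end pipeline driver configuration (paths plus stage configs)."""

    outdir: str = "ces_out"
    seed: int = 0
    sites: str | None = None
    denovo: str | None = None
    denovo_control: str | None = None
    genes_bed: str | None = None
    loeuf: str | None = None
    popcounts: str | None = None
    sperm_counts: str | None = None
    subcohort_counts: str | None = None
    shet_prior: str | None = None
    scan: ScanConfig = field(default_factory=ScanConfig)
    synthetic: SyntheticConfig | None = None
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        scan = ScanConfig(**raw.pop("scan", {}))
        synth_raw = raw.pop("synthetic", None)
        synth = _synthetic_from_dict(synth_raw) if synth_raw is not None else None
        known = {f for f in cls.__dataclass_fields__}  # type: ignore[attr-defined]
        bad = set(raw) - known
        if bad:
            raise ConfigError(f"unknown config keys: {sorted(bad)}")
        cfg = cls(scan=scan, synthetic=synth, **raw)
        cfg.scan.validate()
        if cfg.synthetic is not None:
            cfg.synthetic.validate()
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)


def _synthetic_from_dict(raw: dict) -> SyntheticConfig:
    raw = dict(raw)
    sub = {}
    for key, klass in (("rate_model", RateMixture), ("subcohort", SubcohortSpec),
                       ("popgen", PopgenSpec), ("sperm", SpermSpec)):
        if key in raw:
            sub[key] = klass(**raw.pop(key))
    try:
        return SyntheticConfig(**raw, **sub)
    except TypeError as exc:
        raise ConfigError(f"invalid synthetic config: {exc}") from exc
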