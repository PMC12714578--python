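# Methods

This note documents the statistical models implemented in `cesscan`, the
study conditions its synthetic-data generator emulates, and the numerical
choices made where the design was genuinely open. Every empirical number
referenced here is computed by the test-suite or by
`scripts/acceptance.py`; nothing is asserted that the code does not measure.

## 1. The ascertainment bound

For a de novo variant V and a disease D with prevalence P(D), Bayes' rule
gives the enrichment of V in a cohort ascertained for D as
P(D|V)/P(D) ≤ 1/P(D). The scans therefore test observed counts against
λ/P\*(D), where P\*(D) is a conservative *lower* bound on prevalence
(default 0.01, i.e. a ceiling of 100-fold enrichment, following
epidemiological prevalence estimates of 2–3% for neurodevelopmental
disorders). Under the bound, a positive test cannot be explained by
ascertainment of any penetrance profile and implies inflation of the
mutation rate itself — the signature of clonal expansion in spermatogonia
(CES). The test is conservative by construction: for a variant of penetrance
q the true mean is λ·q/P(D) ≤ λ/P\*(D), with equality only at full
penetrance and P(D) = P\*(D).

## 2. Mutational expectations

Baseline per-site rates μ_v are consumed as *unscaled* relative units (a
Roulette-like table). Expectations are anchored to the observed synonymous
de novo count:

    λ_v = N_S · μ_v / Σ_{v∈S} μ_v,     λ_A = Σ_{v∈A} λ_v,

which absorbs cohort-specific factors (parental age, coverage, sample size)
into one empirical normalisation and guarantees Σ_{v∈S} λ_v = N_S exactly.
N_S is counted over the *admissible* (quality-passing) synonymous set — the
same set the denominator sums over; counting N_S over all synonymous
variants instead would bias λ upward by the fraction of counts at
low-quality sites.

Variant classes are strict conjunctions: every class requires a `high` or
`TFBS` quality label; LoF requires high-confidence annotation *and* a
stop-gained / splice-donor / splice-acceptor consequence; synonymous
requires a pure synonymous consequence; missense requires a pathogenicity
score strictly greater than 0.1 (a score of exactly 0.1 is excluded).
Analyses are restricted to autosomes when the flag is set, because baseline
rates exist only there.

Overlapping coding sequences are resolved exactly: the retained set is the
maximum-total-CDS-length independent set of the CDS-overlap graph, solved
per connected component as a maximum-weight clique on the complement graph
(components are capped at 25 genes; larger components indicate malformed
annotation). Ties in total length are broken towards lexicographically
smaller gene ids so the output is deterministic. For an isolated overlapping
pair this reduces to "keep the longer gene".

Coordinates: BED intervals are 0-based half-open; variant positions are
1-based. Both conventions are validated in the readers.

## 3. Overdispersion model

De novo counts are modelled as Poisson(λ_v) or negative binomial
parameterised by mean λ_v and overdispersion γ, Var = λ_v(1+γ):

    P(n) = C(n + λ/γ − 1, n) (γ/(γ+1))^n (1/(γ+1))^{λ/γ},

a Poisson–Gamma mixture, well defined for non-integer λ/γ. The γ MLE is
found by bounded scalar maximisation of the log-likelihood over
log γ ∈ [log 1e−8, log 10] (positivity and scale-free search); model choice
is by AIC, i.e. the extra parameter must buy more than one log-likelihood
unit. Near the lower boundary the summed log-gamma differences cancel at
~1e−9 per site, so an optimum pinned there is reported as the Poisson limit
rather than a genuine likelihood deficit.

The information content of this fit is worth recording: for small γ the MLE
has sd ≈ √(2/N) *independent of λ*, so at N = 10⁵ sites the resolution is
≈ 0.0045 — recovery of γ = 0.05 and 0.01 is comfortable, while γ = 0.002
sits below the resolution limit and its median estimate is only
order-of-magnitude reliable. Per-site fits include all admissible sites
(zeros carry likelihood weight).

Gene-level diagnostics use χ² = Σ (n_g − λ_g)²/λ_g on G − 1 degrees of
freedom plus the law-of-total-variance decomposition
Var(n) = E(λ) + Var(λ). The χ² reference is poor for tiny expectations, so
genes with λ_g < 0.01 are pooled into one pseudo-gene by default (a raw
mode is available).

## 4. Scans and multiple testing

* Gain-of-function scan: per-missense-variant upper-tail NB p-value against
  λ_v/P\* with γ from the dispersion fit (default 0.004). The expectation
  uses the synonymous-*scaled* λ_v, not the raw rate: the bound is stated on
  the observed/expected ratio, which is defined on the scaled expectation.
  An unscaled option exists for sensitivity analysis.
* LoF-1 scan: per-gene upper-tail Poisson p against λ_g/P\* (the gene-level
  Poisson choice is justified by the gene-level dispersion diagnostics).
* LoF excess scan: per-gene Poisson p against λ_g with no ascertainment
  divisor; the LoF-2 set is {FDR < 0.1} ∩ {LOEUF > 0.5} (both strict),
  minus blocklisted genes, which are reported separately, never silently
  dropped; genes lacking a LOEUF value are excluded with a count.
* Bonferroni factors are configuration inputs (defaults 49,686,008 missense
  variants and 17,791 autosomal genes — annotation-dependent quantities);
  Benjamini–Hochberg q-values are computed within each scan's tested family.
  Both adjusted outputs are always reported, since the Bonferroni and FDR
  sets answer different questions.
* The trio-vs-sperm binomial comparison uses success probability
  p₀ = λ_sperm/(λ_sperm + λ_trio) with n+m trials and is one-sided in each
  named direction (the sidedness is a package choice; both directions are
  returned). Only genes with ≥ 1 LoF in both datasets are tested.
* Pooled set enrichments are Σn/Σλ with gamma-conjugate (Garwood) Poisson
  intervals: lower = Gamma(n)-quantile at (1−level)/2 (zero at n = 0),
  upper = Gamma(n+1)-quantile at (1+level)/2.

An invariant worth noting: at equal FDR the LoF-1 significance set is a
subset of the excess-scan set, because dividing λ by P\* ≤ 1 only raises the
expectation and weakens the evidence.

## 5. Cohort homogeneity

Per-gene subcohort splits are compared across four models (C subcohorts):
fixed multinomial at the synonymous-derived proportions (0 parameters), free
shared multinomial (C−1), Dirichlet-multinomial centred on the null
proportions with free concentration α (1), and free-mean
Dirichlet-multinomial (C). The Dirichlet-multinomial is parameterised by
mean m and concentration α (Dirichlet parameters α·m) so that model 3 is
literally "centred on the observed synonymous proportions". Probabilities
are shared across genes, as the stated parameter counts imply. α is
optimised on a log scale over [1e−3, 1e9]; model 4 is optimised by L-BFGS-B
from multiple starts including the fitted submodels, so the nesting
logL(4) ≥ logL(2), logL(3) ≥ logL(1) holds to optimiser tolerance. Genes
with zero total count contribute no information and are dropped from the
product.

A calibration fact, measured by the acceptance script: under
model-1-generated data, AIC retains model 1 in roughly 70–80% of replicates;
the remainder is the irreducible chi-square overfitting probability of the
1-, 2- and 3-parameter alternatives at AIC's two-units-per-parameter
penalty. This ceiling is a property of AIC itself, not of the
implementation, and it bounds any "null-model recovery rate" one can expect
from this comparison.

## 6. Gamma-Poisson segregation model

Under recurrent mutation and strong heterozygous selection s, a LoF allele's
population frequency is approximately Gamma(4Nₑμ, 1/(4Nₑs)); a sample of n
chromosomes gives k ~ Poisson(n·p). Moments:

    E(k)   = κ·nE(μ)/s
    Var(k) = κ·(nE(μ)/s)(1 + n/(4Nₑs)) + κ²·(n/s)²·Var(μ)

with κ ≥ 1 the CES factor. The decomposition separates Poisson sampling
noise (k̄), drift-induced segregation variance (k̄·n/(4Nₑs)) and
mutation-rate heterogeneity ((nκ/s)²Var(μ)). The heterogeneity term is
estimated from the through-origin Poisson regression of k on μ (closed-form
MLE b̂ = Σk/Σμ, since E(k|μ) has no intercept) as b̂²·Var(μ); subtracting it
and k̄ from Var(k) leaves the segregation term.

Two estimators of inverse selection follow: the mean-based κ/ŝ = k̄/(nμ̄)
(CES-sensitive; reported from the printed mean-ratio form rather than from
b̂, though both are returned) and the variance-based
n/(4Nₑŝ) = Var_seg/k̄ (CES-insensitive). Genes are regressed as
log(mean-based) on log(variance-based) by OLS on natural logs (the base
only shifts the intercept); κ > 1 genes stand out as positive residuals of
size ≈ log κ.

Choices and guards: genes enter with ≥ 10 quality-passing sites of unscaled
rate strictly > 1 (the CpG-like sites that carry essentially all the
information at current sample sizes); negative Var_seg estimates are
reported as-is (unbiasedness over clipping) with an `out_of_regime` flag and
excluded from the residual regression; the generator refuses
s ≤ 1/(4Nₑ), where the approximation is invalid — such genes have *higher*
variance and cannot mimic CES, which makes the procedure conservative. The
`drift_ratio_flag` threshold (default 10) marks genes whose estimated
variance inflation is large relative to sampling noise; it is a warning
flag only and plays no role in estimation or exclusion, because at
biobank-scale n (≈ 1.6M chromosomes) the *true* drift ratio n/(4Nₑs) of
strongly selected genes is routinely in the hundreds.

The per-gene binned view (allele frequency vs rate) cuts sites into
quantile bins of μ, merging bins under 10 sites with the next-highest bin;
under a purely multiplicative CES effect the relation stays linear through
the origin with slope n·κ/s.

## 7. SFS selection model

Sampled allele counts are binned with boundaries
[0,1,2,3,4,5,6,7,8,9,10,11,16,24,36,100], half-open, the k = 0 class its own
(reference) bin; counts at or above the last boundary are clipped into the
final bin (the boundary list does not state overflow handling; clipping
keeps every site informative). Within each mutation-rate bin the neutral SFS
is the saturated multinomial β_i^μ = log(c_i/c_0), fitted on synonymous
sites, with pseudo-count ε = 0.5 for empty non-reference cells (finite
coefficients, minimal bias); an empty reference cell is an error. Rate-bin
edges are configurable, defaulting to deciles of the fitting set (the
original rate model's own bins are not available in synthetic settings).

Selection shifts every polymorphic class: log P(K=i|μ)/P(K=0|μ) =
β_i^μ − β_i^s·√s_het, with β_s[0] ≡ 0 and β^s fitted on all LoF sites by
L-BFGS-B (analytic gradient, bounds ±50) using per-gene *prior* mean s_het
values as covariates; identical priors everywhere leave β^s unidentifiable
and raise. The √ exponent is exposed as a configuration knob for sensitivity
analysis only. Per-gene s_het is then re-estimated by bounded scalar maximum
likelihood on [0, 1] (tolerance 1e−6) with explicit endpoint evaluation, so
boundary optima are found and flagged.

The CES diagnostic direction: fitting a κ-unaware model to genes whose
mutation rate is inflated κ-fold mistakes abundant polymorphism for weak
selection and biases ŝ_het *down* — the sign the population-data
corroboration relies on. The acceptance script measures both the rank
recovery (Spearman ≈ 0.9 over 200 genes under the conditions below) and this
downward bias (sign test).

## 8. Synthetic study conditions

The generator's defaults are the study conditions, chosen once:

* **Rate mixture** — a low-rate body, log-uniform on (0.02, 1], plus a
  CpG-like spike, log-normal(ln 30, 0.3) (CpG transitions run ~30× the
  genome average), spike weight 0.02; the unscaled→per-generation factor
  `mu_scale = 1.4e−8` makes the default mixture's mean per-site
  per-generation rate ≈ 1.2e−8, the human genome-wide average.
* **Cohorts** — 31,058 ascertained probands (NDD-sized) by default; the
  LoF-2-style planted-recovery studies use 47,935 (merged ASD+NDD-sized),
  the setting in which gene-level LoF excess is actually tested. Counts are
  negative binomial with mean N·μ_gen·κ·A and variance m(1+γ), γ = 0.004.
  The control-cohort ascertainment factor (1−q)/(1−P(D)) is included for
  exactness although it is ≈ 1.
* **Gene size** — 18,000 possible SNVs per gene (~1,260 LoF sites, i.e. a
  baseline per-gene LoF expectation λ_g ≈ 0.75 at ASD+NDD scale). These are
  large-gene loci by design: the gene-level LoF scans draw essentially all
  their power from large genes, and a planted κ = 20 on a small gene is
  undetectable at any FDR — the package studies the regime where the method
  operates.
* **Penetrance** — per-gene P(D|V) applying to functional sites; a gene
  absent from the map confers background risk (A = 1). Synonymous sites
  always have κ = 1, A = 1. An uncalibrated multiplicative
  embryonic-survival factor < 1 is available as an optional knob; no
  generative model for embryonic deleteriousness is claimed.
* **Population** — Nₑ = 10⁴ diploids, n = 1.6M sampled chromosomes
  (biobank-scale), per-gene s ∈ [0.01, 0.5] in the recovery studies;
  population studies use all-spike (CpG-like) LoF site tables because only
  such sites pass the μ > 1 filter, and the s_het studies use spike weight
  0.5 with 800 LoF sites/gene — a CpG-rich composition that concentrates
  the information the SFS model consumes.
* **Sperm** — Poisson counts at effective duplex depth 2.1e4 per site, no
  ascertainment.

What the generator does *not* emulate: real genomic coordinates or sequence
context, paternal-age effects, linkage between sites, ancestry structure in
the population sample, and regionally correlated rate-model errors. Passing
tests therefore demonstrate the statistical machinery under its own model
assumptions — calibration of the bound, recovery of planted effects,
estimator consistency — not robustness to annotation error or demographic
misspecification in real data.

## 9. Numerical choices and degenerate inputs

* All tail probabilities go through scipy's stable sf implementations;
  n = 0 short-circuits to p = 1 (also the fast path for sparse scans).
* NB sampling and likelihoods use the mean/overdispersion parameterisation
  r = m/γ, p = 1/(1+γ) exactly matching Var = m(1+γ).
* Seeds fully determine all generator output; independent named streams are
  derived from the config seed via crc32-keyed `SeedSequence` spawn keys
  (Python's builtin string hash is randomised per process and is not used).
* Degenerate inputs raise typed errors: empty synonymous sets, λ = 0 with
  observed counts (annotation inconsistency), proportions not summing to 1
  within 1e−9, s outside the gamma-Poisson regime, fewer than 10 usable
  genes for the residual regression, malformed intervals and duplicate
  table rows. The CLI maps configuration errors to exit 2 and data errors
  to exit 3.
* TSV writers serialise floats at 12 significant digits; readers accept
  everything the writers produce.

## 10. Known limitations

* The γ = 0.002 regime is below the MLE's resolution at 10⁵ sites (§3);
  only larger site counts can pin it down.
* AIC's null-model recovery rate is capped near ~75–80% (§5).
* The SFS selection model is a descriptive fit: √s_het linearity is an
  empirical choice, and per-gene estimates at the [0, 1] boundary carry no
  curvature information (flagged, not interval-estimated).
* The variance-based drift estimator is noisy for genes with few CpG-like
  sites; medians across genes are the intended summary, and single-gene
  values should not be over-read.
* Disease-causality adjudication, gene-set enrichment, expression analyses
  and coordinate liftover are out of scope; flagged-gene lists (clonal
  haematopoiesis, misannotation) are annotation inputs, never inferred.
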