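# Methods

## Model

`mitohet` models the mean per-cell state of a cybrid population as an
algebraic function of heteroplasmy *h* (the mutant fraction of mtDNA).
The assumptions, in causal order:

1. **Total mtDNA copy number is constant.** N is normalized to 1, so the
   wild-type copy number is N⁺ = 1 − h. This relation has no free
   parameters and is therefore never part of the likelihood.
2. **Mutant mtDNAs contribute neither transcripts nor (functional)
   protein.** Transcription of the ETC pool scales with N⁺; translation in
   the vicinity of a mutant genome yields unstable product (a strong local
   genotype–phenotype link), so ETC protein scales with N⁺ twice:
   P⁺ = N⁺ M_ETC / δ_p.
3. **Cells regulate ETC transcript stability, not transcription.** The
   degradation rate δ_m(h) = k_mRNA / (1 + exp(k_m (h − h₀))) is high at
   low h and collapses sigmoidally, letting the cell buffer transcript loss
   by stabilising mRNA. M_ETC = β N⁺ / (δ_m + 1).
4. **Glycolysis toggles at a critical heteroplasmy.** M_gly is constant
   (c₁) up to h\*, then rises linearly with slope m₂; the intercept
   c₂ = c₁ − m₂ h\* is derived, never fitted, so the spline is continuous.
   The boundary point h = h\* itself is assigned to the constant branch.
5. **Power supply equals power demand, and demand scales with volume.**
   V = k_o P⁺ + k_g M_gly.
6. **Individual cells grow linearly in volume through the cycle**, which
   makes the population growth rate reciprocal in mean volume: G = k_gr / V.
7. **Respiratory capacity is protein-limited**: R_max = k_p P⁺.

Twelve adjustable parameters (β, k_mRNA, k_m, h₀, δ_p, c₁, m₂, h\*, k_o,
k_g, k_gr, k_p) describe seven observables (N⁺, M_ETC, P⁺, M_gly, V, G,
R_max). All units are normalized-dimensionless: the model is evaluated and
fitted on the fold-change scale (every observable equals 1 at h = 0).

The model's domain is 0 ≤ h ≤ 0.9. On the 0.9 → 1 transition glycolysis
transcripts fall while volume and growth persist, violating assumption 5,
so h = 1 data are carried through the pipeline for display but flagged
`excluded_from_fit` and never enter the likelihood.

## Normalization pipeline

*Pathway expression.* Per-gene RPKM values e_{i,k}(h) (gene i, technical
replicate k) are combined into one dimensionless statistic per pathway:
each gene is divided by its own replicate-mean at h = 0, summed over genes,
averaged over replicates, and divided by the gene count N. This weights
genes equally regardless of absolute expression and forces the statistic to
exactly 1 at h = 0. Its standard error is (1/N)·sqrt(V_k[Σ_i ratio]/n_r)
with V_k the sample variance over replicates (undefined, by construction,
for a single replicate). The reference level may carry a different
replicate count than the measurement.

*Per-cell transform.* RPKM and normalized Western-blot protein are
concentrations; multiplying by mean cell volume yields per-cell amounts.
The first-order uncertainty of the product is sqrt(Ē² s_V² + V² s_Ē²).
Respirometry is already per-cell and receives no volume transform. ETC
protein is the sample mean of complexes I, III and IV (ATP synthase is
excluded — it is regulated independently of respiratory activity, and rows
naming it are rejected); being single-replicate, its uncertainty surrogate
is the normalized protein value times the volume SEM.

*Growth rate.* Ordinary least squares of ln(count) on day, using days ≤ 5
only — beyond day 5 cultures saturate, and the tests verify that later
observations can never influence the slope. The slope's standard error is
the feature uncertainty.

*Rescaling.* After the per-cell transform every feature is divided by its
h = 0 value (uncertainties by the same factor), putting data and model on a
common fold-change scale. Whether growth rate and respiratory capacity are
rescaled too is a switch (`renormalize_rates`, default on); the likelihood
contract assumes the rescaled table.

## Synthetic study generator

The generator inverts the pipeline from a known parameter set, so the whole
analysis is testable without the original (undeposited) dataset. Defaults
define the study conditions:

| setting | default | rationale |
| --- | --- | --- |
| h grid | 0, 0.2, 0.3, 0.5, 0.6, 0.9, 1.0 | seven levels spanning the phases of the cybrid response |
| ground truth | β=1, k_mRNA=4, k_m=20, h₀=0.42, δ_p=1, c₁=1, m₂=2, h\*=0.4, k_o=5, k_g=1, k_gr=1, k_p=1 | reproduces the qualitative phenotype: transcript dip/recovery, glycolysis doubling by h=0.9, volume minimum just before h\* |
| RNA replicates | 3 | typical technical replication for RNA-seq |
| noise CVs | RNA 5%, volume 3%, protein 5%, respiration 5%, counts 2% | technical (not biological) variability, small relative to the h-dependence |
| growth | days 0–7, exponential to day 5, logistic cap after | exercises the day-5 truncation rule |

RPKM is generated as baseline_i × F(h)/F(0) × V(0)/V(h) × noise — i.e. the
per-cell model feature converted to a concentration — so that with noise
off the pipeline recovers the model's fold-changes exactly (tested to
machine precision). Noise is multiplicative mean-1 log-normal for
positive-valued raw measurements (RPKM, counts, protein) and additive
Gaussian for the volume and respirometry summaries; at these CVs the
propagated feature errors are approximately Gaussian, matching the
likelihood. Every table has its own deterministic RNG stream derived from
the study seed.

The generator emulates *technical* structure only. It does not simulate
biological replicate variability, mtDNA copy-number fluctuation, library
size or batch effects, gene-specific responses within a pathway, or any
h = 0.9 → 1 regime change. Passing recovery tests therefore demonstrate
correctness of the estimation machinery under the stated noise model, not
robustness to the biological messiness of real cybrid data.

## Inference

*Likelihood.* Independent Gaussian terms for the six measured features
(M_ETC, P⁺, M_gly, V, G, R_max) at levels h ≤ 0.9, with the table's
propagated SEs as noise scales. Zero or sub-floor SEs are floored at 1% of
the feature's h = 0 value (logged). One global SE multiplier is inferred by
default (log-uniform on [0.1, 10]): the reported technical SEs understate
effective noise, both because replicate-based SE estimates at n_r = 3 are
themselves highly variable and because the volume transform gives all
features at one h level a shared error component that an independent
Gaussian likelihood cannot represent. With the multiplier fixed at 1 the h\*
intervals are measurably overconfident in the package's own calibration
experiment (the 20-replicate recovery test); inferring it restores
approximate calibration. Set `LikelihoodSpec(infer_noise_scale=False)` to
treat the SEs as exact.

*Priors.* The defaults are weakly informative and support-respecting:
uniform h\* on (0, 0.9), uniform h₀ on (0, 1), log-uniform on [0.01, 100]
for all scale/rate parameters (k_m on [0.1, 100]). All are overridable per
parameter, and the fit records them in its summary.

*Sampling.* Affine-invariant ensemble MCMC (emcee) in transformed
coordinates (logs of positive parameters, bounded fractions as-is), where
the default priors are flat. The changepoint makes the posterior
non-differentiable wherever h\* crosses a data abscissa, so gradient-free
sampling is the natural choice. Moves are a 0.8/0.2 mixture of
differential-evolution and DE-snooker proposals: the fold-change likelihood
cannot identify absolute scales (see below), leaving long flat ridges along
which stretch moves mix an order of magnitude more slowly. Defaults: 32
walkers, 4000 steps, 2000 burn-in, walkers initialized in a 0.3-sd Gaussian
ball (transformed space) around a local optimum found from the
prior-typical point. Runs are deterministic given the seed.

*Point estimates and intervals.* The MAP is the best stored draw refined by
bounded trust-region least squares (exact for flat-in-sampling-space
priors, since a uniform SE multiplier does not move the weighted
least-squares optimum; its own conditional optimum is s² = SSE/n); the
refined point is only accepted if it does not lower the log posterior, so
the reported MAP always dominates every stored draw. Credible intervals and
pointwise bands are empirical quantiles (linear interpolation) over draws;
derived trajectories (N⁺/V, δ_m(h), OXPHOS fraction) are transformed
per-draw before taking quantiles.

*Diagnostics.* Split-R̂ and bulk ESS per parameter (arviz), treating
walkers as chains; runs are flagged when any R̂ exceeds 1.05. On
fold-change data the flag routinely fires on the *non-identifiable*
coordinates, whose marginals are prior-dominated and irrelevant to
predictions; the identifiable block should be checked individually.

## Identifiability

Fold-change data determine only: h\*, h₀, k_m, k_mRNA, the glycolysis
induction ratio m₂/c₁, and the h = 0 OXPHOS supply share
k_o P⁺(0) / (k_o P⁺(0) + k_g M_gly(0)). β and δ_p cancel from
M_ETC/M_ETC(0) and P⁺/P⁺(0); k_gr and k_p cancel from the rescaled G and
R_max. The zero-noise recovery test asserts <1% error exactly for this
identifiable set. Reporting raw-unit rates (`renormalize_rates=False`)
additionally pins k_gr/V(0) and k_p P⁺(0).

## Numerical choices

- The degradation sigmoid is evaluated through the logistic function, so
  extreme steepness returns the exact asymptotes 0 and k_mRNA instead of
  overflowing.
- h = h\* belongs to the constant glycolysis branch (a convention; the
  spline is continuous so no prediction changes).
- Conservation identities (V = k_o P⁺ + k_g M_gly, G·V = k_gr,
  R_max = k_p P⁺) hold to machine precision by construction and are
  asserted exactly in tests.
- Test and recovery problem sizes: fits use 32 walkers × 4000 steps
  (≈7 s per study on one core); the calibration experiment uses 20
  replicate studies; smoke tests use shorter chains. These sizes give
  split-R̂ ≲ 1.1 on identifiable parameters and are the package's default
  trade-off between resolution and turnaround.

## Limitations

- The likelihood treats per-datum errors as independent; the volume
  transform makes them correlated in truth. The global SE multiplier
  absorbs the average effect but not the correlation structure, so
  credible intervals remain approximate (calibration ≈ nominal in the
  package's recovery experiment, not guaranteed beyond it).
- The model is phenomenological and fitted without formal model selection;
  structure was chosen for parsimony, not tested against alternatives
  (e.g. well-mixed tRNA variants).
- Nothing above h = 0.9 is modelled; conclusions about homoplasmic cells
  are out of scope.
- Absolute rates are not recoverable from fold-change data; only the
  combinations listed under *Identifiability* are meaningful.
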