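# Methods

## Model

The observable is a pair of counts per CpG site and subject: methylated
reads `n_mod` out of valid coverage `n_valid`. We model

    y_sj ~ Binomial(n_sj, logit⁻¹(η_sj))
    η_sj = β0 + β_a(s) + β_TE·TE(s) + u_subj(j) + u_tax(t(s)) + u_site(s)
           + u_int(s,j) + Σ_c γ_{c,s}·x_{c,j}

All group-level effects are independent and identically distributed
Gaussians given their standard deviation; sites are deliberately iid
rather than spatially smoothed, because the goal is site-specific
variation and a random-walk prior would shrink differences between
adjacent sites. The site × subject interaction u_int is the object of
interest: its spread across subjects at a site quantifies
inter-individual variability there.

Priors: intercept N(0, 3); annotation coefficients N(0, 2) with intron as
the treatment-coding reference; TE presence N(0, 1.5). Random-effect sds
carry PC priors, parameterized by the tail condition P(σ > u) = α, i.e.
exponential densities with rate λ = −ln(α)/u: subject (1, 0.01), TE
taxonomy (1, 0.05), site (1.5, 0.05), interaction (1, 0.05), and cell
slopes (0.1, 0.05). The candidate-model catalogue additionally offers gene
and CpG-island terms; they are excluded from the complete model because
the site term absorbs site-constant predictors.

## Inference

Empirical-Bayes Laplace approximation:

- **Inner loop.** Given hyperparameters θ (log random-effect sds), Newton
  iterations maximize log p(y|x) + log p(x|θ) over the latent field
  x = (β, u). Convergence at max|∇| < 1e−6 or 100 iterations, with step
  halving (≤20) and a relative acceptance slack of 1e−11·(1+|f|) to absorb
  double-precision granularity of the joint; if halving stalls with
  max|∇| < 1e−3 the point is accepted as the numerical mode.
- **Outer loop.** Nelder–Mead on log σ (started at σ = u/2 per term,
  relative function tolerance 1e−4) maximizes the Laplace approximation to
  log p(θ|y): log p(y, x̂|θ) + ½ log det Q − ½ log det H + log p(θ),
  H(θ) = ZᵀWZ + Q. The latent field warm-starts across evaluations.
- **Marginals.** At the plug-in θ̂, latent marginals are Gaussian with
  mean x̂ and sd from diag H⁻¹; 95% intervals are ±1.96 sd. For small
  models (≤50 latent dimensions, non-Gaussian likelihood) each component
  is refined by the nested Laplace approximation: a grid over x_i with the
  remaining components re-optimized and the conditional Hessian
  determinant correction, which captures the skewness of low-count
  binomial posteriors (and is exact, up to grid quadrature, in one
  dimension). Hyperparameter uncertainty is not propagated (no grid
  integration over θ); skewness corrections at cohort scale are likewise
  out of scope — both are documented deviations from full INLA, in the
  spirit of its empirical-Bayes/Gaussian options.

### Factorization

The Hessian H is sparse; the site × subject interaction dominates its
dimension (one level per observation). Any random term with at most one
observation per level contributes a *diagonal* block, so H is factorized
through the Schur complement of the remaining core block:

    S = Zcᵀ diag(w − c) Zc + Q_core,  c_o = (w_o v_o)² / d_{ℓ(o)}

with a dense Cholesky of S (core = fixed effects + subject + taxonomy +
site + slope terms, typically ≤ ~1000). Solves, log-determinants, inverse
diagonals (marginal variances) and exact Gaussian posterior sampling all
flow through this block factorization; a generic dense-Cholesky /
sparse-LU path (scipy `splu`, fill-reducing ordering) covers models
without a singleton term and serves as a cross-check — the two paths agree
to 1e−10 in the tests. This replaces a CHOLMOD dependency with no
approximation.

### Information criteria

DIC, WAIC and CPO are computed from S = 1000 Monte-Carlo draws of the
Gaussian latent posterior (seeded): DIC = D(x̂) + 2p_D with
p_D = mean_s D(x_s) − D(x̂); WAIC = −2(lppd − p_WAIC); CPO_i via the
harmonic-mean estimator from the joint Gaussian approximation (an
importance-sampling approximation, not a leave-one-out refit; numerically
degenerate weights are flagged per observation). Model selection ranks by
DIC and, within a 4-unit band of the best, prefers the fit with the fewest
effective parameters; discordant WAIC orderings are flagged but do not
override DIC.

## Entropy filtering

Hrel is the plug-in normalized Shannon entropy of per-subject methylation
fractions binned into 10 equal-width bins on [0,1] (left-closed, 1.0 in
the top bin; 10 bins matching a 10× minimum-coverage resolution): with
occupancy proportions p_k over non-empty bins, Hrel = −Σ p_k ln p_k / ln 10.
Each subject contributes one point fraction regardless of coverage.
Percentile filtering keeps values strictly greater than the linear-
interpolation (type-7) percentile; ties at the cut drop. IQR uses type-7
quartiles and SD the n−1 sample estimator everywhere, including the
interaction summaries, for cross-language reproducibility.

## Cell-composition adjustment

The five-part blood differential is compositional: we CLR-transform
(ln x_c − mean of ln x over the five parts; zero percentages replaced by
0.1% with renormalization, since the CLR is undefined at zero), drop
neutrophils (most abundant, least variable), and z-score the remaining
columns across observed subjects — z-scoring after the neutrophil
exclusion. Eosinophils and basophils are computed but excluded from the
final model as weakly identified. Lymphocyte and monocyte CLR-z values
enter as per-site varying slopes, one shared sd per cell type. Subjects
missing the differential get independent N(0, 0.1²) draws per cell type on
the z scale (flagged `imputed`); a missing-as-zero companion mode exists
for robustness checks. A site is called cell-specific when the 95%
interval of its slope excludes 0.

## Synthetic cohorts

`simulate_cohort` draws from the model itself: genes laid along one
synthetic chromosome (promoter = 2 kb upstream of the TSS, UTR/CDS/intron
structure, uniformly placed TEs with taxonomy labels and CpG islands),
sites annotated by the same interval machinery the real pipeline uses;
coverage n_valid = coverage_min + Poisson(coverage_mean − coverage_min)
(defaults 10 and 30, a realistic whole-genome nanopore depth);
blood compositions from a Dirichlet centered on a healthy differential
(α ∝ (30, 7, 2.5, 0.5, 60), concentration 50) with two subjects' values
masked; sparse cell slopes (10% nonzero per cell type). Default latent
scales: sd_subject 0.5, sd_taxonomy 0.1, sd_site 1.63, sd_interaction
0.323 (the latter two read as standard deviations; reported concordance
values are ambiguous between sd and variance, and sd is the conservative
reading). A configurable fraction of sites (default 10%) is flagged
hypervariable with the interaction sd multiplied by 3, and flagged sites
receive regulatory chromatin states (TssA, TssAFlnk, Enh, ReprPC) with a
3-fold boosted probability, so the enrichment stage has a known truth:
the enhancer state's expected log enrichment among flagged sites is ln 2
under the default frequencies. All randomness flows from one seed through
named sub-streams, so changing one component's dimensions leaves the
others' draws intact.

What the generator does **not** emulate: spatial correlation between
neighbouring CpGs, 5hmC, read-level errors, strand asymmetry, batch or
flow-cell effects, and real cell-type deconvolution structure. Passing
tests on these cohorts demonstrate that the machinery recovers the model's
own structure at realistic sizes — not that the model is adequate for any
particular real dataset.

## Hypervariability and enrichment

Site-level summaries (mean, SD, IQR, range) are taken over the posterior
means of u_int(s, ·) across subjects; sites with IQR above the threshold
(default 0.25) are selected and ranked. Chromatin states must partition
the genome (overlap is an error); sites in gaps become "Unannotated" and
are excluded from enrichment with a count report. Expected counts
e_k = n_selected · f_k use the post-assembly, pre-entropy-filter site set
as the frequency background by default (a flag switches to the filtered
set). The per-state log enrichment ratio δ_k has an o_k ~ Poisson(e_k e^{δ_k})
likelihood and a near-flat N(0, 10²) prior; its posterior is computed by
mode-centred grid quadrature (8001 points over ±12 conditional sds — exact
to well below the reporting precision; the engine's Poisson-offset Laplace
path is the independent cross-check in the tests). The threshold scan
(0.10–0.35 by 0.01) reports the full table per threshold plus, per state,
the longest suffix of the grid over which the call is constant. States
with expected count < 1 are flagged low-information but never dropped
automatically.

A note on the default threshold: at the default simulation depth (30×) and
100 subjects, per-(site,subject) posterior interaction means retain enough
binomial noise that a typical site's IQR is ≈ 0.3, so an absolute 0.25
threshold is permissive there; the IQR scale depends on coverage and
cohort size, which is why the threshold scan and the stability summary are
first-class outputs rather than afterthoughts.

## Validation experiment design

The test suite validates each stage against independent oracles:
quadrature for 1-D posteriors and for the enrichment model; a 200k-step
random-walk Metropolis sampler (targeting the latent field at the
empirical-Bayes θ̂, which is what the Laplace fit approximates) for
multi-dimensional binomial models; closed-form conjugate results for the
Gaussian-likelihood limit, where the Laplace approximation is exact to
1e−8.

Problem sizes for the simulation experiments were chosen once as
desk-scale versions of the cohort the generator emulates:

- **Variance-component recovery** uses 40 subjects × 60 sites at 200× mean
  coverage, seeds 1–10. Depth matters here: at 30× the binomial noise per
  observation (se ≈ 0.4–0.6 logit units) exceeds an interaction sd of 0.4,
  so even the exact posterior means cannot correlate with the true
  interaction effects beyond r ≈ 0.65–0.7 — an information ceiling, not an
  estimator deficiency. At 200× (a deep targeted panel) the ceiling lifts
  and the fit achieves r ≈ 0.85 per run with median sd error well under
  25%.
- **Hypervariable detection** uses the generator's stated scale, 100
  subjects × 150 sites with 10% flagged at multiplier 3 (seeds 1–5): with
  15 flagged sites the AUROC estimator itself is stable enough for a ≥0.9
  bound to measure detection rather than estimator noise.
- **Adjustment behavior** uses 25 subjects × 40 sites over 10 seeds with
  all-nonzero lymphocyte slopes (sd 0.3) for the sign test on the median
  per-site interaction-SD change, and 40 subjects × 40 sites at 100× for
  the zero-slope selection-equality check, where boundary jitter of the
  IQR estimates around the 0.25 cut is small relative to inter-site gaps.

## Numerical choices and degenerate inputs

- Binomial weights floored at 1e−12 to keep H positive definite at
  saturated fits; PC-prior hyperparameters optimized as log σ with the
  Jacobian added to the objective.
- Subjects ranked for assembly with lexicographic subject-id tie-breaks;
  observation order is site-major, subject-minor — both fixed so artifacts
  are byte-reproducible.
- Sites with fewer than two covered subjects get NaN metrics, a `usable`
  flag of False, and are excluded downstream; an all-tied metric vector
  retains nothing at any percentile (strictly-greater rule) with a warning.
- A TE-taxonomy term requested on a cohort without TE sites is dropped
  with a warning rather than fitted as an empty factor; non-TE
  observations load on a pinned dummy level through a zero covariate.
- Enrichment with a state observed but absent from the background is an
  error (impossible under the offset model) listing the states.

## Known limitations

- Empirical Bayes: hyperparameter uncertainty is not propagated into the
  latent marginals, so random-effect sds and downstream IQRs are slightly
  over-confident in small cohorts.
- Gaussian marginals at cohort scale (the nested-Laplace refinement is
  restricted to small models for cost reasons) understate skewness at
  extreme methylation fractions.
- CPO uses joint-Gaussian importance weights, not leave-one-out refits.
- The absolute IQR threshold is not transferable across depths or cohort
  sizes (see above); comparisons between datasets should use the scan.
- No strand merging of CpG dyads; no spatial models; no 5hmC.
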