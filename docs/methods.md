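# Methods

This note documents the statistical model behind `serorate`, the numerical
scheme, the design choices made where the design was genuinely open, and
what the synthetic validation study does and does not demonstrate.

## Model

### Exposure process

Infections arrive as a Poisson process with rate λ, constant over time and
across individuals within a stratum. For a subject of age *a* (converted to
days internally; λ is optimized per day and reported per person-year,
×365.25, and per 1000 person-years in summaries):

* P(never infected) = e^(−λa) — an atom, because subjects cannot have been
  infected before birth. We truncate the time since the most recent
  seroconversion τ at age rather than using the stationary untruncated
  exponential; the survey supplies age as a required variable, and for young
  subjects the truncation matters.
* Given at least one infection, τ has density λe^(−λτ)/(1 − e^(−λa)) on
  (0, a); only the most recent seroconversion is modelled (no boosting).

### Seroresponse kinetics

The post-seroconversion trajectory is the standard two-phase model: an
exponential rise from baseline y₀ to peak y₁ at t₁ days
(y(t) = y₀e^(μt), μ = ln(y₁/y₀)/t₁), followed by the solution of the decay
ODE dy/dt = −α yʳ:

* r > 1: y(t) = y₁·[1 + (r−1)·α·y₁^(r−1)·(t−t₁)]^(−1/(r−1))
* r = 1: y(t) = y₁·e^(−α(t−t₁))

α carries units concentration^(1−r)/day, so its numeric value is not
comparable across r; the package never rescales it automatically. The
trajectory parameters are supplied as an ensemble of posterior draws per
antigen-isotype from an upstream longitudinal model fit; the cross-sectional
likelihood is the equal-weight mixture over the K draws, which propagates
between-individual heterogeneity and parameter uncertainty. Draws are fixed
for a whole estimation run, never resampled per subject.

The rise phase is included in the likelihood's latent-time integral by
default (`include_rise=True`). It contributes little mass (t₁ is days while
1/λ is months–years) but removing it would bias the density near and below
the peak; the decay-only switch exists because the analytic oracle used in
testing (below) is decay-only.

### Observation model

The measured value is

    Y = (y_model + B) · E,   B ~ Uniform(0, ν),
    E ~ LogNormal(−σ²/2, σ),  σ² = ln(1 + ε²),

with y_model = 0 for the never-infected. The noise inputs ν (biologic
noise, concentration units) and ε (assay CV, dimensionless) do not by
themselves fix an algebraic composition, so this is a modelling choice:

* **B additive and uniform on (0, ν)**: ν is an upper noise level (in
  practice calibrated as an upper quantile of the response distribution in
  unexposed individuals). Uniform background keeps the λ→0 limit of the
  density flat at 1/ν and is analytically tractable. A normal-tail
  treatment is a plausible alternative; the `no-measurement-noise` and
  `noise-free` modes exist to probe sensitivity to the noise composition.
* **E multiplicative and lognormal with mean 1**: assays are positive-valued
  with errors roughly proportional to the signal; a CV of ε maps to
  σ² = ln(1+ε²), and the −σ²/2 log-mean makes E mean-one so noise does not
  inflate the average titre. ε = 0 gives E ≡ 1 exactly.

The simulator draws from exactly this model — a single source of truth — so
inference is self-consistent and distributional tests (below) close the
loop.

Values v with v ≤ y_low or v ≥ y_high (inclusive, matching "recorded
outside the limits") contribute censored masses P(Y ≤ y_low) or
P(Y ≥ y_high) instead of densities.

### Likelihood and estimation

Per observation, p(y | λ, a) = e^(−λa)·p_never(y) + ∫₀ᵃ λe^(−λτ) ·
(1/K)·Σ_k p_meas(y | y(τ; θ_k)) dτ, and the negative log-likelihood sums
−ln p over all records of all requested antigen-isotypes (biomarkers are
treated as independent; their log-likelihoods add). λ is profiled on
x = ln λ within finite bounds (default [1e−6, 5] per person-year), the SE
comes from the observed information 1/√(d²NLL/dx²), and the 95% CI is
exp(x̂ ± 1.96·SE). Wald-on-log is the reporting convention; a
profile-likelihood interval is available (`profile_ci=True`) and agrees
closely in the well-identified regimes we simulate. Fits at a search bound
or with non-positive curvature are reported with `converged=False`, never
silently dropped. Strata with fewer than 30 observations warn.

## Numerics

**Closed-form noise convolution.** For m = y_model fixed, the density and
CDF of (m+B)E have closed forms in the normal CDF Φ. With
q(u) = (ln(y/u) + 3σ²/2)/σ and h(u) = (ln(c/u) + σ²/2)/σ:

    p(y|m)    = (e^{σ²}/ν)·[Φ(q(m)) − Φ(q(m+ν))]
    P(Y≤c|m) = [A(m+ν) − A(m)]/ν,
    A(u)      = u·Φ(h(u)) − c·e^{σ²}·Φ(h(u)+σ),  A(0) = −c·e^{σ²}

(both derived by substituting w = ln u in the Uniform average of the
lognormal pdf/cdf and completing the square; they reduce to the
Uniform(m, m+ν) pdf/cdf when σ = 0, and are verified against numeric
convolution to 1e−9 in the unit tests). Using the exact kernel leaves the
latent-time integral as the only quadrature.

**Latent-time quadrature.** On each monotone branch of the trajectory the
τ-integral is transformed to ln y_model (dτ = −dm/(α mʳ) on the decay
branch, dτ = dm/(μm) on the rise). Integration is restricted to the window
where the noise kernel is non-negligible (±8 lognormal SDs, widened by ν),
and the window is covered by Gauss–Legendre panels (6 nodes each) whose
widths roughly double with depth below the window top — the survival weight
e^(−λτ) always decays towards lower antibody levels, so resolution is spent
where mass is. The censored-mass kernels have plateau regions (CDF ≡ 1
below the window, survival ≡ 1 above it) that integrate in closed form as
differences of exponentials; censored-high masses are assembled in survival
orientation to avoid 1−CDF cancellation. Setting
`check_quadrature=True` recomputes on a refined grid (double nodes, halved
panel spacing) and raises `QuadratureError` beyond `rel_tol` (default
1e−6). Under the default scheme, total probability (interior density plus
both censored masses) is conserved to ~1e−6 across random configurations —
comfortably inside the 1e−3 the validation asserts.

**Precomputation.** After the change of variables every per-observation
likelihood is Σ_c ω_c e^(−λτ_c) + λ·Σ_j g_j e^(−λτ_j) with λ-independent
weights. A fit precomputes (ω, g, τ) once; each likelihood evaluation and
its analytic first/second derivatives in ln λ are then weighted sums of
exponentials. The default optimizer brackets and root-finds the analytic
gradient (Brent, xtol 1e−6 on ln λ) and reuses the analytic curvature for
the SE; the bounded golden-section/parabolic search and the central-
difference SE (step 1e−4) remain as options and agree to ~1e−8 in tests.
With this fast path one fit of n = 1000 subjects × 20 draws takes ~0.3 s on
one CPU.

**Degenerate inputs.** t exactly at t₁ is assigned to the rise branch
(equal by continuity, fixed for determinism). A density of exactly zero for
any record (e.g. a value above (y₁+ν) with ε = 0) raises `DensityZeroError`
naming the records — it signals model/data incompatibility rather than a
numerical failure. All-censored-low data drive the optimum to the lower
search bound with `converged=False`. In the `noise-free` mode ν is floored
at 1e−9 so the density stays well-defined; at that width the achievable
agreement with the analytic change-of-variables density is limited to
~1e−5 by float64 representation of y−ν, not by the quadrature.

## Synthetic study conditions

The simulator's defaults define the validation conditions and were fixed
once:

* Two enteric-fever-like biomarkers: HlyE_IgG (y₀=1, y₁=100, t₁=10 d,
  α=0.01, r=2) and HlyE_IgA (y₀=1, y₁=60, t₁=8 d, α=0.015, r=1.8), in
  ELISA-like units where the unexposed background is order 1.
* Ensemble dispersion: lognormal CVs of 0.15 on y₀, y₁, α, 0.1 on t₁ and on
  r−1 — heterogeneity comparable to the spread seen across confirmed cases.
* Noise: ν = 1.0/1.5, ε = 0.2, quantification limits [0.1, 5000] /
  [0.3, 5000].
* Ages Uniform(2, 15) years — a child/adolescent serosurvey; the age
  sampler is pluggable.
* λ between 0.05 and 0.8 per person-year — low to high transmission.

By default each biomarker of a subject receives an independent latent τ,
matching the likelihood's independence assumption exactly so that recovery
and coverage tests are oracle tests of a correctly-specified model.
`shared_tau=True` gives every subject one infection clock across
biomarkers — closer to reality — and exists to quantify the cost of the
independence approximation (point estimates are nearly unbiased; CIs become
somewhat anticonservative because the effective number of independent
observations is overstated).

**What passing these tests shows — and does not.** The replicate study
(n = 1000 subjects, 20-draw ensembles, 200 replicates at λ ∈ {0.05, 0.2,
0.8}/PY) demonstrates near-unbiasedness (<2% observed, <10% asserted) and
Wald coverage within (0.90, 0.98) *under the generative model*. Real
surveys add model misspecification the simulator does not emulate:
non-constant λ over age and calendar time, boosting and repeated exposures
(problematic in high-transmission settings), cross-reactive responses
correlated across biomarkers, assay drift between laboratories, and
uncertainty in the upstream kinetics fit beyond what the ensemble captures.
Those effects are outside this package's scope and are not validated here.

## Design decisions

* Internal units: days for kinetics and τ, years for age, λ per day
  internally and per person-year in all reported quantities. Readers convert
  explicitly (`time_unit="year"` multiplies t₁ by 365.25 and divides α by
  365.25); silent unit mixing is the main real-world failure mode this
  guards against.
* Duplicate (id, antigen_iso) rows are an error, never averaged.
* CSV is the only interchange format (dot and underscore header dialects
  accepted; antigen-isotype *values* are case-sensitive exact keys). RDS is
  not read; the one-line R export recipe is in the README.
* Stratified estimation partitions on observed covariate combinations; when
  the seroresponse ensemble carries matching stratum columns the
  cell-specific draws are used, otherwise all cells share the common
  ensemble. Cells are computed independently (identical results for any
  worker count).
* The command-line interface is a thin wrapper over the library (no
  CLI-only logic), logs to stderr, writes machine outputs to files, and
  records provenance (config echo, package version, input SHA-256) for
  every run.

## Known limitations

* Constant-λ Poisson exposure: no age-varying or seasonal force of
  infection, no covariate-adjusted (regression) model for λ.
* Single most-recent infection: no boosting on re-exposure; in
  high-transmission settings repeated exposures reshape the response
  distribution and bias estimates — not addressed here.
* Biomarker independence in the likelihood (see above).
* The upstream longitudinal kinetics fit is out of scope; the ensemble is
  taken as given, and the bundled generator of synthetic ensembles is a
  labelled stand-in for a real posterior, not a replacement for one.
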