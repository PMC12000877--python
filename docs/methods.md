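# Methods

## Models

### Steady-state (age-independent) family

Per allele the telegraph model switches between an inactive and an
active promoter state (rates σ₁ on, σ₀ off) and transcribes at rate ρ
while active; mRNA decays at rate d. All rates are normalised by d
(d = 1 internally), since snapshot data only identify rate ratios. The
stationary pmf involves Kummer's confluent hypergeometric function; we
evaluate it entirely in log-space using the transformation
₁F₁(a, c, −ρ) = e^{−ρ} ₁F₁(c − a, c, ρ), whose series has positive terms
only, so no cancellation occurs. The series is summed by `logsumexp`
with a term count of order ρ + 12√ρ + 60 (the term ratio falls below 1
once k ≳ ρ). Any non-finite value falls back to 50-digit arbitrary
precision (mpmath). A truncated-master-equation solver (null space of
the generator over states (promoter state, m)) serves as an independent
oracle; the two agree to total variation ≲ 1e−14 across the tested
parameter grid.

The bursty limit is NB(f, (1+b)⁻¹) with f = σ₁, b = ρ/σ₀; the
constitutive limit is Poisson(ρ). Zero inflation mixes a point mass p₀
at zero into the *observed* count distribution. Multi-copy expression
(2 alleles in G1, 4 in G2/M) is the k-fold self-convolution of the
allele pmf; Poisson and NB use the closed forms Pois(kρ) and NB(kf, p),
generic pmfs are convolved by direct summation (counts are small, so
exactness beats transform methods).

Zero inflation is applied after the copy-number convolution, because the
inflation models a property of the observed total count (technical
dropout), not of each allele; the pre-convolution alternative is
available via `ModelSpec(zi_post_convolution=False)`.

### Age-dependent bursty model

Each allele fires instantaneous bursts of geometrically distributed size
with mean b(θ) = ρ·e^{βθ}; the burst frequency is f₁ before and f₂ after
DNA replication, ρ ∈ {ρ₁, ρ₂} likewise, and β takes four values on the
segments [0, θ_G1), [θ_G1, θ_r), [θ_r, θ_S), [θ_S, 1). Age θ = t/T is
normalised time in a fixed-duration cycle. The mean and variance of the
total count obey, per segment,

    d⟨m⟩/dθ = c·e^{βθ} − dT·⟨m⟩,
    dσ²/dθ  = −2dT·σ² + c·e^{βθ}(1 + 2ρe^{βθ}) + dT·⟨m⟩(θ),

with c = (copies)·f·ρ·T, copies = 2 before and 4 after θ_r. A
"frequency-scaling" variant instead puts the e^{βθ} factor on the burst
frequency with constant burst size; it has the identical mean equation
(means depend only on the product f·b) but a different variance forcing,
c·e^{βθ}(1 + 2ρ).

**Closed-form solution.** Within a segment every forcing term is
c·u^k·e^{su} in the local coordinate u = θ − θ₀ (k ≤ 1), for which the
particular solution of y′ = −a·y + forcing is analytic; when a forcing
exponent collides with the homogeneous decay (|s + a| < 1e−9) the
resonant limit c·u·e^{su} is used instead. Working in segment-local
coordinates keeps every stored coefficient bounded for arbitrarily fast
degradation. The cyclo-stationary initial condition exploits linearity:
the end-of-cycle moment is affine in the birth moment with homogeneous
factor e^{−dT} (mean) or e^{−2dT} (variance), so the fixed point of the
cycle map — birth mean = half the pre-division mean; birth variance
= (σ²(1) + ⟨m⟩(1))/4, from binomial partitioning — is solved in closed
form. Iterating the cycle map reproduces the fixed point to 1e−10
(tested), and exact stochastic simulation reproduces both moments within
sampling error.

**Count law.** At every age the count distribution is approximated by
the negative binomial matched to (⟨m⟩(θ), σ²(θ)):
r = ⟨m⟩²/(σ² − ⟨m⟩), p = ⟨m⟩/σ². When a parameter combination makes
σ² ≤ ⟨m⟩ (possible transiently during optimisation), the Poisson with
the same mean is used — the overdispersion-free limit of the NB.

### Default segment boundaries

The G1/S and S/G2 transitions are reported at raw ages 0.26–0.27 and
0.63–0.64 on the pre-truncation axis. After removing the ambiguous
[0, 0.09] newborn range and rescaling θ ↦ (θ − 0.1)·0.99/0.89, the
midpoints map to θ_G1 ≈ 0.1835 and θ_S ≈ 0.5951; replication is placed
mid-S, θ_r = (θ_G1 + θ_S)/2 ≈ 0.3893. All three are configurable.
Whether the printed transition ranges refer to pre- or post-rescaling
coordinates is not fully determined by the source material; we map them
through the rescaling. Moments are evaluated at the bin value θ itself
(not bin centres or edges), matching the 0.01-binned data convention.

A consequence worth knowing: the division condition pins ⟨m⟩(0) to half
the pre-division mean, so the θ = 0 bin sits below the G1 quasi-steady
level whenever post-replication production is reduced. Uniform-weight
phase averages over bins therefore differ from idealised quasi-steady
levels by a boundary-layer term that does not vanish even for very fast
degradation (the θ = 0 bin never relaxes); e.g. at dT = 200 with halved
post-replication frequency the G2/M : G1 bin-averaged mean ratio is
≈ 1.031 rather than exactly 1.

## Inference

**Likelihoods.** Counts are deduplicated to (θ-bin, count) pairs with
multiplicities, so one likelihood evaluation costs one moment solve plus
one vectorised NB log-pmf over unique pairs (~0.7 ms for 5000 cells).

**Optimisation.** Transformed coordinates with the following boxes: NB
f ∈ [−10, 10] (log), p ∈ [−30, 30] (logit); telegraph σ₀, σ₁, ρ ∈ [−9, 7]
(log); zero-inflation p₀ ∈ [−30, 30] (logit); ZIP ρ ∈ [−9, 7] (log); age
model f₁, f₂, ρ₁, ρ₂ ∈ [−7, 7] (log) and β₁..β₄ ∈ [−100, 100] (linear).
A differential-evolution global stage (population-based, seeded) is
followed by L-BFGS-B refinement; the whole procedure restarts from fresh
random initialisations (5 steady-state / 10 age-dependent by default)
and keeps the best likelihood. The Poisson MLE is the sample mean per
copy, in closed form. Non-finite likelihoods return a penalty of
1e10 + squared distance from the box centre so the global stage stays
informed. Iteration caps (not wall-clock limits) bound each stage; all
budgets sit in `OptimizerConfig`.

For the age model, `fit_age_model` defaults to a cheaper strategy that
exploits the model structure: per-segment log-linear regression of the
binned means initialises the β's, quasi-steady moment relations
(⟨m⟩ ≈ c·e^{βθ}/(β + dT), Fano ≈ 1 + b) split the production rate into
f and ρ, and L-BFGS-B refines from that point plus jittered restarts.
On data generated by the model this recovers ratio parameters as well as
the global search at a tenth of the cost; the full global strategy
remains available (`use_de=True`).

**Model selection.** BIC = −2 log L + k log n; the ladder Poisson → ZIP
→ NB → ZINB → telegraph → ZI-telegraph starts at the simplest model and
advances only while some more complex model improves BIC by more than
10, returning the simplest adequate family.

**Confidence intervals.** Profile likelihood: the target is stepped
outward from its MLE (initial step 2% of the MLE magnitude or 0.02,
geometric growth ×1.5), nuisance parameters re-optimised at each step
with warm starts, and the crossing of log PL = log L* − χ²₁,₁₋α/2
refined by bisection to 1e−4 relative. Derived quantities use the
prediction profile likelihood: the constraint g(ξ) = z is imposed by
eliminating one transformed coordinate (e.g. log f₂ = log z + log f₁ for
Q_f); two-phase ratios use the product of phase likelihoods. Intervals
that hit a parameter bound are flagged. Against the analytic
likelihood-ratio interval for a Poisson mean the profile interval agrees
to ~1e−4, and 95% NB intervals achieve ~95% empirical coverage.

## Pipeline

Age preprocessing removes cells with θ ≤ 0.09 (possible division
misclassification) and rescales the rest onto [0, 0.99], re-snapped to
the 0.01 grid. The expression filter keeps genes with mean count ≥ 1 in
all of G1/S/G2M ("below one" read strictly: exactly 1 is kept). The
age-model filter cascade then records, per gene, the first failing step:

1. no degradation rate in the input table;
2. negative Pearson correlation between binned mean counts and θ in G1
   or G2/M (no significance test — the sign alone decides);
3. after fitting, sign disagreement between the fitted mean trajectory's
   trend vs θ and the data's, in G1 or G2/M;
4. negative R² (1 − SS_res/SS_tot) of the fitted mean or variance over
   all cycle bins.

Q_f is f₂/f₁ from the age fit; Q_b is the ratio of phase-averaged burst
sizes ρ·Σ_θ g(θ)e^{βθ} using each phase's empirical cell-age histogram
(ρ₁, β₁ for G1; ρ₂, β₄ for G2/M). For the steady-state path, Q_f and Q_b
come directly from the per-phase NB (or telegraph) fits; genes selected
as Poisson/ZIP in either phase have no defined burst parameters and are
dropped as non-bursty. The population-wide age histogram is the default
weight in the synthetic generator's ground-truth Q_b; the pipeline's
estimates use per-phase empirical histograms.

The capture-robustness experiment samples genes from the intersected
5–95 percentile box of the fitted (Q_f, Q_b), divides ρ₁, ρ₂ by the mean
capture efficiency ⟨p⟩, simulates true counts from the (rescaled) fitted
model at the study's cell ages, thins them with per-cell
p ~ Beta(30, 70) (⟨p⟩ = 0.3, CV ≈ 0.15; one p per cell, shared across
genes), refits, and reports per-gene medians and interquartile ranges
over replicates against the pre-capture estimates. Since both ρ's are
rescaled equally, the ground-truth ratios are unchanged by the
rescaling.

## Synthetic data

The generator emulates the *processed* product of the real study: 5294
cells (941/2240/2113 in G1/S/G2M by default, hit exactly by sampling
ages within each phase's bin range), ages on the 0.01 grid, counts drawn
per gene from the age-dependent model's moment-matched NB at each cell's
age, and a degradation-rate table drawn log-normally around the 7.1 h
median mRNA half-life (σ = 0.4 on the log scale; a configurable fraction
of genes can be left rate-less to exercise filter step 1). The default
age structure is the steady exponential-growth law with bin weights
∝ 2^{1−θ} (newborns twice as frequent as about-to-divide cells); uniform
and user-supplied empirical histograms are available, and recovery
behaviour is insensitive to this choice in our tests. With
`emit_raw_ages=True` the written ages are mapped back through the
inverse of the truncation-rescaling so the pipeline's preprocessing step
operates non-trivially; the double rounding can shift a cell by at most
one 0.01 bin.

Gene parameters are drawn from log-uniform priors (f₁ ∈ [0.2, 2] /h,
ρ₁ ∈ [1, 4] molecules) with segment exponents β₁, β₃, β₄ ∈ [0.05, 0.7]
and β₂ ∈ [−0.7, −0.05], matching the rising/dipping/rising/rising mean
profile seen in cycling transcriptomes and giving mean counts of order
5–50 at the fixture's degradation rates. Optional constraints pin every
gene's Q_f (f₂ = Q_f·f₁) and Q_b (ρ₂ solved from the phase-average
identity) exactly, which is how recovery studies with known cohort
medians are built.

The stochastic-simulation oracle is an exact event-driven simulation of
the bursty reaction scheme (instantaneous geometric bursts — not
telegraph switching, consistent with the model being checked; linear
degradation; copy doubling at θ_r; binomial halving at division),
time-inhomogeneous burst rates handled by thinning. Lineages start at
zero molecules and run through 10 warm-up generations before observation
(memory decays like e^{−dT} per cycle, and moments from warm-up 10 vs 20
are statistically indistinguishable in our tests); the inner loop is
numba-compiled.

What the generator does *not* emulate: ambient RNA, doublets,
amplification bias, gene-gene correlations, stochastic cell-cycle
duration, or cell-age misclassification beyond the truncation the
pipeline already applies. Passing recovery tests therefore demonstrate
correctness of the inference machinery under the model's own
assumptions plus capture noise, not robustness to every artefact of real
sequencing data.

## Problem sizes

The study-scale checks run at reduced but honest sizes chosen for a
single CPU: transcriptome recovery uses 200 genes × 5294 cells with
trend-initialised fits (~1.5 s per gene); model-selection consistency
uses 50 replicates per generating family at n = 2000 cells with a
trimmed global-search budget (1 restart, 15 DE iterations — ample for
ΔBIC > 10 discrimination); CI calibration uses 200 datasets of 200
cells; the capture experiment uses 20 genes × 10 replicates at full cell
count. The analysis drivers default to the same sizes.

## Known limitations

- Fixed cell-cycle duration and fixed, gene-independent replication age
  θ_r; no stochastic cycle length, cell-size homeostasis or multi-step
  degradation.
- The NB moment-matched count law is an approximation to the exact
  time-dependent distribution (excellent in practice, but not exact).
- Two-state promoter models only; with bursty data, richer promoter
  architectures collapse onto the NB anyway and would not be selected.
- Steady-state ratio CIs are implemented for the NB family (the
  dominant selection outcome); telegraph-family ratio CIs would need the
  same elimination machinery applied to ρ/σ₀.
- Profile scans assume a unimodal likelihood in the scanned direction;
  multi-modal profiles would need a grid scan.
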