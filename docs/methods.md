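# Methods

This note documents the models, algorithms, numerical choices and known
limitations of the package. Everything quantitative here is computed by the
test suite or the example code; nothing is asserted beyond what those runs
show.

## The CA1 model

A single-compartment conductance-based neuron with eight currents:

    C dV/dt = I_app − I_NaT − I_NaP − I_CaT − I_CaH − I_KDR − I_KM − I_L − I_H

    I_NaT = g_NaT·m∞³(V)·h·(V−E_Na)       I_NaP = g_NaP·m∞(V)·(V−E_Na)
    I_CaT = g_CaT·m²h·(V−E_Ca)            I_CaH = g_CaH·m²h·(V−E_Ca)
    I_KDR = g_KDR·m·h·(V−E_K)             I_KM  = g_KM·m·(V−E_K)
    I_L   = g_L·(V−E_L)                   I_H   = g_H·(p·m_H+(1−p)·n_H)·(V−E_H)

Ten gating variables relax first-order to Boltzmann steady states
x∞(V) = 1/(1+exp(−(V−V_x)/k_x)); the two sodium activations are
instantaneous. All time constants are fixed except the I_NaT inactivation,
τ(V) = 0.2 + 0.007·exp(exp(−(V−40.6)/51.4)) ms, which drops to ~0.2 ms at
depolarized voltages. The single hyperpolarization-activated current I_H
carries a fast and a slow gate mixed by the fraction p.

Units are mV, ms, mS/cm², µA/cm², µF/cm². Experimental pA commands map to
current densities through one constant (`PA_TO_MODEL` = 0.015 µA/cm² per
pA), chosen once so the default cell fires under the +300 pA step; no
membrane area is modeled.

**Default parameters are synthetic.** The package ships a plausible
CA1-like parameter set (docstring-labelled as such) tuned once to produce
spiking under depolarization and H-current sag with rebound under
hyperpolarization. Any published value set can be supplied through
`ModelParameters`/config; all shipped results are relative to the declared
defaults, not to any laboratory's cells.

### Numerics

* Reference path: `simulate` uses LSODA with rtol 1e−8 / atol 1e−10,
  output grid dt_out = 0.02 ms (0.05 ms for the spike-free hyperpolarizing
  protocol).
* Batch path: `simulate_batch` is a numba-compiled classic RK4 at
  dt = 0.02 ms. The fastest time scale (τ_hNaT → 0.2 ms) keeps the system
  only mildly stiff, so explicit RK4 is stable and matches the adaptive
  reference to < 0.3 mV everywhere on the default trace (< 0.1 mV against
  RK4 at dt = 1e−3 in the cross-validation test). Voltage-dependent gating
  curves are precomputed on a 0.01 mV lookup grid and linearly
  interpolated; the interpolation error is orders of magnitude below the
  truncation error.
* Initialization: the bias current holding the cell at −80 mV is the
  algebraic ionic current at the target voltage with gates at steady state
  (dV/dt = 0 there), verified by a settling simulation. Because the initial
  state is this fixed point, the pre-pulse settle is flat; 200 ms of
  settling is integrated anyway as a guard, and `find_bias_current`
  verifies stability over 1000 ms.
* Gates are clipped to [0,1] only when overshoot is below 1e−9; larger
  excursions are an error.

## Feature extraction

Nine action-potential features of the first spike (local maximum above
−20 mV inside the pulse window) and four hyperpolarization features.
Windows follow the experimental convention: rate-of-rise extrema in
[peak−1 ms, peak+2 ms], trough in the 2 ms after the peak, pre-peak minimum
in the 1 ms before, threshold = voltage at the first point reaching 10% of
the max rate of rise within 5 ms before the peak, width = time above the
voltage at max rate of rise. Hyperpolarization: baseline = mean of the
50 ms before onset; sag peak, last-50 ms steady state, 200 ms rebound
window, and the asymptote of a single-exponential fit a + b·exp(−t/τ) from
onset to the sag peak — all as differences from baseline. All windows are
configurable.

**Grid-independence.** The AP upstroke reaches ~1000 mV/ms, so derivatives
tied to the output grid do not converge under refinement. The spike window
is therefore resampled through a cubic spline at 2 µs; dV/dt is a central
difference with a fixed ±20 µs stencil evaluated on the spline; and the
*positions* of the dV/dt extrema — whose voltage readouts amplify a 10 µs
localization error into several mV — use an intensity-weighted (soft)
argmax over the near-extremal region. With these choices every feature
changes by < 1% when dt_out is halved. The same hypersensitivity exists in
real recordings, which is consistent with the voltage-at-max-rate-of-rise
feature being the least reproducible one in validation.

## Calibration

* `de_fit` wraps differential evolution (DE/rand/1/bin; population 15×dim,
  F = 0.8, CR = 0.9, Sobol-sequence init, optional polish). The
  trace-fitting objective is the summed squared error between simulated and
  target voltage traces across categories and both protocols; candidates
  that fail to spike score a 1e9 penalty. Both study modes are supported
  (8 conductances; 8 conductances + V_mNaT via a per-candidate gating
  override).
* `sobol_screen` uses scrambled-Sobol Saltelli sampling with the
  Saltelli-2010 first-order and Jansen total-effect estimators,
  hand-implemented on `scipy.stats.qmc`. Indices are averaged over the 13
  features (zero-variance features excluded); parameters with mean total
  effect above 0.1 are retained. The package's varied set
  {g_NaT, g_CaH, g_KDR, g_KM, g_H} is a configuration constant; with the
  synthetic defaults the screening is a tool, not a reproduced result.

## Synthetic data = the study conditions

* Training sweep: the five varied conductances i.i.d. uniform on
  [0, 2μ_p] (±100% of the defaults), simulate both protocols, extract
  features. Draws whose forward map fails (no spike, or a failed fit) are
  discarded and redrawn, and the count recorded — at the defaults ~35% of
  the box does not spike. The full-scale count (3,000,000 rows) is encoded
  in the `paper_scale` profile; the desk profile uses 6,000 rows.
* Target populations: per-parameter normals N(μ, (μ_p/8)²) *clamped* to
  [0, 2μ_p] (values outside set to the bound, not resampled — realized
  moments are therefore biased slightly inward; with μ ≥ 4σ from the
  bounds the clamping probability is < 1e−4 per draw).
* Two-group scenarios: k of the 5 parameters altered, the altered ones at
  mean 0.5μ_p in one group and 1.5μ_p in the other; C(5,k)·2^(k−1)
  distinct cases counted modulo a global group swap, enumerated in a
  deterministic order (lexicographic subsets, first altered parameter
  fixed "low in group 1").
* Category mimic: a synthetic stand-in for the four experimental mouse
  categories (WT-12m n=26, rTg4510 n=26, WT-24m n=19, PDAPP n=30), with
  per-category per-conductance mean multipliers. It emulates only
  parameter-driven feature variability — no recording noise, no seal-leak
  current, no kinetics variability — so passing mimic-recovery tests shows
  the pipeline recovers parameter structure, not that it handles raw
  experimental artifacts.
* Rosenbrock toy: Y = (1−X₁)² + 100(X₂−X₁²)², X ~ U[−5,5]²; reference
  scale 1,000,000 rows.

## The conditional GAN

Generator G(z‖y) and discriminator D(x‖y) are ReLU MLPs (reference scale:
8 hidden layers of 180 and 130 units; desk scale: 3×64). Features are
z-scored and parameters min-max scaled to [0,1]; an optional
quantile/normal-scores feature transform exists but the z-score is the
default. Implemented losses:

    D: −E[log D(x‖y)] − E[log(1 − D(G(z‖y)‖y))]
    G:  E[log(1 − D(G(z‖y)‖y))] − E[log D(G(z‖y)‖y)]

with probabilities clipped to [1e−7, 1−1e−7]. Each iteration performs one
discriminator Adam step, then unrolls a copy of the discriminator for 5
inner Adam steps (step size 5e−4 at reference scale) and takes the
generator gradient through the unrolled copy (first-order unrolling: the
inner updates are not differentiated through). Reference step sizes are
1e−4 (G) and 2e−5 (D) with β = (0.9, 0.999); a desk run sees ~1000× fewer
optimizer steps, so the desk profile scales the step sizes up to 1e−3/2e−4.
An optional exponential moving average of generator weights is available
for long runs (off by default).

**Reconstruction auxiliary (desk profile).** At desk scale the adversarial
signal alone leaves the generator's conditional mean biased, and the bias
varies with the conditioning region — which is exactly what corrupts
two-group comparisons (a bias that differs between groups mimics a group
difference). The desk profile therefore adds a paired reconstruction term
to the generator update, λ·E‖G(z‖y) − x‖² with λ = 3, the standard
conditional-GAN construction of an adversarial loss plus a paired
regression anchor. The auxiliary pulls the conditional mean toward the
true pairing while the adversarial term shapes the spread; diagnostically,
it cut the group-differential conditional bias from ~16% to a few percent
of the parameter scale. The adversarial losses themselves are unchanged.
λ is 0 (pure adversarial) unless a profile sets it.

**Ensembling (desk profile).** The desk profile trains two independently
seeded generators on the same sweep and pools them at inference (each
sample drawn from a uniformly chosen member). Residual conditional bias is
strongly seed-dependent, so pooling averages it down — the deep-ensemble
argument — and measurably stabilizes the two-group validation across
seeds. At reference scale a single generator is used.

**Stopping.** Adversarial training degrades past an optimum (vanishing
gradients destabilize the generator), so the generator is checkpointed
every few iterations and scored by Jensen–Shannon divergence between its
pushforward joint (generated parameters ‖ conditioning features) and a
held-out slice of the training data; the minimum-JSD checkpoint is the
model. Two JSD readouts are recorded: the per-dimension marginal average
(log base 2, 20 bins, ε = 1e−10, shared ranges padded by one bin width,
out-of-range mass clipped into the edge bins) used as the improvement
diagnostic, and an average over all parameter×feature 2-D pair histograms
(12 bins/dim) used as the selection score, because 2-D pair histograms
respond to the parameter–feature coupling that distinguishes a
conditionally accurate generator from one matching only marginals. The 2-D
score has a small-sample noise floor (two identical distributions at a few
hundred holdout rows score ~0.3), so ratios of improvement are quoted on
the marginal readout.

**Inference.** `sample` normalizes the condition with the stored metadata
(after out-of-training-range feature replacement by the training median —
mean and nearest-value strategies are also provided), draws standard-normal
latents, and de-normalizes the generator output, clipping to the training
bounds. The training prior is itself conditioned on producing a spike
(no-spike draws were discarded), so during validation a latent draw whose
parameters fail the forward map is redrawn (up to 10 times).

## MCMC benchmark

The deliberately simplest baseline: random-walk Metropolis–Hastings on the
varied conductances, uniform prior on [0, 2μ_p], isotropic Gaussian
proposals at 10% of each prior width, Gaussian pseudo-likelihood
−½Σ((F(θ)−y)/h)² with per-feature bandwidths h defaulting to the training
feature SDs, 10,000 steps with 2,000 burn-in, one chain per target feature
vector, thinned to the requested count. No claim of optimality is made for
this sampler; it is the comparison point for amortization.

## Statistical evaluation

Two-sample KS tests at α = 0.01 per test, uncorrected (a Bonferroni switch
exists but is off, matching the study design). Cohen's d is the absolute
mean difference over the (n−1)-weighted pooled SD. Effect-size labels use
Sawilowsky's thresholds (0.01/0.2/0.5/0.8/1.2/2.0, boundary to the higher
category) by default; a `paper_compat` profile (0.42/0.75/0.97 for
medium/large/very large) is provided because the published classifications
are not reproducible from any single standard scale. Scenario agreement
counts matching reject/fail decisions between target-data tests and
generator-sample tests over the 18 quantities (5 parameters + 13
features); cGAN-vs-target rejections per group are tallied separately.

## Scale profiles and problem sizes

| stage | smoke | desk | paper_scale |
|---|---|---|---|
| training rows | 150 | 6,000 | 3,000,000 |
| GAN nets | 2×32 | 3×64 | 8×180 / 8×130 |
| minibatch | 64 | 512 | 10,000 |
| epochs | 10 | 400 | 400 |
| reconstruction λ | 0 | 3 | 0 |
| generators pooled | 1 | 2 | 1 |
| per-group targets | 20 | 100 | 100 |
| samples per cell | 10 | 100 | 100 |

The desk profile is the package's working scale for single-CPU runs; the
`paper_scale` profile encodes the reference constants without being
exercised by the tests. The seeded end-to-end validation (k=1 g_NaT
scenario) runs at desk scale.

## Known limitations

* Single compartment, no morphology, no temperature dependence, no channel
  noise, no experimental seal-leak current.
* The default parameter set is synthetic; quantitative feature values are
  not comparable to any specific laboratory dataset.
* The clamped-normal target generator biases moments near the bounds.
* Desk-scale adversarial training is substantially noisier than the
  reference scale: conditional accuracy, not identifiability, limits
  structure-recovery performance (a gradient-boosted regression of each
  varied conductance on the 13 features reaches R² 0.83–1.0 on the sweep,
  so the features identify the parameters well). The reconstruction
  auxiliary and the two-member ensemble recover most, not all, of that
  gap: the least-identified conductance (g_KM) can still show a marginal
  spurious group difference near the test threshold.
* KS agreement results at desk scale are reported for seeded runs; other
  seeds can differ by a few tests in either direction.
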