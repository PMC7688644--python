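# Methods

## The laminar mass model

Four populations occupy two cortical depths: superficial pyramidal cells (SP)
and interneurons (SI), deep pyramidal cells (DP) and interneurons (DI), with
indices 1=SI, 2=DI, 3=DP, 4=SP so a connection `a_ij` reads "drive to *i*
from *j*". The ten directed connections are fixed by the circuit: the two
within-pair E→I and I→E loops (`a14, a41`; `a23, a32`), the descending
projections SP→DP (`a34`) and SI→DP (`a31`), and four recurrent
self-connections (`a44, a11, a33, a22`). Interneuron sources and all
self-connections are inhibitory — recurrent inhibition precludes runaway
excitation — the remaining pyramidal projections are excitatory. The
canonical (prior-mean) strengths are, in a.u.:
`a44=4.4, a14=4.8, a34=3.3, a41=3.8, a31=5.9, a11=4.2, a33=2.2, a23=4.6,
a32=6.9, a22=4.16`.

Each population's mean depolarization obeys a critically damped second-order
synaptic response,

    dv_i/dt = w_i
    dw_i/dt = κ_i² (h_i m_i − v_i) − 2 κ_i w_i
    m_i     = Σ_j s_ij a_ij f(v_j) + c_i u(t)

with `f` a centred sigmoid (`f(v) = σ(r(v−v0)) − σ(−r v0)`, so `f(0)=0`):
the origin is then an exact fixed point at zero drive and the canonical
linearization point. `s_ij ∈ {+1,−1}` carries the edge sign; magnitudes
`a_ij` are constrained non-negative.

**Kernel defaults.** `κ = (150, 125, 125, 150) s⁻¹` (SI, DI, DP, SP),
`h = (1.6, 0.8, 0.8, 1.6) mV`, sigmoid slope `r = 2 mV⁻¹`, threshold 0.
These were fixed by linear analysis of the two E–I pairs: with loop gain
`g = h·r/4`, the superficial pair resonates near `0.92·κ_s·√(6.1 g_s)/2π ≈
49 Hz` (low gamma) and the deep pair near 28 Hz (high beta). Two
considerations set the deep rate: the model should reproduce the qualitative
laminar separation (fast superficial gamma, slower deep beta), and the deep
resonance's upper flank must lie inside the 30–80 Hz fitting band, otherwise
deep connections are not identifiable from gamma-band spectra at all (with
the deep pole at 22 Hz the recurrent deep-interneuron connection `a22` was
numerically indistinguishable from observation-gain changes). All values are
config keys, logged with every run.

**Integration.** `simulate` uses a fixed-step explicit Heun scheme with
zero-order-hold drive. A first-order scheme is inadequate here: its
effective damping error `|λ|²·dt/2` is comparable to the true decay rate of
the lightly damped gamma mode at any practical step, inflating simulated
band power by tens of percent; the second-order scheme keeps the bias below
1%. A guard rejects `dt·κ_max > 0.5`, and trajectories exceeding a state
bound raise an error naming the step size.

## Spectral forward model

At a stable fixed point the dynamics are linear with Jacobian `J` (8×8,
analytic); input fluctuations with one-sided density `g_u(f) = α_u + β_u/f`
reach every population through input weights `c` (the exogenous noise
propagates to all layers). The transfer function is
`T(f) = C (2πif·I − J)⁻¹ B` with `B = κ²·h·c` and `C` selecting the
depolarizations. A single virtual-sensor channel observes the Q-weighted
mixture through a scalar lead field:

    g(f) = | L · Q·T(f) |² g_u(f) + α_n + β_n/f.

Default `Q = (0, 0, 0.6, 1.0)`: interneurons generate no appreciable dipole,
deep pyramidal currents contribute less than superficial ones. A
wavenumber-resolved lead field would only matter for spatially extended
(field) models, which are out of scope; the point-source mass model needs
only the scalar gain `L` (fixed at 1 and absorbed by `α_u` during fitting).
The layer-resolved variant returns the 2×2 complex cross-spectra of the SP
and DP depolarizations for construct validity. All densities are one-sided,
per Hz (a unit-variance white series sampled at `fs` has density `2/fs`);
the Welch estimator (`scipy.signal.csd`, density scaling, `f=0` dropped)
provides the independent empirical counterpart, and the package's core
forward property — verified in the test suite and acceptance script — is
that the analytic and simulated spectra agree to r > 0.95 with
band-integrated power within 10% on 1–100 Hz.

**Input scale.** `α_u = 4·10⁻⁴, β_u = 2·10⁻⁴` keep the stationary
depolarization SD near 0.1 mV, inside the sigmoid's linear range — the
regime in which a linearized spectral prediction is the right description of
the nonlinear simulation (at 10× this drive the sigmoid compresses the
resonances and the two routes diverge). Channel noise defaults to ~1% of
mean signal power.

## Inversion (variational Laplace)

Latents: log-scaling coefficients on the ten connections and the four noise
densities (positivity is structural), additive offsets on `Q`, and, for
multi-condition fits, per-condition log-offsets on connections (B effects)
shared-latent style — all conditions of a subject are fitted simultaneously.
Priors are zero-mean Gaussians: variance 1/16 on connection and B latents
(a standard weakly-informative log-scaling prior) and 1/64 on observation
latents (`Q`, noise) so that observation gains cannot absorb connectivity
changes. Single-channel data are fitted as power; two-channel layer data
include the real and imaginary cross-spectra.

The free energy is the Gaussian accuracy term (observation precision `e^λ`
per spectral element, with the expected-curvature correction
`tr(Π J Σ Jᵀ)`) minus the KL divergence of the posterior from the prior,
plus a Gaussian hyperprior on λ (variance 16) centred at a data-scale-derived
value. E-steps are Gauss–Newton updates with Marquardt regularization
(trust parameter halved on acceptance, doubled on rejection; only
free-energy-increasing steps are accepted), the M-step is a safeguarded
scalar Newton update of λ; convergence requires ΔF < 10⁻² nats on three
consecutive accepted steps (max 128 iterations; an expected-improvement test
short-circuits exact fits). Prediction Jacobians use central finite
differences (step 10⁻⁴) evaluated in a single vectorized batch through the
resolvent; one subject fit takes ~0.1 s. The fit is deterministic: the same
data give bit-identical posteriors.

Unstable parameter proposals (Jacobian eigenvalues with non-negative real
part) have no stationary spectrum; they yield −∞ free energy and are
rejected, with one-sided differences substituted where a finite-difference
neighbour is unstable.

"Connection change" means posterior-minus-prior latent mean, in log-scaling
units.

## Construct validity

The microscale surrogate (below) is fitted in its layer-resolved form
(`include_q=False`; complex cross-spectra) and the posterior becomes the
empirical prior for subject fits, with covariance inflated by 4 so subjects
can deviate from the group starting point. Self-consistency holds exactly:
a zero-mismatch (analytic) surrogate refits to latents ≈ 0 with ≥ 99%
variance explained. An optional per-frequency weight vector lets low
frequencies be down-weighted when the surrogate's low-frequency content is
not trusted.

## Group level

PEB uses the summary-statistic hierarchy: each subject's posterior mean over
the ten connection latents is a Gaussian observation of its latent effects
with covariance `Σ_i + e^{−γ} I` — the subject's full posterior covariance
(so uncertain subjects are down-weighted, which is what makes the scheme
robust to outliers) plus an isotropic between-subject term whose log
precision γ is optimized against the exact conjugate evidence. The marginal
posterior over the connection block is used; correlations with observation
latents are thereby averaged over, a standard simplification. With a single
subject and a flat second-level prior the GLM mean reduces exactly to that
subject's posterior mean.

Bayesian model reduction is the closed-form Gaussian identity
`ΔF = log ∫ q(θ) p_reduced(θ)/p_full(θ) dθ`; it matches explicit refitting
to ~10⁻¹³ nats on linear-Gaussian problems. The GLM search scores all 1024
connection subsets by shrinking the prior variance of excluded covariate
betas to 10⁻⁸ (soft exclusion keeps dimensions fixed so the analytic
reduction applies); per-connection inclusion probabilities are Bayesian
model averages over the full model space, and a Bayes factor of 20 vs null
corresponds to posterior probability 20/21 ≈ 0.95. Raw probabilities are
reported; 0.5 and 0.95 are conventional "weak" and "very strong" landmarks,
not hard-coded decisions.

Classical statistics: Spearman's rho with exact two-sided permutation p for
n ≤ 9 (cohort sizes of 12–16 use the asymptotic t approximation; the
boundary is configurable), partial correlations as residual correlations
after OLS on the controls with t-test on n−2−k degrees of freedom, and
Bonferroni adjustment `min(1, m·p)` with m defaulting to the number of
connections tested.

## Synthetic data

**Microscale surrogate.** The mass model is simulated for 80 s driven by
burst-like input — 10 groups per second of 2 spikes 10 ms apart, 100 ms
between group onsets, smoothed by a 2 ms Gaussian kernel — plus white+pink
noise, and Welch-estimated into SP/DP cross-spectra on 1–100 Hz. The 10 Hz
group rate leaves an alpha-band line on both layers on top of the deep-beta
and superficial-gamma resonances. Kernel constants are perturbed
log-normally (SD 0.1) so the generating model is *not* the model later
fitted: construct validity is a genuine model-mismatch fit, as when a mass
model is fitted to a detailed compartmental simulation. An `analytic` mode
returns the forward model's own spectrum for self-consistency checks.

**Groups.** A V1-size-like covariate is drawn log-normally
(`exp(N(7.6, 0.3²))` mm², i.e. ~2000 mm² median); each subject's connection
latents are `z_i β + N(0, 0.1²)` with `z` the standardized covariate and β a
configurable latent slope per connection (default planted effect:
covariate → `a22`, slope 0.4). Spectra come from the analytic forward model
on 30–80 Hz; observation noise is Gaussian per frequency with SD 5% of the
subject's mean band power (precision recorded as λ in the ground truth).
The noise default was chosen so that recovery is challenged but achievable:
planted ±0.3 perturbations are recovered with median absolute error ≈ 0.06
and 90%-interval coverage ≈ 90% at the perturbed connections. Optional
three-condition datasets add shared condition offsets (SD 0.05) to emulate
stimulus-size effects fitted as B parameters. Everything regenerates
bit-identically from (seed, config), and the ground truth ships with the
data.

**What the generators do not emulate.** No sensor arrays, head movement,
beamforming or source-localization error; no spike-level or dendritic
dynamics in the surrogate (it is the mass model itself under mismatch, not a
compartmental simulation); observation noise is white across frequencies
whereas real Welch estimates have χ²-distributed, power-proportional errors.
Passing recovery and detection tests therefore demonstrates internal
consistency of the estimation machinery under the model's own assumptions —
not robustness to the full physics of MEG.

## Numerical choices and edge cases

- Frequency grids: 1–100 Hz (1 Hz step) for construct validity, 30–80 Hz for
  subject fits; `f = 0` is rejected everywhere (the pink term diverges).
- Cross-spectrum containers enforce Hermitian symmetry and non-negative
  diagonals; the CSV reader completes a missing conjugate pair by symmetry
  with a logged notice and rejects genuinely non-Hermitian data.
- Variance explained is `1 − SS_res/SS_tot` over pooled real spectral values
  and can be negative; zero-variance data are rejected.
- Fixed points are found by root search on the four-dimensional balance
  equation (the zero-drive fixed point is the origin by construction);
  non-convergence raises with the residual.
- Problem sizes in the test suite and acceptance script (200 s oracle
  simulation, 20 recovery subjects, 16-subject cohorts, 20 null replicates)
  were chosen to give stable statistics at roughly minute-scale runtimes on
  one CPU.

## Known limitations

- Conduction delays default to zero and are not estimated; the `delays`
  field is carried for forward compatibility.
- The λ hyperparameter is a single scalar per fit (no per-channel or
  per-frequency precision components).
- The exhaustive GLM search treats one covariate at a time; multi-covariate
  designs are supported by PEB but searched per covariate.
- Identifiability of deep-layer parameters from 30–80 Hz power alone is
  partial; posteriors for weakly informed directions remain close to the
  prior, which is why group-level conclusions use the full posterior
  covariance rather than point estimates.
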