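# Methods

This note documents the models behind each estimator, the defaults and why
they were chosen, what the synthetic generators do and do not emulate, and
the numerical decisions a maintainer would want written down.

## Phase behavior (`coacerlab.phase`)

**Model.** A sample is "turbid" (two-phase) where OD600 is at least a
fraction *f* of the curve's maximum. Phase windows are the maximal turbid
intervals of the control variable (salt concentration or temperature), with
edges linearly interpolated between grid points; a salt sweep with two or
more disjoint windows is flagged *reentrant*. Cloud points are the threshold
crossings of heating and cooling temperature ramps, reported with their
direction relative to increasing temperature; hysteresis is the
heating-minus-cooling temperature of each matched pair.

**Parameters.** Default `threshold_fraction = 0.1`: turbidity assays do not
come with an absolute "turbid" cutoff, and 10% of the per-curve maximum sits
above typical baseline drift while catching shallow reentrant windows. It is
exposed everywhere. Relative (per-curve) normalization is the default
because raw OD depends on path length and scattering contrast; a global
normalization mode is the caller's choice by rescaling inputs. Replicates
are averaged on a shared grid before detection; per-replicate detection is a
one-line loop.

**Caveats.** The window count is guaranteed non-increasing in the threshold
only for curves whose bumps are unimodal at a shared amplitude (as the
generator produces); measurement noise near the threshold can split a
window, which is a property of thresholding, not of the implementation.

**Composition.** Calibration is ordinary least squares of blank-corrected
peak area on standard concentration (free intercept by default — forcing a
zero intercept is available but discards any residual baseline); inversion
clips negative concentrations to zero with a warning. The dense phase is
closed by the two-phase mass balance c_dense = (c_total·V_total −
c_dilute·V_dilute)/V_dense, the standard route when the dense phase is too
small or too viscous to assay directly.

## Microrheology (`coacerlab.rheology`)

**Model.** Thermal motion of embedded probes: the per-track MSD is
time-averaged over all overlapping origins, then tracks are combined with
equal weight (a pair-count-weighted mode would overweight long tracks; the
unweighted ensemble average is the common default in particle-tracking
practice). The averaged MSD is fit to MSD(τ) = 4Dτ^α on log–log axes; η
follows from Stokes–Einstein, D = k_B T/(6πηr), with k_B = 1.380649×10⁻²³
J/K, default r = 1 μm and T = 295.15 K.

**Fit range.** Lags from 1 frame to 25% of the track length. The variance of
a time-averaged MSD grows roughly linearly in lag/track-length, so long lags
are statistically unreliable; 25% keeps the fit in the well-averaged regime
while spanning over a decade of lag.

**α gating.** η is computed from the power-law D even when α ≠ 1, but any α
outside [0.9, 1.1] triggers a "non-diffusive" warning, because
Stokes–Einstein presumes simple diffusion. Static localization noise is not
subtracted by default (it adds 4·noise² to every MSD point); the generator
can inject it so its effect on recovered η can be measured directly.

## Coalescence tension (`coacerlab.rheology`)

The aspect-ratio deviation A = (L − W)/(L + W) of a freshly merged droplet
decays as A₀e^(−t/τ) in the viscous (inertialess) regime, with τ ≅
(19/20)ηR/σ. τ is fit by nonlinear least squares initialized from the
log-linear solution; fits with τ ≤ 0 or τ > 100× the observation span are
rejected as "no observable decay". σ then follows algebraically from the
microrheology viscosity and the merged-droplet radius.

## PFG-NMR (`coacerlab.nmr`)

Echo attenuation ψ = exp(−(γgδ)²D(Δ − δ/3)). Gradients are input in G/cm
and converted to G/m internally (×100) so the exponent is dimensionless
with D in m²/s; γ defaults to the proton value 2.6752×10⁴ s⁻¹G⁻¹ and is
overridable. The fit works in the gradient factor b = (γgδ)²(Δ − δ/3): a
zero-intercept log-linear solution initializes a nonlinear refinement with
uniform weights in ψ (log-space weighting, which overweights the noisiest
deep-attenuation points, is available by flag). Non-monotone attenuation
beyond a 10% tolerance warns; negative fitted D raises.

## INDUS counting and UWHAM (`coacerlab.indus`)

**Observable.** The hydration volume of a residue is the union of spheres
of radius R_v (default 0.55 nm — first hydration shell) centered on its
heavy atoms. The sharp water count is discontinuous in the coordinates, so
the biasable observable is the coarse count N_v: each water's distance r to
a sphere center passes through the CDF of a truncated, normalized Gaussian
kernel (width σ = 0.01 nm, truncation r_c = 0.02 nm, plateau-subtracted so
the kernel is continuous at ±r_c), giving exactly 1 deeper than r_c inside
the surface and exactly 0 beyond r_c outside. Contributions from
overlapping spheres combine by the complement product h̃ = 1 − Π(1 − h̃_j),
which reduces correctly in the single-sphere and coincident-sphere limits
and keeps 0 ≤ N_v ≤ n_waters. The union rule is this package's choice; any
smooth union rule with those limits would serve.

**Sampling.** Model landscapes are sampled *exactly*: for each bias center
N*, the biased distribution P(N) ∝ exp(−βF(N) − ½βκ(N − N*)²) over the
tabulated integer range is normalized and sampled i.i.d. This removes
Markov-chain equilibration as a confounder when testing the unbiasing
estimator; the equilibration-discard field exists for real (correlated)
window data and defaults to 20% there. Negative N* are legal and push the
count toward zero without clamping.

**Unbiasing.** The binless estimator solves the standard self-consistent
equations for the per-window free energies f_k (f₁ ≡ 0),
f_k = −ln Σ_n exp(−u_k(x_n)) / Σ_l N_l exp(f_l − u_l(x_n)),
which are the stationarity conditions of a convex likelihood. Numerically:
damped fixed-point warm-up, then Newton iteration on the f₁-pinned reduced
system with a backtracking line search; convergence is declared when a
full self-consistent update moves every f_k by < 10⁻⁸ kBT (cap 10⁵
iterations). Pure fixed-point iteration was measured to contract at a rate
indistinguishable from 1 when adjacent windows share few samples, stalling
around 10⁻⁷; Newton reaches 10⁻⁹ in tens of iterations. Unbiased weights
are assembled into P_v(N) on the integer grid **in log space** — the
weights span hundreds of kBT and naive exponentiation underflows —
with continuous samples binned to the nearest integer (half-integer ties
round toward the window's N*). βF = −ln P_v, shifted to min 0.

**Connectivity.** Adjacent windows (ordered by N*) whose sample supports
are separated by more than `max_gap` (default 5) occupancies raise a
disconnected-support error; narrow unsampled stretches are tolerated
because the estimator bridges them through the analytically known harmonic
biases, and windows that merely share few samples warn rather than fail.

**A caution on stiff springs.** With βκ = 10 each biased window has a
standard deviation of 1/√10 ≈ 0.32 in N. A ladder of such windows spaced 3
apart is *statistically* disconnected: the probability of a sample reaching
halfway to the next window is ~e⁻¹¹ per draw, so the relative offsets of
the per-window "islands" are set by essentially unsampled tails, and the
reconstructed profile carries multi-kBT systematic errors that do **not**
shrink with more samples (verified at 20× the default sample count). The
validation suite therefore exercises the estimator on ladders whose spacing
is commensurate with the biased width (e.g. κ = 0.5 kBT with unit spacing),
where the double-well landscape is recovered to better than 0.1 kBT and two
independent solvers (binless vs binned, width-1 bins) agree to ~10⁻⁶ kBT.
Stiff-spring/wide-spacing ladders remain accepted input — the solver
converges and warns — but their output should be treated as qualitative.

**Per-water cost.** From the unbiased profile, N₀ is the equilibrium
occupancy (minimum of βF; a recorded N₀ is preferred when degenerate with
the minimum). For N < N₀ the per-water dewetting cost is
(βF(N) − βF(N₀))/(N₀ − N), plotted against N/N₀. This even spreading of the
total work over the removed waters is this package's documented convention;
the comparator classifies the profile with the lower mean per-water cost as
the more hydrophobic surface. Atomistic dewetting free energies of real
residues require explicit-solvent MD and are out of scope; the module
reproduces the estimator, validated on model landscapes and toy frames.

## Chain observables (`coacerlab.chain`)

R_g is the mass-weighted RMS distance from the center of mass; d_ee the
distance between designated terminal sites (default first/last site,
minimum-image when a box is given). Distributions use Freedman–Diaconis
bins (overridable); differences of ensemble means carry a bootstrap CI
(2000 resamples, seeded). Contact maps count, per site pair, the fraction
of frames within 0.6 nm, zeroing pairs closer in sequence than 3 — both
defaults configurable, chosen as the common heavy-atom contact criterion.
Hydrogen bonds use the standard geometric criterion: donor–acceptor
distance ≤ 0.35 nm and D–H–A angle within 30° of linear.

## Synthetic data (`coacerlab.synth`)

Every generator is deterministic given (parameters, seed) — one seeded
NumPy `default_rng` stream per call, with the ground truth attached to the
output and serialized as a JSON sidecar by the writers. What they emulate,
and deliberately do not:

- **Brownian tracks** are free 2-D Gaussian walks (variance 2DΔt per axis
  per step) with optional Gaussian localization noise. No confinement, no
  viscoelastic memory, no tracking dropouts — so recovery tests certify the
  estimator, not robustness to imaging artifacts. Defaults (50 tracks ×
  2000 frames, 20 ms or 1 s frame intervals, r = 1 μm, T = 295.15 K) mirror
  standard condensate video-microrheology sessions.
- **Echo decays** are single-exponential in b with multiplicative Gaussian
  noise; 16 echoes by default. No multi-component diffusion, no restricted
  diffusion, no rephasing artifacts.
- **Coalescence series** are clean exponentials with additive aspect-ratio
  noise; real events also show early inertial transients that the
  (19/20)ηR/σ law does not cover.
- **Turbidity profiles** are sums of sigmoid-edged bumps; a heating ramp
  shifts edges by +h/2 and a cooling ramp by −h/2 to emulate ramp-rate
  hysteresis. Real curves also drift in baseline and amplitude between
  replicates.
- **Umbrella windows** are exact i.i.d. draws (above). **Solvated frames**
  are uniform Poisson point clouds around fixed solute atoms — no water
  structure or excluded volume, which is precisely what makes the
  density × volume mean-count check exact. **Chain ensembles** are freely
  jointed (exact bond lengths, uniform directions) or hard-core
  self-avoiding walks grown with bounded retries.

Passing tests on these generators certify the estimators' correctness under
their stated models; they do not certify behavior under real-data
pathologies (drift, heteroscedastic noise, correlated samples).

## Problem sizes

Default validation sizes — 50 × 2000-frame track sets, 16-echo decays,
5000-sample umbrella windows, 2000-frame chain ensembles, 100-frame Poisson
solvation sweeps — were chosen so each statistical check has comfortable
power (3-standard-error bands) while the whole suite and the acceptance
script each run in well under a few minutes on a laptop-class single core.
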