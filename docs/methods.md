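# Methods

## Noise model and its evaluation

The camera model has five parameters per pixel: expected photoelectrons per
frame `E`, electron-multiplying gain `g` (≥ 1; g = 1 means the register is
off), ADU conversion factor `φ` (photoelectrons per count), readout offset
`S0` and readout width `σ` (both in counts). The output pmf is the
convolution of the amplified-signal density with a discretized normal
readout kernel, evaluated entirely on the integer count grid of the
digitizer — working in counts keeps the discrete FFT free of resampling
artifacts.

**Poisson-gamma part (g > 1).** The continuous part is evaluated in log
space through the exponentially scaled modified Bessel function I₁ (the
unscaled function overflows beyond arguments of ~700, routinely exceeded at
high gain). The zero-electron atom (weight e⁻ᴱ) is never placed on the
grid; it convolves analytically to e⁻ᴱ·N(S|S0, σ) and is added after the
FFT step. The density value at signal 0 receives half weight because the
support covers only half of that unit bin. The total (atom + continuous)
mass is renormalized to 1 before convolution and the pre-normalization
deficit is kept as a diagnostic on the returned pmf.

**Poisson part (g = 1).** The Poisson density is carried into count units
as `φ·E^(Sφ)e⁻ᴱ/Γ(Sφ+1)`, evaluated at integer counts and renormalized.
This form is smooth in φ, which the series MLE requires — an alternative
discretization that accumulates electron-number mass at the nearest integer
count makes the likelihood a step function of φ (zero gradient almost
everywhere) and is unusable for gradient-based optimization. A consequence
of working on the integer grid: when the Poisson signal is narrower than
about one count (E ≲ φ², reachable only at very low illumination with the
gain off), the discretized moments deviate from the continuous closed forms
at the permille level; the pmf remains properly normalized and the
likelihood well behaved. Above that regime, numeric moments match the
closed forms to better than 1e-4 relative (tested).

**Convolution and grids.** The default output grid is
`[floor(S0 − 8σ), ceil(mean + 12·std)]` from the closed-form moments;
convolution uses scipy's zero-padded linear FFT convolution, so circular
wraparound is structurally absent. If the requested grid would truncate
more than 1e-6 of the mass, the automatic grid widens once and retries; a
user-supplied grid raises instead. Grids larger than 2²² counts are
refused (`GridSizeError`) — no 16-bit acquisition can support such
parameters — and the series objective maps that refusal to a floor
likelihood, which keeps optimizer line searches finite and cheap at
parameter-box corners. Samples outside an evaluated grid contribute
log(1e-300) and a warning.

**Verification.** A brute-force oracle evaluates the Poisson-gamma series
term by term with scipy's gamma density (no Bessel function) and convolves
by direct summation (no FFT); the two paths agree pointwise to better than
1e-10 across g ∈ {1, 5, 25, 300} × E ∈ {0.5, 10, 200}. Since a pmf is
defined on (renormalized over) its evaluation support, the oracle takes the
grid of the pmf it checks; everything else about it is independent.

## Simulator

The forward process mirrors the likelihood exactly: Poisson draws,
continuous gamma amplification, division by φ, additive normal readout
noise, rounding to the nearest integer (the only discretization, as in a
real ADC) and clipping to [0, 65535] with a clip counter. A master seed
spawns one substream per stack and one per pixel within region stacks, so
any pixel regenerates identically in isolation.

Presets encode the study conditions: σ = 10 counts, S0 = 100 counts,
φ = 3.5 e⁻/count, 5000 frames per stack; four log-spaced intensity levels
at 25× for the intensity-series picture, six log-spaced levels spanning
5–500 pe at gain off for ADU calibration (the acquisition description
states six logarithmically spaced levels without printing them; one-to-two
decades reproduces the stated design intent), and gain set-points
1/5/25/100/300 at a common 10 pe for the gain series. Simulated bead
movies hold the photon flux constant across set-points; default fluxes of
~3000 photons/frame follow from the stated aiming rule (peak mean near 2¹⁵
counts at the highest set-point) and keep 1× spots fittable above the
readout noise. The simulator omits spatial noise correlations,
row-position offset artifacts and illumination drift.

A Bernoulli-cascade mode simulates impact ionization stage by stage
(effective gain (1+p)ᴺ). Its empirical excess noise factor approaches 2 at
high gain, matching the gamma model, and falls visibly below 2 at 5×
effective gain — the regime where the gamma approximation is known to be
poorest.

## Mean–variance calibration

Per pixel, dark stacks give S0 and σ (sample mean, n−1 SD). Total variance
is regressed on the dark-subtracted mean with ordinary least squares
(unweighted, as in the standard photon-transfer procedure); with the mean
measured above offset the free intercept estimates the readout variance
directly and is reported against the dark-derived σ² as a consistency
diagnostic (an option forces the intercept to σ²). Slopes convert as
φ = 1/slope (gain off) and g = slope·φ/2 (gain on); standard errors
propagate by the delta method. Log-spaced levels avoid the leverage
concentration at high intensities that linear spacing produces.

## Series MLE

Four parameter-sharing schemes: IS-ADU (shared φ, per-level E, g = 1),
IS-gain (shared g, per-level E; φ supplied from a prior ADU calibration —
with every dataset amplified the density depends on g and φ only through
g/φ, so φ is not separately identifiable there), GS-gain (shared E and φ,
per-set-point g; a 1× dataset enters with the Poisson-normal model and
makes φ jointly identifiable, otherwise φ must be supplied), and the
non-centered hierarchical GS (below). S0 and σ are always fixed from dark
stacks, per gain set-point.

Optimization is bounded L-BFGS-B over log-parameters (bounds: E ∈ [1e-3,
1e4] pe, g ∈ [1, 3000], φ ∈ [0.1, 100]) with ftol 1e-13 — the φ–E ridge is
strongly correlated and a looser stop stalls partway along it. Multi-start
initialization: the moment (PTC) estimates for IS-ADU plus ±25% log
perturbations; for schemes where the moment estimate of φ is dominated by
variance sampling noise (gain series at modest E), a log-spaced grid of
trial φ values seeds the starts instead. Starts disagreeing by more than
1e-4 in log-likelihood flag the pixel multimodal. Within one objective
evaluation, datasets with identical parameter sets reuse one pmf; sample
log-likelihoods use a bincount tabulation over each dataset's observed
count range. Standard errors come from the finite-difference observed
information at the optimum (delta method back to natural scale). Note
these SEs condition on the dark-derived S0/σ; the dark estimates' own
sampling error widens the realized spread of φ̂ in gain-series fits to
roughly 0.2 at the documented design (5000 frames), about 1.5× the
conditional SE.

**Hierarchical gain series (NCH).** Per-set-point intensities are
parameterized non-centrally, E⁽ⁱ⁾ = Ē + σ_Ē·z_i with standard-normal z_i,
and the MAP objective adds Σ log N(z_i|0,1). A flat hyper-prior on log σ_Ē
makes this objective improper — σ_Ē → ∞ with z → 0 raises it
monotonically while freeing every E⁽ⁱ⁾ — so a weakly-informative
half-normal prior with scale 0.05·Ē is placed on σ_Ē, matching the
few-percent illumination-drift magnitude the scheme exists to absorb;
σ_Ē is additionally floored at 1e-6·Ē against the degenerate funnel.
Fixing σ_Ē = 0 reproduces the GS-gain estimates to optimizer tolerance
(tested).

## MCMC

Affine-invariant ensemble sampling (emcee) over the same log-parameter
space with flat priors inside the optimization bounds, initialized in a
1e-3 ball around the MLE; the first 25% of steps are discarded. Affine
invariance matters because φ and the E⁽ⁱ⁾ are strongly *positively*
correlated along the likelihood ridge (each dataset mean pins E/φ).
Summaries report per-parameter means, SDs, credible intervals, split-R̂
over walker halves (warning above 1.05), and the φ–E correlations
explicitly. Chains of ~1500 steps × 16 walkers are needed for R̂ < 1.1 on
the six-level ADU design; posterior SDs then agree with the observed
information.

## PSF validation

Spots are fit per frame by maximizing the PGN log-likelihood over
(x, y, σ_psf, flux, background), where the expected photon count of pixel
(i, j) — covering the half-open unit square [i, i+1)×[j, j+1) — is the
exact integral of the 2-D Gaussian over the pixel (normal-CDF differences),
not a point sample. Because each pixel carries its own E, exact per-pixel
pmf evaluation inside the optimizer is prohibitive; instead log p(S|E) is
tabulated on a √E-spaced grid of 160 intensities (the log-likelihood
curvature of a Poisson-type model is nearly constant in √E) and
interpolated linearly, with analytic gradients through the PSF model. The
tabulated objective agrees with the exact PGN sum to ~5e-3 nats per pixel
and flux recovery is unbiased within Monte-Carlo error at every set-point
(tested). The exact objective remains available and is itself a direct sum
of noise-model log-likelihoods (tested).

Initialization uses the ROI border median for background and the
photon-converted centroid for position/flux. The optional second pass
accumulates data-minus-model residuals, 3× oversampled in the spot frame,
normalizes per unit flux, and refits with the template added to the PSF and
scaled proportionally to flux: for truly Gaussian spots it reproduces the
first pass within Monte-Carlo error, for a distorted (two-component) PSF it
reduces the flux bias (both tested).

The consistency metric σ_means is the (n−1) standard deviation of the
per-set-point mean fluxes, reported both with and without the 1× set-point,
plus means scaled to the 1× mean. Candidate calibrations are ranked by
σ_means; on simulated gain-series bead data the true parameter set ranks
first against three independently perturbed sets (per-gain factors of
0.8–1.25, at least ~10% from unity so the perturbations are systematic
rather than cosmetic) in ≥ 19 of 20 seeds (tested with 2 beads × 10 frames
× 3 set-points — far below the 500-frame experimental design, chosen so the
20-seed study runs in minutes; the discrimination margin is a factor of
~15 in σ_means, so the scale-down does not affect the conclusion).

## Problem sizes and numerical choices

Tests and the acceptance script use the documented 5000-frame designs for
the headline single-pixel recoveries and reduced sizes elsewhere (1000–1500
frames, 2×2 regions, 2 beads × 10 frames) where the property under test is
scale-free. Tolerances: pmf truncation 1e-6, oracle agreement 1e-10,
moment identities 1e-4 relative, optimizer ftol 1e-13, NCH/GS agreement
1e-3 relative. Degenerate inputs are handled explicitly: dark stacks with
zero variance are flagged invalid, a single-set-point consistency report is
flagged degenerate with σ_means = 0, constant-mean PTC designs raise.

## Known limitations

- Fixing S0/σ from darks (as the method prescribes) understates the
  reported SEs slightly, since the dark estimates carry their own noise.
- The ADU factor is weakly identified when the Poisson excess variance is
  small against the readout variance (E/φ² ≪ σ²); at the six-level
  5–500 pe design the top level contributes an excess variance of only
  41 counts² against a readout variance of 100 counts², so single-pixel
  φ̂ scatters by roughly its MCMC SE seed to seed, with a right-skewed
  ridge toward high φ. Brighter top levels or pixel averaging shrink this.
- The hierarchical scheme's drift prior scale (5% of Ē) is an assumption;
  data with larger true drift would need it widened.
- Real-sensor artifacts (row-dependent offsets, saturation, spatial
  correlations, clock-induced charge as a separate term) are outside the
  model; the simulator accordingly does not emulate them, so passing tests
  demonstrate correctness of the estimators under the stated model, not
  robustness to those artifacts.
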