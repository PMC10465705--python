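# Methods

## The physical picture

A double-strand break (DSB) leaves the two halves of a DNA filament
connected only through the residual contact interface: the nucleotides
between and immediately flanking the two backbone nicks, held by
Watson–Crick hydrogen bonds and π-stacking.  Rupture of this interface
is modelled as a two-state, thermally activated process: the molecule
dwells in a bound (metastable) state until a rare fluctuation carries it
over a free-energy barrier into the broken state, after which the
moieties drift apart irreversibly.  Under this picture

* waiting times are exponentially distributed, so the per-scenario
  coefficient of variation of rupture times is ≈ 1 and the sample mean
  carries a relative standard error of 1/√n;
* the mean rupture time obeys an Arrhenius law in the DSB distance b_d
  (intact base pairs between the nicks), ln τ̄ = ln τ̄0 + (βΔΔG‡)·b_d,
  because each intact base pair adds a fixed increment ΔΔG‡ to the
  activation barrier;
* the internal-energy contribution to rupture is linear,
  ΔU/k_BT = α·b_d + ς, with ς the blunt-break (stacking-dominated)
  offset.

The filament is held at a constant end-to-end distance R_ee by a force
given by the Marko–Siggia worm-like-chain interpolation with
persistence length ξ = 50 nm and contour length L = n_bp × 0.34 nm
(3855 bp → 1310.7 nm).  The formula is entropic and valid in the
low-force regime (≲ 5 pN) spanned by the three default scenarios
(R_ee = 1000, 1100, 1200 nm → 0.42, 0.88, 3.06 pN).

## Units

Coarse-grained trajectories tick in reduced Lennard-Jones time units.
The default `UnitSystem` uses τ = 1.7075 ps, the value implied by the
simulation convention of a 100 amu mass unit, 0.8518 nm length unit and
4.142×10⁻²⁰ J energy unit (τ = √(mσ²/ε); the direct evaluation agrees
with the stored constant to ~0.1%).  This single constant links the
simulation diffusion coefficient D_CG (μm²/τ) to D_EXP (μm²/s) in the
time-scaling factor Γ = (D_CG/τ)/D_EXP; with the reference values
2.2×10⁻¹¹ μm²/τ and 1.17 μm²/s it gives Γ ≈ 11.0.  k_B is the CODATA
value; k_BT at 310 K is 0.616 kcal/mol (4.28 pN·nm).

## Synthetic trajectories: what they emulate

The generator replaces the MD simulations as the pipeline's input
source and *defines the study conditions*; its defaults are the fitted
values of the reference scenario at the lowest force:

| parameter | default | meaning |
|---|---|---|
| `tau0_true` | 1.0 ns | blunt-break mean rupture time |
| `k1_true` | 1.7 | activation increment per bp (βΔΔG‡) |
| `alpha_true`, `sigmac_true` | 7.1, 7.8 kT | energy law ΔU = α·b_d + ς |
| `noise_sigma` | 2.0 kT | plateau noise s.d. |
| `noise_corr_time` | 0.5 ns | AR(1) correlation time |
| `m_true` | 5 decades/ns | transition steepness |
| `d_bound`, `d_noise_sigma` | 1.0, 0.15 nm | bound-state interface distance |
| `drift_rate` | 2 nm/ns | post-rupture separation speed |
| `dt` | 0.1759 ns (103 τ) | base frame interval |
| `duration_factor` | 10 | trace length in units of the scenario mean |

Per replica, one exponential rupture time is drawn with the Arrhenius
mean and shared between a paired energy trace and distance trace, so
the two detection criteria can be cross-validated against the same
ground truth.  The energy trace is the base-10 logistic between the
bound plateau E_min and broken plateau E_max = E_min + 2(α·b_d + ς)
— so the value at the flex minus the lower plateau is exactly the
energy law — plus stationary AR(1) (discretised Ornstein–Uhlenbeck)
noise; thermal fluctuations in such traces are correlated, and AR(1) is
the minimal stationary model with a tunable correlation time.  The
distance trace fluctuates about `d_bound`, then ramps linearly after
rupture (clipped at zero).  Brownian tracks are ideal 3-D random walks
with per-step, per-coordinate s.d. √(2·D·dt).

Design choices worth stating:

* **Steepness.** The rupture transition is abrupt and cooperative; the
  default steepness puts the 10–90% width of the transition
  (2·log₁₀(81)/m ≈ 0.76 ns) well below typical dwell times while
  keeping several frames across the transition for fitting.
* **Frame interval.** The saved-frame interval must resolve the
  shortest expected dwell: the generator refines the base interval to
  `min(dt, mean/50)` per scenario, so even the blunt-break scenario
  (mean 1 ns) has ~50 frames before a typical rupture.  With a fixed
  0.18 ns interval the blunt scenario would leave ~6 pre-rupture
  frames, making per-replica fits ill-posed.
* **Censoring.** Replicas whose drawn rupture time exceeds the trace
  window are generated honestly as transition-free traces, not
  resampled; at duration = 10 × mean the censoring probability is
  e⁻¹⁰ ≈ 5×10⁻⁵, but the detection chain's censoring policy remains
  testable by shortening the window.
* **Seeding.** A master seed fans out to one `SeedSequence` per
  (scenario, replica) via spawn keys, so ensembles are reproducible and
  each replica can be regenerated in isolation.

What the generator does **not** emulate: sequence dependence, fraying
micro-states and multi-step unbinding, force-dependent kinetics, and
any nucleotide-resolution geometry.  Passing recovery tests therefore
demonstrate that the analysis chain is consistent and unbiased under
the two-state model's own assumptions — not that real trajectories
satisfy those assumptions.

## Rupture detection

The energy criterion smooths the trace with a centred moving average
(default window 1% of the trace length, forced odd; edges truncated)
and fits the four-parameter base-10 logistic by Levenberg–Marquardt,
initialised from the first/last decile means, the first mid-level
crossing, and the 25–75% crossing interval (2·log₁₀3/m).  The rupture
time is the flex t50; ΔU is read off the fitted curve at the flex,
(E_max−E_min)/2, which is noise-free (a smoothed-data reading at t50 is
available behind a switch).  A fit is censored — not an error — when
it fails to converge, when the fitted amplitude is below 3× the raw
residual s.d. (no detectable transition), or when t50 falls outside
the trace.

Because the fit runs on smoothed data and the noise is serially
correlated, the solver's covariance (which assumes iid residuals) is
optimistic by roughly the smoothing window times the AR inflation
factor.  The reported covariance is rescaled by the raw-residual
variance and by (1+φ̂)/(1−φ̂) with φ̂ the lag-1 autocorrelation of the
raw residuals; Monte-Carlo checks show the resulting 3-s.e. interval
covers the true t50 at the expected rate.

The distance criterion declares rupture at the first run of
`persistence` (default 10) consecutive frames above a threshold.  The
auto-threshold is bound-level + 5 s.d., with the bound level estimated
from the low-distance density peak by a zoomed histogram mode and a
MAD-based s.d. — time- or quantile-decile estimates fail whenever
rupture happens early, because the trace is then dominated by the
drift ramp.  An irreversibility check (the post-crossing mean must
clear the threshold by the same margin) rejects flat, noise-only
traces.  On the default mixed ensemble the median disagreement between
the two criteria is ≈0.8% of the trace span, and the detection lag of
the threshold criterion ((threshold−d_bound)/drift plus noise) is the
dominant contribution.

## Kinetic and energetic fits

Scenario means use uncensored replicas only; censored counts are
reported alongside (an exponential maximum-likelihood mean that adds
censored exposure to the numerator is provided as an optional
extension).  Both laws are unweighted OLS on the scenario means —
a handful of b_d points per force — via statsmodels, with standard
errors from the regression; the base-10 form is the exact
reparameterisation w2 = k1/ln 10.  At 100 replicas per scenario the
s.e. of ln τ̄ is 0.1 per point, giving ≈0.08 on the intercept and
≈0.045 on the slope of the Arrhenius fit; the recovery tests assert
agreement with the generator truth at ~3 of these standard errors.
The exponentiality check is a one-sample KS test against the
exponential law with the rate estimated from the same data, so its
p-value is approximate (conservative).

## Diffusion and time rescaling

`compute_msd` evaluates the time-averaged MSD over all start frames at
up to 100 lags (default cap 25% of the duration).  The diffusion fit is
a through-origin slope with weights ∝ 1/lag², because the standard
deviation of a single-trajectory time-averaged MSD grows roughly
linearly with the lag; an unweighted fit is available.
`estimate_diffusion_from_track` additionally caps the fit lags at 1% of
the duration: for a 10⁵-step track this brings the single-track scatter
of D from ~19–24% (25% cap, unweighted — under which "within 10%"
recovery claims are unattainable) down to ~4%, with no measurable bias.
This mirrors single-particle-tracking practice of fitting only short
lags when localisation noise is absent.

The experimental reference diffusion coefficient is temperature-scaled
by the literal ratio T_target/T_ref by default; a Stokes–Einstein
T/η(T) variant (Vogel water viscosity) is behind a flag.  Physical
times are t = Γ·t_CG.  The extrapolation table reports rescaled mean
rupture times for b_d = 0..b_d_max in scientific notation at one
significant figure (raw doubles retained): rows with measured scenario
means use them; higher b_d rows extrapolate τ̄0·e^{k1·b_d} — a
deliberately speculative extension of the fitted law far beyond the
measured range.

## Problem sizes

Defaults were chosen so the full validation cycle runs on a laptop:
the pipeline recovery uses 100 replicas × 4 DSB distances at one force
(~3 s), distributional checks use 10⁴–10⁵ draws, and diffusion
recovery uses 20–40 tracks of 10⁵ steps.  These sizes put every
Monte-Carlo tolerance at ≥3 standard errors of the corresponding
estimator.

## Known limitations

* The two-state logistic is also the generating model of the synthetic
  traces; model misspecification (multi-step rupture, drifting
  plateaus) is untested by construction.
* Very early ruptures (within a few frames of the start) leave the
  lower plateau unidentifiable; such replicas inflate per-replica
  error and are the main residual bias at the blunt-break scenario.
* The distance criterion's detection lag is systematic (threshold
  margin over drift rate); it cancels in cross-validation medians but
  would bias absolute times if used alone.
* OLS on scenario means ignores the heteroscedasticity of ln τ̄ across
  b_d; with four points and equal replica counts the effect is well
  below the quoted standard errors.
* Γ rests on the single assumption that coarse-graining rescales all
  times uniformly; no claim is made about processes whose acceleration
  differs from centre-of-mass diffusion.
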