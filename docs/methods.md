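# Methods

This note documents the models implemented in `secforce`, the conventions
and defaults they use, the choices made where the design was genuinely open,
and what the synthetic-data tests do and do not demonstrate.

## Worm-like chain and contour-length accounting (`polymer`)

Force–extension of the unfolded polypeptide uses the Marko–Siggia
interpolation formula, F(z) = (k_BT/p)[1/(4(1−z)²) − 1/4 + z] with
z = x/L. The interpolation form (rather than an exact numerical WLC) is the
standard choice at the persistence lengths (p = 0.65 nm) and forces
(< 70 pN) relevant here; its percent-level deviation from the exact model is
far below the spread of measured extension changes. Inversion is by
bracketed bisection to 10⁻¹⁰ in z, guaranteed to converge on the monotone
forward map; round-trip error is below 10⁻⁸ relative over 0.1–100 pN.

Contour-length change of a rip is ΔL = Δx / z(F) at the rupture force — the
protein length change only; DNA-handle elasticity and enthalpic stretching
are intentionally not modelled, matching how the extension changes are
reported. The expected unfolding length change of an n-residue domain is
n × 0.36 nm − 1.6 nm (native end-to-end span); for the 186-residue mDHFR
this gives 65.4 nm.

Thermal energy defaults to k_BT = 4.11 pN·nm (≈ 24.5 °C) and is configurable
everywhere a `BarrierParams` or `RunConfig` is accepted.

## Force-dependent unfolding kinetics (`kinetics`)

The Dudko–Hummer–Szabo rate law with shape exponent ν governs escape over a
single barrier. ν defaults to 2/3 (linear-cubic free-energy profile) and is
configurable but fixed during fitting: with only two loading-rate decades, ν
is not identifiable and acts as a convention that must accompany any
reported (τ₀, Δx‡, ΔG‡) triple. All outputs therefore record ν and k_BT.
`log10_tau0` is log base 10 of the intrinsic lifetime in seconds
(10^5.46 s corresponds to a zero-force rate of 3.5×10⁻⁶ s⁻¹).

**Capped hazard.** For ν < 1 the raw rate rises, peaks at
u* = ((1−ν)/ΔG‡)^ν, and vanishes at the critical force F_c = ΔG‡k_BT/(νΔx‡).
Real rupture data can extend to and beyond the fitted model's F_c, where the
raw formula would assign zero density and an infinite negative
log-likelihood. The package therefore uses the running maximum of k(F) as
the hazard: the raw rate below its maximizer F*, constant k(F*) beyond.
This single policy is applied consistently to the rate, the lifetime, the
cumulative hazard (closed form below F*, linear continuation above), the
rupture density, and the sampler, so the likelihood, the simulator and the
analytic CDF describe the same probability model. The sampler is exact
inverse-transform; draws that would rupture only at or past F_c are recorded
as censored there and enter likelihoods through their survival probability.

The classical binned transform of rupture histograms into lifetimes,
τ(F_i) = Ŝ(F_i)/(p̂(F_i)·⟨r⟩_i), is provided as an independent cross-check of
the binless fit, not as the estimator of record.

**Shape diagnostic.** Unfolding from more than one native state broadens
the rupture-force distribution beyond what any single-barrier parameter set
allows. `barrier_shape_diagnostic` fits a one-population model and a
two-component mixture (weight + two parameter triples sharing ν and k_BT)
and compares them by BIC. It is a screening tool: with overlapping
components or small samples the mixture is legitimately not preferred.

## Binless maximum likelihood (`mle`)

The rupture-force density p(F|r) = k(F)/r · exp(−Λ(F)) is fit directly to
unbinned rips, each at its own loading rate, pooling pulling speeds into one
likelihood. Optimization is L-BFGS-B over (log10 τ₀, Δx‡, ΔG‡) — the log
parameterization of τ₀ avoids scale pathologies — from a deterministic
4×3×4 multi-start grid (log10 τ₀ ∈ {3,5,7,9}, Δx‡ ∈ {0.5,1.5,2.5} nm,
ΔG‡ ∈ {10,15,20,25} k_BT), bounds log10 τ₀ ∈ [0,12], Δx‡ ∈ [0.05,10] nm,
ΔG‡ ∈ [1,50] k_BT; ties break toward the lowest log10 τ₀. Estimates at a
bound are flagged.

Uncertainty defaults to a parametric bootstrap (B = 200): rupture forces are
resampled from the fitted model at the observed loading rates and refit; SDs
and the covariance come from the replicate spread, and the replicates are
retained for downstream Monte-Carlo propagation. A finite-difference
observed-information Hessian is available as a fast alternative
(`uncertainty="hessian"`); the method used is recorded in the output.

## Translocation signal model (`translocation`)

After DTT releases the disulfide stall at t = 0, the substrate advances
quickly to the folded roadblock; the post-release scheme is
S →(k_unfold) U →(k_transloc) T with the competing dead end S →(k_incap) X.
The reduction step and the short pre-roadblock segment are treated as fast
and absorbed into t = 0; incapacitation drains the roadblocked state only;
luciferase-substrate depletion multiplies the signal by exp(−k_deplete·t);
reporter complementation is instantaneous. The observed signal is
RLU(t) = e^(−k_deplete t)·A·(T(t) + T0) + baseline, with T0 the pre-imported
loop-free fraction. The degenerate case k_transloc → k_unfold + k_incap uses
the analytic t·a·e^(−at) limit. Pre-DTT data are excluded from fitting.

Two structural properties of this two-exponential model matter for anyone
fitting it:

* **Amplitude is a calibration, not a fit parameter.** A single post-DTT
  trace determines the two decay rates, k_deplete, the baseline, and only
  the *products* A·k_unfold/(k_unfold+k_incap) and A·T0. The split of the
  decay a = k_unfold + k_incap into its two rates therefore requires the
  RLU-per-imported-substrate conversion A from an assay calibration.
  `fit_trace` warns whenever A is left free.
* **Rate-swap symmetry.** The signal is exactly invariant under exchanging
  a and k_transloc while preserving k_unfold/a. The reported branch is
  k_transloc > k_unfold + k_incap — clearing the folded roadblock, not
  moving the unfolded chain, is the slow step, consistent with independently
  measured translocation rates (0.1–1.2 min⁻¹) for substrates without
  stable structure. Fits started from the swapped assignment converge to
  this branch.

Fitting is homoscedastic nonlinear least squares (per-point weights
accepted), initialized by ranking a coarse rate/depletion grid after
profiling the two linear parameters (A·T0, baseline) out by ordinary least
squares; parameter SDs come from the Jacobian-based covariance. Traces whose
smoothed range is indistinguishable from their local noise are flagged
degenerate and returned without rate estimates. Rates are handled in min⁻¹
throughout; the force-matching step converts via the fixed bridge
τ = 60 s / k_unfold.

## Force matching (`matching`)

The reported motor force is the *equivalent constant force*: the unique
F with τ(F) = 60/k_unfold, found by bracketed root-finding (10⁻⁴ pN) on the
strictly decreasing branch of the lifetime. No duty-cycle correction is
applied — if the motor loads the substrate intermittently, its peak force
exceeds this equivalent. Uncertainty is propagated by Monte Carlo (default
1000 draws, seeded): barrier parameters from the bootstrap replicates when
available (otherwise a Gaussian with the fit covariance), k_unfold from a
normal with its fitted SD; draws without a positive-force solution are
counted and the estimate is flagged if they exceed 20%.

## Synthetic data (`simulate`)

The generators define the study conditions used throughout the tests:

* **Rips**: pulling speeds 20 and 150 nm/s at 0.1 pN/nm trap stiffness;
  per-molecule loading rate r = stiffness × velocity × L with L log-normal
  (median 1, CV 0.3), emulating multiplicative tether-to-tether stiffness
  variation; rupture forces drawn exactly from the capped-hazard model;
  extension changes back-computed through the WLC from the 65.4 nm
  full-unfolding contour change; optional hard censoring at an
  overstretching plateau.
* **Traces**: 0.2 Hz sampling; per-condition recording length until the
  signal plateaus (30/60/90 min for the apo/MTX/M+N rate sets — a few times
  1/(k_unfold+k_incap); a 30-min window carries almost no k_unfold
  information for the slowest condition); amplitude A = 10⁴ RLU, baseline
  200 RLU, T0 = 0.05, k_deplete = 0.005 min⁻¹; Gaussian noise with
  SD = 3 + 0.25·√signal RLU, a shot-noise-like law whose scale was chosen
  once so that single-trace fit SDs of k_unfold match the published
  replicate SDs to within a factor ~2.

What passing the closed-loop tests shows: the estimators recover the
generating parameters without bias at realistic sample sizes, the quoted
uncertainties are calibrated, and every file format round-trips. What they
do not show: robustness to features of real data the generators omit —
baseline drift, non-Gaussian plate-reader artifacts, handle-compliance
variation within a ramp, refolding between pulls, rip mis-detection, or
model misspecification of the depletion form.

## Numerical conventions

* Root-finding and quadrature tolerances: WLC inversion 10⁻¹⁰ (z); force
  matching 10⁻⁴ pN; closed-form hazard validated to 10⁻⁶ relative against
  adaptive quadrature.
* Likelihood evaluations that would be non-finite (invalid parameter
  points) return a large penalty (10¹²) rather than raising, so optimizers
  can traverse them.
* All randomness flows through `numpy.random.default_rng(seed)`; file writes
  are deterministic given config and seed (stable ordering, shortest
  round-trip float formatting, `float_precision="round_trip"` on read).
* Degenerate inputs (flat traces, zero-spread rupture forces, single-bin
  histograms, estimates at bounds, unsolvable Monte-Carlo draws) are flagged
  explicitly, never silently dropped.

## Known limitations

* ν is a convention, not an estimate; parameter triples are comparable only
  at matching ν and k_BT.
* The capped-hazard continuation above F* is a regularization choice; other
  policies (e.g. truncation with explicit censoring) would change the
  likelihood of the small fraction of events near and beyond F_c.
* The kinetic scheme treats the post-reduction, pre-roadblock translocation
  as instantaneous and depletion as a single multiplicative exponential;
  both are simplifications chosen for identifiability from a single trace.
* The equivalent-constant-force interpretation deliberately ignores the
  motor's duty cycle.
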