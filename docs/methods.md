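# Methods

This note documents the models, numerical choices, and limitations of
`pgpkin`. It describes what the code does and why; every number quoted
here is computed by the test suite or `scripts/acceptance.py`.

## The quantification problem

¹¹C-desmethylloperamide is a P-glycoprotein substrate: with P-gp intact
the tracer is pumped back out of the brain endothelium almost as fast as
it enters, so brain uptake stays low; with P-gp absent (Mdr1a knock-out)
or blocked (cyclosporine) the tracer accumulates. A one-tissue compartment
model driven by the arterial parent-plasma concentration C_p(t),

    dC_T/dt = K1·C_p(t) − k2·C_T(t),
    C_model(t) = (1 − vB)·C_T(t) + vB·C_wb(t),

summarizes this with an influx rate K1 (mL/cc/min), an efflux rate k2
(1/min), and a fractional blood volume vB. The equilibrium distribution
ratio K1/k2 (mL/cc) is the functionality index: low (~0.4) with working
P-gp, high (~2) without. Because rapid P-gp efflux occurs while the
tracer transits the endothelial membrane, it depresses the *apparent* K1
rather than inflating k2; restricting the fit to the first two minutes
instead exposes the fast efflux component as a large k2. The package
treats the 2-min refit as a standard report column, not a separate mode.

A serial two-tissue model (k3, k4; optionally k4 ≡ 0) is provided for
model comparison. On data generated by one-tissue kinetics it earns a
comparable AIC with two extra parameters and badly identified k3/k4
(%COV far above the 50% flag threshold), reproducing the rationale for
preferring the one-tissue model.

## Input function

Two measurement routes are supported.

* **Image-derived (the noninvasive route).** Mean over a left-ventricle
  ROI per frame. The ROI comes from a co-registered FDG image in the real
  experiment; in the synthetic phantom the region is known exactly, which
  deliberately idealizes away delineation error.
* **Blood counter.** The catheter line disperses the true curve; the
  package models this as convolution with (1/τ)·e^(−t/τ) and inverts it
  with the analytic correction C_a = g + τ·dg/dt, τ default 28 s. The
  derivative is taken by central differences on the frame-midpoint grid
  (one-sided at the ends), with an optional 3-point moving-average
  pre-smoothing flag (off by default) for noisy traces. τ itself is a
  user parameter; estimating it from catheter geometry is out of scope.

Both routes are then scaled by the plasma-to-whole-blood activity ratio
(a single scalar, default 0.64 — the reported time-resolved values
0.67/0.49/0.67 are deliberately collapsed to their mean, as in the source
analysis) and multiplied by the group-specific parent fraction.

**Parent fraction.** With only three HPLC samples per group (1, 10,
30 min), the model is a piecewise-linear interpolation through the
implied anchor (0 min, 1.0) and the samples, flat beyond the last sample,
clamped to [0, 1]. Anything parametric would be over-modeling.

**Resampling frame data to the fine grid.** The kinetic model needs
C_p(t) on a fine grid (0.5 s), but measurements are frame *averages* on a
schedule whose early frames (5 s) barely resolve the bolus. The default
resampler interpolates the cumulative integral at the frame edges (known
exactly as the running sum of value × duration) with a shape-preserving
monotone PCHIP and differentiates it. This is exact on every frame
average and non-negative whenever the frame values are, so
simulate → bin → reconstruct → bin is an identity. The simpler PCHIP
through frame midpoints is available as `method="midpoint"`; it clips
sharp peaks and biases fitted k2/vB by ~1% under the default conditions,
which is why it is not the default.

**Agreement metrics.** AUC is Σ(value × duration) over the curves'
common span — exact for frame-averaged data, hence no trapezoid rule.
The direct metric is |ΔAUC|/AUC_ref × 100 with the counter as reference;
the indirect metric is the same construction on fitted K1/k2.

## Forward model and fitting

**Convolution.** C_T is a sum of convolutions of C_p with exponentials
(one for 1TC; two, with eigenvalue rates α₁/α₂ of the 2TC system, for
2TC). These are evaluated segment-exactly for piecewise-linear C_p via a
first-order recurrence (dispatched to `scipy.signal.lfilter` on uniform
grids), with a series expansion of the segment moments below α·h = 1e−4
to avoid cancellation. No FFT, no quadrature error; agreement with an
adaptive Runge–Kutta oracle is ~1e−8 relative across the published
parameter range (asserted < 1e−6). A repeated 2TC eigenvalue is split by
a 1e−9 relative nudge; k3 = 0 short-circuits to the one-tissue path, so
the reduction 2TC(k3=0) ≡ 1TC holds bit for bit.

**Fitting.** Bounded least squares (`scipy.optimize.least_squares`, trf)
on frame-averaged predictions. Defaults: initial values K1 = 0.1
mL/cc/min, k2 = 0.1 /min, k3 = k4 = 0.01 /min, vB = 0.05; bounds [0, 10]
per-minute for rates, [0, 1] for vB; 5 multistarts (the first nominal,
the rest perturbed by ±50% log-uniform factors from the seeded
generator); frame-duration weights w_i ∝ Δt_i (PMOD-style; uniform
weighting available). Time is seconds internally; rates are converted to
per-minute only at the reporting boundary. Fits are deterministic under a
fixed seed.

**Uncertainty and selection.** The parameter covariance is
(JᵀJ)⁻¹·RSS/(n−p) from the weighted Jacobian at the optimum; %COV =
100·SE/|estimate|. AIC = n·ln(RSS/n) + 2p with p counting vB; an exactly
zero RSS is floored at the smallest positive float so noiseless fits keep
a finite AIC. `compare_models` ranks by AIC, flags any fit whose largest
%COV exceeds 50%, and selects the fewest-parameter model within ΔAIC ≤ 2.

## Group statistics

One-way ANOVA with the pooled within-group mean square; pairwise
comparisons are two-sided t-tests reusing MS_within with its pooled
degrees of freedom (SPSS-style post hoc), Bonferroni-adjusted by the
number of pairs and capped at 1. On the published per-animal K1 values
this yields adjusted p = 0.008 for WT vs KO, and on the K1/k2 ratios an
omnibus p = 0.001 — matching the reported values at three decimals. The
reported WT-vs-cyclosporine K1 comparison (p = 0.025) is *not* reproduced
by this construction on the rounded table values (it gives ~0.015);
plausibly an unrounded-data effect in the source. It is documented here,
not targeted. Under the null (2000 simulated three-group datasets) the
omnibus p-value is uniform (KS test).

Significance level: 5%. Reports round p to three decimals; JSON keeps
full precision.

## Synthetic data: what it emulates, what it does not

The generator reproduces the study's acquisition conditions: a ~20 MBq
dose, the 30-min framing (12×5 s, 6×10 s, 4×1 min, 2×2 min, 2×5 min,
1×10 min = 1800 s), a 28-s dispersion kernel
on the counter trace, the 0.64 plasma ratio, and the group-stratified
parent-fraction tables. All concentrations are decay-corrected by
construction, so no decay operator exists.

* **Bolus.** A ramp-plus-biexponential C(t) = A1·Δt·e^(l1·Δt) +
  A2·e^(l2·Δt) + A3·e^(l3·Δt) (Δt = t − t0), zero before arrival.
  Defaults: t0 = 10 s, ramp time constant 14.3 s, peak ~100 kBq/cc at
  ~25 s p.i., slow tail (~3.5 kBq/cc at 30 min); A2 = −A3 makes the onset
  continuous. The curve is C⁰ but not C¹ at t0. The amplitude scales with
  injected dose. This is plumbing with realistic shape, not a claim about
  the real tracer's arterial kinetics.
* **Fine grid.** 0.5 s over 0–1800 s: resolves the 5-s frames and the
  28-s kernel.
* **Noise.** Gaussian per frame with sd = scale·sqrt(max(value,0)/Δt), a
  count-statistics proxy in concentration units (variance shrinks with
  frame duration); clipped at zero; seeded. Post-reconstruction PET noise
  is approximately Gaussian, which is why Poisson counts are not drawn.
* **Phantom.** Two labeled boxes (heart-LV, brain) in a low-background
  field; each voxel of a region carries the region's frame-binned curve,
  so ROI means reproduce ground truth exactly. Optional isotropic
  Gaussian blur (off by default); no partial-volume or spill-over
  modeling, matching the premise that the FDG-guided LV ROI is
  spill-in-free. Registration between scans is assumed perfect.
* **Cohorts.** Subject i of a group centers on the (i mod 3)-th published
  (K1, k2) pair for that group and perturbs multiplicatively by
  1 + spread·N(0,1) (spread 0.15 by default, so draws stay centered);
  vB ~ 0.03, dose ~20 MBq, weight ~25 g with small jitter. Zero spread
  reproduces the nine published parameter sets exactly.

Consequently, passing tests demonstrate the *pipeline's* correctness —
corrections invert what the generator applied, fits recover what the
generator used — under idealized geometry. They do not validate ROI
delineation, registration, scanner physics, or the adequacy of the
compartment model for real tissue.

## Measured numerical fidelity

Computed by the acceptance script / test suite at the default conditions:

* Dispersion blur-then-correct round trip on a smooth (C¹)
  arterial-shaped curve at 0.5-s sampling: max error ~0.06% of peak
  (asserted < 1%). On the default bolus itself the error is ~1.1%,
  concentrated entirely at the onset kink where the derivative jumps —
  the analytic correction is exact only where the curve is
  differentiable. Errors are normalized to the curve peak, since
  pointwise relative error is undefined where the curve is zero.
* Noiseless phantom → extraction → corrections → fit: K1, k2, vB
  recovered to < 0.1% (WT-1 set: 0.07% worst). Across all nine published
  sets K1 and k2 stay < 0.07%, while vB (true value 0.03) reaches 0.17%
  for the high-K1 sets — the residual input-reconstruction error near the
  peak loads onto the vascular term.
* Noisy recovery: median K1/k2 bias over 200 realizations at noise scale
  0.05 is ≪ 1% (asserted < 5%).
* 2-min-window refit on fast-efflux kinetics (true fast k2 = 5/min over
  a slow trapped component): windowed k2 exceeds the full-window k2 by
  ~90×, the qualitative signature the short-window analysis exists for.

## Problem sizes

Default test and acceptance runs use 27-frame schedules, 3601-point fine
grids, 9-subject cohorts, 200-seed noise ensembles, and 2000-replicate
null calibrations; the phantom is 16×16×8 voxels. These sizes were chosen
so the whole verification cycle runs on a laptop in well under a minute
per component while keeping Monte-Carlo error far below the asserted
tolerances.

## Known limitations

* No delay (time-shift) correction between blood and tissue curves.
* No partial-volume/spill-over correction; the phantom idealizes the ROI.
* The plasma ratio is a single scalar; its early-time dip (0.49 at
  1 min) is ignored by design.
* Parent-fraction uncertainty (± values of the HPLC table) is not
  propagated.
* The 2-min-window k2 magnitudes are data-dependent; only the direction
  (windowed > full in wild-type-like kinetics) is asserted.
* Whether the source analysis fitted or froze vB in the 2-min window is
  unknown; the package fits it by default and exposes bounds to freeze it.
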