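# Methods

This note documents the models implemented in `cadwave`, the defaults and
why they were chosen, the numerical choices that matter, and what the
synthetic-data tests do and do not establish.

## Gradient model

The *Tc-cad* expression profile is represented as a linear-with-plateau
curve on the normalised AP axis (fraction in [0, 1], 0 = anterior pole):
zero anterior of a border `b`, a linear ramp of slope `m`, and a posterior
plateau `P`.  Validity requires the ramp to reach the plateau on the axis
(`b + P/m <= 1`).  Temporal dynamics:

* **Buildup** — a multiplicative, spatially uniform factor
  `B(t) = 1 - exp(-(t - t_on)/tau)` (identically 1 when `tau = 0`).  A
  uniform scaling is used because the measured plateau and slope grow
  together over 14–16 h AEL while the border does not shift; a shape change
  would move the border.
* **Retraction** — from `retraction_onset` the border shifts posteriorly at
  `v` axis fractions per hour, slope and plateau unchanged, border clamped
  at 1.  Whether late retraction is a border shift at constant slope or a
  whole-profile collapse is not observable in the data we emulate; the
  border-shift parameterisation was chosen as the simpler of the two.

**Wild-type defaults**: `P = 1.0` a.u., `b = 0.40`, `m = 2.5` a.u. per axis
fraction, `t_on = 13.5` h AEL, `tau = 0.5` h, `retraction_onset = 20` h,
`v = 0.05` per hour.  The plateau and slope set the intensity scale (only
ratios to wild type are meaningful); `tau = 0.5` h calibrates the first
posterior cycle to 3.5 h while leaving later cycles at 3 h; retraction
starting after the second stripe reflects the observed posterior retreat of
the gradient during third-stripe formation.  The retraction speed is the
largest round value that keeps the posterior-most cells at frequency
saturation through 23 h, so late retraction repositions stripes without
distorting posterior cycle timing — as observed, where a new cycle peaks in
every 3-hour collection including 20–23 h.

**Knockdown presets** are phenomenological: their absolute numbers are free
choices constrained only by the reported orderings relative to wild type
(posterior/anterior border shifts, lowered plateau, shallower slope, slower
buildup).  They are not a mechanistic Wnt-pathway model.

## Profile fitting

`LinearPlateauModel` fits by least squares over the two knots (border and
ramp-plateau knee); conditional on the knots the curve is linear in the
slope, which is profiled out in closed form.  The search is an exhaustive
grid over knot pairs drawn from the observed positions (subsampled to ~80
quantiles for dense profiles) followed by a Nelder-Mead polish
(`xatol 1e-10`), making the fit deterministic and immune to the local minima
of joint nonlinear fitting of kinked curves.  Degenerate geometries are
flagged rather than hidden: a ramp containing no interior data point (a
constant profile fitted by a step) or a slope pinned at the lower bound (a
flat-zero profile).

Background subtraction is a single scalar per profile, supplied or estimated
as the 5th percentile of the raw intensities.

Group statistics: per-descriptor means with embryo-level percentile
bootstrap 95% CIs (default 2000 resamples, seeded); condition-versus-
reference ratios bootstrap both groups independently; significance uses a
two-sided permutation test on group means (default 10,000 permutations,
add-one p-value).  These are this package's choices — the original
confidence-interval and test procedures behind the published error bars are
not described at this level of detail anywhere we could encode them.

## 1D simulator

Cells at `x_i = (i + 0.5)/n` (default n = 200) carry independent phase
oscillators, `dphi/dt = omega_ref * min(g(x,t), g_ref)/g_ref` with
`omega_ref = 1/3` cycles/h and `g_ref` the wild-type steady plateau.
Linearity of frequency in gradient level (below saturation) is an
assumption — the minimal one consistent with the observed correlation
between posterior *Tc-cad* level and oscillation frequency.

Because the phase velocity is independent of phase, integration is pure
cumulative quadrature.  The per-step frequency is evaluated at the **step
midpoint** (`dt = 0.01` h): this is exact when the frequency is constant
within a step and second-order accurate otherwise.  The distinction matters
because the wild-type calibration places the completion of the third
posterior cycle exactly at the 23 h end of the blastoderm window; midpoint
evaluation keeps the discretisation error (~3e-6 cycles over the run) far
below that margin, whereas a left-endpoint rule biases the phase low by
~2e-3 cycles and pushes the third completion artificially past the window.
Phases start at 0 (high phase) everywhere at `t_start = 13.5` h AEL, the
observed start of the first cycle, and are never wrapped.

**Expression readout** is binary: high during the first half-cycle
(`frac(phi) < 0.5`), and gated to the oscillating domain — a cell whose
frequency has never been positive shows no expression.  Without the gate,
never-active anterior cells (phase parked at 0) would read as expressing,
the anterior border of the expression domain would be identically zero, and
a zero gradient would leave the whole axis "on", contradicting the
observation that strong *Tc-cad* knockdown abolishes *Tc-eve* expression.
One consequence: `classify_stage` labels a pre-onset embryo I.1 (phase
parked at the start of cycle 1), so timing inference should use collection
windows starting at or after onset — as the emulated experiment did (14 h).

Stripes are maximal runs of high expression of at least 2 cells (suppressing
single-cell discretisation slivers), with borders at cell edges; the
posterior-most run is incomplete while the posterior end is still high.
Posterior cycle durations are read off the unwrapped posterior phase with
linear interpolation of the integer crossings.

## 2D robustness study

A `200 x 60` lattice (AP x lateral), `dt = 0.05` h, 20 h run.  The driving
gradient retracts from border 0.10 at `v = 0.05`/h, so the front crosses the
field in 18 h and freezes ~6 stripes at the 3 h period.  Two frequency
profiles are compared under identical conditions:

* **threshold-free**: `omega = omega_ref * min(g, g_ref)/g_ref`;
* **threshold-based**: `omega = omega_ref` where `g >= theta` (default
  `theta = 0.7`), else 0 — the classic sharp arrest front.

Noise is a per-cell multiplicative factor `eta ~ Normal(1, sigma)`,
truncated at zero and frozen for the whole run, applied to the gradient each
cell sees.  Frozen per-cell intensity noise is exactly what converts into
independent lateral shifts of the arrest position, i.e. salt-and-pepper
stripe borders.  Roughness is the fraction of cells differing from the same
mode's noise-free pattern; a secondary metric (lateral SD of border
positions) is provided for border-localised analysis.

The default gradient plateaus at `2 * g_ref` — a **saturation margin**: the
frequency response saturates below the plateau level, so plateau-level noise
is absorbed by the cap and only the noise experienced during the ramp
passage perturbs the accumulated phase.  This margin is what gives the
graded profile its buffering capacity.  Without it (plateau exactly at
`g_ref`), every cell with `eta < 1` runs slow for the entire run and the
graded profile loses its advantage — biologically, that would be a clock
whose rate tracks *Tc-cad* level with no saturation even at peak posterior
expression, which the saturating-response assumption rejects.  Under the
defaults the threshold-free model beats the threshold-based one in every one
of 20 matched noise fields at sigma in {0.05, 0.15, 0.3}, and both produce
identical, laterally uniform five-stripe patterns without noise.

Cells are uncoupled and noise enters only through gradient intensity — no
phase or period noise — matching the scope of the question asked.

## Timing inference

Embryo ages are uniform within their collection window; an embryo displays
cycle `k` iff its age lies in `[s_k, s_{k+1})`.  Window class probabilities
are interval overlaps divided by window length, giving a multinomial
likelihood over the ordered boundaries.  Optimisation works on
`(s_0, log-increments)` (ordering built in), Nelder-Mead from two
deterministic starts (uniform span split and count-weighted class-age
midpoints); bootstrap refits start from the data MLE.  The likelihood is
piecewise linear with kinks at window edges, which Nelder-Mead handles
robustly; the aligned-window case has a sharp V-shaped optimum at the true
boundaries.

Boundaries are only identified within the observed collection span:
estimates are clamped to the span and the adjacent durations flagged
`censored` (the true boundary may lie outside).  Confidence intervals are
parametric-bootstrap percentiles (counts resimulated at the MLE and
refitted, default 1000 draws, seeded).  Phase sub-classes (k.1/k.0) are
collapsed to cycle classes by default.  This estimation model is this
package's construction — the minimal generative model consistent with how
timed egg collections are made; the published estimates used an unspecified
procedure, so agreement is validated only by synthetic recovery
(randomly drawn 2–5 h durations recovered within 0.2 h in >= 90% of
replicates at 500 embryos per 1-h window).

## Synthetic data

The generator emulates: per-embryo axis lengths (lognormal, CV 0.05 — always
positive, modest variation), equally spaced sampling positions, and
intensity `truth(x) * (1 + eps_mult) + eps_add + background` clipped at zero
(defaults `mult_sd 0.1`, `add_sd 0.02`, `background 0.05` — noisy but
identifiable fits); and staged cohorts with ages uniform in their windows
mapped to classes by true boundaries.  It does **not** emulate spatially
correlated staining artefacts, embryo-shape or mounting variation,
non-uniform egg-lay rates within a collection, or any imaging step — so
passing recovery tests establishes correctness of the estimators under the
stated noise model, not robustness to every failure mode of real in situ
data.

## Problem sizes

Default problem sizes (200-cell rows, 200 x 60 lattices, 500 embryos per
window, 100-replicate recovery suites, 2000-resample bootstraps) were chosen
so the full test battery and the acceptance script each run in minutes on a
single CPU while keeping Monte-Carlo error well inside the asserted
tolerances.

## Known limitations

* Frequency is linear in gradient level below saturation; the real transfer
  function is unknown.
* Presets encode orderings, not measured magnitudes; simulated knockdown
  effect sizes are not quantitative predictions.
* No stripe splitting into secondary segmental stripes, no cell movement or
  germband elongation, no pair-rule cross-regulation.
* The timing estimator's absolute accuracy on real collections depends on
  the uniform-age-within-window assumption (steady egg-lay rate).
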