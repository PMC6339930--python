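# Methods

## Model overview

`gridscape` simulates a virtual forager in closed 2-D arenas and drives a
three-stage network with the resulting self-motion stream:

1. **Head-direction (HD) layer.** A Kohonen self-organizing map over unit
   heading vectors `psi = [cos(theta), sin(theta)]`. After training, each of
   the `N_hd = 64` neurons (8 x 8 sheet) has a unit-norm weight vector, so
   the layer's response to a heading is a sheet of cosine tuning curves,
   `theta_HD,k = cos(theta - phi_k)` with preferred directions `phi_k`
   covering the circle.
2. **Oscillatory path integration.** One Hopf limit-cycle oscillator per HD
   neuron with instantaneous angular frequency
   `omega_k(t) = Omega_PI + beta * s(t) * theta_HD,k(t)`,
   where `s` is the running speed and `beta` a spatial gain. Because
   `s * cos(theta - phi_k) * dt` is exactly the displacement component along
   `phi_k`, the phase of oscillator k equals `Omega_PI * t` plus `beta` times
   the net displacement along its preferred direction: a periodic positional
   code (oscillatory interference) with spatial period `2 pi / beta`.
3. **LAHN (lateral anti-Hebbian network).** A single layer of `n = 20`
   linear neurons receiving the concatenated oscillator state through
   afferent weights `q` (Oja-stabilized Hebbian updates) and each other's
   one-step-delayed responses through lateral weights `w` (anti-Hebbian
   updates, zero diagonal). The afferent weights converge to the principal
   subspace of the input stream; the lateral inhibition decorrelates the
   neurons. Individual neurons acquire spatially modulated, weakly hexagonal
   firing fields.

### Default parameters

| parameter | value | meaning |
|---|---|---|
| `Omega_PI` | 12 pi rad/s | baseline oscillator frequency (6 Hz, theta band) |
| `mu` | 1 | limit-cycle radius squared |
| `beta` | 50 rad/unit | spatial gain; positional-code period 2 pi / beta ~ 0.126 units |
| `dt` | 0.01 s | integration/sampling step |
| `n` | 20 | LAHN neurons |
| `eta_F`, `eta_L` | 0.01 | afferent / lateral learning rates |
| HD sheet | 8 x 8 | 64 preferred directions |

## Numerical choices

**Oscillator integration.** The Hopf normal form with piecewise-constant
input is integrated exactly per step: the phase is rotated by `omega * dt`
and the squared radius follows the closed-form logistic solution of
`dr/dt = r (mu - r^2)`. Explicit Euler at `dt = 0.01` would inflate the
discrete limit-cycle radius of a ~0.4 rad/step rotation to ~2.8 instead of
`sqrt(mu)`; the exact step keeps the radius at `sqrt(mu)` to machine
precision and makes the phase/displacement relation exact. Trajectory
integration (positions) remains explicit Euler.

**Speed fed to the oscillators.** `s(t) = ||X(t) - X(t-1)|| / dt`, in
units/s. Dimensional consistency requires this: `beta * s * theta_HD` is
added to `Omega_PI` (rad/s), and `beta` is a spatial scale in rad/unit. With
a raw per-step displacement instead, the positional-code period would be
~12 arena units — larger than every arena — and no spatial structure could
form.

**LAHN input scaling.** The oscillator state is fed to the LAHN divided by
`sqrt(N_hd)`, giving unit total variance independent of the layer size.
Without this the response variance grows with `N_hd` and the default
learning rates overshoot the anti-Hebbian equilibrium (the lateral
recurrence diverges numerically). With it, online learning drives the
lateral spectral radius to ~1 (edge of stability) and responses stay
bounded.

**Frozen-weight scoring.** Rate maps for a given training checkpoint use the
fixed point of the response recurrence, `xi = (I - w)^{-1} q chi`, rather
than iterating `xi(t) = q chi(t) + w xi(t-1)` with frozen weights: at the
self-organized edge of stability the frozen recurrence diverges over long
streams, while its fixed point is well defined. The one-step recurrence is
used online during learning (and is exposed as `replay_lahn` for small
problems).

**Convergence.** Mean `|Delta q|` over a 1000-step window below `1e-5`
declares convergence; with persistent oscillatory input the plasticity
reaches a stochastic equilibrium rather than this strict criterion, in which
case the end of the session is used as the converged state, and "10% of
training" defines the partially trained network.

## Trajectory model

Position integrates `x' = sigma cos(Theta)`, `y' = sigma sin(Theta)` at
`dt = 0.01 s`. The heading performs a bounded random walk: per step a turn
`gamma * rho * dt` with `gamma ~ U[-1, 1]` and `rho = 20 rad/s`. The speed
follows the wall-distance rule `sigma = clip(d_wall, 0.05, 0.5)` units/s:

* the upper cap prevents arena size from dictating the dynamics;
* the lower floor is needed because the pure `sigma = d_wall` rule makes
  `log d_wall` an unbiased random walk, so the forager would spend most of
  the session at microscopic wall distances (occupancy entropy ~0.1 of
  uniform in pilots). With the floor, a 600 s session in a unit square
  visits all of a 10 x 10 occupancy grid with entropy >= 0.9 of uniform,
  while still moving measurably slower near walls (behavioral anisotropy).

A step of length `sigma * dt <= d_wall` cannot cross the boundary; when the
floored speed would (within the thin wall-contact band), the step falls back
to the pure wall-distance speed. Rejection sampling of the turn and
reflection off the wall normal remain as a final guard (relevant only for
exotic parameter choices).

**Trips in connected arenas.** Free foraging essentially never crosses the
corridor between two rooms at session scale (0 crossings in 500 s in
pilots), so the connected-arena studies run structured sessions of trips:
the random turn gains a bias (within the same per-step turn bound) toward
alternating waypoints — left room center, corridor midpoint, right room
center — with 20 s of unbiased foraging after each arrival and a 5 s bias
suspension after 3 s of sustained wall contact (the bias can otherwise pin
the forager against the dividing wall). This yields roughly 6–10 room
crossings per 500 s session with balanced room occupancy. The corridor
rectangle reaches `room_size / 4` into the rooms so that circular rooms get
a full-width opening.

## Gridness analytics

* **Rate maps**: mean rectified response per square bin (default bin 0.02
  units for study scoring), unvisited bins masked, mask-normalized Gaussian
  smoothing (sigma = 1 bin).
* **Autocorrelogram**: Pearson correlation per spatial lag over overlapping
  visited pixels (FFT-accelerated, verified to 1e-10 against the literal
  quadruple loop); lags with fewer than 20 overlapping pixels are masked.
* **HGS**: the autocorrelogram is masked to an annulus from the first
  minimum of the radial profile to 1.5x the radius of the strongest ring
  peak (fallback 0.2–0.8 of the maximum lag), rotated by 30/60/90/120/150
  degrees (cubic interpolation; bilinear attenuates fine rings and biases
  the correlations), and scored
  `min(cor60, cor120) - max(cor30, cor90, cor150)`. The tight outer radius
  is validated against ideal-lattice oracles: a noiseless hexagonal lattice
  scores > 1, a square lattice < 0, and the score is invariant (+-0.05)
  under rotation and co-scaling.
* **Ellipticity**: least-squares ellipse through the central-ring peaks of
  the autocorrelogram (peaks plus their antipodes; at least three required),
  reported as major/minor axis ratio.
* **Half-map similarity**: Pearson correlation between the two equal-area
  halves of a rate map after reflecting one half onto the other's frame,
  over jointly visited bins.
* **Local vs global HGS** (connected arenas): global is the whole-arena
  score; local averages the two per-compartment scores (corridor excluded).

The emergent fields are interference envelopes: their spatial power
concentrates at difference wavevectors of the oscillator ring, giving
speckle-like fields with features of order `pi / beta` ~ 0.06 units and
only weak six-fold symmetry. Absolute HGS values are therefore small
(typically |HGS| < 0.3, as in the modeled study this package reproduces),
and all geometry effects are assessed as trends/orderings over seeds rather
than absolute scores.

## Studies and problem sizes

Every study trains the full pipeline per seed. The convex study scores
"grid neurons" (the top quartile of LAHN neurons by whole-arena HGS); the
checkpoint-trend studies track the single best neuron; the concave and
polygon level studies average HGS over the whole LAHN population, which
avoids the selection noise a top-k rule adds to small between-level
effects. Trend claims use per-seed OLS slopes aggregated as the majority
sign with median R^2; a one-way ANOVA across levels is logged for parity.
Desk-scale sizes (chosen so that maps are well covered at the default bin
size while a full study stays in the minutes range): 400–600 s of simulated
foraging per run (40k–60k steps), 5 seeds per study, concave inner radii
0–1.0 in steps of 0.2 at outer radius 1.2, polygons n = 3..10, compartment
distances {0.1, 0.4, 0.7, 1.0}.

The transforming study uses the hold-ramp-hold breadth schedule (ramp over
the 30%–50% session window), which places the rectangle-to-square
configuration switch at mid-session so the decoder sees balanced classes.
The decoder is scikit-learn's single-hidden-layer MLP (20 logistic units,
backprop, learning rate 0.01, 600 epochs, no early stop) on raw
per-timestep LAHN responses (decimated 10x). The "trained LAHN" decoder
reads the responses recorded online during the session, whose statistics
evolve with learning and therefore carry the arena transformation; the
"partially learned LAHN" control replays the 10%-of-training weight
snapshot over the same oscillator stream — a fixed linear readout of the
phase code, whose positional information is aliased at the grid period and
carries no configuration signal (it decodes at chance). The holdout is
block-wise over 25 contiguous time blocks (20% held out): the response
stream is strongly autocorrelated and a sample-wise random split would leak
near-duplicate samples across the split. Responses are deliberately left
unstandardized: a partially trained LAHN produces small, unnormalized
responses from which a fixed-epoch decoder genuinely extracts less — the
effect the study measures. Accuracy uses a 0.5 output threshold; MSE is the
squared deviation of the sigmoid output from the 0/1 label, per
configuration.

## What the simulation does and does not emulate

The foraging model is a curvature-constrained random walk with wall
slow-down; it reproduces space-filling exploration and thigmotaxis-like
wall occupancy but no accelerations, head scanning, or goal-directed runs.
The network is rate-based and noise-free: all stochasticity enters through
the trajectory and the weight initializations. Passing tests therefore show
that the *model's* geometry effects are reproduced, not that biological
grid cells behave this way.

## Known limitations

* Absolute HGS values depend on binning/masking conventions; only
  directions and orderings are stable. In particular, the HGS statistic has
  an intrinsic negative bias on small maps (30-degree rotations of any
  spatially autocorrelated field stay partially correlated), so half-arena
  scores sit systematically below whole-arena scores.
* Single-run trend signs are noisy at desk scale; the majority-over-seeds
  aggregation is the intended read-out, and individual sub-studies can
  still flip sign for unlucky seed sets. In this implementation the global
  gridness of connected arenas rises with training for *all* room-shape
  pairs; the local/global dissociation reproduces for circle-circle and
  the distance study but not for every pair.
* Response correlations across LAHN neurons *grow* during training (the
  Oja afferents pull toward the dominant input components faster than the
  delayed anti-Hebbian lateral differentiates them); the lateral coupling
  is inhibitory in effect — it reduces correlations relative to no
  coupling — but does not enforce net decorrelation over training.
* The S-shape arena concatenates two half-annuli; its "inner radius" study
  uses the same outer radius as the other concave arenas (the source does
  not state one).
* `config_label` switches at 99% of the final breadth; with the default
  schedule this is mid-session by construction.
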