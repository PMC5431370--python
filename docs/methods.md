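# Methods

## Model

The medium is a two-dimensional lattice of excitable cardiac cells.  Each
node carries three dimensionless state variables: the fast membrane
potential `u`, the slow recovery current `v`, and the magnetic flux `phi`
across the membrane, which accounts for electromagnetic induction set up by
the tissue's own electrical activity.  The kinetics are FitzHugh–Nagumo
type with a state-dependent recovery rate:

```
du/dt = -k u (u - a)(u - 1) - u v + k0 rho(phi) u + D_u lap(u)
dv/dt = (eps + v mu1 / (u + mu2)) (-v - k u (u - a - 1))
dphi/dt = k1 u - k2 phi + F(x, y, t)
```

with the memductance `rho(phi) = alpha + 3 beta phi^2` of a flux-controlled
memristor.  The feedback term `k0 rho(phi) u` is the induced membrane
current; with `k0 = 0` (or in the package's `baseline` mode, which carries a
stimulus current `I_st` instead) the model reduces to the classical
two-variable cardiac kinetics.  The induction mode deliberately carries no
`I_st` term: the three-variable equations as used here set the stimulus to
zero throughout, and the feedback current takes its structural place.

Parameters (all dimensionless) and defaults: `k=8` (cubic gain), `a=0.15`
(excitation threshold), `eps=0.002` (base recovery rate — `v` is slow),
`mu1=0.2`, `mu2=0.3` (recovery shape), `D_u=1` (diffusion of `u` only),
`alpha=1`, `beta=2` (memductance), `k1=0.5` (flux drive), `k2=1` (flux
leak), `k0=0.1` (induction feedback; the spiral-supporting value, and the
gain most often scanned).

Isolated cells are excitable, not oscillatory: a supra-threshold kick yields
one action potential.  Sustained activity at a node of the medium comes from
wave propagation.  At large `k0` the resting state itself is displaced (at
`k0=0.9` every cell sits at a depolarized equilibrium, `u ≈ 1.35`), which is
the mechanism behind spiral suppression: the medium is "magnetized" into a
homogeneous state.

## Discretization

* Grid: 200×200 nodes, physical side length 350, spacing `dx = 350/200 =
  1.75`.  The Laplacian is the five-point stencil divided by `dx^2`.  Many
  excitable-media codes use unit spacing instead; a `unit_spacing` switch is
  provided, but all defaults, presets and shipped results use the physical
  spacing.  (Both conventions produce the same qualitative regimes; the
  physical reading is the literal one and is the package's default.)
* Boundaries: no-flux via mirror ghost nodes (the ghost copies the value of
  the edge node it faces), giving exactly zero normal gradient.  The stencil
  is assembled neighbor-sum-first so a constant field yields an identically
  zero Laplacian in floating point, and the lattice sum of `u` is conserved
  under pure diffusion to machine precision per step.
* Time: explicit Euler forward, `h = 0.03`, `round(duration/h)` steps.
  Requested snapshot times map to the nearest integer step (`h` does not
  divide 10 or 200 exactly); the actual time is recorded alongside the
  requested one.
* Initial condition: the wedge seed writes three horizontal bands over a
  rest background, with band ranges expressed in 1-based inclusive
  (row, column) notation — `(92:97, 1:115) -> (u,v,phi) = (1.0, 0, 0)`,
  `(98:103, 1:115) -> (0.7, 0.6, 0.1)`, `(104:109, 1:115) -> (0, 0.8, 0.2)`
  — converted internally to 0-based half-open slices.  Rows-first indexing
  is a convention choice (the figures cannot disambiguate it); it is
  configurable by supplying custom bands.
* Degenerate inputs: the recovery rate divides by `u + mu2`; evaluation
  aborts with a domain error when `|u + mu2| < 1e-12` (configurable) rather
  than letting NaNs propagate.  Any field magnitude exceeding `1e6`
  (configurable) aborts with a divergence diagnostic carrying the failing
  time; values are never silently clipped.

## External forcing

Forcing acts on the flux equation only.  A radiation source contributes the
static profile `A exp(-m r)`, `r` the Euclidean distance from its center; a
noise patch contributes independent Gaussian increments on the disk
`r <= radius` (or the whole domain).  Centers and radii are in node-index
units by default (centers like (84, 84) and a radius of 40 live naturally in
the 200×200 index space); a `physical` option scales them by `dx`.
Radiation is static — the profile has no time dependence — and the defaults
encode the two studied exposures: `A=12, m=0.06` at (84, 84) with `k2=1.6`,
and `D=9` on the disk `r<=40` at (60, 60).

### Noise discretization

"Gaussian white noise of intensity D" does not determine a per-step update
rule, so two conventions are implemented:

* `naive` (default): per-step increment `h * D * N(0,1)` added to `phi` — a
  draw of amplitude `D` treated as an ordinary rate, the pattern of classic
  excitable-media codes.
* `em`: Euler–Maruyama increment `sqrt(2 D h) * N(0,1)`, the standard
  discretization of white noise with autocorrelation `2 D delta(t-t')`.

The default is `naive` for a concrete stability reason.  Under `em` at the
study condition (`D=9`, `h=0.03`, `k2=1.6`) the flux at an in-disk node is
an Ornstein–Uhlenbeck process with stationary standard deviation
`sqrt(D/k2) ≈ 2.4`; tail excursions of a few standard deviations push the
memristive gain `k0 rho(phi)` past the explicit-Euler stability bound
`2/h ≈ 67`, and with ~10^8 draws per run such excursions are certain: the
fields diverge within a couple of time units of noise onset.  Long noisy
simulations of this model at these parameters are only possible under the
weaker per-step scaling, which reproduces the reported phenomenology
(spiral breakup into tens of singularities while the unperturbed spiral
keeps its single core).  The `em` mode remains available and carries the
exact `2Dh` increment variance, verified statistically in the tests.

Noise is added to `phi` once per step outside the `h * rate` product.  Each
run draws from a single seeded generator (per-patch private seeds are
optional), and a patch with an onset time consumes no random numbers before
it activates — so a run continued from a checkpoint is bit-identical to an
uninterrupted run.

## Measurements

* **Peaks**: a sample is a peak only if it strictly exceeds both temporal
  neighbors; plateaus and endpoints never count.  Bifurcation scans record
  every post-transient peak amplitude per scanned gain value, so both
  classic all-peaks diagrams and max-only curves are derivable.  The
  transient discarded before peak collection defaults to half the run
  (the diagrams aim at asymptotic amplitudes) and is recorded in the result.
* **Activity labels**: quiescent (≤2 peaks or peak-to-trough amplitude
  < 0.05), periodic (inter-peak intervals and peak values with relative
  dispersion < 5%), multimodal (peak values split into >1 cluster under
  gap-based clustering, gap > 3× the typical within-cluster gap), else
  irregular.  All thresholds are explicit configuration.
* **Phase singularities**: the local phase is `atan2(v - v*, u - u*)` about
  a reference `(u*, v*)` inside the oscillation loop — by default the
  centroid of the monitored node's post-transient trajectory.  A spiral core
  is a 2×2 plaquette whose wrapped phase differences wind by ±2π; counts,
  locations and signed topological charges are reported.  This instrument is
  an addition of this package (a standard excitable-media technique) used to
  make "spiral present / suppressed / broken" operational; the counts for
  turbulent states depend on the reference and on grid resolution and should
  be read as an order of magnitude, not as a sharp statistic.
* **Pattern summary**: a run is summarized as `suppressed` when the spatial
  std of `u` falls below 0.02, `broken` at ≥4 singularities, `spiral` with
  ≥1 singularity and std > 0.1, else `intermediate`.

## Reproducibility and problem sizes

Every run directory stores the fully resolved configuration including the
seed; a fixed seed reproduces a run bit-for-bit, and checkpoint continuation
is bit-identical to an uninterrupted run.  The shipped end-to-end checks use
the full published problem size (200×200 nodes, h=0.03): spiral formation,
suppression and the breakup pair run to t=200 (~6,700 steps each), and the
noise-robustness protocol develops a spiral for 200 time units and continues
to t=800 unperturbed and under five noise seeds (~130,000 field updates in
total, a few minutes on one core).  Verification measurements use smaller
exact oracles: a 16×16 random state against a per-node loop reference, the
closed-form flux relaxation at `h = 1e-4`, and 10^6 noise draws for the
increment variance.

## Limitations

* Explicit Euler only (matching the reference scheme); no implicit or
  adaptive integrators.  Accuracy is first order in `h` (verified by step
  halving against the closed-form flux relaxation).
* Rectangular, isotropic, homogeneous tissue; no fiber anisotropy or
  space-varying parameters.
* The `em` noise convention is unusable at the study intensity for the
  reason above; it is provided for smaller `D·h` products.
* Phase-singularity counts in strongly turbulent states (e.g. `k2 = 0.15`)
  are resolution- and reference-dependent; conclusions should rely on
  orders of magnitude and on comparisons within a fixed convention.
* The model is a qualitative excitable-media caricature: nothing here
  supports claims about real cardiac pathology.
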