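# memfhn

Simulation of electrical activity in two-dimensional cardiac tissue under
electromagnetic induction, with the analysis instruments needed to study
spiral-wave formation, suppression, and breakup.

## The model

Cardiac tissue is modeled as an excitable medium of FitzHugh–Nagumo cells
extended with a magnetic-flux variable.  Each node carries a fast membrane
potential *u*, a slow recovery current *v*, and the magnetic flux *φ* across
the membrane; the flux feeds back into the membrane current through a
flux-controlled memristor with memductance ρ(φ) = α + 3βφ²:

```
∂u/∂t = −k·u(u−a)(u−1) − u·v + k0·ρ(φ)·u + D_u ∇²u
∂v/∂t = (ε + v·μ1/(u+μ2)) · [−v − k·u(u−a−1)]
∂φ/∂t = k1·u − k2·φ + F(x, y, t)
```

The gains k0 (induction feedback), k1 (flux drive) and k2 (flux leak) set
how strongly electromagnetic induction modulates the tissue.  F(x, y, t) is
an optional external electromagnetic exposure: a static radiation profile
A·exp(−m·r) around a center, or Gaussian white noise of intensity D confined
to a disk.  The standard kinetic parameters are k=8, a=0.15, μ1=0.2, μ2=0.3,
ε=0.002, with k1=0.5, k2=1, α=1, β=2 and D_u=1.

Fields live on a 200×200 lattice of physical size 350 (spacing 1.75) and are
advanced by the explicit Euler-forward scheme with time step h=0.03 under
no-flux (mirror-ghost) boundaries.  A three-band "wedge" seed — staggered
stripes of excited, refractory and recovering tissue across the left half of
the domain — breaks the nascent wavefront and nucleates a spiral.

Measurements: strict-local-maximum peak detection on node series (a sample
counts as a peak only when it strictly exceeds both temporal neighbors),
bifurcation scans over the gains, activity classification
(quiescent/periodic/multimodal/irregular), the spatial standard deviation of
*u*, and phase-singularity counting — spiral cores are plaquettes around
which the local phase atan2(v−v*, u−u*) winds by ±2π.

## A worked example

`examples/spiral_formation.py` runs the wedge seed to t=200 at two
induction gains:

```
k0=0.1: at t=200, spatial std(u) = 0.4218, phase singularities = 3
k0=0.9: at t=200, spatial std(u) = 0.0000, phase singularities = 0
```

At k0=0.1 the medium is strongly patterned (std(u) ≈ 0.42) and carries phase
singularities — a rotating spiral wave organizes the tissue.  At k0=0.9 the
induction feedback "magnetizes" the medium: every cell settles at the same
depolarized equilibrium, the field is homogeneous, and no spiral survives.

Other examples cover single-cell dynamics (`single_cell_modes.py`), breakup
vs. standing spirals as the flux leak k2 varies (`flux_leak_regimes.py`),
degradation of a developed spiral under disk-confined noise
(`noise_perturbation.py`), and bifurcation scans (`gain_scan.py`).

## Command line

Every study condition is a named preset (`memfhn presets` lists them):

```
memfhn simulate --preset fig3 -o runs/spiral            # k0=0.1 spiral
memfhn simulate --preset fig3 --set params.k0=0.9 -o runs/suppressed
memfhn scan --param k2 --values 0.15,1.0,3.0 -o runs/k2scan
memfhn analyze --run runs/spiral
```

A run directory contains the resolved `config.yaml` (with seed), the
snapshot stack (`snapshots.h5`), per-node series CSVs, `metrics.json`
(spatial std, singularity census, machine-readable pattern summary), and a
log.  Fixed seed ⇒ bit-for-bit reproducible runs.

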