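"""Robustness of a developed spiral to noisy electromagnetic radiation.

A spiral is first developed from the wedge seed over a 200-time-unit
transient (k2=1.6) and checkpointed.  The run then continues to t=800 twice:
unperturbed, and with Gaussian white noise of intensity D=9 confined to the
disk r<=40 around node (60, 60).  Comparing the phase-singularity census at
t=800 shows whether the noise broke the spiral.  ~50 s total.
"""

from memfhn import (
    ForcingSpec,
    GridSpec,
    ModelParams,
    NoisePatch,
    SamplingPlan,
    count_phase_singularities,
    phase_field,
    phase_reference_from_series,
    simulate,
    spatial_std,
    stripe_seed,
)

params = ModelParams(k0=0.1, k2=1.6)
plan = SamplingPlan(snapshot_times=(), nodes=((99, 99),))

dev = simulate(stripe_seed(), params, GridSpec(duration=200.0), sampling=plan)
print(f"developed spiral at t=200: spatial std(u) = {spatial_std(dev.final_state.u):.3f}")

cont = GridSpec(duration=600.0)


def census(res):
    ref = phase_reference_from_series(res.series[(99, 99)], transient=500.0)
    f = res.final_state
    return count_phase_singularities(phase_field(f.u, f.v, ref)).count


base = simulate(dev.final_state, params, cont, sampling=plan)
print(f"unperturbed continuation, t=800: {census(base)} singularities")

noise = ForcingSpec(noise=(NoisePatch(D=9.0, x0=60.0, y0=60.0, radius=40.0),))
noisy = simulate(dev.final_state, params, cont, forcing=noise, sampling=plan, seed=1)
print(f"disk-noise continuation,  t=800: {census(noisy)} singularities")

print(
    "\nThe unperturbed spiral keeps its single core; under local noise the"
    "\ncore multiplies into tens of singularities - the spiral breaks up and"
    "\nthe noisy region turns turbulent."
)
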