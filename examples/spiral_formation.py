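"""Spiral formation and suppression in the 2D media.

Runs the banded (wedge) seed on the full 200x200 grid at two induction
gains: k0=0.1, where a stable spiral wave develops, and k0=0.9, where the
induction feedback magnetizes the media into a homogeneous state.  Each run
takes a few seconds per 100 time units on one core; total ~20 s.
"""

from memfhn import (
    GridSpec,
    ModelParams,
    SamplingPlan,
    count_phase_singularities,
    phase_field,
    phase_reference_from_series,
    simulate,
    spatial_std,
    stripe_seed,
)

grid = GridSpec(duration=200.0)  # 200x200 nodes, size 350, h=0.03
plan = SamplingPlan(snapshot_times=(), nodes=((99, 99),))

for k0 in (0.1, 0.9):
    res = simulate(stripe_seed(), ModelParams(k0=k0), grid, sampling=plan)
    series = res.series[(99, 99)]
    ref = phase_reference_from_series(series, transient=100.0)
    final = res.final_state
    sing = count_phase_singularities(phase_field(final.u, final.v, ref))
    print(
        f"k0={k0}: at t=200, spatial std(u) = {spatial_std(final.u):.4f}, "
        f"phase singularities = {sing.count}"
    )

print(
    "\nA spatial standard deviation of u well above 0.1 with at least one"
    "\nphase singularity means a rotating spiral organizes the media; a"
    "\nnear-zero std with no singularity means the pattern was suppressed."
)
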