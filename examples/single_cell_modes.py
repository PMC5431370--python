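"""Response of one isolated cell under induction feedback.

Integrates the space-free three-variable kinetics (membrane potential u,
recovery v, magnetic flux phi) at several induction gains k0.  An isolated
cell is excitable, not self-oscillatory: a supra-threshold kick produces one
action potential and the cell returns to a resting state — but the
memristive feedback k0*rho(phi)*u moves that resting state.  (Sustained
spiking at a node of the full media comes from wave propagation; see
examples/spiral_formation.py.)
"""

from memfhn import CellState, ModelParams, detect_peaks, integrate_cell

state0 = CellState(u=0.5, v=0.1, phi=0.0)  # a supra-threshold kick
for k0 in (0.1, 0.4, 0.9):
    params = ModelParams(k0=k0)
    traj = integrate_cell(state0, params, duration=400.0, h=0.01)
    peaks = detect_peaks(traj.u, traj.t)
    print(
        f"k0={k0:4.2f}: {len(peaks):2d} action potential(s), "
        f"max u = {traj.u.max():+.3f}, resting u at t=400: {traj.u[-1]:+.3f}"
    )

print(
    "\nEach cell fires once and settles.  At small k0 it returns to u ~ 0;"
    "\nat k0=0.9 the induction feedback holds the cell at a depolarized"
    "\nequilibrium (u ~ 1.35) - the single-cell signature of the magnetized,"
    "\nhomogeneous state that suppresses spiral waves in the full media."
)
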