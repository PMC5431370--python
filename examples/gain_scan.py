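"""A miniature bifurcation scan of the induction gain k0.

Each scanned value is an independent full-media run; the u-series at the
monitored node is reduced to its post-transient peak amplitudes — the raw
material of a bifurcation diagram — plus an activity label.  Three values
(~30 s); scan presets `fig2_scan`, `fig4_scan`, `fig9_scan` hold the full
published ranges.
"""

from memfhn import GridSpec, ModelParams, bifurcation_scan

grid = GridSpec(duration=200.0)
res = bifurcation_scan("k0", [0.1, 0.4, 0.9], ModelParams(), grid, node=(99, 99))
for k0, peaks, label in zip(res.values, res.peaksets, res.labels):
    vmax = f"{peaks.values.max():.3f}" if len(peaks) else "  n/a"
    print(
        f"k0={k0:4.2f}: {len(peaks):3d} post-transient peaks, "
        f"max peak u = {vmax}, activity: {label}"
    )

print(
    "\nThe set of peak amplitudes per gain value is one column of the"
    "\nbifurcation diagram: many distinct amplitudes indicate multimodal or"
    "\nchaotic-like activity, a single repeated amplitude a periodic rhythm,"
    "\nand no peaks a quiescent (suppressed) media."
)
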