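"""Run execution and on-disk artifacts.

``run_config``/``run_preset`` execute a simulation and populate a run
directory with everything needed to reproduce and inspect it:

* ``config.yaml`` — the fully resolved configuration (including the seed);
* ``snapshots.h5`` — the snapshot stack (u, v, phi per requested time) with
  a plain-text JSON header of the parameters and grid;
* ``series_r<row>_c<col>.csv`` — per-node time series (t, u, v, phi);
* ``metrics.json`` — pattern metrics per snapshot and a machine-readable
  summary (spiral present / suppressed / broken / intermediate);
* ``run.log`` — wall time, step count, and any warnings;
* optional PNG renders of the u-field snapshots (human inspection only).
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import __version__
from .analysis import (
    classify_activity,
    detect_peaks,
    pattern_metrics,
    phase_reference_from_series,
)
from .config import SimulationConfig, config_to_dict, save_config
from .media_grid import SimulationResult, simulate
from .presets import get_preset

__all__ = [
    "run_config",
    "run_preset",
    "render_snapshot",
    "summarize_result",
    "write_run_dir",
]

#: classification thresholds for the run summary (documented defaults):
#: a patterned medium has spatial std(u) above SPIRAL_STD and at least one
#: phase singularity; a suppressed (near-homogeneous) one falls below
#: SUPPRESSED_STD; BROKEN_COUNT or more singularities count as breakup.
SPIRAL_STD = 0.1
SUPPRESSED_STD = 0.02
BROKEN_COUNT = 4


def summarize_result(result: SimulationResult, transient: float | None = None) -> dict:
    """Machine-readable qualitative summary of the final state.

    Uses the phase reference derived from the first monitored node's
    post-transient trajectory centroid.
    """
    if transient is None:
        transient = 0.5 * result.grid.duration
    node = next(iter(result.series))
    series = result.series[node]
    reference = phase_reference_from_series(series, transient=transient)
    final = result.final_state
    metrics = pattern_metrics(
        final.u, final.v, reference, node_series=series, transient=transient
    )
    post = series.t >= series.t[0] + transient
    peaks = detect_peaks(series.u, series.t, transient=series.t[0] + transient)
    label = classify_activity(peaks, series.u[post])
    std = metrics.spatial_std_u
    count = metrics.singularities.count
    if std < SUPPRESSED_STD:
        pattern = "suppressed"
    elif count >= BROKEN_COUNT:
        pattern = "broken"
    elif count >= 1 and std > SPIRAL_STD:
        pattern = "spiral"
    else:
        pattern = "intermediate"
    return {
        "t_final": final.t,
        "spatial_std_u": std,
        "singularity_count": count,
        "net_topological_charge": metrics.singularities.net_charge,
        "node": list(node),
        "node_activity": label,
        "dominant_period": metrics.period,
        "phase_reference": list(reference),
        "pattern": pattern,
    }


def write_run_dir(
    result: SimulationResult,
    cfg: SimulationConfig,
    outdir: str | Path,
    render: bool = False,
    elapsed: float | None = None,
) -> Path:
    """Write all artifacts of a finished run into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_config(cfg, outdir / "config.yaml")

    with h5py.File(outdir / "snapshots.h5", "w") as f:
        f.attrs["format"] = "memfhn-snapshots"
        f.attrs["code_version"] = __version__
        f.attrs["header_json"] = json.dumps(config_to_dict(cfg))
        for i, snap in enumerate(result.snapshots):
            g = f.create_group(f"snapshot_{i:03d}")
            g.attrs["t_requested"] = snap.t_requested
            g.attrs["t_actual"] = snap.t_actual
            g.create_dataset("u", data=snap.state.u)
            g.create_dataset("v", data=snap.state.v)
            g.create_dataset("phi", data=snap.state.phi)
        g = f.create_group("final")
        g.attrs["t_actual"] = result.final_state.t
        g.create_dataset("u", data=result.final_state.u)
        g.create_dataset("v", data=result.final_state.v)
        g.create_dataset("phi", data=result.final_state.phi)

    for node, s in result.series.items():
        df = pd.DataFrame({"t": s.t, "u": s.u, "v": s.v, "phi": s.phi})
        df.to_csv(outdir / f"series_r{node[0]}_c{node[1]}.csv", index=False)

    transient = 0.5 * result.grid.duration
    node = next(iter(result.series))
    reference = phase_reference_from_series(result.series[node], transient=transient)
    per_snapshot = []
    for snap in result.snapshots:
        m = pattern_metrics(snap.state.u, snap.state.v, reference)
        per_snapshot.append(
            {
                "t_requested": snap.t_requested,
                "t_actual": snap.t_actual,
                "spatial_std_u": m.spatial_std_u,
                "singularity_count": m.singularities.count,
                "net_topological_charge": m.singularities.net_charge,
            }
        )
    metrics = {
        "summary": summarize_result(result),
        "snapshots": per_snapshot,
        "seed": cfg.seed,
        "code_version": __version__,
    }
    (outdir / "metrics.json").write_text(json.dumps(metrics, indent=2))

    log_lines = [
        f"memfhn {__version__}",
        f"steps: {result.n_steps}",
        f"grid: {result.grid.n_rows}x{result.grid.n_cols}, h={result.grid.h}",
        f"seed: {cfg.seed}",
        f"pattern: {metrics['summary']['pattern']}",
    ]
    if elapsed is not None:
        log_lines.insert(1, f"wall time: {elapsed:.1f} s")
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")

    if render:
        for i, snap in enumerate(result.snapshots):
            render_snapshot(
                snap.state.u, outdir / f"u_t{snap.t_requested:g}.png",
                title=f"u at t={snap.t_actual:.2f}",
            )
    return outdir


def run_config(
    cfg: SimulationConfig,
    outdir: str | Path | None = None,
    render: bool = False,
) -> tuple[SimulationResult, dict]:
    """Execute a resolved config; optionally write the run directory.

    Returns the in-memory result and its summary.  On simulation failure the
    partial artifacts (config, failure marker) are still written when an
    output directory was given.
    """
    t0 = time.perf_counter()
    try:
        result = simulate(
            cfg.recipe,
            cfg.params,
            cfg.grid,
            forcing=cfg.forcing,
            sampling=cfg.sampling,
            mode=cfg.mode,  # type: ignore[arg-type]
            seed=cfg.seed,
        )
    except Exception as exc:
        if outdir is not None:
            out = Path(outdir)
            out.mkdir(parents=True, exist_ok=True)
            save_config(cfg, out / "config.yaml")
            (out / "FAILED").write_text(f"{type(exc).__name__}: {exc}\n")
        raise
    elapsed = time.perf_counter() - t0
    summary = summarize_result(result)
    if outdir is not None:
        write_run_dir(result, cfg, outdir, render=render, elapsed=elapsed)
    return result, summary


def run_preset(
    name: str,
    overrides: dict | None = None,
    outdir: str | Path | None = None,
    render: bool = False,
) -> tuple[SimulationResult, dict]:
    """Execute a named experiment preset with optional dotted overrides."""
    cfg = get_preset(name).config
    if overrides:
        cfg = cfg.override(overrides)
    return run_config(cfg, outdir=outdir, render=render)


def render_snapshot(
    field: np.ndarray,
    path: str | Path,
    vmin: float | None = None,
    vmax: float | None = None,
    title: str | None = None,  # kept for API symmetry; pixel renders have no text
) -> Path:
    """Color raster of one field, exactly one pixel per node.

    For human inspection only; never used as a numeric artifact.  The value
    range is fixed by ``vmin``/``vmax`` (defaulting to the field's own range,
    or a degenerate +-0.5 band around a constant field).
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    field = np.asarray(field, dtype=float)
    if vmin is None:
        vmin = float(field.min())
    if vmax is None:
        vmax = float(field.max())
    if vmax <= vmin:
        vmin, vmax = vmin - 0.5, vmax + 0.5
    path = Path(path)
    plt.imsave(path, field, vmin=vmin, vmax=vmax, cmap="jet", origin="lower")
    return path
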