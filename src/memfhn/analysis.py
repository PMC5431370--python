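"""Measurement instruments for the simulated media.

* strict-local-maximum peak detection on node time series (a peak is a
  sample strictly above both its temporal neighbors);
* bifurcation scans of the induction gains (k0, k1, k2) recording all
  post-transient peak amplitudes at a monitored node;
* activity classification of a node series into quiescent / periodic /
  multimodal / irregular;
* spatial-pattern metrics: the spatial standard deviation of u, and
  phase-singularity (spiral core) detection by topological charge.

The phase instruments are a standard excitable-media addition that makes
"spiral present", "suppressed" and "broken up / turbulent" operational: the
local phase is ``atan2(v - v*, u - u*)`` about a reference point inside the
oscillation loop, and a spiral core is a plaquette around which the phase
winds by +-2*pi.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .media_grid import (
    GridSpec,
    InitialConditionRecipe,
    NodeSeries,
    SamplingPlan,
    simulate,
    stripe_seed,
)
from .model_core import ModelParams

__all__ = [
    "PeakSet",
    "ActivityThresholds",
    "BifurcationResult",
    "PhaseSingularities",
    "PatternMetrics",
    "detect_peaks",
    "classify_activity",
    "bifurcation_scan",
    "spatial_std",
    "phase_field",
    "phase_reference_from_series",
    "count_phase_singularities",
    "pattern_metrics",
    "dominant_period",
]

ActivityLabel = Literal["quiescent", "periodic", "multimodal", "irregular"]


@dataclass
class PeakSet:
    """Detected strict local maxima of a scalar series."""

    times: np.ndarray
    values: np.ndarray
    indices: np.ndarray

    def __len__(self) -> int:
        return self.times.size

    @property
    def intervals(self) -> np.ndarray:
        """Inter-peak intervals."""
        return np.diff(self.times)


def detect_peaks(
    values: np.ndarray | Sequence[float],
    times: np.ndarray | Sequence[float] | None = None,
    transient: float = 0.0,
) -> PeakSet:
    """Strict local maxima of a uniformly sampled series, after a transient.

    A sample is a peak only when it strictly exceeds both the pre-adjacent
    and the post-adjacent sample; plateaus and endpoints are never peaks.
    Samples with ``t < transient`` are discarded before detection.

    Raises
    ------
    ValueError
        if no samples remain after the transient discard.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError(f"series must be 1-D, got shape {x.shape}")
    t = np.arange(x.size, dtype=float) if times is None else np.asarray(times, dtype=float)
    if t.shape != x.shape:
        raise ValueError(f"times shape {t.shape} != values shape {x.shape}")
    keep = t >= transient
    if not keep.any():
        raise ValueError(f"no samples remain after discarding transient t < {transient}")
    start = int(np.argmax(keep))  # series is time-ordered
    x_post = x[start:]
    t_post = t[start:]
    if x_post.size < 3:
        return PeakSet(np.empty(0), np.empty(0), np.empty(0, dtype=int))
    inner = (x_post[1:-1] > x_post[:-2]) & (x_post[1:-1] > x_post[2:])
    idx = np.flatnonzero(inner) + 1
    return PeakSet(t_post[idx], x_post[idx], idx + start)


@dataclass(frozen=True)
class ActivityThresholds:
    """Explicit knobs of the activity classifier.

    amplitude_floor : peak-to-trough amplitude below which the series is
        quiescent (sub-threshold ripple).
    min_peaks : a series with at most this many post-transient peaks is
        quiescent (a decaying transient can leave a stray maximum).
    rel_dispersion : relative dispersion bound under which inter-peak
        intervals and peak values count as constant (periodic).
    cluster_gap_factor : a gap between sorted peak values larger than this
        multiple of the within-cluster spread splits clusters (multimodal).
    """

    amplitude_floor: float = 0.05
    min_peaks: int = 2
    rel_dispersion: float = 0.05
    cluster_gap_factor: float = 3.0


def _cluster_count(values: np.ndarray, gap_factor: float, floor: float) -> int:
    """1-D gap clustering: count clusters of sorted values.

    A consecutive gap splits clusters when it exceeds ``gap_factor`` times
    the typical (median) non-zero gap and also exceeds ``floor`` (so
    numerically identical values never split).
    """
    if values.size <= 1:
        return min(values.size, 1)
    s = np.sort(values)
    gaps = np.diff(s)
    typical = np.median(gaps)
    threshold = max(gap_factor * typical, floor)
    return int(np.count_nonzero(gaps > threshold)) + 1


def classify_activity(
    peaks: PeakSet,
    series: np.ndarray | Sequence[float],
    thresholds: ActivityThresholds | None = None,
) -> ActivityLabel:
    """Label the post-transient activity of a node series.

    quiescent : too few peaks, or peak-to-trough amplitude below the floor.
    periodic : inter-peak intervals and peak values both nearly constant.
    multimodal : peak values fall into more than one cluster (e.g. the
        alternating large/small spikes of a period-doubled rhythm).
    irregular : everything else (chaotic-like series).

    The classifier is a pure function of its arguments.
    """
    th = thresholds or ActivityThresholds()
    x = np.asarray(series, dtype=float)
    amplitude = float(x.max() - x.min()) if x.size else 0.0
    if len(peaks) <= th.min_peaks or amplitude < th.amplitude_floor:
        return "quiescent"
    intervals = peaks.intervals
    vals = peaks.values
    int_disp = float(np.std(intervals) / np.mean(intervals))
    val_disp = float(np.std(vals) / max(amplitude, 1e-300))
    if int_disp < th.rel_dispersion and val_disp < th.rel_dispersion:
        return "periodic"
    n_clusters = _cluster_count(
        vals, th.cluster_gap_factor, th.rel_dispersion * amplitude
    )
    if n_clusters > 1:
        # multimodal only if the within-cluster structure is tight enough to
        # count as distinct modes rather than a continuum
        return "multimodal"
    return "irregular"


@dataclass
class BifurcationResult:
    """Per-parameter-value peak sets from independent full-media runs."""

    param: str
    values: np.ndarray
    peaksets: list[PeakSet]
    labels: list[ActivityLabel]
    node: tuple[int, int]
    transient: float
    failures: dict[int, str]  # value index -> error message

    def peaks_table(self):
        """Long-format (param_value, peak_time, peak_value) pandas DataFrame."""
        import pandas as pd

        rows = []
        for val, ps in zip(self.values, self.peaksets):
            for t, x in zip(ps.times, ps.values):
                rows.append((val, t, x))
        return pd.DataFrame(rows, columns=[self.param, "t", "peak_value"])


def bifurcation_scan(
    param: str,
    values: Sequence[float],
    params: ModelParams,
    grid: GridSpec,
    recipe: InitialConditionRecipe | None = None,
    node: tuple[int, int] = (99, 99),
    transient: float | None = None,
    mode: str = "induction",
    thresholds: ActivityThresholds | None = None,
    seed: int | None = None,
) -> BifurcationResult:
    """Scan one induction gain, one independent full-media run per value.

    Every value is simulated from the same initial recipe (default: the
    standard stripe seed); the u-series at the monitored node is reduced to
    its post-transient :class:`PeakSet` and activity label.  ``transient``
    defaults to half the run duration (the diagrams aim at asymptotic
    amplitudes).  A run that fails (divergence, domain guard) is recorded in
    ``failures`` without aborting the scan.
    """
    if param not in ("k0", "k1", "k2"):
        raise ValueError(f"scan parameter must be one of k0/k1/k2, got {param!r}")
    if recipe is None:
        recipe = stripe_seed()
    if transient is None:
        transient = 0.5 * grid.duration
    sampling = SamplingPlan(snapshot_times=(), nodes=(node,), stride=1)
    peaksets: list[PeakSet] = []
    labels: list[ActivityLabel] = []
    failures: dict[int, str] = {}
    empty = PeakSet(np.empty(0), np.empty(0), np.empty(0, dtype=int))
    for i, val in enumerate(values):
        p_i = params.with_(**{param: float(val)})
        try:
            res = simulate(recipe, p_i, grid, sampling=sampling, mode=mode, seed=seed)
        except Exception as exc:
            failures[i] = f"{type(exc).__name__}: {exc}"
            peaksets.append(empty)
            labels.append("quiescent")
            continue
        ns = res.series[node]
        ps = detect_peaks(ns.u, ns.t, transient=transient)
        post = ns.t >= transient
        peaksets.append(ps)
        labels.append(classify_activity(ps, ns.u[post], thresholds))
    return BifurcationResult(
        param=param,
        values=np.asarray(values, dtype=float),
        peaksets=peaksets,
        labels=labels,
        node=node,
        transient=transient,
        failures=failures,
    )


# ---------------------------------------------------------------------------
# Spatial pattern metrics

def spatial_std(field: np.ndarray) -> float:
    """Standard deviation of a field over all nodes (population convention).

    Near zero for a homogeneous (magnetized or resting) medium; large for
    patterned states.
    """
    return float(np.std(np.asarray(field, dtype=float)))


def phase_reference_from_series(
    series: NodeSeries, transient: float = 0.0
) -> tuple[float, float]:
    """(u*, v*) reference: centroid of a node's post-transient (u, v) loop."""
    post = series.t >= transient
    if not post.any():
        post = slice(None)
    return float(np.mean(series.u[post])), float(np.mean(series.v[post]))


def phase_field(
    u_field: np.ndarray,
    v_field: np.ndarray,
    reference: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Local phase atan2(v - v*, u - u*) in (-pi, pi] at every node.

    The reference (u*, v*) must sit inside the oscillation loop for the
    phase to be meaningful; the centroid of a monitored node's trajectory
    (:func:`phase_reference_from_series`) is the usual choice.  The phase of
    an exactly zero displacement is defined as 0.
    """
    u_ref, v_ref = reference
    return np.arctan2(v_field - v_ref, u_field - u_ref)


@dataclass
class PhaseSingularities:
    """Spiral cores found by the plaquette winding-number test."""

    count: int
    locations: np.ndarray  # (n, 2) plaquette centers as (row, col)
    charges: np.ndarray  # (n,) topological charges, +-1

    @property
    def net_charge(self) -> int:
        return int(self.charges.sum())


def _wrap(angle: np.ndarray) -> np.ndarray:
    """Wrap angles to [-pi, pi)."""
    return (angle + np.pi) % (2.0 * np.pi) - np.pi


def count_phase_singularities(phase: np.ndarray) -> PhaseSingularities:
    """Count phase singularities by the winding of phase around 2x2 plaquettes.

    For every 2x2 plaquette the four wrapped phase differences around the
    loop are summed; the sum is 0 for smooth phase and +-2*pi around a
    spiral core (topological charge +-1).  Returns the total count, the
    plaquette centers (row+0.5, col+0.5), and the individual charges.
    """
    p = np.asarray(phase, dtype=float)
    if p.ndim != 2 or p.shape[0] < 2 or p.shape[1] < 2:
        raise ValueError(f"phase field must be at least 2x2, got shape {p.shape}")
    # corners: a=(i,j) b=(i,j+1) c=(i+1,j+1) d=(i+1,j), loop a->b->c->d->a
    a = p[:-1, :-1]
    b = p[:-1, 1:]
    c = p[1:, 1:]
    d = p[1:, :-1]
    winding = _wrap(b - a) + _wrap(c - b) + _wrap(d - c) + _wrap(a - d)
    charge = np.rint(winding / (2.0 * np.pi)).astype(int)
    rows, cols = np.nonzero(charge)
    locations = np.column_stack([rows + 0.5, cols + 0.5])
    return PhaseSingularities(
        count=int(rows.size), locations=locations, charges=charge[rows, cols]
    )


def dominant_period(peaks: PeakSet) -> float | None:
    """Median inter-peak interval, or None with fewer than two peaks."""
    if len(peaks) < 2:
        return None
    return float(np.median(peaks.intervals))


@dataclass
class PatternMetrics:
    """Summary metrics of one field snapshot (plus optional node series)."""

    spatial_std_u: float
    singularities: PhaseSingularities
    period: float | None
    reference: tuple[float, float]


def pattern_metrics(
    u_field: np.ndarray,
    v_field: np.ndarray,
    reference: tuple[float, float],
    node_series: NodeSeries | None = None,
    transient: float = 0.0,
) -> PatternMetrics:
    """Spatial std of u, singularity census, and the monitored node's period."""
    phase = phase_field(u_field, v_field, reference)
    sing = count_phase_singularities(phase)
    period = None
    if node_series is not None:
        ps = detect_peaks(node_series.u, node_series.t, transient=transient)
        period = dominant_period(ps)
    return PatternMetrics(
        spatial_std_u=spatial_std(u_field),
        singularities=sing,
        period=period,
        reference=reference,
    )
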