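"""Spatially extended memristive FitzHugh-Nagumo media.

A rectangular lattice of cells coupled by diffusion of the membrane
potential, integrated with the explicit Euler-forward scheme under no-flux
(zero normal gradient) boundary conditions.  The defaults reproduce the
standard numerical setting: a 200 x 200 node grid of physical size 350
(node spacing 350/200 = 1.75) with time step h = 0.03.

The module provides the five-point no-flux Laplacian, a single field-update
``step``, initial-condition recipes (notably the three-band "stripe" or
wedge seed that nucleates a spiral), a ``simulate`` driver with snapshot and
node-series sampling, and HDF5 checkpointing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import h5py
import numpy as np

from .model_core import (
    DEFAULT_BLOWUP,
    DEFAULT_GUARD,
    DivergenceError,
    DomainGuardError,
    Mode,
    ModelParams,
    _dphi,
    _du,
    _dv,
)

__all__ = [
    "GridSpec",
    "MediaState",
    "Band",
    "InitialConditionRecipe",
    "SamplingPlan",
    "NodeSeries",
    "Snapshot",
    "SimulationResult",
    "CheckpointError",
    "PAPER_BANDS",
    "stripe_seed",
    "homogeneous",
    "from_checkpoint",
    "build_initial_state",
    "laplacian_noflux",
    "step",
    "simulate",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_FORMAT_VERSION = 1


class CheckpointError(IOError):
    """Raised on a missing, corrupt, or shape-mismatched checkpoint file."""


@dataclass(frozen=True)
class GridSpec:
    """Grid geometry and integrator settings.

    ``dx`` is derived as ``L / n_cols`` (isotropic spacing; the standard
    grid is square).  With ``unit_spacing=True`` the stencil uses dx = 1
    regardless of L, the convention of many excitable-media codes that
    ignore physical spacing.
    """

    n_rows: int = 200
    n_cols: int = 200
    L: float = 350.0
    h: float = 0.03
    duration: float = 200.0
    unit_spacing: bool = False

    def __post_init__(self) -> None:
        if self.n_rows < 3 or self.n_cols < 3:
            raise ValueError(
                f"grid must be at least 3x3, got {self.n_rows}x{self.n_cols}"
            )
        if self.L <= 0:
            raise ValueError(f"L must be > 0, got {self.L}")
        if self.h <= 0:
            raise ValueError(f"h must be > 0, got {self.h}")
        if self.duration <= 0:
            raise ValueError(f"duration must be > 0, got {self.duration}")

    @property
    def dx(self) -> float:
        return 1.0 if self.unit_spacing else self.L / self.n_cols

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_steps(self) -> int:
        return round(self.duration / self.h)


@dataclass
class MediaState:
    """The three fields (u, v, phi) on the lattice plus the current time."""

    u: np.ndarray
    v: np.ndarray
    phi: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        if not (self.u.shape == self.v.shape == self.phi.shape):
            raise ValueError(
                f"field shapes differ: u{self.u.shape} v{self.v.shape} "
                f"phi{self.phi.shape}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.u.shape

    def copy(self) -> "MediaState":
        return MediaState(self.u.copy(), self.v.copy(), self.phi.copy(), self.t)


# ---------------------------------------------------------------------------
# Initial conditions

@dataclass(frozen=True)
class Band:
    """A rectangular band of the seed, in 1-based inclusive (row, col) ranges.

    The 1-based inclusive convention mirrors how such recipes are printed
    (e.g. ``u(92:97, 1:115) = 1.0``); conversion to 0-based half-open numpy
    slices happens in :func:`build_initial_state`.
    """

    rows: tuple[int, int]
    cols: tuple[int, int]
    u: float
    v: float
    phi: float


#: The standard three-band wedge seed on a rest background: three horizontal
#: stripes across the left half of the domain whose staggered recovery
#: state breaks the nascent wavefront and nucleates a spiral.
PAPER_BANDS: tuple[Band, ...] = (
    Band(rows=(92, 97), cols=(1, 115), u=1.0, v=0.0, phi=0.0),
    Band(rows=(98, 103), cols=(1, 115), u=0.7, v=0.6, phi=0.1),
    Band(rows=(104, 109), cols=(1, 115), u=0.0, v=0.8, phi=0.2),
)


@dataclass(frozen=True)
class InitialConditionRecipe:
    kind: Literal["stripe_seed", "homogeneous", "from_checkpoint"] = "stripe_seed"
    bands: tuple[Band, ...] = PAPER_BANDS
    background: tuple[float, float, float] = (0.0, 0.0, 0.0)
    constant: tuple[float, float, float] = (0.0, 0.0, 0.0)
    checkpoint_path: str | None = None


def stripe_seed(
    bands: Sequence[Band] = PAPER_BANDS,
    background: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> InitialConditionRecipe:
    """The banded wedge seed (default: the standard three bands)."""
    return InitialConditionRecipe(
        kind="stripe_seed", bands=tuple(bands), background=background
    )


def homogeneous(u: float = 0.0, v: float = 0.0, phi: float = 0.0) -> InitialConditionRecipe:
    return InitialConditionRecipe(kind="homogeneous", constant=(u, v, phi))


def from_checkpoint(path: str | Path) -> InitialConditionRecipe:
    return InitialConditionRecipe(kind="from_checkpoint", checkpoint_path=str(path))


def build_initial_state(recipe: InitialConditionRecipe, grid: GridSpec) -> MediaState:
    """Materialize an initial-condition recipe on a grid.

    Band index ranges are 1-based inclusive in (row, column) order and are
    converted here to 0-based half-open slices: rows ``(lo, hi)`` become
    ``[lo-1 : hi]``.
    """
    if recipe.kind == "homogeneous":
        cu, cv, cphi = recipe.constant
        return MediaState(
            np.full(grid.shape, float(cu)),
            np.full(grid.shape, float(cv)),
            np.full(grid.shape, float(cphi)),
            t=0.0,
        )
    if recipe.kind == "from_checkpoint":
        if recipe.checkpoint_path is None:
            raise ValueError("from_checkpoint recipe requires checkpoint_path")
        return load_checkpoint(recipe.checkpoint_path, expected_grid=grid)
    if recipe.kind == "stripe_seed":
        bu, bv, bphi = recipe.background
        u = np.full(grid.shape, float(bu))
        v = np.full(grid.shape, float(bv))
        phi = np.full(grid.shape, float(bphi))
        for band in recipe.bands:
            r0, r1 = band.rows
            c0, c1 = band.cols
            if not (1 <= r0 <= r1 <= grid.n_rows and 1 <= c0 <= c1 <= grid.n_cols):
                raise ValueError(
                    f"band rows={band.rows} cols={band.cols} outside the "
                    f"{grid.n_rows}x{grid.n_cols} grid (1-based inclusive)"
                )
            sl = (slice(r0 - 1, r1), slice(c0 - 1, c1))
            u[sl] = band.u
            v[sl] = band.v
            phi[sl] = band.phi
        return MediaState(u, v, phi, t=0.0)
    raise ValueError(f"unknown recipe kind {recipe.kind!r}")


# ---------------------------------------------------------------------------
# Discrete operators and the field update

def laplacian_noflux(field: np.ndarray, dx: float) -> np.ndarray:
    """Five-point Laplacian with mirror-ghost (zero normal gradient) edges.

    Ghost nodes copy the value of the edge node they face, so the normal
    gradient across every boundary is exactly zero and the lattice sum of
    the stencil vanishes identically (no flux leaves the domain).
    """
    if field.ndim != 2 or field.shape[0] < 3 or field.shape[1] < 3:
        raise ValueError(f"field must be at least 3x3, got shape {field.shape}")
    f = field
    # neighbor sum first, 4*center subtracted last: a constant field then
    # cancels exactly (x+x+x+x == 4x in IEEE double), so the stencil of a
    # constant is identically zero
    lap = np.zeros_like(f)
    lap[1:, :] += f[:-1, :]
    lap[0, :] += f[0, :]
    lap[:-1, :] += f[1:, :]
    lap[-1, :] += f[-1, :]
    lap[:, 1:] += f[:, :-1]
    lap[:, 0] += f[:, 0]
    lap[:, :-1] += f[:, 1:]
    lap[:, -1] += f[:, -1]
    lap -= 4.0 * f
    lap /= dx * dx
    return lap


def step(
    state: MediaState,
    params: ModelParams,
    grid: GridSpec,
    forcing_field: np.ndarray | float = 0.0,
    noise: np.ndarray | None = None,
    mode: Mode = "induction",
    reaction: bool = True,
    guard: float = DEFAULT_GUARD,
    blowup: float = DEFAULT_BLOWUP,
) -> MediaState:
    """One Euler-forward update of the three fields.

    Updates::

        u   <- u   + h * (rate_u + D_u * laplacian(u))
        v   <- v   + h * rate_v
        phi <- phi + h * (k1*u - k2*phi + forcing_field) + noise

    ``forcing_field`` is the deterministic external flux drive at time t
    (lattice or scalar); ``noise`` is an already-scaled per-step stochastic
    increment added to phi outside the ``h * rate`` product, as in the
    Euler-Maruyama scheme.  ``reaction=False`` disables all reaction terms
    and the flux drive, leaving pure diffusion of u — a diagnostic used to
    check conservation under the no-flux boundary.

    Raises
    ------
    DomainGuardError
        if any node has ``|u + mu2| < guard``.
    DivergenceError
        if any updated field magnitude exceeds ``blowup``.
    """
    if state.shape != grid.shape:
        raise ValueError(f"state shape {state.shape} != grid shape {grid.shape}")
    h = grid.h
    u, v, phi = state.u, state.v, state.phi
    lap_u = laplacian_noflux(u, grid.dx)
    if reaction:
        denom_min = np.abs(u + params.mu2).min()
        if denom_min < guard:
            raise DomainGuardError(
                f"|u + mu2| fell below guard {guard:g} at t={state.t!r} "
                f"(min {denom_min:g})"
            )
        u2 = u + h * (_du(u, v, phi, params, mode) + params.D_u * lap_u)
        v2 = v + h * _dv(u, v, params)
        phi2 = phi + h * _dphi(u, phi, params, forcing_field)
    else:
        u2 = u + h * (params.D_u * lap_u)
        v2 = v.copy()
        phi2 = phi.copy()
    if noise is not None:
        phi2 += noise
    t2 = state.t + h
    m = max(np.abs(u2).max(), np.abs(v2).max(), np.abs(phi2).max())
    if not (m <= blowup):  # also catches NaN
        raise DivergenceError(
            f"field magnitude {m:.3g} exceeded blow-up bound {blowup:g} "
            f"at t={t2:.6g}",
            t=t2,
        )
    return MediaState(u2, v2, phi2, t2)


# ---------------------------------------------------------------------------
# Simulation driver

@dataclass(frozen=True)
class SamplingPlan:
    """What to record during a run.

    snapshot_times are mapped to the nearest integer step (h rarely divides
    the requested times exactly).  Monitored nodes are 0-based (row, col)
    indices; the default (99, 99) is the standard probe near the domain
    center.  ``stride`` thins the per-node time series.
    """

    snapshot_times: tuple[float, ...] = (10.0, 60.0, 100.0, 200.0)
    nodes: tuple[tuple[int, int], ...] = ((99, 99),)
    stride: int = 1

    def __post_init__(self) -> None:
        if self.stride < 1:
            raise ValueError(f"stride must be >= 1, got {self.stride}")


@dataclass
class NodeSeries:
    """Per-step (possibly strided) time series of one monitored node."""

    node: tuple[int, int]
    t: np.ndarray
    u: np.ndarray
    v: np.ndarray
    phi: np.ndarray


@dataclass
class Snapshot:
    t_requested: float
    t_actual: float
    state: MediaState


@dataclass
class SimulationResult:
    final_state: MediaState
    snapshots: list[Snapshot]
    series: dict[tuple[int, int], NodeSeries]
    params: ModelParams
    grid: GridSpec
    mode: str
    seed: int | None
    n_steps: int


def simulate(
    recipe: InitialConditionRecipe | MediaState,
    params: ModelParams,
    grid: GridSpec,
    forcing=None,
    sampling: SamplingPlan | None = None,
    mode: Mode = "induction",
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    guard: float = DEFAULT_GUARD,
    blowup: float = DEFAULT_BLOWUP,
) -> SimulationResult:
    """Run the spatial model for ``grid.duration`` time units.

    Parameters
    ----------
    recipe : an :class:`InitialConditionRecipe`, or directly a
        :class:`MediaState` (e.g. a loaded checkpoint) to continue from.
        A provided state keeps its own ``t``; the run then covers
        ``grid.duration`` additional time units.
    forcing : a :class:`memfhn.forcing.ForcingSpec` or None.  Radiation
        profiles act as a static deterministic drive on phi; noise patches
        add per-step stochastic increments drawn from ``rng``.
    sampling : snapshot times and monitored nodes; defaults to snapshots at
        t = 10, 60, 100, 200 with node (99, 99) monitored every step.
        Snapshot times are relative to the start time of this run.
    seed : seeds a fresh generator when ``rng`` is not given.  With a fixed
        seed the entire run is reproducible bit-for-bit.
    rng : an explicit generator; lets a caller continue an existing noise
        stream (checkpoint continuation is then bit-identical to an
        uninterrupted run).

    Raises
    ------
    DivergenceError, DomainGuardError
        propagated from :func:`step`, with the failing time attached.
    """
    from .forcing import ForcingContext  # local import to avoid a cycle

    if sampling is None:
        sampling = SamplingPlan()
    if isinstance(recipe, MediaState):
        state = recipe.copy()
    else:
        state = build_initial_state(recipe, grid)
    if state.shape != grid.shape:
        raise ValueError(f"initial state shape {state.shape} != grid {grid.shape}")
    for r, c in sampling.nodes:
        if not (0 <= r < grid.n_rows and 0 <= c < grid.n_cols):
            raise ValueError(f"monitored node {(r, c)} outside the grid")

    if rng is None:
        rng = np.random.default_rng(seed)
    ctx = ForcingContext(forcing, grid, rng) if forcing is not None else None

    n_steps = grid.n_steps
    h = grid.h
    t0 = state.t
    # map requested snapshot times (relative to t0) to step indices
    snap_steps: dict[int, list[float]] = {}
    for ts in sampling.snapshot_times:
        k = int(round(ts / h))
        k = min(max(k, 0), n_steps)
        snap_steps.setdefault(k, []).append(ts)

    rec_steps = set(range(0, n_steps + 1, sampling.stride))
    rec_steps.add(n_steps)
    n_rec = len(rec_steps)
    buf_t = np.empty(n_rec)
    buf = {
        node: (np.empty(n_rec), np.empty(n_rec), np.empty(n_rec))
        for node in sampling.nodes
    }
    snapshots: list[Snapshot] = []

    def record(i_rec: int, st: MediaState) -> None:
        buf_t[i_rec] = st.t
        for node, (bu, bv, bphi) in buf.items():
            bu[i_rec] = st.u[node]
            bv[i_rec] = st.v[node]
            bphi[i_rec] = st.phi[node]

    i_rec = 0
    if 0 in rec_steps:
        record(0, state)
        i_rec = 1
    for ts in snap_steps.get(0, []):
        snapshots.append(Snapshot(ts, state.t, state.copy()))

    for k in range(1, n_steps + 1):
        det: np.ndarray | float = 0.0
        noise = None
        if ctx is not None:
            det = ctx.deterministic
            noise = ctx.sample_noise(state.t)
        state = step(
            state, params, grid, forcing_field=det, noise=noise,
            mode=mode, guard=guard, blowup=blowup,
        )
        if k in rec_steps:
            record(i_rec, state)
            i_rec += 1
        for ts in snap_steps.get(k, []):
            snapshots.append(Snapshot(ts, state.t, state.copy()))

    series = {
        node: NodeSeries(node, buf_t.copy(), bu, bv, bphi)
        for node, (bu, bv, bphi) in buf.items()
    }
    snapshots.sort(key=lambda s: s.t_requested)
    return SimulationResult(
        final_state=state,
        snapshots=snapshots,
        series=series,
        params=params,
        grid=grid,
        mode=mode,
        seed=seed,
        n_steps=n_steps,
    )


# ---------------------------------------------------------------------------
# Checkpointing

def save_checkpoint(
    state: MediaState,
    path: str | Path,
    params: ModelParams | None = None,
    grid: GridSpec | None = None,
) -> None:
    """Write a lossless, version-stamped HDF5 checkpoint of the three fields.

    Optionally embeds the model parameters and grid spec as a plain-text
    JSON header for provenance.
    """
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "memfhn-checkpoint"
        f.attrs["format_version"] = CHECKPOINT_FORMAT_VERSION
        f.attrs["t"] = float(state.t)
        f.create_dataset("u", data=state.u)
        f.create_dataset("v", data=state.v)
        f.create_dataset("phi", data=state.phi)
        header: dict = {}
        if params is not None:
            header["params"] = {k: getattr(params, k) for k in params.__dataclass_fields__}
        if grid is not None:
            header["grid"] = {k: getattr(grid, k) for k in grid.__dataclass_fields__}
        if header:
            f.attrs["header_json"] = json.dumps(header)


def load_checkpoint(
    path: str | Path, expected_grid: GridSpec | None = None
) -> MediaState:
    """Load a checkpoint written by :func:`save_checkpoint`.

    Raises
    ------
    CheckpointError
        on a missing/corrupt file or, when ``expected_grid`` is given, on a
        field-shape mismatch.
    """
    path = Path(path)
    if not path.exists():
        raise CheckpointError(f"checkpoint file not found: {path}")
    try:
        with h5py.File(path, "r") as f:
            if f.attrs.get("format") != "memfhn-checkpoint":
                raise CheckpointError(f"not a memfhn checkpoint: {path}")
            u = f["u"][...]
            v = f["v"][...]
            phi = f["phi"][...]
            t = float(f.attrs["t"])
    except CheckpointError:
        raise
    except Exception as exc:  # h5py raises OSError/KeyError on corruption
        raise CheckpointError(f"failed to read checkpoint {path}: {exc}") from exc
    state = MediaState(u, v, phi, t)
    if expected_grid is not None and state.shape != expected_grid.shape:
        raise CheckpointError(
            f"checkpoint shape {state.shape} does not match expected grid "
            f"{expected_grid.shape}"
        )
    return state
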