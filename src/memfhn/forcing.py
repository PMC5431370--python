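"""External electromagnetic drives on the magnetic-flux field.

Two kinds of forcing act on the phi equation (never on u or v):

* a static radiation profile ``A * exp(-m * r)`` decaying with Euclidean
  distance ``r`` from a source center — a localized continuous exposure;
* Gaussian white noise of intensity ``D`` confined to a disk (or the whole
  domain) — a noisy exposure.

Centers and radii are, by default, expressed in node-index units on the
lattice (a center like (84, 84) or a radius of 40 live naturally in the
200 x 200 index space); set ``coord_units="physical"`` to scale them by the
grid spacing instead.  The coordinate of node (i, j) is (x, y) = (j, i)
(x along columns, y along rows), with no half-node offset.

White-noise discretization is not unique; two conventions are provided:

* ``naive`` (default): per-step increment ``h * D * N(0,1)``, i.e. the
  intensity D is the amplitude of a Gaussian draw treated as an ordinary
  rate — the pattern of classic excitable-media codes;
* ``em`` (Euler-Maruyama): per-step increment ``sqrt(2*D*h) * N(0,1)``,
  the standard discretization of additive white noise with correlation
  ``<xi(t) xi(t')> = 2 D delta(t - t')``.

``naive`` is the default because at the disk-noise study condition
(D=9, h=0.03, k2=1.6) the Euler-Maruyama scaling drives the flux far enough
that the memristive feedback ``k0*rho(phi)*u`` crosses the explicit-Euler
stability boundary (``h * k0 * rho > 2``) and the fields diverge within a
couple of time units — whereas the reported noisy media evolve for hundreds
of time units.  Only the weaker per-step scaling is consistent with that.
See docs/methods.md for the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .media_grid import GridSpec

__all__ = [
    "RadiationSource",
    "NoisePatch",
    "ForcingSpec",
    "ForcingContext",
    "radiation_profile",
    "noise_increment",
    "total_forcing",
]

NoiseMode = Literal["em", "naive"]
CoordUnits = Literal["index", "physical"]


@dataclass(frozen=True)
class RadiationSource:
    """A static exponential radiation profile A*exp(-m*r) centered at (x0, y0).

    A is the radiation amplitude; m >= 0 the spatial gradient (decay) factor.
    Defaults are the localized-exposure setting A=12, m=0.06 at (84, 84).
    """

    A: float = 12.0
    m: float = 0.06
    x0: float = 84.0
    y0: float = 84.0

    def __post_init__(self) -> None:
        if self.m < 0:
            raise ValueError(f"m must be >= 0, got {self.m}")


@dataclass(frozen=True)
class NoisePatch:
    """Gaussian white noise of intensity D on the disk of given radius.

    ``radius=None`` means the whole domain ("imposed on the media
    uniformly").  ``t_on`` delays the onset: no increments (and no random
    draws) before that time, which implements perturbing an already
    developed pattern.  ``seed`` optionally gives the patch its own
    random stream, independent of the simulation stream.
    Defaults are the disk-exposure setting D=9, center (60, 60), r<=40.
    """

    D: float = 9.0
    x0: float = 60.0
    y0: float = 60.0
    radius: float | None = 40.0
    t_on: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.D < 0:
            raise ValueError(f"D must be >= 0, got {self.D}")
        if self.radius is not None and self.radius < 0:
            raise ValueError(f"radius must be >= 0, got {self.radius}")


@dataclass(frozen=True)
class ForcingSpec:
    """Composite external drive: radiation sources plus noise patches.

    Empty lists mean zero forcing.  ``noise_mode`` selects the white-noise
    discretization; ``coord_units`` selects whether centers/radii are in
    node-index or physical units.
    """

    radiation: tuple[RadiationSource, ...] = ()
    noise: tuple[NoisePatch, ...] = ()
    noise_mode: NoiseMode = "naive"
    coord_units: CoordUnits = "index"


def _node_coords(grid: GridSpec, units: CoordUnits) -> tuple[np.ndarray, np.ndarray]:
    """(x, y) coordinate arrays of every node; x along columns, y along rows."""
    scale = grid.dx if units == "physical" else 1.0
    y = np.arange(grid.n_rows)[:, None] * scale
    x = np.arange(grid.n_cols)[None, :] * scale
    return x, y


def radiation_profile(
    source: RadiationSource, grid: GridSpec, coord_units: CoordUnits = "index"
) -> np.ndarray:
    """Time-independent lattice of the drive A*exp(-m*r) from one source."""
    x, y = _node_coords(grid, coord_units)
    r = np.sqrt((x - source.x0) ** 2 + (y - source.y0) ** 2)
    return source.A * np.exp(-source.m * r)


def _patch_mask(
    patch: NoisePatch, grid: GridSpec, coord_units: CoordUnits
) -> np.ndarray:
    if patch.radius is None:
        return np.ones(grid.shape, dtype=bool)
    x, y = _node_coords(grid, coord_units)
    r2 = (x - patch.x0) ** 2 + (y - patch.y0) ** 2
    return r2 <= patch.radius**2


def _increment_sd(patch: NoisePatch, h: float, mode: NoiseMode) -> float:
    if mode == "em":
        return float(np.sqrt(2.0 * patch.D * h))
    if mode == "naive":
        return float(h * patch.D)
    raise ValueError(f"unknown noise mode {mode!r}")


def noise_increment(
    patch: NoisePatch,
    grid: GridSpec,
    h: float,
    stream: np.random.Generator,
    mode: NoiseMode = "naive",
    coord_units: CoordUnits = "index",
    out: np.ndarray | None = None,
) -> np.ndarray:
    """One lattice of per-step stochastic flux increments from one patch.

    In-region nodes receive independent draws of sd(mode) * N(0,1); nodes
    outside the disk are exactly zero.  The increment is added to phi once
    per step, outside the ``h * rate`` product.
    """
    if out is None:
        out = np.zeros(grid.shape)
    mask = _patch_mask(patch, grid, coord_units)
    sd = _increment_sd(patch, h, mode)
    out[mask] += sd * stream.standard_normal(int(mask.sum()))
    return out


def total_forcing(
    spec: ForcingSpec | None,
    grid: GridSpec,
    t: float = 0.0,
    stream: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """(deterministic lattice, stochastic increment lattice) at time t.

    The deterministic part is the sum of all radiation profiles (static);
    the stochastic part sums the active noise patches' increments.  The
    integrator applies ``h * (k1*u - k2*phi + deterministic) + stochastic``.
    """
    det = np.zeros(grid.shape)
    stoch = np.zeros(grid.shape)
    if spec is None:
        return det, stoch
    for src in spec.radiation:
        det += radiation_profile(src, grid, spec.coord_units)
    for patch in spec.noise:
        if t >= patch.t_on:
            if stream is None:
                raise ValueError("noise patches require a random stream")
            noise_increment(
                patch, grid, grid.h, stream, spec.noise_mode, spec.coord_units,
                out=stoch,
            )
    return det, stoch


class ForcingContext:
    """Per-run compiled forcing: cached radiation lattice and patch masks.

    Precomputes the (time-independent) deterministic drive and, per noise
    patch, the in-disk node indices and increment standard deviation, so the
    per-step work is a single Gaussian draw per patch.
    """

    def __init__(
        self,
        spec: ForcingSpec | None,
        grid: GridSpec,
        rng: np.random.Generator,
    ):
        self.spec = spec or ForcingSpec()
        self.grid = grid
        det = np.zeros(grid.shape)
        for src in self.spec.radiation:
            det += radiation_profile(src, grid, self.spec.coord_units)
        #: the cached static drive; 0.0 when there are no radiation sources
        self.deterministic: np.ndarray | float = det if self.spec.radiation else 0.0
        self._patches: list[tuple[NoisePatch, np.ndarray, float, np.random.Generator]] = []
        for patch in self.spec.noise:
            mask = _patch_mask(patch, grid, self.spec.coord_units)
            idx = np.flatnonzero(mask.ravel())
            sd = _increment_sd(patch, grid.h, self.spec.noise_mode)
            stream = np.random.default_rng(patch.seed) if patch.seed is not None else rng
            self._patches.append((patch, idx, sd, stream))
        self._buf = np.zeros(grid.n_rows * grid.n_cols)
        self.has_noise = bool(self._patches)

    def sample_noise(self, t: float) -> np.ndarray | None:
        """Stochastic phi increment for the step starting at time t.

        Returns None when no patch is active (no random numbers consumed),
        so a run continued from a checkpoint sees the same stream positions
        as an uninterrupted run.
        """
        active = [p for p in self._patches if t >= p[0].t_on and p[0].D > 0]
        if not active:
            return None
        self._buf[:] = 0.0
        for _, idx, sd, stream in active:
            self._buf[idx] += sd * stream.standard_normal(idx.size)
        return self._buf.reshape(self.grid.shape)
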