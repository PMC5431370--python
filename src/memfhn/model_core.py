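"""Pointwise dynamics of the memristive FitzHugh-Nagumo cardiac model.

The model couples the classical two-variable cardiac FitzHugh-Nagumo
excitable kinetics (fast membrane potential ``u``, slow recovery current
``v``) to a third variable ``phi``, the magnetic flux across the membrane,
which accounts for electromagnetic induction.  A flux-controlled memristor
with memductance ``rho(phi) = alpha + 3*beta*phi**2`` feeds the flux back
into the membrane current through the term ``k0 * rho(phi) * u``.

This module contains only the space-free (single cell) part: the memductance
function, the three reaction rates, and an explicit-Euler single-cell
integrator used for parameter scans and convergence checks.  Diffusion and
the spatially extended model live in :mod:`memfhn.media_grid`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace
from typing import Callable, Literal, Sequence

import numpy as np

__all__ = [
    "ModelParams",
    "CellState",
    "CellTrajectory",
    "DomainGuardError",
    "DivergenceError",
    "memductance",
    "rate_u",
    "rate_v",
    "rate_phi",
    "integrate_cell",
]

Mode = Literal["baseline", "induction"]

#: default guard width around the removable singularity u = -mu2
DEFAULT_GUARD = 1e-12
#: default magnitude beyond which the integrator declares divergence
DEFAULT_BLOWUP = 1e6


class DomainGuardError(ValueError):
    """Raised when the recovery rate is evaluated too close to u = -mu2.

    The recovery equation divides by ``u + mu2``; rather than letting a NaN
    or huge value propagate silently, evaluation aborts when ``|u + mu2|``
    falls below a configurable guard threshold.
    """


class DivergenceError(RuntimeError):
    """Raised when a trajectory or field leaves the configured blow-up bound."""

    def __init__(self, message: str, t: float | None = None):
        super().__init__(message)
        self.t = t


@dataclass(frozen=True)
class ModelParams:
    """All scalar coefficients of the reaction kinetics, dimensionless.

    Defaults are the standard cardiac-tissue parameter set used throughout
    the simulations: ``k=8.0, a=0.15, mu1=0.2, mu2=0.3, eps=0.002`` for the
    excitable kinetics, ``k1=0.5, k2=1.0, alpha=1.0, beta=2.0`` for the flux
    subsystem, and ``k0=0.1`` (the spiral-supporting induction gain; ``k0``
    is the gain most often scanned).

    Parameters
    ----------
    k : cubic-nonlinearity gain of the fast variable.
    a : excitation threshold.
    eps : base recovery time-scale (small: v is slow).
    mu1, mu2 : shape parameters of the state-dependent recovery rate.
    I_st : external stimulus current (baseline mode only).
    D_u : diffusion coefficient of u in the spatial model.
    k0 : induction feedback gain multiplying ``rho(phi) * u``.
    k1 : flux-drive gain (membrane potential -> flux).
    k2 : flux-leak gain (flux self-decay).
    alpha, beta : memductance offset and curvature.
    """

    k: float = 8.0
    a: float = 0.15
    eps: float = 0.002
    mu1: float = 0.2
    mu2: float = 0.3
    I_st: float = 0.0
    D_u: float = 1.0
    k0: float = 0.1
    k1: float = 0.5
    k2: float = 1.0
    alpha: float = 1.0
    beta: float = 2.0

    def __post_init__(self) -> None:
        for f in fields(self):
            val = getattr(self, f.name)
            if not math.isfinite(val):
                raise ValueError(f"ModelParams.{f.name} must be finite, got {val!r}")
        if self.k <= 0:
            raise ValueError(f"k must be > 0, got {self.k}")
        if self.eps <= 0:
            raise ValueError(f"eps must be > 0, got {self.eps}")
        if self.mu2 <= 0:
            raise ValueError(f"mu2 must be > 0, got {self.mu2}")
        if self.k2 < 0:
            raise ValueError(f"k2 must be >= 0, got {self.k2}")
        if self.D_u < 0:
            raise ValueError(f"D_u must be >= 0, got {self.D_u}")

    def with_(self, **kwargs: float) -> "ModelParams":
        """Return a copy with the given coefficients replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class CellState:
    """State of a single cell: membrane potential, recovery, magnetic flux."""

    u: float = 0.0
    v: float = 0.0
    phi: float = 0.0


def memductance(phi, params: ModelParams):
    """Memductance rho(phi) = alpha + 3*beta*phi**2 of the flux-controlled memristor.

    Even in ``phi``; bounded below by ``alpha`` whenever ``beta >= 0``.
    Accepts scalars or arrays.
    """
    return params.alpha + 3.0 * params.beta * phi * phi


# ---------------------------------------------------------------------------
# Array kernels shared with the spatial integrator.  They operate on plain
# scalars or ndarrays and implement exactly the printed reaction terms.

def _du(u, v, phi, p: ModelParams, mode: Mode):
    reaction = -p.k * u * (u - p.a) * (u - 1.0) - u * v
    if mode == "induction":
        return reaction + p.k0 * memductance(phi, p) * u
    if mode == "baseline":
        return reaction + p.I_st
    raise ValueError(f"unknown mode {mode!r}")


def _dv(u, v, p: ModelParams):
    return (p.eps + v * p.mu1 / (u + p.mu2)) * (-v - p.k * u * (u - p.a - 1.0))


def _dphi(u, phi, p: ModelParams, forcing):
    return p.k1 * u - p.k2 * phi + forcing


def rate_u(state: CellState, params: ModelParams, mode: Mode = "induction") -> float:
    """Time derivative of the membrane potential, reaction part only.

    ``mode="baseline"`` uses the two-variable kinetics with stimulus current
    ``I_st``; ``mode="induction"`` replaces the stimulus with the memristive
    feedback ``k0 * rho(phi) * u``.  The diffusion term is applied by the
    spatial integrator, never here.
    """
    return float(_du(state.u, state.v, state.phi, params, mode))


def rate_v(
    state: CellState, params: ModelParams, guard: float = DEFAULT_GUARD
) -> float:
    """Time derivative of the recovery variable.

    Raises
    ------
    DomainGuardError
        If ``|u + mu2| < guard`` (the rate divides by ``u + mu2``).
    """
    if abs(state.u + params.mu2) < guard:
        raise DomainGuardError(
            f"rate_v evaluated at u={state.u!r} within {guard:g} of the "
            f"singular point u=-mu2={-params.mu2!r}"
        )
    return float(_dv(state.u, state.v, params))


def rate_phi(state: CellState, params: ModelParams, forcing: float = 0.0) -> float:
    """Time derivative of the magnetic flux: ``k1*u - k2*phi + forcing``.

    ``forcing`` is the external electromagnetic drive F at this cell
    (zero in the unforced model).
    """
    return float(_dphi(state.u, state.phi, params, forcing))


@dataclass
class CellTrajectory:
    """Time-indexed single-cell trajectory sampled by :func:`integrate_cell`."""

    t: np.ndarray
    u: np.ndarray
    v: np.ndarray
    phi: np.ndarray

    def __len__(self) -> int:
        return self.t.size

    @property
    def final(self) -> CellState:
        return CellState(float(self.u[-1]), float(self.v[-1]), float(self.phi[-1]))


def integrate_cell(
    state0: CellState,
    params: ModelParams,
    duration: float,
    h: float,
    forcing_fn: Callable[[float], float] | None = None,
    mode: Mode = "induction",
    stride: int = 1,
    frozen: Sequence[str] = (),
    guard: float = DEFAULT_GUARD,
    blowup: float = DEFAULT_BLOWUP,
) -> CellTrajectory:
    """Explicit Euler integration of a single (space-free) cell.

    Parameters
    ----------
    state0 : initial state.
    params : model coefficients.
    duration : total simulated time; the number of steps is
        ``round(duration / h)``.
    h : time step.
    forcing_fn : optional external flux drive as a function of time,
        added to the phi equation.  ``None`` means zero drive.
    mode : "baseline" (two-variable kinetics + I_st) or "induction"
        (memristive feedback).
    stride : record every ``stride``-th step (the initial state and the
        final step are always recorded).
    frozen : names among {"u", "v", "phi"} to hold at their initial value;
        a verification device used to isolate subsystems (e.g. the linear
        flux relaxation at frozen u).
    guard, blowup : domain-guard width and divergence bound.

    Returns
    -------
    CellTrajectory with times and the three state components.

    Raises
    ------
    DomainGuardError
        propagated from the recovery rate.
    DivergenceError
        when any state component magnitude exceeds ``blowup``.
    """
    if h <= 0:
        raise ValueError(f"h must be > 0, got {h}")
    if duration < h:
        raise ValueError(f"duration ({duration}) must be >= h ({h})")
    if stride < 1:
        raise ValueError(f"stride must be >= 1, got {stride}")
    unknown = set(frozen) - {"u", "v", "phi"}
    if unknown:
        raise ValueError(f"unknown frozen variables: {sorted(unknown)}")

    n_steps = round(duration / h)
    rec_idx = list(range(0, n_steps + 1, stride))
    if rec_idx[-1] != n_steps:
        rec_idx.append(n_steps)
    n_rec = len(rec_idx)
    out_t = np.empty(n_rec)
    out_u = np.empty(n_rec)
    out_v = np.empty(n_rec)
    out_phi = np.empty(n_rec)

    u, v, phi = float(state0.u), float(state0.v), float(state0.phi)
    freeze_u = "u" in frozen
    freeze_v = "v" in frozen
    freeze_phi = "phi" in frozen
    t = 0.0
    j = 0
    if rec_idx[0] == 0:
        out_t[0], out_u[0], out_v[0], out_phi[0] = t, u, v, phi
        j = 1
    for step_i in range(1, n_steps + 1):
        if abs(u + params.mu2) < guard:
            raise DomainGuardError(
                f"u={u!r} within {guard:g} of u=-mu2 at t={t!r}"
            )
        drive = forcing_fn(t) if forcing_fn is not None else 0.0
        du = 0.0 if freeze_u else _du(u, v, phi, params, mode)
        dv = 0.0 if freeze_v else _dv(u, v, params)
        dphi = 0.0 if freeze_phi else _dphi(u, phi, params, drive)
        u += h * du
        v += h * dv
        phi += h * dphi
        t += h
        if abs(u) > blowup or abs(v) > blowup or abs(phi) > blowup:
            raise DivergenceError(
                f"cell state exceeded blow-up bound {blowup:g} at t={t:.6g}: "
                f"(u, v, phi)=({u:.3g}, {v:.3g}, {phi:.3g})",
                t=t,
            )
        if j < n_rec and step_i == rec_idx[j]:
            out_t[j], out_u[j], out_v[j], out_phi[j] = t, u, v, phi
            j += 1
    return CellTrajectory(out_t, out_u, out_v, out_phi)
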