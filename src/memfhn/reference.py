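"""Slow, loop-based reference implementations for cross-validation.

These re-derive the discrete operators node by node from their definitions
(explicit ghost values, scalar arithmetic) without any vectorized shortcut,
so the production kernels in :mod:`memfhn.media_grid` can be checked against
an independent formulation.  They are orders of magnitude slower and are
meant for small grids only.
"""

from __future__ import annotations

import numpy as np

from .media_grid import GridSpec, MediaState
from .model_core import Mode, ModelParams, memductance

__all__ = ["laplacian_noflux_naive", "step_naive"]


def laplacian_noflux_naive(field: np.ndarray, dx: float) -> np.ndarray:
    """Five-point no-flux Laplacian via explicit per-node ghost lookups."""
    n, m = field.shape
    out = np.empty_like(field, dtype=float)

    def at(i: int, j: int) -> float:
        # mirror ghost: an out-of-range index maps to the edge node it faces
        i = min(max(i, 0), n - 1)
        j = min(max(j, 0), m - 1)
        return float(field[i, j])

    for i in range(n):
        for j in range(m):
            out[i, j] = (
                at(i - 1, j) + at(i + 1, j) + at(i, j - 1) + at(i, j + 1)
                - 4.0 * at(i, j)
            ) / (dx * dx)
    return out


def step_naive(
    state: MediaState,
    params: ModelParams,
    grid: GridSpec,
    forcing_field: np.ndarray | float = 0.0,
    noise: np.ndarray | None = None,
    mode: Mode = "induction",
) -> MediaState:
    """One Euler-forward field update computed with scalar per-node loops."""
    p = params
    h = grid.h
    u, v, phi = state.u, state.v, state.phi
    n, m = u.shape
    lap = laplacian_noflux_naive(u, grid.dx)
    F = np.broadcast_to(np.asarray(forcing_field, dtype=float), u.shape)
    u2 = np.empty_like(u)
    v2 = np.empty_like(v)
    phi2 = np.empty_like(phi)
    for i in range(n):
        for j in range(m):
            ui, vi, fi = float(u[i, j]), float(v[i, j]), float(phi[i, j])
            reaction = -p.k * ui * (ui - p.a) * (ui - 1.0) - ui * vi
            if mode == "induction":
                du = reaction + p.k0 * memductance(fi, p) * ui
            else:
                du = reaction + p.I_st
            dv = (p.eps + vi * p.mu1 / (ui + p.mu2)) * (
                -vi - p.k * ui * (ui - p.a - 1.0)
            )
            dphi = p.k1 * ui - p.k2 * fi + float(F[i, j])
            u2[i, j] = ui + h * (du + p.D_u * lap[i, j])
            v2[i, j] = vi + h * dv
            phi2[i, j] = fi + h * dphi
    if noise is not None:
        phi2 += noise
    return MediaState(u2, v2, phi2, state.t + h)
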