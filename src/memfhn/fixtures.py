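"""Synthetic objects with known properties, for tests and demonstrations.

Everything here is constructed from closed forms or seeded generators:
phase fields with a prescribed topological charge, series with a known peak
structure, small random fields.  Nothing is measured from a simulation.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "random_field",
    "spiral_phase",
    "spiral_pair_phase",
    "two_cluster_series",
    "sine_series",
    "make_fixtures",
]


def random_field(size: int = 16, seed: int = 0, scale: float = 1.0) -> np.ndarray:
    """A seeded size x size standard-normal field (times ``scale``)."""
    rng = np.random.default_rng(seed)
    return scale * rng.standard_normal((size, size))


def spiral_phase(
    size: int = 64,
    center: tuple[float, float] | None = None,
    charge: int = 1,
    arm_twist: float = 0.0,
) -> np.ndarray:
    """A single-defect phase field theta = charge * atan2(y-yc, x-xc) (+ twist*r).

    By construction it carries exactly one phase singularity of the given
    topological charge at ``center`` (default: just off the domain middle).
    The center must not lie exactly on a lattice node or edge — the phase is
    singular there, and a defect sitting on the sampling grid is invisible
    to plaquette winding.  ``arm_twist`` adds an Archimedean-arm term
    twist*r, which moves no defect and changes no charge.
    """
    if center is None:
        # +0.25 keeps the defect strictly inside a plaquette for any size
        center = ((size - 1) / 2.0 + 0.25, (size - 1) / 2.0 + 0.25)
    yc, xc = center
    y, x = np.mgrid[0:size, 0:size].astype(float)
    theta = charge * np.arctan2(y - yc, x - xc)
    if arm_twist:
        theta = theta + arm_twist * np.hypot(y - yc, x - xc)
    return np.angle(np.exp(1j * theta))


def spiral_pair_phase(
    size: int = 64,
    centers: tuple[tuple[float, float], tuple[float, float]] | None = None,
) -> np.ndarray:
    """Two superposed defects of opposite charge: count 2, net charge 0."""
    if centers is None:
        centers = (
            (size / 2.0 + 0.5, size / 4.0 + 0.5),
            (size / 2.0 + 0.5, 3 * size / 4.0 + 0.5),
        )
    (y1, x1), (y2, x2) = centers
    y, x = np.mgrid[0:size, 0:size].astype(float)
    theta = np.arctan2(y - y1, x - x1) - np.arctan2(y - y2, x - x2)
    return np.angle(np.exp(1j * theta))


def two_cluster_series(
    n_peaks: int = 20,
    low: float = 1.0,
    high: float = 2.0,
    period: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """(t, x): peaks alternating between two fixed amplitudes, troughs at 0.

    A minimal period-doubled rhythm: exactly ``n_peaks`` strict maxima whose
    values form two clusters {low, high}.
    """
    n = n_peaks * period + 1
    t = np.arange(n, dtype=float)
    x = np.zeros(n)
    for k in range(n_peaks):
        x[period // 2 + k * period] = high if k % 2 else low
    return t, x


def sine_series(
    n_periods: int = 4, n_samples: int = 1000
) -> tuple[np.ndarray, np.ndarray]:
    """(t, sin t) over ``n_periods`` full periods.

    The endpoint is included so the sample spacing is incommensurate with
    the peak positions; otherwise each maximum falls exactly midway between
    two equal samples and is (correctly) not a strict peak.
    """
    t = np.linspace(0.0, 2.0 * np.pi * n_periods, n_samples, endpoint=True)
    return t, np.sin(t)


def make_fixtures(kind: str, size: int = 16, seed: int = 0):
    """Dispatch by kind: random_field | spiral_phase | spiral_pair | two_cluster | sine."""
    if kind == "random_field":
        return random_field(size=size, seed=seed)
    if kind == "spiral_phase":
        return spiral_phase(size=size)
    if kind == "spiral_pair":
        return spiral_pair_phase(size=size)
    if kind == "two_cluster":
        return two_cluster_series(n_peaks=max(size, 4))
    if kind == "sine":
        return sine_series(n_samples=max(size, 64))
    raise ValueError(f"unknown fixture kind {kind!r}")
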