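"""Named experiment presets: each study condition as a one-command run.

Every preset encodes one published experimental setting — the stripe-seeded
spiral, its suppression at large induction gain, flux-leak-driven breakup
and standing spirals, local radiation exposure, disk-confined noise, and the
gain scans — with the exact parameter values and snapshot times of the
corresponding setting.  Presets never mutate shared defaults; each call
builds a fresh config.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import SimulationConfig
from .forcing import ForcingSpec, NoisePatch, RadiationSource
from .media_grid import GridSpec, SamplingPlan
from .model_core import ModelParams

__all__ = ["ExperimentPreset", "PRESETS", "get_preset", "SCAN_PRESETS", "ScanPreset"]


@dataclass(frozen=True)
class ExperimentPreset:
    name: str
    description: str
    config: SimulationConfig


def _base(
    k0: float = 0.1,
    k1: float = 0.5,
    k2: float = 1.0,
    duration: float = 200.0,
    snapshot_times: tuple[float, ...] = (10.0, 60.0, 100.0, 200.0),
    forcing: ForcingSpec | None = None,
    seed: int = 0,
) -> SimulationConfig:
    return SimulationConfig(
        params=ModelParams(k0=k0, k1=k1, k2=k2),
        grid=GridSpec(duration=duration),
        forcing=forcing or ForcingSpec(),
        sampling=SamplingPlan(snapshot_times=snapshot_times),
        seed=seed,
    )


def _build_presets() -> dict[str, ExperimentPreset]:
    presets: dict[str, ExperimentPreset] = {}

    def add(name: str, description: str, config: SimulationConfig) -> None:
        presets[name] = ExperimentPreset(name, description, config)

    add(
        "fig3",
        "Stripe-seeded spiral formation at induction gain k0=0.1 "
        "(k1=0.5, k2=1); snapshots at t=10, 60, 100, 200.",
        _base(k0=0.1),
    )
    add(
        "fig3_suppress",
        "Same seed and setting at k0=0.9: strong induction feedback "
        "magnetizes the media toward a homogeneous state and no spiral "
        "survives.  (Use an override params.k0=0.4 for the milder case.)",
        _base(k0=0.9),
    )
    add(
        "fig7",
        "Small flux leak k2=0.15 (k0=0.1, k1=0.5): spiral seeds break up "
        "and the media turns turbulent.",
        _base(k2=0.15),
    )
    add(
        "fig8",
        "Large flux leak k2=3.0 (k0=0.1, k1=0.5): a standing, perfect "
        "spiral wave develops.",
        _base(k2=3.0),
    )
    add(
        "fig10",
        "Small flux-drive gain k1=0.2 (k0=0.1, k2=1.0): excitable media "
        "supporting wave propagation and a surviving spiral.",
        _base(k1=0.2),
    )
    add(
        "fig11",
        "Local electromagnetic radiation A*exp(-m*r), A=12, m=0.06 centered "
        "at (84, 84), on the stripe seed at k0=0.1, k1=0.5, k2=1.6; "
        "snapshots at t=10, 120, 600, 800.",
        _base(
            k2=1.6,
            duration=800.0,
            snapshot_times=(10.0, 120.0, 600.0, 800.0),
            forcing=ForcingSpec(
                radiation=(RadiationSource(A=12.0, m=0.06, x0=84.0, y0=84.0),)
            ),
        ),
    )
    add(
        "fig12",
        "Gaussian white noise D=9 on the disk r<=40 at (60, 60) from t=0, "
        "stripe seed, k0=0.1, k1=0.5, k2=1.6; snapshots at "
        "t=10, 60, 120, 200, 400, 800.",
        _base(
            k2=1.6,
            duration=800.0,
            snapshot_times=(10.0, 60.0, 120.0, 200.0, 400.0, 800.0),
            forcing=ForcingSpec(
                noise=(NoisePatch(D=9.0, x0=60.0, y0=60.0, radius=40.0),)
            ),
        ),
    )
    add(
        "fig14",
        "Spiral robustness to noise: the stripe seed develops a stable "
        "rotating spiral during a ~200-time-unit transient, then the disk "
        "noise (D=9, r<=40 at (60, 60)) switches on; snapshots at "
        "t=10, 100, 200, 300, 400, 800.",
        _base(
            k2=1.6,
            duration=800.0,
            snapshot_times=(10.0, 100.0, 200.0, 300.0, 400.0, 800.0),
            forcing=ForcingSpec(
                noise=(
                    NoisePatch(D=9.0, x0=60.0, y0=60.0, radius=40.0, t_on=200.0),
                )
            ),
        ),
    )
    return presets


PRESETS: dict[str, ExperimentPreset] = _build_presets()


@dataclass(frozen=True)
class ScanPreset:
    """A bifurcation-scan preset: gain name, scanned values, base config.

    The published diagrams show the scan axes but not the sampled grids;
    the value lists below cover each diagram's plotted range at a uniform
    spacing chosen for a readable diagram (each scanned value is one full
    2D run, so the lists are deliberately moderate).
    """

    name: str
    param: str
    values: tuple[float, ...]
    config: SimulationConfig
    description: str


SCAN_PRESETS: dict[str, ScanPreset] = {
    "fig2_scan": ScanPreset(
        name="fig2_scan",
        param="k0",
        values=tuple(round(0.05 * i, 2) for i in range(1, 21)),  # 0.05 .. 1.0
        config=_base(snapshot_times=()),
        description="Peak membrane potential at node (99, 99) vs. induction "
        "gain k0 in [0.05, 1.0] (k1=0.5, k2=1).",
    ),
    "fig4_scan": ScanPreset(
        name="fig4_scan",
        param="k2",
        values=tuple(round(0.1 * i, 2) for i in range(1, 31)),  # 0.1 .. 3.0
        config=_base(snapshot_times=()),
        description="Peak membrane potential vs. flux leak k2 in [0.1, 3.0] "
        "(k0=0.1, k1=0.5).",
    ),
    "fig9_scan": ScanPreset(
        name="fig9_scan",
        param="k1",
        values=tuple(round(0.2 * i, 2) for i in range(1, 15)),  # 0.2 .. 2.8
        config=_base(snapshot_times=()),
        description="Peak membrane potential vs. flux drive k1 in [0.2, 2.8] "
        "(k0=0.1, k2=1.0).",
    ),
}


def get_preset(name: str) -> ExperimentPreset:
    try:
        return PRESETS[name]
    except KeyError:
        known = ", ".join(sorted(PRESETS))
        raise KeyError(f"unknown preset {name!r}; known presets: {known}") from None
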