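"""Spatial model: Laplacian, field updates, recipes, simulate, checkpoints."""

import numpy as np
import pytest

from memfhn import (
    Band,
    CheckpointError,
    GridSpec,
    MediaState,
    ModelParams,
    SamplingPlan,
    build_initial_state,
    homogeneous,
    laplacian_noflux,
    load_checkpoint,
    save_checkpoint,
    simulate,
    step,
    stripe_seed,
)
from memfhn.media_grid import from_checkpoint
from memfhn.reference import laplacian_noflux_naive, step_naive


class TestGridSpec:
    def test_default_spacing_is_physical(self):
        g = GridSpec()
        assert g.shape == (200, 200)
        assert g.dx == pytest.approx(350.0 / 200.0)
        assert g.n_steps == round(200.0 / 0.03)

    def test_unit_spacing_switch(self):
        assert GridSpec(unit_spacing=True).dx == 1.0

    @pytest.mark.parametrize(
        "bad",
        [dict(n_rows=2), dict(n_cols=1), dict(h=-0.1), dict(L=0.0),
         dict(duration=0.0)],
    )
    def test_invariants(self, bad):
        with pytest.raises(ValueError):
            GridSpec(**bad)


class TestLaplacian:
    def test_constant_field_gives_zero(self):
        f = np.full((7, 9), 3.14)
        assert np.all(laplacian_noflux(f, 1.75) == 0.0)

    def test_linear_ramp_hand_computed(self):
        """f(i,j) = i + j on 4x4 with dx=1: zero in the interior, and the
        boundary values fixed by the mirror-ghost rule (hand-derived)."""
        i, j = np.mgrid[0:4, 0:4].astype(float)
        f = i + j
        expected = np.array(
            [
                [2.0, 1.0, 1.0, 0.0],
                [1.0, 0.0, 0.0, -1.0],
                [1.0, 0.0, 0.0, -1.0],
                [0.0, -1.0, -1.0, -2.0],
            ]
        )
        assert np.allclose(laplacian_noflux(f, 1.0), expected, atol=1e-14)

    def test_matches_naive_reference(self, rng):
        f = rng.standard_normal((16, 16))
        got = laplacian_noflux(f, 1.75)
        ref = laplacian_noflux_naive(f, 1.75)
        assert np.max(np.abs(got - ref)) <= 1e-12

    def test_lattice_sum_is_zero(self, rng):
        """No-flux ghosting: the stencil redistributes but never creates u."""
        f = rng.standard_normal((12, 20))
        assert abs(laplacian_noflux(f, 1.3).sum()) < 1e-11

    def test_too_small_field_rejected(self):
        with pytest.raises(ValueError):
            laplacian_noflux(np.zeros((2, 5)), 1.0)


class TestInitialConditions:
    def test_stripe_seed_band_placement(self):
        grid = GridSpec()
        s = build_initial_state(stripe_seed(), grid)
        # 1-based inclusive (92:97, 1:115) -> 0-based rows 91..96, cols 0..114
        assert np.all(s.u[91:97, 0:115] == 1.0)
        assert np.all(s.v[91:97, 0:115] == 0.0)
        assert np.all(s.u[97:103, 0:115] == 0.7)
        assert np.all(s.v[97:103, 0:115] == 0.6)
        assert np.all(s.phi[97:103, 0:115] == 0.1)
        assert np.all(s.u[103:109, 0:115] == 0.0)
        assert np.all(s.v[103:109, 0:115] == 0.8)
        assert np.all(s.phi[103:109, 0:115] == 0.2)
        # background at rest
        assert np.all(s.u[:91] == 0.0)
        assert np.all(s.u[109:] == 0.0)
        assert np.all(s.u[:, 115:] == 0.0)

    def test_band_outside_grid_rejected(self):
        grid = GridSpec(n_rows=10, n_cols=10, L=10.0)
        bad = stripe_seed(bands=[Band(rows=(5, 12), cols=(1, 5), u=1, v=0, phi=0)])
        with pytest.raises(ValueError):
            build_initial_state(bad, grid)

    def test_homogeneous_recipe(self):
        grid = GridSpec(n_rows=5, n_cols=5, L=5.0)
        s = build_initial_state(homogeneous(0.3, 0.1, -0.2), grid)
        assert np.all(s.u == 0.3) and np.all(s.v == 0.1) and np.all(s.phi == -0.2)


class TestStep:
    def test_rest_state_is_invariant(self, params, small_grid):
        s0 = build_initial_state(homogeneous(), small_grid)
        s1 = step(s0, params, small_grid)
        assert np.all(s1.u == 0.0) and np.all(s1.v == 0.0) and np.all(s1.phi == 0.0)
        assert s1.t == pytest.approx(small_grid.h)

    def test_homogeneous_stays_homogeneous(self, params, small_grid):
        """Laplacian of a constant vanishes, so a uniform medium evolves as a
        single cell: fields stay spatially constant to machine precision."""
        s = build_initial_state(homogeneous(0.4, 0.1, 0.05), small_grid)
        for _ in range(50):
            s = step(s, params, small_grid)
        for f in (s.u, s.v, s.phi):
            assert np.ptp(f) == 0.0

    def test_matches_naive_reference_random_state(
        self, params, small_grid, random_state
    ):
        got = step(random_state, params, small_grid)
        ref = step_naive(random_state, params, small_grid)
        assert np.max(np.abs(got.u - ref.u)) <= 1e-12
        assert np.max(np.abs(got.v - ref.v)) <= 1e-12
        assert np.max(np.abs(got.phi - ref.phi)) <= 1e-12

    def test_matches_naive_reference_stripe_seed(self, params):
        grid = GridSpec(n_rows=24, n_cols=24, L=42.0, h=0.03)
        bands = [
            Band(rows=(10, 12), cols=(1, 14), u=1.0, v=0.0, phi=0.0),
            Band(rows=(13, 15), cols=(1, 14), u=0.7, v=0.6, phi=0.1),
        ]
        s0 = build_initial_state(stripe_seed(bands=bands), grid)
        got = step(s0, params, grid)
        ref = step_naive(s0, params, grid)
        assert np.max(np.abs(got.u - ref.u)) <= 1e-12

    def test_diffusion_conserves_total_u(self, params, rng):
        """Reaction off: the no-flux boundary conserves the lattice sum of u
        to relative 1e-10 over 1000 steps."""
        grid = GridSpec(n_rows=20, n_cols=20, L=35.0, h=0.03)
        u = rng.uniform(0.0, 1.0, grid.shape)
        s = MediaState(u.copy(), np.zeros(grid.shape), np.zeros(grid.shape))
        total0 = u.sum()
        for _ in range(1000):
            s = step(s, params, grid, reaction=False)
        assert abs(s.u.sum() - total0) / abs(total0) < 1e-10
        assert np.array_equal(s.v, np.zeros(grid.shape))

    def test_shape_mismatch_rejected(self, params, small_grid):
        s = build_initial_state(homogeneous(), GridSpec(n_rows=5, n_cols=5, L=5.0))
        with pytest.raises(ValueError):
            step(s, params, small_grid)


class TestSimulate:
    def test_zero_recipe_gives_zero_snapshots(self, params):
        grid = GridSpec(n_rows=8, n_cols=8, L=8.0, h=0.03, duration=3.0)
        plan = SamplingPlan(snapshot_times=(1.0, 3.0), nodes=((4, 4),))
        res = simulate(homogeneous(), params, grid, sampling=plan)
        assert len(res.snapshots) == 2
        for snap in res.snapshots:
            assert np.all(snap.state.u == 0.0)
        assert np.all(res.series[(4, 4)].u == 0.0)

    def test_snapshot_times_map_to_nearest_step(self, params):
        grid = GridSpec(n_rows=8, n_cols=8, L=8.0, h=0.03, duration=2.0)
        plan = SamplingPlan(snapshot_times=(1.0,), nodes=((4, 4),))
        res = simulate(homogeneous(), params, grid, sampling=plan)
        snap = res.snapshots[0]
        assert snap.t_requested == 1.0
        assert abs(snap.t_actual - 1.0) <= grid.h / 2 + 1e-12

    def test_series_covers_every_step(self, params):
        grid = GridSpec(n_rows=8, n_cols=8, L=8.0, h=0.03, duration=0.3)
        res = simulate(homogeneous(0.5, 0.0, 0.0), params, grid,
                       sampling=SamplingPlan(snapshot_times=(), nodes=((2, 3),)))
        s = res.series[(2, 3)]
        assert s.t.size == grid.n_steps + 1
        assert s.t[0] == 0.0
        assert s.u[0] == 0.5

    def test_deterministic_runs_identical(self, params):
        grid = GridSpec(n_rows=10, n_cols=10, L=10.0, h=0.03, duration=3.0)
        plan = SamplingPlan(snapshot_times=(3.0,), nodes=((5, 5),))
        a = simulate(homogeneous(0.4, 0.1, 0.0), params, grid, sampling=plan)
        b = simulate(homogeneous(0.4, 0.1, 0.0), params, grid, sampling=plan)
        assert np.array_equal(a.final_state.u, b.final_state.u)
        assert np.array_equal(a.series[(5, 5)].u, b.series[(5, 5)].u)

    def test_monitored_node_validated(self, params, small_grid):
        with pytest.raises(ValueError):
            simulate(homogeneous(), params, small_grid,
                     sampling=SamplingPlan(snapshot_times=(), nodes=((99, 99),)))


class TestCheckpoints:
    def _state(self, grid, rng):
        return MediaState(
            rng.uniform(0, 1, grid.shape),
            rng.uniform(0, 1, grid.shape),
            rng.uniform(-1, 1, grid.shape),
            t=12.34,
        )

    def test_round_trip_bit_for_bit(self, params, small_grid, rng, tmp_path):
        s = self._state(small_grid, rng)
        path = tmp_path / "ckpt.h5"
        save_checkpoint(s, path, params=params, grid=small_grid)
        loaded = load_checkpoint(path, expected_grid=small_grid)
        assert np.array_equal(loaded.u, s.u)
        assert np.array_equal(loaded.v, s.v)
        assert np.array_equal(loaded.phi, s.phi)
        assert loaded.t == s.t

    def test_shape_mismatch_raises(self, small_grid, rng, tmp_path):
        s = self._state(small_grid, rng)
        path = tmp_path / "ckpt.h5"
        save_checkpoint(s, path)
        with pytest.raises(CheckpointError):
            load_checkpoint(path, expected_grid=GridSpec(n_rows=5, n_cols=5, L=5.0))

    def test_missing_and_corrupt_files_raise(self, tmp_path):
        with pytest.raises(CheckpointError):
            load_checkpoint(tmp_path / "nope.h5")
        bad = tmp_path / "bad.h5"
        bad.write_text("not hdf5")
        with pytest.raises(CheckpointError):
            load_checkpoint(bad)

    def test_continuation_bit_identical_to_uninterrupted(self, params, tmp_path):
        """Run 6 time units straight vs. 3 + checkpoint + 3: same fields."""
        grid6 = GridSpec(n_rows=12, n_cols=12, L=21.0, h=0.03, duration=6.0)
        grid3 = GridSpec(n_rows=12, n_cols=12, L=21.0, h=0.03, duration=3.0)
        bands = [Band(rows=(5, 6), cols=(1, 8), u=1.0, v=0.0, phi=0.0)]
        recipe = stripe_seed(bands=bands)
        plan = SamplingPlan(snapshot_times=(), nodes=((6, 6),))
        full = simulate(recipe, params, grid6, sampling=plan)
        first = simulate(recipe, params, grid3, sampling=plan)
        path = tmp_path / "mid.h5"
        save_checkpoint(first.final_state, path)
        resumed = simulate(
            load_checkpoint(path, expected_grid=grid3), params, grid3, sampling=plan
        )
        assert np.array_equal(resumed.final_state.u, full.final_state.u)
        assert np.array_equal(resumed.final_state.v, full.final_state.v)
        assert np.array_equal(resumed.final_state.phi, full.final_state.phi)

    def test_from_checkpoint_recipe(self, params, small_grid, rng, tmp_path):
        s = self._state(small_grid, rng)
        path = tmp_path / "ckpt.h5"
        save_checkpoint(s, path)
        loaded = build_initial_state(from_checkpoint(path), small_grid)
        assert np.array_equal(loaded.u, s.u)
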