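"""Measurement instruments: peaks, activity labels, spatial/phase metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from memfhn import (
    ActivityThresholds,
    GridSpec,
    ModelParams,
    bifurcation_scan,
    classify_activity,
    count_phase_singularities,
    detect_peaks,
    phase_field,
    spatial_std,
    stripe_seed,
)
from memfhn.analysis import dominant_period
from memfhn.fixtures import (
    sine_series,
    spiral_pair_phase,
    spiral_phase,
    two_cluster_series,
)


def peaks_exhaustive(values, times, transient=0.0):
    """Independent scan oracle: check every sample against the definition."""
    out = []
    for i in range(len(values)):
        if times[i] < transient or i == 0 or i == len(values) - 1:
            continue
        # neighbors within the post-transient window only
        if times[i - 1] < transient:
            continue
        if values[i] > values[i - 1] and values[i] > values[i + 1]:
            out.append(i)
    return out


class TestDetectPeaks:
    def test_enumerable_example(self):
        ps = detect_peaks([0, 1, 0, 2, 0])
        assert list(ps.indices) == [1, 3]
        assert list(ps.values) == [1, 2]

    def test_constant_series_has_no_peaks(self):
        assert len(detect_peaks(np.ones(100))) == 0

    def test_plateaus_are_not_peaks(self):
        assert len(detect_peaks([0, 1, 1, 0, 0, 2, 2, 2, 0])) == 0

    def test_endpoints_never_peaks(self):
        ps = detect_peaks([9, 1, 0, 3, 1, 9])
        assert len(ps) == 1 and ps.indices[0] == 3

    def test_sine_four_periods_four_peaks(self):
        t, x = sine_series(n_periods=4, n_samples=1000)
        ps = detect_peaks(x, t)
        assert len(ps) == 4
        assert np.all(np.abs(ps.values - 1.0) < 1e-3)

    def test_transient_discard(self):
        t, x = sine_series(n_periods=4, n_samples=1000)
        ps = detect_peaks(x, t, transient=2 * 2 * np.pi)
        assert len(ps) == 2

    def test_empty_after_transient_raises(self):
        with pytest.raises(ValueError):
            detect_peaks([1, 2, 3], [0.0, 1.0, 2.0], transient=10.0)

    def test_matches_exhaustive_oracle_on_random_series(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 200))
            x = rng.standard_normal(n)
            t = np.arange(n, dtype=float)
            transient = float(rng.uniform(0, n / 3))
            got = detect_peaks(x, t, transient=transient)
            assert list(got.indices) == peaks_exhaustive(x, t, transient)

    @given(
        x=st.lists(
            st.integers(-400, 400).map(lambda k: k * 0.25), min_size=5, max_size=60
        ),
        shift=st.integers(-200, 200).map(lambda k: k * 0.25),
        scale=st.sampled_from([0.25, 0.5, 2.0, 4.0]),
    )
    @settings(max_examples=200, deadline=None)
    def test_shift_invariance_and_scale_equivariance(self, x, shift, scale):
        """Peak positions survive adding a constant; values scale linearly
        under positive scaling.  (Values kept on a dyadic grid so the
        arithmetic is exact and the property holds without FP caveats.)"""
        x = np.asarray(x)
        base = detect_peaks(x)
        shifted = detect_peaks(x + shift)
        assert np.array_equal(base.indices, shifted.indices)
        scaled = detect_peaks(x * scale)
        assert np.array_equal(base.indices, scaled.indices)

    def test_peak_times_strictly_increasing(self, rng):
        x = rng.standard_normal(500)
        ps = detect_peaks(x)
        assert np.all(np.diff(ps.times) > 0)


class TestClassifyActivity:
    def test_empty_peakset_is_quiescent(self):
        x = np.zeros(100)
        assert classify_activity(detect_peaks(x), x) == "quiescent"

    def test_subthreshold_ripple_is_quiescent(self):
        t = np.linspace(0, 40 * np.pi, 4000)
        x = 0.01 * np.sin(t)
        assert classify_activity(detect_peaks(x, t), x) == "quiescent"

    def test_sine_is_periodic(self):
        t, x = sine_series(n_periods=8, n_samples=4000)
        assert classify_activity(detect_peaks(x, t), x) == "periodic"

    def test_two_cluster_peaks_are_multimodal(self):
        t, x = two_cluster_series(n_peaks=20, low=1.0, high=2.0)
        assert classify_activity(detect_peaks(x, t), x) == "multimodal"

    def test_random_walk_is_irregular(self, rng):
        x = np.cumsum(rng.standard_normal(2000)) * 0.1 + np.sin(
            np.linspace(0, 60, 2000)
        )
        label = classify_activity(detect_peaks(x), x)
        assert label == "irregular"

    def test_pure_function_stable(self, rng):
        x = rng.standard_normal(500)
        ps = detect_peaks(x)
        th = ActivityThresholds()
        assert classify_activity(ps, x, th) == classify_activity(ps, x, th)


class TestSpatialStd:
    def test_constant_field_zero(self):
        assert spatial_std(np.full((8, 8), 2.5)) == 0.0

    def test_checkerboard_unit(self):
        f = np.indices((10, 10)).sum(axis=0) % 2 * 2.0 - 1.0
        assert spatial_std(f) == pytest.approx(1.0)

    def test_stripe_seed_matches_direct_summation(self):
        grid = GridSpec()
        from memfhn import build_initial_state

        u = build_initial_state(stripe_seed(), grid).u
        flat = u.ravel()
        mean = sum(flat) / flat.size  # brute-force two-pass oracle
        var = sum((x - mean) ** 2 for x in flat) / flat.size
        assert spatial_std(u) == pytest.approx(var**0.5, rel=1e-10)


class TestPhaseField:
    def test_positive_u_axis_is_zero_phase(self):
        u = np.full((5, 5), 2.0)
        v = np.full((5, 5), 1.0)
        assert np.all(phase_field(u, v, reference=(1.0, 1.0)) == 0.0)

    def test_recovers_synthetic_angle(self):
        theta = spiral_phase(size=32)
        u, v = np.cos(theta), np.sin(theta)
        rec = phase_field(u, v, reference=(0.0, 0.0))
        assert np.allclose(np.angle(np.exp(1j * (rec - theta))), 0.0, atol=1e-12)

    def test_zero_displacement_is_zero(self):
        u = np.zeros((4, 4))
        v = np.zeros((4, 4))
        assert np.all(phase_field(u, v, reference=(0.0, 0.0)) == 0.0)


class TestPhaseSingularities:
    def test_uniform_phase_has_none(self):
        assert count_phase_singularities(np.full((10, 10), 0.7)).count == 0

    def test_smooth_gradient_has_none(self):
        y, x = np.mgrid[0:20, 0:20]
        assert count_phase_singularities(0.1 * x + 0.05 * y).count == 0

    @pytest.mark.parametrize("charge", [1, -1])
    def test_single_synthetic_defect(self, charge):
        theta = spiral_phase(size=33, charge=charge)
        sing = count_phase_singularities(theta)
        assert sing.count == 1
        assert sing.net_charge == charge
        # core within one node of the construction center (16.25, 16.25)
        assert np.all(np.abs(sing.locations[0] - 16.25) <= 1.0)

    def test_opposite_pair_counts_two_net_zero(self):
        theta = spiral_pair_phase(size=48)
        sing = count_phase_singularities(theta)
        assert sing.count == 2
        assert sing.net_charge == 0

    def test_archimedean_twist_moves_no_charge(self):
        """Smooth deformation of the synthetic field (adding spiral arms)
        preserves the total topological charge."""
        for twist in (0.0, 0.2, 0.5):
            theta = spiral_phase(size=41, arm_twist=twist)
            assert count_phase_singularities(theta).net_charge == 1

    def test_defect_translation_preserves_charge(self):
        for cy in (12.4, 16.5, 20.7):
            theta = spiral_phase(size=41, center=(cy, 17.3))
            sing = count_phase_singularities(theta)
            assert sing.count == 1 and sing.net_charge == 1


class TestDominantPeriod:
    def test_sine_period(self):
        t, x = sine_series(n_periods=6, n_samples=3000)
        ps = detect_peaks(x, t)
        assert dominant_period(ps) == pytest.approx(2 * np.pi, rel=1e-2)

    def test_needs_two_peaks(self):
        ps = detect_peaks([0, 1, 0])
        assert dominant_period(ps) is None


class TestBifurcationScan:
    @pytest.fixture
    def tiny(self):
        """A small media that still oscillates: homogeneous-free stripe seed."""
        from memfhn import Band

        grid = GridSpec(n_rows=20, n_cols=20, L=35.0, h=0.03, duration=60.0)
        bands = [
            Band(rows=(9, 10), cols=(1, 12), u=1.0, v=0.0, phi=0.0),
            Band(rows=(11, 12), cols=(1, 12), u=0.7, v=0.6, phi=0.1),
        ]
        return grid, stripe_seed(bands=bands)

    def test_scan_shapes_and_determinism(self, tiny):
        grid, recipe = tiny
        res1 = bifurcation_scan(
            "k0", [0.1, 0.9], ModelParams(), grid, recipe=recipe, node=(10, 10)
        )
        res2 = bifurcation_scan(
            "k0", [0.1, 0.9], ModelParams(), grid, recipe=recipe, node=(10, 10)
        )
        assert len(res1.peaksets) == 2 and len(res1.labels) == 2
        assert res1.transient == pytest.approx(30.0)
        for a, b in zip(res1.peaksets, res2.peaksets):
            assert np.array_equal(a.values, b.values)
        assert res1.labels == res2.labels

    def test_quiescent_media_has_empty_peaksets(self):
        grid = GridSpec(n_rows=10, n_cols=10, L=17.5, h=0.03, duration=10.0)
        from memfhn import homogeneous

        res = bifurcation_scan(
            "k0", [0.1], ModelParams(), grid, recipe=homogeneous(), node=(5, 5)
        )
        assert len(res.peaksets[0]) == 0
        assert res.labels[0] == "quiescent"

    def test_failed_value_flagged_not_fatal(self, tiny):
        grid, recipe = tiny
        res = bifurcation_scan(
            "k0", [0.1, 1e5], ModelParams(), grid, recipe=recipe, node=(10, 10)
        )
        assert 1 in res.failures
        assert 0 not in res.failures

    def test_unknown_parameter_rejected(self, tiny):
        grid, recipe = tiny
        with pytest.raises(ValueError):
            bifurcation_scan("alpha", [1.0], ModelParams(), grid, recipe=recipe)

    def test_peaks_table_long_format(self, tiny):
        grid, recipe = tiny
        res = bifurcation_scan(
            "k0", [0.1], ModelParams(), grid, recipe=recipe, node=(10, 10)
        )
        df = res.peaks_table()
        assert list(df.columns) == ["k0", "t", "peak_value"]
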