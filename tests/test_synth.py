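"""Synthetic environment, scenarios, response surfaces, sampling, tracks."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rangeshift.grid import GridSpec, RasterLayer
from rangeshift.synth import (
    OccurrenceSet,
    ResponseSpec,
    SyntheticScenario,
    Track,
    apply_scenario,
    generate_environment,
    generate_haulouts,
    preprocess_track,
    sample_presences,
    true_suitability,
)


class TestGenerateEnvironment:
    def test_deterministic_given_seed(self, small_grid):
        a = generate_environment(small_grid, seed=7)
        b = generate_environment(small_grid, seed=7)
        for la, lb in zip(a, b):
            assert np.array_equal(la.values, lb.values, equal_nan=True)

    def test_salinity_declines_north_to_south(self, env_stack):
        sal = env_stack["salinity"].values
        assert np.nanmean(sal[-1]) > np.nanmean(sal[0])

    def test_sediment_has_five_classes(self, env_stack):
        sed = env_stack["sediment"].values
        assert set(np.unique(sed[np.isfinite(sed)])) == {1.0, 2.0, 3.0, 4.0, 5.0}

    def test_slope_is_nonnegative(self, env_stack):
        slope = env_stack["slope"].values
        assert np.nanmin(slope) >= 0.0

    def test_small_grid_rejected(self):
        with pytest.raises(ValueError):
            generate_environment(GridSpec(0, 0, 1.0, 10, 10), seed=0)


class TestApplyScenario:
    def test_zero_deltas_identity(self, env_stack):
        out = apply_scenario(env_stack, SyntheticScenario(label="null"))
        for la, lb in zip(env_stack, out):
            assert np.array_equal(la.values, lb.values, equal_nan=True)

    def test_sst_delta_shifts_every_valid_cell(self, env_stack):
        out = apply_scenario(
            env_stack, SyntheticScenario(label="warm", sst_delta=2.7)
        )
        diff = out["temperature"].values - env_stack["temperature"].values
        assert np.allclose(diff[np.isfinite(diff)], 2.7)

    def test_static_layers_unchanged(self, env_stack):
        out = apply_scenario(
            env_stack,
            SyntheticScenario(label="x", sst_delta=1.0, sss_delta=-2.0),
        )
        assert np.array_equal(
            out["bathymetry"].values, env_stack["bathymetry"].values, equal_nan=True
        )

    def test_missing_dynamic_layer_rejected(self, env_stack):
        from rangeshift.grid import RasterStack

        partial = RasterStack(
            env_stack.grid, [lyr for lyr in env_stack if lyr.name != "salinity"]
        )
        with pytest.raises(ValueError):
            apply_scenario(partial, SyntheticScenario(label="x"))


class TestTrueSuitability:
    def test_flat_response_gives_half(self, env_stack):
        suit = true_suitability(env_stack, ResponseSpec())
        ok = np.isfinite(suit.values)
        assert np.allclose(suit.values[ok], 0.5)

    def test_negative_linear_salinity_is_monotone(self, env_stack):
        suit = true_suitability(
            env_stack, ResponseSpec(linear={"salinity": -3.0})
        )
        sal = env_stack["salinity"].values
        ok = np.isfinite(suit.values) & np.isfinite(sal)
        order = np.argsort(sal[ok])
        assert np.all(np.diff(suit.values[ok][order]) <= 1e-12)

    def test_quadratic_peak_at_gradient_midpoint(self, env_stack):
        # peak of a1*s + a2*s^2 at s = -a1/(2 a2) = 0.5 on the scaled axis
        suit = true_suitability(
            env_stack,
            ResponseSpec(linear={"salinity": 8.0}, quadratic={"salinity": -8.0}),
        )
        sal = env_stack["salinity"].values
        ok = np.isfinite(suit.values)
        lo, hi = np.nanmin(sal), np.nanmax(sal)
        best = np.nanargmax(np.where(ok, suit.values, -np.inf))
        mid = (lo + hi) / 2.0
        scaled_err = abs(sal.ravel()[best] - mid) / (hi - lo)
        # argmax salinity is the closest available cell to the midpoint
        closest = np.nanmin(np.abs(sal[ok] - mid)) / (hi - lo)
        assert scaled_err == pytest.approx(closest, abs=1e-12)

    def test_missing_layer_reference_rejected(self, env_stack):
        with pytest.raises(ValueError):
            true_suitability(env_stack, ResponseSpec(linear={"nope": 1.0}))


class TestSamplePresences:
    def test_point_mass_on_single_cell(self, small_grid):
        vals = np.zeros(small_grid.shape)
        vals[3, 4] = 1.0
        suit = RasterLayer(grid=small_grid, name="s", values=vals)
        occ = sample_presences(suit, n=50, seed=1)
        row, col = small_grid.cell_of(occ.points[:, 0], occ.points[:, 1])
        assert np.all(row == 3) and np.all(col == 4)

    def test_uniform_suitability_matches_multinomial(self, small_grid):
        suit = RasterLayer(grid=small_grid, name="s", values=np.ones(small_grid.shape))
        occ = sample_presences(suit, n=10_000, seed=2)
        row, col = small_grid.cell_of(occ.points[:, 0], occ.points[:, 1])
        counts = np.bincount(row * small_grid.n_cols + col,
                             minlength=small_grid.n_cells)
        _, p = stats.chisquare(counts)
        assert p > 0.001

    def test_strong_west_bias_dominates(self, small_grid):
        suit = RasterLayer(grid=small_grid, name="s", values=np.ones(small_grid.shape))
        bias_vals = np.ones(small_grid.shape)
        bias_vals[:, small_grid.n_cols // 2:] = 0.01  # 100:1 west:east
        bias = RasterLayer(grid=small_grid, name="b", values=bias_vals)
        occ = sample_presences(suit, n=2000, bias=bias, seed=3)
        west = occ.points[:, 0] < small_grid.x_min + 15.0
        assert west.mean() >= 0.95

    def test_zero_weights_rejected(self, small_grid):
        suit = RasterLayer(grid=small_grid, name="s", values=np.zeros(small_grid.shape))
        with pytest.raises(ValueError):
            sample_presences(suit, n=5, seed=0)

    def test_marginal_frequencies_converge(self, small_grid, rng):
        # empirical cell frequencies approach normalized weights (3 sigma)
        w = rng.random(small_grid.shape)
        suit = RasterLayer(grid=small_grid, name="s", values=w)
        n = 50_000
        occ = sample_presences(suit, n=n, seed=4)
        row, col = small_grid.cell_of(occ.points[:, 0], occ.points[:, 1])
        counts = np.bincount(row * small_grid.n_cols + col,
                             minlength=small_grid.n_cells)
        p = (w / w.sum()).ravel()
        _, pval = stats.chisquare(counts, n * p)
        assert pval > 0.001


class TestGenerateHaulouts:
    def test_reproducible(self, small_grid):
        a = generate_haulouts(5, small_grid, seed=9)
        b = generate_haulouts(5, small_grid, seed=9)
        assert a == b and len(a) == 5

    def test_elevations_within_declared_range(self, small_grid):
        hs = generate_haulouts(40, small_grid, elevation_range=(0.1, 0.9), seed=1)
        assert all(0.1 <= h.elevation_m <= 0.9 for h in hs)

    def test_default_range_straddles_all_cutoffs(self, small_grid):
        # effective rises span 0.24-0.75 m; defaults must bracket them
        hs = generate_haulouts(200, small_grid, seed=2)
        elevs = [h.elevation_m for h in hs]
        assert min(elevs) < 0.24 and max(elevs) > 0.75


def make_track(hours, deploy_offset_h=48, tag="gps"):
    t0 = pd.Timestamp("2020-06-01 00:00")
    ts = pd.DatetimeIndex([t0 + pd.Timedelta(hours=h) for h in hours])
    n = len(ts)
    return Track(
        species="sp",
        x=np.linspace(0, 1, n),
        y=np.linspace(0, 1, n),
        timestamps=ts,
        tag_type=tag,
        deploy_time=t0 - pd.Timedelta(hours=deploy_offset_h),
    )


class TestPreprocessTrack:
    def test_hourly_gps_day_reduces_to_four_fixes(self):
        out = preprocess_track(make_track(range(24)))
        assert len(out) == 4

    def test_retained_fixes_sit_on_target_hours(self):
        track = make_track(range(24))
        out = preprocess_track(track)
        # map retained x back to the original hour index
        idx = np.round(out.points[:, 0] * 23).astype(int)
        assert sorted(idx.tolist()) == [3, 9, 15, 21]

    def test_all_within_24h_of_deployment_dropped(self):
        out = preprocess_track(make_track(range(6), deploy_offset_h=0))
        assert len(out) == 0

    def test_tie_goes_to_earlier_fix(self):
        out = preprocess_track(make_track([2, 4]))
        idx = np.round(out.points[:, 0] * 1).astype(int)
        assert idx.tolist() == [0]  # the 02:00 fix wins the 03:00 slot

    def test_argos_passthrough_after_24h_cut(self):
        out = preprocess_track(make_track(range(24), tag="argos"))
        assert len(out) == 24

    def test_output_bounded_by_four_per_date(self, rng):
        hours = np.sort(rng.choice(np.arange(0, 24 * 5, dtype=float), 70,
                                   replace=False))
        out = preprocess_track(make_track(hours.tolist()))
        assert len(out) <= 4 * 5

    def test_nonmonotone_timestamps_rejected(self):
        with pytest.raises(ValueError):
            make_track([5, 3])


class TestOccurrenceSet:
    def test_frame_roundtrip(self):
        occ = OccurrenceSet(species="a", points=[[1.0, 2.0], [3.0, 4.0]])
        df = occ.to_frame()
        assert list(df.columns) == ["species", "x", "y"] and len(df) == 2
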