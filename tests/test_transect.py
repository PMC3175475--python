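import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from clinezone import SimConfig, fit_orientation, pava_fit, project_positions, simulate_zone
from clinezone.transect import EARTH_RADIUS_KM, _binom_loglik

from conftest import clean_config


def offset_dataset(base, dlat_km=0.0, dlon_km=0.0, rotate_deg=0.0):
    """Shift/rotate a dataset's coordinates in the local planar frame."""
    ds = base
    lat0, lon0 = float(ds.table["lat"].mean()), float(ds.table["lon"].mean())
    east = EARTH_RADIUS_KM * np.cos(np.deg2rad(lat0)) * np.deg2rad(ds.table["lon"] - lon0)
    north = EARTH_RADIUS_KM * np.deg2rad(ds.table["lat"] - lat0)
    th = np.deg2rad(rotate_deg)
    e2 = east * np.cos(th) + north * np.sin(th) + dlon_km
    n2 = -east * np.sin(th) + north * np.cos(th) + dlat_km
    out = ds.table.copy()
    out["lat"] = lat0 + np.rad2deg(n2 / EARTH_RADIUS_KM)
    out["lon"] = lon0 + np.rad2deg(e2 / (EARTH_RADIUS_KM * np.cos(np.deg2rad(lat0))))
    import dataclasses

    return dataclasses.replace(ds, table=out)


class TestProjectPositions:
    def test_origin_point_maps_to_zero(self, clean_zone):
        cfg, ds = clean_zone
        proj = project_positions(ds, 123.0)
        # centroid origin => centered positions
        assert abs(proj.position.mean()) < 1e-9

    @pytest.mark.parametrize(
        "heading,expected", [(0.0, 1.0), (207.0, np.cos(np.deg2rad(207.0)))]
    )
    def test_point_one_km_north_closed_form(self, heading, expected, clean_zone):
        _, ds = clean_zone
        lat0, lon0 = 33.0, -116.5
        one_km_north = lat0 + np.rad2deg(1.0 / EARTH_RADIUS_KM)
        t = ds.table.iloc[:1].copy()
        t["lat"], t["lon"] = [one_km_north], [lon0]
        import dataclasses

        sub = dataclasses.replace(ds, table=t)
        proj = project_positions(sub, heading, origin=(lat0, lon0))
        assert proj.position[0] == pytest.approx(expected, abs=1e-6)

    def test_heading_reversal_flips_sign(self, clean_zone):
        _, ds = clean_zone
        a = project_positions(ds, 30.0, origin=(33.34, -116.90)).position
        b = project_positions(ds, 210.0, origin=(33.34, -116.90)).position
        assert np.allclose(a, -b, atol=1e-12)

    def test_missing_coordinates_list_ids(self, clean_zone):
        _, ds = clean_zone
        t = ds.table.copy()
        t.loc[t.index[2], "lat"] = np.nan
        import dataclasses

        with pytest.raises(ValueError, match=str(t["id"].iloc[2])):
            project_positions(dataclasses.replace(ds, table=t), 0.0)


def monotone_grid_oracle(x, k, n, step=0.001):
    """DP exhaustive search over non-decreasing sequences on a frequency grid."""
    order = np.argsort(x)
    xs, ks, ns = np.asarray(x)[order], np.asarray(k)[order], np.asarray(n)[order]
    # pool ties like the implementation
    xu, inv = np.unique(xs, return_inverse=True)
    ku = np.bincount(inv, weights=ks)
    nu = np.bincount(inv, weights=ns)
    grid = np.arange(0.0, 1.0 + step / 2, step)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.where(ku[:, None] > 0, ku[:, None] * np.log(grid[None, :]), 0.0) + np.where(
            (nu - ku)[:, None] > 0, (nu - ku)[:, None] * np.log1p(-grid[None, :]), 0.0
        )
    best = ll[0]
    for i in range(1, len(xu)):
        best = np.maximum.accumulate(best) + ll[i]
    return float(best.max())


class TestPava:
    def test_monotone_input_is_fixed_point(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        k = np.array([0.0, 1.0, 2.0, 2.0])
        n = np.full(4, 2.0)
        fit = pava_fit(x, k, n, "increasing")
        assert np.allclose(fit.frequency, k / n)

    def test_single_violator_pooled_to_weighted_mean(self):
        fit = pava_fit([0.0, 1.0], [8.0, 2.0], [10.0, 10.0], "increasing")
        assert np.allclose(fit.frequency, [0.5, 0.5])

    def test_pooled_block_frequency_is_weighted_mean(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 1, 12)
        n = rng.integers(1, 3, 12).astype(float)
        k = rng.integers(0, 3, 12).clip(max=n).astype(float)
        fit = pava_fit(x, k, n, "increasing")
        assert np.diff(fit.frequency).min() >= -1e-12
        assert np.sum(fit.frequency * fit.weight) == pytest.approx(k.sum())

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10_000))
    def test_matches_exhaustive_grid_oracle(self, seed):
        """PAVA loglik equals the brute-force monotone grid max on 6 observations."""
        rng = np.random.default_rng(seed)
        x = rng.uniform(0, 1, 6)
        n = rng.integers(1, 3, 6).astype(float)
        k = np.array([rng.integers(0, int(m) + 1) for m in n], dtype=float)
        fit = pava_fit(x, k, n, "increasing")
        oracle = monotone_grid_oracle(x, k, n)
        assert fit.loglik == pytest.approx(oracle, abs=1e-3)
        assert fit.loglik >= oracle - 1e-3

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 10_000))
    def test_beats_random_monotone_candidates(self, seed):
        rng = np.random.default_rng(seed)
        x = np.sort(rng.uniform(0, 1, 8))
        n = np.full(8, 2.0)
        k = rng.integers(0, 3, 8).astype(float)
        fit = pava_fit(x, k, n, "increasing")
        xu, inv = np.unique(x, return_inverse=True)
        ku = np.bincount(inv, weights=k)
        nu = np.bincount(inv, weights=n)
        for _ in range(50):
            cand = np.sort(rng.uniform(0, 1, len(xu)))
            assert fit.loglik >= _binom_loglik(ku, nu, cand) - 1e-9

    def test_all_missing_locus_errors(self):
        with pytest.raises(ValueError, match="no scored"):
            pava_fit([0.0, 1.0], [np.nan, np.nan], [2.0, 2.0])

    def test_single_observation(self):
        fit = pava_fit([0.3], [1.0], [2.0])
        assert np.allclose(fit.frequency, [0.5])
        assert fit.loglik == pytest.approx(np.log(0.25))


class TestFitOrientation:
    def test_recovers_true_heading(self):
        """Heading MLE tracks the simulated cline axis; support brackets the MLE."""
        headings = []
        for seed in range(6):
            cfg = clean_config(seed=seed, n=335)
            res = fit_orientation(simulate_zone(cfg), grid=2.0)
            headings.append(res.heading)
            lo, hi = res.support
            width = (hi - lo) % 360.0
            assert (res.heading - lo) % 360.0 <= width + 1e-9
            assert res.directions_agree
        err = np.abs((np.array(headings) - 207.0 + 180.0) % 360.0 - 180.0)
        assert err.mean() < 5.0
        assert err.max() < 10.0

    def test_rotation_equivariance(self):
        cfg = clean_config(seed=6, n=200)
        ds = simulate_zone(cfg)
        base = fit_orientation(ds, grid=3.0, refine=False).heading
        rot = fit_orientation(offset_dataset(ds, rotate_deg=30.0), grid=3.0,
                              refine=False).heading
        assert (rot - base) % 360.0 == pytest.approx(30.0, abs=3.0 + 1e-9)

    def test_too_few_distinct_positions_errors(self, clean_zone):
        _, ds = clean_zone
        import dataclasses

        t = ds.table.iloc[:5].copy()
        t["lat"] = 33.34
        t["lon"] = -116.90
        with pytest.raises(ValueError, match="distinct"):
            fit_orientation(dataclasses.replace(ds, table=t))
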