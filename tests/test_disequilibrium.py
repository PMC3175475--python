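import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from clinezone import (
    SimConfig,
    cytonuclear_D_ml,
    het_deficit_ml,
    ld_scan,
    pairwise_D_ml,
    project_positions,
    simulate_zone,
)
from clinezone.disequilibrium import _haplotype_genotype_probs, d_bounds

from conftest import clean_config


class TestHetDeficit:
    @pytest.mark.parametrize(
        "counts,expected",
        [((25, 50, 25), 0.0), ((50, 0, 50), 0.25), ((30, 40, 30), 0.05)],
    )
    def test_plugin_arithmetic(self, counts, expected):
        est = het_deficit_ml(counts)
        assert est.D == pytest.approx(expected)

    def test_equivalent_to_f_times_pq(self):
        est = het_deficit_ml((12, 20, 40))
        p = est.p_a
        n_het_exp = 2 * p * (1 - p)
        f = 1 - (20 / 72) / n_het_exp
        assert est.D == pytest.approx(f * p * (1 - p))

    def test_empty_window_errors(self):
        with pytest.raises(ValueError):
            het_deficit_ml((0, 0, 0))


def random_table(rng, shape, n_max=30):
    N = int(rng.integers(4, n_max))
    return rng.multinomial(N, rng.dirichlet(np.ones(np.prod(shape)))).reshape(shape).astype(float)


def pairwise_grid_oracle(tab, step=0.001, margin_step=0.002, margin_span=0.02):
    """Exhaustive ML over (p_A, p_B, D) around the observed margins."""
    N2 = 2 * tab.sum()
    pa0 = (2 * tab[2].sum() + tab[1].sum()) / N2
    pb0 = (2 * tab[:, 2].sum() + tab[:, 1].sum()) / N2
    best = (-np.inf, 0.0)
    for pa in np.arange(pa0 - margin_span, pa0 + margin_span + 1e-12, margin_step):
        for pb in np.arange(pb0 - margin_span, pb0 + margin_span + 1e-12, margin_step):
            a, b = np.clip(pa, 1e-4, 1 - 1e-4), np.clip(pb, 1e-4, 1 - 1e-4)
            lo, hi = d_bounds(a, b)
            for D in np.arange(lo, hi + 1e-12, step):
                h = np.array(
                    [(1 - a) * (1 - b) + D, (1 - a) * b - D, a * (1 - b) - D, a * b + D]
                )
                if np.any(h < 0):
                    continue
                P = _haplotype_genotype_probs(h)
                ll = float(
                    np.sum(np.where(tab > 0, tab * np.log(np.maximum(P, 1e-300)), 0.0))
                )
                if ll > best[0]:
                    best = (ll, D)
    return best


class TestPairwiseD:
    def test_full_coupling(self):
        tab = np.zeros((3, 3))
        tab[2, 2] = tab[0, 0] = 50
        est = pairwise_D_ml(tab)
        assert est.D == pytest.approx(0.25)
        assert est.p_a == pytest.approx(0.5)

    def test_exact_independence(self):
        tab = np.outer([0.25, 0.5, 0.25], [0.25, 0.5, 0.25]) * 64
        assert pairwise_D_ml(tab).D == pytest.approx(0.0, abs=1e-8)

    @settings(max_examples=12, deadline=None)
    @given(st.integers(0, 10_000))
    def test_em_matches_grid_oracle(self, seed):
        """EM estimate agrees with brute-force grid search on small tables."""
        rng = np.random.default_rng(seed)
        tab = random_table(rng, (3, 3))
        N2 = 2 * tab.sum()
        pa = (2 * tab[2].sum() + tab[1].sum()) / N2
        pb = (2 * tab[:, 2].sum() + tab[:, 1].sum()) / N2
        if pa in (0.0, 1.0) or pb in (0.0, 1.0):
            return
        est = pairwise_D_ml(tab)
        ll_o, d_o = pairwise_grid_oracle(tab)
        if est.degenerate:
            assert abs(abs(d_o) - 0.0) < 0.25  # tie resolved to 0 by convention
        else:
            assert est.D == pytest.approx(d_o, abs=2e-3)
        assert est.loglik >= ll_o - 1e-6

    def test_monomorphic_locus_errors(self):
        tab = np.zeros((3, 3))
        tab[0, 1] = 10
        with pytest.raises(ValueError, match="monomorphic"):
            pairwise_D_ml(tab)

    def test_estimate_respects_frequency_bounds(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            tab = random_table(rng, (3, 3))
            N2 = 2 * tab.sum()
            pa = (2 * tab[2].sum() + tab[1].sum()) / N2
            pb = (2 * tab[:, 2].sum() + tab[:, 1].sum()) / N2
            if pa in (0.0, 1.0) or pb in (0.0, 1.0):
                continue
            est = pairwise_D_ml(tab)
            lo, hi = d_bounds(est.p_a, est.p_b)
            assert lo - 1e-9 <= est.D <= hi + 1e-9
            assert -0.25 - 1e-9 <= est.D <= 0.25 + 1e-9


def cytonuclear_grid_oracle(tab, step=0.001):
    """Brute force over the model (p_mt, p_nuc|mtE, p_nuc|mtK).

    The likelihood factorizes over the three parameters, so each factor is
    maximized independently on its own grid.
    """
    N = tab.sum()
    grid = np.arange(step, 1.0, step)

    def argmax_binom(k, n):
        with np.errstate(divide="ignore"):
            ll = k * np.log(grid) + (n - k) * np.log1p(-grid)
        return grid[np.argmax(ll)]

    p_mt = argmax_binom(tab[1].sum(), N)
    pK = argmax_binom(2 * tab[1, 2] + tab[1, 1], 2 * tab[1].sum())
    pE = argmax_binom(2 * tab[0, 2] + tab[0, 1], 2 * tab[0].sum())
    p_nuc = p_mt * pK + (1 - p_mt) * pE
    ll = None
    return ll, p_mt * pK - p_mt * p_nuc


class TestCytonuclearD:
    def test_full_association(self):
        tab = np.zeros((2, 3))
        tab[1, 2] = tab[0, 0] = 50
        assert cytonuclear_D_ml(tab).D == pytest.approx(0.25)

    def test_exact_independence(self):
        tab = np.outer([0.5, 0.5], [0.25, 0.5, 0.25]) * 40
        assert cytonuclear_D_ml(tab).D == pytest.approx(0.0, abs=1e-12)

    @settings(max_examples=10, deadline=None)
    @given(st.integers(0, 10_000))
    def test_closed_form_matches_grid_oracle(self, seed):
        rng = np.random.default_rng(seed)
        tab = random_table(rng, (2, 3))
        N = tab.sum()
        p_mt = tab[1].sum() / N
        p_nuc = (2 * tab[:, 2].sum() + tab[:, 1].sum()) / (2 * N)
        if p_mt in (0.0, 1.0) or p_nuc in (0.0, 1.0):
            return
        est = cytonuclear_D_ml(tab)
        _, d_o = cytonuclear_grid_oracle(tab)
        assert est.D == pytest.approx(d_o, abs=2e-3)

    def test_monomorphic_marker_errors(self):
        tab = np.zeros((2, 3))
        tab[0, 0] = tab[0, 2] = 5
        with pytest.raises(ValueError, match="monomorphic"):
            cytonuclear_D_ml(tab)


class TestLdScan:
    def test_window_centers_follow_stated_scheme(self, clean_zone):
        """Positions spanning 0-0.5 km, window 0.2, step 0.1 -> centers .1 .2 .3 .4"""
        cfg, ds = clean_zone
        import dataclasses

        sub = dataclasses.replace(ds, table=ds.table.iloc[:50].copy())
        proj = project_positions(sub, 0.0, origin=(33.34, -116.90))
        proj.position = np.linspace(0.0, 0.5, 50)
        out = ld_scan(proj, window=0.2, step=0.1, min_n=1)
        assert np.allclose(out["center"], [0.1, 0.2, 0.3, 0.4])

    def test_null_zone_has_no_disequilibrium(self):
        """Without parental mixing all three components hover near zero."""
        cfg = clean_config(seed=30, n=1000)
        ds = simulate_zone(cfg)
        proj = project_positions(ds, cfg.heading_true, (cfg.origin_lat, cfg.origin_lon))
        out = ld_scan(proj, min_n=25)
        for col in ("D_within", "D_between", "D_cytonuclear"):
            assert abs(np.nanmean(out[col])) < 0.02

    def test_mixing_produces_center_peaked_d(self, default_zone):
        cfg, ds = default_zone
        proj = project_positions(ds, cfg.heading_true, (cfg.origin_lat, cfg.origin_lon))
        out = ld_scan(proj)
        mid = np.abs(out["center"]) < 0.3
        flank = np.abs(out["center"]) > 0.55  # beyond ~1 km loci are monomorphic in-window
        assert np.nanmean(out.loc[mid, "D_between"]) > 0.05
        assert abs(np.nanmean(out.loc[flank, "D_between"])) < 0.03
        assert abs(np.nanmean(out.loc[np.abs(out["center"]) > 0.8, "D_within"])) < 0.02

    def test_asymmetric_mixing_peaks_on_that_flank(self):
        """Signed position of the pooled D peak falls on the mixing flank."""
        import warnings

        peaks = []
        for seed in range(50):
            cfg = SimConfig(seed=seed)
            ds = simulate_zone(cfg)
            proj = project_positions(
                ds, cfg.heading_true, (cfg.origin_lat, cfg.origin_lon)
            )
            out = ld_scan(proj)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                pooled = np.nanmean(
                    np.vstack(
                        [out["D_within"], out["D_between"], out["D_cytonuclear"]]
                    ),
                    axis=0,
                )
            peaks.append(out["center"][np.nanargmax(pooled)])
        n_neg = sum(p < 0 for p in peaks)
        from scipy.stats import binomtest

        assert binomtest(n_neg, len(peaks), 0.5, alternative="greater").pvalue < 0.05

    def test_min_n_omits_thin_windows(self, default_zone):
        cfg, ds = default_zone
        proj = project_positions(ds, cfg.heading_true, (cfg.origin_lat, cfg.origin_lon))
        out = ld_scan(proj, min_n=10_000)
        assert out[["D_within", "D_between", "D_cytonuclear"]].isna().all().all()
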