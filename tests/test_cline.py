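import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from clinezone import (
    TanhClineFitter,
    cline_loglik,
    fit_cline,
    fit_shared_and_test,
    simulate_zone,
    tanh_p,
)
from clinezone.cline import LRTResult

from conftest import clean_config, generator_frame_obs


class TestTanhP:
    def test_center_is_half(self):
        for w in (0.1, 0.75, 3.0):
            assert tanh_p(1.3, 1.3, w) == 0.5

    def test_half_width_point_closed_form(self):
        assert tanh_p(0.375, 0.0, 0.75) == pytest.approx((1 + np.tanh(1.0)) / 2)
        assert tanh_p(0.375, 0.0, 0.75) == pytest.approx(0.88080, abs=1e-5)

    @settings(max_examples=30, deadline=None)
    @given(
        d=st.floats(-5, 5, allow_nan=False),
        c=st.floats(-2, 2),
        w=st.floats(0.05, 3),
    )
    def test_antisymmetry_about_center(self, d, c, w):
        assert tanh_p(c - d, c, w) + tanh_p(c + d, c, w) == pytest.approx(1.0)

    def test_slope_at_center_is_inverse_width(self):
        """Width is the inverse of the maximum slope (slope at c = 1/w)."""
        for w in (0.2, 0.718, 0.764, 2.5):
            h = 1e-6
            slope = (tanh_p(h, 0, w) - tanh_p(-h, 0, w)) / (2 * h)
            assert slope == pytest.approx(1.0 / w, rel=1e-6)

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValueError):
            tanh_p(0.0, 0.0, 0.0)


class TestClineLoglik:
    def test_diploid_heterozygote_at_center(self):
        assert cline_loglik(0.0, 1.0, [0.0], [1.0], [2.0]) == pytest.approx(
            2 * np.log(0.5)
        )

    def test_haploid_at_center(self):
        assert cline_loglik(0.0, 1.0, [0.0], [1.0], [1.0]) == pytest.approx(np.log(0.5))

    def test_perfect_flank_data_approaches_zero(self):
        ll = cline_loglik(0.0, 0.1, [-50.0, 50.0], [0.0, 2.0], [2.0, 2.0])
        assert -1e-9 < ll <= 0.0

    def test_empty_observations_error(self):
        with pytest.raises(ValueError):
            cline_loglik(0.0, 1.0, [], [], [])


class TestFitCline:
    def test_recovers_parameters(self):
        """MLE lands near the simulated truth; supports bracket the MLE.

        (Frequentist coverage of the two-unit supports is checked as a rate
        over replicates in the acceptance suite; a single seed only warrants
        a point-accuracy check.)
        """
        cfg = clean_config(seed=12)
        ds = simulate_zone(cfg)
        obs = generator_frame_obs(ds, cfg)
        f = fit_cline(obs, share=list(obs))
        assert f.center == pytest.approx(0.0, abs=0.1)
        assert f.width == pytest.approx(0.75, abs=0.15)
        assert f.support_center[0] < f.center < f.support_center[1]
        assert f.support_width[0] < f.width < f.support_width[1]

    def test_duplicated_data_same_mle_narrower_support(self):
        cfg = clean_config(seed=13, n=200)
        ds = simulate_zone(cfg)
        obs = generator_frame_obs(ds, cfg)
        x, k, n = obs["CXCR4"]
        single = fit_cline((x, k, n))
        double = fit_cline((np.r_[x, x], np.r_[k, k], np.r_[n, n]))
        assert double.center == pytest.approx(single.center, abs=1e-3)
        assert double.width == pytest.approx(single.width, rel=1e-3)
        assert double.loglik == pytest.approx(2 * single.loglik, rel=1e-6)
        s1 = single.support_width[1] - single.support_width[0]
        s2 = double.support_width[1] - double.support_width[0]
        assert s2 < s1

    def test_monomorphic_data_errors(self):
        with pytest.raises(ValueError, match="monomorphic"):
            fit_cline((np.linspace(0, 1, 10), np.zeros(10), np.full(10, 2.0)))

    def test_profile_maximum_matches_joint_mle(self):
        cfg = clean_config(seed=14, n=150)
        ds = simulate_zone(cfg)
        f = fit_cline(generator_frame_obs(ds, cfg), share=["RAG1"])
        assert f.profile_center.loglik.max() == pytest.approx(f.loglik, abs=1e-4)
        assert f.profile_width.loglik.max() == pytest.approx(f.loglik, abs=1e-4)
        # support intervals contain the MLE
        assert f.support_center[0] <= f.center <= f.support_center[1]
        assert f.support_width[0] <= f.width <= f.support_width[1]

    def test_consistency_at_large_n(self):
        """Fitted (c, w) converge to truth for data generated on the cline."""
        rng = np.random.default_rng(0)
        x = rng.uniform(-1.75, 1.75, 10_000)
        k = rng.binomial(2, tanh_p(x, 0.1, 0.8)).astype(float)
        f = fit_cline((x, k, np.full_like(x, 2.0)), compute_support=False)
        assert f.center == pytest.approx(0.1, abs=0.02)
        assert f.width == pytest.approx(0.8, abs=0.05)


class TestSharedAndTest:
    def test_identical_data_gives_zero_G(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(-1.5, 1.5, 200)
        k = rng.binomial(2, tanh_p(x, 0.0, 0.7)).astype(float)
        n = np.full_like(x, 2.0)
        res = fit_shared_and_test({"a": (x, k, n), "b": (x, k, n)}, "center")
        assert res.lrt.G == pytest.approx(0.0, abs=1e-3)
        assert res.shared_fit.center == pytest.approx(
            res.per_locus_free["a"].center, abs=1e-3
        )

    def test_g_statistic_arithmetic(self):
        """G = 2 (LL_free - LL_shared); df = (L - 1) * shared params."""
        from scipy.stats import chi2

        G = 2.0 * (-100.0 - (-103.2))
        assert G == pytest.approx(6.4)
        res = LRTResult(G=G, df=3, p=float(chi2.sf(G, 3)))
        assert res.p == pytest.approx(chi2.sf(6.4, 3))

    def test_df_counts_loci_and_parameters(self):
        cfg = clean_config(seed=15, n=120)
        ds = simulate_zone(cfg)
        obs = generator_frame_obs(ds, cfg)
        assert fit_shared_and_test(obs, "center").lrt.df == 3
        assert fit_shared_and_test(obs, "width").lrt.df == 3
        assert fit_shared_and_test(obs, "both").lrt.df == 6

    def test_shared_ll_never_exceeds_free(self):
        cfg = clean_config(seed=16, n=120)
        ds = simulate_zone(cfg)
        obs = generator_frame_obs(ds, cfg)
        for shared in ("center", "width", "both"):
            res = fit_shared_and_test(obs, shared)
            assert res.lrt.G >= 0.0

    def test_shifted_locus_detected(self):
        """A locus with a strongly offset center makes the coincidence test reject."""
        cfg = clean_config(seed=17, n=400)
        cfg.center_per_locus["ND4"] = -0.5
        ds = simulate_zone(cfg)
        obs = generator_frame_obs(ds, cfg)
        res = fit_shared_and_test(obs, "center")
        assert res.lrt.p < 0.01
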