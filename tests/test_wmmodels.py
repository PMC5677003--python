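import numpy as np
import pandas as pd
import pytest
from scipy import integrate, special, stats

from serialdep import wmmodels as wm
from serialdep._angles import wrap_signed


def trials_df(err_deg, x_prev=None, delay=0.0):
    df = pd.DataFrame({"residual_error": np.asarray(err_deg, dtype=float)})
    df["delay_s"] = delay
    if x_prev is not None:
        df["x_prev"] = np.asarray(x_prev, dtype=float)
    return df


class TestEPDensity:
    def test_uniform_limit(self):
        e = np.linspace(-180, 180, 19)
        d = wm.ep_density(e, wm.EPParams(1e-8))
        assert np.allclose(d, 1 / (2 * np.pi), atol=1e-8)

    def test_integrates_to_one(self):
        for kappa in (0.5, 5.0, 50.0):
            val, _ = integrate.quad(
                lambda e: wm.ep_density(np.rad2deg(e), wm.EPParams(kappa)),
                -np.pi, np.pi,
            )
            assert val == pytest.approx(1.0, abs=1e-9)

    def test_mode_at_zero(self):
        p = wm.EPParams(4.0)
        d0 = wm.ep_density(0.0, p)
        assert np.all(d0 >= wm.ep_density(np.linspace(-180, 180, 100), p))

    def test_invalid_kappa_rejected(self):
        with pytest.raises(ValueError):
            wm.EPParams(0.0)


class TestKappaJMap:
    def test_small_kappa_limit(self):
        assert wm.kappa_to_j(1e-8) < 1e-10

    def test_round_trip(self):
        assert wm.j_to_kappa(wm.kappa_to_j(7.3)) == pytest.approx(7.3, abs=1e-8)

    def test_against_quadrature_bessel_oracle(self):
        # independent Bessel evaluation: I_n(k) = (1/pi) ∫ e^{k cos t} cos(nt) dt
        k = 2.0
        i0, _ = integrate.quad(lambda t: np.exp(k * np.cos(t)) / np.pi, 0, np.pi)
        i1, _ = integrate.quad(
            lambda t: np.exp(k * np.cos(t)) * np.cos(t) / np.pi, 0, np.pi
        )
        assert wm.kappa_to_j(k) == pytest.approx(k * i1 / i0, rel=1e-10)

    def test_vectorized_inverse_consistent_with_scalar(self):
        js = np.array([0.01, 0.5, 3.0, 40.0])
        ks = wm.j_to_kappa(js)
        for j, k in zip(js, ks):
            assert k == pytest.approx(wm.j_to_kappa(float(j)), rel=1e-5)


class TestVPDensity:
    def test_ep_limit_as_tau_vanishes(self):
        e = np.linspace(-180, 180, 73)
        d_vp = wm.vp_density(e, wm.VPParams(5.0, 1e-6), n_mc=2000, seed=0)
        d_ep = wm.ep_density(e, wm.EPParams(wm.j_to_kappa(5.0)))
        assert np.max(np.abs(d_vp - d_ep)) < 1e-4

    def test_symmetric(self):
        e = np.linspace(0, 180, 30)
        p = wm.VPParams(8.0, 4.0)
        d_pos = wm.vp_density(e, p, n_mc=4000, seed=1)
        d_neg = wm.vp_density(-e, p, n_mc=4000, seed=1)
        assert np.allclose(d_pos, d_neg)

    def test_normalized(self):
        d = wm.vp_density(wm.GRID_DEG, wm.VPParams(8.0, 4.0), n_mc=10_000, seed=2)
        total = np.trapezoid(d, np.deg2rad(wm.GRID_DEG))
        assert total == pytest.approx(1.0, abs=0.01)


class TestVMRWDensity:
    def test_uniform_limit_as_gain_vanishes(self):
        e = np.linspace(-180, 180, 19)
        d = wm.vmrw_density(e, wm.VMRWParams(2.0, 1e-9), n_mc=1000, seed=0)
        assert np.allclose(d, 1 / (2 * np.pi), atol=1e-6)

    def test_normalized(self):
        d = wm.vmrw_density(wm.GRID_DEG, wm.VMRWParams(2.0, 10.0), n_mc=10_000, seed=1)
        total = np.trapezoid(d, np.deg2rad(wm.GRID_DEG))
        assert total == pytest.approx(1.0, abs=0.01)

    def test_matches_forward_simulation(self):
        # density route (tilted r-mixture) vs decoding route (angle of the
        # resultant) on a 72-bin histogram
        rng = np.random.default_rng(2)
        errs = wm.vmrw_sample_errors(2.0, 10.0, 50_000, rng)
        bins = np.linspace(-np.pi, np.pi, 73)
        hist, _ = np.histogram(errs, bins=bins, density=True)
        centers = np.rad2deg((bins[:-1] + bins[1:]) / 2)
        dens = wm.vmrw_density(centers, wm.VMRWParams(2.0, 10.0), n_mc=10_000, seed=3)
        tv = 0.5 * np.sum(np.abs(hist - dens)) * (bins[1] - bins[0])
        assert tv < 0.05


class TestModelLoglik:
    @pytest.fixture
    def ep_data(self):
        rng = np.random.default_rng(4)
        y = np.rad2deg(rng.vonmises(0, 10.0, 500))
        x_prev = rng.uniform(-180, 180, 500)
        x_prev[0] = np.nan
        return trials_df(y, x_prev)

    def test_dog_shift_with_zero_amplitude_is_base(self, ep_data):
        p = wm.EPParams(10.0)
        ll0 = wm.model_loglik(ep_data, "EP", p)
        ll1 = wm.model_loglik(ep_data, "EP", p, wm.HistoryExtension("dog_shift", a=0.0))
        assert ll1 == pytest.approx(ll0, abs=1e-9)

    def test_swap_with_zero_alpha_is_base(self, ep_data):
        p = wm.EPParams(10.0)
        ll0 = wm.model_loglik(ep_data, "EP", p)
        ll1 = wm.model_loglik(ep_data, "EP", p, wm.HistoryExtension("swap", alpha_swap=0.0))
        assert ll1 == pytest.approx(ll0, abs=1e-9)

    def test_full_swap_explains_swap_generated_data(self):
        for seed in range(3):
            rng = np.random.default_rng(100 + seed)
            x_prev = rng.uniform(-180, 180, 600)
            y = wrap_signed(x_prev + np.rad2deg(rng.vonmises(0, 20.0, 600)))
            df = trials_df(y, x_prev)
            p = wm.EPParams(20.0)
            ll_swap = wm.model_loglik(df, "EP", p, wm.HistoryExtension("swap", alpha_swap=1.0))
            ll_base = wm.model_loglik(df, "EP", p)
            assert ll_swap > ll_base

    def test_shifted_mean_raises_likelihood_of_biased_data(self):
        from serialdep.tuning import DoGParams, dog_curve

        rng = np.random.default_rng(5)
        x_prev = rng.uniform(-180, 180, 800)
        shift = dog_curve(x_prev, DoGParams(3.0, 0.02))
        y = wrap_signed(shift + np.rad2deg(rng.vonmises(0, 130.0, 800)))
        df = trials_df(y, x_prev)
        p = wm.EPParams(130.0)
        ll_hyb = wm.model_loglik(df, "EP", p, wm.HistoryExtension("dog_shift", a=3.0, w=0.02))
        assert ll_hyb > wm.model_loglik(df, "EP", p)


class TestAICc:
    def test_hand_arithmetic(self):
        # 2k − 2LL + 2k(k+1)/(n−k−1) with k=2, n=200, LL=−100
        assert wm.aicc(2, 200, -100.0) == pytest.approx(204.0 + 12.0 / 197.0, abs=1e-12)

    def test_requires_enough_trials(self):
        with pytest.raises(ValueError):
            wm.aicc(5, 6, 0.0)


class TestFitWMModel:
    def test_ep_recovery(self):
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(200 + seed)
            df = trials_df(np.rad2deg(rng.vonmises(0, 8.0, 500)))
            fit = wm.fit_wm_model(df, "EP")
            kappa = fit.per_delay_params[0.0]["kappa"]
            hits += abs(kappa - 8.0) / 8.0 < 0.15
        assert hits >= 4

    def test_vmrw_effective_concentration_recovered(self):
        # kappa and xi trade off along a likelihood ridge at this sample
        # size; the identified combination is the effective concentration
        # kappa * (I1/I0)(kappa) * xi
        eff = lambda k, x: k * special.i1e(k) / special.i0e(k) * x
        truth = eff(2.0, 10.0)
        hits = 0
        for seed in range(3):
            rng = np.random.default_rng(300 + seed)
            df = trials_df(np.rad2deg(wm.vmrw_sample_errors(2.0, 10.0, 1000, rng)))
            fit = wm.fit_wm_model(df, "VMRW", n_mc=1000, seed=seed)
            p = fit.per_delay_params[0.0]
            hits += abs(eff(p["kappa"], p["xi"]) - truth) / truth < 0.25
        assert hits >= 2

    def test_per_delay_parameters_independent(self):
        rng = np.random.default_rng(6)
        y0 = np.rad2deg(rng.vonmises(0, 30.0, 400))
        y1 = np.rad2deg(rng.vonmises(0, 5.0, 400))
        df = pd.concat([trials_df(y0, delay=0.0), trials_df(y1, delay=6.0)],
                       ignore_index=True)
        fit = wm.fit_wm_model(df, "EP")
        assert fit.per_delay_params[0.0]["kappa"] > fit.per_delay_params[6.0]["kappa"]
        assert fit.k_params == 2

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            wm.fit_wm_model(trials_df([1.0, 2.0]), "VP")

    def test_hybrid_amplitude_recovery(self):
        from serialdep.tuning import DoGParams, dog_curve

        rng = np.random.default_rng(7)
        x_prev = rng.uniform(-180, 180, 1000)
        shift = dog_curve(x_prev, DoGParams(3.0, 0.02))
        y = wrap_signed(shift + np.rad2deg(rng.vonmises(0, 130.0, 1000)))
        fit = wm.fit_wm_model(trials_df(y, x_prev), "EP", extension_kind="dog_shift")
        assert 2.0 <= fit.per_delay_extension[0.0]["a"] <= 4.0


class TestSharedExtensionFit:
    def test_recovers_common_shift_across_delays(self):
        from serialdep.tuning import DoGParams, dog_curve

        rng = np.random.default_rng(11)
        frames = []
        for delay, kappa in [(0.0, 200.0), (6.0, 80.0)]:
            x_prev = rng.uniform(-180, 180, 600)
            shift = dog_curve(x_prev, DoGParams(2.0, 0.02))
            y = wrap_signed(shift + np.rad2deg(rng.vonmises(0, kappa, 600)))
            frames.append(pd.DataFrame(
                {"residual_error": y, "x_prev": x_prev, "delay_s": delay}))
        df = pd.concat(frames, ignore_index=True)
        fit = wm.fit_wm_model_shared_extension(df, "EP", "dog_shift")
        shared = fit.per_delay_extension["shared"]
        assert 1.3 <= shared["a"] <= 2.7
        # one shared (a, w) on top of one kappa per delay
        assert fit.k_params == 4
        # noise precision still resolved per delay
        assert fit.per_delay_params[0.0]["kappa"] > fit.per_delay_params[6.0]["kappa"]

    def test_requires_history_extension(self):
        df = pd.DataFrame({"residual_error": [1.0] * 20, "delay_s": 0.0})
        with pytest.raises(ValueError):
            wm.fit_wm_model_shared_extension(df, "EP", "none")


class TestCompareModels:
    def test_identical_fits_give_zero_delta(self):
        rng = np.random.default_rng(8)
        fits = [
            wm.fit_wm_model(trials_df(np.rad2deg(rng.vonmises(0, 10.0, 300))), "EP")
            for _ in range(3)
        ]
        out = wm.compare_models({"A": fits, "B": fits})
        assert out.loc[0, "delta_aicc_mean"] == 0.0

    def test_sign_convention_favors_first_named(self):
        rng = np.random.default_rng(9)
        df = trials_df(np.rad2deg(rng.vonmises(0, 10.0, 300)))
        good = wm.fit_wm_model(df, "EP")
        bad = wm.WMModelFit("EP", "none", {}, good.loglik - 50, 1, 300,
                            good.aicc + 100)
        out = wm.compare_models({"good": [good], "bad": [bad]})
        assert out.loc[0, "delta_aicc_mean"] > 0
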