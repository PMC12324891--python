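import numpy as np
import pytest
from scipy import special

from oracles import enumerate_loglik, enumerate_smoothing

from fiddlerwave.hmm import (
    HmmData,
    HmmError,
    HmmParameters,
    _loglik_terms,
    decode_states,
    expected_bout_length,
    fit_hmm,
    forward_loglik,
    transition_matrix,
)

P2 = ("x1", "x2")


def _data(counts, X=None, seg_lens=None):
    counts = np.asarray(counts, dtype=np.int64)
    n = counts.size
    X = np.zeros((n, len(P2))) if X is None else np.asarray(X, dtype=float)
    if seg_lens is None:
        seg_lens = [n]
    starts = np.cumsum([0] + list(seg_lens[:-1]))
    return HmmData(
        counts=counts,
        X=X,
        male_index=np.zeros(n, dtype=np.int64),
        seg_starts=np.asarray(starts, dtype=np.int64),
        seg_lens=np.asarray(seg_lens, dtype=np.int64),
        male_ids=("m1",),
        columns=P2,
    )


def _params(alpha, beta=None, u=None):
    return HmmParameters(
        np.asarray(alpha, dtype=float),
        np.zeros((4, len(P2))) if beta is None else beta,
        np.zeros(4),
        np.zeros((1, 4)) if u is None else u,
        P2,
    )


def _random_instance(rng, T, n_seg=1):
    counts = rng.poisson(1.0, T * n_seg)
    X = rng.normal(size=(T * n_seg, len(P2)))
    alpha = rng.normal(scale=0.8, size=4)
    alpha[2] = abs(alpha[2]) + 0.3
    alpha[3] = alpha[2] - 2.0
    beta = rng.normal(scale=0.5, size=(4, len(P2)))
    return _data(counts, X, [T] * n_seg), _params(alpha, beta)


class TestTransitionMatrix:
    def test_zero_predictors_give_coin_flip_rows(self):
        m = transition_matrix(_params([0.0, 0.0, 0.0, 0.0]), np.zeros(2))
        assert np.allclose(m, 0.5)

    def test_known_logits(self):
        m = transition_matrix(_params([np.log(4.0), np.log(1.5), 0.0, 0.0]), np.zeros(2))
        assert np.allclose(m, [[0.8, 0.2], [0.4, 0.6]])

    def test_link_saturation(self):
        m = transition_matrix(_params([500.0, 0.0, 0.0, 0.0]), np.zeros(2))
        assert m[0, 0] == pytest.approx(1.0)

    def test_rows_sum_to_one(self, rng):
        for _ in range(20):
            _, params = _random_instance(rng, 1)
            m = transition_matrix(params, rng.normal(size=len(P2)))
            assert np.allclose(m.sum(axis=1), 1.0)
            assert np.all((m >= 0) & (m <= 1))

    def test_nonfinite_predictor_rejected(self):
        with pytest.raises(HmmError):
            transition_matrix(_params([0.0, 0.0, 0.0, 0.0]), [np.nan, 0.0])


class TestForwardLoglik:
    def test_single_interval_is_two_state_mixture(self):
        lam_sig, lam_non, y = 1.4, 0.02, 2
        data = _data([y])
        # symmetric transitions -> stationary initial distribution (0.5, 0.5)
        ll = forward_loglik(data, _params([0.0, 0.0, np.log(lam_sig), np.log(lam_non)]))
        from scipy.stats import poisson

        expected = np.log(0.5 * poisson.pmf(y, lam_sig) + 0.5 * poisson.pmf(y, lam_non))
        assert ll == pytest.approx(expected, rel=1e-12)

    def test_degenerate_single_state_chain(self):
        # absorbing signalling state, unit rate: Pois(1;1)^2 = e^-2
        data = _data([1, 1])
        ll = forward_loglik(data, _params([500.0, -500.0, 0.0, -3.0]))
        assert ll == pytest.approx(-2.0, abs=1e-9)

    @pytest.mark.parametrize("T,n_seg", [(1, 1), (3, 1), (6, 1), (4, 3)])
    def test_matches_path_enumeration(self, rng, T, n_seg):
        data, params = _random_instance(rng, T, n_seg)
        eta = params.linear_predictors(data.X, data.male_index)
        expected = sum(
            enumerate_loglik(
                data.counts[s : s + l], eta[s : s + l]
            )
            for s, l in zip(data.seg_starts, data.seg_lens)
        )
        assert forward_loglik(data, params) == pytest.approx(expected, rel=1e-10)

    def test_invariant_to_segment_order(self, rng):
        data, params = _random_instance(rng, 5, 3)
        perm = [2, 0, 1]
        reordered = _data(
            np.concatenate([data.counts[s : s + 5] for s in data.seg_starts[perm]]),
            np.concatenate([data.X[s : s + 5] for s in data.seg_starts[perm]]),
            [5, 5, 5],
        )
        assert forward_loglik(reordered, params) == pytest.approx(
            forward_loglik(data, params), rel=1e-12
        )

    def test_empty_stream_rejected(self):
        with pytest.raises(HmmError):
            _data([])


class TestGradients:
    @pytest.mark.parametrize("emission,init", [("poisson", "stationary"), ("negbin", "uniform")])
    def test_analytic_gradient_matches_finite_differences(self, rng, emission, init):
        data, params = _random_instance(rng, 6, 2)
        eta = params.linear_predictors(data.X, data.male_index)
        log_r = 1.2 if emission == "negbin" else None
        ll, g_eta, g_logr = _loglik_terms(data, eta, emission, log_r, init, True)
        eps = 1e-6
        for t in range(0, eta.shape[0], 3):
            for k in range(4):
                e2 = eta.copy()
                e2[t, k] += eps
                ll2, _, _ = _loglik_terms(data, e2, emission, log_r, init, False)
                fd = (ll2 - ll) / eps
                assert g_eta[t, k] == pytest.approx(fd, rel=1e-4, abs=1e-7)
        if emission == "negbin":
            ll2, _, _ = _loglik_terms(data, eta, emission, log_r + eps, init, False)
            assert g_logr == pytest.approx((ll2 - ll) / eps, rel=1e-4)


class TestDecoding:
    def test_symmetric_unidentifiable_case_gives_half(self):
        data = _data([1, 0, 2, 1])
        out = decode_states(_params([0.0, 0.0, 0.5, 0.5 - 1e-12]), data)
        assert np.allclose(out["p_signalling"], 0.5)

    def test_count_spike_in_quiet_run_flags_signalling(self):
        data = _data([0, 5, 0])
        out = decode_states(_params([1.0, 1.0, np.log(1.4), np.log(0.02)]), data)
        assert out["p_signalling"].iloc[1] > 0.5
        assert out["p_signalling"].iloc[0] < 0.5

    @pytest.mark.parametrize("T", [2, 4, 6])
    def test_matches_enumerated_smoothing_posterior(self, rng, T):
        data, params = _random_instance(rng, T)
        eta = params.linear_predictors(data.X, data.male_index)
        expected = enumerate_smoothing(data.counts, eta)
        got = decode_states(params, data)["p_signalling"].to_numpy()
        assert np.allclose(got, expected, rtol=1e-8, atol=1e-10)

    def test_probabilities_are_complementary(self, rng):
        data, params = _random_instance(rng, 20, 2)
        p = decode_states(params, data)["p_signalling"].to_numpy()
        assert np.all((p >= 0) & (p <= 1))


class TestBoutLength:
    def test_leaving_immediately_gives_one_interval(self):
        assert expected_bout_length(0.0) == 5.0

    def test_stay_point_eight(self):
        assert expected_bout_length(0.8) == pytest.approx(25.0)

    def test_certain_stay_rejected(self):
        with pytest.raises(HmmError):
            expected_bout_length(1.0)

    def test_matches_simulated_chain_dwell_times(self, rng):
        p_stay = 0.5
        stays = rng.random(1_000_000) < p_stay
        # bout = 1 + number of consecutive stays
        lengths = []
        run = 1
        for s in stays:
            if s:
                run += 1
            else:
                lengths.append(run)
                run = 1
        mean_s = 5.0 * np.mean(lengths)
        se = 5.0 * np.std(lengths) / np.sqrt(len(lengths))
        assert abs(expected_bout_length(p_stay) - mean_s) < 4 * se


class TestFit:
    @pytest.fixture(scope="class")
    def tiny_fit(self, small_hmm_data):
        return fit_hmm(
            small_hmm_data, seed=21, n_chains=2, n_warmup=150, n_draws=150, max_leapfrog=24
        )

    def test_same_seed_reproduces_draws(self, small_hmm_data, tiny_fit):
        again = fit_hmm(
            small_hmm_data, seed=21, n_chains=2, n_warmup=150, n_draws=150, max_leapfrog=24
        )
        for name in tiny_fit.draws:
            assert np.array_equal(tiny_fit.draws[name], again.draws[name])

    def test_emission_rates_respect_label_ordering(self, tiny_fit):
        sig = np.asarray(tiny_fit.draws["rate_sig_intercept"])
        non = np.asarray(tiny_fit.draws["rate_non_intercept"])
        assert np.all(sig > non)

    def test_posterior_sds_are_positive(self, tiny_fit):
        for b in ("stay_sig", "stay_non", "rate_sig", "rate_non"):
            assert np.all(np.asarray(tiny_fit.draws[f"sigma_{b}"]) > 0)

    def test_posterior_decode_tracks_count_spikes(self, small_hmm_data, tiny_fit):
        out = decode_states(tiny_fit, small_hmm_data, n_draws=10)
        active = out[out["wave_count"] >= 2]["p_signalling"]
        quiet = out[out["wave_count"] == 0]["p_signalling"]
        assert active.mean() > 0.9
        assert quiet.mean() < 0.5


class TestEmissionInterceptCalibration:
    def test_hdi_coverage_of_generating_rates_over_replicates(self):
        """89% HDIs for both emission intercepts cover the realized truth
        in >= 70% of replicate small-study fits (4 males each)."""
        from fiddlerwave.design import HMM_COLUMNS
        from fiddlerwave.hmm import prepare_hmm_data
        from fiddlerwave.reporting import hdi
        from fiddlerwave.simulate import (
            HmmTruth,
            SimulationConfig,
            simulate_study,
            study_intervals,
        )

        truth = HmmTruth(beta=tuple((0.0,) * len(HMM_COLUMNS) for _ in range(4)))
        n_rep = 20
        cov_sig = cov_non = 0
        for k in range(n_rep):
            study = simulate_study(SimulationConfig(n_blocks=1, hmm=truth), seed=300 + k)
            data = prepare_hmm_data(study_intervals(study), study.metadata)
            post = fit_hmm(
                data, seed=600 + k, n_chains=1, n_warmup=250, n_draws=250, max_leapfrog=24
            )
            u = np.array([t.u_hmm for t in study.trials])
            realized_sig = 1.4 * np.exp(u[:, 2].mean())
            realized_non = 0.02 * np.exp(u[:, 3].mean())
            lo, hi = hdi(np.exp(np.asarray(post.draws["rate_sig_intercept"])).ravel())
            cov_sig += lo <= realized_sig <= hi
            lo, hi = hdi(np.exp(np.asarray(post.draws["rate_non_intercept"])).ravel())
            cov_non += lo <= realized_non <= hi
        assert cov_sig >= int(0.7 * n_rep)
        assert cov_non >= int(0.7 * n_rep)


class TestBoutPredictions:
    def _posterior_with(self, fast_effect_draws):
        """Hand-built posterior: point mass on everything but the fast effect."""
        from fiddlerwave._hmc import SamplerResult
        from fiddlerwave.hmm import HmmPosterior

        n = len(fast_effect_draws)
        zeros = np.zeros((1, n))
        draws = {}
        for b in ("stay_sig", "stay_non", "rate_sig", "rate_non"):
            draws[f"{b}_intercept"] = zeros.copy()
            for c in ("slow_wave", "fast_wave"):
                draws[f"{b}_{c}"] = zeros.copy()
            draws[f"sigma_{b}"] = zeros + 0.1
        draws["stay_sig_fast_wave"] = np.asarray(fast_effect_draws)[None, :]
        sampler = SamplerResult(
            draws=np.zeros((1, n, 1)),
            accept_rate=np.ones(1),
            step_size=np.ones(1),
            n_warmup=0,
            seed=0,
            divergences=np.zeros(1),
        )
        return HmmPosterior(
            draws=draws,
            random_effect_draws=np.zeros((1, n, 1, 4)),
            columns=("slow_wave", "fast_wave"),
            male_ids=("m1",),
            emission="poisson",
            init="stationary",
            sampler=sampler,
        )

    def test_point_mass_at_zero_logit_predicts_ten_seconds(self):
        from fiddlerwave.hmm import predict_bout_lengths

        post = self._posterior_with(np.zeros(200))
        table = predict_bout_lengths(post).set_index("parameter")
        assert table.loc["no_wave", "mean"] == pytest.approx(10.0)
        assert table.loc["fast", "mean"] == pytest.approx(10.0)

    def test_larger_fast_effect_never_shortens_fast_bouts(self, rng):
        from fiddlerwave.hmm import predict_bout_lengths

        base = rng.normal(0.5, 0.2, size=300)
        post_lo = self._posterior_with(base)
        post_hi = self._posterior_with(base + 0.7)
        lo = predict_bout_lengths(post_lo).set_index("parameter").loc["fast", "mean"]
        hi = predict_bout_lengths(post_hi).set_index("parameter").loc["fast", "mean"]
        assert hi >= lo
        no_lo = predict_bout_lengths(post_lo).set_index("parameter").loc["no_wave", "mean"]
        no_hi = predict_bout_lengths(post_hi).set_index("parameter").loc["no_wave", "mean"]
        assert no_lo == pytest.approx(no_hi)
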