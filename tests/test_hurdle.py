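import numpy as np
import pytest
from scipy import stats

from fiddlerwave.design import HURDLE_COLUMNS
from fiddlerwave.hurdle import (
    HurdleData,
    HurdleError,
    HurdleParameters,
    fit_hurdle,
    hurdle_loglik,
    predict_cells,
    prepare_hurdle_data,
)

P = len(HURDLE_COLUMNS)


def _data(entered, proportion, X=None, male_index=None, n_males=None):
    entered = np.asarray(entered, dtype=bool)
    n = entered.size
    male_index = np.zeros(n, dtype=np.int64) if male_index is None else np.asarray(male_index)
    n_males = int(male_index.max()) + 1 if n_males is None else n_males
    return HurdleData(
        X=np.zeros((n, P)) if X is None else X,
        entered=entered,
        proportion=np.asarray(proportion, dtype=float),
        male_index=male_index,
        male_ids=tuple(f"m{i}" for i in range(n_males)),
        columns=HURDLE_COLUMNS,
    )


def _params(ie=0.0, io=0.0, phi=2.0, be=None, bo=None, **kw):
    return HurdleParameters(
        intercept_entry=ie,
        beta_entry=np.zeros(P) if be is None else be,
        intercept_occ=io,
        beta_occ=np.zeros(P) if bo is None else bo,
        phi=phi,
        **kw,
    )


class TestLoglik:
    def test_non_entry_contributes_log_half_at_even_odds(self):
        data = _data([False], [np.nan])
        assert hurdle_loglik(data, _params()) == pytest.approx(np.log(0.5))

    def test_uniform_beta_adds_nothing_for_any_proportion(self):
        # mu=0.5, phi=2 -> Beta(1,1): log-density 0; only the entry term remains
        for prop in (0.17, 0.5, 0.93):
            data = _data([True], [prop])
            assert hurdle_loglik(data, _params()) == pytest.approx(np.log(0.5))

    def test_matches_term_by_term_scipy_oracle(self, rng):
        n = 30
        X = rng.normal(size=(n, P)) * 0.5
        entered = rng.random(n) < 0.6
        prop = np.where(entered, rng.uniform(0.05, 0.95, n), np.nan)
        midx = rng.integers(0, 4, n)
        data = _data(entered, prop, X=X, male_index=midx, n_males=4)
        params = _params(
            ie=0.3,
            io=-0.4,
            phi=7.0,
            be=rng.normal(scale=0.4, size=P),
            bo=rng.normal(scale=0.4, size=P),
            sigma_entry=0.5,
            sigma_occ=0.3,
            u_entry=rng.normal(scale=0.5, size=4),
            u_occ=rng.normal(scale=0.3, size=4),
        )
        expected = 0.0
        for i in range(n):
            eta_e = params.intercept_entry + X[i] @ params.beta_entry + params.u_entry[midx[i]]
            p = 1.0 / (1.0 + np.exp(-eta_e))
            expected += stats.bernoulli.logpmf(int(entered[i]), p)
            if entered[i]:
                eta_o = params.intercept_occ + X[i] @ params.beta_occ + params.u_occ[midx[i]]
                mu = 1.0 / (1.0 + np.exp(-eta_o))
                expected += stats.beta.logpdf(prop[i], mu * params.phi, (1 - mu) * params.phi)
        assert hurdle_loglik(data, params) == pytest.approx(expected, rel=1e-10)

    def test_entry_and_occupancy_parts_decompose(self, rng):
        """Total likelihood = entry-only sum + occupancy-only sum."""
        n = 20
        entered = rng.random(n) < 0.5
        entered[0] = True
        prop = np.where(entered, rng.uniform(0.1, 0.9, n), np.nan)
        data = _data(entered, prop)
        params = _params(ie=0.7, io=-0.2, phi=4.0)
        entry_only = np.sum(
            stats.bernoulli.logpmf(entered.astype(int), 1 / (1 + np.exp(-0.7)))
        )
        mu = 1 / (1 + np.exp(0.2))
        occ_only = np.sum(stats.beta.logpdf(prop[entered], mu * 4.0, (1 - mu) * 4.0))
        assert hurdle_loglik(data, params) == pytest.approx(entry_only + occ_only, rel=1e-10)

    def test_invalid_proportion_rejected(self):
        with pytest.raises(HurdleError):
            _data([True], [1.5])
        with pytest.raises(HurdleError):
            _data([True], [np.nan])


class TestBoundarySmoothing:
    def test_full_occupancy_pulled_inside_open_interval(self):
        data = _data([True, True, True], [1.0, 0.4, 0.6])
        y = data.smoothed_proportion()
        assert y[0] == pytest.approx((1.0 * 2 + 0.5) / 3)
        assert y[1] == 0.4 and y[2] == 0.6

    def test_interior_values_untouched(self):
        data = _data([True, False], [0.25, np.nan])
        assert data.smoothed_proportion()[0] == 0.25


class TestFit:
    @pytest.fixture(scope="class")
    def fitted(self, small_study):
        from fiddlerwave.simulate import study_burrow_use

        data = prepare_hurdle_data(study_burrow_use(small_study), small_study.metadata)
        return data, fit_hurdle(data, seed=5, n_chains=2, n_warmup=200, n_draws=200)

    def test_same_seed_reproduces_draws(self, fitted):
        data, post = fitted
        again = fit_hurdle(data, seed=5, n_chains=2, n_warmup=200, n_draws=200)
        for name in post.draws:
            assert np.array_equal(post.draws[name], again.draws[name])

    def test_precision_and_sds_positive(self, fitted):
        _, post = fitted
        assert np.all(np.asarray(post.draws["phi"]) > 0)
        assert np.all(np.asarray(post.draws["sigma_entry"]) > 0)

    def test_all_entered_pushes_entry_intercept_positive(self):
        rng = np.random.default_rng(0)
        n = 40
        data = _data(
            np.ones(n, dtype=bool),
            rng.uniform(0.2, 0.8, n),
            male_index=np.arange(n) % 10,
            n_males=10,
        )
        post = fit_hurdle(data, seed=1, n_chains=2, n_warmup=200, n_draws=200)
        # complete separation: posterior bounded only by the prior, clearly positive
        assert np.mean(np.asarray(post.draws["entry_intercept"])) > 1.0

    def test_empty_cell_warns(self):
        rng = np.random.default_rng(2)
        X = np.zeros((8, P))  # every record in the no-wave x small cell
        data = _data(
            rng.random(8) < 0.5, np.where(rng.random(8) < 0.5, 0.4, 0.4), X=X
        )
        with pytest.warns(UserWarning, match="empty treatment cell"):
            fit_hurdle(data, seed=3, n_chains=1, n_warmup=50, n_draws=50)


class TestCellPredictions:
    def _posterior(self, draws):
        from fiddlerwave._hmc import SamplerResult
        from fiddlerwave.hurdle import HurdlePosterior

        n = next(iter(draws.values())).shape[1]
        full = {}
        for part in ("entry", "occ"):
            full[f"{part}_intercept"] = np.zeros((1, n))
            for c in HURDLE_COLUMNS:
                full[f"{part}_{c}"] = np.zeros((1, n))
        full["phi"] = np.full((1, n), 5.0)
        full["sigma_entry"] = full["sigma_occ"] = np.full((1, n), 0.1)
        full.update(draws)
        sampler = SamplerResult(np.zeros((1, n, 1)), np.ones(1), np.ones(1), 0, 0, np.zeros(1))
        return HurdlePosterior(full, {}, HURDLE_COLUMNS, ("m1",), sampler)

    def test_zero_coefficients_give_even_odds_everywhere(self):
        post = self._posterior({"entry_intercept": np.zeros((1, 100))})
        table = predict_cells(post)
        entry = table[table["part"] == "p_enter"]
        assert np.allclose(entry["mean"], 0.5)

    def test_cell_contrast_is_linear_on_link_scale(self, rng):
        slow = rng.normal(-1.0, 0.3, size=(1, 200))
        post = self._posterior({"entry_slow_wave": slow})
        b = np.stack([post.draws[f"entry_{c}"] for c in HURDLE_COLUMNS], axis=-1)
        from fiddlerwave.hmm import condition_grid

        grid = condition_grid(HURDLE_COLUMNS, claw_levels=("small",))
        lin_no = post.draws["entry_intercept"] + b @ grid["no_wave"]
        lin_slow = post.draws["entry_intercept"] + b @ grid["slow"]
        assert np.allclose(lin_no - lin_slow, -slow)

    def test_recovers_simulated_entry_ordering(self, small_study):
        from fiddlerwave.simulate import study_burrow_use

        data = prepare_hurdle_data(study_burrow_use(small_study), small_study.metadata)
        post = fit_hurdle(data, seed=9, n_chains=2, n_warmup=250, n_draws=250)
        table = predict_cells(post).set_index("parameter")
        # generator truth: waving robots sharply reduce entry for small-claw cells
        assert (
            table.loc["p_enter[slow_small]", "mode"] < table.loc["p_enter[no_wave_small]", "mode"]
        )
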