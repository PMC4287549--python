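import numpy as np
import pandas as pd
import pytest


from bymst.inference import (
    MCMCSettings,
    PosteriorDraws,
    convergence_report,
    effective_sample_size,
    fit,
    rhat,
    summarize,
)
from bymst.model import ModelSpec
from bymst.synthetic_data import recovery_scenario


def make_fake_draws(draws_dict, spec=None, loglik=None):
    n_kept = len(next(iter(draws_dict.values())))
    base = {
        "beta0": np.zeros(n_kept),
        "upsilon": np.zeros((n_kept, 3)),
        "S": np.zeros((n_kept, 3)),
        "tau_t": np.zeros((n_kept, 2)),
    }
    base.update(draws_dict)
    return PosteriorDraws(
        draws=base,
        loglik=np.zeros(n_kept) if loglik is None else loglik,
        loglik_rows=None,
        n_kept=n_kept,
        n_burnin=0,
        thin=1,
        seed=0,
        acceptance={},
        spec=spec or ModelSpec(),
        tract_ids=np.array(["a", "b", "c"]),
        years=np.array([2000, 2001]),
    )


def reference_glm_sampler(O, X, offset, n_iter=60_000, seed=123):
    """Independent single-site random-walk Metropolis for the Poisson GLM
    with Normal(0, 10^2) coefficient priors."""
    rng = np.random.default_rng(seed)
    p = X.shape[1]
    beta = np.zeros(p)
    lp = offset + X @ beta
    ll = np.sum(O * lp - np.exp(lp))
    keep = []
    step = np.full(p, 0.1)
    for it in range(n_iter):
        for j in range(p):
            prop = beta.copy()
            prop[j] += step[j] * rng.normal()
            lp_new = offset + X @ prop
            ll_new = np.sum(O * lp_new - np.exp(lp_new))
            dprior = -0.5 * (prop[j] ** 2 - beta[j] ** 2) / 100.0
            if np.log(rng.random()) < ll_new - ll + dprior:
                beta, ll = prop, ll_new
                if it < n_iter // 4:
                    step[j] *= 1.02
            elif it < n_iter // 4:
                step[j] *= 0.99
        if it >= n_iter // 4:
            keep.append(beta.copy())
    return np.asarray(keep)


class TestFitOracles:
    def test_fixed_effects_match_reference_sampler(self):
        rng = np.random.default_rng(3)
        n = 150
        q = rng.integers(1, 6, n)
        X = np.column_stack(
            [np.ones(n)] + [(q == j).astype(float) for j in range(2, 6)]
        )
        beta_true = np.array([-0.3, 0.2, -0.1, -0.4, -0.6])
        pob = np.full(n, 50.0)
        offset = np.log(pob)
        O = rng.poisson(np.exp(offset + X @ beta_true))

        from bymst.synthetic_data import generate_geometry

        geom = generate_geometry(n, seed=1)
        panel = pd.DataFrame(
            {
                "tract_id": geom.tract_id,
                "year": 2000,
                "O": O,
                "Pob": pob,
                "P4564": 0.0,
                "P65M": 0.0,
                "quintile": q,
            }
        )
        # a complete grid needs >= 2 years: duplicate the design
        panel2 = panel.assign(year=2001, O=rng.poisson(np.exp(offset + X @ beta_true)))
        full = pd.concat([panel, panel2], ignore_index=True)
        spec = ModelSpec(
            family="poisson",
            include_ages=False,
            include_heterogeneity=False,
            include_spatial=False,
            include_temporal=False,
            seed=5,
        )
        draws = fit(full, geom, spec, MCMCSettings(n_iter=8000, n_burnin=3000, thin=1))
        mine = np.column_stack([draws.draws["beta0"], draws.draws["beta"]])

        O_all = full.sort_values(["tract_id", "year"])["O"].to_numpy(dtype=float)
        # tract ids are zero-padded, so sorted order == construction order
        Xs = X.repeat(2, axis=0)
        offs = np.log(np.full(2 * n, 50.0))
        ref = reference_glm_sampler(O_all, Xs, offs)

        for j in range(5):
            se = np.sqrt(
                mine[:, j].var() / max(effective_sample_size(mine[None, :, j]), 10)
                + ref[:, j].var() / max(effective_sample_size(ref[None, :, j]), 10)
            )
            assert abs(mine[:, j].mean() - ref[:, j].mean()) < 3 * se + 0.01

    def test_null_likelihood_recovers_prior(self):
        geom, panel, _ = recovery_scenario(seed=11, n_tracts=20, n_years=4)
        spec = ModelSpec(
            family="poisson",
            null_likelihood=True,
            include_quintiles=False,
            include_ages=False,
            include_heterogeneity=False,
            include_spatial=False,
            include_temporal=False,
            seed=2,
        )
        draws = fit(panel, geom, spec, MCMCSettings(n_iter=30_000, n_burnin=5000, thin=5))
        b0 = draws.draws["beta0"]
        ess = max(effective_sample_size(b0[None, :]), 20)
        assert abs(b0.mean() - 0.0) < 3 * 10.0 / np.sqrt(ess)
        assert 0.75 < b0.std() / 10.0 < 1.25

    def test_q5_interval_covers_generating_value(self):
        geom, panel, truth = recovery_scenario(seed=2024)
        spec = ModelSpec(family="poisson", seed=2024)
        draws = fit(panel, geom, spec, MCMCSettings(n_iter=5000, n_burnin=2000, thin=1))
        s = summarize(draws)
        assert s.rr.loc["Q5", "lo"] <= np.exp(truth.beta[3]) <= s.rr.loc["Q5", "hi"]

    def test_relabeling_tracts_preserves_summary(self):
        geom, panel, _ = recovery_scenario(seed=31, n_tracts=25, n_years=4)
        spec = ModelSpec(family="poisson", seed=8)
        settings = MCMCSettings(n_iter=4000, n_burnin=1600, thin=1)
        s1 = summarize(fit(panel, geom, spec, settings))

        mapping = {t: f"Z{i:03d}" for i, t in enumerate(reversed(geom.tract_id))}
        panel2 = panel.assign(tract_id=panel["tract_id"].map(mapping))
        import dataclasses

        geom2 = dataclasses.replace(
            geom, tract_id=np.array([mapping[t] for t in geom.tract_id])
        )
        s2 = summarize(fit(panel2, geom2, spec, settings))
        assert np.allclose(
            s1.rr["mean"].to_numpy(), s2.rr["mean"].to_numpy(), atol=0.06
        )

    def test_zip_fit_recovers_zero_inflation(self):
        geom, panel, truth = recovery_scenario(seed=91, n_tracts=40, n_years=6, family="zip")
        spec = ModelSpec(family="zip", seed=91)
        draws = fit(panel, geom, spec, MCMCSettings(n_iter=3000, n_burnin=1200, thin=1))
        p0 = draws.draws["p_zero"]
        assert abs(p0.mean() - truth.p_zero) < 0.06


class TestSummarize:
    def test_degenerate_draws_not_significant(self):
        d = make_fake_draws({"beta": np.zeros((200, 4)), "gamma": np.zeros((200, 2))})
        s = summarize(d)
        assert np.allclose(s.rr["mean"], 1.0)
        assert np.allclose(s.rr["lo"], 1.0) and np.allclose(s.rr["hi"], 1.0)
        assert not s.rr["significant"].any()

    def test_point_mass_log2(self):
        d = make_fake_draws(
            {"beta": np.full((150, 4), np.log(2.0)), "gamma": np.zeros((150, 2))}
        )
        s = summarize(d)
        assert np.allclose(s.rr["mean"], 2.0)
        assert s.rr["significant"].all()

    def test_lognormal_mean_formula(self, rng):
        n = 10_000
        beta = rng.normal(0.0, 0.25, size=(n, 4))
        d = make_fake_draws({"beta": beta, "gamma": np.zeros((n, 2))})
        s = summarize(d)
        expect = np.exp(0.25**2 / 2)
        se = np.exp(0.25**2 / 2) * 0.25 / np.sqrt(n)  # delta-method SE
        assert np.allclose(s.rr["mean"], expect, atol=5 * se)

    def test_too_few_draws_rejected(self):
        d = make_fake_draws({"beta": np.zeros((50, 4)), "gamma": np.zeros((50, 2))})
        with pytest.raises(ValueError, match="100"):
            summarize(d)

    def test_mean_of_exp_not_exp_of_mean(self, rng):
        beta = rng.normal(0.0, 0.5, size=(5000, 4))
        d = make_fake_draws({"beta": beta, "gamma": np.zeros((5000, 2))})
        s = summarize(d)
        assert (s.rr["mean"] > np.exp(beta.mean(axis=0)) + 0.02).all()


class TestConvergence:
    def test_identical_chains_rhat_exactly_one(self, rng):
        chain = rng.normal(size=600)
        spec = ModelSpec(include_quintiles=False, include_ages=False)
        a = make_fake_draws({"beta0": chain}, spec=spec)
        b = make_fake_draws({"beta0": chain.copy()}, spec=spec)
        report = convergence_report([a, b])
        assert report.loc["beta0", "rhat"] == 1.0

    def test_shifted_chains_flagged(self, rng):
        spec = ModelSpec(include_quintiles=False, include_ages=False)
        a = make_fake_draws({"beta0": rng.normal(0, 1, 500)}, spec=spec)
        b = make_fake_draws({"beta0": rng.normal(5, 1, 500)}, spec=spec)
        with pytest.warns(UserWarning, match="R-hat"):
            report = convergence_report([a, b])
        assert report.loc["beta0", "rhat"] > 1.05

    def test_iid_ess_close_to_chain_length(self, rng):
        chains = rng.normal(size=(2, 10_000))
        ess = effective_sample_size(chains)
        assert abs(ess - 20_000) / 20_000 < 0.10

    def test_autocorrelated_ess_is_lower(self, rng):
        x = np.zeros(5000)
        for t in range(1, 5000):
            x[t] = 0.95 * x[t - 1] + rng.normal()
        assert effective_sample_size(x[None, :]) < 1000

    def test_mismatched_lengths_rejected(self):
        spec = ModelSpec(include_quintiles=False, include_ages=False)
        a = make_fake_draws({"beta0": np.zeros(300)}, spec=spec)
        b = make_fake_draws({"beta0": np.zeros(200)}, spec=spec)
        with pytest.raises(ValueError, match="mismatched"):
            convergence_report([a, b])

    def test_single_chain_rejected(self):
        a = make_fake_draws({"beta0": np.zeros(300)})
        with pytest.raises(ValueError):
            convergence_report([a])

    def test_real_chains_mix(self, small_chains):
        report = convergence_report(small_chains)
        # the weakly identified Matern scale is allowed to mix slowly at
        # this chain length; the reported effects must not be
        effects = [r for r in report.index if r.startswith(("beta", "gamma"))]
        assert (report.loc[effects, "rhat"] < 1.25).all()


class TestGuards:
    def test_nan_draws_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            make_fake_draws({"beta0": np.array([0.0, np.nan, 1.0])})

    def test_settings_validation(self):
        with pytest.raises(ValueError):
            MCMCSettings(n_iter=100, n_burnin=100)
        with pytest.raises(ValueError):
            MCMCSettings(thin=0)

    def test_incomplete_grid_rejected(self, small_scenario):
        geom, panel, _ = small_scenario
        with pytest.raises(ValueError, match="one row per"):
            fit(panel.iloc[:-3], geom, ModelSpec())

    def test_acceptance_rates_sane(self, small_fit):
        draws, *_ = small_fit
        for key in ("fe", "ups", "S", "tau_t"):
            assert 0.05 < draws.acceptance[key] < 0.95
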