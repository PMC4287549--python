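import numpy as np
import pandas as pd
import pytest

from bymst.model import zip_pmf
from bymst.synthetic_data import (
    Geometry,
    TruthRecord,
    default_study_scenario,
    generate_geometry,
    make_covariate_panel,
    recovery_scenario,
    simulate_counts,
    simulate_fields,
    simulate_indicator_table,
)


class TestGeometry:
    def test_pythagorean_distance(self):
        geom = Geometry(
            tract_id=np.array(["a", "b"]),
            x=np.array([0.0, 3.0]),
            y=np.array([0.0, 4.0]),
            pairwise_distance=np.array([[0.0, 5.0], [5.0, 0.0]]),
        )
        assert geom.pairwise_distance[0, 1] == 5.0

    def test_generate_542_tracts(self):
        geom = generate_geometry(542, extent=50.0, seed=3)
        assert geom.n_tracts == 542
        assert len(np.unique(geom.tract_id)) == 542
        D = geom.pairwise_distance
        assert D.shape == (542, 542)
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0.0)

    def test_triangle_inequality_sampled(self, rng):
        D = generate_geometry(40, seed=1).pairwise_distance
        i, j, k = rng.integers(0, 40, size=(3, 200))
        assert np.all(D[i, j] <= D[i, k] + D[k, j] + 1e-9)

    def test_deterministic(self):
        a = generate_geometry(25, seed=9)
        b = generate_geometry(25, seed=9)
        assert np.array_equal(a.x, b.x) and np.array_equal(a.y, b.y)

    def test_too_few_tracts(self):
        with pytest.raises(ValueError):
            generate_geometry(1)

    def test_bad_distance_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            Geometry(
                tract_id=np.array(["a", "b"]),
                x=np.zeros(2),
                y=np.zeros(2),
                pairwise_distance=np.array([[0.0, 1.0], [2.0, 0.0]]),
            )


class TestSimulateFields:
    def test_zero_spatial_variance_gives_null_field(self):
        geom = generate_geometry(10, seed=0)
        truth = simulate_fields(geom, 4, TruthRecord(sigma_sp=0.0, sigma_het=0.1), seed=1)
        assert np.all(truth.S == 0.0)

    def test_infinite_precision_flattens_rw1(self):
        geom = generate_geometry(3, seed=0)
        worst = 0.0
        for rep in range(1000):
            truth = simulate_fields(
                geom, 14, TruthRecord(tau_rw=1e8, sigma_sp=0.0), seed=rep
            )
            worst = max(worst, np.max(np.abs(truth.tau_t)))
        assert worst < 1e-2

    def test_fields_are_centered(self):
        geom = generate_geometry(15, seed=2)
        truth = simulate_fields(
            geom, 6, TruthRecord(sigma_het=0.5, sigma_sp=0.5, kappa=0.3), seed=3
        )
        assert abs(truth.upsilon.mean()) < 1e-12
        assert abs(truth.S.mean()) < 1e-12
        assert abs(truth.tau_t.mean()) < 1e-12
        assert np.all(np.abs(truth.eta.mean(axis=1)) < 1e-12)

    def test_long_range_field_more_correlated_nearby(self):
        # Monte-Carlo oracle: with a long-range kappa the closest 5% of
        # pairs must show higher sample correlation than the most distant 5%
        geom = generate_geometry(40, extent=30.0, seed=5)
        truth = TruthRecord(sigma_sp=1.0, kappa=0.1, sigma_het=0.0)
        fields = np.array(
            [simulate_fields(geom, 2, truth, seed=r).S for r in range(200)]
        )
        corr = np.corrcoef(fields.T)
        D = geom.pairwise_distance
        iu = np.triu_indices(40, k=1)
        pair_d, pair_c = D[iu], corr[iu]
        q5, q95 = np.quantile(pair_d, [0.05, 0.95])
        assert pair_c[pair_d <= q5].mean() > pair_c[pair_d >= q95].mean()

    def test_variance_recovers_sigma_sp(self):
        # short-range field so the sum-to-zero centering removes ~1/n only
        geom = generate_geometry(50, extent=30.0, seed=8)
        truth = TruthRecord(sigma_sp=0.7, kappa=2.0)
        fields = np.array(
            [simulate_fields(geom, 2, truth, seed=1000 + r).S for r in range(500)]
        )
        assert fields.var() == pytest.approx(0.7**2, rel=0.05)


class TestSimulateCounts:
    def make_panel(self, n_rows, pob, seed=0):
        return pd.DataFrame(
            {
                "tract_id": [f"T{i:06d}" for i in range(n_rows)],
                "year": 2000,
                "Pob": pob,
                "P4564": 0.0,
                "P65M": 0.0,
                "quintile": 1,
            }
        )

    def test_unit_mean_counts(self):
        panel = self.make_panel(10_000, pob=10_000.0)
        truth = TruthRecord(beta0=np.log(1e-4))
        out = simulate_counts(panel, truth, "poisson", seed=11)
        assert abs(out["O"].mean() - 1.0) < 3.0 / np.sqrt(10_000)

    def test_zip_all_structural_zeros(self):
        panel = self.make_panel(500, pob=10_000.0)
        truth = TruthRecord(beta0=np.log(1e-3), p_zero=1.0)
        out = simulate_counts(panel, truth, "zip", seed=2)
        assert (out["O"] == 0).all()

    def test_zip_zero_fraction_formula(self):
        n = 20_000
        panel = self.make_panel(n, pob=1000.0)
        truth = TruthRecord(beta0=np.log(2.0 / 1000.0), p_zero=0.3)  # lambda = 2
        out = simulate_counts(panel, truth, "zip", seed=3)
        p0 = 0.3 + 0.7 * np.exp(-2.0)
        se = np.sqrt(p0 * (1 - p0) / n)
        assert abs((out["O"] == 0).mean() - p0) < 3 * se

    def test_zip_empirical_pmf_total_variation(self):
        n = 100_000
        panel = self.make_panel(n, pob=1000.0)
        truth = TruthRecord(beta0=np.log(2.0 / 1000.0), p_zero=0.3)
        counts = simulate_counts(panel, truth, "zip", seed=4)["O"].to_numpy()
        kmax = counts.max()
        emp = np.bincount(counts, minlength=kmax + 1) / n
        analytic = zip_pmf(np.arange(kmax + 1), 2.0, 0.3)
        tv = 0.5 * (np.abs(emp - analytic).sum() + (1 - analytic.sum()))
        assert tv < 0.01

    def test_bernoulli_indicator(self):
        n = 20_000
        panel = self.make_panel(n, pob=1000.0)
        truth = TruthRecord(beta0=np.log(np.log(2.0) / 1000.0))  # mu = ln 2
        out = simulate_counts(panel, truth, "bernoulli", seed=5)
        assert set(out["O"].unique()) <= {0, 1}
        assert abs(out["O"].mean() - 0.5) < 3 * 0.5 / np.sqrt(n)

    def test_unknown_family(self):
        with pytest.raises(ValueError, match="family"):
            simulate_counts(self.make_panel(10, 100.0), TruthRecord(), "negbin")

    def test_overflow_guard(self):
        with pytest.raises(ValueError, match="overflow"):
            simulate_counts(
                self.make_panel(10, 100.0), TruthRecord(beta0=40.0), "poisson"
            )

    def test_deterministic_given_seed(self):
        geom, panel1, truth1 = recovery_scenario(seed=77, n_tracts=15, n_years=3)
        _, panel2, truth2 = recovery_scenario(seed=77, n_tracts=15, n_years=3)
        pd.testing.assert_frame_equal(panel1, panel2)
        assert np.array_equal(truth1.S, truth2.S)


class TestScenarios:
    def test_panel_invariants(self):
        geom, panel, truth = recovery_scenario(seed=5, n_tracts=25, n_years=6)
        assert len(panel) == 25 * 6
        assert panel.duplicated(["tract_id", "year"]).sum() == 0
        years = np.sort(panel["year"].unique())
        assert np.all(np.diff(years) == 1)
        assert ((panel["P4564"] + panel["P65M"]) <= 1.0).all()
        assert (panel["Pob"] > 0).all()
        assert panel["quintile"].isin([1, 2, 3, 4, 5]).all()
        assert (panel["O"] >= 0).all()

    def test_quintiles_constant_within_tract(self):
        _, panel, _ = recovery_scenario(seed=6, n_tracts=20, n_years=4)
        assert (panel.groupby("tract_id")["quintile"].nunique() == 1).all()

    def test_default_scenario_reduced_shape(self):
        # the full 542 x 14 default is exercised in the acceptance suite
        geom, panel, truth = default_study_scenario(seed=1, n_tracts=60, years=(1995, 2000))
        assert len(panel) == 60 * 6
        zero_frac = (panel["O"] == 0).mean()
        assert 0.35 < zero_frac < 0.75
        assert np.allclose(
            np.exp(truth.beta), [0.8592, 0.8129, 0.7315, 0.5768]
        )


class TestIndicatorTable:
    def test_shape_and_orientation(self):
        geom = generate_geometry(30, seed=0)
        table = simulate_indicator_table(geom, 16, seed=1)
        assert table.values.shape == (30, 16)
        assert np.all(table.orientation == 1.0)

    def test_indicators_spatially_structured(self):
        geom = generate_geometry(80, extent=30.0, seed=2)
        table = simulate_indicator_table(geom, 6, kappa=0.15, seed=3)
        first = table.values.iloc[:, 0].to_numpy()
        D = geom.pairwise_distance
        iu = np.triu_indices(80, k=1)
        prod = np.outer(first - first.mean(), first - first.mean())[iu]
        near = prod[D[iu] < np.quantile(D[iu], 0.1)].mean()
        far = prod[D[iu] > np.quantile(D[iu], 0.9)].mean()
        assert near > far
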