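"""Full-Bayes MCMC for the spatio-temporal hierarchical count model.

The sampler is Metropolis-within-Gibbs:

* fixed effects (intercept, quintile log-RRs, age coefficients) move as one
  block with an adaptive random-walk proposal whose covariance is learned
  during burn-in;
* each latent field moves as a block (heterogeneity, spatial field,
  temporal RW1) or as vectorized per-tract sub-blocks (interaction paths),
  with proposal increments shaped by the field's own prior and projected
  onto the sum-to-zero subspace so identifiability constraints hold exactly
  after every update;
* field standard deviations and the Matern scale move on the log scale by
  adaptive random walks; the two RW1 precisions are conjugate and drawn by
  Gibbs; the zero-inflation weight moves on the logit scale.

All adaptation freezes at the end of burn-in to preserve detailed balance.

Priors (configurable via ``ModelSpec.priors``): Normal(0, 10^2) on the
fixed effects, half-Normal(0, 1) on the heterogeneity and spatial SDs,
Gamma(1, 5e-5) on the RW1 precisions, log-Normal on the Matern scale
centered so the prior median effective range is half the domain diameter,
and Uniform(0, 1) on the zero-inflation weight.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular

from .model import LOG_MU_BOUND, ModelSpec, loglik, panel_indices, validate_panel
from .random_effects import matern_cholesky
from .synthetic_data import Geometry

__all__ = [
    "MCMCSettings",
    "PosteriorDraws",
    "FitSummary",
    "fit",
    "sample_posterior",
    "summarize",
    "convergence_report",
    "rhat",
    "effective_sample_size",
]

DEFAULT_PRIORS = {
    "beta_sd": 10.0,        # Normal(0, beta_sd^2) on beta0, beta_j, gamma_s
    "sigma_sd": 1.0,        # half-Normal(0, sigma_sd^2) on sigma_het, sigma_sp
    "tau_shape": 1.0,       # Gamma(shape, rate) on tau_rw, tau_int
    "tau_rate": 5e-5,
    "kappa_log_sd": 1.0,    # log-Normal around the half-diameter range
}


@dataclass
class MCMCSettings:
    n_iter: int = 10_000
    n_burnin: int = 5_000
    thin: int = 2
    n_chains: int = 3
    store_rows: bool = True   # keep per-row likelihood terms for CPO

    def __post_init__(self) -> None:
        if not 0 <= self.n_burnin < self.n_iter:
            raise ValueError("need 0 <= n_burnin < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_kept(self) -> int:
        return (self.n_iter - self.n_burnin) // self.thin


@dataclass
class PosteriorDraws:
    """Retained draws of every model quantity for one chain."""

    draws: dict[str, np.ndarray]
    loglik: np.ndarray                   # total log-likelihood per kept draw
    loglik_rows: Optional[np.ndarray]    # (n_kept, n_rows) float32, or None
    n_kept: int
    n_burnin: int
    thin: int
    seed: int
    acceptance: dict[str, float]
    spec: ModelSpec
    tract_ids: np.ndarray
    years: np.ndarray

    def __post_init__(self) -> None:
        for name, arr in self.draws.items():
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite draws in {name!r}")


@dataclass
class FitSummary:
    """Posterior summaries mirroring one table column of the report."""

    rr: pd.DataFrame           # index Q2..Q5: mean, lo, hi, significant
    log_rr_age: pd.DataFrame   # index P4564, P65M: mean, lo, hi, significant
    re_sd: dict[str, float]    # posterior mean field SDs
    dic: Optional[float] = None
    p_d: Optional[float] = None
    cv_ls: Optional[float] = None
    label: str = ""


# --------------------------------------------------------------------------
# data preparation

class _ModelData:
    """Panel unpacked to aligned arrays on the complete (tract, year) grid."""

    def __init__(self, panel: pd.DataFrame, geometry: Geometry, spec: ModelSpec):
        validate_panel(panel)
        if "O" not in panel.columns:
            raise ValueError("panel must contain the count column O")
        panel = panel.sort_values(["tract_id", "year"], ignore_index=True)
        tract_ids, years, tidx, yidx = panel_indices(panel)
        n, T = len(tract_ids), len(years)
        if len(panel) != n * T:
            raise ValueError("panel must contain one row per (tract, year)")
        if np.any(np.diff(years) != 1):
            raise ValueError("years must form a contiguous range")
        expect_t = np.repeat(np.arange(n), T)
        expect_y = np.tile(np.arange(T), n)
        if not (np.array_equal(tidx, expect_t) and np.array_equal(yidx, expect_y)):
            raise ValueError("panel grid is not complete after sorting")
        order = {t: i for i, t in enumerate(geometry.tract_id)}
        try:
            gpos = np.array([order[t] for t in tract_ids])
        except KeyError as err:
            raise ValueError(f"panel tract {err} missing from geometry") from None
        self.panel = panel
        self.tract_ids, self.years = tract_ids, years
        self.n_tracts, self.n_years = n, T
        self.tidx, self.yidx = tidx, yidx
        self.O = panel["O"].to_numpy(dtype=float)
        self.offset = np.log(panel["Pob"].to_numpy(dtype=float))
        self.distances = geometry.pairwise_distance[np.ix_(gpos, gpos)]
        cols = [np.ones(len(panel))]
        self.coef_names = ["beta0"]
        if spec.include_quintiles:
            q = panel["quintile"].to_numpy()
            for j in range(2, 6):
                cols.append((q == j).astype(float))
            self.coef_names += [f"beta_q{j}" for j in range(2, 6)]
        if spec.include_ages:
            cols.append(panel["P4564"].to_numpy(dtype=float))
            cols.append(panel["P65M"].to_numpy(dtype=float))
            self.coef_names += ["gamma_p4564", "gamma_p65m"]
        X = np.column_stack(cols)
        # center non-intercept columns: decorrelates the intercept from the
        # covariates so the fixed-effect block mixes; draws are reported in
        # the original parameterization via col_means
        self.col_means = X.mean(axis=0)
        self.col_means[0] = 0.0
        self.X = X - self.col_means


# --------------------------------------------------------------------------
# sampler internals

def _center(v: np.ndarray) -> np.ndarray:
    return v - v.mean()


class _Sampler:
    def __init__(
        self,
        data: _ModelData,
        spec: ModelSpec,
        settings: MCMCSettings,
        seed: int,
    ):
        self.data = data
        self.spec = spec
        self.settings = settings
        self.rng = np.random.default_rng(seed)
        self.seed = seed
        self.priors = {**DEFAULT_PRIORS, **spec.priors}
        d = data
        self.zip_mode = spec.family == "zip"
        # prior median Matern range = half the domain diameter: sqrt(8)/kappa0
        diam = float(d.distances.max())
        self.kappa0 = np.sqrt(8.0) / max(diam / 2.0, 1e-6)

        # state
        self.fe = np.zeros(d.X.shape[1])
        self.fe[0] = self._init_intercept()
        self.ups = np.zeros(d.n_tracts)
        self.S = np.zeros(d.n_tracts)
        self.tau_t = np.zeros(d.n_years)
        self.eta = np.zeros((d.n_tracts, d.n_years))
        self.sigma_het = 0.05
        self.sigma_sp = 0.05
        self.kappa = self.kappa0
        self.tau_rw = 1000.0
        self.tau_int = 1000.0
        self.p_zero = 0.1 if self.zip_mode else 0.0
        self.Lc = matern_cholesky(d.distances, self.kappa) if spec.include_spatial else None

        self.log_mu = self._full_log_mu()
        self.ll_total, self.ll_rows = self._loglik(self.log_mu, self.p_zero)
        if not np.isfinite(self.ll_total):
            raise RuntimeError("non-finite log-likelihood at initialization")

        # adaptive proposal state
        self.scales = {
            "fe": 0.1, "ups": 0.5, "S": 0.5, "tau_t": 0.5,
            "eta": 1.0, "sigma_het": 0.5, "spatial_hyper": 0.3, "p_zero": 0.5,
            "rescale_ups": 0.5, "rescale_S": 0.5,
            "swap_ups": 0.1, "swap_S": 0.1, "swap_gamma": 0.5,
        }
        # per-tract covariate means for the age-coefficient swap moves
        self.gamma_cols: list[int] = [
            i for i, nm in enumerate(d.coef_names) if nm.startswith("gamma")
        ]
        self.gamma_tract_means = [
            _center(d.X[:, i].reshape(d.n_tracts, d.n_years).mean(axis=1))
            for i in self.gamma_cols
        ]
        # tract membership per quintile dummy column, for the swap moves
        self.quintile_members: list[np.ndarray] = []
        if spec.include_quintiles:
            q_by_tract = d.panel.groupby("tract_id", sort=True)["quintile"].first()
            q_arr = q_by_tract.reindex(d.tract_ids).to_numpy()
            self.quintile_members = [np.flatnonzero(q_arr == j) for j in range(2, 6)]
        self.fe_chol = np.eye(len(self.fe)) * 0.02
        self.acc = {k: 0 for k in self.scales}
        self.tries = {k: 0 for k in self.scales}
        self._fe_history: list[np.ndarray] = []

    # -- likelihood plumbing ------------------------------------------------

    def _init_intercept(self) -> float:
        d = self.data
        total_pob = float(np.exp(d.offset).sum())
        if self.spec.family == "bernoulli":
            ybar = float(np.mean(d.O >= 1))
            rate = -np.log1p(-min(ybar, 1 - 1e-6)) / (total_pob / len(d.O))
            return float(np.log(max(rate, 1e-12)))
        rate = max(float(d.O.sum()), 0.5) / total_pob
        return float(np.log(rate))

    def _full_log_mu(self) -> np.ndarray:
        d = self.data
        lm = d.offset + d.X @ self.fe
        lm = lm + (self.ups + self.S)[d.tidx] + self.tau_t[d.yidx]
        if self.spec.include_interaction:
            lm = lm + self.eta.ravel()
        return lm

    def _loglik(self, log_mu: np.ndarray, p_zero: float):
        if self.spec.null_likelihood:
            return 0.0, np.zeros(len(log_mu))
        if np.max(np.abs(log_mu)) > LOG_MU_BOUND:
            return -np.inf, None
        return loglik(self.data.O, log_mu, self.spec.family, p_zero)

    def _accept(self, key: str, log_alpha: float) -> bool:
        self.tries[key] += 1
        ok = np.log(self.rng.random()) < log_alpha
        if ok:
            self.acc[key] += 1
        return ok

    def _adapt(self, key: str, acc_prob: float, it: int, target: float) -> None:
        step = min(0.25, 4.0 / np.sqrt(it + 10.0))
        self.scales[key] = float(
            np.clip(self.scales[key] * np.exp(step * (acc_prob - target)), 1e-5, 50.0)
        )

    # -- block updates ------------------------------------------------------

    def _update_fe(self, it: int, adapting: bool) -> None:
        z = self.rng.normal(size=len(self.fe))
        delta_fe = self.scales["fe"] * (self.fe_chol @ z)
        lm_new = self.log_mu + self.data.X @ delta_fe
        ll_new, rows_new = self._loglik(lm_new, self.p_zero)
        fe_new = self.fe + delta_fe
        sd = self.priors["beta_sd"]
        dprior = -0.5 * (np.sum(fe_new**2) - np.sum(self.fe**2)) / sd**2
        log_alpha = ll_new - self.ll_total + dprior
        if self._accept("fe", log_alpha):
            self.fe, self.log_mu = fe_new, lm_new
            self.ll_total, self.ll_rows = ll_new, rows_new
        if adapting:
            self._adapt("fe", min(1.0, np.exp(min(0.0, log_alpha))), it, 0.234)
            self._fe_history.append(self.fe.copy())
            if it % 250 == 0 and len(self._fe_history) >= 200:
                hist = np.asarray(self._fe_history[-1000:])
                cov = np.cov(hist.T) + 1e-9 * np.eye(len(self.fe))
                try:
                    self.fe_chol = np.linalg.cholesky(cov)
                    self.scales["fe"] = 2.38 / np.sqrt(len(self.fe))
                except np.linalg.LinAlgError:
                    pass

    def _update_field(
        self, key: str, current: np.ndarray, increment: np.ndarray,
        dprior, gather: str, it: int, adapting: bool,
    ):
        """Shared MH step for a sum-to-zero latent field block."""
        d = self.data
        if gather == "tract":
            lm_new = self.log_mu + increment[d.tidx]
        else:
            lm_new = self.log_mu + increment[d.yidx]
        ll_new, rows_new = self._loglik(lm_new, self.p_zero)
        new = current + increment
        log_alpha = ll_new - self.ll_total + dprior(new) - dprior(current)
        if self._accept(key, log_alpha):
            self.log_mu = lm_new
            self.ll_total, self.ll_rows = ll_new, rows_new
            current = new
        if adapting:
            self._adapt(key, min(1.0, np.exp(min(0.0, log_alpha))), it, 0.234)
        return current

    def _rescale_field(self, key: str, sigma_attr: str, field_attr: str, it: int, adapting: bool) -> None:
        """Joint scaling move (log sigma, field) -> (log sigma + eps, field e^eps).

        The Gaussian field prior and the transform Jacobian cancel exactly, so
        the ratio involves only the likelihood and the SD hyperprior; this move
        lets the sampler climb out of the sigma ~ 0, field ~ 0 funnel.
        """
        eps = self.scales[key] * self.rng.normal()
        sigma = getattr(self, sigma_attr)
        fieldv = getattr(self, field_attr)
        sigma_new = sigma * np.exp(eps)
        field_new = fieldv * np.exp(eps)
        lm_new = self.log_mu + (field_new - fieldv)[self.data.tidx]
        ll_new, rows_new = self._loglik(lm_new, self.p_zero)
        sd = self.priors["sigma_sd"]
        dprior = (
            self._log_half_normal(sigma_new, sd) + np.log(sigma_new)
            - self._log_half_normal(sigma, sd) - np.log(sigma)
        )
        log_alpha = ll_new - self.ll_total + dprior
        if self._accept(key, log_alpha):
            setattr(self, sigma_attr, sigma_new)
            setattr(self, field_attr, field_new)
            self.log_mu = lm_new
            self.ll_total, self.ll_rows = ll_new, rows_new
        if adapting:
            self._adapt(key, min(1.0, np.exp(min(0.0, log_alpha))), it, 0.44)

    def _swap_quintile_field(self, key: str, field_attr: str, dprior, it: int, adapting: bool) -> None:
        """Likelihood-invariant ridge move: shift one quintile coefficient by
        delta and absorb it in the field values of that quintile's tracts
        (recentered, with the mean pushed into the intercept).

        The linear predictor is unchanged row-by-row, so the MH ratio is a
        prior ratio only; this explores the beta_j / field direction that
        block updates cannot move along when the likelihood is sharp.
        """
        n = self.data.n_tracts
        fieldv = getattr(self, field_attr)
        acc_probs = []
        for j, members in enumerate(self.quintile_members):
            if len(members) == 0:
                continue
            delta = self.scales[key] * self.rng.normal()
            # centered dummy column: +delta on the coefficient adds
            # delta*(1_Qj - m_j) per row; the field shift cancels it exactly
            # and keeps the field sum-to-zero (m_j = n_j/n on a full grid)
            m_j = float(self.data.col_means[1 + j])
            shift = np.full(n, delta * m_j)
            shift[members] -= delta
            new = fieldv + shift
            fe_new = self.fe.copy()
            fe_new[1 + j] += delta
            sd = self.priors["beta_sd"]
            dp = (
                dprior(new) - dprior(fieldv)
                - 0.5 * (fe_new[1 + j] ** 2 - self.fe[1 + j] ** 2) / sd**2
            )
            if self._accept(key, dp):
                fieldv = new
                self.fe = fe_new
            acc_probs.append(min(1.0, np.exp(min(0.0, dp))))
        setattr(self, field_attr, fieldv)
        if adapting and acc_probs:
            self._adapt(key, float(np.mean(acc_probs)), it, 0.44)

    def _swap_gamma_ups(self, it: int, adapting: bool) -> None:
        """Ridge move for the age coefficients: shift gamma_k by delta and
        absorb the tract-mean part of the change in the heterogeneity field.

        The covariates vary only slightly within a tract over years, so the
        proposal is nearly likelihood-invariant; the residual is handled by a
        full Metropolis correction."""
        d = self.data
        acc_probs = []
        for col, tract_mean in zip(self.gamma_cols, self.gamma_tract_means):
            delta = self.scales["swap_gamma"] * self.rng.normal()
            shift = -delta * tract_mean  # zero-mean: keeps ups centered
            lm_new = self.log_mu + delta * d.X[:, col] + shift[d.tidx]
            ll_new, rows_new = self._loglik(lm_new, self.p_zero)
            ups_new = self.ups + shift
            fe_new = self.fe.copy()
            fe_new[col] += delta
            sd = self.priors["beta_sd"]
            dp = (
                ll_new - self.ll_total
                - 0.5 * (fe_new[col] ** 2 - self.fe[col] ** 2) / sd**2
                - 0.5 * (np.sum(ups_new**2) - np.sum(self.ups**2)) / self.sigma_het**2
            )
            if self._accept("swap_gamma", dp):
                self.fe, self.ups, self.log_mu = fe_new, ups_new, lm_new
                self.ll_total, self.ll_rows = ll_new, rows_new
            acc_probs.append(min(1.0, np.exp(min(0.0, dp))))
        if adapting and acc_probs:
            self._adapt("swap_gamma", float(np.mean(acc_probs)), it, 0.44)

    def _update_ups(self, it: int, adapting: bool) -> None:
        n = self.data.n_tracts
        inc = self.scales["ups"] * max(self.sigma_het, 0.01) * _center(
            self.rng.normal(size=n)
        )
        def dprior(v):
            return -0.5 * np.sum(v**2) / self.sigma_het**2
        self.ups = self._update_field("ups", self.ups, inc, dprior, "tract", it, adapting)

    def _prior_quad_S(self, S: np.ndarray) -> float:
        w = solve_triangular(self.Lc, S, lower=True)
        return float(w @ w)

    def _update_S(self, it: int, adapting: bool) -> None:
        n = self.data.n_tracts
        inc = self.scales["S"] * max(self.sigma_sp, 0.01) * _center(
            self.Lc @ self.rng.normal(size=n)
        )
        def dprior(v):
            return -0.5 * self._prior_quad_S(v) / self.sigma_sp**2
        self.S = self._update_field("S", self.S, inc, dprior, "tract", it, adapting)

    def _update_tau_t(self, it: int, adapting: bool) -> None:
        T = self.data.n_years
        inc = self.scales["tau_t"] / np.sqrt(self.tau_rw) * _center(
            np.cumsum(self.rng.normal(size=T))
        )
        def dprior(v):
            return -0.5 * self.tau_rw * float(np.sum(np.diff(v) ** 2))
        self.tau_t = self._update_field("tau_t", self.tau_t, inc, dprior, "year", it, adapting)

    def _update_eta(self, it: int, adapting: bool) -> None:
        # per-tract RW1 paths: likelihood and prior separate over tracts, so
        # all tract blocks are proposed and accepted independently at once
        d = self.data
        n, T = d.n_tracts, d.n_years
        steps = np.cumsum(self.rng.normal(size=(n, T)), axis=1)
        inc = self.scales["eta"] / np.sqrt(self.tau_int) * (
            steps - steps.mean(axis=1, keepdims=True)
        )
        eta_new = self.eta + inc
        lm_new = self.log_mu + inc.ravel()
        ll_new, rows_new = self._loglik(lm_new, self.p_zero)
        if rows_new is None:  # divergence guard tripped: reject all blocks
            if adapting:
                self._adapt("eta", 0.0, it, 0.234)
            self.tries["eta"] += 1
            return
        if self.spec.null_likelihood:
            dll = np.zeros(n)
        else:
            dll = (rows_new - self.ll_rows).reshape(n, T).sum(axis=1)
        dq = np.sum(np.diff(eta_new, axis=1) ** 2, axis=1) - np.sum(
            np.diff(self.eta, axis=1) ** 2, axis=1
        )
        log_alpha = dll - 0.5 * self.tau_int * dq
        accept = np.log(self.rng.random(n)) < log_alpha
        if accept.any():
            self.eta[accept] = eta_new[accept]
            mask = np.repeat(accept, T)
            self.log_mu = np.where(mask, lm_new, self.log_mu)
            if not self.spec.null_likelihood:
                self.ll_rows = np.where(mask, rows_new, self.ll_rows)
                self.ll_total = float(np.sum(self.ll_rows))
        self.tries["eta"] += 1
        self.acc["eta"] += float(np.mean(accept))
        if adapting:
            self._adapt("eta", float(np.mean(np.minimum(1.0, np.exp(np.minimum(0.0, log_alpha))))), it, 0.234)

    # -- hyperparameter updates --------------------------------------------

    @staticmethod
    def _log_half_normal(x: float, sd: float) -> float:
        return -0.5 * x**2 / sd**2

    def _update_sigma_het(self, it: int, adapting: bool) -> None:
        n = self.data.n_tracts
        ssq = float(np.sum(self.ups**2))
        ls_new = np.log(self.sigma_het) + self.scales["sigma_het"] * self.rng.normal()
        s_new = float(np.exp(ls_new))
        def logpost(s):
            # half-Normal prior + log-scale Jacobian + Gaussian field term
            return (
                self._log_half_normal(s, self.priors["sigma_sd"]) + np.log(s)
                - n * np.log(s) - 0.5 * ssq / s**2
            )
        log_alpha = logpost(s_new) - logpost(self.sigma_het)
        if self._accept("sigma_het", log_alpha):
            self.sigma_het = s_new
        if adapting:
            self._adapt("sigma_het", min(1.0, np.exp(min(0.0, log_alpha))), it, 0.44)

    def _update_spatial_hyper(self, it: int, adapting: bool) -> None:
        """Joint MH on (log sigma_sp, log kappa); refactors the Matern on accept."""
        n = self.data.n_tracts
        ls_new = np.log(self.sigma_sp) + self.scales["spatial_hyper"] * self.rng.normal()
        lk_new = np.log(self.kappa) + self.scales["spatial_hyper"] * self.rng.normal()
        s_new, k_new = float(np.exp(ls_new)), float(np.exp(lk_new))
        try:
            Lc_new = matern_cholesky(self.data.distances, k_new)
        except np.linalg.LinAlgError:
            self.tries["spatial_hyper"] += 1
            return
        w_new = solve_triangular(Lc_new, self.S, lower=True)
        w_old = solve_triangular(self.Lc, self.S, lower=True)

        def logpost(s, Ldiag, quad, lk):
            return (
                self._log_half_normal(s, self.priors["sigma_sd"]) + np.log(s)
                - 0.5 * ((lk - np.log(self.kappa0)) / self.priors["kappa_log_sd"]) ** 2
                - n * np.log(s) - float(np.sum(np.log(Ldiag)))
                - 0.5 * quad / s**2
            )

        log_alpha = logpost(
            s_new, np.diag(Lc_new), float(w_new @ w_new), lk_new
        ) - logpost(
            self.sigma_sp, np.diag(self.Lc), float(w_old @ w_old), np.log(self.kappa)
        )
        if self._accept("spatial_hyper", log_alpha):
            self.sigma_sp, self.kappa, self.Lc = s_new, k_new, Lc_new
        if adapting:
            self._adapt("spatial_hyper", min(1.0, np.exp(min(0.0, log_alpha))), it, 0.234)

    def _gibbs_taus(self) -> None:
        a, b = self.priors["tau_shape"], self.priors["tau_rate"]
        if self.spec.include_temporal:
            quad = float(np.sum(np.diff(self.tau_t) ** 2))
            shape = a + 0.5 * (self.data.n_years - 1)
            self.tau_rw = float(self.rng.gamma(shape, 1.0 / (b + 0.5 * quad)))
        if self.spec.include_interaction:
            quad = float(np.sum(np.diff(self.eta, axis=1) ** 2))
            shape = a + 0.5 * self.data.n_tracts * (self.data.n_years - 1)
            self.tau_int = float(self.rng.gamma(shape, 1.0 / (b + 0.5 * quad)))

    def _update_p_zero(self, it: int, adapting: bool) -> None:
        logit = np.log(self.p_zero) - np.log1p(-self.p_zero)
        logit_new = logit + self.scales["p_zero"] * self.rng.normal()
        p_new = float(1.0 / (1.0 + np.exp(-logit_new)))
        ll_new, rows_new = self._loglik(self.log_mu, p_new)
        # Uniform(0,1) prior + logit-scale Jacobian log p(1-p)
        djac = (np.log(p_new) + np.log1p(-p_new)) - (
            np.log(self.p_zero) + np.log1p(-self.p_zero)
        )
        log_alpha = ll_new - self.ll_total + djac
        if self._accept("p_zero", log_alpha):
            self.p_zero = p_new
            self.ll_total, self.ll_rows = ll_new, rows_new
        if adapting:
            self._adapt("p_zero", min(1.0, np.exp(min(0.0, log_alpha))), it, 0.44)

    # -- main loop ----------------------------------------------------------

    def run(self) -> PosteriorDraws:
        d, spec, st = self.data, self.spec, self.settings
        n_kept = st.n_kept
        out = {
            "beta0": np.empty(n_kept),
            "sigma_het": np.empty(n_kept),
            "sigma_sp": np.empty(n_kept),
            "kappa": np.empty(n_kept),
            "tau_rw": np.empty(n_kept),
            "tau_int": np.empty(n_kept),
            "upsilon": np.empty((n_kept, d.n_tracts), dtype=np.float32),
            "S": np.empty((n_kept, d.n_tracts), dtype=np.float32),
            "tau_t": np.empty((n_kept, d.n_years), dtype=np.float32),
        }
        if spec.include_quintiles:
            out["beta"] = np.empty((n_kept, 4))
        if spec.include_ages:
            out["gamma"] = np.empty((n_kept, 2))
        if spec.include_interaction:
            out["eta"] = np.empty((n_kept, d.n_tracts, d.n_years), dtype=np.float32)
        if self.zip_mode:
            out["p_zero"] = np.empty(n_kept)
        ll_kept = np.empty(n_kept)
        rows_kept = (
            np.empty((n_kept, len(d.O)), dtype=np.float32) if st.store_rows else None
        )

        kept = 0
        for it in range(st.n_iter):
            adapting = it < st.n_burnin
            self._update_fe(it, adapting)
            if spec.include_heterogeneity:
                self._update_ups(it, adapting)
                self._update_sigma_het(it, adapting)
                self._rescale_field("rescale_ups", "sigma_het", "ups", it, adapting)
                if spec.include_quintiles:
                    self._swap_quintile_field(
                        "swap_ups", "ups",
                        lambda v: -0.5 * np.sum(v**2) / self.sigma_het**2,
                        it, adapting,
                    )
                if spec.include_ages:
                    self._swap_gamma_ups(it, adapting)
            if spec.include_spatial:
                self._update_S(it, adapting)
                if it % 5 == 0:  # Matern refactorization is the costly step
                    self._update_spatial_hyper(it, adapting)
                self._rescale_field("rescale_S", "sigma_sp", "S", it, adapting)
                if spec.include_quintiles:
                    self._swap_quintile_field(
                        "swap_S", "S",
                        lambda v: -0.5 * self._prior_quad_S(v) / self.sigma_sp**2,
                        it, adapting,
                    )
            if spec.include_temporal:
                self._update_tau_t(it, adapting)
            if spec.include_interaction:
                self._update_eta(it, adapting)
            self._gibbs_taus()
            if self.zip_mode:
                self._update_p_zero(it, adapting)

            if not np.isfinite(self.ll_total):
                raise RuntimeError(f"non-finite log-likelihood at iteration {it}")

            if it >= st.n_burnin and (it - st.n_burnin) % st.thin == 0 and kept < n_kept:
                nq = 1
                # un-center: intercept on the original covariate scale
                out["beta0"][kept] = self.fe[0] - float(d.col_means[1:] @ self.fe[1:])
                if spec.include_quintiles:
                    out["beta"][kept] = self.fe[1:5]
                    nq = 5
                if spec.include_ages:
                    out["gamma"][kept] = self.fe[nq : nq + 2]
                out["upsilon"][kept] = self.ups
                out["S"][kept] = self.S
                out["tau_t"][kept] = self.tau_t
                if spec.include_interaction:
                    out["eta"][kept] = self.eta
                out["sigma_het"][kept] = self.sigma_het
                out["sigma_sp"][kept] = self.sigma_sp
                out["kappa"][kept] = self.kappa
                out["tau_rw"][kept] = self.tau_rw
                out["tau_int"][kept] = self.tau_int
                if self.zip_mode:
                    out["p_zero"][kept] = self.p_zero
                ll_kept[kept] = self.ll_total
                if st.store_rows:
                    rows_kept[kept] = self.ll_rows
                kept += 1

        acceptance = {
            k: (self.acc[k] / t if t else float("nan")) for k, t in self.tries.items()
        }
        return PosteriorDraws(
            draws={k: v[:kept] for k, v in out.items()},
            loglik=ll_kept[:kept],
            loglik_rows=rows_kept[:kept] if st.store_rows else None,
            n_kept=kept,
            n_burnin=st.n_burnin,
            thin=st.thin,
            seed=self.seed,
            acceptance=acceptance,
            spec=spec,
            tract_ids=d.tract_ids,
            years=d.years,
        )


# --------------------------------------------------------------------------
# public API

def fit(
    panel: pd.DataFrame,
    geometry: Geometry,
    spec: ModelSpec,
    settings: MCMCSettings | None = None,
    seed: int | None = None,
) -> PosteriorDraws:
    """Run one MCMC chain and return the retained draws."""
    settings = settings or MCMCSettings()
    data = _ModelData(panel, geometry, spec)
    return _Sampler(data, spec, settings, spec.seed if seed is None else seed).run()


def sample_posterior(
    panel: pd.DataFrame,
    geometry: Geometry,
    spec: ModelSpec,
    settings: MCMCSettings | None = None,
) -> list[PosteriorDraws]:
    """Run ``settings.n_chains`` independent chains with offset seeds."""
    settings = settings or MCMCSettings()
    data = _ModelData(panel, geometry, spec)
    return [
        _Sampler(data, spec, settings, spec.seed + 1000 * c).run()
        for c in range(settings.n_chains)
    ]


def _stack(draws, key: str) -> np.ndarray:
    if isinstance(draws, PosteriorDraws):
        return np.asarray(draws.draws[key], dtype=float)
    return np.concatenate([np.asarray(d.draws[key], dtype=float) for d in draws])


def summarize(draws: PosteriorDraws | Sequence[PosteriorDraws]) -> FitSummary:
    """Posterior means and 95% credible intervals on the scales reported.

    Relative risks are summarized draw-by-draw on the exp scale (mean of
    exp(beta), never exp of the mean); a quintile is flagged significant
    when its 95% interval excludes RR = 1.  Random-effect SDs are posterior
    means of the empirical standard deviation of each sampled field.
    """
    one = draws if isinstance(draws, PosteriorDraws) else draws[0]
    spec = one.spec
    n_total = (
        one.n_kept if isinstance(draws, PosteriorDraws) else sum(d.n_kept for d in draws)
    )
    if n_total < 100:
        raise ValueError(f"need at least 100 retained draws, got {n_total}")

    def ci_frame(samples: np.ndarray, names: list[str], null: float) -> pd.DataFrame:
        mean = samples.mean(axis=0)
        lo, hi = np.percentile(samples, [2.5, 97.5], axis=0)
        return pd.DataFrame(
            {
                "mean": mean,
                "lo": lo,
                "hi": hi,
                "significant": (hi < null) | (lo > null),
            },
            index=names,
        )

    if spec.include_quintiles:
        rr = ci_frame(np.exp(_stack(draws, "beta")), ["Q2", "Q3", "Q4", "Q5"], 1.0)
    else:
        rr = pd.DataFrame(columns=["mean", "lo", "hi", "significant"])
    if spec.include_ages:
        ages = ci_frame(_stack(draws, "gamma"), ["P4564", "P65M"], 0.0)
    else:
        ages = pd.DataFrame(columns=["mean", "lo", "hi", "significant"])

    re_sd = {
        "heterogeneity": float(_stack(draws, "upsilon").std(axis=1, ddof=0).mean()),
        "spatial": float(_stack(draws, "S").std(axis=1, ddof=0).mean()),
        "temporal": float(_stack(draws, "tau_t").std(axis=1, ddof=0).mean()),
    }
    if spec.include_interaction:
        eta = _stack(draws, "eta")
        re_sd["interaction"] = float(
            eta.reshape(eta.shape[0], -1).std(axis=1, ddof=0).mean()
        )
    return FitSummary(rr=rr, log_rr_age=ages, re_sd=re_sd)


# --------------------------------------------------------------------------
# convergence diagnostics

def rhat(chains: np.ndarray, split: bool = False) -> float:
    """Potential scale reduction for one scalar across chains.

    ``chains`` is (n_chains, n_draws).  The variance estimate is floored at
    the within-chain variance so identical chains give exactly 1.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need >= 2 chains of equal length")
    if split:
        half = chains.shape[1] // 2
        chains = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    m, n = chains.shape
    W = float(np.mean(np.var(chains, axis=1, ddof=1)))
    if W == 0.0:
        return 1.0 if np.var(chains.mean(axis=1)) == 0 else float("inf")
    B_over_n = float(np.var(chains.mean(axis=1), ddof=1))
    vhat = (n - 1) / n * W + B_over_n
    return float(np.sqrt(max(vhat, W) / W))


def effective_sample_size(chains: np.ndarray) -> float:
    """ESS via Geyer's initial monotone positive sequence on pooled chains."""
    chains = np.atleast_2d(np.asarray(chains, dtype=float))
    m, n = chains.shape
    if n < 4:
        return float(m * n)
    acov = np.zeros(n)
    for c in chains:
        x = c - c.mean()
        f = np.fft.rfft(x, 2 * n)
        acf = np.fft.irfft(f * np.conj(f))[:n] / n
        acov += acf
    acov /= m
    if acov[0] == 0:
        return float(m * n)
    rho = acov / acov[0]
    # Geyer: sum consecutive-lag pairs while positive, enforcing monotone decay
    pairs = rho[1:-1:2] + rho[2::2]
    s, prev = 0.0, np.inf
    for p in pairs:
        if p < 0:
            break
        p = min(p, prev)
        prev = p
        s += p
    tau = max(1.0 + 2.0 * s, 1e-12)
    return float(min(m * n / tau, m * n))


def convergence_report(chains: Sequence[PosteriorDraws]) -> pd.DataFrame:
    """Per-scalar R-hat and ESS table; warns when any R-hat exceeds 1.05."""
    if len(chains) < 2:
        raise ValueError("need at least 2 chains")
    lengths = {c.n_kept for c in chains}
    if len(lengths) != 1:
        raise ValueError(f"chains have mismatched lengths: {sorted(lengths)}")
    spec = chains[0].spec
    scalars: dict[str, np.ndarray] = {"beta0": np.stack([c.draws["beta0"] for c in chains])}
    if spec.include_quintiles:
        for j in range(4):
            scalars[f"beta_q{j + 2}"] = np.stack([c.draws["beta"][:, j] for c in chains])
    if spec.include_ages:
        for j, name in enumerate(["gamma_p4564", "gamma_p65m"]):
            scalars[name] = np.stack([c.draws["gamma"][:, j] for c in chains])
    for name in ("sigma_het", "sigma_sp", "kappa", "tau_rw", "tau_int", "p_zero"):
        if name in chains[0].draws:
            scalars[name] = np.stack([c.draws[name] for c in chains])
    rows = []
    for name, arr in scalars.items():
        rows.append(
            {"parameter": name, "rhat": rhat(arr), "ess": effective_sample_size(arr)}
        )
    report = pd.DataFrame(rows).set_index("parameter")
    bad = report[report["rhat"] > 1.05]
    if len(bad):
        warnings.warn(
            f"R-hat above 1.05 for: {', '.join(bad.index)}", stacklevel=2
        )
    return report
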