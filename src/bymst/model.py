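"""Linear predictor, observation likelihoods and the zero-excess diagnostic.

The log-mean of the counts in tract i, year t is

    log mu_it = log Pob_it + beta0 + sum_j beta_j Q_j
              + gamma_1 P4564_it + gamma_2 P65M_it
              + upsilon_i + S_i + tau_t + eta_it

with the population entering as a fixed additive log term (crude rates with
age-structure covariates, not expected counts as an offset).  Three
observation families share this predictor: Poisson, zero-inflated Poisson
(constant mixing weight), and a Bernoulli indicator of at-least-one-case
with P(y=1) = 1 - exp(-mu), the complementary-log-log link.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "FAMILIES",
    "ModelSpec",
    "LinearPredictor",
    "linear_predictor",
    "loglik",
    "expected_zero_fraction",
    "zip_pmf",
]

FAMILIES = ("poisson", "zip", "bernoulli")

PANEL_COLUMNS = ["tract_id", "year", "O", "Pob", "P4564", "P65M", "quintile"]

#: reject linear predictors beyond this magnitude (divergence guard)
LOG_MU_BOUND = 30.0


@dataclass
class ModelSpec:
    """Which likelihood, covariates and random effects a fit uses.

    ``include_interaction=False`` is "estimation 1" (no spatio-temporal
    interaction), ``True`` is "estimation 2".  ``null_likelihood`` switches
    the likelihood off entirely so the posterior collapses to the prior
    (a sampler diagnostic).
    """

    family: str = "poisson"
    include_interaction: bool = False
    include_quintiles: bool = True
    include_ages: bool = True
    include_heterogeneity: bool = True
    include_spatial: bool = True
    include_temporal: bool = True
    null_likelihood: bool = False
    priors: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")


@dataclass
class LinearPredictor:
    """Parameter bundle for the linear predictor.

    ``beta`` holds the four quintile log-relative-risks (Q2..Q5, first
    quintile is the reference); ``gamma`` the two age-band coefficients.
    Latent fields may be ``None``, in which case they contribute zero.
    """

    beta0: float = 0.0
    beta: np.ndarray = field(default_factory=lambda: np.zeros(4))
    gamma: np.ndarray = field(default_factory=lambda: np.zeros(2))
    upsilon: Optional[np.ndarray] = None
    S: Optional[np.ndarray] = None
    tau_t: Optional[np.ndarray] = None
    eta: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        if self.beta.shape != (4,):
            raise ValueError("beta must hold the 4 quintile coefficients Q2..Q5")
        if self.gamma.shape != (2,):
            raise ValueError("gamma must hold the 2 age coefficients")


def validate_panel(panel: pd.DataFrame) -> None:
    missing = [c for c in PANEL_COLUMNS if c not in panel.columns and c != "O"]
    if missing:
        raise ValueError(f"panel is missing covariate columns: {missing}")
    q = panel["quintile"].to_numpy()
    if not np.isin(q, [1, 2, 3, 4, 5]).all():
        bad = sorted(set(q) - {1, 2, 3, 4, 5})
        raise ValueError(f"quintile outside 1..5: {bad}")
    for col in ("Pob", "P4564", "P65M"):
        if panel[col].isna().any():
            raise ValueError(f"missing values in covariate {col!r}")


def panel_indices(panel: pd.DataFrame):
    """Stable (tract, year) integer codes for aligning latent fields."""
    tract_ids = pd.unique(panel["tract_id"])
    years = np.sort(pd.unique(panel["year"]))
    tidx = pd.Categorical(panel["tract_id"], categories=tract_ids).codes
    yidx = np.searchsorted(years, panel["year"].to_numpy())
    return tract_ids, years, tidx.astype(np.intp), yidx.astype(np.intp)


def linear_predictor(
    panel: pd.DataFrame,
    params: LinearPredictor,
    spec: ModelSpec | None = None,
) -> np.ndarray:
    """Per-row log-mean log(mu_it) of the observation model."""
    validate_panel(panel)
    include_eta = params.eta is not None and (
        spec is None or spec.include_interaction
    )
    _, _, tidx, yidx = panel_indices(panel)
    q = panel["quintile"].to_numpy(dtype=np.intp)
    lp = np.log(panel["Pob"].to_numpy(dtype=float)) + params.beta0
    dummies = np.concatenate([[0.0], [0.0], params.beta])[q]  # q=1 -> 0
    lp += dummies
    lp += params.gamma[0] * panel["P4564"].to_numpy(dtype=float)
    lp += params.gamma[1] * panel["P65M"].to_numpy(dtype=float)
    if params.upsilon is not None:
        lp += np.asarray(params.upsilon, dtype=float)[tidx]
    if params.S is not None:
        lp += np.asarray(params.S, dtype=float)[tidx]
    if params.tau_t is not None:
        lp += np.asarray(params.tau_t, dtype=float)[yidx]
    if include_eta:
        lp += np.asarray(params.eta, dtype=float)[tidx, yidx]
    return lp


def _poisson_terms(O: np.ndarray, log_mu: np.ndarray, mu: np.ndarray) -> np.ndarray:
    # log O! via log-gamma for stability
    return O * log_mu - mu - gammaln(O + 1.0)


def loglik(
    O: np.ndarray,
    log_mu: np.ndarray,
    family: str,
    p_zero: float = 0.0,
) -> tuple[float, np.ndarray]:
    """Total log-likelihood and per-row terms.

    For the Bernoulli family ``O`` may be counts (the 0/1 response is the
    indicator O >= 1) or an already-binary vector.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")
    if not 0.0 <= p_zero <= 1.0:
        raise ValueError(f"p_zero must be in [0, 1], got {p_zero}")
    O = np.asarray(O, dtype=float)
    log_mu = np.asarray(log_mu, dtype=float)
    if O.shape != log_mu.shape:
        raise ValueError("O and log_mu must have matching shapes")
    if np.any(O < 0):
        raise ValueError("counts must be nonnegative")
    mu = np.exp(log_mu)
    if family == "poisson":
        terms = _poisson_terms(O, log_mu, mu)
    elif family == "zip":
        terms = np.empty_like(mu)
        zero = O == 0
        # zeros: log(p0 + (1-p0) e^{-mu}); positives: log(1-p0) + Poisson
        terms[zero] = np.log(p_zero + (1.0 - p_zero) * np.exp(-mu[zero]))
        with np.errstate(divide="ignore"):
            log1mp = np.log1p(-p_zero)
        terms[~zero] = log1mp + _poisson_terms(O[~zero], log_mu[~zero], mu[~zero])
    else:  # bernoulli, cloglog link with log-population offset
        y = (O >= 1).astype(float)
        with np.errstate(divide="ignore"):
            log_p1 = np.log(-np.expm1(-mu))
        terms = y * log_p1 - (1.0 - y) * mu
    return float(np.sum(terms)), terms


def expected_zero_fraction(log_mu: np.ndarray) -> float:
    """Poisson-implied zero probability averaged over rows.

    Contrasted with the observed zero fraction this is the overdispersion
    diagnostic motivating the zero-inflated family (counts with matching
    means but many more zeros than exp(-mu) predicts).
    """
    log_mu = np.asarray(log_mu, dtype=float)
    return float(np.mean(np.exp(-np.exp(log_mu))))


def zip_pmf(k: np.ndarray, mu: float, p_zero: float) -> np.ndarray:
    """Analytic zero-inflated-Poisson pmf at integer support points k."""
    if not 0.0 <= p_zero <= 1.0:
        raise ValueError(f"p_zero must be in [0, 1], got {p_zero}")
    if mu < 0:
        raise ValueError("mu must be nonnegative")
    k = np.asarray(k, dtype=float)
    if np.any(k < 0) or np.any(k != np.floor(k)):
        raise ValueError("support points must be nonnegative integers")
    pois = np.exp(k * np.log(mu) - mu - gammaln(k + 1.0)) if mu > 0 else (k == 0) * 1.0
    return np.where(k == 0, p_zero + (1.0 - p_zero) * pois, (1.0 - p_zero) * pois)
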