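"""Model comparison: DIC, conditional predictive ordinate, report tables.

DIC uses the deviance-based definition: Dbar is the posterior mean of
-2 log-likelihood, the plug-in deviance is evaluated at the posterior mean
of *all* parameters (fixed effects, latent fields and the zero-inflation
weight alike), p_D = Dbar - D(theta_bar) and DIC = D(theta_bar) + 2 p_D,
so the identity DIC = Dbar + p_D holds by construction.

CPO is estimated from a single MCMC run by the harmonic-mean identity
CPO_i = [ (1/S) sum_s 1 / p(y_i | theta_s) ]^{-1}; rows whose importance
weights carry a relative Monte-Carlo error above 10% are flagged unstable
rather than silently trusted.  cv.ls = -mean(log CPO_i): lower is better,
as is lower DIC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .inference import FitSummary, PosteriorDraws, _ModelData, _stack
from .model import LinearPredictor, ModelSpec, linear_predictor, loglik
from .synthetic_data import Geometry

__all__ = ["ComparisonRow", "dic", "cpo", "cpo_from_loglik", "compare", "render_report"]


@dataclass
class ComparisonRow:
    label: str
    dic: float
    p_d: float
    cv_ls: float
    preferred: bool = False


def _posterior_mean_params(
    draws: PosteriorDraws | Sequence[PosteriorDraws],
) -> tuple[LinearPredictor, float]:
    one = draws if isinstance(draws, PosteriorDraws) else draws[0]
    spec = one.spec

    def mean_of(key, default=None):
        if key not in one.draws:
            return default
        return _stack(draws, key).mean(axis=0)

    params = LinearPredictor(
        beta0=float(mean_of("beta0")),
        beta=mean_of("beta", np.zeros(4)),
        gamma=mean_of("gamma", np.zeros(2)),
        upsilon=mean_of("upsilon"),
        S=mean_of("S"),
        tau_t=mean_of("tau_t"),
        eta=mean_of("eta") if spec.include_interaction else None,
    )
    p_zero = float(np.mean(_stack(draws, "p_zero"))) if "p_zero" in one.draws else 0.0
    return params, p_zero


def dic(
    draws: PosteriorDraws | Sequence[PosteriorDraws],
    panel: pd.DataFrame,
    geometry: Geometry,
    spec: ModelSpec | None = None,
) -> tuple[float, float, float]:
    """(DIC, p_D, mean deviance) from stored per-draw log-likelihoods."""
    one = draws if isinstance(draws, PosteriorDraws) else draws[0]
    spec = spec or one.spec
    ll = (
        one.loglik
        if isinstance(draws, PosteriorDraws)
        else np.concatenate([d.loglik for d in draws])
    )
    bad = np.flatnonzero(~np.isfinite(ll))
    if len(bad):
        raise ValueError(f"non-finite deviance at draw indices {bad[:5].tolist()}")
    dbar = float(np.mean(-2.0 * ll))

    params, p_zero = _posterior_mean_params(draws)
    data = _ModelData(panel, geometry, spec)
    log_mu = linear_predictor(data.panel, params, spec)
    ll_hat, _ = loglik(data.O, log_mu, spec.family, p_zero)
    d_hat = -2.0 * ll_hat
    p_d = dbar - d_hat
    return d_hat + 2.0 * p_d, p_d, dbar


def cpo_from_loglik(loglik_rows: np.ndarray) -> tuple[np.ndarray, float, np.ndarray]:
    """Harmonic-mean CPO per observation from an (S, n) log-likelihood matrix.

    Returns (cpo, cv_ls, unstable_flags).  A row with any zero per-draw
    likelihood gets CPO = 0 (and cv.ls becomes infinite) with a warning.
    """
    ll = np.asarray(loglik_rows, dtype=float)
    if ll.ndim != 2:
        raise ValueError("need an (S, n) matrix of per-draw, per-row log-likelihoods")
    S = ll.shape[0]
    neg = -ll
    zero_rows = np.any(~np.isfinite(neg) & (neg > 0), axis=0)
    log_cpo = np.log(S) - logsumexp(neg, axis=0)
    cpo = np.exp(log_cpo)
    if zero_rows.any():
        warnings.warn(
            f"{int(zero_rows.sum())} rows had zero per-draw likelihood; "
            "their CPO is 0 and the log-score is infinite",
            stacklevel=2,
        )
        cpo[zero_rows] = 0.0
    with np.errstate(divide="ignore"):
        cv_ls = float(-np.mean(np.where(cpo > 0, np.log(np.maximum(cpo, 1e-300)), -np.inf)))
        if zero_rows.any():
            cv_ls = float("inf")
    # relative MC error of the importance-weight mean, shift-invariant
    finite_neg = np.where(np.isfinite(neg), neg, -np.inf)
    shift = finite_neg.max(axis=0, keepdims=True)
    with np.errstate(invalid="ignore"):
        w = np.exp(finite_neg - shift)
    w = np.nan_to_num(w, nan=0.0, posinf=0.0)
    wbar = w.mean(axis=0)
    wvar = w.var(axis=0, ddof=1) if S > 1 else np.zeros(ll.shape[1])
    rel_err = np.sqrt(wvar / S) / np.maximum(wbar, 1e-300)
    unstable = rel_err > 0.10
    return cpo, cv_ls, unstable


def cpo(
    draws: PosteriorDraws | Sequence[PosteriorDraws],
) -> tuple[np.ndarray, float, np.ndarray]:
    """CPO and cv.ls from the per-row likelihood terms stored during sampling."""
    if isinstance(draws, PosteriorDraws):
        rows = draws.loglik_rows
    else:
        rows = np.concatenate([d.loglik_rows for d in draws])
    if rows is None:
        raise ValueError("per-row likelihood terms were not stored (store_rows=False)")
    return cpo_from_loglik(rows)


def compare(rows: Sequence[ComparisonRow]) -> pd.DataFrame:
    """Mark the preferred model (lowest DIC) and report criterion agreement."""
    if not rows:
        raise ValueError("need at least one fitted model to compare")
    table = pd.DataFrame(
        [{"label": r.label, "dic": r.dic, "p_d": r.p_d, "cv_ls": r.cv_ls} for r in rows]
    ).set_index("label")
    table["preferred"] = table["dic"] == table["dic"].min()
    table["criteria_agree"] = (
        table["dic"].idxmin() == table["cv_ls"].idxmin()
    )
    for r in rows:
        r.preferred = bool(table.loc[r.label, "preferred"])
    return table


def render_report(
    summaries: dict[str, FitSummary],
    comparisons: Optional[Sequence[ComparisonRow]] = None,
) -> str:
    """Plain-text results table: RR rows per quintile, age log-RRs,
    random-effect SDs, DIC / cv.ls, with ``*`` marking effects whose 95%
    credible interval excludes the null."""
    if not summaries:
        raise ValueError("need at least one fitted model")
    lines = []
    for label, s in summaries.items():
        lines.append(f"=== {label} ===")
        lines.append("RR deprivation (mean, 95% CrI):")
        for name, row in s.rr.iterrows():
            star = " *" if row["significant"] else ""
            lines.append(
                f"  RR_{name}: {row['mean']:.4f} ({row['lo']:.4f}, {row['hi']:.4f}){star}"
            )
        lines.append("log RR age bands:")
        for name, row in s.log_rr_age.iterrows():
            star = " *" if row["significant"] else ""
            lines.append(
                f"  {name}: {row['mean']:.4f} ({row['lo']:.4f}, {row['hi']:.4f}){star}"
            )
        lines.append("random-effect SDs:")
        for name, value in s.re_sd.items():
            lines.append(f"  {name}: {value:.5f}")
        if s.dic is not None:
            lines.append(f"DIC: {s.dic:.2f} (p_D {s.p_d:.2f})")
        if s.cv_ls is not None:
            lines.append(f"cv.ls: {s.cv_ls:.4f}")
        lines.append("")
    if comparisons:
        table = compare(list(comparisons))
        lines.append("model comparison (lower DIC / cv.ls preferred):")
        for label, row in table.iterrows():
            mark = " <- preferred" if row["preferred"] else ""
            lines.append(
                f"  {label}: DIC {row['dic']:.2f}, p_D {row['p_d']:.2f}, "
                f"cv.ls {row['cv_ls']:.4f}{mark}"
            )
    return "\n".join(lines)
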