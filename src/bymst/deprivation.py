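"""DP2 synthetic deprivation index and quintile dummy coding.

The DP2 distance aggregates p standardized indicator distances from a
"least deprived" base tract, down-weighting each indicator by how much of
it is already explained by the indicators ranked above it (correction
factor 1 - R^2).  The indicator ordering is itself determined iteratively
from the correlation of each indicator with the current index.

Conventions fixed here (the construction leaves them open):
* indicators are oriented so that larger = more deprived before anything
  else happens;
* the base tract is the per-indicator minimum after orientation;
* sigma is the population (not sample) standard deviation across tracts;
* quintiles use the empirical 20/40/60/80 percentiles with ties going to
  the lower quintile, tracts unweighted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["IndicatorTable", "DP2Result", "dp2_index", "assign_quintiles"]


@dataclass
class IndicatorTable:
    """Tract-level socioeconomic indicators plus per-indicator orientation.

    ``orientation[k]`` is +1 when larger values of indicator k mean more
    deprivation, -1 when they mean less.
    """

    tract_id: np.ndarray
    values: pd.DataFrame
    orientation: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.tract_id = np.asarray(self.tract_id)
        if self.orientation is None:
            self.orientation = np.ones(self.values.shape[1])
        self.orientation = np.asarray(self.orientation, dtype=float)
        if len(self.tract_id) != len(self.values):
            raise ValueError("tract_id and indicator rows disagree")
        if self.orientation.shape != (self.values.shape[1],):
            raise ValueError("one orientation flag per indicator required")
        if not np.isin(self.orientation, [-1.0, 1.0]).all():
            raise ValueError("orientation flags must be +1 or -1")
        if self.values.isna().any().any():
            raise ValueError("indicator table contains missing values")
        if len(np.unique(self.tract_id)) != len(self.tract_id):
            raise ValueError("tract ids must be unique")


@dataclass
class DP2Result:
    index: pd.Series            # DP2 value per tract (tract_id index)
    weights: np.ndarray         # 1 - R^2 per indicator, original column order
    order: list                 # final indicator ordering (most informative first)
    iterations: int
    base: np.ndarray            # oriented base-tract values, original order
    sigma: np.ndarray           # population SDs used for standardization

    def score(self, values: pd.DataFrame) -> pd.Series:
        """Apply the frozen base/sigma/weights to new oriented indicator rows.

        Monotone: increasing any oriented indicator of a row never decreases
        its score, because all correction weights are nonnegative.
        """
        d = (values.to_numpy(dtype=float) - self.base) / self.sigma
        return pd.Series(np.abs(d) @ self.weights, index=values.index)


def _r_squared(y: np.ndarray, X: np.ndarray) -> float:
    """R^2 of regressing y on X (intercept included)."""
    X1 = np.column_stack([np.ones(len(y)), X])
    coef, *_ = np.linalg.lstsq(X1, y, rcond=None)
    resid = y - X1 @ coef
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0.0:
        return 1.0
    return max(0.0, min(1.0, 1.0 - float(np.sum(resid**2)) / tss))


def dp2_index(
    table: IndicatorTable, tol: float = 1e-10, max_iter: int = 100
) -> DP2Result:
    """Compute Pena's DP2 distance for every tract.

    Algorithm: orient indicators; take the per-indicator minimum as the
    base; start from the Frechet distance sum |x - base| / sigma; then
    iterate: rank indicators by descending |correlation with the current
    index|, recompute DP2 with the (1 - R^2) correction of each indicator
    on all higher-ranked ones, until the ordering is stable or the index
    moves less than ``tol``.
    """
    n, p = table.values.shape
    if n < 2:
        raise ValueError("DP2 needs at least 2 tracts")
    if p < 1:
        raise ValueError("DP2 needs at least 1 indicator")
    cols = list(table.values.columns)
    X = table.values.to_numpy(dtype=float) * table.orientation
    sigma = X.std(axis=0)  # population SD
    const = sigma == 0.0
    if const.any():
        bad = [c for c, flag in zip(cols, const) if flag]
        raise ValueError(f"constant indicators have no DP2 contribution: {bad}")
    base = X.min(axis=0)
    d = np.abs(X - base) / sigma
    index = d.sum(axis=1)  # Frechet distance

    order = list(range(p))
    for iteration in range(1, max_iter + 1):
        corrs = np.array([abs(np.corrcoef(X[:, k], index)[0, 1]) for k in range(p)])
        corrs = np.nan_to_num(corrs)
        new_order = sorted(range(p), key=lambda k: (-corrs[k], k))
        weights = np.empty(p)
        weights[new_order[0]] = 1.0
        for rank in range(1, p):
            k = new_order[rank]
            weights[k] = 1.0 - _r_squared(X[:, k], X[:, new_order[:rank]])
        new_index = d @ weights
        converged = new_order == order or np.max(np.abs(new_index - index)) < tol
        order, index = new_order, new_index
        if converged:
            return DP2Result(
                index=pd.Series(index, index=pd.Index(table.tract_id, name="tract_id")),
                weights=weights,
                order=[cols[k] for k in order],
                iterations=iteration,
                base=base,
                sigma=sigma,
            )
    raise RuntimeError(
        "DP2 did not converge after "
        f"{max_iter} iterations; last orderings {[cols[k] for k in order]} vs "
        f"{[cols[k] for k in new_order]}"
    )


def assign_quintiles(index: pd.Series | np.ndarray) -> tuple[np.ndarray, pd.DataFrame]:
    """Deprivation quintiles (1 = least deprived fifth) and Q2..Q5 dummies.

    Cutpoints are the empirical 20/40/60/80 percentiles; a value equal to a
    cutpoint goes to the lower quintile, so boundary ties never split.
    """
    values = np.asarray(index, dtype=float)
    if values.size < 5:
        raise ValueError("need at least 5 tracts to form quintiles")
    cuts = np.percentile(values, [20, 40, 60, 80])
    quintile = 1 + (values[:, None] > cuts[None, :]).sum(axis=1)
    dummies = np.zeros((values.size, 4), dtype=int)
    for j in range(2, 6):
        dummies[quintile == j, j - 2] = 1
    dummies = pd.DataFrame(dummies, columns=["Q2", "Q3", "Q4", "Q5"])
    if isinstance(index, pd.Series):
        dummies.index = index.index
    if len(np.unique(quintile)) < 5:
        warnings.warn("ties or skew left some quintiles empty", stacklevel=2)
    return quintile, dummies
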