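"""Linear mixed model for hourly movement.

The response y_idh (movement of pig i on day d at hour h, cm/h) is modelled
as

    y_idh = mu + Day_d + Hour_h + (Day x Hour)_dh + b_i + eps_idh

with a random pig intercept b_i ~ N(0, sigma2_pig) and AR(1) residuals
within each pig x day block (lag-1 correlation rho, marginal variance
sigma2_res), estimated by REML.  Internally the fixed part is the saturated
day x hour cell-mean coding over the *observed* cells, which is full rank by
construction; LSMeans, Type-3 F tests and within-day slice tests are
estimable-function contrasts of the cell means.  Denominator degrees of
freedom follow the containment rule: residual df of the combined fixed +
pig-indicator design.

The intraclass correlation sigma2_pig / (sigma2_pig + sigma2_res) summarises
how much of the non-temporal variance is persistent between-pig difference;
rho is deliberately excluded from it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import null_space
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.base import BaseEstimator

from .reml import AR1Design, ar1_neg2_reml, fit_ar1_reml

logger = logging.getLogger(__name__)

__all__ = [
    "VarianceComponents",
    "MovementLMM",
    "build_design",
    "neg2_reml",
    "fit_lmm",
    "icc",
    "lsmeans",
    "blups",
    "type3_tests",
    "slice_tests",
]


@dataclass(frozen=True)
class VarianceComponents:
    sigma2_pig: float
    sigma2_res: float
    rho: float

    def __post_init__(self):
        if self.sigma2_pig < 0:
            raise ValueError("sigma2_pig must be >= 0")
        if self.sigma2_res <= 0:
            raise ValueError("sigma2_res must be > 0")
        if not abs(self.rho) < 1:
            raise ValueError("|rho| must be < 1")


def icc(sigma2_pig, sigma2_res=None) -> float:
    """Intraclass correlation sigma2_pig / (sigma2_pig + sigma2_res).

    Accepts either a :class:`VarianceComponents` or the two variances.  The
    AR(1) parameter does not enter: the ICC partitions marginal variance
    between the persistent pig level and everything else.
    """
    if isinstance(sigma2_pig, VarianceComponents):
        vc = sigma2_pig
        sigma2_pig, sigma2_res = vc.sigma2_pig, vc.sigma2_res
    total = sigma2_pig + sigma2_res
    if total <= 0:
        raise ValueError("sigma2_pig + sigma2_res must be > 0")
    return float(sigma2_pig / total)


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

@dataclass
class DesignBundle:
    """Observed-cell design and rank bookkeeping for the hourly model."""

    ar1: AR1Design
    cells: pd.MultiIndex  # (day, hour) of each fixed-effect column
    pigs: pd.Index
    days: np.ndarray
    hours: np.ndarray
    n_obs: int
    rank_X: int
    rank_additive: int
    interaction_rank: int
    den_df: int
    cell_counts: np.ndarray


def _additive_design(cells: pd.MultiIndex, days, hours) -> np.ndarray:
    """Reference-coded intercept + day + hour design on the observed cells."""
    d = cells.get_level_values(0).to_numpy()
    h = cells.get_level_values(1).to_numpy()
    cols = [np.ones(len(cells))]
    for lev in days[1:]:
        cols.append((d == lev).astype(float))
    for lev in hours[1:]:
        cols.append((h == lev).astype(float))
    return np.column_stack(cols)


def build_design(
    records: pd.DataFrame,
    response_col: str = "dist_cm_per_h",
    pig_col: str = "pig_id",
    day_col: str = "day",
    hour_col: str = "hour",
) -> DesignBundle:
    """Build the sorted cell-mean design, grouping indices and rank accounts.

    Rows are sorted by (pig, day, hour); fixed-effect columns are the
    observed day x hour cells in sorted order.  The interaction rank is the
    dimension of the observed-cell space orthogonal to the additive
    intercept + day + hour span (437 on the complete 20 x 24 grid; one empty
    cell removes exactly one dimension).  The containment denominator df is
    n_obs minus the rank of the combined fixed + pig-indicator design,
    computed exactly from the connected components of the cell x pig
    incidence graph.
    """
    for col in (response_col, pig_col, day_col, hour_col):
        if col not in records.columns:
            raise ValueError(f"records missing required column {col!r}")
    df = records[[pig_col, day_col, hour_col, response_col]].copy()
    if df[response_col].isna().any():
        raise ValueError("response contains missing values; filter to valid rows")
    if (df[hour_col] < 0).any() or (df[hour_col] > 23).any():
        bad = int(((df[hour_col] < 0) | (df[hour_col] > 23)).idxmax())
        raise ValueError(f"hour out of range 0..23 at row index {bad}")
    if df.duplicated([pig_col, day_col, hour_col]).any():
        raise ValueError("duplicate pig x day x hour rows")
    df = df.sort_values([pig_col, day_col, hour_col], kind="stable")

    pig_codes, pigs = pd.factorize(df[pig_col], sort=True)
    if len(pigs) < 2:
        raise ValueError("need >= 2 pigs to identify the pig variance component")
    days = np.sort(df[day_col].unique())
    hours = np.sort(df[hour_col].unique())
    cell_key = pd.MultiIndex.from_arrays(
        [df[day_col], df[hour_col]], names=["day", "hour"]
    )
    cells = cell_key.unique().sortlevel([0, 1])[0]
    cell_codes = cells.get_indexer(cell_key)

    block = pig_codes * (days.max() + 1) + df[day_col].to_numpy()
    same_block = block[1:] == block[:-1]
    pair_left = np.flatnonzero(same_block)
    gaps = np.diff(df[hour_col].to_numpy().astype(float))[pair_left]

    ar1 = AR1Design(
        y=df[response_col].to_numpy(dtype=float),
        cell=cell_codes,
        pig=pig_codes,
        pair_left=pair_left,
        pair_gap=gaps,
        n_cells=len(cells),
        n_pigs=len(pigs),
    )

    Zadd = _additive_design(cells, days, hours)
    rank_additive = int(np.linalg.matrix_rank(Zadd))
    interaction_rank = len(cells) - rank_additive

    inc = coo_matrix(
        (np.ones(len(df)), (cell_codes, pig_codes)), shape=(len(cells), len(pigs))
    )
    from scipy.sparse import bmat
    bip = bmat([[None, inc], [inc.T, None]])
    n_comp, _ = connected_components(bip, directed=False)
    rank_combined = len(cells) + len(pigs) - n_comp
    den_df = len(df) - rank_combined

    return DesignBundle(
        ar1=ar1,
        cells=cells,
        pigs=pigs,
        days=days,
        hours=hours,
        n_obs=len(df),
        rank_X=len(cells),
        rank_additive=rank_additive,
        interaction_rank=interaction_rank,
        den_df=int(den_df),
        cell_counts=np.bincount(cell_codes, minlength=len(cells)),
    )


def neg2_reml(vc: VarianceComponents, design: DesignBundle) -> float:
    """-2 restricted log-likelihood at given variance components."""
    val = ar1_neg2_reml(vc.sigma2_pig, vc.sigma2_res, vc.rho, design.ar1)
    return float(val) if np.isfinite(val) else float("inf")


# ---------------------------------------------------------------------------
# the estimator
# ---------------------------------------------------------------------------

class MovementLMM(BaseEstimator):
    """REML mixed model for hourly movement with AR(1) within-pig-day residuals.

    Parameters
    ----------
    response_col, pig_col, day_col, hour_col : str
        Column names in the analysis-ready frame passed to :meth:`fit`
        (valid hours only; invalid rows must be excluded beforehand).
    fix_sigma2_pig, fix_rho : float or None
        Hold a variance component fixed instead of estimating it (rho is
        also fixed at 0, with a warning, when no pig-day block has two
        observations).
    n_starts : int
        Starting points for the bounded quasi-Newton REML optimisation.
    ci_level : float
        Level for LSMean/BLUP intervals.

    Attributes (after ``fit``)
    --------------------------
    vc_ : VarianceComponents
    icc_ : float
    beta_ : pd.Series of day x hour cell means (cm/h)
    beta_cov_ : ndarray, covariance of the cell means
    reml_value_ : float, -2 restricted log-likelihood
    den_df_ : int, containment denominator df
    converged_ : bool
    """

    def __init__(
        self,
        response_col: str = "dist_cm_per_h",
        pig_col: str = "pig_id",
        day_col: str = "day",
        hour_col: str = "hour",
        fix_sigma2_pig: float | None = None,
        fix_rho: float | None = None,
        n_starts: int = 3,
        max_iter: int = 300,
        ci_level: float = 0.95,
    ):
        self.response_col = response_col
        self.pig_col = pig_col
        self.day_col = day_col
        self.hour_col = hour_col
        self.fix_sigma2_pig = fix_sigma2_pig
        self.fix_rho = fix_rho
        self.n_starts = n_starts
        self.max_iter = max_iter
        self.ci_level = ci_level

    def fit(self, records: pd.DataFrame, y=None):
        design = build_design(
            records, self.response_col, self.pig_col, self.day_col, self.hour_col
        )
        fix_rho = self.fix_rho
        if design.ar1.pair_left.size == 0 and fix_rho is None:
            logger.warning(
                "no pig-day block has >= 2 observations: rho unidentifiable, "
                "fixed at 0"
            )
            fix_rho = 0.0
        res = fit_ar1_reml(
            design.ar1,
            fix_sigma2_pig=self.fix_sigma2_pig,
            fix_rho=fix_rho,
            n_starts=self.n_starts,
            maxiter=self.max_iter,
        )
        if not res.converged:
            logger.warning("REML optimizer did not report clean convergence")
        self.design_ = design
        self.result_ = res
        self.vc_ = VarianceComponents(
            res.variances["sigma2_pig"],
            res.variances["sigma2_res"],
            res.variances["rho"],
        )
        self.icc_ = icc(self.vc_)
        self.beta_ = pd.Series(res.beta, index=design.cells, name="cell_mean")
        self.beta_cov_ = res.beta_cov
        self.reml_value_ = res.reml_value
        self.n_obs_ = design.n_obs
        self.rank_X_ = design.rank_X
        self.den_df_ = design.den_df
        self.converged_ = res.converged
        self.group_sizes_ = pd.Series(
            np.bincount(design.ar1.pig, minlength=len(design.pigs)),
            index=design.pigs, name="n_obs_pig",
        )
        return self

    # -- estimable-function machinery ------------------------------------

    def _check_fitted(self):
        if not hasattr(self, "result_"):
            raise RuntimeError("model is not fitted")

    def _lsmean_weights(self, effect: str):
        """Rows of (level, weight-vector-or-None) for one effect.

        A main-effect LSMean averages the cell means over all levels of the
        other factor with equal weight; if any required cell is unobserved
        the LSMean is inestimable and the weight vector is None.
        """
        d = self.design_
        observed = set(zip(*[d.cells.get_level_values(i) for i in (0, 1)]))
        rows = []
        if effect == "day":
            for day in d.days:
                need = [(day, h) for h in d.hours]
                if all(c in observed for c in need):
                    w = np.zeros(len(d.cells))
                    w[d.cells.get_indexer(need)] = 1.0 / len(d.hours)
                    rows.append((day, w))
                else:
                    rows.append((day, None))
        elif effect == "hour":
            for hour in d.hours:
                need = [(day, hour) for day in d.days]
                if all(c in observed for c in need):
                    w = np.zeros(len(d.cells))
                    w[d.cells.get_indexer(need)] = 1.0 / len(d.days)
                    rows.append((hour, w))
                else:
                    rows.append((hour, None))
        elif effect in ("day_hour", "day x hour"):
            for k, c in enumerate(d.cells):
                w = np.zeros(len(d.cells))
                w[k] = 1.0
                rows.append((c, w))
        else:
            raise ValueError(f"unknown effect {effect!r}")
        return rows

    def lsmeans(self, effect: str = "hour") -> pd.DataFrame:
        """Least-squares means with SEs and t-based confidence intervals.

        ``effect`` is "day", "hour" or "day_hour".  Levels whose equal-weight
        average would involve an unobserved cell are flagged inestimable
        (NaN estimate) rather than silently dropped.
        """
        self._check_fitted()
        beta = self.beta_.to_numpy()
        tcrit = stats.t.ppf(0.5 + self.ci_level / 2, self.den_df_)
        recs = []
        for level, w in self._lsmean_weights(effect):
            if w is None:
                recs.append(
                    dict(effect=effect, level=level, estimate=np.nan, se=np.nan,
                         ci_lo=np.nan, ci_hi=np.nan, estimable=False,
                         note="unobserved cell in equal-weight average")
                )
                continue
            est = float(w @ beta)
            se = float(np.sqrt(w @ self.beta_cov_ @ w))
            recs.append(
                dict(effect=effect, level=level, estimate=est, se=se,
                     ci_lo=est - tcrit * se, ci_hi=est + tcrit * se,
                     estimable=True, note="")
            )
        return pd.DataFrame(recs)

    def _wald_f(self, L: np.ndarray):
        Lb = L @ self.beta_.to_numpy()
        S = L @ self.beta_cov_ @ L.T
        r = L.shape[0]
        F = float(Lb @ np.linalg.solve(S, Lb)) / r
        p = float(stats.f.sf(F, r, self.den_df_))
        return F, r, p

    def type3(self) -> pd.DataFrame:
        """Type-3 F tests for Day, Hour and Day x Hour.

        Main effects test equality of the estimable LSMeans; the interaction
        tests departure of the observed cell means from the additive
        day + hour span (rank = n observed cells - additive rank).  All use
        the containment denominator df.
        """
        self._check_fitted()
        d = self.design_
        rows = []
        for effect in ("day", "hour"):
            ws = [w for _, w in self._lsmean_weights(effect) if w is not None]
            dropped = sum(1 for _, w in self._lsmean_weights(effect) if w is None)
            if len(ws) < 2:
                logger.warning("type3: effect %s has rank 0, skipped", effect)
                continue
            L = np.array([w - ws[0] for w in ws[1:]])
            F, r, p = self._wald_f(L)
            rows.append(
                dict(effect=effect, num_df=r, den_df=self.den_df_, F=F, p=p,
                     n_inestimable=dropped)
            )
        if d.interaction_rank > 0:
            Zadd = _additive_design(d.cells, d.days, d.hours)
            L = null_space(Zadd.T).T
            F, r, p = self._wald_f(L)
            rows.append(
                dict(effect="day x hour", num_df=r, den_df=self.den_df_, F=F,
                     p=p, n_inestimable=0)
            )
        return pd.DataFrame(rows)

    def slice_tests(self) -> pd.DataFrame:
        """Per-day F tests of equality of that day's observed hourly means."""
        self._check_fitted()
        d = self.design_
        cell_day = d.cells.get_level_values(0).to_numpy()
        rows = []
        for day in d.days:
            idx = np.flatnonzero(cell_day == day)
            if idx.size < 2:
                logger.warning("slice_tests: day %s has < 2 observed hours, skipped", day)
                continue
            L = np.zeros((idx.size - 1, len(d.cells)))
            L[np.arange(idx.size - 1), idx[1:]] = 1.0
            L[:, idx[0]] -= 1.0
            F, r, p = self._wald_f(L)
            rows.append(dict(day=day, num_df=r, den_df=self.den_df_, F=F, p=p))
        return pd.DataFrame(rows)

    def blups(self) -> pd.DataFrame:
        """Conditional modes of the pig random intercept with prediction CIs.

        b_i-hat = sigma2_pig * 1' V_i^-1 (y_i - X_i beta-hat); the prediction
        variance includes the fixed-effect uncertainty term, so pigs with few
        observations shrink toward zero with wider intervals.
        """
        self._check_fitted()
        aux = self.result_.aux
        s2p = self.vc_.sigma2_pig
        bhat = s2p * aux["vr_pig"]
        t = aux["t_pig"]
        q = aux["q_pig"]
        var = s2p - s2p**2 * t + s2p**2 * np.einsum("ip,pq,iq->i", q, self.beta_cov_, q)
        var = np.maximum(var, 0.0)
        se = np.sqrt(var)
        tcrit = stats.t.ppf(0.5 + self.ci_level / 2, self.den_df_)
        return pd.DataFrame(
            {
                "pig_id": self.design_.pigs,
                "deviation": bhat,
                "se_pred": se,
                "ci_lo": bhat - tcrit * se,
                "ci_hi": bhat + tcrit * se,
                "n_obs_pig": self.group_sizes_.to_numpy(),
            }
        )


# ---------------------------------------------------------------------------
# thin functional wrappers
# ---------------------------------------------------------------------------

def fit_lmm(records: pd.DataFrame, **params) -> MovementLMM:
    """Fit the hourly-movement mixed model; returns the fitted estimator."""
    return MovementLMM(**params).fit(records)


def lsmeans(fit: MovementLMM, effect: str = "hour") -> pd.DataFrame:
    return fit.lsmeans(effect)


def blups(fit: MovementLMM) -> pd.DataFrame:
    return fit.blups()


def type3_tests(fit: MovementLMM) -> pd.DataFrame:
    return fit.type3()


def slice_tests(fit: MovementLMM) -> pd.DataFrame:
    return fit.slice_tests()
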