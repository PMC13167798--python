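"""Environmental aggregation and the day x timeline covariate model.

Barn-climate records (temperature, relative humidity, PM1/PM2.5/PM10) are
averaged to day x timeline blocks — Timeline 1 = 00:00-07:00,
2 = 08:00-15:00, 3 = 16:00-23:00 — and pig movement to the matching
pig x day x timeline means (weight = number of contributing valid hours).
Because the PM fractions travel together (pairwise Pearson r near 1), a
collinearity screen retains only PM2.5 when every pairwise correlation
exceeds a threshold.  The covariate model is then

    dist_mean = Day + Timeline + temp + rh + pm25 + u_pig + u_DayTL + e,

with independent crossed random intercepts for pig and day-by-timeline and
residual variance sigma2_res / n_hours (observations weighted by the hours
behind each mean), fitted by REML.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .reml import DiagDesign, fit_diag_reml

logger = logging.getLogger(__name__)

__all__ = [
    "TIMELINE_BLOCKS",
    "timeline_of_hour",
    "aggregate_env",
    "pm_screen",
    "movement_to_blocks",
    "EnvLMM",
    "fit_env_model",
]

#: hour ranges (inclusive) of the three timeline blocks
TIMELINE_BLOCKS = {1: (0, 7), 2: (8, 15), 3: (16, 23)}

PM_COLS = ["pm1_mean", "pm25_mean", "pm10_mean"]


def timeline_of_hour(hour: int) -> int:
    """Map an hour 0..23 to its timeline block 1..3 (0-7 / 8-15 / 16-23)."""
    h = np.asarray(hour)
    if np.any(h < 0) or np.any(h > 23):
        raise ValueError("hour must be in 0..23")
    out = 1 + h // 8
    return int(out) if out.ndim == 0 else out.astype(int)


def aggregate_env(records: pd.DataFrame) -> pd.DataFrame:
    """Mean environmental conditions per day x timeline block.

    ``records`` needs columns day, time_s (seconds since midnight) and the
    sensor variables temp_c, rh_pct, pm1, pm25, pm10.  Blocks with no
    records are absent from the output.
    """
    df = records.copy()
    hour = (df["time_s"] // 3600).astype(int).clip(0, 23)
    df["timeline"] = timeline_of_hour(hour)
    agg = (
        df.groupby(["day", "timeline"])
        .agg(
            temp_mean=("temp_c", "mean"),
            rh_mean=("rh_pct", "mean"),
            pm1_mean=("pm1", "mean"),
            pm25_mean=("pm25", "mean"),
            pm10_mean=("pm10", "mean"),
            n_records=("temp_c", "size"),
        )
        .reset_index()
    )
    logger.info("aggregate_env: %d records -> %d day x timeline blocks", len(df), len(agg))
    return agg


def pm_screen(env_table: pd.DataFrame, r_threshold: float = 0.95):
    """Collinearity screen of the PM fractions.

    Computes pairwise Pearson correlations among the block-level PM1, PM2.5
    and PM10 means.  If every pair exceeds ``r_threshold`` only PM2.5 is
    retained (the intermediate fraction); otherwise all three are kept.
    Zero-variance columns make a correlation undefined and are flagged.

    Returns ``(retained_columns, report)`` where the report lists each pair
    with its r and a flag column.
    """
    if len(env_table) < 3:
        raise ValueError("need >= 3 blocks for a meaningful correlation screen")
    rows = []
    degenerate = set()
    for a, b in combinations(PM_COLS, 2):
        xa = env_table[a].to_numpy(dtype=float)
        xb = env_table[b].to_numpy(dtype=float)
        if np.std(xa) == 0 or np.std(xb) == 0:
            if np.std(xa) == 0:
                degenerate.add(a)
            if np.std(xb) == 0:
                degenerate.add(b)
            rows.append(dict(var_a=a, var_b=b, r=np.nan, flag="zero-variance column"))
            continue
        r = float(stats.pearsonr(xa, xb)[0])
        rows.append(dict(var_a=a, var_b=b, r=r, flag=""))
    report = pd.DataFrame(rows)
    finite = report["r"].dropna()
    if degenerate:
        logger.warning("pm_screen: zero-variance PM columns: %s", sorted(degenerate))
    if len(finite) == len(report) and (finite > r_threshold).all():
        retained = ["pm25_mean"]
    else:
        retained = list(PM_COLS)
    logger.info("pm_screen: retained %s (threshold %.2f)", retained, r_threshold)
    return retained, report


def movement_to_blocks(hourly: pd.DataFrame) -> pd.DataFrame:
    """Pig x day x timeline movement means from valid hours only.

    ``dist_mean`` is the mean of the valid hourly values in the block and
    ``n_hours`` their count (1..8); blocks with no valid hour are absent.
    """
    df = hourly[hourly["valid"].astype(bool)].copy()
    df["timeline"] = timeline_of_hour(df["hour"].to_numpy())
    out = (
        df.groupby(["pig_id", "day", "timeline"])
        .agg(dist_mean=("dist_cm_per_h", "mean"), n_hours=("dist_cm_per_h", "size"))
        .reset_index()
    )
    logger.info(
        "movement_to_blocks: %d valid hours -> %d pig x day x timeline blocks",
        len(df), len(out),
    )
    return out


class EnvLMM(BaseEstimator):
    """Weighted mixed model of movement on environmental covariates.

    Fixed effects: day (factor), timeline (factor) and the retained
    continuous covariates; independent crossed random intercepts for pig
    and day-by-timeline; residual variance sigma2_res / n_hours.  Type-3 F
    tests use the containment denominator df
    (n - rank[fixed, pig dummies, day-timeline dummies]).

    Attributes (after ``fit``): ``beta_`` (pd.Series), ``beta_cov_``,
    ``vc_`` (dict with sigma2_res, sigma2_pig, sigma2_daytl),
    ``reml_value_``, ``den_df_``, ``type3_`` (DataFrame), ``dropped_``.
    """

    def __init__(
        self,
        covariates: tuple = ("temp_mean", "rh_mean", "pm25_mean"),
        weight_col: str = "n_hours",
        response_col: str = "dist_mean",
        n_starts: int = 3,
        ci_level: float = 0.95,
    ):
        self.covariates = covariates
        self.weight_col = weight_col
        self.response_col = response_col
        self.n_starts = n_starts
        self.ci_level = ci_level

    def _build_fixed(self, df: pd.DataFrame):
        days = np.sort(df["day"].unique())
        tls = np.sort(df["timeline"].unique())
        cols, names, effects = [np.ones(len(df))], ["intercept"], ["intercept"]
        for lev in days[1:]:
            cols.append((df["day"] == lev).to_numpy(dtype=float))
            names.append(f"day[{lev}]")
            effects.append("day")
        for lev in tls[1:]:
            cols.append((df["timeline"] == lev).to_numpy(dtype=float))
            names.append(f"timeline[{lev}]")
            effects.append("timeline")
        X = np.column_stack(cols)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError(
                "day/timeline factor design is rank deficient; check the "
                "block layout"
            )
        # add covariates greedily; a covariate adding no rank (constant, or
        # collinear with the factors / earlier covariates) is inestimable
        flagged = []
        for cov in self.covariates:
            x = df[cov].to_numpy(dtype=float)
            cand = np.column_stack([X, x])
            if np.std(x) == 0 or np.linalg.matrix_rank(cand) == X.shape[1]:
                flagged.append(cov)
                continue
            X = cand
            names.append(cov)
            effects.append(cov)
        return X, names, effects, flagged

    def fit(self, blocks: pd.DataFrame, y=None):
        required = {"pig_id", "day", "timeline", self.response_col, self.weight_col}
        missing = required - set(blocks.columns)
        if missing:
            raise ValueError(f"blocks missing columns: {sorted(missing)}")
        df = blocks.reset_index(drop=True)
        X, names, effects, flagged = self._build_fixed(df)
        if flagged:
            logger.warning(
                "EnvLMM: covariates flagged inestimable (constant or "
                "collinear) and dropped: %s", flagged,
            )
        y_arr = df[self.response_col].to_numpy(dtype=float)
        w = df[self.weight_col].to_numpy(dtype=float)
        if np.any(w <= 0):
            raise ValueError("weights must be positive")
        # weights are relative: normalise to mean 1 so that proportional
        # weight vectors give identical fits (sigma2_res then refers to an
        # average-weight observation)
        w = w / w.mean()

        pig_codes, pigs = pd.factorize(df["pig_id"], sort=True)
        dt_key = pd.MultiIndex.from_arrays([df["day"], df["timeline"]])
        dt_codes, dts = pd.factorize(dt_key, sort=True)
        Zp = np.zeros((len(df), len(pigs)))
        Zp[np.arange(len(df)), pig_codes] = 1.0
        Zd = np.zeros((len(df), len(dts)))
        Zd[np.arange(len(df)), dt_codes] = 1.0
        Z = np.hstack([Zp, Zd])
        slices = [slice(0, len(pigs)), slice(len(pigs), len(pigs) + len(dts))]

        design = DiagDesign(X=X, y=y_arr, w=w, Z=Z, factor_slices=slices)
        res = fit_diag_reml(design, n_starts=self.n_starts)

        den_df = len(df) - int(np.linalg.matrix_rank(np.hstack([X, Zp, Zd])))

        self.design_ = design
        self.result_ = res
        self.coef_names_ = names
        self.coef_effects_ = effects
        self.flagged_covariates_ = flagged
        self.beta_ = pd.Series(res.beta, index=names, name="estimate")
        self.beta_cov_ = res.beta_cov
        self.vc_ = {
            "sigma2_res": res.variances["sigma2_res"],
            "sigma2_pig": res.variances["sigma2_factor0"],
            "sigma2_daytl": res.variances["sigma2_factor1"],
        }
        self.reml_value_ = res.reml_value
        self.converged_ = res.converged
        self.n_obs_ = len(df)
        self.den_df_ = den_df
        self.type3_ = self._type3()
        return self

    def _type3(self) -> pd.DataFrame:
        """Type-3 F per fixed effect (factor coefficient blocks; no
        interactions, so Type-3 coincides with testing the coefficients)."""
        beta = self.beta_.to_numpy()
        rows = []
        order = ["day", "timeline", *[c for c in self.covariates
                                      if c not in self.flagged_covariates_]]
        for eff in order:
            idx = [i for i, e in enumerate(self.coef_effects_) if e == eff]
            if not idx:
                continue
            L = np.zeros((len(idx), len(beta)))
            L[np.arange(len(idx)), idx] = 1.0
            Lb = L @ beta
            S = L @ self.beta_cov_ @ L.T
            F = float(Lb @ np.linalg.solve(S, Lb)) / len(idx)
            p = float(stats.f.sf(F, len(idx), self.den_df_))
            rows.append(dict(effect=eff, num_df=len(idx), den_df=self.den_df_,
                             F=F, p=p))
        for cov in self.flagged_covariates_:
            rows.append(dict(effect=cov, num_df=0, den_df=self.den_df_,
                             F=np.nan, p=np.nan))
        return pd.DataFrame(rows)


def fit_env_model(
    movement_blocks: pd.DataFrame,
    env_table: pd.DataFrame,
    retained: list | None = None,
    **params,
):
    """Join movement and environmental blocks and fit the covariate model.

    ``retained`` defaults to the outcome of :func:`pm_screen` on
    ``env_table`` plus temperature and humidity.  Movement blocks without a
    matching environmental block are dropped with a logged count (sensor
    outages leave some day x timeline combinations unmeasured).

    Returns ``(type3_table, fitted_EnvLMM)``.
    """
    if retained is None:
        pm_retained, _ = pm_screen(env_table)
        retained = ["temp_mean", "rh_mean", *pm_retained]
    joined = movement_blocks.merge(env_table, on=["day", "timeline"], how="inner")
    dropped = len(movement_blocks) - len(joined)
    if dropped:
        logger.warning(
            "fit_env_model: dropped %d movement blocks without environmental "
            "data", dropped,
        )
    model = EnvLMM(covariates=tuple(retained), **params).fit(joined)
    model.dropped_ = dropped
    return model.type3_, model
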