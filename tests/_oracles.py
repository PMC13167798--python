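"""Independent brute-force oracles used by the tests.

These deliberately build dense n x n covariance matrices and use generic
linear algebra (or explicit loops), so they share no code path with the
package's O(n) kernels.
"""

import numpy as np
import pandas as pd


def dense_V(df, sigma2_pig, sigma2_res, rho):
    """Explicit marginal covariance of the hourly model: pig-intercept block
    plus AR(1) (rho**|delta hour|) within pig x day."""
    df = df.sort_values(["pig_id", "day", "hour"])
    pig = df["pig_id"].to_numpy()
    day = df["day"].to_numpy()
    h = df["hour"].to_numpy(dtype=float)
    n = len(df)
    V = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if pig[i] == pig[j]:
                V[i, j] += sigma2_pig
                if day[i] == day[j]:
                    V[i, j] += sigma2_res * rho ** abs(h[i] - h[j])
    return V


def cell_design(df, cells):
    """Saturated day x hour cell-indicator matrix on sorted rows."""
    df = df.sort_values(["pig_id", "day", "hour"])
    lookup = {c: k for k, c in enumerate(cells)}
    X = np.zeros((len(df), len(cells)))
    for r, (d, h) in enumerate(zip(df["day"], df["hour"])):
        X[r, lookup[(d, h)]] = 1.0
    return X


def dense_neg2_reml(df, cells, sigma2_pig, sigma2_res, rho):
    """-2 restricted log-likelihood from the full V matrix."""
    df = df.sort_values(["pig_id", "day", "hour"])
    y = df["dist_cm_per_h"].to_numpy(dtype=float)
    V = dense_V(df, sigma2_pig, sigma2_res, rho)
    X = cell_design(df, cells)
    Vi = np.linalg.inv(V)
    A = X.T @ Vi @ X
    beta = np.linalg.solve(A, X.T @ Vi @ y)
    r = y - X @ beta
    n, p = X.shape
    return (
        np.linalg.slogdet(V)[1]
        + np.linalg.slogdet(A)[1]
        + r @ Vi @ r
        + (n - p) * np.log(2 * np.pi)
    )


def dense_gls_beta(df, cells, sigma2_pig, sigma2_res, rho):
    df = df.sort_values(["pig_id", "day", "hour"])
    y = df["dist_cm_per_h"].to_numpy(dtype=float)
    V = dense_V(df, sigma2_pig, sigma2_res, rho)
    X = cell_design(df, cells)
    Vi = np.linalg.inv(V)
    return np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)


def henderson_blups(df, cells, sigma2_pig, sigma2_res, rho):
    """Random-effect solutions of the mixed-model (Henderson) equations."""
    df = df.sort_values(["pig_id", "day", "hour"])
    y = df["dist_cm_per_h"].to_numpy(dtype=float)
    pigs = sorted(df["pig_id"].unique())
    Z = np.zeros((len(df), len(pigs)))
    for r, p in enumerate(df["pig_id"]):
        Z[r, pigs.index(p)] = 1.0
    X = cell_design(df, cells)
    # residual covariance only (no pig term)
    R = dense_V(df, 0.0, sigma2_res, rho)
    Ri = np.linalg.inv(R)
    q = len(pigs)
    top = np.hstack([X.T @ Ri @ X, X.T @ Ri @ Z])
    bot = np.hstack([Z.T @ Ri @ X, Z.T @ Ri @ Z + np.eye(q) / sigma2_pig])
    rhs = np.concatenate([X.T @ Ri @ y, Z.T @ Ri @ y])
    sol = np.linalg.solve(np.vstack([top, bot]), rhs)
    return pigs, sol[X.shape[1]:]


def anova_two_way_f(df):
    """Classical balanced two-way ANOVA with interaction: sums-of-squares
    decomposition, returning F for rows (day), columns (hour), interaction."""
    piv = df.pivot_table(
        index=["day", "hour"], columns="pig_id", values="dist_cm_per_h"
    )
    y = df["dist_cm_per_h"].to_numpy(dtype=float)
    n = len(df)
    grand = y.mean()
    days = sorted(df["day"].unique())
    hours = sorted(df["hour"].unique())
    reps = n // (len(days) * len(hours))
    cell = df.groupby(["day", "hour"])["dist_cm_per_h"].mean()
    dmean = df.groupby("day")["dist_cm_per_h"].mean()
    hmean = df.groupby("hour")["dist_cm_per_h"].mean()
    ss_day = reps * len(hours) * ((dmean - grand) ** 2).sum()
    ss_hour = reps * len(days) * ((hmean - grand) ** 2).sum()
    ss_cell = reps * ((cell - grand) ** 2).sum()
    ss_int = ss_cell - ss_day - ss_hour
    resid = df["dist_cm_per_h"] - cell.loc[
        list(zip(df["day"], df["hour"]))
    ].to_numpy()
    ss_err = (resid ** 2).sum()
    df_err = n - len(days) * len(hours)
    mse = ss_err / df_err
    return {
        "day": ss_day / (len(days) - 1) / mse,
        "hour": ss_hour / (len(hours) - 1) / mse,
        "day x hour": ss_int / ((len(days) - 1) * (len(hours) - 1)) / mse,
        "df_err": df_err,
    }


def loop_increment_sum(distances):
    total = 0.0
    for a, b in zip(distances[:-1], distances[1:]):
        total += abs(b - a)
    return total


def group_mean_oracle(df, keys, value):
    """Brute-force group-then-average, independent of pandas groupby."""
    out = {}
    for _, row in df.iterrows():
        k = tuple(row[c] for c in keys)
        out.setdefault(k, []).append(row[value])
    return {k: (float(np.mean(v)), len(v)) for k, v in out.items()}
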