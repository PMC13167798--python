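"""Restricted-likelihood kernels for the two mixed models in the pipeline.

Two covariance families are supported:

* ``AR1Design`` / ``ar1_neg2_reml`` — random pig intercept plus AR(1)
  residuals within pig x day blocks (the hourly-movement model).  Per pig,
  V_i = sigma2_pig * J + blockdiag over days of sigma2_res * R(rho), with
  R the Markov correlation rho**|delta hours| over the observed (possibly
  gappy) hours.  R's inverse is tridiagonal and the pig intercept is a
  rank-one update, so one evaluation of -2 restricted log-likelihood costs
  O(n) plus a p x p Cholesky — no n x n matrix is ever formed.

* ``DiagDesign`` / ``diag_neg2_reml`` — weighted independent residuals plus
  any number of crossed random-intercept factors (the environmental model),
  evaluated through the Woodbury identity with a q x q inner solve.

Both evaluate

    -2 l_R = log|V| + log|X' V^-1 X| + r' V^-1 r + (n - p) log(2 pi)

with r the GLS residual at the profiled beta, and both are checked in the
test suite against dense brute-force V-matrix oracles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve

logger = logging.getLogger(__name__)

_LOG2PI = np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# pig-intercept + AR(1) family
# ---------------------------------------------------------------------------

@dataclass
class AR1Design:
    """Preprocessed layout for the hourly model.

    Rows must be sorted by (pig, day, hour).  ``cell`` indexes the observed
    day x hour cells (the fixed-effect design is the saturated cell-mean
    coding, full rank by construction); ``pair_left`` lists row indices i
    such that rows i and i+1 fall in the same pig-day block, with
    ``pair_gap`` the hour spacing between them.
    """

    y: np.ndarray
    cell: np.ndarray
    pig: np.ndarray
    pair_left: np.ndarray
    pair_gap: np.ndarray
    n_cells: int
    n_pigs: int

    def __post_init__(self):
        if np.any(self.pair_gap <= 0):
            raise ValueError("duplicate or unsorted hours within a pig-day block")


def ar1_neg2_reml(
    sigma2_pig: float,
    sigma2_res: float,
    rho: float,
    design: AR1Design,
    want_aux: bool = False,
):
    """-2 restricted log-likelihood for the pig-intercept + AR(1) model.

    Returns the scalar objective, or ``(value, aux)`` with the fitted-state
    quantities (GLS beta, Cholesky of X'V^-1X, per-pig Woodbury terms)
    when ``want_aux`` is set.
    """
    if sigma2_pig < 0 or sigma2_res <= 0 or not abs(rho) < 1:
        raise ValueError("theta outside the parameter space")
    y = design.y
    n = y.size
    p = design.n_cells
    pl = design.pair_left
    cell = design.cell

    a = rho ** design.pair_gap
    a2 = a * a
    om = 1.0 - a2
    # tridiagonal entries of C = (sigma2_res * R)^-1 per block
    diag = np.full(n, 1.0 / sigma2_res)
    wpair = a2 / om / sigma2_res
    np.add.at(diag, pl, wpair)
    np.add.at(diag, pl + 1, wpair)
    off = -a / om / sigma2_res
    logdet_B = n * np.log(sigma2_res) + float(np.sum(np.log(om)))

    Cy = diag * y
    np.add.at(Cy, pl, off * y[pl + 1])
    np.add.at(Cy, pl + 1, off * y[pl])
    v = diag.copy()  # C @ 1
    np.add.at(v, pl, off)
    np.add.at(v, pl + 1, off)

    s = np.bincount(design.pig, v, minlength=design.n_pigs)
    vy = np.bincount(design.pig, v * y, minlength=design.n_pigs)
    denom = 1.0 + sigma2_pig * s
    kappa = sigma2_pig / denom
    logdet_V = logdet_B + float(np.sum(np.log(denom)))

    A = np.zeros((p, p))
    np.add.at(A, (cell, cell), diag)
    np.add.at(A, (cell[pl], cell[pl + 1]), off)
    np.add.at(A, (cell[pl + 1], cell[pl]), off)
    G = np.zeros((design.n_pigs, p))
    np.add.at(G, (design.pig, cell), v)
    A -= (G * kappa[:, None]).T @ G

    b = np.bincount(cell, Cy, minlength=p) - G.T @ (kappa * vy)
    yVy = float(y @ Cy - kappa @ (vy * vy))

    cho = cho_factor(A, lower=True)
    logdet_A = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
    beta = cho_solve(cho, b)
    quad = yVy - float(b @ beta)
    value = logdet_V + logdet_A + quad + (n - p) * _LOG2PI

    if not want_aux:
        return value
    # per-pig quantities for BLUPs: 1'V_i^-1 r, 1'V_i^-1 1, X_i'V_i^-1 1
    r = y.copy()
    np.subtract(r, beta[cell], out=r)
    vr = np.bincount(design.pig, v * r, minlength=design.n_pigs)
    aux = {
        "beta": beta,
        "cho": cho,
        "A": A,
        "quad": quad,
        "logdet_V": logdet_V,
        "logdet_A": logdet_A,
        "t_pig": s / denom,                 # 1' V_i^-1 1
        "q_pig": G / denom[:, None],        # X_i' V_i^-1 1
        "vr_pig": vr / denom,               # 1' V_i^-1 (y - X beta)
    }
    return value, aux


@dataclass
class REMLResult:
    """Outcome of a REML optimisation."""

    variances: dict
    beta: np.ndarray
    beta_cov: np.ndarray
    reml_value: float
    converged: bool
    n_evals: int
    message: str
    aux: dict = field(default_factory=dict, repr=False)


_AR1_STARTS = [(0.3, 0.2), (0.1, 0.0), (0.6, 0.4)]


def fit_ar1_reml(
    design: AR1Design,
    fix_sigma2_pig: float | None = None,
    fix_rho: float | None = None,
    n_starts: int = 3,
    maxiter: int = 300,
) -> REMLResult:
    """Maximise the restricted likelihood over (sigma2_pig, sigma2_res, rho).

    Optimises bounded quasi-Newton (L-BFGS-B) over log-variance / atanh(rho)
    transforms from ``n_starts`` spread starting points; either variance
    ratio or rho may be held fixed (used for classical-limit checks and for
    designs where rho is unidentifiable).
    """
    y = design.y
    # moment start: within-cell residual variance
    counts = np.bincount(design.cell, minlength=design.n_cells).astype(float)
    means = np.bincount(design.cell, y, minlength=design.n_cells) / counts
    resid0 = y - means[design.cell]
    v0 = max(float(resid0 @ resid0) / max(y.size - design.n_cells, 1), 1e-12)

    free_pig = fix_sigma2_pig is None
    free_rho = fix_rho is None

    def unpack(x):
        i = 0
        if free_pig:
            s2p = v0 * np.exp(np.clip(x[i], -30, 15)); i += 1
        else:
            s2p = fix_sigma2_pig
        s2r = v0 * np.exp(np.clip(x[i], -30, 15)); i += 1
        if free_rho:
            rho = np.tanh(np.clip(x[i], -8, 8)); i += 1
        else:
            rho = fix_rho
        return s2p, s2r, rho

    n_evals = 0

    def objective(x):
        nonlocal n_evals
        n_evals += 1
        try:
            val = ar1_neg2_reml(*unpack(x), design)
        except (np.linalg.LinAlgError, ValueError, FloatingPointError):
            return 1e12
        return val if np.isfinite(val) else 1e12

    best = None
    for icc0, rho0 in _AR1_STARTS[:max(n_starts, 1)]:
        x0 = []
        if free_pig:
            x0.append(np.log(max(icc0, 1e-3)))
        x0.append(np.log(max(1.0 - icc0, 1e-3)))
        if free_rho:
            x0.append(np.arctanh(np.clip(rho0, -0.95, 0.95)))
        res = optimize.minimize(
            objective, np.asarray(x0), method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-8},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best.fun >= 1e12:
        raise RuntimeError(f"REML optimisation failed: {best.message}")

    s2p, s2r, rho = unpack(best.x)
    # exact profile step for the overall scale: at fixed variance ratio and
    # rho, the restricted likelihood is maximised where the GLS quadratic
    # form equals n - p; apply it when both variances are free to scale
    if free_pig or fix_sigma2_pig == 0.0:
        _, aux0 = ar1_neg2_reml(s2p, s2r, rho, design, want_aux=True)
        c = aux0["quad"] / max(y.size - design.n_cells, 1)
        if np.isfinite(c) and c > 0:
            s2p, s2r = s2p * c, s2r * c
    value, aux = ar1_neg2_reml(s2p, s2r, rho, design, want_aux=True)
    beta_cov = cho_solve(aux["cho"], np.eye(design.n_cells))
    result = REMLResult(
        variances={"sigma2_pig": float(s2p), "sigma2_res": float(s2r), "rho": float(rho)},
        beta=aux["beta"],
        beta_cov=beta_cov,
        reml_value=float(value),
        converged=bool(best.success),
        n_evals=n_evals,
        message=str(best.message),
        aux=aux,
    )
    if not best.success:
        logger.warning("fit_ar1_reml: optimizer flag not set: %s", best.message)
    logger.info(
        "fit_ar1_reml: sigma2_pig=%.1f sigma2_res=%.1f rho=%.3f (-2logLik_R=%.2f, "
        "%d evals)", s2p, s2r, rho, value, n_evals,
    )
    return result


# ---------------------------------------------------------------------------
# weighted diagonal residual + crossed random intercepts family
# ---------------------------------------------------------------------------

@dataclass
class DiagDesign:
    """Layout for the environmental model.

    ``Z`` stacks the one-hot indicator blocks of each random-intercept
    factor (columns grouped by factor per ``factor_slices``); ``w`` are the
    observation weights (residual variance sigma2_res / w).  ``X`` must have
    full column rank.
    """

    X: np.ndarray
    y: np.ndarray
    w: np.ndarray
    Z: np.ndarray
    factor_slices: list

    def __post_init__(self):
        if np.any(self.w <= 0):
            raise ValueError("weights must be positive")


def diag_neg2_reml(
    sigma2_res: float,
    sigma2_factors: Sequence[float],
    design: DiagDesign,
    want_aux: bool = False,
):
    """-2 restricted log-likelihood for the weighted crossed-intercepts model."""
    if sigma2_res <= 0 or any(s < 0 for s in sigma2_factors):
        raise ValueError("variances outside the parameter space")
    X, y, w, Z = design.X, design.y, design.w, design.Z
    n, p = X.shape
    g = np.concatenate(
        [np.full(sl.stop - sl.start, max(s2, 1e-12) )
         for sl, s2 in zip(design.factor_slices, sigma2_factors)]
    )
    D = w / sigma2_res
    DZ = Z * D[:, None]
    M = Z.T @ DZ + np.diag(1.0 / g)
    choM = cho_factor(M, lower=True)
    logdet_V = (
        2.0 * float(np.sum(np.log(np.diag(choM[0]))))
        + float(np.sum(np.log(g)))
        + float(np.sum(np.log(sigma2_res / w)))
    )

    def vinv(B):
        DB = B * D[:, None] if B.ndim == 2 else B * D
        return DB - DZ @ cho_solve(choM, DZ.T @ B)

    VX = vinv(X)
    A = X.T @ VX
    b = VX.T @ y
    yVy = float(y @ vinv(y))
    cho = cho_factor(A, lower=True)
    logdet_A = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
    beta = cho_solve(cho, b)
    quad = yVy - float(b @ beta)
    value = logdet_V + logdet_A + quad + (n - p) * _LOG2PI
    if not want_aux:
        return value
    aux = {"beta": beta, "cho": cho, "A": A}
    return value, aux


def fit_diag_reml(
    design: DiagDesign, n_starts: int = 3, maxiter: int = 300
) -> REMLResult:
    """REML fit of the weighted model with crossed random intercepts."""
    X, y = design.X, design.y
    n, p = X.shape
    n_factors = len(design.factor_slices)
    beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
    r0 = y - X @ beta0
    v0 = max(float(r0 @ r0) / max(n - p, 1), 1e-12)

    def unpack(x):
        s = v0 * np.exp(np.clip(x, -30, 15))
        return float(s[0]), s[1:]

    n_evals = 0

    def objective(x):
        nonlocal n_evals
        n_evals += 1
        try:
            val = diag_neg2_reml(*unpack(x), design)
        except (np.linalg.LinAlgError, ValueError, FloatingPointError):
            return 1e12
        return val if np.isfinite(val) else 1e12

    shares = [
        [0.6] + [0.2] * n_factors,
        [0.9] + [0.05] * n_factors,
        [0.3] + [0.35] * n_factors,
    ]
    best = None
    for sh in shares[:max(n_starts, 1)]:
        x0 = np.log(np.asarray(sh))
        res = optimize.minimize(
            objective, x0, method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-8},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best.fun >= 1e12:
        raise RuntimeError(f"REML optimisation failed: {best.message}")

    s2e, s2f = unpack(best.x)
    value, aux = diag_neg2_reml(s2e, s2f, design, want_aux=True)
    beta_cov = cho_solve(aux["cho"], np.eye(p))
    variances = {"sigma2_res": float(s2e)}
    variances.update(
        {f"sigma2_factor{i}": float(s) for i, s in enumerate(s2f)}
    )
    return REMLResult(
        variances=variances,
        beta=aux["beta"],
        beta_cov=beta_cov,
        reml_value=float(value),
        converged=bool(best.success),
        n_evals=n_evals,
        message=str(best.message),
        aux=aux,
    )
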