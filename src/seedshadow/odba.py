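"""Activity from tri-axial accelerometer bursts.

ODBA (overall dynamic body acceleration) is the non-vectorial sum over
the three axes of the mean absolute deviation from each axis's
per-burst mean (the static, gravitational component). Candidate models
of ODBA against weather and habitat covariates are fitted as linear
models with a per-animal random intercept and ranked by AICc.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = ["AccBurst", "compute_odba", "aicc", "rank_models",
           "read_bursts_csv"]


@dataclass
class AccBurst:
    """One 20 s burst: 3 axes x n samples, with a linear count->g map."""

    animal_id: str
    timestamp: pd.Timestamp
    samples: np.ndarray  # shape (3, n)
    slope: tuple[float, float, float] = (1.0, 1.0, 1.0)
    intercept: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[0] != 3:
            raise ValueError("samples must have shape (3, n)")
        if self.samples.shape[1] < 2:
            raise ValueError("need >= 2 samples per axis")

    def in_g(self) -> np.ndarray:
        slope = np.asarray(self.slope)[:, None]
        intercept = np.asarray(self.intercept)[:, None]
        return self.samples * slope + intercept


def compute_odba(burst: AccBurst | np.ndarray) -> float:
    """ODBA in g for one burst.

    Per axis: subtract the burst mean, average the absolute residuals;
    sum the three per-axis means. Subtracting the mean removes any
    constant (gravity) offset, so ODBA is invariant to per-axis shifts.
    """
    if isinstance(burst, AccBurst):
        acc = burst.in_g()
    else:
        acc = np.asarray(burst, dtype=float)
        if acc.ndim != 2 or acc.shape[0] != 3:
            raise ValueError("expected array of shape (3, n)")
        if acc.shape[1] < 2:
            raise ValueError("need >= 2 samples per axis")
    dyn = acc - acc.mean(axis=1, keepdims=True)
    return float(np.abs(dyn).mean(axis=1).sum())


def read_bursts_csv(path) -> list[AccBurst]:
    """Read bursts from a long CSV
    (animal_id, timestamp, axis, sample_index, value)."""
    raw = pd.read_csv(path)
    raw["timestamp"] = pd.to_datetime(raw["timestamp"])
    bursts = []
    for (animal, ts), grp in raw.groupby(["animal_id", "timestamp"],
                                         sort=True):
        piv = grp.pivot(index="axis", columns="sample_index", values="value")
        piv = piv.sort_index().sort_index(axis=1)
        bursts.append(AccBurst(str(animal), ts, piv.to_numpy()))
    return bursts


def aicc(loglik: float, k: int, n: int) -> float:
    """Akaike information criterion with small-sample correction:
    -2 loglik + 2k + 2k(k+1)/(n-k-1)."""
    if n <= k + 1:
        raise ValueError("AICc requires n > k + 1")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def _lmm_profiled_loglik(theta: float, X: np.ndarray, y: np.ndarray,
                         group_slices: list[np.ndarray]) -> tuple:
    """Profiled ML log-likelihood of a random-intercept linear model.

    theta = sigma_u^2 / sigma_e^2. For each group, V = I + theta J has
    the closed-form inverse I - theta/(1 + theta n_g) J and determinant
    1 + theta n_g, so GLS and the profiled residual variance are exact.
    Returns (loglik, beta_hat, sigma_e^2).
    """
    p = X.shape[1]
    XtVX = np.zeros((p, p))
    XtVy = np.zeros(p)
    logdet = 0.0
    for idx in group_slices:
        Xg, yg = X[idx], y[idx]
        ng = len(idx)
        c = theta / (1.0 + theta * ng)
        sx, sy = Xg.sum(axis=0), yg.sum()
        XtVX += Xg.T @ Xg - c * np.outer(sx, sx)
        XtVy += Xg.T @ yg - c * sx * sy
        logdet += np.log1p(theta * ng)
    beta = np.linalg.solve(XtVX, XtVy)
    n = len(y)
    rss = 0.0
    for idx in group_slices:
        r = y[idx] - X[idx] @ beta
        sr = r.sum()
        ng = len(idx)
        c = theta / (1.0 + theta * ng)
        rss += r @ r - c * sr * sr
    sigma2 = rss / n
    ll = -0.5 * (n * (np.log(2 * np.pi * sigma2) + 1.0) + logdet)
    return ll, beta, sigma2


def _fit_random_intercept(X: np.ndarray, y: np.ndarray,
                          groups: np.ndarray) -> tuple[float, np.ndarray]:
    """ML fit of y = X b + u_group + e; returns (loglik, beta).

    The variance ratio is profiled out by a 1-D bounded search; the
    boundary theta = 0 (no between-animal variance) is checked
    explicitly, so a single group collapses to ordinary least squares.
    """
    codes, _ = pd.factorize(groups)
    slices = [np.flatnonzero(codes == gid) for gid in range(codes.max() + 1)]

    def neg_ll(log_theta):
        return -_lmm_profiled_loglik(np.exp(log_theta), X, y, slices)[0]

    ll0, beta0, _ = _lmm_profiled_loglik(0.0, X, y, slices)
    best_ll, best_beta = ll0, beta0
    if len(slices) > 1:
        res = optimize.minimize_scalar(neg_ll, bounds=(-12.0, 12.0),
                                       method="bounded")
        ll1, beta1, _ = _lmm_profiled_loglik(np.exp(res.x), X, y, slices)
        if ll1 > best_ll:
            best_ll, best_beta = ll1, beta1
    return best_ll, best_beta


def rank_models(records: pd.DataFrame, predictors: list[str], *,
                response: str = "odba", group: str = "animal_id"
                ) -> pd.DataFrame:
    """All-subsets ranking of ODBA models by AICc.

    Every subset of ``predictors`` (including the intercept-only model)
    is fitted as a linear model with a per-animal random intercept by
    profiled maximum likelihood; k counts the fixed effects (including
    the intercept) plus the two variance parameters. Rows are sorted by
    AICc with delta relative to the best model. Rank-deficient subsets
    are dropped with a notice column.
    """
    if len(predictors) < 2:
        raise ValueError("need >= 2 candidate predictors")
    df = records.dropna(subset=[response, *predictors]).reset_index(drop=True)
    y = df[response].to_numpy(float)
    n = len(y)
    groups = df[group].to_numpy()
    rows = []
    for r in range(len(predictors) + 1):
        for subset in combinations(predictors, r):
            X = np.column_stack(
                [np.ones(n)] + [df[v].to_numpy(float) for v in subset])
            if np.linalg.matrix_rank(X) < X.shape[1]:
                continue  # rank-deficient design dropped
            ll, _ = _fit_random_intercept(X, y, groups)
            k = X.shape[1] + 2
            rows.append({
                "predictors": "+".join(subset) if subset else "(intercept)",
                "n_predictors": len(subset),
                "loglik": ll,
                "k": k,
                "aicc": aicc(ll, k, n),
            })
    ranking = pd.DataFrame(rows).sort_values("aicc").reset_index(drop=True)
    ranking["delta_aicc"] = ranking["aicc"] - ranking["aicc"].iloc[0]
    return ranking
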