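"""Integrated step-selection analysis (iSSA).

Per individual: fit tentative movement distributions (gamma step length,
von Mises turn angle) used to propose control steps, screen covariate
collinearity, and estimate the habitat-selection function

    w(x) = exp(beta_1 x_1 + ... + beta_n x_n)

by conditional logistic regression over strata of one used step and K
control steps. Movement-kernel terms log(SL + 1) and cos(TA) enter the
linear predictor alongside habitat covariates so that selection and
movement are estimated jointly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TentativeKernel",
    "SelectionModel",
    "CorrelationScreen",
    "DEFAULT_FORMULA",
    "fit_tentative",
    "screen_correlation",
    "add_swamp_temperature_interaction",
    "fit_clogit",
    "relative_selection",
]

#: the fitted model structure: habitat terms, swamp x temperature
#: interaction, and the movement-kernel adjustment terms
DEFAULT_FORMULA = (
    "canopy_height", "vci", "dist_gap_small", "dist_gap_large", "swamp",
    "swamp_x_temperature", "log_sl", "cos_ta",
)

KAPPA_CAP = 500.0
SEPARATION_BOUND = 15.0


@dataclass
class TentativeKernel:
    """Selection-free movement distributions fitted to observed steps.

    Step lengths ~ Gamma(sl_shape, rate=sl_rate) in metres; turn angles
    ~ von Mises(ta_mu, ta_kappa) in radians.
    """

    sl_shape: float
    sl_rate: float
    ta_mu: float = 0.0
    ta_kappa: float = 1.0
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (self.sl_shape > 0 and self.sl_rate > 0):
            raise ValueError("gamma parameters must be positive")
        if not self.ta_kappa > 0:
            raise ValueError("ta_kappa must be positive")
        if not (-np.pi < self.ta_mu <= np.pi):
            raise ValueError("ta_mu must lie in (-pi, pi]")

    @property
    def sl_mean(self) -> float:
        return self.sl_shape / self.sl_rate

    def to_dict(self) -> dict:
        return {"sl_shape": self.sl_shape, "sl_rate": self.sl_rate,
                "ta_mu": self.ta_mu, "ta_kappa": self.ta_kappa,
                "degenerate": self.degenerate}

    @classmethod
    def from_dict(cls, d: dict) -> "TentativeKernel":
        return cls(**d)


def fit_tentative(steps: pd.DataFrame, *, min_steps: int = 30,
                  zero_length_offset: float = 5.0,
                  kappa_cap: float = KAPPA_CAP) -> TentativeKernel:
    """Maximum-likelihood tentative kernel from observed steps.

    ``steps`` needs columns ``sl`` and ``ta``; rows with undefined turn
    angle (burst starts) contribute to the length fit only. Zero step
    lengths are offset by half a covariate cell (default 5 m) so the
    gamma likelihood is finite. A concentration above ``kappa_cap``
    (e.g. all angles identical) is pinned at the cap and flagged.
    """
    sl = steps["sl"].to_numpy(float)
    ta = steps["ta"].to_numpy(float)
    ta = ta[np.isfinite(ta)]
    if len(ta) < min_steps:
        raise ValueError(
            f"need >= {min_steps} steps with defined turn angles, "
            f"got {len(ta)}")
    sl = sl[np.isfinite(sl)]
    sl = np.where(sl <= 0, zero_length_offset, sl)
    shape, _, scale = stats.gamma.fit(sl, floc=0)
    degenerate = False
    if np.allclose(ta, ta[0]):
        kappa, mu = kappa_cap, float(ta[0])
        degenerate = True
    else:
        kappa, mu, _ = stats.vonmises.fit(ta, fscale=1)
        if kappa > kappa_cap:
            kappa = kappa_cap
            degenerate = True
        # vonmises.fit can return tiny negative kappa on uniform data
        kappa = max(kappa, 1e-8)
    mu = float(-((-mu + np.pi) % (2 * np.pi) - np.pi))
    return TentativeKernel(float(shape), float(1.0 / scale), mu,
                           float(kappa), degenerate=degenerate)


@dataclass
class CorrelationScreen:
    """Pairwise Pearson screen over used + control steps."""

    matrix: pd.DataFrame
    threshold: float
    excluded_pairs: list[tuple[str, str]]
    undefined: list[str] = field(default_factory=list)


def screen_correlation(stepset: pd.DataFrame, variables: list[str],
                       threshold: float = 0.6) -> CorrelationScreen:
    """Flag covariate pairs with |Pearson r| strictly above ``threshold``.

    Flagged pairs should not enter one model together. Constant
    variables have undefined correlations and are reported separately.
    """
    if len(stepset) < 3:
        raise ValueError("need >= 3 observations")
    sub = stepset[variables].astype(float)
    undefined = [v for v in variables if sub[v].std(ddof=1) == 0
                 or not np.isfinite(sub[v].std(ddof=1))]
    mat = sub.corr(method="pearson")
    for v in variables:
        mat.loc[v, v] = 1.0
    pairs = []
    for i, a in enumerate(variables):
        for b in variables[i + 1:]:
            r = mat.loc[a, b]
            if np.isfinite(r) and abs(r) > threshold:
                pairs.append((a, b))
    return CorrelationScreen(mat, threshold, pairs, undefined)


def add_swamp_temperature_interaction(stepset: pd.DataFrame) -> pd.DataFrame:
    """Interaction column: standardised temperature x raw binary swamp."""
    out = stepset.copy()
    out["swamp_x_temperature"] = out["temperature"] * out["swamp"]
    return out


@dataclass
class SelectionModel:
    """A fitted per-individual (or population) selection model."""

    coef: dict[str, float]
    se: dict[str, float]
    vcov: np.ndarray
    loglik: float
    n_strata: int
    converged: bool
    formula: tuple[str, ...]
    standardization: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)
    animal_id: str | None = None
    species: str | None = None

    @property
    def beta(self) -> np.ndarray:
        return np.array([self.coef[v] for v in self.formula])

    def pvalues(self) -> dict[str, float]:
        """Two-sided Wald p-values."""
        out = {}
        for v in self.formula:
            se = self.se[v]
            if se <= 0 or not np.isfinite(se):
                out[v] = float("nan")
            else:
                z = self.coef[v] / se
                out[v] = float(2 * stats.norm.sf(abs(z)))
        return out

    def significant(self, alpha: float = 0.05) -> dict[str, float]:
        p = self.pvalues()
        return {v: self.coef[v] for v in self.formula if p[v] < alpha}

    def confint(self, level: float = 0.95) -> dict[str, tuple[float, float]]:
        z = stats.norm.ppf(0.5 + level / 2)
        return {v: (self.coef[v] - z * self.se[v],
                    self.coef[v] + z * self.se[v]) for v in self.formula}

    def to_json(self, path=None) -> str:
        payload = {
            "coef": self.coef, "se": self.se,
            "vcov": np.asarray(self.vcov).tolist(),
            "loglik": self.loglik, "n_strata": self.n_strata,
            "converged": self.converged, "formula": list(self.formula),
            "standardization": self.standardization,
            "diagnostics": self.diagnostics,
            "animal_id": self.animal_id, "species": self.species,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "SelectionModel":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            d = json.loads(source)
        else:
            with open(source) as fh:
                d = json.load(fh)
        return cls(coef=d["coef"], se=d["se"], vcov=np.asarray(d["vcov"]),
                   loglik=d["loglik"], n_strata=d["n_strata"],
                   converged=d["converged"], formula=tuple(d["formula"]),
                   standardization=d.get("standardization", {}),
                   diagnostics=d.get("diagnostics", {}),
                   animal_id=d.get("animal_id"), species=d.get("species"))


def _clogit_loglik(beta, X, g, used, n_strata):
    """Conditional-logit log-likelihood, gradient, Hessian.

    X is the (rows, p) design, g the stratum index per row, used a bool
    mask with exactly one True per stratum.
    """
    eta = X @ beta
    m = np.full(n_strata, -np.inf)
    np.maximum.at(m, g, eta)
    w = np.exp(eta - m[g])
    Z = np.bincount(g, weights=w, minlength=n_strata)
    P = w / Z[g]
    ll = float(eta[used].sum() - (np.log(Z) + m).sum())
    # E[x] per stratum
    M = np.empty((n_strata, X.shape[1]))
    for j in range(X.shape[1]):
        M[:, j] = np.bincount(g, weights=P * X[:, j], minlength=n_strata)
    grad = X[used].sum(axis=0) - M.sum(axis=0)
    A = X.T @ (P[:, None] * X)
    H = -(A - M.T @ M)
    return ll, grad, H


def fit_clogit(stepset: pd.DataFrame, formula=DEFAULT_FORMULA, *,
               max_iter: int = 100, grad_tol: float = 1e-8,
               separation_bound: float = SEPARATION_BOUND,
               standardization: dict | None = None) -> SelectionModel:
    """Fit the conditional logistic regression by Newton ascent.

    Maximises sum over strata of
    ``beta' x_used - log sum_j exp(beta' x_j)`` with step halving;
    ``vcov`` is the inverse observed information at the optimum.
    Strata whose rows are all identical in the design columns are
    dropped (uninformative) and counted; strata containing NaN in any
    design column are likewise dropped (e.g. missing temperature).
    Apparent separation (a coefficient running past
    ``separation_bound`` with a non-vanishing gradient) is flagged and
    the fit returned with ``converged=False``.
    """
    formula = tuple(formula)
    df = stepset.copy()
    missing = [v for v in formula if v not in df.columns]
    if missing:
        raise ValueError(f"stepset lacks design columns: {missing}")

    bad = df[list(formula)].isna().any(axis=1)
    n_dropped_na = 0
    if bad.any():
        bad_strata = set(df.loc[bad, "stratum_id"])
        n_dropped_na = len(bad_strata)
        df = df[~df["stratum_id"].isin(bad_strata)]

    counts = df.groupby("stratum_id")["case"].sum()
    if not (counts == 1).all():
        raise ValueError("every stratum must contain exactly one used step")

    # drop strata with no within-stratum design variation (incl. ties)
    nunique = df.groupby("stratum_id")[list(formula)].nunique()
    degenerate = nunique.max(axis=1) <= 1
    n_dropped_ties = int(degenerate.sum())
    if n_dropped_ties:
        df = df[~df["stratum_id"].isin(degenerate[degenerate].index)]
    if df.empty:
        raise ValueError("no informative strata remain")

    codes, _ = pd.factorize(df["stratum_id"], sort=False)
    X = df[list(formula)].to_numpy(float)
    used = df["case"].to_numpy(bool)
    S = int(codes.max()) + 1

    # identifiability: some stratum must vary in each design column
    col_var = df.groupby("stratum_id")[list(formula)].nunique().max(axis=0)
    if (col_var <= 1).any():
        names = list(col_var[col_var <= 1].index)
        raise ValueError(
            f"not identifiable: covariate(s) {names} constant within "
            "every stratum")

    beta = np.zeros(X.shape[1])
    ll, grad, H = _clogit_loglik(beta, X, codes, used, S)
    converged = False
    flagged_separation = False
    for _ in range(max_iter):
        if np.max(np.abs(grad)) < grad_tol:
            converged = True
            break
        try:
            direction = np.linalg.solve(-H, grad)
        except np.linalg.LinAlgError:
            direction = grad  # fall back to gradient ascent
        step = 1.0
        for _ in range(40):
            cand = beta + step * direction
            ll_new, grad_new, H_new = _clogit_loglik(cand, X, codes, used, S)
            if ll_new > ll - 1e-12:
                break
            step *= 0.5
        beta, ll, grad, H = cand, ll_new, grad_new, H_new
        if np.max(np.abs(beta)) > separation_bound and \
                np.max(np.abs(grad)) > grad_tol:
            flagged_separation = True
            break
    else:
        ll, grad, H = _clogit_loglik(beta, X, codes, used, S)
        converged = bool(np.max(np.abs(grad)) < grad_tol)

    info = -H
    try:
        vcov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        vcov = np.linalg.pinv(info)
    se = np.sqrt(np.clip(np.diag(vcov), 0, None))

    sub = df[df["case"]]
    animal = sub["animal_id"].iloc[0] if "animal_id" in sub and \
        sub["animal_id"].nunique() == 1 else None
    species = sub["species"].iloc[0] if "species" in sub and \
        sub["species"].nunique() == 1 else None

    return SelectionModel(
        coef={v: float(b) for v, b in zip(formula, beta)},
        se={v: float(s) for v, s in zip(formula, se)},
        vcov=vcov,
        loglik=ll,
        n_strata=S,
        converged=converged and not flagged_separation,
        formula=formula,
        standardization=standardization or {},
        diagnostics={
            "separation": flagged_separation,
            "n_strata_dropped_missing": n_dropped_na,
            "n_strata_dropped_degenerate": n_dropped_ties,
            "max_abs_gradient": float(np.max(np.abs(grad))),
        },
        animal_id=animal,
        species=species,
    )


def relative_selection(model: SelectionModel, x1, x2) -> float:
    """Relative selection strength w(x1)/w(x2) = exp(beta'(x1 - x2))."""
    if not model.converged:
        raise ValueError("model did not converge")
    x1 = np.asarray(x1, float)
    x2 = np.asarray(x2, float)
    beta = model.beta
    if x1.shape != beta.shape or x2.shape != beta.shape:
        raise ValueError("covariate vectors must match the model formula")
    return float(np.exp(beta @ (x1 - x2)))
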