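"""Population-level inference from per-individual selection models.

Individual conditional-logit coefficients are pooled to species level by
inverse-variance weighting; swamp selection is re-estimated within
ambient-temperature bins to expose the temperature x swamp interaction;
species differences are tested by weighted-least-squares ANOVA on the
individual coefficients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .issa import SelectionModel, fit_clogit

__all__ = [
    "PooledEstimate",
    "TemperatureBinnedEstimates",
    "SpeciesComparison",
    "TEMPERATURE_BINS",
    "pool_inverse_variance",
    "bin_temperature_estimates",
    "compare_species",
    "fit_population_model",
]

#: ambient-temperature bins (deg C), half-open and left-closed:
#: (-inf, 22), [22, 25), [25, 27), [27, inf)
TEMPERATURE_BINS = ((-np.inf, 22.0), (22.0, 25.0), (25.0, 27.0),
                    (27.0, np.inf))


@dataclass
class PooledEstimate:
    covariate: str
    beta_pooled: float
    se_pooled: float
    n_individuals: int
    method: str = "inverse_variance"

    def confint(self, level: float = 0.95) -> tuple[float, float]:
        z = stats.norm.ppf(0.5 + level / 2)
        return (self.beta_pooled - z * self.se_pooled,
                self.beta_pooled + z * self.se_pooled)


def pool_inverse_variance(fits: list[SelectionModel],
                          covariate: str) -> PooledEstimate:
    """Fixed-effect inverse-variance pooling of one coefficient.

    beta = sum(b_i / se_i^2) / sum(1 / se_i^2);
    se = (sum 1/se_i^2)^(-1/2). Only converged fits containing the
    covariate contribute.
    """
    usable = [f for f in fits if f.converged and covariate in f.coef]
    if len(usable) < 2:
        raise ValueError(
            f"need >= 2 converged fits containing {covariate!r}, "
            f"got {len(usable)}")
    beta = np.array([f.coef[covariate] for f in usable])
    se = np.array([f.se[covariate] for f in usable])
    if np.any(se == 0):
        raise ValueError("zero standard error in an individual fit")
    w = 1.0 / se ** 2
    finite = np.isfinite(w)
    if not finite.any():
        raise ValueError("no fit with finite standard error")
    w = np.where(finite, w, 0.0)
    pooled = float(np.sum(w * beta) / np.sum(w))
    se_pooled = float(1.0 / np.sqrt(np.sum(w)))
    return PooledEstimate(covariate, pooled, se_pooled, int(finite.sum()))


def _bin_index(temp: float, bins=TEMPERATURE_BINS) -> int:
    for i, (lo, hi) in enumerate(bins):
        if lo <= temp < hi:
            return i
    raise ValueError(f"temperature {temp} outside all bins")


@dataclass
class TemperatureBinnedEstimates:
    """Per-bin, per-species pooled swamp selection with 95% CI."""

    bins: tuple = TEMPERATURE_BINS
    estimates: pd.DataFrame = field(default_factory=pd.DataFrame)
    # columns: species, bin, beta, se, lo95, hi95, n_individuals, n_strata


def bin_temperature_estimates(strata: pd.DataFrame,
                              bins=TEMPERATURE_BINS, *,
                              formula=("swamp", "log_sl", "cos_ta"),
                              covariate: str = "swamp",
                              temp_col: str = "temperature_c",
                              min_strata: int = 30,
                              ) -> TemperatureBinnedEstimates:
    """Swamp selection by ambient-temperature bin and species.

    Strata are assigned to bins by their used step's raw temperature
    (deg C, half-open left-closed intervals). Within each bin the
    conditional logit is refit per individual with a reduced formula and
    pooled by inverse variance. Bins with fewer than ``min_strata``
    strata for a species are reported with NaN estimates.
    """
    used = strata[strata["case"]]
    temp_of_stratum = used.set_index("stratum_id")[temp_col]
    bin_of_stratum = temp_of_stratum.dropna().map(
        lambda t: _bin_index(t, bins))
    rows = []
    for species, sp_strata in strata.groupby("species", sort=False):
        for b in range(len(bins)):
            ids = bin_of_stratum[bin_of_stratum == b].index
            sub = sp_strata[sp_strata["stratum_id"].isin(ids)]
            n_str = sub["stratum_id"].nunique()
            row = {"species": species, "bin": b,
                   "bin_lo": bins[b][0], "bin_hi": bins[b][1],
                   "n_strata": n_str}
            fits = []
            if n_str >= min_strata:
                for _, animal_sub in sub.groupby("animal_id", sort=False):
                    if animal_sub["stratum_id"].nunique() < min_strata:
                        continue
                    try:
                        fits.append(fit_clogit(animal_sub, formula))
                    except (ValueError, np.linalg.LinAlgError):
                        continue
            fits = [f for f in fits if f.converged]
            if len(fits) >= 2:
                est = pool_inverse_variance(fits, covariate)
                beta, se, n_ind = (est.beta_pooled, est.se_pooled,
                                   est.n_individuals)
            elif len(fits) == 1:
                beta = fits[0].coef[covariate]
                se = fits[0].se[covariate]
                n_ind = 1
            else:
                beta = se = float("nan")
                n_ind = 0
            row.update({
                "beta": beta, "se": se,
                "lo95": beta - 1.96 * se, "hi95": beta + 1.96 * se,
                "n_individuals": n_ind,
            })
            rows.append(row)
    return TemperatureBinnedEstimates(bins, pd.DataFrame(rows))


@dataclass
class SpeciesComparison:
    covariate: str
    f_stat: float
    df: tuple[int, int]
    p_value: float


def compare_species(fits: list[SelectionModel], covariate: str,
                    species: list[str] | None = None) -> SpeciesComparison:
    """Weighted ANOVA of individual coefficients on species.

    Weighted least squares of beta_i on a species indicator with weights
    1 / se_i^2; F tests the species term with df = (g - 1, n - g).
    """
    usable = [(f, s) for f, s in zip(
        fits, species or [f.species for f in fits])
        if f.converged and covariate in f.coef and s is not None]
    beta = np.array([f.coef[covariate] for f, _ in usable])
    se = np.array([f.se[covariate] for f, _ in usable])
    labels = np.array([s for _, s in usable])
    groups = pd.unique(labels)
    if len(groups) < 2:
        raise ValueError("need >= 2 species")
    if min((labels == g).sum() for g in groups) < 2:
        raise ValueError("need >= 2 individuals per species")
    w = 1.0 / se ** 2
    n, g = len(beta), len(groups)
    # null: weighted grand mean
    mu0 = np.sum(w * beta) / np.sum(w)
    rss0 = np.sum(w * (beta - mu0) ** 2)
    # alternative: weighted group means
    rss1 = 0.0
    for grp in groups:
        m = labels == grp
        mu = np.sum(w[m] * beta[m]) / np.sum(w[m])
        rss1 += np.sum(w[m] * (beta[m] - mu) ** 2)
    df1, df2 = g - 1, n - g
    if rss1 <= 0:
        f_stat = 0.0 if rss0 <= 1e-300 or rss0 == rss1 else np.inf
    else:
        f_stat = ((rss0 - rss1) / df1) / (rss1 / df2)
    f_stat = max(float(f_stat), 0.0)
    p = float(stats.f.sf(f_stat, df1, df2)) if np.isfinite(f_stat) else 0.0
    return SpeciesComparison(covariate, f_stat, (df1, df2), p)


def fit_population_model(stepsets: pd.DataFrame, formula) -> SelectionModel:
    """Population selection model across individuals.

    The random-slopes mixed-model reformulation is not implemented;
    this falls back to two-stage estimation — a conditional logit per
    individual, pooled by inverse variance — and says so with a warning.
    """
    warnings.warn(
        "random-slopes mixed model not implemented; falling back to "
        "two-stage inverse-variance pooling", stacklevel=2)
    if stepsets["animal_id"].nunique() < 3:
        raise ValueError("need >= 3 individuals")
    fits = []
    for _, sub in stepsets.groupby("animal_id", sort=False):
        try:
            fits.append(fit_clogit(sub, formula))
        except (ValueError, np.linalg.LinAlgError):
            continue
    fits = [f for f in fits if f.converged]
    if len(fits) < 2:
        raise ValueError("fewer than 2 converged individual fits")
    coef, se = {}, {}
    for v in formula:
        est = pool_inverse_variance(fits, v)
        coef[v] = est.beta_pooled
        se[v] = est.se_pooled
    vcov = np.diag([se[v] ** 2 for v in formula])
    species = {f.species for f in fits}
    return SelectionModel(
        coef=coef, se=se, vcov=vcov,
        loglik=float("nan"), n_strata=sum(f.n_strata for f in fits),
        converged=True, formula=tuple(formula),
        standardization=fits[0].standardization,
        diagnostics={"method": "two_stage_inverse_variance",
                     "n_individuals": len(fits)},
        species=species.pop() if len(species) == 1 else None,
    )
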