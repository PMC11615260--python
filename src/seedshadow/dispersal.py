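"""Mechanistic seed-shadow simulation.

Combines three ingredients into a spatially explicit model of seed
deposition around a fruiting tree:

1. a redistribution kernel — the tentative movement distributions
   (gamma step length, von Mises turn angle) re-weighted by the
   habitat-selection function w(x) = exp(beta'x), using only
   coefficients that were significant (p < 0.05) plus the fitted
   movement terms;
2. simulated foraging trajectories (default 100 per tree, 50 steps of
   20 min, initial heading uniform) started at the tree crown;
3. a gamma model of gut-passage time converted to a per-step deposition
   probability, so each step endpoint carries the probability that a
   seed ingested at the tree is voided during that step.

Weighted endpoints are smoothed with a truncated Gaussian kernel onto
the 10 m grid; the mean per-pixel deposition probability is the
intensity lambda of the Poisson point process from which seed-fall
locations can be drawn.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .issa import SelectionModel, TentativeKernel
from .landscape import LandscapeStack, RasterGrid

__all__ = [
    "GutPassageModel",
    "RedistributionKernel",
    "Trajectory",
    "SeedShadow",
    "fit_gut_passage",
    "deposition_weights",
    "simulate_trajectory",
    "seed_shadow",
    "sample_seed_points",
    "evaluate_movement_model",
    "weighted_quantile",
    "read_trees",
    "read_gut_passage_csv",
]


def read_trees(path) -> pd.DataFrame:
    """Fruiting-tree crown positions from GeoJSON points or a CSV with
    columns (id, species, x, y); returns (id, species, x, y)."""
    import json as _json

    with open(path) as fh:
        head = fh.read(2048)
    if head.lstrip().startswith("{"):
        with open(path) as fh:
            gj = _json.load(fh)
        rows = []
        for feat in gj.get("features", []):
            geom = feat.get("geometry", {})
            if geom.get("type") != "Point":
                continue
            x, y = geom["coordinates"][:2]
            props = feat.get("properties", {})
            rows.append({"id": props.get("id", len(rows)),
                         "species": props.get("species", "unknown"),
                         "x": float(x), "y": float(y)})
        return pd.DataFrame(rows)
    df = pd.read_csv(path)
    return df[["id", "species", "x", "y"]].copy()


def read_gut_passage_csv(path) -> list[GutPassageModel]:
    """Gut-passage table: one gamma model per
    (hornbill_species, tree_species, mean_min, spread_min) row."""
    df = pd.read_csv(path)
    return [fit_gut_passage(r["mean_min"], r["spread_min"],
                            species=str(r["hornbill_species"]),
                            tree_species=str(r["tree_species"]))
            for _, r in df.iterrows()]

MOVEMENT_TERMS = ("log_sl", "cos_ta")


@dataclass
class GutPassageModel:
    """Gamma gut-passage-time model for one hornbill x tree pair.

    ``mean`` and ``spread`` are the published minutes (mean +/- spread);
    the spread is used as the standard deviation in a method-of-moments
    fit: shape = (mean/spread)^2, scale = spread^2/mean.
    """

    mean: float
    spread: float
    gamma_shape: float
    gamma_scale: float
    species: str = ""
    tree_species: str = ""

    def __post_init__(self) -> None:
        if not (self.mean > 0 and self.spread > 0):
            raise ValueError("mean and spread must be positive")
        if abs(self.gamma_shape * self.gamma_scale - self.mean) > 1e-9 * max(
                1.0, self.mean):
            raise ValueError("gamma moments inconsistent with mean")

    def cdf(self, minutes) -> np.ndarray:
        return stats.gamma.cdf(minutes, a=self.gamma_shape,
                               scale=self.gamma_scale)


def fit_gut_passage(mean: float, spread: float, *, species: str = "",
                    tree_species: str = "") -> GutPassageModel:
    """Method-of-moments gamma fit to a published mean +/- spread (min)."""
    if not (mean > 0 and spread > 0):
        raise ValueError("mean and spread must be positive")
    shape = (mean / spread) ** 2
    scale = spread ** 2 / mean
    return GutPassageModel(mean, spread, shape, scale, species, tree_species)


def deposition_weights(gpm: GutPassageModel, step_minutes: float = 20.0,
                       n_steps: int = 50) -> tuple[np.ndarray, float]:
    """Per-step deposition probabilities from the gut-passage gamma.

    w_k = F(k dt) - F((k-1) dt) for k = 1..n_steps; the returned tail is
    1 - F(n_steps dt), the probability the seed is still carried after
    the simulated foraging bout (reported, never renormalised away).
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    edges = np.arange(n_steps + 1) * step_minutes
    cdf = gpm.cdf(edges)
    weights = np.diff(cdf)
    tail = float(1.0 - cdf[-1])
    return weights, tail


@dataclass
class RedistributionKernel:
    """Selection-informed movement kernel over a landscape stack.

    ``beta`` holds the habitat coefficients to score candidates with
    (typically the significant subset of a population model) plus the
    fitted movement terms; ``standardization`` maps covariate name to
    the (mean, sd) used in fitting so simulated locations are scored on
    the training scale.
    """

    tentative: TentativeKernel
    beta: dict[str, float]
    stack: LandscapeStack
    standardization: dict[str, tuple[float, float]] = field(
        default_factory=dict)
    n_candidates: int = 100

    def __post_init__(self) -> None:
        known = set(LandscapeStack.LAYERS) | set(MOVEMENT_TERMS)
        unknown = set(self.beta) - known
        if unknown:
            raise ValueError(
                f"kernel coefficients {sorted(unknown)} match neither a "
                "stack layer nor a movement term")
        if self.n_candidates < 1:
            raise ValueError("n_candidates must be >= 1")

    @classmethod
    def from_model(cls, model: SelectionModel, tentative: TentativeKernel,
                   stack: LandscapeStack, *, alpha: float = 0.05,
                   standardization: dict | None = None,
                   n_candidates: int = 100) -> "RedistributionKernel":
        """Kernel from a fitted model: habitat terms filtered at
        ``alpha``; movement terms carried over as fitted; any
        time-varying interaction term dropped (the kernel is
        time-agnostic)."""
        p = model.pvalues()
        beta = {}
        for v in model.formula:
            if v in MOVEMENT_TERMS:
                beta[v] = model.coef[v]
            elif v in LandscapeStack.LAYERS and p.get(v, 1.0) < alpha:
                beta[v] = model.coef[v]
        std = standardization
        if std is None:
            std = {v: tuple(ms) for v, ms in
                   _flatten_standardization(model.standardization).items()}
        return cls(tentative, beta, stack, std, n_candidates)

    def standardize(self, var: str, values):
        mean, sd = self.standardization.get(var, (0.0, 1.0))
        return (np.asarray(values, float) - mean) / sd

    def score(self, covs: dict[str, np.ndarray], sl: np.ndarray,
              ta: np.ndarray, extra: np.ndarray | None = None) -> np.ndarray:
        """Unnormalised selection weights w(x) for candidate steps.

        Candidates with any non-finite covariate (off-raster / nodata)
        get weight 0.
        """
        n = len(sl)
        eta = np.zeros(n)
        valid = np.ones(n, dtype=bool)
        for var, b in self.beta.items():
            if var == "log_sl":
                eta += b * np.log(sl + 1.0)
            elif var == "cos_ta":
                eta += b * np.cos(ta)
            else:
                vals = covs[var]
                valid &= np.isfinite(vals)
                eta += b * np.nan_to_num(self.standardize(var, vals))
        for var, vals in covs.items():
            if np.isnan(vals).all():
                continue  # layer unavailable (e.g. no vertical profiles)
            valid &= np.isfinite(vals)
        if extra is not None:
            eta += extra
        eta -= eta.max() if np.isfinite(eta).any() else 0.0
        w = np.exp(eta)
        w[~valid] = 0.0
        return w


def _flatten_standardization(std: dict) -> dict:
    """Model JSONs store standardization either flat (var -> (mean, sd))
    or nested per animal; for a single animal the nesting is removed."""
    if not std:
        return {}
    first = next(iter(std.values()))
    if isinstance(first, dict):  # animal -> var -> (mean, sd)
        if len(std) == 1:
            return {v: tuple(ms) for v, ms in first.items()}
        # average across animals
        out: dict[str, tuple[float, float]] = {}
        vars_ = set().union(*(set(v) for v in std.values()))
        for var in vars_:
            pairs = [vs[var] for vs in std.values() if var in vs]
            out[var] = (float(np.mean([p[0] for p in pairs])),
                        float(np.mean([p[1] for p in pairs])))
        return out
    return {v: tuple(ms) for v, ms in std.items()}


@dataclass
class Trajectory:
    """One simulated foraging path: n_steps + 1 positions."""

    positions: np.ndarray  # (n_steps + 1, 2)
    step_lengths: np.ndarray
    turn_angles: np.ndarray
    step_minutes: float
    rng_seed: int | None = None
    stuck: bool = False

    @property
    def n_steps(self) -> int:
        return len(self.positions) - 1

    def endpoints(self) -> np.ndarray:
        return self.positions[1:]


def simulate_trajectory(kernel: RedistributionKernel,
                        start: tuple[float, float], n_steps: int = 50,
                        rng_seed: int | np.random.Generator = 0, *,
                        step_minutes: float = 20.0,
                        initial_heading: float | None = None,
                        extra_linear=None,
                        max_retries: int = 10) -> Trajectory:
    """Simulate one selection-informed trajectory from ``start``.

    At each step ``n_candidates`` proposals are drawn from the tentative
    distributions and one is kept with probability proportional to
    w(x) = exp(beta'x) (movement terms included). Proposals off-raster
    or on nodata get weight 0; if every candidate is invalid the draw is
    repeated up to ``max_retries`` times, after which the trajectory is
    flagged stuck and truncated at its current position.

    ``extra_linear``, if given, is called as
    ``extra_linear(step_index, covariate_arrays)`` and must return an
    additive term on the linear-predictor scale (used by the synthetic
    track generator for time-varying effects).
    """
    grid = kernel.stack.grid
    if not grid.contains(*start):
        raise ValueError("start position off-raster")
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    seed_val = None if isinstance(rng_seed, np.random.Generator) else rng_seed
    t = kernel.tentative
    heading = (float(rng.uniform(-np.pi, np.pi))
               if initial_heading is None else float(initial_heading))
    pos = np.array(start, dtype=float)
    positions = [pos.copy()]
    sls: list[float] = []
    tas: list[float] = []
    stuck = False
    for k in range(n_steps):
        chosen = None
        for _ in range(max_retries):
            sl = rng.gamma(t.sl_shape, 1.0 / t.sl_rate,
                           size=kernel.n_candidates)
            ta = rng.vonmises(t.ta_mu, t.ta_kappa, size=kernel.n_candidates)
            hdg = heading + ta
            xs = pos[0] + sl * np.cos(hdg)
            ys = pos[1] + sl * np.sin(hdg)
            covs = kernel.stack.covariates_at_many(xs, ys)
            extra = extra_linear(k, covs) if extra_linear is not None else None
            w = kernel.score(covs, sl, ta, extra)
            total = w.sum()
            if total > 0:
                i = rng.choice(kernel.n_candidates, p=w / total)
                chosen = (xs[i], ys[i], sl[i], ta[i], hdg[i])
                break
        if chosen is None:
            stuck = True
            break
        x, y, sl_i, ta_i, hdg_i = chosen
        pos = np.array([x, y])
        positions.append(pos.copy())
        sls.append(float(sl_i))
        tas.append(float(ta_i))
        heading = float(hdg_i)
    return Trajectory(np.array(positions), np.array(sls), np.array(tas),
                      step_minutes, rng_seed=seed_val, stuck=stuck)


@dataclass
class SeedShadow:
    """Deposition-probability raster with its point-process intensity."""

    deposition: RasterGrid
    lam: float
    source: tuple[float, float]
    n_trajectories: int
    distance_summary: dict[str, float]
    tail_mass: float = 0.0
    truncated_mass: float = 0.0

    @property
    def total_mass(self) -> float:
        return float(np.nansum(self.deposition.values))


def weighted_quantile(values, weights, q) -> np.ndarray:
    """Quantiles of a weighted sample (interpolation on the weighted CDF)."""
    values = np.asarray(values, float)
    weights = np.asarray(weights, float)
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cw = np.cumsum(w)
    if cw[-1] <= 0:
        return np.full(np.shape(q), np.nan)
    cdf = (cw - 0.5 * w) / cw[-1]
    return np.interp(q, cdf, v)


def _gaussian_deposit(points: np.ndarray, masses: np.ndarray,
                      grid: RasterGrid, bandwidth: float) -> np.ndarray:
    """Bin point masses to cells, then smooth with a Gaussian kernel
    truncated at 4 sigma. The discrete kernel is normalised, so mass is
    conserved wherever the 4-sigma support stays on the raster."""
    nr, nc = grid.shape
    x0, y0 = grid.origin
    col = np.floor((points[:, 0] - x0) / grid.cell_size).astype(int)
    row = np.floor((y0 - points[:, 1]) / grid.cell_size).astype(int)
    ok = (row >= 0) & (row < nr) & (col >= 0) & (col < nc)
    binned = np.zeros((nr, nc))
    np.add.at(binned, (row[ok], col[ok]), masses[ok])
    lost = float(masses[~ok].sum())
    sigma_cells = bandwidth / grid.cell_size
    smoothed = ndimage.gaussian_filter(binned, sigma=sigma_cells,
                                       mode="constant", truncate=4.0)
    return smoothed, lost


def seed_shadow(trajectories: list[Trajectory], weights: np.ndarray, *,
                bandwidth: float = 30.0,
                grid: RasterGrid | None = None,
                cell_size: float = 10.0,
                tail_mass: float = 0.0) -> SeedShadow:
    """Rasterised seed-deposition probability from weighted trajectories.

    Step endpoint k of each trajectory carries mass
    ``weights[k-1] / n_trajectories``. With no explicit ``grid`` the
    extent is the bounding box of all endpoints padded by 4 sigma.
    lambda is total deposited mass / number of pixels. The distance
    summary gives the deposition-weighted median and the maximum
    endpoint distance from the source.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    if not trajectories:
        raise ValueError("no trajectories")
    weights = np.asarray(weights, float)
    source = tuple(trajectories[0].positions[0])
    for tr in trajectories:
        if not np.allclose(tr.positions[0], source):
            raise ValueError("all trajectories must share the source")

    pts, mass = [], []
    n_traj = len(trajectories)
    for tr in trajectories:
        ends = tr.endpoints()
        k = len(ends)
        if k > len(weights):
            raise ValueError("trajectory longer than the weight vector")
        pts.append(ends)
        mass.append(weights[:k] / n_traj)
    points = np.vstack(pts) if pts else np.empty((0, 2))
    masses = np.concatenate(mass) if mass else np.empty(0)

    if grid is None:
        # pad beyond the truncated kernel support so no mass leaves
        pad = 4.0 * bandwidth + 3.0 * cell_size
        xmin = min(points[:, 0].min(), source[0]) - pad
        xmax = max(points[:, 0].max(), source[0]) + pad
        ymin = min(points[:, 1].min(), source[1]) - pad
        ymax = max(points[:, 1].max(), source[1]) + pad
        nc = max(int(np.ceil((xmax - xmin) / cell_size)), 1)
        nr = max(int(np.ceil((ymax - ymin) / cell_size)), 1)
        grid = RasterGrid(np.zeros((nr, nc)), cell_size, (xmin, ymax))

    smoothed, lost = _gaussian_deposit(points, masses, grid, bandwidth)
    total = float(smoothed.sum())
    lam = total / smoothed.size
    dist = np.hypot(points[:, 0] - source[0], points[:, 1] - source[1])
    if masses.sum() > 0:
        median = float(weighted_quantile(dist, masses, 0.5))
        dmax = float(dist[masses > 0].max())
    else:
        median = dmax = float("nan")
    dep = RasterGrid(smoothed, grid.cell_size, grid.origin, grid.crs_id)
    return SeedShadow(dep, lam, source, n_traj,
                      {"median_m": median, "max_m": dmax},
                      tail_mass=tail_mass, truncated_mass=lost)


def sample_seed_points(shadow: SeedShadow, total_seeds: float,
                       rng_seed: int = 0) -> np.ndarray:
    """Seed-fall locations from the deposition surface.

    Per-pixel counts are Poisson(deposition x total_seeds); each seed is
    placed uniformly within its pixel. Returns an (n, 2) array.
    """
    if not total_seeds > 0:
        raise ValueError("total_seeds must be > 0")
    rng = np.random.default_rng(rng_seed)
    dep = shadow.deposition
    lam = np.clip(dep.values * total_seeds, 0, None)
    counts = rng.poisson(lam)
    rows, cols = np.nonzero(counts)
    reps = counts[rows, cols]
    rows = np.repeat(rows, reps)
    cols = np.repeat(cols, reps)
    if len(rows) == 0:
        return np.empty((0, 2))
    x0, y0 = dep.origin
    s = dep.cell_size
    x = x0 + (cols + rng.uniform(0, 1, size=len(cols))) * s
    y = y0 - (rows + rng.uniform(0, 1, size=len(rows))) * s
    return np.column_stack([x, y])


def evaluate_movement_model(used: pd.DataFrame, available: pd.DataFrame,
                            simulated: pd.DataFrame,
                            covariates: list[str], *, n_bins: int = 20
                            ) -> dict[str, dict]:
    """Covariate-distribution check of the movement model.

    For each covariate, compares the values at used, available and
    simulated step endpoints: shared-bin histograms (densities), a
    quantile table, and the total-variation divergence between the used
    and simulated histograms (0 = identical). A fitted kernel should
    bring the simulated distribution closer to the used one than a
    selection-free kernel does.
    """
    for name, df in (("used", used), ("available", available),
                     ("simulated", simulated)):
        if len(df) == 0:
            raise ValueError(f"{name} step set is empty")
    qs = np.linspace(0.05, 0.95, 19)
    out: dict[str, dict] = {}
    for var in covariates:
        vals = {
            "used": used[var].dropna().to_numpy(float),
            "available": available[var].dropna().to_numpy(float),
            "simulated": simulated[var].dropna().to_numpy(float),
        }
        allv = np.concatenate(list(vals.values()))
        lo, hi = float(allv.min()), float(allv.max())
        if hi <= lo:
            hi = lo + 1.0
        edges = np.linspace(lo, hi, n_bins + 1)
        hists = {k: np.histogram(v, bins=edges, density=False)[0] / len(v)
                 for k, v in vals.items()}
        tv = 0.5 * float(np.abs(hists["used"] - hists["simulated"]).sum())
        out[var] = {
            "bin_edges": edges,
            "density": hists,
            "quantiles": pd.DataFrame(
                {k: np.quantile(v, qs) for k, v in vals.items()}, index=qs),
            "tv_used_vs_simulated": tv,
        }
    return out
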