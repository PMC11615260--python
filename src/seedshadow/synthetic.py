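"""Synthetic inputs with known ground truth.

Generates everything the pipeline consumes — spatially autocorrelated
canopy and complexity fields with carved gap patches and swamp blobs,
diel temperature cycles, GPS tracks simulated from the selection
function with known coefficients, and accelerometer bursts with known
expected activity — so parameter recovery can be tested end to end.

Movement decisions are simulated at the 30-min analysis scale (one
selection event per decision) and emitted as 5-min fixes on the tags'
daytime schedule (05:45-18:30) by linear interpolation, so the
resampling stage is exercised while the decision-scale selection
coefficients remain the estimand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .dispersal import RedistributionKernel, simulate_trajectory
from .issa import TentativeKernel
from .landscape import (GAP_HEIGHT_M, LandscapeStack, RasterGrid,
                        detect_gaps, distance_to_gaps)

__all__ = [
    "SyntheticLandscapeConfig",
    "SyntheticTrackConfig",
    "gen_landscape",
    "gen_temperature",
    "gen_tracks",
    "gen_bursts",
]


@dataclass
class SyntheticLandscapeConfig:
    """Landscape generator settings (defaults: 3 x 3 km at 10 m)."""

    shape: tuple[int, int] = (300, 300)
    cell_size: float = 10.0
    autocorr_range_m: float = 50.0
    canopy_mean: float = 25.0
    canopy_sd: float = 8.0
    canopy_floor: float = 8.0  # keeps random field clear of the gap cut
    gap_height: float = 0.5  # canopy height inside carved gaps
    small_gap_areas_m2: tuple = (100.0,) * 8
    large_gap_areas_m2: tuple = (600.0, 800.0, 1200.0)
    swamp_blobs: int = 3
    swamp_radius_m: float = 150.0
    vci_canopy_corr: float = 0.3
    seed: int = 0


def _gaussian_field(shape, range_cells, rng) -> np.ndarray:
    """Unit-variance Gaussian random field by smoothing white noise."""
    z = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(z, sigma=range_cells, mode="wrap")
    return (f - f.mean()) / f.std()


def _carve_blob(mask_free: np.ndarray, n_cells: int, rng,
                margin: int = 3) -> np.ndarray | None:
    """Grow a 4-connected blob of n_cells on free ground; returns cell
    indices or None if placement failed."""
    nr, nc = mask_free.shape
    for _ in range(200):
        r0 = rng.integers(margin, nr - margin)
        c0 = rng.integers(margin, nc - margin)
        if not mask_free[r0, c0]:
            continue
        cells = [(r0, c0)]
        taken = {(r0, c0)}
        frontier = [(r0, c0)]
        ok = True
        while len(cells) < n_cells:
            if not frontier:
                ok = False
                break
            r, c = frontier[rng.integers(len(frontier))]
            nbrs = [(r + dr, c + dc)
                    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1))
                    if (r + dr, c + dc) not in taken
                    and margin <= r + dr < nr - margin
                    and margin <= c + dc < nc - margin
                    and mask_free[r + dr, c + dc]]
            if not nbrs:
                frontier.remove((r, c))
                continue
            cell = nbrs[rng.integers(len(nbrs))]
            taken.add(cell)
            cells.append(cell)
            frontier.append(cell)
        if ok:
            return np.array(cells)
    return None


def gen_landscape(config: SyntheticLandscapeConfig | None = None,
                  ) -> tuple[LandscapeStack, dict]:
    """Generate a landscape stack plus the ground truth used to build it.

    Canopy height is a clipped Gaussian random field; gap patches of the
    requested areas are carved below the gap height threshold with
    buffered separation so each requested patch maps to exactly one
    detected region; swamp blobs are disks; the VCI field is built with
    a fixed correlation (default 0.3, below the collinearity screen)
    with canopy height.
    """
    cfg = config or SyntheticLandscapeConfig()
    rng = np.random.default_rng(cfg.seed)
    nr, nc = cfg.shape
    range_cells = cfg.autocorr_range_m / cfg.cell_size
    z_h = _gaussian_field(cfg.shape, range_cells, rng)
    canopy = np.clip(cfg.canopy_mean + cfg.canopy_sd * z_h,
                     cfg.canopy_floor, 60.0)

    cell_area = cfg.cell_size ** 2
    all_areas = [(a, "small") for a in cfg.small_gap_areas_m2] + \
                [(a, "large") for a in cfg.large_gap_areas_m2]
    free = np.ones(cfg.shape, dtype=bool)
    patches = []
    for area, klass in all_areas:
        n_cells = max(int(round(area / cell_area)), 1)
        if n_cells > nr * nc:
            raise ValueError("gap patch exceeds the grid")
        cells = _carve_blob(free, n_cells, rng)
        if cells is None:
            raise ValueError("could not place a gap patch; grid too full")
        canopy[cells[:, 0], cells[:, 1]] = cfg.gap_height
        # buffer so separate patches never merge under 4-connectivity
        blocked = np.zeros(cfg.shape, dtype=bool)
        blocked[cells[:, 0], cells[:, 1]] = True
        blocked = ndimage.binary_dilation(blocked, iterations=3)
        free &= ~blocked
        patches.append({"cells": cells, "area_m2": n_cells * cell_area,
                        "requested_m2": area, "class": klass})

    swamp = np.zeros(cfg.shape)
    rr, cc = np.mgrid[0:nr, 0:nc]
    swamp_centres = []
    for _ in range(cfg.swamp_blobs):
        r0 = rng.integers(0, nr)
        c0 = rng.integers(0, nc)
        rad = cfg.swamp_radius_m / cfg.cell_size
        swamp[(rr - r0) ** 2 + (cc - c0) ** 2 <= rad ** 2] = 1.0
        swamp_centres.append((int(r0), int(c0)))

    z_i = _gaussian_field(cfg.shape, range_cells, rng)
    rho = cfg.vci_canopy_corr
    z_v = rho * z_h + np.sqrt(1 - rho ** 2) * z_i
    vci = stats.norm.cdf(z_v)

    origin = (0.0, nr * cfg.cell_size)
    chm = RasterGrid(canopy, cfg.cell_size, origin)
    gaps_small = detect_gaps(chm, GAP_HEIGHT_M, 50.0)
    gaps_large = detect_gaps(chm, GAP_HEIGHT_M, 500.0)
    stack = LandscapeStack(
        canopy_height=chm,
        vci=RasterGrid(vci, cfg.cell_size, origin),
        dist_gap_small=distance_to_gaps(gaps_small, chm),
        dist_gap_large=distance_to_gaps(gaps_large, chm),
        swamp=RasterGrid(swamp, cfg.cell_size, origin),
        provenance={"generator": "synthetic", "seed": cfg.seed},
    )
    truth = {"patches": patches, "swamp_centres": swamp_centres,
             "gaps_small": gaps_small, "gaps_large": gaps_large,
             "config": cfg}
    return stack, truth


def gen_temperature(n_days: int = 30, interval_min: float = 30.0, *,
                    mean: float = 23.0, amplitude: float = 5.0,
                    noise_sd: float = 0.5,
                    start: str = "2023-06-01",
                    seed: int = 0) -> pd.DataFrame:
    """Diel temperature cycle: sinusoid peaking at 14:00 plus noise.

    Defaults span roughly 20-28 deg C across the tags' daytime window so
    every analysis temperature bin is populated.
    """
    rng = np.random.default_rng(seed)
    t0 = pd.Timestamp(start)
    stamps = pd.date_range(t0, t0 + pd.Timedelta(days=n_days),
                           freq=pd.Timedelta(minutes=interval_min),
                           inclusive="left")
    hours = stamps.hour + stamps.minute / 60.0
    temp = mean + amplitude * np.cos(2 * np.pi * (hours - 14.0) / 24.0)
    temp = temp + rng.normal(0, noise_sd, size=len(stamps))
    return pd.DataFrame({"timestamp": stamps, "temp_c": temp})


@dataclass
class SyntheticTrackConfig:
    """Track generator settings.

    ``true_beta`` are the selection coefficients on standardised
    covariates (standardisation over valid stack cells); the tentative
    kernel defaults give a mean step of ~200 m per 30-min decision,
    comparable to a foraging hornbill's displacement scale.
    """

    true_beta: dict = field(
        default_factory=lambda: {"canopy_height": 0.3})
    n_animals: int = 5
    n_steps: int = 600  # decision steps per animal
    tentative: TentativeKernel = field(
        default_factory=lambda: TentativeKernel(2.0, 0.01, 0.0, 0.5))
    fix_interval_min: float = 5.0
    decision_interval_min: float = 30.0
    interaction_slope: float = 0.0  # temperature x swamp, per sd of temp
    n_candidates: int = 50
    species_of: dict | None = None  # animal_id -> species
    start_date: str = "2023-06-01"
    seed: int = 0


def _stack_standardization(stack: LandscapeStack) -> dict:
    """Mean/sd of each continuous layer over valid cells (swamp excluded)."""
    out = {}
    for name in ("canopy_height", "vci", "dist_gap_small", "dist_gap_large"):
        vals = stack.layer(name).values
        vals = vals[np.isfinite(vals)]
        out[name] = (float(vals.mean()), float(vals.std(ddof=1)))
    return out


def gen_tracks(config: SyntheticTrackConfig, stack: LandscapeStack,
               temperature: pd.DataFrame | None = None
               ) -> tuple[pd.DataFrame, dict]:
    """Simulate GPS fixes from the selection process with known truth.

    Each animal makes one selection decision per 30 min during the tag's
    daytime window: candidate steps from the tentative kernel are scored
    by exp(beta'x) on stack-standardised covariates (plus the optional
    temperature x swamp interaction) and one is kept. Decision positions
    are emitted as 5-min fixes by linear interpolation.

    Returns the fixes and a truth dict with the generating coefficients,
    the standardisation used (pass to ``standardize_covariates`` via
    ``fixed_params`` when refitting), the tentative kernel and the
    temperature series.
    """
    rng = np.random.default_rng(config.seed)
    std = _stack_standardization(stack)
    habitat_beta = {k: v for k, v in config.true_beta.items()}
    kernel = RedistributionKernel(config.tentative, habitat_beta, stack,
                                  standardization=std,
                                  n_candidates=config.n_candidates)

    dec_per_day = int(((18.5 - 5.75) * 60) // config.decision_interval_min)
    n_days = int(np.ceil(config.n_steps / dec_per_day))
    if temperature is None:
        temperature = gen_temperature(
            n_days + 1, start=config.start_date,
            seed=int(rng.integers(2 ** 31)))
    temp_mean = float(temperature["temp_c"].mean())
    temp_sd = float(temperature["temp_c"].std(ddof=1))
    std_full = dict(std)
    std_full["temperature"] = (temp_mean, temp_sd)
    t_stamps = temperature["timestamp"].to_numpy()
    t_vals = temperature["temp_c"].to_numpy()

    def temp_at(ts: np.datetime64) -> float:
        i = np.searchsorted(t_stamps, ts)
        i = min(max(i, 0), len(t_stamps) - 1)
        return float(t_vals[i])

    grid = stack.grid
    nr, nc = grid.shape
    x0, y0 = grid.origin
    day0 = pd.Timestamp(config.start_date)
    sub_per_dec = int(round(config.decision_interval_min
                            / config.fix_interval_min))

    frames = []
    for a in range(config.n_animals):
        animal = f"synth{a:02d}"
        species = (config.species_of or {}).get(
            animal, "BCH" if a % 2 == 0 else "WTH")
        # start inside the middle third of the raster
        pos = (x0 + (nc * (1 / 3 + rng.uniform(0, 1 / 3))) * grid.cell_size,
               y0 - (nr * (1 / 3 + rng.uniform(0, 1 / 3))) * grid.cell_size)
        steps_left = config.n_steps
        day = 0
        max_days = 3 * n_days + 3  # guard against a repeatedly stuck walker
        rows_x, rows_y, rows_t = [], [], []
        while steps_left > 0 and day < max_days:
            n_dec = min(dec_per_day, steps_left)
            t_day0 = (day0 + pd.Timedelta(days=day)
                      + pd.Timedelta(hours=5, minutes=45))
            dec_times = np.array(
                [np.datetime64(t_day0 + pd.Timedelta(
                    minutes=config.decision_interval_min * k))
                 for k in range(n_dec + 1)])

            if config.interaction_slope != 0.0:
                slope = config.interaction_slope

                def extra(k, covs, _times=dec_times):
                    zt = (temp_at(_times[k + 1]) - temp_mean) / temp_sd
                    return slope * zt * np.nan_to_num(covs["swamp"])
            else:
                extra = None

            traj = simulate_trajectory(
                kernel, pos, n_steps=n_dec,
                rng_seed=rng, step_minutes=config.decision_interval_min,
                extra_linear=extra)
            dec_pos = traj.positions
            # interpolate 5-min fixes along each decision step
            for k in range(len(dec_pos) - 1):
                p0, p1 = dec_pos[k], dec_pos[k + 1]
                for s in range(sub_per_dec):
                    frac = s / sub_per_dec
                    rows_x.append(p0[0] + frac * (p1[0] - p0[0]))
                    rows_y.append(p0[1] + frac * (p1[1] - p0[1]))
                    rows_t.append(dec_times[k] + np.timedelta64(
                        int(config.fix_interval_min * s * 60), "s"))
            rows_x.append(dec_pos[-1][0])
            rows_y.append(dec_pos[-1][1])
            rows_t.append(dec_times[len(dec_pos) - 1])
            pos = tuple(dec_pos[-1])
            steps_left -= len(dec_pos) - 1
            day += 1
            if traj.stuck and len(dec_pos) < 2:
                break
        frames.append(pd.DataFrame({
            "animal_id": animal,
            "timestamp": pd.to_datetime(rows_t),
            "x": rows_x, "y": rows_y, "species": species,
        }))
    fixes = pd.concat(frames, ignore_index=True)
    truth = {
        "true_beta": dict(config.true_beta),
        "interaction_slope": config.interaction_slope,
        "standardization": std_full,
        "tentative": config.tentative,
        "temperature": temperature,
        "config": config,
    }
    return fixes, truth


def gen_strata(n_strata: int, beta: dict, k_controls: int,
               tentative: TentativeKernel, stack: LandscapeStack,
               standardization: dict, seed: int = 0, *,
               n_candidates: int = 100, margin_cells: int = 30
               ) -> pd.DataFrame:
    """Simulate conditional-logit strata directly from the selection process.

    Each stratum starts at an independent uniform interior cell with a
    uniform previous heading; the used step is chosen among
    ``n_candidates`` tentative proposals with probability proportional
    to w(x) = exp(beta'x), and K fresh tentative draws become the
    control steps. This is the step-scale data-generating process of the
    selection model without trajectory autocorrelation, cheap enough for
    replicated recovery and coverage experiments.
    """
    rng = np.random.default_rng(seed)
    kernel = RedistributionKernel(tentative, dict(beta), stack,
                                  standardization=standardization,
                                  n_candidates=n_candidates)
    grid = stack.grid
    nr, nc = grid.shape
    x0, y0 = grid.origin
    s = grid.cell_size
    rows = []
    made = 0
    attempts = 0
    while made < n_strata and attempts < 20 * n_strata:
        attempts += 1
        xs = x0 + rng.uniform(margin_cells, nc - margin_cells) * s
        ys = y0 - rng.uniform(margin_cells, nr - margin_cells) * s
        heading0 = rng.uniform(-np.pi, np.pi)
        sl = rng.gamma(tentative.sl_shape, 1.0 / tentative.sl_rate,
                       size=n_candidates)
        ta = rng.vonmises(tentative.ta_mu, tentative.ta_kappa,
                          size=n_candidates)
        hx = xs + sl * np.cos(heading0 + ta)
        hy = ys + sl * np.sin(heading0 + ta)
        covs = stack.covariates_at_many(hx, hy)
        w = kernel.score(covs, sl, ta)
        if w.sum() <= 0:
            continue
        i = rng.choice(n_candidates, p=w / w.sum())
        sl_ctl = rng.gamma(tentative.sl_shape, 1.0 / tentative.sl_rate,
                           size=k_controls)
        ta_ctl = rng.vonmises(tentative.ta_mu, tentative.ta_kappa,
                              size=k_controls)
        ex = np.concatenate([[hx[i]], xs + sl_ctl * np.cos(heading0 + ta_ctl)])
        ey = np.concatenate([[hy[i]], ys + sl_ctl * np.sin(heading0 + ta_ctl)])
        esl = np.concatenate([[sl[i]], sl_ctl])
        eta_ = np.concatenate([[ta[i]], ta_ctl])
        cc = stack.covariates_at_many(ex, ey)
        if not all(np.isfinite(v).all() or np.isnan(v).all()
                   for v in cc.values()):
            continue
        for j in range(k_controls + 1):
            row = {"animal_id": "synth00", "species": "BCH",
                   "stratum_id": f"s{made}", "case": j == 0,
                   "x_start": xs, "y_start": ys,
                   "x_end": ex[j], "y_end": ey[j],
                   "sl": esl[j], "ta": eta_[j]}
            for name, vals in cc.items():
                mean, sd = standardization.get(name, (0.0, 1.0))
                row[name] = (vals[j] - mean) / sd
            rows.append(row)
        made += 1
    out = pd.DataFrame(rows)
    out["log_sl"] = np.log(out["sl"] + 1.0)
    out["cos_ta"] = np.cos(out["ta"])
    return out


def gen_bursts(n: int, odba_levels, rng_seed: int = 0, *,
               n_samples: int = 20,
               animal_ids: tuple[str, ...] = ("synth00",),
               start: str = "2023-06-01") -> tuple[list, np.ndarray]:
    """Tri-axial bursts whose expected ODBA equals the requested level.

    ``odba_levels`` is a scalar or sequence cycled over bursts (g).
    Each axis gets a random constant gravity offset plus Gaussian
    dynamic noise scaled so that the mean absolute deviation from the
    burst mean sums to the level across the three axes.
    """
    from .odba import AccBurst

    rng = np.random.default_rng(rng_seed)
    levels = np.resize(np.asarray(odba_levels, dtype=float), n)
    if np.any(levels < 0):
        raise ValueError("odba levels must be >= 0")
    # E|X - Xbar| = sigma sqrt((n-1)/n) sqrt(2/pi) for iid normal noise
    corr = np.sqrt((n_samples - 1) / n_samples) * np.sqrt(2 / np.pi)
    t0 = pd.Timestamp(start)
    bursts = []
    for i in range(n):
        sigma_axis = (levels[i] / 3.0) / corr
        gravity = rng.normal(0, 1, size=3)
        gravity = gravity / np.linalg.norm(gravity)  # |g| = 1
        samples = (gravity[:, None]
                   + rng.normal(0, sigma_axis, size=(3, n_samples)))
        bursts.append(AccBurst(
            animal_ids[i % len(animal_ids)],
            t0 + pd.Timedelta(minutes=10 * i), samples))
    return bursts, levels
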