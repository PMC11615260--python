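"""GPS track preparation for step-selection analysis.

Takes raw fixes (Movebank-style CSV), filters animals by in-area fix
count, regularises each track to the analysis fix rate (30 min), builds
steps and matched strata (1 used + K control steps), attaches weather-
station temperature, and standardises covariates per animal.

All tabular state is plain pandas DataFrames:

fixes
    columns ``animal_id, timestamp, x, y, species`` (+ optional
    ``burst`` after resampling); timestamps are tz-naive UTC.
steps / strata ("StepSet")
    one row per step; strata carry ``stratum_id`` and ``case``
    (True = used, False = control) plus covariate columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Point
from shapely.geometry.base import BaseGeometry

__all__ = [
    "read_movebank_csv",
    "read_temperature_csv",
    "filter_eligible",
    "resample_track",
    "steps_from_fixes",
    "build_strata",
    "attach_temperature",
    "standardize_covariates",
    "Standardization",
    "HABITAT_COVARIATES",
    "SCALED_COVARIATES",
    "DAY_START",
    "DAY_END",
]

#: covariates sampled from the landscape stack at step endpoints
HABITAT_COVARIATES = ("canopy_height", "vci", "dist_gap_small",
                      "dist_gap_large", "swamp")
#: covariates that are centred and scaled (binary swamp is not)
SCALED_COVARIATES = ("canopy_height", "vci", "dist_gap_small",
                     "dist_gap_large", "temperature")

#: tags record fixes only between these local times (GPS off overnight)
DAY_START = pd.Timedelta(hours=5, minutes=45)
DAY_END = pd.Timedelta(hours=18, minutes=30)

_EARTH_RADIUS_M = 6_371_000.0


def _lonlat_to_local_metres(lon, lat, lon0: float, lat0: float):
    """Equirectangular projection about (lon0, lat0).

    Adequate for study areas a few tens of km across near the equator;
    for anything larger supply projected coordinates directly.
    """
    x = np.radians(np.asarray(lon) - lon0) * _EARTH_RADIUS_M * np.cos(
        np.radians(lat0))
    y = np.radians(np.asarray(lat) - lat0) * _EARTH_RADIUS_M
    return x, y


def read_movebank_csv(path, *, column_map: dict[str, str] | None = None,
                      species_map: dict[str, str] | None = None,
                      origin_lonlat: tuple[float, float] | None = None,
                      ) -> pd.DataFrame:
    """Read a Movebank-style CSV of GPS fixes.

    Default column mapping follows Movebank export names
    (``individual-local-identifier``, ``timestamp``, ``location-long``,
    ``location-lat``). If the file carries projected ``x``/``y`` columns
    they are used as-is; otherwise lon/lat are projected to local metres
    about ``origin_lonlat`` (default: the mean fix position).

    Duplicate (animal, timestamp) rows are dropped, keeping the first;
    output is sorted by animal then time.
    """
    cmap = {
        "animal_id": "individual-local-identifier",
        "timestamp": "timestamp",
        "lon": "location-long",
        "lat": "location-lat",
        "x": "x",
        "y": "y",
        "species": "species",
    }
    if column_map:
        cmap.update(column_map)
    raw = pd.read_csv(path)
    df = pd.DataFrame()
    df["animal_id"] = raw[cmap["animal_id"]].astype(str)
    df["timestamp"] = pd.to_datetime(raw[cmap["timestamp"]])
    if cmap["x"] in raw.columns and cmap["y"] in raw.columns:
        df["x"] = raw[cmap["x"]].astype(float)
        df["y"] = raw[cmap["y"]].astype(float)
    else:
        lon = raw[cmap["lon"]].astype(float)
        lat = raw[cmap["lat"]].astype(float)
        if origin_lonlat is None:
            origin_lonlat = (float(lon.mean()), float(lat.mean()))
        df["x"], df["y"] = _lonlat_to_local_metres(
            lon, lat, origin_lonlat[0], origin_lonlat[1])
    if cmap["species"] in raw.columns:
        df["species"] = raw[cmap["species"]].astype(str)
    elif species_map:
        df["species"] = df["animal_id"].map(species_map)
    else:
        df["species"] = "unknown"
    df = df.drop_duplicates(subset=["animal_id", "timestamp"], keep="first")
    return df.sort_values(["animal_id", "timestamp"]).reset_index(drop=True)


def read_temperature_csv(path, *, timestamp_col: str = "timestamp",
                         temp_col: str = "temp_c") -> pd.DataFrame:
    """Weather-station series as a sorted (timestamp, temp_c) frame."""
    raw = pd.read_csv(path)
    out = pd.DataFrame({
        "timestamp": pd.to_datetime(raw[timestamp_col]),
        "temp_c": raw[temp_col].astype(float),
    })
    if not np.isfinite(out["temp_c"]).all():
        raise ValueError("non-finite temperature record")
    return out.sort_values("timestamp").reset_index(drop=True)


def filter_eligible(fixes: pd.DataFrame, min_fixes: int = 1000,
                    study_polygon: BaseGeometry | None = None,
                    ) -> tuple[pd.DataFrame, pd.Series]:
    """Keep animals with at least ``min_fixes`` fixes inside the study area.

    Returns the retained fixes (all of them, not only in-area ones) and a
    per-animal Series of in-area fix counts for reporting.
    """
    if study_polygon is not None:
        if study_polygon.is_empty or study_polygon.area == 0:
            warnings.warn("degenerate study polygon: all animals excluded")
            inside = pd.Series(False, index=fixes.index)
        else:
            inside = pd.Series(
                [study_polygon.contains(Point(x, y))
                 for x, y in zip(fixes["x"], fixes["y"])],
                index=fixes.index,
            )
    else:
        inside = pd.Series(True, index=fixes.index)
    counts = fixes.loc[inside, "animal_id"].value_counts().reindex(
        fixes["animal_id"].unique(), fill_value=0)
    keep = counts[counts >= min_fixes].index
    return fixes[fixes["animal_id"].isin(keep)].reset_index(drop=True), counts


def _resample_one(times: np.ndarray, target: float, tol: float
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Greedy forward regularisation of one animal's timestamps.

    Returns (kept indices, burst id per kept index). A kept fix anchors
    the search for the next: the first later fix whose gap from the
    anchor lies in [target-tol, target+tol] continues the burst; a fix
    beyond target+tol ends the burst and starts a new one there.
    """
    kept: list[int] = []
    bursts: list[int] = []
    n = len(times)
    if n == 0:
        return np.array([], int), np.array([], int)
    burst = 0
    i = 0
    kept.append(0)
    bursts.append(0)
    while i < n - 1:
        # admissible continuations: gaps in [target-tol, target+tol];
        # among them take the one closest to the target (earlier on ties)
        j = i + 1
        best = -1
        best_err = np.inf
        while j < n:
            gap = (times[j] - times[i]) / np.timedelta64(60, "s")
            if gap < target - tol:
                j += 1
                continue
            if gap > target + tol:
                break
            err = abs(gap - target)
            if err < best_err:
                best, best_err = j, err
            j += 1
        if best < 0:
            if j >= n:
                break
            burst += 1
            i = j
        else:
            i = best
        kept.append(i)
        bursts.append(burst)
    return np.asarray(kept, int), np.asarray(bursts, int)


def resample_track(fixes: pd.DataFrame, target_rate: float = 30.0,
                   tolerance: float = 5.0, min_burst: int = 3
                   ) -> pd.DataFrame:
    """Resample fixes to the analysis rate (default 30 +/- 5 min).

    Greedy forward pass per animal; gaps outside the window start a new
    burst; bursts with fewer than ``min_burst`` fixes are dropped (a turn
    angle needs two consecutive steps). Adds a ``burst`` column unique
    per (animal, burst).
    """
    if not target_rate > 0:
        raise ValueError("target_rate must be > 0")
    out = []
    for animal, grp in fixes.groupby("animal_id", sort=False):
        grp = grp.sort_values("timestamp")
        idx, burst = _resample_one(
            grp["timestamp"].to_numpy(), target_rate, tolerance)
        sub = grp.iloc[idx].copy()
        sub["burst"] = [f"{animal}:{b}" for b in burst]
        counts = sub["burst"].value_counts()
        sub = sub[sub["burst"].map(counts) >= min_burst]
        out.append(sub)
    if not out:
        return fixes.iloc[0:0].assign(burst=pd.Series(dtype=str))
    return pd.concat(out, ignore_index=True)


def _wrap_angle(a):
    """Wrap to (-pi, pi]."""
    a = np.asarray(a, dtype=float)
    wrapped = -((-a + np.pi) % (2 * np.pi) - np.pi)
    return wrapped


def _crosses_night(t_start: pd.Series, t_end: pd.Series) -> np.ndarray:
    """True where a step leaves the tag's daily on-window (05:45-18:30)."""
    same_day = t_start.dt.normalize() == t_end.dt.normalize()
    tod_start = t_start - t_start.dt.normalize()
    tod_end = t_end - t_end.dt.normalize()
    ok = (same_day & (tod_start >= DAY_START) & (tod_end <= DAY_END))
    return ~ok.to_numpy()


def steps_from_fixes(fixes: pd.DataFrame) -> pd.DataFrame:
    """Observed steps from regularised fixes.

    One row per consecutive within-burst fix pair, with step length (m),
    absolute heading and turn angle (radians, CCW-from-+x convention;
    the first step of a burst has NaN turn angle). Steps spanning the
    nightly GPS-off window are excluded.
    """
    frames = []
    for burst, grp in fixes.groupby("burst", sort=False):
        grp = grp.sort_values("timestamp")
        if len(grp) < 2:
            continue
        x = grp["x"].to_numpy()
        y = grp["y"].to_numpy()
        t = grp["timestamp"].to_numpy()
        dx, dy = np.diff(x), np.diff(y)
        heading = np.arctan2(dy, dx)
        turn = np.concatenate([[np.nan], _wrap_angle(np.diff(heading))])
        step = pd.DataFrame({
            "animal_id": grp["animal_id"].iloc[0],
            "species": grp["species"].iloc[0] if "species" in grp else "unknown",
            "burst": burst,
            "t_start": t[:-1],
            "t_end": t[1:],
            "x_start": x[:-1], "y_start": y[:-1],
            "x_end": x[1:], "y_end": y[1:],
            "sl": np.hypot(dx, dy),
            "heading": heading,
            "ta": turn,
        })
        frames.append(step)
    if not frames:
        return pd.DataFrame(columns=[
            "animal_id", "species", "burst", "t_start", "t_end", "x_start",
            "y_start", "x_end", "y_end", "sl", "heading", "ta"])
    steps = pd.concat(frames, ignore_index=True)
    steps["duration_min"] = (
        (steps["t_end"] - steps["t_start"]).dt.total_seconds() / 60.0)
    night = _crosses_night(pd.Series(steps["t_start"]),
                           pd.Series(steps["t_end"]))
    return steps[~night].reset_index(drop=True)


@dataclass
class Standardization:
    """Per-animal centring/scaling parameters, kept for back-transform
    and for reuse when scoring simulated locations."""

    params: dict[str, dict[str, tuple[float, float]]]  # animal -> var -> (mean, sd)

    def transform_value(self, animal: str, var: str, value):
        mean, sd = self.params[animal][var]
        return (value - mean) / sd

    def to_dict(self) -> dict:
        return {a: {v: list(ms) for v, ms in vs.items()}
                for a, vs in self.params.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "Standardization":
        return cls({a: {v: (float(m), float(s)) for v, (m, s) in vs.items()}
                    for a, vs in d.items()})


def build_strata(fixes: pd.DataFrame, k_controls: int, tentative, stack,
                 rng_seed: int, *, report: dict | None = None
                 ) -> pd.DataFrame:
    """Build conditional-logit strata: each observed step plus K control
    steps sharing its start point and time.

    Control lengths are drawn from the tentative gamma and control turns
    from the tentative von Mises applied to the previous observed
    heading. Habitat covariates are the stack-cell values at each step's
    endpoint; strata with any endpoint off-raster or on nodata are
    dropped and counted in ``report``.
    """
    if k_controls < 1:
        raise ValueError("k_controls must be >= 1")
    rng = np.random.default_rng(rng_seed)
    steps = steps_from_fixes(fixes)
    steps = steps[np.isfinite(steps["ta"])].reset_index(drop=True)
    n = len(steps)
    if n == 0:
        if report is not None:
            report["n_strata"] = 0
            report["n_dropped"] = 0
        return pd.DataFrame(columns=[
            "animal_id", "species", "stratum_id", "case", "t_start", "t_end",
            "x_start", "y_start", "x_end", "y_end", "sl", "ta",
            *HABITAT_COVARIATES, "log_sl", "cos_ta"])

    prev_heading = (steps["heading"] - steps["ta"]).to_numpy()
    sl_ctl = rng.gamma(tentative.sl_shape, 1.0 / tentative.sl_rate,
                       size=(n, k_controls))
    ta_ctl = rng.vonmises(tentative.ta_mu, tentative.ta_kappa,
                          size=(n, k_controls))
    heading_ctl = prev_heading[:, None] + ta_ctl
    x0 = steps["x_start"].to_numpy()[:, None]
    y0 = steps["y_start"].to_numpy()[:, None]
    end_x = np.column_stack([steps["x_end"].to_numpy(),
                             x0 + sl_ctl * np.cos(heading_ctl)])
    end_y = np.column_stack([steps["y_end"].to_numpy(),
                             y0 + sl_ctl * np.sin(heading_ctl)])
    end_sl = np.column_stack([steps["sl"].to_numpy(), sl_ctl])
    end_ta = np.column_stack([steps["ta"].to_numpy(), ta_ctl])

    covs = stack.covariates_at_many(end_x.ravel(), end_y.ravel())
    valid = np.ones(end_x.size, dtype=bool)
    for arr in covs.values():
        valid &= np.isfinite(arr)
    keep = valid.reshape(n, k_controls + 1).all(axis=1)
    n_kept = int(keep.sum())
    if report is not None:
        report["n_strata"] = n_kept
        report["n_dropped"] = int(n - n_kept)

    kk = k_controls + 1
    rep = np.repeat(keep, kk)
    strata = pd.DataFrame({
        "animal_id": np.repeat(steps["animal_id"].to_numpy(), kk)[rep],
        "species": np.repeat(steps["species"].to_numpy(), kk)[rep],
        "stratum_id": np.char.add(
            np.repeat(steps["animal_id"].to_numpy().astype(str), kk),
            np.char.add(":", np.repeat(
                np.arange(n).astype(str), kk)))[rep],
        "case": np.tile(np.arange(kk) == 0, n)[rep],
        "t_start": np.repeat(steps["t_start"].to_numpy(), kk)[rep],
        "t_end": np.repeat(steps["t_end"].to_numpy(), kk)[rep],
        "x_start": np.repeat(steps["x_start"].to_numpy(), kk)[rep],
        "y_start": np.repeat(steps["y_start"].to_numpy(), kk)[rep],
        "x_end": end_x.ravel()[rep],
        "y_end": end_y.ravel()[rep],
        "sl": end_sl.ravel()[rep],
        "ta": end_ta.ravel()[rep],
    })
    for name, arr in covs.items():
        strata[name] = arr[rep]
    strata["log_sl"] = np.log(strata["sl"] + 1.0)
    strata["cos_ta"] = np.cos(strata["ta"])
    return strata


def attach_temperature(steps: pd.DataFrame, series: pd.DataFrame,
                       max_gap: float = 60.0) -> pd.DataFrame:
    """Attach the nearest station temperature (by step end time).

    The nearest record within ``max_gap`` minutes wins; exact ties go to
    the earlier record. Steps with no record in range get NaN (and are
    excluded later from models with temperature terms).
    """
    if series.empty:
        raise ValueError("empty temperature series")
    st = series.sort_values("timestamp").reset_index(drop=True)
    stamps = st["timestamp"].to_numpy()
    temps = st["temp_c"].to_numpy()
    t = pd.to_datetime(steps["t_end"]).to_numpy()
    pos = np.searchsorted(stamps, t)
    left = np.clip(pos - 1, 0, len(stamps) - 1)
    right = np.clip(pos, 0, len(stamps) - 1)
    dl = np.abs((t - stamps[left]) / np.timedelta64(60, "s"))
    dr = np.abs((stamps[right] - t) / np.timedelta64(60, "s"))
    use_left = dl <= dr  # earlier record wins ties
    best = np.where(use_left, left, right)
    dist = np.where(use_left, dl, dr)
    out = steps.copy()
    out["temperature"] = np.where(dist <= max_gap, temps[best], np.nan)
    return out


def standardize_covariates(stepset: pd.DataFrame,
                           variables: tuple[str, ...] = SCALED_COVARIATES,
                           fixed_params: dict | None = None,
                           ) -> tuple[pd.DataFrame, Standardization]:
    """Centre and scale covariates per animal over used + control steps.

    Uses the sample standard deviation (n-1). Binary covariates (swamp)
    are deliberately left unscaled. Raises on zero variance, naming the
    variable. ``fixed_params`` (var -> (mean, sd)) applies externally
    supplied parameters instead — e.g. the scale a simulation was
    generated on — identically for every animal.
    """
    out = stepset.copy()
    if "temperature" in variables and "temperature" in out.columns:
        # raw deg C retained for temperature binning downstream
        out["temperature_c"] = out["temperature"].astype(float)
    params: dict[str, dict[str, tuple[float, float]]] = {}
    for animal, grp in stepset.groupby("animal_id", sort=False):
        params[animal] = {}
        for var in variables:
            if var not in grp.columns:
                continue
            vals = grp[var].astype(float)
            if fixed_params is not None and var in fixed_params:
                mean, sd = map(float, fixed_params[var])
            else:
                mean = float(vals.mean())
                sd = float(vals.std(ddof=1))
            if not np.isfinite(sd) or sd == 0:
                raise ValueError(
                    f"zero variance in covariate {var!r} for animal {animal!r}")
            params[animal][var] = (mean, sd)
            out.loc[grp.index, var] = (vals - mean) / sd
    return out, Standardization(params)
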