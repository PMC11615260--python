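"""Raster covariate layers describing 3D forest structure.

Builds the 10 m covariate stack used by the step-selection models:
canopy height, vertical complexity, distance to small/large canopy gaps,
and a binary swamp mask, all co-registered on one projected-metre grid.

Conventions
-----------
* Rasters are row-major 2-D float arrays; row 0 is the northern edge.
  Cell (row, col) covers the half-open box
  ``[x0 + col*s, x0 + (col+1)*s) x (y0 - (row+1)*s, y0 - row*s]``
  where ``(x0, y0)`` is the outer corner of cell (0, 0) and ``s`` the
  cell size in metres.
* Missing data are carried as NaN in memory; the ``nodata`` sentinel is
  only used at the file boundary.
* Canopy gaps are connected regions (4-connectivity) of cells whose
  canopy height is below 5 m, classed small (>= 50 m^2) or large
  (>= 500 m^2).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "RasterGrid",
    "GapSet",
    "LandscapeStack",
    "read_ascii_grid",
    "write_ascii_grid",
    "detect_gaps",
    "distance_to_gaps",
    "vertical_complexity",
    "aggregate_chm",
    "build_stack",
]

GAP_HEIGHT_M = 5.0
GAP_SMALL_M2 = 50.0
GAP_LARGE_M2 = 500.0


@dataclass
class RasterGrid:
    """A single raster layer on a projected, metre-based grid.

    Parameters
    ----------
    values
        2-D float array; NaN marks missing cells.
    cell_size
        Cell edge length in metres (> 0).
    origin
        Map coordinates ``(x, y)`` of the outer (north-west) corner of
        cell (0, 0).
    crs_id
        Identifier of the projected CRS, e.g. ``"EPSG:32633"``. Only
        compared for equality; no reprojection is performed.
    nodata
        Sentinel written to/read from files in place of NaN.
    """

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    crs_id: str = "local-metre"
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2-D array")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def same_grid(self, other: "RasterGrid") -> bool:
        return (
            self.shape == other.shape
            and self.cell_size == other.cell_size
            and self.origin == other.origin
            and self.crs_id == other.crs_id
        )

    def cell_centre(self, row: int, col: int) -> tuple[float, float]:
        x0, y0 = self.origin
        s = self.cell_size
        return (x0 + (col + 0.5) * s, y0 - (row + 0.5) * s)

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """Row/col of the cell containing map point (x, y); may be off-grid."""
        x0, y0 = self.origin
        col = int(np.floor((x - x0) / self.cell_size))
        row = int(np.floor((y0 - y) / self.cell_size))
        return row, col

    def contains(self, x: float, y: float) -> bool:
        row, col = self.cell_of(x, y)
        nr, nc = self.shape
        return 0 <= row < nr and 0 <= col < nc

    def value_at(self, x: float, y: float) -> float:
        """Value of the cell containing (x, y); NaN if off-grid or nodata."""
        row, col = self.cell_of(x, y)
        nr, nc = self.shape
        if not (0 <= row < nr and 0 <= col < nc):
            return float("nan")
        return float(self.values[row, col])

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the raster footprint."""
        x0, y0 = self.origin
        nr, nc = self.shape
        return (x0, y0 - nr * self.cell_size, x0 + nc * self.cell_size, y0)


def write_ascii_grid(grid: RasterGrid, path) -> None:
    """Write an ESRI ASCII grid (.asc) with a sidecar-free header.

    The CRS identifier is stored as a trailing comment line, which common
    GIS readers ignore.
    """
    nr, nc = grid.shape
    x0, y0 = grid.origin
    vals = np.where(np.isnan(grid.values), grid.nodata, grid.values)
    with open(path, "w") as fh:
        fh.write(f"ncols {nc}\n")
        fh.write(f"nrows {nr}\n")
        fh.write(f"xllcorner {x0!r}\n")
        fh.write(f"yllcorner {y0 - nr * grid.cell_size!r}\n")
        fh.write(f"cellsize {grid.cell_size!r}\n")
        fh.write(f"NODATA_value {grid.nodata!r}\n")
        for row in vals:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")
        fh.write(f"# crs {grid.crs_id}\n")


def read_ascii_grid(path, crs_id: str | None = None) -> RasterGrid:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`."""
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    crs = crs_id
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if len(parts) >= 2 and parts[0] == "crs" and crs_id is None:
                    crs = parts[1]
                continue
            parts = line.split()
            if len(header) < 6 and parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                "nodata_value",
            ):
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    vals = np.array(rows, dtype=float)
    nodata = header.get("nodata_value", -9999.0)
    vals[vals == nodata] = np.nan
    cell = header["cellsize"]
    origin = (header["xllcorner"], header["yllcorner"] + header["nrows"] * cell)
    return RasterGrid(vals, cell, origin, crs_id=crs or "local-metre",
                      nodata=nodata)


@dataclass
class GapSet:
    """Connected canopy-gap regions above a minimum area.

    ``labels`` is an integer lattice aligned with the source raster:
    0 marks non-gap cells, positive ids mark retained regions. ``areas``
    maps region id to area in m^2 (cell count x cell area).
    """

    labels: np.ndarray
    areas: dict[int, float]
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    crs_id: str = "local-metre"
    threshold_small: float = GAP_SMALL_M2
    threshold_large: float = GAP_LARGE_M2

    @property
    def n_gaps(self) -> int:
        return len(self.areas)

    def mask(self) -> np.ndarray:
        return self.labels > 0


def detect_gaps(chm: RasterGrid, height_thresh: float = GAP_HEIGHT_M,
                min_area: float = GAP_SMALL_M2) -> GapSet:
    """Delineate canopy gaps: connected low-canopy regions above a size cut.

    A gap cell has canopy height strictly below ``height_thresh`` (the
    "no vegetation above 5 m" rule). Cells join a region under
    4-connectivity; regions smaller than ``min_area`` m^2 are discarded
    and their cells relabelled 0. Nodata cells never belong to gaps.
    """
    if not height_thresh > 0:
        raise ValueError("height_thresh must be > 0")
    vals = chm.values
    if np.all(np.isnan(vals)):
        raise ValueError("empty CHM")
    low = (vals < height_thresh) & ~np.isnan(vals)
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])  # rook
    labels, n = ndimage.label(low, structure=structure)
    cell_area = chm.cell_size ** 2
    areas: dict[int, float] = {}
    if n:
        counts = np.bincount(labels.ravel(), minlength=n + 1)
        keep = {}
        next_id = 1
        for rid in range(1, n + 1):
            area = counts[rid] * cell_area
            if area >= min_area:
                keep[rid] = next_id
                areas[next_id] = float(area)
                next_id += 1
        relabel = np.zeros(n + 1, dtype=labels.dtype)
        for old, new in keep.items():
            relabel[old] = new
        labels = relabel[labels]
    return GapSet(labels, areas, chm.cell_size, chm.origin, chm.crs_id,
                  threshold_small=min_area)


def distance_to_gaps(gaps: GapSet, grid: RasterGrid,
                     cap: float | None = None) -> RasterGrid:
    """Euclidean distance (m) from each cell centre to the nearest gap cell.

    Gap regions are mapped onto ``grid`` by "any overlap": a target cell
    is a gap cell if any source gap cell centre falls inside it. Distance
    is centre-to-centre and 0 inside gaps. With no gaps at all, every
    cell receives ``cap`` (default: the diagonal length of the raster).
    """
    nr, nc = grid.shape
    if cap is None:
        cap = float(np.hypot(nr * grid.cell_size, nc * grid.cell_size))
    gap_on_grid = np.zeros((nr, nc), dtype=bool)
    src_rows, src_cols = np.nonzero(gaps.labels > 0)
    if src_rows.size:
        sx0, sy0 = gaps.origin
        cx = sx0 + (src_cols + 0.5) * gaps.cell_size
        cy = sy0 - (src_rows + 0.5) * gaps.cell_size
        gx0, gy0 = grid.origin
        tc = np.floor((cx - gx0) / grid.cell_size).astype(int)
        tr = np.floor((gy0 - cy) / grid.cell_size).astype(int)
        ok = (tr >= 0) & (tr < nr) & (tc >= 0) & (tc < nc)
        gap_on_grid[tr[ok], tc[ok]] = True
    if not gap_on_grid.any():
        out = np.full((nr, nc), cap)
    else:
        out = ndimage.distance_transform_edt(
            ~gap_on_grid, sampling=grid.cell_size)
    return RasterGrid(out, grid.cell_size, grid.origin, grid.crs_id,
                      nodata=grid.nodata)


def vertical_complexity(profile_counts: np.ndarray,
                        n_bins: int | None = None) -> np.ndarray:
    """Vertical complexity index: normalised Shannon entropy of the
    per-cell vertical profile of LiDAR return heights.

    Parameters
    ----------
    profile_counts
        Array of shape (nrows, ncols, n_bins) of non-negative return
        counts per fixed-width height bin (default bins: 1 m, 0-60 m).
    n_bins
        Number of bins used for normalisation; defaults to the last
        axis length.

    Returns
    -------
    2-D array with VCI = -sum(p_i ln p_i) / ln(n_bins) in [0, 1];
    cells with zero total count are NaN.
    """
    counts = np.asarray(profile_counts, dtype=float)
    if counts.ndim != 3:
        raise ValueError("profile_counts must be (nrows, ncols, n_bins)")
    if n_bins is None:
        n_bins = counts.shape[-1]
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if np.any(counts < 0):
        raise ValueError("negative counts")
    total = counts.sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = counts / total[..., None]
        plogp = np.where(p > 0, p * np.log(p), 0.0)
        vci = -plogp.sum(axis=-1) / np.log(n_bins)
    vci = np.where(total > 0, vci, np.nan)
    # clip tiny negative round-off
    return np.clip(vci, 0.0, 1.0, out=vci)


def aggregate_chm(chm_1m: RasterGrid, target_cell: float = 10.0) -> RasterGrid:
    """Block-mean a fine raster to a coarser cell size.

    ``target_cell`` must be an integer multiple of the source cell size.
    Nodata cells do not enter the mean; all-nodata blocks stay nodata.
    """
    ratio = target_cell / chm_1m.cell_size
    k = int(round(ratio))
    if abs(ratio - k) > 1e-9 or k < 1:
        raise ValueError("target_cell must be an integer multiple of "
                         "the source cell size")
    nr, nc = chm_1m.shape
    out_r, out_c = nr // k, nc // k
    vals = chm_1m.values[: out_r * k, : out_c * k]
    blocks = vals.reshape(out_r, k, out_c, k)
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN blocks
        out = np.nanmean(blocks, axis=(1, 3))
    return RasterGrid(out, target_cell, chm_1m.origin, chm_1m.crs_id,
                      nodata=chm_1m.nodata)


@dataclass
class LandscapeStack:
    """Five co-registered covariate layers on one 10 m grid."""

    canopy_height: RasterGrid
    vci: RasterGrid
    dist_gap_small: RasterGrid
    dist_gap_large: RasterGrid
    swamp: RasterGrid
    provenance: dict = field(default_factory=dict)

    LAYERS = ("canopy_height", "vci", "dist_gap_small", "dist_gap_large",
              "swamp")

    def __post_init__(self) -> None:
        ref = self.canopy_height
        for name in self.LAYERS[1:]:
            if not ref.same_grid(getattr(self, name)):
                raise ValueError(f"layer {name!r} is not on the stack grid")

    @property
    def grid(self) -> RasterGrid:
        return self.canopy_height

    def layer(self, name: str) -> RasterGrid:
        if name not in self.LAYERS:
            raise KeyError(name)
        return getattr(self, name)

    def covariates_at(self, x: float, y: float) -> dict[str, float]:
        """Covariate values of the cell containing (x, y); NaN off-grid."""
        return {name: self.layer(name).value_at(x, y) for name in self.LAYERS}

    def covariates_at_many(self, x, y) -> dict[str, np.ndarray]:
        """Vectorised cell lookup; off-grid points come back NaN."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        g = self.grid
        x0, y0 = g.origin
        col = np.floor((x - x0) / g.cell_size).astype(int)
        row = np.floor((y0 - y) / g.cell_size).astype(int)
        nr, nc = g.shape
        ok = (row >= 0) & (row < nr) & (col >= 0) & (col < nc)
        row_c = np.clip(row, 0, nr - 1)
        col_c = np.clip(col, 0, nc - 1)
        out = {}
        for name in self.LAYERS:
            vals = self.layer(name).values[row_c, col_c]
            out[name] = np.where(ok, vals, np.nan)
        return out

    def save(self, directory) -> None:
        import os

        os.makedirs(directory, exist_ok=True)
        for name in self.LAYERS:
            write_ascii_grid(self.layer(name),
                             os.path.join(directory, f"{name}.asc"))
        with open(os.path.join(directory, "provenance.json"), "w") as fh:
            json.dump(self.provenance, fh, indent=1)

    @classmethod
    def load(cls, directory) -> "LandscapeStack":
        import os

        layers = {name: read_ascii_grid(os.path.join(directory, f"{name}.asc"))
                  for name in cls.LAYERS}
        prov_path = os.path.join(directory, "provenance.json")
        prov = {}
        if os.path.exists(prov_path):
            with open(prov_path) as fh:
                prov = json.load(fh)
        return cls(provenance=prov, **layers)


def build_stack(chm: RasterGrid,
                profiles: np.ndarray | None = None,
                swamp_mask: RasterGrid | None = None,
                *,
                gap_height: float = GAP_HEIGHT_M,
                gap_small: float = GAP_SMALL_M2,
                gap_large: float = GAP_LARGE_M2,
                target_cell: float = 10.0) -> LandscapeStack:
    """Assemble the covariate stack from a CHM and auxiliary inputs.

    Gap detection runs at the CHM's native resolution; distances are
    computed at the covariate (``target_cell``) resolution after mapping
    gap regions onto the coarse grid by any-overlap. ``profiles`` are
    per-cell vertical return histograms on the target grid (already
    coarse); if absent the VCI layer is all-NaN. ``swamp_mask`` must be
    on the target grid with values {0, 1}; its nodata propagates.
    """
    chm10 = chm if chm.cell_size == target_cell else aggregate_chm(
        chm, target_cell)

    gaps_small = detect_gaps(chm, gap_height, gap_small)
    gaps_large = detect_gaps(chm, gap_height, gap_large)
    d_small = distance_to_gaps(gaps_small, chm10)
    d_large = distance_to_gaps(gaps_large, chm10)

    if profiles is not None:
        vci_vals = vertical_complexity(profiles)
        if vci_vals.shape != chm10.shape:
            raise ValueError("profiles shape does not match target grid")
    else:
        vci_vals = np.full(chm10.shape, np.nan)
    vci = RasterGrid(vci_vals, target_cell, chm10.origin, chm10.crs_id)

    if swamp_mask is not None:
        if swamp_mask.crs_id != chm10.crs_id:
            raise ValueError("CRS mismatch between swamp mask and CHM; "
                             "no transform available")
        sv = swamp_mask.values.copy()
        bad = ~np.isnan(sv) & ~np.isin(sv, (0.0, 1.0))
        sv[bad] = np.nan  # unexpected codes treated as nodata, not coerced
        swamp = RasterGrid(sv, target_cell, chm10.origin, chm10.crs_id)
    else:
        swamp = RasterGrid(np.zeros(chm10.shape), target_cell, chm10.origin,
                           chm10.crs_id)
    if not chm10.same_grid(swamp):
        raise ValueError("swamp mask is not on the target grid")

    prov = {
        "gap_height_m": gap_height,
        "gap_small_m2": gap_small,
        "gap_large_m2": gap_large,
        "cell_size_m": target_cell,
        "source_cell_size_m": chm.cell_size,
    }
    return LandscapeStack(chm10, vci, d_small, d_large, swamp,
                          provenance=prov)
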