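"""Areal lattices, adjacency graphs and point-to-cell aggregation.

The spatial support of the model is a lattice of non-overlapping areal
units (cells).  Occurrence points and covariate samples are aggregated
to cells; the cells' rook or queen neighbourhood graph provides the
adjacency matrix of the CAR spatial random effect.

Cells are axis-aligned half-open rectangles ``[x0, x1) x [y0, y1)`` so
that a point on a shared border belongs to exactly one cell.  Cell
ordering is row-major from the south-west corner and is stable for a
given bounding box, resolution and mask.
"""

from __future__ import annotations

import json
import warnings
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import scipy.io
import scipy.sparse as sp

try:  # mask clipping only; everything else is index arithmetic
    from shapely.geometry import box as _shapely_box, shape as _shapely_shape
except ImportError:  # pragma: no cover
    _shapely_box = None
    _shapely_shape = None

#: sentinel for a missing (unobserved) cell response
MISSING: int = -1


@dataclass(frozen=True)
class Lattice:
    """A rectangular grid lattice, possibly clipped to a mask polygon.

    Attributes
    ----------
    x0, y0 : float
        Coordinates of the south-west corner of the full grid.
    resolution : float
        Cell edge length (same units as the coordinates).
    nx, ny : int
        Number of columns / rows of the full (unclipped) grid.
    rows, cols : ndarray of int
        Row and column index of each kept cell, row-major from the
        south-west corner.
    """

    x0: float
    y0: float
    resolution: float
    nx: int
    ny: int
    rows: np.ndarray
    cols: np.ndarray
    cell_ids: tuple = field(default=None)

    def __post_init__(self):
        if self.cell_ids is None:
            ids = tuple(f"r{r}c{c}" for r, c in zip(self.rows, self.cols))
            object.__setattr__(self, "cell_ids", ids)

    @property
    def n_cells(self) -> int:
        return len(self.rows)

    @property
    def cell_index(self) -> dict:
        """Mapping cell identifier -> 0-based position."""
        return {cid: i for i, cid in enumerate(self.cell_ids)}

    def cell_bounds(self, pos: int) -> tuple:
        """(xmin, ymin, xmax, ymax) of the cell at position ``pos``."""
        r, c = int(self.rows[pos]), int(self.cols[pos])
        x = self.x0 + c * self.resolution
        y = self.y0 + r * self.resolution
        return (x, y, x + self.resolution, y + self.resolution)

    def centroids(self) -> np.ndarray:
        """(n_cells, 2) array of cell centre coordinates."""
        xs = self.x0 + (self.cols + 0.5) * self.resolution
        ys = self.y0 + (self.rows + 0.5) * self.resolution
        return np.column_stack([xs, ys])

    def locate(self, x, y) -> np.ndarray:
        """Map point coordinates to cell positions (-1 if outside).

        Uses the half-open convention: a point on a shared edge belongs
        to the cell to its north-east.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        c = np.floor((x - self.x0) / self.resolution).astype(int)
        r = np.floor((y - self.y0) / self.resolution).astype(int)
        inside = (c >= 0) & (c < self.nx) & (r >= 0) & (r < self.ny)
        pos = np.full(x.shape, -1, dtype=int)
        lut = -np.ones(self.nx * self.ny, dtype=int)
        lut[self.rows * self.nx + self.cols] = np.arange(self.n_cells)
        flat = np.where(inside, r * self.nx + c, 0)
        pos[inside] = lut[flat[inside]]
        return pos

    def coarsen(self, factor: int) -> "Lattice":
        """Lattice of ``factor`` x ``factor`` blocks of this grid.

        Partial blocks at the north/east edges are kept.  A block is a
        cell of the coarse lattice iff it contains at least one kept
        fine cell.
        """
        if factor < 1:
            raise ValueError("factor must be >= 1")
        br = self.rows // factor
        bc = self.cols // factor
        keys = np.unique(br * ((self.nx + factor - 1) // factor) + bc)
        cnx = (self.nx + factor - 1) // factor
        cny = (self.ny + factor - 1) // factor
        rows = keys // cnx
        cols = keys % cnx
        return Lattice(
            x0=self.x0,
            y0=self.y0,
            resolution=self.resolution * factor,
            nx=cnx,
            ny=cny,
            rows=rows,
            cols=cols,
        )

    # -- GeoJSON I/O ---------------------------------------------------
    def to_geojson(self, path=None):
        """Export as a GeoJSON FeatureCollection (one polygon per cell)."""
        feats = []
        for i, cid in enumerate(self.cell_ids):
            xmin, ymin, xmax, ymax = self.cell_bounds(i)
            ring = [[xmin, ymin], [xmax, ymin], [xmax, ymax],
                    [xmin, ymax], [xmin, ymin]]
            feats.append({
                "type": "Feature",
                "properties": {"cell_id": cid,
                               "row": int(self.rows[i]),
                               "col": int(self.cols[i])},
                "geometry": {"type": "Polygon", "coordinates": [ring]},
            })
        obj = {
            "type": "FeatureCollection",
            "grid": {"x0": self.x0, "y0": self.y0,
                     "resolution": self.resolution,
                     "nx": self.nx, "ny": self.ny},
            "features": feats,
        }
        if path is None:
            return obj
        with open(path, "w") as fh:
            json.dump(obj, fh)
        return None

    @classmethod
    def from_geojson(cls, path_or_obj) -> "Lattice":
        if isinstance(path_or_obj, (str, bytes)) or hasattr(path_or_obj, "__fspath__"):
            with open(path_or_obj) as fh:
                obj = json.load(fh)
        else:
            obj = path_or_obj
        g = obj["grid"]
        rows = np.array([f["properties"]["row"] for f in obj["features"]])
        cols = np.array([f["properties"]["col"] for f in obj["features"]])
        ids = tuple(f["properties"]["cell_id"] for f in obj["features"])
        return cls(x0=g["x0"], y0=g["y0"], resolution=g["resolution"],
                   nx=g["nx"], ny=g["ny"], rows=rows, cols=cols,
                   cell_ids=ids)


@dataclass(frozen=True)
class Adjacency:
    """Sparse symmetric binary neighbourhood matrix of a lattice.

    ``matrix`` is the adjacency matrix W; ``degrees`` are the row sums,
    i.e. the diagonal of the degree matrix D used by the proper-CAR
    precision tau * (D - lambda * W).
    """

    matrix: sp.csr_matrix
    degrees: np.ndarray

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    def to_mtx(self, path):
        """Write the adjacency pattern in Matrix Market format."""
        scipy.io.mmwrite(path, sp.coo_matrix(self.matrix),
                         field="pattern", symmetry="symmetric")

    @classmethod
    def from_mtx(cls, path) -> "Adjacency":
        m = sp.csr_matrix(scipy.io.mmread(path))
        m.data = np.ones_like(m.data)
        return cls(matrix=m, degrees=np.asarray(m.sum(axis=1)).ravel())


@dataclass
class CellResponse:
    """Per-cell ternary response: present (1), absent (0) or missing.

    Missing cells are encoded internally by :data:`MISSING` (-1).
    """

    values: np.ndarray  # int8, entries in {1, 0, MISSING}

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.int8)
        bad = ~np.isin(self.values, [0, 1, MISSING])
        if bad.any():
            raise ValueError("response values must be 0, 1 or MISSING")

    @property
    def n_cells(self) -> int:
        return self.values.size

    @property
    def n_present(self) -> int:
        return int((self.values == 1).sum())

    @property
    def n_absent(self) -> int:
        return int((self.values == 0).sum())

    @property
    def n_missing(self) -> int:
        return int((self.values == MISSING).sum())

    @property
    def observed(self) -> np.ndarray:
        """Boolean mask of cells with an observed (non-missing) value."""
        return self.values != MISSING

    def to_csv(self, path, lattice: Lattice, column: str = "value"):
        import pandas as pd

        vals = [("" if v == MISSING else int(v)) for v in self.values]
        pd.DataFrame({"cell_id": list(lattice.cell_ids),
                      column: vals}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, lattice: Lattice, column: str = "value"):
        import pandas as pd

        df = pd.read_csv(path, dtype={"cell_id": str})
        df = df.set_index("cell_id").reindex(list(lattice.cell_ids))
        raw = df[column].to_numpy()
        vals = np.full(lattice.n_cells, MISSING, dtype=np.int8)
        ok = ~pd.isna(raw)
        vals[ok] = np.asarray(raw[ok], dtype=float).astype(np.int8)
        return cls(values=vals)


def build_grid_lattice(bbox, resolution, mask=None) -> Lattice:
    """Build a regular grid lattice over a bounding box.

    Parameters
    ----------
    bbox : (xmin, ymin, xmax, ymax)
        Extent of the grid.  The number of columns/rows is the ceiling
        of extent / resolution, so the grid covers the whole box.
    resolution : float
        Cell edge length in the bbox's units (degrees or km).
    mask : shapely geometry or GeoJSON-like mapping, optional
        Only cells whose rectangle intersects the mask are kept.

    Raises
    ------
    ValueError
        If the bbox is degenerate, the resolution non-positive, or no
        cell intersects the mask.
    """
    xmin, ymin, xmax, ymax = map(float, bbox)
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    if xmax <= xmin or ymax <= ymin:
        raise ValueError("bbox is degenerate")
    nx = int(np.ceil((xmax - xmin) / resolution - 1e-12))
    ny = int(np.ceil((ymax - ymin) / resolution - 1e-12))
    rr, cc = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    rows, cols = rr.ravel(), cc.ravel()
    if mask is not None:
        if _shapely_box is None:  # pragma: no cover
            raise ImportError("shapely is required for mask clipping")
        geom = mask if hasattr(mask, "intersects") else _shapely_shape(mask)
        # positive-area overlap: cells merely touching the mask's
        # boundary are not part of the region
        keep = np.array([
            geom.intersection(_shapely_box(
                xmin + c * resolution, ymin + r * resolution,
                xmin + (c + 1) * resolution,
                ymin + (r + 1) * resolution)).area > 0
            for r, c in zip(rows, cols)
        ])
        if not keep.any():
            raise ValueError("mask does not intersect any grid cell")
        rows, cols = rows[keep], cols[keep]
    return Lattice(x0=xmin, y0=ymin, resolution=float(resolution),
                   nx=nx, ny=ny, rows=rows, cols=cols)


def adjacency_from_lattice(lattice: Lattice, rule: str = "rook") -> Adjacency:
    """Neighbourhood matrix of a grid lattice.

    ``rook`` connects cells sharing an edge; ``queen`` additionally
    connects cells sharing only a corner.
    """
    if rule not in ("rook", "queen"):
        raise ValueError("rule must be 'rook' or 'queen'")
    if lattice.n_cells == 0:
        raise ValueError("lattice is empty")
    offsets = [(0, 1), (1, 0)]
    if rule == "queen":
        offsets += [(1, 1), (1, -1)]
    lut = -np.ones(lattice.nx * lattice.ny, dtype=int)
    lut[lattice.rows * lattice.nx + lattice.cols] = np.arange(lattice.n_cells)
    ii, jj = [], []
    for dr, dc in offsets:
        r2 = lattice.rows + dr
        c2 = lattice.cols + dc
        ok = (r2 >= 0) & (r2 < lattice.ny) & (c2 >= 0) & (c2 < lattice.nx)
        j = np.where(ok, lut[np.clip(r2 * lattice.nx + c2, 0, lut.size - 1)], -1)
        ok &= j >= 0
        ii.append(np.arange(lattice.n_cells)[ok])
        jj.append(j[ok])
    i = np.concatenate(ii)
    j = np.concatenate(jj)
    n = lattice.n_cells
    w = sp.coo_matrix(
        (np.ones(2 * i.size, dtype=np.int8),
         (np.concatenate([i, j]), np.concatenate([j, i]))),
        shape=(n, n),
    ).tocsr()
    return Adjacency(matrix=w, degrees=np.asarray(w.sum(axis=1)).ravel())


def aggregate_presence(points, lattice: Lattice) -> CellResponse:
    """Presence/absence per cell from occurrence points.

    A cell is 1 iff at least one point falls inside it, 0 otherwise.
    Points outside every cell are counted on the returned response's
    ``n_outside`` attribute and trigger a warning; they are not fatal.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    vals = np.zeros(lattice.n_cells, dtype=np.int8)
    if pts.size:
        pos = lattice.locate(pts[:, 0], pts[:, 1])
        vals[pos[pos >= 0]] = 1
        n_outside = int((pos < 0).sum())
    else:
        n_outside = 0
    resp = CellResponse(values=vals)
    resp.n_outside = n_outside
    if n_outside:
        warnings.warn(f"{n_outside} point(s) fell outside the lattice")
    return resp


def aggregate_covariates(points, values, lattice: Lattice,
                         reducer: str = "mean",
                         impute: str = "none") -> np.ndarray:
    """Aggregate point-sampled covariate values to cells by mean.

    Parameters
    ----------
    points : (m, 2) array of coordinates
    values : (m,) or (m, p) array of numeric values
    impute : "none" or "nearest"
        With "nearest", cells without data take the value of the
        nearest cell (by adjacency-graph breadth-first search) that has
        data; with "none" they are flagged NaN.

    Returns
    -------
    (n_cells,) or (n_cells, p) array; NaN marks cells with no data
    when ``impute="none"``.
    """
    if reducer != "mean":
        raise ValueError("only the 'mean' reducer is supported")
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    vals = np.asarray(values, dtype=float)
    squeeze = vals.ndim == 1
    vals = vals.reshape(len(pts), -1)
    pos = lattice.locate(pts[:, 0], pts[:, 1])
    inside = pos >= 0
    if not inside.any():
        raise ValueError("no covariate value falls inside the lattice")
    out = np.full((lattice.n_cells, vals.shape[1]), np.nan)
    counts = np.bincount(pos[inside], minlength=lattice.n_cells)
    for p in range(vals.shape[1]):
        sums = np.bincount(pos[inside], weights=vals[inside, p],
                           minlength=lattice.n_cells)
        nz = counts > 0
        out[nz, p] = sums[nz] / counts[nz]
    if impute == "nearest":
        out = _impute_nearest(out, lattice)
    elif impute != "none":
        raise ValueError("impute must be 'none' or 'nearest'")
    return out[:, 0] if squeeze else out


def _impute_nearest(values: np.ndarray, lattice: Lattice) -> np.ndarray:
    """Fill NaN cells from the nearest cell with data (BFS over rook
    neighbours, position order breaking ties)."""
    adj = adjacency_from_lattice(lattice, "rook").matrix
    out = values.copy()
    empty = np.where(np.isnan(out).any(axis=1))[0]
    for cell in empty:
        seen = {int(cell)}
        queue = deque([int(cell)])
        while queue:
            cur = queue.popleft()
            if not np.isnan(values[cur]).any():
                out[cell] = values[cur]
                break
            for nb in sorted(adj.indices[adj.indptr[cur]:adj.indptr[cur + 1]]):
                if int(nb) not in seen:
                    seen.add(int(nb))
                    queue.append(int(nb))
    return out


def coarsen_response(response: CellResponse, lattice: Lattice,
                     factor: int) -> CellResponse:
    """Aggregate a cell response to ``factor`` x ``factor`` blocks.

    A block is present (1) if any member cell is present, absent (0) if
    no member is present but at least one is an observed absence, and
    missing otherwise.  The coarse lattice is ``lattice.coarsen(factor)``.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    coarse = lattice.coarsen(factor)
    cnx = coarse.nx
    keys = (lattice.rows // factor) * cnx + (lattice.cols // factor)
    ckeys = coarse.rows * cnx + coarse.cols
    order = {int(k): i for i, k in enumerate(ckeys)}
    idx = np.array([order[int(k)] for k in keys])
    vals = np.full(coarse.n_cells, MISSING, dtype=np.int8)
    any_zero = np.zeros(coarse.n_cells, dtype=bool)
    any_one = np.zeros(coarse.n_cells, dtype=bool)
    np.logical_or.at(any_one, idx, response.values == 1)
    np.logical_or.at(any_zero, idx, response.values == 0)
    vals[any_zero] = 0
    vals[any_one] = 1
    return CellResponse(values=vals)
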