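"""Point-cloud containers and the plot-conditioning chain.

The conditioning chain applied to every plot/survey cloud is

    normalize -> clip (negative buffer) -> SOR noise filter -> voxel decimation

i.e. heights are expressed above a ground surface estimated from the cloud
itself, points are clipped to the plot polygon shrunk by a −0.5 m buffer
(excluding the planted edge row), statistical outliers among vegetation
returns are removed, and the cloud is thinned to at most one point per
1 cm voxel.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from shapely.geometry import Point, Polygon

logger = logging.getLogger(__name__)

# LAS-like classification codes
UNASSIGNED = 1
GROUND = 2
VEGETATION = 5
NOISE = 7

_REQUIRED_COLUMNS = ("x", "y", "z", "return_number", "number_of_returns")


@dataclass
class PointCloud:
    """Columnar 3-D returns for one plot and survey date.

    Coordinates are metres; ``z`` is raw elevation until
    :func:`classify_and_normalize` replaces it with height above ground.
    ``return_number`` runs 1..k top-down within each pulse and
    ``number_of_returns`` is k for every return of that pulse.
    """

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    return_number: np.ndarray
    number_of_returns: np.ndarray
    classification: np.ndarray | None = None
    plot_id: str | None = None
    doy: int | None = None
    normalized: bool = field(default=False)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        self.return_number = np.asarray(self.return_number, dtype=np.int32)
        self.number_of_returns = np.asarray(self.number_of_returns, dtype=np.int32)
        if self.classification is None:
            self.classification = np.full(self.x.size, UNASSIGNED, dtype=np.int32)
        else:
            self.classification = np.asarray(self.classification, dtype=np.int32)
        n = self.x.size
        for name in ("y", "z", "return_number", "number_of_returns", "classification"):
            if getattr(self, name).size != n:
                raise ValueError(f"column {name!r} has length != {n}")
        if n and not (
            np.isfinite(self.x).all()
            and np.isfinite(self.y).all()
            and np.isfinite(self.z).all()
        ):
            raise ValueError("non-finite coordinates in point cloud")
        if n:
            bad = (self.return_number < 1) | (self.return_number > self.number_of_returns)
            if bad.any():
                raise ValueError("return_number must satisfy 1 <= rn <= number_of_returns")

    def __len__(self) -> int:
        return int(self.x.size)

    def select(self, mask: np.ndarray) -> "PointCloud":
        """Row subset preserving metadata and input order."""
        return replace(
            self,
            x=self.x[mask],
            y=self.y[mask],
            z=self.z[mask],
            return_number=self.return_number[mask],
            number_of_returns=self.number_of_returns[mask],
            classification=self.classification[mask],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x": self.x,
                "y": self.y,
                "z": self.z,
                "return_number": self.return_number,
                "number_of_returns": self.number_of_returns,
                "classification": self.classification,
            }
        )

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, plot_id: str | None = None, doy: int | None = None
    ) -> "PointCloud":
        missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(
                f"point cloud table missing required column(s) {missing}; "
                "return metadata are required (fractional cover needs them)"
            )
        cls_col = df["classification"].to_numpy() if "classification" in df.columns else None
        return cls(
            x=df["x"].to_numpy(),
            y=df["y"].to_numpy(),
            z=df["z"].to_numpy(),
            return_number=df["return_number"].to_numpy(),
            number_of_returns=df["number_of_returns"].to_numpy(),
            classification=cls_col,
            plot_id=plot_id,
            doy=doy,
        )


@dataclass
class PlotPolygon:
    """Plot boundary ring with a signed buffer (negative = shrink)."""

    plot_id: str
    vertices: np.ndarray  # (n, 2) closed or open ring
    buffer_m: float = -0.5

    def polygon(self) -> Polygon:
        poly = Polygon(np.asarray(self.vertices, dtype=float))
        if not poly.is_valid or poly.area <= 0:
            raise ValueError(f"invalid plot polygon for {self.plot_id!r}")
        return poly

    def buffered(self) -> Polygon:
        poly = self.polygon()
        if self.buffer_m == 0:
            return poly
        out = poly.buffer(self.buffer_m, join_style="mitre")
        if out.is_empty or out.area <= 0:
            raise ValueError(
                f"buffer {self.buffer_m} m collapses plot polygon {self.plot_id!r}"
            )
        return out

    @classmethod
    def square(cls, plot_id: str, side_m: float = 10.0, origin: tuple[float, float] = (0.0, 0.0),
               buffer_m: float = -0.5) -> "PlotPolygon":
        x0, y0 = origin
        ring = np.array(
            [[x0, y0], [x0 + side_m, y0], [x0 + side_m, y0 + side_m], [x0, y0 + side_m]]
        )
        return cls(plot_id=plot_id, vertices=ring, buffer_m=buffer_m)


# ---------------------------------------------------------------------------
# I/O — columnar text only; the CSV dialect requires a header with at least
# x,y,z,return_number,number_of_returns (classification optional).
# ---------------------------------------------------------------------------

def read_point_cloud(path, fmt: str = "csv", plot_id: str | None = None,
                     doy: int | None = None) -> PointCloud:
    """Read a cloud from CSV (optionally gzip-compressed by extension).

    LAS/LAZ input is not supported by this build; convert to CSV upstream.
    """
    if fmt.lower() in ("las", "laz"):
        raise NotImplementedError("LAS/LAZ input is not supported; use CSV")
    if fmt.lower() != "csv":
        raise ValueError(f"unknown point-cloud format {fmt!r}")
    df = pd.read_csv(path)
    if df.empty:
        warnings.warn(f"empty point cloud file: {path}")
        return PointCloud(
            x=np.empty(0), y=np.empty(0), z=np.empty(0),
            return_number=np.empty(0, dtype=int),
            number_of_returns=np.empty(0, dtype=int),
            plot_id=plot_id, doy=doy,
        )
    return PointCloud.from_frame(df, plot_id=plot_id, doy=doy)


def write_point_cloud(cloud: PointCloud, path) -> None:
    cloud.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Conditioning stages
# ---------------------------------------------------------------------------

def classify_and_normalize(
    cloud: PointCloud,
    cell_m: float = 1.0,
    ground_tol: float = 0.25,
) -> PointCloud:
    """Estimate the ground surface and replace z by height above it.

    The ground surface is the per-cell lowest point on a ``cell_m`` grid,
    bilinearly interpolated between cell centres (empty cells filled from
    their nearest occupied cell).  Afterwards points with height
    <= ``ground_tol`` are classified ground, the rest vegetation; heights are
    clamped at 0 from below.  Adequate for the flat terrain this pipeline
    targets; steep terrain would need a proper progressive filter.
    """
    if len(cloud) == 0:
        raise ValueError("cannot normalize an empty cloud")
    if cell_m <= 0:
        raise ValueError("cell_m must be positive")

    x, y, z = cloud.x, cloud.y, cloud.z
    x0, y0 = x.min(), y.min()
    ix = np.floor((x - x0) / cell_m).astype(int)
    iy = np.floor((y - y0) / cell_m).astype(int)
    nx, ny = ix.max() + 1, iy.max() + 1

    grid = np.full((nx, ny), np.inf)
    np.minimum.at(grid, (ix, iy), z)

    if nx * ny == 1 or np.isfinite(grid).sum() == 1:
        surface_at_points = np.full(x.size, z.min())
    else:
        empty = ~np.isfinite(grid)
        if empty.any():
            # fill empty cells from the nearest occupied cell
            idx = ndimage.distance_transform_edt(
                empty, return_distances=False, return_indices=True
            )
            grid = grid[tuple(idx)]
        # bilinear interpolation at point positions, cell-centre anchored
        fx = np.clip((x - x0) / cell_m - 0.5, 0, nx - 1)
        fy = np.clip((y - y0) / cell_m - 0.5, 0, ny - 1)
        surface_at_points = ndimage.map_coordinates(
            grid, np.vstack([fx, fy]), order=1, mode="nearest"
        )

    height = np.maximum(z - surface_at_points, 0.0)
    classification = np.where(height <= ground_tol, GROUND, VEGETATION).astype(np.int32)
    out = replace(cloud, z=height, classification=classification)
    out.normalized = True
    return out


def clip_plot(cloud: PointCloud, polygon: PlotPolygon) -> PointCloud:
    """Retain points strictly inside the (negatively) buffered polygon."""
    region = polygon.buffered()
    if len(cloud) == 0:
        return cloud
    from shapely import contains_xy

    inside = contains_xy(region, cloud.x, cloud.y)  # strict: boundary excluded
    return cloud.select(inside)


def sor_filter(
    cloud: PointCloud,
    k: int = 30,
    quantile: float = 0.975,
    z_min: float = 0.25,
) -> PointCloud:
    """Statistical outlier removal on vegetation returns.

    For each point with z > ``z_min``, the mean Euclidean distance to its
    ``k`` nearest neighbours (among points with z > ``z_min``) is computed;
    points whose mean distance exceeds the ``quantile`` (linear-interpolation
    definition) of the mean-distance distribution are dropped.  Points at or
    below ``z_min`` pass through untouched.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0, 1)")
    veg = cloud.z > z_min
    n_veg = int(veg.sum())
    if n_veg <= k:
        warnings.warn(
            f"SOR pass-through: only {n_veg} points above {z_min} m (k={k})"
        )
        return cloud
    pts = np.column_stack([cloud.x[veg], cloud.y[veg], cloud.z[veg]])
    tree = cKDTree(pts)
    # query k+1 since the nearest neighbour of a point is itself
    dists, _ = tree.query(pts, k=k + 1)
    mean_d = dists[:, 1:].mean(axis=1)
    thresh = np.quantile(mean_d, quantile)  # type-7 / linear interpolation
    keep_veg = mean_d <= thresh
    keep = np.ones(len(cloud), dtype=bool)
    keep[np.flatnonzero(veg)[~keep_veg]] = False
    return cloud.select(keep)


def voxel_decimate(cloud: PointCloud, edge_m: float = 0.01) -> PointCloud:
    """Keep at most one point per occupied voxel.

    The voxel grid is anchored at the cloud's minimum corner; within a voxel
    the first point in input order survives (stable tie-break — the grid
    origin and tie rule matter because decimation and box counting are both
    origin-sensitive).
    """
    if edge_m <= 0:
        raise ValueError("edge_m must be positive")
    if len(cloud) == 0:
        return cloud
    idx = voxel_keys(cloud.x, cloud.y, cloud.z, edge_m)
    ny = idx[:, 1].max() + 1
    nz = idx[:, 2].max() + 1
    key = (idx[:, 0] * ny + idx[:, 1]) * nz + idx[:, 2]
    _, first_idx = np.unique(key, return_index=True)  # first in input order
    first = np.zeros(len(cloud), dtype=bool)
    first[first_idx] = True
    return cloud.select(first)


def voxel_keys(x: np.ndarray, y: np.ndarray, z: np.ndarray, edge_m: float) -> np.ndarray:
    """Integer voxel indices anchored at the cloud minimum corner, shape (n, 3)."""
    mins = np.array([x.min(), y.min(), z.min()])
    idx = np.floor(
        (np.column_stack([x, y, z]) - mins) / edge_m
    ).astype(np.int64)
    return idx


def condition_cloud(
    cloud: PointCloud,
    polygon: PlotPolygon,
    cell_m: float = 1.0,
    sor_k: int = 30,
    sor_quantile: float = 0.975,
    z_min: float = 0.25,
    voxel_edge_m: float = 0.01,
    normalize: bool = True,
) -> PointCloud:
    """Full conditioning chain: normalize -> clip -> SOR -> decimate."""
    out = classify_and_normalize(cloud, cell_m=cell_m) if normalize else cloud
    out = clip_plot(out, polygon)
    if len(out) == 0:
        logger.warning("plot %s doy %s: no points after clipping", cloud.plot_id, cloud.doy)
        return out
    out = sor_filter(out, k=sor_k, quantile=sor_quantile, z_min=z_min)
    out = voxel_decimate(out, edge_m=voxel_edge_m)
    return out
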