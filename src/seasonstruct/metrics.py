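"""Per-plot canopy structural metrics and their seasonal stability.

Three metrics per plot per survey:

* ``HH_CV`` — coefficient of variation of canopy height over 0.1 m digital
  canopy model (DCM) cells; horizontal heterogeneity of the canopy surface.
* ``FC`` — fractional plant cover: the fraction of emitted pulses intercepted
  by vegetation, weighting each vegetation return by the inverse of its
  return number.
* ``d_D`` — fractal dimension: the SMA slope of log Hill diversity of voxel
  occupancy against log inverse voxel edge size, over edges 0.1–2.25 m.

Seasonal structural stability (SS) of each metric is its inverse coefficient
of variation (mean/sd) over the repeated surveys of one growing season.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pointcloud import PointCloud

DEFAULT_SCALES = np.geomspace(0.1, 2.25, 12)


# ---------------------------------------------------------------------------
# Digital canopy model & HH_CV
# ---------------------------------------------------------------------------

def canopy_model(cloud: PointCloud, resolution_m: float = 0.1) -> np.ndarray:
    """DCM: grid of max normalized height per cell; empty cells are NaN."""
    if resolution_m <= 0:
        raise ValueError("resolution must be positive")
    if len(cloud) == 0:
        return np.full((0, 0), np.nan)
    x0, y0 = cloud.x.min(), cloud.y.min()
    ix = np.floor((cloud.x - x0) / resolution_m).astype(int)
    iy = np.floor((cloud.y - y0) / resolution_m).astype(int)
    grid = np.full((ix.max() + 1, iy.max() + 1), -np.inf)
    np.maximum.at(grid, (ix, iy), cloud.z)
    grid[~np.isfinite(grid)] = np.nan
    return grid


def canopy_height_cv(cloud: PointCloud, resolution_m: float = 0.1) -> float:
    """CV (sample sd / mean) of non-empty DCM cell heights."""
    dcm = canopy_model(cloud, resolution_m)
    heights = dcm[np.isfinite(dcm)]
    if heights.size < 2:
        raise ValueError("need >= 2 non-empty DCM cells for HH_CV")
    mean = heights.mean()
    if mean <= 0:
        raise ValueError("degenerate plot: mean canopy height is zero")
    return float(heights.std(ddof=1) / mean)


def max_canopy_height(cloud: PointCloud, resolution_m: float = 0.1) -> float:
    dcm = canopy_model(cloud, resolution_m)
    finite = dcm[np.isfinite(dcm)]
    return float(finite.max()) if finite.size else 0.0


# ---------------------------------------------------------------------------
# Fractional cover
# ---------------------------------------------------------------------------

def fractional_cover(cloud: PointCloud, z_min: float = 0.25) -> float:
    """Inverse-return-number weighted fraction of pulses hitting vegetation.

    FC = sum over returns with z > z_min of (1/return_number), divided by the
    pulse count.  Pulses are identified by their first returns
    (return_number == 1) since pulse IDs are not carried in the cloud.
    """
    n_pulses = int((cloud.return_number == 1).sum())
    if n_pulses == 0:
        raise ValueError("no first returns: cannot count pulses")
    veg = cloud.z > z_min
    weight = float((1.0 / cloud.return_number[veg]).sum())
    fc = weight / n_pulses
    if fc > 1.0:
        warnings.warn(f"FC weighting exceeded 1 ({fc:.4f}); clamping")
        fc = 1.0
    return fc


# ---------------------------------------------------------------------------
# Hill diversity and box counting
# ---------------------------------------------------------------------------

def hill_diversity(p: np.ndarray, q: float) -> float:
    """Hill number of order q for a proportion vector.

    ``D = (sum p_i^q)^(1/(1-q))`` for q != 1, with the Shannon limit
    ``exp(-sum p ln p)`` used when |q - 1| < 1e-6.  Zero entries are ignored;
    p is normalized internally.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty proportion vector")
    if (p < 0).any():
        raise ValueError("negative proportions")
    if q < 0:
        raise ValueError("Hill order q must be >= 0")
    p = p[p > 0]
    p = p / p.sum()
    if abs(q - 1.0) < 1e-6:
        return float(np.exp(-(p * np.log(p)).sum()))
    return float((p ** q).sum() ** (1.0 / (1.0 - q)))


@dataclass
class BoxCountCurve:
    scales: np.ndarray      # voxel edge sizes, m
    diversities: np.ndarray  # Hill diversity of voxel occupancy per scale
    q: float


def box_counting_curve(
    cloud: PointCloud, scales: np.ndarray | None = None, q: float = 0.999
) -> BoxCountCurve:
    """Hill diversity of voxel point shares across a sequence of edge sizes.

    Voxels are anchored at the cloud's minimum corner.  At q=0 the diversity
    is simply the occupied-voxel count, i.e. classic box counting.
    """
    if len(cloud) == 0:
        raise ValueError("empty cloud")
    scales = DEFAULT_SCALES if scales is None else np.asarray(scales, dtype=float)
    if (scales <= 0).any():
        raise ValueError("voxel edge sizes must be positive")
    mins = np.array([cloud.x.min(), cloud.y.min(), cloud.z.min()])
    pts = np.column_stack([cloud.x, cloud.y, cloud.z]) - mins
    divs = np.empty(scales.size)
    for i, s in enumerate(scales):
        idx = np.floor(pts / s).astype(np.int64)
        # pack 3-D indices into one integer key (exact, no collisions)
        ny = idx[:, 1].max() + 1
        nz = idx[:, 2].max() + 1
        key = (idx[:, 0] * ny + idx[:, 1]) * nz + idx[:, 2]
        _, counts = np.unique(key, return_counts=True)
        divs[i] = hill_diversity(counts / counts.sum(), q)
    return BoxCountCurve(scales=scales, diversities=divs, q=q)


@dataclass
class FractalFit:
    slope: float
    intercept: float
    r: float
    degenerate: bool = False


def sma_fit(x: np.ndarray, y: np.ndarray) -> FractalFit:
    """Standardized major axis fit: slope = sign(r) * sd(y)/sd(x)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise ValueError("SMA needs >= 3 paired points")
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if sx == 0:
        raise ValueError("zero variance in x")
    if sy == 0:
        # uniform response across scales (e.g. one occupied voxel everywhere)
        return FractalFit(slope=0.0, intercept=float(y.mean()), r=0.0, degenerate=True)
    r = float(np.corrcoef(x, y)[0, 1])
    slope = math.copysign(sy / sx, r if r != 0 else 1.0)
    intercept = float(y.mean() - slope * x.mean())
    return FractalFit(slope=float(slope), intercept=intercept, r=r)


def fractal_dimension(
    cloud: PointCloud, q: float = 0.999, scales: np.ndarray | None = None
) -> float:
    """d_D: SMA slope of log D against log(1/S) over the scale sequence."""
    curve = box_counting_curve(cloud, scales=scales, q=q)
    fit = sma_fit(np.log(1.0 / curve.scales), np.log(curve.diversities))
    return fit.slope


# ---------------------------------------------------------------------------
# Seasonal structural stability
# ---------------------------------------------------------------------------

def structural_stability(values) -> float:
    """SS = mean/sd (sample sd) of a metric across the season's surveys.

    Returns ``inf`` for a perfectly stable (zero-variance) series.  Missing
    values are an error: SS is only defined on complete survey series.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("SS needs >= 2 surveys")
    if not np.isfinite(values).all():
        raise ValueError("SS requires a complete series (no missing surveys)")
    sd = values.std(ddof=1)
    if sd == 0:
        return float("inf")
    return float(values.mean() / sd)


# ---------------------------------------------------------------------------
# Per-plot series & inclusion rules
# ---------------------------------------------------------------------------

def metric_series(
    clouds: dict[int, PointCloud],
    resolution_m: float = 0.1,
    z_min: float = 0.25,
    q: float = 0.999,
    scales: np.ndarray | None = None,
) -> pd.DataFrame:
    """Tidy table of (doy, hh_cv, fc, d_D, max_height) for one plot."""
    rows = []
    for doy in sorted(clouds):
        cloud = clouds[doy]
        rows.append(
            {
                "plot_id": cloud.plot_id,
                "doy": doy,
                "hh_cv": canopy_height_cv(cloud, resolution_m),
                "fc": fractional_cover(cloud, z_min),
                "d_D": fractal_dimension(cloud, q=q, scales=scales),
                "max_height": max_canopy_height(cloud, resolution_m),
            }
        )
    return pd.DataFrame(rows)


def stability_table(series: pd.DataFrame) -> pd.DataFrame:
    """Per-plot SS of each metric from a tidy per-plot-per-doy table."""
    records = []
    for plot_id, sub in series.groupby("plot_id"):
        records.append(
            {
                "plot_id": plot_id,
                "n_surveys": len(sub),
                "ss_hhcv": structural_stability(sub["hh_cv"].to_numpy()),
                "ss_fc": structural_stability(sub["fc"].to_numpy()),
                "ss_dD": structural_stability(sub["d_D"].to_numpy()),
            }
        )
    return pd.DataFrame(records)


def plot_inclusion_filter(
    series: pd.DataFrame,
    min_height_m: float = 1.5,
    planting_year_before: int = 2019,
    mean_planting_year: float | None = None,
    replanted: bool = False,
) -> bool:
    """Keep a plot only if its canopy tops ``min_height_m`` at every survey,
    it was (on average) planted before ``planting_year_before``, and it was
    not replanted during the study year."""
    if series.empty:
        return False
    tall_enough = bool((series["max_height"] > min_height_m).all())
    old_enough = True
    if mean_planting_year is not None:
        old_enough = mean_planting_year < planting_year_before
    return tall_enough and old_enough and not replanted
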