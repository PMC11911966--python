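"""Ground-based productivity: tree/plot wood volume, AWP, NBE and its
complementarity/selection partition.

Stem volume treats the stem as a conoid (paraboloid-like solid of
revolution): for trees up to breast height (1.3 m)

    V = H * pi * D_rc^2 / 12,

and for taller trees the conoid frustum below 1.3 m plus a conoid above it

    V = 1.3 * (D_rc^2 + D_rc*DBH + DBH^2) * pi / 12
        + (H - 1.3) * pi * DBH^2 / 12,

with D_rc the root-collar diameter and DBH the diameter at breast height
(metres throughout).

Annual wood productivity (AWP, m^3 yr^-1 ha^-1) is the volume increment
between two consecutive inventories divided by the interval (365 d/yr) and
the effective plot area (0.0081 ha after removing the edge row).  The net
biodiversity effect is NBE = AWP_plot - sum_i p_i * AWP_i with AWP_i the
mean monoculture AWP of species i and p_i its planted proportion, and is
additively partitioned into complementarity and selection effects following
Loreau & Hector's relative-yield algebra.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

BREAST_HEIGHT_M = 1.3
PLOT_AREA_HA = 0.0081  # 9 m x 9 m effective area after edge-row removal
DAYS_PER_YEAR = 365.0


def tree_volume(
    height_m: float,
    d_rc_m: float,
    dbh_m: float | None = None,
    alive: bool = True,
) -> float:
    """Stem volume (m^3) from height and diameter measurements."""
    if not alive or height_m == 0:
        return 0.0
    if height_m < 0 or d_rc_m < 0:
        raise ValueError("negative measurements")
    if height_m <= BREAST_HEIGHT_M:
        return height_m * np.pi * d_rc_m**2 / 12.0
    if dbh_m is None or not np.isfinite(dbh_m):
        raise ValueError(f"tree of height {height_m} m > 1.3 m lacks DBH")
    frustum = BREAST_HEIGHT_M * (d_rc_m**2 + d_rc_m * dbh_m + dbh_m**2) * np.pi / 12.0
    top = (height_m - BREAST_HEIGHT_M) * np.pi * dbh_m**2 / 12.0
    return float(frustum + top)


def tree_volume_vec(
    height_m: np.ndarray,
    d_rc_m: np.ndarray,
    dbh_m: np.ndarray,
    alive: np.ndarray,
) -> np.ndarray:
    """Vectorized :func:`tree_volume` (NaN DBH on a tall tree raises)."""
    h = np.asarray(height_m, dtype=float)
    d = np.asarray(d_rc_m, dtype=float)
    dbh = np.asarray(dbh_m, dtype=float)
    live = np.asarray(alive, dtype=bool)
    tall = live & (h > BREAST_HEIGHT_M)
    if np.isnan(dbh[tall]).any():
        raise ValueError("tree taller than 1.3 m lacks DBH")
    short_v = h * np.pi * d**2 / 12.0
    with np.errstate(invalid="ignore"):
        tall_v = (
            BREAST_HEIGHT_M * (d**2 + d * dbh + dbh**2) * np.pi / 12.0
            + (h - BREAST_HEIGHT_M) * np.pi * dbh**2 / 12.0
        )
    v = np.where(h > BREAST_HEIGHT_M, tall_v, short_v)
    v[~live] = 0.0
    return v


def _with_volumes(trees: pd.DataFrame, year1: int, year2: int,
                  plot_area_ha: float, interval_days: float) -> pd.DataFrame:
    interval_years = interval_days / DAYS_PER_YEAR
    df = trees.copy()
    for year, col in ((year1, "v1"), (year2, "v2")):
        alive = (
            df[f"alive_{year}"].to_numpy()
            if f"alive_{year}" in df.columns
            else np.ones(len(df), dtype=bool)
        )
        dbh = (
            df[f"dbh_{year}"].to_numpy()
            if f"dbh_{year}" in df.columns
            else np.full(len(df), np.nan)
        )
        df[col] = tree_volume_vec(
            df[f"height_{year}"].to_numpy(), df[f"d_rc_{year}"].to_numpy(), dbh, alive
        )
    df["awp_tree"] = (df["v2"] - df["v1"]) / interval_years / plot_area_ha
    return df


def plot_volume_and_awp(
    trees: pd.DataFrame,
    year1: int,
    year2: int,
    plot_area_ha: float = PLOT_AREA_HA,
    interval_days: float = DAYS_PER_YEAR,
) -> pd.DataFrame:
    """Per-plot volume (both years) and AWP from a wide per-tree table.

    ``trees`` has one row per interior tree with columns ``plot_id``,
    ``species_id`` and per-year ``height_<yr>``, ``d_rc_<yr>``, ``dbh_<yr>``,
    ``alive_<yr>``.  Edge-row trees must already be excluded.  Mortality
    contributes a negative increment (year-2 volume of a dead tree is 0).
    """
    if interval_days <= 0:
        raise ValueError("interval must be positive")
    df = _with_volumes(trees, year1, year2, plot_area_ha, interval_days)

    out = (
        df.groupby("plot_id")
        .agg(
            volume_y1=("v1", "sum"),
            volume_y2=("v2", "sum"),
            awp_plot=("awp_tree", "sum"),
            n_trees=("v1", "size"),
        )
        .reset_index()
    )
    # plot volume on a per-hectare basis, matching AWP units
    out["volume_y1_ha"] = out["volume_y1"] / plot_area_ha
    out["volume_y2_ha"] = out["volume_y2"] / plot_area_ha
    return out


def species_awp(
    trees: pd.DataFrame,
    year1: int,
    year2: int,
    plot_area_ha: float = PLOT_AREA_HA,
    interval_days: float = DAYS_PER_YEAR,
) -> pd.DataFrame:
    """Per-plot per-species AWP (needed for the Loreau-Hector partition)."""
    df = _with_volumes(trees, year1, year2, plot_area_ha, interval_days)
    return (
        df.groupby(["plot_id", "species_id"])["awp_tree"].sum().rename("awp").reset_index()
    )


def monoculture_means(
    plot_awp: pd.DataFrame,
    design: pd.DataFrame,
    planting_year_before: int = 2019,
) -> pd.Series:
    """Mean monoculture AWP_plot per species over qualifying monocultures.

    ``design`` needs columns plot_id, species_id, proportion, planting_year,
    replanted (one row per species per plot).  Monocultures planted in or
    after ``planting_year_before``, or replanted, are excluded.
    """
    n_species = design.groupby("plot_id")["species_id"].nunique()
    monos = design[design["plot_id"].map(n_species) == 1]
    monos = monos[
        (monos["planting_year"] < planting_year_before) & (~monos["replanted"].astype(bool))
    ]
    merged = monos.merge(plot_awp[["plot_id", "awp_plot"]], on="plot_id")
    return merged.groupby("species_id")["awp_plot"].mean()


def expected_awp(proportions: pd.Series, mono_means: pd.Series) -> float:
    """Expected mixture AWP: sum_i p_i * mean monoculture AWP_i."""
    missing = [s for s in proportions.index if s not in mono_means.index]
    if missing:
        raise ValueError(f"no monoculture mean for species: {missing}")
    return float((proportions * mono_means.reindex(proportions.index)).sum())


def nbe(observed_awp: float, expected: float) -> float:
    """Net biodiversity effect: observed minus expected plot productivity."""
    if not (np.isfinite(observed_awp) and np.isfinite(expected)):
        raise ValueError("NBE needs finite observed and expected AWP")
    return float(observed_awp - expected)


def loreau_hector_partition(
    observed: np.ndarray | pd.Series,
    mono: np.ndarray | pd.Series,
    proportions: np.ndarray | pd.Series,
) -> tuple[float, float]:
    """Additive partition of NBE into complementarity and selection effects.

    With relative yield deviations dRY_i = Y_i / M_i - p_i,

        CE = n * mean(dRY) * mean(M)
        SE = n * cov_pop(dRY, M)

    so that CE + SE = sum Y_i - sum p_i M_i = NBE exactly (population
    covariance, divide-by-n, keeps the identity exact).  Species with zero
    monoculture mean are excluded with a warning.
    """
    y = np.asarray(observed, dtype=float)
    m = np.asarray(mono, dtype=float)
    p = np.asarray(proportions, dtype=float)
    if not (y.size == m.size == p.size) or y.size == 0:
        raise ValueError("observed, mono and proportions must be equal-length, nonempty")
    ok = m > 0
    if not ok.all():
        warnings.warn("excluding species with zero monoculture mean from partition")
        y, m, p = y[ok], m[ok], p[ok]
        if y.size == 0:
            raise ValueError("no species with positive monoculture mean")
    n = y.size
    d_ry = y / m - p
    ce = n * d_ry.mean() * m.mean()
    se = n * float(np.mean((d_ry - d_ry.mean()) * (m - m.mean())))
    return float(ce), float(se)


def productivity_table(
    trees: pd.DataFrame,
    design: pd.DataFrame,
    year1: int,
    year2: int,
    plot_area_ha: float = PLOT_AREA_HA,
    interval_days: float = DAYS_PER_YEAR,
) -> pd.DataFrame:
    """Per-plot volume, AWP, expected AWP, NBE, CE and SE.

    Monocultures carry NaN for NBE/CE/SE; plots flagged replanted are
    excluded from the NBE columns (volume and AWP are still reported).
    """
    plot_awp = plot_volume_and_awp(trees, year1, year2, plot_area_ha, interval_days)
    sp_awp = species_awp(trees, year1, year2, plot_area_ha, interval_days)
    mono = monoculture_means(plot_awp, design)

    comp_by_plot = {
        pid: sub.set_index("species_id") for pid, sub in design.groupby("plot_id")
    }
    sp_by_plot = dict(tuple(sp_awp.groupby("plot_id")))
    rows = []
    for _, rec in plot_awp.iterrows():
        pid = rec["plot_id"]
        comp = comp_by_plot.get(pid, pd.DataFrame())
        out = dict(rec)
        out["richness_planted"] = len(comp)
        out["nbe"] = out["ce"] = out["se"] = out["awp_expected"] = np.nan
        replanted = bool(comp["replanted"].astype(bool).any()) if len(comp) else False
        out["replanted"] = replanted
        if len(comp) >= 2 and not replanted:
            try:
                exp = expected_awp(comp["proportion"], mono)
            except ValueError:
                rows.append(out)
                continue
            obs_sp = (
                sp_by_plot.get(pid, pd.DataFrame(columns=["species_id", "awp"]))
                .set_index("species_id")["awp"]
                .reindex(comp.index)
                .fillna(0.0)
            )
            ce, se = loreau_hector_partition(
                obs_sp.to_numpy(),
                mono.reindex(comp.index).to_numpy(),
                comp["proportion"].to_numpy(),
            )
            out["awp_expected"] = exp
            out["nbe"] = nbe(rec["awp_plot"], exp)
            out["ce"], out["se"] = ce, se
        rows.append(out)
    return pd.DataFrame(rows)
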