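"""Statistical layer: transformed analysis tables, cross-sectional
regressions per survey date, mixed models with plots nested in blocks,
latent-variable SEMs, and the end-to-end pipeline.

Strictly positive structural metrics, stabilities, volumes and diversity
values are natural-log transformed before regression; NBE (which can be
negative) never is.  Significance is two-sided at 0.05 with no
multiple-testing correction — each model is reported on its own.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as smapi
import statsmodels.formula.api as smf

from . import biodiversity, inventory, metrics, synthetic
from .pointcloud import PlotPolygon, condition_cloud
from .sem import DEFAULT_SEM_SPEC, SemModel

logger = logging.getLogger(__name__)

LOG_COLUMNS = (
    "hh_cv", "fc", "d_D", "ss_hhcv", "ss_fc", "ss_dD",
    "volume_y2_ha", "richness", "pd", "fd",
)


def log_transform(table: pd.DataFrame, columns=LOG_COLUMNS) -> pd.DataFrame:
    """Natural log on strictly positive flagged columns; non-positive or
    non-finite entries become NaN (dropped listwise downstream)."""
    out = table.copy()
    for col in columns:
        if col in out.columns:
            vals = out[col].to_numpy(dtype=float)
            with np.errstate(divide="ignore", invalid="ignore"):
                out[col] = np.where(np.isfinite(vals) & (vals > 0), np.log(vals), np.nan)
    return out


def fit_cross_sections(
    table: pd.DataFrame,
    response: str,
    predictor: str,
    by: str = "doy",
    min_n: int = 10,
) -> pd.DataFrame:
    """Per-date OLS of response on predictor; tidy slopes, R^2 and p."""
    rows = []
    for key, sub in table.groupby(by):
        sub = sub[[response, predictor]].dropna()
        if len(sub) < min_n:
            continue
        x = sub[predictor].to_numpy()
        if np.ptp(x) == 0:
            raise ValueError(f"zero variance in predictor {predictor!r} at {by}={key}")
        X = smapi.add_constant(x)
        fit = smapi.OLS(sub[response].to_numpy(), X).fit()
        rows.append(
            {
                by: key, "n": len(sub),
                "slope": fit.params[1], "intercept": fit.params[0],
                "r2": fit.rsquared, "pvalue": fit.pvalues[1],
            }
        )
    return pd.DataFrame(rows)


def fit_mixed_model(
    table: pd.DataFrame,
    response: str,
    predictor: str,
    doy_col: str = "doy",
    plot_col: str = "plot_id",
    block_col: str = "block",
):
    """Mixed model: response ~ predictor * DOY with random intercepts for
    plots nested in blocks.

    DOY enters as a continuous covariate (rescaled to [0, 1] across its
    range for a well-conditioned design).  If the nested fit is singular the
    model falls back to a plot-only random intercept (logged).  Returns the
    fitted statsmodels results plus a tidy fixed-effects frame.
    """
    df = table[[response, predictor, doy_col, plot_col, block_col]].dropna().copy()
    if df[response].nunique() <= 1:
        raise ValueError(f"response {response!r} is constant: degenerate fit")
    if df[block_col].nunique() < 2:
        raise ValueError("need >= 2 blocks")
    span = np.ptp(df[doy_col].to_numpy())
    df["_doy"] = (df[doy_col] - df[doy_col].min()) / (span if span else 1.0)
    formula = f"{response} ~ {predictor} * _doy"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = smf.mixedlm(
                formula, df, groups=df[block_col],
                re_formula="1",
                vc_formula={"plot": f"0 + C({plot_col})"},
            )
            fit = model.fit(reml=True)
            singular = not np.isfinite(fit.bse.to_numpy()).all()
        except (np.linalg.LinAlgError, ValueError):
            singular = True
            fit = None
        if singular:
            logger.warning("nested random effects singular; plot-only fallback")
            model = smf.mixedlm(formula, df, groups=df[plot_col], re_formula="1")
            fit = model.fit(reml=True)
    fe = pd.DataFrame(
        {
            "term": fit.fe_params.index,
            "estimate": fit.fe_params.to_numpy(),
            "se": fit.bse.loc[fit.fe_params.index].to_numpy(),
            "pvalue": fit.pvalues.loc[fit.fe_params.index].to_numpy(),
        }
    )
    fe["term"] = fe["term"].str.replace("_doy", "doy", regex=False)
    return fit, fe


def fit_sem(table: pd.DataFrame, ss_metric: str = "ss_dD", spec: str | None = None):
    """SEM with latent Diversity and Variability predicting the chosen SS
    metric and NBE.  See :mod:`seasonstruct.sem` for the estimator."""
    if ss_metric not in ("ss_hhcv", "ss_fc", "ss_dD"):
        raise ValueError(f"unknown SS metric {ss_metric!r}")
    model_spec = (spec or DEFAULT_SEM_SPEC).replace("ss ~", f"{ss_metric} ~").replace(
        "~ ss +", f"~ {ss_metric} +"
    )
    return SemModel(table, model_spec).fit()


# ---------------------------------------------------------------------------
# Table assembly
# ---------------------------------------------------------------------------

def surviving_communities(trees: pd.DataFrame, year: int) -> dict[str, list[str]]:
    """Species present per plot after mortality (interior trees only)."""
    alive = trees[trees[f"alive_{year}"].astype(bool) & trees["interior"]]
    return {
        pid: sorted(sub["species_id"].unique())
        for pid, sub in alive.groupby("plot_id")
    }


def build_analysis_table(
    stability: pd.DataFrame,
    productivity: pd.DataFrame,
    diversity: pd.DataFrame,
    design: synthetic.ExperimentDesign,
    pool: synthetic.SpeciesPool,
    series: pd.DataFrame | None = None,
    min_height_m: float = 1.5,
) -> pd.DataFrame:
    """One row per plot: SS metrics, productivity/NBE, diversity and
    variability, planted angiosperm proportion and block.

    Plots failing the inclusion rules (canopy <= ``min_height_m`` at any
    survey, mean planting year >= 2019, or replanted) are dropped.
    """
    tab = stability.merge(productivity, on="plot_id", how="inner")
    tab = tab.merge(diversity, on="plot_id", how="left")
    tab = tab.merge(
        design.plots[["plot_id", "block", "richness", "planting_year", "replanted"]],
        on="plot_id", how="left", suffixes=("", "_design"),
    )
    habit = pool.table["leaf_habit"]
    prop_ang = {}
    for pid in tab["plot_id"]:
        props = design.proportions(pid)
        prop_ang[pid] = float(
            props[habit.reindex(props.index) == "deciduous"].sum()
        )
    tab["prop_angiosperm"] = tab["plot_id"].map(prop_ang)

    keep = (~tab["replanted"].astype(bool)) & (tab["planting_year"] < 2019)
    if series is not None:
        tall = series.groupby("plot_id")["max_height"].min() > min_height_m
        keep &= tab["plot_id"].map(tall).fillna(False)
    return tab[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

DEFAULT_CONFIG = {
    "seed": 0,
    "n_species": 12,
    "n_evergreen": 4,
    "n_blocks": 3,
    "plots_per_richness": 2,
    "mixtures_per_richness": 12,
    "doys": list(synthetic.DEFAULT_DOYS),
    "density": 50.0,
    "noise_fraction": 0.001,
    "complementarity_strength": 0.5,
    "mortality_rate": 0.05,
    "phenology_jitter_sd": 6.0,
    "q": 0.999,
    "run_sem": True,
    "run_mixed": True,
    "ss_metric": "ss_dD",
    "clouds_mixtures_only": False,
    "out_dir": None,
}


def run_pipeline(config: dict | None = None) -> dict:
    """Simulate -> condition -> metrics -> SS -> inventory -> diversity ->
    models; returns a dict of tidy tables and fitted results.

    Every stage failure is re-raised with a stage label.  If
    ``config["out_dir"]`` is set, tables and a JSON report are written there
    (deterministic content for a fixed seed).
    """
    cfg = dict(DEFAULT_CONFIG)
    if config:
        cfg.update(config)
    seed = int(cfg["seed"])

    def stage(name):
        logger.info("pipeline stage: %s", name)
        return name

    out: dict = {"config": cfg}
    current = stage("simulate")
    try:
        pool = synthetic.generate_species_pool(
            cfg["n_species"], cfg["n_evergreen"], seed=seed
        )
        design = synthetic.generate_design(
            pool, cfg["n_blocks"], cfg["plots_per_richness"],
            cfg["mixtures_per_richness"], seed=seed,
        )
        trees, truth = synthetic.generate_inventories(
            design, pool,
            complementarity_strength=cfg["complementarity_strength"],
            mortality_rate=cfg["mortality_rate"],
            phenology_jitter_sd=cfg["phenology_jitter_sd"], seed=seed,
        )
        plot_ids = None
        if cfg["clouds_mixtures_only"]:
            plot_ids = design.plots.loc[design.plots["richness"] > 1, "plot_id"]
        clouds = synthetic.generate_point_cloud_series(
            design, pool, trees, doys=cfg["doys"], density=cfg["density"],
            noise_fraction=cfg["noise_fraction"], seed=seed, plot_ids=plot_ids,
        )

        current = stage("condition+metrics")
        poly = PlotPolygon.square("plot", side_m=synthetic.PLOT_SIDE_M, buffer_m=-0.5)
        rows = []
        for (pid, doy), cloud in clouds.items():
            cleaned = condition_cloud(cloud, poly, normalize=False)
            if len(cleaned) == 0:
                continue
            rows.append(
                {
                    "plot_id": pid, "doy": doy,
                    "hh_cv": metrics.canopy_height_cv(cleaned),
                    "fc": metrics.fractional_cover(cleaned),
                    "d_D": metrics.fractal_dimension(cleaned, q=cfg["q"]),
                    "max_height": metrics.max_canopy_height(cleaned),
                }
            )
        series = pd.DataFrame(rows)
        stability = metrics.stability_table(series)

        current = stage("inventory")
        interior = trees[trees["interior"]]
        productivity = inventory.productivity_table(
            interior, design.design_table(), 2021, 2022
        )

        current = stage("biodiversity")
        communities = surviving_communities(trees, 2022)
        diversity = biodiversity.community_metrics(
            communities, pool.tree, pool.traits, pool.taxonomy
        )

        current = stage("analysis-table")
        table = build_analysis_table(
            stability, productivity, diversity, design, pool, series=series
        )
        table_log = log_transform(table)
        series_log = log_transform(
            series.merge(
                table[["plot_id", "volume_y2_ha", "richness", "pd", "fd"]],
                on="plot_id",
            )
        )

        current = stage("models")
        cross = fit_cross_sections(series_log, "fc", "volume_y2_ha")
        mixed_fe = pd.DataFrame()
        if cfg["run_mixed"]:
            _, mixed_fe = fit_mixed_model(
                series_log.merge(table[["plot_id", "block"]], on="plot_id"),
                "fc", "volume_y2_ha",
            )
        nbe_vs_ss = fit_cross_sections(
            table_log.assign(_one=1), "nbe", cfg["ss_metric"], by="_one", min_n=5
        )
        sem_res = None
        if cfg["run_sem"]:
            sem_table = table_log.rename(columns={"var_taxo": "var_taxo"})
            sem_res = fit_sem(sem_table, cfg["ss_metric"])
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {current!r}: {exc}") from exc

    out.update(
        pool=pool, design=design, trees=trees, truth=truth,
        series=series, stability=stability, productivity=productivity,
        diversity=diversity, table=table, table_log=table_log,
        cross_sections=cross, mixed_effects=mixed_fe,
        nbe_vs_ss=nbe_vs_ss, sem=sem_res,
    )

    if cfg.get("out_dir"):
        _write_report(out, Path(cfg["out_dir"]))
    return out


def _write_report(out: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    for name in ("series", "stability", "productivity", "diversity", "table"):
        out[name].to_csv(out_dir / f"{name}.csv", index=False)
    report = {
        "n_plots_analyzed": int(len(out["table"])),
        "mean_nbe": float(out["table"]["nbe"].mean(skipna=True)),
        "mean_ce": float(out["table"]["ce"].mean(skipna=True)),
        "mean_se": float(out["table"]["se"].mean(skipna=True)),
        "nbe_vs_ss": out["nbe_vs_ss"].to_dict(orient="records"),
        "cross_sections": out["cross_sections"].to_dict(orient="records"),
        "mixed_effects": out["mixed_effects"].to_dict(orient="records"),
    }
    if out["sem"] is not None:
        report["sem_rsquared"] = out["sem"].rsquared
        report["sem_paths"] = out["sem"].paths.to_dict(orient="records")
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=float)
    out["truth"].to_json(out_dir / "truth.json")
    _write_figures(out, out_dir)


def _write_figures(out: dict, out_dir: Path) -> None:
    """Diagnostic figures: seasonal metric trajectories and NBE vs SS."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    series, table = out["series"], out["table"]
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5), constrained_layout=True)
    for ax, col, label in zip(axes, ("hh_cv", "fc", "d_D"),
                              ("HH$_{CV}$", "FC", "$d_D$")):
        for _, sub in series.groupby("plot_id"):
            ax.plot(sub["doy"], sub[col], color="0.6", lw=0.5, alpha=0.5)
        ax.set_xlabel("DOY")
        ax.set_ylabel(label)
    fig.savefig(out_dir / "metric_seasonality.png", dpi=120)
    plt.close(fig)

    ss_metric = out["config"]["ss_metric"]
    mix = table.dropna(subset=["nbe", ss_metric])
    fig, ax = plt.subplots(figsize=(4.2, 3.5), constrained_layout=True)
    ax.scatter(np.log(mix[ss_metric]), mix["nbe"], s=14,
               c=mix["prop_angiosperm"], cmap="viridis")
    ax.set_xlabel(f"log {ss_metric}")
    ax.set_ylabel("NBE (m$^3$ yr$^{-1}$ ha$^{-1}$)")
    fig.savefig(out_dir / "nbe_vs_stability.png", dpi=120)
    plt.close(fig)
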