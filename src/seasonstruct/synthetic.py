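"""Synthetic tree-diversity experiment: species pool, design, inventories
and per-plot per-survey point clouds.

The generator emulates a young common-garden diversity experiment on flat
ground: 100 m^2 plots planted on a 1 m grid with 12 species (a deciduous
angiosperm clade and an evergreen gymnosperm clade), replicated monocultures
plus 2-, 4-, 6- and 12-species mixtures in blocks, two consecutive annual
inventories, and repeated LiDAR-like surveys across one growing season
(default DOYs 100-297).

Two mechanisms are injected so downstream analyses have something to
recover:

* a *complementarity multiplier* on growth that increases with the planted
  community's functional variability (zero in monocultures), producing
  overyielding in variable mixtures; and
* deciduous foliage scaled by a smooth double-sigmoid phenology curve of
  DOY (evergreen foliage constant), so mixtures of leaf habits have more
  seasonally stable cover than deciduous monocultures.

Deciduous crowns keep a woody-return floor out of leaf so bare branches are
still visible to the scanner, as they are in reality.

All randomness flows from one master seed; per-plot per-survey streams are
derived by hashing (plot_id, doy) so any single cloud can be regenerated in
isolation.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .biodiversity import functional_dendrogram, variability_psv
from .pointcloud import GROUND, NOISE, VEGETATION, PointCloud

DEFAULT_DOYS = (100, 138, 163, 188, 215, 250, 261, 297)
RICHNESS_LEVELS = (1, 2, 4, 6, 12)
PLOT_SIDE_M = 10.0
TREE_SPACING_M = 1.0
EDGE_BUFFER_M = 0.5
MAX_RETURNS = 3

TRAIT_COLUMNS = ["wood_density", "lma", "max_height", "rgr", "shade_tolerance"]


@dataclass
class SpeciesPool:
    """Species-level parameters: traits, phenology, crown geometry, growth."""

    table: pd.DataFrame           # index species_id
    tree: dendropy.Tree           # ultrametric phylogeny
    taxonomy: pd.DataFrame        # order/family/genus per species

    @property
    def species(self) -> list[str]:
        return list(self.table.index)

    @property
    def traits(self) -> pd.DataFrame:
        return self.table[TRAIT_COLUMNS]


@dataclass
class ExperimentDesign:
    """Plot layout and planted composition."""

    plots: pd.DataFrame        # plot_id, block, richness, planting_year, replanted
    composition: pd.DataFrame  # plot_id, species_id, proportion

    def proportions(self, plot_id: str) -> pd.Series:
        sub = self.composition[self.composition["plot_id"] == plot_id]
        return sub.set_index("species_id")["proportion"]

    def design_table(self) -> pd.DataFrame:
        """One row per species per plot, joined with plot metadata (the
        layout the inventory module consumes)."""
        return self.composition.merge(self.plots, on="plot_id")


@dataclass
class SimulationTruth:
    """Ground truth stored alongside outputs for parameter recovery."""

    seed: int
    complementarity_strength: float
    mortality_rate: float
    noise_fraction: float
    plot_multiplier: dict[str, float] = field(default_factory=dict)
    plot_var_func: dict[str, float] = field(default_factory=dict)
    plot_asynchrony: dict[str, float] = field(default_factory=dict)
    plot_phenology_offsets: dict[str, dict[str, float]] = field(default_factory=dict)
    phenology: dict[str, dict] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1, default=float)


def _stream(seed: int, *keys) -> np.random.Generator:
    """Deterministic child RNG from the master seed and string/int keys."""
    parts = [int(seed) & 0x7FFFFFFF]
    for k in keys:
        if isinstance(k, str):
            parts.append(zlib.crc32(k.encode()))
        else:
            parts.append(int(k) & 0xFFFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(parts))


# ---------------------------------------------------------------------------
# Species pool
# ---------------------------------------------------------------------------

def _random_ultrametric(labels: list[str], depth: float, rng: np.random.Generator) -> str:
    """Random ultrametric subtree newick (without trailing ';'), coalescent-
    style: lineages merge pairwise at increasing heights below ``depth``."""
    n = len(labels)
    if n == 1:
        return f"{labels[0]}:{depth:.10g}"
    heights = np.sort(rng.uniform(0.1 * depth, 0.9 * depth, size=n - 1))
    nodes = [(lab, 0.0) for lab in labels]
    for h in heights:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        sj, hj = nodes.pop(j)
        si, hi = nodes.pop(i)
        nodes.append((f"({si}:{h - hi:.10g},{sj}:{h - hj:.10g})", float(h)))
    s, h = nodes[0]
    return f"{s}:{depth - h:.10g}"


def _brownian_traits(tree: dendropy.Tree, n_traits: int, rng: np.random.Generator,
                     noise: float = 0.4) -> pd.DataFrame:
    """Standard-normal-ish traits evolved by Brownian motion on the tree,
    plus independent noise (partial phylogenetic autocorrelation)."""
    values: dict[int, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            values[id(node)] = np.zeros(n_traits)
        else:
            el = node.edge.length or 0.0
            values[id(node)] = values[id(node.parent_node)] + rng.normal(
                0.0, np.sqrt(max(el, 1e-9)), size=n_traits
            )
    rows = {}
    for leaf in tree.leaf_node_iter():
        rows[leaf.taxon.label] = values[id(leaf)] + rng.normal(0, noise, size=n_traits)
    return pd.DataFrame.from_dict(rows, orient="index")


def generate_species_pool(
    n_species: int = 12,
    n_evergreen: int = 4,
    seed: int = 0,
) -> SpeciesPool:
    """Species pool with an ultrametric phylogeny whose deepest split
    separates the evergreen from the deciduous clade."""
    if n_species < 2:
        raise ValueError("need at least 2 species")
    if not 0 < n_evergreen < n_species:
        raise ValueError("need at least one evergreen and one deciduous species")
    rng = _stream(seed, "pool")

    ever = [f"EG{i+1:02d}" for i in range(n_evergreen)]
    decid = [f"DC{i+1:02d}" for i in range(n_species - n_evergreen)]
    clade_depth = 0.6  # deep split at depth 1.0
    newick = (
        "(" + _random_ultrametric_or_tip(ever, clade_depth, rng, 1.0)
        + "," + _random_ultrametric_or_tip(decid, clade_depth, rng, 1.0) + ");"
    )
    tree = dendropy.Tree.get(data=newick, schema="newick")

    raw = _brownian_traits(tree, len(TRAIT_COLUMNS), rng)
    raw = (raw - raw.mean()) / raw.std(ddof=1).replace(0, 1.0)
    species = ever + decid
    raw = raw.loc[species]
    is_ever = np.array([s in ever for s in species])

    table = pd.DataFrame(index=pd.Index(species, name="species_id"))
    table["leaf_habit"] = np.where(is_ever, "evergreen", "deciduous")
    # traits on realistic scales; leaf habit shifts LMA, RGR and shade tolerance
    table["wood_density"] = np.clip(0.48 + 0.08 * raw[0], 0.3, 0.75)
    table["lma"] = np.clip(120 + 40 * raw[1] + np.where(is_ever, 80, 0), 40, 350)
    table["max_height"] = np.clip(22 + 4 * raw[2], 12, 35)
    table["rgr"] = np.clip(0.30 + 0.08 * raw[3], 0.08, 0.6)
    table["shade_tolerance"] = np.clip(3.0 + 0.9 * raw[4], 1.0, 5.0)
    # phenology: deciduous flush/senescence windows; evergreen constant
    table["flush_doy"] = np.where(is_ever, np.nan, rng.uniform(110, 135, n_species))
    table["senesce_doy"] = np.where(is_ever, np.nan, rng.uniform(270, 295, n_species))
    table["sharpness"] = np.where(is_ever, np.nan, rng.uniform(5, 8, n_species))
    table["crown_shape"] = np.where(is_ever, "cone", "ellipsoid")
    table["crown_radius_ratio"] = rng.uniform(0.15, 0.25, n_species)
    table["crown_depth_ratio"] = rng.uniform(0.55, 0.75, n_species)
    table["foliage_density"] = rng.uniform(1.5, 2.5, n_species)  # 1/m extinction
    table["wood_fraction"] = 0.08  # leafless crowns still return off branches
    table["height_incr"] = np.clip(0.55 + 0.35 * (table["rgr"] - 0.30) / 0.08 * 0.25,
                                   0.25, 1.0)
    table["diam_incr"] = table["height_incr"] * 0.022

    taxonomy = _taxonomy_from_clades(species, is_ever, rng)
    return SpeciesPool(table=table, tree=tree, taxonomy=taxonomy)


def _random_ultrametric_or_tip(labels, clade_depth, rng, total_depth):
    """Clade newick with stem reaching back to the root at ``total_depth``."""
    if len(labels) == 1:
        return f"{labels[0]}:{total_depth:.10g}"
    inner = _random_ultrametric(labels, clade_depth, rng)
    return f"({inner}):{total_depth - clade_depth:.10g}"


def _taxonomy_from_clades(species, is_ever, rng) -> pd.DataFrame:
    """Simple nested taxonomy: one order per leaf habit, two families per
    order, genera of up to two consecutive species."""
    rows = []
    for habit, order in ((True, "Coniferales"), (False, "Fagales")):
        members = [s for s, e in zip(species, is_ever) if e == habit]
        half = max(1, len(members) // 2)
        for i, sp in enumerate(members):
            fam = f"{order[:4]}aceae{1 if i < half else 2}"
            rows.append(
                {"species_id": sp, "order": order, "family": fam,
                 "genus": f"{fam[:5]}_g{i // 2}"}
            )
    return pd.DataFrame(rows).set_index("species_id")


# ---------------------------------------------------------------------------
# Experimental design
# ---------------------------------------------------------------------------

def generate_design(
    pool: SpeciesPool,
    n_blocks: int = 3,
    plots_per_richness: int = 2,
    mixtures_per_richness: int | None = None,
    replanted_fraction: float = 0.05,
    planting_years=(2017,),
    seed: int = 0,
) -> ExperimentDesign:
    """Monocultures for every species plus random mixtures per richness level.

    ``plots_per_richness`` monocultures are planted per species;
    ``mixtures_per_richness`` plots (default ``plots_per_richness *
    n_species // 2``) at each richness level in {2, 4, 6, 12} that does not
    exceed the pool.  Proportions are equal within a plot; the experiment is
    a single cohort by default (``planting_years``) and a small fraction of
    plots is flagged replanted.
    """
    if plots_per_richness < 1:
        raise ValueError("plots_per_richness must be >= 1")
    species = pool.species
    n_sp = len(species)
    if mixtures_per_richness is None:
        mixtures_per_richness = max(1, plots_per_richness * n_sp // 2)
    rng = _stream(seed, "design")

    plot_rows, comp_rows = [], []
    counter = 0

    def add_plot(members: list[str]) -> None:
        nonlocal counter
        pid = f"P{counter:04d}"
        counter += 1
        plot_rows.append(
            {
                "plot_id": pid,
                "block": f"B{counter % n_blocks + 1}",
                "richness": len(members),
                "planting_year": int(rng.choice(list(planting_years))),
                "replanted": bool(rng.random() < replanted_fraction),
            }
        )
        for sp in members:
            comp_rows.append(
                {"plot_id": pid, "species_id": sp, "proportion": 1.0 / len(members)}
            )

    for sp in species:
        for _ in range(plots_per_richness):
            add_plot([sp])
    for r in RICHNESS_LEVELS[1:]:
        if r > n_sp:
            raise ValueError(f"richness level {r} exceeds pool size {n_sp}")
        for _ in range(mixtures_per_richness):
            members = list(rng.choice(species, size=r, replace=False))
            add_plot(members)

    plots = pd.DataFrame(plot_rows)
    # blocks assigned at random but balanced
    plots["block"] = [f"B{(i % n_blocks) + 1}" for i in rng.permutation(len(plots))]
    return ExperimentDesign(plots=plots, composition=pd.DataFrame(comp_rows))


# ---------------------------------------------------------------------------
# Inventories
# ---------------------------------------------------------------------------

def _conoid_dbh(height: np.ndarray, d_rc: np.ndarray) -> np.ndarray:
    """Diameter at 1.3 m for a conoid stem: d(h) = d_rc * sqrt(1 - h/H)."""
    with np.errstate(invalid="ignore"):
        dbh = d_rc * np.sqrt(np.clip(1.0 - 1.3 / height, 0.0, None))
    dbh[height <= 1.3] = np.nan
    return dbh


def plot_variability_scores(design: ExperimentDesign, pool: SpeciesPool) -> pd.Series:
    """Functional variability (PSV on the trait dendrogram) of the planted
    community; 0 for monocultures."""
    func_tree = functional_dendrogram(pool.traits)
    scores = {}
    for pid in design.plots["plot_id"]:
        members = list(design.proportions(pid).index)
        scores[pid] = variability_psv(func_tree, members) if len(members) >= 2 else 0.0
    return pd.Series(scores, name="var_func")


def plot_asynchrony_scores(
    design: ExperimentDesign, pool: SpeciesPool, doys=DEFAULT_DOYS
) -> pd.Series:
    """Phenological asynchrony of the planted community in [0, 1).

    Mean pairwise RMS distance between the species' seasonal foliage-display
    curves sampled at the survey dates (deciduous double-sigmoid with a
    woody floor, evergreen constant).  Zero for monocultures and for
    communities of identical phenology; largest for evergreen-deciduous
    mixtures with spread flush/senescence dates.  This realized asynchrony —
    the quantity the seasonal-stability metrics sense — is what the injected
    complementarity multiplier acts on."""
    doys = np.asarray(doys, dtype=float)
    curves = {}
    for sp, row in pool.table.iterrows():
        phen = phenology_curve(doys, row["flush_doy"], row["senesce_doy"], row["sharpness"])
        curves[sp] = row["wood_fraction"] + (1 - row["wood_fraction"]) * phen
    scores = {}
    for pid in design.plots["plot_id"]:
        members = list(design.proportions(pid).index)
        if len(members) < 2:
            scores[pid] = 0.0
            continue
        dists = [
            np.sqrt(np.mean((curves[a] - curves[b]) ** 2))
            for i, a in enumerate(members)
            for b in members[i + 1:]
        ]
        scores[pid] = float(np.mean(dists))
    return pd.Series(scores, name="asynchrony")


def plot_cover_stability_gain(
    design: ExperimentDesign, pool: SpeciesPool, doys=DEFAULT_DOYS
) -> pd.Series:
    """Gain in seasonal canopy-cover stability of the mixture over its
    monocultures, in [0, ~0.3]; zero for monocultures.

    For each species the foliage-display curve phi_i(doy) (woody floor
    included) has a cover-stability score 1 - CV(phi_i); the community curve
    is the proportion-weighted mean of its members' curves.  The gain is the
    community score minus the proportion-weighted mean of the member scores:
    positive whenever phenological complementarity lets the mixture hold its
    canopy cover steadier than its constituents do alone (largest for
    evergreen-deciduous mixtures, zero for single-habit communities with
    identical phenology).  The injected complementarity multiplier on growth
    is proportional to this gain, so overyielding is strongest exactly where
    the seasonal-stability metrics are high relative to the monocultures."""
    gains = {
        pid: cover_stability_gain(dict(design.proportions(pid)), pool, doys)
        for pid in design.plots["plot_id"]
    }
    return pd.Series(gains, name="cover_stability_gain")


def _foliage_curves(
    pool: SpeciesPool, doys, offsets: dict[str, float] | None = None
) -> dict[str, np.ndarray]:
    doys = np.asarray(doys, dtype=float)
    offsets = offsets or {}
    curves = {}
    for sp, row in pool.table.iterrows():
        off = offsets.get(sp, 0.0)
        phen = phenology_curve(
            doys, row["flush_doy"] + off, row["senesce_doy"] + off, row["sharpness"]
        )
        curves[sp] = row["wood_fraction"] + (1 - row["wood_fraction"]) * phen
    return curves


def _stab(curve: np.ndarray) -> float:
    m = curve.mean()
    return float(1.0 - curve.std(ddof=1) / m) if m > 0 else 0.0


def cover_stability_score(
    weights: dict[str, float],
    pool: SpeciesPool,
    doys=DEFAULT_DOYS,
    offsets: dict[str, float] | None = None,
) -> float:
    """Seasonal stability (1 - CV) of the community foliage-cover curve.

    ``weights`` are species shares summing to 1; ``offsets`` shift species
    phenology by plot-level microsite effects (days).  Near 1 for evergreen
    communities, ~0.2 for purely deciduous ones, intermediate for mixtures —
    and, because averaging across asynchronous species smooths the community
    curve, a mixture always scores at least as high as the weighted mean of
    its members alone (the overyielding surplus the growth model injects)."""
    curves = _foliage_curves(pool, doys, offsets)
    community = np.sum([w * curves[sp] for sp, w in weights.items()], axis=0)
    return _stab(community)


def cover_stability_gain(
    weights: dict[str, float],
    pool: SpeciesPool,
    doys=DEFAULT_DOYS,
    offsets: dict[str, float] | None = None,
) -> float:
    """Cover-stability gain of the community over its monocultures."""
    if len(weights) < 2:
        return 0.0
    curves = _foliage_curves(pool, doys, offsets)
    mono_mean = float(sum(w * _stab(curves[sp]) for sp, w in weights.items()))
    return max(0.0, cover_stability_score(weights, pool, doys, offsets) - mono_mean)


FINE_DOY_GRID = np.arange(90.0, 305.0, 3.0)


def temporal_complementarity(
    weights: dict[str, float],
    pool: SpeciesPool,
    offsets: dict[str, float] | None = None,
) -> dict[str, float]:
    """Per-species temporal niche benefit in a community.

    For species i, ``b_i = sum_j w_j * (d_ij - d_ii)`` with
    ``d_ij = mean_t[phi_i(t) * (1 - phi_j(t))] / mean_t[phi_i(t)]`` — the
    fraction of i's activity-weighted season during which neighbour j's
    canopy is dormant — over the realized foliage curves on a fine DOY
    grid.  The benefit is directional and measured against the conspecific
    baseline, so it is exactly 0 in monocultures: a tree active while its
    neighbours are leafless intercepts their share of light and grows more
    (evergreens among deciduous partners gain most; deciduous species gain
    modestly from spread flush dates and lose under year-round evergreen
    shade).  The community mean benefit rises with the canopy's seasonal
    evenness, the same property the stability metrics sense.
    """
    curves = _foliage_curves(pool, FINE_DOY_GRID, offsets)
    b = {}
    for si in weights:
        ci = curves[si]
        mean_i = float(ci.mean())
        if mean_i <= 0:
            b[si] = 0.0
            continue
        d_ii = float((ci * (1.0 - ci)).mean() / mean_i)
        benefit = 0.0
        for sj, w in weights.items():
            cj = curves[sj]
            d_ij = float((ci * (1.0 - cj)).mean() / mean_i)
            benefit += w * (d_ij - d_ii)
        # gains only: competition for light is already in the baseline, so a
        # species surrounded by denser seasonal shade grows at its base
        # rate rather than being actively suppressed
        b[si] = max(0.0, benefit)
    return b


def generate_inventories(
    design: ExperimentDesign,
    pool: SpeciesPool,
    complementarity_strength: float = 0.5,
    mortality_rate: float = 0.05,
    growth_noise_sd: float = 0.10,
    phenology_jitter_sd: float = 6.0,
    year1: int = 2021,
    year2: int = 2022,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Two consecutive annual inventories for every tree of every plot.

    Year-1 size comes from age * species height increment (lognormal noise);
    year-2 growth of each tree is ``base * (1 + strength * b_i / 0.1)``
    where ``b_i`` is its species' temporal niche benefit in the realized
    surviving community (:func:`temporal_complementarity`, with plot-level
    phenology offsets).  The benefit is exactly zero in monocultures, so
    mixtures of phenologically asynchronous species overyield relative to
    the monoculture expectation — and the same asynchrony stabilises the
    canopy cover the scanner sees across the season.  A ``mortality_rate``
    fraction of trees dies before year 2 (zeroed measurements).  Trees are
    on a 1 m grid; ``interior`` marks trees strictly inside the 0.5 m edge
    buffer.
    """
    var_scores = plot_variability_scores(design, pool)
    asyn = plot_asynchrony_scores(design, pool)
    truth = SimulationTruth(
        seed=seed,
        complementarity_strength=complementarity_strength,
        mortality_rate=mortality_rate,
        noise_fraction=np.nan,
        plot_var_func={k: float(v) for k, v in var_scores.items()},
        plot_asynchrony={k: float(v) for k, v in asyn.items()},
        plot_multiplier={},
        phenology={
            sp: {
                "flush_doy": None if pd.isna(r["flush_doy"]) else float(r["flush_doy"]),
                "senesce_doy": None if pd.isna(r["senesce_doy"]) else float(r["senesce_doy"]),
                "sharpness": None if pd.isna(r["sharpness"]) else float(r["sharpness"]),
            }
            for sp, r in pool.table.iterrows()
        },
    )

    n_side = int(round(PLOT_SIDE_M / TREE_SPACING_M))
    gx, gy = np.meshgrid(np.arange(n_side) + 0.5, np.arange(n_side) + 0.5)
    gx, gy = gx.ravel(), gy.ravel()
    interior = (
        (gx > EDGE_BUFFER_M) & (gx < PLOT_SIDE_M - EDGE_BUFFER_M)
        & (gy > EDGE_BUFFER_M) & (gy < PLOT_SIDE_M - EDGE_BUFFER_M)
    )

    taper = 0.022  # d_rc / height for young open-grown stems
    rows = []
    for _, prow in design.plots.iterrows():
        pid = prow["plot_id"]
        rng = _stream(seed, "inv", pid)
        props = design.proportions(pid)
        # planted layout: species tiled to the grid in a seeded shuffle
        members = np.concatenate(
            [np.repeat(sp, int(round(p * gx.size))) for sp, p in props.items()]
        )
        if members.size < gx.size:  # rounding remainder
            members = np.concatenate(
                [members, rng.choice(props.index.to_numpy(), gx.size - members.size)]
            )
        members = members[:gx.size]
        rng.shuffle(members)

        age1 = year1 - prow["planting_year"]
        sp_tab = pool.table.loc[members]
        h_incr = sp_tab["height_incr"].to_numpy()
        h1 = age1 * h_incr * np.exp(rng.normal(0, 0.2, gx.size))
        h1 = np.minimum(h1, sp_tab["max_height"].to_numpy() * 0.9)
        dead = rng.random(gx.size) < mortality_rate
        # plot-level phenology microsite effect: each species' flush and
        # senescence shift together by a plot-specific offset (days)
        offsets = {
            sp: float(rng.normal(0.0, phenology_jitter_sd))
            for sp in props.index
            if not pd.isna(pool.table.loc[sp, "flush_doy"])
        }
        # temporal niche complementarity of the realized (surviving,
        # microsite-shifted) community; zero in monocultures
        alive_members = members[~dead]
        weights = {
            sp: float((alive_members == sp).sum()) / max(alive_members.size, 1)
            for sp in np.unique(alive_members)
        }
        benefit = temporal_complementarity(weights, pool, offsets=offsets)
        # typical cross-habit benefit ~0.1 -> multiplier ~1 + strength
        tree_mult = 1.0 + complementarity_strength * np.array(
            [benefit.get(sp, 0.0) for sp in members]
        ) / 0.1
        truth.plot_multiplier[pid] = float(
            sum(w * benefit.get(sp, 0.0) for sp, w in weights.items())
            * complementarity_strength / 0.1
        )
        truth.plot_phenology_offsets[pid] = offsets
        growth = h_incr * tree_mult * np.exp(rng.normal(0, growth_noise_sd, gx.size))
        h2 = np.minimum(h1 + growth, sp_tab["max_height"].to_numpy())
        d1 = taper * h1
        d2 = taper * h2
        dbh1 = _conoid_dbh(h1, d1)
        dbh2 = _conoid_dbh(h2, d2)
        h2w = np.where(dead, 0.0, h2)
        d2w = np.where(dead, 0.0, d2)
        dbh2 = np.where(dead, np.nan, dbh2)
        off_vec = np.array([offsets.get(sp, 0.0) for sp in members])
        rows.append(
            pd.DataFrame(
                {
                    "tree_id": [f"{pid}_T{t:03d}" for t in range(gx.size)],
                    "plot_id": pid,
                    "species_id": members,
                    "x": gx,
                    "y": gy,
                    "interior": interior,
                    "planting_year": prow["planting_year"],
                    "phen_offset": off_vec,
                    f"height_{year1}": h1,
                    f"d_rc_{year1}": d1,
                    f"dbh_{year1}": dbh1,
                    f"alive_{year1}": True,
                    f"height_{year2}": h2w,
                    f"d_rc_{year2}": d2w,
                    f"dbh_{year2}": dbh2,
                    f"alive_{year2}": ~dead,
                }
            )
        )
    return pd.concat(rows, ignore_index=True), truth


# ---------------------------------------------------------------------------
# Phenology & point clouds
# ---------------------------------------------------------------------------

def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def phenology_curve(doy, flush_doy: float, senesce_doy: float, sharpness: float) -> np.ndarray:
    """Double-sigmoid leaf display in [0, 1]: exactly 0 at or before
    ``flush_doy - 3*sharpness``, 1 at mid-season, falling through
    senescence.  NaN phenology parameters (evergreen) give a constant 1."""
    doy = np.asarray(doy, dtype=float)
    if np.isnan(flush_doy):
        return np.ones_like(doy)
    w = 6.0 * sharpness
    rise = _smoothstep((doy - (flush_doy - 3 * sharpness)) / w)
    fall = _smoothstep((doy - (senesce_doy - 3 * sharpness)) / w)
    return rise * (1.0 - fall)


def _crown_segments(px, py, tx, ty, h, shape, r_ratio, depth_ratio):
    """Vertical [z_lo, z_hi] of the crown solid pierced by each pulse.

    Returns (mask, z_lo, z_hi) arrays over pulses.  Cones have their apex at
    the tree top, ellipsoids are centred on the crown midpoint.
    """
    r = np.hypot(px - tx, py - ty)
    radius = r_ratio * h
    crown_base = h * (1.0 - depth_ratio)
    inside = r < radius
    z_lo = np.full(px.size, np.nan)
    z_hi = np.full(px.size, np.nan)
    if shape == "cone":
        # radius grows linearly from 0 at the top to `radius` at crown base
        z_top = h - (r / radius) * (h - crown_base)
        z_lo[inside] = crown_base
        z_hi[inside] = z_top[inside]
    else:  # ellipsoid
        zc = 0.5 * (h + crown_base)
        b = 0.5 * (h - crown_base)
        with np.errstate(invalid="ignore"):
            dz = b * np.sqrt(np.clip(1.0 - (r / radius) ** 2, 0.0, None))
        z_lo[inside] = (zc - dz)[inside]
        z_hi[inside] = (zc + dz)[inside]
    return inside, z_lo, z_hi


def generate_point_cloud(
    design: ExperimentDesign,
    pool: SpeciesPool,
    inventory: pd.DataFrame,
    plot_id: str,
    doy: int,
    density: float = 200.0,
    height_year: int = 2022,
    noise_fraction: float = 0.001,
    ground_offset: float = 0.0,
    continue_prob: float = 0.6,
    seed: int = 0,
) -> PointCloud:
    """Simulate one plot/survey cloud by vertical-pulse ray casting.

    Pulses sit on a jittered horizontal grid at ``density`` pulses/m^2.
    Each pulse crosses the crown solids of the plot's live trees top-down;
    a crown segment of length L and effective foliage density lam intercepts
    with probability 1 - exp(-lam * L), the beam continues after a return
    with probability ``continue_prob`` (sensor supports up to 3 returns),
    and a pulse that reaches the ground yields a ground return.  Deciduous
    foliage density is scaled by the phenology curve with a woody floor;
    a ``noise_fraction`` of high outliers is added above the canopy.
    ``ground_offset`` shifts all z to exercise height normalization.
    """
    if density <= 0:
        raise ValueError("density must be positive")
    if plot_id not in set(design.plots["plot_id"]):
        raise ValueError(f"unknown plot {plot_id!r}")
    rng = _stream(seed, "cloud", plot_id, int(doy))
    trees = inventory[
        (inventory["plot_id"] == plot_id)
        & inventory[f"alive_{height_year}"].astype(bool)
        & (inventory[f"height_{height_year}"] > 0.3)
    ]

    # jittered pulse grid over the full (unbuffered) plot
    spacing = 1.0 / np.sqrt(density)
    ax = np.arange(0.5 * spacing, PLOT_SIDE_M, spacing)
    px, py = np.meshgrid(ax, ax)
    px = px.ravel() + rng.uniform(-0.5 * spacing, 0.5 * spacing, px.size)
    py = py.ravel() + rng.uniform(-0.5 * spacing, 0.5 * spacing, py.size)
    n_pulse = px.size

    sp_cols = pool.table.loc[
        trees["species_id"],
        ["crown_shape", "crown_radius_ratio", "crown_depth_ratio",
         "flush_doy", "senesce_doy", "sharpness", "foliage_density",
         "wood_fraction"],
    ]
    t_x = trees["x"].to_numpy()
    t_y = trees["y"].to_numpy()
    t_h = trees[f"height_{height_year}"].to_numpy()
    t_off = (
        trees["phen_offset"].fillna(0.0).to_numpy()
        if "phen_offset" in trees.columns
        else np.zeros(len(trees))
    )

    seg_pulse, seg_lo, seg_hi, seg_lam = [], [], [], []
    for i, sp in enumerate(sp_cols.itertuples(index=False)):
        mask, z_lo, z_hi = _crown_segments(
            px, py, t_x[i], t_y[i], t_h[i], sp.crown_shape,
            sp.crown_radius_ratio, sp.crown_depth_ratio,
        )
        if not mask.any():
            continue
        off = float(t_off[i])
        phen = float(
            phenology_curve(doy, sp.flush_doy + off, sp.senesce_doy + off,
                            sp.sharpness)
        )
        lam = sp.foliage_density * (sp.wood_fraction + (1 - sp.wood_fraction) * phen)
        idx = np.flatnonzero(mask)
        seg_pulse.append(idx)
        seg_lo.append(z_lo[idx])
        seg_hi.append(z_hi[idx])
        seg_lam.append(np.full(idx.size, lam))

    if seg_pulse:
        sp_idx = np.concatenate(seg_pulse)
        lo = np.concatenate(seg_lo)
        hi = np.concatenate(seg_hi)
        lam = np.concatenate(seg_lam)
        # order segments per pulse, top down
        order = np.lexsort((-hi, sp_idx))
        sp_idx, lo, hi, lam = sp_idx[order], lo[order], hi[order], lam[order]
        p_hit = 1.0 - np.exp(-lam * np.maximum(hi - lo, 0.0))
        hit = rng.random(sp_idx.size) < p_hit
        go_on = rng.random(sp_idx.size) < continue_prob

        # within-pulse candidate rank among hits, top-down
        s_idx, s_hit, s_go = sp_idx[hit], np.flatnonzero(hit), go_on[hit]
        new_pulse = np.ones(s_idx.size, dtype=bool)
        new_pulse[1:] = s_idx[1:] != s_idx[:-1]
        grp_start = np.maximum.accumulate(np.where(new_pulse, np.arange(s_idx.size), 0))
        rank = np.arange(s_idx.size) - grp_start  # 0-based hit rank in pulse
        # beam terminated by the first non-continuing realized hit or cap
        stop_rank = np.full(n_pulse, np.inf)
        stopped = ~s_go
        np.minimum.at(stop_rank, s_idx[stopped], rank[stopped])
        realized = (rank <= stop_rank[s_idx]) & (rank < MAX_RETURNS)
        veg_pulse = s_idx[realized]
        seg_of = s_hit[realized]
        veg_z = rng.uniform(lo[seg_of], hi[seg_of])
        # re-sort realized returns by (pulse, z desc) to number them
        o2 = np.lexsort((-veg_z, veg_pulse))
        veg_pulse, veg_z = veg_pulse[o2], veg_z[o2]
        veg_x = px[veg_pulse] + rng.normal(0, 0.02, veg_pulse.size)
        veg_y = py[veg_pulse] + rng.normal(0, 0.02, veg_pulse.size)
        n_veg = np.bincount(veg_pulse, minlength=n_pulse)
        # ground return iff the beam was never terminated and cap not reached
        terminated = np.isfinite(stop_rank) & (stop_rank < MAX_RETURNS)
        reached_ground = (~terminated) & (n_veg < MAX_RETURNS)
    else:
        veg_pulse = np.empty(0, dtype=int)
        veg_x = veg_y = veg_z = np.empty(0)
        n_veg = np.zeros(n_pulse, dtype=int)
        reached_ground = np.ones(n_pulse, dtype=bool)

    g_idx = np.flatnonzero(reached_ground)
    g_x, g_y = px[g_idx], py[g_idx]
    g_z = rng.normal(0.0, 0.02, g_idx.size).clip(-0.06, 0.06)

    # assemble: vegetation returns numbered 1.. top-down, ground return last
    new_p = np.ones(veg_pulse.size, dtype=bool)
    if veg_pulse.size:
        new_p[1:] = veg_pulse[1:] != veg_pulse[:-1]
        starts = np.maximum.accumulate(np.where(new_p, np.arange(veg_pulse.size), 0))
        veg_rn = np.arange(veg_pulse.size) - starts + 1
    else:
        veg_rn = np.empty(0, dtype=int)
    n_total = n_veg + reached_ground.astype(int)
    ground_rn = n_total[g_idx]

    x = np.concatenate([veg_x, g_x])
    y = np.concatenate([veg_y, g_y])
    z = np.concatenate([veg_z, g_z])
    rn = np.concatenate([veg_rn, ground_rn]).astype(int)
    nor = np.concatenate([n_total[veg_pulse], n_total[g_idx]]).astype(int)
    cls = np.concatenate(
        [np.full(veg_pulse.size, VEGETATION), np.full(g_idx.size, GROUND)]
    )

    # high outlier noise above the canopy, as extra single-return pulses
    n_noise = rng.poisson(noise_fraction * max(x.size, 1))
    if n_noise:
        top = z.max() if z.size else 5.0
        nx = rng.uniform(0, PLOT_SIDE_M, n_noise)
        ny = rng.uniform(0, PLOT_SIDE_M, n_noise)
        nz = rng.uniform(top + 2.0, top + 10.0, n_noise)
        x = np.concatenate([x, nx])
        y = np.concatenate([y, ny])
        z = np.concatenate([z, nz])
        rn = np.concatenate([rn, np.ones(n_noise, dtype=int)])
        nor = np.concatenate([nor, np.ones(n_noise, dtype=int)])
        cls = np.concatenate([cls, np.full(n_noise, NOISE)])

    return PointCloud(
        x=x, y=y, z=z + ground_offset, return_number=rn, number_of_returns=nor,
        classification=cls, plot_id=plot_id, doy=int(doy),
    )


def generate_point_cloud_series(
    design: ExperimentDesign,
    pool: SpeciesPool,
    inventory: pd.DataFrame,
    doys=DEFAULT_DOYS,
    density: float = 200.0,
    noise_fraction: float = 0.001,
    ground_offset: float = 0.0,
    height_year: int = 2022,
    seed: int = 0,
    plot_ids=None,
) -> dict[tuple[str, int], PointCloud]:
    """One cloud per plot per DOY; per-cloud RNG streams hashed from
    (plot_id, doy) so the set is order-independent."""
    if not len(doys):
        raise ValueError("doys must be nonempty")
    pids = list(plot_ids) if plot_ids is not None else list(design.plots["plot_id"])
    out = {}
    for pid in pids:
        for doy in doys:
            out[(pid, int(doy))] = generate_point_cloud(
                design, pool, inventory, pid, int(doy),
                density=density, noise_fraction=noise_fraction,
                ground_offset=ground_offset, height_year=height_year, seed=seed,
            )
    return out
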