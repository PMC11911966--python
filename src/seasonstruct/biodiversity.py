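"""Taxonomic, phylogenetic and functional diversity and variability.

Diversity metrics (Hill order q=0 by default) grow with the number of
species: richness, phylogenetic diversity (total branch length of the pruned
tree, PD) and functional diversity (effective total functional distance
between species, FD).  Variability is Helmus' phylogenetic species
variability (PSV) — one minus the mean pairwise correlation implied by
shared branch lengths — which is independent of richness and is applied to
three tree types: the phylogeny, a UPGMA dendrogram of functional-trait
distances, and a unit-step taxonomic-distinctness tree.
"""

from __future__ import annotations

import warnings

import dendropy
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform

from .metrics import hill_diversity


# ---------------------------------------------------------------------------
# Hill-number diversity
# ---------------------------------------------------------------------------

def hill_taxa(abundances: pd.Series | np.ndarray, q: float = 0) -> float:
    """Taxonomic Hill diversity; at q=0 the count of present species."""
    a = np.asarray(abundances, dtype=float)
    a = a[a > 0]
    if a.size == 0:
        raise ValueError("empty community")
    if q == 0:
        return float(a.size)
    return hill_diversity(a / a.sum(), q)


# ---------------------------------------------------------------------------
# Tree utilities
# ---------------------------------------------------------------------------

def _tip_paths(tree: dendropy.Tree) -> dict[str, list]:
    """Map tip label -> list of edges on the root-to-tip path."""
    paths: dict[str, list] = {}
    for leaf in tree.leaf_node_iter():
        edges = []
        node = leaf
        while node.parent_node is not None:
            edges.append(node.edge)
            node = node.parent_node
        paths[leaf.taxon.label] = edges
    return paths


def phylo_diversity(tree: dendropy.Tree, community: list[str]) -> float:
    """Faith-style PD: total branch length spanning the community and root.

    The stem path to the root is included, so a single-species community has
    PD equal to its root-to-tip path length.
    """
    paths = _tip_paths(tree)
    unknown = [s for s in community if s not in paths]
    if unknown:
        raise ValueError(f"species not in tree: {unknown}")
    if not community:
        raise ValueError("empty community")
    edges = set()
    for sp in community:
        edges.update(id(e) for e in paths[sp])
    by_id = {id(e): e for sp in community for e in paths[sp]}
    return float(sum((by_id[i].length or 0.0) for i in edges))


def tree_depths_and_mrca(tree: dendropy.Tree, labels: list[str]):
    """Root-to-tip depths and root-to-MRCA shared depths for the labels.

    Returns (depths vector, shared matrix) where shared[i, j] is the distance
    from the root to the MRCA of tips i and j.
    """
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    unknown = [s for s in labels if s not in taxa]
    if unknown:
        raise ValueError(f"species not in tree: {unknown}")
    depth = {}
    for leaf in tree.leaf_node_iter():
        depth[leaf.taxon.label] = leaf.distance_from_root()
    n = len(labels)
    depths = np.array([depth[s] for s in labels])
    shared = np.zeros((n, n))
    for i in range(n):
        shared[i, i] = depths[i]
        for j in range(i + 1, n):
            d_ij = pdm.distance(taxa[labels[i]], taxa[labels[j]])
            shared[i, j] = shared[j, i] = 0.5 * (depths[i] + depths[j] - d_ij)
    return depths, shared


def variability_psv(tree: dendropy.Tree, community: list[str]) -> float:
    """Helmus phylogenetic species variability on any tree-like object.

    Builds the covariance of shared root-to-MRCA branch lengths, scales it to
    a correlation matrix, and returns 1 minus the mean off-diagonal
    correlation.  1 on a star tree (no shared history), approaching 0 for
    near-identical species.  Undefined for fewer than 2 species.
    """
    if len(set(community)) != len(community):
        raise ValueError("duplicated species labels in community")
    n = len(community)
    if n < 2:
        raise ValueError("PSV needs >= 2 species (monocultures excluded)")
    depths, shared = tree_depths_and_mrca(tree, community)
    if (depths <= 0).any():
        raise ValueError("zero root-to-tip depth: degenerate tree")
    denom = np.sqrt(np.outer(depths, depths))
    corr = shared / denom
    off = corr[~np.eye(n, dtype=bool)]
    return float(1.0 - off.mean())


# ---------------------------------------------------------------------------
# Functional diversity & dendrograms
# ---------------------------------------------------------------------------

def standardize_traits(traits: pd.DataFrame) -> pd.DataFrame:
    """Column z-scores; trait units are incommensurable so distances are
    computed on standardized values."""
    sd = traits.std(ddof=1).replace(0, 1.0)
    return (traits - traits.mean()) / sd


def functional_diversity(
    traits: pd.DataFrame,
    community: list[str],
    q: float = 0,
    standardized: bool = False,
    convention: str = "total_distance",
    tree: dendropy.Tree | None = None,
) -> float:
    """FD as the effective total functional distance between species.

    Default convention (q=0): the sum of pairwise Euclidean trait distances
    over *ordered* pairs, i.e. ``2 * sum_{i<j} d_ij``.  The alternative
    ``convention="dendrogram"`` returns the total branch length of the
    functional dendrogram pruned to the community (Faith-style on the
    functional tree).  Singleton communities return 0 with a warning.
    """
    missing = [s for s in community if s not in traits.index]
    if missing:
        raise ValueError(f"species missing from trait table: {missing}")
    if len(community) == 0:
        raise ValueError("empty community")
    if len(community) == 1:
        warnings.warn("singleton community: FD = 0")
        return 0.0
    if convention == "dendrogram":
        t = tree if tree is not None else functional_dendrogram(traits, standardized=standardized)
        return phylo_diversity(t, community)
    if convention != "total_distance":
        raise ValueError(f"unknown FD convention {convention!r}")
    z = traits if standardized else standardize_traits(traits)
    sub = z.loc[community].to_numpy(dtype=float)
    d = pdist(sub)
    if q == 0:
        return float(2.0 * d.sum())
    # abundance-free effective distance at general q: Hill diversity of the
    # ordered-pair distance shares times mean distance
    shares = np.concatenate([d, d])
    shares = shares / shares.sum()
    return float(hill_diversity(shares, q) * np.mean(np.concatenate([d, d])))


def _linkage_to_tree(link: np.ndarray, labels: list[str]) -> dendropy.Tree:
    """Convert a scipy linkage matrix into an ultrametric dendropy tree.

    Node heights are half the cophenetic merge distance, so the cophenetic
    distance between two tips equals their dendrogram distance.
    """
    n = len(labels)
    newick_parts: dict[int, tuple[str, float]] = {
        i: (labels[i].replace(" ", "_"), 0.0) for i in range(n)
    }
    for k, (a, b, h, _) in enumerate(link):
        a, b = int(a), int(b)
        height = h / 2.0
        sa, ha = newick_parts.pop(a)
        sb, hb = newick_parts.pop(b)
        part = f"({sa}:{height - ha:.12g},{sb}:{height - hb:.12g})"
        newick_parts[n + k] = (part, height)
    (final, _), = newick_parts.values()
    tree = dendropy.Tree.get(data=final + ";", schema="newick")
    return tree


def functional_dendrogram(
    traits: pd.DataFrame, standardized: bool = False
) -> dendropy.Tree:
    """UPGMA dendrogram on Euclidean trait distances, as an ultrametric tree
    usable wherever a phylogeny is (PSV, pruned-tree FD)."""
    if len(traits) < 2:
        raise ValueError("need >= 2 species for a dendrogram")
    z = traits if standardized else standardize_traits(traits)
    link = linkage(pdist(z.to_numpy(dtype=float)), method="average")
    return _linkage_to_tree(link, list(traits.index))


def taxonomic_distinctness_tree(taxonomy: pd.DataFrame) -> dendropy.Tree:
    """Unit-step taxonomic-distinctness tree from an order/family/genus table.

    The distance between two species is the number of rank levels one must
    ascend before they join (congeners 1, confamilial non-congeners 2, same
    order different family 3, different orders 4 — equal single steps per
    level), clustered by UPGMA into an ultrametric tree.
    """
    required = ["order", "family", "genus"]
    missing = [c for c in required if c not in taxonomy.columns]
    if missing:
        raise ValueError(f"taxonomy table missing columns: {missing}")
    if taxonomy.index.duplicated().any():
        raise ValueError("duplicated species labels in taxonomy")
    species = list(taxonomy.index)
    n = len(species)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = taxonomy.iloc[i], taxonomy.iloc[j]
            if a["genus"] == b["genus"]:
                d = 1
            elif a["family"] == b["family"]:
                d = 2
            elif a["order"] == b["order"]:
                d = 3
            else:
                d = 4
            dist[i, j] = dist[j, i] = d
    link = linkage(squareform(dist), method="average")
    return _linkage_to_tree(link, species)


# ---------------------------------------------------------------------------
# Community-level table
# ---------------------------------------------------------------------------

def community_metrics(
    communities: dict[str, list[str]],
    phylogeny: dendropy.Tree,
    traits: pd.DataFrame,
    taxonomy: pd.DataFrame | None = None,
    functional_tree: dendropy.Tree | None = None,
) -> pd.DataFrame:
    """Richness, PD, FD and the three PSV variabilities per plot.

    ``communities`` maps plot_id to the list of species present (after
    mortality).  Variability columns are NaN for monocultures.
    """
    func_tree = functional_tree or functional_dendrogram(traits)
    tax_tree = taxonomic_distinctness_tree(taxonomy) if taxonomy is not None else None
    rows = []
    for pid, sp in communities.items():
        row = {
            "plot_id": pid,
            "richness": float(len(sp)),
            "pd": phylo_diversity(phylogeny, sp),
            "fd": functional_diversity(traits, sp) if len(sp) > 1 else 0.0,
            "var_phylo": np.nan,
            "var_func": np.nan,
            "var_taxo": np.nan,
        }
        if len(sp) >= 2:
            row["var_phylo"] = variability_psv(phylogeny, sp)
            row["var_func"] = variability_psv(func_tree, sp)
            if tax_tree is not None:
                row["var_taxo"] = variability_psv(tax_tree, sp)
        rows.append(row)
    return pd.DataFrame(rows)
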