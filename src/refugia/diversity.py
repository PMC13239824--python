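"""Species richness and Faith phylogenetic diversity surfaces.

SR is the per-cell count of species predicted present. Faith PD is the
total branch length of the minimal subtree connecting a cell's species;
under the rooted convention (default, matching picante's
``include.root=TRUE``) the subtree always includes the path to the root,
so a single-species cell has PD equal to its root-to-tip distance.
Empty cells have PD = 0.

PD over a raster stack is computed as a tip x edge incidence-matrix
reduction: an edge contributes wherever at least one tip below it is
present.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .grid import RasterGrid, combined_valid_mask, require_all_aligned

__all__ = [
    "load_tree",
    "species_richness",
    "faith_pd",
    "diversity_change",
    "ChangeSummary",
]


def load_tree(path_or_newick: str) -> dendropy.Tree:
    """Read a rooted Newick tree from a path or a literal Newick string."""
    src = str(path_or_newick)
    if src.lstrip().startswith(("(", "[")):
        tree = dendropy.Tree.get(data=src, schema="newick")
    else:
        tree = dendropy.Tree.get(path=src, schema="newick")
    tree.is_rooted = True
    return tree


def _tip_edge_incidence(tree: dendropy.Tree, species_ids, rooted: bool):
    """(n_species, n_edges) 0/1 incidence of each tip's root path, and edge
    lengths. Unrooted convention drops edges shared by *all* tips later."""
    labels = {}
    for leaf in tree.leaf_node_iter():
        labels[leaf.taxon.label] = leaf
    missing = [s for s in species_ids if s not in labels]
    if missing:
        raise KeyError(f"species missing from tree: {missing}")

    edges = [e for e in tree.preorder_edge_iter() if e.head_node is not tree.seed_node]
    edge_index = {id(e): i for i, e in enumerate(edges)}
    lengths = np.array([e.length or 0.0 for e in edges], dtype=float)

    inc = np.zeros((len(species_ids), len(edges)), dtype=bool)
    for si, sp in enumerate(species_ids):
        node = labels[sp]
        while node.edge is not None and node is not tree.seed_node:
            inc[si, edge_index[id(node.edge)]] = True
            node = node.parent_node
    return inc, lengths


def species_richness(binary_maps: list[RasterGrid]) -> RasterGrid:
    """Per-cell count of present species; nodata where any input is nodata."""
    if not binary_maps:
        raise ValueError("empty binary map list")
    require_all_aligned(binary_maps, "species_richness")
    mask = combined_valid_mask(binary_maps)
    sr = np.zeros(binary_maps[0].shape, dtype=int)
    for b in binary_maps:
        sr += (b.values > 0).astype(int)
    sr[~mask] = 0
    return binary_maps[0].copy_with(sr, mask)


def faith_pd(
    binary_maps: list[RasterGrid],
    tree: dendropy.Tree,
    species_ids: list[str],
    rooted: bool = True,
) -> RasterGrid:
    """Faith PD per cell from a stack of per-species binary maps.

    ``species_ids[i]`` names the tip for ``binary_maps[i]``. With
    ``rooted=False`` the connecting subtree is not forced through the root:
    edges ancestral to every present tip are excluded (single-species cells
    then have PD = 0).
    """
    if len(binary_maps) != len(species_ids):
        raise ValueError("one binary map per species id required")
    if not binary_maps:
        raise ValueError("empty binary map list")
    require_all_aligned(binary_maps, "faith_pd")
    inc, lengths = _tip_edge_incidence(tree, species_ids, rooted)

    mask = combined_valid_mask(binary_maps)
    pres = np.stack([(b.values > 0) & mask for b in binary_maps])  # (S, r, c)
    n_sp = len(species_ids)
    flat = pres.reshape(n_sp, -1)  # (S, n_cells)

    # edge e is in a cell's subtree iff some present tip lies below e
    edge_present = (inc.T.astype(np.float64) @ flat) > 0  # (E, n_cells)
    if not rooted:
        # drop edges on the shared root path: those below *all* present tips
        n_present = flat.sum(axis=0)  # per cell
        below_counts = inc.T.astype(np.float64) @ flat  # tips below e, per cell
        shared = (below_counts == n_present) & (n_present > 0)
        edge_present &= ~shared
    pd_flat = lengths @ edge_present
    pd_vals = pd_flat.reshape(binary_maps[0].shape)
    pd_vals[~mask] = 0.0
    return binary_maps[0].copy_with(pd_vals, mask)


@dataclass
class ChangeSummary:
    """Per-cell change classification and stratified class fractions."""

    change: RasterGrid  # +1 increase, -1 decrease, 0 unchanged
    fractions: pd.DataFrame  # index: stratum, columns: increase/decrease/unchanged
    mean_change: pd.Series  # mean (future - current) per stratum


def diversity_change(
    current: RasterGrid,
    future: RasterGrid,
    mountain_mask: RasterGrid,
) -> ChangeSummary:
    """Classify per-cell future-minus-current change and stratify by the
    mountain mask (fractions per stratum sum to 1 over valid cells)."""
    current.require_aligned(future, "diversity_change")
    current.require_aligned(mountain_mask, "diversity_change mask")
    valid = current.mask & future.mask & mountain_mask.mask
    delta = np.where(valid, future.values - current.values, 0)
    cls = np.sign(delta).astype(int)
    change = current.copy_with(cls, valid)

    mountain = mountain_mask.values > 0
    strata = {
        "mountain": valid & mountain,
        "non_mountain": valid & ~mountain,
        "overall": valid,
    }
    rows = {}
    means = {}
    for name, sel in strata.items():
        n = int(sel.sum())
        if n == 0:
            rows[name] = {"increase": np.nan, "decrease": np.nan, "unchanged": np.nan}
            means[name] = np.nan
            continue
        rows[name] = {
            "increase": float((cls[sel] > 0).sum()) / n,
            "decrease": float((cls[sel] < 0).sum()) / n,
            "unchanged": float((cls[sel] == 0).sum()) / n,
        }
        means[name] = float(delta[sel].mean())
    frac = pd.DataFrame.from_dict(rows, orient="index")[["increase", "decrease", "unchanged"]]
    return ChangeSummary(change, frac, pd.Series(means, name="mean_change"))
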