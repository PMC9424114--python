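"""Voronoi neighborhood graphs and the Monte-Carlo proximity test.

Each cell's neighborhood is its Voronoi region, clipped to the tissue
outline; two cells are neighbors when their clipped regions share a
boundary segment of positive length.  Whether CD8+ cells sit next to
Tregs more often than chance is tested per sample by permuting the
category labels over the fixed cell positions (preserving category
counts), recomputing the neighbor count on each permuted cell map, and
flagging the sample as a significant interaction when the observed count
strictly exceeds the nearest-rank 95th percentile of the permuted counts.

Samples without CD8+ cells cannot be evaluated and are excluded; samples
with CD8+ cells but no target cells are classified non-significant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy.sparse import csr_matrix
from scipy.spatial import Delaunay, QhullError
from shapely.geometry import MultiPoint, MultiPolygon, Polygon
from shapely.ops import voronoi_diagram
from shapely.strtree import STRtree

from .io import SampleCellTable, TissueOutline

log = logging.getLogger("tregspatial")

#: minimum shared boundary length (µm) for two clipped Voronoi regions to
#: count as neighbors; excludes point-contact from cocircular degeneracies
EDGE_EPSILON_UM = 1e-6

#: maximum magnitude (µm) of the seeded jitter applied to exact duplicate
#: coordinates before tessellation; far below the 0.5 µm pixel scale
DUPLICATE_JITTER_UM = 0.005

DEFAULT_PERMUTATIONS = 2000
TARGETS = ("FOXP3-any", "tpTreg")


def build_outline(table: SampleCellTable) -> TissueOutline:
    """Tissue outline for spatial analysis.

    Uses the mask-derived outline when present; otherwise falls back to the
    convex hull of the cell coordinates buffered by the median
    nearest-neighbor distance (logged as a warning).
    """
    if table.outline is not None:
        return table.outline
    coords = table.coords
    if len(np.unique(coords, axis=0)) < 3:
        raise ValueError(
            f"sample {table.sample_id}: no tissue mask and fewer than 3 distinct "
            "cells — cannot build an outline"
        )
    from scipy.spatial import cKDTree

    d, _ = cKDTree(coords).query(coords, k=2)
    buffer = float(np.median(d[:, 1]))
    hull = MultiPoint(coords).convex_hull.buffer(buffer)
    log.warning(
        "sample %s: no tissue mask; using buffered convex hull (buffer %.2f µm)",
        table.sample_id, buffer,
    )
    return TissueOutline(MultiPolygon([hull]))


@dataclass
class NeighborGraph:
    """Undirected cell-adjacency graph from a clipped Voronoi tessellation."""

    coords: np.ndarray  # (n, 2) µm, after any duplicate jitter
    categories: np.ndarray  # (n,) str
    adjacency: csr_matrix  # symmetric boolean
    polygons: list = field(repr=False, default_factory=list)  # clipped regions, audit
    n_jittered: int = 0

    @property
    def n_nodes(self) -> int:
        return len(self.coords)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.nnz // 2)

    def category_mask(self, target: str) -> np.ndarray:
        if target == "FOXP3-any":  # a tp-Treg is FOXP3+ by definition
            return np.isin(self.categories, ("FOXP3", "tpTreg"))
        if target in ("CD8", "FOXP3", "tpTreg", "other"):
            return self.categories == target
        raise ValueError(f"unknown category/target '{target}'")


def _resolve_duplicates(coords: np.ndarray, rng: np.random.Generator):
    """Jitter exact duplicate coordinates by a seeded offset < 0.01 µm."""
    out = coords.astype(float).copy()
    _, first, counts = np.unique(out, axis=0, return_index=True, return_counts=True)
    n_dup = int(np.sum(counts > 1))
    if n_dup == 0:
        return out, 0
    seen = set()
    n_moved = 0
    for i in range(len(out)):
        key = (out[i, 0], out[i, 1])
        if key in seen:
            out[i] += rng.uniform(-DUPLICATE_JITTER_UM, DUPLICATE_JITTER_UM, 2)
            n_moved += 1
        else:
            seen.add(key)
    if len(np.unique(out, axis=0)) < len(out):
        raise ValueError("coincident cells remain after duplicate jitter")
    log.debug("jittered %d duplicate coordinates", n_moved)
    return out, n_moved


def _voronoi_cells(coords: np.ndarray, outline: TissueOutline) -> np.ndarray:
    """Clipped Voronoi region per site, matched back to sites by containment."""
    pts = MultiPoint([tuple(p) for p in coords])
    envelope = shapely.box(*outline.geometry.buffer(1.0).bounds)
    raw = voronoi_diagram(pts, envelope=envelope)
    cells = list(raw.geoms)
    tree = STRtree(cells)
    site_pts = shapely.points(coords[:, 0], coords[:, 1])
    pt_idx, cell_idx = tree.query(site_pts, predicate="within")
    if len(pt_idx) != len(coords) or len(set(pt_idx.tolist())) != len(coords):
        # boundary-precision fallback: nearest cell by distance
        mapping = np.full(len(coords), -1, int)
        mapping[pt_idx] = cell_idx
        for i in np.flatnonzero(mapping < 0):
            mapping[i] = int(np.argmin([site_pts[i].distance(c) for c in cells]))
        cell_idx = mapping
        pt_idx = np.arange(len(coords))
    ordered = np.empty(len(coords), object)
    ordered[pt_idx] = [cells[j] for j in cell_idx]
    return shapely.intersection(ordered, outline.geometry)


def _candidate_edges(coords: np.ndarray) -> np.ndarray:
    """Delaunay edges as candidates for Voronoi adjacency (any shared Voronoi
    boundary corresponds to a Delaunay edge); degenerate inputs fall back to
    all pairs, which the shared-boundary test then filters."""
    n = len(coords)
    if n < 2:
        return np.empty((0, 2), int)
    try:
        tri = Delaunay(coords)
        edges = set()
        for simplex in tri.simplices:
            for a in range(3):
                i, j = int(simplex[a]), int(simplex[(a + 1) % 3])
                edges.add((min(i, j), max(i, j)))
        return np.array(sorted(edges), int)
    except QhullError:
        ii, jj = np.triu_indices(n, k=1)
        return np.column_stack([ii, jj])


def voronoi_neighbor_graph(
    table: SampleCellTable,
    categories: pd.Series | np.ndarray,
    outline: TissueOutline | None = None,
    seed: int = 0,
) -> NeighborGraph:
    """Build the clipped Voronoi neighbor graph for one sample.

    Adjacency requires a shared boundary longer than ``EDGE_EPSILON_UM`` on
    the outline-clipped regions, so holes and excluded tissue break
    adjacency across them.  Exact duplicate coordinates are jittered by a
    seeded sub-0.01 µm offset first.
    """
    outline = outline if outline is not None else build_outline(table)
    coords = table.coords
    n = len(coords)
    cats = np.asarray(categories, str)
    if cats.shape[0] != n:
        raise ValueError("categories length does not match cell count")
    rng = np.random.default_rng([seed, 0x7E55])
    coords, n_jittered = _resolve_duplicates(coords, rng)
    if n < 1 or len(np.unique(coords, axis=0)) < 1:
        raise ValueError("no cells to tessellate")

    if n == 1:
        adj = csr_matrix((1, 1), dtype=bool)
        return NeighborGraph(coords, cats, adj, polygons=[outline.geometry],
                             n_jittered=n_jittered)

    polys = _voronoi_cells(coords, outline)
    cand = _candidate_edges(coords)
    if len(cand):
        shared = shapely.intersection(polys[cand[:, 0]], polys[cand[:, 1]])
        keep = shapely.length(shared) > EDGE_EPSILON_UM
        edges = cand[keep]
    else:
        edges = cand
    if len(edges):
        rows = np.concatenate([edges[:, 0], edges[:, 1]])
        cols = np.concatenate([edges[:, 1], edges[:, 0]])
        adj = csr_matrix(
            (np.ones(len(rows), bool), (rows, cols)), shape=(n, n), dtype=bool
        )
    else:
        adj = csr_matrix((n, n), dtype=bool)
    return NeighborGraph(coords, cats, adj, polygons=list(polys), n_jittered=n_jittered)


def neighbor_count(graph: NeighborGraph, source: str = "CD8",
                   target: str = "tpTreg") -> int:
    """Number of source-category cells with at least one target neighbor."""
    src = graph.category_mask(source)
    tgt = graph.category_mask(target)
    has_target_neighbor = graph.adjacency.dot(tgt.astype(np.int32)) > 0
    return int(np.sum(src & has_target_neighbor))


def neighbor_fraction(graph: NeighborGraph, source: str = "CD8",
                      target: str = "tpTreg") -> float:
    """Fraction of source cells with >= 1 target neighbor (undefined without
    source cells)."""
    n_src = int(graph.category_mask(source).sum())
    if n_src == 0:
        raise ValueError(f"no {source} cells: neighbor fraction undefined")
    return neighbor_count(graph, source, target) / n_src


@dataclass
class ProximityResult:
    sample_id: str
    target: str
    k_obs: int
    B: int
    permuted: np.ndarray = field(repr=False, default=None)
    q95: int | None = None
    classification: str = "non_significant"  # significant / non_significant / excluded
    seed: int | None = None
    n_CD8: int = 0
    n_target: int = 0


def permutation_proximity_test(
    graph: NeighborGraph,
    target: str = "tpTreg",
    B: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
    source: str = "CD8",
    sample_id: str = "",
) -> ProximityResult:
    """Monte-Carlo permutation test of spatial proximity within one sample.

    Cell positions and the per-category cell counts stay fixed while the
    category labels are randomized over the cell map ``B`` times (default
    2000).  The observed neighbor count is significant when strictly above
    the nearest-rank 95th percentile of the permuted counts; ties at the
    critical value are non-significant.
    """
    if B < 20:
        raise ValueError("B < 20 permutations makes the 95th percentile meaningless")
    src_mask = graph.category_mask(source)
    n_src = int(src_mask.sum())
    if n_src == 0:
        raise ValueError(f"no {source} cells; classify with classify_sample_proximity")
    tgt_mask = graph.category_mask(target)
    k_obs = neighbor_count(graph, source, target)

    rng = np.random.default_rng(seed)
    n = graph.n_nodes
    # canonical node order (lexicographic on coordinates) so the permuted
    # distribution is invariant to how the input cells were ordered
    order = np.lexsort((graph.coords[:, 1], graph.coords[:, 0]))
    adj = graph.adjacency[order][:, order].astype(np.int32)
    src_int = src_mask[order].astype(np.int32)
    tgt_int = tgt_mask[order].astype(np.int32)
    permuted = np.empty(B, dtype=np.int64)
    for b in range(B):
        perm = rng.permutation(n)
        t_p = tgt_int[perm]
        s_p = src_int[perm]
        permuted[b] = int(np.sum((adj.dot(t_p) > 0) & (s_p > 0)))

    order = np.sort(permuted)
    q95 = int(order[int(np.ceil(0.95 * B)) - 1])  # nearest rank
    classification = "significant" if k_obs > q95 else "non_significant"
    return ProximityResult(
        sample_id=sample_id, target=target, k_obs=k_obs, B=B, permuted=permuted,
        q95=q95, classification=classification, seed=seed,
        n_CD8=n_src, n_target=int(tgt_mask.sum()),
    )


def classify_sample_proximity(
    table: SampleCellTable,
    categories: pd.Series | np.ndarray,
    target: str = "tpTreg",
    B: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
    outline: TissueOutline | None = None,
) -> ProximityResult:
    """Full per-sample proximity classification with the exclusion rules.

    Samples without CD8+ cells are excluded from spatial analysis; samples
    without target cells are classified non-significant without permuting.
    """
    cats = np.asarray(categories, str)
    n_cd8 = int(np.sum(cats == "CD8"))
    if target == "FOXP3-any":
        n_tgt = int(np.sum(np.isin(cats, ("FOXP3", "tpTreg"))))
    else:
        n_tgt = int(np.sum(cats == target))
    if n_cd8 == 0:
        return ProximityResult(
            sample_id=table.sample_id, target=target, k_obs=0, B=B,
            classification="excluded", seed=seed, n_CD8=0, n_target=n_tgt,
        )
    if n_tgt == 0:
        return ProximityResult(
            sample_id=table.sample_id, target=target, k_obs=0, B=B,
            classification="non_significant", seed=seed, n_CD8=n_cd8, n_target=0,
        )
    graph = voronoi_neighbor_graph(table, cats, outline=outline, seed=seed)
    return permutation_proximity_test(
        graph, target=target, B=B, seed=seed, sample_id=table.sample_id
    )


CATEGORY_COLORS = {"CD8": "#2ca02c", "FOXP3": "#d62728", "tpTreg": "#9467bd",
                   "other": "#d9d9d9"}


def plot_voronoi(graph: NeighborGraph, path, title: str | None = None) -> None:
    """Render the clipped Voronoi diagram colored by category (audit aid)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Polygon as MplPolygon

    fig, ax = plt.subplots(figsize=(6, 6))
    for poly, cat in zip(graph.polygons, graph.categories):
        if poly is None or poly.is_empty:
            continue
        geoms = getattr(poly, "geoms", [poly])
        for g in geoms:
            if g.geom_type != "Polygon":
                continue
            ax.add_patch(
                MplPolygon(np.asarray(g.exterior.coords),
                           facecolor=CATEGORY_COLORS.get(str(cat), "#ffffff"),
                           edgecolor="black", linewidth=0.3)
            )
    ax.autoscale_view()
    ax.set_aspect("equal")
    ax.set_xlabel("x (µm)")
    ax.set_ylabel("y (µm)")
    if title:
        ax.set_title(title)
    fig.savefig(path)
    plt.close(fig)


def proximity_results_to_frame(results) -> pd.DataFrame:
    rows = []
    for r in results:
        perm = r.permuted
        rows.append(
            {
                "sample_id": r.sample_id,
                "target": r.target,
                "n_CD8": r.n_CD8,
                "n_target": r.n_target,
                "k_obs": r.k_obs,
                "B": r.B,
                "q95": r.q95,
                "perm_mean": float(np.mean(perm)) if perm is not None else None,
                "perm_sd": float(np.std(perm)) if perm is not None else None,
                "classification": r.classification,
                "seed": r.seed,
            }
        )
    return pd.DataFrame(rows)
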