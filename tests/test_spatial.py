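"""Voronoi neighbor graphs and the permutation proximity test."""

import itertools

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import MultiPolygon, Point

from tregspatial import (
    SyntheticConfig,
    TissueOutline,
    build_outline,
    classify_sample_proximity,
    generate_sample,
    neighbor_count,
    neighbor_fraction,
    permutation_proximity_test,
    spatial_calibration_config,
    voronoi_neighbor_graph,
)

from conftest import make_table


def brute_delaunay_edges(pts, tol=1e-7):
    """Independent Delaunay oracle: empty-circumcircle test over all triples."""
    pts = np.asarray(pts, float)
    n = len(pts)
    edges = set()
    for i, j, k in itertools.combinations(range(n), 3):
        a, b, c = pts[i], pts[j], pts[k]
        m = 2.0 * np.array([b - a, c - a])
        rhs = np.array([b @ b - a @ a, c @ c - a @ a])
        det = m[0, 0] * m[1, 1] - m[0, 1] * m[1, 0]
        if abs(det) < 1e-12:
            continue  # collinear
        centre = np.linalg.solve(m, rhs)
        r = np.hypot(*(a - centre))
        d = np.hypot(pts[:, 0] - centre[0], pts[:, 1] - centre[1])
        others = np.ones(n, bool)
        others[[i, j, k]] = False
        if np.all(d[others] > r - tol):
            edges.update({(min(i, j), max(i, j)), (min(j, k), max(j, k)),
                          (min(i, k), max(i, k))})
    return edges


def graph_edges(graph):
    rows, cols = graph.adjacency.nonzero()
    return {(int(i), int(j)) for i, j in zip(rows, cols) if i < j}


def interior_points(pts):
    from scipy.spatial import ConvexHull

    hull = set(ConvexHull(pts).vertices.tolist())
    return set(range(len(pts))) - hull


def random_disc_points(rng, n=30, radius=500.0, centre=(500.0, 500.0)):
    r = radius * np.sqrt(rng.uniform(size=n))
    ang = rng.uniform(0, 2 * np.pi, n)
    return np.column_stack([centre[0] + r * np.cos(ang),
                            centre[1] + r * np.sin(ang)])


def test_voronoi_adjacency_matches_brute_force_delaunay():
    """Interior-pair adjacency equals the empty-circumcircle oracle on
    random point sets in a disc (outline far away, so clipping is inert)."""
    rng = np.random.default_rng(123)
    big = TissueOutline(MultiPolygon([Point(500, 500).buffer(2000.0)]))
    for _ in range(10):
        pts = random_disc_points(rng)
        t = make_table(pts)
        graph = voronoi_neighbor_graph(t, ["other"] * len(pts), outline=big)
        interior = interior_points(pts)
        got = {e for e in graph_edges(graph)
               if e[0] in interior and e[1] in interior}
        expected = {e for e in brute_delaunay_edges(pts)
                    if e[0] in interior and e[1] in interior}
        assert got == expected


def test_two_points_single_edge(disc_outline):
    t = make_table([[400, 500], [600, 500]])
    g = voronoi_neighbor_graph(t, ["CD8", "tpTreg"], outline=disc_outline)
    assert g.n_edges == 1


def test_single_point_no_edges(disc_outline):
    t = make_table([[500, 500]])
    g = voronoi_neighbor_graph(t, ["CD8"], outline=disc_outline)
    assert g.n_edges == 0


def test_duplicate_coordinates_jittered(disc_outline):
    t = make_table([[500, 500], [500, 500], [300, 300]])
    g = voronoi_neighbor_graph(t, ["CD8"] * 3, outline=disc_outline, seed=1)
    assert g.n_jittered == 1
    assert len(np.unique(g.coords, axis=0)) == 3
    assert np.abs(g.coords[1] - [500, 500]).max() < 0.01


def test_symmetry_and_planarity(disc_outline):
    rng = np.random.default_rng(77)
    for _ in range(5):
        pts = random_disc_points(rng, n=60)
        t = make_table(pts)
        g = voronoi_neighbor_graph(t, ["other"] * 60, outline=disc_outline)
        assert (g.adjacency != g.adjacency.T).nnz == 0
        assert g.adjacency.diagonal().sum() == 0
        assert g.n_edges <= 3 * g.n_nodes - 6


def test_clipping_breaks_adjacency_across_hole():
    """Two cells separated by a hole in the tissue are not neighbors even
    though their unclipped Voronoi regions touch."""
    ring = Point(500, 500).buffer(400.0).difference(Point(500, 500).buffer(150.0))
    outline = TissueOutline(MultiPolygon([ring]))
    # two cells on opposite sides of the hole plus flankers
    pts = np.array([[330, 500], [670, 500], [500, 170], [500, 830]])
    t = make_table(pts)
    g = voronoi_neighbor_graph(t, ["CD8", "tpTreg", "other", "other"],
                               outline=outline)
    assert (0, 1) not in graph_edges(g)


def test_build_outline_fallback_contains_cells():
    rng = np.random.default_rng(5)
    pts = random_disc_points(rng, n=100)
    t = make_table(pts)
    outline = build_outline(t)
    assert outline.contains_points(pts[:, 0], pts[:, 1]).all()
    with pytest.raises(ValueError, match="3 distinct"):
        build_outline(make_table([[0, 0], [1, 1]]))


def test_neighbor_count_matches_scan_oracle(disc_outline):
    rng = np.random.default_rng(8)
    pts = random_disc_points(rng, n=50)
    cats = rng.choice(["CD8", "FOXP3", "tpTreg", "other"], 50,
                      p=[0.3, 0.2, 0.1, 0.4])
    g = voronoi_neighbor_graph(make_table(pts), cats, outline=disc_outline)
    adj = g.adjacency.toarray()
    for target, accepted in (("tpTreg", {"tpTreg"}),
                             ("FOXP3-any", {"FOXP3", "tpTreg"})):
        oracle = sum(
            1 for i in range(50)
            if cats[i] == "CD8" and any(
                adj[i, j] and cats[j] in accepted for j in range(50))
        )
        assert neighbor_count(g, "CD8", target) == oracle
        assert neighbor_fraction(g, "CD8", target) == pytest.approx(
            oracle / (cats == "CD8").sum())


def test_neighbor_fraction_requires_source(disc_outline):
    g = voronoi_neighbor_graph(make_table([[400, 500], [600, 500]]),
                               ["other", "tpTreg"], outline=disc_outline)
    assert neighbor_count(g, "CD8", "tpTreg") == 0
    with pytest.raises(ValueError, match="CD8"):
        neighbor_fraction(g, "CD8", "tpTreg")


def test_permutation_invariant_two_cell_configuration(disc_outline):
    """One CD8 and one tp-Treg, mutually adjacent: every permutation gives
    k = 1, so the observed count can never exceed the critical value."""
    g = voronoi_neighbor_graph(make_table([[400, 500], [600, 500]]),
                               ["CD8", "tpTreg"], outline=disc_outline)
    res = permutation_proximity_test(g, target="tpTreg", B=100, seed=3)
    assert res.k_obs == 1
    assert set(res.permuted.tolist()) == {1}
    assert res.classification == "non_significant"


def test_no_targets_is_non_significant():
    cfg = SyntheticConfig(n_samples=1, p_tptreg=0.02, seed=4)
    t, truth = generate_sample(cfg, 0, return_truth=True)
    truth = truth.replace("tpTreg", "other")
    res = classify_sample_proximity(t, truth, target="tpTreg", B=50, seed=0)
    assert res.k_obs == 0 and res.classification == "non_significant"


def test_no_cd8_is_excluded():
    cfg = SyntheticConfig(n_samples=1, seed=4)
    t, truth = generate_sample(cfg, 0, return_truth=True)
    truth = truth.replace("CD8", "other")
    res = classify_sample_proximity(t, truth, target="tpTreg", B=50, seed=0)
    assert res.classification == "excluded"


def test_permutation_distribution_invariant_to_node_order(disc_outline):
    rng = np.random.default_rng(31)
    pts = random_disc_points(rng, n=80)
    cats = rng.choice(["CD8", "FOXP3", "tpTreg", "other"], 80,
                      p=[0.2, 0.15, 0.1, 0.55])
    g1 = voronoi_neighbor_graph(make_table(pts), cats, outline=disc_outline)
    r1 = permutation_proximity_test(g1, target="tpTreg", B=200, seed=5)
    perm = rng.permutation(80)
    g2 = voronoi_neighbor_graph(make_table(pts[perm]), cats[perm],
                                outline=disc_outline)
    r2 = permutation_proximity_test(g2, target="tpTreg", B=200, seed=5)
    assert r1.k_obs == r2.k_obs
    assert sorted(r1.permuted.tolist()) == sorted(r2.permuted.tolist())
    assert r1.q95 == r2.q95


def test_voronoi_plot_written(tmp_path, disc_outline):
    from tregspatial.spatial import plot_voronoi

    rng = np.random.default_rng(2)
    pts = random_disc_points(rng, n=40)
    cats = rng.choice(["CD8", "FOXP3", "tpTreg", "other"], 40)
    g = voronoi_neighbor_graph(make_table(pts), cats, outline=disc_outline)
    out = tmp_path / "voronoi.svg"
    plot_voronoi(g, out, title="audit")
    assert out.stat().st_size > 1000


def test_permutation_needs_enough_draws(disc_outline):
    g = voronoi_neighbor_graph(make_table([[400, 500], [600, 500]]),
                               ["CD8", "tpTreg"], outline=disc_outline)
    with pytest.raises(ValueError, match="B"):
        permutation_proximity_test(g, B=10)


def test_type_one_error_at_desk_scale_cellularity():
    """Under the null (theta = 0) at ~300 cells per core the strict
    95th-percentile rule is conservative: flag rate stays below 8%."""
    cfg = SyntheticConfig(n_samples=120, theta=0.0, fixed_counts=True, seed=5)
    flags = 0
    for i in range(cfg.n_samples):
        t, truth = generate_sample(cfg, i, return_truth=True)
        res = classify_sample_proximity(t, truth, target="tpTreg", B=300,
                                        seed=500 + i)
        flags += res.classification == "significant"
    assert flags / cfg.n_samples <= 0.08


def test_fraction_tracks_abundance_more_than_classification():
    """Under the null the neighbor fraction is strongly driven by target
    abundance, while the permutation classification is not — the rationale
    for preferring the permutation score."""
    cfg = SyntheticConfig(n_samples=60, theta=0.0, seed=6)
    fracs, sig, abund = [], [], []
    for i in range(cfg.n_samples):
        t, truth = generate_sample(cfg, i, return_truth=True)
        cats = truth.to_numpy()
        if (cats == "CD8").sum() == 0 or (cats == "tpTreg").sum() == 0:
            continue
        g = voronoi_neighbor_graph(t, cats, seed=i)
        fracs.append(neighbor_fraction(g, "CD8", "tpTreg"))
        res = permutation_proximity_test(g, target="tpTreg", B=200, seed=700 + i)
        sig.append(res.classification == "significant")
        abund.append(np.log2((cats == "tpTreg").sum() + 1))
    rho = np.corrcoef(fracs, abund)[0, 1]
    assert rho > 0.5
    sig = np.asarray(sig, float)
    if 0 < sig.mean() < 1:
        pb = abs(np.corrcoef(sig, abund)[0, 1])
        assert pb < rho
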