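"""Clustering: normalization, the 1-|cor| dissimilarity, single-linkage
agglomeration against brute-force oracles, tree cuts, and COI selection."""

import numpy as np
import pytest
from _oracles import (
    naive_single_linkage_heights,
    prim_mst_weights,
    threshold_components,
)
from conftest import make_universe
from scipy.spatial.distance import squareform

from exomatch.cluster import (
    MetricMatrix,
    build_tree,
    cut_tree,
    dissimilarity_matrix,
    gene_dissimilarity,
    height_scan,
    normalize_metrics,
    select_coi,
)


def _random_matrix(p, seed):
    rng = np.random.default_rng(seed)
    return MetricMatrix(
        rng.standard_normal((10, p)), tuple(f"G{i:03d}" for i in range(p))
    )


# ---------------------------------------------------------------- normalize


def test_normalize_zero_mean_unit_sample_sd(small_universe):
    m = normalize_metrics(small_universe)
    np.testing.assert_allclose(m.values.mean(axis=1), 0.0, atol=1e-8)
    np.testing.assert_allclose(m.values.std(axis=1, ddof=1), 1.0, atol=1e-8)


def test_normalize_simple_row():
    # a metric taking values (1, 2, 3) z-scores to (-1, 0, 1) (sample sd = 1)
    u = make_universe(["A", "B", "C"], seed=0)
    u.frame["oe_lof"] = [1.0, 2.0, 3.0]
    m = normalize_metrics(u)
    np.testing.assert_allclose(m.values[0], [-1.0, 0.0, 1.0], atol=1e-12)


def test_normalize_idempotent(small_universe):
    # z-scoring an already z-scored matrix changes nothing
    m1 = normalize_metrics(small_universe)
    mean = m1.values.mean(axis=1, keepdims=True)
    sd = m1.values.std(axis=1, ddof=1, keepdims=True)
    again = (m1.values - mean) / sd
    np.testing.assert_allclose(again, m1.values, atol=1e-8)


def test_normalize_constant_metric_rejected(small_universe):
    u = small_universe.frame.copy()
    u["pli"] = 0.5
    from exomatch.constraints import ConstraintUniverse

    with pytest.raises(ValueError, match="pli"):
        normalize_metrics(ConstraintUniverse(u))


# ------------------------------------------------------------ dissimilarity


def test_dissimilarity_identity_and_negation():
    x = np.array([0.3, -1.2, 0.8, 2.0, -0.5])
    assert gene_dissimilarity(x, x) == pytest.approx(0.0, abs=1e-12)
    assert gene_dissimilarity(x, -x) == pytest.approx(0.0, abs=1e-12)


def test_dissimilarity_orthogonal_patterns():
    xi = np.array([1.0, -1.0, 1.0, -1.0])
    xj = np.array([1.0, 1.0, -1.0, -1.0])
    assert gene_dissimilarity(xi, xj) == pytest.approx(1.0)


def test_dissimilarity_symmetric_bounded():
    rng = np.random.default_rng(0)
    for _ in range(20):
        a, b = rng.standard_normal((2, 10))
        d1, d2 = gene_dissimilarity(a, b), gene_dissimilarity(b, a)
        assert d1 == pytest.approx(d2, abs=1e-12)
        assert 0.0 <= d1 <= 1.0


def test_dissimilarity_zero_variance_rejected():
    with pytest.raises(ValueError):
        gene_dissimilarity(np.ones(5), np.arange(5.0))


def test_dissimilarity_matrix_matches_pairwise():
    m = _random_matrix(12, seed=3)
    d = squareform(dissimilarity_matrix(m))
    for i in range(12):
        for j in range(i + 1, 12):
            expected = gene_dissimilarity(m.values[:, i], m.values[:, j])
            assert d[i, j] == pytest.approx(expected, abs=1e-12)


# ------------------------------------------------------------------- trees


@pytest.mark.parametrize("p,seed", [(6, 0), (20, 1), (50, 2)])
def test_merge_heights_match_naive_agglomeration(p, seed):
    m = _random_matrix(p, seed=seed)
    tree = build_tree(m)
    d = squareform(dissimilarity_matrix(m))
    expected = naive_single_linkage_heights(d)
    np.testing.assert_allclose(tree.heights, expected, atol=1e-10)


@pytest.mark.parametrize("p,seed", [(10, 5), (30, 6), (50, 7)])
def test_merge_heights_equal_mst_edge_weights(p, seed):
    m = _random_matrix(p, seed=seed)
    tree = build_tree(m)
    d = squareform(dissimilarity_matrix(m))
    np.testing.assert_allclose(
        np.sort(tree.heights), np.sort(prim_mst_weights(d)), atol=1e-10
    )


def test_two_genes_single_merge():
    m = _random_matrix(2, seed=9)
    tree = build_tree(m)
    expected = gene_dissimilarity(m.values[:, 0], m.values[:, 1])
    assert tree.linkage.shape == (1, 4)
    assert tree.heights[0] == pytest.approx(expected, abs=1e-12)


def test_heights_monotone_nondecreasing():
    for seed in range(5):
        tree = build_tree(_random_matrix(25, seed=seed))
        assert np.all(np.diff(tree.heights) >= -1e-12)


def test_newick_roundtrip_leaf_count():
    tree = build_tree(_random_matrix(8, seed=1))
    nwk = tree.to_newick()
    assert nwk.endswith(";")
    for leaf in tree.leaves:
        assert leaf in nwk


# -------------------------------------------------------------------- cuts


def test_cut_boundaries():
    m = _random_matrix(40, seed=4)
    tree = build_tree(m)
    low = cut_tree(tree, 0.0)
    assert low.n_clusters == 40  # distinct continuous profiles: no 0 merges
    high = cut_tree(tree, 1.0)
    assert high.n_clusters == 1


def test_cut_just_below_first_merge_gives_singletons():
    tree = build_tree(_random_matrix(15, seed=8))
    h = float(tree.heights.min()) - 1e-9
    assert cut_tree(tree, max(h, 0.0)).n_clusters == 15


def test_cut_outside_range_rejected():
    tree = build_tree(_random_matrix(5, seed=0))
    for h in (-0.1, 1.1):
        with pytest.raises(ValueError):
            cut_tree(tree, h)


@pytest.mark.parametrize("h", [0.3, 0.6, 0.9])
def test_cut_matches_threshold_graph_components(h):
    """Genes share a flat cluster iff connected through edges d <= h."""
    m = _random_matrix(30, seed=10)
    tree = build_tree(m)
    d = squareform(dissimilarity_matrix(m))
    ours = cut_tree(tree, h).labels
    oracle = threshold_components(d, h)
    # same partition up to label renaming
    pairs_ours = np.equal.outer(ours, ours)
    pairs_oracle = np.equal.outer(oracle, oracle)
    np.testing.assert_array_equal(pairs_ours, pairs_oracle)


def test_cut_refinement_monotonicity():
    tree = build_tree(_random_matrix(35, seed=11))
    heights = np.linspace(0, 1, 7)
    parts = [cut_tree(tree, h) for h in heights]
    for fine, coarse in zip(parts, parts[1:]):
        same_fine = np.equal.outer(fine.labels, fine.labels)
        same_coarse = np.equal.outer(coarse.labels, coarse.labels)
        assert np.all(same_coarse[same_fine])  # co-membership never lost


# --------------------------------------------------------------------- COI


def test_select_coi_singletons():
    m = _random_matrix(30, seed=12)
    tree = build_tree(m)
    part = cut_tree(tree, 0.0)
    goi = frozenset(list(m.gene_order)[:5])
    sel = select_coi(part, goi)
    assert sel.total_genes == 5
    assert sel.proportion == pytest.approx(5 / 30)
    assert sel.control_genes == frozenset()


def test_select_coi_whole_universe():
    m = _random_matrix(20, seed=13)
    tree = build_tree(m)
    sel = select_coi(cut_tree(tree, 1.0), frozenset([m.gene_order[0]]))
    assert sel.median_coi_size == 20
    assert sel.proportion == pytest.approx(1.0)
    assert len(sel.control_genes) == 19


def test_two_goi_in_one_cluster_counted_once():
    m = _random_matrix(20, seed=14)
    tree = build_tree(m)
    part = cut_tree(tree, 1.0)
    sel = select_coi(part, frozenset(list(m.gene_order)[:2]))
    assert len(sel.coi_cluster_ids) == 1


def test_goi_absent_from_partition_rejected():
    m = _random_matrix(10, seed=15)
    part = cut_tree(build_tree(m), 0.5)
    with pytest.raises(ValueError, match="MISSING"):
        select_coi(part, frozenset(["MISSING"]))


def test_coi_invariants():
    m = _random_matrix(40, seed=16)
    part = cut_tree(build_tree(m), 0.4)
    goi = frozenset(list(m.gene_order)[::7])
    sel = select_coi(part, goi)
    assert not (sel.control_genes & sel.goi)
    assert sel.total_genes == len(sel.control_genes) + len(goi)


# ------------------------------------------------------------- height scan


def test_height_scan_boundary_rows():
    m = _random_matrix(30, seed=17)
    tree = build_tree(m)
    goi = frozenset(list(m.gene_order)[:4])
    scan = height_scan(tree, goi, [0.0, 1.0])
    assert scan.iloc[0]["total_genes"] == 4
    assert scan.iloc[-1]["proportion"] == pytest.approx(1.0)


def test_height_scan_proportion_monotone(sim_tree, sim_universe):
    goi = frozenset(list(sim_universe.symbols)[::500])
    scan = height_scan(tree=sim_tree, goi=goi, heights=[0, 0.05, 0.1, 0.5, 1.0])
    assert scan["proportion"].is_monotonic_increasing


def test_height_scan_toy_matches_enumeration():
    """p=8 with one GOI: totals at every merge height agree with the
    exhaustive threshold-graph enumeration of the 7 merges."""
    m = _random_matrix(8, seed=18)
    tree = build_tree(m)
    d = squareform(dissimilarity_matrix(m))
    goi_gene = m.gene_order[3]
    heights = sorted(tree.heights) + [1.0]
    scan = height_scan(tree, frozenset([goi_gene]), heights)
    for h, total in zip(scan["height"], scan["total_genes"]):
        comp = threshold_components(d, h)
        expected = int(np.sum(comp == comp[3]))
        assert total == expected


def test_height_scan_empty_heights_rejected():
    tree = build_tree(_random_matrix(5, seed=0))
    with pytest.raises(ValueError):
        height_scan(tree, frozenset([tree.leaves[0]]), [])
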