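"""Tests of the co-expression network, TOM, paths, and the clustering test."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mutexpr import coexpression as cx


def _network_from_correlation(cor, cor_floor=0.1):
    """A CoexprNetwork wrapping a given correlation matrix (paths only)."""
    cor = np.asarray(cor, dtype=float)
    n = cor.shape[0]
    ids = np.array([f"g{i}" for i in range(n)])
    adj = np.abs(cor) ** 2
    np.fill_diagonal(adj, 1.0)
    labels = np.zeros(n, dtype=int)
    conn = pd.DataFrame(
        {"gene_id": ids, "module": labels, "k_total": adj.sum(0) - 1,
         "k_intra": adj.sum(0) - 1, "is_hub": False}
    )
    return cx.CoexprNetwork(
        gene_ids=ids, correlation=cor, adjacency=adj,
        tom=cx.topological_overlap(adj),
        modules=pd.Series(labels, index=ids), connectivity=conn,
        beta=2.0, cor_floor=cor_floor,
    )


# -- TOM --------------------------------------------------------------------


def test_tom_perfectly_correlated_pair_is_one():
    rng = np.random.default_rng(0)
    base = rng.normal(0, 1, 10)
    expr = pd.DataFrame([base, 2 * base + 3], index=["a", "b"])
    cor = np.corrcoef(expr)
    adj = np.abs(cor) ** 2
    tom = cx.topological_overlap(adj)
    assert adj[0, 1] == pytest.approx(1.0)
    assert tom[0, 1] == pytest.approx(1.0)


def test_tom_matches_hand_formula_on_4x4():
    a = np.array(
        [
            [1.0, 0.64, 0.09, 0.25],
            [0.64, 1.0, 0.16, 0.04],
            [0.09, 0.16, 1.0, 0.49],
            [0.25, 0.04, 0.49, 1.0],
        ]
    )
    tom = cx.topological_overlap(a)
    k = a.sum(axis=0) - 1.0
    for i in range(4):
        for j in range(4):
            if i == j:
                assert tom[i, j] == 1.0
                continue
            l = sum(a[i, u] * a[u, j] for u in range(4) if u not in (i, j))
            expect = (l + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
            assert tom[i, j] == pytest.approx(expect, rel=1e-12)


def test_tom_invariants(modular_network):
    net, _ = modular_network
    tom = net.tom
    assert np.allclose(tom, tom.T)
    assert np.allclose(np.diag(tom), 1.0)
    assert tom.min() >= 0.0 and tom.max() <= 1.0


def test_network_outputs_permute_with_gene_order(modular_expression):
    expr, _ = modular_expression
    expr = expr.iloc[:30]
    net = cx.build_network(expr, n_modules_target=5)
    rng = np.random.default_rng(1)
    perm = rng.permutation(len(expr))
    net_p = cx.build_network(expr.iloc[perm], n_modules_target=5)
    assert list(net_p.gene_ids) == list(net.gene_ids[perm])
    assert np.allclose(net_p.tom, net.tom[np.ix_(perm, perm)])
    # module labels relabel consistently: same partition of gene ids
    part = {frozenset(net.modules.index[net.modules == m])
            for m in net.modules.unique()}
    part_p = {frozenset(net_p.modules.index[net_p.modules == m])
              for m in net_p.modules.unique()}
    assert part == part_p


def test_build_network_requires_observations_and_drops_constants():
    rng = np.random.default_rng(2)
    with pytest.raises(ValueError, match="observations"):
        cx.build_network(pd.DataFrame(rng.normal(size=(5, 3))))
    expr = pd.DataFrame(rng.normal(size=(6, 10)))
    expr.iloc[2] = 7.0  # constant gene
    with pytest.warns(UserWarning, match="constant"):
        net = cx.build_network(expr, n_modules_target=2)
    assert net.n_genes == 5


def test_module_recovery_and_merge_properties(modular_network):
    net, module_of = modular_network
    # planted 6-module structure is recovered exactly
    assert net.modules.nunique() == 6
    labels = net.modules.to_numpy()
    for m in np.unique(labels):
        assert len(set(module_of[labels == m])) == 1


def test_merging_reduces_modules_and_caps_eigengene_correlation(
    modular_expression,
):
    expr, _ = modular_expression
    net = cx.build_network(expr, n_modules_target=12, merge_threshold=0.75)
    vals = expr.to_numpy()
    expr_std = (vals - vals.mean(1, keepdims=True)) / vals.std(1, keepdims=True)
    labels = net.modules.to_numpy()
    mods = np.unique(labels)
    assert mods.size <= 12
    if mods.size >= 2:
        eig = np.array([cx._eigengene(expr_std[labels == m]) for m in mods])
        c = np.corrcoef(eig)
        np.fill_diagonal(c, -np.inf)
        assert c.max() < 0.75


def test_hub_count_is_ceil_of_five_percent(modular_network):
    net, _ = modular_network
    conn = net.connectivity
    for _, grp in conn.groupby("module"):
        assert grp["is_hub"].sum() == math.ceil(cx.HUB_FRACTION * len(grp))
        # hubs have the largest intramodular connectivity in their module
        assert grp.loc[grp["is_hub"], "k_intra"].min() >= \
            grp.loc[~grp["is_hub"], "k_intra"].max() - 1e-12


# -- shortest paths ---------------------------------------------------------


def test_single_edge_distance_is_inverse_correlation():
    cor = np.array([[1.0, 0.5], [0.5, 1.0]])
    net = _network_from_correlation(cor)
    out = cx.deg_path_distances(net, ["g0", "g1"])
    assert len(out) == 1
    assert out["distance"].iloc[0] == pytest.approx(2.0)


def test_paths_match_exhaustive_enumeration_on_toy_graph():
    rng = np.random.default_rng(3)
    n = 6
    cor = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            c = rng.uniform(-0.9, 0.9) if rng.random() < 0.7 else 0.0
            cor[i, j] = cor[j, i] = c
    np.fill_diagonal(cor, 1.0)
    floor = 0.1
    net = _network_from_correlation(cor, cor_floor=floor)
    out = cx.deg_path_distances(net, [f"g{i}" for i in range(n)])
    got = {(r["gene_a"], r["gene_b"]): r["distance"] for _, r in out.iterrows()}
    # brute force over every simple path
    for a in range(n):
        for b in range(a + 1, n):
            best = np.inf
            for k in range(0, n - 1):
                for mids in itertools.permutations(
                    [v for v in range(n) if v not in (a, b)], k
                ):
                    path = (a, *mids, b)
                    length = 0.0
                    ok = True
                    for u, v in zip(path, path[1:]):
                        c = abs(cor[u, v])
                        if c < floor:
                            ok = False
                            break
                        length += 1.0 / c
                    if ok:
                        best = min(best, length)
            if np.isinf(best):
                assert (f"g{a}", f"g{b}") not in got
            else:
                assert got[(f"g{a}", f"g{b}")] == pytest.approx(best, rel=1e-9)


def test_adding_an_edge_never_lengthens_paths():
    rng = np.random.default_rng(4)
    n = 8
    cor = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            c = rng.uniform(0.2, 0.9) if rng.random() < 0.4 else 0.0
            cor[i, j] = cor[j, i] = c
    np.fill_diagonal(cor, 1.0)
    before = _network_from_correlation(cor).distance_matrix()
    zero = np.argwhere(np.triu(cor == 0, 1))
    i, j = zero[0]
    cor2 = cor.copy()
    cor2[i, j] = cor2[j, i] = 0.6
    after = _network_from_correlation(cor2).distance_matrix()
    assert np.all(after <= before + 1e-12)


def test_triangle_inequality_on_sampled_triples(modular_network):
    net, _ = modular_network
    d = net.distance_matrix()
    rng = np.random.default_rng(5)
    n = net.n_genes
    for _ in range(300):
        i, j, k = rng.choice(n, 3, replace=False)
        if np.isfinite(d[i, k]) and np.isfinite(d[k, j]):
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-9


def test_empty_deg_set_gives_empty_paths(modular_network):
    net, _ = modular_network
    assert cx.deg_path_distances(net, []).empty


# -- clustering test --------------------------------------------------------


def _ancestral_expression(net, seed=0):
    rng = np.random.default_rng(seed)
    return pd.Series(rng.lognormal(3, 1, net.n_genes), index=net.gene_ids)


def test_clustering_single_deg_is_undefined(modular_network):
    net, _ = modular_network
    res = cx.deg_clustering_test(net, ["g000"], _ancestral_expression(net),
                                 n_perm=10, seed=0)
    assert res.undefined
    assert "pair" in res.reason


def test_clustering_detects_planted_module(modular_network):
    net, module_of = modular_network
    anc = _ancestral_expression(net)
    rng = np.random.default_rng(6)
    hits = 0
    for s in range(10):
        members = net.gene_ids[module_of == s % 6]
        degs = list(rng.choice(members, 12, replace=False))
        res = cx.deg_clustering_test(net, degs, anc, n_perm=199, seed=s)
        hits += res.p_value < 0.05
    assert hits >= 9


def test_clustering_null_p_values_are_uniform(modular_network):
    net, _ = modular_network
    anc = _ancestral_expression(net)
    rng = np.random.default_rng(7)
    ps = []
    for s in range(100):
        degs = list(rng.choice(net.gene_ids, 15, replace=False))
        res = cx.deg_clustering_test(net, degs, anc, n_perm=99, seed=1000 + s)
        ps.append(res.p_value)
    # uniformity up to the discreteness of (b+1)/(n+1) p-values
    assert stats.kstest(ps, "uniform").pvalue > 0.001
    assert 0.25 < np.mean(ps) < 0.75


def test_expression_strata_split_top_bin(modular_network):
    net, _ = modular_network
    anc = _ancestral_expression(net, seed=1)
    strata = cx._expression_strata(anc.reindex(net.gene_ids), n_bins=5,
                                   split_top=2)
    sizes = strata.value_counts().sort_index()
    # 5 quantile bins of 120 genes with the top bin split in two
    assert list(sizes) == [24, 24, 24, 24, 12, 12]
    # stratum labels are monotone in expression rank
    order = anc.reindex(net.gene_ids).rank(method="first")
    assert (strata.iloc[np.argsort(order.to_numpy())].diff().dropna() >= 0).all()
    # matched null draws therefore always find a pool at least as large as
    # the DEG count in each stratum: the replacement flag stays off
    rng = np.random.default_rng(10)
    degs = list(rng.choice(net.gene_ids, 20, replace=False))
    res = cx.deg_clustering_test(net, degs, anc, n_perm=20, seed=0)
    assert not res.with_replacement


# -- connectivity vs change -------------------------------------------------


def test_connectivity_change_null_slope_covers_zero():
    rng = np.random.default_rng(8)
    idx = [f"g{i}" for i in range(200)]
    k = pd.Series(rng.uniform(1, 50, 200), index=idx)
    change = pd.Series(rng.normal(0.5, 0.1, 200), index=idx)
    out = cx.connectivity_vs_change(k, change)
    assert out["r_squared"] < 0.05
    assert out["p_value"] > 0.01


def test_connectivity_change_exact_line_gives_r2_one():
    idx = [f"g{i}" for i in range(20)]
    k = pd.Series(np.linspace(1, 20, 20), index=idx)
    out = cx.connectivity_vs_change(k, 0.01 * k)
    assert out["r_squared"] == pytest.approx(1.0)
    assert out["slope"] == pytest.approx(0.01)


def test_connectivity_change_matches_normal_equations():
    rng = np.random.default_rng(9)
    idx = [f"g{i}" for i in range(12)]
    k = pd.Series(rng.uniform(0, 10, 12), index=idx)
    change = pd.Series(rng.normal(1, 0.3, 12), index=idx)
    out = cx.connectivity_vs_change(k, change)
    X = np.column_stack([np.ones(12), k.to_numpy()])
    beta = np.linalg.solve(X.T @ X, X.T @ change.to_numpy())
    assert out["intercept"] == pytest.approx(beta[0], rel=1e-9)
    assert out["slope"] == pytest.approx(beta[1], rel=1e-9)


def test_connectivity_change_requires_join():
    k = pd.Series([1.0, 2.0], index=["a", "b"])
    with pytest.raises(ValueError, match="10"):
        cx.connectivity_vs_change(k, pd.Series([1.0], index=["a"]))
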