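"""Weighted co-expression network: adjacency, topological overlap, modules,
hubs, and the DEG-clustering permutation test.

The network is built from an expression matrix (genes x observations, e.g. a
diurnal time course): unsigned adjacency ``a_ij = |cor(i,j)|^beta`` with a
soft threshold ``beta`` (default 2), transformed to a topological overlap
matrix (TOM), clustered by average-linkage hierarchical clustering of
``1 - TOM``, with modules whose eigengenes correlate at or above a merge
threshold collapsed.  Hub genes are the top 5% of intramodular connectivity
per module.

For path queries each retained edge (|cor| above a sparsification floor)
gets length ``1/|cor|``, so short paths chain strong correlations; DEG
clustering in a line is tested against expression-matched random gene sets.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.cluster import hierarchy
from scipy.sparse import csgraph
from scipy.spatial.distance import squareform

HUB_FRACTION = 0.05


@dataclass
class CoexprNetwork:
    """A fitted co-expression network."""

    gene_ids: np.ndarray
    correlation: np.ndarray  # signed Pearson correlations
    adjacency: np.ndarray  # |cor|^beta, unit diagonal
    tom: np.ndarray
    modules: pd.Series  # gene_id -> module label (int)
    connectivity: pd.DataFrame  # gene_id, module, k_total, k_intra, is_hub
    beta: float
    cor_floor: float
    _dist_matrix: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_genes(self) -> int:
        return self.gene_ids.size

    def gene_index(self, genes) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([pos[g] for g in genes])

    def edge_lengths(self) -> sparse.csr_matrix:
        """Sparse symmetric matrix of path lengths 1/|cor| over retained edges."""
        c = np.abs(self.correlation.copy())
        np.fill_diagonal(c, 0.0)
        c[c < self.cor_floor] = 0.0
        with np.errstate(divide="ignore"):
            lengths = np.where(c > 0, 1.0 / np.maximum(c, 1e-12), 0.0)
        return sparse.csr_matrix(lengths)

    def to_graph(self):
        """The sparsified network as a networkx Graph with 'length' weights."""
        import networkx as nx

        g = nx.from_scipy_sparse_array(self.edge_lengths(), edge_attribute="length")
        return nx.relabel_nodes(g, dict(enumerate(self.gene_ids)))

    def distance_matrix(self) -> np.ndarray:
        """All-pairs shortest-path lengths (cached; inf where unconnected)."""
        if self._dist_matrix is None:
            self._dist_matrix = csgraph.dijkstra(self.edge_lengths(), directed=False)
        return self._dist_matrix

    @property
    def hub_genes(self) -> np.ndarray:
        return self.connectivity.loc[self.connectivity["is_hub"], "gene_id"].to_numpy()


def topological_overlap(adjacency: np.ndarray) -> np.ndarray:
    """TOM_ij = (sum_u a_iu*a_uj + a_ij) / (min(k_i,k_j) + 1 - a_ij).

    The shared-neighbor sum excludes u in {i, j}; the diagonal is set to 1.
    """
    a = np.asarray(adjacency, dtype=float)
    k = a.sum(axis=0) - np.diag(a)
    l = a @ a - 2.0 * a * np.diag(a)[None, :]  # remove u=i and u=j terms (a_ii=1)
    num = l + a
    den = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = np.where(den > 0, num / den, 0.0)
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def _eigengene(expr_std: np.ndarray) -> np.ndarray:
    """First principal component of a module's standardized expression,
    signed to correlate positively with mean expression."""
    u, s, vt = np.linalg.svd(expr_std, full_matrices=False)
    pc = vt[0]
    if np.corrcoef(pc, expr_std.mean(axis=0))[0, 1] < 0:
        pc = -pc
    return pc


def _merge_modules(labels: np.ndarray, expr_std: np.ndarray, threshold: float):
    """Iteratively merge the most correlated module-eigengene pair >= threshold."""
    labels = labels.copy()
    while True:
        mods = np.unique(labels)
        if mods.size < 2:
            return labels
        eig = np.array([_eigengene(expr_std[labels == m]) for m in mods])
        c = np.corrcoef(eig)
        np.fill_diagonal(c, -np.inf)
        i, j = np.unravel_index(np.argmax(c), c.shape)
        if c[i, j] < threshold:
            return labels
        labels[labels == mods[j]] = mods[i]


def build_network(
    expression: pd.DataFrame,
    beta: float = 2.0,
    merge_threshold: float = 0.75,
    n_modules_target: int = 33,
    cor_floor: float = 0.1,
) -> CoexprNetwork:
    """Build the co-expression network from genes x observations expression.

    Constant-expression genes (undefined correlations) are dropped with a
    warning.  The dendrogram of ``1 - TOM`` is cut into at most
    ``n_modules_target`` clusters before eigengene merging.
    """
    if expression.shape[1] < 4:
        raise ValueError("need >= 4 expression observations per gene")
    vals = expression.to_numpy(dtype=float)
    sds = vals.std(axis=1)
    if (sds == 0).any():
        dropped = expression.index[sds == 0].tolist()
        warnings.warn(f"dropping {len(dropped)} constant-expression genes")
        expression = expression.loc[sds > 0]
        vals = expression.to_numpy(dtype=float)
    gene_ids = expression.index.to_numpy()
    n = len(gene_ids)

    cor = np.corrcoef(vals)
    adj = np.abs(cor) ** beta
    np.fill_diagonal(adj, 1.0)
    tom = topological_overlap(adj)

    if n > max(n_modules_target, 1):
        dissim = 1.0 - tom
        np.fill_diagonal(dissim, 0.0)
        condensed = squareform(dissim, checks=False)
        link = hierarchy.linkage(condensed, method="average")
        labels = hierarchy.fcluster(link, t=min(n_modules_target, n), criterion="maxclust")
    else:
        labels = np.ones(n, dtype=int)
    expr_std = (vals - vals.mean(axis=1, keepdims=True)) / vals.std(
        axis=1, keepdims=True
    )
    labels = _merge_modules(np.asarray(labels), expr_std, merge_threshold)
    # relabel modules to consecutive integers
    labels = pd.factorize(labels)[0]

    k_total = adj.sum(axis=0) - 1.0
    k_intra = np.array(
        [adj[i, labels == labels[i]].sum() - 1.0 for i in range(n)]
    )
    conn = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "module": labels,
            "k_total": k_total,
            "k_intra": k_intra,
        }
    )
    conn["is_hub"] = False
    for m, grp in conn.groupby("module"):
        n_hub = math.ceil(HUB_FRACTION * len(grp))
        top = grp.nlargest(n_hub, "k_intra").index
        conn.loc[top, "is_hub"] = True

    return CoexprNetwork(
        gene_ids=gene_ids,
        correlation=cor,
        adjacency=adj,
        tom=tom,
        modules=pd.Series(labels, index=gene_ids),
        connectivity=conn,
        beta=beta,
        cor_floor=cor_floor,
    )


def deg_path_distances(network: CoexprNetwork, deg_set) -> pd.DataFrame:
    """Shortest-path lengths between all connected DEG pairs.

    Edge lengths are 1/|cor| over retained edges; unconnected pairs are
    excluded from the result.
    """
    degs = [g for g in dict.fromkeys(deg_set)]
    if not degs:
        return pd.DataFrame(columns=["gene_a", "gene_b", "distance"])
    idx = network.gene_index(degs)
    dmat = csgraph.dijkstra(network.edge_lengths(), directed=False, indices=idx)
    rows = []
    for a in range(len(degs)):
        for b in range(a + 1, len(degs)):
            d = dmat[a, idx[b]]
            if np.isfinite(d):
                rows.append({"gene_a": degs[a], "gene_b": degs[b], "distance": d})
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "distance"])


def _expression_strata(
    ancestral_expression: pd.Series, n_bins: int = 5, split_top: int = 2
) -> pd.Series:
    """Quantile strata of ancestral expression for matched null draws.

    ``n_bins`` quantile bins with the top bin subdivided into ``split_top``
    further quantile bins (expression is strongly right-skewed, so the top
    bin would otherwise mix moderately and extremely expressed genes).
    """
    ranks = ancestral_expression.rank(method="first")
    labels = pd.qcut(ranks, n_bins, labels=False)
    if split_top > 1:
        top = labels == n_bins - 1
        sub = pd.qcut(ranks[top], split_top, labels=False)
        labels = labels.astype(float)
        labels[top] = n_bins - 1 + sub / split_top
    return labels


@dataclass
class ClusteringTestResult:
    observed_median: float
    p_value: float
    n_perm: int
    n_pairs: int
    undefined: bool = False
    reason: str = ""
    with_replacement: bool = False


def deg_clustering_test(
    network: CoexprNetwork,
    deg_set,
    ancestral_expression: pd.Series,
    n_perm: int = 1000,
    seed: int | None = None,
    n_bins: int = 5,
    split_top: int = 2,
) -> ClusteringTestResult:
    """Permutation test for DEG clustering in the co-expression network.

    The statistic is the median shortest-path length over connected DEG
    pairs; the null draws gene sets matched to the DEGs' ancestral
    expression strata.  p is the add-one fraction of draws whose median is
    <= the observed one (shorter paths = tighter clustering).
    """
    degs = [g for g in dict.fromkeys(deg_set)]
    if len(degs) < 2:
        return ClusteringTestResult(
            float("nan"), float("nan"), n_perm, 0, undefined=True,
            reason="fewer than 2 DEGs: no pairs",
        )
    expr = ancestral_expression.reindex(network.gene_ids)
    if expr.isna().any():
        raise ValueError("ancestral expression missing for some network genes")
    strata = _expression_strata(expr, n_bins=n_bins, split_top=split_top)
    dmat = network.distance_matrix()
    idx = network.gene_index(degs)

    def median_pair_distance(indices):
        sub = dmat[np.ix_(indices, indices)]
        vals = sub[np.triu_indices(len(indices), k=1)]
        vals = vals[np.isfinite(vals)]
        return (float(np.median(vals)), vals.size) if vals.size else (float("nan"), 0)

    observed, n_pairs = median_pair_distance(idx)
    if n_pairs == 0:
        return ClusteringTestResult(
            float("nan"), float("nan"), n_perm, 0, undefined=True,
            reason="no connected DEG pair",
        )

    rng = np.random.default_rng(seed)
    stratum_of_deg = strata.iloc[idx]
    counts = stratum_of_deg.value_counts()
    pools = {s: np.flatnonzero((strata == s).to_numpy()) for s in counts.index}
    replaced = False
    null_medians = np.empty(n_perm)
    for t in range(n_perm):
        parts = []
        for s, c in counts.items():
            pool = pools[s]
            if pool.size >= c:
                parts.append(rng.choice(pool, size=c, replace=False))
            else:
                replaced = True
                parts.append(rng.choice(pool, size=c, replace=True))
        null_medians[t], _ = median_pair_distance(np.concatenate(parts))
    valid = np.isfinite(null_medians)
    b = int(np.sum(null_medians[valid] <= observed))
    n_valid = int(valid.sum())
    p = (b + 1) / (n_valid + 1)
    return ClusteringTestResult(
        observed_median=observed,
        p_value=p,
        n_perm=n_valid,
        n_pairs=n_pairs,
        with_replacement=replaced,
    )


def connectivity_vs_change(
    connectivity: pd.Series, median_abs_change: pd.Series
) -> dict:
    """OLS of per-gene median |log2fc| on connectivity, plus a top-vs-bottom
    decile comparison by the Brunner–Munzel test."""
    import statsmodels.api as sm

    from .correlates import brunner_munzel

    joined = pd.concat(
        {"k": connectivity, "change": median_abs_change}, axis=1
    ).dropna()
    if len(joined) < 10:
        raise ValueError("fewer than 10 genes joinable on gene_id")
    X = sm.add_constant(joined["k"].to_numpy())
    fit = sm.OLS(joined["change"].to_numpy(), X).fit()
    lo_cut, hi_cut = joined["k"].quantile([0.1, 0.9])
    low = joined.loc[joined["k"] <= lo_cut, "change"]
    high = joined.loc[joined["k"] >= hi_cut, "change"]
    bm = brunner_munzel(low.to_numpy(), high.to_numpy())
    return {
        "slope": float(fit.params[1]),
        "intercept": float(fit.params[0]),
        "r_squared": float(fit.rsquared),
        "p_value": float(fit.pvalues[1]),
        "n_genes": int(len(joined)),
        "low_group_median": float(low.median()),
        "high_group_median": float(high.median()),
        "brunner_munzel_p": bm["p_value"],
        "brunner_munzel_statistic": bm["statistic"],
    }
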