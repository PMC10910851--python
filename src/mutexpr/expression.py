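"""Count normalization, filtering, replicate QC, and DEG calling.

The differential-expression contract is: per MA line, a gene is a DEG when a
negative-binomial Wald test of the line-vs-ancestor contrast gives a
Benjamini–Hochberg adjusted p below 0.05.  The caller here is a deliberately
simplified reimplementation of that contract — median-of-ratios size
factors, a moment dispersion estimate shrunk toward a fitted mean–dispersion
trend, and a per-gene NB GLM with size-factor offsets solved by IRLS,
vectorized across genes.  Externally produced DEG tables in the same schema
are accepted anywhere a DEG table is consumed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEG_COLUMNS = ["line_id", "gene_id", "log2fc", "p", "p_adj", "significant", "direction"]


@dataclass
class CountMatrix:
    """Genes x samples raw read counts with per-sample metadata.

    ``meta`` has one row per matrix column, in column order, with fields
    sample_id, strain, line_id, replicate, is_ancestor, generations,
    n_mutations.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self):
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate gene ids")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        if list(self.counts.columns) != list(self.meta["sample_id"]):
            raise ValueError("metadata rows must match matrix columns exactly")
        vals = self.counts.to_numpy()
        if not np.isfinite(vals).all() or (vals < 0).any():
            raise ValueError("counts must be finite and nonnegative")
        for strain, grp in self.meta.groupby("strain"):
            if (~grp["is_ancestor"]).any() and not grp["is_ancestor"].any():
                raise ValueError(f"strain {strain} has MA lines but no ancestor")
        self.meta = self.meta.reset_index(drop=True)

    @property
    def gene_ids(self) -> np.ndarray:
        return self.counts.index.to_numpy()

    def samples_of(self, line_id: str) -> list[str]:
        return list(self.meta.loc[self.meta["line_id"] == line_id, "sample_id"])

    def ancestor_of(self, line_id: str) -> str:
        strain = self.meta.loc[self.meta["line_id"] == line_id, "strain"].iloc[0]
        anc = self.meta[(self.meta["strain"] == strain) & self.meta["is_ancestor"]]
        return anc["line_id"].iloc[0]

    def subset_genes(self, gene_ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(gene_ids)], self.meta.copy())

    @property
    def ma_line_ids(self) -> list[str]:
        return list(self.meta.loc[~self.meta["is_ancestor"], "line_id"].unique())


def size_factors(counts: pd.DataFrame | CountMatrix) -> pd.Series:
    """Median-of-ratios size factors (sequencing-depth normalization).

    Reference genes are those with nonzero counts in every sample; each
    sample's factor is the median over reference genes of the ratio of its
    count to the gene's geometric mean across samples.
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    vals = df.to_numpy(dtype=float)
    ref = (vals > 0).all(axis=1)
    if not ref.any():
        raise ValueError(
            "no reference gene: every gene has a zero count in some sample"
        )
    log_geo = np.log(vals[ref]).mean(axis=1)
    ratios = np.log(vals[ref]) - log_geo[:, None]
    return pd.Series(np.exp(np.median(ratios, axis=0)), index=df.columns)


def normalized_counts(cm: CountMatrix, factors: pd.Series | None = None) -> pd.DataFrame:
    factors = size_factors(cm) if factors is None else factors
    return cm.counts / factors


def fpkm(
    counts: pd.DataFrame | CountMatrix, exonic_lengths: pd.Series
) -> pd.DataFrame:
    """Fragments per kilobase of exon per million mapped fragments."""
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    lengths = exonic_lengths.reindex(df.index)
    if lengths.isna().any():
        missing = df.index[lengths.isna()][:3].tolist()
        raise ValueError(f"missing exonic length for genes {missing}")
    if (lengths <= 0).any():
        raise ValueError("exonic lengths must be positive")
    lib = df.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("zero library size")
    return df * 1e9 / lengths.to_numpy()[:, None] / lib.to_numpy()[None, :]


def filter_low_counts(
    cm: CountMatrix, target_retained: float = 0.95
) -> CountMatrix:
    """Drop the lowest-expressed genes, retaining ~``target_retained``.

    The filter statistic is the mean normalized count across samples within
    each strain, averaged over strains; genes are ranked by it and the
    lowest-ranked dropped.
    """
    if not 0.0 < target_retained <= 1.0:
        raise ValueError("target_retained must lie in (0, 1]")
    if target_retained == 1.0:
        return cm
    norm = normalized_counts(cm)
    strain_means = []
    for strain, grp in cm.meta.groupby("strain"):
        strain_means.append(norm[grp["sample_id"]].mean(axis=1))
    stat = pd.concat(strain_means, axis=1).mean(axis=1)
    n_keep = int(np.ceil(target_retained * len(stat)))
    order = np.argsort(-stat.to_numpy(), kind="stable")
    keep_idx = np.sort(order[:n_keep])
    return cm.subset_genes(cm.counts.index[keep_idx])


def replicate_qc(
    fpkm_table: pd.DataFrame, meta: pd.DataFrame, threshold: float = 0.96
) -> pd.DataFrame:
    """Flag replicates whose mean Pearson correlation with siblings is low.

    Flagged replicates are excluded from averaged-count analyses only; the
    DEG caller keeps all replicates.  Returns one row per replicate with the
    mean sibling correlation, the flag, and a reason.
    """
    rows = []
    for line, grp in meta.groupby("line_id"):
        ids = list(grp["sample_id"])
        if len(ids) < 2:
            raise ValueError(f"line {line} has fewer than 2 replicates")
        sub = fpkm_table[ids].to_numpy()
        sds = sub.std(axis=0)
        corr = np.corrcoef(sub.T) if (sds > 0).all() else None
        for i, sid in enumerate(ids):
            if sds[i] == 0:
                rows.append(
                    {
                        "sample_id": sid,
                        "line_id": line,
                        "mean_r": np.nan,
                        "flagged": True,
                        "reason": "constant expression; correlation undefined",
                    }
                )
                continue
            if corr is None:
                others = [
                    j for j in range(len(ids)) if j != i and sds[j] > 0
                ]
                rs = [np.corrcoef(sub[:, i], sub[:, j])[0, 1] for j in others]
            else:
                rs = [corr[i, j] for j in range(len(ids)) if j != i]
            mean_r = float(np.mean(rs)) if rs else np.nan
            flagged = not (mean_r > threshold)
            rows.append(
                {
                    "sample_id": sid,
                    "line_id": line,
                    "mean_r": mean_r,
                    "flagged": flagged,
                    "reason": "low replicate correlation" if flagged else "",
                }
            )
    return pd.DataFrame(rows)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# NB Wald DEG caller
# ---------------------------------------------------------------------------


def _moment_dispersions(y, sf, group):
    """Per-gene NB dispersion by the method of moments on normalized counts,
    shrunk toward a 1/mean trend fitted across genes."""
    q = y / sf[None, :]
    means, varis, ns = [], [], []
    for g in np.unique(group):
        sel = group == g
        means.append(q[:, sel].mean(axis=1))
        varis.append(q[:, sel].var(axis=1, ddof=1))
        ns.append(sel.sum())
    # pooled within-group moments
    w = np.array(ns, dtype=float)
    mean_q = np.average(np.column_stack(means), axis=1, weights=w)
    var_q = np.average(np.column_stack(varis), axis=1, weights=w - 1)
    c = float(np.mean(1.0 / sf))  # Poisson part of Var(q) is ~ mu * mean(1/sf)
    mean_q = np.maximum(mean_q, 1e-8)
    alpha_mom = (var_q - mean_q * c) / mean_q**2
    alpha_mom = np.clip(alpha_mom, 1e-8, 10.0)
    # trend alpha(mu) = a0 + a1/mu, least squares on informative genes
    use = mean_q > 1.0
    if use.sum() >= 10:
        X = np.column_stack([np.ones(use.sum()), 1.0 / mean_q[use]])
        coef, *_ = np.linalg.lstsq(X, alpha_mom[use], rcond=None)
        a0, a1 = np.maximum(coef, 0.0)
        alpha_trend = np.clip(a0 + a1 / mean_q, 1e-6, 10.0)
    else:
        alpha_trend = np.full_like(alpha_mom, max(np.median(alpha_mom), 1e-6))
    # with a handful of replicates the per-gene moment estimate is very
    # noisy and its underestimates inflate Wald statistics, so shrink hard
    # toward the trend and do not let a gene fall far below it
    alpha_mom = np.maximum(alpha_mom, alpha_trend / 10.0)
    w_gene = 0.2
    return np.exp(w_gene * np.log(alpha_mom) + (1 - w_gene) * np.log(alpha_trend))


def _nb_wald_vectorized(y, sf, x, alpha, max_iter=50, tol=1e-8, ridge=1e-8):
    """Fit log mu = b0 + b1*x + log sf per gene (rows of y) and Wald-test b1.

    Returns (beta1, se, converged).  IRLS with NB working weights
    w = mu / (1 + alpha*mu), all genes advanced in lock-step.
    """
    n_genes, n = y.shape
    off = np.log(sf)
    X = np.column_stack([np.ones(n), x.astype(float)])
    # init from group means of normalized counts
    q = y / sf[None, :]
    m0 = np.maximum(q[:, x == 0].mean(axis=1), 1e-3)
    m1 = np.maximum(q[:, x == 1].mean(axis=1), 1e-3)
    beta = np.column_stack([np.log(m0), np.log(m1) - np.log(m0)])
    conv = np.zeros(n_genes, dtype=bool)
    for _ in range(max_iter):
        eta = beta @ X.T + off[None, :]
        eta = np.clip(eta, -30.0, 30.0)
        mu = np.exp(eta)
        w = mu / (1.0 + alpha[:, None] * mu)
        z = eta - off[None, :] + (y - mu) / mu
        # per-gene 2x2 normal equations
        s00 = w.sum(axis=1) + ridge
        s01 = (w * X[:, 1]).sum(axis=1)
        s11 = (w * X[:, 1] ** 2).sum(axis=1) + ridge
        t0 = (w * z).sum(axis=1)
        t1 = (w * z * X[:, 1]).sum(axis=1)
        det = s00 * s11 - s01**2
        new0 = (s11 * t0 - s01 * t1) / det
        new1 = (s00 * t1 - s01 * t0) / det
        new1 = np.clip(new1, -15.0, 15.0)
        new0 = np.clip(new0, -30.0, 30.0)
        step = np.maximum(np.abs(new0 - beta[:, 0]), np.abs(new1 - beta[:, 1]))
        beta = np.column_stack([new0, new1])
        conv |= step < tol
        if conv.all():
            break
    # Wald SE of b1 from the inverse information at the final iterate
    eta = np.clip(beta @ X.T + off[None, :], -30.0, 30.0)
    mu = np.exp(eta)
    w = mu / (1.0 + alpha[:, None] * mu)
    s00 = w.sum(axis=1) + ridge
    s01 = (w * X[:, 1]).sum(axis=1)
    s11 = (w * X[:, 1] ** 2).sum(axis=1) + ridge
    det = s00 * s11 - s01**2
    se = np.sqrt(np.maximum(s00 / det, 1e-300))
    return beta[:, 1], se, conv


def call_degs(
    cm: CountMatrix,
    line_id: str,
    alpha: float = 0.05,
    target_retained: float = 0.95,
    factors: pd.Series | None = None,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Call DEGs for one MA line against its unmutated ancestor.

    Filters low-count genes, fits a per-gene NB GLM of the line-vs-ancestor
    contrast with size-factor offsets, Wald-tests the contrast against a
    normal reference, and BH-adjusts across retained genes.
    Reported log2 fold changes are ratios of mean normalized counts, with a
    ``pseudocount`` applied when a group mean is zero.
    """
    anc = cm.ancestor_of(line_id)
    line_samples = cm.samples_of(line_id)
    anc_samples = cm.samples_of(anc)
    if len(line_samples) < 2 or len(anc_samples) < 2:
        raise ValueError("need >= 2 replicates in both the line and its ancestor")
    factors = size_factors(cm) if factors is None else factors
    strain = cm.meta.loc[cm.meta["line_id"] == line_id, "strain"].iloc[0]
    strain_cm = CountMatrix(
        cm.counts[cm.meta.loc[cm.meta["strain"] == strain, "sample_id"]],
        cm.meta[cm.meta["strain"] == strain].reset_index(drop=True),
    )
    retained = filter_low_counts(strain_cm, target_retained).counts.index

    samples = anc_samples + line_samples
    y = cm.counts.loc[retained, samples].to_numpy(dtype=float)
    sf = factors[samples].to_numpy()
    x = np.array([0] * len(anc_samples) + [1] * len(line_samples))

    disp = _moment_dispersions(y, sf, x)
    beta1, se, conv = _nb_wald_vectorized(y, sf, x, disp)
    wald = beta1 / se
    p = 2.0 * stats.norm.sf(np.abs(wald))
    p_adj = bh_adjust(p)

    q = y / sf[None, :]
    m_anc = q[:, x == 0].mean(axis=1)
    m_line = q[:, x == 1].mean(axis=1)
    need_pc = (m_anc == 0) | (m_line == 0)
    l2fc = np.log2(np.where(need_pc, m_line + pseudocount, m_line)) - np.log2(
        np.where(need_pc, m_anc + pseudocount, m_anc)
    )

    out = pd.DataFrame(
        {
            "line_id": line_id,
            "gene_id": retained,
            "log2fc": l2fc,
            "p": p,
            "p_adj": p_adj,
            "significant": p_adj < alpha,
            "direction": np.where(l2fc >= 0, "up", "down"),
        }
    )
    if not conv.all():
        warnings.warn(
            f"{int((~conv).sum())} gene fits did not fully converge for {line_id}"
        )
    return out.reset_index(drop=True)


def call_all_degs(cm: CountMatrix, alpha: float = 0.05, **kwargs) -> pd.DataFrame:
    """DEG tables for every MA line, concatenated."""
    factors = kwargs.pop("factors", None)
    if factors is None:
        factors = size_factors(cm)
    tables = [
        call_degs(cm, line, alpha=alpha, factors=factors, **kwargs)
        for line in cm.ma_line_ids
    ]
    return pd.concat(tables, ignore_index=True)


def directional_change_sums(degs: pd.DataFrame) -> pd.DataFrame:
    """Per-line sums of positive and negative log2 fold changes over DEGs.

    Returns one row per line with sum_up (>= 0), sum_down (<= 0), n_degs and
    the total absolute change, the per-line divergence measures plotted
    against mutation count and used in the fitness regressions.
    """
    rows = []
    for line, grp in degs.groupby("line_id"):
        sig = grp[grp["significant"]]
        lfc = sig["log2fc"].to_numpy()
        rows.append(
            {
                "line_id": line,
                "sum_up": float(lfc[lfc > 0].sum()),
                "sum_down": float(lfc[lfc < 0].sum()),
                "n_degs": int(len(sig)),
                "sum_abs_log2fc": float(np.abs(lfc).sum()),
            }
        )
    return pd.DataFrame(rows)
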