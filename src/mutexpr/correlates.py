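"""Expression-level correlates of mutational expression change, rank-based
group comparisons, and the fitness vs expression-divergence regressions.

Genes are binned into expression percentiles of the ancestral FPKM; per-bin
distributions of the median log2 fold change summarize whether highly
expressed genes are buffered against mutational perturbation.  Two-group
comparisons use the Brunner–Munzel studentized rank statistic (robust to
unequal variances), and per-line relative fitness is regressed on the DEG
count or the summed absolute fold change, with a systematic leave-one-out
influence report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


@dataclass
class FitnessTable:
    """Per-line relative fitness with expression-divergence summaries."""

    table: pd.DataFrame  # line_id, fitness_rel, n_degs, sum_abs_log2fc

    def __post_init__(self):
        if self.table["line_id"].duplicated().any():
            raise ValueError("every line must have exactly one fitness row")
        if not np.isfinite(self.table["fitness_rel"]).all():
            raise ValueError("fitness_rel must be finite")

    @classmethod
    def from_frames(
        cls, fitness: pd.DataFrame, deg_sums: pd.DataFrame
    ) -> "FitnessTable":
        merged = fitness.merge(deg_sums, on="line_id", how="inner")
        return cls(merged)


def percentile_bins(ancestral_fpkm: pd.Series, n_bins: int = 10) -> pd.Series:
    """Equal-size expression-rank bins (0 = lowest expression).

    Ties are broken by stable input order; bin sizes differ by at most one.
    Labels depend only on ranks, so any monotone transform of the FPKM
    values yields the same binning.
    """
    if len(ancestral_fpkm) < n_bins:
        raise ValueError("fewer genes than bins")
    values = ancestral_fpkm.to_numpy()
    order = np.argsort(values, kind="stable")
    labels = np.empty(len(values), dtype=int)
    for b, chunk in enumerate(np.array_split(order, n_bins)):
        labels[chunk] = b
    return pd.Series(labels, index=ancestral_fpkm.index, name="bin")


def median_change_by_bin(
    bins: pd.Series, log2fc_tables: pd.DataFrame
) -> tuple[pd.Series, pd.DataFrame]:
    """Per-gene median log2fc across lines, summarized per expression bin.

    ``log2fc_tables`` holds per-line fold changes with columns
    (line_id, gene_id, log2fc).  Returns the per-gene medians and a per-bin
    summary (median and IQR of those medians).
    """
    med = log2fc_tables.groupby("gene_id")["log2fc"].median()
    joined = pd.concat({"bin": bins, "median_log2fc": med}, axis=1).dropna()
    grp = joined.groupby("bin")["median_log2fc"]
    summary = pd.DataFrame(
        {
            "median": grp.median(),
            "q25": grp.quantile(0.25),
            "q75": grp.quantile(0.75),
            "n_genes": grp.size(),
        }
    ).reset_index()
    return med, summary


def brunner_munzel(x, y) -> dict:
    """Brunner–Munzel two-sample rank test with superiority estimate.

    Returns the studentized statistic with Satterthwaite-approximated
    degrees of freedom, the two-sided p, and the stochastic-superiority
    estimate P(X < Y) + 0.5*P(X = Y).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both samples must have size >= 2")
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    rx, ry = ranks[: x.size], ranks[x.size:]
    # superiority estimate from mean mid-ranks
    p_hat = (ry.mean() - (y.size + 1) / 2) / x.size
    # studentized statistic via scipy (degenerate rank variance -> error)
    rx_inner = stats.rankdata(x)
    ry_inner = stats.rankdata(y)
    sx2 = np.var(rx - rx_inner, ddof=1)
    sy2 = np.var(ry - ry_inner, ddof=1)
    if sx2 == 0 and sy2 == 0:
        if p_hat == 0.5:
            return {"statistic": 0.0, "p_value": 1.0, "superiority": 0.5}
        if p_hat in (0.0, 1.0):
            # complete separation: the studentized statistic diverges but
            # the superiority estimate is exact
            sign = 1.0 if p_hat == 1.0 else -1.0
            return {"statistic": sign * np.inf, "p_value": 0.0,
                    "superiority": float(p_hat)}
        raise ValueError(
            "degenerate rank variance in both samples; statistic undefined"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.brunnermunzel(x, y, alternative="two-sided", distribution="t")
    statistic, p = float(res.statistic), float(res.pvalue)
    if not np.isfinite(statistic):
        bad = "x" if sx2 == 0 else "y"
        raise ValueError(f"degenerate rank variance in sample {bad}")
    return {"statistic": statistic, "p_value": p, "superiority": float(p_hat)}


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    predictor: str
    leave_one_out: pd.DataFrame  # line_id, r_squared, p_value without the line


def fitness_regression(
    table: FitnessTable, predictor: str = "n_degs"
) -> RegressionResult:
    """OLS of relative fitness on an expression-divergence predictor.

    ``predictor`` is ``n_degs`` or ``sum_abs_log2fc``.  The leave-one-out
    report refits without each line in turn, surfacing influential points
    the way a manual single-exclusion analysis would.
    """
    df = table.table
    if predictor not in df.columns:
        raise KeyError(f"unknown predictor {predictor!r}")
    if len(df) < 3:
        raise ValueError("need >= 3 lines")
    xvals = df[predictor].to_numpy(dtype=float)
    if np.ptp(xvals) == 0:
        raise ValueError("constant predictor")
    yvals = df["fitness_rel"].to_numpy(dtype=float)

    def ols(x, y):
        fit = sm.OLS(y, sm.add_constant(x)).fit()
        return (
            float(fit.params[1]),
            float(fit.params[0]),
            float(fit.rsquared),
            float(fit.pvalues[1]),
        )

    slope, intercept, r2, p = ols(xvals, yvals)
    loo_rows = []
    for i in range(len(df)):
        mask = np.arange(len(df)) != i
        if np.ptp(xvals[mask]) == 0:
            loo_rows.append(
                {
                    "line_id": df["line_id"].iloc[i],
                    "r_squared": np.nan,
                    "p_value": np.nan,
                }
            )
            continue
        _, _, r2_i, p_i = ols(xvals[mask], yvals[mask])
        loo_rows.append(
            {"line_id": df["line_id"].iloc[i], "r_squared": r2_i, "p_value": p_i}
        )
    return RegressionResult(
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        p_value=p,
        n=len(df),
        predictor=predictor,
        leave_one_out=pd.DataFrame(loo_rows),
    )
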