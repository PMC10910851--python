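"""Mutational variance of gene expression from a per-gene Poisson GLMM.

Per gene, raw read counts are modeled as Poisson with log link:

    ln E[Y_s] = beta0 + beta1 * x_i + u_i * x_i + b_s + offset_s

where ``x_i`` is the number of generations the MA line accumulated mutations
for (or its mutation count, when scaling variance per mutation),
``u_i ~ N(0, sigma2_u)`` is a per-line random slope capturing independent
divergence of each line, and ``b_s ~ N(0, sigma2_b)`` is an
observation-level random effect absorbing extra-Poisson dispersion.  The
offset is ``-ln(size factor)`` by default, with a switch for the opposite
sign convention.

The mutational variance per covariate unit is ``V_m = 2 * Var(u)``, the
environmental variance ``V_e = sigma2_b`` (the observation-level effect is
the model's extra-Poisson residual), and the mutational heritability
``h2_m = V_m / V_e``.

Random effects are integrated out with a Laplace approximation: the joint
posterior mode of ``(u, b)`` is found by Newton iteration (the Poisson
log-link makes it concave) and the marginal likelihood is maximized over
``(beta0, beta1, ln sigma_u, ln sigma_b)`` by Nelder–Mead.  A fixed
intercept is included even though the variance decomposition does not use
it — a count model for expression is not meaningful without one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special

CovariateKind = Literal["generations", "mutations"]

_SENTINEL = float("nan")


@dataclass
class VarianceComponents:
    """Per-gene variance decomposition from the mutational-variance model."""

    gene_id: str
    beta0: float
    beta1: float
    var_u: float  # variance of the per-line random slope
    v_m: float  # 2 * var_u, per covariate unit
    v_e: float  # observation-level (residual) variance sigma2_b
    h2_m: float  # v_m / v_e; NaN when v_e == 0
    covariate_kind: CovariateKind
    converged: bool
    loglik: float

    def to_row(self) -> dict:
        return {
            "gene_id": self.gene_id,
            "covariate_kind": self.covariate_kind,
            "beta1": self.beta1,
            "var_u": self.var_u,
            "v_m": self.v_m,
            "v_e": self.v_e,
            "h2_m": self.h2_m,
            "converged": self.converged,
            "loglik": self.loglik,
        }


@dataclass
class GlmmOptions:
    """Numerical knobs of the Laplace/Nelder–Mead fit."""

    offset_sign: int = -1  # offset = offset_sign * ln(size factor)
    max_outer_iter: int = 400
    fatol: float = 1e-6
    xatol: float = 1e-4
    max_newton_iter: int = 50
    newton_tol: float = 1e-9
    log_sigma_floor: float = -14.0  # hard floor on ln sigma to keep H finite


def _inner_mode(y, x, line_index, offset, beta0, beta1, s2u, s2b, opts):
    """Newton maximization of the joint log density over (u, b).

    Returns (v_hat, f_at_mode, log_det_H).  The random-effect vector is
    v = (u_1..u_L, b_1..b_n); the Hessian of the negative joint density is
    Z' diag(mu) Z + D^-1 with Z = [x*line-indicator | I].
    """
    n = y.size
    L = line_index.max() + 1
    q = L + n
    prec = np.concatenate([np.full(L, 1.0 / s2u), np.full(n, 1.0 / s2b)])
    v = np.zeros(q)

    def eta_of(v):
        return beta0 + beta1 * x + v[line_index] * x + v[L:] + offset

    def f_of(v):
        eta = eta_of(v)
        # clip only inside exp: an overshooting trial step must still score
        # worse than the current point, not overflow
        rate = np.exp(np.clip(eta, -40.0, 40.0))
        return float(np.sum(y * eta - rate) - 0.5 * np.sum(prec * v**2))

    f = f_of(v)
    for _ in range(opts.max_newton_iter):
        eta = eta_of(v)
        mu = np.exp(np.clip(eta, -40.0, 40.0))
        r = y - mu
        grad = np.empty(q)
        np.add.at(grad := np.zeros(q), line_index, r * x)
        grad[L:] += r
        grad -= prec * v
        if np.max(np.abs(grad)) < opts.newton_tol:
            break
        # assemble the dense Hessian blocks
        H = np.zeros((q, q))
        wu = np.zeros(L)
        np.add.at(wu, line_index, mu * x**2)
        H[np.arange(L), np.arange(L)] = wu
        H[L:, L:] = np.diag(mu)
        H[line_index, np.arange(n) + L] = mu * x
        H[np.arange(n) + L, line_index] = mu * x
        H[np.arange(q), np.arange(q)] += prec
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            break
        # damped update
        t = 1.0
        for _ in range(30):
            v_new = v + t * step
            f_new = f_of(v_new)
            if f_new >= f:
                break
            t *= 0.5
        if f_new < f:
            break
        v, f = v_new, f_new

    eta = eta_of(v)
    mu = np.exp(np.clip(eta, -40.0, 40.0))
    H = np.zeros((q, q))
    wu = np.zeros(L)
    np.add.at(wu, line_index, mu * x**2)
    H[np.arange(L), np.arange(L)] = wu
    H[L:, L:] = np.diag(mu)
    H[line_index, np.arange(n) + L] = mu * x
    H[np.arange(n) + L, line_index] = mu * x
    H[np.arange(q), np.arange(q)] += prec
    sign, logdet = np.linalg.slogdet(H)
    if sign <= 0:
        logdet = np.inf
    return v, f_of(v), logdet


def _laplace_loglik(theta, y, x, line_index, offset, opts):
    beta0, beta1, log_su, log_sb = theta
    log_su = max(log_su, opts.log_sigma_floor)
    log_sb = max(log_sb, opts.log_sigma_floor)
    s2u, s2b = np.exp(2 * log_su), np.exp(2 * log_sb)
    n = y.size
    L = line_index.max() + 1
    v, f, logdet = _inner_mode(y, x, line_index, offset, beta0, beta1, s2u, s2b, opts)
    if not np.isfinite(f) or not np.isfinite(logdet):
        return -1e12
    const = (
        -np.sum(special.gammaln(y + 1))
        - L * (np.log(2 * np.pi) / 2 + log_su)
        - n * (np.log(2 * np.pi) / 2 + log_sb)
    )
    return f + const + 0.5 * (L + n) * np.log(2 * np.pi) - 0.5 * logdet


def fit_gene_glmm(
    y: Sequence[float],
    covariate: Sequence[float],
    line_index: Sequence[int],
    size_factors: Sequence[float] | None = None,
    covariate_kind: CovariateKind = "generations",
    gene_id: str = "",
    options: GlmmOptions | None = None,
) -> VarianceComponents:
    """Fit the per-gene mutational-variance model.

    ``y`` are raw counts per observation, ``covariate`` the per-observation
    generations (or mutation count), ``line_index`` integer line labels per
    observation (the ancestor is a line with covariate 0), and
    ``size_factors`` per-observation normalization factors.
    """
    opts = options or GlmmOptions()
    y = np.asarray(y, dtype=float)
    x = np.asarray(covariate, dtype=float)
    line_index = np.asarray(line_index, dtype=int)
    if y.size == 0 or np.all(y == 0):
        raise ValueError(f"gene {gene_id!r}: all counts are zero")
    sf = np.ones_like(y) if size_factors is None else np.asarray(size_factors, float)
    if np.unique(line_index[x > 0]).size < 3:
        raise ValueError("need >= 3 lines with a varying covariate")
    # offset_sign=-1 is the model's ln(1/size factor); +1 the conventional
    # +ln(size factor)
    offset = -np.log(sf) if opts.offset_sign == -1 else np.log(sf)

    # crude initial values
    q = y / np.exp(offset)
    beta0_init = float(np.log(np.maximum(q.mean(), 1e-3)))
    line_mean = pd.Series(q).groupby(line_index).mean()
    line_x = pd.Series(x).groupby(line_index).max()
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (np.log(np.maximum(line_mean, 1e-3)) - beta0_init) / np.maximum(line_x, 1.0)
    r = r[line_x > 0]
    su_init = float(np.clip(np.nanstd(r), 1e-6, 1.0))
    theta0 = np.array([beta0_init, 0.0, np.log(su_init), np.log(0.2)])

    def neg(theta):
        return -_laplace_loglik(theta, y, x, line_index, offset, opts)

    res = optimize.minimize(
        neg,
        theta0,
        method="Nelder-Mead",
        options={
            "maxiter": opts.max_outer_iter,
            "fatol": opts.fatol,
            "xatol": opts.xatol,
        },
    )
    beta0, beta1, log_su, log_sb = res.x
    var_u = float(np.exp(2 * max(log_su, opts.log_sigma_floor)))
    v_e = float(np.exp(2 * max(log_sb, opts.log_sigma_floor)))
    v_m = 2.0 * var_u
    h2_m = v_m / v_e if v_e > 0 else _SENTINEL
    return VarianceComponents(
        gene_id=gene_id,
        beta0=float(beta0),
        beta1=float(beta1),
        var_u=var_u,
        v_m=v_m,
        v_e=v_e,
        h2_m=h2_m,
        covariate_kind=covariate_kind,
        converged=bool(res.success),
        loglik=float(-res.fun),
    )


def _design_for_strain(cm, strain, covariate_kind):
    meta = cm.meta[cm.meta["strain"] == strain]
    samples = list(meta["sample_id"])
    lines = list(meta["line_id"].unique())
    line_pos = {l: i for i, l in enumerate(lines)}
    line_index = np.array([line_pos[l] for l in meta["line_id"]])
    key = "generations" if covariate_kind == "generations" else "n_mutations"
    x = meta[key].to_numpy(dtype=float)
    return samples, x, line_index


def variance_table(
    cm,
    covariate_kind: CovariateKind = "generations",
    exclude_lines: Sequence[str] = (),
    size_factors_: pd.Series | None = None,
    options: GlmmOptions | None = None,
    genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-gene variance components for every strain in a count matrix.

    Lines in ``exclude_lines`` (e.g. mutator lines) are removed before
    fitting.  Per-gene failures are propagated as non-converged rows, never
    silently dropped.  Strain-level medians are available via
    :func:`strain_medians`.
    """
    from .expression import CountMatrix, size_factors as _sf

    assert isinstance(cm, CountMatrix)
    if exclude_lines:
        keep = ~cm.meta["line_id"].isin(exclude_lines)
        cm = CountMatrix(
            cm.counts[cm.meta.loc[keep, "sample_id"]],
            cm.meta[keep].reset_index(drop=True),
        )
    factors = _sf(cm) if size_factors_ is None else size_factors_
    gene_list = list(genes) if genes is not None else list(cm.counts.index)
    rows = []
    for strain in cm.meta["strain"].unique():
        samples, x, line_index = _design_for_strain(cm, strain, covariate_kind)
        sf = factors[samples].to_numpy()
        sub = cm.counts.loc[gene_list, samples]
        for gene in gene_list:
            y = sub.loc[gene].to_numpy(dtype=float)
            try:
                vc = fit_gene_glmm(
                    y, x, line_index, sf, covariate_kind, gene_id=gene,
                    options=options,
                )
                row = vc.to_row()
            except (ValueError, np.linalg.LinAlgError) as exc:
                row = {
                    "gene_id": gene,
                    "covariate_kind": covariate_kind,
                    "beta1": np.nan,
                    "var_u": np.nan,
                    "v_m": np.nan,
                    "v_e": np.nan,
                    "h2_m": np.nan,
                    "converged": False,
                    "loglik": np.nan,
                }
                warnings.warn(f"gene {gene} ({strain}): {exc}")
            row["strain"] = strain
            rows.append(row)
    return pd.DataFrame(rows)


def strain_medians(table: pd.DataFrame) -> pd.DataFrame:
    """Median V_m and h2_m per strain over converged gene fits."""
    ok = table[table["converged"]]
    return (
        ok.groupby("strain")[["v_m", "v_e", "h2_m"]]
        .median()
        .rename(columns={"v_m": "median_v_m", "v_e": "median_v_e", "h2_m": "median_h2_m"})
        .reset_index()
    )
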