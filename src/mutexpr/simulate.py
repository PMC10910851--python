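"""Synthetic mutation-accumulation (MA) experiment generator.

Generates every input the analysis pipeline consumes — a toy genome
annotation, per-line mutations with known expression effects, structural
variants, relative fitness, and a gene-by-sample read-count matrix — together
with a truth table for recovery tests.

The generative model mirrors the study design it emulates: two ancestral
strains with 13 and 15 MA lines, three replicates each, 800–1,100 generations
of accumulation, a mean of 112.1 and 76.2 mutations per line, per-mutation
DEG effects drawn from a zero-spike shifted-gamma DEE, cis effects placed
within 100 bp of their single target gene, trans effects spread over one
co-expression module, SV–gene overlaps, and fitness declining linearly with
the number of perturbed genes.  Read counts follow the per-gene Poisson
model with a per-line effect, an observation-level log-normal perturbation
(overdispersion), and per-sample size factors.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .dee import DEEFit, sample_per_mutation_effects

CIS_WINDOW_BP = 100  # proximity that defines a cis placement

SV_TYPES = ("insertion", "deletion", "duplication", "excision", "inversion", "translocation")
# relative frequencies and typical lengths of the six SV classes in the
# 8-line SV callset the generator emulates
_SV_FREQS = np.array([125, 14, 41, 18, 11, 29], dtype=float) / 238.0
_SV_MEAN_LEN = {
    "insertion": 263,
    "deletion": 12405,
    "duplication": 16227,
    "excision": 9,
    "inversion": 1504,
    "translocation": 10,
}


@dataclass
class SimConfig:
    """Parameters of the simulated MA experiment.

    Defaults reproduce the study conditions: strain sizes, generation span,
    mean mutation counts, and the fitted DEE parameters.
    """

    n_strains: int = 2
    lines_per_strain: tuple[int, ...] = (13, 15)
    replicates: int = 3
    n_genes: int = 1000
    chrom_lengths: tuple[int, ...] = (2_000_000, 2_000_000, 2_000_000, 2_000_000)
    generations_range: tuple[int, int] = (800, 1100)
    mean_mutations_per_line: tuple[float, ...] = (112.1, 76.2)
    dee_pi0: float = 0.42
    dee_pi1: float = 0.0
    dee_shape: float = 0.0118
    dee_scale: float = 2005.0
    cis_fraction: float = 0.9
    effect_sd_log2: float = 1.5
    baseline_log_mean: float = 4.5
    baseline_log_sd: float = 1.2
    olre_sd: float = 0.2
    size_factor_range: tuple[float, float] = (0.7, 1.4)
    sv_per_line: float = 30.0
    fitness_slope: float = -1e-4
    fitness_noise_sd: float = 0.1
    n_modules: int = 12
    seed: int = 0

    def __post_init__(self):
        for p in (self.dee_pi0, self.dee_pi1, self.cis_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.dee_pi0 + self.dee_pi1 > 1.0:
            raise ValueError("dee_pi0 + dee_pi1 must not exceed 1")
        if self.n_strains <= 0 or self.replicates <= 0 or self.n_genes < 0:
            raise ValueError("counts must be positive")
        if len(self.lines_per_strain) != self.n_strains:
            raise ValueError("lines_per_strain must have one entry per strain")
        if len(self.mean_mutations_per_line) != self.n_strains:
            raise ValueError("mean_mutations_per_line must have one entry per strain")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")
        if self.fitness_slope > 0:
            raise ValueError("fitness_slope must be <= 0")
        if self.dee_shape <= 0 or self.dee_scale <= 0:
            raise ValueError("DEE gamma parameters must be positive")

    @property
    def strains(self) -> list[str]:
        return [f"S{i + 1}" for i in range(self.n_strains)]

    def dee_fit(self) -> DEEFit:
        kind = "zero_one_gamma" if self.dee_pi1 > 0 else "zero_gamma"
        return DEEFit(
            model_kind=kind,
            pi0=self.dee_pi0,
            pi1=self.dee_pi1,
            shape=self.dee_shape,
            scale=self.dee_scale,
            loglik=float("nan"),
            aic=float("nan"),
            bic=float("nan"),
            n_lines=0,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        for key in (
            "lines_per_strain",
            "chrom_lengths",
            "generations_range",
            "mean_mutations_per_line",
            "size_factor_range",
        ):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class GenomeAnnotation:
    """Non-overlapping gene models with strand and UTR intervals.

    Coordinates are 0-based half-open.  Gene models here are intron-free, so
    the exonic length equals the gene span; UTRs are the strand-appropriate
    leading and trailing segments of the span.
    """

    genes: pd.DataFrame  # gene_id, chrom, start, end, strand, utr5/utr3, exonic_length
    chrom_lengths: dict[str, int]

    def __post_init__(self):
        self.genes = self.genes.reset_index(drop=True)

    @property
    def gene_ids(self) -> np.ndarray:
        return self.genes["gene_id"].to_numpy()

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def exonic_lengths(self) -> pd.Series:
        return self.genes.set_index("gene_id")["exonic_length"]


@dataclass
class Mutation:
    chrom: str
    pos: int  # 0-based
    line_id: str
    mut_type: str  # SNM | indel
    x_effect: int  # number of genes whose expression the mutation perturbs
    target_genes: tuple[str, ...]
    is_cis: bool


@dataclass
class SV:
    chrom: str
    start: int
    end: int  # half-open
    sv_type: str
    line_id: str


@dataclass
class ExperimentTruth:
    """Ground truth of a simulated MA experiment."""

    config: SimConfig
    line_strain: dict[str, str]
    line_generations: dict[str, int]
    mutations: dict[str, list[Mutation]]  # per line
    effects_log2: dict[str, dict[str, float]]  # line -> gene -> true log2 shift
    svs: dict[str, list[SV]]
    fitness: dict[str, float]
    gene_modules: dict[str, int]  # synthetic co-expression module per gene

    def __post_init__(self):
        for line, muts in self.mutations.items():
            for mu in muts:
                if mu.x_effect == 0 and mu.target_genes:
                    raise ValueError("zero-effect mutation with target genes")

    @property
    def line_ids(self) -> list[str]:
        return list(self.line_strain)

    def mutation_counts(self) -> dict[str, int]:
        return {line: len(m) for line, m in self.mutations.items()}

    def true_deg_counts(self) -> dict[str, int]:
        return {line: len(e) for line, e in self.effects_log2.items()}

    # -- JSON round trip -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "line_strain": self.line_strain,
            "line_generations": self.line_generations,
            "mutations": {
                line: [asdict(m) | {"target_genes": list(m.target_genes)} for m in ms]
                for line, ms in self.mutations.items()
            },
            "effects_log2": self.effects_log2,
            "svs": {line: [asdict(s) for s in ss] for line, ss in self.svs.items()},
            "fitness": self.fitness,
            "gene_modules": self.gene_modules,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentTruth":
        return cls(
            config=SimConfig.from_dict(d["config"]),
            line_strain=dict(d["line_strain"]),
            line_generations={k: int(v) for k, v in d["line_generations"].items()},
            mutations={
                line: [
                    Mutation(**{**m, "target_genes": tuple(m["target_genes"])})
                    for m in ms
                ]
                for line, ms in d["mutations"].items()
            },
            effects_log2={
                line: {g: float(v) for g, v in eff.items()}
                for line, eff in d["effects_log2"].items()
            },
            svs={line: [SV(**s) for s in ss] for line, ss in d["svs"].items()},
            fitness={k: float(v) for k, v in d["fitness"].items()},
            gene_modules={k: int(v) for k, v in d["gene_modules"].items()},
        )

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def read_json(cls, path: str | Path) -> "ExperimentTruth":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _child_rng(cfg: SimConfig, label: str) -> np.random.Generator:
    """Derive a deterministic child generator from the master seed."""
    h = zlib.crc32(label.encode()) % (2**31)
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, h]))


def generate_annotation(cfg: SimConfig) -> GenomeAnnotation:
    """Pack non-overlapping gene models onto the configured chromosomes.

    Genes are allotted to chromosomes proportionally to length, given random
    lengths (1–4 kb) and strand, and separated by random intergenic gaps.
    Raises if the genes cannot fit.
    """
    rng = _child_rng(cfg, "annotation")
    chrom_names = [f"chr{i + 1}" for i in range(len(cfg.chrom_lengths))]
    chrom_lengths = dict(zip(chrom_names, cfg.chrom_lengths))
    if cfg.n_genes == 0:
        empty = pd.DataFrame(
            columns=[
                "gene_id", "chrom", "start", "end", "strand",
                "utr5_start", "utr5_end", "utr3_start", "utr3_end", "exonic_length",
            ]
        )
        return GenomeAnnotation(empty, chrom_lengths)

    total_len = sum(cfg.chrom_lengths)
    # proportional allocation, largest-remainder rounding
    raw = np.array(cfg.chrom_lengths) / total_len * cfg.n_genes
    n_per = np.floor(raw).astype(int)
    rem = cfg.n_genes - n_per.sum()
    order = np.argsort(-(raw - n_per))
    n_per[order[:rem]] += 1

    rows = []
    gi = 0
    min_gap = 50
    for chrom, clen, n in zip(chrom_names, cfg.chrom_lengths, n_per):
        if n == 0:
            continue
        lengths = rng.integers(1000, 4001, size=n)
        needed = lengths.sum() + min_gap * (n + 1)
        if needed > clen:
            raise ValueError(
                f"cannot pack {n} genes ({needed} bp with gaps) into {chrom} "
                f"of {clen} bp"
            )
        slack = clen - needed
        # distribute the slack over the n+1 gaps
        extra = rng.multinomial(slack, np.full(n + 1, 1.0 / (n + 1)))
        gaps = min_gap + extra
        pos = 0
        for k in range(n):
            pos += gaps[k]
            start, end = pos, pos + int(lengths[k])
            pos = end
            strand = "+" if rng.random() < 0.5 else "-"
            u5 = int(rng.integers(100, 401))
            u3 = int(rng.integers(100, 401))
            if strand == "+":
                utr5 = (start, start + u5)
                utr3 = (end - u3, end)
            else:
                utr5 = (end - u5, end)
                utr3 = (start, start + u3)
            rows.append(
                {
                    "gene_id": f"g{gi:05d}",
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "strand": strand,
                    "utr5_start": utr5[0],
                    "utr5_end": utr5[1],
                    "utr3_start": utr3[0],
                    "utr3_end": utr3[1],
                    "exonic_length": end - start,
                }
            )
            gi += 1
    return GenomeAnnotation(pd.DataFrame(rows), chrom_lengths)


def generate_truth(cfg: SimConfig, annotation: GenomeAnnotation) -> ExperimentTruth:
    """Draw mutations, expression effects, SVs, and fitness for every line."""
    if annotation.n_genes == 0:
        raise ValueError("annotation is empty")
    rng = _child_rng(cfg, "truth")
    genes = annotation.genes
    gene_ids = annotation.gene_ids
    n_genes = annotation.n_genes
    dee_fit = cfg.dee_fit()

    module_of = rng.integers(0, cfg.n_modules, size=n_genes)
    gene_modules = {g: int(m) for g, m in zip(gene_ids, module_of)}
    module_members = {
        m: np.flatnonzero(module_of == m) for m in range(cfg.n_modules)
    }

    chrom_names = list(annotation.chrom_lengths)
    clens = np.array([annotation.chrom_lengths[c] for c in chrom_names])
    chrom_p = clens / clens.sum()

    line_strain: dict[str, str] = {}
    line_generations: dict[str, int] = {}
    mutations: dict[str, list[Mutation]] = {}
    effects: dict[str, dict[str, float]] = {}
    svs: dict[str, list[SV]] = {}
    fitness: dict[str, float] = {}

    for s_idx, strain in enumerate(cfg.strains):
        for l_idx in range(cfg.lines_per_strain[s_idx]):
            line = f"{strain}_L{l_idx + 1}"
            line_strain[line] = strain
            line_generations[line] = int(
                rng.integers(cfg.generations_range[0], cfg.generations_range[1] + 1)
            )
            m = int(rng.poisson(cfg.mean_mutations_per_line[s_idx]))
            muts: list[Mutation] = []
            line_eff: dict[str, float] = {}
            xs = (
                sample_per_mutation_effects(dee_fit, m, rng, discretize=True)
                if m
                else np.array([], dtype=int)
            )
            for x in xs:
                ci = int(rng.choice(len(chrom_names), p=chrom_p))
                chrom = chrom_names[ci]
                pos = int(rng.integers(0, clens[ci]))
                mut_type = "SNM" if rng.random() < 0.9 else "indel"
                targets: tuple[str, ...] = ()
                is_cis = False
                if x == 1:
                    tgt = int(rng.integers(0, n_genes))
                    targets = (str(gene_ids[tgt]),)
                    if rng.random() < cfg.cis_fraction:
                        is_cis = True
                        row = genes.iloc[tgt]
                        chrom = row["chrom"]
                        off = int(rng.integers(1, CIS_WINDOW_BP + 1))
                        if rng.random() < 0.5:
                            pos = max(int(row["start"]) - off, 0)
                        else:
                            pos = min(
                                int(row["end"]) + off - 1,
                                annotation.chrom_lengths[chrom] - 1,
                            )
                elif x >= 2:
                    mod = int(rng.integers(0, cfg.n_modules))
                    members = module_members[mod]
                    take = min(x, members.size)
                    idx = rng.choice(members, size=take, replace=False)
                    targets = tuple(str(g) for g in gene_ids[idx])
                muts.append(
                    Mutation(chrom, pos, line, mut_type, int(x), targets, is_cis)
                )
                for g in targets:
                    eff = float(rng.normal(0.0, cfg.effect_sd_log2))
                    line_eff[g] = line_eff.get(g, 0.0) + eff
            mutations[line] = muts
            effects[line] = line_eff

            n_sv = int(rng.poisson(cfg.sv_per_line))
            line_svs: list[SV] = []
            for _ in range(n_sv):
                ci = int(rng.choice(len(chrom_names), p=chrom_p))
                chrom = chrom_names[ci]
                sv_type = str(rng.choice(SV_TYPES, p=_SV_FREQS))
                length = max(1, int(rng.exponential(_SV_MEAN_LEN[sv_type])))
                start = int(rng.integers(0, max(clens[ci] - length, 1)))
                line_svs.append(SV(chrom, start, start + length, sv_type, line))
            svs[line] = line_svs

            fitness[line] = float(
                1.0
                + cfg.fitness_slope * len(line_eff)
                + rng.normal(0.0, cfg.fitness_noise_sd)
            )

    return ExperimentTruth(
        config=cfg,
        line_strain=line_strain,
        line_generations=line_generations,
        mutations=mutations,
        effects_log2=effects,
        svs=svs,
        fitness=fitness,
        gene_modules=gene_modules,
    )


def generate_counts(
    truth: ExperimentTruth, annotation: GenomeAnnotation
) -> "CountMatrix":
    """Sample the gene-by-sample read-count matrix implied by the truth.

    Per gene j and sample s the count is Poisson with rate
    ``sf_s * exp(mu_j + delta_{j,line(s)} + b)`` where ``mu_j`` is the
    log-normal ancestral log level, ``delta`` the line's true effect in
    natural-log units (zero for ancestors), and ``b`` an independent
    N(0, olre_sd) observation-level perturbation per matrix cell.
    """
    from .expression import CountMatrix  # local import to avoid a cycle

    cfg = truth.config
    rng = _child_rng(cfg, "counts")
    gene_ids = annotation.gene_ids
    n_genes = annotation.n_genes
    gene_pos = {g: i for i, g in enumerate(gene_ids)}

    mu = rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd, size=n_genes)

    meta_rows = []
    delta_cols = []
    ln2 = np.log(2.0)
    for strain in cfg.strains:
        anc = f"{strain}_ANC"
        for rep in range(1, cfg.replicates + 1):
            meta_rows.append(
                {
                    "sample_id": f"{anc}_r{rep}",
                    "strain": strain,
                    "line_id": anc,
                    "replicate": rep,
                    "is_ancestor": True,
                    "generations": 0,
                    "n_mutations": 0,
                }
            )
            delta_cols.append(np.zeros(n_genes))
        for line, ls in truth.line_strain.items():
            if ls != strain:
                continue
            delta = np.zeros(n_genes)
            for g, e in truth.effects_log2[line].items():
                delta[gene_pos[g]] = e * ln2
            for rep in range(1, cfg.replicates + 1):
                meta_rows.append(
                    {
                        "sample_id": f"{line}_r{rep}",
                        "strain": strain,
                        "line_id": line,
                        "replicate": rep,
                        "is_ancestor": False,
                        "generations": truth.line_generations[line],
                        "n_mutations": len(truth.mutations[line]),
                    }
                )
                delta_cols.append(delta)

    meta = pd.DataFrame(meta_rows)
    n_samples = len(meta)
    sf = rng.uniform(*cfg.size_factor_range, size=n_samples)
    delta_mat = np.column_stack(delta_cols)
    b = (
        rng.normal(0.0, cfg.olre_sd, size=(n_genes, n_samples))
        if cfg.olre_sd > 0
        else 0.0
    )
    lam = sf[None, :] * np.exp(mu[:, None] + delta_mat + b)
    counts = rng.poisson(lam)
    df = pd.DataFrame(counts, index=gene_ids, columns=meta["sample_id"].to_numpy())
    meta["true_size_factor"] = sf
    return CountMatrix(df, meta)


def simulate_glmm_gene(
    n_lines: int,
    replicates: int,
    covariates: Sequence[float],
    beta0: float,
    beta1: float,
    sigma2_u: float,
    sigma2_b: float,
    size_factors: Sequence[float] | None = None,
    rng: np.random.Generator | None = None,
):
    """Simulate one gene's counts from the mutational-variance model itself.

    Returns ``(y, x, line_index, size_factors, u)`` for a design of
    ``n_lines`` MA lines (plus one ancestor with covariate 0) with
    ``replicates`` observations each: a per-line random slope
    u_i ~ N(0, sigma2_u) on the covariate and an observation-level effect
    b ~ N(0, sigma2_b), with counts Poisson(sf * exp(eta)).
    """
    rng = rng or np.random.default_rng()
    x_line = np.concatenate([[0.0], np.asarray(covariates, dtype=float)])
    if x_line.size != n_lines + 1:
        raise ValueError("need one covariate per MA line")
    u = np.concatenate([[0.0], rng.normal(0.0, np.sqrt(sigma2_u), n_lines)])
    line_index = np.repeat(np.arange(n_lines + 1), replicates)
    x = x_line[line_index]
    n_obs = x.size
    sf = (
        np.ones(n_obs)
        if size_factors is None
        else np.asarray(size_factors, dtype=float)
    )
    b = rng.normal(0.0, np.sqrt(sigma2_b), n_obs)
    eta = beta0 + beta1 * x + u[line_index] * x + b
    y = rng.poisson(sf * np.exp(eta))
    return y, x, line_index, sf, u
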