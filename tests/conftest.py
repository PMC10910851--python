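"""Shared fixtures: small synthetic experiments and hand-built inputs."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mutexpr import coexpression as cx
from mutexpr import expression as xp
from mutexpr import simulate as sim


@pytest.fixture(scope="session")
def small_cfg() -> sim.SimConfig:
    """A desk-scale experiment: 2 strains, 3+3 lines, 120 genes."""
    return sim.SimConfig(
        n_strains=2,
        lines_per_strain=(3, 3),
        replicates=3,
        n_genes=120,
        chrom_lengths=(600_000, 600_000),
        mean_mutations_per_line=(8.0, 6.0),
        sv_per_line=5.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_experiment(small_cfg):
    ann = sim.generate_annotation(small_cfg)
    truth = sim.generate_truth(small_cfg, ann)
    cm = sim.generate_counts(truth, ann)
    return small_cfg, ann, truth, cm


@pytest.fixture(scope="session")
def modular_expression():
    """120 genes in 6 equal-size modules over 20 observations.

    Within-module correlation ~0.8, across-module ~0; the module labels are
    returned for planted-signal tests.
    """
    rng = np.random.default_rng(0)
    n_genes, n_modules, n_obs = 120, 6, 20
    module_of = np.repeat(np.arange(n_modules), n_genes // n_modules)
    factors = rng.normal(0.0, 1.0, (n_modules, n_obs))
    expr = 0.9 * factors[module_of] + np.sqrt(1 - 0.81) * rng.normal(
        0.0, 1.0, (n_genes, n_obs)
    )
    df = pd.DataFrame(expr, index=[f"g{i:03d}" for i in range(n_genes)])
    return df, module_of


@pytest.fixture(scope="session")
def modular_network(modular_expression):
    expr, module_of = modular_expression
    net = cx.build_network(expr, n_modules_target=10)
    net.distance_matrix()  # warm the cache once for the whole session
    return net, module_of


def make_annotation(genes: list[dict], chrom_lengths: dict[str, int]):
    """A GenomeAnnotation from plain dicts; UTRs default to empty intervals."""
    rows = []
    for g in genes:
        row = {
            "strand": "+",
            "utr5_start": -1,
            "utr5_end": -1,
            "utr3_start": -1,
            "utr3_end": -1,
        }
        row.update(g)
        row.setdefault("exonic_length", row["end"] - row["start"])
        rows.append(row)
    df = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "chrom", "start", "end", "strand",
            "utr5_start", "utr5_end", "utr3_start", "utr3_end", "exonic_length",
        ],
    )
    return sim.GenomeAnnotation(df, chrom_lengths)


def make_count_matrix(counts: np.ndarray, n_anc: int, n_line: int,
                      gene_ids=None, strain="S1", line_id="S1_L1"):
    """A one-strain CountMatrix: ancestor replicates first, then one MA line."""
    counts = np.asarray(counts)
    n_genes = counts.shape[0]
    gene_ids = gene_ids or [f"g{i}" for i in range(n_genes)]
    sample_ids = [f"{strain}_ANC_r{i+1}" for i in range(n_anc)] + [
        f"{line_id}_r{i+1}" for i in range(n_line)
    ]
    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "strain": strain,
            "line_id": [f"{strain}_ANC"] * n_anc + [line_id] * n_line,
            "replicate": list(range(1, n_anc + 1)) + list(range(1, n_line + 1)),
            "is_ancestor": [True] * n_anc + [False] * n_line,
            "generations": [0] * n_anc + [1000] * n_line,
            "n_mutations": [0] * n_anc + [100] * n_line,
        }
    )
    df = pd.DataFrame(counts, index=gene_ids, columns=sample_ids)
    return xp.CountMatrix(df, meta)
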