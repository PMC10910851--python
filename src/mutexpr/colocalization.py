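"""Permutation tests for mutation–DEG proximity, UTR enrichment, and SV overlap.

Evidence for cis-acting regulatory mutations is an excess of DEGs with a
mutation nearby.  The null keeps mutation positions fixed (mutations are not
uniform along the genome) and randomizes which genes are labeled DEGs; the
permutation p-value is the add-one fraction of random DEG sets with at least
as many near-mutation genes as observed.  The same label-randomizing null is
used for the structural-variant overlap test.

Coordinates are 0-based half-open throughout; GFF3/VCF inputs are converted
at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import GenomeAnnotation

MUTATION_COLUMNS = ["chrom", "pos", "line_id", "mut_type"]
SV_COLUMNS = ["chrom", "start", "end", "sv_type", "line_id"]

#: distance assigned to mutations inside a gene body (UTRs, exons, introns)
INTRAGENIC_DISTANCE = 1


def gene_mutation_distances(
    mutations: pd.DataFrame, annotation: GenomeAnnotation
) -> pd.Series:
    """Distance from every annotated gene to its nearest mutation.

    A mutation inside the gene body gives distance ``INTRAGENIC_DISTANCE``;
    otherwise the distance is the number of bases strictly between the
    mutation and the nearer gene edge (0 = immediately adjacent).  Genes on
    chromosomes without mutations get +inf.
    """
    genes = annotation.genes
    out = np.full(len(genes), np.inf)
    for chrom, mgrp in mutations.groupby("chrom"):
        sel = np.flatnonzero((genes["chrom"] == chrom).to_numpy())
        if sel.size == 0:
            continue
        pos = mgrp["pos"].to_numpy()[None, :]
        start = genes["start"].to_numpy()[sel][:, None]
        end = genes["end"].to_numpy()[sel][:, None]
        inside = (pos >= start) & (pos < end)
        left = start - pos - 1  # bases between an upstream mutation and start
        right = pos - end  # bases between end and a downstream mutation
        dist = np.where(inside, INTRAGENIC_DISTANCE, np.maximum(left, right))
        out[sel] = np.minimum(out[sel], dist.min(axis=1))
    return pd.Series(out, index=genes["gene_id"].to_numpy())


def nearest_mutation_distance(
    deg_genes, mutations: pd.DataFrame, annotation: GenomeAnnotation
) -> pd.Series:
    """Per-DEG distance to the nearest mutation of the same line."""
    deg_genes = list(deg_genes)
    all_dist = gene_mutation_distances(mutations, annotation)
    missing = [g for g in deg_genes if g not in all_dist.index]
    if missing:
        raise KeyError(f"genes absent from annotation: {missing[:5]}")
    return all_dist.loc[deg_genes]


@dataclass
class PermutationResult:
    observed: float
    p_value: float
    n_perm: int
    extra: dict

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05

    @property
    def marginal(self) -> bool:
        return 0.05 <= self.p_value < 0.1


def _sample_gene_sets(rng, n_genes, k, n_perm, chunk=2000):
    """Yield (chunk_size, index array) batches of uniform k-gene draws."""
    done = 0
    while done < n_perm:
        c = min(chunk, n_perm - done)
        idx = np.argpartition(rng.random((c, n_genes)), k - 1, axis=1)[:, :k]
        yield idx
        done += c


def cis_enrichment_test(
    deg_genes,
    mutations: pd.DataFrame,
    annotation: GenomeAnnotation,
    window: int = 100,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> PermutationResult:
    """Test whether a line's DEGs are enriched near its mutations.

    ``observed`` is the number of DEGs with a mutation within ``window`` bp
    of a gene flank (intragenic mutations count).  The null redraws the DEG
    labels uniformly over annotated genes, keeping mutation positions fixed.
    Also reports the number of unique mutations within the window of a DEG
    and the number of mutation–DEG pairs.
    """
    deg_genes = list(dict.fromkeys(deg_genes))
    if len(deg_genes) == 0 or len(mutations) == 0:
        raise ValueError("need at least one DEG and one mutation")
    n_genes = annotation.n_genes
    k = len(deg_genes)
    if k > n_genes:
        raise ValueError("more DEGs than genes in the annotation universe")
    dist = gene_mutation_distances(mutations, annotation)
    near = (dist.to_numpy() <= window)
    gene_pos = {g: i for i, g in enumerate(annotation.gene_ids)}
    try:
        deg_idx = np.array([gene_pos[g] for g in deg_genes])
    except KeyError as exc:
        raise KeyError(f"gene absent from annotation: {exc}") from exc
    observed = int(near[deg_idx].sum())

    rng = np.random.default_rng(seed)
    exceed = 0
    for idx in _sample_gene_sets(rng, n_genes, k, n_perm):
        exceed += int((near[idx].sum(axis=1) >= observed).sum())
    p = (exceed + 1) / (n_perm + 1)

    # per-mutation bookkeeping for the cis-candidate counts
    deg_set = set(deg_genes)
    genes = annotation.genes
    n_pair = 0
    near_mut = 0
    for _, mu in mutations.iterrows():
        same = genes[genes["chrom"] == mu["chrom"]]
        start = same["start"].to_numpy()
        end = same["end"].to_numpy()
        pos = mu["pos"]
        inside = (pos >= start) & (pos < end)
        d = np.where(inside, INTRAGENIC_DISTANCE, np.maximum(start - pos - 1, pos - end))
        hit = same["gene_id"].to_numpy()[(d <= window)]
        hits_deg = [g for g in hit if g in deg_set]
        n_pair += len(hits_deg)
        near_mut += bool(hits_deg)
    return PermutationResult(
        observed=observed,
        p_value=p,
        n_perm=n_perm,
        extra={
            "n_degs": k,
            "n_mutations": len(mutations),
            "n_cis_mutations": near_mut,
            "n_mutation_deg_pairs": n_pair,
        },
    )


def utr_enrichment(
    mutations: pd.DataFrame,
    annotation: GenomeAnnotation,
    denominator: str = "gene_model",
) -> dict:
    """Fold enrichment of intragenic mutations in UTRs.

    The numerator is the fraction of intragenic mutations that fall in a
    5'/3' UTR; the denominator is the UTR fraction of total gene-model bp
    (default) or of the whole genome (``denominator='genome'``).
    """
    genes = annotation.genes
    utr_bp = int(
        (genes["utr5_end"] - genes["utr5_start"]).sum()
        + (genes["utr3_end"] - genes["utr3_start"]).sum()
    )
    gene_bp = int((genes["end"] - genes["start"]).sum())
    if utr_bp == 0:
        raise ValueError("annotation has no UTR sequence")
    if denominator == "gene_model":
        expected = utr_bp / gene_bp
    elif denominator == "genome":
        expected = utr_bp / sum(annotation.chrom_lengths.values())
    else:
        raise ValueError("denominator must be 'gene_model' or 'genome'")

    n_intra = 0
    n_utr = 0
    for chrom, mgrp in mutations.groupby("chrom"):
        sub = genes[genes["chrom"] == chrom]
        if sub.empty:
            continue
        pos = mgrp["pos"].to_numpy()[:, None]
        inside = (pos >= sub["start"].to_numpy()) & (pos < sub["end"].to_numpy())
        in_utr5 = (pos >= sub["utr5_start"].to_numpy()) & (
            pos < sub["utr5_end"].to_numpy()
        )
        in_utr3 = (pos >= sub["utr3_start"].to_numpy()) & (
            pos < sub["utr3_end"].to_numpy()
        )
        n_intra += int(inside.any(axis=1).sum())
        n_utr += int(((in_utr5 | in_utr3) & inside).any(axis=1).sum())
    if n_intra == 0:
        raise ValueError("no intragenic mutation")
    observed = n_utr / n_intra
    return {
        "n_intragenic": n_intra,
        "n_in_utr": n_utr,
        "observed_utr_fraction": observed,
        "expected_utr_fraction": expected,
        "fold_enrichment": observed / expected,
    }


def sv_overlapped_genes(svs: pd.DataFrame, annotation: GenomeAnnotation) -> set[str]:
    """Genes whose model interval intersects any SV interval by >= 1 bp."""
    bad = svs[svs["start"] >= svs["end"]]
    if len(bad):
        raise ValueError("malformed SV interval (start >= end)")
    genes = annotation.genes
    out: set[str] = set()
    for chrom, grp in svs.groupby("chrom"):
        sub = genes[genes["chrom"] == chrom]
        if sub.empty:
            continue
        s = sub["start"].to_numpy()[:, None]
        e = sub["end"].to_numpy()[:, None]
        hit = ((s < grp["end"].to_numpy()) & (e > grp["start"].to_numpy())).any(axis=1)
        out.update(sub["gene_id"].to_numpy()[hit])
    return out


def sv_deg_overlap_test(
    svs: pd.DataFrame,
    deg_genes,
    annotation: GenomeAnnotation,
    n_perm: int = 1000,
    seed: int | None = None,
) -> PermutationResult:
    """Test whether SV-overlapped genes are enriched for DEGs.

    ``observed`` is the proportion of SV-overlapped genes that are DEGs; the
    null redraws equally sized DEG sets uniformly over annotated genes.
    With no SVs (or no overlapped gene) the proportion is 0 and p = 1.
    """
    deg_genes = list(dict.fromkeys(deg_genes))
    k = len(deg_genes)
    n_genes = annotation.n_genes
    if k > n_genes:
        raise ValueError("more DEGs than genes in the annotation universe")
    overlapped = sv_overlapped_genes(svs, annotation) if len(svs) else set()
    if not overlapped or k == 0:
        return PermutationResult(0.0, 1.0, n_perm, {"n_overlapped_genes": 0})
    gene_pos = {g: i for i, g in enumerate(annotation.gene_ids)}
    ov = np.zeros(n_genes, dtype=bool)
    ov[[gene_pos[g] for g in overlapped]] = True
    deg_idx = np.array([gene_pos[g] for g in deg_genes])
    n_ov = int(ov.sum())
    observed = float(ov[deg_idx].sum() / n_ov)

    rng = np.random.default_rng(seed)
    exceed = 0
    for idx in _sample_gene_sets(rng, n_genes, k, n_perm):
        exceed += int((ov[idx].sum(axis=1) / n_ov >= observed).sum())
    p = (exceed + 1) / (n_perm + 1)
    return PermutationResult(
        observed=observed,
        p_value=p,
        n_perm=n_perm,
        extra={"n_overlapped_genes": n_ov, "n_degs": k},
    )
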