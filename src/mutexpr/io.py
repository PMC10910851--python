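"""Readers and writers for the pipeline's plain-text fixture formats.

A fixture directory holds: counts.tsv (gene x sample), samples.tsv,
annotation.gff3, mutations.tsv (or mutations.vcf with a LINE_ID INFO tag),
svs.tsv, fitness.tsv, and truth.json.  GFF3 is 1-based inclusive and VCF
1-based; both are converted to the package's 0-based half-open convention on
read and back on write.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .colocalization import MUTATION_COLUMNS, SV_COLUMNS
from .expression import CountMatrix
from .simulate import ExperimentTruth, GenomeAnnotation

META_COLUMNS = [
    "sample_id", "strain", "line_id", "replicate", "is_ancestor",
    "generations", "n_mutations",
]


# -- counts -----------------------------------------------------------------


def write_counts(cm: CountMatrix, counts_path, samples_path) -> None:
    cm.counts.rename_axis("gene_id").to_csv(counts_path, sep="\t")
    cm.meta[META_COLUMNS].to_csv(samples_path, sep="\t", index=False)


def read_counts(counts_path, samples_path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = pd.read_csv(samples_path, sep="\t")
    meta["is_ancestor"] = meta["is_ancestor"].astype(bool)
    return CountMatrix(counts[meta["sample_id"]], meta)


# -- annotation (GFF3) ------------------------------------------------------


def write_annotation_gff3(annotation: GenomeAnnotation, path) -> None:
    lines = ["##gff-version 3"]
    for chrom, length in annotation.chrom_lengths.items():
        lines.append(f"##sequence-region {chrom} 1 {length}")
    for _, g in annotation.genes.iterrows():
        gid = g["gene_id"]
        common = f"{g['chrom']}\tmutexpr\t"
        lines.append(
            common
            + f"gene\t{g['start'] + 1}\t{g['end']}\t.\t{g['strand']}\t.\tID={gid}"
        )
        lines.append(
            common
            + f"five_prime_UTR\t{g['utr5_start'] + 1}\t{g['utr5_end']}\t.\t"
            + f"{g['strand']}\t.\tParent={gid}"
        )
        lines.append(
            common
            + f"three_prime_UTR\t{g['utr3_start'] + 1}\t{g['utr3_end']}\t.\t"
            + f"{g['strand']}\t.\tParent={gid}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def _gff_attr(attrs: str, key: str) -> str:
    for part in attrs.split(";"):
        k, _, v = part.partition("=")
        if k == key:
            return v
    raise KeyError(f"attribute {key} not in {attrs!r}")


def read_annotation_gff3(path) -> GenomeAnnotation:
    chrom_lengths: dict[str, int] = {}
    names = [
        "chrom", "source", "type", "start", "end", "score", "strand", "phase",
        "attributes",
    ]
    rows = []
    with open(path) as fh:
        body = []
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##sequence-region"):
                _, chrom, _, end = line.split()
                chrom_lengths[chrom] = int(end)
            elif line and not line.startswith("#"):
                body.append(line.split("\t"))
    df = pd.DataFrame(body, columns=names)
    df["start"] = df["start"].astype(int) - 1  # to 0-based half-open
    df["end"] = df["end"].astype(int)
    genes = df[df["type"] == "gene"].copy()
    genes["gene_id"] = genes["attributes"].map(lambda a: _gff_attr(a, "ID"))
    utr5 = df[df["type"] == "five_prime_UTR"].copy()
    utr5["gene_id"] = utr5["attributes"].map(lambda a: _gff_attr(a, "Parent"))
    utr3 = df[df["type"] == "three_prime_UTR"].copy()
    utr3["gene_id"] = utr3["attributes"].map(lambda a: _gff_attr(a, "Parent"))
    out = genes[["gene_id", "chrom", "start", "end", "strand"]].merge(
        utr5[["gene_id", "start", "end"]].rename(
            columns={"start": "utr5_start", "end": "utr5_end"}
        ),
        on="gene_id",
        how="left",
    ).merge(
        utr3[["gene_id", "start", "end"]].rename(
            columns={"start": "utr3_start", "end": "utr3_end"}
        ),
        on="gene_id",
        how="left",
    )
    out["exonic_length"] = out["end"] - out["start"]
    for c in ("utr5_start", "utr5_end", "utr3_start", "utr3_end"):
        out[c] = out[c].fillna(-1).astype(int)
    if not chrom_lengths:
        for chrom, grp in out.groupby("chrom"):
            chrom_lengths[chrom] = int(grp["end"].max())
    return GenomeAnnotation(out, chrom_lengths)


# -- mutations --------------------------------------------------------------


def write_mutations_tsv(truth: ExperimentTruth, path) -> None:
    rows = [
        {"chrom": m.chrom, "pos": m.pos, "line_id": line, "mut_type": m.mut_type}
        for line, ms in truth.mutations.items()
        for m in ms
    ]
    pd.DataFrame(rows, columns=MUTATION_COLUMNS).to_csv(path, sep="\t", index=False)


def read_mutations_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(MUTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"mutations table missing columns {sorted(missing)}")
    return df[MUTATION_COLUMNS]


def write_mutations_vcf(truth: ExperimentTruth, path) -> None:
    """Minimal VCF 4.2 with per-record LINE_ID and TYPE INFO tags."""
    header = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=LINE_ID,Number=1,Type=String,Description="MA line">',
        '##INFO=<ID=TYPE,Number=1,Type=String,Description="SNM or indel">',
    ]
    anno_chroms = sorted({m.chrom for ms in truth.mutations.values() for m in ms})
    for c in anno_chroms:
        header.append(f"##contig=<ID={c}>")
    header.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    recs = []
    for line, ms in truth.mutations.items():
        for m in ms:
            recs.append(
                (m.chrom, m.pos + 1, f"{m.chrom}\t{m.pos + 1}\t.\tN\tA\t.\t.\t"
                 f"LINE_ID={line};TYPE={m.mut_type}")
            )
    recs.sort(key=lambda r: (r[0], r[1]))
    Path(path).write_text("\n".join(header + [r[2] for r in recs]) + "\n")


def read_mutations_vcf(path) -> pd.DataFrame:
    """Read mutations from a VCF with LINE_ID INFO tags (requires cyvcf2)."""
    from cyvcf2 import VCF

    rows = []
    for rec in VCF(str(path)):
        rows.append(
            {
                "chrom": rec.CHROM,
                "pos": rec.POS - 1,
                "line_id": rec.INFO.get("LINE_ID"),
                "mut_type": rec.INFO.get("TYPE", "SNM"),
            }
        )
    return pd.DataFrame(rows, columns=MUTATION_COLUMNS)


# -- SVs, fitness, DEGs, networks -------------------------------------------


def write_svs_tsv(truth: ExperimentTruth, path) -> None:
    rows = [
        {
            "chrom": s.chrom, "start": s.start, "end": s.end,
            "sv_type": s.sv_type, "line_id": line,
        }
        for line, ss in truth.svs.items()
        for s in ss
    ]
    pd.DataFrame(rows, columns=SV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_svs_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(SV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"SV table missing columns {sorted(missing)}")
    return df[SV_COLUMNS]


def write_fitness_tsv(truth: ExperimentTruth, path) -> None:
    pd.DataFrame(
        {"line_id": list(truth.fitness), "fitness_rel": list(truth.fitness.values())}
    ).to_csv(path, sep="\t", index=False)


def read_fitness_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_deg_table(degs: pd.DataFrame, path) -> None:
    degs.to_csv(path, sep="\t", index=False)


def read_deg_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["significant"] = df["significant"].astype(bool)
    return df


def write_edge_list(network, path) -> None:
    """Write the sparsified network as an edge-list TSV (gene_a, gene_b, cor)."""
    c = network.correlation
    rows = []
    n = network.n_genes
    for i in range(n):
        for j in range(i + 1, n):
            if abs(c[i, j]) >= network.cor_floor:
                rows.append(
                    {
                        "gene_a": network.gene_ids[i],
                        "gene_b": network.gene_ids[j],
                        "correlation": c[i, j],
                    }
                )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_edge_list(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# -- whole fixture directories ----------------------------------------------


def write_fixture_dir(out_dir, annotation, truth, cm, vcf: bool = False) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_counts(cm, out / "counts.tsv", out / "samples.tsv")
    write_annotation_gff3(annotation, out / "annotation.gff3")
    write_mutations_tsv(truth, out / "mutations.tsv")
    if vcf:
        write_mutations_vcf(truth, out / "mutations.vcf")
    write_svs_tsv(truth, out / "svs.tsv")
    write_fitness_tsv(truth, out / "fitness.tsv")
    truth.write_json(out / "truth.json")
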