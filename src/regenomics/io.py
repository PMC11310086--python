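"""Readers and writers for the pipeline's plain-text table formats.

All tables are TSV; gene coordinate and repeat tables are BED-like
(0-based half-open); trees are newick.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = [
    "read_expression",
    "write_expression",
    "read_families",
    "write_families",
    "read_hits",
    "read_bed_genes",
    "write_bed_genes",
    "read_repeats_bed",
    "write_repeats_bed",
    "read_de_table",
    "write_table",
]


def read_expression(path) -> pd.DataFrame:
    """Expression TSV: gene_id column then one column per sample."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression(matrix: pd.DataFrame, path) -> None:
    matrix.rename_axis("gene_id").to_csv(path, sep="\t")


def read_families(path) -> pd.DataFrame:
    """Families TSV: family_id, species, gene_id."""
    return pd.read_csv(path, sep="\t", dtype=str)


def write_families(families: pd.DataFrame, path) -> None:
    families.to_csv(path, sep="\t", index=False)


def read_hits(path) -> pd.DataFrame:
    """3-column similarity hit TSV: query, target, score."""
    df = pd.read_csv(path, sep="\t", header=None, names=["query", "target", "score"])
    df["score"] = df["score"].astype(float)
    return df


def read_bed_genes(path) -> pd.DataFrame:
    """Gene BED (chrom, start, end, gene_id) -> per-gene chromosome/ordinal.

    Genes are ranked along each chromosome by start to give the 0-based
    ordinal ``position`` used by synteny bundling.
    """
    bed = pd.read_csv(
        path, sep="\t", header=None, names=["chromosome", "start", "end", "gene_id"]
    )
    bed = bed.sort_values(["chromosome", "start"])
    bed["position"] = bed.groupby("chromosome").cumcount()
    return bed.set_index("gene_id")[["chromosome", "position"]]


def write_bed_genes(genome: pd.DataFrame, path) -> None:
    """Inverse of :func:`read_bed_genes` using ordinals as coordinates."""
    out = genome.reset_index()
    out["start"] = out["position"] * 1000
    out["end"] = out["start"] + 500
    out[["chromosome", "start", "end", "gene_id"]].to_csv(
        path, sep="\t", index=False, header=False
    )


def read_repeats_bed(path) -> pd.DataFrame:
    """Repeat BED + family, class, divergence columns."""
    return pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chromosome", "start", "end", "copy_id", "family", "class", "divergence"],
    )


def write_repeats_bed(repeats: pd.DataFrame, path) -> None:
    repeats[
        ["chromosome", "start", "end", "copy_id", "family", "class", "divergence"]
    ].to_csv(path, sep="\t", index=False, header=False)


def read_de_table(path) -> pd.DataFrame:
    """DE TSV: gene_id, contrast, log2fc, pvalue, padj."""
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)
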