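"""Orthology and gene-family utilities.

Reciprocal-best-hit one-to-one orthologs from similarity score tables,
cross-species family retention filtering, and phylostratigraphic gene-age
assignment on a species tree.

Homologous gene families are represented as a long-format DataFrame with
columns ``family_id``, ``species``, ``gene_id`` (one row per gene); a gene
belongs to exactly one family.
"""

from __future__ import annotations

import dendropy
import pandas as pd

__all__ = [
    "reciprocal_best_hits",
    "filter_families",
    "assign_phylostrata",
    "family_genes",
]

FAMILY_COLUMNS = ["family_id", "species", "gene_id"]
LINEAGE_SPECIFIC = "lineage-specific"


def family_genes(families: pd.DataFrame, species: str) -> pd.Series:
    """Map gene_id -> family_id for one species."""
    sub = families[families["species"] == species]
    return pd.Series(sub["family_id"].to_numpy(), index=sub["gene_id"].to_numpy())


def _unique_best(hits: pd.DataFrame) -> dict:
    """Best target per query; queries whose top score is tied are dropped."""
    best: dict = {}
    for query, grp in hits.groupby("query", sort=False):
        top = grp["score"].max()
        winners = grp.loc[grp["score"] == top, "target"].unique()
        if len(winners) == 1:
            best[query] = winners[0]
    return best


def reciprocal_best_hits(
    scores_1to2: pd.DataFrame, scores_2to1: pd.DataFrame
) -> pd.DataFrame:
    """One-to-one orthologs by reciprocal best hit.

    A pair (a, b) is kept iff b is a's unique best target and a is b's
    unique best target. Score ties for the best hit disqualify the query
    (one-to-one semantics: an ambiguous best is not a best).

    Parameters
    ----------
    scores_1to2, scores_2to1 : DataFrame
        Hit tables with columns ``query``, ``target``, ``score``
        (higher is better).

    Returns
    -------
    DataFrame with columns ``gene1``, ``gene2``.
    """
    for tab in (scores_1to2, scores_2to1):
        missing = {"query", "target", "score"} - set(tab.columns)
        if missing:
            raise ValueError(f"hit table missing columns: {sorted(missing)}")
    best12 = _unique_best(scores_1to2)
    best21 = _unique_best(scores_2to1)
    pairs = [
        (a, b) for a, b in best12.items() if best21.get(b) == a
    ]
    return pd.DataFrame(pairs, columns=["gene1", "gene2"])


def filter_families(
    families: pd.DataFrame,
    sp1: str,
    sp2: str,
    min_per_species: int = 1,
    max_per_species: int = 4,
) -> tuple[pd.DataFrame, dict]:
    """Retain families by per-species gene-count bounds.

    A family is kept iff its gene count in each of ``sp1`` and ``sp2``
    lies within [min_per_species, max_per_species] (defaults 1 and 4,
    i.e. present in both species and fewer than 5 copies in each).

    Returns
    -------
    (filtered, report) : (DataFrame, dict)
        ``report`` holds retained family and per-species gene counts.
    """
    if min_per_species > max_per_species:
        raise ValueError("min_per_species must be <= max_per_species")
    counts = (
        families[families["species"].isin([sp1, sp2])]
        .groupby(["family_id", "species"])
        .size()
        .unstack(fill_value=0)
        .reindex(columns=[sp1, sp2], fill_value=0)
    )
    all_fams = families["family_id"].unique()
    counts = counts.reindex(all_fams, fill_value=0)
    ok = counts.apply(
        lambda col: col.between(min_per_species, max_per_species)
    ).all(axis=1)
    keep = set(counts.index[ok])
    filtered = families[families["family_id"].isin(keep)].reset_index(drop=True)
    report = {
        "n_families_in": int(len(all_fams)),
        "n_families_retained": int(len(keep)),
        "n_genes_retained": {
            sp: int((filtered["species"] == sp).sum()) for sp in (sp1, sp2)
        },
    }
    return filtered, report


def assign_phylostrata(
    families: pd.DataFrame,
    tree: dendropy.Tree | str,
    focal: str,
    lineage_specific_label: str = LINEAGE_SPECIFIC,
) -> tuple[pd.Series, list]:
    """Phylostratigraphic age stratum of every focal-species gene.

    A gene's stratum is the most ancient node on the root-to-focal path
    whose subtree contains at least one *other* species present in the
    gene's family; a family restricted to the focal species gets the
    youngest (lineage-specific) stratum. Internal node labels on the
    focal lineage name the strata.

    Parameters
    ----------
    tree : dendropy.Tree or newick str
        Species tree whose leaves cover the species in ``families``;
        internal nodes on the focal path should carry labels.
    focal : str
        Focal species (leaf taxon label).

    Returns
    -------
    (strata, order) : (Series, list)
        ``strata`` maps focal gene_id -> stratum label; ``order`` lists
        strata from youngest (lineage-specific) to oldest.
    """
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick", preserve_underscores=True)
    leaf_names = {lf.taxon.label for lf in tree.leaf_node_iter()}
    if focal not in leaf_names:
        raise ValueError(f"focal species {focal!r} is not a leaf of the tree")
    focal_leaf = next(
        lf for lf in tree.leaf_node_iter() if lf.taxon.label == focal
    )
    # root -> focal path, excluding the focal leaf itself
    path = []
    node = focal_leaf.parent_node
    while node is not None:
        path.append(node)
        node = node.parent_node
    path = path[::-1]  # most ancient first
    node_species = [
        {lf.taxon.label for lf in n.leaf_iter()} - {focal} for n in path
    ]
    labels = [
        n.label if n.label else f"stratum_{i}" for i, n in enumerate(path)
    ]
    order = [lineage_specific_label] + labels[::-1]

    # MRCA(focal, s) = most recent path node whose subtree holds s
    level: dict = {}
    for i, spp in enumerate(node_species):
        for s in spp:
            level[s] = i  # later (deeper) nodes overwrite earlier ones

    fam_species = families.groupby("family_id")["species"].agg(set)
    focal_rows = families[families["species"] == focal]
    strata = {}
    for gene, fam in zip(focal_rows["gene_id"], focal_rows["family_id"]):
        others = fam_species[fam] - {focal}
        known = [level[s] for s in others if s in level]
        if not known:
            strata[gene] = lineage_specific_label
        else:
            # the most ancient MRCA across family members sets the age
            strata[gene] = labels[min(known)]
    return pd.Series(strata, name="stratum"), order
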