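"""Hypergeometric enrichment and depletion with custom backgrounds.

One-sided hypergeometric tests against a user-supplied background with
Benjamini-Hochberg correction, family-level annotation propagation, and
wrappers for per-cluster gene-age and curated-list enrichment.
"""

from __future__ import annotations

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "propagate_to_families",
    "hypergeom_test",
    "age_and_list_enrichment",
]


def propagate_to_families(
    gene_annotations: pd.DataFrame,
    families: pd.DataFrame,
    species_subset=None,
) -> pd.DataFrame:
    """Annotate each family with the union of its member genes' terms.

    Transfers flat per-gene annotations (columns ``gene_id``,
    ``term_id``) to the family level: a family's term set is the union
    over its members, optionally restricted to genes of
    ``species_subset``. Idempotent; unannotated families simply get no
    rows.

    Returns a DataFrame with columns ``family_id``, ``term_id``.
    """
    fams = families
    if species_subset is not None:
        fams = fams[fams["species"].isin(set(species_subset))]
    merged = fams.merge(gene_annotations, on="gene_id")
    out = merged[["family_id", "term_id"]].drop_duplicates().reset_index(drop=True)
    return out


def hypergeom_test(
    foreground,
    background,
    annotations: dict,
    direction: str = "enrich",
    min_term_size: int = 3,
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment or depletion per term.

    With background size M, term hits in the background K, foreground
    size n and foreground hits k: the enrichment p-value is the upper
    tail P(X >= k) and the depletion p-value the lower tail P(X <= k)
    of Hypergeometric(M, K, n). BH correction is applied across all
    tested terms. Terms with K = 0 or K < ``min_term_size`` are skipped
    and listed in ``result.attrs["skipped"]``.

    Parameters
    ----------
    foreground, background : iterable
        Entity sets; the foreground must be contained in the background.
    annotations : mapping
        term -> set of entities.
    direction : {'enrich', 'deplete'}
    """
    fg = set(foreground)
    bg = set(background)
    stray = fg - bg
    if stray:
        raise ValueError(
            f"foreground not contained in background; offending ids: {sorted(stray)[:10]}"
        )
    if not bg:
        raise ValueError("background is empty")
    if direction not in ("enrich", "deplete"):
        raise ValueError("direction must be 'enrich' or 'deplete'")
    M, n = len(bg), len(fg)
    rows, skipped = [], []
    for term in sorted(annotations):
        members = set(annotations[term]) & bg
        K = len(members)
        if K == 0 or K < min_term_size:
            skipped.append(term)
            continue
        k = len(members & fg)
        if direction == "enrich":
            p = float(stats.hypergeom.sf(k - 1, M, K, n))
        else:
            p = float(stats.hypergeom.cdf(k, M, K, n))
        rows.append((term, k, n, K, M, direction, min(p, 1.0)))
    result = pd.DataFrame(
        rows,
        columns=["term", "k", "n", "K", "M", "direction", "pvalue"],
    )
    if len(result):
        result["padj"] = multipletests(result["pvalue"], method="fdr_bh")[1]
    else:
        result["padj"] = pd.Series(dtype=float)
    result.attrs["skipped"] = skipped
    return result


def age_and_list_enrichment(
    hard: pd.Series,
    labels,
    background=None,
    direction: str = "enrich",
    min_term_size: int = 3,
) -> pd.DataFrame:
    """Per-cluster enrichment of gene-age strata or curated gene lists.

    For each cluster, tests the cluster's genes (foreground) against all
    clustered genes (default background) for over-representation of
    each stratum/list; BH correction is applied within each cluster's
    test family, matching per-panel FDR control. Pass an explicit
    ``background`` for conservation-aware tests (e.g. all focal genes
    whose expression conservation could be assessed).

    Parameters
    ----------
    hard : Series
        Gene -> cluster hard assignment.
    labels : Series or mapping
        Either a Series gene -> stratum label, or a mapping
        list_name -> iterable of genes.

    Returns one concatenated DataFrame with a ``cluster`` column.
    """
    if isinstance(labels, pd.Series):
        annotations = {
            str(lbl): set(labels.index[labels == lbl]) for lbl in labels.unique()
        }
    else:
        annotations = {str(name): set(genes) for name, genes in labels.items()}
    bg = set(hard.index) if background is None else set(background)
    if not bg:
        raise ValueError("background is empty")
    pieces = []
    for cluster in sorted(hard.unique()):
        fg = set(hard.index[hard == cluster]) & bg
        if not fg:
            continue
        res = hypergeom_test(
            fg, bg, annotations, direction=direction, min_term_size=min_term_size
        )
        res.insert(0, "cluster", cluster)
        pieces.append(res)
    if not pieces:
        return pd.DataFrame(
            columns=["cluster", "term", "k", "n", "K", "M", "direction", "pvalue", "padj"]
        )
    return pd.concat(pieces, ignore_index=True)
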