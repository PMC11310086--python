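"""Explant differential-expression filtering and categorisation.

An explanted arm regenerates at its distal cut and only wound-heals at
its proximal cut; contrasting each against medial control segments
separates regenerative from generic wound responses. This module
consumes per-contrast DE statistic tables (the negative-binomial model
fitting itself is upstream), applies the retention thresholds, and
categorises genes by their distal/proximal behaviour.
"""

from __future__ import annotations

import pandas as pd
from statsmodels.stats.multitest import multipletests

from regenomics.enrichment import hypergeom_test

__all__ = ["deg_filter", "categorize_degs", "deg_cluster_enrichment"]


def deg_filter(
    table: pd.DataFrame,
    alpha: float = 0.05,
    lfc: float = 1.0,
    adjust_raw: bool = False,
) -> dict:
    """Up/down DEG sets per contrast.

    A gene is retained iff its adjusted p < ``alpha`` and its absolute
    log2 fold change is strictly greater than ``lfc`` (defaults 0.05
    and 1). Expects columns ``gene_id``, ``contrast``, ``log2fc`` and
    ``padj`` (or ``pvalue`` with ``adjust_raw=True`` to BH-adjust
    within each contrast).

    Returns
    -------
    dict
        contrast -> {"up": set, "down": set}.
    """
    required = {"gene_id", "contrast", "log2fc"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    df = table.copy()
    if "padj" not in df.columns:
        if not adjust_raw or "pvalue" not in df.columns:
            raise ValueError(
                "missing padj column (pass adjust_raw=True with a pvalue column to BH-adjust)"
            )
        df["padj"] = df.groupby("contrast")["pvalue"].transform(
            lambda p: multipletests(p, method="fdr_bh")[1]
        )
    out = {}
    for contrast, sub in df.groupby("contrast"):
        sig = sub[sub["padj"] < alpha]
        out[contrast] = {
            "up": set(sig.loc[sig["log2fc"] > lfc, "gene_id"]),
            "down": set(sig.loc[sig["log2fc"] < -lfc, "gene_id"]),
        }
    return out


def categorize_degs(distal: dict, proximal: dict) -> tuple[pd.DataFrame, dict]:
    """Categorise DEGs by distal vs proximal behaviour at one timepoint.

    Categories: ``distal_specific``, ``proximal_specific``, ``shared``
    (same direction in both segments) and ``opposite`` (up in one,
    down in the other). The categories are disjoint and cover the
    union of all four input sets.

    Parameters
    ----------
    distal, proximal : dict
        {"up": set, "down": set} from :func:`deg_filter`, same timepoint.

    Returns
    -------
    (table, summary)
        Per-gene categories and a summary with the fraction of proximal
        DEGs shared with distal and the fraction of distal DEGs that
        are distal-specific.
    """
    d_up, d_dn = set(distal["up"]), set(distal["down"])
    p_up, p_dn = set(proximal["up"]), set(proximal["down"])
    assert not (d_up & d_dn) and not (p_up & p_dn), "a gene cannot be both up and down"
    d_all = d_up | d_dn
    p_all = p_up | p_dn
    rows = []
    for g in sorted(d_all | p_all):
        in_d, in_p = g in d_all, g in p_all
        if in_d and in_p:
            same = (g in d_up) == (g in p_up)
            cat = "shared" if same else "opposite"
        elif in_d:
            cat = "distal_specific"
        else:
            cat = "proximal_specific"
        rows.append((g, cat))
    table = pd.DataFrame(rows, columns=["gene_id", "category"])
    cats = dict(zip(table["gene_id"], table["category"]))
    shared_prox = sum(
        1 for g in p_all if cats[g] in ("shared", "opposite")
    )
    summary = {
        "n_distal": len(d_all),
        "n_proximal": len(p_all),
        "frac_proximal_shared_with_distal": shared_prox / len(p_all) if p_all else 0.0,
        "frac_distal_specific": (
            sum(1 for g in d_all if cats[g] == "distal_specific") / len(d_all)
            if d_all
            else 0.0
        ),
    }
    return table, summary


def deg_cluster_enrichment(
    deg_sets: dict,
    hard: pd.Series,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric enrichment of DEG sets in time-course clusters.

    For each named DEG set, each co-expression cluster is tested for
    over-representation of the set's genes among all clustered genes;
    BH correction within each DEG set. DEG genes absent from the
    clustering are dropped from the foreground. Empty sets are skipped
    and listed in ``result.attrs["skipped"]``.
    """
    background = set(hard.index)
    clusters = {
        str(c): set(hard.index[hard == c]) for c in sorted(hard.unique())
    }
    pieces, skipped = [], []
    for name, genes in deg_sets.items():
        fg = set(genes) & background
        if not fg:
            skipped.append(name)
            continue
        res = hypergeom_test(fg, background, clusters, direction="enrich",
                             min_term_size=1)
        res.insert(0, "deg_set", name)
        res = res.rename(columns={"term": "cluster"})
        res["significant"] = res["padj"] < alpha
        pieces.append(res)
    if not pieces:
        out = pd.DataFrame(
            columns=["deg_set", "cluster", "k", "n", "K", "M", "direction",
                     "pvalue", "padj", "significant"]
        )
    else:
        out = pd.concat(pieces, ignore_index=True)
    out.attrs["skipped"] = skipped
    return out
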