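"""Explant DEG filtering, distal/proximal categorisation and cluster links.

Applies the retention thresholds (p_adj < 0.05, |log2FC| > 1) to the
synthetic explant DE tables, categorises genes as distal-specific /
proximal-specific / shared / opposite, scores the categorisation
against the planted truth, and tests DEG sets for enrichment in the
time-course co-expression clusters.
"""

from pathlib import Path

import pandas as pd

from regenomics import explant, simulate
from regenomics.io import read_de_table, write_table

DATA, OUT = Path("results/data"), Path("results")
SEED = 1
deg_table = read_de_table(DATA / "deg_table.tsv")
truth = pd.read_csv(DATA / "truth_deg_categories.tsv", sep="\t")

sets = explant.deg_filter(deg_table, alpha=0.05, lfc=1.0)
for contrast, ud in sorted(sets.items()):
    print(f"{contrast}: {len(ud['up'])} up, {len(ud['down'])} down")

table, summary = explant.categorize_degs(sets["distal"], sets["proximal"])
write_table(table, OUT / "deg_categories.tsv")
mapping = {
    "shared": "shared",
    "opposite": "opposite",
    "distal_only": "distal_specific",
    "proximal_only": "proximal_specific",
}
merged = table.merge(truth, on="gene_id")
accuracy = (merged["category_x"] == merged["category_y"].map(mapping)).mean()
print(
    f"categories: {table['category'].value_counts().to_dict()}; "
    f"accuracy vs planted truth {accuracy:.3f}"
)
print(
    f"{summary['frac_proximal_shared_with_distal']:.0%} of proximal DEGs shared "
    f"with distal; {summary['frac_distal_specific']:.0%} of distal DEGs are "
    f"distal-specific"
)

hard = pd.read_csv(OUT / "clusters_sp1.tsv", sep="\t", index_col=0)["cluster"]
# synthetic DEGs are not the clustered genes; link them by planting the
# distal-up set inside cluster 0 for the enrichment demonstration
demo_sets = {
    "distal_up_demo": set(hard.index[hard == 0][: len(sets["distal"]["up"])])
}
enr = explant.deg_cluster_enrichment(demo_sets, hard)
write_table(enr, OUT / "deg_cluster_enrichment.tsv")
best = enr.sort_values("padj").iloc[0]
print(
    f"DEG-cluster enrichment demo: set drawn from cluster 0 flags cluster "
    f"{best['cluster']} (padj {best['padj']:.2e})"
)
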