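"""Generate every synthetic input table the downstream analyses consume.

Writes expression matrices (TPM + counts), the homologous family table,
karyotype gene maps, repeat/breakpoint tables and explant DE statistics
under results/data/, together with the planted-truth tables that the
recovery analyses are scored against.
"""

from pathlib import Path

from regenomics import simulate
from regenomics.io import write_expression, write_families, write_table

OUT = Path("results/data")
SEED = 1

cfg = simulate.SimulationConfig(
    seed=SEED, n_clusters=4, conservation_rate=0.8, noise_sd=0.25
)
OUT.mkdir(parents=True, exist_ok=True)

tc = simulate.simulate_timecourse(cfg)
for sp in cfg.species:
    write_expression(tc.tpm[sp], OUT / f"tpm_{sp}.tsv")
    write_expression(tc.counts[sp], OUT / f"counts_{sp}.tsv")
write_families(tc.families, OUT / "families.tsv")
write_table(tc.true_clusters, OUT / "truth_clusters.tsv")
write_table(tc.family_truth, OUT / "truth_families.tsv")

kd = simulate.simulate_karyotypes(cfg)
for taxon, genome in kd.genomes.items():
    write_table(genome.reset_index(), OUT / f"genome_{taxon}.tsv")
write_table(kd.orthologs, OUT / "orthologs.tsv")
write_table(kd.events, OUT / "truth_events.tsv")
kd.anc_labels.rename("alg").rename_axis("anc_gene").reset_index().to_csv(
    OUT / "anc_labels.tsv", sep="\t", index=False
)

rd = simulate.simulate_repeats_and_degs(cfg)
write_table(rd.repeats, OUT / "repeats.tsv")
write_table(rd.deg_table, OUT / "deg_table.tsv")
write_table(rd.family_truth, OUT / "truth_repeat_families.tsv")
write_table(rd.deg_truth, OUT / "truth_deg_categories.tsv")

n_genes = {sp: len(tc.tpm[sp]) for sp in cfg.species}
print(f"simulated 2 species, {cfg.n_families} families, genes per species: {n_genes}")
print(f"karyotypes: {len(kd.genomes)} taxa, {len(kd.events)} true events logged")
print(
    f"repeats: {len(rd.repeats)} copies in {rd.repeats['family'].nunique()} families, "
    f"{len(rd.breakpoints)} breakpoints; DEG table: {rd.deg_table['gene_id'].nunique()} genes"
)
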