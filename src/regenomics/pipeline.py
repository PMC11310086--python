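"""End-to-end orchestration of the analysis stages on synthetic data.

A single YAML/dict config drives the run; stages execute in dependency
order (simulate -> cluster -> conserve/enrich; paint; repeats; explant),
write their statistic tables as TSVs under the output directory, and a
provenance record (config hash, seed, package version) is stored with
every run. Reruns with identical config and seed produce identical
tables.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from regenomics import __version__, clustering, conservation, enrichment, explant
from regenomics import karyotype as kt
from regenomics import repeats as rp
from regenomics import simulate as sim
from regenomics.io import write_table

ALL_STAGES = ("simulate", "cluster", "conserve", "enrich", "paint", "repeats", "explant")

DEFAULT_CONFIG = {
    "seed": 0,
    "outdir": "results/pipeline",
    "stages": list(ALL_STAGES),
    "simulate": {"n_clusters": 5, "n_families": 300, "conservation_rate": 0.8,
                 "noise_sd": 0.3},
    "cluster": {"m": 1.25},
    "conserve": {"n_perm": 1000, "alpha": 0.05},
    "paint": {"threshold": 1e-5},
    "repeats": {"n_perm": 1000, "window": 10000.0},
    "explant": {"alpha": 0.05, "lfc": 1.0},
}


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    config = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    for k, v in user.items():
        if isinstance(v, dict) and isinstance(config.get(k), dict):
            config[k].update(v)
        else:
            config[k] = v
    return config


def _provenance(config: dict, outdir: Path) -> None:
    blob = json.dumps(config, sort_keys=True, default=str)
    record = {
        "config_hash": hashlib.sha256(blob.encode()).hexdigest(),
        "seed": config.get("seed", 0),
        "version": __version__,
        "config": config,
    }
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(record, fh, indent=2, default=str)


def run(config: dict | str | Path) -> dict:
    """Execute the requested stages; returns in-memory stage outputs.

    ``config`` may be a dict or a YAML path. Each stage is idempotent
    given identical inputs, config and seed. A stage whose inputs are
    missing raises a named error telling which stage to run first.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    merged = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    for k, v in config.items():
        if isinstance(v, dict) and isinstance(merged.get(k), dict):
            merged[k].update(v)
        else:
            merged[k] = v
    config = merged
    stages = list(config["stages"])
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    state: dict = {}

    def require(key: str, needed_by: str, producer: str):
        if key not in state:
            raise RuntimeError(
                f"stage {needed_by!r} needs output of stage {producer!r}; run it first"
            )

    if "simulate" in stages:
        scfg = sim.SimulationConfig(seed=seed, **config["simulate"])
        state["sim_config"] = scfg
        state["timecourse"] = sim.simulate_timecourse(scfg)
        state["karyotypes"] = sim.simulate_karyotypes(scfg)
        state["repeat_deg"] = sim.simulate_repeats_and_degs(scfg)
        for sp, mat in state["timecourse"].tpm.items():
            write_table(mat.rename_axis("gene_id"), outdir / f"tpm_{sp}.tsv", index=True)
        write_table(state["timecourse"].families, outdir / "families.tsv")

    if "cluster" in stages:
        require("timecourse", "cluster", "simulate")
        tc = state["timecourse"]
        scfg = state["sim_config"]
        clusterings = {}
        for sp, mat in tc.tpm.items():
            std, _ = clustering.transform_standardize(mat)
            cl = clustering.fuzzy_cmeans(
                std, scfg.n_clusters, m=config["cluster"]["m"], seed=seed
            )
            clusterings[sp] = cl
            memb = cl.membership.max(axis=1).rename("membership_max").to_frame()
            memb["cluster"] = cl.hard
            write_table(memb.rename_axis("gene_id"), outdir / f"clusters_{sp}.tsv",
                        index=True)
            write_table(cl.centroids.rename_axis("cluster"),
                        outdir / f"centroids_{sp}.tsv", index=True)
        state["clusterings"] = clusterings

    if "conserve" in stages:
        require("clusterings", "conserve", "cluster")
        tc = state["timecourse"]
        cls = state["clusterings"]
        sps = sorted(cls)
        res = conservation.permutation_test(
            cls[sps[0]].hard,
            cls[sps[1]].hard,
            tc.families,
            sps[0],
            sps[1],
            n_perm=int(config["conserve"]["n_perm"]),
            seed=seed,
            alpha=float(config["conserve"]["alpha"]),
        )
        state["conservation"] = res
        write_table(res.counts.rename_axis("cluster1"), outdir / "overlap_counts.tsv",
                    index=True)
        long = (
            res.pvalues.rename_axis("cluster1").reset_index()
            .melt(id_vars="cluster1", var_name="cluster2", value_name="pvalue")
        )
        long["padj"] = (
            res.padj.rename_axis("cluster1").reset_index()
            .melt(id_vars="cluster1", var_name="cluster2")["value"]
        )
        write_table(long, outdir / "overlap_pvalues.tsv")
        conserved = [
            (i, j, g) for (i, j), genes in res.conserved.items() for g in genes
        ]
        write_table(
            pd.DataFrame(conserved, columns=["cluster1", "cluster2", "gene_id"]),
            outdir / "conserved_genes.tsv",
        )

    if "enrich" in stages:
        require("clusterings", "enrich", "cluster")
        scfg = state["sim_config"]
        sp = sorted(state["clusterings"])[0]
        hard = state["clusterings"][sp].hard
        genes = pd.DataFrame(
            {"gene_id": hard.index, "cluster": hard.to_numpy()}
        )
        annotations, _ = sim.simulate_annotations(genes, scfg)
        ann = {
            t: set(sub["gene_id"]) for t, sub in annotations.groupby("term_id")
        }
        results = enrichment.age_and_list_enrichment(hard, ann)
        state["enrichment"] = results
        write_table(results, outdir / "enrichment.tsv")

    if "paint" in stages:
        require("karyotypes", "paint", "simulate")
        kd = state["karyotypes"]
        paintings = {}
        rows = []
        for taxon, genome in kd.genomes.items():
            labels = kd.taxon_labels(taxon)
            p = kt.fisher_painting(
                labels, genome["chromosome"], threshold=float(config["paint"]["threshold"])
            )
            paintings[taxon] = p
            events, _ = kt.count_events(p)
            rows.append((taxon, events))
            write_table(p.table, outdir / f"painting_{taxon}.tsv")
        state["paintings"] = paintings
        state["event_counts"] = pd.DataFrame(rows, columns=["taxon", "events"])
        write_table(state["event_counts"], outdir / "event_counts.tsv")

    if "repeats" in stages:
        require("repeat_deg", "repeats", "simulate")
        rd = state["repeat_deg"]
        assoc = rp.breakpoint_association_test(
            rd.repeats,
            rd.breakpoints,
            rd.region,
            window=float(config["repeats"]["window"]),
            n_perm=int(config["repeats"]["n_perm"]),
            seed=seed,
        )
        state["breakpoint_assoc"] = assoc
        write_table(assoc, outdir / "breakpoint_association.tsv")
        lands = rp.landscape(rd.repeats, genome_length=rd.region[1])
        write_table(lands, outdir / "repeat_landscape.tsv")

    if "explant" in stages:
        require("repeat_deg", "explant", "simulate")
        rd = state["repeat_deg"]
        sets = explant.deg_filter(
            rd.deg_table,
            alpha=float(config["explant"]["alpha"]),
            lfc=float(config["explant"]["lfc"]),
        )
        table, summary = explant.categorize_degs(sets["distal"], sets["proximal"])
        state["deg_categories"] = table
        state["deg_summary"] = summary
        write_table(table, outdir / "deg_categories.tsv")

    _provenance(config, outdir)
    return state


def report(state: dict) -> str:
    """Human-readable run summary; every number comes from a stage table."""
    lines = ["# Pipeline report", ""]
    if "clusterings" in state:
        for sp, cl in sorted(state["clusterings"].items()):
            sizes = cl.hard.value_counts().sort_index()
            lines.append(
                f"{sp}: {cl.n_clusters} clusters, sizes "
                + ", ".join(f"{c}:{n}" for c, n in sizes.items())
            )
    if "conservation" in state:
        res = state["conservation"]
        pairs = res.significant_pairs()
        if pairs:
            lines.append(
                f"conserved cluster pairs ({len(pairs)}): "
                + ", ".join(f"{i}-{j}" for i, j in pairs)
            )
            lines.append(f"conserved genes: {len(res.conserved_genes())}")
        else:
            lines.append("no conserved clusters")
    if "enrichment" in state:
        sig = state["enrichment"]
        n_sig = int((sig["padj"] < 0.05).sum()) if len(sig) else 0
        lines.append(f"enriched (cluster, term) pairs at FDR<0.05: {n_sig}")
    if "event_counts" in state:
        for row in state["event_counts"].itertuples():
            lines.append(f"{row.taxon}: {row.events} interchromosomal events")
    if "breakpoint_assoc" in state:
        sig = state["breakpoint_assoc"]
        fams = sorted(sig.loc[sig["significant"], "family"]) if len(sig) else []
        lines.append(f"breakpoint-associated repeat families: {fams or 'none'}")
    if "deg_summary" in state:
        s = state["deg_summary"]
        lines.append(
            f"DEGs: {s['n_distal']} distal, {s['n_proximal']} proximal; "
            f"{s['frac_proximal_shared_with_distal']:.0%} of proximal shared with distal; "
            f"{s['frac_distal_specific']:.0%} of distal are distal-specific"
        )
    return "\n".join(lines) + "\n"
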