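"""Synthetic data with planted ground truth for every pipeline stage.

Generates expression time courses with planted co-expression clusters
and cross-species conserved families, karyotype histories with logged
fusion/fission/translocation events, annotation tables with planted
enrichment odds, and repeat/DEG tables with planted breakpoint
association and DE categories. Identical config + seed reproduce
byte-identical outputs; per-stage substreams are derived from the
global seed (offset 0 = time course, 1 = karyotype, 2 = annotations,
3 = repeats/DEGs) so stages can be rerun independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SimulationConfig",
    "KaryotypeConfig",
    "RepeatRegionConfig",
    "TimecourseData",
    "KaryotypeData",
    "RepeatDegData",
    "simulate_timecourse",
    "simulate_karyotypes",
    "simulate_annotations",
    "simulate_age_strata",
    "simulate_repeats_and_degs",
    "STRATA_TREE",
    "STRATA_ORDER",
]

#: default regeneration sampling design: one non-regenerating control
#: then seven regenerating stages (early wound healing through late
#: differentiation), mirroring an arm-regeneration time course
DEFAULT_STAGES = (
    "control",
    "48hpa",
    "72hpa",
    "stage3",
    "stage4",
    "stage5",
    "50pct_D",
    "50pct_P",
)

#: toy species tree used for phylostratum simulation; internal labels
#: name the strata on the focal root path
STRATA_TREE = (
    "(((((focal:1,sp_class:1)class:1,sp_phylum:1)phylum:1,"
    "sp_ambulacraria:2)Ambulacraria:1,sp_deuterostome:3)Deuterostomia:1,"
    "sp_metazoan:4)Metazoa;"
)
STRATA_ORDER = [
    "lineage-specific",
    "class",
    "phylum",
    "Ambulacraria",
    "Deuterostomia",
    "Metazoa",
]
#: extra species whose presence in a family certifies each stratum
_STRATUM_WITNESS = {
    "class": "sp_class",
    "phylum": "sp_phylum",
    "Ambulacraria": "sp_ambulacraria",
    "Deuterostomia": "sp_deuterostome",
    "Metazoa": "sp_metazoan",
}


@dataclass
class KaryotypeConfig:
    """Ancestral karyotype and per-branch rearrangement rates.

    Rates are expected events per unit branch length; event counts per
    branch are Poisson(rate * length).
    """

    n_algs: int = 20
    genes_per_alg: int = 100
    fusion_rate: float = 1.0
    fission_rate: float = 0.5
    translocation_rate: float = 0.25
    #: smallest chromosome fragment (genes) a fission/translocation may
    #: leave behind; keeps planted rearrangements statistically visible
    min_fragment: int = 25
    tree: str = "((ingroup1:1,ingroup2:1)ingroup:1,outgroup:2)root;"

    def __post_init__(self):
        if self.n_algs < 1 or self.genes_per_alg < 1:
            raise ValueError("counts must be >= 1")
        for r in (self.fusion_rate, self.fission_rate, self.translocation_rate):
            if r < 0:
                raise ValueError("event rates must be >= 0")


@dataclass
class RepeatRegionConfig:
    """Repeat region geometry and planted breakpoint association."""

    length: int = 1_000_000
    n_breakpoints: int = 3
    clustering_weight: float = 0.9  #: fraction pi of associated copies near breakpoints
    n_families: int = 10
    copies_per_family: int = 200
    n_associated: int = 1
    window: float = 10_000.0

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError("region length must be > 0")
        if not 0 <= self.clustering_weight <= 1:
            raise ValueError("clustering weight pi must be in [0, 1]")


@dataclass
class SimulationConfig:
    """All knobs of the synthetic-data generator (one global seed)."""

    seed: int = 0
    n_species: int = 2
    stages: tuple = DEFAULT_STAGES
    n_clusters: int = 5
    n_families: int = 500
    conservation_rate: float = 0.5
    noise_sd: float = 0.3
    family_size_max: int = 4
    template_width: float = 1.5
    n_terms: int = 50
    term_prevalence: float = 0.1
    enrichment_odds: float = 10.0
    karyotype: KaryotypeConfig = field(default_factory=KaryotypeConfig)
    repeat_region: RepeatRegionConfig = field(default_factory=RepeatRegionConfig)

    def __post_init__(self):
        if not 0 <= self.conservation_rate <= 1:
            raise ValueError("conservation_rate must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.enrichment_odds <= 0:
            raise ValueError("enrichment_odds must be > 0")
        for c in (self.n_species, self.n_clusters, self.n_families,
                  self.family_size_max, self.n_terms):
            if c < 1:
                raise ValueError("all counts must be >= 1")

    @property
    def species(self) -> list:
        return [f"sp{i + 1}" for i in range(self.n_species)]

    def rng(self, offset: int) -> np.random.Generator:
        """Substream generator for one pipeline stage."""
        return np.random.default_rng([self.seed, offset])


@dataclass
class TimecourseData:
    """Per-species expression, family table and planted truth."""

    tpm: dict  #: species -> genes x samples TPM DataFrame
    counts: dict  #: species -> Poisson count variant
    regenerating: pd.Series  #: per sample, False for the control
    families: pd.DataFrame  #: family_id, species, gene_id
    true_clusters: pd.DataFrame  #: species, gene_id, cluster
    family_truth: pd.DataFrame  #: family_id, conserved, template_cluster

    def hard_truth(self, species: str) -> pd.Series:
        sub = self.true_clusters[self.true_clusters["species"] == species]
        return pd.Series(sub["cluster"].to_numpy(), index=sub["gene_id"].to_numpy())


def _templates(n_stages: int, n_clusters: int, width: float) -> np.ndarray:
    """Unimodal (Gaussian bump) templates with evenly spaced peaks."""
    peaks = np.linspace(0, n_stages - 1, n_clusters)
    s = np.arange(n_stages)
    return np.exp(-((s[None, :] - peaks[:, None]) ** 2) / (2 * width**2))


def simulate_timecourse(config: SimulationConfig) -> TimecourseData:
    """Simulate conserved co-expression time courses for several species.

    Each gene follows the unimodal template of its cluster (Gaussian
    bump over the ordered stage index, fixed width) plus Gaussian noise,
    scaled by a lognormal gene-level abundance. A fraction rho
    (``conservation_rate``) of families is conserved: all member genes
    in every species take the family's template cluster; the remaining
    families assign each gene a cluster independently at random. A
    Poisson count layer with uneven library depths is emitted for
    normalisation tests.
    """
    n_stages = len(config.stages)
    if n_stages < 2:
        raise ValueError("need at least 2 samples per species")
    if config.n_clusters < 2:
        raise ValueError("need at least 2 clusters")
    if n_stages < config.n_clusters:
        raise ValueError("fewer stages than clusters requested")
    rng = config.rng(0)
    C = config.n_clusters
    templates = _templates(n_stages, C, config.template_width)

    conserved = rng.random(config.n_families) < config.conservation_rate
    template_cluster = rng.integers(0, C, size=config.n_families)
    fam_rows, cluster_rows = [], []
    gene_clusters: dict = {sp: {} for sp in config.species}
    for f in range(config.n_families):
        fid = f"fam{f:05d}"
        for sp in config.species:
            size = int(rng.integers(1, config.family_size_max + 1))
            for i in range(size):
                gene = f"{sp}_f{f:05d}g{i}"
                cl = (
                    int(template_cluster[f])
                    if conserved[f]
                    else int(rng.integers(0, C))
                )
                fam_rows.append((fid, sp, gene))
                cluster_rows.append((sp, gene, cl))
                gene_clusters[sp][gene] = cl

    tpm, counts = {}, {}
    for sp in config.species:
        genes = list(gene_clusters[sp])
        cl = np.array([gene_clusters[sp][g] for g in genes])
        abundance = rng.lognormal(mean=np.log(50.0), sigma=1.0, size=len(genes))
        noise = rng.normal(0.0, config.noise_sd, size=(len(genes), n_stages))
        profiles = np.clip(templates[cl] + noise, 0.0, None)
        x = profiles * abundance[:, None]
        tpm[sp] = pd.DataFrame(x, index=genes, columns=list(config.stages))
        depth = rng.uniform(0.5, 2.0, size=n_stages)
        counts[sp] = pd.DataFrame(
            rng.poisson(x * depth[None, :]),
            index=genes,
            columns=list(config.stages),
        )
    regenerating = pd.Series(
        [s != "control" for s in config.stages], index=list(config.stages)
    )
    return TimecourseData(
        tpm=tpm,
        counts=counts,
        regenerating=regenerating,
        families=pd.DataFrame(fam_rows, columns=["family_id", "species", "gene_id"]),
        true_clusters=pd.DataFrame(
            cluster_rows, columns=["species", "gene_id", "cluster"]
        ),
        family_truth=pd.DataFrame(
            {
                "family_id": [f"fam{f:05d}" for f in range(config.n_families)],
                "conserved": conserved,
                "template_cluster": template_cluster,
            }
        ),
    )


# ---------------------------------------------------------------------------
# Karyotype histories
# ---------------------------------------------------------------------------


@dataclass
class KaryotypeData:
    """Simulated genomes, ortholog map, ancestral labels and event log."""

    genomes: dict  #: taxon -> DataFrame(index=gene, columns=[chromosome, position])
    orthologs: pd.DataFrame  #: anc_gene, taxon, gene_id
    anc_labels: pd.Series  #: ancestral gene -> ALG name
    events: pd.DataFrame  #: branch, type, detail
    tree: str

    def taxon_labels(self, taxon: str) -> pd.Series:
        """True ALG label of every gene of one taxon."""
        sub = self.orthologs[self.orthologs["taxon"] == taxon]
        return pd.Series(
            self.anc_labels.loc[sub["anc_gene"]].to_numpy(),
            index=sub["gene_id"].to_numpy(),
        )

    def ortholog_pairs(self, taxon1: str, taxon2: str) -> pd.DataFrame:
        a = self.orthologs[self.orthologs["taxon"] == taxon1]
        b = self.orthologs[self.orthologs["taxon"] == taxon2]
        merged = a.merge(b, on="anc_gene", suffixes=("1", "2"))
        return merged[["gene_id1", "gene_id2"]].rename(
            columns={"gene_id1": "gene1", "gene_id2": "gene2"}
        )


def _valid_cuts(chrom: list, min_fragment: int) -> list:
    """Cut positions leaving >= min_fragment genes of every ancestral
    linkage group on each side of the cut (a cut at a block boundary is
    always allowed): keeps every planted rearrangement detectable."""
    labels = [g.split("_")[0] for g in chrom]
    n = len(chrom)
    cuts = []
    for c in range(min_fragment, n - min_fragment + 1):
        if labels[c - 1] != labels[c]:
            cuts.append(c)  # block boundary, nothing split
            continue
        s = c
        while s > 0 and labels[s - 1] == labels[c]:
            s -= 1
        e = c
        while e < n and labels[e] == labels[c]:
            e += 1
        if c - s >= min_fragment and e - c >= min_fragment:
            cuts.append(c)
    return cuts


def _apply_event(genome: list, etype: str, rng, min_fragment: int = 10):
    """Mutate the chromosome list in place; returns (type, detail) or
    None when no chromosome is large enough to cut."""
    if etype == "fusion":
        i, j = rng.choice(len(genome), size=2, replace=False)
        genome[int(i)] = genome[int(i)] + genome[int(j)]
        genome.pop(int(j))
        return "fusion", f"{i}+{j}"
    if etype == "fission":
        options = [
            (k, _valid_cuts(ch, min_fragment)) for k, ch in enumerate(genome)
        ]
        options = [(k, cuts) for k, cuts in options if cuts]
        if not options:
            return None
        k, cuts = options[int(rng.integers(len(options)))]
        cut = int(cuts[int(rng.integers(len(cuts)))])
        genome.append(genome[k][cut:])
        genome[k] = genome[k][:cut]
        return "fission", f"{k}@{cut}"
    # reciprocal translocation: exchange terminal segments
    options = [
        (k, _valid_cuts(ch, min_fragment)) for k, ch in enumerate(genome)
    ]
    options = [(k, cuts) for k, cuts in options if cuts]
    if len(options) < 2:
        return None
    a, b = rng.choice(len(options), size=2, replace=False)
    (i, cuts_i), (j, cuts_j) = options[int(a)], options[int(b)]
    cut_i = int(cuts_i[int(rng.integers(len(cuts_i)))])
    cut_j = int(cuts_j[int(rng.integers(len(cuts_j)))])
    ci, cj = genome[i], genome[j]
    genome[i] = ci[:cut_i] + cj[cut_j:]
    genome[j] = cj[:cut_j] + ci[cut_i:]
    return "translocation", f"{i}@{cut_i}x{j}@{cut_j}"


def simulate_karyotypes(config: SimulationConfig) -> KaryotypeData:
    """Evolve an ancestral karyotype along a species tree.

    The ancestor carries ``n_algs`` chromosomes of ``genes_per_alg``
    genes each (one ancestral linkage group per chromosome). Along each
    branch, Poisson(rate x length) fusions, fissions and reciprocal
    translocations are applied; a fusion drawn on a one-chromosome
    genome is resampled to another event type and logged. Every event
    is recorded in the true per-branch event log.
    """
    kc = config.karyotype
    rng = config.rng(1)
    tree = dendropy.Tree.get(data=kc.tree, schema="newick", preserve_underscores=True)
    anc = [
        [f"anc{a:03d}_{i:04d}" for i in range(kc.genes_per_alg)]
        for a in range(kc.n_algs)
    ]
    anc_labels = pd.Series(
        {g: f"ALG{a:02d}" for a, chrom in enumerate(anc) for g in chrom}
    )
    rates = np.array([kc.fusion_rate, kc.fission_rate, kc.translocation_rate])
    total = rates.sum()
    events, genomes = [], {}

    def node_name(node) -> str:
        if node.is_leaf():
            return node.taxon.label
        return node.label or "internal"

    def recurse(node, genome):
        for child in node.child_nodes():
            g = [list(ch) for ch in genome]
            length = child.edge.length or 1.0
            n_ev = rng.poisson(total * length) if total > 0 else 0
            for _ in range(n_ev):
                etype = rng.choice(
                    ["fusion", "fission", "translocation"], p=rates / total
                )
                if etype in ("fusion", "translocation") and len(g) < 2:
                    events.append((node_name(child), "resampled", etype))
                    etype = "fission"
                applied = _apply_event(g, etype, rng, kc.min_fragment)
                if applied is None:
                    continue  # nothing cuttable; degenerate genome
                events.append((node_name(child), *applied))
            if child.is_leaf():
                genomes[child.taxon.label] = g
            recurse(child, g)

    recurse(tree.seed_node, anc)

    genome_tables, orth_rows = {}, []
    for taxon, chroms in genomes.items():
        rows = []
        for k, ch in enumerate(chroms):
            for pos, anc_gene in enumerate(ch):
                gene = f"{taxon}|{anc_gene}"
                rows.append((gene, f"{taxon}_chr{k:02d}", pos))
                orth_rows.append((anc_gene, taxon, gene))
        genome_tables[taxon] = pd.DataFrame(
            rows, columns=["gene_id", "chromosome", "position"]
        ).set_index("gene_id")
    return KaryotypeData(
        genomes=genome_tables,
        orthologs=pd.DataFrame(orth_rows, columns=["anc_gene", "taxon", "gene_id"]),
        anc_labels=anc_labels,
        events=pd.DataFrame(events, columns=["branch", "type", "detail"]),
        tree=kc.tree,
    )


# ---------------------------------------------------------------------------
# Annotations and age strata
# ---------------------------------------------------------------------------


def simulate_annotations(
    genes: pd.DataFrame,
    config: SimulationConfig,
    planted: list | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw flat term annotations with planted (term, cluster) odds.

    Background membership probability is ``term_prevalence`` p0; for a
    planted (term, cluster) pair the in-cluster membership probability
    p1 satisfies odds(p1) = theta * odds(p0) with theta =
    ``enrichment_odds``. ``planted=None`` plants term 0 in cluster 0;
    pass ``[]`` for a fully null annotation set.

    Parameters
    ----------
    genes : DataFrame with columns gene_id, cluster.

    Returns
    -------
    (annotations, truth)
        annotations: gene_id, term_id rows; truth: planted pairs.
    """
    theta = config.enrichment_odds
    p0 = config.term_prevalence
    if planted is None:
        planted = [("T000", 0)]
    rng = config.rng(2)
    odds1 = theta * p0 / (1 - p0)
    p1 = odds1 / (1 + odds1)
    planted_map = {term: cluster for term, cluster in planted}
    rows = []
    gene_ids = genes["gene_id"].to_numpy()
    clusters = genes["cluster"].to_numpy()
    for t in range(config.n_terms):
        term = f"T{t:03d}"
        probs = np.full(len(gene_ids), p0)
        if term in planted_map:
            probs[clusters == planted_map[term]] = p1
        member = rng.random(len(gene_ids)) < probs
        rows.extend((g, term) for g in gene_ids[member])
    truth = pd.DataFrame(planted, columns=["term_id", "cluster"])
    return pd.DataFrame(rows, columns=["gene_id", "term_id"]), truth


def simulate_age_strata(
    genes: pd.DataFrame,
    config: SimulationConfig,
    planted: list | None = None,
    focal: str = "focal",
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Plant phylostratum ages consistent with the toy species tree.

    Each focal gene gets its own single-gene family; the family's
    stratum is drawn uniformly over ``STRATA_ORDER`` except for genes
    of a planted (stratum, cluster) pair, whose odds for the planted
    stratum are multiplied by ``enrichment_odds``. The emitted family
    table contains, per family, the focal gene plus the witness species
    certifying exactly the drawn stratum, so a tree walk on
    ``STRATA_TREE`` recovers the planted ages.

    Returns
    -------
    (families, truth_strata, truth_planted)
    """
    rng = config.rng(2)
    if planted is None:
        planted = [(STRATA_ORDER[0], 0)]
    planted_map = {stratum: cluster for stratum, cluster in planted}
    theta = config.enrichment_odds
    base = np.ones(len(STRATA_ORDER))
    rows, strata = [], {}
    for i, (gene, cluster) in enumerate(
        zip(genes["gene_id"], genes["cluster"])
    ):
        w = base.copy()
        for stratum, cl in planted_map.items():
            if cluster == cl:
                w[STRATA_ORDER.index(stratum)] *= theta
        stratum = str(rng.choice(STRATA_ORDER, p=w / w.sum()))
        strata[gene] = stratum
        fid = f"agefam{i:05d}"
        rows.append((fid, focal, gene))
        witness = _STRATUM_WITNESS.get(stratum)
        if witness is not None:
            rows.append((fid, witness, f"{witness}_g{i:05d}"))
    families = pd.DataFrame(rows, columns=["family_id", "species", "gene_id"])
    truth = pd.DataFrame(planted, columns=["stratum", "cluster"])
    return families, pd.Series(strata, name="stratum"), truth


# ---------------------------------------------------------------------------
# Repeats and DEG tables
# ---------------------------------------------------------------------------


@dataclass
class RepeatDegData:
    repeats: pd.DataFrame
    breakpoints: np.ndarray
    region: tuple
    deg_table: pd.DataFrame
    family_truth: pd.DataFrame  #: family, associated flag
    deg_truth: pd.DataFrame  #: gene_id, category


_DEG_CATEGORIES = ("shared", "opposite", "distal_only", "proximal_only", "null")
_DEG_PROPORTIONS = (0.10, 0.05, 0.20, 0.05, 0.60)


def simulate_repeats_and_degs(
    config: SimulationConfig,
    n_deg_genes: int = 1000,
    effect: float = 3.0,
    se: float = 0.5,
) -> RepeatDegData:
    """Simulate a repeat region with breakpoints plus explant DE tables.

    Associated repeat families place a fraction pi of their copies
    within +/- window of a breakpoint, the rest uniformly in the
    region; non-associated families are fully uniform. The DE table
    draws log2 fold changes around +/- ``effect`` (normal error ``se``)
    for the planted category of each gene in two contrasts (distal and
    proximal vs medial) and converts them to Wald-type p-values; an
    ``opposite`` gene has distal and proximal effects of opposing sign
    by construction.
    """
    rc = config.repeat_region
    rng = config.rng(3)
    L = float(rc.length)
    w = rc.window
    bps = np.sort(rng.uniform(0.1 * L, 0.9 * L, size=rc.n_breakpoints))
    rows = []
    classes = ("LINE", "SINE", "DNA", "LTR", "Unknown")
    for f in range(rc.n_families):
        fam = f"repfam{f:02d}"
        associated = f < rc.n_associated
        cls = classes[f % len(classes)]
        for c in range(rc.copies_per_family):
            length = int(rng.integers(100, 1000))
            if associated and rng.random() < rc.clustering_weight:
                bp = float(rng.choice(bps))
                lo = max(0.0, bp - w)
                hi = min(L - length, bp + w)
                start = float(rng.uniform(lo, hi))
            else:
                start = float(rng.uniform(0, L - length))
            rows.append(
                (
                    f"{fam}_c{c:04d}",
                    fam,
                    cls,
                    "region_chr",
                    int(start),
                    int(start) + length,
                    float(rng.uniform(0, 30)),
                )
            )
    repeats = pd.DataFrame(
        rows,
        columns=[
            "copy_id",
            "family",
            "class",
            "chromosome",
            "start",
            "end",
            "divergence",
        ],
    )
    family_truth = pd.DataFrame(
        {
            "family": [f"repfam{f:02d}" for f in range(rc.n_families)],
            "associated": [f < rc.n_associated for f in range(rc.n_families)],
        }
    )

    categories = rng.choice(
        _DEG_CATEGORIES, size=n_deg_genes, p=_DEG_PROPORTIONS
    )
    deg_rows = []
    for i, cat in enumerate(categories):
        gene = f"deg{i:05d}"
        sign = 1.0 if rng.random() < 0.5 else -1.0
        mu_d, mu_p = {
            "shared": (sign * effect, sign * effect),
            "opposite": (sign * effect, -sign * effect),
            "distal_only": (sign * effect, 0.0),
            "proximal_only": (0.0, sign * effect),
            "null": (0.0, 0.0),
        }[cat]
        for contrast, mu in (("distal", mu_d), ("proximal", mu_p)):
            lfc = float(rng.normal(mu, se))
            p = float(2 * sps.norm.sf(abs(lfc) / se))
            deg_rows.append((gene, contrast, lfc, p))
    deg = pd.DataFrame(deg_rows, columns=["gene_id", "contrast", "log2fc", "pvalue"])
    from statsmodels.stats.multitest import multipletests

    deg["padj"] = deg.groupby("contrast")["pvalue"].transform(
        lambda p: multipletests(p, method="fdr_bh")[1]
    )
    return RepeatDegData(
        repeats=repeats,
        breakpoints=bps,
        region=(0.0, L),
        deg_table=deg,
        family_truth=family_truth,
        deg_truth=pd.DataFrame(
            {"gene_id": [f"deg{i:05d}" for i in range(n_deg_genes)],
             "category": categories}
        ),
    )
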