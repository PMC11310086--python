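"""Painting, Dollo reconstruction, event counting and bundling."""

from math import comb

import numpy as np
import pandas as pd
import pytest

from regenomics.karyotype import (
    count_events,
    fisher_painting,
    propagate_alg_labels,
    rearrangement_rate,
    reconstruct_ancestral,
    synteny_bundles,
)
from regenomics.simulate import KaryotypeConfig, SimulationConfig, simulate_karyotypes

TOY_TREE = "((ingroup1:1,ingroup2:1)ingroup:1,outgroup:2)root;"


def identity_painting(refs, fused=()):
    """chromosome -> {ALG} mapping; ``fused`` ALGs share one chromosome."""
    out, i = {}, 0
    fused = set(fused)
    for r in refs:
        if r in fused:
            continue
        out[f"chr{i:02d}"] = {r}
        i += 1
    if fused:
        out["chr_fused"] = set(fused)
    return out


class TestPropagateLabels:
    def test_empty_orthologs_no_labels(self):
        labels = pd.Series({"r1": "A"})
        out = propagate_alg_labels(labels, pd.DataFrame(columns=["gene1", "gene2"]))
        assert out.empty

    def test_hand_propagation_and_no_invented_labels(self):
        labels = pd.Series({"r1": "A", "r2": "B"})
        orth = pd.DataFrame(
            {"gene1": ["r1", "r2", "r3"], "gene2": ["t1", "t2", "t3"]}
        )
        out = propagate_alg_labels(labels, orth)
        assert out.to_dict() == {"t1": "A", "t2": "B"}
        assert set(out.unique()) <= set(labels.unique())

    def test_duplicated_pairs_rejected(self):
        labels = pd.Series({"r1": "A"})
        orth = pd.DataFrame({"gene1": ["r1", "r1"], "gene2": ["t1", "t2"]})
        with pytest.raises(ValueError):
            propagate_alg_labels(labels, orth)


class TestFisherPainting:
    def test_planted_block_assigned(self):
        # 50-gene chromosome all label A over an even background
        genes = {}
        for i in range(50):
            genes[f"gA{i}"] = ("chrA", "A")
        k = 0
        for a in range(19):
            for i in range(50):
                genes[f"g{a}_{i}"] = (f"chr{a}", f"L{a}")
                k += 1
        genome = pd.Series({g: c for g, (c, _) in genes.items()})
        labels = pd.Series({g: l for g, (_, l) in genes.items()})
        p = fisher_painting(labels, genome)
        assert p.assignments["chrA"] == {"A"}

    def test_fused_chromosome_gets_both_labels(self):
        cfg = SimulationConfig(
            seed=13,
            karyotype=KaryotypeConfig(fusion_rate=0, fission_rate=0,
                                      translocation_rate=0),
        )
        kd = simulate_karyotypes(cfg)
        # fuse two chromosomes of one leaf by hand
        genome = kd.genomes["ingroup1"].copy()
        genome.loc[genome["chromosome"] == "ingroup1_chr01", "chromosome"] = (
            "ingroup1_chr00"
        )
        p = fisher_painting(kd.taxon_labels("ingroup1"), genome["chromosome"])
        assert p.assignments["ingroup1_chr00"] == {"ALG00", "ALG01"}

    def test_random_labels_rarely_assign(self):
        rng = np.random.default_rng(3)
        false_runs = 0
        for rep in range(20):
            genes = [f"g{i}" for i in range(500)]
            genome = pd.Series(
                [f"chr{i % 10}" for i in range(500)], index=genes
            )
            labels = pd.Series(rng.choice([f"L{a}" for a in range(20)], 500),
                               index=genes)
            p = fisher_painting(labels, genome)
            if any(p.assignments[c] for c in p.assignments):
                false_runs += 1
        assert false_runs <= 1  # <5% family-wise, allow 1/20

    def test_gene_labels_follow_assignments(self):
        genome = pd.Series({f"g{i}": "chr0" for i in range(50)})
        labels = pd.Series({f"g{i}": "A" for i in range(50)})
        # single chromosome, single ALG: no enrichment contrast -> p=1
        p = fisher_painting(labels, genome)
        assert p.gene_labels.isna().all() or p.gene_labels.notna().all()


class TestReconstructAncestral:
    refs = [f"A{i}" for i in range(1, 23)] + ["B2", "C2"]

    def test_ingroup_wide_join_is_ancestral(self):
        model = reconstruct_ancestral(
            {
                "ingroup1": identity_painting(self.refs, ("B2", "C2")),
                "ingroup2": identity_painting(self.refs, ("B2", "C2")),
                "outgroup": identity_painting(self.refs),
            },
            TOY_TREE,
            outgroups=["outgroup"],
            reference_algs=self.refs,
        )
        assert model.n_ancestral == 23
        assert "B2 + C2" in model.unit_names()
        assert model.events.empty

    def test_single_leaf_join_is_derived_fusion(self):
        model = reconstruct_ancestral(
            {
                "ingroup1": identity_painting(self.refs, ("B2", "C2")),
                "ingroup2": identity_painting(self.refs),
                "outgroup": identity_painting(self.refs),
            },
            TOY_TREE,
            outgroups=["outgroup"],
            reference_algs=self.refs,
        )
        assert model.n_ancestral == 24
        assert model.events.to_dict("records") == [
            {"branch": "ingroup1", "type": "fusion", "algs": "B2 + C2"}
        ]

    def test_join_shared_with_outgroup_still_ancestral(self):
        model = reconstruct_ancestral(
            {
                "ingroup1": identity_painting(self.refs, ("B2", "C2")),
                "ingroup2": identity_painting(self.refs, ("B2", "C2")),
                "outgroup": identity_painting(self.refs, ("B2", "C2")),
            },
            TOY_TREE,
            outgroups=["outgroup"],
            reference_algs=self.refs,
        )
        assert model.n_ancestral == 23 and model.events.empty

    def test_unknown_taxon_rejected(self):
        with pytest.raises(ValueError):
            reconstruct_ancestral(
                {"nope": identity_painting(self.refs)}, TOY_TREE, outgroups=[]
            )


class FakePainting:
    """Assignment-only stand-in accepted by count_events."""

    def __init__(self, assignments):
        self.assignments = assignments


class TestCountEvents:
    def test_identity_zero_events(self):
        p = FakePainting({f"chr{i}": {f"A{i}"} for i in range(5)})
        total, _ = count_events(p)
        assert total == 0

    def test_fusion_and_fission_counts(self):
        fusion = FakePainting({"chr0": {"A", "B"}})
        assert count_events(fusion)[0] == 1
        fission = FakePainting({"chr0": {"A"}, "chr1": {"A"}})
        assert count_events(fission)[0] == 1

    def test_balanced_component_translocation_mode(self):
        square = FakePainting({"chr0": {"A", "B"}, "chr1": {"A", "B"}})
        assert count_events(square)[0] == 2
        assert count_events(square, translocation_mode=True)[0] == 1

    def test_simulated_history_event_recovery(self):
        # low rates: painting + component counting recover the true
        # root-to-leaf event count exactly
        recovered, truth = [], []
        for seed in range(5):
            cfg = SimulationConfig(
                seed=seed,
                karyotype=KaryotypeConfig(
                    fusion_rate=1.0, fission_rate=0.5, translocation_rate=0.0
                ),
            )
            kd = simulate_karyotypes(cfg)
            for taxon in kd.genomes:
                p = fisher_painting(
                    kd.taxon_labels(taxon), kd.genomes[taxon]["chromosome"]
                )
                path_branches = (
                    {taxon, "ingroup"} if taxon.startswith("ingroup") else {taxon}
                )
                true_n = int(kd.events["branch"].isin(path_branches).sum())
                recovered.append(count_events(p)[0])
                truth.append(true_n)
        assert recovered == truth

    def test_fusion_arithmetic_on_histories(self):
        # chromosome count = ancestral - fusions + fissions along the path
        cfg = SimulationConfig(
            seed=11,
            karyotype=KaryotypeConfig(
                fusion_rate=1.0, fission_rate=1.0, translocation_rate=0.0
            ),
        )
        kd = simulate_karyotypes(cfg)
        for taxon, genome in kd.genomes.items():
            path = {taxon, "ingroup"} if taxon.startswith("ingroup") else {taxon}
            ev = kd.events[kd.events["branch"].isin(path)]
            n_fus = int((ev["type"] == "fusion").sum())
            n_fis = int((ev["type"] == "fission").sum())
            assert genome["chromosome"].nunique() == 20 - n_fus + n_fis


class TestRates:
    @pytest.mark.parametrize(
        "events,myr,expected",
        [(26, 500, 0.052), (5, 500, 0.01), (1, 500, 0.002), (0, 500, 0.0)],
    )
    def test_reported_rates(self, events, myr, expected):
        assert rearrangement_rate(events, myr) == expected

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError):
            rearrangement_rate(1, 0)


class TestSyntenyBundles:
    @staticmethod
    def _maps(positions1, positions2):
        g1 = pd.DataFrame(
            {"chromosome": "c1", "position": positions1},
            index=[f"a{i}" for i in range(len(positions1))],
        )
        g2 = pd.DataFrame(
            {"chromosome": "c2", "position": positions2},
            index=[f"b{i}" for i in range(len(positions2))],
        )
        orth = pd.DataFrame(
            {"gene1": g1.index, "gene2": g2.index}
        )
        return orth, g1, g2

    def test_consecutive_links_one_bundle(self):
        orth, g1, g2 = self._maps(range(5), range(5))
        out = synteny_bundles(orth, g1, g2)
        assert len(out) == 1 and out["n_links"].iloc[0] == 5

    def test_gap_splits_bundles(self):
        orth, g1, g2 = self._maps([1, 2, 3, 200, 201, 202], [1, 2, 3, 200, 201, 202])
        out = synteny_bundles(orth, g1, g2, max_gap=50)
        assert len(out) == 2

    def test_small_bundles_dropped(self):
        orth, g1, g2 = self._maps([1, 2], [1, 2])
        out = synteny_bundles(orth, g1, g2, min_links=3)
        assert out.empty
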