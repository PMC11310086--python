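"""Cluster-overlap counting, the constrained permutation null, and the
three-way consistency / breakdown / heterochrony reports."""

import itertools

import numpy as np
import pandas as pd
import pytest

from regenomics.conservation import (
    count_cluster_overlaps,
    heterochrony_report,
    homology_breakdown,
    permutation_test,
    threeway_consistency,
)


def _families(pairs) -> pd.DataFrame:
    """pairs: iterable of (family, sp1 genes, sp2 genes)."""
    rows = []
    for fid, g1, g2 in pairs:
        rows += [(fid, "sp1", g) for g in g1]
        rows += [(fid, "sp2", g) for g in g2]
    return pd.DataFrame(rows, columns=["family_id", "species", "gene_id"])


class TestCounting:
    def test_hand_counted_overlaps(self):
        fams = _families([("f1", ["a1"], ["b1"]), ("f2", ["a2"], ["b2"])])
        hard1 = pd.Series({"a1": "A", "a2": "A"})
        hard2 = pd.Series({"b1": "B", "b2": "C"})
        counts, _ = count_cluster_overlaps(hard1, hard2, fams, "sp1", "sp2")
        assert counts.loc["A", "B"] == 1 and counts.loc["A", "C"] == 1

    def test_gene_counted_once_despite_two_homologues(self):
        fams = _families([("f1", ["a1"], ["b1", "b2"])])
        hard1 = pd.Series({"a1": "A"})
        hard2 = pd.Series({"b1": "B", "b2": "B"})
        counts, _ = count_cluster_overlaps(hard1, hard2, fams, "sp1", "sp2")
        assert counts.loc["A", "B"] == 1

    def test_no_shared_families_all_zero(self):
        fams = _families([("f1", ["a1"], []), ("f2", [], ["b1"])])
        hard1 = pd.Series({"a1": "A"})
        hard2 = pd.Series({"b1": "B"})
        counts, cov = count_cluster_overlaps(hard1, hard2, fams, "sp1", "sp2")
        assert (counts.to_numpy() == 0).all()

    def test_unfamilied_genes_reported_in_coverage(self):
        fams = _families([("f1", ["a1"], ["b1"])])
        hard1 = pd.Series({"a1": "A", "orphan": "A"})
        hard2 = pd.Series({"b1": "B"})
        _, cov = count_cluster_overlaps(hard1, hard2, fams, "sp1", "sp2")
        assert cov["sp1_clustered_without_family"] == 1

    def test_independence_expectation_at_rho_zero(self):
        # with random assignment, E[n_ij] ~= |cluster_i| * P(partner in j);
        # for 1:1 families P = |cluster_j| / n2, checked over 200 draws
        rng = np.random.default_rng(0)
        n = 60
        fams = _families([(f"f{i}", [f"a{i}"], [f"b{i}"]) for i in range(n)])
        sizes1 = {0: 30, 1: 30}
        total = np.zeros((2, 2))
        reps = 200
        for _ in range(reps):
            hard1 = pd.Series(
                rng.permutation([0] * 30 + [1] * 30), index=[f"a{i}" for i in range(n)]
            )
            hard2 = pd.Series(
                rng.permutation([0] * 20 + [1] * 40), index=[f"b{i}" for i in range(n)]
            )
            counts, _ = count_cluster_overlaps(hard1, hard2, fams, "sp1", "sp2")
            total += counts.to_numpy()
        mean = total / reps
        expected = np.array([[30 * 20 / 60, 30 * 40 / 60]] * 2)
        assert np.allclose(mean, expected, atol=1.0)


class TestPermutationTest:
    def test_minimum_attainable_p(self):
        fams = _families([("f1", ["a1"], ["b1"])])
        hard1 = pd.Series({"a1": "A"})
        hard2 = pd.Series({"b1": "B"})
        res = permutation_test(hard1, hard2, fams, "sp1", "sp2", n_perm=100, seed=0)
        assert res.pvalues.to_numpy().min() >= 1 / 101
        assert res.pvalues.to_numpy().max() <= 1.0

    def test_sampled_null_matches_exhaustive_enumeration(self):
        # 3 species-2 genes -> 6 label permutations; compare the sampled
        # null distribution of one cell's count with full enumeration
        fams = _families(
            [("f1", ["a1"], ["b1"]), ("f2", ["a2"], ["b2"]), ("f3", ["a3"], ["b3"])]
        )
        hard1 = pd.Series({"a1": "A", "a2": "A", "a3": "B"})
        labels2 = ["X", "X", "Y"]
        genes2 = ["b1", "b2", "b3"]
        partners = {"a1": "b1", "a2": "b2", "a3": "b3"}

        def cell_count(assign: dict) -> int:
            return sum(
                1 for a, b in partners.items()
                if hard1[a] == "A" and assign[b] == "X"
            )

        exhaustive = [
            cell_count(dict(zip(genes2, perm)))
            for perm in itertools.permutations(labels2)
        ]
        exhaustive_dist = pd.Series(exhaustive).value_counts(normalize=True)

        rng = np.random.default_rng(42)
        sampled = []
        for _ in range(10_000):
            perm = rng.permutation(labels2)
            sampled.append(cell_count(dict(zip(genes2, perm))))
        sampled_dist = pd.Series(sampled).value_counts(normalize=True)
        support = sorted(set(exhaustive_dist.index) | set(sampled_dist.index))
        tv = 0.5 * sum(
            abs(exhaustive_dist.get(v, 0) - sampled_dist.get(v, 0)) for v in support
        )
        assert tv < 0.02

    def test_planted_diagonal_recovered(self):
        from regenomics.simulate import SimulationConfig, simulate_timecourse

        cfg = SimulationConfig(
            seed=5, n_clusters=5, n_families=170, conservation_rate=1.0, noise_sd=0.1
        )
        tc = simulate_timecourse(cfg)
        res = permutation_test(
            tc.hard_truth("sp1"), tc.hard_truth("sp2"), tc.families,
            "sp1", "sp2", n_perm=1000, seed=9,
        )
        sig = set(res.significant_pairs())
        assert {(c, c) for c in range(5)} <= sig
        assert sig == {(c, c) for c in range(5)}

    def test_seeded_determinism(self):
        fams = _families([(f"f{i}", [f"a{i}"], [f"b{i}"]) for i in range(20)])
        rng = np.random.default_rng(1)
        hard1 = pd.Series(rng.integers(0, 3, 20), index=[f"a{i}" for i in range(20)])
        hard2 = pd.Series(rng.integers(0, 3, 20), index=[f"b{i}" for i in range(20)])
        r1 = permutation_test(hard1, hard2, fams, "sp1", "sp2", n_perm=200, seed=7)
        r2 = permutation_test(hard1, hard2, fams, "sp1", "sp2", n_perm=200, seed=7)
        pd.testing.assert_frame_equal(r1.pvalues, r2.pvalues)

    def test_invalid_n_perm_rejected(self):
        fams = _families([("f1", ["a1"], ["b1"])])
        with pytest.raises(ValueError):
            permutation_test(
                pd.Series({"a1": 0}), pd.Series({"b1": 0}), fams, "sp1", "sp2",
                n_perm=0,
            )

    def test_conserved_lists_subset_of_cluster(self):
        from regenomics.simulate import SimulationConfig, simulate_timecourse

        cfg = SimulationConfig(
            seed=3, n_clusters=5, n_families=100, conservation_rate=1.0, noise_sd=0.1
        )
        tc = simulate_timecourse(cfg)
        h1 = tc.hard_truth("sp1")
        res = permutation_test(
            h1, tc.hard_truth("sp2"), tc.families, "sp1", "sp2",
            n_perm=500, seed=2,
        )
        for (i, _j), genes in res.conserved.items():
            assert set(genes) <= set(h1.index[h1 == i])


def _result_stub(species, sig_pairs, conserved):
    """Minimal ClusterOverlapResult for the report operations."""
    from regenomics.conservation import ClusterOverlapResult

    clusters1 = sorted({i for i, _ in sig_pairs} | {0})
    clusters2 = sorted({j for _, j in sig_pairs} | {0})
    sig = pd.DataFrame(False, index=clusters1, columns=clusters2)
    for i, j in sig_pairs:
        sig.loc[i, j] = True
    counts = pd.DataFrame(0, index=clusters1, columns=clusters2)
    return ClusterOverlapResult(
        species=species, counts=counts, significant=sig, conserved=conserved
    )


class TestThreewayAndBreakdown:
    def test_hand_intersection(self):
        ab = _result_stub(
            ("A", "B"), [(1, 2)], {(1, 2): ["g1", "g2", "g3"]}
        )
        ac = _result_stub(("A", "C"), [(1, 5)], {(1, 5): ["g1", "g2"]})
        clusters, genes = threeway_consistency(ab, ac)
        assert clusters == {1}
        assert genes == ["g1", "g2"]

    def test_empty_when_one_comparison_has_no_pairs(self):
        ab = _result_stub(("A", "B"), [(1, 2)], {(1, 2): ["g1"]})
        ac = _result_stub(("A", "C"), [], {})
        clusters, genes = threeway_consistency(ab, ac)
        assert clusters == set() and genes == []

    def test_mismatched_focal_rejected(self):
        ab = _result_stub(("A", "B"), [], {})
        cb = _result_stub(("C", "B"), [], {})
        with pytest.raises(ValueError):
            threeway_consistency(ab, cb)

    def test_breakdown_fractions_hand_case(self):
        # 10 conserved AB genes: 4 without any C homologue, 3 with a C
        # homologue but divergent, 3 also conserved with C
        genes = [f"g{i}" for i in range(10)]
        ab = _result_stub(("A", "B"), [(0, 0)], {(0, 0): genes})
        ac = _result_stub(("A", "C"), [(0, 1)], {(0, 1): genes[7:]})
        fam_rows = []
        for g in genes[4:]:  # 6 genes with a family containing C members
            fam_rows.append((f"fam_{g}", "A", g))
            fam_rows.append((f"fam_{g}", "C", f"c_{g}"))
        for g in genes[:4]:
            fam_rows.append((f"fam_{g}", "A", g))
        fams = pd.DataFrame(fam_rows, columns=["family_id", "species", "gene_id"])
        out = homology_breakdown(ab, fams, ac, third_species="C")
        assert np.allclose(out["fraction"].to_numpy(), [0.4, 0.3, 0.3])
        assert out["fraction"].sum() == pytest.approx(1.0)

    def test_breakdown_all_no_homologue_when_no_c_families(self):
        ab = _result_stub(("A", "B"), [(0, 0)], {(0, 0): ["g1", "g2"]})
        ac = _result_stub(("A", "C"), [], {})
        fams = pd.DataFrame(columns=["family_id", "species", "gene_id"])
        out = homology_breakdown(ab, fams, ac, third_species="C")
        assert out.loc["no_homologue", "fraction"] == 1.0


class TestHeterochrony:
    def test_collinear_matching_gives_tau_one(self):
        res = _result_stub(
            ("A", "B"), [(i, i) for i in range(5)], {}
        )
        order = {i: i for i in range(5)}
        tau, table = heterochrony_report(res, order, order)
        assert tau == pytest.approx(1.0)

    def test_single_inverted_pair_is_top_outlier(self):
        pairs = [(0, 0), (1, 1), (2, 2), (3, 3), (4, 0)]
        res = _result_stub(("A", "B"), pairs, {})
        order1 = {i: i for i in range(5)}
        order2 = {i: i for i in range(5)}
        tau, table = heterochrony_report(res, order1, order2)
        top = table.iloc[0]
        assert (top["cluster1"], top["cluster2"]) == (4, 0)
        assert top["tau_gain_if_removed"] > 0

    def test_fewer_than_two_pairs_undefined(self):
        res = _result_stub(("A", "B"), [(0, 0)], {})
        tau, table = heterochrony_report(res, {0: 0}, {0: 0})
        assert tau is None and len(table) == 1
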