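import numpy as np
import pandas as pd
import pytest

import tnlineage as tl
from tnlineage.count_io import GeneAnnotation
from tnlineage.profiles import (EnvPools, assign_knockout_like, build_environments,
                                curate_beneficial_knockouts, find_novel_clusters,
                                gene_split_profiles, genomic_distance,
                                lineage_profiles, profile_distance,
                                replicate_split_bands, set_profile, KnockoutProfile)


def pools_from(f0: dict, f1: dict) -> EnvPools:
    df0, df1 = pd.DataFrame(f0), pd.DataFrame(f1)
    return EnvPools([], df0, df1)


class TestBuildEnvironments:
    def test_canonical_panel_has_ten_environments(self):
        envs = build_environments(["LF/HPP", "HF/HS", "LHL", "HLH"])
        assert len(envs) == 10
        first = [e for e in envs if (e.t0, e.t1) == (0.0, 4.0)]
        assert len(first) == 2  # LF/LHL merged, HF/HLH merged on days 0-4

    def test_invitro_media_appended(self):
        envs = build_environments(["LF/HPP", "HF/HS", "LHL", "HLH"],
                                  invitro_media=["arabinose", "glucose"])
        assert len(envs) == 12
        assert envs[-1].t1 - envs[-1].t0 == 1.0

    def test_synthetic_constant_conditions(self):
        envs = build_environments(["e1", "e2"], timepoints=(0.0, 4.0, 10.0))
        assert len(envs) == 4


class TestProfiles:
    def test_constant_frequencies_zero_profile(self):
        p = pools_from({"e1": {"a": 0.1}, "e2": {"a": 0.1}},
                       {"e1": {"a": 0.1}, "e2": {"a": 0.1}})
        assert np.allclose(lineage_profiles(p).loc["a"], 0.0)

    def test_tenfold_single_environment(self):
        p = pools_from({"e1": {"a": 1e-4}, "e2": {"a": 1e-4}},
                       {"e1": {"a": 1e-3}, "e2": {"a": 1e-4}})
        W = lineage_profiles(p).loc["a"]
        assert W["e1"] == pytest.approx(np.log(10))
        assert W["e2"] == pytest.approx(0.0)

    def test_zero_endpoint_masked(self):
        p = pools_from({"e1": {"a": 0.0}}, {"e1": {"a": 1e-3}})
        assert np.isnan(lineage_profiles(p).loc["a", "e1"])

    def test_union_profile_between_members_at_equal_start(self):
        f0 = {"e1": {"a": 1e-3, "b": 1e-3}}
        f1 = {"e1": {"a": 4e-3, "b": 1e-3}}
        p = pools_from(f0, f1)
        W = lineage_profiles(p)
        union = set_profile(["a", "b"], p)
        assert min(W["e1"]) - 1e-12 <= union[0] <= max(W["e1"]) + 1e-12


class TestDistance:
    def test_identical_zero(self):
        assert profile_distance([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_single_component_unit(self):
        assert profile_distance([0.0, 1.0], [0.0, 0.0]) == 1.0

    def test_masked_components_skipped(self):
        assert profile_distance([1.0, np.nan], [0.0, 5.0]) == 1.0

    def test_no_shared_components_undefined(self):
        assert np.isnan(profile_distance([np.nan], [1.0]))

    def test_triangle_inequality_random_triples(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            a, b, c = rng.normal(0, 2, (3, 6))
            assert (profile_distance(a, c)
                    <= profile_distance(a, b) + profile_distance(b, c) + 1e-12)


class TestGenomicDistance:
    def test_inside_zero_and_endpoints(self):
        g = GeneAnnotation("g", "chr1", 1000, 2000, "+")
        assert genomic_distance(1500, "chr1", g) == 0.0
        assert genomic_distance(900, "chr1", g) == 100.0
        assert genomic_distance(2300, "chr1", g) == 300.0

    def test_other_contig_infinite(self):
        g = GeneAnnotation("g", "chr1", 1000, 2000, "+")
        assert genomic_distance(1500, "chr2", g) == np.inf


def gene_pools(member_f0, member_f1, n_env=3):
    """Pools where each member has the given per-env start/end frequencies."""
    ids = list(member_f0)
    f0 = {f"e{k}": {m: member_f0[m][k] for m in ids} for k in range(n_env)}
    f1 = {f"e{k}": {m: member_f1[m][k] for m in ids} for k in range(n_env)}
    return pools_from(f0, f1)


class TestKnockoutCuration:
    def test_consistent_gene_retained(self):
        # 3 lineages, each 12x in environment 0: all leave-one-outs ~ ln 12
        f0 = {m: [1e-4, 1e-4, 1e-4] for m in "abc"}
        f1 = {m: [1.2e-3, 1e-4, 1e-4] for m in "abc"}
        pools = gene_pools(f0, f1)
        gm = pd.Series({"a": "g", "b": "g", "c": "g"})
        assert "g" in curate_beneficial_knockouts(gm, pools)

    def test_single_lineage_driven_gene_excluded(self):
        # one lineage x100, others flat: its leave-one-out profile collapses
        f0 = {m: [1e-4, 1e-4, 1e-4] for m in "abc"}
        f1 = {"a": [1e-2, 1e-4, 1e-4], "b": [1e-4, 1e-4, 1e-4],
              "c": [1e-4, 1e-4, 1e-4]}
        pools = gene_pools(f0, f1)
        gm = pd.Series({"a": "g", "b": "g", "c": "g"})
        assert curate_beneficial_knockouts(gm, pools) == {}

    def test_weak_gene_excluded_at_stage_one(self):
        f0 = {m: [1e-4] * 3 for m in "abc"}
        f1 = {m: [4e-4] * 3 for m in "abc"}  # max fold 4 < 5 everywhere
        pools = gene_pools(f0, f1)
        gm = pd.Series({"a": "g", "b": "g", "c": "g"})
        assert curate_beneficial_knockouts(gm, pools) == {}

    def test_singleton_gene_cannot_pass(self):
        pools = gene_pools({"a": [1e-4] * 3}, {"a": [1e-2] * 3})
        assert curate_beneficial_knockouts(pd.Series({"a": "g"}), pools) == {}


class TestKnockoutLikeAssignment:
    def setup_method(self):
        self.gene = GeneAnnotation("target", "chr1", 10_000, 12_000, "+")
        self.ko = KnockoutProfile("target", ["t1", "t2"],
                                  np.array([2.5, 0.0, 0.0]), pd.DataFrame())
        self.coords = pd.DataFrame({
            "contig": ["chr1", "chr1", "chr2"],
            "position": [250_000, 60_000, 5_000],
        }, index=["far", "near", "other_contig"])

    def profiles(self, rows):
        return pd.DataFrame(rows, columns=["e0", "e1", "e2"])

    def test_matching_far_lineage_assigned(self):
        W = self.profiles({"far": [2.5, 0.0, 0.0]}.values()).set_axis(["far"])
        cluster = assign_knockout_like(W, self.ko, self.coords, self.gene)
        assert cluster.members == ["far"]

    def test_nearby_lineage_excluded(self):
        W = pd.DataFrame([[2.5, 0.0, 0.0]], index=["near"], columns=["e0", "e1", "e2"])
        cluster = assign_knockout_like(W, self.ko, self.coords, self.gene)
        assert cluster.members == []

    def test_other_contig_counts_as_far(self):
        W = pd.DataFrame([[2.5, 0.0, 0.0]], index=["other_contig"],
                         columns=["e0", "e1", "e2"])
        cluster = assign_knockout_like(W, self.ko, self.coords, self.gene)
        assert cluster.members == ["other_contig"]

    def test_multiply_represented_off_target_gene_removed(self):
        W = pd.DataFrame([[2.5, 0, 0], [2.5, 0, 0], [2.4, 0.1, 0]],
                         index=["x1", "x2", "y"], columns=["e0", "e1", "e2"])
        coords = pd.DataFrame({"contig": "chr1",
                               "position": [300_000, 301_000, 400_000]},
                              index=["x1", "x2", "y"])
        gm = pd.Series({"x1": "off", "x2": "off", "y": "other"})
        cluster = assign_knockout_like(W, self.ko, coords, self.gene, gene_map=gm)
        assert cluster.members == ["y"]

    def test_unmeasured_lineage_not_candidate(self):
        W = pd.DataFrame([[2.5, np.nan, 0.0]], index=["far"],
                         columns=["e0", "e1", "e2"])
        cluster = assign_knockout_like(W, self.ko, self.coords, self.gene)
        assert cluster.members == []


class TestNovelClusters:
    @staticmethod
    def planted(n_per=100, noise=0.5, seed=0, n_env=10):
        rng = np.random.default_rng(seed)
        arch = np.zeros((3, n_env))
        arch[0, :3] = 3.0
        arch[1, 3:6] = 3.0
        arch[2, 6:9] = 3.0
        rows, labels = [], []
        for a in range(3):
            for _ in range(n_per):
                rows.append(arch[a] + rng.normal(0, noise, n_env))
                labels.append(a)
        W = pd.DataFrame(rows, index=[f"l{i}" for i in range(3 * n_per)],
                         columns=[f"e{k}" for k in range(n_env)])
        return W, np.array(labels), arch

    def test_planted_archetypes_recovered(self):
        from sklearn.metrics import adjusted_rand_score
        W, labels, _ = self.planted()
        gm = pd.Series(np.nan, index=W.index)
        clusters = find_novel_clusters(W, gm, gene_profiles=None)
        pred = {m: i for i, c in enumerate(clusters) for m in c.members}
        common = [l for l in W.index if l in pred]
        assert len(common) / len(W) > 0.95
        ari = adjusted_rand_score(labels[[int(l[1:]) for l in common]],
                                  [pred[l] for l in common])
        assert ari > 0.9

    def test_singleton_clusters_dropped(self):
        W = pd.DataFrame([[3.0] * 5, [-3.0] * 5], index=["a", "b"],
                         columns=[f"e{k}" for k in range(5)])
        gm = pd.Series(np.nan, index=W.index)
        assert find_novel_clusters(W, gm) == []

    def test_matched_vs_orthogonal_gene_profiles(self):
        W, labels, arch = self.planted(seed=1)
        gm = pd.Series(np.nan, index=W.index)
        gene_profiles = {"geneA": arch[0]}
        clusters = find_novel_clusters(W, gm, gene_profiles=gene_profiles)
        kinds = {}
        for c in clusters:
            lab = labels[int(c.members[0][1:])]
            kinds[lab] = (c.kind, c.distance)
        assert kinds[0][0] == "candidate" and kinds[0][1] < 2.0
        assert kinds[1][0] == "novel" and kinds[1][1] > 4.0
        assert kinds[2][0] == "novel"

    def test_multiply_hit_gene_filter(self):
        rng = np.random.default_rng(2)
        W = pd.DataFrame(3.0 + rng.normal(0, 0.2, (5, 4)),
                         index=[f"l{i}" for i in range(5)],
                         columns=[f"e{k}" for k in range(4)])
        gm = pd.Series({"l0": "g1", "l1": "g1", "l2": "g2", "l3": "g3", "l4": "g4"})
        # cluster of 5 with g1 represented twice (> max{1, floor(log10 5)} = 1)
        assert find_novel_clusters(W, gm) == []

    def test_random_placement_rarely_hits_gene_twice(self):
        """With <=10 members placed uniformly on a genome with a realistic
        gene-length distribution, doubly-hit genes are rare (<1.5%)."""
        rng = np.random.default_rng(3)
        n_genes = 4500
        lengths = rng.gamma(3.0, 350, n_genes).astype(int) + 100  # ~1.1 kb genes
        starts = np.cumsum(lengths + 200)
        genome = starts[-1]
        hits = 0
        trials = 2000
        for _ in range(trials):
            pos = rng.integers(0, genome, size=10)
            gidx = np.searchsorted(starts, pos)
            inside = pos >= (starts[gidx] - lengths[gidx])
            genes = gidx[inside]
            if len(genes) != len(np.unique(genes)):
                hits += 1
        assert hits / trials < 0.015

    def test_order_invariance(self):
        W, labels, _ = self.planted(seed=4)
        gm = pd.Series(np.nan, index=W.index)
        a = find_novel_clusters(W, gm)
        perm = W.sample(frac=1.0, random_state=0)
        b = find_novel_clusters(perm, gm.reindex(perm.index))
        sets_a = sorted(frozenset(c.members) for c in a)
        sets_b = sorted(frozenset(c.members) for c in b)
        assert sets_a == sets_b


class TestGeneSplitProfiles:
    def test_split_average_converges_to_full_profile(self):
        rng = np.random.default_rng(5)
        ids = [f"m{i}" for i in range(40)]
        f0 = {f"e{k}": {m: 1e-4 for m in ids} for k in range(3)}
        f1 = {f"e{k}": {m: 1e-3 * np.exp(rng.normal(0, 0.1)) for m in ids}
              for k in range(3)}
        pools = pools_from(f0, f1)
        gm = pd.Series("g", index=ids)
        ko = gene_split_profiles(gm, pools, seed=0, screen_outliers=False)["g"]
        w1, w2 = ko.split_profiles
        full = set_profile(ids, pools)
        assert np.allclose(0.5 * (w1 + w2), full, atol=0.05)

    def test_outlier_member_screened(self):
        ids = [f"m{i}" for i in range(6)]
        f0 = {f"e{k}": {m: 1e-4 for m in ids} for k in range(3)}
        f1 = {f"e{k}": {m: (2e-2 if (m == "m0" and k == 0) else 1e-4) for m in ids}
              for k in range(3)}
        pools = pools_from(f0, f1)
        gm = pd.Series("g", index=ids)
        out = gene_split_profiles(gm, pools, seed=0, screen_outliers=True)
        assert "m0" not in out["g"].members


class TestReplicateSplitBands:
    def make_table_for_bands(self, n=30, hosts=4, seed=0):
        cfg = tl.SimulationConfig(n_lineages=n, conditions={"HF/HS": hosts},
                                  timepoints=(0.0, 4.0), Ne=np.inf, depth=100_000,
                                  seed=seed, fitness=tl.FitnessModel(0.3, 0.3))
        table, _ = tl.simulate_experiment(cfg)
        envs = build_environments(["HF/HS"], timepoints=(0.0, 4.0))
        return table, envs

    def test_band_rule_by_cluster_size(self):
        table, envs = self.make_table_for_bands()
        members9 = list(table.counts.index[:9])
        members11 = list(table.counts.index[:11])
        avg9, lo9, hi9 = replicate_split_bands(members9, table, envs, seed=1)
        avg11, lo11, hi11 = replicate_split_bands(members11, table, envs, seed=1)
        col = avg9.columns[0]
        assert lo9[col] == pytest.approx(avg9[col].min())
        assert hi9[col] == pytest.approx(avg9[col].max())
        assert lo11[col] == pytest.approx(avg11[col].quantile(0.25))

    def test_identical_halves_zero_band_width(self):
        # 2 hosts with identical counts: both halves agree, single lineage
        # band width is zero
        rng = np.random.default_rng(1)
        from conftest import make_table
        counts = rng.integers(50, 500, size=10).tolist()
        t = make_table({"r1": counts, "a": counts, "b": counts},
                       hosts={"r1": "input", "a": "m1", "b": "m2"},
                       days={"r1": 0.0, "a": 4.0, "b": 4.0},
                       kinds={"r1": "input_technical_replicate",
                              "a": "fecal", "b": "fecal"},
                       conditions={"r1": "input", "a": "HF/HS", "b": "HF/HS"})
        envs = build_environments(["HF/HS"], timepoints=(0.0, 4.0))
        member = [t.counts.index[0]]
        avg, lo, hi = replicate_split_bands(member, t, envs, seed=0)
        assert np.allclose(hi - lo, 0.0, atol=1e-12)

    def test_band_width_shrinks_with_depth(self):
        widths = []
        for depth in (10 ** 4, 10 ** 6):
            cfg = tl.SimulationConfig(n_lineages=50, conditions={"e": 4},
                                      timepoints=(0.0, 4.0), Ne=np.inf, depth=depth,
                                      seed=5, fitness=tl.FitnessModel(0.0, 0.3))
            table, _ = tl.simulate_experiment(cfg)
            envs = build_environments(["e"], timepoints=(0.0, 4.0))
            members = list(table.counts.index[:20])
            avg, lo, hi = replicate_split_bands(members, table, envs, seed=2)
            widths.append(float((hi - lo).iloc[0]))
        assert widths[1] < widths[0]
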