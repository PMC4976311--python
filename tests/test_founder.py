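"""Founder identification, scanning, partition and the printed-table sums."""
import math

import numpy as np
import pytest

from mitofounder.founder_analysis import (FounderCluster, adjust_counts,
                                          flag_major, founder_scan,
                                          identify_founders, partition,
                                          summarize_major_haplogroups)
from mitofounder.mito_model import parse_variant as pv
from mitofounder.phylogeny import ClockModel, Node, PhyloTree, Sample
from mitofounder.synthetic_data import (FounderEventSpec, GeneratorConfig,
                                        generate)

CLK = ClockModel(3570.0)


def _leaf(name, muts, samples):
    nd = Node(name, [pv(m) for m in muts])
    for sid, pop, grp in samples:
        nd.samples.append(Sample(sid, pop, grp, name))
    return nd


def _case2a_tree():
    root = Node("R")
    p = root.add_child(Node("P", [pv("A100G")]))
    sc = p.add_child(Node("SC", [pv("A200G")]))
    for i in range(3):
        sc.add_child(_leaf(f"h{i}", [f"A{300+i}G"], [(f"t{i}", "tib", "sink")]))
    p.add_child(_leaf("src", ["A400G"], [("e1", "han", "source")]))
    root.add_child(_leaf("out", ["A500G"], [("e2", "han", "source")]))
    return PhyloTree(root)


class TestIdentify:
    def test_case_2a_single_founder(self):
        clusters = identify_founders(_case2a_tree())
        assert len(clusters) == 1
        c = clusters[0]
        assert c.case == "2a"
        assert c.node.name == "P"
        assert c.n == 3
        assert c.m == 6          # each sink path: SC stem + private
        assert c.rho == pytest.approx(2.0)

    def test_case_1_shared_leaf_haplotype(self):
        root = Node("R")
        shared = root.add_child(_leaf("H", ["A100G"],
                                      [("t0", "tib", "sink"),
                                       ("e0", "han", "source")]))
        root.add_child(_leaf("out", ["A200G"], [("e1", "han", "source")]))
        clusters = identify_founders(PhyloTree(root))
        assert len(clusters) == 1
        assert clusters[0].case == "1"
        assert clusters[0].node is shared
        assert clusters[0].rho == 0.0

    def test_case_2b_sampled_sink_ancestor(self):
        # internal haplotype sampled in sinks (zero-branch leaf) with a
        # source immediate derivative
        root = Node("R")
        anc = root.add_child(Node("ANC", [pv("A100G")]))
        anc.add_child(_leaf("ancself", [], [("t0", "tib", "sink")]))
        anc.add_child(_leaf("d1", ["A200G"], [("e0", "han", "source")]))
        root.add_child(_leaf("out", ["A300G"], [("e1", "han", "source")]))
        clusters = identify_founders(PhyloTree(root))
        assert {c.case for c in clusters} == {"2b"}

    def test_case_2c_sampled_source_ancestor(self):
        root = Node("R")
        anc = root.add_child(Node("ANC", [pv("A100G")]))
        anc.add_child(_leaf("ancself", [], [("e0", "han", "source")]))
        anc.add_child(_leaf("d1", ["A200G"], [("t0", "tib", "sink")]))
        root.add_child(_leaf("out", ["A300G"], [("e1", "han", "source")]))
        clusters = identify_founders(PhyloTree(root))
        assert {c.case for c in clusters} == {"2c"}

    def test_requires_both_groups(self):
        t = _case2a_tree()
        for nd in t:
            nd.samples = [s for s in nd.samples if s.group == "sink"]
        with pytest.raises(ValueError):
            identify_founders(t)

    def test_whitelisted_clade_spawns_no_internal_founder(self):
        # a source sample inside a whitelisted sink clade is back migration:
        # the founder stays at the clade stem parent
        t = _case2a_tree()
        sc = next(n for n in t if n.name == "SC")
        sc.children[0].samples.append(Sample("bm", "han", "source", "h0"))
        unwl = identify_founders(t)
        assert any(c.node.name == "SC" for c in unwl)  # internal founder appears
        wl = identify_founders(t, back_migration_whitelist=["SC"])
        assert {c.node.name for c in wl} == {"P"}

    def test_clusters_partition_sink_samples(self):
        # no sink sample is in two clusters; assignment matches a
        # brute-force most-recent-founder ancestor walk
        cfg = GeneratorConfig(seed=99, founder_events=[
            FounderEventSpec(8000.0, 6, mean_samples_per_founder=5.0)],
            n_source_lineages=40)
        ds = generate(cfg)
        clusters = identify_founders(ds.tree)
        seen = [s.id for c in clusters for s in c.samples]
        assert len(seen) == len(set(seen))
        founder_nodes = {id(c.node) for c in clusters}
        by_sample = {s.id: c.node for c in clusters for s in c.samples}
        for leaf in ds.tree.leaves():
            for s in leaf.samples:
                if s.group != "sink":
                    continue
                cur = leaf
                hit = None
                while cur is not None and hit is None:
                    if id(cur) in founder_nodes:
                        hit = cur
                    cur = cur.parent
                assert hit is by_sample[s.id]


class TestAdjustAndMajor:
    def _clusters(self):
        t = _case2a_tree()
        return identify_founders(t)

    def test_subset_all_and_empty(self):
        cl = self._clusters()
        adjust_counts(cl, [s.id for c in cl for s in c.samples])
        assert all(c.n_adj == c.n for c in cl)
        adjust_counts(cl, [])
        assert all(c.n_adj == 0 for c in cl)

    def test_unknown_ids_rejected(self):
        cl = self._clusters()
        with pytest.raises(ValueError):
            adjust_counts(cl, ["nope"], all_sink_ids={"t0", "t1", "t2"})

    def test_random_half_subset_binomial(self):
        cfg = GeneratorConfig(seed=5, founder_events=[
            FounderEventSpec(8000.0, 10, mean_samples_per_founder=20.0)],
            n_source_lineages=60)
        ds = generate(cfg)
        clusters = identify_founders(ds.tree)
        sink_ids = [s.id for s in ds.samples if s.group == "sink"]
        rng = np.random.default_rng(0)
        half = rng.choice(sink_ids, size=len(sink_ids) // 2, replace=False)
        adjust_counts(clusters, half)
        tot_n = sum(c.n for c in clusters)
        tot_adj = sum(c.n_adj for c in clusters)
        se = math.sqrt(tot_n * 0.25)
        assert abs(tot_adj - 0.5 * tot_n) <= 1 + 3 * se

    def test_flag_major(self):
        cl = [FounderCluster(node=Node("a"), case="2a", m=0, rho=0, sigma=0,
                             samples=[Sample(f"s{i}", p, "sink", "a")
                                      for i, p in enumerate(
                                          ["tib", "deng", "lhoba"])]),
              FounderCluster(node=Node("b"), case="2a", m=0, rho=0, sigma=0,
                             samples=[Sample("x", "tib", "sink", "b")])]
        flag_major(cl, freq_threshold=0.5, subset_size=4)
        assert cl[0].major and not cl[1].major      # 3 ethnic groups
        flag_major(cl, freq_threshold=0.0, subset_size=4)
        assert all(c.major for c in cl)             # threshold 0: all major
        with pytest.raises(ValueError):
            flag_major(cl, freq_threshold=1.5)


class TestScan:
    def _cluster(self, age, sd, w=1):
        c = FounderCluster(node=Node("x"), case="2a", m=0, rho=0, sigma=0,
                           samples=[Sample(f"s{age}{i}", "tib", "sink", "x")
                                    for i in range(w)])
        c.age, c.age_sd = age, sd
        return c

    def test_grid_shape_and_normalisation(self):
        scan = founder_scan([self._cluster(8000, 1000)])
        assert len(scan.ages) == 251
        assert scan.density.sum() == pytest.approx(1.0, abs=1e-9)
        assert (scan.density >= 0).all()

    def test_single_cluster_argmax(self):
        scan = founder_scan([self._cluster(8000, 1000)])
        assert scan.ages[np.argmax(scan.density)] == 8000

    def test_two_separated_clusters_two_maxima(self):
        scan = founder_scan([self._cluster(1200, 300), self._cluster(30000, 300)])
        peaks = scan.peaks(min_density=0.001)
        assert 1200 in peaks and 30000 in peaks

    def test_zero_weight_rejected(self):
        c = self._cluster(8000, 1000)
        c.n_adj = 0
        with pytest.raises(ValueError):
            founder_scan([c])

    def test_equivariant_under_relabeling(self):
        cl = [self._cluster(5000, 500, 2), self._cluster(12000, 800, 3)]
        d1 = founder_scan(cl).density
        d2 = founder_scan(cl[::-1]).density
        assert np.allclose(d1, d2)


class TestPartition:
    def test_single_migration(self):
        c = FounderCluster(node=Node("x"), case="2a", m=3, rho=1, sigma=0.5,
                           samples=[Sample("s", "tib", "sink", "x")])
        part = partition([c], [8000.0], CLK, bootstrap_B=100, seed=0)
        assert part.fractions.tolist() == [1.0]
        assert part.se.tolist() == [0.0]

    def test_two_point_poisson_posterior_closed_form(self):
        c = FounderCluster(node=Node("x"), case="2a", m=0, rho=0, sigma=0,
                           samples=[Sample(f"s{i}", "tib", "sink", "x")
                                    for i in range(5)])
        part = partition([c], [1200.0, 30000.0], CLK, bootstrap_B=0)
        lam1, lam2 = 5 * 1200 / 3570, 5 * 30000 / 3570
        expect_young = math.exp(-lam1) / (math.exp(-lam1) + math.exp(-lam2))
        assert part.fractions[0] == pytest.approx(expect_young, abs=1e-12)
        assert part.fractions[0] > 1 - 1e-15
        assert part.fractions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_empty_times_rejected(self):
        c = FounderCluster(node=Node("x"), case="2a", m=0, rho=0, sigma=0,
                           samples=[Sample("s", "tib", "sink", "x")])
        with pytest.raises(ValueError):
            partition([c], [], CLK)

    def test_synthetic_three_wave_recovery(self):
        ds = generate(GeneratorConfig(seed=42))
        clusters = identify_founders(ds.tree, clock=ClockModel.complete_linear())
        part = partition(clusters, [30000.0, 16800.0, 8000.0],
                         ClockModel.complete_linear(), bootstrap_B=500, seed=1)
        truth = {w["time_years"]: w["proportion"] for w in ds.truth["waves"]}
        for t, p, se in zip(part.times, part.fractions, part.se):
            assert abs(p - truth[t]) <= 2 * se

    def test_mean_recovery_error_under_5_points(self):
        # end-to-end recovery over seeded replicates
        errs = []
        for seed in range(20):
            ds = generate(GeneratorConfig(seed=1000 + seed))
            clusters = identify_founders(ds.tree)
            part = partition(clusters, [30000.0, 16800.0, 8000.0],
                             ClockModel.complete_linear(), bootstrap_B=0)
            truth = {w["time_years"]: w["proportion"] for w in ds.truth["waves"]}
            errs.extend(abs(p - truth[t])
                        for t, p in zip(part.times, part.fractions))
        assert float(np.mean(errs)) < 0.05


class TestPrintedTableSummaries:
    def test_all_printed_quantities(self):
        s = summarize_major_haplogroups()
        assert round(s["coverage_pct"], 2) == 63.19
        assert s["n_shared_haplogroups"] == 13
        assert s["n_shared_individuals"] == 206
        assert s["n_postlgm_shared_haplogroups"] == 3
        assert round(s["postlgm_shared_pct"], 2) == 4.86
        assert s["n_young_haplogroups"] == 17
        assert round(s["young_pct"], 2) == 57.41
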