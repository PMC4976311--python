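"""Tree construction, annotated-Newick I/O, rho statistic and clock."""
import itertools
import math

import numpy as np
import pytest

from mitofounder.mito_model import Variant, parse_variant
from mitofounder.phylogeny import (ClockModel, Node,
                                   PhyloTree, Sample, build_tree, canonicalize,
                                   enumerate_haplogroups,
                                   read_annotated_newick, rho, rho_to_years,
                                   write_annotated_newick)


def pv(tok):
    return parse_variant(tok)


def _leaf(name, muts, n_samples=1, group="sink"):
    nd = Node(name, [pv(m) for m in muts])
    for i in range(n_samples):
        nd.samples.append(Sample(f"{name}s{i}", "pop", group, name))
    return nd


def _random_tree(rng, max_leaves=64, max_muts=3, p_sample=1.0):
    """Random topology with random per-edge mutation counts and samples."""
    n_leaves = int(rng.integers(2, max_leaves + 1))
    counter = itertools.count()
    nodes = [_leaf(f"L{i}", [], n_samples=int(rng.integers(1, 3)))
             for i in range(n_leaves)]
    while len(nodes) > 1:
        k = int(rng.integers(2, min(3, len(nodes)) + 1))
        idx = rng.choice(len(nodes), size=k, replace=False)
        parent = Node(f"I{next(counter)}")
        for i in sorted(idx, reverse=True):
            parent.add_child(nodes.pop(i))
        nodes.append(parent)
    tree = PhyloTree(nodes[0])
    pos = itertools.count(1)
    for node in tree:
        if node is tree.root:
            continue
        node.muts = [Variant(next(pos), "A", "G")
                     for _ in range(int(rng.integers(0, max_muts + 1)))]
    return tree


def _oracle_rho(clade):
    """Path-walking oracle: average root->sample path mutation count."""
    total = 0
    n = 0
    for node in clade.postorder():
        if not node.samples:
            continue
        path = 0
        cur = node
        while cur is not clade:
            path += len(cur.muts)
            cur = cur.parent
        total += path * len(node.samples)
        n += len(node.samples)
    return total / n


def _oracle_sigma(clade):
    n = sum(len(nd.samples) for nd in clade.postorder())

    def samples_below(node):
        return sum(len(nd.samples) for nd in node.postorder())

    var = 0.0
    for node in clade.postorder():
        if node is clade:
            continue
        var += (samples_below(node) / n) ** 2 * len(node.muts)
    return math.sqrt(var)


class TestRho:
    def test_single_leaf(self):
        leaf = _leaf("A", [])
        assert rho(leaf) == (0.0, 0.0)

    def test_star_four_private(self):
        r = Node("r")
        for i in range(4):
            r.add_child(_leaf(f"L{i}", [f"A{100+i}G"]))
        assert rho(r) == (1.0, 0.5)

    def test_nested_hand_case(self):
        r = Node("r")
        inner = r.add_child(Node("I", [pv("A100G")]))
        inner.add_child(_leaf("L1", ["A201G"]))
        inner.add_child(_leaf("L2", ["A202G"]))
        r.add_child(_leaf("L3", ["A300G"]))
        rv, sv = rho(r)
        assert rv == pytest.approx(5 / 3)
        assert sv == pytest.approx(math.sqrt(7) / 3)

    def test_matches_oracle_on_random_trees(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            tree = _random_tree(rng)
            rv, sv = rho(tree.root)
            assert rv == pytest.approx(_oracle_rho(tree.root))
            assert sv == pytest.approx(_oracle_sigma(tree.root))

    def test_sigma_zero_iff_no_mutations_below(self):
        r = Node("r")
        for i in range(3):
            r.add_child(_leaf(f"L{i}", []))
        assert rho(r) == (0.0, 0.0)
        r.children[0].muts = [pv("A100G")]
        assert rho(r)[1] > 0

    def test_clock_linearity_doubling(self):
        rng = np.random.default_rng(3)
        tree = _random_tree(rng, max_leaves=20)
        r1, s1 = rho(tree.root)
        for node in tree:
            node.muts = node.muts + list(node.muts)
        r2, s2 = rho(tree.root)
        assert r2 == pytest.approx(2 * r1)
        assert s2 == pytest.approx(math.sqrt(2) * s1)


class TestClock:
    def test_complete_linear_preset(self):
        clk = ClockModel.complete_linear()
        age, _ = rho_to_years(1.0, 0.0, clk)
        assert age == pytest.approx(1.0 / (1.691e-8 * 16569))
        assert age == pytest.approx(3570, rel=0.001)

    def test_linearity(self):
        clk = ClockModel(3570.0)
        age, sd = rho_to_years(2.0, 0.5, clk)
        assert (age, sd) == (7140.0, 1785.0)

    def test_zero_rho(self):
        assert rho_to_years(0.0, 0.0, ClockModel(3570.0)) == (0.0, 0.0)

    def test_nonpositive_clock_rejected(self):
        with pytest.raises(ValueError):
            ClockModel(0.0)


class TestEnumerate:
    def test_small_star_empty(self):
        r = Node("r")
        for i in range(3):
            r.add_child(_leaf(f"L{i}", [f"A{100+i}G"]))
        assert enumerate_haplogroups(PhyloTree(r)) == []

    def test_balanced_eight(self):
        # balanced 8-leaf tree, every edge 1 mutation: the two 4-leaf
        # clades qualify, and so does any deeper annotated clade
        pos = itertools.count(1)

        def build(depth, name):
            nd = Node(name, [Variant(next(pos), "A", "G")])
            if depth:
                nd.add_child(build(depth - 1, name + "0"))
                nd.add_child(build(depth - 1, name + "1"))
            else:
                nd.samples.append(Sample(name, "p", "sink", name))
            return nd

        root = Node("root")
        root.add_child(build(2, "a"))
        root.add_child(build(2, "b"))
        got = {hg.name for hg in enumerate_haplogroups(PhyloTree(root))}
        assert got == {"a", "b"}

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            tree = _random_tree(rng, max_leaves=64)
            fast = {id(h.node) for h in enumerate_haplogroups(tree)}
            slow = set()
            for node in tree:
                if node is tree.root or not node.muts:
                    continue
                n_hap = len(node.leaves())
                n_s = len(node.clade_samples())
                if n_hap >= 4 and n_s >= 3:
                    slow.add(id(node))
            assert fast == slow


# --- exhaustive parsimony oracle -------------------------------------------

def _all_rooted_topologies(leaves):
    """All rooted binary topologies over the given leaf names."""
    if len(leaves) == 1:
        yield leaves[0]
        return
    first, rest = leaves[0], leaves[1:]
    for k in range(len(rest)):
        for left_idx in itertools.combinations(range(len(rest)), k):
            left = [first] + [rest[i] for i in left_idx]
            right = [rest[i] for i in range(len(rest)) if i not in left_idx]
            if not right:
                continue
            for lt in _all_rooted_topologies(left):
                for rt in _all_rooted_topologies(right):
                    yield (lt, rt)


def _fitch_length(topo, char_sets, root_state):
    """Minimal mutation count for binary characters on a fixed topology."""
    total = 0
    for site, carriers in char_sets.items():
        def fitch(node):
            nonlocal total_site
            if isinstance(node, str):
                return {node in carriers}
            l = fitch(node[0])
            r = fitch(node[1])
            inter = l & r
            if inter:
                return inter
            total_site[0] += 1
            return l | r
        total_site = [0]
        states = fitch(topo)
        if root_state not in states:
            total_site[0] += 1
        total += total_site[0]
    return total


def _oracle_min_parsimony(haplotypes, root_id):
    root_set = frozenset(haplotypes[root_id])
    others = [h for h in haplotypes if h != root_id]
    chars = {}
    for h in others:
        for v in frozenset(haplotypes[h]) ^ root_set:
            chars.setdefault(v, set()).add(h)
    best = None
    for topo in _all_rooted_topologies(others):
        length = _fitch_length(topo, chars, root_state=False)
        best = length if best is None else min(best, length)
    return best


class TestBuildTree:
    def test_single_haplotype(self):
        t = build_tree({"R": frozenset()}, "R")
        assert t.total_mutations() == 0
        assert t.root.is_leaf

    def test_compatible_nesting_is_perfect(self):
        hap = {
            "R": frozenset(),
            "A": frozenset({pv("A100G")}),
            "B": frozenset({pv("A100G"), pv("A200G")}),
            "C": frozenset({pv("A300G")}),
        }
        t = build_tree(hap, "R")
        assert t.total_mutations() == 3
        assert t.total_mutations() == _oracle_min_parsimony(hap, "R")

    def test_recurrent_site_adds_one(self):
        hap = {
            "R": frozenset(),
            "A": frozenset({pv("A100G"), pv("T500C")}),
            "B": frozenset({pv("A100G")}),
            "C": frozenset({pv("A200G"), pv("T500C")}),
            "D": frozenset({pv("A200G")}),
        }
        t = build_tree(hap, "R")
        assert t.total_mutations() == 4  # 3 distinct + 1 recurrence
        assert t.total_mutations() == _oracle_min_parsimony(hap, "R")

    def test_matches_exhaustive_oracle_small(self):
        rng = np.random.default_rng(13)
        tokens = [f"A{100+i}G" for i in range(6)]
        for _ in range(25):
            n = int(rng.integers(2, 6))
            hap = {"R": frozenset()}
            for i in range(n):
                k = int(rng.integers(0, 4))
                idx = rng.choice(len(tokens), size=k, replace=False)
                hap[f"H{i}"] = frozenset(pv(tokens[j]) for j in idx)
            # dedupe identical haplotypes under different ids
            if len({hap[h] for h in hap}) != len(hap):
                continue
            t = build_tree(hap, "R")
            assert t.total_mutations() == _oracle_min_parsimony(hap, "R")

    def test_duplicate_and_empty_rejected(self):
        with pytest.raises(ValueError):
            build_tree({}, "R")
        with pytest.raises(ValueError):
            build_tree({"A": frozenset()}, "R")

    def test_haplotype_reconstruction_invariant(self):
        hap = {
            "R": frozenset(),
            "A": frozenset({pv("A100G")}),
            "B": frozenset({pv("A100G"), pv("A200G")}),
            "C": frozenset({pv("A300G"), pv("T500C")}),
        }
        t = build_tree(hap, "R")
        for leaf in t.leaves():
            assert t.haplotype_of(leaf) == hap[leaf.name]


class TestNewickIO:
    def test_trivial(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("(A[&muts=T3394C],B)R;\n")
        t = read_annotated_newick(p)
        annotated = [n for n in t if n.muts]
        assert len(annotated) == 1
        assert str(annotated[0].muts[0]) == "T3394C"

    def test_round_trip_random_50(self, tmp_path):
        rng = np.random.default_rng(17)
        tree = _random_tree(rng, max_leaves=50)
        canonicalize(tree)
        p1, p2 = tmp_path / "a.nwk", tmp_path / "b.nwk"
        write_annotated_newick(tree, p1)
        t2 = canonicalize(read_annotated_newick(p1))
        write_annotated_newick(t2, p2)
        assert p1.read_text() == p2.read_text()

    def test_build_tree_round_trip_preserves_rho(self, tmp_path):
        hap = {"R": frozenset(),
               "A": frozenset({pv("A100G")}),
               "B": frozenset({pv("A100G"), pv("A200G")}),
               "C": frozenset({pv("A300G")}),
               "D": frozenset({pv("A300G"), pv("T500C")})}
        t = build_tree(hap, "R")
        for leaf in t.leaves():
            leaf.samples.append(Sample(leaf.name, "p", "sink", leaf.name))
        p = tmp_path / "t.nwk"
        write_annotated_newick(t, p)
        t2 = read_annotated_newick(p)
        for leaf in t2.leaves():
            leaf.samples.append(Sample(leaf.name, "p", "sink", leaf.name))
        assert rho(t2.root) == rho(t.root)

    def test_malformed_rejected(self, tmp_path):
        p = tmp_path / "bad.nwk"
        p.write_text("(A[&muts=XYZ],B)R;\n")
        with pytest.raises(Exception):
            read_annotated_newick(p)
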