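"""Mutation-annotated rooted phylogenies and rho-statistic dating.

A :class:`PhyloTree` is a rooted tree whose edges carry lists of
:class:`~mitofounder.mito_model.Variant` (the mutations inferred on that
branch) and whose leaves carry one haplotype id plus the samples sharing
that haplotype.  The rho statistic of a clade is the average number of
mutations between the clade root and each member sample; its standard
deviation follows the branch-weighted variance formula of Saillard et al.,
sigma^2 = sum_e (n_e/n)^2 m_e over edges below the clade root.  A linear
molecular clock converts rho to years.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional

import dendropy

from mitofounder.constants import (GENERATION_TIME_YEARS,
                                   YEARS_PER_MUTATION_COMPLETE)
from mitofounder.mito_model import Variant, parse_variant


@dataclass(frozen=True)
class Sample:
    """One sequenced individual attached to a leaf haplotype."""

    id: str
    population: str
    group: str          # 'sink' (study population) or 'source'
    haplotype_id: str

    def __post_init__(self):
        if self.group not in ("sink", "source"):
            raise ValueError(f"group must be sink/source, got {self.group!r}")


class Node:
    """Tree node; ``muts`` are the mutations on the edge above this node."""

    __slots__ = ("name", "parent", "children", "muts", "samples")

    def __init__(self, name: str = "", muts: Optional[list[Variant]] = None):
        self.name = name
        self.parent: Optional[Node] = None
        self.children: list[Node] = []
        self.muts: list[Variant] = list(muts or [])
        self.samples: list[Sample] = []

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["Node"]:
        for c in self.children:
            yield from c.postorder()
        yield self

    def preorder(self) -> Iterator["Node"]:
        yield self
        for c in self.children:
            yield from c.preorder()

    def leaves(self) -> list["Node"]:
        return [n for n in self.postorder() if n.is_leaf]

    def clade_samples(self) -> list[Sample]:
        return [s for n in self.postorder() for s in n.samples]

    def __repr__(self):
        return f"Node({self.name!r}, muts={len(self.muts)}, children={len(self.children)})"


class PhyloTree:
    """Rooted mutation-annotated phylogeny with samples at leaves."""

    def __init__(self, root: Node):
        self.root = root

    def __iter__(self) -> Iterator[Node]:
        return self.root.preorder()

    def leaves(self) -> list[Node]:
        return self.root.leaves()

    def samples(self) -> list[Sample]:
        return self.root.clade_samples()

    def total_mutations(self) -> int:
        return sum(len(n.muts) for n in self)

    def attach_samples(self, samples: Iterable[Sample]) -> None:
        """Attach samples to the leaves carrying their haplotype id."""
        by_hap: dict[str, Node] = {}
        carriers = self.leaves()
        if not self.root.is_leaf:
            carriers.append(self.root)  # root haplotype may itself be sampled
        for leaf in carriers:
            if leaf.name and leaf.name in by_hap:
                raise ValueError(f"duplicate leaf haplotype id {leaf.name!r}")
            if leaf.name:
                by_hap[leaf.name] = leaf
        for s in samples:
            if s.haplotype_id not in by_hap:
                raise ValueError(f"sample {s.id}: unknown haplotype {s.haplotype_id!r}")
            by_hap[s.haplotype_id].samples.append(s)

    def haplotype_of(self, node: Node, root_haplotype: frozenset[Variant] = frozenset()
                     ) -> frozenset[Variant]:
        """Apply edge mutations root->node; a repeated position toggles state."""
        path = []
        cur: Optional[Node] = node
        while cur is not None:
            path.append(cur)
            cur = cur.parent
        state = dict()  # position -> Variant
        for v in root_haplotype:
            state[v.position] = v
        for nd in reversed(path):
            for v in nd.muts:
                if v.position in state and state[v.position].alt == v.ref:
                    prev = state.pop(v.position)
                    if prev.ref != v.alt:    # partial back mutation
                        state[v.position] = Variant(v.position, prev.ref, v.alt)
                else:
                    state[v.position] = v
        return frozenset(state.values())


# ---------------------------------------------------------------------------
# clock

@dataclass(frozen=True)
class ClockModel:
    """Linear molecular clock: age = rho * years_per_mutation."""

    years_per_mutation: float
    generation_time: float = GENERATION_TIME_YEARS

    def __post_init__(self):
        if self.years_per_mutation <= 0:
            raise ValueError("years_per_mutation must be positive")

    @classmethod
    def complete_linear(cls) -> "ClockModel":
        """Whole-molecule linear clock from the 1.691e-8 subs/site/year rate."""
        return cls(years_per_mutation=YEARS_PER_MUTATION_COMPLETE)


def rho(clade: Node) -> tuple[float, float]:
    """Rho statistic and Saillard SD of a clade.

    rho = mean over member samples of the mutation count on the path from
    the clade root to the sample's leaf (samples sharing a leaf each count);
    sigma = sqrt( sum over edges below the clade root of (n_e/n)^2 m_e ).
    """
    counts: dict[int, int] = {}

    def n_below(node: Node) -> int:
        c = len(node.samples) + sum(n_below(ch) for ch in node.children)
        counts[id(node)] = c
        return c

    n = n_below(clade)
    if n == 0:
        raise ValueError("empty clade")
    total = 0.0
    var = 0.0
    for node in clade.postorder():
        if node is clade:
            continue  # the clade's own stem is not below the clade root
        n_e = counts[id(node)]
        m_e = len(node.muts)
        total += n_e * m_e
        var += (n_e / n) ** 2 * m_e
    return total / n, math.sqrt(var)


def rho_to_years(rho_value: float, sigma: float, clock: ClockModel
                 ) -> tuple[float, float]:
    return rho_value * clock.years_per_mutation, sigma * clock.years_per_mutation


# ---------------------------------------------------------------------------
# haplogroup enumeration

@dataclass
class HaplogroupClade:
    node: Node
    defining_variants: list[Variant]
    members: list[Sample]
    n_haplotypes: int
    rho: float
    sigma: float
    age: Optional[float] = None
    age_sd: Optional[float] = None

    @property
    def name(self) -> str:
        return self.node.name


def enumerate_haplogroups(tree: PhyloTree, min_haplotypes: int = 4,
                          min_samples: int = 3,
                          clock: Optional[ClockModel] = None
                          ) -> list[HaplogroupClade]:
    """All clades with >=1 defining mutation meeting both size thresholds.

    Nested qualifying clades are all reported.  Defining variants are the
    mutations on the clade's subtending branch.
    """
    out = []
    for node in tree:
        if node is tree.root or not node.muts:
            continue
        n_hap = len(node.leaves())
        members = node.clade_samples()
        if n_hap >= min_haplotypes and len(members) >= min_samples:
            r, s = rho(node)
            hg = HaplogroupClade(node=node, defining_variants=list(node.muts),
                                 members=members, n_haplotypes=n_hap,
                                 rho=r, sigma=s)
            if clock is not None:
                hg.age, hg.age_sd = rho_to_years(r, s, clock)
            out.append(hg)
    return out


# ---------------------------------------------------------------------------
# annotated-Newick I/O

def _quote(name: str) -> str:
    if not name:
        return ""
    if all(c not in name for c in "(),:;[] \t'"):
        return name
    return "'" + name.replace("'", "''") + "'"


def _node_to_newick(node: Node) -> str:
    inner = ""
    if node.children:
        inner = "(" + ",".join(_node_to_newick(c) for c in node.children) + ")"
    ann = ""
    if node.muts:
        toks = sorted(str(v) for v in node.muts)
        ann = "[&muts=" + "|".join(toks) + "]"
    return inner + _quote(node.name) + ann


def write_annotated_newick(tree: PhyloTree, path: str | Path) -> None:
    """Write the tree in Newick with ``[&muts=...]`` branch annotations."""
    with open(path, "w") as fh:
        fh.write(_node_to_newick(tree.root) + ";\n")


def read_annotated_newick(path: str | Path) -> PhyloTree:
    """Read a Newick file whose comments carry ``[&muts=T3394C|...]`` blocks."""
    dt = dendropy.Tree.get(path=str(path), schema="newick",
                           suppress_internal_node_taxa=False)

    def convert(dnode) -> Node:
        label = dnode.taxon.label if dnode.taxon else (dnode.label or "")
        muts = []
        val = dnode.annotations.get_value("muts", None)
        if val:
            for tok in str(val).split("|"):
                muts.append(parse_variant(tok))
        node = Node(name=label, muts=muts)
        for ch in dnode.child_nodes():
            node.add_child(convert(ch))
        return node

    return PhyloTree(convert(dt.seed_node))


def canonicalize(tree: PhyloTree) -> PhyloTree:
    """Sort children (by leaf-name set) and mutation lists, in place."""
    def key(node: Node):
        return min(l.name for l in node.leaves()) if node.children else node.name

    for node in tree:
        node.muts.sort(key=str)
        node.children.sort(key=key)
    return tree


# ---------------------------------------------------------------------------
# greedy maximum-parsimony construction

def build_tree(haplotypes: dict[str, frozenset[Variant] | set[Variant]],
               root_id: str) -> PhyloTree:
    """Greedy maximum-parsimony tree from haplotype variant sets.

    Characters are variant presence relative to the designated root
    haplotype.  Sites whose carrier sets form a laminar (nested/disjoint)
    family — taken in order of decreasing carrier count, then token — yield
    a perfect phylogeny; each remaining (recurrent) site is placed once on
    the stem of every maximal clade wholly contained in its carrier set,
    which is the minimal placement on the fixed tree.  Ties in the greedy
    ordering and placements are resolved by clade size then lexicographic
    leaf name.
    """
    if not haplotypes:
        raise ValueError("no haplotypes")
    if root_id not in haplotypes:
        raise ValueError(f"root haplotype {root_id!r} not in input")
    ids = list(haplotypes)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate haplotype ids")
    root_set = frozenset(haplotypes[root_id])

    carriers: dict[Variant, frozenset[str]] = {}
    universe = frozenset(h for h in ids if h != root_id)
    for h in universe:
        for v in frozenset(haplotypes[h]) ^ root_set:
            carriers.setdefault(v, frozenset())
            carriers[v] = carriers[v] | {h}

    order = sorted(carriers, key=lambda v: (-len(carriers[v]), str(v)))
    accepted: list[Variant] = []
    deferred: list[Variant] = []
    fam: set[frozenset[str]] = set()

    def laminar(c: frozenset[str]) -> bool:
        return all(c <= f or f <= c or not (c & f) for f in fam)

    for v in order:
        c = carriers[v]
        if c and laminar(c):
            accepted.append(v)
            fam.add(c)
        else:
            deferred.append(v)

    # containment tree over the laminar family (plus the universe as root)
    sets = sorted(fam | {universe}, key=lambda s: (-len(s), sorted(s)))
    root = Node(name=root_id)
    nodes: dict[frozenset[str], Node] = {universe: root}
    for s in sets:
        if s != universe:
            nodes[s] = Node(name="")
    for s in sets:
        if s == universe:
            continue
        parent = min((t for t in sets if s < t), key=len, default=universe)
        nodes[parent].add_child(nodes[s])

    for v in accepted:
        nodes[carriers[v]].muts.append(v)

    # attach each haplotype as a leaf under its smallest containing set
    leaf_of: dict[str, Node] = {}
    for h in sorted(universe):
        smallest = min((s for s in sets if h in s), key=len)
        leaf = Node(name=h)
        nodes[smallest].add_child(leaf)
        leaf_of[h] = leaf
    # collapse: a laminar set with exactly one haplotype and that haplotype's
    # leaf as only child duplicates the leaf; merge stem mutations down
    for s in sorted(fam, key=len):
        nd = nodes[s]
        if len(nd.children) == 1 and nd.children[0].is_leaf and len(s) == 1:
            leaf = nd.children[0]
            leaf.muts = nd.muts + leaf.muts
            parent = nd.parent
            parent.children[parent.children.index(nd)] = leaf
            leaf.parent = parent
            leaf_of[leaf.name] = leaf

    tree = PhyloTree(root)

    # recurrent sites: one occurrence per maximal clade inside the carrier set
    def leafset(node: Node) -> frozenset[str]:
        return frozenset(l.name for l in node.leaves())

    for v in sorted(deferred, key=lambda v: (-len(carriers[v]), str(v))):
        target = carriers[v]

        def place(node: Node):
            for ch in node.children:
                ls = leafset(ch)
                if ls <= target and ls:
                    ch.muts.append(v)
                elif ls & target:
                    place(ch)

        place(root)

    return canonicalize(tree)
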