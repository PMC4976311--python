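"""Nonsynonymous/synonymous branch statistics stratified by lineage age.

Every coding-region mutation on a phylogeny branch is counted once as
nonsynonymous (N) or synonymous (S); RNA and control-region mutations are
excluded.  Each branch is assigned to the rho bin (rounded half-up,
capped) of the clade it subtends, so external branches — those subtending
single haplotypes with rho = 0 — form bin 0 and deeper branches bins
1..max.  Purifying selection depresses N/S on older (internal) branches;
the external-vs-internal contrast is tested on the pooled 2x2 count
table.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

from scipy import stats

from mitofounder.mito_model import (GeneAnnotation, classify_consequences,
                                    AnnotationError)
from mitofounder.phylogeny import Node, PhyloTree, rho

log = logging.getLogger(__name__)

NS_UNDEFINED = float("inf")


@dataclass
class NSCounts:
    label: str
    N: int = 0
    S: int = 0
    n_branches: int = 0

    @property
    def ratio(self) -> float:
        return self.N / self.S if self.S else NS_UNDEFINED

    def add(self, other: "NSCounts") -> None:
        self.N += other.N
        self.S += other.S
        self.n_branches += other.n_branches


def count_branch_ns(tree: PhyloTree, annotations: Sequence[GeneAnnotation],
                    ref_seq: str) -> dict[int, NSCounts]:
    """Per-branch N/S counts, keyed by id(node) of the subtended node.

    A mutation nonsynonymous in any overlapping reading frame counts as N.
    Unannotatable variants are excluded and tallied in the 'diagnostics'
    entry's n_branches field.
    """
    out: dict[int, NSCounts] = {}
    n_bad = 0
    for node in tree:
        if node is tree.root:
            continue
        c = NSCounts(label=node.name or "", n_branches=1)
        for v in node.muts:
            try:
                calls = classify_consequences(v, annotations, ref_seq)
            except AnnotationError as exc:
                n_bad += 1
                log.debug("unannotatable variant %s: %s", v, exc)
                continue
            cats = {x.category for x in calls}
            if "nonsynonymous" in cats:
                c.N += 1
            elif "synonymous" in cats:
                c.S += 1
            # rna / control_region excluded
        out[id(node)] = c
    if n_bad:
        log.warning("%d unannotatable variants excluded from N/S counts",
                    n_bad)
        out[-1] = NSCounts(label="diagnostics:unannotatable", n_branches=n_bad)
    return out


def rho_bin(node: Node, max_rho: int = 4) -> int:
    """Age bin of a branch: round-half-up of the subtended clade's rho,
    capped at max_rho.  Leaf branches are bin 0 (external)."""
    if node.is_leaf:
        return 0
    r, _ = rho(node)
    return min(int(math.floor(r + 0.5)), max_rho)


@dataclass
class NSByRho:
    bins: list[NSCounts]          # index = rho bin
    external: NSCounts            # bin 0
    internal: NSCounts            # bins 1..max pooled


def ns_by_rho(tree: PhyloTree, annotations: Sequence[GeneAnnotation],
              ref_seq: str, max_rho: int = 4,
              per_branch: Optional[dict[int, NSCounts]] = None) -> NSByRho:
    """N/S per rho unit plus the external (rho=0) / internal (1..max) split."""
    if per_branch is None:
        per_branch = count_branch_ns(tree, annotations, ref_seq)
    bins = [NSCounts(label=f"rho={b}") for b in range(max_rho + 1)]
    for node in tree:
        if node is tree.root or id(node) not in per_branch:
            continue
        bins[rho_bin(node, max_rho)].add(per_branch[id(node)])
    external = NSCounts(label="external")
    external.add(bins[0])
    internal = NSCounts(label="internal")
    for b in bins[1:]:
        internal.add(b)
    return NSByRho(bins=bins, external=external, internal=internal)


def compare_classes(external: NSCounts, internal: NSCounts) -> float:
    """Two-sided Fisher exact p for the [[N_ext,S_ext],[N_int,S_int]] table."""
    if external.N + external.S == 0 or internal.N + internal.S == 0:
        raise ValueError("empty branch class")
    table = [[external.N, external.S], [internal.N, internal.S]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def ns_by_complex(tree: PhyloTree, annotations: Sequence[GeneAnnotation],
                  ref_seq: str) -> dict[str, NSCounts]:
    """N/S per respiratory complex (I, III, IV, V) over all branches.

    A mutation contributes to the complex of each protein gene it hits;
    within a complex it is N if nonsynonymous in any frame of that
    complex's genes.
    """
    out = {c: NSCounts(label=f"complex {c}") for c in ("I", "III", "IV", "V")}
    gene_complex = {a.gene: a.complex_label for a in annotations
                    if a.feature_type == "protein"}
    for node in tree:
        if node is tree.root:
            continue
        for v in node.muts:
            try:
                calls = classify_consequences(v, annotations, ref_seq)
            except AnnotationError:
                continue
            by_cx: dict[str, set[str]] = {}
            for c in calls:
                if c.category in ("nonsynonymous", "synonymous"):
                    cx = gene_complex.get(c.gene, "none")
                    by_cx.setdefault(cx, set()).add(c.category)
            for cx, cats in by_cx.items():
                if cx not in out:
                    continue
                if "nonsynonymous" in cats:
                    out[cx].N += 1
                else:
                    out[cx].S += 1
    return out
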