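"""Sink-specific lineages, pathogenic annotation and exact enrichment tests.

A sink-specific lineage is a qualifying clade (>=4 haplotypes, >=3
samples by default) whose members are all sink samples; clades on a
back-migration whitelist may contain listed source members.  Each
lineage's defining (stem-branch) variants are looked up in the filtered
pathogenicity table, lineages are classed by 0 / 1 / >=2 pathogenic
defining mutations, and the 2xC contingency table against a comparison
set of haplogroups is tested with an exact conditional test: 2x2 by the
two-sided hypergeometric rule, 2x3 by Freeman-Halton full enumeration.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from mitofounder.mito_model import PathogenicityRecord, Variant
from mitofounder.phylogeny import (ClockModel, HaplogroupClade, PhyloTree,
                                   enumerate_haplogroups)

log = logging.getLogger(__name__)


@dataclass
class LineageRecord:
    clade: HaplogroupClade
    specific: bool
    pathogenic_hits: Optional[int] = None
    hit_variants: Optional[list[Variant]] = None

    @property
    def name(self) -> str:
        return self.clade.name

    @property
    def defining_variants(self) -> list[Variant]:
        return self.clade.defining_variants

    @property
    def rho_bin(self) -> int:
        return int(math.floor(self.clade.rho + 0.5))  # round half up


def find_specific_lineages(tree: PhyloTree, min_haplotypes: int = 4,
                           min_samples: int = 3,
                           whitelist: Iterable[str] = (),
                           clock: Optional[ClockModel] = None
                           ) -> list[LineageRecord]:
    """Qualifying clades whose members are all sink samples.

    Whitelisted clades (by node name) are treated as sink-specific despite
    source members attributed to back migration.  Nested qualifying clades
    are all reported, deduplicated by node.
    """
    wl = set(whitelist)
    out = []
    seen = set()
    for hg in enumerate_haplogroups(tree, min_haplotypes, min_samples, clock):
        if id(hg.node) in seen:
            continue
        seen.add(id(hg.node))
        groups = {s.group for s in hg.members}
        if groups == {"sink"} or (hg.name in wl and "sink" in groups):
            out.append(LineageRecord(clade=hg, specific=True))
    return out


def classify_pathogenic(lineages: Sequence[LineageRecord],
                        pathogenicity: Sequence[PathogenicityRecord]
                        ) -> list[LineageRecord]:
    """Count defining variants present in the filtered pathogenicity table."""
    table = {r.variant for r in pathogenicity}
    for lin in lineages:
        hits = [v for v in lin.defining_variants if v in table]
        lin.pathogenic_hits = len(hits)
        lin.hit_variants = hits
    return list(lineages)


def hit_class_counts(hit_counts: Iterable[int]) -> tuple[int, int, int]:
    """(n with 0, n with 1, n with >=2) pathogenic defining mutations."""
    c0 = c1 = c2 = 0
    for h in hit_counts:
        if h == 0:
            c0 += 1
        elif h == 1:
            c1 += 1
        else:
            c2 += 1
    return c0, c1, c2


# ---------------------------------------------------------------------------
# exact contingency-table tests

def _log_choose(n: int, k: int) -> float:
    if k < 0 or k > n:
        return -math.inf
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def _fisher_2xC(table: Sequence[Sequence[int]]) -> float:
    """Freeman-Halton exact p for a 2xC table by full enumeration.

    Conditional on all margins, the probability of a first row
    (a_1..a_C) is prod_j C(colsum_j, a_j) / C(N, rowsum_1); the two-sided
    p sums the probabilities of all tables no more probable than the
    observed one.
    """
    r1 = list(table[0])
    cols = [a + b for a, b in zip(table[0], table[1])]
    n1 = sum(r1)
    N = sum(cols)
    denom = _log_choose(N, n1)

    def log_prob(row) -> float:
        return sum(_log_choose(c, a) for c, a in zip(cols, row)) - denom

    obs = log_prob(r1)
    C = len(cols)
    p = 0.0

    def rec(j: int, rem: int, row: list[int]):
        nonlocal p
        if j == C - 1:
            if 0 <= rem <= cols[-1]:
                lp = log_prob(row + [rem])
                if lp <= obs + 1e-7:
                    p += math.exp(lp)
            return
        lo = max(0, rem - sum(cols[j + 1:]))
        for a in range(lo, min(rem, cols[j]) + 1):
            rec(j + 1, rem - a, row + [a])

    rec(0, n1, [])
    return min(p, 1.0)


def fisher_exact(table: Sequence[Sequence[int]]) -> float:
    """Two-sided exact p for a 2x2 or 2x3 contingency table.

    2x2 uses the standard hypergeometric two-sided rule (sum of tables
    with probability <= observed); 2x3 uses Freeman-Halton enumeration.
    A zero row or column margin returns p = 1 with a warning.
    """
    t = np.asarray(table, dtype=int)
    if t.shape[0] != 2 or t.shape[1] not in (2, 3):
        raise ValueError(f"expected a 2x2 or 2x3 table, got {t.shape}")
    if (t < 0).any():
        raise ValueError("negative counts")
    if (t.sum(axis=1) == 0).any() or (t.sum(axis=0) == 0).any():
        log.warning("degenerate margins in %s: p = 1", t.tolist())
        return 1.0
    if t.shape[1] == 2:
        return float(stats.fisher_exact(t, alternative="two-sided")[1])
    return _fisher_2xC(t)


# ---------------------------------------------------------------------------
# enrichment comparisons

@dataclass
class EnrichmentTable:
    counts: np.ndarray          # 2xC; row 0 specific lineages, row 1 comparison
    p: float
    construction: str           # e.g. '2x3:0/1/2+'


def enrichment_test(specific_hits: Iterable[int],
                    comparison_hits: Iterable[int],
                    construction: str = "2x3") -> EnrichmentTable:
    """Test whether pathogenic defining mutations are enriched.

    ``construction``: '2x3' classes lineages by 0/1/>=2 hits (the default,
    which reproduces the published comparison); '2x2_ge1' and '2x2_ge2'
    collapse to carrier / non-carrier at the 1 or 2 hit threshold.
    """
    s = hit_class_counts(specific_hits)
    c = hit_class_counts(comparison_hits)
    if construction == "2x3":
        tab = np.array([s, c])
    elif construction == "2x2_ge1":
        tab = np.array([[s[0], s[1] + s[2]], [c[0], c[1] + c[2]]])
    elif construction == "2x2_ge2":
        tab = np.array([[s[0] + s[1], s[2]], [c[0] + c[1], c[2]]])
    else:
        raise ValueError(f"unknown construction {construction!r}")
    return EnrichmentTable(counts=tab, p=fisher_exact(tab),
                           construction=construction)


def young_comparison(all_haplogroups: Sequence[HaplogroupClade],
                     lineages: Sequence[LineageRecord],
                     pathogenicity: Sequence[PathogenicityRecord],
                     rho_max: float = 1.0,
                     construction: str = "2x3") -> EnrichmentTable:
    """Enrichment test restricted to young comparison haplogroups (rho <= rho_max)."""
    young = [h for h in all_haplogroups if h.rho <= rho_max]
    if not young:
        raise ValueError(f"no comparison haplogroups with rho <= {rho_max}")
    table = {r.variant for r in pathogenicity}
    young_hits = [sum(1 for v in h.defining_variants if v in table) for h in young]
    spec_hits = [lin.pathogenic_hits for lin in lineages]
    return enrichment_test(spec_hits, young_hits, construction)


def classification_proportions(n_specific_individuals: int, n_random: int,
                               n_all_one: int, n_all_two_plus: int,
                               n_all: int) -> dict:
    """Percentage summaries of lineage-classification counts:
    specific-lineage individuals / random cohort, and the one / >=2
    pathogenic-hit fractions of the full haplogroup set."""
    return {
        "specific_individuals_pct": 100.0 * n_specific_individuals / n_random,
        "all_one_pct": 100.0 * n_all_one / n_all,
        "all_two_plus_pct": 100.0 * n_all_two_plus / n_all,
    }
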