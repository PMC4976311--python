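"""Founder identification, dating, age-distribution scan and wave partition.

A founder is the most recent common ancestor shared between the colonising
("sink") population and its source, under the least-stringent f0
eligibility criterion: a haplotype observed in both groups (case 1), or a
reconstructed ancestor with both sink and source immediate derivatives
(cases 2a/2b/2c).  Every sink sample is assigned to its most recent
founder ancestor, giving a partition into founder clusters.  Clusters are
dated with the rho statistic, their age distribution is scanned on a
200-year grid with Gaussian kernels, and extant lineages are fractionated
over candidate migration times with a per-cluster Poisson likelihood.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from mitofounder.phylogeny import ClockModel, Node, PhyloTree, Sample, rho_to_years


@dataclass
class FounderCluster:
    """One founder node with its assigned sink lineages."""

    node: Node
    case: str                    # '1', '2a', '2b' or '2c'
    samples: list[Sample]        # assigned sink samples
    m: int                       # total mutations over sink paths from founder
    rho: float
    sigma: float
    n_adj: Optional[int] = None
    age: Optional[float] = None
    age_sd: Optional[float] = None
    major: Optional[bool] = None

    @property
    def n(self) -> int:
        return len(self.samples)

    @property
    def populations(self) -> set[str]:
        return {s.population for s in self.samples}


def _own_and_derivatives(node: Node) -> tuple[list[Sample], list[Node]]:
    """Samples sitting on the node's own haplotype vs derived branches.

    A child leaf with no mutations on its stem carries the node's own
    (ancestral) haplotype; all other children are immediate derivatives.
    """
    own = list(node.samples)
    derivatives = []
    for ch in node.children:
        if ch.is_leaf and not ch.muts:
            own.extend(ch.samples)
        else:
            derivatives.append(ch)
    return own, derivatives


def identify_founders(tree: PhyloTree, f_criterion: str = "f0",
                      back_migration_whitelist: Iterable[str] = (),
                      clock: Optional[ClockModel] = None
                      ) -> list[FounderCluster]:
    """Identify founder clusters of sink lineages in a labelled phylogeny.

    Source samples inside whitelisted (back-migration) clades are ignored,
    so those clades remain sink-specific and do not spawn internal
    founders.
    """
    if f_criterion != "f0":
        raise NotImplementedError("only the f0 criterion is implemented")
    whitelist = set(back_migration_whitelist)
    all_samples = tree.samples()
    if not any(s.group == "sink" for s in all_samples):
        raise ValueError("no sink samples in tree")
    if not any(s.group == "source" for s in all_samples):
        raise ValueError("no source samples in tree")

    # group visibility below each node, masking whitelisted-clade sources
    has: dict[int, dict[str, bool]] = {}
    masked_at: dict[int, bool] = {}

    def scan(node: Node, masked: bool) -> dict[str, bool]:
        masked = masked or (node.name in whitelist)
        masked_at[id(node)] = masked
        h = {"sink": False, "source": False}
        for s in node.samples:
            if s.group == "source" and masked:
                continue
            h[s.group] = True
        for ch in node.children:
            sub = scan(ch, masked)
            h["sink"] |= sub["sink"]
            h["source"] |= sub["source"]
        has[id(node)] = dict(h)
        return h

    scan(tree.root, False)

    def founder_case(node: Node) -> Optional[str]:
        own, derivs = _own_and_derivatives(node)
        own_groups = {s.group for s in own}
        if masked_at[id(node)]:
            own_groups.discard("source")
        if {"sink", "source"} <= own_groups:
            return "1"
        d_sink = any(has[id(d)]["sink"] for d in derivs)
        d_source = any(has[id(d)]["source"] for d in derivs)
        if not own_groups and d_sink and d_source:
            return "2a"
        if own_groups == {"sink"} and d_source:
            return "2b"
        if own_groups == {"source"} and d_sink:
            return "2c"
        return None

    # assign each sink sample to its most recent founder ancestor
    clusters: dict[int, tuple[Node, str, list[tuple[Sample, int]]]] = {}

    def walk(node: Node, ancestry: list[tuple[Node, str, int]], depth_muts: int):
        """ancestry: (founder node, case, mutation count root->founder)."""
        case = founder_case(node)
        anc = ancestry + [(node, case, depth_muts)] if case else ancestry
        own, _ = _own_and_derivatives(node)
        for carrier in [node] + [ch for ch in node.children
                                 if ch.is_leaf and not ch.muts]:
            for s in carrier.samples:
                if s.group != "sink":
                    continue
                if anc:
                    fnode, fcase, fdepth = anc[-1]
                    key = id(fnode)
                    clusters.setdefault(key, (fnode, fcase, []))
                    clusters[key][2].append((s, depth_muts - fdepth))
        for ch in node.children:
            if ch.is_leaf and not ch.muts:
                continue  # handled as carrier of this node's haplotype
            walk(ch, anc, depth_muts + len(ch.muts))

    walk(tree.root, [], 0)

    out = []
    for fnode, fcase, pairs in clusters.values():
        samples = [s for s, _ in pairs]
        m = sum(d for _, d in pairs)
        n = len(samples)
        r = m / n
        sigma = _saillard_sigma(fnode, {s.id for s in samples})
        fc = FounderCluster(node=fnode, case=fcase, samples=samples,
                            m=m, rho=r, sigma=sigma)
        if clock is not None:
            fc.age, fc.age_sd = rho_to_years(r, sigma, clock)
        out.append(fc)
    out.sort(key=lambda c: (-c.n, c.node.name))
    return out


def _saillard_sigma(founder: Node, sample_ids: set[str]) -> float:
    """sigma = sqrt( sum_e (n_e/n)^2 m_e ) over edges below the founder,
    counting only the assigned sink samples."""
    counts: dict[int, int] = {}

    def below(node: Node) -> int:
        c = sum(1 for s in node.samples if s.id in sample_ids)
        c += sum(below(ch) for ch in node.children)
        counts[id(node)] = c
        return c

    n = below(founder)
    if n == 0:
        return 0.0
    var = 0.0
    for node in founder.postorder():
        if node is founder:
            continue
        var += (counts[id(node)] / n) ** 2 * len(node.muts)
    return math.sqrt(var)


def adjust_counts(clusters: Sequence[FounderCluster],
                  random_subset_ids: Iterable[str],
                  all_sink_ids: Optional[set[str]] = None
                  ) -> list[FounderCluster]:
    """Set n_adj = cluster membership restricted to a random sample subset."""
    subset = set(random_subset_ids)
    if all_sink_ids is not None:
        unknown = subset - all_sink_ids
        if unknown:
            raise ValueError(f"unknown subset ids: {sorted(unknown)[:5]}")
    for c in clusters:
        c.n_adj = sum(1 for s in c.samples if s.id in subset)
    return list(clusters)


def flag_major(clusters: Sequence[FounderCluster],
               freq_threshold: float, min_ethnic_groups: int = 3,
               subset_size: Optional[int] = None) -> list[FounderCluster]:
    """Major = high frequency in the random subset OR present in >=3 sink
    populations."""
    if not (0.0 <= freq_threshold <= 1.0):
        raise ValueError("freq_threshold outside [0,1]")
    for c in clusters:
        n_adj = c.n_adj if c.n_adj is not None else c.n
        denom = subset_size if subset_size else max(
            1, sum((x.n_adj if x.n_adj is not None else x.n) for x in clusters))
        freq = n_adj / denom
        c.major = (freq >= freq_threshold) or (len(c.populations) >= min_ethnic_groups)
    return list(clusters)


# ---------------------------------------------------------------------------
# founder-age scan

@dataclass
class FounderScan:
    ages: np.ndarray       # grid cell centres, years
    density: np.ndarray    # normalised to sum 1

    def peaks(self, min_density: float = 0.0) -> list[float]:
        """Ages of local maxima of the scan, in decreasing density order."""
        d = self.density
        idx = [i for i in range(len(d))
               if d[i] >= min_density
               and (i == 0 or d[i] > d[i - 1])
               and (i == len(d) - 1 or d[i] >= d[i + 1])]
        idx.sort(key=lambda i: -d[i])
        return [float(self.ages[i]) for i in idx]


def founder_scan(clusters: Sequence[FounderCluster],
                 clock: Optional[ClockModel] = None,
                 grid_max_years: float = 50_000.0,
                 grid_step_years: float = 200.0) -> FounderScan:
    """Weighted Gaussian-kernel scan of founder ages on a 200-year grid.

    density(t) propto sum_k w_k Normal(t; age_k, max(sd_k, grid step)),
    with weights w_k = n_adj (falling back to n).  The kernel SD is floored
    at one grid step so an exactly-dated founder does not collapse to a
    spike.
    """
    ages = np.arange(0.0, grid_max_years + grid_step_years / 2, grid_step_years)
    dens = np.zeros_like(ages)
    total_w = 0.0
    for c in clusters:
        w = c.n_adj if c.n_adj is not None else c.n
        if w == 0:
            continue
        if c.age is None:
            if clock is None:
                raise ValueError("clusters are undated and no clock given")
            c.age, c.age_sd = rho_to_years(c.rho, c.sigma, clock)
        sd = max(c.age_sd, grid_step_years)
        dens += w * stats.norm.pdf(ages, loc=c.age, scale=sd)
        total_w += w
    if total_w == 0:
        raise ValueError("all cluster weights are zero")
    dens /= dens.sum()
    return FounderScan(ages=ages, density=dens)


# ---------------------------------------------------------------------------
# migration-wave partition

@dataclass
class MigrationPartition:
    times: np.ndarray       # migration times tau_j, years
    fractions: np.ndarray   # p_j, sum to 1
    se: np.ndarray          # bootstrap standard errors

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"migration_time_y": self.times,
                             "fraction": self.fractions, "se": self.se})


def _posteriors(m: np.ndarray, n: np.ndarray, times: np.ndarray,
                ypm: float) -> np.ndarray:
    """P(migration j | cluster k) under a uniform prior, Poisson likelihood
    of the cluster's total mutation count m_k with mean n_k tau_j / ypm."""
    lam = np.outer(n, times) / ypm           # (K, J)
    logL = stats.poisson.logpmf(m[:, None], lam)
    logL -= logL.max(axis=1, keepdims=True)
    post = np.exp(logL)
    return post / post.sum(axis=1, keepdims=True)


def partition(clusters: Sequence[FounderCluster],
              migration_times_years: Sequence[float],
              clock: ClockModel, bootstrap_B: int = 1000,
              seed: Optional[int] = None) -> MigrationPartition:
    """Fractionate extant sink lineages over candidate migration times.

    p_j = sum_k n_adj,k P(j|k) / sum_k n_adj,k; SEs from a nonparametric
    bootstrap over clusters (resampled with replacement, weights carried).
    """
    times = np.asarray(sorted(migration_times_years), dtype=float)
    if times.size == 0:
        raise ValueError("empty migration time list")
    m = np.array([c.m for c in clusters], dtype=float)
    n = np.array([c.n for c in clusters], dtype=float)
    w = np.array([c.n_adj if c.n_adj is not None else c.n for c in clusters],
                 dtype=float)
    if w.sum() == 0:
        raise ValueError("zero total cluster weight")
    post = _posteriors(m, n, times, clock.years_per_mutation)
    p = (w[:, None] * post).sum(axis=0) / w.sum()

    if bootstrap_B > 0 and len(clusters) > 1:
        rng = np.random.default_rng(seed)
        K = len(clusters)
        reps = np.empty((bootstrap_B, times.size))
        for b in range(bootstrap_B):
            idx = rng.integers(0, K, size=K)
            wb = w[idx]
            if wb.sum() == 0:
                reps[b] = p
                continue
            reps[b] = (wb[:, None] * post[idx]).sum(axis=0) / wb.sum()
        se = reps.std(axis=0, ddof=1)
    else:
        se = np.zeros_like(times)
    return MigrationPartition(times=times, fractions=p, se=se)


# ---------------------------------------------------------------------------
# printed major-haplogroup table summaries

def load_major_haplogroup_table(path: Optional[str | Path] = None) -> pd.DataFrame:
    """Load the bundled 21-major-haplogroup frequency/age matrix."""
    if path is None:
        ref = resources.files("mitofounder.data") / "major_haplogroups.tsv"
        with resources.as_file(ref) as p:
            return pd.read_csv(p, sep="\t")
    return pd.read_csv(path, sep="\t")


ETHNIC_COLUMNS = ["tibetans", "dengs", "lhobas", "sherpas", "monpas"]


def summarize_major_haplogroups(df: Optional[pd.DataFrame] = None,
                                n_random: int = 432,
                                young_kya: float = 10.0,
                                min_ethnic_groups: int = 3) -> dict:
    """Coverage/sharing/age summaries of the major-haplogroup matrix.

    A haplogroup is *young* if either age estimate (rho-based or ML) falls
    below ``young_kya``; *shared* if present in at least
    ``min_ethnic_groups`` ethnic groups; the post-LGM shared group is the
    shared haplogroups that are not young.
    """
    if df is None:
        df = load_major_haplogroup_table()
    counts = df["highlanders"]
    shared_mask = (df[ETHNIC_COLUMNS] > 0).sum(axis=1) >= min_ethnic_groups
    young_mask = df[["t_rho_kya", "t_ml_kya"]].min(axis=1) < young_kya
    postlgm_mask = shared_mask & ~young_mask
    return {
        "n_major_haplogroups": int(len(df)),
        "coverage_pct": float(100.0 * counts.sum() / n_random),
        "n_shared_haplogroups": int(shared_mask.sum()),
        "n_shared_individuals": int(counts[shared_mask].sum()),
        "shared_pct": float(100.0 * counts[shared_mask].sum() / n_random),
        "n_postlgm_shared_haplogroups": int(postlgm_mask.sum()),
        "postlgm_shared_pct": float(100.0 * counts[postlgm_mask].sum() / n_random),
        "n_young_haplogroups": int(young_mask.sum()),
        "young_pct": float(100.0 * counts[young_mask].sum() / n_random),
    }
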