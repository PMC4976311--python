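"""Haploid Wright-Fisher forward simulation under purifying selection.

The simulator produces the null distribution of the internal/external N/S
ratio statistic under piecewise-constant demography.  Each generation,
parents are drawn multinomially with multiplicative fitness weights; new
mutations arrive Poisson(L mu) per individual and are classified
nonsynonymous with probability f_ns.  A fraction of nonsynonymous
mutations is under purifying selection with population-scaled coefficient
gamma (s = gamma / N_ref); a fraction of the selected mutations is lethal
(the carrier leaves no descendants and is never sampled).  At the end a
sample genealogy is reconstructed from parent pointers, typed mutation
counts are placed on its branches, and branches are binned by the rho of
the clade they subtend exactly as in the branch-based N/S analysis:
R = (N/S over rho bins 1..3) / (N/S over bin 0).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Epoch:
    duration: int      # generations
    size: int          # haploid population size

    def __post_init__(self):
        if self.size < 2:
            raise ValueError("population size must be >= 2")
        if self.duration < 1:
            raise ValueError("epoch duration must be >= 1")


@dataclass(frozen=True)
class DemographicModel:
    """Ordered epochs, past to present."""

    epochs: tuple[Epoch, ...]
    generation_time: float = 25.0

    @property
    def n_generations(self) -> int:
        return sum(e.duration for e in self.epochs)

    @property
    def initial_size(self) -> int:
        return self.epochs[0].size

    def sizes_by_generation(self) -> np.ndarray:
        return np.concatenate([np.full(e.duration, e.size, dtype=np.int64)
                               for e in self.epochs])

    @classmethod
    def constant(cls, size: int, generations: int) -> "DemographicModel":
        return cls(epochs=(Epoch(generations, size),))

    @classmethod
    def eastasia_like(cls, scale: float = 1.0) -> "DemographicModel":
        """Sustained growth to a large present size (approximate shape)."""
        f = scale
        return cls(epochs=(
            Epoch(max(1, int(400 * f)), max(2, int(2_000 * f))),
            Epoch(max(1, int(400 * f)), max(2, int(10_000 * f))),
            Epoch(max(1, int(400 * f)), max(2, int(50_000 * f))),
        ))

    @classmethod
    def eastasia_like_scaled(cls) -> "DemographicModel":
        """Desk-scale East Asian-like history (sizes capped at 2,000 while
        keeping enough generations for the sample genealogy to accumulate
        internal-branch mutations)."""
        return cls(epochs=(Epoch(250, 500), Epoch(150, 1_000), Epoch(150, 2_000)))

    @classmethod
    def highlander_like_scaled(cls) -> "DemographicModel":
        """Desk-scale highlander-like history: expansion, growth, crash,
        late boom, recent decline, sizes capped at 2,000."""
        return cls(epochs=(Epoch(150, 500), Epoch(120, 1_000), Epoch(100, 2_000),
                           Epoch(60, 400), Epoch(80, 2_000), Epoch(40, 250)))

    @classmethod
    def highlander_like(cls, scale: float = 1.0) -> "DemographicModel":
        """Expansion, post-glacial growth, crash, late boom, recent decline
        (approximate shape; sizes and durations scale together)."""
        f = scale
        return cls(epochs=(
            Epoch(max(1, int(600 * f)), max(2, int(1_000 * f))),    # ancient
            Epoch(max(1, int(400 * f)), max(2, int(20_000 * f))),   # pre-LGM plateau
            Epoch(max(1, int(400 * f)), max(2, int(50_000 * f))),   # post-LGM growth
            Epoch(max(1, int(120 * f)), max(2, int(8_000 * f))),    # crash
            Epoch(max(1, int(120 * f)), max(2, int(80_000 * f))),   # late boom
            Epoch(max(1, int(60 * f)),  max(2, int(4_600 * f))),    # recent decline
        ))


@dataclass
class SimulationConfig:
    seed: int
    L: int = 11_367
    # Per-generation rate rescaled upward for the desk-scale population
    # sizes (theta-preserving convention for scaled-down forward runs);
    # the unscaled biological rate is ~1.691e-8 /site/year * 25 y/gen.
    mu_per_site_per_gen: float = 2.0e-6
    f_ns: float = 0.7
    selected_fraction: float = 0.8
    gamma: float = -20.0                  # 0 => fully neutral
    lethal_fraction: float = 0.1          # SFS_CODE non-lethality 0.9
    sample_size: int = 300

    def __post_init__(self):
        for name in ("f_ns", "selected_fraction", "lethal_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} outside [0,1]")
        if self.L <= 0:
            raise ValueError("L must be positive")


class _SimNode:
    """Genealogy node; nN/nS are typed mutation counts on its stem."""

    __slots__ = ("children", "nN", "nS", "n_leaves")

    def __init__(self):
        self.children: list[_SimNode] = []
        self.nN = 0
        self.nS = 0
        self.n_leaves = 1

    def postorder(self):
        for c in self.children:
            yield from c.postorder()
        yield self


@dataclass
class SimulationRun:
    root: _SimNode
    sample_size: int
    n_extinction_restarts: int
    counts_by_bin: dict[int, tuple[int, int]]   # bin -> (N, S)
    R: Optional[float]                          # None when undefined

    @property
    def external_NS(self) -> tuple[int, int]:
        return self.counts_by_bin.get(0, (0, 0))

    def internal_NS(self, bins: tuple[int, int] = (1, 3)) -> tuple[int, int]:
        N = S = 0
        for b, (nb, sb) in self.counts_by_bin.items():
            if bins[0] <= b <= bins[1]:
                N += nb
                S += sb
        return N, S

    def mean_pairwise_differences(self) -> float:
        """Average pairwise mutation-count distance between sampled leaves,
        from branch leaf counts: sum_e m_e * 2 n_e (n - n_e) / (n (n-1))."""
        n = self.root.n_leaves
        if n < 2:
            return 0.0
        tot = 0.0
        for node in self.root.postorder():
            if node is self.root:
                continue
            m = node.nN + node.nS
            tot += m * 2.0 * node.n_leaves * (n - node.n_leaves)
        return tot / (n * (n - 1))


def _clade_rho(node: _SimNode) -> float:
    """Mean mutations from the clade root to each leaf (all types)."""
    total = 0.0
    for sub in node.postorder():
        if sub is node:
            continue
        total += (sub.nN + sub.nS) * sub.n_leaves
    return total / node.n_leaves


def rho_bin_counts(root: _SimNode, max_rho: int = 3) -> dict[int, tuple[int, int]]:
    """Per-rho-bin (N, S) totals; branch bin = round-half-up of the
    subtended clade's rho, capped at max_rho; leaves are bin 0."""
    out: dict[int, list[int]] = {}
    for node in root.postorder():
        if node is root:
            continue
        if node.children:
            b = min(int(math.floor(_clade_rho(node) + 0.5)), max_rho)
        else:
            b = 0
        acc = out.setdefault(b, [0, 0])
        acc[0] += node.nN
        acc[1] += node.nS
    return {b: (v[0], v[1]) for b, v in out.items()}


def ns_ratio_statistic(counts_by_bin: dict[int, tuple[int, int]],
                       internal_bins: tuple[int, int] = (1, 3)
                       ) -> Optional[float]:
    """R = (N/S internal) / (N/S external); None when any denominator is 0."""
    N_ext, S_ext = counts_by_bin.get(0, (0, 0))
    N_int = S_int = 0
    for b, (nb, sb) in counts_by_bin.items():
        if internal_bins[0] <= b <= internal_bins[1]:
            N_int += nb
            S_int += sb
    if S_ext == 0 or S_int == 0 or N_ext == 0:
        return None
    return (N_int / S_int) / (N_ext / S_ext)


def simulate(config: SimulationConfig, demography: DemographicModel,
             max_restarts: int = 10) -> SimulationRun:
    """Run one forward Wright-Fisher replicate and compute its statistic."""
    rng = np.random.default_rng(config.seed)
    restarts = 0
    while True:
        run = _simulate_once(config, demography, rng)
        if run is not None:
            run.n_extinction_restarts = restarts
            return run
        restarts += 1
        log.warning("population extinct (all fitness zero); restarting")
        if restarts > max_restarts:
            raise RuntimeError("repeated extinction; selection too strong")


def _simulate_once(config: SimulationConfig, demography: DemographicModel,
                   rng: np.random.Generator) -> Optional[SimulationRun]:
    sizes = demography.sizes_by_generation()
    T = len(sizes)
    N_ref = demography.initial_size
    s = config.gamma / N_ref if config.gamma != 0 else 0.0
    genome_mu = config.L * config.mu_per_site_per_gen

    fitness = np.ones(sizes[0], dtype=float)
    parents_hist: list[np.ndarray] = []
    newN_hist: list[np.ndarray] = []
    newS_hist: list[np.ndarray] = []

    for t in range(T):
        N_next = sizes[t]
        w = fitness
        tot = w.sum()
        if tot <= 0:
            return None
        parents = rng.choice(len(w), size=N_next, p=w / tot)

        n_mut = rng.poisson(genome_mu, size=N_next)
        n_ns = rng.binomial(n_mut, config.f_ns)
        n_s = n_mut - n_ns
        n_sel = rng.binomial(n_ns, config.selected_fraction) if s != 0 or \
            config.lethal_fraction > 0 else np.zeros_like(n_ns)
        n_lethal = rng.binomial(n_sel, config.lethal_fraction)
        n_del = n_sel - n_lethal

        fit_next = fitness[parents] * np.power(1.0 + s, n_del)
        fit_next[n_lethal > 0] = 0.0
        m = fit_next.max()
        if m > 0:
            fit_next = fit_next / m     # renormalise; only ratios matter

        parents_hist.append(parents.astype(np.int32))
        newN_hist.append(n_ns.astype(np.int16))
        newS_hist.append(n_s.astype(np.int16))
        fitness = fit_next

    alive = np.flatnonzero(fitness > 0)
    if alive.size == 0:
        return None
    k = min(config.sample_size, alive.size)
    sampled = rng.choice(alive, size=k, replace=False)

    # genealogy reconstruction from parent pointers
    lineages: dict[int, _SimNode] = {}
    for i in sampled:
        nd = _SimNode()
        nd.nN = int(newN_hist[-1][i])
        nd.nS = int(newS_hist[-1][i])
        lineages[int(i)] = nd
    for t in range(T - 1, -1, -1):
        parents = parents_hist[t]
        nextgen: dict[int, list[_SimNode]] = {}
        for i, nd in lineages.items():
            nextgen.setdefault(int(parents[i]), []).append(nd)
        merged: dict[int, _SimNode] = {}
        for p, nds in nextgen.items():
            if len(nds) == 1:
                nd = nds[0]
            else:
                nd = _SimNode()
                nd.children = nds
                nd.n_leaves = sum(c.n_leaves for c in nds)
            if t > 0:
                nd.nN += int(newN_hist[t - 1][p])
                nd.nS += int(newS_hist[t - 1][p])
            merged[p] = nd
        lineages = merged
        if len(lineages) == 1 and t == 0:
            break
    remaining = list(lineages.values())
    if len(remaining) == 1:
        root = remaining[0]
        # the root lineage's own stem mutations are above the sample MRCA
        root.nN = 0
        root.nS = 0
    else:
        root = _SimNode()
        root.children = remaining
        root.n_leaves = sum(c.n_leaves for c in remaining)

    counts = rho_bin_counts(root, max_rho=3)
    R = ns_ratio_statistic(counts)
    return SimulationRun(root=root, sample_size=k, n_extinction_restarts=0,
                         counts_by_bin=counts, R=R)


def exceedance(runs: Sequence[SimulationRun], R_obs: float = 1.129
               ) -> tuple[float, float, int]:
    """Fraction of valid runs with R >= R_obs, its binomial SE, and the
    number of valid (defined-R) runs; undefined-R runs are excluded."""
    valid = [r.R for r in runs if r.R is not None]
    if not valid:
        raise ValueError("no valid runs (all R undefined)")
    n = len(valid)
    p = sum(1 for r in valid if r >= R_obs) / n
    se = math.sqrt(p * (1 - p) / n)
    n_dropped = len(runs) - n
    if n_dropped:
        log.info("excluded %d runs with undefined R", n_dropped)
    return p, se, n
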