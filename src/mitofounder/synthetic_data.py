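"""Synthetic sink/source datasets with known founder events and planted
pathogenic variants.

The generator emulates the sampling structure of a high-altitude founder
study: a source-population phylogeny, K founder events at configured
times attaching sink clades, Poisson mutation accumulation under a
linear clock, five sink subpopulation labels, and optional planting of
pathogenic-flagged variants on lineage stems.  Everything the pipeline
consumes (sample table, annotated Newick, truth JSON) is emitted in the
pipeline's own input dialects, and a truth record retains the ground
truth for recovery tests.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from mitofounder.constants import MT_LENGTH, YEARS_PER_MUTATION_COMPLETE
from mitofounder.io import write_sample_table
from mitofounder.mito_model import Variant, load_reference, parse_variant
from mitofounder.phylogeny import (Node, PhyloTree, Sample,
                                   write_annotated_newick)

SINK_POPULATIONS = ("tibetan", "lhoba", "deng", "monpa", "sherpa")
SOURCE_POPULATIONS = ("han", "japanese", "korean", "dai")


@dataclass
class FounderEventSpec:
    """One migration wave: n_founders sink clades attached at time_years."""

    time_years: float
    n_founders: int
    mean_samples_per_founder: float = 7.0
    populations: Sequence[str] = SINK_POPULATIONS

    def __post_init__(self):
        if self.time_years <= 0:
            raise ValueError("founder times must be positive")


def default_waves() -> list[FounderEventSpec]:
    """Three-wave default emulating a pre-LGM / post-LGM / Neolithic history:
    5% of lineages at 30 kya, 30% at 16.8 kya, 65% at 8 kya."""
    return [
        FounderEventSpec(30_000.0, 3),
        FounderEventSpec(16_800.0, 18),
        FounderEventSpec(8_000.0, 39),
    ]


@dataclass
class GeneratorConfig:
    seed: int
    # enough source lineages that every wave finds a distinct source branch
    # alive at its event time (each founder consumes one spanning branch)
    n_source_lineages: int = 150
    source_root_age_years: float = 60_000.0
    founder_events: list[FounderEventSpec] = field(default_factory=default_waves)
    years_per_mutation: float = YEARS_PER_MUTATION_COMPLETE
    samples_per_source_leaf: int = 1
    # Forced minimum mutations on each sink-clade stem.  Useful when a test
    # needs every planted clade to be a detectable haplogroup (a clade with
    # no defining mutation is invisible to haplogroup enumeration), but it
    # inflates path lengths slightly, so dating studies leave it at 0.
    min_stem_mutations: int = 0
    pathogenic_planting: list[tuple[str, list[str]]] = field(default_factory=list)
    back_migration_rate: float = 0.0 # per-founder prob of one source contaminant
    recurrence_rate: float = 0.0     # per-mutation prob of reusing a used site
    # 'coalescent': sink clades coalesce below the founder (realistic
    # internal structure); 'star': all lineages radiate from the founder
    # (instant post-founding expansion, maximal dating precision)
    clade_shape: str = "coalescent"


@dataclass
class SyntheticDataset:
    tree: PhyloTree
    samples: list[Sample]
    profiles: dict[str, frozenset[Variant]]
    truth: dict

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_annotated_newick(self.tree, outdir / "tree.nwk")
        write_sample_table(outdir / "samples.tsv", self.samples, self.profiles)
        with open(outdir / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True)


class _MutationSampler:
    """Draws variant identities without positional collisions while fresh
    positions remain; an optional recurrence knob (and position
    exhaustion) reuses an existing variant, exercising the recurrent-site
    handling downstream."""

    def __init__(self, ref_seq: str, rng: np.random.Generator,
                 recurrence_rate: float = 0.0):
        self.ref = ref_seq
        self.rng = rng
        self.recurrence_rate = recurrence_rate
        self.used: dict[int, Variant] = {}
        self._used_list: list[Variant] = []
        self._fresh = list(rng.permutation(np.arange(1, MT_LENGTH + 1)))

    def reserve(self, v: Variant) -> None:
        """Pin a specific variant (planted token) at its position."""
        if v.position in self.used and self.used[v.position] != v:
            raise ValueError(f"planting collision at position {v.position}")
        if v.position not in self.used:
            self.used[v.position] = v
            self._used_list.append(v)

    def _recurrent(self) -> Variant:
        return self._used_list[int(self.rng.integers(len(self._used_list)))]

    def draw(self) -> Variant:
        if (self._used_list and self.recurrence_rate > 0
                and self.rng.random() < self.recurrence_rate):
            return self._recurrent()
        while self._fresh:
            pos = int(self._fresh.pop())
            if pos in self.used:
                continue
            ref = self.ref[pos - 1]
            alt = str(self.rng.choice([b for b in "ACGT" if b != ref]))
            v = Variant(pos, ref, alt)
            self.used[pos] = v
            self._used_list.append(v)
            return v
        return self._recurrent()

    def draw_n(self, n: int) -> list[Variant]:
        return [self.draw() for _ in range(n)]


def _random_coalescent(k: int, root_age: float, rng: np.random.Generator,
                       leaf_prefix: str) -> tuple[Node, dict[int, float]]:
    """Random binary coalescent topology: k leaves at age 0, internal node
    ages sorted uniforms in (0, root_age), root exactly at root_age."""
    ages: dict[int, float] = {}
    nodes = []
    for i in range(k):
        nd = Node(name=f"{leaf_prefix}L{i:03d}")
        ages[id(nd)] = 0.0
        nodes.append(nd)
    if k == 1:
        ages[id(nodes[0])] = 0.0
        return nodes[0], ages
    merge_ages = np.sort(rng.uniform(0.0, root_age, size=k - 1))
    merge_ages[-1] = root_age
    for age in merge_ages:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = Node(name="")
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        ages[id(parent)] = float(age)
        nodes[j] = parent
        nodes.pop(i)
    return nodes[0], ages


def generate(config: GeneratorConfig,
             ref_seq: Optional[str] = None) -> SyntheticDataset:
    """Generate a labelled sink/source dataset with known ground truth."""
    rng = np.random.default_rng(config.seed)
    if ref_seq is None:
        ref_seq = load_reference()
    sampler = _MutationSampler(ref_seq, rng, config.recurrence_rate)
    # pin planted tokens up front so background mutations cannot take the
    # same positions with different alleles
    for _selector, _tokens in config.pathogenic_planting:
        for tok in _tokens:
            sampler.reserve(parse_variant(tok))
    ypm = config.years_per_mutation

    # source phylogeny
    root, ages = _random_coalescent(config.n_source_lineages,
                                    config.source_root_age_years, rng, "SRC")
    root.name = "ROOT"

    # founder events: split a *source* branch alive at the event time
    # (sink clades attached earlier are never valid attachment points)
    source_ids = {id(n) for n in root.preorder()}
    truth_founders = []
    planting = dict(config.pathogenic_planting)
    for w, wave in enumerate(config.founder_events):
        tau = wave.time_years
        # branches alive at tau: age(child) < tau < age(parent)
        for f in range(wave.n_founders):
            candidates = []
            for node in root.preorder():
                for ch in node.children:
                    if id(ch) in source_ids and ages[id(ch)] < tau < ages[id(node)]:
                        candidates.append((node, ch))
            if not candidates:
                raise ValueError(f"no source branch alive at {tau} years")
            parent, child = candidates[int(rng.integers(len(candidates)))]
            fnode = Node(name=f"W{w}F{f:03d}anc")
            ages[id(fnode)] = tau
            source_ids.add(id(fnode))
            parent.children[parent.children.index(child)] = fnode
            fnode.parent = parent
            fnode.add_child(child)
            k = max(1, int(rng.poisson(wave.mean_samples_per_founder)))
            prefix = f"W{w}F{f:03d}"
            if config.clade_shape == "star" and k > 1:
                # immediate post-founding expansion: every sampled lineage
                # radiates straight from the founder haplotype, so paths
                # are independent and dating noise averages out fastest
                clade = Node(name=prefix)
                ages[id(clade)] = tau
                for i in range(k):
                    leaf = clade.add_child(Node(name=f"{prefix}L{i:03d}"))
                    ages[id(leaf)] = 0.0
            else:
                # the sink clade coalesces below the founder event, so the
                # stem branch (founder -> clade MRCA) has real duration and
                # its defining mutations accrue under the same Poisson
                # clock; every root-to-leaf path still spans tau years
                t_mrca = float(rng.uniform(0.5, 0.95) * tau) if k > 1 else 0.0
                clade, sub_ages = _random_coalescent(k, t_mrca, rng, prefix)
                clade.name = prefix
                ages.update(sub_ages)
            fnode.add_child(clade)
            pops = list(wave.populations)
            leaf_pops = [pops[int(rng.integers(len(pops)))]
                         for _ in clade.leaves()]
            truth_founders.append({
                "name": clade.name, "wave": w, "time_years": tau,
                "n_leaves": k, "populations": sorted(set(leaf_pops)),
                "leaf_populations": dict(zip(
                    (l.name for l in clade.leaves()), leaf_pops)),
            })

    # mutations: Poisson(branch duration / years-per-mutation) per branch
    def drop_mutations(node: Node):
        for ch in node.children:
            dur = ages[id(node)] - ages[id(ch)]
            n_mut = int(rng.poisson(max(dur, 0.0) / ypm))
            ch.muts = sampler.draw_n(n_mut)
            drop_mutations(ch)

    drop_mutations(root)

    # forced stem mutations so every sink clade is a detectable haplogroup
    tree = PhyloTree(root)
    by_name = {n.name: n for n in tree if n.name}
    for rec in truth_founders:
        nd = by_name[rec["name"]]
        while len(nd.muts) < config.min_stem_mutations:
            nd.muts.append(sampler.draw())
        rec["stem_mutations"] = sorted(str(v) for v in nd.muts)

    # planted pathogenic variants on selected stems (verbatim tokens)
    truth_planted = {}
    for selector, tokens in planting.items():
        if selector not in by_name:
            raise ValueError(f"planting selector {selector!r} matches no lineage")
        nd = by_name[selector]
        for tok in tokens:
            v = parse_variant(tok)
            sampler.reserve(v)
            nd.muts.append(v)
        truth_planted[selector] = sorted(tokens)

    # samples
    samples: list[Sample] = []
    leaf_pop: dict[str, str] = {}
    for rec in truth_founders:
        leaf_pop.update(rec["leaf_populations"])
    si = 0
    for leaf in tree.leaves():
        if leaf.name.startswith("SRC"):
            for _ in range(config.samples_per_source_leaf):
                pop = SOURCE_POPULATIONS[int(rng.integers(len(SOURCE_POPULATIONS)))]
                samples.append(Sample(id=f"E{si:04d}", population=pop,
                                      group="source", haplotype_id=leaf.name))
                si += 1
        else:
            samples.append(Sample(id=f"T{si:04d}", population=leaf_pop[leaf.name],
                                  group="sink", haplotype_id=leaf.name))
            si += 1

    # optional back-migration contamination: one source sample on a sink leaf
    contaminated = []
    for rec in truth_founders:
        if rng.random() < config.back_migration_rate:
            nd = by_name[rec["name"]]
            leaf = nd.leaves()[int(rng.integers(len(nd.leaves())))]
            samples.append(Sample(id=f"E{si:04d}", population="han",
                                  group="source", haplotype_id=leaf.name))
            si += 1
            contaminated.append(rec["name"])

    tree.attach_samples(samples)

    # haplotype profiles for the sample table
    profiles: dict[str, frozenset[Variant]] = {}
    for leaf in tree.leaves():
        if leaf.samples:
            hap = tree.haplotype_of(leaf)
            for s in leaf.samples:
                profiles[s.id] = hap

    n_sink = sum(1 for s in samples if s.group == "sink")
    wave_samples = {w: 0 for w in range(len(config.founder_events))}
    for rec in truth_founders:
        nd = by_name[rec["name"]]
        rec["n_samples"] = sum(1 for s in nd.clade_samples() if s.group == "sink")
        wave_samples[rec["wave"]] += rec["n_samples"]
    truth = {
        "seed": config.seed,
        "years_per_mutation": ypm,
        "waves": [{
            "time_years": wave.time_years,
            "n_founders": wave.n_founders,
            "n_samples": wave_samples[w],
            "proportion": wave_samples[w] / n_sink if n_sink else 0.0,
        } for w, wave in enumerate(config.founder_events)],
        "founders": truth_founders,
        "planted": truth_planted,
        "back_migrated": contaminated,
        "n_sink_samples": n_sink,
    }
    return SyntheticDataset(tree=tree, samples=samples, profiles=profiles,
                            truth=truth)


def wave_recovery_config(seed: int, scale: float = 1.0) -> GeneratorConfig:
    """Study conditions for founder-wave recovery on the 200-year grid.

    Three waves at 30.0 / 16.8 / 8.0 kya holding 5% / 30% / 65% of the
    sink lineages.  Peak-localisation error on the age grid scales as
    sqrt(years_per_mutation * tau / N_wave), so the study uses a
    dense-marker clock (200 years per mutation) and star-shaped founder
    clades (instant post-founding expansion) to make the 200-year grid
    informative at ~10,000 sink samples; the scan and partition machinery
    is clock-agnostic, so this validates the method, not mtDNA-specific
    precision.
    """
    return GeneratorConfig(
        seed=seed,
        n_source_lineages=max(60, int(400 * scale)),
        source_root_age_years=60_000.0,
        founder_events=[
            FounderEventSpec(30_000.0, max(2, int(12 * scale)),
                             mean_samples_per_founder=40.0),
            FounderEventSpec(16_800.0, max(2, int(72 * scale)),
                             mean_samples_per_founder=40.0),
            FounderEventSpec(8_000.0, max(2, int(156 * scale)),
                             mean_samples_per_founder=40.0),
        ],
        years_per_mutation=200.0,
        clade_shape="star",
    )


# ---------------------------------------------------------------------------
# case/control cohort emission

@dataclass
class CohortConfig:
    seed: int
    n_cases: int = 432
    n_controls: int = 367
    base_burden_mean: float = 2.8
    burden_shift: float = 0.0        # added to the case mean
    planted_sites: list[tuple[str, float, float]] = field(default_factory=list)
    # (variant token, case carrier freq, control carrier freq)


def emit_cohorts(config: CohortConfig,
                 pathogenic_pool: Sequence[Variant]
                 ) -> tuple[list[frozenset[Variant]], list[frozenset[Variant]]]:
    """Two cohorts of variant profiles with configured pathogenic-burden
    means and planted per-site carrier frequencies."""
    rng = np.random.default_rng(config.seed)
    planted = [(parse_variant(t), fc, fo) for t, fc, fo in config.planted_sites]
    for _, fc, fo in planted:
        if not (0 <= fc <= 1 and 0 <= fo <= 1):
            raise ValueError("planted carrier frequency outside [0,1]")
    planted_set = {v for v, _, _ in planted}
    pool = sorted(set(pathogenic_pool) - planted_set)
    if not pool:
        raise ValueError("empty background pathogenic pool")

    def cohort(n: int, mean: float, which: int) -> list[frozenset[Variant]]:
        out = []
        for _ in range(n):
            k = min(int(rng.poisson(mean)), len(pool))
            idx = rng.choice(len(pool), size=k, replace=False)
            prof = {pool[i] for i in idx}
            for v, fc, fo in planted:
                if rng.random() < (fc if which == 0 else fo):
                    prof.add(v)
            out.append(frozenset(prof))
        return out

    cases = cohort(config.n_cases, config.base_burden_mean + config.burden_shift, 0)
    controls = cohort(config.n_controls, config.base_burden_mean, 1)
    return cases, controls
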