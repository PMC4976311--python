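"""Case-control site association and per-individual pathogenic burden.

Site association: for every polymorphic site whose alternate allele is
pathogenic-annotated, a 2x2 carrier-count Fisher exact test between cases
and controls, with a Bonferroni-adjusted significance threshold
alpha / (number of tested sites).  Burden: per-sample counts of
pathogenic variants under three modes — the full pathogenicity catalogue,
a tRNA candidate list, or nonsynonymous variants above a Mutpred score
cutoff — compared between groups with the Mann-Whitney U test.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from mitofounder.mito_model import (PathogenicityRecord, Variant,
                                    parse_variant)


#: A sample's variant profile is simply the set of its Variants.
Profile = frozenset


def load_trna_candidates(path: Optional[str | Path] = None) -> set[Variant]:
    """tRNA pathogenicity candidate list (bundled synthetic fixture by default)."""
    if path is None:
        ref = resources.files("mitofounder.data") / "trna_pathogenic_synthetic.tsv"
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    return {parse_variant(t) for t in df["variant"]}


@dataclass
class SiteAssociationResult:
    variant: Variant
    case_carriers: int
    n_cases: int
    control_carriers: int
    n_controls: int
    p: float
    threshold: float
    significant: bool

    @property
    def fold(self) -> float:
        """Carrier-frequency fold change, cases over controls."""
        fc = self.case_carriers / self.n_cases
        fo = self.control_carriers / self.n_controls
        return np.inf if fo == 0 else fc / fo


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    return alpha / n_tests


def site_association(cases: Sequence[Profile], controls: Sequence[Profile],
                     pathogenicity: Sequence[PathogenicityRecord],
                     alpha: float = 0.05) -> list[SiteAssociationResult]:
    """Per-site carrier Fisher tests at pathogenic-annotated alleles.

    A carrier carries the pathogenic-annotated allele itself (position,
    ref and alt must match), not merely a non-reference base.  Tested
    sites are the pathogenic alleles polymorphic in the pooled cohorts;
    the Bonferroni threshold is alpha over their number.
    """
    if not cases or not controls:
        raise ValueError("empty cohort")
    pathogenic = {r.variant for r in pathogenicity}
    observed = set().union(*cases, *controls) if (cases or controls) else set()
    tested = sorted(pathogenic & observed)
    if not tested:
        return []
    thr = bonferroni_threshold(alpha, len(tested))
    out = []
    for v in tested:
        a = sum(1 for p in cases if v in p)
        b = sum(1 for p in controls if v in p)
        table = [[a, len(cases) - a], [b, len(controls) - b]]
        p = float(stats.fisher_exact(table, alternative="two-sided")[1])
        out.append(SiteAssociationResult(
            variant=v, case_carriers=a, n_cases=len(cases),
            control_carriers=b, n_controls=len(controls),
            p=p, threshold=thr, significant=p < thr))
    return out


def burden(profile: Iterable[Variant], mode: str,
           pathogenicity: Optional[Sequence[PathogenicityRecord]] = None,
           trna_list: Optional[set[Variant]] = None,
           mutpred_cutoff: Optional[float] = None) -> int:
    """Pathogenic burden of one sample profile.

    mode='mitomap': variants present in the filtered pathogenicity table;
    mode='trna':    variants present in the tRNA candidate list;
    mode='mutpred': nonsynonymous catalogue variants with Mutpred score
                    >= cutoff (cutoff in [0,1]).
    """
    prof = set(profile)
    if mode == "mitomap":
        return len(prof & {r.variant for r in pathogenicity})
    if mode == "trna":
        return len(prof & set(trna_list))
    if mode == "mutpred":
        if mutpred_cutoff is None or not (0.0 <= mutpred_cutoff <= 1.0):
            raise ValueError("mutpred mode needs a cutoff in [0,1]")
        scored = {r.variant for r in pathogenicity
                  if r.category == "nonsynonymous" and r.mutpred is not None
                  and r.mutpred >= mutpred_cutoff}
        return len(prof & scored)
    raise ValueError(f"unknown burden mode {mode!r}")


@dataclass
class BurdenResult:
    mode: str
    case_burdens: np.ndarray
    control_burdens: np.ndarray
    u: float
    p: float

    @property
    def case_mean_sd(self) -> tuple[float, float]:
        return float(self.case_burdens.mean()), float(self.case_burdens.std(ddof=1))

    @property
    def control_mean_sd(self) -> tuple[float, float]:
        return float(self.control_burdens.mean()), float(self.control_burdens.std(ddof=1))


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U: exact for small samples (n_x+n_y <= 12,
    no ties), otherwise tie-corrected normal approximation with continuity
    correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty input")
    exact = (x.size + y.size) <= 12 and np.unique(np.concatenate([x, y])).size == x.size + y.size
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="exact" if exact else "asymptotic",
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def compare_burdens(cases: Sequence[Profile], controls: Sequence[Profile],
                    mode: str, **kwargs) -> BurdenResult:
    cb = np.array([burden(p, mode, **kwargs) for p in cases], dtype=float)
    ob = np.array([burden(p, mode, **kwargs) for p in controls], dtype=float)
    u, p = mann_whitney(cb, ob)
    return BurdenResult(mode=mode, case_burdens=cb, control_burdens=ob, u=u, p=p)
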