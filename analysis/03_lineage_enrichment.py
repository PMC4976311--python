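#!/usr/bin/env python
"""Pathogenic-mutation enrichment on sink-specific lineages.

Generates a dataset with 22 planted sink-specific clades — five carrying
two planted pathogenic defining mutations and six carrying one,
mirroring the published pattern — classifies every
lineage's defining variants against the bundled pathogenicity catalogue,
and tests enrichment against the full set of qualifying haplogroups with
the 2x3 Freeman-Halton exact test.  Also evaluates the published
comparison table (11/6/5 specific lineages vs 6088/701/68 haplogroups by
0/1/>=2 pathogenic defining mutations).
"""
import argparse
from pathlib import Path

import pandas as pd

from mitofounder.lineage_enrichment import (classify_pathogenic,
                                            enrichment_test, fisher_exact,
                                            find_specific_lineages,
                                            young_comparison)
from mitofounder.mito_model import load_pathogenicity_table
from mitofounder.phylogeny import enumerate_haplogroups
from mitofounder.synthetic_data import (FounderEventSpec, GeneratorConfig,
                                        generate)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=20160808)
    ap.add_argument("--outdir", type=Path, default=Path("results/enrichment"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    # 22 planted sink-specific clades; five carry two pathogenic defining
    # mutations and six carry one, mirroring the published pattern
    planting = [
        ("W0F000", ["T3394C"]), ("W0F001", ["A636G", "T9101C"]),
        ("W0F002", ["G13708A"]), ("W0F003", ["C1192A", "A3397G"]),
        ("W0F004", ["G7598A", "G13708A"]), ("W0F005", ["T2352C", "T4363C"]),
        ("W0F006", ["G7697A"]), ("W0F007", ["T10454C"]),
        ("W0F008", ["T1005C"]), ("W0F009", ["T4216C", "A15924G"]),
        ("W0F010", ["A12634G"]),
    ]
    cfg = GeneratorConfig(
        seed=args.seed,
        founder_events=[FounderEventSpec(8000.0, 22,
                                         mean_samples_per_founder=12.0)],
        n_source_lineages=400, min_stem_mutations=1,
        pathogenic_planting=planting)
    ds = generate(cfg)
    pathogenicity = load_pathogenicity_table()

    lineages = find_specific_lineages(ds.tree)
    classify_pathogenic(lineages, pathogenicity)
    table = {r.variant for r in pathogenicity}
    by_var = {str(r.variant): r for r in pathogenicity}
    rows = []
    for lin in lineages:
        for v in lin.defining_variants:
            rec = by_var.get(str(v))
            if rec is None:
                continue
            rows.append({"lineage": lin.name, "variant": str(v),
                         "gene": rec.gene, "ci": rec.conservation_index,
                         "mutpred": rec.mutpred, "disease": rec.disease})
    pd.DataFrame(rows).to_csv(args.outdir / "pathogenic_defining.tsv",
                              sep="\t", index=False)
    print(f"{len(lineages)} sink-specific lineages; "
          f"{sum(1 for l in lineages if l.pathogenic_hits == 1)} with one and "
          f"{sum(1 for l in lineages if l.pathogenic_hits >= 2)} with >=2 "
          "pathogenic defining mutations")

    all_hg = enumerate_haplogroups(ds.tree)
    hg_hits = [sum(1 for v in h.defining_variants if v in table)
               for h in all_hg]
    res = enrichment_test([l.pathogenic_hits for l in lineages], hg_hits)
    print(f"enrichment vs all {len(all_hg)} qualifying haplogroups: "
          f"table {res.counts.tolist()}, Freeman-Halton p = {res.p:.3g}")
    young = young_comparison(all_hg, lineages, pathogenicity, rho_max=1.0)
    print(f"young-haplogroup (rho<=1) comparison: p = {young.p:.3g}")

    p_published = fisher_exact([[11, 6, 5], [6088, 701, 68]])
    print(f"published comparison table (11,6,5) vs (6088,701,68): "
          f"p = {p_published:.3g}")
    with open(args.outdir / "tests.tsv", "w") as fh:
        fh.write("comparison\tp\n")
        fh.write(f"synthetic_2x3\t{res.p}\n")
        fh.write(f"synthetic_young_rho_le1\t{young.p}\n")
        fh.write(f"published_2x3\t{p_published}\n")


if __name__ == "__main__":
    main()
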