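"""Sample-table I/O.

The sample table is a TSV with columns ``sample_id, population, group,
variants`` where ``variants`` is a space-separated list of substitution
tokens against the reference.  An optional ``haplotype`` column records
the leaf id of an accompanying tree; without it each sample is its own
haplotype (the profile then defines it).
"""
from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from mitofounder.mito_model import Variant, parse_variant
from mitofounder.phylogeny import Sample


def write_sample_table(path: str | Path, samples: Sequence[Sample],
                       profiles: dict[str, frozenset[Variant]]) -> None:
    rows = []
    for s in samples:
        toks = " ".join(sorted(str(v) for v in profiles[s.id]))
        rows.append((s.id, s.population, s.group, s.haplotype_id, toks))
    df = pd.DataFrame(rows, columns=["sample_id", "population", "group",
                                     "haplotype", "variants"])
    df.to_csv(path, sep="\t", index=False)


def read_sample_table(path: str | Path
                      ) -> tuple[list[Sample], dict[str, frozenset[Variant]]]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    samples, profiles = [], {}
    for row in df.itertuples(index=False):
        sid = str(row.sample_id)
        toks = str(row.variants).split()
        profiles[sid] = frozenset(parse_variant(t) for t in toks)
        hap = str(getattr(row, "haplotype", "") or sid)
        samples.append(Sample(id=sid, population=str(row.population),
                              group=str(row.group), haplotype_id=hap))
    return samples, profiles
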