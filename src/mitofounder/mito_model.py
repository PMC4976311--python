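"""Domain types for mtDNA variants, gene annotation and consequence calls.

Variants are single-nucleotide substitutions against a 16,569-bp circular
reference, written in the conventional ``T3394C`` notation (reference base,
1-based position, alternate base).  Protein-coding hits are translated
under the vertebrate mitochondrial genetic code; tRNA/rRNA hits are
classified ``rna`` and control-region hits ``control_region``.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from mitofounder.constants import MT_LENGTH, in_control_region

log = logging.getLogger(__name__)

_BASES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Vertebrate mitochondrial genetic code (NCBI translation table 2).
MITO_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "M", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "W", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "*", "AGG": "*",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


class VariantParseError(ValueError):
    """Malformed variant token."""


class PositionError(VariantParseError):
    """Position outside 1..16569."""


class DegenerateVariantError(VariantParseError):
    """Reference and alternate alleles are identical."""


class AnnotationError(ValueError):
    """Variant inconsistent with the reference or annotation."""


@dataclass(frozen=True, order=True)
class Variant:
    """One substitution against the circular reference."""

    position: int
    ref: str
    alt: str

    def __post_init__(self):
        if not (1 <= self.position <= MT_LENGTH):
            raise PositionError(f"position {self.position} outside 1..{MT_LENGTH}")
        if self.ref not in _BASES or self.alt not in _BASES:
            raise VariantParseError(f"alleles must be A/C/G/T: {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise DegenerateVariantError(f"ref == alt at {self.position}")

    def __str__(self) -> str:
        return f"{self.ref}{self.position}{self.alt}"


_TOKEN_RE = re.compile(r"^([ACGT])(\d+)([ACGT])")


def parse_variant(token: str) -> Variant:
    """Parse a ``T3394C``-style token, ignoring trailing annotation marks.

    Insertions/deletions/heteroplasmies (e.g. ``523d``, ``16093Y``) are
    rejected: only single-nucleotide substitutions are modelled.
    """
    m = _TOKEN_RE.match(token.strip())
    if not m:
        raise VariantParseError(f"malformed variant token: {token!r}")
    ref, pos, alt = m.group(1), int(m.group(2)), m.group(3)
    return Variant(pos, ref, alt)


def format_variant(v: Variant) -> str:
    return str(v)


@dataclass(frozen=True)
class GeneAnnotation:
    """One annotated feature on the linearised reference."""

    gene: str
    feature_type: str           # protein | tRNA | rRNA | control_region
    start: int                  # 1-based inclusive
    end: int
    frame_anchor: Optional[int] # codon-1 first base (protein only); for '-'
                                # strand genes the anchor is the *end*
    strand: str = "+"
    complex_label: str = "none" # I | III | IV | V | none

    def covers(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass(frozen=True)
class Consequence:
    """Functional consequence of a Variant within one feature."""

    gene: str
    category: str                     # synonymous | nonsynonymous | rna | control_region
    codon_index: Optional[int] = None # 1-based within gene (protein only)
    ref_aa: Optional[str] = None
    alt_aa: Optional[str] = None

    @property
    def label(self) -> str:
        if self.category in ("synonymous", "nonsynonymous") and self.codon_index:
            return f"{self.gene}({self.ref_aa}{self.codon_index}{self.alt_aa})"
        return self.gene


@dataclass(frozen=True)
class PathogenicityRecord:
    variant: Variant
    gene: str
    disease: str
    mutpred: Optional[float]
    conservation_index: Optional[float]
    category: str


def load_reference(path: Optional[str | Path] = None) -> str:
    """Load the reference sequence (bundled synthetic rCRS stand-in by default)."""
    if path is None:
        ref = resources.files("mitofounder.data") / "rcrs_synthetic.fasta"
        with resources.as_file(ref) as p:
            record = next(SeqIO.parse(str(p), "fasta"))
    else:
        record = next(SeqIO.parse(str(path), "fasta"))
    seq = str(record.seq).upper()
    if len(seq) != MT_LENGTH:
        raise AnnotationError(f"reference length {len(seq)} != {MT_LENGTH}")
    return seq


def load_gene_annotation(path: Optional[str | Path] = None) -> list[GeneAnnotation]:
    """Load the gene annotation TSV (bundled table by default).

    Columns: gene, type, start, end, frame_anchor, strand, complex.
    Unknown columns are ignored.
    """
    if path is None:
        ref = resources.files("mitofounder.data") / "gene_annotation.tsv"
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    for col in ("gene", "type", "start", "end"):
        if col not in df.columns:
            raise AnnotationError(f"gene annotation missing column {col!r}")
    out = []
    for row in df.itertuples(index=False):
        anchor = getattr(row, "frame_anchor", None)
        anchor = int(anchor) if pd.notna(anchor) and str(anchor) != "" else None
        out.append(GeneAnnotation(
            gene=row.gene,
            feature_type=row.type,
            start=int(row.start),
            end=int(row.end),
            frame_anchor=anchor,
            strand=getattr(row, "strand", "+") or "+",
            complex_label=str(getattr(row, "complex", "none")),
        ))
    return out


def _codon_at(ref_seq: str, ann: GeneAnnotation, position: int) -> tuple[int, int, str]:
    """Return (codon_index, offset-in-codon 0..2, codon string) in gene frame.

    Both are in the gene's reading direction.  Incomplete terminal codons
    (mtDNA stop codons completed by polyadenylation) are padded with 'A'.
    """
    if ann.strand == "+":
        off = position - ann.frame_anchor
        codon_index = off // 3 + 1
        within = off % 3
        c0 = ann.frame_anchor + (codon_index - 1) * 3  # 1-based first base
        bases = []
        for i in range(3):
            p = c0 + i
            bases.append(ref_seq[p - 1] if p <= ann.end else "A")
        return codon_index, within, "".join(bases)
    # light strand: gene read 3'->5' on the heavy strand, anchored at end
    off = ann.frame_anchor - position
    codon_index = off // 3 + 1
    within = off % 3
    c0 = ann.frame_anchor - (codon_index - 1) * 3
    bases = []
    for i in range(3):
        p = c0 - i
        bases.append(_COMPLEMENT[ref_seq[p - 1]] if p >= ann.start else "A")
    return codon_index, within, "".join(bases)


def classify_in_feature(v: Variant, ann: GeneAnnotation, ref_seq: str) -> Consequence:
    """Consequence of v within a single covering feature."""
    if ann.feature_type in ("tRNA", "rRNA"):
        return Consequence(gene=ann.gene, category="rna")
    if ann.feature_type == "control_region":
        return Consequence(gene=ann.gene, category="control_region")
    codon_index, within, codon = _codon_at(ref_seq, ann, v.position)
    if ann.strand == "+":
        alt_codon = codon[:within] + v.alt + codon[within + 1:]
    else:
        alt_codon = codon[:within] + _COMPLEMENT[v.alt] + codon[within + 1:]
    ref_aa = MITO_CODON_TABLE[codon]
    alt_aa = MITO_CODON_TABLE[alt_codon]
    category = "synonymous" if ref_aa == alt_aa else "nonsynonymous"
    return Consequence(gene=ann.gene, category=category, codon_index=codon_index,
                       ref_aa=ref_aa, alt_aa=alt_aa)


def classify_consequences(v: Variant, annotations: Iterable[GeneAnnotation],
                          ref_seq: str) -> list[Consequence]:
    """All consequences of a variant (one per covering feature).

    A variant in the ATP8/ATP6 or ND4L/ND4 overlap yields one call per gene.
    """
    if ref_seq[v.position - 1] != v.ref:
        raise AnnotationError(
            f"reference mismatch at {v.position}: expected {v.ref}, "
            f"reference has {ref_seq[v.position - 1]}")
    hits = [a for a in annotations if a.covers(v.position)]
    if not hits:
        if in_control_region(v.position):
            return [Consequence(gene="control_region", category="control_region")]
        raise AnnotationError(f"position {v.position} covered by no feature")
    return [classify_in_feature(v, a, ref_seq) for a in hits]


def classify_consequence(v: Variant, annotations: Iterable[GeneAnnotation],
                         ref_seq: str) -> Consequence:
    """Primary consequence of a variant.

    For overlap positions the calls are ranked: nonsynonymous in any frame
    dominates (conservative for N/S counting), then synonymous, then rna.
    """
    calls = classify_consequences(v, annotations, ref_seq)
    rank = {"nonsynonymous": 0, "synonymous": 1, "rna": 2, "control_region": 3}
    return min(calls, key=lambda c: rank[c.category])


def is_nonsynonymous(v: Variant, annotations: Iterable[GeneAnnotation],
                     ref_seq: str) -> bool:
    """OR rule across overlapping genes."""
    return any(c.category == "nonsynonymous"
               for c in classify_consequences(v, annotations, ref_seq))


def load_pathogenicity_table(path: Optional[str | Path] = None,
                             annotations: Optional[list[GeneAnnotation]] = None,
                             ref_seq: Optional[str] = None,
                             ) -> list[PathogenicityRecord]:
    """Load a MITOMAP-style pathogenicity TSV and filter it.

    Columns: ``variant, gene, disease, mutpred, ci`` (mutpred/ci may be
    empty; unknown columns ignored).  Records whose consequence against the
    reference is synonymous or control-region are removed, mirroring the
    curation of pathogenic-mutation catalogues ("synonymous and HVS
    mutations removed"); unparsable rows are skipped with a warning.
    """
    if path is None:
        ref = resources.files("mitofounder.data") / "pathogenicity_synthetic.tsv"
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    for col in ("variant", "gene", "disease"):
        if col not in df.columns:
            raise AnnotationError(f"pathogenicity table missing column {col!r}")
    if annotations is None:
        annotations = load_gene_annotation()
    if ref_seq is None:
        ref_seq = load_reference()

    records: list[PathogenicityRecord] = []
    n_skipped = n_syn = n_cr = 0
    for row in df.itertuples(index=False):
        try:
            v = parse_variant(str(row.variant))
        except VariantParseError as exc:
            n_skipped += 1
            log.warning("skipping pathogenicity row %r: %s", row.variant, exc)
            continue
        cons = classify_consequence(v, annotations, ref_seq)
        if cons.category == "synonymous":
            n_syn += 1
            continue
        if cons.category == "control_region":
            n_cr += 1
            continue
        mutpred = getattr(row, "mutpred", None)
        mutpred = float(mutpred) if pd.notna(mutpred) else None
        if mutpred is not None and not (0.0 <= mutpred <= 1.0):
            raise AnnotationError(f"Mutpred score {mutpred} outside [0,1]")
        ci = getattr(row, "ci", None)
        ci = float(ci) if pd.notna(ci) else None
        records.append(PathogenicityRecord(
            variant=v, gene=str(row.gene), disease=str(row.disease),
            mutpred=mutpred, conservation_index=ci, category=cons.category))
    log.info("pathogenicity table: %d kept, %d synonymous removed, "
             "%d control-region removed, %d unparsable skipped",
             len(records), n_syn, n_cr, n_skipped)
    return records
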