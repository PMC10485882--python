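"""Core domain types shared across the pipeline.

Coordinates are 1-based inclusive everywhere at module boundaries,
matching GTF and VCF conventions.  Gene/circRNA models are strand-aware:
"upstream" and "downstream" flanks follow the direction of transcription,
not genomic coordinate order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

BASES = ("A", "C", "G", "T")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Default size of the gene flanking window, in bp, used both for
#: variant-to-gene assignment ("up 10 kb" / "down 10 kb" regions) and for
#: window SNV collection in the association test.
DEFAULT_FLANK_BP = 10_000


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


@dataclass(frozen=True)
class VariantRecord:
    """A single bi-allelic SNV with per-sample allele depths.

    ``per_sample`` maps sample name to ``(ref_depth, alt_depth)``.  The
    per-sample mutation frequency is ``alt / (ref + alt)``; it is
    *undefined* (``None``) when the total depth is below ``min_depth`` —
    absence of coverage is never conflated with an observed zero.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    per_sample: Mapping[str, tuple[int, int]]

    def __post_init__(self) -> None:
        if self.ref not in BASES or self.alt not in BASES:
            raise ValueError(f"non-SNV alleles {self.ref!r}>{self.alt!r} at {self.chrom}:{self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        for sample, (rd, ad) in self.per_sample.items():
            if rd < 0 or ad < 0:
                raise ValueError(f"negative depth for sample {sample} at {self.chrom}:{self.pos}")

    @property
    def variant_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"

    def total_depth(self, sample: str) -> int:
        rd, ad = self.per_sample[sample]
        return rd + ad

    def frequency(self, sample: str, min_depth: int = 1) -> Optional[float]:
        """Mutation frequency for one sample, or None if depth < min_depth."""
        rd, ad = self.per_sample[sample]
        total = rd + ad
        if total < max(min_depth, 1):
            return None
        return ad / total


Interval = tuple[int, int]  # 1-based inclusive


def _check_intervals(ivs: Sequence[Interval], label: str) -> None:
    for s, e in ivs:
        if s > e:
            raise ValueError(f"{label} interval ({s}, {e}) has start > end")
    for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
        if s2 <= e1:
            raise ValueError(f"{label} intervals overlap or are unsorted: ({s1},{e1}) vs ({s2},{e2})")


@dataclass
class GeneModel:
    """Strand-aware single-transcript gene model.

    Built from the representative transcript of a gene (longest CDS).
    ``cds`` includes the stop codon, so its total length is divisible by
    3 and stop-codon substitutions are classifiable (stop->stop silent,
    stop->sense missense).
    """

    gene_id: str
    biotype: str  # "coding" | "lncRNA" | "miRNA"
    chrom: str
    strand: str  # "+" | "-"
    exons: list[Interval]
    cds: list[Interval] = field(default_factory=list)
    utr5: list[Interval] = field(default_factory=list)
    utr3: list[Interval] = field(default_factory=list)
    transcript_id: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: invalid strand {self.strand!r}")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: no exons")
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        self.utr5 = sorted(self.utr5)
        self.utr3 = sorted(self.utr3)
        _check_intervals(self.exons, f"{self.gene_id} exon")
        _check_intervals(self.cds, f"{self.gene_id} CDS")
        if self.biotype == "coding":
            if self.cds_length % 3 != 0:
                raise ValueError(
                    f"{self.gene_id}/{self.transcript_id}: CDS length {self.cds_length} not divisible by 3"
                )
        for s, e in self.cds:
            if not any(xs <= s and e <= xe for xs, xe in self.exons):
                raise ValueError(f"{self.gene_id}: CDS interval ({s},{e}) not contained in an exon")

    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    @property
    def exonic_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    def flank_up(self, window: int = DEFAULT_FLANK_BP) -> Interval:
        """Transcription-upstream window, outside the span, clipped at 1."""
        s, e = self.span
        if self.strand == "+":
            return (max(1, s - window), s - 1)
        return (e + 1, e + window)

    def flank_down(self, window: int = DEFAULT_FLANK_BP) -> Interval:
        s, e = self.span
        if self.strand == "+":
            return (e + 1, e + window)
        return (max(1, s - window), s - 1)


@dataclass
class CircModel:
    """A circRNA as the back-spliced exon set of its host gene."""

    circ_id: str
    host_gene_id: str
    chrom: str
    strand: str
    exons: list[Interval]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.circ_id}: empty exon set")
        self.exons = sorted(self.exons)
        _check_intervals(self.exons, f"{self.circ_id} exon")

    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def exonic_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    def flank_up(self, window: int = DEFAULT_FLANK_BP) -> Interval:
        s, e = self.span
        return (max(1, s - window), s - 1) if self.strand == "+" else (e + 1, e + window)

    def flank_down(self, window: int = DEFAULT_FLANK_BP) -> Interval:
        s, e = self.span
        return (e + 1, e + window) if self.strand == "+" else (max(1, s - window), s - 1)


RNA_CLASSES = ("mRNA", "circRNA", "lncRNA", "miRNA")
#: Normalization unit per RNA class, following common practice for each
#: assay: length-normalized FPKM for polyadenylated/long RNAs, reads per
#: million back-splice reads for circRNA, tags per million for miRNA.
NORM_UNITS = {"mRNA": "FPKM", "lncRNA": "FPKM", "circRNA": "RPM", "miRNA": "TPM"}


@dataclass
class ExpressionMatrix:
    """Raw (and optionally normalized) counts for one RNA class."""

    rna_class: str
    counts: pd.DataFrame  # features x samples, raw counts
    groups: pd.Series  # sample -> group label
    lengths: Optional[pd.Series] = None  # feature -> exonic length in bp
    normalized: Optional[pd.DataFrame] = None
    norm_unit: Optional[str] = None

    def __post_init__(self) -> None:
        if self.rna_class not in RNA_CLASSES:
            raise ValueError(f"unknown RNA class {self.rna_class!r}")
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        missing = set(self.counts.columns) - set(self.groups.index)
        if missing:
            raise ValueError(f"samples without a group label: {sorted(missing)}")
        self.groups = self.groups.loc[list(self.counts.columns)]
        if self.lengths is not None:
            lacking = set(self.counts.index) - set(self.lengths.index)
            if lacking:
                raise ValueError(f"features without a length: {sorted(lacking)[:5]} ...")
            self.lengths = self.lengths.loc[list(self.counts.index)].astype(float)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def features(self) -> list[str]:
        return list(self.counts.index)

    def samples_in_groups(self, group_labels: Sequence[str]) -> list[str]:
        wanted = set(group_labels)
        return [s for s in self.samples if self.groups[s] in wanted]

    def log2_normalized(self, pseudocount: float = 0.5) -> pd.DataFrame:
        if self.normalized is None:
            raise ValueError("matrix is not normalized yet; call expression.normalize first")
        return np.log2(self.normalized + pseudocount)
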