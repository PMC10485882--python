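"""Variant-to-feature region assignment and coding-effect classification.

Each SNV is assigned exactly one region per feature, by specificity:
CDS exon > 5'UTR > 3'UTR > non-coding exon > intron > up-10kb >
down-10kb.  CDS variants are further classified silent / missense /
nonsense by splicing the CDS in transcript order (reverse-complemented
for minus-strand genes) and translating with the standard genetic code.
Stop-retaining changes count as silent and stop-loss as missense, so the
three classes form a partition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .models import (
    BASES,
    COMPLEMENT,
    DEFAULT_FLANK_BP,
    CircModel,
    GeneModel,
    VariantRecord,
)

REGIONS = ("exon", "utr5", "utr3", "intron", "up10kb", "down10kb")

STOP_CODONS = tuple(sorted(standard_dna_table.stop_codons))
SENSE_CODONS = tuple(sorted(standard_dna_table.forward_table))  # 61 codons


@dataclass(frozen=True)
class RegionCall:
    feature_id: str
    region: str
    #: lower = more specific; used to pick a host among overlapping genes
    rank: int
    multi_gene: bool = False


@dataclass(frozen=True)
class CodingEffect:
    effect: str  # "silent" | "missense" | "nonsense"
    codon_before: str
    codon_after: str
    aa_before: str
    aa_after: str
    cds_codon_index: int


class ReferenceMismatchError(ValueError):
    def __init__(self, chrom: str, pos: int, expected: str, found: str):
        super().__init__(
            f"reference mismatch at {chrom}:{pos}: variant ref {expected!r}, genome has {found!r}"
        )
        self.expected = expected
        self.found = found


def _in_any(pos: int, intervals: Sequence[tuple[int, int]]) -> bool:
    return any(s <= pos <= e for s, e in intervals)


def region_rank(pos: int, model: GeneModel | CircModel, window: int = DEFAULT_FLANK_BP) -> Optional[tuple[str, int]]:
    """(region, specificity rank) of a position relative to one feature,
    or None when the position is outside span +/- window.

    circRNA models only distinguish exon vs intron between their
    back-splice coordinates.
    """
    if isinstance(model, CircModel):
        s, e = model.span
        if s <= pos <= e:
            return ("exon", 3) if _in_any(pos, model.exons) else ("intron", 4)
        return None
    s, e = model.span
    if s <= pos <= e:
        if _in_any(pos, model.cds):
            return ("exon", 0)
        if _in_any(pos, model.utr5):
            return ("utr5", 1)
        if _in_any(pos, model.utr3):
            return ("utr3", 2)
        if _in_any(pos, model.exons):
            return ("exon", 3)
        return ("intron", 4)
    fs, fe = model.flank_up(window)
    if fs <= pos <= fe:
        return ("up10kb", 5)
    fs, fe = model.flank_down(window)
    if fs <= pos <= fe:
        return ("down10kb", 6)
    return None


def assign_region(
    variant: VariantRecord, model: GeneModel | CircModel, window: int = DEFAULT_FLANK_BP
) -> Optional[RegionCall]:
    """Single region call for one (variant, feature) pair, or None."""
    if variant.chrom != model.chrom:
        return None
    hit = region_rank(variant.pos, model, window)
    if hit is None:
        return None
    region, rank = hit
    feature_id = model.circ_id if isinstance(model, CircModel) else model.gene_id
    return RegionCall(feature_id=feature_id, region=region, rank=rank)


class GeneIndex:
    """Interval-tree lookup of gene models by span +/- window."""

    def __init__(self, models: Sequence[GeneModel], window: int = DEFAULT_FLANK_BP):
        from intervaltree import IntervalTree

        self.window = window
        self.models = list(models)
        self._trees: dict[str, "IntervalTree"] = {}
        for m in models:
            s, e = m.span
            tree = self._trees.setdefault(m.chrom, IntervalTree())
            tree.addi(max(1, s - window), e + window + 1, m)

    def overlapping(self, chrom: str, pos: int) -> list[GeneModel]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree.at(pos)]


def assign_best_host(
    pos: int,
    chrom: str,
    models: "Sequence[GeneModel] | GeneIndex",
    window: int = DEFAULT_FLANK_BP,
) -> list[tuple[GeneModel, str, int]]:
    """Hosts whose window covers the position, restricted to the most
    specific region observed; more than one entry means a multi-gene tie."""
    if isinstance(models, GeneIndex):
        if models.window != window:
            raise ValueError("GeneIndex window does not match the requested window")
        candidates = models.overlapping(chrom, pos)
    else:
        candidates = [m for m in models if m.chrom == chrom]
    hits = []
    for m in candidates:
        rr = region_rank(pos, m, window)
        if rr is not None:
            hits.append((m, rr[0], rr[1]))
    if not hits:
        return []
    best = min(rank for _, _, rank in hits)
    return [h for h in hits if h[2] == best]


# ---------------------------------------------------------------------------
# Coding effects

def spliced_cds(model: GeneModel, genome: Mapping[str, str]) -> str:
    """CDS sequence in transcript (5'->3') order, stop codon included."""
    chrom_seq = genome[model.chrom]
    pieces = [chrom_seq[s - 1 : e] for s, e in model.cds]
    if model.strand == "+":
        return "".join(pieces)
    return "".join(str(Seq(p).reverse_complement()) for p in reversed(pieces))


def _cds_offset(model: GeneModel, pos: int) -> Optional[int]:
    """0-based offset of a genomic position within the spliced CDS."""
    if model.strand == "+":
        off = 0
        for s, e in model.cds:
            if s <= pos <= e:
                return off + (pos - s)
            off += e - s + 1
        return None
    off = 0
    for s, e in reversed(model.cds):
        if s <= pos <= e:
            return off + (e - pos)
        off += e - s + 1
    return None


def _translate(codon: str) -> str:
    return str(Seq(codon).translate())  # "*" for stop


def _classify_codon_change(codon_before: str, codon_after: str) -> str:
    aa_b, aa_a = _translate(codon_before), _translate(codon_after)
    if aa_b == aa_a:
        return "silent"
    if aa_b != "*" and aa_a == "*":
        return "nonsense"
    return "missense"  # includes stop-loss


def coding_effect(
    variant: VariantRecord, model: GeneModel, genome: Mapping[str, str]
) -> CodingEffect:
    """Classify a CDS SNV as silent / missense / nonsense.

    The affected codon is reconstructed from the spliced CDS, so codons
    spanning exon junctions are handled transparently.  Raises
    ReferenceMismatchError when the genome disagrees with the variant's
    REF allele, and ValueError when the variant is outside the CDS.
    """
    genome_base = genome[model.chrom][variant.pos - 1]
    if genome_base != variant.ref:
        raise ReferenceMismatchError(variant.chrom, variant.pos, variant.ref, genome_base)
    offset = _cds_offset(model, variant.pos)
    if offset is None:
        raise ValueError(f"variant {variant.variant_id} is not inside the CDS of {model.gene_id}")
    cds = spliced_cds(model, genome)
    tx_ref = variant.ref if model.strand == "+" else COMPLEMENT[variant.ref]
    tx_alt = variant.alt if model.strand == "+" else COMPLEMENT[variant.alt]
    assert cds[offset] == tx_ref, "spliced CDS disagrees with genome"
    ci = offset // 3
    within = offset % 3
    codon_before = cds[ci * 3 : ci * 3 + 3]
    codon_after = codon_before[:within] + tx_alt + codon_before[within + 1 :]
    return CodingEffect(
        effect=_classify_codon_change(codon_before, codon_after),
        codon_before=codon_before,
        codon_after=codon_after,
        aa_before=_translate(codon_before),
        aa_after=_translate(codon_after),
        cds_codon_index=ci,
    )


def enumerate_effect_space(substitution: tuple[str, str]) -> dict[str, int]:
    """Exhaustive silent/missense/nonsense counts for one substitution
    over all 61 sense codons x positions carrying the source base.

    Serves as the independent oracle for coding_effect: e.g. A->G (the
    A-to-I channel) can never create a stop codon, while C->T (C-to-U)
    creates one exactly from CAA, CAG and CGA.
    """
    src, dst = substitution
    if src not in BASES or dst not in BASES or src == dst:
        raise ValueError(f"invalid substitution {substitution!r}")
    counts = {"silent": 0, "missense": 0, "nonsense": 0}
    for codon in SENSE_CODONS:
        for i in range(3):
            if codon[i] != src:
                continue
            after = codon[:i] + dst + codon[i + 1 :]
            counts[_classify_codon_change(codon, after)] += 1
    return counts


def tally_regions(assignments: Sequence[tuple[str, str]]) -> pd.DataFrame:
    """Fraction table from (editing_class, region) pairs.

    Fractions are within each editing class and sum to 1 per class.
    """
    if not assignments:
        return pd.DataFrame(columns=["editing_class", "region", "count", "fraction"])
    df = pd.DataFrame(assignments, columns=["editing_class", "region"])
    out = df.groupby(["editing_class", "region"], sort=True).size().rename("count").reset_index()
    totals = out.groupby("editing_class")["count"].transform("sum")
    out["fraction"] = out["count"] / totals
    return out
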