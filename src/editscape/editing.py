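"""Strand-aware classification of off-target SNVs into editing channels.

A deaminated adenosine (inosine) is read as G, so an A-to-I event shows
up as A->G on the transcribed strand: genomic A->G for a plus-strand
host, T->C for a minus-strand host.  C-to-U is likewise C->T on the
transcribed strand.  Everything else is "other".  A site covered by
genes on both strands whose strand-resolved classes disagree is
"ambiguous" and is kept for genome-wide distributions but excluded from
coding-effect and association analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .annotation import GeneIndex, assign_best_host
from .models import DEFAULT_FLANK_BP, GeneModel, VariantRecord

EDITING_CLASSES = ("A_to_I", "C_to_U", "other", "ambiguous")

#: transcript-strand substitution -> editing channel
_TX_CLASS = {("A", "G"): "A_to_I", ("C", "T"): "C_to_U"}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def strand_class(ref: str, alt: str, strand: str) -> str:
    """Editing channel of a genomic substitution seen from one strand."""
    if strand == "-":
        ref, alt = _COMP[ref], _COMP[alt]
    return _TX_CLASS.get((ref, alt), "other")


@dataclass(frozen=True)
class EditingEvent:
    variant: VariantRecord
    editing_class: str
    resolved_strand: str  # "+", "-", or "none"
    host_gene_id: Optional[str]
    region: Optional[str] = None
    multi_gene: bool = False


def classify_editing(
    variant: VariantRecord,
    gene_models: "Sequence[GeneModel] | GeneIndex",
    window: int = DEFAULT_FLANK_BP,
) -> EditingEvent:
    """Classify one SNV against all hosts whose span +/- window covers it.

    Hostless variants are classified on the plus-strand convention and
    flagged host=None, so genome-wide tallies drop nothing.
    """
    hosts = assign_best_host(variant.pos, variant.chrom, gene_models, window)
    if not hosts:
        return EditingEvent(
            variant=variant,
            editing_class=strand_class(variant.ref, variant.alt, "+"),
            resolved_strand="none",
            host_gene_id=None,
        )
    strands = {m.strand for m, _, _ in hosts}
    classes = {strand_class(variant.ref, variant.alt, s) for s in strands}
    if len(classes) > 1:
        return EditingEvent(
            variant=variant,
            editing_class="ambiguous",
            resolved_strand="none",
            host_gene_id=None,
            multi_gene=len(hosts) > 1,
        )
    host, region, _ = hosts[0]
    return EditingEvent(
        variant=variant,
        editing_class=classes.pop(),
        resolved_strand=host.strand,
        host_gene_id=host.gene_id,
        region=region,
        multi_gene=len(hosts) > 1,
    )


@dataclass
class EfficiencyResult:
    per_sample: dict[str, Optional[float]]
    group_means: dict[str, Optional[float]]
    excluded_samples: list[str]


def editing_efficiency(
    variant: VariantRecord, groups: Mapping[str, str]
) -> EfficiencyResult:
    """Per-sample editing fraction alt/(ref+alt) and unweighted group
    means over replicates; zero-coverage samples are excluded and listed.
    """
    per_sample: dict[str, Optional[float]] = {}
    excluded: list[str] = []
    for sample in variant.per_sample:
        f = variant.frequency(sample)
        per_sample[sample] = f
        if f is None:
            excluded.append(sample)
    group_means: dict[str, Optional[float]] = {}
    for group in dict.fromkeys(groups.values()):
        vals = [
            per_sample[s]
            for s, g in groups.items()
            if g == group and s in per_sample and per_sample[s] is not None
        ]
        group_means[group] = float(np.mean(vals)) if vals else None
    return EfficiencyResult(per_sample=per_sample, group_means=group_means, excluded_samples=excluded)


@dataclass
class DistributionSummary:
    editing_class: str
    total: int
    per_chromosome: dict[str, list[tuple[int, float]]] = field(default_factory=dict)
    chi2: Optional[float] = None
    chi2_pvalue: Optional[float] = None

    @property
    def counts(self) -> dict[str, int]:
        return {c: len(v) for c, v in self.per_chromosome.items()}


def summarize_distribution(
    events: Sequence[EditingEvent],
    editing_class: str,
    chrom_lengths: Optional[Mapping[str, int]] = None,
    treated_samples: Optional[Sequence[str]] = None,
) -> DistributionSummary:
    """Chromosome-wise event positions/frequencies for one channel, with
    a chi-square test of uniformity against chromosome lengths.

    The per-site frequency is the mean defined frequency over the
    treated samples (all samples when none are given) — the quantity a
    Manhattan-style plot would show on the y axis.
    """
    selected = [ev for ev in events if ev.editing_class == editing_class]
    per_chrom: dict[str, list[tuple[int, float]]] = {}
    for ev in selected:
        samples = treated_samples if treated_samples is not None else list(ev.variant.per_sample)
        freqs = [f for s in samples if (f := ev.variant.frequency(s)) is not None]
        mean_f = float(np.mean(freqs)) if freqs else 0.0
        per_chrom.setdefault(ev.variant.chrom, []).append((ev.variant.pos, mean_f))
    for sites in per_chrom.values():
        sites.sort()
    summary = DistributionSummary(
        editing_class=editing_class, total=len(selected), per_chromosome=per_chrom
    )
    if chrom_lengths and selected:
        chroms = sorted(chrom_lengths)
        observed = np.array([len(per_chrom.get(c, [])) for c in chroms], dtype=float)
        lengths = np.array([chrom_lengths[c] for c in chroms], dtype=float)
        expected = observed.sum() * lengths / lengths.sum()
        chi2, p = sps.chisquare(observed, expected)
        summary.chi2, summary.chi2_pvalue = float(chi2), float(p)
    return summary
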