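"""Synthetic data with the statistical structure the analysis assumes.

The generator emulates the study design end to end: three treated
editing conditions (CTNNB1, KRAS, non-target) plus eGFP and wild-type
controls with three replicates each; an Ensembl-style annotation of
coding, lncRNA and miRNA genes with circRNAs as back-spliced exon
subsets; planted strand-consistent A-to-I and C-to-U off-target events
at roughly 20x coverage with Beta-distributed editing frequencies and
exactly-zero control alt depths; negative-binomial count matrices with
planted differential expression; and planted SNV-frequency/expression
couplings.  A ground-truth sidecar records every planted event exactly
once so each downstream stage can be verified against it.

The emitted variant table emulates the post-selection callset (only
sites meeting the coverage standard are reported), so per-sample depths
are drawn from a Poisson truncated below at the coverage floor.

Randomness: one global seed, split into named per-stage substreams, so
stages can be regenerated independently and reproducibly.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from itertools import product
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import io_formats
from .annotation import coding_effect
from .editing import strand_class
from .models import (
    COMPLEMENT,
    DEFAULT_FLANK_BP,
    CircModel,
    ExpressionMatrix,
    GeneModel,
    VariantRecord,
    revcomp,
)

SENSE_NO_ATG = tuple(
    c for c in ("".join(p) for p in product("ACGT", repeat=3)) if c not in ("TAA", "TAG", "TGA")
)
STOPS = ("TAA", "TAG", "TGA")

DEFAULT_REGION_MIX = {
    "exon": 0.35,
    "utr5": 0.05,
    "utr3": 0.20,
    "intron": 0.25,
    "up10kb": 0.075,
    "down10kb": 0.075,
}


class CapacityError(ValueError):
    """Requested gene set does not fit in the configured genome."""


class PlacementError(ValueError):
    """No genomic position available for a requested planted event."""


class ConfigurationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    seed: int = 0
    n_chromosomes: int = 4
    chrom_length_bp: int = 600_000
    n_genes: int = 40
    n_circ: int = 20
    n_lnc: int = 16
    n_mirna: int = 10
    #: (label, replicates); the three editing conditions plus controls
    groups: tuple[tuple[str, int], ...] = (
        ("CTNNB1", 3),
        ("KRAS", 3),
        ("non-target", 3),
        ("eGFP", 3),
        ("WT", 3),
    )
    control_groups: tuple[str, ...] = ("eGFP", "WT")
    mean_depth: float = 20.0
    #: coverage selection standard: emitted sites have depth >= floor
    depth_floor: int = 20
    n_offtarget_ai: int = 300
    n_offtarget_cu: int = 200
    #: intergenic non-editing decoys exercising the classifier's "other"
    #: path and the control-zero rejection path (germline-like, ~0.5 VAF
    #: in every sample including controls)
    n_decoys: int = 60
    region_mix: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_REGION_MIX))
    window_bp: int = DEFAULT_FLANK_BP
    frac_de: float = 0.1
    planted_log2fc: float = 2.0
    nb_dispersion: float = 0.1
    frac_coupled: float = 0.1
    coupling_r: float = 0.9
    freq_beta_params: tuple[float, float] = (2.0, 6.0)
    base_mean: float = 500.0
    #: natural-log sigma of per-feature base means (0 = all equal)
    mean_sigma: float = 1.0
    #: intended on-target editing efficiency per guided condition
    on_target_efficiency: Mapping[str, float] = field(
        default_factory=lambda: {"CTNNB1": 0.327, "KRAS": 0.427}
    )
    on_target_concentration: float = 200.0

    def __post_init__(self) -> None:
        if self.planted_log2fc < 1:
            raise ConfigurationError("planted_log2fc must be >= 1")
        for name in ("n_genes", "n_circ", "n_lnc", "n_mirna", "n_offtarget_ai", "n_offtarget_cu", "n_decoys"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if abs(sum(self.region_mix.values()) - 1.0) > 1e-9:
            raise ConfigurationError("region_mix must sum to 1")
        if not (0 < self.coupling_r <= 1):
            raise ConfigurationError("coupling_r must lie in (0, 1]")
        if self.n_circ > self.n_genes:
            raise ConfigurationError("n_circ cannot exceed n_genes (one circRNA per host)")

    @property
    def samples(self) -> list[str]:
        return [f"{g}_r{i}" for g, n in self.groups for i in range(1, n + 1)]

    @property
    def sample_groups(self) -> dict[str, str]:
        return {f"{g}_r{i}": g for g, n in self.groups for i in range(1, n + 1)}

    @property
    def treated_groups(self) -> list[str]:
        return [g for g, _ in self.groups if g not in self.control_groups]

    def rng(self, stage: str) -> np.random.Generator:
        """Named substream of the global seed for one pipeline stage."""
        return np.random.default_rng([self.seed, zlib.crc32(stage.encode()) & 0x7FFFFFFF])


# ---------------------------------------------------------------------------
# Ground truth

@dataclass
class PlantedVariant:
    chrom: str
    pos: int
    ref: str
    alt: str
    gene_id: Optional[str]
    editing_class: str
    region: Optional[str]
    coding_effect: Optional[str]
    kind: str  # "offtarget" | "on_target" | "decoy"
    treated_freqs: dict[str, float] = field(default_factory=dict)

    @property
    def variant_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass
class GroundTruth:
    planted_variants: list[PlantedVariant] = field(default_factory=list)
    #: rna_class -> list of {"feature_id", "sign", "log2fc"}
    planted_de: dict[str, list[dict]] = field(default_factory=dict)
    #: list of {"gene_id", "variant_ids", "sign"}
    planted_couplings: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "planted_variants": [asdict(v) for v in self.planted_variants],
            "planted_de": self.planted_de,
            "planted_couplings": self.planted_couplings,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            planted_variants=[PlantedVariant(**v) for v in d["planted_variants"]],
            planted_de=d["planted_de"],
            planted_couplings=d["planted_couplings"],
        )


# ---------------------------------------------------------------------------
# Annotation generation

_BASE_LUT = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_bases(rng: np.random.Generator, n: int) -> bytearray:
    return bytearray(_BASE_LUT[rng.integers(0, 4, size=n)].tobytes())


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASE_LUT[rng.integers(0, 4, size=n)].tobytes().decode()


def _split_exons(rng: np.random.Generator, tx_len: int, n_exons: int, min_exon: int = 30) -> list[int]:
    """Exon lengths summing to tx_len, each >= min_exon."""
    if n_exons * min_exon > tx_len:
        n_exons = max(1, tx_len // min_exon)
    for _ in range(50):
        cuts = np.sort(rng.choice(np.arange(min_exon, tx_len - min_exon + 1), size=n_exons - 1, replace=False))
        lengths = np.diff(np.concatenate([[0], cuts, [tx_len]]))
        if (lengths >= min_exon).all():
            return [int(x) for x in lengths]
    base = tx_len // n_exons
    lengths = [base] * n_exons
    lengths[-1] += tx_len - base * n_exons
    return lengths


def _tx_range_to_genomic(
    exons: Sequence[tuple[int, int]], strand: str, tx_lo: int, tx_hi: int
) -> list[tuple[int, int]]:
    """Map a 0-based inclusive transcript range to genomic intervals."""
    out = []
    offset = 0
    ordered = exons if strand == "+" else list(reversed(exons))
    for s, e in ordered:
        length = e - s + 1
        lo = max(tx_lo, offset)
        hi = min(tx_hi, offset + length - 1)
        if lo <= hi:
            if strand == "+":
                out.append((s + (lo - offset), s + (hi - offset)))
            else:
                out.append((e - (hi - offset), e - (lo - offset)))
        offset += length
    return sorted(out)


@dataclass
class Annotation:
    genome: dict[str, str]
    genes: list[GeneModel]
    circs: list[CircModel]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}

    def genes_of(self, biotype: str) -> list[GeneModel]:
        return [g for g in self.genes if g.biotype == biotype]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "genome.fa",
            "gtf": outdir / "annotation.gtf",
            "circ": outdir / "circ_models.tsv",
        }
        io_formats.write_fasta(self.genome, paths["fasta"])
        io_formats.write_gtf(self.genes, paths["gtf"])
        io_formats.write_circ_models(self.circs, paths["circ"])
        return paths


def _build_gene_layout(rng: np.random.Generator, biotype: str) -> dict:
    """Transcript-level structure: sequence plus exon/CDS/UTR extents."""
    if biotype == "coding":
        utr5 = int(rng.integers(30, 121))
        n_codons = int(rng.integers(50, 151))
        utr3 = int(rng.integers(30, 201))
        cds_len = 3 * n_codons
        body = "".join(rng.choice(SENSE_NO_ATG, size=n_codons - 2))
        cds_seq = "ATG" + body + str(rng.choice(STOPS))
        seq = _random_seq(rng, utr5) + cds_seq + _random_seq(rng, utr3)
        n_exons = int(rng.integers(2, 6))
        return {"seq": seq, "utr5": utr5, "cds": cds_len, "utr3": utr3, "n_exons": n_exons}
    if biotype == "lncRNA":
        tx_len = int(rng.integers(300, 1201))
        return {"seq": _random_seq(rng, tx_len), "utr5": 0, "cds": 0, "utr3": 0,
                "n_exons": int(rng.integers(2, 5))}
    tx_len = int(rng.integers(70, 121))  # miRNA precursor
    return {"seq": _random_seq(rng, tx_len), "utr5": 0, "cds": 0, "utr3": 0, "n_exons": 1}


def generate_annotation(config: SimulationConfig) -> Annotation:
    """Random genome + non-overlapping gene models + circRNA models.

    Adjacent genes are separated by more than twice the flanking window
    so that every position belongs to at most one gene's span-plus-flank
    territory: planted events always have a unique, unambiguous host.
    """
    rng = config.rng("annotation")
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    chroms = {name: _random_bases(rng, config.chrom_length_bp) for name in chrom_names}

    specs = (
        [("coding", f"G{i + 1:04d}") for i in range(config.n_genes)]
        + [("lncRNA", f"L{i + 1:04d}") for i in range(config.n_lnc)]
        + [("miRNA", f"M{i + 1:04d}") for i in range(config.n_mirna)]
    )
    rng.shuffle(specs)
    n_total = len(specs)
    strands = np.array(["+"] * ((n_total + 1) // 2) + ["-"] * (n_total // 2))
    rng.shuffle(strands)

    gap = 2 * config.window_bp + 500
    margin = config.window_bp + 500
    genes: list[GeneModel] = []
    chrom_idx, cursor = 0, margin
    for (biotype, gene_id), strand in zip(specs, strands):
        layout = _build_gene_layout(rng, biotype)
        exon_lengths = _split_exons(rng, len(layout["seq"]), layout["n_exons"])
        introns = [int(rng.integers(200, 801)) for _ in range(len(exon_lengths) - 1)]
        span_len = sum(exon_lengths) + sum(introns)
        while cursor + span_len + margin > config.chrom_length_bp:
            chrom_idx += 1
            cursor = margin
            if chrom_idx >= config.n_chromosomes:
                raise CapacityError(
                    f"cannot place {n_total} genes: gene {gene_id} (span {span_len} bp, "
                    f"inter-gene gap {gap} bp) exceeds {config.n_chromosomes} x "
                    f"{config.chrom_length_bp} bp"
                )
        chrom = chrom_names[chrom_idx]
        exons: list[tuple[int, int]] = []
        pos = cursor
        for i, length in enumerate(exon_lengths):
            exons.append((pos, pos + length - 1))
            pos += length + (introns[i] if i < len(introns) else 0)
        # overwrite exonic genome bases with the transcript sequence
        seq = layout["seq"]
        tx_off = 0
        ordered = exons if strand == "+" else list(reversed(exons))
        for s, e in ordered:
            piece = seq[tx_off : tx_off + (e - s + 1)]
            if strand == "-":
                piece = revcomp(piece)
            chroms[chrom][s - 1 : e] = piece.encode()
            tx_off += e - s + 1
        cds, utr5, utr3 = [], [], []
        if biotype == "coding":
            u5, cl, u3 = layout["utr5"], layout["cds"], layout["utr3"]
            utr5 = _tx_range_to_genomic(exons, strand, 0, u5 - 1)
            cds = _tx_range_to_genomic(exons, strand, u5, u5 + cl - 1)
            utr3 = _tx_range_to_genomic(exons, strand, u5 + cl, len(seq) - 1)
        genes.append(
            GeneModel(
                gene_id=gene_id,
                biotype=biotype,
                chrom=chrom,
                strand=strand,
                exons=exons,
                cds=cds,
                utr5=utr5,
                utr3=utr3,
                transcript_id=f"{gene_id}.t1",
            )
        )
        cursor = exons[-1][1] + 1 + gap

    coding = sorted((g for g in genes if g.biotype == "coding"), key=lambda g: g.gene_id)
    hosts = rng.choice(len(coding), size=config.n_circ, replace=False)
    circs = []
    for i, hi in enumerate(sorted(int(h) for h in hosts)):
        host = coding[hi]
        n_ex = len(host.exons)
        start = int(rng.integers(0, n_ex))
        k = int(rng.integers(1, min(3, n_ex - start) + 1))
        circs.append(
            CircModel(
                circ_id=f"circ{i + 1:04d}",
                host_gene_id=host.gene_id,
                chrom=host.chrom,
                strand=host.strand,
                exons=host.exons[start : start + k],
            )
        )
    genome = {name: bytes(buf).decode() for name, buf in chroms.items()}
    return Annotation(genome=genome, genes=sorted(genes, key=lambda g: g.gene_id), circs=circs)


# ---------------------------------------------------------------------------
# Variant generation

_EDIT_ALLELES = {
    ("A_to_I", "+"): ("A", "G"),
    ("A_to_I", "-"): ("T", "C"),
    ("C_to_U", "+"): ("C", "T"),
    ("C_to_U", "-"): ("G", "A"),
}
_DECOY_ALTS = {"A": ("C", "T"), "C": ("A", "G"), "G": ("A", "C", "T"), "T": ("A", "C", "G")}


def _region_intervals(gene: GeneModel, region: str, window: int) -> list[tuple[int, int]]:
    if region == "exon":
        return gene.cds if gene.biotype == "coding" else gene.exons
    if region == "utr5":
        return gene.utr5
    if region == "utr3":
        return gene.utr3
    if region == "intron":
        s, e = gene.span
        out, prev = [], None
        for xs, xe in gene.exons:
            if prev is not None and xs > prev + 1:
                out.append((prev + 1, xs - 1))
            prev = xe
        return out
    if region == "up10kb":
        return [gene.flank_up(window)]
    if region == "down10kb":
        return [gene.flank_down(window)]
    raise ValueError(f"unknown region {region!r}")


def _find_candidates(genome: Mapping[str, str], chrom: str, intervals, base: str, occupied: set) -> list[int]:
    seq = genome[chrom]
    out = []
    for s, e in intervals:
        s = max(1, s)
        e = min(len(seq), e)
        if s > e:
            continue
        segment = seq[s - 1 : e]
        out.extend(
            s + i for i, b in enumerate(segment) if b == base and (chrom, s + i) not in occupied
        )
    return out


def _truncated_poisson(rng: np.random.Generator, lam: float, floor: int, size: int) -> np.ndarray:
    """Poisson(lam) conditioned on >= floor (the coverage selection)."""
    out = rng.poisson(lam, size=size)
    for _ in range(1000):
        low = out < floor
        if not low.any():
            return out
        out[low] = rng.poisson(lam, size=int(low.sum()))
    out[out < floor] = floor
    return out


def generate_variants(
    annotation: Annotation, config: SimulationConfig
) -> tuple[list[VariantRecord], GroundTruth]:
    """Plant off-target events, on-target sites and decoys.

    Off-target events carry Beta-distributed editing frequencies in
    every treated replicate and exactly zero alt depth in every control
    replicate.  Decoys are intergenic germline-like hets, non-zero in
    controls too, so they must be rejected by the control-zero filter.
    """
    rng = config.rng("variants")
    samples = config.samples
    sample_groups = config.sample_groups
    treated_samples = [s for s in samples if sample_groups[s] in config.treated_groups]
    a, b = config.freq_beta_params
    occupied: set[tuple[str, int]] = set()
    truth = GroundTruth()

    host_pool = {
        "exon": [g for g in annotation.genes if g.biotype in ("coding", "lncRNA")],
        "intron": [g for g in annotation.genes if g.biotype in ("coding", "lncRNA")],
        "utr5": annotation.genes_of("coding"),
        "utr3": annotation.genes_of("coding"),
        "up10kb": [g for g in annotation.genes if g.biotype in ("coding", "lncRNA")],
        "down10kb": [g for g in annotation.genes if g.biotype in ("coding", "lncRNA")],
    }
    region_names = sorted(config.region_mix)
    region_probs = np.array([config.region_mix[r] for r in region_names])

    def plant(editing_class: str, n_events: int) -> None:
        regions = rng.choice(region_names, size=n_events, p=region_probs)
        for region in regions:
            placed = False
            for _ in range(60):
                pool = host_pool[region]
                if not pool:
                    break
                gene = pool[int(rng.integers(0, len(pool)))]
                ref, alt = _EDIT_ALLELES[(editing_class, gene.strand)]
                intervals = _region_intervals(gene, region, config.window_bp)
                cands = _find_candidates(annotation.genome, gene.chrom, intervals, ref, occupied)
                if not cands:
                    continue
                pos = int(cands[int(rng.integers(0, len(cands)))])
                occupied.add((gene.chrom, pos))
                freqs = {s: float(rng.beta(a, b)) for s in treated_samples}
                pv = PlantedVariant(
                    chrom=gene.chrom, pos=pos, ref=ref, alt=alt, gene_id=gene.gene_id,
                    editing_class=editing_class, region=region, coding_effect=None,
                    kind="offtarget", treated_freqs=freqs,
                )
                if region == "exon" and gene.biotype == "coding":
                    probe = VariantRecord(gene.chrom, pos, ref, alt, {})
                    pv.coding_effect = coding_effect(probe, gene, annotation.genome).effect
                truth.planted_variants.append(pv)
                placed = True
                break
            if not placed:
                raise PlacementError(
                    f"no available position for a {editing_class} event in region {region!r}"
                )

    plant("A_to_I", config.n_offtarget_ai)
    plant("C_to_U", config.n_offtarget_cu)

    # one strongly edited on-target site per guided condition
    coding = annotation.genes_of("coding")
    for group in sorted(config.on_target_efficiency):
        if group not in config.treated_groups or not coding:
            continue
        eff = config.on_target_efficiency[group]
        k = config.on_target_concentration
        for _ in range(60):
            gene = coding[int(rng.integers(0, len(coding)))]
            ref, alt = _EDIT_ALLELES[("A_to_I", gene.strand)]
            cands = _find_candidates(annotation.genome, gene.chrom, gene.cds, ref, occupied)
            if not cands:
                continue
            pos = int(cands[int(rng.integers(0, len(cands)))])
            occupied.add((gene.chrom, pos))
            freqs = {
                s: (float(rng.beta(eff * k, (1 - eff) * k)) if sample_groups[s] == group else 0.0)
                for s in treated_samples
            }
            probe = VariantRecord(gene.chrom, pos, ref, alt, {})
            truth.planted_variants.append(
                PlantedVariant(
                    chrom=gene.chrom, pos=pos, ref=ref, alt=alt, gene_id=gene.gene_id,
                    editing_class="A_to_I", region="exon",
                    coding_effect=coding_effect(probe, gene, annotation.genome).effect,
                    kind="on_target", treated_freqs=freqs,
                )
            )
            break
        else:
            raise PlacementError(f"no CDS position available for the {group} on-target site")

    # intergenic decoys: outside every gene's span +/- window
    territories: dict[str, list[tuple[int, int]]] = {c: [] for c in annotation.genome}
    for g in annotation.genes:
        s, e = g.span
        territories[g.chrom].append((s - config.window_bp, e + config.window_bp))
    intergenic: list[tuple[str, int, int]] = []
    for chrom, ivs in territories.items():
        length = len(annotation.genome[chrom])
        prev = 0
        for s, e in sorted(ivs) + [(length + 1, length + 1)]:
            if s - 1 > prev:
                intergenic.append((chrom, prev + 1, s - 1))
            prev = max(prev, e)
    for _ in range(config.n_decoys):
        for _ in range(200):
            chrom, s, e = intergenic[int(rng.integers(0, len(intergenic)))]
            pos = int(rng.integers(s, e + 1))
            if (chrom, pos) in occupied:
                continue
            occupied.add((chrom, pos))
            ref = annotation.genome[chrom][pos - 1]
            alt = str(rng.choice(_DECOY_ALTS[ref]))
            freqs = {s_: float(rng.beta(10, 10)) for s_ in samples}  # germline-like het
            truth.planted_variants.append(
                PlantedVariant(
                    chrom=chrom, pos=pos, ref=ref, alt=alt, gene_id=None,
                    editing_class=strand_class(ref, alt, "+"), region=None,
                    coding_effect=None, kind="decoy", treated_freqs=freqs,
                )
            )
            break
        else:
            raise PlacementError("no intergenic position available for a decoy variant")

    # realize per-sample depths: truncated-Poisson coverage, binomial alt
    records: list[VariantRecord] = []
    for pv in truth.planted_variants:
        depths = _truncated_poisson(rng, config.mean_depth, config.depth_floor, len(samples))
        per_sample: dict[str, tuple[int, int]] = {}
        for s, depth in zip(samples, depths):
            f = pv.treated_freqs.get(s, 0.0)
            alt_d = int(rng.binomial(int(depth), f)) if f > 0 else 0
            per_sample[s] = (int(depth) - alt_d, alt_d)
        records.append(VariantRecord(pv.chrom, pv.pos, pv.ref, pv.alt, per_sample))
    records.sort(key=lambda r: (r.chrom, r.pos))
    truth.planted_variants.sort(key=lambda v: (v.chrom, v.pos))
    return records, truth


# ---------------------------------------------------------------------------
# Expression generation

def _nb_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mean mu, variance mu + dispersion * mu^2); Poisson at 0."""
    if dispersion <= 0:
        return rng.poisson(mu)
    n = 1.0 / dispersion
    p = n / (n + mu)
    return rng.negative_binomial(n, p)


def simulate_count_matrix(
    rng: np.random.Generator,
    feature_ids: Sequence[str],
    lengths: Optional[Sequence[float]],
    rna_class: str,
    config: SimulationConfig,
    de_signs: Optional[Mapping[str, int]] = None,
    log2_shifts: Optional[Mapping[str, Mapping[str, float]]] = None,
) -> ExpressionMatrix:
    """Negative-binomial counts for one RNA class.

    de_signs maps feature -> +/-1 (treated groups shifted by
    2^(sign * planted_log2fc)); log2_shifts maps feature -> per-sample
    additive log2 offsets (the coupling mechanism).
    """
    samples = config.samples
    sample_groups = config.sample_groups
    treated = set(config.treated_groups)
    n_f, n_s = len(feature_ids), len(samples)
    base = config.base_mean * np.exp(
        config.mean_sigma * rng.standard_normal(n_f) - config.mean_sigma**2 / 2
    )
    mu = np.tile(base[:, None], (1, n_s))
    treated_cols = np.array([sample_groups[s] in treated for s in samples])
    if de_signs:
        for i, fid in enumerate(feature_ids):
            sign = de_signs.get(fid)
            if sign:
                mu[i, treated_cols] *= 2.0 ** (sign * config.planted_log2fc)
    if log2_shifts:
        for i, fid in enumerate(feature_ids):
            shifts = log2_shifts.get(fid)
            if shifts:
                mu[i] *= 2.0 ** np.array([shifts.get(s, 0.0) for s in samples])
    counts = _nb_counts(rng, mu, config.nb_dispersion)
    df = pd.DataFrame(counts, index=list(feature_ids), columns=samples)
    groups = pd.Series({s: sample_groups[s] for s in samples})
    length_series = (
        pd.Series(np.asarray(lengths, dtype=float), index=list(feature_ids))
        if lengths is not None
        else None
    )
    return ExpressionMatrix(rna_class=rna_class, counts=df, groups=groups, lengths=length_series)


def _coupling_shifts(
    gene: GeneModel,
    variant: PlantedVariant,
    sign: int,
    base_mu: float,
    config: SimulationConfig,
) -> dict[str, float]:
    """Per-sample log2 offsets making expression track the variant's
    frequency with population correlation ~ sign * coupling_r.

    The slope solves r^2 = var(signal) / (var(signal) + var(noise)) with
    the NB log2-count noise variance from the delta method.
    """
    samples = config.samples
    f = np.array([variant.treated_freqs.get(s, 0.0) for s in samples])
    sd_f = float(np.std(f))
    if sd_f == 0:
        raise ConfigurationError(f"coupling variant {variant.variant_id} has constant frequency")
    noise_sd = np.sqrt(1.0 / base_mu + config.nb_dispersion) / np.log(2)
    r = config.coupling_r
    slope = sign * (r / np.sqrt(1 - r**2)) * noise_sd / sd_f if r < 1 else sign * 50.0 * noise_sd / sd_f
    centered = f - f.mean()
    return {s: float(slope * c) for s, c in zip(samples, centered)}


def generate_expression(
    annotation: Annotation, truth: GroundTruth, config: SimulationConfig
) -> dict[str, ExpressionMatrix]:
    """Count matrices for the four RNA classes, with planted DE and
    planted SNV-frequency couplings recorded in the ground truth."""
    rng = config.rng("expression")
    coding = annotation.genes_of("coding")
    lnc = annotation.genes_of("lncRNA")
    mirna = annotation.genes_of("miRNA")
    features = {
        "mRNA": ([g.gene_id for g in coding], [g.exonic_length for g in coding]),
        "circRNA": ([c.circ_id for c in annotation.circs], [c.exonic_length for c in annotation.circs]),
        "lncRNA": ([g.gene_id for g in lnc], [g.exonic_length for g in lnc]),
        "miRNA": ([g.gene_id for g in mirna], [g.exonic_length for g in mirna]),
    }

    # couplings: genes hosting an off-target event within span +/- window
    by_gene: dict[str, list[PlantedVariant]] = {}
    gene_index = {g.gene_id: g for g in coding}
    offtargets = sorted(
        (pv for pv in truth.planted_variants if pv.kind == "offtarget"),
        key=lambda pv: (pv.chrom, pv.pos),
    )
    pos_by_chrom: dict[str, tuple[np.ndarray, list[PlantedVariant]]] = {}
    for chrom in {pv.chrom for pv in offtargets}:
        pvs = [pv for pv in offtargets if pv.chrom == chrom]
        pos_by_chrom[chrom] = (np.array([pv.pos for pv in pvs]), pvs)
    for g in coding:
        if g.chrom not in pos_by_chrom:
            continue
        positions, pvs = pos_by_chrom[g.chrom]
        s, e = g.span
        lo = int(np.searchsorted(positions, s - config.window_bp, side="left"))
        hi = int(np.searchsorted(positions, e + config.window_bp, side="right"))
        if hi > lo:
            by_gene[g.gene_id] = pvs[lo:hi]
    n_coupled = int(round(config.frac_coupled * len(coding)))
    eligible = sorted(by_gene)
    if n_coupled > len(eligible):
        raise ConfigurationError(
            f"frac_coupled={config.frac_coupled} requests {n_coupled} coupled genes but only "
            f"{len(eligible)} genes have window variants"
        )
    coupled_ids = [eligible[i] for i in rng.choice(len(eligible), size=n_coupled, replace=False)] if n_coupled else []

    log2_shifts: dict[str, dict[str, float]] = {}
    truth.planted_couplings = []
    for gid in sorted(coupled_ids):
        pv = by_gene[gid][int(rng.integers(0, len(by_gene[gid])))]
        sign = int(rng.choice([-1, 1]))
        log2_shifts[gid] = _coupling_shifts(gene_index[gid], pv, sign, config.base_mean, config)
        truth.planted_couplings.append(
            {"gene_id": gid, "variant_ids": [pv.variant_id], "sign": sign}
        )

    truth.planted_de = {}
    matrices: dict[str, ExpressionMatrix] = {}
    for rna_class in ("mRNA", "circRNA", "lncRNA", "miRNA"):
        fids, lengths = features[rna_class]
        excluded = set(log2_shifts) if rna_class == "mRNA" else set()
        candidates = [f for f in fids if f not in excluded]
        n_de = int(round(config.frac_de * len(fids)))
        n_de = min(n_de, len(candidates))
        chosen = (
            [candidates[i] for i in rng.choice(len(candidates), size=n_de, replace=False)]
            if n_de
            else []
        )
        signs = {fid: int(rng.choice([-1, 1])) for fid in sorted(chosen)}
        truth.planted_de[rna_class] = [
            {"feature_id": fid, "sign": sign, "log2fc": sign * config.planted_log2fc}
            for fid, sign in sorted(signs.items())
        ]
        matrices[rna_class] = simulate_count_matrix(
            rng, fids, lengths, rna_class, config,
            de_signs=signs,
            log2_shifts=log2_shifts if rna_class == "mRNA" else None,
        )
    return matrices


# ---------------------------------------------------------------------------
# Gene sets + full fixture to disk

def generate_gene_sets(
    annotation: Annotation, config: SimulationConfig, n_sets: int = 10
) -> dict[str, set[str]]:
    rng = config.rng("gene_sets")
    gene_ids = [g.gene_id for g in annotation.genes_of("coding")]
    sets = {}
    for i in range(n_sets):
        size = int(rng.integers(5, max(6, len(gene_ids) // 3)))
        size = min(size, len(gene_ids))
        members = rng.choice(gene_ids, size=size, replace=False)
        sets[f"set{i + 1:02d}"] = set(str(m) for m in members)
    return sets


def sample_sheet_frame(config: SimulationConfig) -> pd.DataFrame:
    rows = [
        {"sample": f"{g}_r{i}", "group": g, "replicate": i}
        for g, n in config.groups
        for i in range(1, n + 1)
    ]
    return pd.DataFrame(rows)


def generate_all(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate the full fixture and write every artifact to outdir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    annotation = generate_annotation(config)
    paths = annotation.write(outdir)
    records, truth = generate_variants(annotation, config)
    paths["vcf"] = outdir / "variants.vcf"
    io_formats.write_vcf(records, config.samples, annotation.chrom_lengths, paths["vcf"])
    matrices = generate_expression(annotation, truth, config)
    for rna_class, matrix in matrices.items():
        key = f"counts_{rna_class}"
        paths[key] = outdir / f"counts_{rna_class}.tsv"
        io_formats.write_counts(matrix, paths[key])
    paths["sample_sheet"] = outdir / "samples.tsv"
    io_formats.write_sample_sheet(sample_sheet_frame(config), paths["sample_sheet"])
    paths["gmt"] = outdir / "gene_sets.gmt"
    io_formats.write_gmt(generate_gene_sets(annotation, config), paths["gmt"])
    paths["truth"] = outdir / "ground_truth.json"
    io_formats.write_json(truth.to_dict(), paths["truth"])
    return paths
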