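"""Readers and writers for every on-disk format the pipeline touches.

FASTA via Biopython, GTF via gffutils, VCF via cyvcf2; tables are plain
TSV through pandas.  All interval coordinates are 1-based inclusive, as
in GTF/VCF.  Chromosome names must match exactly across files — no
silent "chr" prefix normalization is attempted.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from cyvcf2 import VCF

from .models import BASES, CircModel, ExpressionMatrix, GeneModel, VariantRecord

log = logging.getLogger(__name__)

_BIOTYPE_TO_GTF = {"coding": "protein_coding", "lncRNA": "lncRNA", "miRNA": "miRNA"}
_GTF_TO_BIOTYPE = {v: k for k, v in _BIOTYPE_TO_GTF.items()}


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# VCF

@dataclass
class VcfResult:
    records: list[VariantRecord]
    samples: list[str]
    n_skipped_non_snv: int


def read_vcf(path: str | Path) -> VcfResult:
    """Read an AD-carrying VCF into bi-allelic SNV records.

    Multi-allelic rows are split into one record per ALT allele;
    non-SNV alleles (indels, symbolic) are skipped and counted.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    records: list[VariantRecord] = []
    n_skipped = 0
    for var in vcf:
        ad = var.format("AD")
        if ad is None:
            raise ValueError(f"{path}: FORMAT field AD missing at {var.CHROM}:{var.POS}")
        ad = np.asarray(ad)
        for j, alt in enumerate(var.ALT):
            if len(var.REF) != 1 or len(alt) != 1 or var.REF not in BASES or alt not in BASES:
                n_skipped += 1
                continue
            per_sample = {
                s: (max(int(ad[i, 0]), 0), max(int(ad[i, j + 1]), 0))
                for i, s in enumerate(samples)
            }
            records.append(VariantRecord(var.CHROM, var.POS, var.REF, alt, per_sample))
    if n_skipped:
        log.info("read_vcf: skipped %d non-SNV allele(s) in %s", n_skipped, path)
    return VcfResult(records, samples, n_skipped)


def write_vcf(
    records: Sequence[VariantRecord],
    samples: Sequence[str],
    contig_lengths: Mapping[str, int],
    path: str | Path,
) -> None:
    """Write bi-allelic SNVs as VCF v4.2 with GT:AD per sample."""
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">',
    ]
    for name, length in contig_lengths.items():
        lines.append(f"##contig=<ID={name},length={length}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples))
    for rec in sorted(records, key=lambda r: (r.chrom, r.pos, r.alt)):
        fields = [rec.chrom, str(rec.pos), ".", rec.ref, rec.alt, ".", "PASS", ".", "GT:AD"]
        for s in samples:
            rd, ad = rec.per_sample[s]
            gt = "0/1" if ad > 0 else "0/0"
            fields.append(f"{gt}:{rd},{ad}")
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# GTF

def _transcript_sort_key(tx: dict) -> tuple:
    cds_len = sum(e - s + 1 for s, e in tx["cds"])
    exonic = sum(e - s + 1 for s, e in tx["exons"])
    # longest CDS, then longest exonic span, then lexicographically
    # smallest transcript id (negated lengths so one ascending sort works)
    return (-cds_len, -exonic, tx["transcript_id"])


def read_gtf(path: str | Path) -> list[GeneModel]:
    """Parse an Ensembl-dialect GTF into one GeneModel per gene.

    The representative transcript is the one with the longest CDS (ties:
    longest exonic span, then lexicographic transcript id).
    """
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes: dict[str, dict] = {}
    transcripts: dict[str, dict] = {}
    for feat in db.all_features():
        gene_id = feat.attributes.get("gene_id", [None])[0]
        if gene_id is None:
            raise ValueError(f"{path}: feature without gene_id at {feat.seqid}:{feat.start}")
        if feat.featuretype == "gene":
            biotype = feat.attributes.get("gene_biotype", ["protein_coding"])[0]
            genes[gene_id] = {
                "biotype": _GTF_TO_BIOTYPE.get(biotype, "coding"),
                "chrom": feat.seqid,
                "strand": feat.strand,
            }
            continue
        tx_id = feat.attributes.get("transcript_id", [None])[0]
        if tx_id is None:
            continue
        tx = transcripts.setdefault(
            tx_id,
            {
                "transcript_id": tx_id,
                "gene_id": gene_id,
                "chrom": feat.seqid,
                "strand": feat.strand,
                "exons": [],
                "cds": [],
                "utr5": [],
                "utr3": [],
            },
        )
        iv = (feat.start, feat.end)
        if feat.featuretype == "exon":
            tx["exons"].append(iv)
        elif feat.featuretype == "CDS":
            tx["cds"].append(iv)
        elif feat.featuretype == "five_prime_utr":
            tx["utr5"].append(iv)
        elif feat.featuretype == "three_prime_utr":
            tx["utr3"].append(iv)

    by_gene: dict[str, list[dict]] = {}
    for tx in transcripts.values():
        by_gene.setdefault(tx["gene_id"], []).append(tx)

    models: list[GeneModel] = []
    for gene_id, txs in by_gene.items():
        tx = min(txs, key=_transcript_sort_key)
        meta = genes.get(gene_id, {"biotype": "coding", "chrom": tx["chrom"], "strand": tx["strand"]})
        cds_len = sum(e - s + 1 for s, e in tx["cds"])
        if tx["cds"] and cds_len % 3 != 0:
            raise ValueError(
                f"{path}: transcript {tx['transcript_id']} CDS length {cds_len} not divisible by 3"
            )
        models.append(
            GeneModel(
                gene_id=gene_id,
                biotype=meta["biotype"],
                chrom=meta["chrom"],
                strand=meta["strand"],
                exons=sorted(tx["exons"]),
                cds=sorted(tx["cds"]),
                utr5=sorted(tx["utr5"]),
                utr3=sorted(tx["utr3"]),
                transcript_id=tx["transcript_id"],
            )
        )
    models.sort(key=lambda m: m.gene_id)
    return models


def _gtf_attrs(**kwargs: str) -> str:
    return " ".join(f'{k} "{v}";' for k, v in kwargs.items())


def write_gtf(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene models as Ensembl-dialect GTF (1-based inclusive)."""
    rows: list[str] = []

    def line(chrom: str, feature: str, start: int, end: int, strand: str, frame: str, attrs: str) -> None:
        rows.append(f"{chrom}\teditscape\t{feature}\t{start}\t{end}\t.\t{strand}\t{frame}\t{attrs}")

    for g in sorted(genes, key=lambda g: (g.chrom, g.span[0], g.gene_id)):
        tx_id = g.transcript_id or f"{g.gene_id}.t1"
        s, e = g.span
        gene_attrs = _gtf_attrs(gene_id=g.gene_id, gene_biotype=_BIOTYPE_TO_GTF[g.biotype])
        tx_attrs = _gtf_attrs(
            gene_id=g.gene_id, transcript_id=tx_id, gene_biotype=_BIOTYPE_TO_GTF[g.biotype]
        )
        line(g.chrom, "gene", s, e, g.strand, ".", gene_attrs)
        line(g.chrom, "transcript", s, e, g.strand, ".", tx_attrs)
        for iv in g.exons:
            line(g.chrom, "exon", iv[0], iv[1], g.strand, ".", tx_attrs)
        cds_in_tx_order = g.cds if g.strand == "+" else list(reversed(g.cds))
        consumed = 0
        frames = []
        for iv in cds_in_tx_order:
            frames.append((iv, (3 - consumed % 3) % 3))
            consumed += iv[1] - iv[0] + 1
        for iv, frame in sorted(frames):
            line(g.chrom, "CDS", iv[0], iv[1], g.strand, str(frame), tx_attrs)
        for iv in g.utr5:
            line(g.chrom, "five_prime_utr", iv[0], iv[1], g.strand, ".", tx_attrs)
        for iv in g.utr3:
            line(g.chrom, "three_prime_utr", iv[0], iv[1], g.strand, ".", tx_attrs)
    Path(path).write_text("\n".join(rows) + "\n")


# ---------------------------------------------------------------------------
# circRNA models (TSV sidecar; GTF has no standard back-splice encoding)

def write_circ_models(circs: Sequence[CircModel], path: str | Path) -> None:
    rows = [
        {
            "circ_id": c.circ_id,
            "host_gene_id": c.host_gene_id,
            "chrom": c.chrom,
            "strand": c.strand,
            "exons": ";".join(f"{s}-{e}" for s, e in c.exons),
        }
        for c in sorted(circs, key=lambda c: c.circ_id)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_circ_models(path: str | Path) -> list[CircModel]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    circs = []
    for _, row in df.iterrows():
        exons = [tuple(int(x) for x in part.split("-")) for part in row["exons"].split(";")]
        circs.append(CircModel(row["circ_id"], row["host_gene_id"], row["chrom"], row["strand"], exons))
    return circs


# ---------------------------------------------------------------------------
# Count matrices and sample sheets

def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "group": str})
    required = {"sample", "group"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: sample sheet must have columns {sorted(required)}")
    return df


def write_sample_sheet(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_counts(path: str | Path, sample_sheet: pd.DataFrame, rna_class: str) -> ExpressionMatrix:
    """Read a features x samples TSV (optional `length` column) into an
    ExpressionMatrix; samples must match the sheet exactly."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    lengths = None
    if "length" in df.columns:
        lengths = df["length"].astype(float)
        df = df.drop(columns=["length"])
    sheet_samples = set(sample_sheet["sample"])
    matrix_samples = set(df.columns)
    if sheet_samples != matrix_samples:
        diff = sorted(sheet_samples.symmetric_difference(matrix_samples))
        raise ValueError(f"{path}: sample sheet / matrix mismatch: {diff}")
    groups = sample_sheet.set_index("sample")["group"]
    return ExpressionMatrix(rna_class=rna_class, counts=df, groups=groups, lengths=lengths)


def write_counts(matrix: ExpressionMatrix, path: str | Path) -> None:
    df = matrix.counts.copy()
    if matrix.lengths is not None:
        df.insert(0, "length", matrix.lengths.astype(int))
    df.sort_index().to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# GMT gene sets, generic tables, JSON

def read_gmt(path: str | Path) -> dict[str, set[str]]:
    sets: dict[str, set[str]] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if not raw.strip():
            continue
        parts = raw.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line needs name, description and >=1 gene")
        sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    lines = [
        "\t".join([name, "na", *sorted(set(members))]) for name, members in sorted(sets.items())
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Deterministic TSV: UTF-8, header, rows sorted by the first column."""
    out = df.sort_values(list(df.columns[:1]), kind="stable") if len(df) else df
    out.to_csv(path, sep="\t", index=False)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
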