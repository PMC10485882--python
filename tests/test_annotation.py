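"""Region assignment and coding-effect classification against
independent brute-force oracles."""

import numpy as np
import pytest
from Bio.Seq import Seq

from editscape.annotation import (
    SENSE_CODONS,
    ReferenceMismatchError,
    assign_region,
    coding_effect,
    enumerate_effect_space,
    region_rank,
    tally_regions,
)
from editscape.models import COMPLEMENT, CircModel, GeneModel, VariantRecord, revcomp
from editscape.synthetic import SimulationConfig, generate_annotation

SUBSTITUTIONS = [(r, a) for r in "ACGT" for a in "ACGT" if r != a]


def _gene_for_codon(codon: str, strand: str):
    """Minimal single-exon gene whose CDS is ATG + codon + TAA."""
    tx = "ATG" + codon + "TAA"
    genome_seq = tx if strand == "+" else revcomp(tx)
    gene = GeneModel(
        gene_id="g", biotype="coding", chrom="c", strand=strand,
        exons=[(1, 9)], cds=[(1, 9)],
    )
    return gene, {"c": genome_seq}


def _effect_oracle(codon: str, after: str) -> str:
    aa_b, aa_a = str(Seq(codon).translate()), str(Seq(after).translate())
    if aa_b == aa_a:
        return "silent"
    if aa_b != "*" and aa_a == "*":
        return "nonsense"
    return "missense"


class TestCodingEffect:
    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_exhaustive_codon_space_matches_oracle(self, strand):
        """All 61 sense codons x 3 positions x 3 alternates, on both
        strands, against direct translation of the mutated codon."""
        for codon in SENSE_CODONS:
            gene, genome = _gene_for_codon(codon, strand)
            for i in range(3):
                tx_ref = codon[i]
                tx_pos = 3 + i  # 0-based offset inside the CDS
                genomic_pos = tx_pos + 1 if strand == "+" else 9 - tx_pos
                for tx_alt in "ACGT":
                    if tx_alt == tx_ref:
                        continue
                    ref = tx_ref if strand == "+" else COMPLEMENT[tx_ref]
                    alt = tx_alt if strand == "+" else COMPLEMENT[tx_alt]
                    var = VariantRecord("c", genomic_pos, ref, alt, {})
                    ce = coding_effect(var, gene, genome)
                    after = codon[:i] + tx_alt + codon[i + 1 :]
                    assert ce.codon_before == codon and ce.codon_after == after
                    assert ce.effect == _effect_oracle(codon, after), (codon, i, tx_alt, strand)

    @pytest.mark.parametrize(
        "codon,pos,alt,expected",
        [
            ("CAA", 0, "T", "nonsense"),   # CAA -> TAA
            ("GCA", 2, "G", "silent"),     # GCA -> GCG, Ala -> Ala
            ("AAA", 1, "G", "missense"),   # AAA -> AGA, Lys -> Arg
        ],
    )
    def test_worked_examples(self, codon, pos, alt, expected):
        gene, genome = _gene_for_codon(codon, "+")
        var = VariantRecord("c", 4 + pos, codon[pos], alt, {})
        assert coding_effect(var, gene, genome).effect == expected

    def test_stop_to_stop_is_silent_and_stop_loss_is_missense(self):
        gene, genome = _gene_for_codon("AAA", "+")  # CDS ends ...TAA
        assert coding_effect(VariantRecord("c", 9, "A", "G", {}), gene, genome).effect == "silent"  # TAA->TAG
        assert coding_effect(VariantRecord("c", 7, "T", "C", {}), gene, genome).effect == "missense"  # TAA->CAA

    def test_splice_junction_codon_reconstructed_across_exons(self):
        # codon GAT split 1+2 across an intron; genome carries the pieces
        genome = {"c": "ATGG" + "T" * 100 + "ATTAA" + "G" * 20}
        gene = GeneModel(
            gene_id="g", biotype="coding", chrom="c", strand="+",
            exons=[(1, 4), (105, 109)], cds=[(1, 4), (105, 109)],
        )
        ce = coding_effect(VariantRecord("c", 105, "A", "G", {}), gene, genome)
        assert ce.codon_before == "GAT" and ce.codon_after == "GGT"
        assert ce.effect == "missense"  # Asp -> Gly

    def test_reference_mismatch_raises_with_both_bases(self):
        gene, genome = _gene_for_codon("AAA", "+")
        with pytest.raises(ReferenceMismatchError, match="ref 'C', genome has 'A'"):
            coding_effect(VariantRecord("c", 4, "C", "T", {}), gene, genome)

    def test_agreement_with_planted_effect_ground_truth(self, dataset):
        genes = {g.gene_id: g for g in dataset["annotation"].genes}
        checked = 0
        for pv in dataset["truth"].planted_variants:
            if pv.coding_effect is None:
                continue
            var = VariantRecord(pv.chrom, pv.pos, pv.ref, pv.alt, {})
            ce = coding_effect(var, genes[pv.gene_id], dataset["annotation"].genome)
            assert ce.effect == pv.coding_effect
            checked += 1
        assert checked > 20


class TestEffectSpace:
    def test_a_to_g_never_creates_a_stop(self):
        assert enumerate_effect_space(("A", "G"))["nonsense"] == 0

    def test_c_to_t_nonsense_comes_only_from_caa_cag_cga(self):
        # independent brute force over the genetic code
        sources = set()
        for codon in SENSE_CODONS:
            for i in range(3):
                if codon[i] == "C" and _effect_oracle(codon, codon[:i] + "T" + codon[i + 1 :]) == "nonsense":
                    sources.add(codon)
        assert sources == {"CAA", "CAG", "CGA"}
        counts = enumerate_effect_space(("C", "T"))
        assert counts["nonsense"] == 3

    @pytest.mark.parametrize("sub", SUBSTITUTIONS)
    def test_counts_partition_the_enumerated_positions(self, sub):
        counts = enumerate_effect_space(sub)
        n_positions = sum(c.count(sub[0]) for c in SENSE_CODONS)
        assert sum(counts.values()) == n_positions


def _region_oracle(pos, gene, window=10_000):
    """Independent membership check using only raw interval arithmetic."""
    inside = lambda ivs: any(s <= pos <= e for s, e in ivs)
    span_s, span_e = gene.exons[0][0], gene.exons[-1][1]
    if span_s <= pos <= span_e:
        if inside(gene.cds):
            return "exon"
        if inside(gene.utr5):
            return "utr5"
        if inside(gene.utr3):
            return "utr3"
        if inside(gene.exons):
            return "exon"
        return "intron"
    if gene.strand == "+":
        up = (span_s - window, span_s - 1)
        down = (span_e + 1, span_e + window)
    else:
        up = (span_e + 1, span_e + window)
        down = (span_s - window, span_s - 1)
    if up[0] <= pos <= up[1]:
        return "up10kb"
    if down[0] <= pos <= down[1]:
        return "down10kb"
    return None


class TestRegionAssignment:
    def test_matches_brute_force_oracle_on_random_positions(self):
        config = SimulationConfig(seed=5, n_genes=50, n_circ=10, n_lnc=0, n_mirna=0,
                                  n_chromosomes=4, chrom_length_bp=800_000)
        annotation = generate_annotation(config)
        rng = np.random.default_rng(99)
        chroms = sorted(annotation.genome)
        n_checked = 0
        for _ in range(10_000):
            chrom = chroms[rng.integers(0, len(chroms))]
            pos = int(rng.integers(1, len(annotation.genome[chrom]) + 1))
            for gene in annotation.genes:
                if gene.chrom != chrom:
                    continue
                expected = _region_oracle(pos, gene)
                got = region_rank(pos, gene)
                assert (got[0] if got else None) == expected
                n_checked += 1
        assert n_checked > 10_000

    def test_partition_conservation_per_gene(self, dataset, events):
        # every assigned variant maps to exactly one region of its host
        hosted = [ev for ev in events if ev.host_gene_id is not None]
        tallied = tally_regions([(ev.editing_class, ev.region) for ev in hosted])
        assert tallied["count"].sum() == len(hosted)
        for _, grp in tallied.groupby("editing_class"):
            assert grp["fraction"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_window_boundary_rules(self):
        gene = GeneModel("g", "lncRNA", "c", "+", exons=[(20_000, 25_000)])
        var_in = VariantRecord("c", 12_000, "A", "G", {})
        var_out = VariantRecord("c", 9_000, "A", "G", {})
        assert assign_region(var_in, gene).region == "up10kb"
        assert assign_region(var_out, gene) is None

    def test_circ_model_regions_are_exon_or_intron(self):
        circ = CircModel("circ1", "g", "c", "+", exons=[(100, 200), (400, 500)])
        assert assign_region(VariantRecord("c", 150, "A", "G", {}), circ).region == "exon"
        assert assign_region(VariantRecord("c", 300, "A", "G", {}), circ).region == "intron"
        assert assign_region(VariantRecord("c", 600, "A", "G", {}), circ) is None

    def test_planted_region_mix_is_recovered_exactly(self, dataset, events):
        truth_regions = {
            v.variant_id: v.region
            for v in dataset["truth"].planted_variants
            if v.kind == "offtarget"
        }
        for ev in events:
            if ev.variant.variant_id in truth_regions:
                assert ev.region == truth_regions[ev.variant.variant_id]

    def test_tally_fractions(self):
        pairs = [("A_to_I", "exon")] * 10 + [("A_to_I", "intron")] * 10
        t = tally_regions(pairs)
        assert set(t["fraction"]) == {0.5}

    def test_empty_tally(self):
        assert len(tally_regions([])) == 0
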