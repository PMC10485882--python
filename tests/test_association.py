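"""Window collection, control-zero filtering and the correlation test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from editscape.association import (
    AssociationConfig,
    associate_features,
    collect_window_snvs,
    control_zero_filter,
    correlate,
)
from editscape.editing import classify_editing
from editscape.models import ExpressionMatrix, GeneModel, VariantRecord

CFG = AssociationConfig()


def _event(chrom, pos, ref="A", alt="G", per_sample=None):
    return classify_editing(VariantRecord(chrom, pos, ref, alt, per_sample or {}), [])


class TestWindowCollection:
    gene = GeneModel("g", "lncRNA", "c", "+", exons=[(20_000, 25_000)])

    def test_window_rule(self):
        events = [_event("c", 12_000), _event("c", 9_000), _event("c", 22_000)]
        got = collect_window_snvs(self.gene, events, CFG)
        assert [ev.variant.pos for ev in got] == [12_000, 22_000]

    def test_zero_window_keeps_only_in_span(self):
        cfg = AssociationConfig(window_bp=0)
        events = [_event("c", 19_999), _event("c", 20_000), _event("c", 25_000), _event("c", 25_001)]
        got = collect_window_snvs(self.gene, events, cfg)
        assert [ev.variant.pos for ev in got] == [20_000, 25_000]


class TestControlZeroFilter:
    def _var(self, depths):
        per_sample = {f"eGFP_r{i+1}": d for i, d in enumerate(depths)}
        return VariantRecord("c", 1, "A", "G", per_sample)

    def test_all_zero_with_coverage_passes(self):
        var = self._var([(25, 0), (30, 0), (22, 0)])
        assert control_zero_filter(var, list(var.per_sample), CFG)

    def test_any_nonzero_alt_fails(self):
        var = self._var([(25, 0), (22, 3), (30, 0)])
        assert not control_zero_filter(var, list(var.per_sample), CFG)

    def test_undefined_frequency_fails_even_at_zero_alt(self):
        var = self._var([(5, 0), (25, 0), (25, 0)])  # depth 5 < min_depth 20
        assert not control_zero_filter(var, list(var.per_sample), CFG)


class TestCorrelate:
    def test_six_sample_worked_example(self):
        r, p = correlate([0.4, 0.5, 0.6, 0, 0, 0], [8, 9, 10, 5, 5, 5], CFG)
        assert r == pytest.approx(0.9985, abs=1e-3)
        assert p < 1e-4

    def test_matches_brute_force_pearson(self):
        rng = np.random.default_rng(12)
        for _ in range(1000):
            n = int(rng.integers(3, 40))
            x, y = rng.normal(size=n), rng.normal(size=n)
            r, p = correlate(x, y, CFG)
            xc, yc = x - x.mean(), y - y.mean()
            r_brute = float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))
            t = r_brute * np.sqrt((n - 2) / (1 - r_brute**2))
            p_brute = float(2 * sps.t.sf(abs(t), n - 2))
            assert r == pytest.approx(r_brute, abs=1e-12)
            assert p == pytest.approx(p_brute, abs=1e-9)

    def test_zero_variance_is_undefined(self):
        r, p = correlate([0.3, 0.3, 0.3, 0.3], [1, 2, 3, 4], CFG)
        assert np.isnan(r) and np.isnan(p)

    def test_permutation_null_pvalues_are_uniform(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(size=20)
        y = rng.normal(size=20)
        pvals = []
        for _ in range(1000):
            perm = rng.permutation(y)
            pvals.append(correlate(x, perm, CFG)[1])
        assert sps.kstest(pvals, "uniform").pvalue > 0.01


def _toy_assoc_setup():
    """Two genes, one variant tracking gene A's expression perfectly."""
    samples = [f"T_r{i}" for i in range(1, 6)] + [f"eGFP_r{i}" for i in range(1, 4)]
    groups = pd.Series({s: ("T" if s.startswith("T") else "eGFP") for s in samples})
    freqs = [0.5, 0.4, 0.3, 0.2, 0.1, 0, 0, 0]
    expr_a = [2 ** (5 + 4 * f) for f in freqs]
    counts = pd.DataFrame(
        {s: [expr_a[i], 100] for i, s in enumerate(samples)}, index=["GA", "GB"]
    )
    matrix = ExpressionMatrix("miRNA", counts, groups)
    from editscape.expression import normalize

    normalize(matrix)
    per_sample = {
        s: (100 - int(100 * f), int(100 * f)) for s, f in zip(samples, freqs)
    }
    events = [_event("c", 600, per_sample=per_sample)]
    genes = [
        GeneModel("GA", "miRNA", "c", "+", exons=[(500, 700)]),
        GeneModel("GB", "miRNA", "c", "+", exons=[(50_000, 50_200)]),
    ]
    return events, matrix, genes


class TestAssociateFeatures:
    def test_tracking_gene_is_significant_and_distant_gene_untested(self):
        events, matrix, genes = _toy_assoc_setup()
        results = {
            r.feature_id: r
            for r in associate_features(events, matrix, genes, {"GA"}, ["T"], CFG, "A_to_I")
        }
        assert results["GA"].significant and results["GA"].associated_de
        assert results["GA"].best_r > 0.9
        assert not results["GB"].variant_ids and not np.isfinite(results["GB"].p_value)

    def test_significant_feature_not_in_de_set_is_not_associated_de(self):
        events, matrix, genes = _toy_assoc_setup()
        (res,) = [
            r
            for r in associate_features(events, matrix, genes, set(), ["T"], CFG, "A_to_I")
            if r.feature_id == "GA"
        ]
        assert res.significant and not res.associated_de

    def test_set_inclusions(self, dataset, events):
        matrix = dataset["matrices"]["mRNA"]
        genes = dataset["annotation"].genes_of("coding")
        cfg = AssociationConfig(control_groups=("eGFP",))
        results = associate_features(
            events, matrix, genes, set(), ["CTNNB1", "KRAS", "non-target"], cfg, "A_to_I"
        )
        for r in results:
            if r.significant:
                assert r.passed_control_zero and np.isfinite(r.p_value)
            if r.associated_de:
                assert r.significant
            if np.isfinite(r.fdr):
                assert r.fdr >= r.p_value - 1e-12

    def test_invariant_to_variant_and_sample_order(self, dataset, events):
        matrix = dataset["matrices"]["mRNA"]
        genes = dataset["annotation"].genes_of("coding")
        cfg = AssociationConfig(control_groups=("eGFP",))
        treated = ["CTNNB1", "KRAS", "non-target"]
        base = associate_features(events, matrix, genes, set(), treated, cfg, "A_to_I")

        rng = np.random.default_rng(0)
        shuffled_events = list(events)
        rng.shuffle(shuffled_events)
        cols = list(matrix.counts.columns)
        rng.shuffle(cols)
        from editscape.expression import normalize

        shuffled_matrix = ExpressionMatrix(
            "mRNA", matrix.counts[cols], matrix.groups, matrix.lengths
        )
        normalize(shuffled_matrix)
        other = associate_features(
            shuffled_events, shuffled_matrix, genes, set(), treated, cfg, "A_to_I"
        )
        for a, b in zip(base, other):
            assert a.feature_id == b.feature_id
            assert a.variant_ids == b.variant_ids
            assert a.p_value == pytest.approx(b.p_value, nan_ok=True, abs=1e-12)
            assert a.significant == b.significant

    def test_decoys_fail_the_control_zero_filter(self, dataset, events):
        """Germline-like decoys carry alt reads in controls, so no decoy
        position may survive into any tested variant set."""
        decoy_ids = {
            v.variant_id for v in dataset["truth"].planted_variants if v.kind == "decoy"
        }
        matrix = dataset["matrices"]["mRNA"]
        genes = dataset["annotation"].genes_of("coding")
        cfg = AssociationConfig(control_groups=("eGFP",))
        results = associate_features(
            events, matrix, genes, set(), ["CTNNB1", "KRAS", "non-target"], cfg, "A_to_I"
        )
        tested = {vid for r in results for vid in r.per_variant}
        assert not (tested & decoy_ids)
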