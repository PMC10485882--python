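"""Normalization identities, BH correctness, and DE calling."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from editscape.expression import call_de_sets, de_test, normalize, _direction
from editscape.models import ExpressionMatrix
from editscape.stats import bh_adjust
from editscape.synthetic import SimulationConfig, simulate_count_matrix


def _matrix(counts, lengths=None, rna_class="mRNA", groups=None):
    df = pd.DataFrame(counts)
    if groups is None:
        groups = {c: "g" for c in df.columns}
    return ExpressionMatrix(
        rna_class=rna_class,
        counts=df,
        groups=pd.Series(groups),
        lengths=pd.Series(lengths) if lengths is not None else None,
    )


class TestNormalize:
    def test_fpkm_worked_example(self):
        # 100 fragments on a 2 kb feature in a 10M-fragment library -> 5.0
        m = _matrix({"s": [100, 9_999_900]}, lengths={0: 2000.0, 1: 1000.0})
        normalize(m)
        assert m.normalized.loc[0, "s"] == pytest.approx(100 / (2 * 10))

    def test_tpm_columns_sum_to_a_million(self):
        m = _matrix({"s": [10, 30, 60]}, rna_class="miRNA")
        normalize(m)
        assert list(m.normalized["s"]) == [1e5, 3e5, 6e5]
        assert m.normalized["s"].sum() == pytest.approx(1e6, rel=1e-12)

    def test_rpm_worked_example(self):
        m = _matrix({"s": [300, 1_999_700]}, rna_class="circRNA")
        normalize(m)
        assert m.normalized.loc[0, "s"] == pytest.approx(300 / 2.0)

    def test_fpkm_invariant_under_uniform_scaling(self):
        counts = {"s1": [100, 400, 500], "s2": [200, 800, 1000]}  # s2 = 2 x s1
        m = _matrix(counts, lengths={0: 1000.0, 1: 2000.0, 2: 500.0})
        normalize(m)
        pd.testing.assert_series_equal(
            m.normalized["s1"], m.normalized["s2"], check_names=False
        )

    def test_missing_lengths_rejected(self):
        with pytest.raises(ValueError, match="lengths"):
            normalize(_matrix({"s": [1, 2]}))

    def test_zero_library_names_the_sample(self):
        m = _matrix({"good": [1, 2], "empty": [0, 0]}, rna_class="miRNA")
        with pytest.raises(ValueError, match="empty"):
            normalize(m)


def _bh_brute_force(p):
    """Literal step-up definition: q_(i) = min_{j>=i} p_(j) * m / j."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q_sorted = [0.0] * m
    running = float("inf")
    for rank in range(m, 0, -1):
        running = min(running, p[order[rank - 1]] * m / rank)
        q_sorted[rank - 1] = min(running, 1.0)
    q = [0.0] * m
    for rank, idx in enumerate(order):
        q[idx] = max(q_sorted[rank], p[idx])  # q >= p by definition
    return np.array(q)


class TestBenjaminiHochberg:
    def test_exact_equality_with_brute_force(self):
        rng = np.random.default_rng(17)
        for _ in range(1000):
            n = int(rng.integers(1, 501))
            p = rng.uniform(size=n)
            q = bh_adjust(p)
            assert np.array_equal(q, _bh_brute_force(p))

    def test_monotone_and_dominating(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=300)
        q = bh_adjust(p)
        assert (q >= p).all() and (q <= 1).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_worked_example_flattens_to_largest(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_agrees_with_statsmodels(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            p = rng.uniform(size=int(rng.integers(2, 200)))
            _, q_sm, _, _ = multipletests(p, method="fdr_bh")
            assert np.allclose(bh_adjust(p), q_sm, atol=1e-12)


class TestDifferentialExpression:
    def test_direction_thresholds(self):
        assert _direction(1.5, 0.01) == "up"
        assert _direction(0.8, 0.001) == "ns"
        assert _direction(-1.5, 0.01) == "down"
        assert _direction(1.5, 0.2) == "ns"

    def test_null_type_one_error_is_calibrated(self):
        config = SimulationConfig(seed=1, frac_de=0.0)
        fids = [f"F{i}" for i in range(2500)]
        matrix = simulate_count_matrix(config.rng("null"), fids, None, "miRNA", config)
        results = de_test(matrix, ["CTNNB1"], ["eGFP", "WT"])
        frac = np.mean([r.p_value < 0.05 for r in results])
        assert 0.03 <= frac <= 0.07

    def test_relabeled_null_recovers_nothing(self):
        config = SimulationConfig(
            seed=6, frac_de=0.0, groups=(("A", 3), ("B", 3)), control_groups=("B",),
            on_target_efficiency={},
        )
        fids = [f"F{i}" for i in range(400)]
        matrix = simulate_count_matrix(config.rng("x"), fids, None, "miRNA", config)
        sets = call_de_sets({"miRNA": de_test(matrix, ["A"], ["B"])})
        # no planting: the truth set is empty, so anything called is a
        # false positive; at q<0.05 over 400 features expect none or almost
        assert len(sets.all("miRNA")) <= 2

    def test_planted_recovery_sensitivity_and_precision(self):
        config = SimulationConfig(seed=2, base_mean=500.0, mean_sigma=0.0, nb_dispersion=0.1)
        fids = [f"F{i}" for i in range(2000)]
        planted = {f"F{i}": (1 if i % 2 else -1) for i in range(0, 2000, 10)}
        matrix = simulate_count_matrix(
            config.rng("power"), fids, None, "miRNA", config, de_signs=planted
        )
        results = de_test(matrix, config.treated_groups, list(config.control_groups))
        sets = call_de_sets({"miRNA": results})
        called = sets.all("miRNA")
        tp = len(called & set(planted))
        assert tp / len(planted) >= 0.7
        assert tp / len(called) >= 0.8
        # planted signs match called directions
        for r in results:
            if r.feature_id in planted and r.direction != "ns":
                assert (r.log2fc > 0) == (planted[r.feature_id] > 0)

    def test_up_and_down_sets_are_disjoint(self, dataset):
        results = {
            c: de_test(m, ["CTNNB1", "KRAS", "non-target"], ["eGFP", "WT"])
            for c, m in dataset["matrices"].items()
        }
        sets = call_de_sets(results)
        for c in results:
            assert not (sets.up[c] & sets.down[c])

    def test_too_few_replicates_rejected(self, dataset):
        m = dataset["matrices"]["mRNA"]
        with pytest.raises(ValueError, match="replicates"):
            de_test(m, [], ["eGFP"])

    def test_empty_results_give_empty_sets(self):
        sets = call_de_sets({"mRNA": []})
        assert sets.all("mRNA") == set()
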