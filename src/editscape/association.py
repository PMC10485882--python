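"""SNV-frequency / expression association.

For each feature (gene, circRNA or lncRNA) the off-target SNVs inside
the feature and within a 10 kb flank on either side are collected.  A
variant enters the test only if every control sample has a *defined*
frequency (total depth at or above the minimum) that is exactly zero —
observed zeros, not missing data.  Per-sample mutation frequency is then
correlated with log2 normalized expression across the treated and
control replicates; controls anchor the zero-frequency end.  The
feature-level p-value is the best variant p after a within-feature
Bonferroni correction over the number of variants tested, and FDR is
Benjamini–Hochberg across features within one (editing class x RNA
class) stratum.  A feature is significant at P < 0.05 and FDR < 0.5;
intersecting significant features with the DE sets yields the
SNV-associated differentially expressed RNAs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .editing import EditingEvent
from .models import CircModel, ExpressionMatrix, GeneModel, VariantRecord
from .stats import bh_adjust, pearson_test


@dataclass
class AssociationConfig:
    window_bp: int = 10_000
    #: minimum per-sample total depth for a defined mutation frequency
    min_depth: int = 20
    p_threshold: float = 0.05
    #: the permissive published cutoff; tighten via configuration if needed
    fdr_threshold: float = 0.5
    control_groups: tuple[str, ...] = ("eGFP",)
    correlation: str = "pearson"  # or "spearman"

    def __post_init__(self) -> None:
        if self.window_bp < 0:
            raise ValueError("window_bp must be >= 0")
        for name in ("p_threshold", "fdr_threshold"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.correlation not in ("pearson", "spearman"):
            raise ValueError(f"unknown correlation {self.correlation!r}")


@dataclass
class AssociationResult:
    feature_id: str
    rna_class: str
    editing_class: str
    variant_ids: list[str] = field(default_factory=list)
    per_variant: dict[str, tuple[float, float]] = field(default_factory=dict)  # id -> (r, p)
    n_tested: int = 0
    best_variant: Optional[str] = None
    best_r: float = float("nan")
    p_value: float = float("nan")
    fdr: float = float("nan")
    passed_control_zero: bool = False
    significant: bool = False
    associated_de: bool = False
    skip_reasons: dict[str, str] = field(default_factory=dict)  # variant id -> reason


def collect_window_snvs(
    model: GeneModel | CircModel,
    events: Sequence[EditingEvent],
    config: AssociationConfig,
) -> list[EditingEvent]:
    """Events on the feature's chromosome within span +/- window, sorted
    by position."""
    s, e = model.span
    lo, hi = s - config.window_bp, e + config.window_bp
    hits = [
        ev
        for ev in events
        if ev.variant.chrom == model.chrom and lo <= ev.variant.pos <= hi
    ]
    hits.sort(key=lambda ev: (ev.variant.pos, ev.variant.alt))
    return hits


def control_zero_filter(
    variant: VariantRecord, control_samples: Sequence[str], config: AssociationConfig
) -> bool:
    """True iff every control sample has a defined frequency of exactly 0."""
    if not control_samples:
        return False
    for s in control_samples:
        f = variant.frequency(s, min_depth=config.min_depth)
        if f is None or f != 0.0:
            return False
    return True


def correlate(
    frequencies: Sequence[float], expression: Sequence[float], config: AssociationConfig
) -> tuple[float, float]:
    """Correlation between per-sample mutation frequency and log2
    normalized expression; (nan, nan) when undefined (callers skip)."""
    x = np.asarray(frequencies, dtype=float)
    y = np.asarray(expression, dtype=float)
    if config.correlation == "spearman":
        if x.size < 3 or np.std(x) == 0 or np.std(y) == 0:
            return (float("nan"), float("nan"))
        res = sps.spearmanr(x, y)
        return (float(res.statistic), float(res.pvalue))
    return pearson_test(x, y)


def associate_features(
    events: Sequence[EditingEvent],
    matrix: ExpressionMatrix,
    models: Sequence[GeneModel | CircModel],
    de_set: set[str],
    treated_groups: Sequence[str],
    config: AssociationConfig,
    editing_class: str,
) -> list[AssociationResult]:
    """Run the association procedure for one editing class over one RNA
    class's features.  Ambiguous-strand events never reach this stage
    because they carry a different editing_class label.
    """
    if matrix.normalized is None:
        raise ValueError("expression matrix must be normalized first")
    class_events = [ev for ev in events if ev.editing_class == editing_class]
    # per-chromosome position index so window collection is O(log n)
    by_chrom: dict[str, tuple[np.ndarray, list[EditingEvent]]] = {}
    for chrom in {ev.variant.chrom for ev in class_events}:
        evs = sorted(
            (ev for ev in class_events if ev.variant.chrom == chrom),
            key=lambda ev: (ev.variant.pos, ev.variant.alt),
        )
        by_chrom[chrom] = (np.array([ev.variant.pos for ev in evs]), evs)
    control_samples = matrix.samples_in_groups(config.control_groups)
    treated_samples = matrix.samples_in_groups(treated_groups)
    samples = treated_samples + control_samples
    log_expr = matrix.log2_normalized()

    results: list[AssociationResult] = []
    for model in models:
        fid = model.circ_id if isinstance(model, CircModel) else model.gene_id
        res = AssociationResult(feature_id=fid, rna_class=matrix.rna_class, editing_class=editing_class)
        if fid not in log_expr.index:
            results.append(res)
            continue
        if model.chrom in by_chrom:
            positions, evs = by_chrom[model.chrom]
            s, e = model.span
            lo = int(np.searchsorted(positions, s - config.window_bp, side="left"))
            hi = int(np.searchsorted(positions, e + config.window_bp, side="right"))
            window = evs[lo:hi]
        else:
            window = []
        res.variant_ids = [ev.variant.variant_id for ev in window]
        expr_row = log_expr.loc[fid]
        for ev in window:
            var = ev.variant
            if not control_zero_filter(var, control_samples, config):
                res.skip_reasons[var.variant_id] = "control_nonzero_or_undefined"
                continue
            res.passed_control_zero = True
            freqs, exprs = [], []
            for s in samples:
                f = var.frequency(s, min_depth=config.min_depth)
                if f is None:
                    continue
                freqs.append(f)
                exprs.append(float(expr_row[s]))
            if len(freqs) < 3:
                res.skip_reasons[var.variant_id] = "fewer_than_3_usable_samples"
                continue
            r, p = correlate(freqs, exprs, config)
            if not np.isfinite(p):
                res.skip_reasons[var.variant_id] = "zero_variance"
                continue
            res.per_variant[var.variant_id] = (r, p)
        if res.per_variant:
            res.n_tested = len(res.per_variant)
            bonf = {
                vid: min(p * res.n_tested, 1.0) for vid, (r, p) in res.per_variant.items()
            }
            res.best_variant = min(bonf, key=lambda v: (bonf[v], v))
            res.best_r = res.per_variant[res.best_variant][0]
            res.p_value = bonf[res.best_variant]
        results.append(res)

    tested = [r for r in results if np.isfinite(r.p_value)]
    if tested:
        q = bh_adjust([r.p_value for r in tested])
        for r, qv in zip(tested, q):
            r.fdr = float(qv)
            r.significant = (
                r.passed_control_zero
                and r.p_value < config.p_threshold
                and r.fdr < config.fdr_threshold
            )
            r.associated_de = r.significant and r.feature_id in de_set
    return results


def association_frame(results: Sequence[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "feature_id": r.feature_id,
                "rna_class": r.rna_class,
                "editing_class": r.editing_class,
                "n_window_variants": len(r.variant_ids),
                "n_tested": r.n_tested,
                "best_variant": r.best_variant or "",
                "best_r": r.best_r,
                "p_value": r.p_value,
                "fdr": r.fdr,
                "passed_control_zero": r.passed_control_zero,
                "significant": r.significant,
                "associated_de": r.associated_de,
            }
            for r in results
        ]
    )


def associated_de_summary(
    results: Sequence[AssociationResult], de_up: set[str], de_down: set[str]
) -> dict[str, int]:
    hits = [r for r in results if r.associated_de]
    return {
        "total": len(hits),
        "up": sum(1 for r in hits if r.feature_id in de_up),
        "down": sum(1 for r in hits if r.feature_id in de_down),
    }
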