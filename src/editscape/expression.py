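"""Per-class normalization and differential expression.

Normalization follows the assay type: FPKM for mRNA and lncRNA
(length-corrected), reads-per-million for circRNA back-splice counts,
and tags-per-million for miRNA.  Library size is the column sum of the
class's own matrix divided by 1e6.

The DE test is a two-sided Welch t-test on log2(normalized + 0.5) with
the fold change computed on group means of normalized values (same
pseudo-count) and Benjamini–Hochberg adjustment within each RNA class.
A feature is called up when log2FC > 1 and q < 0.05, down when
log2FC < -1 and q < 0.05.  The test is deliberately simple and fully
specified here, behind a module boundary that would admit a negative
binomial GLM without touching callers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .models import NORM_UNITS, ExpressionMatrix
from .stats import bh_adjust

PSEUDOCOUNT = 0.5
LOG2FC_THRESHOLD = 1.0
Q_THRESHOLD = 0.05


def normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Attach normalized values in the class's own unit (FPKM/RPM/TPM)."""
    unit = NORM_UNITS[matrix.rna_class]
    counts = matrix.counts.astype(float)
    library = counts.sum(axis=0)
    zero = library[library == 0]
    if len(zero):
        raise ValueError(f"zero column sum for sample(s): {list(zero.index)}")
    millions = library / 1e6
    if unit == "FPKM":
        if matrix.lengths is None:
            raise ValueError(f"{matrix.rna_class}: FPKM requires feature lengths")
        kb = matrix.lengths / 1e3
        normalized = counts.div(millions, axis=1).div(kb, axis=0)
    elif unit == "RPM":
        normalized = counts.div(millions, axis=1)
    else:  # TPM, tags per million: column scaled to 1e6
        normalized = counts.div(library, axis=1) * 1e6
    matrix.normalized = normalized
    matrix.norm_unit = unit
    return matrix


@dataclass(frozen=True)
class DEResult:
    feature_id: str
    rna_class: str
    log2fc: float
    p_value: float
    q_value: float
    direction: str  # "up" | "down" | "ns"
    mean_a: float
    mean_b: float


def _direction(log2fc: float, q: float) -> str:
    if q < Q_THRESHOLD and log2fc > LOG2FC_THRESHOLD:
        return "up"
    if q < Q_THRESHOLD and log2fc < -LOG2FC_THRESHOLD:
        return "down"
    return "ns"


def de_test(
    matrix: ExpressionMatrix, group_a: Sequence[str] | str, group_b: Sequence[str] | str
) -> list[DEResult]:
    """Differential expression, group A (treated) vs group B (control).

    Either argument may be one group label or several to pool.  Features
    with all-zero counts in both groups are excluded; zero-variance
    features that survive get p = 1.
    """
    if matrix.normalized is None:
        normalize(matrix)
    labels_a = [group_a] if isinstance(group_a, str) else list(group_a)
    labels_b = [group_b] if isinstance(group_b, str) else list(group_b)
    samples_a = matrix.samples_in_groups(labels_a)
    samples_b = matrix.samples_in_groups(labels_b)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError(
            f"need >=2 replicates per side, got {len(samples_a)} vs {len(samples_b)}"
        )
    counts_a = matrix.counts[samples_a]
    counts_b = matrix.counts[samples_b]
    keep = (counts_a.sum(axis=1) + counts_b.sum(axis=1)) > 0
    norm_a = matrix.normalized.loc[keep, samples_a]
    norm_b = matrix.normalized.loc[keep, samples_b]
    mean_a = norm_a.mean(axis=1)
    mean_b = norm_b.mean(axis=1)
    log2fc = np.log2((mean_a + PSEUDOCOUNT) / (mean_b + PSEUDOCOUNT))
    log_a = np.log2(norm_a + PSEUDOCOUNT)
    log_b = np.log2(norm_b + PSEUDOCOUNT)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = sps.ttest_ind(log_a, log_b, axis=1, equal_var=False)
    p = np.where(np.isfinite(p), p, 1.0)
    q = bh_adjust(p)
    results = []
    for i, fid in enumerate(norm_a.index):
        results.append(
            DEResult(
                feature_id=str(fid),
                rna_class=matrix.rna_class,
                log2fc=float(log2fc.iloc[i]),
                p_value=float(p[i]),
                q_value=float(q[i]),
                direction=_direction(float(log2fc.iloc[i]), float(q[i])),
                mean_a=float(mean_a.iloc[i]),
                mean_b=float(mean_b.iloc[i]),
            )
        )
    return results


@dataclass
class DESets:
    """Up/down feature id sets per RNA class (DEG/DEC/DEL/DEM)."""

    up: dict[str, set[str]]
    down: dict[str, set[str]]

    def all(self, rna_class: str) -> set[str]:
        return self.up.get(rna_class, set()) | self.down.get(rna_class, set())

    def summary(self) -> dict[str, dict[str, int]]:
        classes = sorted(set(self.up) | set(self.down))
        return {
            c: {
                "up": len(self.up.get(c, set())),
                "down": len(self.down.get(c, set())),
                "total": len(self.all(c)),
            }
            for c in classes
        }


def call_de_sets(results_per_class: Mapping[str, Sequence[DEResult]]) -> DESets:
    up: dict[str, set[str]] = {}
    down: dict[str, set[str]] = {}
    for rna_class, results in results_per_class.items():
        up[rna_class] = {r.feature_id for r in results if r.direction == "up"}
        down[rna_class] = {r.feature_id for r in results if r.direction == "down"}
    return DESets(up=up, down=down)


def de_results_frame(results: Sequence[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "feature_id": r.feature_id,
                "rna_class": r.rna_class,
                "log2fc": r.log2fc,
                "p_value": r.p_value,
                "q_value": r.q_value,
                "direction": r.direction,
                "mean_treated": r.mean_a,
                "mean_control": r.mean_b,
            }
            for r in results
        ]
    )
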