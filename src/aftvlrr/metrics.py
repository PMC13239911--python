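"""Partition-agreement metrics: adjusted Rand index and normalised mutual
information, computed from the contingency table.

NMI uses the arithmetic-mean normalisation ``2 I(X;Y) / (H(X) + H(Y))``;
ARI is the chance-corrected Rand index with the hypergeometric expectation,

    ARI = (RI - E[RI]) / (max RI - E[RI]),

evaluated in the standard pair-counting contingency form.  Degenerate cases
where the normaliser vanishes (both partitions trivial) return 1 when the
partitions are identical and 0 otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["MetricReport", "contingency_table", "nmi", "ari", "rand_index", "evaluate"]


def _comb2(x: np.ndarray | float):
    return x * (x - 1) / 2.0


def contingency_table(truth: Sequence, pred: Sequence) -> np.ndarray:
    """Count table n_ij = #{items with truth class i and predicted class j}."""
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    if truth.shape != pred.shape or truth.ndim != 1:
        raise ValueError("label vectors must be 1-D and of equal length")
    if truth.size < 1:
        raise ValueError("empty label vectors")
    _, ti = np.unique(truth, return_inverse=True)
    _, pi = np.unique(pred, return_inverse=True)
    table = np.zeros((ti.max() + 1, pi.max() + 1), dtype=np.int64)
    np.add.at(table, (ti, pi), 1)
    return table


def nmi(truth: Sequence, pred: Sequence) -> float:
    """Normalised mutual information, arithmetic-mean normalisation."""
    table = contingency_table(truth, pred).astype(float)
    n = table.sum()
    pij = table / n
    pi = pij.sum(axis=1)
    pj = pij.sum(axis=0)
    hx = -np.sum(pi[pi > 0] * np.log(pi[pi > 0]))
    hy = -np.sum(pj[pj > 0] * np.log(pj[pj > 0]))
    if hx + hy == 0.0:
        # both partitions are single-cluster, hence identical and trivial
        return 1.0
    nz = pij > 0
    mi = np.sum(pij[nz] * np.log(pij[nz] / np.outer(pi, pj)[nz]))
    return float(2.0 * mi / (hx + hy))


def rand_index(truth: Sequence, pred: Sequence) -> float:
    """Plain Rand index: fraction of item pairs on which the partitions agree."""
    table = contingency_table(truth, pred).astype(float)
    n = table.sum()
    if n < 2:
        raise ValueError("need at least 2 items")
    pairs = _comb2(n)
    same_same = _comb2(table).sum()  # a: together in both
    a_pairs = _comb2(table.sum(axis=1)).sum()
    b_pairs = _comb2(table.sum(axis=0)).sum()
    # b: apart in both = total - (together in truth) - (together in pred) + a
    diff_diff = pairs - a_pairs - b_pairs + same_same
    return float((same_same + diff_diff) / pairs)


def ari(truth: Sequence, pred: Sequence) -> float:
    """Adjusted Rand index (chance-corrected, hypergeometric expectation)."""
    table = contingency_table(truth, pred).astype(float)
    n = table.sum()
    if n < 2:
        raise ValueError("need at least 2 items")
    sum_ij = _comb2(table).sum()
    sum_a = _comb2(table.sum(axis=1)).sum()
    sum_b = _comb2(table.sum(axis=0)).sum()
    expected = sum_a * sum_b / _comb2(n)
    max_index = 0.5 * (sum_a + sum_b)
    denom = max_index - expected
    if denom == 0.0:
        # degenerate: both trivial (all-singletons or single-cluster) partitions
        return 1.0 if sum_ij == sum_a == sum_b else 0.0
    return float((sum_ij - expected) / denom)


@dataclass
class MetricReport:
    """ARI/NMI/RI of a predicted partition against the reference."""

    ari: float
    nmi: float
    rand_index: float
    contingency: np.ndarray

    def as_dict(self) -> dict[str, float]:
        return {"ari": self.ari, "nmi": self.nmi, "rand_index": self.rand_index}


def evaluate(truth: Sequence, pred: Sequence) -> MetricReport:
    """Bundle ARI, NMI and RI for one pair of partitions."""
    return MetricReport(
        ari=ari(truth, pred),
        nmi=nmi(truth, pred),
        rand_index=rand_index(truth, pred),
        contingency=contingency_table(truth, pred),
    )
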