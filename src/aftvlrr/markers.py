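"""Cluster marker-gene ranking by one-vs-rest Welch t statistics.

For every cluster and every gene the two-sample t statistic (unequal
variances) compares the gene's preprocessed expression inside the cluster
against all remaining cells; genes are ranked per cluster by |t| and the top
``top_n`` (default 25) are reported as marker candidates.  Variances are
floored at a tiny positive constant so zero-variance genes yield finite
scores instead of NaN.  No multiple-testing correction is applied — the
output is a ranking, not a hypothesis test.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

__all__ = ["rank_marker_genes"]

_VAR_FLOOR = 1e-12


def rank_marker_genes(
    X: ExpressionMatrix,
    labels: Sequence,
    top_n: int = 25,
) -> pd.DataFrame:
    """Rank one-vs-rest marker genes per cluster.

    Returns a tidy table with columns ``cluster, rank, gene_id, t_score,
    mean_in, mean_out``, sorted by |t_score| descending within each cluster
    and truncated to ``top_n`` rows per cluster (all genes if fewer).
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    labels = np.asarray(labels)
    if labels.shape[0] != X.n_cells:
        raise ValueError("labels must align with cells")

    V = X.values
    rows = []
    for cluster in np.unique(labels):
        mask = labels == cluster
        n_in, n_out = int(mask.sum()), int((~mask).sum())
        if n_in < 2 or n_out < 2:
            raise ValueError(
                f"cluster {cluster!r} needs >= 2 cells on both sides of the split"
            )
        in_vals, out_vals = V[:, mask], V[:, ~mask]
        mean_in, mean_out = in_vals.mean(axis=1), out_vals.mean(axis=1)
        var_in = np.maximum(in_vals.var(axis=1, ddof=1), _VAR_FLOOR)
        var_out = np.maximum(out_vals.var(axis=1, ddof=1), _VAR_FLOOR)
        t = (mean_in - mean_out) / np.sqrt(var_in / n_in + var_out / n_out)

        order = np.argsort(-np.abs(t), kind="stable")[: min(top_n, X.n_genes)]
        for rank, g in enumerate(order, start=1):
            rows.append(
                {
                    "cluster": cluster,
                    "rank": rank,
                    "gene_id": X.gene_ids[g],
                    "t_score": float(t[g]),
                    "mean_in": float(mean_in[g]),
                    "mean_out": float(mean_out[g]),
                }
            )
    return pd.DataFrame(rows, columns=["cluster", "rank", "gene_id", "t_score", "mean_in", "mean_out"])
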