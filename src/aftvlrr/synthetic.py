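"""Seeded generator of cluster-structured, dropout-sparse expression matrices.

The generator realises the union-of-subspaces picture the low-rank
representation model targets: every cluster owns a low-dimensional
nonnegative subspace (a sparse nonnegative gene-program basis), each cell is
a nonnegative combination of its cluster's programs, and the observation
layer adds the defining corruptions of scRNA-seq — multiplicative log-normal
noise, per-cell library-size variation, and Bernoulli dropout zeroing.
Marker genes are boosted inside their cluster's basis rows, so the clean
matrix keeps exact rank <= n_clusters * latent_dim.

Everything is a pure function of the spec (including the seed), so fixtures
are generated at test time instead of being shipped as files.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ExpressionMatrix

__all__ = ["SyntheticSpec", "simulate", "standard_fixture", "clean_fixture"]


@dataclass
class SyntheticSpec:
    """Conditions of one simulated dataset.

    n_clusters : number of cell groups.
    cells_per_cluster : cells in each group (int, or one int per group).
    n_genes : number of genes.
    latent_dim : dimension of each cluster's subspace (programs per cluster).
    signal_scale : overall expression magnitude of the basis.
    noise_sigma : width of the multiplicative log-normal noise (0 = clean).
    dropout_rate : Bernoulli zeroing probability per entry; by default the
        zeroing is expression-dependent (low-expression entries drop out
        preferentially at the same average rate, mimicking capture-efficiency
        loss); set ``expression_dependent_dropout=False`` for uniform zeroing.
    n_marker_genes_per_cluster : genes boosted in one cluster's basis and
        silenced in every other cluster's (a marker defines its cell type).
    basis_support : fraction of genes participating in each program
        (sparse programs keep different clusters' subspaces distinguishable).
    marker_boost : additive basis boost applied to marker-gene rows.
    libsize_sigma : log-normal spread of per-cell library sizes.
    integer_counts : draw Poisson counts around the signal (for testing the
        count-preprocessing path); default is real-valued post-normalisation
        scale, which is what the model consumes.
    seed : RNG seed; identical specs are bitwise reproducible.
    """

    n_clusters: int = 3
    cells_per_cluster: int | list[int] = 30
    n_genes: int = 200
    latent_dim: int = 3
    signal_scale: float = 1.0
    noise_sigma: float = 0.1
    dropout_rate: float = 0.3
    n_marker_genes_per_cluster: int = 5
    basis_support: float = 0.3
    marker_boost: float = 3.0
    libsize_sigma: float = 0.2
    expression_dependent_dropout: bool = True
    integer_counts: bool = False
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_clusters < 1 or self.n_genes < 1 or self.latent_dim < 1:
            raise ValueError("counts must be positive")
        sizes = self.cluster_sizes()
        if any(s < 2 for s in sizes):
            raise ValueError("each cluster needs >= 2 cells")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.n_clusters * self.n_marker_genes_per_cluster > self.n_genes:
            raise ValueError("marker genes exceed gene count")
        if self.signal_scale <= 0:
            raise ValueError("signal_scale must be positive")
        if self.noise_sigma < 0 or self.libsize_sigma < 0:
            raise ValueError("noise widths must be >= 0")

    def cluster_sizes(self) -> list[int]:
        if isinstance(self.cells_per_cluster, int):
            return [self.cells_per_cluster] * self.n_clusters
        if len(self.cells_per_cluster) != self.n_clusters:
            raise ValueError("cells_per_cluster list length != n_clusters")
        return list(self.cells_per_cluster)


def simulate(spec: SyntheticSpec) -> tuple[ExpressionMatrix, np.ndarray]:
    """Draw one (ExpressionMatrix, label vector) pair from the spec."""
    rng = np.random.default_rng(spec.seed)
    sizes = spec.cluster_sizes()
    n_cells = sum(sizes)
    m = spec.n_genes

    # disjoint marker-gene blocks, one per cluster
    marker_idx = [
        np.arange(c * spec.n_marker_genes_per_cluster, (c + 1) * spec.n_marker_genes_per_cluster)
        for c in range(spec.n_clusters)
    ]

    signal = np.zeros((m, n_cells))
    labels = np.zeros(n_cells, dtype=int)
    start = 0
    for c, size in enumerate(sizes):
        # sparse nonnegative gene-program basis for this cluster's subspace
        support = rng.random((m, spec.latent_dim)) < spec.basis_support
        B = rng.uniform(0.5, 1.5, size=(m, spec.latent_dim)) * support
        B[marker_idx[c], :] += spec.marker_boost
        for other in range(spec.n_clusters):
            if other != c:
                B[marker_idx[other], :] = 0.0  # markers are exclusive
        B *= spec.signal_scale
        coeff = rng.uniform(0.2, 1.0, size=(spec.latent_dim, size))
        signal[:, start : start + size] = B @ coeff
        labels[start : start + size] = c
        start += size

    X = signal
    if spec.noise_sigma > 0:
        X = X * np.exp(spec.noise_sigma * rng.standard_normal(X.shape))
    if spec.libsize_sigma > 0:
        X = X * np.exp(spec.libsize_sigma * rng.standard_normal(n_cells))[None, :]
    if spec.integer_counts:
        X = rng.poisson(X).astype(float)
    if spec.dropout_rate > 0:
        if spec.expression_dependent_dropout:
            # low expression drops out preferentially; rescale keeps the
            # average rate at dropout_rate
            scale = np.exp(-X / (X[X > 0].mean() if np.any(X > 0) else 1.0))
            p = spec.dropout_rate * scale / max(scale.mean(), 1e-12)
            p = np.clip(p, 0.0, 1.0)
        else:
            p = spec.dropout_rate
        X = np.where(rng.random(X.shape) < p, 0.0, X)
    X = np.maximum(X, 0.0)

    gene_ids = [f"gene_{i}" for i in range(m)]
    cell_ids = [f"cell_{j}" for j in range(n_cells)]
    return ExpressionMatrix(X, gene_ids, cell_ids), labels


def standard_fixture(seed: int = 1) -> tuple[ExpressionMatrix, np.ndarray]:
    """The canonical noisy test dataset: 3 clusters x 30 cells, 200 genes,
    latent dimension 3, multiplicative noise 0.1, dropout 0.3, 5 planted
    markers per cluster."""
    return simulate(SyntheticSpec(seed=seed))


def clean_fixture(seed: int = 1) -> tuple[ExpressionMatrix, np.ndarray]:
    """Noise-free, dropout-free variant of the standard dataset; the signal
    matrix has exact rank <= n_clusters * latent_dim."""
    return simulate(
        SyntheticSpec(noise_sigma=0.0, dropout_rate=0.0, libsize_sigma=0.0, seed=seed)
    )
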