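# aftvlrr

Similarity learning and clustering for single-cell RNA-seq expression
matrices by **adaptive fractional-order total-variation regularised low-rank
representation (AFTV-LRR)**, with spectral clustering, ARI/NMI evaluation,
marker-gene ranking, and a synthetic-data generator.

## Who this is for

scRNA-seq clustering lives or dies on the quality of the cell–cell affinity
graph. Dropout (technical zeroing of expressed genes), multiplicative noise
and library-size variation corrupt pairwise similarities long before any
community detection runs. Subspace methods address this globally: if cells of
one type live in a low-dimensional expression subspace, every cell can be
written as a combination of the *other cells*, and a low-rank, nonnegative
coefficient matrix exposes the block structure of cell types. This package is
for analysts who want that affinity matrix — plus the clustering and marker
ranking on top of it — from a plain genes × cells matrix.

## The model

Given a preprocessed matrix `X ∈ R^{m×n}` (m genes, n cells, columns
L2-normalised), AFTV-LRR learns coefficients `R ∈ R^{n×n}`:

```
min_R  1/2 ‖X − XR‖_F²  +  α ‖R‖_*  +  λ_tv ‖XR‖_AFTV     s.t.  R ≥ 0
```

* `‖R‖_*` — nuclear norm, the convex surrogate for rank; α sets the
  low-rankness strength.
* `‖·‖_AFTV` — adaptive fractional-order total variation of the
  reconstruction `XR`. Fractional differences of order β (Grünwald–Letnikov,
  truncated at K stencil points, weights `w_k = (−1)^k C(β,k)`) aggregate a
  neighbourhood rather than a single first difference, suppressing isolated
  dropout noise while keeping weak structure. A spatially varying exponent
  `l(x,y) ∈ (1,2)` interpolates between edge-preserving TV behaviour (l→1,
  at sharp transitions) and Tikhonov-like smoothing (l→2, in flat regions).
* Nonnegativity makes `R` interpretable as similarity mass.

The problem is solved by ADMM with the splitting `R = Q`: a cached-Cholesky
linear solve for `R` (fractional-TV gradient lagged at the previous
reconstruction), singular value thresholding for `Q`, a dual ascent for the
multiplier, and nonnegative projections of both blocks. The learnt
coefficients are symmetrised, `S = (R + Rᵀ)/2`, and S feeds normalised-cut
spectral clustering (symmetric normalised Laplacian, row-normalised spectral
embedding, seeded restarted k-means).

Setting `λ_tv = 0` recovers plain nonnegative low-rank representation, which
the package exposes as an ablation baseline.

## Worked example

Simulate a dropout-sparse dataset with ground-truth labels (3 clusters × 30
cells, 200 genes, 30% expression-dependent dropout), run the full pipeline,
and evaluate:

```bash
aftvlrr simulate --seed 1 --out demo/data
# wrote 200 genes x 90 cells to demo/data

aftvlrr run --input demo/data/matrix.csv -k 3 \
    --labels demo/data/labels.txt --seed 0 --out demo/run
# beta=1.3 K=3 ARI=1.0000 NMI=1.0000

aftvlrr eval --truth demo/data/labels.txt --pred demo/run/labels.txt
# ari     1.000000
# nmi     1.000000
# rand_index      1.000000
```

ARI (adjusted Rand index) is chance-corrected pair agreement — 1.0 means the
recovered partition matches the generator's labels exactly; NMI (normalised
mutual information, arithmetic-mean normalisation) agrees. The output
directory contains every intermediate artifact:

```
demo/run/
├── preprocessed.csv   # filtered, log-normalised, L2-normalised matrix
├── similarity.csv     # learnt symmetric affinity S
├── trace.csv          # per-iteration objective and ADMM residuals
├── labels.txt         # one cluster label per cell
├── eigenvalues.csv    # leading Laplacian spectrum (eigengap report)
├── metrics.json       # {"ari": 1.0, "nmi": 1.0, "rand_index": 1.0}
├── filtered_genes.txt # genes removed by the >95%-zeros filter
└── params.json        # resolved hyperparameters + convergence flag
```

The first lines of `trace.csv` show the solver settling (the objective drops
from 15.2 to 11.2 within three iterations; the change trace later falls below
the 1e-5 stopping tolerance):

```
iteration,objective,primal_residual,dual_residual,change
1,15.200628082953473,1.8002596416556709,0.8060406364833521,2.278846458755693
2,11.787781568662759,0.42183545575533743,0.8367240470458015,1.216014040410306
3,11.232881961613549,0.16365132661760673,0.09761252201083928,0.28950807517501487
```

Passing comma lists sweeps the fractional order and truncation, writing an
ARI/NMI row per combination:

```bash
aftvlrr run --input demo/data/matrix.csv -k 3 --labels demo/data/labels.txt \
    --beta 1.1,1.3,1.5 --K 2,3 --out demo/sweep
```

Key hyperparameters (all exposed as flags and in the YAML `--config`):
`--alpha` nuclear-norm weight (0.5), `--mu` ADMM penalty in the 1/μ
convention (1.0), `--beta` fractional order (1.3, robust range ≈1.1–1.5),
`--K` stencil length (3), `--lambda-tv` AFTV weight (1e-3; 0 = plain
nonnegative LRR). See `docs/methods.md` for what each default means and why.

The same functionality is available as a library:

```python
import aftvlrr as a

X, truth = a.standard_fixture()          # 200 genes x 90 cells, 3 clusters
Xp = a.preprocess(X)                     # filter -> log-normalise -> L2
state, S = a.fit_aftv_lrr(Xp.values)     # ADMM; state carries the traces
labels = a.spectral_clustering(S, k=3, seed=0).labels
print(a.evaluate(truth, labels).as_dict())
markers = a.rank_marker_genes(Xp, labels, top_n=25)
```

## Scope

The package operates on a single expression matrix. Batch-effect correction,
highly-variable-gene selection, doublet removal, automatic selection of the
cluster count k, GO enrichment, and embedding visualisation are deliberately
out of scope.
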