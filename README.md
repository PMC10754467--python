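# csdgi

Cancer **s**ubtype-specific **d**river **g**ene **i**nference from
single-cell expression data.

Tumors are heterogeneous: different subpopulations of malignant cells are
driven by different genes, and methods that pool a whole cohort report only
drivers common to all of them. `csdgi` implements an unsupervised
encoder-decoder that *simultaneously* assigns single tumor cells to
subtypes and ranks genes as subtype-specific drivers, together with its
preprocessing (gene prevalence filtering and earth-mover's-distance
differential expression between tumor and non-tumor cells) and downstream
evaluation (classification/clustering metrics, subtype-number estimation
by the within-cluster-sum-of-squares elbow, driver co-expression
networks).

## The model

The input is a cells × genes log-scale expression matrix
X ∈ R^{m×n}, X_i the profile of cell *i*. One shared residual encoder and
*s* competing reconstruction branches, one per candidate subtype:

- **Encoder** (shared): X^{l+1} = X^l + ReLU(W^l X^l + b^l) for *p*
  residual blocks, giving X^p.
- **Low-rank propagation** (per subtype k): D_k = tanh(S0_k · X^p), where
  S0_k = V_k V_k^T with zeroed diagonal is a rank-*r* gene–gene similarity
  (r = 1 by default) with self-association removed.
- **Decoder**: x̂_k = M_k ∘ tanh(G·D_k + e) + E_k, with shared G, e and
  per-subtype scale M_k and bias E_k.
- **Gene weights**: λ^k = |μ_k| normalized to unit length, μ_k the left
  eigenvector of I − L_k with the smallest-magnitude eigenvalue, where
  L_k = B_k^{-1} V_k V_k^T is the random-walk normalization of the
  similarity. For r = 1 this closes to λ^k = |V_k| / ‖V_k‖₂.
- **Loss**: L = (1/m) Σ_i min_k ‖(X_i − x̂_{ik}) ∘ λ^k‖²₂. Each cell is
  assigned to the branch that reconstructs it best under that branch's own
  gene weighting; gradients flow only through the winning branch
  (competitive learning). Per subtype, genes are ranked by λ^k and the top
  5 % are reported as that subtype's driver genes.

Training is full-batch Adam in NumPy (analytic gradients, verified against
finite differences in the test suite); the network widths are all *n*, so
no GPU framework is required at the scales this package targets.

## Worked example

```bash
csdgi simulate --preset default --cells 200 --genes 100 --seed 0 --out-dir sim
csdgi run --matrix sim/matrix.tsv --k 2 --epochs 400 --seed 0 --out-dir out
csdgi evaluate --labels sim/true_labels.tsv --pred out/labels.tsv
```

The simulated matrix has two planted cell subtypes of ~100 cells, each
with 10 driver genes up-shifted by 2.0 log-units, 30 % dropout zeros and
per-cell Gaussian noise. The `run` command filters genes by prevalence,
trains the model and writes per-cell labels (`labels.tsv`), per-gene
weights (`lambda.tsv`), top-5 % driver lists per subtype and Pearson
co-expression networks. The final `evaluate` step prints

```
{"ari": 0.9799998282856902, "n_cells": 200}
```

an adjusted Rand index of ≈ 0.98 between the planted and the inferred
subtype assignment (1.0 = identical partitions, ≈ 0 = chance).

The same library surface is importable from Python:

```python
from csdgi import SyntheticScenario, generate, fit, ModelConfig, adjusted_rand_index
X, truth = generate(SyntheticScenario(seed=0))
model, weights, assignment, trace = fit(X, ModelConfig(n_subtypes=2, seed=0))
adjusted_rand_index(truth.labels, assignment.labels)   # 0.98
```

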