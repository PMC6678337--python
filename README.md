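# scina

Semi-supervised cell-type assignment for scRNA-seq, CyTOF/FACS and bulk
expression matrices, driven by marker-gene signatures and fitted with an
EM mixture model — together with a matched synthetic benchmark generator
and evaluation metrics.

## The problem

Unsupervised pipelines cluster cells first and leave the naming of the
clusters to manual inspection of marker genes. When the major cell types
and their signatures are already known, that two-stage workflow discards
prior knowledge and is subjective on borderline cells. This package goes
the other way: given a log-scale expression matrix (genes × cells) and a
list of signature genes per cell type, it assigns every cell directly to
one of the supplied types — or to an explicit **unknown** class when no
signature fits.

## The model

Restrict the matrix to the union of signature genes. Each signature gene
*g* is assumed **bimodal** across cells: a high mode
N(μ<sup>hi</sup><sub>g</sub>, σ<sup>hi</sup><sub>g</sub>) in the cell
type(s) whose signature contains *g*, and a low mode
N(μ<sup>lo</sup><sub>g</sub>, σ<sup>lo</sup><sub>g</sub>) everywhere
else. With R labelled types plus the unknown class (low mode on every
gene), the likelihood of cell *j* under class *k* is

  p(x<sub>j</sub> | k) = ∏<sub>g</sub> N(x<sub>gj</sub>; μ<sup>m(g,k)</sup><sub>g</sub>, σ<sup>m(g,k)</sup><sub>g</sub>),  m(g,k) = hi if g ∈ signature(k) else lo,

and the marginal is the τ-weighted mixture over the R+1 classes. EM
alternates posterior responsibilities (E) with responsibility-weighted
moment updates of the per-gene modes and the priors τ (M); cells are
assigned by maximum posterior. A gene whose *low* expression marks a
type is written `low_X` in the signature list and handled by negating
its values into a pseudo-gene row, e.g. values (5, 6, 4, 0) become
(−5, −6, −4, 0).

## Worked example

```bash
# 400 cells from 5 signatured types plus an unknown class
scina simulate --n-cells 400 --n-types 5 --seed 7 --out sim/
scina fit --expr sim/expression.csv --signatures sim/signatures.csv --out fit/
scina evaluate --truth sim/truth.csv --pred fit/labels.csv --out eval/
```

prints

```
simulated 400 cells x 54 genes -> sim
assigned 400 cells; wrote fit/labels.csv
ACC = 97.50%  ARI = 97.75%  (n = 400)
```

ACC is the percentage of cells whose predicted class — including
"unknown" — equals the simulated truth; ARI is the Hubert–Arabie
adjusted Rand index between the two partitions on a 0–100 scale, where
100 is perfect agreement and ≈0 a random relabelling. Here 10 cells out
of 400 were misplaced — at this small size a couple of the randomly
drawn signature genes have wide, overlapping modes, which the larger
benchmark averages out. `fit/` also holds the per-cell
posterior matrix, the fitted per-gene mode parameters (`model.json`) and
a run log; `scina qc` exports a heatmap-ready table plus a per-gene
standardized mode-separation score to judge how bimodal each signature
gene really is.

The same works from Python:

```python
import scina
ds = scina.simulate_dataset(scina.SimulationConfig(r=30, n_cells=10_000, seed=1))
result = scina.fit(ds.expression, ds.signatures)
print(scina.acc(ds.truth.true_labels, result.labels))   # 99.31
```

## The synthetic benchmark

`scina.simulate` reproduces the validation benchmark end-to-end: 30
signature lists with sizes drawn from U{2..10}; cells allocated to types
by weights U(1, 50) plus an unknown class weighted U(5, 15); high-mode
gene means U(3, 5) and near-zero low-mode means U(10⁻⁶, 10⁻³), both
modes with sd U(10⁻⁵, 3). Four noise injections probe sensitivity to the
prior information: phantom extra signatures, withheld true signatures
(cells of those types should then be called "unknown"), signatures
padded to double length with decoy genes, and dropout of high-mode draws
at n × 3.33 %. All draws are reproducible from a single seed.

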