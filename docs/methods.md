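# Methods

## Model and assumptions

Cells are profiled on a log-scale expression matrix X (genes × cells)
that the caller has already normalised; the package never transforms
values. Prior knowledge enters as R signature gene lists, one per cell
type. The model is defined only on the union of signature genes: every
other gene is ignored, keeping the cost O(cells × signature genes ×
classes).

Each signature gene g is modelled as a two-component Gaussian across
cells — a high mode (mu_high_g, sd_high_g) realised in the cell type(s)
whose signature contains g and a low mode (mu_low_g, sd_low_g)
everywhere else. Genes are conditionally independent given the class, so
the class likelihood is the product of per-gene mode densities. An
"unknown" class draws every signature gene from its low mode and
captures cells matching none of the supplied signatures; it is a
first-class mixture component whose prior is estimated like any other
(the benchmark generator itself gives the unknown population a weight
comparable to a small real type). A switch (`allow_unknown=False`)
removes the class and renormalises posteriors over the R known types.

Assumptions worth stating: bimodality need not be sharp per gene — the
separation that matters is in the joint space of all signature genes;
multi-type marker genes are allowed (a gene may sit in several
signatures and is then high-mode in all of them); low-expression markers
are folded into the same framework by negating their values into a
pseudo-gene (`low_X`), an involution that the tests check exactly.

## EM fit

* **E-step.** Posterior responsibilities computed in log space with a
  log-sum-exp normalisation; each row of the posterior sums to 1 within
  1e−9.
* **M-step.** For each gene, the high-mode responsibility of a cell is
  its total posterior mass on classes marking that gene; means and
  variances are responsibility-weighted moments, priors are mean
  responsibilities. If a mode's total responsibility underflows
  (< 1e−12) its previous parameters are kept and a warning logged.
* **Identifiability.** After every M-step the ordering mu_high > mu_low
  is enforced by swapping a gene's two components if they crossed.
  Standard deviations are floored at `sd_floor` = 1e−4 (log-expression
  units) to keep densities finite on near-constant genes; genes with
  exactly zero variance are dropped with a warning before fitting.
* **Initialisation.** Deterministic and label-free: cells at or above a
  gene's 75th expression percentile seed its high mode, the rest the low
  mode; class priors start uniform over R+1 (or R) classes. No
  randomness is consumed, so fits are bit-reproducible.
* **Convergence.** Relative change of every parameter below `conv_tol`
  (default 1e−4) for `conv_checks` (default 3) consecutive iterations,
  capped at `max_iter` (default 100). On the benchmark the fit typically
  converges in 15–25 iterations. The log-likelihood trace is recorded
  and tested for monotone ascent (tolerance 1e−6; the mode swap and sd
  floor could in principle break exact monotonicity, but do not in
  practice across the seeded test battery).
* **Assignment.** Argmax of the posterior row; exact ties go to the
  lowest class index with unknown ordered last, so a known type wins a
  tie against unknown. Deterministic by construction.

## Synthetic benchmark generator

The generator reproduces the validation study's conditions, which are
its defaults: R = 30 cell types; signature sizes drawn from U{2..10};
type weights U(1, 50) and unknown weight U(5, 15), converted to cell
counts over N total cells; per signature gene a high mode with mean
U(3, 5) and a low mode with mean U(1e−6, 1e−3), both with sd
U(1e−5, 3); unknown cells draw every gene from its low mode. Negative
draws are retained — the model operates on log-scale values where
negatives are legal.

Choices the conditions left open, decided once:

* **Weight-to-count allocation** uses largest-remainder rounding of
  N·w/Σw, so counts sum to N exactly and each count is within 1 of the
  proportional share; a multinomial draw is available behind
  `allocation="multinomial"`.
* **Decoy pool.** Alongside the signature genes the matrix carries an
  equal-sized pool of decoy genes simulated entirely from low-mode
  parameters. They give the signature-padding noise method a defined
  pool of "non-signature genes" and are otherwise invisible to the model
  (which only reads signature genes).
* **Seeding.** One master seed; every stage (structure, expression, and
  each noise method) draws from its own fixed-key child stream, so a
  noise method applied alone is bit-identical to the same method inside
  a combination. The expression stage draws full high- and low-mode
  panels before masking, so zeroing type weights does not shift the
  stream.

Four noise injections degrade the prior information: (1) *extra* — n
types keep their signature but get no cells (weights zeroed, matrix
regenerated); (2) *remove* — n true signatures are withheld from the
input lists, and the scorer counts cells of those types as correct when
predicted "unknown", since that is the behaviour the scenario probes
(removed types drawn uniformly; the conditions do not say otherwise);
(3) *pad* — n signatures are doubled with decoys; (4) *dropout* — each
high-mode draw is independently replaced by a fresh low-mode draw with
probability n × 3.33 % (n ≤ 10, so up to 33.3 %). Combinations apply the
methods in that order; the proportion of signatures obscured by the
list-level methods, (n₁+n₂+n₃)/R, is capped at 0.5. Dropout is validated
separately by its own n ≤ 10 bound rather than folded into that
proportion — it perturbs draws, not signature lists, and has its own
stated range.

What the generator does **not** emulate: count/UMI noise, library-size
variation, negative-binomial overdispersion, batch effects, or gene-gene
correlation. Passing the benchmark therefore demonstrates correctness of
the estimation machinery under the model's own assumptions, not
performance on real scRNA-seq data; the real-data behaviour of the
method has to be judged with the QC export (per-gene standardized mode
separation) on the data at hand.

## Evaluation

ACC is 100 × the fraction of cells whose predicted class (unknown
included) equals the truth. ARI is the Hubert–Arabie adjusted Rand
index on the percentage scale, computed from the contingency table
(scikit-learn's implementation behind the module surface; the test
oracle is an independent brute-force pair count). The repeat-stability
experiment re-simulates and re-fits fresh datasets and reports the grand
mean of per-cell correctness indicators. The PCA + k-means baseline
(default 10 components, k = R+1, both exposed as flags since the
reference analysis does not pin them) returns anonymous cluster IDs and
is compared by ARI only — an unsupervised clustering cannot name cell
types, so its ACC is undefined here.

## Problem sizes used in the shipped checks

The test suite exercises the headline configuration (10,000 cells, 30
types, five seeds), a 20-repeat stability run at 4000 cells, and two
noise levels per scenario at 4000 cells; the acceptance script runs the
full 100-repeat stability experiment. Property-style invariants
(EM ascent over 50 seeded fits, oracle equality at 1e−10, simulator
determinism) run on small instances where brute-force enumeration is
exact.

## Known limitations

* Every signature gene carries two free variances; there is no
  mechanism to up-weight stronger markers beyond what the fitted
  variances imply.
* Gene IDs are matched as exact strings — no symbol/Ensembl translation.
* Signature genes missing from the matrix are dropped with a warning
  rather than an error (sparse panels such as CyTOF have few channels);
  a type that loses all its genes is a hard error.
* The EM objective is non-convex; the deterministic quantile
  initialisation is robust on well-separated data but can settle in a
  poor optimum when a signature gene's two modes overlap heavily.
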