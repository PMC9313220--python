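# Methods

## Problem and model

`sipgcn` predicts whether a protein is self-interacting (a SIP — a protein
that binds another copy of itself) from its sequence profile alone.  The
pipeline has four stages:

1. **Profile encoding.**  Each protein is represented by its PSI-BLAST
   position-specific scoring matrix (PSSM), an N×20 matrix of per-position
   log-odds substitution scores that summarises evolutionary conservation.
   The package parses the ASCII profiles PSI-BLAST writes
   (`-out_ascii_pssm`); it never runs PSI-BLAST itself.  Profiles are
   conventionally generated with e-value 0.001 and 3 iterations against
   SwissProt.
2. **Fixed-length descriptors.**  Raw log-odds x are squashed with the
   logistic function 1/(1+e^(−x)) to (0, 1), then grouped by residue: the
   20×20 composition matrix C[a, j] is the mean normalised score in
   profile column j over positions carrying amino acid a (zero rows for
   absent residues), flattened to 400 values.  Composition is
   row-permutation invariant and length-independent, which is what the
   graph stage needs.  An autocovariance (AC) descriptor — lagged
   covariances of each profile column, 20×lag values, default lag 5 — is
   provided as the feature-ablation baseline.
3. **Graph feature extraction.**  Proteins become nodes of a
   cosine-similarity k-nearest-neighbour graph (k = 10, symmetrised by
   union, self-loops, Â = D^(−1/2)(A+I)D^(−1/2)).  A two-layer graph
   convolutional network treats layer propagation as an integral of the
   embedding function over a vertex probability measure P and estimates it
   per layer with t i.i.d. vertex samples:

       ĥ(v) = (1/t) Σ_j Â(v, u_j) h(u_j) W / q(u_j),   u_j ~ q,

   an importance-sampled estimator whose expectation equals the full-batch
   product (ÂHW)_v for any positive q.  The default q(u) ∝ ‖Â(:, u)‖² is
   the variance-reducing choice; uniform is selectable.  The network
   (input → 256 ReLU → 2 softmax) is trained for 200 iterations at
   learning rate 0.1 on cross-entropy plus an L2 weight penalty
   (λ = 5·10⁻⁴), with the loss restricted to training-fold nodes.  The
   post-activation hidden layer (n×256) is the learned protein feature
   matrix.
4. **Classification.**  A random forest: each of 100 trees is fit on a
   bootstrap resample of size n drawn with replacement, predictions are
   combined by majority vote, and the SIP score is the fraction of trees
   voting positive (ties at exactly ½ go to the negative class, the
   majority in SIP data).  KNN (Euclidean, k = 5, neighbour-fraction
   score) and an extreme learning machine (random sigmoid hidden layer,
   least-squares output weights, default width 256) are the classifier
   ablations.

## Evaluation protocol

Five-fold cross-validation: indices are shuffled and split into five
disjoint subsets whose sizes differ by at most one (not stratified — a
stratified option exists but is off by default); each subset is the test
set exactly once.  Metrics per fold: accuracy, specificity
TN/(TN+FP), F1 = 2TP/(2TP+FP+FN), Matthews correlation, and trapezoidal
ROC AUC (tie-grouped, so it equals the Mann–Whitney statistic).  A metric
with a zero denominator is defined as 0; AUC on a single-class fold is
recorded as undefined and excluded from aggregates.  Reports give the
arithmetic mean and sample (n−1) standard deviation over folds; the whole
procedure can be repeated (`repetitions`, 100 for a full run) with all
randomness derived from one master seed.

The similarity graph is built over all nodes (transductive: test-node
*features* are visible during training through the graph, test-node
*labels* never are).  This is the standard FastGCN-style setting; callers
who need strict inductive evaluation should rebuild the graph per fold
from training nodes only.

## Synthetic data

The generator emulates a curated SIP dataset's layout (FASTA, one ASCII
profile per protein, label table) with: uniform random sequences over the
20 amino acids, lengths uniform in [50, 300] (the lower end of the 50–5000
curation filter, kept short for speed), and integer scores
round(N(0, 2) + δ·1[positive ∧ signal column]).  The class signal is a
column-mean shift so that the composition featuriser provably carries it —
it is a test scaffold, not a biological claim.  It does **not** emulate
residue-dependent substitution structure, positional autocorrelation, or
homology between proteins, so passing tests show pipeline correctness and
signal propagation, not real-data performance.  Note the AC descriptor
centres each profile column and is therefore mathematically blind to this
planted shift; AC runs on shifted synthetic data sit at chance, which is a
property of the descriptor, not an implementation defect.

Three study conditions are fixed:

* separable: 200+200 proteins, δ = 3 on profile columns 0–4;
* null: 500+500 proteins, δ = 0 (classes exchangeable);
* imbalanced weak-signal: 60 SIPs vs 660 non-SIPs (the ≈1:11 ratio of the
  curated human set, scaled down) with δ = 0.25 on two columns — weak
  enough that recall stays low under majority voting, reproducing the
  characteristic specificity > accuracy > F1 ordering of imbalanced SIP
  benchmarks.

Imbalance presets `human` (1441:15,938) and `yeast` (710:5511) mirror the
curated class counts.

## Numerical choices

* **Estimator scaling.**  The plain (1/t)Σ Monte-Carlo form estimates the
  integral under P; to make the full-batch layer ÂHW its exact
  expectation for any sampling distribution we divide each sampled term by
  q(u_j).  Under uniform q this is the integral form with Â rescaled by n.
  Samples are drawn with replacement, so t may exceed n; the exhaustive
  test mode (t = n) replaces the average by the exact expectation.
* **Optimiser.**  Adam (β₁ = 0.9, β₂ = 0.999) at the stated learning rate
  0.1; plain gradient descent is selectable.  Weights are Glorot-uniform
  initialised from the config seed; training is bit-reproducible.
* **Loss trajectory.**  The recorded per-epoch loss is the sampled-batch
  objective already computed in the forward pass (an unbiased-in-spirit,
  noisy estimate of the full training loss); convergence checks compare
  the mean over the last 10 % of epochs with the first 10 %.
* **Ties and degenerate input.**  RF/KNN score ties at ½ predict 0;
  zero-denominator metrics are 0; ELM falls back to a ridge solve when the
  hidden layer is constant; zero-norm feature rows are an error in graph
  construction (cosine undefined).
* **Column order.**  The 20 PSSM columns keep the source file's header
  order (standard PSI-BLAST order `ARNDCQEGHILKMFPSTWYV`); composition
  rows are alphabetical.  All profiles in a dataset must share one column
  order for features to be comparable.

## Design choices on genuinely open points

How variable-length profiles become fixed node features, how proteins form
a graph, the sampling distribution, optimiser, layer count, and all
classifier hyperparameters are open design points; the choices above
(composition descriptor, cosine kNN, importance sampling, Adam, M = 2,
community-default classifier settings) are this package's own and are
exposed as configuration.  The network is trained supervised on
training-fold labels and its hidden activations harvested as features; an
unsupervised variant would also be defensible.

## Problem sizes

Defaults are sized so the full test suite and the acceptance script each
run in minutes on one CPU: synthetic proteins of 50–300 residues, datasets
of 40–1000 proteins, one CV repetition.  Full-scale runs (curated human
set, 100 repetitions) use the same code paths via `repetitions` and the
CLI.

## Known limitations

* Transductive graph (see above) — flagged, standard for this family of
  models, but a leakage-adjacent choice.
* The generator's i.i.d. profiles make the composition features nearly
  sufficient; the GCN stage can only be validated for signal
  *preservation*, not for the relational gains claimed on real data.
* No physicochemical or structural features; no resampling (SMOTE-style)
  for imbalance — all samples are used as-is.
* Dense n×n adjacency: fine up to tens of thousands of proteins, not
  beyond.
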