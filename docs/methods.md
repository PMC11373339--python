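# Methods

This note documents the models, algorithms, and design choices behind
`pepimpute`: what the imputer computes, what the synthetic generator
emulates, and which decisions were genuinely open.

## Problem setting

Label-free bottom-up proteomics quantifies peptides, not proteins: a run
yields an `n x s` matrix **A** of peptide intensities over samples with a
large fraction of missing values (commonly 20-70% at the peptide level).
Missingness is a mixture of MCAR (stochastic acquisition effects,
independent of abundance) and MNAR (abundance below the detection limit,
hence left-censoring-like). `pepimpute` imputes on the peptide level —
no peptide-to-protein aggregation is performed anywhere in the package —
and attaches a per-value uncertainty to each imputation.

All modeling happens on the standardized natural-log scale: **A** is
logged, and one global mean/standard deviation (computed over observed
entries, sample sd) maps it to zero mean and unit variance.  The scope of
standardization (global rather than per-sample or per-peptide) follows
the matrix-level formulation of the transform; per-sample and per-peptide
variants exist behind configuration but are off by default.  Reported
uncertainties live on this standardized-log scale so that a given
threshold (say sigma = 0.2) is comparable across datasets; completed
matrices are returned on the raw measurement scale with observed entries
passed through bit for bit.

## The graph attention imputer

Peptides of the same protein share regulation, so their abundance
profiles are strongly correlated, and shared (non-unique) peptides tie
protein cliques into larger connected components.  The model exploits
three information sources:

1. the peptide's own abundance vector across samples;
2. a sequence embedding (any `n x d` matrix keyed by peptide; a
   deterministic k-mer feature-hashing embedder ships for fully
   self-contained runs, and precomputed protein-language-model embeddings
   can be supplied via the HDF5 container);
3. the peptide-peptide graph: an edge wherever two peptides share a
   protein, so each protein contributes a full clique.  Self-loops are
   not stored; the attention layer adds a self-connection per node.

Architecture (defaults in `ModelConfig`): the embedding is projected to
16 dims (affine + ReLU) and concatenated with the encoded abundance
vector; a two-layer MLP produces a 128-dim latent representation; one
GATv2-style dynamic-attention layer (64 heads, each emitting
`floor(s/2)` dims; per-edge scores from a learned vector applied after a
LeakyReLU(0.2) of the transformed endpoint features, softmax-normalized
over each node's in-neighborhood) aggregates neighbor latents; a skip
connection concatenates the latent back onto the attention output before
a second two-layer MLP; finally two affine heads emit a predicted mean
and variance per matrix entry, the variance through softplus + 1e-6.
The network runs on a small reverse-mode autodiff engine written on
numpy (`pepimpute.autograd`), gradient-checked against finite
differences in the test suite.

Missing-input encoding was unspecified territory: missing entries are
filled with 0 (the global mean on the standardized scale) and, by
default, an `s`-dim binary observed-indicator channel is appended so the
network can distinguish "mean" from "missing" (`use_mask_channel`, on by
default; off reproduces the plain zero-fill variant).

### Training

Self-supervised two-round protocol.  A test set (10% of observed values,
uniform) and a validation set (10% of the remainder) are masked up
front.  Each training step masks a further fraction gamma ~ U[0.05,
0.15) of the visible values, runs the network on the freshly masked
view, and computes the loss on exactly those masked entries; one epoch
is `epoch_size` such steps (500 by default).  Round one trains only the
mean head with MSE and early-stops on validation MSE (patience 5,
best-weights restore).  Round two continues from the best round-one
weights with the Gaussian negative log-likelihood
`0.5 * (log s2 + (y - mu)^2 / s2)` over both heads.

Two deliberate deviations from a strictly uniform protocol, both
measured to be necessary at small scale:

* **Round-two step size.**  Adam with the round-one learning rate
  destabilizes the jointly trained heads; round two defaults to 0.1 x
  the round-one rate (`round2_learning_rate`).
* **Round-two model selection.**  Selecting round-two weights by
  validation MSE can never reward the variance head (MSE ignores it), and
  in short runs it provably restores the round-two *initial* weights,
  i.e. an untrained variance head.  Round two therefore early-stops on
  the validation NLL with the variance scale first calibrated in closed
  form on the validation residuals (`c = mean(r^2 / s2)`); the selected
  calibration factor is folded into the model's predicted variances.
  This rewards per-value variance structure rather than a global scale a
  constant head could match.  Scale calibration on held-out residuals is
  standard practice for heteroscedastic regressors.  The MSE-only
  variant remains available (`round2_selection="mse"`).

The variance-head bias is warm-started at the softplus-inverse of the
round-one validation MSE so round two begins from a correctly scaled,
uniform uncertainty.  Adam supports decoupled weight decay, and the two
MLP hidden layers support train-time dropout (both off in the full-size
defaults, on in the desk-scale configuration below); inference never
applies dropout.

Training is full-graph (no mini-batching) and bit-reproducible given the
seed.  Ablations: `use_gnn=false` replaces the attention output with
zeros of the same width (keeping every layer shape fixed so the ablation
isolates the graph's contribution), and `use_embeddings=false` zeroes
the projected embedding.

## Baseline imputers

Eleven standard imputers share one contract (standardized-log matrix in,
completed matrix out, observed entries untouched, seeded determinism):
MinDet (per-sample 0.01-quantile fill, linear-interpolation quantile
convention — documented because the convention shifts 0.01-quantile
fills noticeably), MinProb (normal draws around that quantile, spread =
`sd_scale` x the column sd, default 0.01), peptide-wise Median (global
median for all-missing rows), KNN (k nearest rows by co-observation-
scaled Euclidean distance, donor mean per column), MICE with Bayesian
ridge chained equations and RF (missForest-style) via scikit-learn's
IterativeImputer, iterative SVD, Bayesian PCA (variational, with
automatic relevance determination choosing the effective rank), and
compact reference versions of a denoising autoencoder, a variational
autoencoder, and matrix-factorization collaborative filtering on the
same autodiff engine.  The DAE/VAE/CF implementations are deliberately
small (layer sizes in their signatures) and documented as
lower-fidelity: they represent their method class rather than replicate
any specific published architecture.

## Evaluation

* **Abundance error**: RMSE per sample (the sample-wise split enables
  bootstrap CIs; 95% percentile bootstrap, 1000 replicates by default),
  dataset MAE, and RMSE stratified by each peptide's missingness
  fraction (computed on the dataset before evaluation masking).
* **Pairwise significance**: one-sided paired Wilcoxon signed-rank tests
  on absolute errors for every ordered method pair, Bonferroni-corrected
  over all `k(k-1)` ordered pairs (the family was an open choice; the
  full ordered family is the conservative one).  Zero differences are
  dropped before ranking (classic Wilcoxon handling) and an all-zero
  difference vector scores p = 1 by convention.  Win counts: a
  significant winner takes 1 per pair, otherwise both sides take 0.5, so
  each pair distributes exactly one point.
* **Differential expression**: Welch's t-test per peptide between two
  condition groups (peptides with fewer than two observed values in
  either group are excluded and counted), Benjamini-Hochberg correction,
  ROC/PR curves swept over q-values (q rather than raw p — an open
  choice; both are available), AUC by trapezoid, and the operating point
  of the q <= 0.05 rule marked.
* **Uncertainty diagnostics**: Spearman correlation between predicted
  sigma and absolute error, RMSE over ascending sigma-quantile subsets,
  and uncertainty-filtered DE: imputations with sigma above a threshold
  revert to missing before the DE pipeline runs.  Peptides that then
  fail the two-per-group rule are excluded from the ROC population
  (logged); assigning them q = 1 instead is available by flag.

## Synthetic data

The generator produces the statistical structure the imputer exploits,
with full ground truth and no external files.  Hierarchical model on the
log scale: protein base level `b_p ~ N(mu0, sigma0^2)` (defaults 20, 1 —
typical log-intensity location/spread), protein-by-sample biological
effect `u_pj ~ N(0, 0.6^2)` shared by all peptides of a protein, peptide
ionization-efficiency offset `o_i ~ N(0, 0.3^2)`, and heteroscedastic
residual `eps_ij ~ N(0, sigma_i^2)` with `sigma_i ~ U(0.1, 0.8)`.  The
wide noise range matters: per-peptide noise in real label-free data
spans an order of magnitude, and a generator with near-uniform noise
would make per-value uncertainty unidentifiable in principle.  A
`shared_peptide_fraction` of peptides receives a second parent protein
and the mean of both parents' signals (alternatives behind config),
creating the cross-clique linkage the graph exploits.  Two-condition
designs shift a fraction of proteins by a signed log-effect in
condition 2; DE labels mark all peptides of shifted proteins.

The implied within-protein peptide correlation has the closed form

    rho = (sigma0^2 + protein_sd^2) /
          (sigma0^2 + protein_sd^2 + offset_sd^2 + E[sigma_i^2]),

with `E[sigma_i^2] = (hi^3 - lo^3) / (3 (hi - lo))`; the generator is
tested against it by Monte Carlo.  Missingness: MCAR as iid Bernoulli,
MNAR as Bernoulli with logistic probability `1 / (1 + exp((y - tau) /
beta))` (low values drop out), union applied; entries hit by both
mechanisms are attributed to MCAR in the cause table (a documented
tie-break).  Sequence embeddings are a random linear map of the latent
peptide properties (offset, noise sd, parent base level) plus Gaussian
noise — informative but imperfect, like real sequence embeddings.
Random tryptic-like sequences (ending K/R) are emitted so the hashing
embedder path is exercisable.

Presets: `small` (~200 peptides x 8 samples, MCAR + mild MNAR),
`medium` (~2000 x 12, within-protein correlation 0.80, 30% MCAR, no
MNAR), `de_spikein` (~750 x 12, two conditions, 10% DE proteins at
log-effect 1.2, MCAR + MNAR).  Preset datasets are fixed-seed and byte
reproducible.

What the generator does **not** emulate: intensity-dependent mass-
spectrometer noise curves, retention-time or charge-state structure,
correlated missingness across technical replicates, isotope or
modification effects, and real amino-acid-sequence-to-propensity
relationships (embeddings carry the latent truth by construction).
Passing tests therefore demonstrate that the implementation exploits
clique correlation, heteroscedasticity, and missingness structure as
designed — not that it attains any particular accuracy on real
instrument data.

## Problem sizes and numerical choices

Desk-scale runs (tests, the acceptance script, the CLI default) train
with 8 attention heads, 150 steps per epoch, at most 12 epochs per
round, patience 3, learning rate 1e-3 in both rounds, weight decay 1e-2
and dropout 0.2 (`pepimpute.pipeline.desk_model_config`): about three
minutes per fit of the `medium` preset on one CPU core.  The
regularization matters at this scale — without it the network overfits
the visible entries within one or two epochs, which truncates both
rounds' useful training.  The full-size defaults (64 heads, 500 steps
per epoch, patience 5, learning rate 1e-3) remain in `ModelConfig`.
Variances are floored at 1e-6 inside the NLL; training aborts with a
diagnostic on non-finite or exploding (>1e12) loss; ISVD/BPCA return
their best iterate with a warning on non-convergence; all-missing rows
and columns fail fast with validation errors at the API boundary.

## Known limitations

* The GNN trains per dataset; no weight transfer across datasets.
* Full-clique graphs are quadratic in peptides-per-protein; an optional
  seeded per-protein edge cap exists as a memory escape hatch (off by
  default).
* DAE/VAE/CF baselines are compact stand-ins for their method class.
* The uncertainty calibration uses the single validation split; with
  very few validation positions the calibrated scale is noisy.
* The DDA/DIA mean matching defaults to one additive shift on the log
  scale for the whole dataset (per-sample/per-peptide variants are
  config options); which scope real pipelines should use is genuinely
  ambiguous.
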