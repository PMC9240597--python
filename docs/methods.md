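# Methods

This note documents the models implemented in `gmploc`, the choices
made where the design was genuinely open, and what the synthetic
studies do and do not demonstrate.

## PSSM featurization

A PSI-BLAST PSSM is an L×20 matrix of integer log-odds scores; L
varies per protein, so a fixed-size encoding is needed. Two modes are
provided (`discretize_pssm`):

* `grouped20x20` (default): entry (a, j) is the mean score E(i→j)
  over sequence positions i whose residue is type a — the standard
  PSSM-composition encoding. This is the only mode that yields a
  genuinely two-dimensional 20×20 matrix, which the convolutional GAN
  architecture presumes; rows for residue types absent from the
  sequence are filled with 0 (the neutral log-odds value).
* `column_mean20`: the plain per-column mean, a 20-vector stored in
  row 0 of a 20×20 matrix. Kept because the averaged form is the
  simplest length-free summary and some pipelines use it directly.

Non-standard residues (X/B/Z/U) have no row in the grouped encoding;
they are counted at parse time (`PSSMMatrix.n_nonstandard`) and
contribute only to the column mean. Only the first 20 numeric columns
of the PSSM file (the log-odds block) are read; the weighted-percentage
block and statistics footer are ignored. Amino-acid column order is
taken from the file header and permuted to the canonical
ARNDCQEGHILKMFPSTWYV.

Features are standardized per coordinate with a scaler fitted on
training data only (fold-restricted inside cross-validation). Both the
GAN and the classifier are scale-sensitive, and fitting the scaler on
a full dataset before splitting would leak test statistics into
training. Constant features pass through centred (scale forced to 1,
with a relative threshold so floating-point residue of a constant
column still counts as zero variance).

## Minority-class GAN

One unconditional GAN is trained per under-represented label on the
(scaled) feature vectors of samples bearing that label. On top of the
standard non-saturating adversarial objectives, both players see a
log-distance term d(G(z), x̄) — the Euclidean distance between a
generated sample and the mean x̄ of the real minority pool:

* discriminator (maximized): E[log D(x)] + E[log(1−D(G(z)))] + E[log d]
* generator (minimized):  E[−log D(G(z))] + λ·E[log d]

The distance term contains no discriminator parameters, so the
discriminator update is the standard one; the generator feels an
extra pull of strength λ toward the minority mean. This pull is a
mode-seeking force by construction; the floor d ≥ ε (default 1e−6)
before the logarithm keeps the objective finite if a sample lands on
the mean exactly. λ defaults to 0.1, small enough that the adversarial
signal, not the pull, shapes the distribution. The latent distribution
is standard normal with dimension 64.

Architectures: for 20×20 features the generator is one dense layer
feeding three transposed convolutions (5×5 → 10×10 → 20×20, linear
output since features are standardized and unbounded), the
discriminator two strided convolutions feeding a dense sigmoid head.
For other feature shapes both players are small dense stacks, so the
GAN and classifier studies can run on low-dimensional toys in seconds.
Training alternates one discriminator and one generator Adam step per
batch (β at common defaults, lr 1e−4), with the batch size clipped to
the pool size.

A practical budget note: with minority pools far below the batch size,
one epoch is a single optimizer update. Budgets in this package are
therefore best thought of in update counts; the per-class GANs in the
reference study run 4,000 updates, and empirically the synthetic-mean
error on a 30-sample 16-D pool falls from ≈1.7 (1,000 updates) to
≈0.5 (6,000 updates), the latter within the sampling noise of the
pool mean itself. Classes with fewer than 2 real samples fall back to
duplicate-with-jitter (sd 0.05 in scaled units) with a logged warning.

Rebalancing policy (`plan_rebalance`): `match_majority` synthesizes
max_k(c_k) − c_k samples for each label k (c_k = samples bearing label
k); a `ratio` policy targets ⌈r·max_k(c_k)⌉ instead. Synthetic samples
carry only the label whose GAN produced them — how multi-label
annotations should be assigned to synthetic samples is an open
question, and single-label is the conservative choice — and are
flagged `synthetic=True` so provenance is checkable.

## Multi-label DeepFM

Two components score a dense feature vector x in parallel and their
K-vectors are summed, ŷ = y_FM + y_Deep.

The FM layer computes the first-order term Σ wᵢxᵢ and, per latent
factor f (k_lat = 8), the pooled pairwise term
0.5[(Σᵢ V_if xᵢ)² − Σᵢ V_if² xᵢ²], an O(n·k) identity for the classic
Σ_{i<j} ⟨vᵢ,vⱼ⟩xᵢxⱼ. The dense head maps the emission
[linear ⊕ pooled] together with a first-order bypass of the raw
features to K scores. The bypass makes the component a standard
multi-output FM: without it every label shares a single first-order
scalar, which cannot represent per-label linear effects and in
practice cripples the FM-only classifier (average precision ≈0.68 vs
≈0.96 with the bypass on the reference study's balanced data).

The deep component is a ReLU multilayer perceptron with hidden widths
256/128/64/32, dropout 0.5 on hidden layers, and a linear K-way output
with no activation — raw scores must be able to go negative so that
thresholding at y₀ = 0 is meaningful.

The loss per sample, with relevant set R, irrelevant set I and
threshold y₀:

    log( 1 + Σ_{k∈I, r∈R} e^{ŷₖ−ŷᵣ} + Σ_{k∈I} e^{ŷₖ−y₀}
           + Σ_{r∈R} e^{y₀−ŷᵣ} )

computed with log-sum-exp reductions throughout, summed over the batch
(a mean reduction is available for learning-rate comparability). The
leading 1 bounds the loss below by 0 — the bare sum inside the log is
unbounded below at perfect separation — and `plus_one=false` recovers
the literal form. y₀ is fixed at 0, the natural symmetric choice for
an unactivated linear head; the same threshold drives `decide_labels`,
with a top-1 fallback for empty predictions and lowest-index
tie-breaking for determinism. The loss's analytic gradient is verified
against central finite differences to 1e−4 in the test suite.

## Evaluation metrics

Hamming loss, one-error, coverage, ranking loss and average precision,
each verified against an independent brute-force implementation on
randomized instances. Conventions (each a genuine choice):

* Hamming loss is normalized by N·K (the standard definition; the
  unnormalized per-sample count is available via a flag).
* Coverage counts ranks starting at 1 with no minus-one correction
  (so its floor is the mean label cardinality, not 0); a `minus_one`
  flag provides the other literature convention.
* Ranks break ties toward the lower label index, deterministically.
* Samples whose labels are all relevant are excluded from ranking
  loss (the pair denominator is zero) with a logged warning.
* A (relevant, irrelevant) pair counts as mis-ordered when the
  irrelevant score is ≥ the relevant score.

## Cross-validation protocol

`kfold_split` assigns folds randomly (sizes differing by at most 1,
deterministic per seed); label-stratified assignment was considered
and left out of the default to keep the protocol the plain random one.
Per fold: the scaler is fitted on the training split; rebalancing
plans, GAN training and synthesis use the training split only; each
classifier arm (FM-only, deep-only, both — all trained under the same
ranking loss) is trained on the training split (augmented or not) and
evaluated on the untouched test split. Synthetic samples are
re-generated inside every fold; applying the GAN before splitting
would place synthetic copies of test-fold neighbours into training.

## The synthetic data generator and the reference study

`generate_multilabel_dataset` draws class-conditional isotropic
Gaussians: base class k contributes n_k samples at mean μ_k with
standard deviation σ, labelled k plus each co-label j independently
with probability C[k, j]. This is the simplest structure under which
the GAN's mean-matching regularizer has a known target and minority
recovery is measurable.

The reference imbalance study (`imbalanced_three_class_config`, used
by the acceptance script and the heavyweight acceptance tests) uses
three classes with 500/50/20 samples in 16 dimensions; class means are
sign patterns ±a over the first three coordinates (a = 1.8, ≈5σ
between any two classes), noise σ = 1, and the two minority classes
co-occur with probability 0.2. The conditions were designed against an
explicit oracle: training on 500/500/500 *real* samples (the ideal
limit of any rebalancing scheme) must beat the imbalanced baseline on
held-out coverage and average precision — i.e. the dataset must
actually exhibit an imbalance deficit that balancing can repair.
Low-dimensional or widely-separated variants fail that bar: with 2-D
features twenty minority samples already pin down the class, and with
heavy class overlap the imbalanced class prior is close to
Bayes-optimal, so balanced training *hurts* aggregate metrics on an
87%-majority test set. In 16-D the minority boundary is genuinely
under-determined from tens of samples while remaining learnable from
hundreds.

Training budgets in the study are update-count-parity reductions of
the pipeline defaults (1,000 epochs, batch 512, lr 1e−4): the
classifier runs 150 epochs at lr 1e−3 (Adam's step size bounds total
parameter movement by roughly lr × updates, so a few hundred updates
at lr 1e−4 cannot move hidden layers materially — the model learns
only output biases, i.e. the majority prior), and each per-class GAN
runs 4,000 updates (below the ≈6,000 updates the defaults imply on a
3,000-sample dataset). The study runs 3 folds × 6 arms × 5 seeds in
≈4 minutes on one CPU.

What the study shows: rebalancing lowers coverage and raises average
precision across the classifier family (mean over the three
with/without pairs), and for the FM-only and deep-only arms
individually. What it does not show: the full DeepFM arm's pair is a
statistical tie at these conditions — its FM bypass learns the
majority prior quickly while its deep half learns minority features,
making it the most imbalance-resistant baseline — and the deep-only
arm does not fall below the FM-only arm, so a reported ordering of
classifier families on real PSSM data (FM above deep) is not
reproduced by this Gaussian emulation at desk scale. Both facts are
asserted honestly in the acceptance tests (the ordering test fails by
design rather than being weakened). More generally, the generator
emulates neither real PSSM score distributions, sequence-length
effects, nor feature-dependent label co-occurrence; passing tests
establish the machinery and its directional behaviour, not benchmark
performance.

## Numerical choices and degenerate inputs

* Discriminator probabilities are clamped to [1e−6, 1−1e−6] inside
  objectives and gradients; objectives are finite for any input batch.
* Distances are floored at ε = 1e−6 before logs; the floor region has
  zero gradient.
* Log-sum-exp is used for the ranking loss and its gradient; empty
  irrelevant sets (all labels relevant) contribute −inf summands that
  vanish correctly.
* `FeatureScaler` forces unit scale on (numerically) constant
  features; applying an unfitted scaler raises.
* Parsing rejects malformed PSSM rows with the offending line number,
  non-consecutive position indices, and empty score blocks.
* All training is deterministic given the configured seed; derived
  seeds stay below 2³¹.

## Known limitations

* The generator's pull toward the minority mean (λ·E[log d]) is
  implemented exactly as specified even though it shrinks synthetic
  variance somewhat below the real pool's; the reference study
  absorbs this, but variance-sensitive downstream analyses should
  check synthetic spread.
* The numpy networks are single-threaded and sized for hundreds of
  features; 400-feature PSSM compositions train in minutes, not
  seconds.
* Coverage and average precision on heavily majority-dominated test
  sets are insensitive to minority gains; per-class breakdowns (as in
  the tests) are more informative in that regime.
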