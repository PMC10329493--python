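# Methods

## Problem setting

A paired MSA (pMSA) holds M rows, each pairing an aligned source-domain
sequence B (fixed length Nin) with the interacting target-domain sequence A
(fixed length Nout) from the same protein or complex.  Because interacting
residues coevolve, B carries information about A beyond the target family's
own statistics.  `d2d` models the conditional distribution

    log P(A|B) = Σ_{i=1..Nout} log P(a_i | B, a_1..a_{i-1})

autoregressively over a fixed 21-symbol residue alphabet
(`ACDEFGHIKLMNPQRSTVWY-`; the gap is an ordinary symbol that is predicted,
scored and sampled like any amino acid — real alignments are gapped and a
partner model must reproduce gap structure).  Three special tokens (SOS, EOS,
PAD; ids 21–23) serve decoder plumbing only.  An EOS prediction is appended
after the last residue and included in the training loss, so the decoder
contract extends unchanged to variable-length use; all reported metrics sum
over the Nout residue positions only.

## Models

**Transformer.**  The original post-norm encoder–decoder translation
architecture: learned token embeddings scaled by √d_model, fixed sinusoidal
positional encodings (parameter-free, which keeps the parameter count
independent of Nin and Nout), single-head scaled dot-product attention, ReLU
feed-forward blocks, causal masking in the decoder, and a softmax output over
all 24 tokens.  Presets: *shallow* (2 layers, 1 head, d_model 55, d_ff 2048)
and *large* (3 layers, 1 head, d_model 105, d_ff 2048).  Pre-norm variants
and weight tying are deliberately not used: post-norm is the canonical
translation setup and untied output weights keep ablations clean.  Dropout
defaults to 0.1 and is disabled (0.0) in all desk-scale studies so that
regularization comparisons isolate the entropic term.

The models run on a small reverse-mode automatic-differentiation engine over
numpy (`d2d._autodiff`) providing exactly the primitives needed (broadcast
arithmetic, batched matmul, fused softmax/log-softmax/layer-norm backward,
embedding gather, concat/stack, Adam).  Gradients are verified against
central finite differences in the test suite.

**arDCA baseline.**  Fields h_i(a) plus couplings J_{i,j}(a, b) from each
target position i to every preceding position j of the concatenated pair
(source fully precedes target; within-target order is alignment order; a
permutation hook exists for entropy-ordered variants).  Each conditional is
an exact softmax over the 21 residues, so the total probability over target
space sums to one exactly.  Fitting maximizes the L2-penalized conditional
log-likelihood with L-BFGS and analytic gradients from a zero start
(deterministic).  The parameter count grows as (Nin+Nout)², in contrast to
the length-independent Transformer.  The default penalty λ=0.01 (applied to
the summed log-likelihood) is a light numerical regularizer; the parameter
recovery study instead uses the prior-matched ridge λ = 1/(2σ²) because its
generator draws parameters from N(0, σ²) — with ~5 × 10³ free parameters per
conditional and M = 10⁴ samples, unpenalized maximum likelihood has an
irreducible mean KL of ≈ k/2M ≈ 0.09, while the matched MAP estimator
recovers the conditionals to mean KL ≈ 0.005.

## Training and the entropic regularizer

The base loss is teacher-forced cross-entropy, averaged over batch rows and
decoder positions (Nout residues + EOS).  Optimizer: Adam, lr 5 × 10⁻⁴, batch
32–128 depending on study, no warm-up.  Early stopping on validation
perplexity (patience configurable) retains the best checkpoint; the studies
below train for a fixed epoch count instead so both arms of a comparison see
identical optimization budgets.

With regularization strength α > 0, S relaxed target sequences are drawn per
training pair from the model's own conditionals by Gumbel-softmax
(temperature τ, default 1.0).  Sampling conditions every position on the
*true* preceding residues, so all S sequences come from the single
teacher-forced forward pass.  Their log-likelihoods R_{l,k} = log P(A^{l,k}|B)
are then evaluated exactly in a second decoder pass teacher-forced on the
relaxed samples themselves; the relaxed one-hots enter as linearly mixed
embeddings, keeping the whole pathway differentiable (verified by finite
differences).  Scoring the samples against the same rows they were drawn
from — tempting because it avoids the second pass — is biased upward and
feeds a ⟨∂y/∂logits, log p⟩ gradient term with unbounded |log p|
coefficients; it destabilized training in every variant we tried, so the
two-pass evaluation is the implementation.

With R_l = log P(A|B) the regularizer is the (S+1)-way softmax
cross-entropy of identifying the true sequence among the samples,

    loss = CE + α · mean_l [ −R_ent(A^l, B^l) ],
    R_ent = R_l − log( e^{R_l} + Σ_k e^{R_{l,k}} )  ∈ (−∞, 0],

computed with a stable log-sum-exp.  This term is bounded below, vanishes
once true and sampled sequences score alike (all-equal value −log(S+1)), and
is equivalent to maximizing the conditional Rényi entropy of order 2 — it
suppresses the overconfident conditionals that drive perplexity overfitting
on small families while leaving accuracy and matching intact.  The opposite
orientation (adding +R_ent) is unbounded below: its gradient on the data
log-likelihood channel is α(1−w₀) − 1/Nout > 0 whenever the model's samples
outscore the data (w₀ ≈ 0, always true early in training), and it provably
and empirically diverges.  Standard setting when enabled: α = 0.7, S = 5.
The straight-through estimator (hard one-hot forward, soft backward) is
available but off by default.

## Evaluation

All metrics consume any model exposing teacher-forced per-position residue
log-probabilities, so Transformer and arDCA are compared on identical code:

* **Perplexity** PP(A,B) = exp(−log P(A|B)/Nout); reported as the arithmetic
  mean of per-sequence PP (a geometric-mean variant, exp of mean CE, is also
  reported; by Jensen's inequality the arithmetic mean dominates and the
  relation is asserted at runtime).  Uniform-over-residues gives PP = 21
  exactly, a perfect model PP = 1.
* **Accuracy**: per-position argmax over the 21 residues (specials excluded),
  ties broken deterministically toward the lowest token id.
* **Matching specificity**: the M×M matrix of log P(A_j|B_i) over a held-out
  set feeds `scipy`'s Hungarian solver; the matched fraction is the share of
  fixed points of the optimal assignment, against the 1/M random baseline.
  Optimality is certified against brute-force permutation enumeration for
  M ≤ 6 in the tests.  Subsampled matching curves (mean ± stderr over random
  subsamples) make different M comparable.
* **Mutual-information estimate**: mean validation difference between the
  log-likelihood under a model trained on true pairs and one trained on
  shuffled pairs, in nats per sequence.  The shuffled model approximates the
  target marginal, so the gap estimates MI(A;B).

## Synthetic families

The generator (`d2d.synthetic`) is a latent-class model: each row draws a
hidden class c from K classes; one to four *informative* columns per domain
draw symbols from class-specific distributions; every other column draws
i.i.d. from a background distribution (uniform over all 21 symbols by
default, gap included).  Source and target are conditionally independent
given c, so MI(A;B) has a closed form computed by exhaustive summation over
the informative-column supports; with class-deterministic columns and equal
class probabilities it equals H(class) = log K exactly.  A class-based
generator was chosen over a pairwise Potts sampler precisely because of this
exact oracle.  The standard recipe plants one informative column per domain
(middle column, class c → residue symbol c).

The optional phylogeny mode draws n_clusters ancestor pairs from the model
and derives each row from a random ancestor by resampling every site
independently with probability μ from its generative distribution — enough
clustered redundancy to exercise the near/far machinery, but not a realistic
birth–death phylogeny (no tree depth structure, no site-rate heterogeneity).

What passing these tests shows — and does not show.  The synthetic families
have i.i.d. (or shallowly clustered) rows, a single planted dependence
channel, and uniform backgrounds; they validate that the pipeline extracts
planted inter-domain information, matches partners above chance, and that the
regularizer controls overfitting.  They say nothing about profile HMM
alignment artifacts, long-range intra-domain epistasis, or real phylogenetic
depth.

## Splits and near/far stratification

Random 70/15/15 split (floor-rounded, remainder to train, deterministic per
seed).  Held-out rows are annotated with the minimum Hamming distance to the
training set — computed on the target sequence by default, since all metrics
concern the target; source or concatenated-pair distance is a flag — and
partitioned at the median, ties labeled "near" so the far half is
conservatively far.  With discrete distances the tie rule can make the halves
unequal; exact balance is only enforced in the degenerate all-equal case.

## Desk-scale study conditions

The canonical studies (`d2d.studies`) fix these problem sizes, chosen so each
runs in minutes on one CPU while keeping its effect decisively larger than
seed noise:

* MI recovery: coupled K=2 family (planted MI = log 2), Nin = Nout = 8,
  M = 5000, shallow preset, 4 epochs (batch 64); independent K=1 control,
  2 epochs.  The estimate is evaluated on the 750-row validation split.
* Matching: same recipe with K = 21 (planted MI = log 21), 12 epochs,
  100-pair validation subsamples.  K must be large here: with K classes the optimal
  matcher can only identify class blocks, bounding the expected matched
  fraction near K/M — for K=2 that is 0.02, indistinguishable from baseline,
  while K=21 yields ≈ 0.2 against 0.01.
* arDCA recovery: Nin = Nout = 3, M = 10⁴, σ = 0.05 generator,
  prior-matched ridge.
* Regularization: K=21, Nin = Nout = 6, M = 300 (210 training rows), large
  preset, 12 epochs at batch 16, α = 0.7, S = 5 versus α = 0 at identical
  budgets.
* Near/far: K=4 phylo family, M = 400, 30 clusters, μ = 0.15, shallow,
  12 epochs.

## Known limitations

* CPU-only; training cost is dominated by the d_ff = 2048 feed-forward
  blocks, and the two-pass regularizer multiplies decoder cost by ≈ S.
* Checkpoints are npz archives keyed by a tokenizer hash; cross-platform
  bitwise reproducibility is not guaranteed at the ULP level (BLAS summation
  order), though trajectories agree numerically.
* The joined multi-family model with family-indicator tokens, pretrained
  protein language models, and structure-based scoring of samples are out of
  scope; `export_augmented_pmsa` only produces the input a downstream DCA
  contact analysis would consume.
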