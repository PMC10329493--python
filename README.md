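# d2d — domain-to-domain translation of interacting protein sequences

Interacting protein domains coevolve: substitutions at a binding interface in
one domain are compensated by substitutions in its partner.  `d2d` treats the
generation of a partner domain as a *translation* problem.  Given a paired
multiple sequence alignment (pMSA) whose rows pair an aligned source-domain
sequence B (length `Nin`) with its interacting target-domain sequence A
(length `Nout`), it trains a conditional autoregressive sequence model

```
log P(A | B) = Σ_{i=1..Nout} log P(a_i | B, a_1, …, a_{i−1})
```

over the 21-symbol alphabet (20 amino acids + alignment gap).  Two model
families share one evaluation stack:

* an encoder–decoder **Transformer** (presets: *shallow* — 2 layers, 1 head,
  d_model 55, d_ff 2048; *large* — 3 layers, d_model 105), whose parameter
  count is independent of the alignment lengths, and
* an **arDCA**-style shallow autoregressive baseline with fields and pairwise
  couplings to all preceding positions of the concatenated pair, whose
  parameter count grows quadratically with `Nin + Nout`.

The package is aimed at researchers studying coevolution-aware generative
models of protein families: it provides the data plumbing (aligned FASTA
pMSAs, 70/15/15 splits, near/far Hamming stratification), training with an
optional entropic Gumbel-softmax regularizer, evaluation (conditional
perplexity `PP = exp(−log P(A|B)/Nout)`, per-position accuracy,
interaction-partner matching via the Hungarian algorithm, a paired-vs-shuffled
mutual-information estimate), conditional sampling of novel partner
sequences, and a synthetic pMSA generator with analytically known planted
mutual information so that every stage is testable without external data.

## Worked example

Simulate a coupled two-class family (planted mutual information exactly
log 2 ≈ 0.693 nats per sequence pair), train a shallow Transformer on the
true pairing and a control on shuffled pairs, and measure the information the
model extracts from the interaction partner:

```python
import numpy as np
from d2d import (SyntheticSpec, generate, shuffle_pairs, analytic_mi,
                 Tokenizer, build_model, TrainConfig, train,
                 random_split, mi_estimate)
from d2d.evaluation import encode_rows

spec = SyntheticSpec.coupled(M=5000, K=2, seed=1)
print(f"planted MI = {analytic_mi(spec):.3f} nats")   # 0.693
pmsa, _ = generate(spec)
split = random_split(pmsa.M, seed=1)
tok = Tokenizer()

paired = build_model("shallow", tok, seed=1)
paired, _ = train(paired, pmsa, split,
                  TrainConfig(epochs=4, batch_size=64, seed=1, dropout=0.0), tok)

null = build_model("shallow", tok, seed=2)
null, _ = train(null, shuffle_pairs(pmsa, seed=11), split,
                TrainConfig(epochs=4, batch_size=64, seed=2, dropout=0.0), tok)

src, tgt = encode_rows(pmsa, split.val_idx, tok)
print(f"estimated MI = {mi_estimate(paired, null, src, tgt):.3f} nats")
```

Output:

```
planted MI = 0.693 nats
estimated MI = 0.474 nats
```

The paired model's validation log-likelihood exceeds the shuffled control's
by ~0.47 nats per sequence — a finite-sample, finite-training estimate of the
planted 0.693 nats of inter-domain information.  The same trained models
plug into partner matching (`d2d.evaluation.match_subset`) and conditional
sampling (`d2d.sampling.sample_target`).

The command-line interface mirrors the library:

```bash
d2d simulate --recipe coupled --m 5000 --k 2 --seed 1 --out fam
d2d split --source fam_source.fasta --target fam_target.fasta --seed 1 --out split.tsv
d2d train --source fam_source.fasta --target fam_target.fasta --split split.tsv \
          --preset shallow --epochs 4 --seed 1 --out model.npz
d2d eval  --source fam_source.fasta --target fam_target.fasta --split split.tsv \
          --model-file model.npz --out metrics.json
```

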